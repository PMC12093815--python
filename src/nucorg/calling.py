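"""Nucleosome summit calling from dyad-coverage tracks.

The caller smooths the (optionally capped) dyad track with a truncated
Gaussian kernel and selects strict local maxima greedily by height under a
hard minimum-distance constraint.  This is a deliberately simple, fully
specified stand-in for heavier nucleosome-positioning callers: downstream
analyses here need only summit coordinates and heights.

Defaults: bandwidth 15 bp (kernel sd), minimum summit distance 110 bp (below
the 147 bp nucleosome footprint, so tightly packed arrays survive), per-base
cap 200 before smoothing (clonal-signal guard), and a relative height floor
of 5% of the track mean over nonzero bases (depth-invariant).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .tracks import DyadTrack

CALL_COLUMNS = ["chrom", "summit", "height", "raw_dyads"]


@dataclass(frozen=True)
class CallerParams:
    bandwidth: float = 15.0
    min_distance: int = 110
    min_height: float | None = None  # None -> 0.05 x mean over nonzero bases
    max_height_cap: float | None = 200.0

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")
        if self.max_height_cap is not None and self.max_height_cap <= 0:
            raise ValueError("max_height_cap must be > 0 when set")


def gaussian_kernel(bandwidth: float) -> np.ndarray:
    """Discrete Gaussian truncated at +-4 sd, renormalized to sum 1."""
    radius = int(np.ceil(4 * bandwidth))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / bandwidth) ** 2)
    return k / k.sum()


def smooth_track(track: DyadTrack, bandwidth: float = 15.0,
                 max_height_cap: float | None = 200.0) -> dict[str, np.ndarray]:
    """Per-base cap (if configured) followed by Gaussian convolution.

    Output arrays have the input length; edges are zero-padded, so a
    constant track stays constant away from the edges.
    """
    kernel = gaussian_kernel(bandwidth)
    out = {}
    for chrom, arr in track.coverage.items():
        a = arr.astype(float)
        if max_height_cap is not None:
            a = np.minimum(a, max_height_cap)
        out[chrom] = convolve1d(a, kernel, mode="constant", cval=0.0)
    return out


def resolve_min_height(track: DyadTrack, params: CallerParams,
                       rel_frac: float = 0.05) -> float:
    """Absolute height floor: configured value, else rel_frac x mean of
    nonzero bases of the (capped) raw track."""
    if params.min_height is not None:
        return float(params.min_height)
    total = 0.0
    nonzero = 0
    for arr in track.coverage.values():
        a = arr
        if params.max_height_cap is not None:
            a = np.minimum(a, params.max_height_cap)
        mask = arr > 0
        total += float(a[mask].sum())
        nonzero += int(mask.sum())
    if nonzero == 0:
        return np.inf  # empty track: nothing can be called
    return rel_frac * total / nonzero


def _plateau_maxima(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima; plateaus resolved to their leftmost base.

    A run of equal values is a maximum iff it is higher than both adjacent
    runs; the first and last runs of the array are never maxima.
    """
    if len(a) < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    change = np.flatnonzero(np.diff(a) != 0) + 1
    run_starts = np.concatenate([[0], change])
    vals = a[run_starts]
    if len(vals) < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    interior = np.arange(1, len(vals) - 1)
    is_max = (vals[interior] > vals[interior - 1]) & (vals[interior] > vals[interior + 1])
    pos = run_starts[interior[is_max]]
    return pos, a[pos]


def _greedy_select(positions: np.ndarray, heights: np.ndarray,
                   min_distance: int) -> np.ndarray:
    """Accept maxima in height-descending order (ties: leftmost first),
    rejecting any candidate within min_distance of an accepted summit."""
    order = np.lexsort((positions, -heights))
    accepted: list[int] = []
    for i in order:
        p = int(positions[i])
        j = bisect.bisect_left(accepted, p)
        if j > 0 and p - accepted[j - 1] < min_distance:
            continue
        if j < len(accepted) and accepted[j] - p < min_distance:
            continue
        accepted.insert(j, p)
    return np.asarray(accepted, dtype=int)


def call_summits(smoothed: dict[str, np.ndarray], params: CallerParams,
                 min_height: float = 0.0,
                 raw: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Greedy constrained summit selection on smoothed per-chromosome arrays.

    ``raw``, if given, maps chromosome -> un-extended dyad count array used
    to report the raw dyad support in summit +- bandwidth.  Returns calls
    sorted by (chrom, summit).
    """
    rows = []
    bw = int(round(params.bandwidth))
    for chrom in sorted(smoothed):
        a = smoothed[chrom]
        pos, height = _plateau_maxima(a)
        keep = height >= min_height
        pos, height = pos[keep], height[keep]
        chosen = _greedy_select(pos, height, params.min_distance)
        for p in chosen:
            if raw is not None and chrom in raw:
                r = raw[chrom]
                support = int(r[max(0, p - bw):p + bw + 1].sum())
            else:
                support = -1
            rows.append((chrom, int(p), float(a[p]), support))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["chrom", "summit"], ignore_index=True)


def dyad_count_arrays(frags: pd.DataFrame,
                      chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Un-extended per-base dyad counts (support for ``raw_dyads``)."""
    from .fragments import fragment_dyad

    dyads = fragment_dyad(frags)
    chrom_arr = frags["chrom"].to_numpy()
    out = {}
    for chrom, size in chrom_sizes.items():
        d = dyads[chrom_arr == chrom]
        out[chrom] = np.bincount(d, minlength=size).astype(np.int64)[:size]
    return out


def call_nucleosomes(track: DyadTrack, params: CallerParams | None = None,
                     raw: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Smooth a dyad track and call summits with resolved parameters."""
    params = params or CallerParams()
    smoothed = smooth_track(track, params.bandwidth, params.max_height_cap)
    floor = resolve_min_height(track, params)
    return call_summits(smoothed, params, min_height=floor, raw=raw)


# ---------------------------------------------------------------------------
# IO


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """BED6 of 3 bp summit features (summit-1, summit+2)."""
    with open(path, "w") as fh:
        for i, row in enumerate(calls.itertuples(index=False)):
            start = max(0, row.summit - 1)
            fh.write(f"{row.chrom}\t{start}\t{row.summit + 2}\t"
                     f"nuc_{i:06d}\t{row.height:.4f}\t.\n")
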