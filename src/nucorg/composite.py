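"""Anchor-aligned composite dyad-coverage profiles over gene sets.

Windows are taken around the TSS (or a supplied per-gene +1 summit) in
transcript orientation: minus-strand windows are reversed so downstream is
always rightward.  The composite value at each relative position is the
mean over genes, optionally after dividing each gene's window by its own
mean coverage (per-gene-mean normalization; off by default so amplitudes
reflect raw coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import validate_genes
from .tracks import DyadTrack

DEFAULT_WINDOW = (-300, 1300)


@dataclass
class CompositeProfile:
    window: tuple[int, int]
    values: np.ndarray
    n_genes: int
    n_dropped: int = 0
    anchor_mode: str = "tss"
    normalization: str = "none"

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)


def composite(track: DyadTrack, genes: pd.DataFrame,
              window: tuple[int, int] = DEFAULT_WINDOW,
              anchor_mode: str = "tss",
              normalization: str = "none",
              anchors: pd.Series | None = None) -> CompositeProfile:
    """Mean anchor-aligned coverage over a gene set.

    ``anchors`` (gene_id -> genomic position) overrides the TSS when
    ``anchor_mode='plus1'``.  Genes whose window leaves the chromosome (or,
    under per-gene-mean normalization, has zero coverage) are dropped and
    counted in ``n_dropped``.
    """
    validate_genes(genes)
    if genes.empty:
        raise ValueError("composite requires a non-empty gene set")
    if normalization not in ("none", "per-gene-mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if anchor_mode not in ("tss", "plus1"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    if anchor_mode == "plus1" and anchors is None:
        raise ValueError("anchor_mode='plus1' needs per-gene anchor positions")
    w0, w1 = window
    span = w1 - w0 + 1
    acc = np.zeros(span, dtype=float)
    n_used = 0
    n_dropped = 0
    for row in genes.itertuples(index=False):
        arr = track.coverage.get(row.chrom)
        if arr is None:
            n_dropped += 1
            continue
        if anchor_mode == "plus1":
            if row.gene_id not in anchors.index or pd.isna(anchors[row.gene_id]):
                n_dropped += 1
                continue
            anchor = int(anchors[row.gene_id])
        else:
            anchor = int(row.tss)
        if row.strand == "+":
            lo, hi = anchor + w0, anchor + w1 + 1
        else:
            lo, hi = anchor - w1, anchor - w0 + 1
        if lo < 0 or hi > len(arr):
            n_dropped += 1
            continue
        sl = arr[lo:hi].astype(float)
        if row.strand == "-":
            sl = sl[::-1]
        if normalization == "per-gene-mean":
            m = sl.mean()
            if m == 0:
                n_dropped += 1
                continue
            sl = sl / m
        acc += sl
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene window fits on the track")
    return CompositeProfile(window=(w0, w1), values=acc / n_used,
                            n_genes=n_used, n_dropped=n_dropped,
                            anchor_mode=anchor_mode, normalization=normalization)


def peak_shift(profile_a: CompositeProfile, profile_b: CompositeProfile,
               peak_window: tuple[int, int]) -> int:
    """Argmax position of b minus argmax of a within a relative window.

    Plateau argmax resolves to the leftmost position.  Both profiles must
    share window and anchor mode.
    """
    if profile_a.window != profile_b.window or profile_a.anchor_mode != profile_b.anchor_mode:
        raise ValueError("profiles do not share window/anchor")
    w0, w1 = profile_a.window
    p0, p1 = peak_window
    if p0 < w0 or p1 > w1 or p0 > p1:
        raise ValueError(f"peak_window {peak_window} outside profile window {profile_a.window}")
    sl = slice(p0 - w0, p1 - w0 + 1)
    pos_a = int(np.argmax(profile_a.values[sl])) + p0
    pos_b = int(np.argmax(profile_b.values[sl])) + p0
    return pos_b - pos_a


def profile_table(profiles: dict[str, CompositeProfile]) -> pd.DataFrame:
    """Long-to-wide table: position column plus one column per profile."""
    first = next(iter(profiles.values()))
    data = {"position": first.positions}
    for label, prof in profiles.items():
        if prof.window != first.window:
            raise ValueError("profiles do not share a window")
        data[label] = prof.values
    return pd.DataFrame(data)


def write_profiles(profiles: dict[str, CompositeProfile], path: str | Path) -> None:
    profile_table(profiles).to_csv(path, sep="\t", index=False,
                                   float_format="%.6f")


def plot_profiles(profiles: dict[str, CompositeProfile], path: str | Path,
                  title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, prof in profiles.items():
        ax.plot(prof.positions, prof.values, label=f"{label} (n={prof.n_genes})")
    ax.set_xlabel(f"position relative to {next(iter(profiles.values())).anchor_mode} (bp)")
    ax.set_ylabel("mean dyad coverage")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def locus_excerpt(track: DyadTrack, chrom: str, start: int, end: int,
                  path: str | Path) -> None:
    """bedGraph slice of one locus for genome-browser viewing."""
    arr = track.coverage.get(chrom)
    if arr is None:
        raise ValueError(f"chromosome {chrom!r} not in track")
    start, end = max(0, start), min(len(arr), end)
    sub = arr[start:end]
    with open(path, "w") as fh:
        change = np.flatnonzero(np.diff(sub)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(sub)]])
        for s, e in zip(starts, ends):
            v = sub[s]
            if v != 0:
                fh.write(f"{chrom}\t{start + s}\t{start + e}\t{int(v)}\n")
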