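"""Extended-dyad coverage tracks.

Each fragment contributes its dyad (midpoint), extended symmetrically by
``extension_radius`` bp (default 50, i.e. a 101 bp footprint approximating
the nucleosome), to an integer per-base coverage array per chromosome.
Away from chromosome edges the genome-wide sum is therefore exactly
``n_fragments x (2 * extension_radius + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import fragment_dyad


@dataclass
class DyadTrack:
    coverage: dict[str, np.ndarray]
    extension_radius: int
    n_fragments_used: int
    provenance: dict = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.coverage)

    def genome_sum(self) -> int:
        return int(sum(arr.sum() for arr in self.coverage.values()))

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.coverage.items()}


def build_dyad_track(frags: pd.DataFrame, chrom_sizes: dict[str, int],
                     extension_radius: int = 50,
                     provenance: dict | None = None) -> DyadTrack:
    """Accumulate extended dyads into per-chromosome coverage arrays.

    Every base in ``[dyad - r, dyad + r]`` intersected with the chromosome
    gets +1 per fragment.  Fragments on chromosomes absent from
    ``chrom_sizes`` raise an error listing the offending names.
    """
    if extension_radius < 0:
        raise ValueError("extension_radius must be >= 0")
    unknown = sorted(set(frags["chrom"].unique()) - set(chrom_sizes))
    if unknown:
        raise ValueError(f"fragments on chromosomes missing from chrom_sizes: {unknown}")
    coverage = {c: np.zeros(size, dtype=np.int64)
                for c, size in chrom_sizes.items()}
    dyads = fragment_dyad(frags)
    chrom_arr = frags["chrom"].to_numpy()
    for chrom, size in chrom_sizes.items():
        d = dyads[chrom_arr == chrom]
        if d.size == 0:
            continue
        starts = np.clip(d - extension_radius, 0, size)
        ends = np.clip(d + extension_radius + 1, 0, size)
        delta = np.bincount(starts, minlength=size + 1).astype(np.int64)
        delta -= np.bincount(ends, minlength=size + 1).astype(np.int64)
        coverage[chrom] = np.cumsum(delta[:size])
    return DyadTrack(coverage=coverage, extension_radius=extension_radius,
                     n_fragments_used=len(frags),
                     provenance=dict(provenance or {}))


# ---------------------------------------------------------------------------
# IO


def _runs(arr: np.ndarray):
    """Yield maximal (start, end, value) runs of a per-base array."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(arr)]])
    for s, e in zip(starts, ends):
        yield int(s), int(e), arr[s]


def write_bedgraph(track: DyadTrack, path: str | Path) -> None:
    """bedGraph with maximal runs; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom, arr in track.coverage.items():
            for s, e, v in _runs(arr):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def write_wig(track: DyadTrack, path: str | Path) -> None:
    """fixedStep wiggle, one value per base (verbose but lossless)."""
    with open(path, "w") as fh:
        for chrom, arr in track.coverage.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            np.savetxt(fh, arr, fmt="%d")


def write_bigwig(track: DyadTrack, path: str | Path) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    sizes = track.chrom_sizes()
    bw.addHeader(list(sizes.items()))
    for chrom, arr in track.coverage.items():
        starts, ends, values = [], [], []
        for s, e, v in _runs(arr):
            if v != 0:
                starts.append(s)
                ends.append(e)
                values.append(float(v))
        if starts:
            bw.addEntries([chrom] * len(starts), starts, ends=ends, values=values)
    bw.close()


def write_track(track: DyadTrack, path: str | Path, fmt: str | None = None) -> None:
    """Write a track as bedGraph, wig, or bigWig (format from extension)."""
    path = Path(path)
    if fmt is None:
        fmt = {".bedgraph": "bedGraph", ".bg": "bedGraph", ".wig": "wig",
               ".bw": "bigWig", ".bigwig": "bigWig"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer track format from {path.name}; pass fmt=")
    if fmt == "bedGraph":
        write_bedgraph(track, path)
    elif fmt == "wig":
        write_wig(track, path)
    elif fmt == "bigWig":
        write_bigwig(track, path)
    else:
        raise ValueError(f"unknown track format {fmt!r}")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int],
                  extension_radius: int = 50) -> DyadTrack:
    coverage = {c: np.zeros(size, dtype=np.int64)
                for c, size in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for row in df.itertuples(index=False):
        if row.chrom not in coverage:
            raise ValueError(f"bedGraph chromosome {row.chrom} not in chrom_sizes")
        coverage[row.chrom][int(row.start):int(row.end)] = row.value
    return DyadTrack(coverage=coverage, extension_radius=extension_radius,
                     n_fragments_used=-1, provenance={"source": str(path)})


def read_bigwig(path: str | Path, extension_radius: int = 50) -> DyadTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    coverage = {}
    for chrom, size in bw.chroms().items():
        vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, size), dtype=float))
        coverage[chrom] = np.rint(vals).astype(np.int64)
    bw.close()
    return DyadTrack(coverage=coverage, extension_radius=extension_radius,
                     n_fragments_used=-1, provenance={"source": str(path)})


def read_track(path: str | Path, chrom_sizes: dict[str, int] | None = None,
               extension_radius: int = 50) -> DyadTrack:
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return read_bigwig(path, extension_radius)
    if chrom_sizes is None:
        raise ValueError("chrom_sizes required to read bedGraph")
    return read_bedgraph(path, chrom_sizes, extension_radius)
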