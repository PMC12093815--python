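"""Paired-end fragment ingestion and the standard MNase-Seq filters.

Fragments are genomic intervals (0-based half-open) held in a DataFrame with
columns ``chrom``, ``start``, ``end``.  The canonical filter order of the
pipeline is: size selection (mono-nucleosome, 140-160 bp inclusive) ->
exclusion of blacklisted regions (e.g. the yeast rDNA locus,
chrXII:451000-469000) -> uniform subsampling to a fixed depth (5 million
fragments by default).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end"]

#: rDNA exclusion interval on sacCer3, 0-based half-open
RDNA_REGION = ("chrXII", 451000, 469000)


def _empty_fragments() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def _read_fragments_bed(path: Path) -> pd.DataFrame:
    import csv

    try:
        # whole lines, split vectorized: tolerates ragged column counts
        lines = pd.read_csv(path, sep="\x01", header=None, names=["line"],
                            dtype=str, skip_blank_lines=True,
                            quoting=csv.QUOTE_NONE)["line"]
    except pd.errors.EmptyDataError:
        lines = pd.Series(dtype=str)
    lines = lines[~lines.str.startswith(("#", "track", "browser"), na=True)]
    if lines.empty:
        logger.warning("no fragments in %s", path)
        return _empty_fragments()
    raw = lines.str.split("\t", n=3, expand=True).reindex(columns=range(3))
    raw.columns = ["c0", "c1", "c2"]
    start = pd.to_numeric(raw["c1"], errors="coerce")
    end = pd.to_numeric(raw["c2"], errors="coerce")
    ok = start.notna() & end.notna() & (start >= 0) & (end > start)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d malformed line(s) skipped in %s", n_bad, path)
    frags = pd.DataFrame({"chrom": raw.loc[ok, "c0"].astype(str),
                          "start": start[ok].astype(np.int64),
                          "end": end[ok].astype(np.int64)}).reset_index(drop=True)
    frags.attrs["n_malformed"] = n_bad
    return frags


def _read_fragments_bam(path: Path) -> pd.DataFrame:
    import pysam

    chroms, starts, ends = [], [], []
    n_unpaired = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                n_unpaired += 1
                continue
            if not read.is_proper_pair:
                continue
            # count each template once, from its leftmost mate
            if read.template_length <= 0:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    if n_unpaired and not chroms:
        raise ValueError(
            f"{path} contains no paired reads with pairing flags; convert the "
            "fragments to BED and use that as input instead")
    if not chroms:
        logger.warning("no fragments in %s", path)
        return _empty_fragments()
    return pd.DataFrame({"chrom": chroms,
                         "start": np.asarray(starts, dtype=np.int64),
                         "end": np.asarray(ends, dtype=np.int64)})


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read fragments from BED (>=3 columns) or from name-agnostic BAM/SAM.

    For alignments, one fragment per properly paired template is emitted,
    spanning leftmost mate start to rightmost mate end.  Malformed BED lines
    are counted, logged, and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".bam", ".sam", ".cram"):
        return _read_fragments_bam(path)
    return _read_fragments_bed(path)


def fragment_lengths(frags: pd.DataFrame) -> pd.Series:
    return frags["end"] - frags["start"]


def filter_by_length(frags: pd.DataFrame, min_len: int = 140,
                     max_len: int = 160) -> pd.DataFrame:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError(f"min_len={min_len} > max_len={max_len}")
    length = fragment_lengths(frags)
    return frags[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Exclusion regions from BED3+ as (chrom, start, end) tuples."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]


def exclude_regions(frags: pd.DataFrame,
                    regions: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Remove fragments overlapping any region by >= 1 bp (half-open)."""
    if not regions:
        return frags.reset_index(drop=True)
    keep = np.ones(len(frags), dtype=bool)
    chrom_arr = frags["chrom"].to_numpy()
    start = frags["start"].to_numpy()
    end = frags["end"].to_numpy()
    for chrom, rstart, rend in regions:
        if rstart >= rend:
            raise ValueError(f"malformed exclusion region {chrom}:{rstart}-{rend}")
        keep &= ~((chrom_arr == chrom) & (start < rend) & (end > rstart))
    return frags[keep].reset_index(drop=True)


def subsample(frags: pd.DataFrame, n: int = 5_000_000,
              seed: int = 0) -> pd.DataFrame:
    """Draw exactly min(n, available) fragments uniformly without replacement.

    Deterministic given the seed; the selection preserves the input order of
    the surviving fragments.
    """
    if n < 0:
        raise ValueError(f"subsample size must be >= 0, got {n}")
    if n >= len(frags):
        if n > len(frags):
            logger.warning("requested %d fragments but only %d available; "
                           "keeping all", n, len(frags))
        return frags.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(frags), size=n, replace=False))
    return frags.iloc[idx].reset_index(drop=True)


def fragment_dyad(frags: pd.DataFrame) -> np.ndarray:
    """Dyad position per fragment: floor((start + end) / 2)."""
    return ((frags["start"].to_numpy() + frags["end"].to_numpy()) // 2)
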