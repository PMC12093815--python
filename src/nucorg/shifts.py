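"""+1-nucleosome assignment, condition shifts, and dependence classification.

For every gene the +1 nucleosome is the called summit with the smallest
transcript offset inside a search window around the TSS (default -30 to
+250 bp; downstream positive on both strands).  The shift of a gene between
conditions is (mutant offset - reference offset); a gene is classified
remodeler-dependent when the shift is at least the threshold (default 10 bp
downstream) in every replicate — the all-replicates rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import validate_genes

DEFAULT_WINDOW = (-30, 250)


@dataclass(frozen=True)
class PlusOneAssignment:
    gene_id: str
    summit: int
    offset: int


def transcript_offsets(summits: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Signed transcript offsets of genomic positions (downstream positive)."""
    summits = np.asarray(summits)
    return summits - tss if strand == "+" else tss - summits


def assign_plus_one(calls: pd.DataFrame, gene,
                    window: tuple[int, int] = DEFAULT_WINDOW) -> PlusOneAssignment | None:
    """Smallest-offset summit within the window, or None.

    ``gene`` is any object with gene_id/chrom/tss/strand attributes (e.g. a
    row from a gene table via ``itertuples``).
    """
    sub = calls[calls["chrom"] == gene.chrom]
    if sub.empty:
        return None
    summits = sub["summit"].to_numpy()
    offsets = transcript_offsets(summits, gene.tss, gene.strand)
    ok = (offsets >= window[0]) & (offsets <= window[1])
    if not ok.any():
        return None
    i = np.flatnonzero(ok)[np.argmin(offsets[ok])]
    return PlusOneAssignment(gene.gene_id, int(summits[i]), int(offsets[i]))


def assign_plus_one_table(calls: pd.DataFrame, genes: pd.DataFrame,
                          window: tuple[int, int] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Vectorized +1 assignment for a gene table.

    Returns a DataFrame indexed like ``genes`` with columns ``gene_id``,
    ``summit``, ``offset`` (NaN where no summit falls in the window).
    """
    validate_genes(genes)
    out_summit = np.full(len(genes), np.nan)
    out_offset = np.full(len(genes), np.nan)
    for chrom, sub in calls.groupby("chrom", sort=False):
        summits = np.sort(sub["summit"].to_numpy())
        gsel = genes["chrom"] == chrom
        if not gsel.any() or summits.size == 0:
            continue
        for gi in np.flatnonzero(gsel.to_numpy()):
            tss = int(genes["tss"].iat[gi])
            strand = genes["strand"].iat[gi]
            if strand == "+":
                lo, hi = tss + window[0], tss + window[1]
            else:
                lo, hi = tss - window[1], tss - window[0]
            a = np.searchsorted(summits, lo, side="left")
            b = np.searchsorted(summits, hi, side="right")
            if a == b:
                continue
            cand = summits[a:b]
            offs = transcript_offsets(cand, tss, strand)
            j = np.argmin(offs)
            out_summit[gi] = cand[j]
            out_offset[gi] = offs[j]
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                         "summit": out_summit, "offset": out_offset})


def compute_shift(wt: PlusOneAssignment, mut: PlusOneAssignment) -> int:
    """Signed +1 shift (mutant - reference) along the transcript."""
    if wt.gene_id != mut.gene_id:
        raise ValueError(f"gene mismatch: {wt.gene_id} vs {mut.gene_id}")
    return mut.offset - wt.offset


def classify_dependent(shifts: Sequence[float], threshold: float = 10.0) -> bool:
    """True iff every replicate shift is >= threshold (downstream)."""
    shifts = list(shifts)
    if not shifts:
        raise ValueError("classify_dependent requires at least one replicate shift")
    return all(s >= threshold for s in shifts)


def shift_table(calls_by_sample: Mapping[tuple[str, int], pd.DataFrame],
                genes: pd.DataFrame,
                wt_condition: str = "wt", mut_condition: str = "mut",
                threshold: float = 10.0,
                window: tuple[int, int] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-gene shift records across replicate pairs.

    ``calls_by_sample`` maps (condition, replicate) -> calls DataFrame.
    With equal replicate counts, replicate i of the mutant is compared to
    replicate i of the reference (by sorted replicate id); otherwise each
    mutant replicate is compared to the mean reference offset.  Genes
    missing a +1 call in any required sample are left unclassified with a
    reason.
    """
    wt_reps = sorted(r for c, r in calls_by_sample if c == wt_condition)
    mut_reps = sorted(r for c, r in calls_by_sample if c == mut_condition)
    if not wt_reps or not mut_reps:
        raise ValueError(
            f"need calls for both conditions {wt_condition!r} and {mut_condition!r}")
    paired = len(wt_reps) == len(mut_reps)

    assign = {key: assign_plus_one_table(calls, genes, window)
              for key, calls in calls_by_sample.items()}

    n_pairs = len(mut_reps)
    shift_cols = {f"shift_rep{i + 1}": np.full(len(genes), np.nan)
                  for i in range(n_pairs)}
    na_reason = np.array([""] * len(genes), dtype=object)

    wt_offsets = np.vstack([assign[(wt_condition, r)]["offset"].to_numpy()
                            for r in wt_reps])
    mut_offsets = np.vstack([assign[(mut_condition, r)]["offset"].to_numpy()
                             for r in mut_reps])

    missing_wt = np.isnan(wt_offsets).any(axis=0)
    missing_mut = np.isnan(mut_offsets).any(axis=0)
    na_reason[missing_wt] = f"no_plus_one_in_{wt_condition}"
    na_reason[missing_mut & ~missing_wt] = f"no_plus_one_in_{mut_condition}"
    complete = ~(missing_wt | missing_mut)

    for i in range(n_pairs):
        ref = wt_offsets[i] if paired else wt_offsets.mean(axis=0)
        shift_cols[f"shift_rep{i + 1}"][complete] = (
            mut_offsets[i][complete] - ref[complete])

    table = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(), **shift_cols})
    shift_mat = table[[c for c in table.columns if c.startswith("shift_rep")]]
    table["mean_shift"] = shift_mat.mean(axis=1)
    dependent = pd.array([pd.NA] * len(genes), dtype="boolean")
    dependent[complete] = (shift_mat[complete] >= threshold).all(axis=1).to_numpy()
    table["dependent"] = dependent
    table["na_reason"] = na_reason
    table.attrs["pairing"] = "by_replicate_index" if paired else "mut_vs_mean_wt"
    table.attrs["threshold"] = threshold
    table.attrs["window"] = tuple(window)
    if complete.sum() == 0 and len(genes):
        # every gene unclassified: likely disjoint annotations/calls
        if (missing_wt & missing_mut).all():
            raise ValueError("no gene has a +1 call in any sample; check inputs")
    return table


def dependent_genes(table: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Subset of the gene table classified dependent."""
    dep_ids = set(table.loc[table["dependent"].fillna(False).astype(bool), "gene_id"])
    return genes[genes["gene_id"].isin(dep_ids)].reset_index(drop=True)


def write_shift_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["dependent"] = out["dependent"].map(
        lambda v: "NA" if pd.isna(v) else ("true" if v else "false"))
    out.to_csv(path, sep="\t", index=False, float_format="%.3f")
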