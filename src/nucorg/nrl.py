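"""Nucleosome repeat length (NRL) estimation and strain comparison.

The per-gene NRL is the ordinary-least-squares slope of summit transcript
offset against nucleosome index over the +1..+k array (k capped at 8,
requiring at least 4 nucleosomes).  For a perfectly phased array the slope
is exactly the repeat length; for fuzzy data it is the maximum-likelihood
spacing under Gaussian positional noise.  Gene-set distributions are
summarized as Tukey boxplot statistics (type-7 linear-interpolation
quartiles, whiskers at 1.5xIQR clipped to the data range), and strains are
compared with a two-tailed Welch's t-test on per-replicate mean NRLs — a
deliberately low-n design (2-3 datasets per strain) matching common
practice; its low power is a feature of the comparison, not of this code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .shifts import DEFAULT_WINDOW, assign_plus_one_table, transcript_offsets


@dataclass(frozen=True)
class NRLEstimate:
    scope: str
    nrl: float
    n_nucs: int
    r2: float


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def estimate_gene_nrl(offsets: Sequence[float], gene_id: str = "",
                      min_nucs: int = 4, max_nucs: int = 8) -> NRLEstimate | None:
    """OLS slope of offset vs index over the first min(N, max_nucs) calls.

    ``offsets`` are the gene's +1..+N summit offsets in transcript order.
    Returns None when fewer than ``min_nucs`` calls are available.
    """
    offsets = np.asarray(offsets, dtype=float)
    if len(offsets) < min_nucs:
        return None
    y = offsets[:max_nucs]
    x = np.arange(len(y), dtype=float)
    res = stats.linregress(x, y)
    return NRLEstimate(scope=gene_id, nrl=float(res.slope), n_nucs=len(y),
                       r2=float(res.rvalue ** 2))


def gene_array_offsets(calls: pd.DataFrame, genes: pd.DataFrame,
                       window: tuple[int, int] = DEFAULT_WINDOW) -> dict[str, np.ndarray]:
    """Per-gene ordered summit offsets from the +1 through the gene body.

    The +1 is assigned by the smallest-offset-in-window rule; every further
    summit with offset up to the transcript length is appended in order.
    Genes without a +1 are omitted.
    """
    plus1 = assign_plus_one_table(calls, genes, window)
    out: dict[str, np.ndarray] = {}
    by_chrom = {c: np.sort(sub["summit"].to_numpy())
                for c, sub in calls.groupby("chrom", sort=False)}
    for gi, row in enumerate(genes.itertuples(index=False)):
        if np.isnan(plus1["offset"].iat[gi]):
            continue
        summits = by_chrom.get(row.chrom)
        if summits is None:
            continue
        body_len = abs(row.body_end - row.tss)
        offs = transcript_offsets(summits, row.tss, row.strand)
        sel = (offs >= plus1["offset"].iat[gi]) & (offs <= body_len)
        out[row.gene_id] = np.sort(offs[sel])
    return out


def nrl_table(calls: pd.DataFrame, genes: pd.DataFrame,
              window: tuple[int, int] = DEFAULT_WINDOW,
              min_nucs: int = 4, max_nucs: int = 8) -> pd.DataFrame:
    """Per-gene NRL estimates (genes failing min_nucs are omitted)."""
    arrays = gene_array_offsets(calls, genes, window)
    rows = []
    for gene_id, offsets in arrays.items():
        est = estimate_gene_nrl(offsets, gene_id, min_nucs, max_nucs)
        if est is not None:
            rows.append((gene_id, est.nrl, est.n_nucs, est.r2))
    return pd.DataFrame(rows, columns=["gene_id", "nrl", "n_nucs", "r2"])


def set_nrl(estimates: Sequence[float], label: str = "set") -> dict:
    """Boxplot summary (median, type-7 quartiles, 1.5xIQR whiskers clipped
    to the data range) plus the mean used for the Welch comparison."""
    values = np.asarray(list(estimates), dtype=float)
    if values.size == 0:
        raise ValueError(f"empty NRL set {label!r}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo = max(values.min(), q1 - 1.5 * iqr)
    hi = min(values.max(), q3 + 1.5 * iqr)
    return {"label": label, "n": int(values.size), "median": float(med),
            "q1": float(q1), "q3": float(q3), "iqr": float(iqr),
            "whisker_low": float(lo), "whisker_high": float(hi),
            "mean": float(values.mean())}


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-tailed Welch's t-test on per-replicate mean NRLs.

    Requires >= 2 values with nonzero variance in each group.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    for name, g in (("group_a", a), ("group_b", b)):
        if g.size < 2:
            raise ValueError(f"{name} has {g.size} value(s); Welch's t needs >= 2")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"{name} has zero variance; Welch's t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", None)
    if df is None:  # older scipy: Welch-Satterthwaite by hand
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def write_nrl_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
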