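"""+1 assignment, shift computation, and the all-replicates rule."""

import numpy as np
import pandas as pd
import pytest

from nucorg.annotation import GENE_COLUMNS
from nucorg.shifts import (PlusOneAssignment, assign_plus_one,
                           assign_plus_one_table, classify_dependent,
                           compute_shift, shift_table)


def gene_row(gene_id="g1", chrom="c", tss=1000, strand="+", body_end=None):
    if body_end is None:
        body_end = tss + 1400 if strand == "+" else tss - 1400
    return pd.DataFrame([[gene_id, chrom, tss, strand, body_end]],
                        columns=GENE_COLUMNS).iloc[0]


def calls_at(summits, chrom="c"):
    return pd.DataFrame({"chrom": chrom, "summit": summits,
                         "height": 10.0, "raw_dyads": 100})


def test_plus_strand_assignment_window_and_smallest_offset():
    a = assign_plus_one(calls_at([940, 1060, 1225]), gene_row(tss=1000))
    assert (a.summit, a.offset) == (1060, 60)  # 940 excluded (offset -60)


def test_minus_strand_mirror():
    g = gene_row(tss=1000, strand="-")
    a = assign_plus_one(calls_at([940]), g)
    assert (a.summit, a.offset) == (940, 60)


def test_no_summit_in_window_returns_none():
    assert assign_plus_one(calls_at([2000]), gene_row(tss=1000)) is None


def test_table_assignment_matches_scalar(small_experiment):
    genes = small_experiment["genes"].head(6)
    calls = calls_at(list(genes["tss"] + np.where(genes["strand"] == "+", 60, -60)))
    calls["chrom"] = genes["chrom"].iloc[0]
    tab = assign_plus_one_table(calls, genes)
    assert (tab["offset"] == 60).all()


def test_compute_shift_and_antisymmetry():
    wt = PlusOneAssignment("g", 1060, 60)
    mut = PlusOneAssignment("g", 1084, 84)
    assert compute_shift(wt, mut) == 24
    assert compute_shift(mut, wt) == -24
    assert compute_shift(wt, wt) == 0
    with pytest.raises(ValueError, match="mismatch"):
        compute_shift(wt, PlusOneAssignment("other", 1, 1))


@pytest.mark.parametrize("shifts,expected", [
    ([12, 15, 11], True),
    ([12, 8], False),
    ([10, 10], True),  # threshold is inclusive
])
def test_all_replicates_rule(shifts, expected):
    assert classify_dependent(shifts, threshold=10) is expected


def test_classify_empty_errors():
    with pytest.raises(ValueError):
        classify_dependent([])


def test_threshold_monotonicity():
    rng = np.random.default_rng(2)
    shift_sets = rng.normal(12, 6, size=(50, 2))
    counts = [sum(classify_dependent(s, t) for s in shift_sets)
              for t in (5, 10, 15, 20)]
    assert counts == sorted(counts, reverse=True)


def single_gene_table(wt_offset=60, mut_offset=84, tss=1000):
    genes = gene_row(tss=tss).to_frame().T.reset_index(drop=True)
    calls = {("wt", 1): calls_at([tss + wt_offset]),
             ("mut", 1): calls_at([tss + mut_offset])}
    return shift_table(calls, genes)


def test_shift_table_single_gene_composition():
    tab = single_gene_table()
    row = tab.iloc[0]
    assert row["shift_rep1"] == 24
    assert row["mean_shift"] == 24
    assert bool(row["dependent"]) is True


def test_mean_shift_is_arithmetic_mean():
    genes = gene_row().to_frame().T.reset_index(drop=True)
    calls = {("wt", 1): calls_at([1060]), ("wt", 2): calls_at([1062]),
             ("mut", 1): calls_at([1084]), ("mut", 2): calls_at([1072])}
    tab = shift_table(calls, genes)
    assert tab["mean_shift"].iloc[0] == pytest.approx((24 + 10) / 2)


def test_unequal_replicates_compared_to_mean_wt():
    genes = gene_row().to_frame().T.reset_index(drop=True)
    calls = {("wt", 1): calls_at([1060]), ("wt", 2): calls_at([1070]),
             ("mut", 1): calls_at([1089])}
    tab = shift_table(calls, genes)
    assert tab.attrs["pairing"] == "mut_vs_mean_wt"
    assert tab["shift_rep1"].iloc[0] == pytest.approx(89 - 65)


def test_missing_plus_one_leaves_gene_unclassified():
    genes = pd.DataFrame([["g1", "c", 1000, "+", 2400],
                          ["g2", "c", 5000, "+", 6400]], columns=GENE_COLUMNS)
    calls = {("wt", 1): calls_at([1060]),  # no +1 for g2 in wt
             ("mut", 1): calls_at([1084, 5060])}
    tab = shift_table(calls, genes).set_index("gene_id")
    assert pd.isna(tab.loc["g2", "dependent"])
    assert tab.loc["g2", "na_reason"] == "no_plus_one_in_wt"
    assert bool(tab.loc["g1", "dependent"]) is True


def test_strand_symmetry_under_genome_mirror():
    """Mirroring coordinates (x -> L-x) and flipping strands preserves
    offsets, shifts, and classifications."""
    L = 10_000
    genes = pd.DataFrame([["g1", "c", 1000, "+", 2400],
                          ["g2", "c", 6000, "-", 4600]], columns=GENE_COLUMNS)
    calls = {("wt", 1): calls_at([1060, 5940]),
             ("mut", 1): calls_at([1084, 5916])}
    mirror_genes = genes.copy()
    mirror_genes["tss"] = L - genes["tss"]
    mirror_genes["body_end"] = L - genes["body_end"]
    mirror_genes["strand"] = genes["strand"].map({"+": "-", "-": "+"})
    mirror_calls = {k: calls_at(sorted(L - v["summit"])) for k, v in calls.items()}
    a = shift_table(calls, genes).set_index("gene_id")
    b = shift_table(mirror_calls, mirror_genes).set_index("gene_id")
    for g in ("g1", "g2"):
        assert a.loc[g, "mean_shift"] == b.loc[g, "mean_shift"] == 24
        assert bool(a.loc[g, "dependent"]) and bool(b.loc[g, "dependent"])


def test_shift_table_requires_both_conditions():
    genes = gene_row().to_frame().T.reset_index(drop=True)
    with pytest.raises(ValueError, match="conditions"):
        shift_table({("wt", 1): calls_at([1060])}, genes)
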