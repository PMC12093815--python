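"""Fragment ingestion and the size/exclusion/subsampling filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nucorg.fragments import (exclude_regions, filter_by_length,
                              fragment_dyad, read_fragments, subsample)
from nucorg.simulate import sample_fragments, write_fragments_bed


def make_frags(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# reading


def test_read_bed_line(tmp_path):
    p = tmp_path / "f.bed"
    p.write_text("chrI\t100\t250\n")
    frags = read_fragments(p)
    assert frags.iloc[0].tolist() == ["chrI", 100, 250]


def test_read_empty_and_malformed_bed(tmp_path, caplog):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert len(read_fragments(p)) == 0

    q = tmp_path / "mixed.bed"
    q.write_text("track name=junk\nchrI\t10\t20\nchrI\tnope\t30\nchrI\t5\t2\n")
    frags = read_fragments(q)
    assert len(frags) == 1
    assert frags.attrs["n_malformed"] == 2


def test_simulator_round_trip(tmp_path, small_experiment, small_config):
    frags = small_experiment["samples"][("mut", 2)]
    bed = tmp_path / "sim.bed"
    write_fragments_bed(frags, bed)
    back = read_fragments(bed)
    assert len(back) == small_config.depth
    pd.testing.assert_frame_equal(back, frags[["chrom", "start", "end"]])


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrI\tLN:10000\n"


def test_read_sam_proper_pairs(tmp_path):
    # one template chrI:100-250 (leftmost mate carries tlen +150)
    sam = SAM_HEADER
    sam += "t1\t99\tchrI\t101\t60\t50M\t=\t201\t150\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
    sam += "t1\t147\tchrI\t201\t60\t50M\t=\t101\t-150\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
    p = tmp_path / "pairs.sam"
    p.write_text(sam)
    frags = read_fragments(p)
    assert frags.values.tolist() == [["chrI", 100, 250]]


def test_read_sam_without_pairing_flags_advises_bed(tmp_path):
    sam = SAM_HEADER + "r1\t0\tchrI\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
    p = tmp_path / "single.sam"
    p.write_text(sam)
    with pytest.raises(ValueError, match="BED"):
        read_fragments(p)


# ---------------------------------------------------------------------------
# length filter


def test_length_bounds_inclusive():
    frags = make_frags([("c", 0, L) for L in (139, 140, 150, 160, 161)])
    kept = filter_by_length(frags, 140, 160)
    assert sorted(kept["end"]) == [140, 150, 160]


def test_length_filter_identity_and_error():
    frags = make_frags([("c", 0, 10), ("c", 5, 400)])
    pd.testing.assert_frame_equal(filter_by_length(frags, 0, 10**9), frags)
    with pytest.raises(ValueError):
        filter_by_length(frags, 10, 5)


def test_kept_fraction_matches_normal_cdf(small_experiment, small_config):
    """Size selection keeps the normal-law mass on [140,160] (3 sigma bound)."""
    frags = small_experiment["samples"][("wt", 2)]
    kept = filter_by_length(frags, 140, 160)
    # rounded lengths: mass of N(mean, sd) on [139.5, 160.5]
    dist = stats.norm(small_config.frag_len_mean, small_config.frag_len_sd)
    p = dist.cdf(160.5) - dist.cdf(139.5)
    n = len(frags)
    assert abs(len(kept) / n - p) < 3 * np.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# exclusion


RDNA = [("chrXII", 451000, 469000)]


def test_exclusion_any_overlap_removes():
    frags = make_frags([("chrXII", 450900, 451050)])
    assert len(exclude_regions(frags, RDNA)) == 0


def test_exclusion_half_open_boundary_kept():
    frags = make_frags([("chrXII", 469000, 469150), ("chrXII", 450850, 451000)])
    assert len(exclude_regions(frags, RDNA)) == 2


def test_exclusion_empty_region_list_is_identity():
    frags = make_frags([("chrXII", 451000, 451150)])
    pd.testing.assert_frame_equal(exclude_regions(frags, []), frags)


# ---------------------------------------------------------------------------
# subsampling


def test_subsample_exact_count_and_determinism(small_experiment):
    frags = small_experiment["samples"][("wt", 1)]
    a = subsample(frags, 1000, seed=3)
    b = subsample(frags, 1000, seed=3)
    c = subsample(frags, 1000, seed=4)
    assert len(a) == 1000
    pd.testing.assert_frame_equal(a, b)
    assert not a.equals(c)


def test_subsample_zero_and_oversized():
    frags = make_frags([("c", 0, 150), ("c", 10, 160)])
    assert len(subsample(frags, 0, seed=1)) == 0
    full = subsample(frags, 10, seed=1)
    assert sorted(map(tuple, full.values.tolist())) == sorted(
        map(tuple, frags.values.tolist()))


def test_filter_exclude_subsample_order_invariance(small_experiment):
    """filter->exclude->subsample == exclude->filter->subsample (same seed)."""
    frags = small_experiment["samples"][("mut", 1)]
    region = [("chrS01", 30_000, 40_000)]
    a = subsample(exclude_regions(filter_by_length(frags), region), 5000, seed=9)
    b = subsample(filter_by_length(exclude_regions(frags, region)), 5000, seed=9)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# dyads


@pytest.mark.parametrize("start,end,mid", [(100, 250, 175), (100, 251, 175),
                                           (0, 2, 1)])
def test_fragment_dyad_floor_midpoint(start, end, mid):
    assert fragment_dyad(make_frags([("c", start, end)]))[0] == mid


@settings(derandomize=True, max_examples=50)
@given(start=st.integers(0, 10**6), length=st.integers(1, 500))
def test_fragment_dyad_within_fragment(start, length):
    mid = fragment_dyad(make_frags([("c", start, start + length)]))[0]
    assert start <= mid < start + length
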