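"""Summit caller: smoothing, constrained selection, and truth recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucorg.calling import (CallerParams, call_nucleosomes, call_summits,
                            gaussian_kernel, smooth_track)
from nucorg.fragments import filter_by_length
from nucorg.simulate import SimConfig, simulate_experiment
from nucorg.tracks import DyadTrack, build_dyad_track


def as_track(arr, chrom="c"):
    return DyadTrack({chrom: np.asarray(arr, dtype=np.int64)},
                     extension_radius=50, n_fragments_used=-1)


def smoothed_of(arr, bandwidth=15.0, cap=None):
    return smooth_track(as_track(arr), bandwidth, cap)["c"]


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_zero_track_stays_zero():
    assert not smoothed_of(np.zeros(500)).any()


def test_smooth_impulse_is_normalized_kernel():
    out = smoothed_of(np.eye(1, 801, 400).ravel())
    k = gaussian_kernel(15.0)
    assert np.allclose(out.sum(), 1.0)
    assert np.allclose(out[400 - 60:400 + 61], k)


def test_smooth_constant_away_from_edges():
    out = smoothed_of(np.full(500, 7))
    assert np.allclose(out[100:400], 7.0)


def test_cap_applied_before_smoothing():
    arr = np.zeros(500)
    arr[250] = 1000
    out = smoothed_of(arr, cap=200.0)
    assert np.isclose(out.sum(), 200.0)


# ---------------------------------------------------------------------------
# summit selection


def bump(center, height, width=30, n=2000):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


def run_caller(smoothed, min_distance=110, min_height=0.5):
    params = CallerParams(min_distance=min_distance)
    return call_summits({"c": smoothed}, params, min_height=min_height)


def test_single_bump_single_call_at_mode():
    calls = run_caller(bump(700, 10))
    assert calls["summit"].tolist() == [700]


def test_two_bumps_distance_rule():
    far = run_caller(bump(600, 10) + bump(900, 10))
    assert far["summit"].tolist() == [600, 900]
    near = run_caller(bump(600, 10, width=20) + bump(680, 10, width=20))
    assert len(near) == 1


def test_plateau_resolved_to_leftmost():
    arr = np.zeros(400)
    arr[100:110] = 5  # 10 bp plateau
    calls = run_caller(arr, min_height=1.0)
    assert calls["summit"].tolist() == [100]


def test_min_distance_invariant_holds_pairwise():
    rng = np.random.default_rng(0)
    arr = rng.poisson(3, 5000).astype(float)
    calls = run_caller(smoothed_of(arr), min_distance=110, min_height=0.0)
    summits = calls["summit"].to_numpy()
    assert (np.diff(summits) >= 110).all()


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10**6))
def test_min_distance_invariant_random_tracks(seed):
    rng = np.random.default_rng(seed)
    arr = rng.poisson(2, 2000).astype(float)
    calls = run_caller(smoothed_of(arr, bandwidth=5), min_distance=50,
                       min_height=0.0)
    assert (np.diff(calls["summit"].to_numpy()) >= 50).all()


def brute_force_best(positions, heights, min_distance):
    """Exhaustive max-total-height subset under the distance constraint."""
    best, best_score = (), -1.0
    for r in range(len(positions) + 1):
        for combo in itertools.combinations(range(len(positions)), r):
            pos = [positions[i] for i in combo]
            if any(b - a < min_distance for a, b in zip(pos, pos[1:])):
                continue
            score = sum(heights[i] for i in combo)
            if score > best_score:
                best, best_score = combo, score
    return {positions[i] for i in best}


def test_greedy_matches_brute_force_on_separated_bumps():
    centers = [300, 520, 900, 1300, 1800]
    heights = [10, 8, 12, 6, 9]
    arr = sum(bump(c, h, width=25) for c, h in zip(centers, heights))
    calls = run_caller(arr, min_distance=110, min_height=1.0)
    assert set(calls["summit"]) == brute_force_best(centers, heights, 110)


# ---------------------------------------------------------------------------
# recovery against ground truth


def summit_errors(fuzziness_sd, per_nuc=300, seed=31):
    n_genes = 10
    cfg = SimConfig(seed=seed, n_genes=n_genes, chrom_length=60_000,
                    fuzziness_sd=fuzziness_sd,
                    depth=int(round(n_genes * 8 * per_nuc / 0.95)))
    exp = simulate_experiment(cfg, conditions=("wt",), n_replicates=1)
    frags = filter_by_length(exp["samples"][("wt", 1)])
    track = build_dyad_track(frags, exp["chrom_sizes"])
    calls = call_nucleosomes(track)
    errors = []
    summits = np.sort(calls["summit"].to_numpy())
    for dyad in exp["truth"]["dyad_pos"]:
        errors.append(np.abs(summits - dyad).min())
    return np.asarray(errors)


@pytest.mark.parametrize("fuzz", [5.0, 20.0, 40.0])
def test_recovery_error_scales_with_fuzziness(fuzz):
    err = summit_errors(fuzz)
    bound = 3 * fuzz / np.sqrt(300) + 1
    assert np.median(err) <= bound


def test_every_true_dyad_matched_no_spurious_calls_in_gaps():
    """Fuzz 20, ~500 frags/nucleosome: calls within 10 bp of every true dyad
    and none in nucleosome-free gaps."""
    cfg = SimConfig(seed=8, n_genes=6, chrom_length=40_000, fuzziness_sd=20.0,
                    background_frac=0.0, depth=6 * 8 * 500)
    exp = simulate_experiment(cfg, conditions=("wt",), n_replicates=1)
    track = build_dyad_track(exp["samples"][("wt", 1)], exp["chrom_sizes"])
    calls = call_nucleosomes(track)
    summits = np.sort(calls["summit"].to_numpy())
    dyads = np.sort(exp["truth"]["dyad_pos"].to_numpy())
    for dyad in dyads:
        assert np.abs(summits - dyad).min() <= 10
    for s in summits:  # no call farther than 60 bp from any true dyad
        assert np.abs(dyads - s).min() <= 60
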