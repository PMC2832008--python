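"""Ploidy calling, endoreduplication index, bacteroid differentiation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nodulewaves import (
    call_ploidy_fractions,
    classify_bacteroid_differentiation,
    classify_symbiotic_cell_differentiation,
    cluster_ploidy_profiles,
    endoreduplication_index,
    max_occupied_class,
    simulate_ploidy,
)
from nodulewaves.differentiation import (
    PLOIDY_CLASSES,
    PloidyError,
    PloidyHistogram,
    PloidyProfile,
    estimate_anchor_2c,
    profiles_to_frame,
)
from nodulewaves.synthetic import (
    ARCHETYPE_ROOT,
    ARCHETYPE_UNINFECTED,
    ARCHETYPE_WILD_TYPE,
    DEFAULT_PLOIDY_MIXTURES,
)
from conftest import small_config


def hist(centers, counts, sample="s"):
    return PloidyHistogram(bin_centers=np.asarray(centers, float),
                           counts=np.asarray(counts, float), sample_id=sample)


def profile(percent_by_class, sample="s"):
    full = {c: 0.0 for c in PLOIDY_CLASSES}
    full.update(percent_by_class)
    return PloidyProfile(percentages=full, n_nuclei=1000, sample_id=sample)


# ---------------------------------------------------------------------------
# fraction calling
# ---------------------------------------------------------------------------

def test_all_mass_at_anchor_is_pure_2c():
    h = hist([100.0, 200.0], [500.0, 0.0])
    p = call_ploidy_fractions(h, anchor_2c=100.0)
    assert p.percentages[2] == pytest.approx(100.0)


def test_equal_split_between_anchor_and_4x():
    h = hist([100.0, 400.0], [250.0, 250.0])
    p = call_ploidy_fractions(h, anchor_2c=100.0)
    assert p.percentages[2] == pytest.approx(50.0)
    assert p.percentages[8] == pytest.approx(50.0)
    assert p.percentages[4] == pytest.approx(0.0)


def test_percentages_always_sum_to_100():
    rng = np.random.default_rng(0)
    h = hist(np.linspace(5, 9000, 300), rng.integers(0, 50, 300))
    p = call_ploidy_fractions(h, anchor_2c=100.0)
    assert sum(p.percentages.values()) == pytest.approx(100.0)


@given(st.floats(min_value=0.1, max_value=10.0))
def test_fluorescence_scale_invariance(c):
    centers = np.array([100.0, 220.0, 400.0, 790.0])
    counts = np.array([40.0, 25.0, 20.0, 15.0])
    base = call_ploidy_fractions(hist(centers, counts), anchor_2c=100.0)
    scaled = call_ploidy_fractions(hist(centers * c, counts), anchor_2c=100.0 * c)
    for cls in PLOIDY_CLASSES:
        assert scaled.percentages[cls] == pytest.approx(base.percentages[cls])


def test_empty_histogram_and_bad_anchor_rejected():
    with pytest.raises(PloidyError):
        call_ploidy_fractions(hist([100.0], [0.0]), anchor_2c=100.0)
    with pytest.raises(PloidyError):
        call_ploidy_fractions(hist([100.0], [5.0]), anchor_2c=-1.0)


def test_replicate_averaging():
    h1 = hist([100.0, 400.0], [100.0, 0.0])
    h2 = hist([100.0, 400.0], [0.0, 300.0])
    p = call_ploidy_fractions([h1, h2], anchor_2c=100.0)
    # averaged after per-replicate percentages: (100+0)/2 and (0+100)/2
    assert p.percentages[2] == pytest.approx(50.0)
    assert p.percentages[8] == pytest.approx(50.0)
    assert p.replicate_averaged


def test_anchor_estimation_finds_lowest_prominent_peak():
    cfg = small_config()
    hists, _ = simulate_ploidy(cfg, ARCHETYPE_WILD_TYPE, n_nuclei=5000, seed=2)
    est = estimate_anchor_2c(hists[0])
    assert est == pytest.approx(cfg.ploidy_anchor, rel=0.1)


# ---------------------------------------------------------------------------
# endoreduplication index
# ---------------------------------------------------------------------------

def test_ei_pure_2c_is_zero():
    assert endoreduplication_index(profile({2: 100.0})) == 0.0


def test_ei_weighted_formula():
    p = profile({2: 83.0, 16: 10.0, 32: 5.0, 64: 2.0})
    assert endoreduplication_index(p) == pytest.approx(10 * 3 + 5 * 4 + 2 * 5)


def test_ei_linear_in_the_profile():
    p1 = profile({2: 90.0, 16: 10.0})
    p2 = profile({2: 90.0, 32: 10.0})
    mix = profile({2: 90.0, 16: 5.0, 32: 5.0})
    assert endoreduplication_index(mix) == pytest.approx(
        0.5 * endoreduplication_index(p1) + 0.5 * endoreduplication_index(p2)
    )


@pytest.mark.parametrize("ei,call", [
    (0.5, "undifferentiated"), (1.99, "undifferentiated"),
    (60.0, "differentiated"), (15.01, "differentiated"),
    (7.0, "indeterminate"), (2.0, "indeterminate"), (15.0, "indeterminate"),
])
def test_ei_decision_bounds(ei, call):
    assert classify_symbiotic_cell_differentiation(ei) == call


def test_archetype_eis_fall_on_the_right_side_of_the_bounds():
    cfg = small_config()
    for archetype, bound, side in [(ARCHETYPE_ROOT, 2.0, "below"),
                                   (ARCHETYPE_WILD_TYPE, 15.0, "above")]:
        hists, _ = simulate_ploidy(cfg, archetype, n_nuclei=5000, seed=3)
        ei = endoreduplication_index(call_ploidy_fractions(hists, cfg.ploidy_anchor))
        assert (ei < bound) if side == "below" else (ei > bound)


def test_max_occupied_class():
    assert max_occupied_class(profile({2: 60.0, 4: 30.0, 8: 10.0})) == 8
    assert max_occupied_class(profile({2: 99.7, 64: 0.3})) == 2  # below the floor


# ---------------------------------------------------------------------------
# ploidy clustering
# ---------------------------------------------------------------------------

def test_identical_profiles_merge_at_height_zero():
    p = profile({2: 60.0, 4: 40.0}, sample="a")
    q = profile({2: 60.0, 4: 40.0}, sample="b")
    labels, linkage, _ = cluster_ploidy_profiles([p, q], k=1)
    assert linkage[0, 2] == pytest.approx(0.0)


def test_root_like_vs_nodule_like_split_at_k2():
    cfg = small_config()
    profiles = []
    panel = {
        "root": ARCHETYPE_ROOT, "V1": ARCHETYPE_UNINFECTED,
        "TR3": "infected_undifferentiated", "exoY": ARCHETYPE_UNINFECTED,
        "wild_type": ARCHETYPE_WILD_TYPE, "bacA": "bacteroid_blocked",
        "nifH": "fix_minus_differentiated",
    }
    for i, (sample, archetype) in enumerate(sorted(panel.items())):
        hists, _ = simulate_ploidy(cfg, archetype, n_nuclei=3000, seed=10 + i)
        p = call_ploidy_fractions(hists, cfg.ploidy_anchor)
        p.sample_id = sample
        profiles.append(p)
    labels, _, newick = cluster_ploidy_profiles(profiles, k=2)
    root_like = {"root", "V1", "TR3", "exoY"}
    groups = {}
    for sample, label in labels.items():
        groups.setdefault(label, set()).add(sample)
    assert root_like in groups.values()


def test_profile_order_permutation_gives_same_partition():
    cfg = small_config()
    profiles = []
    for i, arch in enumerate([ARCHETYPE_ROOT, ARCHETYPE_WILD_TYPE,
                              ARCHETYPE_UNINFECTED, "bacteroid_blocked"]):
        hists, _ = simulate_ploidy(cfg, arch, n_nuclei=2000, seed=20 + i)
        p = call_ploidy_fractions(hists, cfg.ploidy_anchor)
        p.sample_id = f"s{i}"
        profiles.append(p)
    l1, _, _ = cluster_ploidy_profiles(profiles, k=2)
    l2, _, _ = cluster_ploidy_profiles(profiles[::-1], k=2)
    part1 = {frozenset(l1.index[l1 == c]) for c in l1.unique()}
    part2 = {frozenset(l2.index[l2 == c]) for c in l2.unique()}
    assert part1 == part2


# ---------------------------------------------------------------------------
# bacteroid differentiation
# ---------------------------------------------------------------------------

def test_identical_length_distributions_fold_one_undifferentiated():
    lengths = np.linspace(1.0, 2.0, 50)
    call = classify_bacteroid_differentiation(lengths, lengths)
    assert call.fold == pytest.approx(1.0)
    assert not call.differentiated


def test_fold_exactly_at_threshold_is_differentiated():
    cultured = np.full(20, 1.0)
    nodule = np.full(20, 2.5)
    call = classify_bacteroid_differentiation(nodule, cultured, threshold=2.5)
    assert call.differentiated


def test_too_few_lengths_rejected():
    with pytest.raises(PloidyError):
        classify_bacteroid_differentiation([1.0] * 5, [1.0] * 50)
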