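"""Generator contracts: determinism, planted structure, truth completeness."""

import numpy as np
import pandas as pd
import pytest

from nodulewaves import (
    build_ratio_matrix,
    simulate_bacteroid_lengths,
    simulate_mutant_panel,
    simulate_ploidy,
    simulate_qpcr,
    simulate_timecourse,
)
from nodulewaves.differentiation import PLOIDY_CLASSES, call_ploidy_fractions
from nodulewaves.qpcr import pfaffl_relative_expression
from nodulewaves.synthetic import (
    ARCHETYPE_ROOT,
    ARCHETYPE_WILD_TYPE,
    GeneratorConfig,
    GeneratorConfigError,
    simulate_annotations,
)
from conftest import small_config


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "overrides",
    [
        {"n_genes": 100, "n_de": 80, "n_invariant": 50},  # counts exceed n_genes
        {"noise_sd": -0.1},
        {"replicate_spots": 0},
        {"ploidy_mixtures": {"root": {2: 0.7, 4: 0.7}}},  # does not sum to 1
        {"profile_shapes": {1: (1, 0, 0), 2: (1, 0, 0)}},  # duplicate shapes
    ],
)
def test_invalid_config_rejected(overrides):
    with pytest.raises(GeneratorConfigError):
        GeneratorConfig(**{**dict(n_genes=100, n_de=10, n_invariant=50), **overrides}).validate()


def test_bad_qpcr_efficiency_rejected():
    cfg = small_config()
    cfg.qpcr.efficiencies["x"] = 2.5
    with pytest.raises(GeneratorConfigError):
        cfg.validate()


def test_unknown_mutant_archetype_rejected():
    cfg = small_config(mutant_archetypes={"mutX": "no_such_archetype"})
    with pytest.raises(GeneratorConfigError):
        simulate_mutant_panel(cfg, seed=1)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_timecourse_deterministic_and_seed_sensitive():
    cfg = small_config()
    t1, _ = simulate_timecourse(cfg, seed=1)
    t2, _ = simulate_timecourse(cfg, seed=1)
    t3, _ = simulate_timecourse(cfg, seed=2)
    a = next(iter(t1))
    pd.testing.assert_frame_equal(t1[a].data, t2[a].data)
    assert not t1[a].data["sample_intensity"].equals(t3[a].data["sample_intensity"])


def test_bacteroid_lengths_deterministic():
    cfg = small_config()
    x = simulate_bacteroid_lengths(cfg, "differentiated", n=50, seed=3)
    y = simulate_bacteroid_lengths(cfg, "differentiated", n=50, seed=3)
    np.testing.assert_array_equal(x, y)


def test_timecourse_and_panel_share_gene_roles():
    """Both generators describe the same probe set, so the planted gene
    labels must agree for a common seed."""
    cfg = small_config()
    _, tc_truth = simulate_timecourse(cfg, seed=5)
    _, panel_truth = simulate_mutant_panel(cfg, seed=5)
    de_tc = {g: tc_truth.profile_of(g) for g in tc_truth.de_genes()}
    de_panel = {g: panel_truth.profile_of(g) for g in panel_truth.de_genes()}
    assert de_tc == de_panel
    assert tc_truth.invariant_genes() == panel_truth.invariant_genes()


# ---------------------------------------------------------------------------
# planted structure
# ---------------------------------------------------------------------------

def test_truth_labels_complete():
    cfg = small_config()
    tables, truth = simulate_timecourse(cfg, seed=1)
    assert set(truth.gene_labels) == set(cfg.gene_ids())
    assert set(truth.sample_stages) == set(tables)


def test_zero_noise_de_means_equal_templates():
    cfg = small_config(noise_sd=0.0, array_scale_sd=0.0)
    tables, truth = simulate_timecourse(cfg, seed=1)
    raw = build_ratio_matrix(tables.values())
    templates = cfg.profile_templates()
    stage_of = truth.sample_stages
    stage_idx = {"roots": 0, "incipient": 1, "nodules": 2}
    log2 = np.log2(raw.ratios)
    for gene in truth.de_genes()[:20]:
        p = truth.profile_of(gene)
        for array_id in raw.array_ids:
            expected = templates[p][stage_idx[stage_of[array_id]]]
            assert log2.loc[gene, array_id] == pytest.approx(expected, abs=1e-9)


def test_mutant_archetype_expression_levels():
    """Wild-type-like genotypes put profile-7 genes at their nodule template
    level; the bacA-like archetype leaves them at the root level."""
    cfg = small_config(noise_sd=0.0, array_scale_sd=0.0,
                       mutant_archetypes={"wtlike": "fix_minus_differentiated",
                                          "bacalike": "bacteroid_blocked"})
    tables, truth = simulate_mutant_panel(cfg, seed=2, include_roots=False,
                                          include_wild_type=False)
    templates = cfg.profile_templates()
    p7 = [g for g in truth.de_genes() if truth.profile_of(g) == 7]
    raw = build_ratio_matrix(tables.values())
    log2 = np.log2(raw.ratios)
    wt_cols = [a for a in raw.array_ids if a.startswith("wtlike")]
    baca_cols = [a for a in raw.array_ids if a.startswith("bacalike")]
    for g in p7[:5]:
        assert log2.loc[g, wt_cols].mean() == pytest.approx(templates[7][2], abs=1e-9)
        assert log2.loc[g, baca_cols].mean() == pytest.approx(templates[7][0], abs=1e-9)
    # first-wave genes are at nodule levels in both archetypes
    p6 = [g for g in truth.de_genes() if truth.profile_of(g) == 6][:5]
    for g in p6:
        assert log2.loc[g, baca_cols].mean() == pytest.approx(templates[6][2], abs=1e-9)


# ---------------------------------------------------------------------------
# ploidy and bacteroid generators
# ---------------------------------------------------------------------------

def test_degenerate_ploidy_mixture_all_mass_in_2c():
    cfg = small_config(ploidy_mixtures={"pure": {2: 1.0}}, ploidy_cv=1e-9)
    hists, _ = simulate_ploidy(cfg, "pure", n_nuclei=500, seed=1)
    profile = call_ploidy_fractions(hists, anchor_2c=cfg.ploidy_anchor)
    assert profile.percentages[2] == pytest.approx(100.0)


def test_root_mixture_fraction_recovery():
    cfg = small_config()
    hists, truth = simulate_ploidy(cfg, ARCHETYPE_ROOT, n_nuclei=10000, seed=4)
    profile = call_ploidy_fractions(hists, anchor_2c=cfg.ploidy_anchor)
    planted = truth.ploidy_mixtures[ARCHETYPE_ROOT]
    for cls in PLOIDY_CLASSES:
        assert profile.percentages[cls] == pytest.approx(
            100 * planted.get(cls, 0.0), abs=2.0
        )


def test_ploidy_replicates_and_guards():
    cfg = small_config()
    hists, _ = simulate_ploidy(cfg, ARCHETYPE_WILD_TYPE, n_nuclei=200, seed=1)
    assert len(hists) == cfg.ploidy_replicates
    with pytest.raises(GeneratorConfigError):
        simulate_ploidy(cfg, "no_such_mixture", n_nuclei=200, seed=1)
    with pytest.raises(GeneratorConfigError):
        simulate_ploidy(cfg, ARCHETYPE_ROOT, n_nuclei=10, seed=1)


def test_cultured_lengths_within_support_and_fold_ratio():
    cfg = small_config()
    cultured = simulate_bacteroid_lengths(cfg, "cultured", n=1000, seed=1)
    assert (cultured >= 1.0).all() and (cultured <= 2.0).all()
    differentiated = simulate_bacteroid_lengths(cfg, "differentiated", n=1000, seed=2)
    ratio = differentiated.mean() / cultured.mean()
    assert 4.0 <= ratio <= 5.0


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------

def test_qpcr_planted_fold_8_gives_delta_cp_3():
    cfg = small_config()
    cfg.qpcr.folds = {"t": {"a": 1.0, "b": 8.0}}
    cfg.qpcr.cp_noise_sd = 0.0
    cfg.qpcr.input_shift_sd = 0.0
    ds, _ = simulate_qpcr(cfg, seed=1)
    cp = ds.cp.groupby(["transcript", "sample"])["cp"].mean()
    assert cp[("t", "a")] - cp[("t", "b")] == pytest.approx(3.0)


def test_qpcr_flat_folds_recovered_as_one():
    cfg = small_config()
    cfg.qpcr.folds = {"t": {"a": 1.0, "b": 1.0, "c": 1.0}}
    cfg.qpcr.cp_noise_sd = 0.0
    ds, _ = simulate_qpcr(cfg, seed=1)
    rel = pfaffl_relative_expression(ds, "t")
    assert np.allclose(rel.folds.to_numpy(), 1.0)


def test_qpcr_fold_recovery_with_noise():
    cfg = small_config()
    cfg.qpcr.folds = {"t": {"a": 1.0, "b": 4.0, "c": 16.0}}
    cfg.qpcr.cp_noise_sd = 0.1
    ds, truth = simulate_qpcr(cfg, seed=3)
    rel = pfaffl_relative_expression(ds, "t")
    for sample, fold in truth.qpcr_folds["t"].items():
        assert rel.folds[sample] == pytest.approx(fold, rel=0.15)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_annotations_cover_probe_set_with_wave_enrichment():
    cfg = small_config()
    _, truth = simulate_timecourse(cfg, seed=1)
    ann = simulate_annotations(cfg, truth, seed=1)
    assert set(cfg.gene_ids()) <= set(ann["gene_id"])
    wave = [g for g in truth.de_genes() if truth.profile_of(g) >= 5]
    rest = [g for g in cfg.gene_ids() if g not in set(wave)]
    sp = ann.set_index("gene_id")["signal_peptide"]
    assert sp.loc[wave].mean() > sp.loc[rest].mean()
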