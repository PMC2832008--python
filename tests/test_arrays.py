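"""Spot-table I/O, replicate collapse, invariant selection, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nodulewaves import (
    build_ratio_matrix,
    collapse_replicates,
    normalize_arrays,
    read_expression_matrix,
    read_spot_table,
    select_invariant_genes,
    simulate_timecourse,
    write_expression_matrix,
    write_spot_table,
)
from nodulewaves.arrays import (
    NormalizationError,
    ParseError,
    RatioMatrix,
    SpotTable,
    SpotTableError,
)
from nodulewaves.de import assign_stages
from conftest import small_config


def make_table(rows, array_id="a1"):
    df = pd.DataFrame(
        rows,
        columns=["spot_id", "gene_id", "replicate_index",
                 "sample_intensity", "reference_intensity"],
    )
    return SpotTable(array_id=array_id, data=df)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_spot_table_roundtrip(tmp_path):
    t = make_table([("s1", "g1", 0, 100.0, 50.0),
                    ("s2", "g2", 0, 10.0, 20.0),
                    ("s3", "g3", 0, 5.0, 5.0)])
    path = tmp_path / "wt__4dpi__r1.tsv"
    write_spot_table(t, path)
    back = read_spot_table(path)
    assert len(back.data) == 3
    assert back.genotype == "wt" and back.dpi == 4.0
    np.testing.assert_allclose(
        back.data["sample_intensity"], t.data["sample_intensity"]
    )


def test_anchor_replicate_count_is_preserved(tmp_path, small_cfg):
    tables, _ = simulate_timecourse(small_cfg, seed=1)
    table = next(iter(tables.values()))
    path = tmp_path / "x__0dpi__r1.tsv"
    write_spot_table(table, path)
    counts = read_spot_table(path).replicate_counts()
    assert counts[small_cfg.anchor_id] == 12


def test_parse_error_names_the_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "spot_id\tgene_id\treplicate_index\tsample_intensity\treference_intensity\n"
        "s1\tg1\t0\t10\t20\n"
        "s2\tg2\t0\toops\t20\n"
    )
    with pytest.raises(ParseError, match="line 3"):
        read_spot_table(path)


def test_negative_intensity_rejected(tmp_path):
    path = tmp_path / "neg.tsv"
    path.write_text(
        "spot_id\tgene_id\treplicate_index\tsample_intensity\treference_intensity\n"
        "s1\tg1\t0\t-5\t20\n"
    )
    with pytest.raises(SpotTableError):
        read_spot_table(path)


# ---------------------------------------------------------------------------
# replicate collapse
# ---------------------------------------------------------------------------

def test_collapse_single_spot_ratio():
    ratios, excluded = collapse_replicates(make_table([("s1", "g1", 0, 100.0, 50.0)]))
    assert ratios["g1"] == pytest.approx(2.0)
    assert excluded == []


def test_collapse_is_the_median_over_spots():
    t = make_table([("s1", "g1", 0, 10.0, 10.0),
                    ("s2", "g1", 1, 20.0, 10.0),
                    ("s3", "g1", 2, 90.0, 10.0)])
    ratios, _ = collapse_replicates(t)
    assert ratios["g1"] == pytest.approx(2.0)


def test_collapse_excludes_genes_without_usable_spots():
    t = make_table([("s1", "g1", 0, 0.0, 10.0), ("s2", "g2", 0, 10.0, 10.0)])
    ratios, excluded = collapse_replicates(t)
    assert excluded == ["g1"] and list(ratios.index) == ["g2"]


def test_anchor_collapse_recovers_planted_ratio():
    rng = np.random.default_rng(0)
    spots = [
        (f"s{i}", "anchor", i, 1.5 * r * np.exp2(rng.normal(0, 0.1)), r)
        for i, r in enumerate(rng.uniform(500, 2000, size=12))
    ]
    ratios, _ = collapse_replicates(make_table(spots))
    assert ratios["anchor"] == pytest.approx(1.5, rel=0.1)


# ---------------------------------------------------------------------------
# invariant selection
# ---------------------------------------------------------------------------

def _ratio_matrix(values: dict[str, list[float]]) -> RatioMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"a{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame({"array_id": df.columns, "genotype": "x", "dpi": 0.0}).set_index("array_id")
    return RatioMatrix(ratios=df, metadata=meta)


def test_all_proportional_genes_tie_break_lexicographic():
    rm = _ratio_matrix({"anchor": [1, 2, 4], "gB": [2, 4, 8], "gA": [3, 6, 12],
                        "gC": [0.5, 1, 2]})
    assert select_invariant_genes(rm, "anchor", 2) == ["gA", "gB"]


def test_planted_invariants_recovered_exactly():
    rng = np.random.default_rng(1)
    n_arrays = 8
    values = {"anchor": list(np.exp2(rng.normal(0, 1, n_arrays)))}
    anchor = np.log2(values["anchor"])
    for i in range(30):  # invariant: constant offset from the anchor
        values[f"inv{i:02d}"] = list(np.exp2(anchor + rng.normal(0, 0.3)))
    for i in range(70):  # variable: independent per-array noise
        values[f"var{i:02d}"] = list(np.exp2(anchor + rng.normal(0, 1.0, n_arrays)))
    rm = _ratio_matrix(values)
    selected = select_invariant_genes(rm, "anchor", 30)
    assert sorted(selected) == [f"inv{i:02d}" for i in range(30)]


def test_default_invariant_count_on_default_probe_set(small_cfg, small_timecourse):
    tables, _ = small_timecourse
    raw = build_ratio_matrix(tables.values())
    selected = select_invariant_genes(raw, small_cfg.anchor_id, small_cfg.n_invariant)
    assert len(selected) == small_cfg.n_invariant


def test_missing_anchor_is_a_hard_error():
    rm = _ratio_matrix({"g1": [1, 2], "g2": [2, 4]})
    with pytest.raises(NormalizationError):
        select_invariant_genes(rm, "anchor", 1)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalization_divides_by_invariant_median():
    rm = _ratio_matrix({"i1": [2.0], "i2": [2.0], "i3": [2.0], "g": [6.0]})
    expr = normalize_arrays(rm, ["i1", "i2", "i3"])
    assert expr.linear().loc["g"].iloc[0] == pytest.approx(3.0)
    assert expr.values.loc["g"].iloc[0] == pytest.approx(np.log2(3.0))


def test_invariant_median_identity_on_synthetic_arrays(small_cfg, small_expr):
    medians = small_expr.linear().loc[small_expr.invariant_genes].median(axis=0)
    np.testing.assert_allclose(medians, 1.0, atol=1e-9)


def test_zero_noise_normalized_values_reproduce_templates():
    cfg = small_config(noise_sd=0.0)
    tables, truth = simulate_timecourse(cfg, seed=3)
    raw = build_ratio_matrix(tables.values())
    invariant = select_invariant_genes(raw, cfg.anchor_id, cfg.n_invariant)
    assert sorted(invariant) == sorted(truth.invariant_genes())
    expr = normalize_arrays(raw, invariant)
    templates = cfg.profile_templates()
    stage_idx = {"roots": 0, "incipient": 1, "nodules": 2}
    for gene in truth.de_genes()[:15]:
        p = truth.profile_of(gene)
        for a in expr.values.columns:
            expected = templates[p][stage_idx[truth.sample_stages[a]]]
            assert expr.values.loc[gene, a] == pytest.approx(expected, abs=1e-9)


def test_normalization_idempotent(small_expr):
    lin = small_expr.linear()
    meta = small_expr.metadata
    again = normalize_arrays(
        RatioMatrix(ratios=lin, metadata=meta), small_expr.invariant_genes
    )
    np.testing.assert_allclose(again.scales.to_numpy(), 1.0, atol=1e-12)
    pd.testing.assert_frame_equal(again.values, small_expr.values)


@given(st.floats(min_value=0.01, max_value=100.0))
def test_normalization_scale_equivariance(c):
    rm = _ratio_matrix({"i1": [2.0, 1.0], "i2": [3.0, 1.5], "i3": [4.0, 2.0],
                        "g": [6.0, 1.0]})
    base = normalize_arrays(rm, ["i1", "i2", "i3"]).values
    scaled = rm.ratios.copy()
    scaled["a0"] = scaled["a0"] * c
    rescaled = normalize_arrays(
        RatioMatrix(ratios=scaled, metadata=rm.metadata), ["i1", "i2", "i3"]
    ).values
    np.testing.assert_allclose(rescaled.to_numpy(), base.to_numpy(), atol=1e-9)


def test_expression_matrix_roundtrip(tmp_path, small_expr):
    path = tmp_path / "expr.tsv"
    write_expression_matrix(small_expr, path)
    back = read_expression_matrix(path)
    pd.testing.assert_frame_equal(back.values, small_expr.values)
    assert back.invariant_genes == small_expr.invariant_genes
    assert assign_stages(back.metadata).stages == assign_stages(small_expr.metadata).stages
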