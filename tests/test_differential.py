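"""Contrast statistics, the expression filter and DEP-calling thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import isletshift as ish


def _two_group_matrix(values_a, values_b):
    """Matrix with one protein, groups S5 (linear 2**a) and ISLET (2**b)."""
    data = {}
    rows = []
    for i, v in enumerate(values_a, 1):
        data[f"S5_{i}"] = [2.0**v]
        rows.append({"sample_id": f"S5_{i}", "condition": "S5", "replicate": i})
    for i, v in enumerate(values_b, 1):
        data[f"ISLET_{i}"] = [2.0**v]
        rows.append({"sample_id": f"ISLET_{i}", "condition": "ISLET", "replicate": i})
    matrix = ish.AbundanceMatrix(pd.DataFrame(data, index=["P1"]))
    annotation = ish.SampleAnnotation(pd.DataFrame(rows))
    return matrix, annotation


def test_contrast_matches_hand_computed_pooled_t():
    # log2 groups {1.0, 1.2} vs {0.1, 0.3}: diff 0.9, pooled sd 0.1*sqrt(2),
    # t = 0.9 / (0.141421 * 1) = 6.3640, p (2 df) = 0.023813 (frozen oracle)
    matrix, annotation = _two_group_matrix([1.0, 1.2], [0.1, 0.3])
    row = ish.compute_contrast(matrix, annotation, "S5", "ISLET").iloc[0]
    assert row["log2_fc"] == pytest.approx(0.9, abs=1e-12)
    assert row["p_value"] == pytest.approx(0.023812939816047204, abs=1e-12)
    assert (row["n_a"], row["n_b"]) == (2, 2)


def test_contrast_degenerate_variance_conventions():
    # identical constant groups: no evidence of change
    matrix, annotation = _two_group_matrix([1.0, 1.0], [1.0, 1.0])
    row = ish.compute_contrast(matrix, annotation, "S5", "ISLET").iloc[0]
    assert row["log2_fc"] == 0.0 and row["p_value"] == 1.0
    # constant but different: the infinite-t limit
    matrix, annotation = _two_group_matrix([3.0, 3.0], [1.0, 1.0])
    row = ish.compute_contrast(matrix, annotation, "S5", "ISLET").iloc[0]
    assert row["log2_fc"] == 2.0 and row["p_value"] == 0.0


def test_contrast_single_observation_gives_undefined_p():
    data = pd.DataFrame(
        {"S5_1": [2.0], "S5_2": [np.nan], "ISLET_1": [1.0], "ISLET_2": [1.2]},
        index=["P1"],
    )
    ann = ish.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["S5_1", "S5_2", "ISLET_1", "ISLET_2"],
                "condition": ["S5", "S5", "ISLET", "ISLET"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )
    row = ish.compute_contrast(ish.AbundanceMatrix(data), ann, "S5", "ISLET").iloc[0]
    assert row["n_a"] == 1 and np.isnan(row["p_value"])
    assert np.isfinite(row["log2_fc"])  # means still use the available value


def test_t_and_p_match_scipy_on_random_groups():
    """Vectorised pooled-variance test == scipy.stats.ttest_ind, 1000 draws."""
    rng = np.random.default_rng(11)
    n = 1000
    sizes = rng.integers(2, 6, size=(n, 2))
    rows, anns = {}, []
    max_a, max_b = sizes[:, 0].max(), sizes[:, 1].max()
    a_vals = rng.normal(0, 1, (n, max_a))
    b_vals = rng.normal(0.3, 1.2, (n, max_b))
    for j in range(max_a):
        rows[f"S5_{j+1}"] = np.where(j < sizes[:, 0], np.exp2(a_vals[:, j]), np.nan)
        anns.append({"sample_id": f"S5_{j+1}", "condition": "S5", "replicate": j + 1})
    for j in range(max_b):
        rows[f"ISLET_{j+1}"] = np.where(j < sizes[:, 1], np.exp2(b_vals[:, j]), np.nan)
        anns.append({"sample_id": f"ISLET_{j+1}", "condition": "ISLET", "replicate": j + 1})
    matrix = ish.AbundanceMatrix(
        pd.DataFrame(rows, index=[f"P{i}" for i in range(n)])
    )
    annotation = ish.SampleAnnotation(pd.DataFrame(anns))
    table = ish.compute_contrast(matrix, annotation, "S5", "ISLET")
    for i in range(n):
        a = a_vals[i, : sizes[i, 0]]
        b = b_vals[i, : sizes[i, 1]]
        expected = stats.ttest_ind(a, b, equal_var=True)
        assert table["p_value"].iloc[i] == pytest.approx(expected.pvalue, abs=1e-9)
        assert table["log2_fc"].iloc[i] == pytest.approx(a.mean() - b.mean(), abs=1e-9)


def test_contrast_antisymmetry(tiny_matrix, tiny_annotation):
    ab = ish.compute_contrast(tiny_matrix, tiny_annotation, "S5", "ISLET")
    ba = ish.compute_contrast(tiny_matrix, tiny_annotation, "ISLET", "S5")
    np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-12)
    np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_contrast_scale_invariance(scale):
    rng = np.random.default_rng(5)
    base = pd.DataFrame(
        np.exp2(rng.normal(0, 1, (8, 4))),
        index=[f"P{i}" for i in range(8)],
        columns=["S5_1", "S5_2", "ISLET_1", "ISLET_2"],
    )
    ann = ish.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": base.columns,
                "condition": ["S5", "S5", "ISLET", "ISLET"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )
    raw = ish.compute_contrast(ish.AbundanceMatrix(base), ann, "S5", "ISLET")
    scaled = ish.compute_contrast(ish.AbundanceMatrix(base * scale), ann, "S5", "ISLET")
    np.testing.assert_allclose(raw["log2_fc"], scaled["log2_fc"], atol=1e-9)
    np.testing.assert_allclose(raw["p_value"], scaled["p_value"], atol=1e-9)


def test_filter_expressed_rules(study_design_annotation):
    ann = study_design_annotation
    cols = ann.sample_ids
    data = pd.DataFrame(1.0, index=["full", "islet_gone", "one_each"], columns=cols)
    data.loc["islet_gone", ["ISLET_1", "ISLET_2", "ISLET_3"]] = np.nan
    data.loc["one_each"] = np.nan
    for cond in ("S5", "S7", "S5_bead", "S7_bead", "ISLET"):
        data.loc["one_each", f"{cond}_1"] = 2.0
    kept = ish.filter_expressed(ish.AbundanceMatrix(data), ann)
    assert kept == ["full", "one_each"]


def test_filter_expressed_requires_matching_annotation(tiny_matrix):
    ann = ish.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["x1", "x2"],
                "condition": ["S5", "S5"],
                "replicate": [1, 2],
            }
        )
    )
    with pytest.raises(ish.ConsistencyError):
        ish.filter_expressed(tiny_matrix, ann)


def test_call_deps_thresholds_inclusive():
    contrasts = pd.DataFrame(
        {
            "protein_id": ["at_both_bounds", "fc_too_small", "p_undefined", "down"],
            "mean_log2_a": [0.0] * 4,
            "mean_log2_b": [0.0] * 4,
            "log2_fc": [np.log2(1.5), 0.5, 2.0, -1.0],
            "p_value": [0.05, 0.001, np.nan, 0.01],
            "n_a": [2] * 4,
            "n_b": [2] * 4,
        }
    )
    deps = ish.call_deps(contrasts, fc_threshold=1.5, p_threshold=0.05)
    assert list(deps["protein_id"]) == ["at_both_bounds", "down"]
    assert list(deps["direction"]) == ["up", "down"]
    strict = ish.call_deps(contrasts, strict_p=True)
    assert list(strict["protein_id"]) == ["down"]


def test_call_deps_threshold_monotonicity():
    rng = np.random.default_rng(3)
    contrasts = pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(300)],
            "mean_log2_a": 0.0,
            "mean_log2_b": 0.0,
            "log2_fc": rng.normal(0, 1, 300),
            "p_value": rng.uniform(0, 1, 300),
            "n_a": 2,
            "n_b": 3,
        }
    )
    base = set(ish.call_deps(contrasts, 1.5, 0.05)["protein_id"])
    assert base <= set(ish.call_deps(contrasts, 1.2, 0.05)["protein_id"])
    assert base <= set(ish.call_deps(contrasts, 1.5, 0.20)["protein_id"])
    assert set(ish.call_deps(contrasts, 2.0, 0.01)["protein_id"]) <= base


def test_null_study_dep_count_below_p_only_count():
    """FC + p jointly are stricter than p alone on a pure-null study."""
    cfg = ish.SimulationConfig(
        n_proteins=1000, class_proportions={"null": 1.0}, noise_sd_log2=0.4, seed=9
    )
    matrix, annotation, _ = ish.generate_study(cfg)
    contrasts = ish.compute_contrast(matrix, annotation, "S5", "ISLET")
    p_only = int((contrasts["p_value"] <= 0.05).sum())
    joint = len(ish.call_deps(contrasts))
    assert joint < p_only
    assert joint <= 0.05 * len(contrasts) * 1.5 + 5
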