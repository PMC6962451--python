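"""Effect taxonomy, regulation-call rules and summary tallies."""

import numpy as np
import pandas as pd
import pytest

import isletshift as ish
from conftest import run_classification_chain

LOG2_15 = np.log2(1.5)


def _contrast_frame(pairs):
    """Minimal contrast table: protein_id -> log2_fc (vs ISLET), p = 0.01."""
    return pd.DataFrame(
        {
            "protein_id": list(pairs),
            "mean_log2_a": [v for v in pairs.values()],
            "mean_log2_b": 0.0,
            "log2_fc": list(pairs.values()),
            "p_value": 0.01,
            "n_a": 2,
            "n_b": 3,
        }
    )


def _deps_for(contrast):
    return ish.call_deps(contrast)


def test_canonical_effects_taxonomy():
    effects = ish.canonical_effects()
    assert len(effects) == 4
    by_name = {e.name: e for e in effects}
    assert by_name["differentiation_cocktail"].baseline_condition == "S5"
    assert by_name["differentiation_cocktail"].effect_condition == "S7"
    assert by_name["early_encapsulation"].effect_condition == "S5_bead"
    # late encapsulation is assessed on the S7-vs-islet DEP list
    assert by_name["late_encapsulation"].baseline_condition == "S7"
    # confounding and late encapsulation share the effect condition, not the baseline
    assert by_name["confounding"].effect_condition == "S7_bead"
    assert by_name["late_encapsulation"].effect_condition == "S7_bead"
    assert by_name["confounding"].baseline_condition == "S5"


@pytest.mark.parametrize(
    "baseline, effect_level, category, subtype, reaches",
    [
        (2.0, 0.8, "islet_promoting", "from_up", False),
        (-1.0, -2.0, "islet_antagonizing", "from_down", False),
        (1.0, 0.9, "unchanged", "from_up", False),
        (1.0, 0.2, "islet_promoting", "from_up", True),
        (-2.0, -0.3, "islet_promoting", "from_down", True),
        (1.0, 2.1, "islet_antagonizing", "from_up", False),
    ],
)
def test_classification_rules(baseline, effect_level, category, subtype, reaches):
    base = _contrast_frame({"P1": baseline})
    eff = _contrast_frame({"P1": effect_level})
    effect = ish.effect_by_name("early_encapsulation")
    calls = ish.classify_effect(_deps_for(base), base, eff, effect)
    row = calls.iloc[0]
    assert row["category"] == category
    assert row["subtype"] == subtype
    assert bool(row["reaches_islet"]) is reaches
    assert row["delta_log2"] == pytest.approx(effect_level - baseline)


def test_overshoot_flagged_but_still_promoting():
    base = _contrast_frame({"P1": 2.0})
    eff = _contrast_frame({"P1": -0.9})  # crossed the islet level by > 1.5-fold
    calls = ish.classify_effect(
        _deps_for(base), base, eff, ish.effect_by_name("confounding")
    )
    assert calls.iloc[0]["category"] == "islet_promoting"
    assert bool(calls.iloc[0]["overshoot"]) is True
    assert not calls.iloc[0]["reaches_islet"]


def test_reaches_islet_level_boundaries():
    assert ish.reaches_islet_level(0.0) is True
    # boundary: attainment is the strict complement of the DEP fold criterion
    assert ish.reaches_islet_level(LOG2_15) is False
    assert ish.reaches_islet_level(-LOG2_15) is False
    assert ish.reaches_islet_level(0.2, require_nonsignificance=True, p_value=0.001) is False
    assert ish.reaches_islet_level(0.2, require_nonsignificance=True, p_value=0.4) is True
    assert ish.reaches_islet_level(0.2, require_nonsignificance=True) is True  # undefined p


def test_unquantified_effect_proteins_dropped_with_count():
    base = _contrast_frame({"P1": 2.0, "P2": -1.5})
    eff = _contrast_frame({"P1": 0.5})  # P2 missing from the effect contrast
    calls = ish.classify_effect(
        _deps_for(base), base, eff, ish.effect_by_name("early_encapsulation")
    )
    assert list(calls["protein_id"]) == ["P1"]
    assert calls.attrs["n_dropped"] == 1


def test_dep_missing_from_baseline_contrast_is_inconsistent():
    base = _contrast_frame({"P1": 2.0})
    deps = pd.DataFrame(
        {
            "protein_id": ["P1", "P_ghost"],
            "direction": ["up", "up"],
            "baseline_log2_fc": [2.0, 2.0],
            "baseline_p": [0.01, 0.01],
        }
    )
    with pytest.raises(ish.ConsistencyError, match="P_ghost"):
        ish.classify_effect(deps, base, base, ish.effect_by_name("confounding"))


def test_category_partition_and_summary_counts():
    rng = np.random.default_rng(7)
    base = _contrast_frame(
        {f"P{i}": s for i, s in enumerate(rng.uniform(1.0, 3.0, 50) * rng.choice([-1, 1], 50))}
    )
    eff = _contrast_frame(
        {f"P{i}": s for i, s in enumerate(rng.uniform(-3.0, 3.0, 50))}
    )
    effect = ish.effect_by_name("late_encapsulation")
    calls = ish.classify_effect(_deps_for(base), base, eff, effect)
    summary = ish.summarize_effect(calls)
    assert summary.n_promoting + summary.n_antagonizing + summary.n_unchanged == summary.n_deps
    assert summary.n_deps == len(calls)
    assert set(calls["category"]) <= {"islet_promoting", "islet_antagonizing", "unchanged"}


def test_summary_fraction_example():
    calls = pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(10)],
            "effect": "confounding",
            "category": ["islet_promoting"] * 6 + ["islet_antagonizing"] * 3 + ["unchanged"],
            "subtype": ["from_up"] * 5 + ["from_down"] * 5,
            "baseline_log2_vs_islet": 1.0,
            "effect_log2_vs_islet": 0.0,
            "delta_log2": -1.0,
            "reaches_islet": [True] * 4 + [False] * 6,
            "overshoot": False,
        }
    )
    s = ish.summarize_effect(calls)
    assert (s.n_deps, s.n_promoting, s.n_antagonizing, s.n_unchanged) == (10, 6, 3, 1)
    assert s.fraction_promoting_from_up == pytest.approx(5 / 6)
    assert s.fraction_reaching_islet_of_deps == pytest.approx(0.4)


def test_summary_empty_and_mixed_effects():
    empty = ish.summarize_effect(pd.DataFrame(columns=["effect", "category", "subtype",
                                                       "reaches_islet", "protein_id"]))
    assert empty.n_deps == 0 and empty.fraction_promoting_from_up == 0.0
    mixed = pd.DataFrame(
        {
            "protein_id": ["P1", "P2"],
            "effect": ["confounding", "early_encapsulation"],
            "category": ["unchanged", "unchanged"],
            "subtype": ["from_up", "from_up"],
            "reaches_islet": [False, False],
        }
    )
    with pytest.raises(ish.ConsistencyError):
        ish.summarize_effect(mixed)


def test_mirror_symmetry_swaps_subtypes_preserves_categories():
    """Inverting all abundances (x -> 1/x) flips from_up/from_down only."""
    cfg = ish.SimulationConfig(n_proteins=250, noise_sd_log2=0.1, seed=21)
    matrix, annotation, _ = ish.generate_study(cfg)
    inverted = ish.AbundanceMatrix(1.0 / matrix.data)
    _, _, _, calls = run_classification_chain(matrix, annotation)
    _, _, _, calls_inv = run_classification_chain(inverted, annotation)
    for name in calls:
        a = calls[name].set_index("protein_id")
        b = calls_inv[name].set_index("protein_id")
        assert set(a.index) == set(b.index)
        b = b.loc[a.index]
        assert (a["category"] == b["category"]).all()
        assert (a["reaches_islet"] == b["reaches_islet"]).all()
        swapped = b["subtype"].map({"from_up": "from_down", "from_down": "from_up"})
        assert (a["subtype"] == swapped).all()


def test_movement_threshold_monotonicity():
    """Raising fc_threshold never turns an unchanged call into a moved one."""
    cfg = ish.SimulationConfig(n_proteins=200, noise_sd_log2=0.15, seed=13)
    matrix, annotation, _ = ish.generate_study(cfg)
    _, _, _, low = run_classification_chain(matrix, annotation, fc_threshold=1.5)
    _, _, _, high = run_classification_chain(matrix, annotation, fc_threshold=2.0)
    for name in low:
        a = low[name].set_index("protein_id")["category"]
        b = high[name].set_index("protein_id")["category"]
        shared = a.index.intersection(b.index)
        became_moved = (a.loc[shared] == "unchanged") & (b.loc[shared] != "unchanged")
        assert not became_moved.any()
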