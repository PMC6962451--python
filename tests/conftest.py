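"""Shared fixtures: tiny hand-built tables and the analysis-chain helper."""

import numpy as np
import pandas as pd
import pytest

import isletshift as ish

CATEGORY_TO_TRUTH = {
    "islet_promoting": "promoting",
    "islet_antagonizing": "antagonizing",
    "unchanged": "unchanged",
}


@pytest.fixture
def tiny_matrix() -> ish.AbundanceMatrix:
    data = pd.DataFrame(
        {
            "S5_1": [2.0, 4.0, 1.0],
            "S5_2": [2.2, 4.1, 1.1],
            "ISLET_1": [1.0, 8.0, 1.0],
            "ISLET_2": [1.1, 8.2, 1.05],
        },
        index=["P1", "P2", "P3"],
    )
    return ish.AbundanceMatrix(data)


@pytest.fixture
def tiny_annotation() -> ish.SampleAnnotation:
    return ish.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["S5_1", "S5_2", "ISLET_1", "ISLET_2"],
                "condition": ["S5", "S5", "ISLET", "ISLET"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def study_design_annotation() -> ish.SampleAnnotation:
    """The five-group design with replicate counts (2, 2, 2, 2, 3)."""
    rows = []
    for cond, reps in (("S5", 2), ("S7", 2), ("S5_bead", 2), ("S7_bead", 2), ("ISLET", 3)):
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"{cond}_{r}", "condition": cond, "replicate": r})
    return ish.SampleAnnotation(pd.DataFrame(rows))


def run_classification_chain(matrix, annotation, fc_threshold=1.5, p_threshold=0.05):
    """Universe filter -> contrasts -> DEPs -> all four effect classifications."""
    universe = ish.filter_expressed(matrix, annotation)
    sub = ish.AbundanceMatrix(matrix.data.loc[universe])
    contrasts = {
        cond: ish.compute_contrast(sub, annotation, cond, "ISLET")
        for cond in ("S5", "S7", "S5_bead", "S7_bead")
    }
    deps = {
        b: ish.call_deps(contrasts[b], fc_threshold, p_threshold) for b in ("S5", "S7")
    }
    calls = {}
    for effect in ish.canonical_effects():
        calls[effect.name] = ish.classify_effect(
            deps[effect.baseline_condition],
            contrasts[effect.baseline_condition],
            contrasts[effect.effect_condition],
            effect,
            fc_threshold=fc_threshold,
        )
    return universe, contrasts, deps, calls


def recall_precision(calls: pd.DataFrame, truth: ish.SyntheticTruth, effect: str):
    """Per-class recall and precision of one effect's calls vs planted truth."""
    pred = calls.set_index("protein_id")["category"].map(CATEGORY_TO_TRUTH)
    true = truth.response_labels(effect)
    out = {}
    for cls in ("promoting", "antagonizing", "unchanged"):
        n_true = int((true == cls).sum())
        n_pred = int((pred == cls).sum())
        tp = int(((pred == cls) & (true.reindex(pred.index) == cls)).sum())
        out[cls] = (
            tp / n_true if n_true else 1.0,
            tp / n_pred if n_pred else 1.0,
        )
    return out
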