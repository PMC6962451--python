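"""Reference-anchored classification of DEP responses to the four effects.

Every comparison is anchored to the native-islet reference: a baseline
contrast (S5 or S7 vs ISLET) defines the DEP set and each protein's starting
deviation from islet abundance, and an effect contrast (the effect condition
vs ISLET) gives its deviation after the effect. The per-protein movement

    delta_log2 = effect_log2_vs_islet - baseline_log2_vs_islet

is compared against the same fold threshold used for DEP calling:

* |delta| >= log2(fc_threshold) moving toward the islet level (sign of delta
  opposite to the baseline deviation)  →  ``islet_promoting``;
* |delta| >= log2(fc_threshold) moving away                  →  ``islet_antagonizing``;
* otherwise                                                   →  ``unchanged``.

The four canonical effects and their condition pairs:

=======================  ========  ================
effect                   baseline  effect condition
=======================  ========  ================
differentiation_cocktail   S5        S7
early_encapsulation        S5        S5_bead
confounding                S5        S7_bead
late_encapsulation         S7        S7_bead
=======================  ========  ================

A DEP additionally *reaches the islet level* under an effect when its
effect-condition deviation sits strictly inside the fold band,
|effect_log2_vs_islet| < log2(fc_threshold) — the complement of the DEP fold
criterion. A promoting protein that lands >= fc_threshold-fold on the far
side of the islet level stays promoting but is flagged ``overshoot``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError, VocabularyError

logger = logging.getLogger(__name__)

CATEGORIES = ("islet_promoting", "islet_antagonizing", "unchanged")
EFFECT_NAMES = (
    "differentiation_cocktail",
    "early_encapsulation",
    "confounding",
    "late_encapsulation",
)

CALL_COLUMNS = [
    "protein_id", "effect", "category", "subtype",
    "baseline_log2_vs_islet", "effect_log2_vs_islet", "delta_log2",
    "reaches_islet", "overshoot",
]


@dataclass(frozen=True)
class EffectDefinition:
    """One of the four condition comparisons assessed on a baseline DEP set."""

    name: str
    baseline_condition: str
    effect_condition: str

    def __post_init__(self):
        if self.name not in EFFECT_NAMES:
            raise VocabularyError(f"unknown effect {self.name!r}")


_CANONICAL = (
    EffectDefinition("differentiation_cocktail", "S5", "S7"),
    EffectDefinition("early_encapsulation", "S5", "S5_bead"),
    EffectDefinition("confounding", "S5", "S7_bead"),
    EffectDefinition("late_encapsulation", "S7", "S7_bead"),
)


def canonical_effects() -> tuple[EffectDefinition, ...]:
    """The four canonical effects; baselines S5 except late_encapsulation (S7)."""
    return _CANONICAL


def effect_by_name(name: str) -> EffectDefinition:
    for e in _CANONICAL:
        if e.name == name:
            return e
    raise VocabularyError(f"unknown effect {name!r}; expected one of {EFFECT_NAMES}")


def reaches_islet_level(
    log2_fc_vs_islet: float,
    fc_threshold: float = 1.5,
    require_nonsignificance: bool = False,
    p_value: float = float("nan"),
    p_threshold: float = 0.05,
) -> bool:
    """Whether an effect-condition abundance is islet-indistinguishable.

    True iff |log2 FC vs islet| < log2(fc_threshold) (strict: attainment is
    the complement of the DEP fold criterion). With ``require_nonsignificance``
    the t-test against islets must additionally not reach significance
    (p > p_threshold, or undefined).
    """
    band = np.log2(fc_threshold)
    if not abs(log2_fc_vs_islet) < band:
        return False
    if require_nonsignificance:
        return bool(np.isnan(p_value) or p_value > p_threshold)
    return True


def classify_effect(
    deps: pd.DataFrame,
    baseline_contrast: pd.DataFrame,
    effect_contrast: pd.DataFrame,
    effect: EffectDefinition,
    fc_threshold: float = 1.5,
    require_nonsignificance: bool = False,
    p_threshold: float = 0.05,
    movement_contrast: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every baseline DEP's response to one effect.

    ``deps`` must come from ``baseline_contrast`` (baseline condition vs
    ISLET); ``effect_contrast`` is the effect condition vs ISLET. DEPs absent
    or unquantified in the effect contrast are dropped with a logged count
    (available as ``result.attrs['n_dropped']``), never imputed.

    The movement criterion is fold-change only, mirroring the single stated
    threshold; passing ``movement_contrast`` (effect condition vs baseline
    condition) additionally requires that contrast's p <= p_threshold for a
    protein to count as moved.
    """
    if fc_threshold < 1:
        raise ValidationError(f"fc_threshold must be >= 1, got {fc_threshold}")
    band = np.log2(fc_threshold)

    base = baseline_contrast.set_index("protein_id")
    missing = set(deps["protein_id"]) - set(base.index)
    if missing:
        raise ConsistencyError(
            f"DEPs absent from baseline contrast: {sorted(missing)[:5]}"
        )
    eff = effect_contrast.set_index("protein_id")

    proteins = deps["protein_id"].to_numpy()
    eff_index = set(eff.index)
    in_effect = np.array([p in eff_index for p in proteins], dtype=bool)
    eff_fc = np.full(len(proteins), np.nan)
    eff_p = np.full(len(proteins), np.nan)
    if in_effect.any():
        found = eff.loc[proteins[in_effect]]
        eff_fc[in_effect] = found["log2_fc"].to_numpy(dtype=float)
        eff_p[in_effect] = found["p_value"].to_numpy(dtype=float)
    quantified = in_effect & ~np.isnan(eff_fc)
    n_dropped = int((~quantified).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d DEP(s) unquantified in effect condition %s",
            effect.name, n_dropped, effect.effect_condition,
        )

    proteins = proteins[quantified]
    base_fc = base.loc[proteins, "log2_fc"].to_numpy(dtype=float)
    eff_fc = eff_fc[quantified]
    eff_p = eff_p[quantified]

    delta = eff_fc - base_fc
    moved = np.abs(delta) >= band
    if movement_contrast is not None:
        mv = movement_contrast.set_index("protein_id")
        mv_p = np.array(
            [mv.loc[p, "p_value"] if p in mv.index else np.nan for p in proteins],
            dtype=float,
        )
        moved &= ~np.isnan(mv_p) & (mv_p <= p_threshold)
    toward = np.sign(delta) == -np.sign(base_fc)
    category = np.where(
        moved & toward, "islet_promoting",
        np.where(moved & ~toward, "islet_antagonizing", "unchanged"),
    )
    subtype = np.where(base_fc > 0, "from_up", "from_down")
    reaches = np.abs(eff_fc) < band
    if require_nonsignificance:
        reaches &= np.isnan(eff_p) | (eff_p > p_threshold)
    overshoot = (
        (category == "islet_promoting")
        & (np.sign(eff_fc) == -np.sign(base_fc))
        & (np.abs(eff_fc) >= band)
    )

    out = pd.DataFrame(
        {
            "protein_id": proteins,
            "effect": effect.name,
            "category": category,
            "subtype": subtype,
            "baseline_log2_vs_islet": base_fc,
            "effect_log2_vs_islet": eff_fc,
            "delta_log2": delta,
            "reaches_islet": reaches,
            "overshoot": overshoot,
        }
    )
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass(frozen=True)
class EffectSummary:
    """Tallies of one effect's regulation calls, with both attainment denominators."""

    effect_name: str
    n_deps: int
    n_promoting: int
    n_promoting_from_up: int
    n_promoting_from_down: int
    n_antagonizing: int
    n_unchanged: int
    n_reaching_islet: int
    n_reaching_islet_promoting: int
    fraction_promoting_from_up: float
    fraction_reaching_islet_of_deps: float
    fraction_reaching_islet_of_promoting: float

    def __post_init__(self):
        if self.n_promoting + self.n_antagonizing + self.n_unchanged != self.n_deps:
            raise ValidationError("category tallies must sum to n_deps")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_effect(calls: pd.DataFrame) -> EffectSummary:
    """Exact tallies of one effect's calls (all rows must share the effect)."""
    if len(calls) == 0:
        return EffectSummary("", 0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0)
    names = calls["effect"].unique()
    if len(names) > 1:
        raise ConsistencyError(f"mixed effects in one summary: {sorted(names)}")
    promoting = calls["category"] == "islet_promoting"
    n_promoting = int(promoting.sum())
    n_from_up = int((promoting & (calls["subtype"] == "from_up")).sum())
    n_deps = len(calls)
    n_reach = int(calls["reaches_islet"].sum())
    n_reach_promoting = int((promoting & calls["reaches_islet"]).sum())
    return EffectSummary(
        effect_name=str(names[0]),
        n_deps=n_deps,
        n_promoting=n_promoting,
        n_promoting_from_up=n_from_up,
        n_promoting_from_down=n_promoting - n_from_up,
        n_antagonizing=int((calls["category"] == "islet_antagonizing").sum()),
        n_unchanged=int((calls["category"] == "unchanged").sum()),
        n_reaching_islet=n_reach,
        n_reaching_islet_promoting=n_reach_promoting,
        fraction_promoting_from_up=(n_from_up / n_promoting) if n_promoting else 0.0,
        fraction_reaching_islet_of_deps=(n_reach / n_deps) if n_deps else 0.0,
        fraction_reaching_islet_of_promoting=(
            n_reach_promoting / n_promoting if n_promoting else 0.0
        ),
    )
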