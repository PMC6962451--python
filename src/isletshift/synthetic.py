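"""Synthetic abundance studies with planted, fully known regulation classes.

The generator emulates the five-group encapsulated-differentiation design
(S5, S7, S5_bead, S7_bead and the native-islet reference, default replicate
counts 2, 2, 2, 2, 3) on a log-normal observation model: each protein has a
true log2 mean per condition and observations are that mean plus Gaussian
noise in log2 space, exponentiated to the linear scale.

Planting works in islet-centred log2 coordinates (y = condition mean - islet
mean, so the islet reference sits at y = 0):

* a baseline class (null / dep_up / dep_down) places the S5 mean at 0 or at
  +-offset, with offsets drawn beyond the fold threshold by a safety margin;
* a response class per effect (promoting / antagonizing / unchanged) places
  each effect condition's mean relative to its baseline, again with margins,
  so the planted label — not the classifier — carries identifiability;
* because S7_bead is shared by the confounding effect (baseline S5) and the
  late-encapsulation effect (baseline S7), those two responses are drawn
  jointly from the feasible combinations (interval intersection), and the
  S7-vs-islet DEP universe is derived from the planted cocktail response
  with an explicit exclusion gap around the fold threshold so universe
  membership is itself robust to replicate noise.

The emitted truth table records every planted class, the attainment flag
(|y_effect| < log2 fold threshold), the overshoot flag and the true means,
and is the oracle for all recovery tests. Generation is driven by a single
integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CONDITIONS, AbundanceMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

LOG2_15 = float(np.log2(1.5))

BASELINE_CLASSES = ("null", "dep_up", "dep_down")
RESPONSE_CLASSES = ("promoting", "antagonizing", "unchanged")

_DEFAULT_REPLICATES = {"S5": 2, "S7": 2, "S5_bead": 2, "S7_bead": 2, "ISLET": 3}
_DEFAULT_CLASS_PROPORTIONS = {"null": 0.30, "dep_up": 0.35, "dep_down": 0.35}
# Encapsulation-containing effects plant more promoting responses than the
# differentiation cocktail, mirroring the observed direction of the design.
_DEFAULT_RESPONSE_PROPORTIONS = {
    "differentiation_cocktail": {"promoting": 0.25, "antagonizing": 0.45, "unchanged": 0.30},
    "early_encapsulation": {"promoting": 0.45, "antagonizing": 0.25, "unchanged": 0.30},
    "confounding": {"promoting": 0.45, "antagonizing": 0.25, "unchanged": 0.30},
    "late_encapsulation": {"promoting": 0.45, "antagonizing": 0.25, "unchanged": 0.30},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study. All abundance units are log2."""

    n_proteins: int = 5000
    replicates: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICATES)
    )
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROPORTIONS)
    )
    response_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_RESPONSE_PROPORTIONS.items()}
    )
    baseline_islet_log2_mean: float = 0.0
    baseline_islet_log2_sd: float = 2.0
    dep_log2_offset_range: tuple[float, float] = (LOG2_15 + 0.5, LOG2_15 + 1.5)
    effect_shift_log2_range: tuple[float, float] = (LOG2_15 + 0.5, LOG2_15 + 1.5)
    attainment_given_promoting: float = 0.25  # cocktail effect only
    stay_margin_log2: float = 0.3     # unchanged responses stay this far inside the band
    attain_margin_log2: float = 0.3   # exclusion gap around the band for planted zones
    overshoot_span_log2: float = 1.3  # how far past the islet level overshoots may land
    noise_sd_log2: float = 0.15
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        for cond in CONDITIONS:
            if cond not in self.replicates:
                raise ConfigurationError(f"replicates missing condition {cond!r}")
            if self.replicates[cond] < 2:
                raise ConfigurationError(
                    f"condition {cond!r} needs >= 2 replicates for the t-test"
                )
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        if set(self.class_proportions) - set(BASELINE_CLASSES):
            raise ConfigurationError(
                f"class labels must be among {BASELINE_CLASSES}"
            )
        for effect, props in self.response_proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"response_proportions[{effect!r}] must sum to 1"
                )
        for name in ("dep_log2_offset_range", "effect_shift_log2_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} bounds must be ordered")
            if lo <= LOG2_15:
                raise ConfigurationError(f"{name} lower bound must exceed log2(1.5)")
        if not 0 <= self.attainment_given_promoting <= 1:
            raise ConfigurationError("attainment_given_promoting must be in [0,1]")
        if not 0 <= self.attain_margin_log2 < LOG2_15:
            raise ConfigurationError(
                "attain_margin_log2 must be in [0, log2 1.5): the attainment band "
                "is otherwise incompatible with the planted offsets"
            )
        if not 0 <= self.stay_margin_log2 < LOG2_15:
            raise ConfigurationError("stay_margin_log2 must be in [0, log2 1.5)")
        if self.dep_log2_offset_range[0] - LOG2_15 <= self.stay_margin_log2:
            raise ConfigurationError(
                "dep offsets too close to the fold band for unchanged responses: "
                "need dep_log2_offset_range[0] > log2(1.5) + stay_margin_log2"
            )
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: one row per protein.

    Columns: baseline_class (S5 vs islet), s7_baseline_class (derived S7 vs
    islet universe), mu_islet_log2, the centred true offsets y_<condition>,
    and per effect response_/attain_/overshoot_<effect> (NA where the protein
    is not in that effect's baseline DEP universe).
    """

    table: pd.DataFrame

    def baseline_dep_ids(self, baseline: str = "S5") -> set[str]:
        col = "baseline_class" if baseline == "S5" else "s7_baseline_class"
        sel = self.table[col].isin(["dep_up", "dep_down"])
        return set(self.table.loc[sel, "protein_id"])

    def response_labels(self, effect: str) -> pd.Series:
        sel = self.table[f"response_{effect}"].notna()
        return self.table.loc[sel].set_index("protein_id")[f"response_{effect}"]


class MissingnessInjection(NamedTuple):
    matrix: AbundanceMatrix
    log: pd.DataFrame  # uniform: protein_id, sample_id; knockout: protein_id, condition


# ---------------------------------------------------------------------------
# Interval machinery (islet-centred log2 coordinates)
# ---------------------------------------------------------------------------


def _mirror(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    return [(-hi, -lo) for lo, hi in intervals]


def _intersect(a: list[tuple[float, float]], b: list[tuple[float, float]]):
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if lo <= hi:
                out.append((lo, hi))
    return out


def _draw(intervals: list[tuple[float, float]], rng: np.random.Generator) -> float:
    lengths = np.array([hi - lo for lo, hi in intervals])
    total = lengths.sum()
    if total == 0:
        return intervals[0][0]
    k = rng.choice(len(intervals), p=lengths / total)
    return float(rng.uniform(*intervals[k]))


def _class_intervals(
    b: float, response: str, cfg: SimulationConfig, band: float
) -> list[tuple[float, float]]:
    """Admissible effect-condition positions y for one response class.

    ``b`` is the baseline position (|b| > band by construction). Promoting
    positions span from just short of the minimum planted shift down through
    the islet level and past it by the overshoot span; antagonizing positions
    move further from the islet by a shift drawn from the configured range;
    unchanged positions stay within the band minus the stay margin on both
    the movement and the baseline's own distance to the band.
    """
    move_min = cfg.effect_shift_log2_range[0]
    shift_lo, shift_hi = cfg.effect_shift_log2_range
    far = band + cfg.attain_margin_log2 + cfg.overshoot_span_log2
    if response == "promoting":
        ivals = [(-far, b - move_min)]
    elif response == "antagonizing":
        ivals = [(b + shift_lo, b + shift_hi)]
    elif response == "unchanged":
        stay = min(band, abs(b) - band) - cfg.stay_margin_log2
        if stay < 0:
            return []
        ivals = [(b - stay, b + stay)]
    else:
        raise ValidationError(f"unknown response class {response!r}")
    if b < 0:
        # rules above are written for an upregulated baseline; mirror otherwise
        ivals_pos = _class_intervals(-b, response, cfg, band)
        return _mirror(ivals_pos)
    return [iv for iv in ivals if iv[0] <= iv[1]]


def _cocktail_intervals(
    b: float, response: str, attained: bool, cfg: SimulationConfig, band: float
) -> list[tuple[float, float]]:
    """Cocktail positions with an exclusion gap around the band.

    The S7-vs-islet DEP universe is derived from these positions, so they
    must keep a margin on *both* sides of the fold band: attained promoting
    responses land within band - attain_margin of the islet level, everything
    else at least band + attain_margin away.
    """
    base = _class_intervals(b, response, cfg, band)
    gap = cfg.attain_margin_log2
    inner = [(-(band - gap), band - gap)]
    outer = [(-np.inf, -(band + gap)), (band + gap, np.inf)]
    zone = inner if (response == "promoting" and attained) else outer
    return _intersect(base, zone)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def _sample_class(rng: np.random.Generator, proportions: Mapping[str, float]) -> str:
    labels = list(proportions.keys())
    return labels[rng.choice(len(labels), p=np.array(list(proportions.values())))]


def generate_study(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate one synthetic study with its ground-truth label table.

    Identical configs (including seed) produce bit-identical output. Every
    protein keeps at least one observation per condition even under
    ``missing_rate`` > 0, so the expression-universe filter is exercised
    separately via :func:`inject_missingness`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    band = LOG2_15
    n = cfg.n_proteins

    protein_ids = [f"P{i:05d}" for i in range(n)]
    mu_islet = rng.normal(cfg.baseline_islet_log2_mean, cfg.baseline_islet_log2_sd, n)

    rows = []
    y = {cond: np.zeros(n) for cond in ("S5", "S7", "S5_bead", "S7_bead")}
    props = cfg.response_proportions
    for i in range(n):
        base_cls = _sample_class(rng, cfg.class_proportions)
        record = {
            "protein_id": protein_ids[i],
            "baseline_class": base_cls,
            "s7_baseline_class": "null",
            "mu_islet_log2": mu_islet[i],
        }
        for eff in props:
            record[f"response_{eff}"] = pd.NA
            record[f"attain_{eff}"] = pd.NA
            record[f"overshoot_{eff}"] = pd.NA
        if base_cls == "null":
            rows.append(record)
            continue

        sign = 1.0 if base_cls == "dep_up" else -1.0
        b5 = sign * rng.uniform(*cfg.dep_log2_offset_range)
        y["S5"][i] = b5

        # --- differentiation cocktail (S5 -> S7), with universe exclusion gap
        c1 = _sample_class(rng, props["differentiation_cocktail"])
        attained1 = c1 == "promoting" and rng.random() < cfg.attainment_given_promoting
        ivals = _cocktail_intervals(b5, c1, attained1, cfg, band)
        if not ivals:  # fall back to the feasible attainment branch
            attained1 = not attained1 if c1 == "promoting" else attained1
            ivals = _cocktail_intervals(b5, c1, attained1, cfg, band)
        if not ivals:
            raise ConfigurationError(
                "infeasible config: no admissible cocktail position for "
                f"baseline {b5:.3f}, response {c1!r}"
            )
        x7 = _draw(ivals, rng)
        y["S7"][i] = x7
        record["response_differentiation_cocktail"] = c1
        record["attain_differentiation_cocktail"] = bool(abs(x7) < band)
        record["overshoot_differentiation_cocktail"] = bool(
            c1 == "promoting" and np.sign(x7) == -np.sign(b5) and abs(x7) >= band
        )

        # --- early encapsulation (S5 -> S5_bead), unconstrained otherwise
        c2 = _sample_class(rng, props["early_encapsulation"])
        x5b = _draw(_class_intervals(b5, c2, cfg, band), rng)
        y["S5_bead"][i] = x5b
        record["response_early_encapsulation"] = c2
        record["attain_early_encapsulation"] = bool(abs(x5b) < band)
        record["overshoot_early_encapsulation"] = bool(
            c2 == "promoting" and np.sign(x5b) == -np.sign(b5) and abs(x5b) >= band
        )

        # --- confounding (S5 -> S7_bead) and late encapsulation (S7 -> S7_bead)
        # share the S7_bead mean; draw the feasible pair jointly.
        s7_dep = abs(x7) >= band
        record["s7_baseline_class"] = (
            "null" if not s7_dep else ("dep_up" if x7 > 0 else "dep_down")
        )
        if s7_dep:
            combos, weights = [], []
            for late_cls, w_late in props["late_encapsulation"].items():
                late_ivals = _class_intervals(x7, late_cls, cfg, band)
                for conf_cls, w_conf in props["confounding"].items():
                    joint = _intersect(
                        _class_intervals(b5, conf_cls, cfg, band), late_ivals
                    )
                    if joint:
                        combos.append((late_cls, conf_cls, joint))
                        weights.append(w_late * w_conf)
            if not combos:
                raise ConfigurationError(
                    "infeasible config: no joint confounding/late-encapsulation "
                    f"position for baselines {b5:.3f} (S5) and {x7:.3f} (S7)"
                )
            weights = np.array(weights)
            if weights.sum() == 0:
                weights = np.ones(len(combos))
            pick = combos[rng.choice(len(combos), p=weights / weights.sum())]
            late_cls, conf_cls, joint = pick
            x7b = _draw(joint, rng)
            record["response_late_encapsulation"] = late_cls
            record["attain_late_encapsulation"] = bool(abs(x7b) < band)
            record["overshoot_late_encapsulation"] = bool(
                late_cls == "promoting"
                and np.sign(x7b) == -np.sign(x7)
                and abs(x7b) >= band
            )
        else:
            conf_cls = _sample_class(rng, props["confounding"])
            x7b = _draw(_class_intervals(b5, conf_cls, cfg, band), rng)
        y["S7_bead"][i] = x7b
        record["response_confounding"] = conf_cls
        record["attain_confounding"] = bool(abs(x7b) < band)
        record["overshoot_confounding"] = bool(
            conf_cls == "promoting" and np.sign(x7b) == -np.sign(b5) and abs(x7b) >= band
        )
        rows.append(record)

    truth_table = pd.DataFrame(rows)
    for cond in ("S5", "S7", "S5_bead", "S7_bead"):
        truth_table[f"y_{cond}"] = y[cond]

    # observations: true log2 mean + noise, exponentiated to the linear scale
    columns, data, ann_rows = [], [], []
    for cond in CONDITIONS:
        reps = cfg.replicates[cond]
        offset = np.zeros(n) if cond == "ISLET" else y[cond]
        for r in range(1, reps + 1):
            noise = (
                rng.normal(0.0, cfg.noise_sd_log2, n)
                if cfg.noise_sd_log2 > 0
                else np.zeros(n)
            )
            data.append(np.exp2(mu_islet + offset + noise))
            columns.append(f"{cond}_{r}")
            ann_rows.append({"sample_id": f"{cond}_{r}", "condition": cond, "replicate": r})

    frame = pd.DataFrame(np.column_stack(data), index=protein_ids, columns=columns)
    frame.index.name = "protein_id"

    if cfg.missing_rate > 0:
        mask = rng.random(frame.shape) < cfg.missing_rate
        # guarantee >= 1 observation per protein per condition
        col_idx = {c: k for k, c in enumerate(columns)}
        for cond in CONDITIONS:
            cols = [col_idx[f"{cond}_{r}"] for r in range(1, cfg.replicates[cond] + 1)]
            block = mask[:, cols]
            all_gone = block.all(axis=1)
            for row in np.flatnonzero(all_gone):
                keep = cols[rng.integers(len(cols))]
                mask[row, keep] = False
        frame = frame.mask(mask)

    matrix = AbundanceMatrix(frame)
    annotation = SampleAnnotation(pd.DataFrame(ann_rows))
    return matrix, annotation, SyntheticTruth(truth_table)


def inject_missingness(
    matrix: AbundanceMatrix,
    rate: float,
    mode: str = "uniform",
    seed: int = 0,
    annotation: SampleAnnotation | None = None,
) -> MissingnessInjection:
    """Introduce missing values into an abundance matrix.

    ``uniform`` drops cells independently at ``rate``. ``condition_knockout``
    removes *all* values of one randomly chosen condition for a ``rate``
    fraction of proteins (requires ``annotation``), creating proteins the
    expression-universe filter must exclude; the returned log records exactly
    which protein/condition pairs were knocked out.
    """
    if not 0 <= rate < 1:
        raise ValidationError(f"rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    frame = matrix.data.copy()
    if mode == "uniform":
        mask = rng.random(frame.shape) < rate
        frame = frame.mask(mask)
        where = np.argwhere(mask)
        log = pd.DataFrame(
            {
                "protein_id": [frame.index[i] for i, _ in where],
                "sample_id": [frame.columns[j] for _, j in where],
            }
        )
        return MissingnessInjection(AbundanceMatrix(frame), log)
    if mode == "condition_knockout":
        if annotation is None:
            raise ValidationError("condition_knockout mode needs an annotation")
        annotation.check_covers(matrix)
        conditions = annotation.conditions_present
        chosen = rng.random(len(frame)) < rate
        picks = rng.integers(len(conditions), size=len(frame))
        records = []
        for i in np.flatnonzero(chosen):
            cond = conditions[picks[i]]
            cols = [s for s in annotation.samples_for(cond) if s in frame.columns]
            frame.iloc[i, [frame.columns.get_loc(c) for c in cols]] = np.nan
            records.append({"protein_id": frame.index[i], "condition": cond})
        log = pd.DataFrame(records, columns=["protein_id", "condition"])
        return MissingnessInjection(AbundanceMatrix(frame), log)
    raise ValidationError(f"unknown mode {mode!r}; use 'uniform' or 'condition_knockout'")


def gradient_config(**overrides) -> SimulationConfig:
    """Convenience config for the planted proximity gradient (see below)."""
    return replace(SimulationConfig(), **overrides)


def generate_gradient_study(
    n_proteins: int = 400,
    shift_fractions: Mapping[str, float] | None = None,
    offset_log2_range: tuple[float, float] = (1.0, 2.5),
    baseline_islet_log2_mean: float = 0.0,
    baseline_islet_log2_sd: float = 2.0,
    noise_sd_log2: float = 0.05,
    replicates: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[AbundanceMatrix, SampleAnnotation, dict[str, float]]:
    """Study with a planted toward-islet gradient across conditions.

    Every protein deviates from the islet level in S5 by a random signed
    offset; each other condition retains ``1 - shift_fraction`` of that
    deviation. Larger fractions therefore sit closer to the islet centroid,
    emulating a design where encapsulated conditions converge on the
    reference (default order S7_bead > S5_bead > S7 > S5 = 0). Returns the
    matrix, annotation and the fraction map (the planted truth).
    """
    fractions = dict(shift_fractions or {"S7": 0.15, "S5_bead": 0.55, "S7_bead": 0.8})
    fractions.setdefault("S5", 0.0)
    reps = dict(replicates or _DEFAULT_REPLICATES)
    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]
    mu_islet = rng.normal(baseline_islet_log2_mean, baseline_islet_log2_sd, n_proteins)
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    offsets = signs * rng.uniform(*offset_log2_range, n_proteins)
    columns, data, ann_rows = [], [], []
    for cond in CONDITIONS:
        dev = np.zeros(n_proteins) if cond == "ISLET" else (1.0 - fractions[cond]) * offsets
        for r in range(1, reps[cond] + 1):
            noise = rng.normal(0.0, noise_sd_log2, n_proteins) if noise_sd_log2 > 0 else 0.0
            data.append(np.exp2(mu_islet + dev + noise))
            columns.append(f"{cond}_{r}")
            ann_rows.append({"sample_id": f"{cond}_{r}", "condition": cond, "replicate": r})
    frame = pd.DataFrame(np.column_stack(data), index=protein_ids, columns=columns)
    frame.index.name = "protein_id"
    return (
        AbundanceMatrix(frame),
        SampleAnnotation(pd.DataFrame(ann_rows)),
        fractions,
    )
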