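"""End-to-end run orchestration and the assembled summary report.

``run_full_pipeline`` executes the reference-anchored workflow:

    universe filter → baseline contrasts (S5 and S7 vs ISLET) → DEP calls →
    per-effect classification → summaries → Venn partition of the promoting
    sets → sample clustering and condition proximity → optional enrichment
    and concordance

writing every intermediate table plus a JSON manifest (inputs, thresholds,
version, seed, row counts per stage). Any stage failure aborts with the
stage name; partial outputs are flagged in the manifest. Every number in the
rendered report is recomputed from the emitted tables — there is no
report-only arithmetic.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import (
    condition_proximity_to_reference,
    sample_distance_matrix,
    ward_linkage,
)
from .differential import call_deps, compute_contrast, filter_expressed
from .effects import (
    EffectSummary,
    canonical_effects,
    classify_effect,
    summarize_effect,
)
from .errors import ConfigurationError, PipelineError, ReportingError
from .io import (
    REFERENCE_CONDITION,
    AbundanceMatrix,
    SampleAnnotation,
    read_abundance_matrix,
    read_results,
    read_sample_annotation,
    write_results,
)
from .sets import direction_concordance, enrichment_test, read_gmt, venn_partition

logger = logging.getLogger(__name__)

_ALL_EFFECTS = tuple(e.name for e in canonical_effects())


@dataclass(frozen=True)
class RunConfig:
    """Inputs, thresholds and options of one pipeline run."""

    matrix_path: str
    annotation_path: str
    out_dir: str
    gmt_path: str | None = None
    external_contrast_path: str | None = None
    concordance_conditions: tuple[str, str] = ("S7_bead", "S7")
    concordance_min_abs_log2_fc: float = 0.0
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    strict_p: bool = False
    fdr: bool = False
    require_nonsignificance: bool = False
    effects: tuple[str, ...] = _ALL_EFFECTS
    transform: str = "log2"
    centering: str = "none"
    missing_token: str = "NA"
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.fc_threshold:
            raise ConfigurationError("fc_threshold must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ConfigurationError("p_threshold must be in (0, 1]")
        unknown = set(self.effects) - set(_ALL_EFFECTS)
        if unknown:
            raise ConfigurationError(f"unknown effect(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        for key in ("effects", "concordance_conditions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    config: RunConfig
    universe: list[str]
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)  # cond vs ISLET
    deps: dict[str, pd.DataFrame] = field(default_factory=dict)  # per baseline
    calls: dict[str, pd.DataFrame] = field(default_factory=dict)  # per effect
    summaries: dict[str, EffectSummary] = field(default_factory=dict)
    venn: dict | None = None
    proximity: list[tuple[str, float]] | None = None
    tree: object | None = None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    concordance: dict | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return decorate


def run_full_pipeline(
    config: RunConfig,
    matrix: AbundanceMatrix | None = None,
    annotation: SampleAnnotation | None = None,
) -> PipelineResult:
    """Run the whole anchored workflow and write all outputs to out_dir.

    ``matrix``/``annotation`` may be passed in-memory (e.g. straight from the
    generator); otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "matrix": str(config.matrix_path),
            "annotation": str(config.annotation_path),
            "gmt": config.gmt_path,
            "external_contrast": config.external_contrast_path,
        },
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "strict_p": config.strict_p,
            "fdr": config.fdr,
            "require_nonsignificance": config.require_nonsignificance,
        },
        "effects": list(config.effects),
        "stages": {},
        "complete": False,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }

    @_stage("read_inputs")
    def read_inputs():
        m = matrix if matrix is not None else read_abundance_matrix(
            config.matrix_path, config.missing_token
        )
        a = annotation if annotation is not None else read_sample_annotation(
            config.annotation_path
        )
        a.check_covers(m)
        if REFERENCE_CONDITION not in a.conditions_present:
            raise ConfigurationError(
                f"reference condition {REFERENCE_CONDITION!r} missing: "
                "anchored analysis impossible"
            )
        return m, a

    mat, ann = read_inputs()
    manifest["stages"]["read_inputs"] = {
        "n_proteins": len(mat.protein_ids),
        "n_samples": len(mat.sample_ids),
    }

    result = PipelineResult(config=config, universe=[])

    @_stage("universe_filter")
    def universe_filter():
        universe = filter_expressed(mat, ann)
        sub = AbundanceMatrix(mat.data.loc[universe])
        write_results(
            pd.DataFrame({"protein_id": universe}), out / "universe.tsv", "tsv"
        )
        return universe, sub

    result.universe, mat_u = universe_filter()
    manifest["stages"]["universe_filter"] = {"n_universe": len(result.universe)}

    effects = [e for e in canonical_effects() if e.name in config.effects]
    needed_conditions = sorted(
        {e.baseline_condition for e in effects} | {e.effect_condition for e in effects}
    )

    @_stage("contrasts")
    def contrasts():
        tables = {}
        for cond in needed_conditions:
            tables[cond] = compute_contrast(mat_u, ann, cond, REFERENCE_CONDITION)
            write_results(tables[cond], out / f"contrast_{cond}_vs_ISLET.tsv", "tsv")
        return tables

    result.contrasts = contrasts()
    manifest["stages"]["contrasts"] = {c: len(t) for c, t in result.contrasts.items()}

    @_stage("dep_calling")
    def dep_calling():
        tables = {}
        for baseline in sorted({e.baseline_condition for e in effects}):
            tables[baseline] = call_deps(
                result.contrasts[baseline],
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
                strict_p=config.strict_p,
                fdr=config.fdr,
            )
            write_results(tables[baseline], out / f"deps_{baseline}_vs_ISLET.tsv", "tsv")
        return tables

    result.deps = dep_calling()
    manifest["stages"]["dep_calling"] = {b: len(t) for b, t in result.deps.items()}

    @_stage("effect_classification")
    def effect_classification():
        calls, summaries, dropped = {}, {}, {}
        for effect in effects:
            table = classify_effect(
                result.deps[effect.baseline_condition],
                result.contrasts[effect.baseline_condition],
                result.contrasts[effect.effect_condition],
                effect,
                fc_threshold=config.fc_threshold,
                require_nonsignificance=config.require_nonsignificance,
                p_threshold=config.p_threshold,
            )
            calls[effect.name] = table
            summaries[effect.name] = summarize_effect(table)
            dropped[effect.name] = table.attrs.get("n_dropped", 0)
            write_results(table, out / f"calls_{effect.name}.tsv", "tsv")
        summary_frame = pd.DataFrame([s.to_dict() for s in summaries.values()])
        write_results(summary_frame, out / "summary_effects.tsv", "tsv")
        write_results(summary_frame, out / "summary_effects.json", "json")
        return calls, summaries, dropped

    result.calls, result.summaries, dropped = effect_classification()
    manifest["stages"]["effect_classification"] = {
        name: {"n_calls": len(result.calls[name]), "n_dropped": dropped[name]}
        for name in result.calls
    }

    if len(result.calls) >= 2:

        @_stage("venn")
        def venn():
            promoting = {
                name: set(
                    table.loc[table["category"] == "islet_promoting", "protein_id"]
                )
                for name, table in result.calls.items()
            }
            part = venn_partition(promoting)
            payload = part.to_json_dict()
            with open(out / "venn_promoting.json", "w") as fh:
                json.dump(payload, fh, indent=1)
                fh.write("\n")
            return payload

        result.venn = venn()
        manifest["stages"]["venn"] = {
            "n_regions": len(result.venn["regions"]),
            "n_union": sum(r["size"] for r in result.venn["regions"]),
        }

    @_stage("clustering")
    def clustering():
        distances = sample_distance_matrix(
            mat_u, transform=config.transform, centering=config.centering
        )
        tree = ward_linkage(distances)
        tree.save_json(out / "sample_tree.json")
        (out / "sample_tree.newick").write_text(tree.to_newick() + "\n")
        proximity = condition_proximity_to_reference(distances, ann, REFERENCE_CONDITION)
        write_results(
            pd.DataFrame(proximity, columns=["condition", "sq_distance_to_islet_centroid"]),
            out / "condition_proximity.tsv",
            "tsv",
        )
        return tree, proximity

    result.tree, result.proximity = clustering()
    manifest["stages"]["clustering"] = {
        "n_leaves": result.tree.n_leaves,
        "proximity_order": [c for c, _ in result.proximity],
    }

    if config.gmt_path:

        @_stage("enrichment")
        def enrichment():
            sets = read_gmt(config.gmt_path)
            universe = set(result.universe)
            tables = {}
            for name, table in result.calls.items():
                query = set(
                    table.loc[table["category"] == "islet_promoting", "protein_id"]
                ) & universe
                tables[name] = enrichment_test(query, universe, sets)
                write_results(tables[name], out / f"enrichment_{name}.tsv", "tsv")
            return tables

        result.enrichment = enrichment()
        manifest["stages"]["enrichment"] = {
            n: len(t) for n, t in result.enrichment.items()
        }

    if config.external_contrast_path:

        @_stage("concordance")
        def concordance():
            external = read_results(config.external_contrast_path)
            cond_a, cond_b = config.concordance_conditions
            internal = compute_contrast(mat_u, ann, cond_a, cond_b)
            record = direction_concordance(
                internal, external, config.concordance_min_abs_log2_fc
            ).to_dict()
            with open(out / "concordance.json", "w") as fh:
                json.dump(record, fh, indent=1)
                fh.write("\n")
            return record

        result.concordance = concordance()
        manifest["stages"]["concordance"] = result.concordance

    manifest["complete"] = True
    result.manifest = manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")

    report = render_summary_report(result)
    (out / "report.md").write_text(report)
    return result


def render_summary_report(result: PipelineResult) -> str:
    """Markdown per-effect summary with percentages recomputed from counts."""
    if result.summaries is None or result.universe is None:
        raise ReportingError("bundle incomplete: missing summaries or universe")
    missing = [e for e in result.config.effects if e not in result.summaries]
    if missing:
        raise ReportingError(f"bundle incomplete: no summary for {missing}")

    def pct(part: int, whole: int) -> str:
        return f"{100.0 * part / whole:.1f}%" if whole else "-"

    lines = [
        "# Reference-anchored proteome classification report",
        "",
        f"Protein universe (expressed in every condition): {len(result.universe)}",
        "",
        "| effect | DEPs | promoting (from up / from down) | antagonizing | "
        "unchanged | reaching islet level |",
        "|---|---|---|---|---|---|",
    ]
    for name, s in result.summaries.items():
        lines.append(
            f"| {name} | {s.n_deps} | "
            f"{s.n_promoting} ({pct(s.n_promoting_from_up, s.n_promoting)} / "
            f"{pct(s.n_promoting_from_down, s.n_promoting)}) | "
            f"{s.n_antagonizing} ({pct(s.n_antagonizing, s.n_deps)} of DEPs) | "
            f"{s.n_unchanged} ({pct(s.n_unchanged, s.n_deps)} of DEPs) | "
            f"{s.n_reaching_islet} ({pct(s.n_reaching_islet, s.n_deps)} of DEPs, "
            f"{pct(s.n_reaching_islet_promoting, s.n_promoting)} of promoting) |"
        )
    if result.venn is not None:
        lines += ["", "## Promoting-set overlap (exclusive Venn regions)", ""]
        for region in result.venn["regions"]:
            shares = ", ".join(
                f"{100.0 * v:.1f}% of {k}" for k, v in region["shares"].items()
            )
            lines.append(f"- {region['label']}: {region['size']} ({shares})")
    if result.proximity is not None:
        lines += ["", "## Condition proximity to the islet centroid", ""]
        for cond, dist in result.proximity:
            lines.append(f"- {cond}: {dist:.4g}")
    if result.concordance is not None:
        c = result.concordance
        lines += [
            "",
            "## Direction concordance with the external contrast",
            "",
            f"- shared ids: {c['n_shared']}, concordant: {c['n_concordant']}, "
            f"fraction: {c['fraction'] if c['fraction'] is not None else 'NA'}",
        ]
    return "\n".join(lines) + "\n"
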