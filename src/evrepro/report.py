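"""Pipeline orchestration: run every analysis stage on one cell line's
tables and assemble a machine- and human-readable report bundle.

The bundle mirrors a full replicate-variability work-up: occupancy classes,
per-triad Venn partitions, qualitative (count) and quantitative (abundance)
RSDs under the technical and biological groupings, the most-abundant-protein
set, repeated-measures ANOVA at Bonferroni-corrected thresholds, and the
power / accumulation-curve replicate-sufficiency estimates.

The ``numbering`` convention decides which label triads are treated as
technical: with ``tr_triads_same_lysate`` the consecutive triads
({R1,R2,R3}, ...) share a lysate; with ``br_triads_same_lysate`` the strided
triads do, and the two schemes swap membership.  ``calibrate`` compares all
four (numbering x interpretation) combinations against user-supplied
reference RSDs for whoever holds the original tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import inferential, plots, qualitative, quantitative
from .io_design import (
    AbundanceTable,
    Flavor,
    GroupingScheme,
    Numbering,
    ReplicateDesign,
    Scheme,
    build_design,
    derive_grouping,
    read_abundance_table,
    write_results,
    _jsonable,
)
from .qualitative import Interpretation
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger("evrepro")

__all__ = [
    "RunConfig",
    "ReportBundle",
    "PipelineError",
    "run_pipeline",
    "rsd_gap",
    "calibrate",
    "paired_groupings",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the stages already done."""

    def __init__(self, stage: str, completed: Sequence[str], cause: BaseException):
        super().__init__(
            f"pipeline stage {stage!r} failed after completing "
            f"{list(completed)}: {cause}"
        )
        self.stage = stage
        self.completed = list(completed)
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of (``lfq_path`` + ``apex_path``) or ``synthetic`` must be
    provided.  ``alpha`` is the family-wise level before Bonferroni
    correction; the power search runs at ``power_alpha`` (the corrected
    3-group threshold by default).
    """

    lfq_path: str | Path | None = None
    apex_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    numbering: Numbering = Numbering.TR_TRIADS_SAME_LYSATE
    interpretation: Interpretation = Interpretation.WITHIN_GROUP_MEAN
    presence_threshold: float = 0.0
    abundance_cutoff: float = quantitative.DEFAULT_ABUNDANCE_CUTOFF
    alpha: float = 0.05
    power_alpha: float = 0.016
    power_target: float = 0.8
    n_target: int | None = None  # default: 2x the observed replicate count
    accumulation_model: inferential.AccumulationModel = (
        inferential.AccumulationModel.MICHAELIS_MENTEN
    )
    log_transform_anova: bool = False
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "numbering", Numbering(self.numbering))
        object.__setattr__(self, "interpretation", Interpretation(self.interpretation))
        object.__setattr__(
            self,
            "accumulation_model",
            inferential.AccumulationModel(self.accumulation_model),
        )
        has_files = self.lfq_path is not None and self.apex_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of (lfq_path + apex_path) or synthetic must be set"
            )

    def to_dict(self) -> dict:
        d = {
            "lfq_path": str(self.lfq_path) if self.lfq_path else None,
            "apex_path": str(self.apex_path) if self.apex_path else None,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "numbering": self.numbering.value,
            "interpretation": self.interpretation.value,
            "presence_threshold": self.presence_threshold,
            "abundance_cutoff": self.abundance_cutoff,
            "alpha": self.alpha,
            "power_alpha": self.power_alpha,
            "power_target": self.power_target,
            "n_target": self.n_target,
            "accumulation_model": self.accumulation_model.value,
            "log_transform_anova": self.log_transform_anova,
            "seed": self.seed,
        }
        return d


@dataclass(frozen=True)
class ReportBundle:
    """Every result of one run plus the configuration that produced it."""

    config: RunConfig
    design: ReplicateDesign
    occupancy: qualitative.OccupancyProfile
    venn_tr: qualitative.VennPartition
    venn_br: qualitative.VennPartition
    count_rsd_tr: qualitative.RSDResult
    count_rsd_br: qualitative.RSDResult
    abundance_rsd_tr: qualitative.RSDResult
    abundance_rsd_br: qualitative.RSDResult
    qualitative_gap: float
    quantitative_gap: float
    top_abundant: quantitative.TopAbundantSet
    anova_tr: inferential.AnovaResult
    anova_br: inferential.AnovaResult
    anova_all: inferential.AnovaResult
    alpha_groups: float
    alpha_replicates: float
    power: inferential.PowerResult
    fold: inferential.FoldIncreaseEstimate

    def summary(self) -> dict[str, Any]:
        """Nested, JSON-ready view of every reported number."""
        return _jsonable(
            {
                "config": self.config.to_dict(),
                "occupancy": self.occupancy.to_dict(),
                "venn": {"TR": self.venn_tr.to_dict(), "BR": self.venn_br.to_dict()},
                "rsd": {
                    "qualitative": {
                        "TR": self.count_rsd_tr.to_dict(),
                        "BR": self.count_rsd_br.to_dict(),
                        "br_minus_tr": self.qualitative_gap,
                    },
                    "quantitative": {
                        "TR": self.abundance_rsd_tr.to_dict(),
                        "BR": self.abundance_rsd_br.to_dict(),
                        "br_minus_tr": self.quantitative_gap,
                    },
                },
                "top_abundant": {
                    "cutoff": self.top_abundant.cutoff,
                    "n_proteins": len(self.top_abundant),
                },
                "anova": {
                    "TR": self.anova_tr.to_dict(),
                    "BR": self.anova_br.to_dict(),
                    "all_replicates": self.anova_all.to_dict(),
                    "alpha_groups": self.alpha_groups,
                    "alpha_replicates": self.alpha_replicates,
                },
                "power": self.power.to_dict(),
                "fold_increase": self.fold.to_dict(),
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True, allow_nan=False)

    def to_markdown(self) -> str:
        """Human-readable digest; every number is rendered from the JSON
        summary so the two views can never disagree."""
        s = self.summary()
        occ = s["occupancy"]
        rq, ra = s["rsd"]["qualitative"], s["rsd"]["quantitative"]
        lines = [
            "# Replicate variability report",
            "",
            f"Replicates: {occ['n_replicates']} | numbering: {s['config']['numbering']}"
            f" | RSD interpretation: {s['config']['interpretation']}",
            "",
            "## Occupancy",
            f"- total proteins: {occ['n_total']}",
            f"- in all replicates: {occ['n_all']}",
            f"- intermediate: {occ['n_intermediate']}",
            f"- singletons: {occ['n_singleton']}",
            "",
            "## RSD (%)",
            f"- qualitative TR: {rq['TR']['scheme_rsd_percent']}",
            f"- qualitative BR: {rq['BR']['scheme_rsd_percent']}",
            f"- qualitative BR-TR gap: {rq['br_minus_tr']}",
            f"- quantitative TR: {ra['TR']['scheme_rsd_percent']}",
            f"- quantitative BR: {ra['BR']['scheme_rsd_percent']}",
            f"- quantitative BR-TR gap: {ra['br_minus_tr']}",
            "",
            "## Most abundant proteins",
            f"- cutoff: {s['top_abundant']['cutoff']}",
            f"- proteins at/above cutoff: {s['top_abundant']['n_proteins']}",
            "",
            "## Repeated-measures ANOVA",
        ]
        for key in ("TR", "BR", "all_replicates"):
            a = s["anova"][key]
            lines.append(
                f"- {key}: F = {a['f_value']}, p = {a['p_value']}, "
                f"df = ({a['df_between']}, {a['df_error']}), subjects = {a['n_subjects']}"
            )
        lines += [
            f"- group threshold (Bonferroni): {s['anova']['alpha_groups']}",
            f"- per-replicate threshold (Bonferroni): {s['anova']['alpha_replicates']}",
            "",
            "## Replicate sufficiency",
            f"- Cohen's f: {s['power']['effect_size_f']}",
            f"- replicates required (power {s['power']['power_target']}, "
            f"alpha {s['power']['alpha']}): {s['power']['n_required']}",
            f"- achieved power: {s['power']['achieved_power']}",
            f"- fold increase at n = {s['fold_increase']['n_target']}: "
            f"{s['fold_increase']['fold_increase']}",
            "",
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path, figures: bool = True) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["summary_json"] = outdir / "summary.json"
        paths["summary_json"].write_text(self.to_json() + "\n")
        paths["summary_md"] = outdir / "summary.md"
        paths["summary_md"].write_text(self.to_markdown())
        for name, rec in {
            "occupancy": self.occupancy,
            "rsd_qualitative_tr": self.count_rsd_tr,
            "rsd_qualitative_br": self.count_rsd_br,
            "rsd_quantitative_tr": self.abundance_rsd_tr,
            "rsd_quantitative_br": self.abundance_rsd_br,
            "top_abundant": self.top_abundant,
        }.items():
            p = outdir / f"{name}.tsv"
            write_results(rec, p, format="tsv")
            paths[name] = p
        return paths


def rsd_gap(tr_rsds: Sequence[float], br_rsds: Sequence[float]) -> float:
    """Headline gap between biological and technical variability: the mean of
    the BR-scheme RSDs minus the mean of the TR-scheme RSDs (percentage
    points).  Accepts one value per cell line (or any collection of runs)."""
    tr = np.asarray(list(tr_rsds), dtype=float)
    br = np.asarray(list(br_rsds), dtype=float)
    if tr.size == 0 or br.size == 0:
        raise ValueError("need at least one RSD on each side")
    return float(br.mean() - tr.mean())


def paired_groupings(
    design: ReplicateDesign, numbering: Numbering | str
) -> tuple[GroupingScheme, GroupingScheme]:
    """(technical, biological) groupings under a numbering convention.

    Under ``tr_triads_same_lysate`` the consecutive label blocks are the
    technical groups; under ``br_triads_same_lysate`` the strided blocks are,
    and the two canonical label groupings swap roles.
    """
    numbering = Numbering(numbering)
    consecutive = derive_grouping(design, Scheme.TR).groups
    strided = derive_grouping(design, Scheme.BR).groups
    if numbering is Numbering.TR_TRIADS_SAME_LYSATE:
        tr_groups, br_groups = consecutive, strided
    else:
        tr_groups, br_groups = strided, consecutive
    return (
        GroupingScheme(scheme=Scheme.TR, groups=tr_groups),
        GroupingScheme(scheme=Scheme.BR, groups=br_groups),
    )


def _load_tables(
    config: RunConfig,
) -> tuple[AbundanceTable, AbundanceTable, ReplicateDesign]:
    if config.synthetic is not None:
        lfq, apex, design, _ = generate(config.synthetic)
        return lfq, apex, design
    lfq = read_abundance_table(config.lfq_path, flavor=Flavor.LFQ)
    apex = read_abundance_table(config.apex_path, flavor=Flavor.APEX)
    if lfq.n_replicates != apex.n_replicates:
        raise ValueError(
            "LFQ and APEX tables disagree on the replicate count "
            f"({lfq.n_replicates} vs {apex.n_replicates})"
        )
    n_reps = lfq.n_replicates
    n_bio = _infer_bio(n_reps)
    design = build_design(n_bio, n_reps // n_bio, config.numbering)
    return lfq, apex, design


def _infer_bio(n_reps: int) -> int:
    if n_reps == 9:
        return 3
    root = int(round(n_reps**0.5))
    if root * root == n_reps and root >= 2:
        return root
    raise ValueError(
        f"cannot infer a bio x tech crossing from {n_reps} replicates; "
        "provide a synthetic config or a square design"
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage in order; deterministic for a fixed config.

    A stage failure aborts the run with :class:`PipelineError` naming the
    stage and listing the stages already completed.
    """
    completed: list[str] = []
    results: dict[str, Any] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except PipelineError:
            raise
        except Exception as exc:  # surface with stage context
            raise PipelineError(name, completed, exc) from exc
        completed.append(name)
        logger.info("stage %-18s %.3fs", name, time.perf_counter() - t0)
        return out

    logger.info(
        "numbering=%s interpretation=%s",
        config.numbering.value,
        config.interpretation.value,
    )
    lfq, apex, design = stage("load", lambda: _load_tables(config))
    tr_grouping, br_grouping = paired_groupings(design, config.numbering)
    presence = stage(
        "presence", lambda: qualitative.presence_matrix(lfq, config.presence_threshold)
    )
    occupancy = stage("occupancy", lambda: qualitative.occupancy_profile(presence))
    venn_tr = stage("venn_tr", lambda: qualitative.venn_partition(presence, tr_grouping))
    venn_br = stage("venn_br", lambda: qualitative.venn_partition(presence, br_grouping))
    count_tr = stage(
        "count_rsd_tr",
        lambda: qualitative.count_rsd(presence, tr_grouping, config.interpretation),
    )
    count_br = stage(
        "count_rsd_br",
        lambda: qualitative.count_rsd(presence, br_grouping, config.interpretation),
    )
    abund_tr = stage(
        "abundance_rsd_tr",
        lambda: quantitative.abundance_rsd(apex, tr_grouping, config.interpretation),
    )
    abund_br = stage(
        "abundance_rsd_br",
        lambda: quantitative.abundance_rsd(apex, br_grouping, config.interpretation),
    )
    top = stage("top_abundant", lambda: quantitative.top_abundant(apex, config.abundance_cutoff))
    anova_tr = stage(
        "anova_tr",
        lambda: inferential.rm_anova(apex, tr_grouping, config.log_transform_anova),
    )
    anova_br = stage(
        "anova_br",
        lambda: inferential.rm_anova(apex, br_grouping, config.log_transform_anova),
    )
    anova_all = stage(
        "anova_all", lambda: inferential.rm_anova(apex, None, config.log_transform_anova)
    )
    power = stage(
        "power",
        lambda: inferential.required_replicates(
            apex, alpha=config.power_alpha, power_target=config.power_target
        ),
    )
    n_target = config.n_target if config.n_target is not None else 2 * lfq.n_replicates
    fold = stage(
        "fold_increase",
        lambda: inferential.fold_increase(
            presence,
            n_target=n_target,
            model=config.accumulation_model,
            seed=config.seed,
        ),
    )

    bundle = ReportBundle(
        config=config,
        design=design,
        occupancy=occupancy,
        venn_tr=venn_tr,
        venn_br=venn_br,
        count_rsd_tr=count_tr,
        count_rsd_br=count_br,
        abundance_rsd_tr=abund_tr,
        abundance_rsd_br=abund_br,
        qualitative_gap=rsd_gap(
            [count_tr.scheme_rsd_percent], [count_br.scheme_rsd_percent]
        ),
        quantitative_gap=rsd_gap(
            [abund_tr.scheme_rsd_percent], [abund_br.scheme_rsd_percent]
        ),
        top_abundant=top,
        anova_tr=anova_tr,
        anova_br=anova_br,
        anova_all=anova_all,
        alpha_groups=inferential.bonferroni_alpha(config.alpha, len(tr_grouping.groups)),
        alpha_replicates=inferential.bonferroni_alpha(config.alpha, lfq.n_replicates),
        power=power,
        fold=fold,
    )
    if config.outdir is not None:
        paths = bundle.write(config.outdir)
        try:
            plots.occupancy_heatmap(presence, Path(config.outdir) / "occupancy_heatmap.png")
            plots.venn_figure(venn_tr, Path(config.outdir) / "venn_tr.png")
            plots.venn_figure(venn_br, Path(config.outdir) / "venn_br.png")
            ranking = quantitative.rank_for_heatmap(apex, tr_grouping)
            plots.abundance_heatmap(ranking, Path(config.outdir) / "abundance_heatmap_tr.png")
            ranking_br = quantitative.rank_for_heatmap(apex, br_grouping)
            plots.abundance_heatmap(ranking_br, Path(config.outdir) / "abundance_heatmap_br.png")
        except Exception as exc:
            raise PipelineError("figures", completed, exc) from exc
        logger.info("report written to %s", paths["summary_json"].parent)
    return bundle


def calibrate(
    lfq: AbundanceTable,
    reference: dict[str, float],
    apex: AbundanceTable | None = None,
    presence_threshold: float = 0.0,
    tolerance: float = 0.2,
) -> dict[str, Any]:
    """Score all four (numbering x interpretation) combinations against
    user-supplied reference scheme RSDs.

    ``reference`` keys: ``qualitative_tr``, ``qualitative_br`` and optionally
    ``quantitative_tr`` / ``quantitative_br`` (with ``apex``), in percent.
    Returns each combination's computed RSDs, its maximum absolute deviation
    from the reference, and the winner (deviation within ``tolerance``
    percentage points, if any combination achieves it).
    """
    presence = qualitative.presence_matrix(lfq, presence_threshold)
    n_bio = _infer_bio(lfq.n_replicates)
    combos: dict[str, Any] = {}
    best_name, best_dev = None, np.inf
    for numbering in Numbering:
        design = build_design(n_bio, lfq.n_replicates // n_bio, numbering)
        tr_g, br_g = paired_groupings(design, numbering)
        for interp in Interpretation:
            name = f"{numbering.value}|{interp.value}"
            computed = {
                "qualitative_tr": qualitative.count_rsd(presence, tr_g, interp).scheme_rsd_percent,
                "qualitative_br": qualitative.count_rsd(presence, br_g, interp).scheme_rsd_percent,
            }
            if apex is not None:
                computed["quantitative_tr"] = quantitative.abundance_rsd(
                    apex, tr_g, interp
                ).scheme_rsd_percent
                computed["quantitative_br"] = quantitative.abundance_rsd(
                    apex, br_g, interp
                ).scheme_rsd_percent
            devs = [
                abs(computed[k] - reference[k]) for k in reference if k in computed
            ]
            max_dev = max(devs) if devs else np.inf
            combos[name] = {"computed": computed, "max_abs_deviation": max_dev}
            if max_dev < best_dev:
                best_name, best_dev = name, max_dev
    return {
        "combinations": combos,
        "best": best_name,
        "best_max_abs_deviation": best_dev,
        "within_tolerance": bool(best_dev <= tolerance),
        "tolerance": tolerance,
    }
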