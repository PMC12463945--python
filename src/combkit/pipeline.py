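"""End-to-end orchestration: simulate -> psychometrics -> sem -> categorize -> mine -> report.

Every run resolves a :class:`PipelineConfig` (whose defaults are the
analysis thresholds used throughout the package), executes the enabled
stages in order, writes each stage's outputs under the output directory,
and records a manifest with content hashes so that identical configs can
be checked for identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize as cat
from . import psychometrics as psy
from . import rulemining as rm
from . import sem as sem_mod
from .instrument import InstrumentSpec, default_instrument
from .simulate import (GroundTruthParams, default_ground_truth,
                       generate_responses, read_responses, write_responses)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "psychometrics", "sem", "categorize", "mine", "report")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved configuration; defaults are the analysis' stated thresholds."""

    out_dir: str = "combkit_out"
    responses_path: str | None = None     # if None, the simulate stage must run
    stages: tuple[str, ...] = STAGES
    n_respondents: int = 484
    seed: int = 1
    # psychometrics thresholds
    item_total_threshold: float = 0.5
    loading_threshold: float = 0.5
    cross_loading_threshold: float = 0.5
    eigen_threshold: float = 1.0
    split_mode: str = "first-half"
    # sem / mediation
    bootstrap_b: int = 5000
    # mining thresholds
    min_support: float = 0.05
    min_confidence: float = 0.5
    min_lift: float = 2.0
    top_n: int = 10
    frequency_threshold: int = 5
    recode_map: list = field(default_factory=list)
    middle_exceptions: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages {unknown}")
        if not 0 < self.min_support <= 1:
            raise PipelineError("min_support must be in (0, 1]")
        if not 0 < self.min_confidence <= 1:
            raise PipelineError("min_confidence must be in (0, 1]")
        if self.min_lift <= 0:
            raise PipelineError("min_lift must be positive")
        if self.bootstrap_b < 100:
            raise PipelineError("bootstrap_b must be >= 100")
        if self.n_respondents < 1:
            raise PipelineError("n_respondents must be >= 1")
        if "simulate" not in self.stages and self.responses_path is None:
            raise PipelineError("responses_path required when simulate stage is off")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    stages: list[dict]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"seed": self.seed, "stages": self.stages,
                       "warnings": self.warnings}, fh, indent=2)


def run_pipeline(
    config: PipelineConfig, spec: InstrumentSpec | None = None,
    params: GroundTruthParams | None = None,
) -> RunManifest:
    """Execute the enabled stages in order, failing fast with stage-tagged errors."""
    config.validate()
    spec = spec or default_instrument()
    params = params or default_ground_truth(spec)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest = RunManifest(stages=[], seed=config.seed)
    outputs: dict[str, object] = {}

    data: pd.DataFrame | None = None
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        files: list[Path] = []
        try:
            if stage == "simulate":
                data = generate_responses(spec, params, config.n_respondents,
                                          seed=config.seed)
                path = out / "responses.csv"
                write_responses(data, path)
                files.append(path)
            elif stage == "psychometrics":
                data = _require_data(data, config, stage)
                outputs["psychometrics"] = _run_psychometrics(
                    data, spec, config, out, files
                )
            elif stage == "sem":
                data = _require_data(data, config, stage)
                outputs["sem"] = _run_sem(data, spec, config, out, files)
            elif stage == "categorize":
                data = _require_data(data, config, stage)
                table = cat.build_transactions(data, spec)
                if config.recode_map:
                    table = cat.recode_levels(
                        table, [tuple(r) for r in config.recode_map]
                    )
                outputs["transactions"] = table
                path = out / "basket.txt"
                table.write_basket(path)
                files.append(path)
                long_path = out / "transactions.csv"
                table.to_long_frame().to_csv(long_path, index=False)
                files.append(long_path)
            elif stage == "mine":
                table = outputs.get("transactions")
                if table is None:
                    raise PipelineError("mine stage requires the categorize stage")
                exceptions = {k: set(v) for k, v in config.middle_exceptions.items()}
                partitions, profiles = rm.mine_behavior_rules(
                    table, list(spec.behavior_items),
                    min_support=config.min_support,
                    min_confidence=config.min_confidence,
                    min_lift=config.min_lift,
                    top_n=config.top_n,
                    frequency_threshold=config.frequency_threshold,
                    exceptions=exceptions or None,
                )
                outputs["partitions"], outputs["profiles"] = partitions, profiles
                path = out / "rules.csv"
                rm.rules_to_frame(partitions).to_csv(path, index=False)
                files.append(path)
                freq_path = out / "domain_frequency.csv"
                pd.DataFrame([
                    {"partition": p.partition_key, "domain": d, "count": c,
                     "flagged": d in p.flagged}
                    for p in profiles for d, c in sorted(p.counts.items())
                ]).to_csv(freq_path, index=False)
                files.append(freq_path)
            elif stage == "report":
                report = render_report(outputs)
                json_path = out / "report.json"
                with open(json_path, "w", encoding="utf-8") as fh:
                    json.dump(report, fh, indent=2, default=str)
                files.append(json_path)
                md_path = out / "report.md"
                md_path.write_text(_report_markdown(report), encoding="utf-8")
                files.append(md_path)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages.append({
            "stage": stage,
            "outputs": {str(f.name): _sha256(f) for f in files},
            "wall_time_s": round(time.perf_counter() - t0, 3),
        })
    manifest.to_json(out / "manifest.json")
    return manifest


def _require_data(data, config, stage) -> pd.DataFrame:
    if data is not None:
        return data
    if config.responses_path is None:
        raise PipelineError(f"stage {stage!r}: no responses available")
    return read_responses(config.responses_path)


def _run_psychometrics(data, spec, config, out: Path, files: list) -> dict:
    """Per-subscale screening, EFA, and reliability/validity."""
    efa_half, _ = psy.split_half(data, mode=config.split_mode, seed=config.seed)
    results: dict[str, dict] = {}
    for module in spec.domains:
        items = [i for d in spec.domains[module] for i in spec.items[d]]
        item_totals: dict[str, float] = {}
        for dom in spec.domains[module]:
            item_totals.update(
                psy.corrected_item_total(efa_half, list(spec.items[dom]))
            )
        screening = psy.ItemScreeningReport(
            item_total=item_totals,
            eliminated={i: psy.REASON_LOW_ITEM_TOTAL
                        for i, v in item_totals.items()
                        if v < config.item_total_threshold},
            thresholds={"item_total": config.item_total_threshold},
        )
        kept = [i for i in items if i not in screening.eliminated]
        solution = psy.efa_pca_varimax(efa_half[kept],
                                       eigen_threshold=config.eigen_threshold)
        sub_screen = psy.ItemScreeningReport(
            item_total={i: item_totals[i] for i in kept},
            thresholds=screening.thresholds,
        )
        final = psy.apply_item_retention_rules(
            solution, sub_screen,
            loading_threshold=config.loading_threshold,
            cross_loading_threshold=config.cross_loading_threshold,
        )
        final.eliminated.update(screening.eliminated)
        final.item_total.update(item_totals)
        retained = [i for i in items if i not in final.eliminated]
        domain_items = {
            d: [i for i in spec.items[d] if i in retained]
            for d in spec.domains[module]
        }
        domain_items = {d: li for d, li in domain_items.items() if len(li) >= 2}
        loadings_by_domain = {
            d: [float(solution.loadings.loc[i].abs().max()) for i in li]
            for d, li in domain_items.items()
        }
        rv = psy.reliability_validity_report(data, domain_items, loadings_by_domain)
        adequacy = psy.sampling_adequacy(efa_half[kept])
        results[module] = {
            "screening": final.to_frame().to_dict(orient="records"),
            "kmo": adequacy.kmo,
            "bartlett_chi2": adequacy.bartlett_chi2,
            "bartlett_df": adequacy.bartlett_df,
            "bartlett_p": adequacy.bartlett_p,
            "n_factors": solution.n_factors,
            "total_pct_variance": solution.total_pct_variance,
            "reliability": rv.to_frame().to_dict(orient="records"),
            "retained_items": retained,
        }
        csv_path = out / f"psychometrics_{module.lower()}.csv"
        rv.to_frame().to_csv(csv_path, index=False)
        files.append(csv_path)
    return results


def _run_sem(data, spec, config, out: Path, files: list) -> dict:
    """Fit the structural COM-B model on domain scores; bootstrap mediation."""
    scores = cat.domain_score_table(data, spec)
    model = sem_mod.parse_model(sem_mod.comb_model_text(spec))
    s = scores[model.observed].cov()
    fit = sem_mod.fit_ml(model, s, n=len(scores), seed=config.seed)
    indices = sem_mod.fit_indices(fit, s, n=len(scores))
    mediations = {}
    for x in ("Capability", "Opportunity"):
        med = sem_mod.bootstrap_mediation(
            model, scores, x=x, mediator="Motivation", y="Behavior",
            n_boot=config.bootstrap_b, seed=config.seed,
        )
        mediations[x] = med
    med_rows = []
    for x, med in mediations.items():
        for _, row in med.to_frame().iterrows():
            if row["effect"] == "total":
                continue
            med_rows.append({"path": f"{x} -> Motivation -> Behavior", **row})
    med_frame = pd.DataFrame(med_rows)
    med_path = out / "mediation.csv"
    med_frame.to_csv(med_path, index=False)
    files.append(med_path)
    params_path = out / "sem_parameters.csv"
    pd.DataFrame({
        "name": list(fit.params),
        "estimate": list(fit.params.values()),
        "standardized": [fit.standardized.get(k, np.nan) for k in fit.params],
    }).to_csv(params_path, index=False)
    files.append(params_path)
    idx_path = out / "fit_indices.json"
    with open(idx_path, "w", encoding="utf-8") as fh:
        json.dump(indices.to_dict(), fh, indent=2)
    files.append(idx_path)
    return {
        "fit_indices": indices.to_dict(),
        "paths": {k: fit.standardized[k] for k in fit.standardized
                  if k.count("~") == 1 and "=~" not in k},
        "mediation": {x: med.to_frame().to_dict(orient="records")
                      for x, med in mediations.items()},
        "classification": {x: med.classification for x, med in mediations.items()},
        "heywood": fit.heywood,
    }


def render_report(outputs: dict) -> dict:
    """Assemble a single report dict; absent stages become explicit gaps."""
    report: dict = {"sections": {}, "warnings": []}
    if "psychometrics" in outputs:
        report["sections"]["psychometrics"] = outputs["psychometrics"]
    else:
        report["sections"]["psychometrics"] = None
        report["warnings"].append("psychometrics stage not run")
    if "sem" in outputs:
        report["sections"]["sem"] = outputs["sem"]
    else:
        report["sections"]["sem"] = None
        report["warnings"].append("sem stage not run; mediation table omitted")
    if "partitions" in outputs:
        partitions, profiles = outputs["partitions"], outputs["profiles"]
        report["sections"]["rules"] = [
            {
                "partition": p.key,
                "n_rules": len(p.rules),
                "strong_rules": [str(r) for r in p.strong_rules]
                or ["no strong rules"],
                "domain_counts": prof.counts,
                "high_frequency_domains": prof.flagged,
            }
            for p, prof in zip(partitions, profiles)
        ]
    else:
        report["sections"]["rules"] = None
        report["warnings"].append("mining stage not run")
    return report


def _report_markdown(report: dict) -> str:
    lines = ["# COM-B analysis report", ""]
    psych = report["sections"]["psychometrics"]
    lines.append("## Reliability and validity")
    if psych is None:
        lines.append("_not run_")
    else:
        for module, res in psych.items():
            lines.append(f"### {module}")
            lines.append(f"KMO = {res['kmo']:.3f}, Bartlett chi2 = "
                         f"{res['bartlett_chi2']:.1f} (df {res['bartlett_df']}, "
                         f"p = {res['bartlett_p']:.3g})")
            lines.append("")
            lines.append("| domain | alpha | CR | AVE | sqrt(AVE) |")
            lines.append("|---|---|---|---|---|")
            for row in res["reliability"]:
                lines.append(
                    f"| {row['domain']} | {row['alpha']:.3f} | {row['CR']:.3f} "
                    f"| {row['AVE']:.3f} | {row['sqrt_AVE']:.3f} |"
                )
            lines.append("")
    sem_res = report["sections"]["sem"]
    lines.append("## Structural model and mediation")
    if sem_res is None:
        lines.append("_not run_")
    else:
        lines.append("Standardized paths: " + ", ".join(
            f"{k} = {v:.3f}" for k, v in sem_res["paths"].items()))
        lines.append("")
        lines.append("| path | effect | estimate | SE | BC 95% CI | percentile 95% CI | p |")
        lines.append("|---|---|---|---|---|---|---|")
        for x, rows in sem_res["mediation"].items():
            for row in rows:
                if row["effect"] == "total":
                    continue
                lines.append(
                    f"| {x} -> Motivation -> Behavior | {row['effect']} "
                    f"| {row['estimate']:.3f} | {row['se']:.3f} "
                    f"| ({row['bc_low']:.3f}, {row['bc_high']:.3f}) "
                    f"| ({row['pct_low']:.3f}, {row['pct_high']:.3f}) "
                    f"| {row['p']:.3g} |"
                )
        lines.append("")
    rules = report["sections"]["rules"]
    lines.append("## Strong association rules")
    if rules is None:
        lines.append("_not run_")
    else:
        for part in rules:
            lines.append(f"### {part['partition']} ({part['n_rules']} rules)")
            for r in part["strong_rules"]:
                lines.append(f"- {r}")
            if part["high_frequency_domains"]:
                lines.append(
                    "High-frequency domains: "
                    + ", ".join(part["high_frequency_domains"])
                )
            lines.append("")
    if report["warnings"]:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in report["warnings"])
    return "\n".join(lines) + "\n"
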