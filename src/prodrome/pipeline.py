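"""End-to-end orchestration: simulate -> phenotype -> featurize -> train ->
evaluate -> moderators, with a reproducible run manifest and a summary
report (Markdown + JSON).

Every random draw flows from the master seed through a per-stage seed
registry; replaying a manifest's config and seed reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import CutoffSpec
from .moderators import run_moderator_analysis
from .outcomes import (
    MEDICATION,
    PSYCHOTHERAPY,
    first_treatment_episodes,
    improvement_summary,
)
from .phenotyping import PhenotypeConfig, assemble_cohort, cohort_composition
from .prediction import (
    SplitSpec,
    run_horizon_experiment,
    run_response_experiment,
    run_severity_experiment,
)
from .features import ghri_feature_matrix
from .records import write_events_csv, write_patients_csv, write_treatments_csv
from .synthetic_ehr import (
    SimulationConfig,
    TreatmentSimConfig,
    simulate_ghri_population,
    simulate_pamf_population,
)

STAGES = (
    "simulate_pamf",
    "phenotype",
    "horizon",
    "simulate_ghri",
    "response",
    "severity",
    "moderators",
)


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    seed_registry: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (all below 2**31) from one master."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {stage: int(s % 2**31) for stage, s in zip(STAGES, state)}


def load_config(source: str | Path | dict | None) -> dict:
    if source is None:
        return {}
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh) or {}


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_all(
    config: str | Path | dict | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
    write_tables: bool = True,
) -> dict:
    """Run the full pipeline on freshly simulated populations.

    Returns the report dict; writes the canonical CSV tables, the manifest,
    and the report to ``out_dir``.  A stage failure raises RuntimeError
    naming the failing stage.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest = RunManifest(
        config_hash=_config_hash(cfg), master_seed=seed, seed_registry=seeds
    )
    report: dict = {"seed": seed, "config_hash": manifest.config_hash}
    pheno = PhenotypeConfig(**cfg.get("phenotype", {}))
    split_cfg = cfg.get("prediction", {})

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- primary-care arm -------------------------------------------------
    pamf_cfg = SimulationConfig(**{**cfg.get("pamf", {}), "seed": seeds["simulate_pamf"]})
    pop = stage("simulate_pamf")(lambda: simulate_pamf_population(pamf_cfg))
    if write_tables:
        write_events_csv(pop.events, out / "pamf_events.csv")
        write_patients_csv(pop.patients, out / "pamf_patients.csv")
        manifest.outputs["pamf_events"] = str(out / "pamf_events.csv")

    cohort = stage("phenotype")(
        lambda: assemble_cohort(pop.events, pop.patients, pheno, seeds["phenotype"])
    )
    composition = cohort_composition(cohort)
    report["cohort"] = composition
    if write_tables:
        cohort.to_csv(out / "pamf_cohort.csv", index=False)
        manifest.outputs["pamf_cohort"] = str(out / "pamf_cohort.csv")

    horizon = stage("horizon")(
        lambda: run_horizon_experiment(
            cohort, pop.events, pop.patients, pheno,
            split=SplitSpec(
                train_fraction=split_cfg.get("train_fraction", 0.8),
                seed=seeds["horizon"],
            ),
            seed=seeds["horizon"],
        )
    )
    report["diagnosis"] = {
        str(offset): roc.summary() for offset, roc in horizon.per_cutoff.items()
    }
    report["diagnosis_n_nonzero"] = horizon.fit.n_nonzero

    # --- treated arm ------------------------------------------------------
    ghri_cfg = TreatmentSimConfig(
        **{**cfg.get("ghri", {}), "seed": seeds["simulate_ghri"]}
    )
    tpop = stage("simulate_ghri")(lambda: simulate_ghri_population(ghri_cfg))
    if write_tables:
        write_events_csv(tpop.events, out / "ghri_events.csv")
        write_patients_csv(tpop.patients, out / "ghri_patients.csv")
        write_treatments_csv(tpop.treatments, out / "ghri_treatments.csv")
        manifest.outputs["ghri_treatments"] = str(out / "ghri_treatments.csv")
    episodes = first_treatment_episodes(tpop.treatments)
    report["improvement"] = improvement_summary(episodes).to_dict("records")

    response = {}
    for modality in (MEDICATION, PSYCHOTHERAPY):
        result = stage("response")(
            lambda m=modality: run_response_experiment(
                episodes, tpop.events, tpop.patients, pheno, m,
                seed=seeds["response"],
            )
        )
        response[modality] = {
            **result.roc.summary(),
            "n_nonzero": result.fit.n_nonzero,
            "top_feature": result.top_feature,
        }
    report["response"] = response

    severity = stage("severity")(
        lambda: run_severity_experiment(
            episodes, tpop.events, tpop.patients, pheno, seed=seeds["severity"]
        )
    )
    report["severity"] = {
        **severity.roc.summary(),
        "n_nonzero": severity.fit.n_nonzero,
    }

    def run_mods():
        single = episodes[episodes["modality"].isin([MEDICATION, PSYCHOTHERAPY])]
        single = single.reset_index(drop=True)
        matrix = ghri_feature_matrix(
            single, tpop.events, tpop.patients, pheno, include_baseline_phq9=False
        )
        order = {p: i for i, p in enumerate(matrix.patient_ids)}
        single = single.iloc[
            np.argsort([order[p] for p in single["patient_id"].astype(str)])
        ].reset_index(drop=True)
        binary = [
            j for j, c in enumerate(matrix.columns) if not c.startswith("demo:age")
        ]
        mods_cfg = cfg.get("moderators", {})
        return run_moderator_analysis(
            matrix.X[:, binary],
            [matrix.columns[j] for j in binary],
            single,
            k=mods_cfg.get("k", 100),
            outcome_kind=mods_cfg.get("outcome", "abs_change"),
        )

    moderators = stage("moderators")(run_mods)
    report["moderators"] = {
        "n_significant": int(
            (moderators.table["adjusted_p"] < 0.05).fillna(False).sum()
        ),
        "top": moderators.table.head(10).to_dict("records"),
    }
    if write_tables:
        moderators.table.to_csv(out / "moderators.csv", index=False)
        manifest.outputs["moderators"] = str(out / "moderators.csv")

    manifest.write(out / "manifest.json")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n"
    )
    (out / "report.md").write_text(render_report(report))
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def render_report(report: dict) -> str:
    lines = ["# Pipeline report", ""]
    comp = report.get("cohort", {})
    if comp:
        lines += [
            "## Cohort composition",
            "",
            f"- cases: {comp['n_cases']}",
            f"- matched controls: {comp['n_controls']}",
            f"- modelling cohort: {comp['n_cohort']} "
            f"({comp['percent_depressed']}% depressed)",
            "",
        ]
    diag = report.get("diagnosis", {})
    if diag:
        lines += ["## Diagnosis prediction by truncation cutoff", "",
                  "| cutoff (days) | AUC | 95% CI |", "|---|---|---|"]
        for offset in sorted(diag, key=lambda s: -int(s)):
            s = diag[offset]
            lines.append(
                f"| {offset} | {s['auc']:.3f} | "
                f"{s['ci_low']:.3f}-{s['ci_high']:.3f} |"
            )
        lines.append("")
    if "improvement" in report:
        lines += ["## Treatment response", ""]
        for row in report["improvement"]:
            lines.append(
                f"- {row['modality']}: {row['n_improved']}/{row['n']} improved "
                f"({row['percent_improved']}%)"
            )
        lines.append("")
    for modality, s in report.get("response", {}).items():
        lines.append(
            f"- {modality} model AUC {s['auc']:.3f} "
            f"({s['ci_low']:.3f}-{s['ci_high']:.3f}); top feature {s['top_feature']}"
        )
    if "severity" in report:
        s = report["severity"]
        lines += [
            "",
            "## Severity (severe vs minimal/mild)",
            "",
            f"- AUC {s['auc']:.3f} ({s['ci_low']:.3f}-{s['ci_high']:.3f})",
        ]
    if "moderators" in report:
        lines += [
            "",
            "## Moderator screen",
            "",
            f"- BH-significant interactions at 0.05: "
            f"{report['moderators']['n_significant']}",
        ]
    return "\n".join(lines) + "\n"
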