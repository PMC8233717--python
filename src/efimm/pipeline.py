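"""One-command end-to-end orchestration.

``run_pipeline`` executes simulate/read -> cohort -> frailty scoring (all
measurement variants) -> baseline covariates -> survival analyses -> variant
comparison, and writes the report surfaces of a frailty-index cohort study:

* ``attrition.csv``    — selection flow;
* ``table1.csv``       — baseline characteristics by severity category;
* ``table2.csv``       — deficit prevalence by severity (catalog order);
* ``table3.csv``       — unadjusted and adjusted HRs for death and
  hospitalization;
* ``km_<outcome>.csv`` — Kaplan–Meier curve data per category, plus medians
  and 1-/5-year survival with CIs in ``survival_at_horizons.csv``;
* ``variant_comparison.csv`` / ``variant_hr_table.csv`` — measurement-variant
  reclassification and HR stability;
* ``decisions.csv``, ``scores.csv``, ``baseline.csv``, ``truth.csv`` (simulate
  mode) and a JSON ``manifest.json`` with config hash, seed and stage
  timings.

Defaults reproduce the primary specification: VA+CMS sources, 3-year window,
death outcome, multivariable model on imputed covariates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DeficitCatalog, default_catalog, load_catalog
from .cohort import CohortCriteria, build_cohort
from .covariates import extract_baseline
from .frailty import (
    MeasurementConfig,
    Severity,
    ascertain_deficits,
    compute_fi,
    score_patient,
)
from .io import BundlePaths, read_bundle, write_bundle
from .model import EventBundle, Source
from .reclassification import association_stability, compare_fi_variants
from .simulate import SimulationConfig, simulate_cohort
from .survival import (
    OutcomeType,
    build_survival_records,
    cox_fit,
    cox_fit_mice,
    encode_design,
    km_estimate,
    logrank,
    records_frame,
)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_VARIANTS"]

PRIMARY_VARIANT = MeasurementConfig(window_years=3, sources=frozenset({Source.VA, Source.CMS}), label="va_cms,3y")
DEFAULT_VARIANTS = [
    PRIMARY_VARIANT,
    MeasurementConfig(window_years=3, sources=frozenset({Source.VA}), label="va_only,3y"),
    MeasurementConfig(window_years=1, sources=frozenset({Source.VA, Source.CMS}), label="va_cms,1y"),
]

MULTIVARIABLE_COLS = [
    "category",
    "age",
    "male",
    "race_black",
    "race_other",
    "race_missing",
    "income",
    "treatment_year",
    "iss_stage",
    "ca_high",
    "cr_high",
    "hgb_low",
    "plt_low",
]


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "files"
    sim: SimulationConfig | None = None
    input_dir: str | Path | None = None
    criteria: CohortCriteria = field(default_factory=CohortCriteria)
    catalog_path: str | Path | None = None
    variants: list[MeasurementConfig] = field(default_factory=lambda: list(DEFAULT_VARIANTS))
    m_imputations: int = 20
    ties: str = "efron"
    seed: int = 0
    out_dir: str | Path = "efimm_out"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and self.input_dir is None:
            raise ValueError("files mode requires input_dir")
        if self.mode == "simulate" and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (dt.date,)):
            return obj.isoformat()
        if isinstance(obj, frozenset):
            return sorted(str(x) for x in obj)
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        return str(obj)

    payload = enc(config)
    payload.pop("out_dir", None)  # output location is not part of the analysis
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pct(x: pd.Series) -> float:
    return float(np.round(100 * x.mean(), 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON).

    A stage failure is recorded in the manifest with partial outputs
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "artifacts": [],
        "status": "ok",
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "status": "failed" if exc_type else "ok",
                }
                if exc_type:
                    manifest["status"] = f"failed at {name}: {exc}"
                return False

        return _Timer()

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False)
        manifest["artifacts"].append(name)

    try:
        catalog = load_catalog(config.catalog_path) if config.catalog_path else default_catalog()

        with stage("input"):
            if config.mode == "simulate":
                bundle, truth = simulate_cohort(config.sim, catalog)
                write_bundle(bundle, out / "bundle")
                truth.table.reset_index(drop=True).assign(
                    true_deficits=[";".join(sorted(truth.deficits[p])) for p in truth.table.index]
                ).to_csv(out / "truth.csv", index=False)
                manifest["artifacts"] += ["bundle/", "truth.csv"]
            else:
                bundle = read_bundle(BundlePaths(config.input_dir))

        with stage("cohort"):
            decisions, attrition = build_cohort(bundle, config.criteria)
            emit("attrition.csv", pd.DataFrame(attrition.to_records()))
            emit(
                "decisions.csv",
                pd.DataFrame(
                    [
                        {
                            "patient_id": d.patient_id,
                            "included": d.included,
                            "index_date": d.index_date.isoformat() if d.index_date else "",
                            "exclusion_reason": d.exclusion_reason or "",
                        }
                        for d in decisions
                    ]
                ),
            )
            included = [d for d in decisions if d.included]
            if not included:
                raise RuntimeError("empty cohort after selection")

        with stage("score"):
            events_by = bundle.events_by_patient()
            primary = config.variants[0]
            profiles = {}
            scores_by_variant: dict[str, dict] = {mc.name: {} for mc in config.variants}
            for d in included:
                evs = events_by[d.patient_id]
                prof = ascertain_deficits(evs, catalog, primary, d.index_date, patient_id=d.patient_id)
                profiles[d.patient_id] = prof
                scores_by_variant[primary.name][d.patient_id] = compute_fi(prof, catalog)
                for mc in config.variants[1:]:
                    scores_by_variant[mc.name][d.patient_id] = score_patient(
                        evs, catalog, mc, d.index_date, patient_id=d.patient_id
                    )
            scores = scores_by_variant[primary.name]
            emit(
                "scores.csv",
                pd.DataFrame(
                    [
                        {
                            "patient_id": pid,
                            **{
                                mc.name: scores_by_variant[mc.name][pid].score
                                for mc in config.variants
                            },
                            "category": scores[pid].category.label,
                        }
                        for pid in sorted(scores)
                    ]
                ),
            )

        with stage("covariates"):
            labs_by = bundle.labs_by_patient()
            covariates = {
                d.patient_id: extract_baseline(
                    bundle.patient(d.patient_id),
                    events_by[d.patient_id],
                    labs_by[d.patient_id],
                    d.index_date,
                )
                for d in included
            }
            emit("baseline.csv", _baseline_table(covariates))
            emit("table1.csv", _table1(scores, covariates))
            emit("table2.csv", _table2(profiles, scores, catalog))

        with stage("survival"):
            table3_rows = []
            horizon_rows = []
            for outcome in (OutcomeType.DEATH, OutcomeType.HOSPITALIZATION):
                records = build_survival_records(bundle, included, outcome, scores)
                curves = km_estimate(records)
                km_rows = []
                for label, c in curves.items():
                    for t, s, lo, hi in zip(c.times, c.survival, c.ci_lower, c.ci_upper):
                        km_rows.append(
                            {"group": label, "time": t, "survival": s, "ci_lower": lo, "ci_upper": hi}
                        )
                    for h, (s, lo, hi) in c.horizons.items():
                        horizon_rows.append(
                            {
                                "outcome": outcome.value,
                                "group": label,
                                "horizon_years": h,
                                "survival": s,
                                "ci_lower": lo,
                                "ci_upper": hi,
                            }
                        )
                    horizon_rows.append(
                        {
                            "outcome": outcome.value,
                            "group": label,
                            "horizon_years": "median",
                            "survival": c.median,
                            "ci_lower": c.median_ci[0],
                            "ci_upper": c.median_ci[1],
                        }
                    )
                emit(f"km_{outcome.name.lower()}.csv", pd.DataFrame(km_rows))
                chi2, df_, p = logrank(records)
                manifest[f"logrank_{outcome.name.lower()}"] = {"chi2": chi2, "df": df_, "p": p}

                frame = records_frame(records, covariates)
                uni_design = encode_design(frame, ["category"])
                uni_design[["time", "event"]] = frame[["time", "event"]]
                uni = cox_fit(
                    uni_design,
                    [c for c in uni_design.columns if c not in ("time", "event")],
                    ties=config.ties,
                )
                adj = cox_fit_mice(
                    frame,
                    MULTIVARIABLE_COLS,
                    m=config.m_imputations,
                    seed=config.seed + 17,
                    ties=config.ties,
                )
                for model_name, fit in (("unadjusted", uni), ("adjusted", adj)):
                    for cov, row in fit.table.iterrows():
                        table3_rows.append(
                            {
                                "outcome": outcome.value,
                                "model": model_name,
                                "covariate": cov,
                                "hr": row["hr"],
                                "ci_lower": row["ci_lower"],
                                "ci_upper": row["ci_upper"],
                            }
                        )
            emit("table3.csv", pd.DataFrame(table3_rows))
            emit("survival_at_horizons.csv", pd.DataFrame(horizon_rows))

        if len(config.variants) < 2:
            manifest["stages"]["variants"] = {"status": "skipped: <2 variants"}
        else:
            with stage("variants"):
                comp_rows = []
                records_by_variant = {}
                for mc in config.variants:
                    recs = build_survival_records(
                        bundle, included, OutcomeType.DEATH, scores_by_variant[mc.name]
                    )
                    records_by_variant[mc.name] = recs
                for mc in config.variants[1:]:
                    comp = compare_fi_variants(
                        scores_by_variant[mc.name],
                        scores_by_variant[primary.name],
                        label_a=mc.name,
                        label_b=primary.name,
                    )
                    comp_rows.append(
                        {
                            "baseline": comp.label_a,
                            "comparator": comp.label_b,
                            "n": comp.n,
                            "mean_delta": comp.mean_delta,
                            "ci_lower": comp.ci[0],
                            "ci_upper": comp.ci[1],
                            "t": comp.t_statistic,
                            "p": comp.p_value,
                            "pct_reclassified_up": comp.pct_reclassified_up,
                            "pct_delta_ge_threshold": comp.pct_delta_ge_threshold,
                        }
                    )
                emit("variant_comparison.csv", pd.DataFrame(comp_rows))
                emit("variant_hr_table.csv", association_stability(records_by_variant, ties=config.ties))

    except Exception:
        pass  # stage recorded the failure; partial outputs retained

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _baseline_table(covariates: dict) -> pd.DataFrame:
    rows = []
    for pid in sorted(covariates):
        c = covariates[pid]
        rows.append(
            {
                "patient_id": pid,
                "age_at_index": round(c.age_at_index, 2),
                "sex": c.sex.value,
                "race": c.race.value,
                "income": c.income,
                "treatment_year": c.treatment_year,
                "iss_stage": c.iss_stage,
                "ca_high": c.ca_high,
                "cr_high": c.cr_high,
                "hgb_low": c.hgb_low,
                "plt_low": c.plt_low,
                "novel_therapy": c.novel_therapy,
                "agents": ";".join(sorted(c.agents)),
            }
        )
    return pd.DataFrame(rows)


def _table1(scores: dict, covariates: dict) -> pd.DataFrame:
    """Characteristics by severity category (columns) — Table-1 layout."""
    df = _baseline_table(covariates).set_index("patient_id")
    df["category"] = [scores[p].category.label for p in df.index]
    groups = ["overall"] + [s.label for s in Severity]
    rows = []

    def summarize(sub: pd.DataFrame) -> dict:
        if sub.empty:
            return {}
        return {
            "n": len(sub),
            "age_median": round(float(sub["age_at_index"].median()), 1),
            "male_pct": _pct(sub["sex"] == "M"),
            "income_median": round(float(sub["income"].dropna().median()), 0)
            if sub["income"].notna().any()
            else None,
            "iss_3_pct": _pct(sub["iss_stage"] == 3),
            "iss_missing_pct": _pct(sub["iss_stage"].isna()),
            "ca_high_pct": _pct(sub["ca_high"] == True),  # noqa: E712
            "cr_high_pct": _pct(sub["cr_high"] == True),  # noqa: E712
            "hgb_low_pct": _pct(sub["hgb_low"] == True),  # noqa: E712
            "plt_low_pct": _pct(sub["plt_low"] == True),  # noqa: E712
            "novel_therapy_pct": _pct(sub["novel_therapy"] == True),  # noqa: E712
        }

    for g in groups:
        sub = df if g == "overall" else df[df["category"] == g]
        s = summarize(sub)
        for k, v in s.items():
            rows.append({"characteristic": k, "group": g, "value": v})
    return pd.DataFrame(rows)


def _table2(profiles: dict, scores: dict, catalog: DeficitCatalog) -> pd.DataFrame:
    """Deficit prevalence (%) by severity, rows in catalog (domain) order."""
    pids = sorted(profiles)
    cats = {p: scores[p].category for p in pids}
    rows = []
    for item in catalog.items:
        row = {"deficit_id": item.deficit_id, "name": item.name, "domain": item.domain.value}
        present = {p: profiles[p].present.get(item.deficit_id, False) for p in pids}
        row["overall_pct"] = round(100 * np.mean([present[p] for p in pids]), 1)
        for sev in Severity:
            sub = [present[p] for p in pids if cats[p] is sev]
            row[f"{sev.name.lower()}_pct"] = round(100 * float(np.mean(sub)), 1) if sub else None
        rows.append(row)
    return pd.DataFrame(rows)
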