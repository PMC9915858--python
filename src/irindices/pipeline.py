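"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` wires the stages together the way the underlying study
ran them: raw cohort → index panel → NCEP ATP III classification →
descriptive/comparative statistics → ROC curves with Youden-optimal
cutoffs — and writes one CSV artifact per stage plus a run log.  All data
artifacts are deterministic functions of (config, cohort); the log line
carries the wall-clock timestamp.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as cohort_stats
from .indices import InsulinResistanceIndices, GLUCOSE_MGDL_PER_MMOL, TG_MGDL_PER_MMOL
from .mets import ATPIIIClassifier, ATPIIIThresholds, bmi_category
from .roc import bootstrap_auc_ci, roc_curve, optimal_cutoff
from .schema import read_cohort
from .simulate import default_config, simulate_cohort

logger = logging.getLogger(__name__)

#: Indices ranked by ROC, and whether the cutoff is derived per sex.
#: TG:HDL is sex-stratified (its HDL denominator differs systematically
#: between men and women); the others are derived on the pooled cohort.
DEFAULT_STRATIFY = {"homa_ir": False, "tyg": False, "tg_hdl": True, "lap": False}

ARTIFACTS = (
    "indices.csv",
    "classification.csv",
    "group_comparison.csv",
    "correlations.csv",
    "trend_by_bmi.csv",
    "roc_points.csv",
    "cutoffs.csv",
)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the cohort itself.

    Unknown keys in a config document are rejected — a misspelled
    threshold silently falling back to a default would corrupt results.
    """

    thresholds: ATPIIIThresholds = field(default_factory=ATPIIIThresholds)
    convention: str = "gte"
    glucose_divisor: float = GLUCOSE_MGDL_PER_MMOL
    tg_mmol_factor: float = TG_MGDL_PER_MMOL
    stratify_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_STRATIFY))
    bootstrap_auc: bool = False
    simulation_n: int = 192
    output_dir: str = "results"
    seed: int | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if isinstance(doc.get("thresholds"), dict):
            tdoc = doc["thresholds"]
            tknown = {f.name for f in dataclasses.fields(ATPIIIThresholds)}
            tunknown = set(tdoc) - tknown
            if tunknown:
                raise ValueError(f"unknown threshold key(s): {', '.join(sorted(tunknown))}")
            doc["thresholds"] = ATPIIIThresholds(**tdoc)
        return cls(**doc)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for the run log."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and subjects."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def compute_cutoffs(
    panel: pd.DataFrame,
    mets: np.ndarray,
    sex: np.ndarray,
    stratify: dict | None = None,
    bootstrap: bool = False,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Youden-optimal cutoff and diagnostics per index; plus ROC points.

    Returns ``(cutoffs, roc_points)``.  Stratified indices are fitted
    within each sex against that sex's outcome labels; pooled indices on
    the whole cohort.
    """
    stratify = stratify if stratify is not None else dict(DEFAULT_STRATIFY)
    mets = np.asarray(mets, dtype=int)
    sex = np.asarray(sex)
    cut_rows, pt_rows = [], []
    for index_name, per_sex in stratify.items():
        strata = [("male", sex == "M"), ("female", sex == "F")] if per_sex else [("", slice(None))]
        for label, mask in strata:
            scores = panel[index_name].to_numpy(float)[mask]
            labels = mets[mask]
            keep = np.isfinite(scores)
            scores, labels = scores[keep], labels[keep]
            name = f"{index_name}_{label}" if label else index_name
            curve = roc_curve(scores, labels)
            rep = optimal_cutoff(curve)
            row = {"index": name, **rep.as_dict(), "n": len(scores), "n_pos": curve.n_pos}
            if bootstrap:
                lo, hi = bootstrap_auc_ci(scores, labels, seed=seed)
                row["auc_ci_low"], row["auc_ci_high"] = lo, hi
            cut_rows.append(row)
            for p in zip(curve.thresholds, curve.sensitivity, curve.specificity):
                pt_rows.append({"index": name, "threshold": p[0], "sensitivity": p[1], "specificity": p[2]})
    return pd.DataFrame(cut_rows), pd.DataFrame(pt_rows)


def _format_cutoffs(cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Report-precision view: cutoffs to 2 decimals, percentages to 1."""
    out = pd.DataFrame({"index": cutoffs["index"]})
    out["optimal_cutoff"] = cutoffs["cutoff"].round(2)
    for col in ("sensitivity", "specificity", "ppv", "npv"):
        out[f"{col}_pct"] = (100.0 * cutoffs[col]).round(1)
    out["youden_j"] = cutoffs["youden_j"].round(2)
    out["auc"] = cutoffs["auc"].round(3)
    for col in ("tp", "fp", "tn", "fn", "n", "n_pos"):
        out[col] = cutoffs[col]
    for col in ("auc_ci_low", "auc_ci_high"):
        if col in cutoffs:
            out[col] = cutoffs[col].round(3)
    return out


def run_pipeline(
    config: PipelineConfig | None = None,
    cohort: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write all artifacts.

    When no cohort is supplied, a default synthetic cohort of
    ``config.simulation_n`` subjects is generated from ``config.seed``
    (and written alongside the artifacts, with its planted-label sidecar).
    Returns the artifact frames keyed by file name.
    """
    config = config or PipelineConfig()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    simulated = cohort is None
    if simulated:
        sim_cfg = default_config(seed=config.seed, n=config.simulation_n)
        cohort, truth = _stage("simulate")(simulate_cohort)(sim_cfg)
        cohort.to_csv(out / "cohort.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        results["cohort.csv"] = cohort
        results["truth.csv"] = truth

    panel = _stage("indices")(
        InsulinResistanceIndices(
            glucose_divisor=config.glucose_divisor, tg_mmol_factor=config.tg_mmol_factor
        ).fit(cohort).transform
    )(cohort)
    indices_out = pd.concat([cohort[["id"]], panel], axis=1)
    indices_out["bmi_category"] = bmi_category(panel["bmi"].to_numpy())
    results["indices.csv"] = indices_out

    clf = ATPIIIClassifier(thresholds=config.thresholds, convention=config.convention).fit()
    flags = _stage("classify")(clf.criteria)(cohort)
    classification = pd.concat([cohort[["id"]], flags], axis=1)
    results["classification.csv"] = classification
    mets = flags["mets"].to_numpy()
    if np.isnan(mets).any():
        bad = list(cohort.loc[np.isnan(mets), "id"])
        raise StageError(f"stage 'classify' failed: missing criterion fields for subjects {bad}")
    mets = mets.astype(int)

    analysis = pd.concat(
        [cohort.drop(columns=["id", "sex", "ldl_mgdl"], errors="ignore"), panel], axis=1
    )
    analysis["mets"] = mets
    results["group_comparison.csv"] = _stage("cohort_stats")(cohort_stats.compare_table)(
        analysis, "mets"
    )
    corr_vars = ["homa_ir", "tyg", "tg_hdl", "lap", "bmi", "whr", "whtr"]
    results["correlations.csv"] = cohort_stats.correlation_frame(
        _stage("cohort_stats")(cohort_stats.spearman_matrix)(panel, corr_vars)
    )
    results["trend_by_bmi.csv"] = _stage("cohort_stats")(cohort_stats.trend_by_bmi)(
        panel[["bmi", "homa_ir", "tyg", "tg_hdl", "lap"]]
    )

    cutoffs, roc_points = _stage("roc_cutoffs")(compute_cutoffs)(
        panel,
        mets,
        cohort["sex"].to_numpy(),
        stratify=config.stratify_by_sex,
        bootstrap=config.bootstrap_auc,
        seed=config.seed,
    )
    results["cutoffs_full"] = cutoffs  # full precision, not written
    results["cutoffs.csv"] = _format_cutoffs(cutoffs)
    results["roc_points.csv"] = roc_points

    for name in ARTIFACTS:
        results[name].to_csv(out / name, index=False, float_format="%.10g")
    log_line = (
        f"{datetime.now(timezone.utc).isoformat()} run_pipeline "
        f"config_hash={config.digest()} seed={config.seed} n={len(cohort)} "
        f"simulated={simulated} artifacts={','.join(ARTIFACTS)}\n"
    )
    with open(out / "run.log", "a") as fh:
        fh.write(log_line)
    logger.info("pipeline complete: %d subjects, artifacts in %s", len(cohort), out)
    return results


def run_from_files(
    config_path: str | Path | None = None,
    input_path: str | Path | None = None,
    **overrides,
) -> dict[str, pd.DataFrame]:
    """File-oriented wrapper used by the CLI."""
    config = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(config, k, v)
    cohort = read_cohort(input_path) if input_path else None
    return run_pipeline(config, cohort)
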