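"""End-to-end stratified-care run: simulate -> filter -> split ->
outcomes -> fit -> thresholds -> stratify -> evaluate.

Stages run in a fixed order and communicate only forward.  Every random
draw flows from a named sub-seed derived deterministically from the one
top-level seed, so a stage can be re-run in isolation and an identical
config + seed reproduces every artifact byte for byte.  (Wall-clock
timestamps go to ``run.log`` only, keeping the data artifacts
deterministic.)

Models are fitted on the training half; probability cut-offs are derived
from the training-sample ROC and then applied unchanged.  Complexity
predictions and the clinician comparison are produced for the full
included sample (mirroring a deployment over the whole intake
population, at the cost of partially reusing training clients) and,
separately, for the held-out test half.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ClientRecord,
    apply_exclusions,
    encode_cohort,
    impute_missing,
    outcome_table,
    read_cohort_csv,
    split_train_test,
    write_cohort_csv,
    write_exclusion_report,
    SplitResult,
)
from .evaluate import compare_policies, confusion, odds_ratio, report_text
from .outcomes import GAD7, PHQ9, InstrumentRule
from .prognostic import FittedLassoModel, LambdaGrid, fit_lasso, predict_score, select_lambda
from .stratify import clinician_assignment_label, predict_complexity
from .synthetic import CohortConfig, generate_cohort, write_ground_truth_csv
from .thresholds import CutoffPolicy, fixed_cutoff, predict_rcsi, roc_curve, youden_cutoff

__all__ = [
    "RunConfig",
    "RunManifest",
    "InstrumentFit",
    "run_pipeline",
    "fit_instrument_model",
    "score_cohort",
    "decide_cohort",
    "derive_seed",
]

logger = logging.getLogger(__name__)

INSTRUMENTS = ("PHQ9", "GAD7")
POLICIES = ("fixed_0.5", "roc_optimal")
_STATUS_COL = {"PHQ9": "phq9_status", "GAD7": "gad7_status"}
_INITIAL_COL = {"PHQ9": "phq9_initial", "GAD7": "gad7_initial"}
_STAGE_TAGS = {"simulate": 11, "split": 23, "boot_PHQ9": 31, "boot_GAD7": 37}


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), _STAGE_TAGS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: Path
    cohort: CohortConfig | None = None
    cohort_csv: str | None = None
    phq_rule: InstrumentRule = PHQ9
    gad_rule: InstrumentRule = GAD7
    grid: LambdaGrid = field(default_factory=LambdaGrid)
    B: int = 1000
    split_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.cohort is None and self.cohort_csv is None:
            self.cohort = CohortConfig()

    def rule(self, instrument: str) -> InstrumentRule:
        return self.phq_rule if instrument == "PHQ9" else self.gad_rule

    @classmethod
    def from_yaml(cls, path, out_dir, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs: dict = {"out_dir": out_dir}
        if "cohort" in doc:
            kwargs["cohort"] = CohortConfig.from_dict(doc["cohort"])
        if "cohort_csv" in doc:
            kwargs["cohort_csv"] = doc["cohort_csv"]
        if "grid" in doc:
            kwargs["grid"] = LambdaGrid(**doc["grid"])
        for key in ("B", "split_ratio", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if seed is not None:
            kwargs["seed"] = seed
        cfg = cls(**kwargs)
        if seed is not None and cfg.cohort is not None:
            cfg.cohort.seed = derive_seed(seed, "simulate")
        return cfg


@dataclass
class RunManifest:
    """Machine-readable record of a run (deterministic; no timestamps)."""

    version: str
    seeds: dict[str, int]
    input_hash: str
    stage_counts: dict[str, int]
    artifacts: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class InstrumentFit:
    """One instrument's fitted model plus its selection diagnostics."""

    model: FittedLassoModel
    curve: "object"             # Dot632Curve
    train_roc: "object"         # RocCurve
    policies: dict[str, CutoffPolicy]


# ---------------------------------------------------------------------------
# Reusable stages (also backing the CLI subcommands)


def fit_instrument_model(instrument: str, split: SplitResult, outcomes: pd.DataFrame,
                         grid: LambdaGrid, B: int, seed: int) -> InstrumentFit:
    """Select lambda on the training half, fit, and derive both cut-off
    policies from the training-sample ROC.

    The returned model's ``meta`` carries the training imputation means
    and the cut-offs, so the persisted JSON is self-contained for
    scoring new clients.
    """
    X_train = encode_cohort(split.train, instrument)
    X_train_imp = impute_missing(X_train)
    y_train = (outcomes.loc[X_train.index, _STATUS_COL[instrument]] == "rcsi").to_numpy(dtype=float)

    lam, curve = select_lambda(X_train_imp, y_train, grid, B, seed)
    model = fit_lasso(X_train_imp, y_train, lam, instrument=instrument)
    logger.info("%s: lambda=%.5g, %d non-zero coefficients",
                instrument, lam, len(model.nonzero_features))

    score_train = predict_score(model, X_train_imp)
    train_roc = roc_curve(score_train, y_train.astype(int))
    policies = {"fixed_0.5": fixed_cutoff(0.5), "roc_optimal": youden_cutoff(train_roc)}

    model.meta = {
        "B": B,
        "seed": seed,
        "grid": {"lower": grid.lower, "upper": grid.upper, "n_points": grid.n_points},
        "n_train": len(split.train),
        "imputation_means": {k: float(v) for k, v in X_train.mean(axis=0).items()},
        "cutoffs": {name: p.threshold for name, p in policies.items()},
    }
    return InstrumentFit(model=model, curve=curve, train_roc=train_roc, policies=policies)


def score_cohort(model: FittedLassoModel, records: Sequence[ClientRecord]) -> np.ndarray:
    """RCSI probability scores for arbitrary records, imputing missing
    cells with the model's stored training means."""
    X = encode_cohort(records, model.instrument)
    means = model.meta.get("imputation_means")
    if means is None:
        raise ValueError("model carries no imputation means; refit with fit_instrument_model")
    X = X.fillna(pd.Series(means))
    return predict_score(model, X)


def decide_cohort(records: Sequence[ClientRecord], outcomes: pd.DataFrame,
                  scores: dict[str, np.ndarray],
                  policies: dict[str, dict[str, CutoffPolicy]],
                  phq_rule: InstrumentRule = PHQ9,
                  gad_rule: InstrumentRule = GAD7) -> tuple[pd.DataFrame, dict[str, list[str]], dict]:
    """Apply both cut-off policies and the dual-model complexity rule.

    Returns the decision table, per-policy complexity labels, and the
    per-(instrument, policy) predicted-RCSI vectors.
    """
    clinician = [clinician_assignment_label(r.modality) for r in records]
    decision_rows = []
    pred_labels: dict[str, list[str]] = {}
    pred_rcsi: dict[tuple[str, str], np.ndarray] = {}
    for policy_name in POLICIES:
        phq_pred = predict_rcsi(scores["PHQ9"], policies["PHQ9"][policy_name])
        gad_pred = predict_rcsi(scores["GAD7"], policies["GAD7"][policy_name])
        pred_rcsi[("PHQ9", policy_name)] = phq_pred
        pred_rcsi[("GAD7", policy_name)] = gad_pred
        labels = []
        for i, r in enumerate(records):
            d = predict_complexity(
                outcomes.loc[r.client_id, _INITIAL_COL["PHQ9"]],
                outcomes.loc[r.client_id, _INITIAL_COL["GAD7"]],
                int(phq_pred[i]), int(gad_pred[i]),
                phq_rule, gad_rule, policy_kind=policy_name)
            labels.append(d.predicted_complexity)
            decision_rows.append({
                "client_id": r.client_id,
                "policy": policy_name,
                "predicted_complexity": d.predicted_complexity,
                "recommended_intensity": d.recommended_intensity,
                "clinician_label": clinician[i],
            })
        pred_labels[policy_name] = labels
    return pd.DataFrame(decision_rows), pred_labels, pred_rcsi


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("straticare")
    root.addHandler(log_handler)
    if root.level == logging.NOTSET or root.level > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, out: Path) -> RunManifest:
    seeds = {"top_level": config.seed}
    counts: dict[str, int] = {}
    artifacts: list[str] = []

    # -- stage 0: obtain the cohort ------------------------------------
    if config.cohort_csv is not None:
        records = read_cohort_csv(config.cohort_csv)
        cohort_path = Path(config.cohort_csv)
        logger.info("loaded %d records from %s", len(records), cohort_path)
    else:
        assert config.cohort is not None
        records, truth = generate_cohort(config.cohort)
        seeds["simulate"] = config.cohort.seed
        cohort_path = out / "cohort.csv"
        write_cohort_csv(records, cohort_path)
        write_ground_truth_csv(truth, out / "ground_truth.csv")
        artifacts += ["cohort.csv", "ground_truth.csv"]
        logger.info("simulated %d records", len(records))
    counts["input_records"] = len(records)

    # -- stage 1: inclusion/exclusion ----------------------------------
    included, excluded = apply_exclusions(records, config.phq_rule, config.gad_rule)
    write_exclusion_report(excluded, out / "exclusions.csv")
    artifacts.append("exclusions.csv")
    counts["included"] = len(included)
    counts["excluded"] = len(excluded)
    logger.info("inclusion filter: %d included, %d excluded", len(included), len(excluded))

    # -- stage 2: 50-50 split ------------------------------------------
    split_seed = derive_seed(config.seed, "split")
    seeds["split"] = split_seed
    split = split_train_test(included, config.split_ratio, split_seed)
    counts["train"] = len(split.train)
    counts["test"] = len(split.test)
    logger.info("split: %d train, %d test", len(split.train), len(split.test))
    pd.DataFrame(
        [(r.client_id, "train") for r in split.train] + [(r.client_id, "test") for r in split.test],
        columns=["client_id", "fold"],
    ).to_csv(out / "split.csv", index=False)
    artifacts.append("split.csv")

    # -- stage 3: outcomes ---------------------------------------------
    outcomes = outcome_table(included, config.phq_rule, config.gad_rule)
    outcomes.to_csv(out / "outcomes.csv")
    artifacts.append("outcomes.csv")
    test_ids = {r.client_id for r in split.test}

    # -- stages 4-5: per-instrument models, scores, cut-offs -----------
    fits: dict[str, InstrumentFit] = {}
    scores_full: dict[str, np.ndarray] = {}
    aucs: dict[str, dict] = {}
    for inst in INSTRUMENTS:
        boot_seed = derive_seed(config.seed, f"boot_{inst}")
        seeds[f"boot_{inst}"] = boot_seed
        fit = fit_instrument_model(inst, split, outcomes, config.grid, config.B, boot_seed)
        fits[inst] = fit
        fit.curve.to_frame().to_csv(out / f"lambda_curve_{inst.lower()}.csv", index=False)
        fit.train_roc.to_frame().to_csv(out / f"roc_train_{inst.lower()}.csv", index=False)
        fit.model.to_json(out / f"model_{inst.lower()}.json")
        artifacts += [f"lambda_curve_{inst.lower()}.csv", f"roc_train_{inst.lower()}.csv",
                      f"model_{inst.lower()}.json"]

        scores_full[inst] = score_cohort(fit.model, included)
        y_full = (outcomes[_STATUS_COL[inst]] == "rcsi").to_numpy(dtype=int)
        test_mask = np.asarray([r.client_id in test_ids for r in included])
        test_roc = roc_curve(scores_full[inst][test_mask], y_full[test_mask])
        aucs[inst] = {
            "train": {"auc": fit.train_roc.auc, "ci95": list(fit.train_roc.auc_ci)},
            "test": {"auc": test_roc.auc, "ci95": list(test_roc.auc_ci)},
        }

    # -- stage 6: stratification decisions -----------------------------
    policies = {inst: fits[inst].policies for inst in INSTRUMENTS}
    decisions, pred_labels, pred_rcsi = decide_cohort(
        included, outcomes, scores_full, policies, config.phq_rule, config.gad_rule)
    decisions.to_csv(out / "decisions.csv", index=False)
    artifacts.append("decisions.csv")

    # -- stage 7: evaluation -------------------------------------------
    actual = list(outcomes["complexity"])
    clinician = [clinician_assignment_label(r.modality) for r in included]
    arms = {"clinician": clinician, **pred_labels}
    report = compare_policies(arms, actual)

    test_pos = [i for i, r in enumerate(included) if r.client_id in test_ids]
    report_test = compare_policies(
        {name: [labels[i] for i in test_pos] for name, labels in arms.items()},
        [actual[i] for i in test_pos])

    # instrument-level predictive validity on the held-out half
    instrument_or = {}
    for inst in INSTRUMENTS:
        y_test = (outcomes.loc[[included[i].client_id for i in test_pos],
                               _STATUS_COL[inst]] == "rcsi")
        for policy_name in POLICIES:
            pred = pred_rcsi[(inst, policy_name)][test_pos]
            cm = confusion(["Cx" if p else "St" for p in pred],
                           ["Cx" if t else "St" for t in y_test])
            orr = odds_ratio(cm)
            instrument_or[f"{inst}_{policy_name}"] = {
                "odds_ratio": orr.or_point, "ci95": list(orr.ci95),
                "continuity_corrected": orr.continuity_corrected,
                "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            }

    full_report = {
        "full_sample": report,
        "test_sample": report_test,
        "auc": aucs,
        "instrument_odds_ratios_test": instrument_or,
        "lambda_selected": {inst: fits[inst].model.lambda_selected for inst in INSTRUMENTS},
        "cutoffs": {inst: {k: p.threshold for k, p in fits[inst].policies.items()}
                    for inst in INSTRUMENTS},
        "counts": counts,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(full_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(report_text(report))
    artifacts += ["report.json", "report.txt"]

    manifest = RunManifest(
        version=__version__,
        seeds=seeds,
        input_hash=_sha256(cohort_path),
        stage_counts=counts,
        artifacts=sorted(artifacts),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
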