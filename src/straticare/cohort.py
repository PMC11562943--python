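"""Treatment-episode records: filtering, encoding, imputation, splitting.

One :class:`ClientRecord` is a single outpatient CBT treatment episode:
sociodemographics, four neighbourhood marginalization quantiles, the
assigned treatment modality, and date-ordered PHQ-9 / GAD-7 session
scores.

Inclusion requires at least two recorded sessions on *each* instrument
(the initial one included) and a completed treatment: the last recorded
session falls within the delivery format's completion window (98 days
from admission for eCBT, 147 days for group or one-on-one CBT; the
boundary day counts as complete), or reliable improvement was reached on
either instrument before the window closed.

Feature encoding produces a purely numeric design matrix: the
instrument's initial score, age, and one-hot indicators with fixed
reference categories (male; employed; lives by self; 1st quantile of each
marginalization index).  Missing categorical data leaves the whole dummy
group NaN; single mean imputation then fills every missing cell with the
training-sample column mean, so imputed indicator cells are fractional
probabilities.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .outcomes import GAD7, PHQ9, InstrumentRule, RcsiStatus, compute_rcsi

__all__ = [
    "ClientRecord",
    "SplitResult",
    "LIVING_ARRANGEMENTS",
    "MODALITIES",
    "DELIVERY_FORMATS",
    "QUANTILE_FIELDS",
    "COMPLETION_WINDOW_DAYS",
    "FEATURE_NAMES",
    "apply_exclusions",
    "encode_features",
    "encode_cohort",
    "impute_missing",
    "split_train_test",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_exclusion_report",
    "outcome_table",
]

LIVING_ARRANGEMENTS = (
    "by_self",
    "with_children",
    "with_non_family",
    "with_other_relatives",
    "with_parents",
    "with_spouse_partner",
    "with_spouse_partner_roommate",
)
MODALITIES = ("HICBT", "stepped", "LICBT")
DELIVERY_FORMATS = ("individual", "group", "ecbt")
QUANTILE_FIELDS = (
    "instability_q",
    "deprivation_q",
    "dependency_q",
    "ethnic_concentration_q",
)

#: Days from admission within which treatment counts as complete.
COMPLETION_WINDOW_DAYS = {"ecbt": 98, "group": 147, "individual": 147}

# Reference categories (omitted from the dummy encoding): male, employed,
# by_self, 1st quantile of each index.
FEATURE_NAMES = (
    ("initial_score", "age")
    + ("sex_female", "employment_not_employed")
    + tuple(f"living_{lvl}" for lvl in LIVING_ARRANGEMENTS[1:])
    + tuple(f"{q}{k}" for q in QUANTILE_FIELDS for k in (2, 3, 4, 5))
)


@dataclass
class ClientRecord:
    """A single treatment episode.

    ``phq9_scores`` / ``gad7_scores`` are date-sorted ``(date, score)``
    lists.  Categorical fields use ``None`` for missing.
    """

    client_id: str
    age_at_admission: float
    sex: str
    employment: str | None
    living_arrangement: str | None
    instability_q: int | None
    deprivation_q: int | None
    dependency_q: int | None
    ethnic_concentration_q: int | None
    modality: str
    admission_date: date
    phq9_scores: list[tuple[date, int]] = field(default_factory=list)
    gad7_scores: list[tuple[date, int]] = field(default_factory=list)
    #: Delivery format drives the completion window.  When absent it is
    #: inferred from the modality (HICBT -> one-on-one, otherwise eCBT).
    delivery_format: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.employment is not None and self.employment not in ("employed", "not_employed"):
            raise ValueError(f"unknown employment {self.employment!r}")
        if self.living_arrangement is not None and self.living_arrangement not in LIVING_ARRANGEMENTS:
            raise ValueError(f"unknown living arrangement {self.living_arrangement!r}")
        if self.delivery_format is not None and self.delivery_format not in DELIVERY_FORMATS:
            raise ValueError(f"unknown delivery format {self.delivery_format!r}")
        for name in QUANTILE_FIELDS:
            q = getattr(self, name)
            if q is not None and q not in (1, 2, 3, 4, 5):
                raise ValueError(f"{name} must be in 1..5, got {q}")
        for rule, attr in ((PHQ9, "phq9_scores"), (GAD7, "gad7_scores")):
            scores = sorted(getattr(self, attr), key=lambda ds: ds[0])
            setattr(self, attr, scores)
            for _, s in scores:
                rule.validate_score(s)

    # -- score helpers -------------------------------------------------

    def scores(self, instrument: str) -> list[tuple[date, int]]:
        if instrument == "PHQ9":
            return self.phq9_scores
        if instrument == "GAD7":
            return self.gad7_scores
        raise ValueError(f"unknown instrument {instrument!r}")

    def initial_score(self, instrument: str) -> int:
        scores = self.scores(instrument)
        if not scores:
            raise ValueError(f"{self.client_id}: no {instrument} scores recorded")
        return scores[0][1]

    def last_score_within(self, instrument: str, cutoff: date) -> int | None:
        """Latest recorded score on or before ``cutoff``, or None."""
        in_window = [s for d, s in self.scores(instrument) if d <= cutoff]
        return in_window[-1] if in_window else None

    def last_session_date(self) -> date | None:
        dates = [d for d, _ in self.phq9_scores] + [d for d, _ in self.gad7_scores]
        return max(dates) if dates else None

    def format_for_window(self) -> str:
        if self.delivery_format is not None:
            return self.delivery_format
        return "individual" if self.modality == "HICBT" else "ecbt"

    def completion_cutoff(self) -> date:
        """Last admissible session date (inclusive) for a complete episode."""
        return self.admission_date + timedelta(days=COMPLETION_WINDOW_DAYS[self.format_for_window()])


@dataclass
class SplitResult:
    """Random train/test partition of a record list."""

    train: list[ClientRecord]
    test: list[ClientRecord]
    seed: int


# ---------------------------------------------------------------------------
# Inclusion / exclusion


def _reliable_improvement_before(record: ClientRecord, cutoff: date,
                                 phq_rule: InstrumentRule, gad_rule: InstrumentRule) -> bool:
    for rule, instrument in ((phq_rule, "PHQ9"), (gad_rule, "GAD7")):
        scores = record.scores(instrument)
        if not scores:
            continue
        initial = scores[0][1]
        for d, s in scores[1:]:
            if d <= cutoff and initial - s >= rule.reliable_change:
                return True
    return False


def apply_exclusions(
    records: Iterable[ClientRecord],
    phq_rule: InstrumentRule = PHQ9,
    gad_rule: InstrumentRule = GAD7,
) -> tuple[list[ClientRecord], list[tuple[ClientRecord, str]]]:
    """Partition records into included episodes and (record, reason) pairs.

    Reason codes: ``insufficient_scores`` (fewer than two recorded
    sessions on either instrument) and ``incomplete_treatment`` (last
    session past the completion window without prior reliable
    improvement).
    """
    included: list[ClientRecord] = []
    excluded: list[tuple[ClientRecord, str]] = []
    for record in records:
        if len(record.phq9_scores) < 2 or len(record.gad7_scores) < 2:
            excluded.append((record, "insufficient_scores"))
            continue
        cutoff = record.completion_cutoff()
        last = record.last_session_date()
        assert last is not None
        if last <= cutoff or _reliable_improvement_before(record, cutoff, phq_rule, gad_rule):
            included.append(record)
        else:
            excluded.append((record, "incomplete_treatment"))
    return included, excluded


# ---------------------------------------------------------------------------
# Feature encoding


def encode_features(record: ClientRecord, instrument: str) -> dict[str, float]:
    """Numeric feature map for one record; NaN marks missing cells."""
    feats: dict[str, float] = dict.fromkeys(FEATURE_NAMES, 0.0)
    feats["initial_score"] = float(record.initial_score(instrument))
    feats["age"] = float(record.age_at_admission)
    feats["sex_female"] = 1.0 if record.sex == "female" else 0.0
    if record.employment is None:
        feats["employment_not_employed"] = math.nan
    elif record.employment == "not_employed":
        feats["employment_not_employed"] = 1.0
    if record.living_arrangement is None:
        for lvl in LIVING_ARRANGEMENTS[1:]:
            feats[f"living_{lvl}"] = math.nan
    elif record.living_arrangement != "by_self":
        feats[f"living_{record.living_arrangement}"] = 1.0
    for qname in QUANTILE_FIELDS:
        q = getattr(record, qname)
        if q is None:
            for k in (2, 3, 4, 5):
                feats[f"{qname}{k}"] = math.nan
        elif q != 1:
            feats[f"{qname}{q}"] = 1.0
    return feats


def encode_cohort(records: Sequence[ClientRecord], instrument: str) -> pd.DataFrame:
    """Design matrix for a record list, indexed by client_id."""
    rows = [encode_features(r, instrument) for r in records]
    index = pd.Index([r.client_id for r in records], name="client_id")
    return pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES), dtype=float)


def impute_missing(train: pd.DataFrame, apply_to: pd.DataFrame | None = None) -> pd.DataFrame:
    """Single mean imputation: fill each missing cell with the training
    column mean (for one-hot indicator columns this is the observed
    category probability).  Observed cells are never altered.
    """
    if train.empty:
        raise ValueError("training frame is empty")
    all_missing = [c for c in train.columns if train[c].isna().all()]
    if all_missing:
        raise ValueError(f"column(s) entirely missing in training data: {all_missing}")
    means = train.mean(axis=0)
    target = train if apply_to is None else apply_to
    return target.fillna(means)


# ---------------------------------------------------------------------------
# Train/test split


def split_train_test(records: Sequence[ClientRecord], ratio: float = 0.5,
                     seed: int = 0) -> SplitResult:
    """Uniform random partition; ``ratio`` is the training fraction.

    The training size is round-half-up of ``n * ratio``, so with an odd n
    at ratio 0.5 the extra record goes to training.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be strictly between 0 and 1")
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty record list")
    n_train = int(math.floor(n * ratio + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [records[i] for i in sorted(order[:n_train])]
    test = [records[i] for i in sorted(order[n_train:])]
    return SplitResult(train=train, test=test, seed=seed)


# ---------------------------------------------------------------------------
# CSV dialect

_CSV_COLUMNS = [
    "client_id", "age_at_admission", "sex", "employment", "living_arrangement",
    "instability_q", "deprivation_q", "dependency_q", "ethnic_concentration_q",
    "modality", "delivery_format", "admission_date", "phq9_scores", "gad7_scores",
]


def _format_scores(scores: list[tuple[date, int]]) -> str:
    return ";".join(f"{d.isoformat()}={s}" for d, s in scores)


def _parse_scores(text: str) -> list[tuple[date, int]]:
    if not text:
        return []
    out = []
    for item in text.split(";"):
        d, s = item.split("=")
        out.append((date.fromisoformat(d), int(s)))
    return out


def write_cohort_csv(records: Iterable[ClientRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.client_id,
                f"{r.age_at_admission:g}",
                r.sex,
                r.employment or "",
                r.living_arrangement or "",
                r.instability_q if r.instability_q is not None else "",
                r.deprivation_q if r.deprivation_q is not None else "",
                r.dependency_q if r.dependency_q is not None else "",
                r.ethnic_concentration_q if r.ethnic_concentration_q is not None else "",
                r.modality,
                r.delivery_format or "",
                r.admission_date.isoformat(),
                _format_scores(r.phq9_scores),
                _format_scores(r.gad7_scores),
            ])


def read_cohort_csv(path) -> list[ClientRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(ClientRecord(
                client_id=row["client_id"],
                age_at_admission=float(row["age_at_admission"]),
                sex=row["sex"],
                employment=row["employment"] or None,
                living_arrangement=row["living_arrangement"] or None,
                instability_q=int(row["instability_q"]) if row["instability_q"] else None,
                deprivation_q=int(row["deprivation_q"]) if row["deprivation_q"] else None,
                dependency_q=int(row["dependency_q"]) if row["dependency_q"] else None,
                ethnic_concentration_q=int(row["ethnic_concentration_q"]) if row["ethnic_concentration_q"] else None,
                modality=row["modality"],
                delivery_format=row["delivery_format"] or None,
                admission_date=date.fromisoformat(row["admission_date"]),
                phq9_scores=_parse_scores(row["phq9_scores"]),
                gad7_scores=_parse_scores(row["gad7_scores"]),
            ))
    return records


def write_exclusion_report(excluded: Iterable[tuple[ClientRecord, str]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["client_id", "reason"])
        for record, reason in excluded:
            writer.writerow([record.client_id, reason])


def outcome_table(records: Sequence[ClientRecord],
                  phq_rule: InstrumentRule = PHQ9,
                  gad_rule: InstrumentRule = GAD7) -> pd.DataFrame:
    """Per-episode RCSI statuses and actual complexity for included records.

    The last score is the latest recorded score within the completion
    window.
    """
    from .outcomes import actual_complexity

    rows = []
    for r in records:
        cutoff = r.completion_cutoff()
        phq_last = r.last_score_within("PHQ9", cutoff)
        gad_last = r.last_score_within("GAD7", cutoff)
        if phq_last is None or gad_last is None:
            raise ValueError(f"{r.client_id}: no score within the completion window")
        phq = compute_rcsi(r.initial_score("PHQ9"), phq_last, phq_rule)
        gad = compute_rcsi(r.initial_score("GAD7"), gad_last, gad_rule)
        rows.append({
            "client_id": r.client_id,
            "phq9_initial": phq.initial,
            "phq9_last": phq.last,
            "phq9_status": phq.status.value,
            "gad7_initial": gad.initial,
            "gad7_last": gad.last,
            "gad7_status": gad.status.value,
            "complexity": actual_complexity(phq, gad),
        })
    return pd.DataFrame(rows).set_index("client_id")
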