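"""Seeded synthetic cohort generator.

Emulates the marginal structure of an outpatient CBT clinic sample
(n = 953, 69% female, age 34.6 +/- 13.11, first PHQ-9 15.0 +/- 5.96,
first GAD-7 13.1 +/- 5.06, modality mix 36/7/57% HICBT/stepped/LICBT,
and the published employment / living-arrangement / marginalization-
quantile frequencies) with a *known* linear outcome process so that
ground truth is recoverable:

    last = clip(round(initial - (b0 + sum_j b_j x_j) + eps), range)

where ``x`` is the encoded covariate vector of :mod:`straticare.cohort`,
``b`` the configured ``true_coefficients`` for the instrument and
``eps ~ N(0, noise_sd)``.  Covariates are drawn as independent marginals;
missingness is injected completely at random (MCAR) at the configured
rates, independent of outcomes, and jointly across the four
neighbourhood quantiles (in the source data the four indices derive from
one postal code, so they are missing together).

The generator does not simulate session-by-session trajectories: each
episode carries a first score at admission and a last score at a random
in-window session day.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from . import cohort as _cohort
from .cohort import (
    COMPLETION_WINDOW_DAYS,
    LIVING_ARRANGEMENTS,
    QUANTILE_FIELDS,
    ClientRecord,
    encode_features,
)
from .outcomes import GAD7, PHQ9, InstrumentRule, compute_rcsi

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "write_ground_truth_csv",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


_PROB_TOL = 1e-9

# Observed-category frequencies conditional on non-missing (counts / observed n).
_DEFAULT_EMPLOYMENT = {"employed": 418 / 893, "not_employed": 475 / 893}
_DEFAULT_LIVING = {
    "by_self": 115 / 923,
    "with_children": 60 / 923,
    "with_non_family": 32 / 923,
    "with_other_relatives": 77 / 923,
    "with_parents": 287 / 923,
    "with_spouse_partner": 171 / 923,
    "with_spouse_partner_roommate": 181 / 923,
}
_DEFAULT_QUANTILES = {
    "instability_q": [233 / 902, 186 / 902, 198 / 902, 152 / 902, 133 / 902],
    "deprivation_q": [149 / 902, 253 / 902, 197 / 902, 146 / 902, 157 / 902],
    "dependency_q": [300 / 902, 187 / 902, 168 / 902, 138 / 902, 109 / 902],
    "ethnic_concentration_q": [85 / 902, 168 / 902, 248 / 902, 248 / 902, 153 / 902],
}
_DEFAULT_MODALITY = {"HICBT": 347 / 953, "stepped": 62 / 953, "LICBT": 544 / 953}

# Default outcome process: improvement driven by initial severity.  At the
# default first-score means the expected decreases are ~5.0 (PHQ-9) and
# ~4.3 (GAD-7) points, matching the published last-score means; the noise
# SDs approximately reproduce the published last-score SDs.
_DEFAULT_COEFFS = {
    "PHQ9": {"intercept": -1.0, "initial_score": 0.4},
    "GAD7": {"intercept": -0.9, "initial_score": 0.4},
}
_DEFAULT_NOISE = {"PHQ9": 4.9, "GAD7": 4.4}


@dataclass
class CohortConfig:
    """Generator settings; defaults target the published sample margins."""

    n_clients: int = 953
    seed: int = 0
    age_mean: float = 34.6
    age_sd: float = 13.11
    female_prop: float = 0.69
    employment_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EMPLOYMENT))
    living_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LIVING))
    quantile_probs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_QUANTILES.items()})
    modality_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MODALITY))
    first_score_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PHQ9": (15.0, 5.96), "GAD7": (13.1, 5.06)})
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COEFFS.items()})
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"employment": 0.06, "living_arrangement": 0.03,
                                 "neighbourhood": 0.05})
    #: Share of non-HICBT episodes delivered as eCBT (vs group CBT); the
    #: split within low-intensity care is not published.
    ecbt_prop: float = 0.5
    admission_start: date = date(2017, 1, 1)
    admission_end: date = date(2021, 12, 31)

    def validate(self) -> None:
        if self.n_clients < 1:
            raise ConfigurationError("n_clients must be >= 1")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be > 0")
        if not 0 <= self.female_prop <= 1:
            raise ConfigurationError("female_prop must be in [0, 1]")
        for name, probs in (("employment_probs", self.employment_probs),
                            ("living_probs", self.living_probs),
                            ("modality_probs", self.modality_probs)):
            if abs(sum(probs.values()) - 1.0) > _PROB_TOL:
                raise ConfigurationError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} has a negative probability")
        for qname, probs in self.quantile_probs.items():
            if qname not in QUANTILE_FIELDS:
                raise ConfigurationError(f"quantile_probs has unknown field {qname!r}")
            if len(probs) != 5 or abs(sum(probs) - 1.0) > _PROB_TOL or any(p < 0 for p in probs):
                raise ConfigurationError(f"quantile_probs[{qname!r}] must be 5 probabilities summing to 1")
        for inst, (mean, sd) in self.first_score_params.items():
            if sd <= 0:
                raise ConfigurationError(f"first_score_params[{inst!r}] SD must be > 0")
        for inst, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd[{inst!r}] must be >= 0")
        for fname, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise ConfigurationError(f"missing_rates[{fname!r}] must be in [0, 1)")
        if not 0 <= self.ecbt_prop <= 1:
            raise ConfigurationError("ecbt_prop must be in [0, 1]")
        valid_features = set(_cohort.FEATURE_NAMES) | {"intercept"}
        for inst, coeffs in self.true_coefficients.items():
            unknown = set(coeffs) - valid_features
            if unknown:
                raise ConfigurationError(
                    f"true_coefficients[{inst!r}] names unknown features {sorted(unknown)}")

    # -- plain-dict round trip (YAML/JSON configs) ---------------------

    def to_dict(self) -> dict:
        d = {
            "n_clients": self.n_clients, "seed": self.seed,
            "age_mean": self.age_mean, "age_sd": self.age_sd,
            "female_prop": self.female_prop,
            "employment_probs": dict(self.employment_probs),
            "living_probs": dict(self.living_probs),
            "quantile_probs": {k: list(v) for k, v in self.quantile_probs.items()},
            "modality_probs": dict(self.modality_probs),
            "first_score_params": {k: list(v) for k, v in self.first_score_params.items()},
            "true_coefficients": {k: dict(v) for k, v in self.true_coefficients.items()},
            "noise_sd": dict(self.noise_sd),
            "missing_rates": dict(self.missing_rates),
            "ecbt_prop": self.ecbt_prop,
            "admission_start": self.admission_start.isoformat(),
            "admission_end": self.admission_end.isoformat(),
        }
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        kwargs = dict(data)
        for key in ("admission_start", "admission_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = date.fromisoformat(kwargs[key])
        if "first_score_params" in kwargs:
            kwargs["first_score_params"] = {
                k: tuple(v) for k, v in kwargs["first_score_params"].items()}
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown cohort config field(s) {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Latent outcome process behind a generated cohort."""

    client_ids: list[str]
    expected_change: dict[str, np.ndarray]  # instrument -> latent mean decrease
    true_rcsi: dict[str, np.ndarray]        # instrument -> bool, rule applied to realized scores
    coefficients: dict[str, dict[str, float]]


_RULES = {"PHQ9": PHQ9, "GAD7": GAD7}


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p / p.sum())


def generate_cohort(config: CohortConfig) -> tuple[list[ClientRecord], GroundTruth]:
    """Draw a seeded cohort plus its ground truth.

    Identical configs (including the seed) produce identical cohorts.
    Scores are rounded to integers and clamped to the instrument ranges.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_clients

    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 16.0, 90.0).round(1)
    female = rng.random(n) < config.female_prop
    employment = _draw_categorical(rng, config.employment_probs, n)
    living = _draw_categorical(rng, config.living_probs, n)
    quantiles = {q: rng.choice(np.arange(1, 6), size=n, p=np.asarray(probs) / sum(probs))
                 for q, probs in config.quantile_probs.items()}
    modality = _draw_categorical(rng, config.modality_probs, n)
    ecbt = rng.random(n) < config.ecbt_prop

    span = (config.admission_end - config.admission_start).days
    admit_offsets = rng.integers(0, span + 1, n)

    firsts: dict[str, np.ndarray] = {}
    for inst, (mean, sd) in config.first_score_params.items():
        lo, hi = _RULES[inst].score_range
        firsts[inst] = np.clip(np.round(rng.normal(mean, sd, n)), lo, hi).astype(int)

    records: list[ClientRecord] = []
    width = len(str(n))
    for i in range(n):
        fmt = "individual" if modality[i] == "HICBT" else ("ecbt" if ecbt[i] else "group")
        admission = config.admission_start + timedelta(days=int(admit_offsets[i]))
        window = COMPLETION_WINDOW_DAYS[fmt]
        last_day = int(rng.integers(28, window + 1))
        records.append(ClientRecord(
            client_id=f"c{i:0{width}d}",
            age_at_admission=float(ages[i]),
            sex="female" if female[i] else "male",
            employment=str(employment[i]),
            living_arrangement=str(living[i]),
            instability_q=int(quantiles["instability_q"][i]),
            deprivation_q=int(quantiles["deprivation_q"][i]),
            dependency_q=int(quantiles["dependency_q"][i]),
            ethnic_concentration_q=int(quantiles["ethnic_concentration_q"][i]),
            modality=str(modality[i]),
            delivery_format=fmt,
            admission_date=admission,
            phq9_scores=[(admission, int(firsts["PHQ9"][i]))],
            gad7_scores=[(admission, int(firsts["GAD7"][i]))],
        ))
        records[-1]._last_day = last_day  # type: ignore[attr-defined]

    # Outcome process on the fully observed covariates (before missingness).
    expected_change: dict[str, np.ndarray] = {}
    true_rcsi: dict[str, np.ndarray] = {}
    for inst in ("PHQ9", "GAD7"):
        rule = _RULES[inst]
        lo, hi = rule.score_range
        coeffs = config.true_coefficients.get(inst, {})
        lp = np.zeros(n)
        for i, r in enumerate(records):
            feats = encode_features(r, inst)
            lp[i] = coeffs.get("intercept", 0.0) + sum(
                coeffs[name] * feats[name] for name in coeffs if name != "intercept")
        noise = rng.normal(0.0, config.noise_sd.get(inst, 0.0), n)
        lasts = np.clip(np.round(firsts[inst] - lp + noise), lo, hi).astype(int)
        expected_change[inst] = lp
        rcsi = np.empty(n, dtype=bool)
        for i, r in enumerate(records):
            session = r.admission_date + timedelta(days=r._last_day)  # type: ignore[attr-defined]
            pair = (session, int(lasts[i]))
            (r.phq9_scores if inst == "PHQ9" else r.gad7_scores).append(pair)
            rcsi[i] = compute_rcsi(int(firsts[inst][i]), int(lasts[i]), rule).status.value == "rcsi"
        true_rcsi[inst] = rcsi
    for r in records:
        del r._last_day  # type: ignore[attr-defined]

    miss_seed = int(rng.integers(0, 2**31))
    records = inject_missingness(records, config.missing_rates, miss_seed)

    truth = GroundTruth(
        client_ids=[r.client_id for r in records],
        expected_change=expected_change,
        true_rcsi=true_rcsi,
        coefficients={k: dict(v) for k, v in config.true_coefficients.items()},
    )
    return records, truth


def inject_missingness(records: Sequence[ClientRecord],
                       rates: Mapping[str, float], seed: int) -> list[ClientRecord]:
    """Blank out covariates completely at random at the given rates.

    Recognised rate keys: ``employment``, ``living_arrangement`` and
    ``neighbourhood`` (the latter blanks all four marginalization
    quantiles together).  Returns new records; inputs are not mutated.
    """
    for fname, rate in rates.items():
        if fname not in ("employment", "living_arrangement", "neighbourhood"):
            raise ConfigurationError(f"missing_rates has unknown field {fname!r}")
        if not 0 <= rate < 1:
            raise ConfigurationError(f"missing_rates[{fname!r}] must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(records)
    mask_emp = rng.random(n) < rates.get("employment", 0.0)
    mask_liv = rng.random(n) < rates.get("living_arrangement", 0.0)
    mask_nbh = rng.random(n) < rates.get("neighbourhood", 0.0)
    out = []
    for i, r in enumerate(records):
        changes: dict[str, object] = {}
        if mask_emp[i]:
            changes["employment"] = None
        if mask_liv[i]:
            changes["living_arrangement"] = None
        if mask_nbh[i]:
            changes.update({q: None for q in QUANTILE_FIELDS})
        out.append(replace(r, **changes) if changes else replace(r))
    return out


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["client_id", "expected_change_phq9", "expected_change_gad7",
                         "true_rcsi_phq9", "true_rcsi_gad7"])
        for i, cid in enumerate(truth.client_ids):
            writer.writerow([
                cid,
                f"{truth.expected_change['PHQ9'][i]:.6f}",
                f"{truth.expected_change['GAD7'][i]:.6f}",
                int(truth.true_rcsi["PHQ9"][i]),
                int(truth.true_rcsi["GAD7"][i]),
            ])
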