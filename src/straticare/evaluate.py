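"""Confusion matrices, odds ratios, and the three-way policy comparison.

The positive class is the *complex* case (Cx) throughout: sensitivity is
the fraction of actually complex clients a policy routes to
high-intensity CBT, specificity the fraction of standard clients routed
to low-intensity care.  Values are kept at full precision internally and
rounded half-up to three decimals only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ConfusionSummary", "OddsRatioResult", "confusion", "odds_ratio",
           "compare_policies", "report_text"]


def round3(value: float) -> float:
    """Half-up rounding to 3 decimals (presentation only)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 counts with Cx as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    def rounded(self) -> dict[str, float]:
        return {
            "accuracy": round3(self.accuracy),
            "sensitivity": round3(self.sensitivity),
            "specificity": round3(self.specificity),
        }


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci95: tuple[float, float]
    continuity_corrected: bool


def confusion(predicted: Sequence[str], actual: Sequence[str],
              positive: str = "Cx") -> ConfusionSummary:
    """Tabulate predicted vs actual labels (both two-valued)."""
    if len(predicted) != len(actual):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(actual)} labels")
    p = np.asarray([lbl == positive for lbl in predicted])
    a = np.asarray([lbl == positive for lbl in actual])
    return ConfusionSummary(
        tp=int(np.sum(p & a)),
        fp=int(np.sum(p & ~a)),
        fn=int(np.sum(~p & a)),
        tn=int(np.sum(~p & ~a)),
    )


def odds_ratio(cm: ConfusionSummary) -> OddsRatioResult:
    """Cross-product odds ratio with a Wald (log-scale) 95% interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    cells = [cm.tp, cm.fp, cm.fn, cm.tn]
    corrected = any(c == 0 for c in cells)
    tp, fp, fn, tn = [c + 0.5 for c in cells] if corrected else [float(c) for c in cells]
    point = (tp * tn) / (fp * fn)
    se = np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    lo = float(np.exp(np.log(point) - 1.96 * se))
    hi = float(np.exp(np.log(point) + 1.96 * se))
    return OddsRatioResult(or_point=float(point), ci95=(lo, hi),
                           continuity_corrected=corrected)


def compare_policies(arms: Mapping[str, Sequence[str]],
                     actual: Sequence[str]) -> dict:
    """Evaluate each arm's predicted complexity labels against actual
    complexity.

    ``arms`` maps an arm name (e.g. ``clinician``, ``fixed_0.5``,
    ``roc_optimal``) to its per-client Cx/St labels, aligned with
    ``actual``.  Returns a JSON-ready report: per-arm 2x2 counts,
    full-precision and 3-decimal statistics, odds ratio, and a frequency
    table (rows: predicted Cx/St per arm; columns: actual Cx/St).
    """
    if not arms:
        raise ValueError("no comparison arms supplied")
    report: dict = {"n": len(actual), "positive_class": "Cx", "arms": {}, "frequency_table": []}
    for name, predicted in arms.items():
        cm = confusion(predicted, actual)
        orr = odds_ratio(cm)
        report["arms"][name] = {
            "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "accuracy": cm.accuracy,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "rounded": cm.rounded(),
            "odds_ratio": {"point": orr.or_point, "ci95": list(orr.ci95),
                           "continuity_corrected": orr.continuity_corrected},
        }
        report["frequency_table"].extend([
            {"arm": name, "predicted": "Cx", "actual_cx": cm.tp, "actual_st": cm.fp,
             "total": cm.tp + cm.fp},
            {"arm": name, "predicted": "St", "actual_cx": cm.fn, "actual_st": cm.tn,
             "total": cm.fn + cm.tn},
        ])
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering of a :func:`compare_policies` report."""
    lines = [f"Policy comparison against actual case complexity (n = {report['n']})",
             f"Positive class: {report['positive_class']}", ""]
    header = f"{'arm':<16}{'accuracy':>10}{'sensitivity':>13}{'specificity':>13}{'OR':>10}"
    lines.append(header)
    lines.append("-" * len(header))
    for name, arm in report["arms"].items():
        r = arm["rounded"]
        lines.append(f"{name:<16}{r['accuracy']:>10.3f}{r['sensitivity']:>13.3f}"
                     f"{r['specificity']:>13.3f}{arm['odds_ratio']['point']:>10.2f}")
    lines.append("")
    lines.append(f"{'arm':<16}{'predicted':>10}{'actual Cx':>11}{'actual St':>11}{'total':>8}")
    for row in report["frequency_table"]:
        lines.append(f"{row['arm']:<16}{row['predicted']:>10}{row['actual_cx']:>11}"
                     f"{row['actual_st']:>11}{row['total']:>8}")
    return "\n".join(lines) + "\n"
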