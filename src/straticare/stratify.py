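"""Case-complexity prediction and treatment-intensity recommendation.

A client is predicted *complex* (Cx) — and recommended high-intensity
CBT — only when all four conditions hold: the initial PHQ-9 score is
clinically significant (>= 10), the initial GAD-7 score is clinically
significant (>= 8), and *neither* instrument model predicts RCSI.  A
predicted RCSI on either or both instruments, or a sub-clinical initial
score on either, makes the client a standard case (St), recommended
low-intensity CBT.

For comparison with clinician triage, the observed modality maps to the
equivalent label: one-on-one HICBT counts as a clinician "Cx" call,
while LICBT and stepped-care episodes count as "St" (a stepped episode's
*initial* assignment was low-intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

from .outcomes import GAD7, PHQ9, InstrumentRule

__all__ = ["StratificationDecision", "predict_complexity", "clinician_assignment_label"]


@dataclass(frozen=True)
class StratificationDecision:
    predicted_complexity: str   # "Cx" | "St"
    recommended_intensity: str  # "HICBT" | "LICBT"
    initial_phq9: float
    initial_gad7: float
    phq_pred_rcsi: int
    gad_pred_rcsi: int
    policy_kind: str = ""

    def __post_init__(self) -> None:
        expected = "HICBT" if self.predicted_complexity == "Cx" else "LICBT"
        if self.recommended_intensity != expected:
            raise ValueError("recommended intensity inconsistent with predicted complexity")


def predict_complexity(initial_phq: float, initial_gad: float,
                       phq_pred_rcsi: int, gad_pred_rcsi: int,
                       phq_rule: InstrumentRule = PHQ9,
                       gad_rule: InstrumentRule = GAD7,
                       policy_kind: str = "") -> StratificationDecision:
    """Combine the two instrument-level predictions into one decision."""
    phq_rule.validate_score(initial_phq)
    gad_rule.validate_score(initial_gad)
    complex_case = (
        initial_phq >= phq_rule.clinical_threshold
        and initial_gad >= gad_rule.clinical_threshold
        and not phq_pred_rcsi
        and not gad_pred_rcsi
    )
    label = "Cx" if complex_case else "St"
    return StratificationDecision(
        predicted_complexity=label,
        recommended_intensity="HICBT" if complex_case else "LICBT",
        initial_phq9=initial_phq,
        initial_gad7=initial_gad,
        phq_pred_rcsi=int(bool(phq_pred_rcsi)),
        gad_pred_rcsi=int(bool(gad_pred_rcsi)),
        policy_kind=policy_kind,
    )


def clinician_assignment_label(modality: str) -> str:
    """Clinician-equivalent complexity label for an observed modality."""
    if modality == "HICBT":
        return "Cx"
    if modality in ("LICBT", "stepped"):
        return "St"
    raise ValueError(f"unknown modality {modality!r}")
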