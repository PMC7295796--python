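"""Phenotype labelling from TNS(c)-PV trajectories.

The Total Neuropathy Score - Pediatric Vincristine (TNS(c)-PV) is a
clinician-scored severity instrument assessed repeatedly over the 2-3 year
course of treatment.  A visit score below 3 is low intensity, above 8 high
intensity, and anything in between medium.  A patient whose score stays low
throughout is labelled LN (low neuropathy); a patient whose score is high even
once is labelled HN (high neuropathy) — susceptibility, once shown, is not
undone by later improvement.  Patients who are neither (medium at some visit,
never high) are labelled MEDIUM and excluded from modelling.

Both score thresholds are exposed as keyword arguments; the defaults encode
the strict readings "less than 3" and "greater than 8" (a score of exactly 3
or exactly 8 is medium intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import TnsTrajectory, ValidationError

__all__ = [
    "PhenotypeLabel",
    "score_to_intensity",
    "classify_overall",
    "cohort_summary",
    "LOW_THRESHOLD",
    "HIGH_THRESHOLD",
]

LOW_THRESHOLD = 3.0
HIGH_THRESHOLD = 8.0


@dataclass
class PhenotypeLabel:
    """Overall LN/HN/MEDIUM label plus the per-visit intensity categories."""

    patient_id: str
    overall: str
    per_visit_intensity: list[str]

    @property
    def excluded(self) -> bool:
        """MEDIUM patients are excluded from model building."""
        return self.overall == "MEDIUM"


def score_to_intensity(
    score: float,
    low_threshold: float = LOW_THRESHOLD,
    high_threshold: float = HIGH_THRESHOLD,
) -> str:
    """Map one TNS(c)-PV score to an intensity category.

    ``score < low_threshold`` is ``"low"``, ``score > high_threshold`` is
    ``"high"``, anything in between (inclusive of both thresholds) is
    ``"medium"``.
    """
    if score < 0:
        raise ValidationError(f"TNS score must be non-negative, got {score!r}")
    if score < low_threshold:
        return "low"
    if score > high_threshold:
        return "high"
    return "medium"


def classify_overall(
    traj: TnsTrajectory,
    low_threshold: float = LOW_THRESHOLD,
    high_threshold: float = HIGH_THRESHOLD,
) -> PhenotypeLabel:
    """Derive the overall phenotype from a patient's full trajectory.

    HN if any visit is high intensity; LN if every visit is low; MEDIUM
    otherwise.  The result does not depend on visit order.
    """
    intensities = [
        score_to_intensity(s, low_threshold, high_threshold) for s in traj.scores
    ]
    if "high" in intensities:
        overall = "HN"
    elif all(i == "low" for i in intensities):
        overall = "LN"
    else:
        overall = "MEDIUM"
    return PhenotypeLabel(traj.patient_id, overall, intensities)


def cohort_summary(labels: list[PhenotypeLabel]) -> dict:
    """Counts and fractions per overall phenotype class.

    Returns ``{"counts": {...}, "fractions": {...}, "n": total}``; fractions
    sum to 1 over the classes present.
    """
    if not labels:
        raise ValidationError("cohort_summary requires at least one label")
    counts = {"LN": 0, "HN": 0, "MEDIUM": 0}
    for lab in labels:
        counts[lab.overall] += 1
    n = len(labels)
    fractions = {k: v / n for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "n": n}
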