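"""Core in-memory containers shared across the pipeline.

A :class:`ProfileMatrix` holds one treatment time point's samples-by-metabolite
intensity table together with the missingness mask (NaN cells) and per-sample
phenotype labels.  A :class:`TnsTrajectory` holds one patient's longitudinal
TNS(c)-PV neuropathy scores, from which the overall LN/HN phenotype is derived.

CSV dialect (shared with the CLI): profile files carry the columns
``patient_id, timepoint, phenotype`` followed by one column per metabolite
feature; missing intensities are empty cells.  TNS files are long-format with
columns ``patient_id, visit, score``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "TnsTrajectory",
    "ValidationError",
    "read_profile_csv",
    "read_tns_csv",
    "write_tns_csv",
]

#: Reserved leading columns of the profile CSV dialect.
_META_COLS = ("patient_id", "timepoint", "phenotype")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class TnsTrajectory:
    """Per-patient ordered TNS(c)-PV scores across clinic visits.

    Scores are non-negative clinician-assigned neuropathy severities; the
    visit label is free text (``day8``, ``day29``, ``month6``, ``late`` ...).
    """

    patient_id: str
    visits: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if len(self.visits) == 0:
            raise ValidationError(f"trajectory for {self.patient_id!r} has no visits")
        for label, score in self.visits:
            if score < 0:
                raise ValidationError(
                    f"negative TNS score {score!r} at visit {label!r} "
                    f"for patient {self.patient_id!r}"
                )

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.visits]


@dataclass
class ProfileMatrix:
    """One time point's samples x metabolite-feature intensity matrix.

    ``values`` is a float array with ``NaN`` marking missing (non-detected)
    intensities; ``missing_mask`` is derived from it.  ``labels`` carries the
    per-sample overall phenotype (``"HN"``/``"LN"``, or ``"MEDIUM"`` before
    exclusion, or ``""`` when unknown, e.g. new samples at prediction time).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: list[str]
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.labels = list(self.labels)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.feature_ids) != p:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {p} matrix columns"
            )
        if len(self.labels) != n:
            raise ValidationError(f"{len(self.labels)} labels for {n} samples")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the intensity was not observed."""
        return np.isnan(self.values)

    def y(self, positive: str = "HN") -> np.ndarray:
        """Binary response vector (1 = positive class, default HN)."""
        bad = sorted({l for l in self.labels if l not in ("HN", "LN")})
        if bad:
            raise ValidationError(f"non-binary phenotype labels present: {bad}")
        return np.asarray([1 if l == positive else 0 for l in self.labels])

    # ------------------------------------------------------------- selections
    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "ProfileMatrix":
        """Restrict to the given sample ids (order given) or a boolean mask."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in keep if s not in pos]
            if missing:
                raise ValidationError(f"unknown sample ids: {missing}")
            idx = np.asarray([pos[s] for s in keep])
        return ProfileMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx],
            [self.labels[i] for i in idx],
            self.timepoint,
        )

    def subset_features(self, keep: Sequence[str]) -> "ProfileMatrix":
        """Restrict to the given feature ids, in the order given."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in pos]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        idx = np.asarray([pos[f] for f in keep], dtype=int)
        return ProfileMatrix(
            list(self.sample_ids),
            [self.feature_ids[j] for j in idx],
            self.values[:, idx],
            list(self.labels),
            self.timepoint,
        )

    def exclude_medium(self) -> "ProfileMatrix":
        """Drop samples with the MEDIUM overall phenotype."""
        keep = np.asarray([l != "MEDIUM" for l in self.labels])
        return self.subset_samples(keep)

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(
            list(self.sample_ids),
            list(self.feature_ids),
            self.values.copy(),
            list(self.labels),
            self.timepoint,
        )

    # ------------------------------------------------------------------- i/o
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "phenotype", self.labels)
        df.insert(0, "timepoint", self.timepoint)
        df.insert(0, "patient_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProfileMatrix":
        for col in ("patient_id",):
            if col not in df.columns:
                raise ValidationError(f"profile table lacks required column {col!r}")
        feature_cols = [c for c in df.columns if c not in _META_COLS]
        timepoint = ""
        if "timepoint" in df.columns and len(df):
            timepoint = str(df["timepoint"].iloc[0])
        labels = (
            df["phenotype"].fillna("").astype(str).tolist()
            if "phenotype" in df.columns
            else [""] * len(df)
        )
        return cls(
            df["patient_id"].astype(str).tolist(),
            feature_cols,
            df[feature_cols].to_numpy(dtype=float),
            labels,
            timepoint,
        )


def read_profile_csv(path: str | Path) -> ProfileMatrix:
    """Read one time point's profile matrix from the shared CSV dialect."""
    return ProfileMatrix.from_frame(pd.read_csv(path))


def read_tns_csv(path: str | Path) -> list[TnsTrajectory]:
    """Read long-format TNS(c)-PV trajectories (patient_id, visit, score)."""
    df = pd.read_csv(path)
    for col in ("patient_id", "visit", "score"):
        if col not in df.columns:
            raise ValidationError(f"TNS table lacks required column {col!r}")
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        visits = [(str(v), float(s)) for v, s in zip(grp["visit"], grp["score"])]
        out.append(TnsTrajectory(str(pid), visits))
    return out


def write_tns_csv(trajectories: Iterable[TnsTrajectory], path: str | Path) -> None:
    rows = [
        {"patient_id": t.patient_id, "visit": v, "score": s}
        for t in trajectories
        for v, s in t.visits
    ]
    pd.DataFrame(rows, columns=["patient_id", "visit", "score"]).to_csv(
        path, index=False
    )
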