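"""Synthetic cohort generator for the VIPN prediction pipeline.

Emulates the statistical structure the analysis assumes so that every
downstream stage (phenotyping, filtering, imputation, clustering, the
longitudinal coupled classifier, RFE, model training) can be exercised and
tested without patient data:

* ~36 pediatric patients with an unbalanced 2:1 HN:LN phenotype split,
  profiled at three treatment time points (day 8, day 29, month 6);
* ~2000 LC-MS metabolite features keyed by m/z and retention time, intensities
  log-normal (normal on the log10 scale) with a per-feature baseline shared
  across time points plus a global per-time-point offset (so profiles cluster
  by time point);
* a small, *disjoint* informative feature subset per time point whose HN/LN
  group means differ by ``effect_size`` standard deviations on the log scale
  (the structure behind time-point-specific predictive metabolite sets);
* a ``vincristine_conc`` plasma-concentration column uncorrelated with
  phenotype (it should never survive feature selection);
* missing-not-at-random dropouts: by default the lowest-intensity values are
  masked first, mimicking LC-MS limit-of-detection censoring;
* TNS(c)-PV trajectories consistent with the phenotype labels, with high
  scores appearing mostly at later visits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .containers import ProfileMatrix, TnsTrajectory

__all__ = ["SyntheticConfig", "CohortTruth", "ConfigurationError", "generate_cohort"]

_TIMEPOINT_NAMES = ("day8", "day29", "month6")


class ConfigurationError(ValueError):
    """A SyntheticConfig invariant is violated; the message names it."""


@dataclass
class SyntheticConfig:
    """Cohort-level knobs of the generator.

    Defaults encode the study conditions being emulated: 24 HN vs 12 LN
    patients, three time points, ~2000 features, a handful of informative
    metabolites per time point with a strong (d = 2) group separation on the
    log10 scale, a one-decade global shift between consecutive time points,
    and 20% missingness censored from below.
    """

    n_hn: int = 24
    n_ln: int = 12
    n_medium: int = 0
    n_features: int = 2000
    n_timepoints: int = 3
    n_informative_per_timepoint: int = 5
    effect_size: float = 2.0
    timepoint_shift: float = 1.0
    missing_rate: float = 0.2
    missing_mechanism: str = "below-threshold"
    shared_informative: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hn, self.n_ln, self.n_medium) < 0:
            raise ConfigurationError("class sizes must be non-negative")
        if self.n_hn + self.n_ln < 4:
            raise ConfigurationError("invariant violated: n_hn + n_ln >= 4")
        if self.n_timepoints < 1:
            raise ConfigurationError("n_timepoints must be >= 1")
        if self.n_informative_per_timepoint < 0:
            raise ConfigurationError("n_informative_per_timepoint must be >= 0")
        if self.n_features < self.n_informative_per_timepoint * self.n_timepoints:
            raise ConfigurationError(
                "invariant violated: n_features >= "
                "n_informative_per_timepoint * n_timepoints"
            )
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("random", "below-threshold"):
            raise ConfigurationError(
                "missing_mechanism must be 'random' or 'below-threshold', "
                f"got {self.missing_mechanism!r}"
            )

    @property
    def timepoint_names(self) -> list[str]:
        if self.n_timepoints == len(_TIMEPOINT_NAMES):
            return list(_TIMEPOINT_NAMES)
        return [f"tp{i + 1}" for i in range(self.n_timepoints)]


@dataclass
class CohortTruth:
    """Generator ground truth, for recovery tests and audit.

    ``informative`` maps each time point label to the feature ids planted with
    a phenotype signal there; the per-time-point lists are disjoint.
    """

    informative: dict[str, list[str]]
    labels: dict[str, str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["informative"], d["labels"], d["seed"])


def _feature_ids(rng: np.random.Generator, n: int) -> list[str]:
    """LC-MS style feature keys: m/z in 70-1000, retention time in 0.5-20 min."""
    mz = rng.uniform(70, 1000, size=n)
    rt = rng.uniform(0.5, 20.0, size=n)
    return [f"mz{m:.4f}_rt{r:.2f}" for m, r in zip(mz, rt)]


def _apply_missingness(
    rng: np.random.Generator, x: np.ndarray, rate: float, mechanism: str
) -> np.ndarray:
    """Mask round(rate * n_cells) intensities in-place with NaN."""
    n_cells = x.size
    n_mask = int(round(rate * n_cells))
    if n_mask == 0:
        return x
    if mechanism == "below-threshold":
        # LC-MS dropouts are intensity-dependent: censor the lowest values.
        flat_idx = np.argsort(x, axis=None, kind="stable")[:n_mask]
    else:
        flat_idx = rng.choice(n_cells, size=n_mask, replace=False)
    x.flat[flat_idx] = np.nan
    return x


def _trajectory(
    rng: np.random.Generator, pid: str, label: str, first_high: int | None
) -> TnsTrajectory:
    """One patient's TNS(c)-PV trajectory over four visits.

    Visits are the three profiling time points plus a catch-all ``late`` visit
    covering the remainder of the 2-3 year treatment, so HN patients whose
    first high score falls after month 6 are still labelled HN.
    """
    visit_names = list(_TIMEPOINT_NAMES) + ["late"]
    scores: list[float] = []
    if label == "LN":
        scores = [float(rng.integers(0, 3)) for _ in visit_names]
    elif label == "MEDIUM":
        med_at = int(rng.integers(0, len(visit_names)))
        for i in range(len(visit_names)):
            if i == med_at:
                scores.append(float(rng.integers(4, 9)))
            else:
                scores.append(float(rng.integers(0, 3)))
    else:  # HN
        assert first_high is not None
        for i in range(len(visit_names)):
            if i < first_high:
                # mostly low before onset, occasionally medium
                if rng.random() < 0.2:
                    scores.append(float(rng.integers(4, 9)))
                else:
                    scores.append(float(rng.integers(0, 3)))
            elif i == first_high:
                scores.append(float(rng.integers(9, 17)))
            else:
                # neuropathy may improve after dose modification
                scores.append(float(rng.integers(2, 13)))
    return TnsTrajectory(pid, list(zip(visit_names, scores)))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ProfileMatrix], list[TnsTrajectory], CohortTruth]:
    """Generate one synthetic cohort.

    Returns one :class:`ProfileMatrix` per time point (shared patient ids,
    ``n_features`` metabolite columns plus a trailing ``vincristine_conc``
    column), the per-patient TNS(c)-PV trajectories, and the ground truth.
    Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_hn + config.n_ln + config.n_medium
    labels = (
        ["HN"] * config.n_hn + ["LN"] * config.n_ln + ["MEDIUM"] * config.n_medium
    )
    sample_ids = [f"P{i + 1:03d}" for i in range(n)]
    feature_ids = _feature_ids(rng, config.n_features)

    # Informative subsets per time point: disjoint by default (the structure
    # behind time-point-specific biomarker sets); with shared_informative the
    # same subset carries signal at every time point (fresh noise draws), the
    # regime in which the longitudinal coupling parameter becomes positive.
    n_inf = config.n_informative_per_timepoint
    tp_names = config.timepoint_names
    informative: dict[str, list[str]] = {}
    if config.shared_informative:
        inf_pool = rng.choice(config.n_features, size=n_inf, replace=False)
        for tp in tp_names:
            informative[tp] = [feature_ids[j] for j in inf_pool]
    else:
        inf_pool = rng.choice(
            config.n_features, size=n_inf * config.n_timepoints, replace=False
        )
        for t, tp in enumerate(tp_names):
            idx = inf_pool[t * n_inf : (t + 1) * n_inf]
            informative[tp] = [feature_ids[j] for j in idx]

    # Per-feature baseline on the log10 scale, shared across time points.
    baseline = rng.normal(6.0, 0.8, size=config.n_features)
    is_hn = np.asarray([l == "HN" for l in labels], dtype=float)

    # HN patients' first-high visit: mostly later visits (visit 0 rare),
    # mirroring the rising incidence of high scores over treatment.
    onset_p = np.array([1.0, 8.0, 8.0, 7.0])
    onset_p /= onset_p.sum()
    first_high = rng.choice(4, size=config.n_hn, p=onset_p)

    matrices: list[ProfileMatrix] = []
    for t, tp in enumerate(tp_names):
        z = baseline[None, :] + config.timepoint_shift * t + rng.normal(
            0.0, 1.0, size=(n, config.n_features)
        )
        for rank, fid in enumerate(informative[tp]):
            j = feature_ids.index(fid)
            sign = 1.0 if rank % 2 == 0 else -1.0
            z[:, j] += sign * config.effect_size * is_hn
        intensities = np.power(10.0, z)
        _apply_missingness(
            rng, intensities, config.missing_rate, config.missing_mechanism
        )
        # Plasma vincristine concentration (ng/mL): phenotype-independent,
        # quantified by a separate targeted assay, hence fully observed.
        vinc = np.power(10.0, rng.normal(1.5, 0.3, size=(n, 1)))
        matrices.append(
            ProfileMatrix(
                sample_ids,
                feature_ids + ["vincristine_conc"],
                np.hstack([intensities, vinc]),
                labels,
                tp,
            )
        )

    trajectories: list[TnsTrajectory] = []
    hn_counter = 0
    for pid, label in zip(sample_ids, labels):
        fh = None
        if label == "HN":
            fh = int(first_high[hn_counter])
            hn_counter += 1
        trajectories.append(_trajectory(rng, pid, label, fh))

    truth = CohortTruth(informative, dict(zip(sample_ids, labels)), config.seed)
    return matrices, trajectories, truth
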