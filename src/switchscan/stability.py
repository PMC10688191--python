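"""Dynamic stability of switch angles: state traces and the instability ratio.

Two switch angles with near-identical bimodal densities can differ
completely in kinetics: a *stable switch* (SS) sits in one angular state
and jumps once, while an *unstable switch* (US) oscillates between the
states throughout the dynamics.  Frames are assigned to the two angular
states by 1-D two-cluster k-means; the instability ratio is

    100 * (inter-state transitions) / (total frames)   [percent]

with transitions never counted across trajectory seams.  Ratios below
~1% indicate SS and above ~6% indicate US; the intermediate range is
resolved by a one-dimensional logistic regression trained on labeled
ratios, whose 0.5-probability point is the operational SS/US boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .classifier import CVReport
from .geometry import AngleSeries

__all__ = [
    "StateTrace",
    "InstabilityRecord",
    "StabilityModel",
    "assign_states",
    "count_transitions",
    "instability_ratio",
    "train_stability_classifier",
    "classify_stability",
]

_KMEANS_TOL = 1e-8
_KMEANS_MAX_ITER = 300
_LOGISTIC_C = 1000.0  # weak regularization; boundary near the class gap


@dataclass
class StateTrace:
    """Per-frame binary angular-state assignment for one angle."""

    states: np.ndarray
    centers: tuple[float, float]  # (low-angle center, high-angle center)
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0 or 1")
        if not self.centers[0] < self.centers[1]:
            raise ValueError("centers must satisfy center_0 < center_1")
        if not self.segments:
            self.segments = [(0, self.states.size)]

    @property
    def n_frames(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class InstabilityRecord:
    transitions: int
    n_frames: int

    @property
    def ratio_percent(self) -> float:
        return 100.0 * self.transitions / self.n_frames


@dataclass
class StabilityModel:
    """1-D logistic SS/US classifier on the instability ratio (percent)."""

    intercept: float
    slope: float
    cv_report: CVReport | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(
                "logistic slope must be positive (higher instability ratio "
                "must mean more likely US); check the label orientation"
            )

    @property
    def boundary_percent(self) -> float:
        """Instability ratio at which P(US) = 0.5."""
        return -self.intercept / self.slope

    def probability_us(self, ratio_percent) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(ratio_percent, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def assign_states(series: AngleSeries, seed: int = 0) -> StateTrace:
    """Two-cluster 1-D k-means state assignment, relabeled so the
    lower-angle center is state 0.

    Initialization uses the 10th/90th percentiles of the series (falling
    back to min/max when those coincide), so the result does not depend
    on ``seed``; the argument is kept for interface uniformity.
    """
    values = series.values
    if np.unique(values).size < 2:
        raise ValueError(
            f"no two states resolvable for angle {series.triplet.label} "
            f"of residue {series.triplet.residue_index}: series is constant"
        )
    init = np.percentile(values, [10.0, 90.0])
    if init[0] == init[1]:
        init = np.array([values.min(), values.max()])
    km = KMeans(
        n_clusters=2,
        init=init.reshape(2, 1),
        n_init=1,
        max_iter=_KMEANS_MAX_ITER,
        tol=_KMEANS_TOL,
        random_state=seed,
    ).fit(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(2, dtype=int)
    relabel[order] = [0, 1]
    states = relabel[km.labels_]
    c0, c1 = centers[order]
    return StateTrace(states, (float(c0), float(c1)), list(series.segments))


def count_transitions(trace: StateTrace) -> int:
    """Consecutive-frame state changes, never counted across segment seams."""
    total = 0
    for start, end in trace.segments:
        seg = trace.states[start:end]
        total += int(np.count_nonzero(np.diff(seg)))
    return total


def instability_ratio(trace: StateTrace) -> InstabilityRecord:
    if trace.n_frames < 1:
        raise ValueError("instability ratio needs at least one frame")
    return InstabilityRecord(count_transitions(trace), trace.n_frames)


def _as_binary_labels(labels) -> np.ndarray:
    """Map SS/US labels (strings or 0/1) to 0=SS, 1=US."""
    out = []
    for lab in labels:
        if isinstance(lab, str):
            u = lab.upper()
            if u not in ("SS", "US"):
                raise ValueError(f"stability label must be 'SS' or 'US', got {lab!r}")
            out.append(0 if u == "SS" else 1)
        else:
            v = int(lab)
            if v not in (0, 1):
                raise ValueError("numeric stability labels must be 0 (SS) or 1 (US)")
            out.append(v)
    return np.asarray(out, dtype=int)


def train_stability_classifier(
    ratios_percent, labels, seed: int = 0, n_folds: int = 5
) -> StabilityModel:
    """Fit the 1-D logistic SS/US model on instability ratios (percent).

    ``ratios_percent`` may be floats or :class:`InstabilityRecord` objects;
    ``labels`` are 'SS'/'US' strings or 0/1.  Also reports stratified
    k-fold CV accuracy in the same convention as the switch classifier.
    """
    x = np.asarray(
        [r.ratio_percent if isinstance(r, InstabilityRecord) else float(r) for r in ratios_percent]
    )
    y = _as_binary_labels(labels)
    if x.size != y.size:
        raise ValueError("ratios and labels must have the same length")
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both SS and US examples are required for training")

    X = x.reshape(-1, 1)
    cv_report = None
    if counts.min() >= n_folds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, y):
            clf = LogisticRegression(C=_LOGISTIC_C, max_iter=5000, random_state=seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        cv_report = CVReport(accs, n_folds)

    clf = LogisticRegression(C=_LOGISTIC_C, max_iter=5000, random_state=seed)
    clf.fit(X, y)
    return StabilityModel(
        intercept=float(clf.intercept_[0]),
        slope=float(clf.coef_[0, 0]),
        cv_report=cv_report,
        metadata={"seed": seed, "n_training_rows": int(x.size)},
    )


def classify_stability(model: StabilityModel, record: InstabilityRecord | float) -> str:
    """SS/US call for one instability ratio; ties (P(US) = 0.5) go to US."""
    ratio = record.ratio_percent if isinstance(record, InstabilityRecord) else float(record)
    return "US" if model.probability_us(ratio) >= 0.5 else "SS"
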