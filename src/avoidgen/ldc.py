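"""Cross-validated linear discriminant contrast (crossnobis) distances.

Condition-pattern dissimilarity estimated by projecting a held-out run's
pattern difference onto the difference estimated from the training runs,
after multivariate noise normalization.  Cross-validation removes the
noise-induced positive bias, so the statistic has a meaningful zero: its
expectation is 0 when the two conditions share a distribution, and
negative sample values are possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

__all__ = [
    "PatternDataset",
    "DistanceEstimate",
    "noise_normalize",
    "cv_ldc",
    "distance_change",
]


@dataclass(frozen=True)
class PatternDataset:
    """Run x condition x voxel activation estimates (+ optional residuals)."""

    estimates: np.ndarray          # (n_runs, n_conditions, n_voxels)
    condition_labels: tuple[str, ...]
    run_labels: tuple[str, ...]
    residuals: np.ndarray | None = None   # (n_runs, n_time, n_voxels)

    def __post_init__(self):
        E = np.asarray(self.estimates, dtype=float)
        if E.ndim != 3:
            raise ValueError("estimates must be run x condition x voxel")
        if E.shape[0] < 2:
            raise ValueError("need >= 2 runs for cross-validation")
        if E.shape[1] != len(self.condition_labels):
            raise ValueError("condition label count mismatch")
        if E.shape[0] != len(self.run_labels):
            raise ValueError("run label count mismatch")
        if self.residuals is not None:
            R = np.asarray(self.residuals, dtype=float)
            if R.ndim != 3 or R.shape[0] != E.shape[0] or \
                    R.shape[2] != E.shape[2]:
                raise ValueError("residuals must be run x time x voxel")
        object.__setattr__(self, "estimates", E)

    @property
    def n_runs(self) -> int:
        return self.estimates.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.estimates.shape[2]

    def condition_index(self, label: str) -> int:
        return self.condition_labels.index(label)

    def subset_runs(self, runs: list[str]) -> "PatternDataset":
        idx = [self.run_labels.index(r) for r in runs]
        return PatternDataset(
            estimates=self.estimates[idx],
            condition_labels=self.condition_labels,
            run_labels=tuple(runs),
            residuals=None if self.residuals is None
            else self.residuals[idx],
        )

    # -- plain-text serialization -----------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k, r in enumerate(self.run_labels):
            np.savetxt(d / f"run_{r}.tsv", self.estimates[k], delimiter="\t")
        (d / "manifest.json").write_text(json.dumps(
            {"condition_labels": list(self.condition_labels),
             "run_labels": list(self.run_labels)}, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PatternDataset":
        d = Path(directory)
        man = json.loads((d / "manifest.json").read_text())
        runs = man["run_labels"]
        E = np.stack([
            np.loadtxt(d / f"run_{r}.tsv", delimiter="\t", ndmin=2)
            for r in runs
        ])
        return cls(estimates=E,
                   condition_labels=tuple(man["condition_labels"]),
                   run_labels=tuple(runs))


@dataclass(frozen=True)
class DistanceEstimate:
    pair: tuple[str, str]
    value: float
    n_folds: int


def _shrunk_cov(residuals: np.ndarray, shrinkage: float | None) -> np.ndarray:
    """Residual covariance shrunk toward its diagonal.

    ``shrinkage=None`` uses an analytic (Ledoit-Wolf style) coefficient
    estimated from the residuals themselves.
    """
    X = residuals - residuals.mean(axis=0, keepdims=True)
    n = X.shape[0]
    S = X.T @ X / max(n - 1, 1)
    target = np.diag(np.diag(S))
    if shrinkage is None:
        # variance of covariance entries relative to dispersion from target
        X2 = X**2
        var_S = (X2.T @ X2 / max(n - 1, 1) - S**2) / max(n, 1)
        num = np.sum(var_S) - np.sum(np.diag(var_S))
        den = np.sum((S - target) ** 2)
        shrinkage = 1.0 if den <= 0 else float(np.clip(num / den, 0.0, 1.0))
    return (1.0 - shrinkage) * S + shrinkage * target


def noise_normalize(dataset: PatternDataset,
                    shrinkage: float | None = None) -> PatternDataset:
    """Whiten patterns by the run-wise shrunk residual covariance.

    Each run's patterns are right-multiplied by the inverse matrix square
    root of its own shrunk residual covariance (multivariate noise
    normalization, turning Euclidean into Mahalanobis geometry).  With few
    residual samples (< voxels/10) shrinkage is forced to at least 0.5.
    """
    if dataset.residuals is None:
        raise ValueError("dataset has no residuals for noise normalization")
    E = np.empty_like(dataset.estimates)
    P = dataset.n_voxels
    for k in range(dataset.n_runs):
        res = dataset.residuals[k]
        s = shrinkage
        if res.shape[0] < P / 10:
            s = max(0.5, s or 0.0)
        cov = _shrunk_cov(res, s)
        try:
            w = linalg.fractional_matrix_power(cov, -0.5)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise ValueError("singular shrunk covariance") from e
        if not np.all(np.isfinite(w)):
            raise ValueError("singular shrunk covariance")
        E[k] = dataset.estimates[k] @ np.real(w)
    return PatternDataset(
        estimates=E,
        condition_labels=dataset.condition_labels,
        run_labels=dataset.run_labels,
        residuals=dataset.residuals,
    )


def cv_ldc(dataset: PatternDataset, pair: tuple[str, str]) -> DistanceEstimate:
    """Leave-one-run-out cross-validated squared distance for one pair.

    For each fold, the training pattern difference (mean over the other
    runs) is dotted with the held-out run's difference and divided by the
    voxel count, making values comparable across regions of different
    size.  The mean over folds is returned; values may be negative.
    """
    i = dataset.condition_index(pair[0])
    j = dataset.condition_index(pair[1])
    deltas = dataset.estimates[:, i, :] - dataset.estimates[:, j, :]
    n_runs, P = deltas.shape
    folds = np.empty(n_runs)
    for k in range(n_runs):
        train = np.mean(np.delete(deltas, k, axis=0), axis=0)
        folds[k] = float(train @ deltas[k]) / P
    return DistanceEstimate(pair=(pair[0], pair[1]),
                            value=float(np.mean(folds)), n_folds=n_runs)


def distance_change(dataset: PatternDataset, pair: tuple[str, str],
                    early_runs: list[str], late_runs: list[str]) -> float:
    """Late-minus-early change in the cross-validated pair distance.

    Negative values mean the two conditions became *more* similar later in
    the task.  Early and late run sets must be disjoint with >= 2 runs
    each (cross-validation needs folds inside each epoch).
    """
    if set(early_runs) & set(late_runs):
        raise ValueError("early and late run sets overlap")
    if len(early_runs) < 2 or len(late_runs) < 2:
        raise ValueError("each epoch needs >= 2 runs")
    d_early = cv_ldc(dataset.subset_runs(early_runs), pair).value
    d_late = cv_ldc(dataset.subset_runs(late_runs), pair).value
    return d_late - d_early
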