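"""Single support-vector-regression member models.

Members are RBF-kernel SVRs in either the epsilon (tube-width) or nu
(support-fraction) parameterisation, each tied to a named descriptor
subset.  Hyperparameters are tuned by exhaustive grid search scored with
k-fold cross-validated RMSE on the training table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold
from sklearn.svm import SVR, NuSVR
from sklearn.utils.validation import check_is_fitted

from .validation import determination_coefficient

__all__ = ["GridSpec", "MemberSVR", "cross_validate", "grid_search"]

Mode = Literal["epsilon", "nu"]


@dataclass
class GridSpec:
    """Cartesian hyperparameter grid for SVR tuning.

    Every combination of cost, kernel width and (per mode) tube width or
    nu fraction is evaluated; no early stopping.
    """

    c_values: tuple[float, ...]
    gamma_values: tuple[float, ...]
    epsilon_values: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5)
    nu_values: tuple[float, ...] = (0.25, 0.5, 0.75)
    modes: tuple[Mode, ...] = ("epsilon", "nu")

    @classmethod
    def default(cls) -> "GridSpec":
        """Conventional LIBSVM-style log2 grids: C in 2^-5..2^15, gamma in
        2^-15..2^3, both stepped by 2^2."""
        return cls(
            c_values=tuple(float(2.0**e) for e in range(-5, 16, 2)),
            gamma_values=tuple(float(2.0**e) for e in range(-15, 4, 2)),
        )

    @classmethod
    def coarse(cls) -> "GridSpec":
        """Small grid for desk-scale pipelines and simulations."""
        return cls(
            c_values=(1.0, 10.0, 100.0),
            gamma_values=(0.01, 0.1, 1.0),
            epsilon_values=(0.01, 0.1),
            nu_values=(0.5,),
            modes=("epsilon",),
        )

    @classmethod
    def meta_default(cls) -> "GridSpec":
        """Grid for the second-level SVR over member predictions.

        The blend surface lives in a low-dimensional, strongly
        informative input space on the response scale; narrow kernels
        only let the meta chase individual member errors, so the width
        range is kept smooth.
        """
        return cls(
            c_values=(1.0, 10.0, 100.0),
            gamma_values=(0.01, 0.1),
            epsilon_values=(0.01, 0.1),
            nu_values=(0.5,),
            modes=("epsilon",),
        )

    def points(self) -> list[dict]:
        """Enumerate grid points in deterministic order."""
        out = []
        for mode in self.modes:
            tube_values = self.epsilon_values if mode == "epsilon" else self.nu_values
            tube_key = "epsilon" if mode == "epsilon" else "nu"
            for C in self.c_values:
                for gamma in self.gamma_values:
                    for tube in tube_values:
                        out.append({"mode": mode, "C": C, "gamma": gamma, tube_key: tube})
        return out

    def __len__(self) -> int:
        return len(self.points())


class MemberSVR(RegressorMixin, BaseEstimator):
    """One RBF-kernel SVR member bound to a named descriptor subset.

    Parameters
    ----------
    mode : {"epsilon", "nu"}
        Regression formulation: epsilon-SVR fixes the insensitivity tube
        width; nu-SVR bounds the support-vector/error fraction.
    C : float
        Cost of constraint violation.
    gamma : float or "scale"
        RBF kernel width.
    epsilon : float
        Tube width (epsilon mode only).
    nu : float
        Support fraction in (0, 1] (nu mode only).
    descriptor_subset : sequence of str, optional
        Column names used as inputs; None means all columns of the fitted
        table.  Prediction aligns columns by name, so input column order
        never matters.
    """

    def __init__(
        self,
        mode: Mode = "epsilon",
        C: float = 32.0,
        gamma: float | str = "scale",
        epsilon: float = 0.1,
        nu: float = 0.5,
        descriptor_subset: Sequence[str] | None = None,
    ):
        self.mode = mode
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self.nu = nu
        self.descriptor_subset = descriptor_subset

    def _select(self, X: pd.DataFrame) -> np.ndarray:
        names = list(self.subset_)
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"descriptor(s) missing from input table: {missing}")
        return X.loc[:, names].to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "MemberSVR":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        yv = np.asarray(y, dtype=float).ravel()
        if self.mode not in ("epsilon", "nu"):
            raise ValueError(f"unknown SVR mode {self.mode!r}")
        self.subset_ = (
            list(self.descriptor_subset)
            if self.descriptor_subset is not None
            else [str(c) for c in X.columns]
        )
        Xv = self._select(X)
        if self.mode == "epsilon":
            self.estimator_ = SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.epsilon)
        else:
            self.estimator_ = NuSVR(kernel="rbf", C=self.C, gamma=self.gamma, nu=self.nu)
        self.estimator_.fit(Xv, yv)
        self.n_features_in_ = Xv.shape[1]
        self.training_predictions_ = self.estimator_.predict(Xv)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        return self.estimator_.predict(self._select(X))

    def config_dict(self) -> dict:
        cfg = {"mode": self.mode, "C": self.C, "gamma": self.gamma}
        if self.mode == "epsilon":
            cfg["epsilon"] = self.epsilon
        else:
            cfg["nu"] = self.nu
        return cfg


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous blocks; sizes differ by at most 1."""
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed sample count ({n})")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    model: MemberSVR | BaseEstimator,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """k-fold cross-validation with pooled out-of-fold predictions.

    Returns (q2_cv, out_of_fold_predictions, fold_index_lists).  q2_cv is
    the determination coefficient of the pooled out-of-fold predictions
    against the observed responses; every sample is predicted exactly once
    out-of-fold.
    """
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    fold_idx = _fold_indices(n, folds, seed)
    oof = np.empty(n, dtype=float)
    for test_idx in fold_idx:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        m = clone(model)
        m.fit(X.iloc[mask], yv[mask])
        oof[test_idx] = m.predict(X.iloc[test_idx])
    q2cv = determination_coefficient(yv, oof)
    return q2cv, oof, fold_idx


def cv_rmse(
    X: pd.DataFrame,
    y: Sequence[float],
    model: BaseEstimator,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated RMSE of the pooled out-of-fold predictions."""
    yv = np.asarray(y, dtype=float).ravel()
    _, oof, _ = cross_validate(X, yv, model, folds=folds, seed=seed)
    return float(np.sqrt(np.mean((yv - oof) ** 2)))


def cv_rmse_with_se(
    X: pd.DataFrame,
    y: Sequence[float],
    model: BaseEstimator,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Pooled CV RMSE plus the standard error of the per-fold RMSEs."""
    yv = np.asarray(y, dtype=float).ravel()
    _, oof, fold_idx = cross_validate(X, yv, model, folds=folds, seed=seed)
    rmse = float(np.sqrt(np.mean((yv - oof) ** 2)))
    per_fold = np.array(
        [np.sqrt(np.mean((yv[idx] - oof[idx]) ** 2)) for idx in fold_idx]
    )
    se = float(np.std(per_fold, ddof=1) / np.sqrt(len(per_fold))) if len(per_fold) > 1 else 0.0
    return rmse, se


def grid_search(
    X: pd.DataFrame,
    y: Sequence[float],
    subset: Sequence[str] | None,
    grid: GridSpec,
    folds: int = 10,
    seed: int = 0,
) -> list[tuple[dict, float]]:
    """Exhaustive grid search scored by k-fold CV RMSE.

    Every grid point is evaluated on identical folds; the result list is
    sorted ascending by objective with first-occurrence order preserved on
    ties, so the top entry is the grid optimum.
    """
    points = grid.points()
    if not points:
        raise ValueError("empty grid")
    scored = []
    for i, params in enumerate(points):
        model = MemberSVR(descriptor_subset=subset, **params)
        objective = cv_rmse(X, y, model, folds=folds, seed=seed)
        scored.append((i, params, objective))
    scored.sort(key=lambda t: (t[2], t[0]))
    return [(params, obj) for _, params, obj in scored]


def select_config(
    ranked: list[tuple[dict, float]],
    X: pd.DataFrame,
    y: Sequence[float],
    subset: Sequence[str] | None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict, float]:
    """One-standard-error pick from a ranked grid-search result.

    Among configurations whose CV RMSE is within one standard error of
    the grid optimum, prefer the least flexible: smallest C, then
    smallest gamma, then the widest tube.  A parsimonious pick resists
    chance correlation under Y-scrambling without measurably hurting the
    cross-validated objective.
    """
    best_params, best_obj = ranked[0]
    model = MemberSVR(descriptor_subset=subset, **best_params)
    _, se = cv_rmse_with_se(X, y, model, folds=folds, seed=seed)
    cutoff = best_obj + se

    def flexibility(params: dict) -> tuple:
        gamma = params["gamma"]
        gamma_val = float(gamma) if not isinstance(gamma, str) else 0.0
        tube = params.get("epsilon", 0.0)
        return (params["C"], gamma_val, -tube)

    candidates = [(p, o) for p, o in ranked if o <= cutoff]
    candidates.sort(key=lambda t: flexibility(t[0]))
    return candidates[0]
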