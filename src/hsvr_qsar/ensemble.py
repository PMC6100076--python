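"""Hierarchical SVR: an ensemble of member SVRs whose predictions are
regressed by a second-level SVR.

Each member is a local model trained on its own descriptor subset; the
meta-SVR consumes only the members' predictions (one input dimension per
member), yielding a global model that blends local behaviours.  Ensemble
growth proceeds Occam-style: all two-member combinations are tried first,
then three, then four, and the first size class with a combination that
passes the validation criteria wins; within the class, the passer using
the fewest distinct descriptors is preferred.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from .svr_engine import GridSpec, MemberSVR, cross_validate, grid_search, select_config
from .validation import (
    CriteriaThresholds,
    CriteriaVerdict,
    MetricReport,
    check_criteria,
    evaluate_predictions,
)

__all__ = ["HsvrRegressor", "PoolEntry", "build_candidate_pool", "grow_and_select", "HsvrSelection"]


class HsvrRegressor(RegressorMixin, BaseEstimator):
    """Two-level stacked SVR regressor.

    Parameters
    ----------
    members : sequence of MemberSVR
        Unfitted member configurations (>= 2), each carrying its own
        descriptor subset and hyperparameters.  They are cloned and fitted
        on the training table.
    meta_grid : GridSpec, optional
        Grid searched for the second-level SVR on the member-prediction
        matrix; None uses :meth:`GridSpec.coarse`.
    folds, seed : int
        Cross-validation folds and fold seed for the meta grid search.

    Attributes
    ----------
    members_ : list of fitted MemberSVR
    meta_ : fitted MemberSVR over member-prediction inputs
    meta_config_ : dict, the selected meta hyperparameters
    """

    def __init__(
        self,
        members: Sequence[MemberSVR],
        meta_grid: GridSpec | None = None,
        meta_inputs: str = "oof",
        folds: int = 10,
        seed: int = 0,
    ):
        self.members = members
        self.meta_grid = meta_grid
        self.meta_inputs = meta_inputs
        self.folds = folds
        self.seed = seed

    def _member_matrix(self, X: pd.DataFrame, members: Sequence[MemberSVR]) -> pd.DataFrame:
        cols = {}
        for i, m in enumerate(members):
            try:
                cols[f"member_{i}"] = m.predict(X)
            except KeyError as err:
                raise KeyError(f"member {i}: {err.args[0]}") from err
        return pd.DataFrame(cols, index=X.index)

    def fit(
        self,
        X: pd.DataFrame,
        y: Sequence[float],
        member_oof: Sequence[np.ndarray] | None = None,
    ) -> "HsvrRegressor":
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.meta_inputs not in ("oof", "insample"):
            raise ValueError("meta_inputs must be 'oof' or 'insample'")
        yv = np.asarray(y, dtype=float).ravel()
        self.members_ = []
        for m in self.members:
            mm = clone(m)
            mm.fit(X, yv)
            self.members_.append(mm)
        folds = min(self.folds, X.shape[0])
        if self.meta_inputs == "oof":
            # stacked generalization: the meta trains on each member's
            # out-of-fold predictions so it sees honest generalization
            # behaviour, not in-sample memorization; precomputed
            # out-of-fold columns may be supplied to avoid re-deriving
            # them for every candidate combination.  Out-of-fold columns
            # use at least 10 folds so each fold's member is trained on
            # nearly the full table and the columns match test-time
            # prediction quality
            oof_folds = min(max(folds, 10), X.shape[0])
            cols = {}
            for i, m in enumerate(self.members):
                if member_oof is not None:
                    cols[f"member_{i}"] = np.asarray(member_oof[i], dtype=float)
                else:
                    _, oof, _ = cross_validate(X, yv, m, folds=oof_folds, seed=self.seed)
                    cols[f"member_{i}"] = oof
            Z = pd.DataFrame(cols, index=X.index)
        else:
            Z = self._member_matrix(X, self.members_)
        if np.allclose(Z.to_numpy().std(axis=0), 0.0):
            warnings.warn(
                "all member predictions are constant; meta model degenerates",
                UserWarning,
                stacklevel=2,
            )
        grid = self.meta_grid or GridSpec.meta_default()
        ranked = grid_search(Z, yv, None, grid, folds=folds, seed=self.seed)
        # plain CV optimum: the meta input space is low-dimensional and
        # strongly informative, so parsimony pressure (useful for members
        # in descriptor space) only biases the blend toward the mean here
        self.meta_config_, self.meta_objective_ = ranked[0]
        self.meta_ = MemberSVR(**self.meta_config_)
        self.meta_.fit(Z, yv)
        self.meta_training_inputs_ = Z
        self.n_features_in_ = X.shape[1]
        return self

    def member_predictions(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "meta_")
        return self._member_matrix(X, self.members_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.member_predictions(X)
        return self.meta_.predict(Z)

    def frozen_clone(self) -> "HsvrRegressor":
        """Unfitted copy whose meta grid is pinned to the selected
        hyperparameters, for refits that must not re-tune (Y-scrambling)."""
        check_is_fitted(self, "meta_")
        cfg = self.meta_config_
        grid = GridSpec(
            c_values=(cfg["C"],),
            gamma_values=(cfg["gamma"],),
            epsilon_values=(cfg.get("epsilon", 0.1),),
            nu_values=(cfg.get("nu", 0.5),),
            modes=(cfg["mode"],),
        )
        return HsvrRegressor(
            members=[clone(m) for m in self.members_],
            meta_grid=grid,
            meta_inputs=self.meta_inputs,
            folds=self.folds,
            seed=self.seed,
        )

    @property
    def descriptor_union_(self) -> list[str]:
        check_is_fitted(self, "members_")
        seen: list[str] = []
        for m in self.members_:
            for n in m.subset_:
                if n not in seen:
                    seen.append(n)
        return seen


@dataclass
class PoolEntry:
    """One grid-optimised candidate member with its training diagnostics."""

    model: MemberSVR
    subset: list[str]
    config: dict
    cv_rmse: float
    q2_cv: float
    train_report: MetricReport

    @property
    def subset_size(self) -> int:
        return len(self.subset)


def build_candidate_pool(
    X: pd.DataFrame,
    y: Sequence[float],
    subsets: Sequence[Sequence[str]],
    grid: GridSpec | None = None,
    folds: int = 10,
    seed: int = 0,
) -> list[PoolEntry]:
    """Grid-search one best member model per descriptor subset.

    Duplicate subsets are allowed (flagged with a warning) and produce
    identical models.
    """
    grid = grid or GridSpec.coarse()
    yv = np.asarray(y, dtype=float).ravel()
    seen: set[frozenset] = set()
    pool: list[PoolEntry] = []
    for subset in subsets:
        names = list(subset)
        key = frozenset(names)
        if key in seen:
            warnings.warn(f"duplicate candidate subset {sorted(key)}", UserWarning, stacklevel=2)
        seen.add(key)
        ranked = grid_search(X, yv, names, grid, folds=min(folds, len(yv)), seed=seed)
        config, objective = select_config(
            ranked, X, yv, names, folds=min(folds, len(yv)), seed=seed
        )
        model = MemberSVR(descriptor_subset=names, **config)
        model.fit(X, yv)
        q2cv, _, _ = cross_validate(X, yv, model, folds=min(folds, len(yv)), seed=seed)
        report = evaluate_predictions(yv, model.predict(X), context="training", q2_cv=q2cv)
        pool.append(
            PoolEntry(
                model=model,
                subset=names,
                config=config,
                cv_rmse=objective,
                q2_cv=q2cv,
                train_report=report,
            )
        )
    return pool


def fit_meta(
    members: Sequence[MemberSVR],
    X: pd.DataFrame,
    y: Sequence[float],
    grid: GridSpec | None = None,
    meta_inputs: str = "oof",
    folds: int = 10,
    seed: int = 0,
    member_oof: Sequence[np.ndarray] | None = None,
) -> HsvrRegressor:
    """Fit the second-level SVR on the member-prediction matrix."""
    model = HsvrRegressor(
        members=list(members), meta_grid=grid, meta_inputs=meta_inputs, folds=folds, seed=seed
    )
    model.fit(X, y, member_oof=member_oof)
    return model


@dataclass
class HsvrSelection:
    """Result of the Occam's-razor ensemble search."""

    model: HsvrRegressor
    member_indices: tuple[int, ...]
    passed: bool
    verdict: CriteriaVerdict
    train_report: MetricReport
    test_report: MetricReport | None
    objective: float
    cv_improvement: float = 0.0  # best member CV RMSE minus stack CV RMSE
    candidates_evaluated: int = 0


def _stack_cv(
    model: HsvrRegressor, X: pd.DataFrame, y: np.ndarray, folds: int, seed: int
) -> tuple[float, float, float]:
    """Cross-validate the fitted stack: members and meta are refit per
    fold with their selected hyperparameters held fixed, the standard way
    a finished model is cross-validated.  Returns (q2_cv, pooled RMSE,
    standard error of the per-fold RMSEs)."""
    q2cv, oof, fold_idx = cross_validate(
        X, y, model.frozen_clone(), folds=min(folds, y.size), seed=seed
    )
    rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
    per_fold = np.array([np.sqrt(np.mean((y[idx] - oof[idx]) ** 2)) for idx in fold_idx])
    se = float(np.std(per_fold, ddof=1) / np.sqrt(len(per_fold))) if len(per_fold) > 1 else 0.0
    return q2cv, rmse, se


def grow_and_select(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    pool: Sequence[PoolEntry],
    X_test: pd.DataFrame | None = None,
    y_test: Sequence[float] | None = None,
    thresholds: CriteriaThresholds | None = None,
    max_members: int = 4,
    meta_grid: GridSpec | None = None,
    meta_inputs: str = "oof",
    folds: int = 10,
    seed: int = 0,
    paper_faithful_selection: bool = False,
) -> HsvrSelection:
    """Grow ensembles Occam-style and return the first passing size class.

    Two-member combinations are evaluated first, then three, then four (up
    to ``max_members``).  Within the first size class containing passers,
    the passer with the fewest distinct descriptors wins, ties broken by
    validation objective.  If nothing passes, the best-objective candidate
    is returned with ``passed=False``.

    The selection objective is the cross-validated RMSE of the full stack
    on the training set; with ``paper_faithful_selection=True`` the
    test-set RMSE is used instead (leakage-prone: the test set then
    informs model choice).  Criteria are checked on the training report
    and, when a test table is supplied, the external report.

    Among passing combinations, those whose stack cross-validates at
    least as well as every one of their own members are preferred: an
    ensemble that cannot beat its constituents on internal validation
    does not justify its extra complexity.  This dominance preference
    uses only training-internal quantities.
    """
    if max_members < 2:
        raise ValueError("max_members must be >= 2")
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 candidate members")
    yv = np.asarray(y_train, dtype=float).ravel()
    y_ext = None if y_test is None else np.asarray(y_test, dtype=float).ravel()
    th = thresholds or CriteriaThresholds()

    best_overall: HsvrSelection | None = None
    evaluated = 0

    # member out-of-fold predictions are combination-independent; at
    # least 10 folds so the columns match test-time prediction quality
    oof_cache: dict[int, np.ndarray] = {}
    if meta_inputs == "oof":
        oof_folds = min(max(folds, 10), yv.size)
        for i, entry in enumerate(pool):
            _, oof, _ = cross_validate(
                X_train, yv, entry.model, folds=oof_folds, seed=seed
            )
            oof_cache[i] = oof

    true_cv: dict[tuple[int, ...], tuple[float, float, float]] = {}

    def stack_cv_of(sel: HsvrSelection) -> tuple[float, float, float]:
        if sel.member_indices not in true_cv:
            true_cv[sel.member_indices] = _stack_cv(sel.model, X_train, yv, folds, seed)
        return true_cv[sel.member_indices]

    def finalize(sel: HsvrSelection) -> HsvrSelection:
        # the winner gets the full-fidelity stack cross-validation for
        # its reported q2_cv and final verdict
        q2cv, _, _ = stack_cv_of(sel)
        sel.train_report = evaluate_predictions(
            yv, sel.model.predict(X_train), context="training", q2_cv=q2cv
        )
        sel.verdict = check_criteria(sel.train_report, sel.test_report, th)
        sel.passed = sel.verdict.overall_pass
        sel.candidates_evaluated = evaluated
        return sel

    def linear_blend_rmse(combo: tuple[int, ...]) -> float:
        """Closed-form training RMSE of the best linear blend of the
        members' out-of-fold predictions; a cheap prescreen for larger
        combinations before the full meta fit."""
        A = np.column_stack(
            [np.ones(yv.size)] + [oof_cache[i] for i in combo]
        )
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        return float(np.sqrt(np.mean((yv - A @ coef) ** 2)))

    lenient: list[HsvrSelection] = []

    for size in range(2, min(max_members, len(pool)) + 1):
        combos = list(itertools.combinations(range(len(pool)), size))
        if size >= 3 and len(combos) > 25 and oof_cache:
            combos.sort(key=linear_blend_rmse)
            combos = combos[:25]
        passers: list[tuple[bool, HsvrSelection]] = []
        for combo in combos:
            members = [pool[i].model for i in combo]
            model = fit_meta(
                members, X_train, yv, grid=meta_grid, meta_inputs=meta_inputs,
                folds=folds, seed=seed,
                member_oof=[oof_cache[i] for i in combo] if meta_inputs == "oof" else None,
            )
            # screening diagnostics from the meta's own CV over its
            # training inputs (out-of-fold member predictions), a cheap
            # proxy for cross-validating the whole stack
            Z = model.meta_training_inputs_
            meta_clone = MemberSVR(**model.meta_config_)
            q2cv, oof_meta, fold_idx = cross_validate(
                Z, yv, meta_clone, folds=min(folds, yv.size), seed=seed
            )
            cv_rmse_stack = float(np.sqrt(np.mean((yv - oof_meta) ** 2)))
            per_fold = np.array(
                [np.sqrt(np.mean((yv[idx] - oof_meta[idx]) ** 2)) for idx in fold_idx]
            )
            cv_se_stack = (
                float(np.std(per_fold, ddof=1) / np.sqrt(len(per_fold)))
                if len(per_fold) > 1
                else 0.0
            )
            # strict dominance: the stack must improve on every one of its
            # members' internal validation by more than one standard error
            # before its extra complexity is considered justified
            best_member_cv = min(pool[i].cv_rmse for i in combo)
            dominates = cv_rmse_stack <= best_member_cv - cv_se_stack
            train_rep = evaluate_predictions(
                yv, model.predict(X_train), context="training", q2_cv=q2cv
            )
            test_rep = None
            if X_test is not None and y_ext is not None:
                test_rep = evaluate_predictions(
                    y_ext, model.predict(X_test), context="external", observed_train=yv
                )
            verdict = check_criteria(train_rep, test_rep, th)
            if paper_faithful_selection and test_rep is not None:
                objective = test_rep.rmse
            else:
                objective = cv_rmse_stack
            sel = HsvrSelection(
                model=model,
                member_indices=combo,
                passed=verdict.overall_pass,
                verdict=verdict,
                train_report=train_rep,
                test_report=test_rep,
                objective=objective,
                cv_improvement=best_member_cv - cv_rmse_stack,
            )
            evaluated += 1
            if sel.passed:
                passers.append((dominates, sel))
            if best_overall is None or sel.objective < best_overall.objective:
                best_overall = sel
        dominant = [s for d, s in passers if d]
        if dominant:
            # parsimony governs the ensemble size (2 before 3 before 4);
            # within a size class the combination with the strongest
            # internal evidence of added value over its own members wins,
            # descriptor economy and the objective breaking ties
            dominant.sort(
                key=lambda s: (-s.cv_improvement, len(s.model.descriptor_union_), s.objective)
            )
            return finalize(dominant[0])
        if not lenient:
            # remember the smallest size class that at least passed the
            # statistical criteria, in case no larger class dominates
            lenient = [s for _, s in passers]

    if lenient:
        lenient.sort(
            key=lambda s: (-s.cv_improvement, len(s.model.descriptor_union_), s.objective)
        )
        return finalize(lenient[0])

    assert best_overall is not None
    winner = finalize(best_overall)
    winner.passed = False
    return winner
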