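"""Statistical validation battery for QSAR regression models.

Implements the full external/internal validation toolkit used to certify
efflux-ratio models: squared correlation coefficients for training and
external sets, residual summaries, through-origin regression statistics,
the Roy/Ojha rm^2 family, the external qF1/qF2/qF3 coefficients, Lin's
concordance correlation coefficient (CCC), Y-scrambling, and the combined
Golbraikh/Tropsha-style pass/fail criteria checker.

Conventions
-----------
Determination coefficients are of the form ``1 - SS_res / SS_tot``.  The
denominator is centred on the *observed* mean by default, which keeps the
training-set coefficient consistent with the external qF2 definition; a
``center="predicted"`` option reproduces the variant that centres on the
mean predicted value instead.

Undefined quantities (zero-variance denominators) propagate as NaN and are
reported as ``not_applicable`` by the criteria checker, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetricReport",
    "ScrambleReport",
    "CriteriaThresholds",
    "CriteriaVerdict",
    "basic_metrics",
    "origin_stats",
    "roy_metrics",
    "external_metrics",
    "evaluate_predictions",
    "y_scramble",
    "check_criteria",
    "residual_analysis",
]

UNDEFINED = float("nan")

Context = Literal["training", "external"]


def _as_float_array(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} must contain at least 2 values, got {arr.size}")
    return arr


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0 or not math.isfinite(den):
        return UNDEFINED
    return num / den


def determination_coefficient(
    observed: np.ndarray,
    predicted: np.ndarray,
    center: Literal["observed", "predicted"] = "observed",
) -> float:
    """r^2 / q^2 = 1 - sum((yhat-y)^2) / sum((y-<c>)^2).

    ``center`` picks the mean the denominator is centred on; "observed" is
    the default convention, "predicted" the alternate printed form.
    """
    ref = predicted.mean() if center == "predicted" else observed.mean()
    ss_res = float(np.sum((predicted - observed) ** 2))
    ss_tot = float(np.sum((observed - ref) ** 2))
    ratio = _safe_ratio(ss_res, ss_tot)
    return UNDEFINED if math.isnan(ratio) else 1.0 - ratio


@dataclass
class MetricReport:
    """All validation statistics for one (observed, predicted) pairing.

    ``context`` distinguishes training-set reports (r^2, q^2_cv) from
    external/test-set reports (q^2, qF1/qF2/qF3, CCC).  Fields that do not
    apply to a context, or whose denominators vanish, hold NaN.
    """

    context: Context
    n: int
    r2: float  # determination coefficient: r^2 (training) or q^2 (external)
    residuals: np.ndarray
    rmse: float
    mae: float
    s: float  # sample sd of residuals (n-1 denominator)
    delta_max: float
    mean_residual: float
    q2_cv: float = UNDEFINED
    ro2: float = UNDEFINED
    ro2_prime: float = UNDEFINED
    k: float = UNDEFINED
    rm2: float = UNDEFINED
    rm2_prime: float = UNDEFINED
    rm2_mean: float = UNDEFINED
    delta_rm2: float = UNDEFINED
    qf1: float = UNDEFINED
    qf2: float = UNDEFINED
    qf3: float = UNDEFINED
    ccc: float = UNDEFINED
    y_train_mean: float = UNDEFINED
    y_ext_mean: float = UNDEFINED
    yhat_ext_mean: float = UNDEFINED
    yhat_mean: float = UNDEFINED
    n_train: int = 0

    def to_dict(self) -> dict:
        d = {
            "context": self.context,
            "n": self.n,
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "s": self.s,
            "delta_max": self.delta_max,
            "mean_residual": self.mean_residual,
            "q2_cv": self.q2_cv,
            "ro2": self.ro2,
            "ro2_prime": self.ro2_prime,
            "k": self.k,
            "rm2": self.rm2,
            "rm2_prime": self.rm2_prime,
            "rm2_mean": self.rm2_mean,
            "delta_rm2": self.delta_rm2,
            "qf1": self.qf1,
            "qf2": self.qf2,
            "qf3": self.qf3,
            "ccc": self.ccc,
        }
        return d


def basic_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    context: Context = "training",
    center: Literal["observed", "predicted"] = "observed",
) -> MetricReport:
    """Residual-based statistics: r^2/q^2, RMSE, MAE, s, max residual."""
    y = _as_float_array(observed, "observed")
    yhat = _as_float_array(predicted, "predicted")
    if y.size != yhat.size:
        raise ValueError("observed and predicted must have equal length")
    resid = y - yhat
    n = y.size
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    s = float(np.std(resid, ddof=1))
    return MetricReport(
        context=context,
        n=n,
        r2=determination_coefficient(y, yhat, center=center),
        residuals=resid,
        rmse=rmse,
        mae=mae,
        s=s,
        delta_max=float(np.max(np.abs(resid))),
        mean_residual=float(np.mean(resid)),
        yhat_mean=float(np.mean(yhat)),
    )


def origin_stats(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float]:
    """Through-origin regression statistics (ro^2, r'o^2, k).

    ``k`` is the least-squares slope of the through-origin line fitted as
    predicted-vs-observed (yhat = k * y).  ro^2 is the coefficient of
    determination of the points about that line, with the total sum of
    squares centred on the mean of the dependent axis (predicted); r'o^2
    swaps the roles (observed-vs-predicted line, centred on the observed
    mean).  This is the Golbraikh/Tropsha convention.
    """
    y = _as_float_array(observed, "observed")
    yhat = _as_float_array(predicted, "predicted")
    if y.size != yhat.size:
        raise ValueError("observed and predicted must have equal length")

    def _through_origin(x: np.ndarray, z: np.ndarray) -> tuple[float, float]:
        # z = slope * x through the origin; R^2 about the dependent-axis mean
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            return UNDEFINED, UNDEFINED
        slope = float(np.sum(x * z) / sxx)
        ss_res = float(np.sum((z - slope * x) ** 2))
        ss_tot = float(np.sum((z - z.mean()) ** 2))
        r2o = UNDEFINED if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        return slope, r2o

    k, ro2 = _through_origin(y, yhat)
    _, ro2_prime = _through_origin(yhat, y)
    return ro2, ro2_prime, k


def roy_metrics(
    r2: float,
    ro2: float,
    ro2_prime: float,
    variant: Literal["sqrt", "printed"] = "sqrt",
) -> tuple[float, float, float, float]:
    """Roy/Ojha modified coefficients (rm^2, r'm^2, <rm^2>, Δrm^2).

    variant "sqrt" is the standard rm^2 = r^2 (1 - sqrt(|r^2 - ro^2|));
    "printed" omits the square root.  The average and the absolute gap are
    variant-independent combinations of whichever pair is supplied.
    """
    def _rm(base: float, through_origin: float) -> float:
        if math.isnan(base) or math.isnan(through_origin):
            return UNDEFINED
        gap = abs(base - through_origin)
        penalty = math.sqrt(gap) if variant == "sqrt" else gap
        return base * (1.0 - penalty)

    rm2 = _rm(r2, ro2)
    rm2_prime = _rm(r2, ro2_prime)
    mean, delta = combine_rm2(rm2, rm2_prime)
    return rm2, rm2_prime, mean, delta


def combine_rm2(rm2: float, rm2_prime: float) -> tuple[float, float]:
    """<rm^2> = (rm^2 + r'm^2)/2 and Δrm^2 = |rm^2 - r'm^2|."""
    if math.isnan(rm2) or math.isnan(rm2_prime):
        return UNDEFINED, UNDEFINED
    return (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


def external_metrics(
    observed_ext: Sequence[float],
    predicted_ext: Sequence[float],
    observed_train: Sequence[float],
    train_mean_convention: Literal["observed", "predicted"] = "observed",
    predicted_train: Sequence[float] | None = None,
) -> tuple[float, float, float, float]:
    """External-set coefficients qF1^2, qF2^2, qF3^2 and CCC.

    qF1 and qF3 reference the training-set mean; by default the *observed*
    training mean (the standard convention).  ``train_mean_convention=
    "predicted"`` uses the mean predicted training value instead, in which
    case ``predicted_train`` must be given.
    """
    y = _as_float_array(observed_ext, "observed_ext")
    yhat = _as_float_array(predicted_ext, "predicted_ext")
    ytr = np.asarray(observed_train, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("external observed/predicted must have equal length")
    if ytr.size < 2:
        raise ValueError("training observations required for qF1/qF3")
    if train_mean_convention == "predicted":
        if predicted_train is None:
            raise ValueError("predicted_train required for the predicted-mean convention")
        ref_train_mean = float(np.mean(np.asarray(predicted_train, dtype=float)))
    else:
        ref_train_mean = float(ytr.mean())

    n_ext = y.size
    ss_res = float(np.sum((y - yhat) ** 2))

    den1 = float(np.sum((y - ref_train_mean) ** 2))
    qf1 = UNDEFINED if den1 == 0.0 else 1.0 - ss_res / den1

    den2 = float(np.sum((y - y.mean()) ** 2))
    qf2 = UNDEFINED if den2 == 0.0 else 1.0 - ss_res / den2

    den3 = float(np.sum((ytr - float(ytr.mean())) ** 2)) / ytr.size
    qf3 = UNDEFINED if den3 == 0.0 else 1.0 - (ss_res / n_ext) / den3

    ym, yhm = float(y.mean()), float(yhat.mean())
    num = 2.0 * float(np.sum((y - ym) * (yhat - yhm)))
    den = (
        float(np.sum((y - ym) ** 2))
        + float(np.sum((yhat - yhm) ** 2))
        + n_ext * (ym - yhm) ** 2
    )
    ccc = UNDEFINED if den == 0.0 else num / den

    return qf1, qf2, qf3, ccc


def evaluate_predictions(
    observed: Sequence[float],
    predicted: Sequence[float],
    context: Context = "training",
    observed_train: Sequence[float] | None = None,
    q2_cv: float = UNDEFINED,
    rm2_variant: Literal["sqrt", "printed"] = "sqrt",
    center: Literal["observed", "predicted"] = "observed",
) -> MetricReport:
    """Assemble the complete MetricReport for one prediction set.

    For ``context="external"``, ``observed_train`` supplies the training
    responses needed by qF1/qF3; CCC is computed there and left NaN for
    training reports (where the criteria table marks it not applicable).
    """
    report = basic_metrics(observed, predicted, context=context, center=center)
    report.q2_cv = q2_cv
    report.ro2, report.ro2_prime, report.k = origin_stats(observed, predicted)
    report.rm2, report.rm2_prime, report.rm2_mean, report.delta_rm2 = roy_metrics(
        report.r2, report.ro2, report.ro2_prime, variant=rm2_variant
    )
    if context == "external":
        if observed_train is None:
            raise ValueError("observed_train is required for external-context reports")
        report.qf1, report.qf2, report.qf3, report.ccc = external_metrics(
            observed, predicted, observed_train
        )
        ytr = np.asarray(observed_train, dtype=float)
        report.y_train_mean = float(ytr.mean())
        report.n_train = int(ytr.size)
        report.y_ext_mean = float(np.asarray(observed, dtype=float).mean())
        report.yhat_ext_mean = float(np.asarray(predicted, dtype=float).mean())
    return report


# ---------------------------------------------------------------------------
# Y-scrambling


@dataclass
class ScrambleReport:
    """Chance-correlation diagnostic from refits on permuted responses."""

    rs2_values: list[float]
    seed: int

    @property
    def mean_rs2(self) -> float:
        return float(np.mean(self.rs2_values))

    @property
    def count(self) -> int:
        return len(self.rs2_values)


def y_scramble(
    X: pd.DataFrame,
    y: Sequence[float],
    model_factory: Callable[[], "object"],
    scrambles: int = 25,
    seed: int = 0,
    _permutations: Sequence[np.ndarray] | None = None,
) -> ScrambleReport:
    """Refit the model on randomly permuted responses, descriptors unchanged.

    ``model_factory`` returns a fresh unfitted estimator with the same
    hyperparameters each call (e.g. ``lambda: clone(model)``).  Each of the
    ``scrambles`` rounds permutes y, refits, and records the squared
    correlation rs^2 between the permuted response and the refit's training
    predictions; their mean <rs^2> near zero indicates the unscrambled fit
    is not a chance correlation.

    ``_permutations`` is a test hook forcing explicit permutations.
    """
    if scrambles < 1:
        raise ValueError("scrambles must be >= 1")
    yv = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    rs2 = []
    for i in range(scrambles):
        if _permutations is not None:
            perm = np.asarray(_permutations[i])
        else:
            perm = rng.permutation(yv.size)
        y_perm = yv[perm]
        model = model_factory()
        model.fit(X, y_perm)
        yhat = np.asarray(model.predict(X), dtype=float)
        rs2.append(determination_coefficient(y_perm, yhat))
    return ScrambleReport(rs2_values=rs2, seed=seed)


# ---------------------------------------------------------------------------
# Criteria verdict


@dataclass
class CriteriaThresholds:
    """Pass thresholds of the combined stringent-validation battery."""

    coefficient_floor: float = 0.70      # r^2, q^2_cv, q^2, qFn^2 >=
    r2_q2cv_gap: float = 0.10            # |r^2 - q^2_cv| <
    origin_gap_fraction: float = 0.10    # (r^2 - ro^2)/r^2 <
    k_low: float = 0.85
    k_high: float = 1.15
    origin_symmetry_gap: float = 0.30    # |ro^2 - r'o^2| <
    rm2_floor: float = 0.65              # rm^2 >=
    rm2_mean_floor: float = 0.65         # <rm^2> >=
    delta_rm2_ceiling: float = 0.20      # Δrm^2 <
    ccc_floor: float = 0.85              # CCC >= (external only)


Status = Literal["pass", "fail", "not_applicable"]

CRITERION_NAMES = (
    "coefficients_floor",
    "r2_q2cv_gap",
    "origin_regression",
    "origin_symmetry",
    "rm2_floor",
    "rm2_mean_and_delta",
    "ccc_floor",
)


@dataclass
class CriteriaVerdict:
    """Per-criterion pass/fail/not-applicable statuses for both contexts.

    ``statuses[name]`` maps to a (training, external) status pair mirroring
    the two columns of the published criteria table; overall pass iff no
    entry fails.
    """

    statuses: dict[str, tuple[Status, Status]] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(
            s != "fail" for pair in self.statuses.values() for s in pair
        )

    def to_dict(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "criteria": {
                name: {"training": pair[0], "external": pair[1]}
                for name, pair in self.statuses.items()
            },
            "notes": dict(self.notes),
        }


def _status(condition_inputs: list[float], passed: bool) -> Status:
    if any(math.isnan(v) for v in condition_inputs):
        return "not_applicable"
    return "pass" if passed else "fail"


def check_criteria(
    train_report: MetricReport | None,
    test_report: MetricReport | None,
    thresholds: CriteriaThresholds | None = None,
) -> CriteriaVerdict:
    """Evaluate the stringent combined validation criteria.

    Context applicability follows the published layout: the |r^2 - q^2_cv|
    gap applies to the training set only, the CCC floor to the external set
    only; every other criterion is evaluated in both contexts.  Reports
    missing entirely, or NaN inputs, yield ``not_applicable``.
    """
    th = thresholds or CriteriaThresholds()
    verdict = CriteriaVerdict()

    def eval_context(rep: MetricReport | None, context: Context) -> dict[str, Status]:
        na: Status = "not_applicable"
        if rep is None:
            return {name: na for name in CRITERION_NAMES}
        out: dict[str, Status] = {}

        coeffs = [rep.r2, rep.q2_cv] if context == "training" else [
            rep.r2, rep.qf1, rep.qf2, rep.qf3
        ]
        out["coefficients_floor"] = _status(
            coeffs, all(c >= th.coefficient_floor for c in coeffs if not math.isnan(c))
        )

        if context == "training":
            out["r2_q2cv_gap"] = _status(
                [rep.r2, rep.q2_cv], abs(rep.r2 - rep.q2_cv) < th.r2_q2cv_gap
            )
        else:
            out["r2_q2cv_gap"] = na

        if rep.r2 == 0.0 or math.isnan(rep.r2):
            out["origin_regression"] = na
        else:
            out["origin_regression"] = _status(
                [rep.r2, rep.ro2, rep.k],
                (rep.r2 - rep.ro2) / rep.r2 < th.origin_gap_fraction
                and th.k_low <= rep.k <= th.k_high,
            )

        out["origin_symmetry"] = _status(
            [rep.ro2, rep.ro2_prime],
            abs(rep.ro2 - rep.ro2_prime) < th.origin_symmetry_gap,
        )
        out["rm2_floor"] = _status([rep.rm2], rep.rm2 >= th.rm2_floor)
        out["rm2_mean_and_delta"] = _status(
            [rep.rm2_mean, rep.delta_rm2],
            rep.rm2_mean >= th.rm2_mean_floor and rep.delta_rm2 < th.delta_rm2_ceiling,
        )
        if context == "external":
            out["ccc_floor"] = _status([rep.ccc], rep.ccc >= th.ccc_floor)
        else:
            out["ccc_floor"] = na
        return out

    train_statuses = eval_context(train_report, "training")
    test_statuses = eval_context(test_report, "external")
    for name in CRITERION_NAMES:
        verdict.statuses[name] = (train_statuses[name], test_statuses[name])
    return verdict


def residual_analysis(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[pd.DataFrame, float]:
    """Residual-vs-predicted table plus the signed mean residual.

    The table supports the standard residual scatter diagnostic: residuals
    evenly straddling zero across the predicted range indicate no
    systematic error.
    """
    y = _as_float_array(observed, "observed")
    yhat = _as_float_array(predicted, "predicted")
    resid = y - yhat
    table = pd.DataFrame({"predicted": yhat, "residual": resid})
    return table, float(resid.mean())
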