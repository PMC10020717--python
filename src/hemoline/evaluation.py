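"""Accuracy metrics, equivalence testing and explainability.

Per-case metrics: pressure RMSE (mmHg), pressure NRMSE normalized by the
reference maximum pressure drop (inlet minus infimum), WSS NRMSE normalized
by the reference WSS supremum.  Method-equivalence of transvalvular
pressure gradients (TPG) uses a two one-sided tests (TOST) procedure with
Wilcoxon signed-rank tests and a +-5 mmHg margin (the accuracy of clinical
catheter-based pressure measurement).  Explainability follows a local
feature-perturbation scheme: a feature is shifted by +-1 training SD over a
small centerline window and the induced output RMSE is recorded.

Cohort summaries report medians and IQRs (linear-interpolation quantiles),
Pearson correlations of case RMSE against stenosis severity (MPD, peak WSS),
a Wilcoxon rank-sum comparison of test-subset versus cohort MPDs, and a
Lilliefors normality test for the WSS RMSE distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .dataset import CaseRecord, FeatureSequence
from .exceptions import InputError
from .oracle import HemodynamicProfile, compute_mpd, compute_tpg
from .surrogate import SurrogateModel, predict

TOST_EPSILON_MMHG = 5.0
TOST_ALPHA = 0.05


# ---------------------------------------------------------------------------
# per-case metrics


def rmse_pressure(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square pointwise pressure error, mmHg."""
    pred, ref = _paired(pred, ref)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def nrmse_pressure(pred: np.ndarray, ref: np.ndarray) -> float:
    """Pressure RMSE normalized by the reference maximum pressure drop.

    Each residual is divided by (first reference value minus reference
    infimum) inside the root-mean-square; since that denominator is constant
    per case this equals RMSE / MPD_ref.
    """
    pred, ref = _paired(pred, ref)
    denom = ref[0] - np.min(ref)
    if denom <= 0:
        raise InputError("reference profile has no pressure drop (zero denominator)")
    return float(np.sqrt(np.mean(((pred - ref) / denom) ** 2)))


def nrmse_wss(pred: np.ndarray, ref: np.ndarray) -> float:
    """WSS RMSE normalized by the reference WSS supremum."""
    pred, ref = _paired(pred, ref)
    denom = np.max(ref)
    if denom <= 0:
        raise InputError("all-zero reference WSS (zero denominator)")
    return float(np.sqrt(np.mean(((pred - ref) / denom) ** 2)))


def _paired(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or len(pred) == 0:
        raise InputError("pred and ref must be equal-length non-empty 1D arrays")
    return pred, ref


@dataclass
class CaseMetrics:
    """Accuracy of one surrogate prediction against its reference profile."""

    rmse_p: float
    nrmse_p: float
    rmse_wss: float
    nrmse_wss: float
    mpd_ref: float
    peak_wss_ref: float
    tpg_ref: float
    tpg_pred: float
    geometry_id: str = ""
    flow_condition: str = ""


def case_metrics(
    pred: HemodynamicProfile, ref: HemodynamicProfile,
    geometry_id: str = "", flow_condition: str = "",
) -> CaseMetrics:
    return CaseMetrics(
        rmse_p=rmse_pressure(pred.pressure, ref.pressure),
        nrmse_p=nrmse_pressure(pred.pressure, ref.pressure),
        rmse_wss=rmse_pressure(pred.wss, ref.wss),  # same RMS form, Pa
        nrmse_wss=nrmse_wss(pred.wss, ref.wss),
        mpd_ref=compute_mpd(ref),
        peak_wss_ref=float(np.max(ref.wss)),
        tpg_ref=compute_tpg(ref),
        tpg_pred=compute_tpg(pred),
        geometry_id=geometry_id,
        flow_condition=flow_condition,
    )


# ---------------------------------------------------------------------------
# TOST equivalence of TPG


@dataclass
class EquivalenceResult:
    """Outcome of the two one-sided signed-rank tests on paired TPG values."""

    theta: float  # median paired difference, mmHg
    theta0: float
    epsilon: float
    alpha: float
    p_lower: float  # H1_0: theta < theta0 - epsilon
    p_upper: float  # H2_0: theta > theta0 + epsilon
    equivalent: bool
    mu_ref: float
    mu_pred: float
    n: int


def _signed_rank_p(x: np.ndarray, alternative: str) -> float:
    """One-sided Wilcoxon signed-rank p-value.

    Exact null distribution for n <= 25 without zeros; zeros are handled by
    Pratt's method under the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    has_zeros = np.any(x == 0)
    if np.all(x == 0):
        return 1.0
    if has_zeros:
        res = sps.wilcoxon(x, zero_method="pratt", alternative=alternative,
                           method="approx", correction=True)
    else:
        method = "exact" if len(x) <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tie warnings under exact mode
            res = sps.wilcoxon(x, alternative=alternative, method=method)
    return float(res.pvalue)


def tost_tpg(
    tpg_ref, tpg_pred,
    epsilon: float = TOST_EPSILON_MMHG,
    alpha: float = TOST_ALPHA,
    theta0: float = 0.0,
) -> EquivalenceResult:
    """TOST equivalence of paired reference vs surrogate TPG values.

    With d_j = ref_j - pred_j, H1_0 (median difference below theta0 - eps) is
    tested one-sided on d + eps - theta0 against location <= 0 and H2_0 on
    d - eps - theta0 against location >= 0; equivalence is declared iff both
    are rejected at alpha.
    """
    tpg_ref = np.asarray(tpg_ref, dtype=float)
    tpg_pred = np.asarray(tpg_pred, dtype=float)
    if tpg_ref.shape != tpg_pred.shape or tpg_ref.ndim != 1:
        raise InputError("paired TPG lists must share one length")
    n = len(tpg_ref)
    if n < 6:
        raise InputError(f"need at least 6 pairs for the signed-rank TOST, got {n}")
    if epsilon <= 0:
        raise InputError("epsilon must be positive")
    d = tpg_ref - tpg_pred
    p_lower = _signed_rank_p(d - theta0 + epsilon, alternative="greater")
    p_upper = _signed_rank_p(d - theta0 - epsilon, alternative="less")
    return EquivalenceResult(
        theta=float(np.median(d)),
        theta0=theta0,
        epsilon=epsilon,
        alpha=alpha,
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=bool(p_lower < alpha and p_upper < alpha),
        mu_ref=float(np.median(tpg_ref)),
        mu_pred=float(np.median(tpg_pred)),
        n=n,
    )


# ---------------------------------------------------------------------------
# perturbation explainability


def perturb_sensitivity(
    model: SurrogateModel,
    features: FeatureSequence,
    point_index: int,
    feature_index: int,
    window_halfwidth: int = 3,
) -> tuple[float, float]:
    """Local +-1 SD feature perturbation around one centerline point.

    The chosen feature column is shifted by plus and minus one training SD
    over points [i - w, i + w]; both perturbed predictions are compared with
    the unperturbed prediction and the two output RMSEs are averaged.
    Returns (pressure RMSE in mmHg, WSS RMSE in Pa).  Constant (zero-SD)
    features yield (0, 0) because the guarded scale leaves them untouched.
    """
    n, width = features.n_points, features.width
    if not (0 <= point_index < n):
        raise InputError("point_index out of range")
    if not (0 <= feature_index < width):
        raise InputError("feature_index out of range")
    lo = point_index - window_halfwidth
    hi = point_index + window_halfwidth
    if lo < 0 or hi >= n:
        warnings.warn("perturbation window clipped at the sequence boundary")
        lo, hi = max(lo, 0), min(hi, n - 1)

    sd = float(model.feature_stats.raw_sd()[feature_index])
    if sd == 0.0:  # constant training feature: perturbation is a no-op
        return 0.0, 0.0
    base = predict(model, features)

    out = []
    for sign in (+1.0, -1.0):
        perturbed = features.values.copy()
        perturbed[lo : hi + 1, feature_index] += sign * sd
        pert_pred = predict(
            model,
            FeatureSequence(values=perturbed, geometry_id=features.geometry_id,
                            flow_condition=features.flow_condition),
        )
        out.append(
            (
                rmse_pressure(pert_pred.pressure, base.pressure),
                float(np.sqrt(np.mean((pert_pred.wss - base.wss) ** 2))),
            )
        )
    d_p = 0.5 * (out[0][0] + out[1][0])
    d_w = 0.5 * (out[0][1] + out[1][1])
    return d_p, d_w


@dataclass
class SensitivityMap:
    """Output RMSE under local perturbation, per (point, feature)."""

    delta_rmse_p: np.ndarray  # (n_points, n_features), mmHg
    delta_rmse_wss: np.ndarray  # (n_points, n_features), Pa
    window_halfwidth: int
    feature_names: list[str] = field(default_factory=list)


def sensitivity_map(
    model: SurrogateModel,
    features: FeatureSequence,
    point_indices=None,
    feature_indices=None,
    window_halfwidth: int = 3,
) -> SensitivityMap:
    """Dense perturbation scan over the requested points and features."""
    pts = list(point_indices) if point_indices is not None else range(features.n_points)
    fts = list(feature_indices) if feature_indices is not None else range(features.width)
    dp = np.zeros((features.n_points, features.width))
    dw = np.zeros_like(dp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary windows clip en masse here
        for i in pts:
            for j in fts:
                dp[i, j], dw[i, j] = perturb_sensitivity(
                    model, features, i, j, window_halfwidth
                )
    m = features.width - 5
    names = ["x", "y", "z", "area", "q_over_a"] + [f"shape_{k}" for k in range(m)]
    return SensitivityMap(
        delta_rmse_p=dp, delta_rmse_wss=dw,
        window_halfwidth=window_halfwidth, feature_names=names,
    )


# ---------------------------------------------------------------------------
# cohort statistics


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear-interpolation quantiles
    return float(q3 - q1)


def cohort_report(
    metrics: list[CaseMetrics],
    test_mpds=None,
    cohort_mpds=None,
    lilliefors_on: str = "rmse_wss",
) -> dict:
    """Cohort-level summary of a list of per-case metrics.

    Returns medians/IQRs for every metric, Pearson correlations of pressure
    RMSE vs reference MPD and WSS RMSE vs reference peak WSS, optionally a
    Wilcoxon rank-sum comparison of test-subset MPDs against the full-cohort
    MPDs, and a Lilliefors normality test on the chosen metric.
    """
    if len(metrics) < 3:
        raise InputError("need at least 3 cases for a cohort report")
    cols = {
        name: np.array([getattr(m, name) for m in metrics])
        for name in ("rmse_p", "nrmse_p", "rmse_wss", "nrmse_wss",
                     "mpd_ref", "peak_wss_ref", "tpg_ref", "tpg_pred")
    }
    report: dict = {"n_cases": len(metrics), "summary": {}}
    for name, x in cols.items():
        report["summary"][name] = {"median": float(np.median(x)), "iqr": _iqr(x)}

    def _pearson(x, y):
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            return {"r": None, "p": None, "defined": False}
        r, p = sps.pearsonr(x, y)
        return {"r": float(r), "p": float(p), "defined": True}

    report["corr_rmse_p_vs_mpd"] = _pearson(cols["rmse_p"], cols["mpd_ref"])
    report["corr_rmse_wss_vs_peak_wss"] = _pearson(cols["rmse_wss"], cols["peak_wss_ref"])

    if test_mpds is not None and cohort_mpds is not None:
        stat, p = sps.ranksums(np.asarray(test_mpds), np.asarray(cohort_mpds))
        report["ranksum_test_vs_cohort_mpd"] = {"statistic": float(stat), "p": float(p)}

    x = cols[lilliefors_on]
    if np.std(x) > 1e-12 and len(x) >= 4:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        report["lilliefors"] = {"on": lilliefors_on, "statistic": float(stat), "p": float(p)}
    else:
        report["lilliefors"] = {"on": lilliefors_on, "statistic": None, "p": None}
    return report


def evaluate_records(
    model: SurrogateModel,
    features: list[FeatureSequence],
    records: list[CaseRecord],
) -> list[CaseMetrics]:
    """Predict every record and collect per-case metrics."""
    out = []
    for f, r in zip(features, records):
        pred = predict(model, f)
        out.append(case_metrics(pred, r.profile, r.geometry_id, r.flow_condition))
    return out
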