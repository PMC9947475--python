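"""Method-comparison statistics and permutation feature importance.

All agreement statistics treat the force-platform height as the reference and
work on the difference d = estimate − reference:

* accuracy = RMSD = √mean(d²); bias = mean(d); precision = sample SD of d;
  MAE = mean|d| ± SD of |d| (by construction
  RMSD² = bias² + ((n−1)/n)·precision²);
* heteroscedasticity screen: Kendall's τ (tau-b, tie-corrected) between the
  pairwise means (ref+est)/2 and the absolute differences; τ ≥ 0.1 flags a
  magnitude-dependent error;
* two-sided paired t-test on d with a 95% CI of the mean difference;
* calibration: OLS of the reference on the estimate, with the residual
  standard deviation (SEE) and Pearson r;
* Bland-Altman: bias, limits of agreement bias ± 1.96·SD, and the Giavarina
  confidence intervals — bias CI half-width t(0.975, n−1)·SD/√n, LoA CI
  half-width t(0.975, n−1)·√(3·SD²/n) — plus the average-vs-difference
  regression and the standardized bias (bias/SD).

Permutation feature importance follows the half-swap scheme: the evaluation
set is split at random into two halves and a feature's values are exchanged
between them, which permutes the column while preserving its marginal
distribution; the importance is the ratio of permuted to baseline MSE,
averaged over repeats.  An ignored feature therefore scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .model import M_TO_CM, ModelBundle, predict_height

TAU_THRESHOLD = 0.1


@dataclass
class AgreementReport:
    """Core agreement metrics between an estimate and the reference, in cm."""

    n: int
    rmsd: float
    bias: float
    precision_sd: float
    mae: float
    mae_sd: float
    tau: float
    heteroscedastic: bool
    t_stat: float
    p_value: float
    dof: int
    ci95: tuple[float, float]
    calib_intercept: float
    calib_slope: float
    calib_see: float
    calib_r: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d

    def __str__(self) -> str:  # one-decimal cm formatting, table style
        return (
            f"n={self.n}  accuracy(RMSD)={self.rmsd:.1f} cm  bias={self.bias:.1f} cm  "
            f"precision={self.precision_sd:.1f} cm  MAE={self.mae:.1f}±{self.mae_sd:.1f} cm\n"
            f"tau={self.tau:.2f} ({'hetero' if self.heteroscedastic else 'homo'}scedastic)  "
            f"paired t({self.dof})={self.t_stat:.3f}, p={self.p_value:.3f}, "
            f"CI95=[{self.ci95[0]:.1f}, {self.ci95[1]:.1f}] cm\n"
            f"calibration: ref = {self.calib_intercept:.3f} + {self.calib_slope:.3f}·est, "
            f"SEE={self.calib_see:.3f} cm, r={self.calib_r:.3f}"
        )


@dataclass
class BlandAltman:
    """Bland-Altman quantities with Giavarina confidence intervals, in cm."""

    bias: float
    bias_ci: tuple[float, float]
    loa_low: float
    loa_low_ci: tuple[float, float]
    loa_high: float
    loa_high_ci: tuple[float, float]
    sd_diff: float
    standardized_bias: float
    slope: float  # average-vs-difference regression
    r2: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("bias_ci", "loa_low_ci", "loa_high_ci"):
            d[k] = list(d[k])
        return d


@dataclass
class FeatureImportance:
    """Half-swap permutation importances FI_j = MSE_permuted / MSE_baseline."""

    names: list[str]
    fi: np.ndarray
    e0: float
    ej: np.ndarray

    def ranking(self) -> list[str]:
        """Feature names by descending importance."""
        order = np.argsort(-self.fi, kind="stable")
        return [self.names[i] for i in order]


def agreement_metrics(h_true, h_est) -> dict:
    """RMSD / bias / precision / MAE of est − true (units follow the inputs)."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    if h_true.shape != h_est.shape:
        raise ValueError("h_true and h_est must have equal length")
    n = h_true.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    d = h_est - h_true
    ae = np.abs(d)
    return {
        "n": n,
        "rmsd": float(np.sqrt(np.mean(d ** 2))),
        "bias": float(np.mean(d)),
        "precision_sd": float(np.std(d, ddof=1)),
        "mae": float(np.mean(ae)),
        "mae_sd": float(np.std(ae, ddof=1)),
    }


def kendall_tau_hetero(h_true, h_est) -> tuple[float, bool]:
    """Tau-b between pairwise means and absolute differences; flag at τ ≥ 0.1."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    if h_true.size < 5:
        raise ValueError("need at least 5 pairs for the heteroscedasticity screen")
    means = (h_true + h_est) / 2.0
    absd = np.abs(h_true - h_est)
    tau = stats.kendalltau(means, absd, variant="b").statistic
    if not np.isfinite(tau):
        raise DataError("Kendall tau undefined (all-tied input)")
    return float(tau), bool(tau >= TAU_THRESHOLD)


def paired_t(h_true, h_est) -> tuple[float, float, int, tuple[float, float]]:
    """Two-sided paired t-test of est − true with the 95% CI of the mean."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    n = h_true.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = h_est - h_true
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DataError("zero-variance differences: paired t-test degenerate")
    res = stats.ttest_rel(h_est, h_true)
    dof = n - 1
    half = stats.t.ppf(0.975, dof) * sd / np.sqrt(n)
    mean_d = float(np.mean(d))
    return float(res.statistic), float(res.pvalue), dof, (mean_d - half, mean_d + half)


def calibration_regression(h_true, h_est) -> tuple[float, float, float, float]:
    """OLS of reference on estimate: (intercept, slope, SEE, r)."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    if h_true.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(h_est) == 0.0:
        raise DataError("zero-variance estimate: calibration regression undefined")
    fit = stats.linregress(h_est, h_true)
    resid = h_true - (fit.intercept + fit.slope * h_est)
    see = float(np.sqrt(np.sum(resid ** 2) / max(h_true.size - 2, 1)))
    return float(fit.intercept), float(fit.slope), see, float(fit.rvalue)


def bland_altman(h_true, h_est) -> BlandAltman:
    """Bland-Altman bias, 1.96·SD limits of agreement and Giavarina CIs."""
    h_true = np.asarray(h_true, dtype=float)
    h_est = np.asarray(h_est, dtype=float)
    n = h_true.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = h_est - h_true
    avg = (h_est + h_true) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = sd == 0.0
    tq = float(stats.t.ppf(0.975, n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_loa = tq * np.sqrt(3.0 * sd ** 2 / n)
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    if np.std(avg) > 0 and not degenerate:
        fit = stats.linregress(avg, d)
        slope, r2 = float(fit.slope), float(fit.rvalue ** 2)
    else:
        slope, r2 = 0.0, 0.0
    return BlandAltman(
        bias=bias,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low=loa_low,
        loa_low_ci=(loa_low - half_loa, loa_low + half_loa),
        loa_high=loa_high,
        loa_high_ci=(loa_high - half_loa, loa_high + half_loa),
        sd_diff=sd,
        standardized_bias=bias / sd if sd > 0 else 0.0,
        slope=slope,
        r2=r2,
        degenerate=degenerate,
    )


def evaluate_heights(h_true_m, h_est_m) -> tuple[AgreementReport, BlandAltman]:
    """Full agreement battery on heights given in metres; reports in cm."""
    t_cm = np.asarray(h_true_m, dtype=float) * M_TO_CM
    e_cm = np.asarray(h_est_m, dtype=float) * M_TO_CM
    core = agreement_metrics(t_cm, e_cm)
    tau, flag = kendall_tau_hetero(t_cm, e_cm)
    t_stat, p, dof, ci = paired_t(t_cm, e_cm)
    intercept, slope, see, r = calibration_regression(t_cm, e_cm)
    report = AgreementReport(
        **core,
        tau=tau,
        heteroscedastic=flag,
        t_stat=t_stat,
        p_value=p,
        dof=dof,
        ci95=ci,
        calib_intercept=intercept,
        calib_slope=slope,
        calib_see=see,
        calib_r=r,
    )
    return report, bland_altman(t_cm, e_cm)


# ---------------------------------------------------------------------------
# permutation feature importance


def half_swap_permutation(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exchange a column's values between two random halves of the rows."""
    n = values.size
    perm = rng.permutation(n)
    half = n // 2
    first, second = perm[:half], perm[half:2 * half]
    out = values.copy()
    out[first], out[second] = values[second], values[first]
    return out


def half_swap_importance(
    predict, x: np.ndarray, y: np.ndarray, seed: int = 0, n_repeats: int = 10
) -> tuple[float, np.ndarray]:
    """Baseline MSE and per-column permuted MSEs for a bare predict function."""
    rng = np.random.default_rng(seed)
    e0 = float(np.mean((y - predict(x)) ** 2))
    if e0 <= 0:
        raise DataError("baseline MSE is zero: importances undefined")
    ej = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        # accumulate MSE ratios so an untouched prediction gives exactly 1.0
        acc = 0.0
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = half_swap_permutation(x[:, j], rng)
            acc += float(np.mean((y - predict(xp)) ** 2)) / e0
        ej[j] = e0 * (acc / n_repeats)
    return e0, ej


def permutation_importance(
    bundle: ModelBundle,
    features: pd.DataFrame,
    h_fp_m,
    seed: int = 0,
    n_repeats: int = 10,
) -> FeatureImportance:
    """Half-swap PFI of the selected features on a (training) feature table.

    The error is the MSE in cm² between the reference heights and the
    bundle's predictions; each selected feature is swapped between two random
    halves of the rows, ``n_repeats`` times, and the mean permuted MSE is
    divided by the baseline.
    """
    y_cm = np.asarray(h_fp_m, dtype=float) * M_TO_CM

    def predict_selected(x_sel: np.ndarray) -> np.ndarray:
        df = features.copy()
        df.loc[:, bundle.selected] = x_sel
        return predict_height(bundle, df) * M_TO_CM

    x = features[bundle.selected].to_numpy(dtype=float)
    e0, ej = half_swap_importance(predict_selected, x, y_cm, seed=seed, n_repeats=n_repeats)
    return FeatureImportance(names=list(bundle.selected), fi=ej / e0, e0=e0, ej=ej)


# ---------------------------------------------------------------------------
# plots (optional, matplotlib)


def bland_altman_plot(h_true_cm, h_est_cm, ax=None, label: str = "estimate"):
    """Average-vs-difference plot with bias, LoA and shaded Giavarina CIs."""
    import matplotlib.pyplot as plt

    h_true_cm = np.asarray(h_true_cm, dtype=float)
    h_est_cm = np.asarray(h_est_cm, dtype=float)
    ba = bland_altman(h_true_cm, h_est_cm)
    avg = (h_true_cm + h_est_cm) / 2.0
    d = h_est_cm - h_true_cm
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(avg, d, s=14, color="k", zorder=3)
    for val, ci, style in (
        (ba.bias, ba.bias_ci, "-"),
        (ba.loa_low, ba.loa_low_ci, "-."),
        (ba.loa_high, ba.loa_high_ci, "-."),
    ):
        ax.axhline(val, linestyle=style, color="k", linewidth=1)
        ax.axhspan(ci[0], ci[1], color="0.85", zorder=0)
    xs = np.linspace(avg.min(), avg.max(), 50)
    fit = stats.linregress(avg, d)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="0.4")
    ax.set_xlabel("average of methods (cm)")
    ax.set_ylabel(f"difference {label} − reference (cm)")
    return ax


def importance_barchart(fi: FeatureImportance, ax=None):
    """Bar chart of FI ratios, descending."""
    import matplotlib.pyplot as plt

    order = np.argsort(-fi.fi, kind="stable")
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(len(order)), fi.fi[order], color="0.4")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([fi.names[i] for i in order], rotation=90)
    ax.axhline(1.0, color="k", linewidth=0.8)
    ax.set_ylabel("FI = MSE_perm / MSE_0")
    return ax
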