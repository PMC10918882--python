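"""Univariable two-sample MR estimators and sensitivity diagnostics.

All estimators operate on a single-exposure :class:`~twostepmr.sumstats.
HarmonizedSet`.  The primary estimator is inverse-variance weighting
(IVW): a zero-intercept weighted regression of outcome betas on exposure
betas with weights 1/se_Y^2, equivalently a precision-weighted mean of
per-SNP Wald ratios.  MR-Egger frees the intercept (directional
pleiotropy test under InSIDE), the weighted median is consistent with up
to half the instrument weight invalid, and MR-PRESSO detects and removes
per-SNP pleiotropic outliers via a simulated residual-sum-of-squares
null.

Statsmodels-style surface: ``UnivariableMR(harmonized)`` is the model;
``.fit(method=...)`` returns an :class:`MRResults` carrying the
estimate, SE, CI, p, heterogeneity block and (for Egger) the intercept
block, with a ``summary()`` table.  The module-level functions (``ivw``,
``mr_egger`` ...) are thin wrappers for script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class QBlock:
    """Cochran's Q heterogeneity statistic with its df and p-value."""

    q: float
    df: int
    pvalue: float


@dataclass
class MRResults:
    """One MR estimator's fit.

    ``estimate`` is the causal effect of a 1-SD (or one exposure-unit)
    increase in the exposure, on the outcome's additive scale (``scale``
    tag: 'sd' for continuous outcomes, 'log-odds' for binary — exponentiate
    for an OR).
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    scale: str = "sd"
    exposure: str = ""
    outcome: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: QBlock | None = None
    extra: dict = field(default_factory=dict)

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    @property
    def zvalue(self) -> float:
        return self.estimate / self.se

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lo, hi); only meaningful when scale == 'log-odds'."""
        return (float(np.exp(self.estimate)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "exposure": self.exposure, "outcome": self.outcome,
            "estimate": self.estimate, "se": self.se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pvalue": self.pvalue, "n_snp": self.n_snp,
            "scale": self.scale,
        }
        if self.intercept is not None:
            d.update(intercept=self.intercept, intercept_se=self.intercept_se,
                     intercept_p=self.intercept_p)
        if self.q is not None:
            d.update(q=self.q.q, q_df=self.q.df, q_p=self.q.pvalue)
        return d

    def summary(self) -> str:
        lines = [
            f"{'MR results':^60}",
            "=" * 60,
            f"exposure: {self.exposure or '-'}    outcome: {self.outcome or '-'}",
            f"method: {self.method}    instruments: {self.n_snp}    scale: {self.scale}",
            "-" * 60,
            f"estimate {self.estimate:>12.4f}   se {self.se:.4f}   "
            f"95% CI ({self.ci_low:.4f}, {self.ci_high:.4f})   p {self.pvalue:.3g}",
        ]
        if self.scale == "log-odds":
            orr, lo, hi = self.odds_ratio()
            lines.append(f"OR       {orr:>12.4f}   95% CI ({lo:.4f}, {hi:.4f})")
        if self.intercept is not None:
            lines.append(
                f"intercept {self.intercept:>11.4f}   se {self.intercept_se:.4f}   "
                f"p {self.intercept_p:.3g}")
        if self.q is not None:
            lines.append(f"Cochran Q {self.q.q:>11.3f}   df {self.q.df}   p {self.q.pvalue:.3g}")
        lines.append("=" * 60)
        return "\n".join(lines)


def _base(h: HarmonizedSet, method: str, est: float, se: float, p: float,
          **kw) -> MRResults:
    return MRResults(
        method=method, estimate=float(est), se=float(se),
        ci_low=float(est - Z95 * se), ci_high=float(est + Z95 * se),
        pvalue=float(p), n_snp=h.n_snp, scale=h.outcome_scale,
        exposure=h.exposure_ids[0], outcome=h.outcome_id, **kw)


# ---------------------------------------------------------------------------
# per-SNP quantities


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_Y/beta_X with delta-method SEs.

    First-order SE is se_Y/|beta_X|; with ``second_order`` the exposure
    sampling error is propagated too:
    sqrt(se_Y^2/beta_X^2 + beta_Y^2 se_X^2 / beta_X^4).
    SNPs with beta_X == 0 are flagged (``valid`` False) and must be
    excluded from ratio-based methods.
    """
    h = h.single()
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    by, sy = h.beta_out, h.se_out
    valid = bx != 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, by / bx, np.nan)
        if second_order:
            rse = np.where(valid,
                           np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4), np.nan)
        else:
            rse = np.where(valid, sy / np.abs(bx), np.nan)
        weight = np.where(valid, 1.0 / rse**2, 0.0)
    return pd.DataFrame({
        "snp_id": h.snp_ids, "ratio": ratio, "ratio_se": rse,
        "weight": weight, "f_stat": (bx / sx) ** 2, "valid": valid,
    })


def instrument_strength(h: HarmonizedSet) -> dict:
    """Per-SNP F statistics (beta_X/se_X)^2 with min/mean/max and weak count.

    F > 10 is the conventional bar for acceptable instrument strength.
    """
    h = h.single()
    f = (h.beta_exp[:, 0] / h.se_exp[:, 0]) ** 2
    return {
        "per_snp": pd.DataFrame({"snp_id": h.snp_ids, "f_stat": f}),
        "min": float(f.min()), "mean": float(f.mean()), "max": float(f.max()),
        "n_below_10": int((f < 10).sum()),
    }


# ---------------------------------------------------------------------------
# estimators


def _ivw_sums(h: HarmonizedSet):
    bx = h.beta_exp[:, 0]
    w = 1.0 / h.se_out**2
    s_xy = float(np.sum(w * bx * h.beta_out))
    s_xx = float(np.sum(w * bx**2))
    return bx, w, s_xy, s_xx


def ivw(h: HarmonizedSet, model: str = "multiplicative-random") -> MRResults:
    """Inverse-variance-weighted estimate.

    estimate = sum(w beta_X beta_Y) / sum(w beta_X^2), w = 1/se_Y^2;
    fixed-effect SE = sum(w beta_X^2)^(-1/2); under the multiplicative
    random-effects model (default) the SE is inflated by
    max(1, sqrt(Q/(J-1))).  p is two-sided normal.  A Cochran Q block is
    attached whenever J >= 2.
    """
    h = h.single()
    if h.n_snp < 1:
        raise EmptyInstrumentError("IVW needs at least one instrument")
    if model not in ("fixed", "multiplicative-random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if model == "multiplicative-random" and h.n_snp < 2:
        raise InsufficientInstrumentsError("random-effects IVW needs >= 2 instruments")
    bx, w, s_xy, s_xx = _ivw_sums(h)
    est = s_xy / s_xx
    se_fe = s_xx ** -0.5
    qblock = None
    se = se_fe
    if h.n_snp >= 2:
        q = float(np.sum(w * (h.beta_out - est * bx) ** 2))
        qdf = h.n_snp - 1
        qblock = QBlock(q=q, df=qdf, pvalue=float(stats.chi2.sf(q, qdf)))
        if model == "multiplicative-random":
            se = se_fe * max(1.0, np.sqrt(q / qdf))
    p = 2.0 * stats.norm.sf(abs(est / se))
    label = "ivw-fe" if model == "fixed" else "ivw-mre"
    return _base(h, label, est, se, p, q=qblock)


def mr_egger(h: HarmonizedSet) -> MRResults:
    """MR-Egger regression: weighted regression of beta_Y on beta_X with intercept.

    Each SNP is first oriented so beta_X >= 0 (the estimator is otherwise
    not orientation-invariant).  Weights are 1/se_Y^2.  The slope is the
    causal estimate; a nonzero intercept indicates directional pleiotropy.
    SEs are inflated by max(1, residual dispersion) and both tests use a
    t reference with J-2 df, which behaves better than the normal at the
    small instrument counts Egger regression is typically run at.
    """
    h = h.single()
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {h.n_snp}")
    sign = np.where(h.beta_exp[:, 0] < 0, -1.0, 1.0)
    bx = h.beta_exp[:, 0] * sign
    by = h.beta_out * sign
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones_like(bx), bx])
    coef, cov_u, rss_w, dof = _wls(X, by, w)
    disp = max(1.0, rss_w / dof)
    se = np.sqrt(np.diag(cov_u) * disp)
    tstats = coef / se
    p_slope = 2.0 * stats.t.sf(abs(tstats[1]), dof)
    p_int = 2.0 * stats.t.sf(abs(tstats[0]), dof)
    qblock = QBlock(q=float(rss_w), df=dof, pvalue=float(stats.chi2.sf(rss_w, dof)))
    res = _base(h, "egger", coef[1], se[1], p_slope,
                intercept=float(coef[0]), intercept_se=float(se[0]),
                intercept_p=float(p_int), q=qblock)
    # t-based CI for consistency with the t test
    tcrit = stats.t.ppf(0.975, dof)
    res.ci_low = float(coef[1] - tcrit * se[1])
    res.ci_high = float(coef[1] + tcrit * se[1])
    return res


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares by normal equations.

    Returns (coef, unscaled covariance (X'WX)^-1, weighted RSS, residual df).
    """
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    coef = np.linalg.solve(xtwx, Xw.T @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    dof = X.shape[0] - X.shape[1]
    return coef, np.linalg.inv(xtwx), rss_w, dof


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized CDF.

    With ratios sorted ascending and normalized weights w', the cumulative
    position of the k-th ratio is p_k = (S_k - w'_k/2) / S_J; the estimate
    interpolates linearly between the ratios bracketing p = 0.5.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    csum = np.cumsum(w)
    p = (csum - w / 2.0) / csum[-1]
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5))  # first p_k >= 0.5
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MRResults:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Consistent when instruments carrying at least half the total weight
    are valid.  The SE resamples beta_X and beta_Y from their normal
    sampling distributions ``n_boot`` times and takes the SD of the
    recomputed medians; identical seeds give bit-identical SEs.
    """
    h = h.single()
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {h.n_snp}")
    wr = wald_ratios(h)
    if not wr["valid"].all():
        keep = wr["valid"].to_numpy()
        h = h.subset(keep)
        wr = wr[wr["valid"]]
    est = weighted_median_point(wr["ratio"].to_numpy(), wr["weight"].to_numpy())
    rng = np.random.default_rng(seed)
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = rng.normal(bx, sx)
        byi = rng.normal(h.beta_out, h.se_out)
        ok = bxi != 0.0
        ratio = byi[ok] / bxi[ok]
        wgt = (np.abs(bxi[ok]) / h.se_out[ok]) ** 2
        boots[i] = weighted_median_point(ratio, wgt)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else 1e-300
    return _base(h, "weighted-median", est, se, p,
                 extra={"n_boot": n_boot, "seed": seed})


def cochran_q(h: HarmonizedSet, fit: MRResults | float) -> QBlock:
    """Cochran's Q heterogeneity of per-SNP Wald ratios around an estimate.

    Q = sum w_j (ratio_j - estimate)^2 with w_j = 1/ratio_se_j^2
    (first-order SEs), chi-square with J-1 df (J-2 for an Egger-style fit,
    where Q is taken about the pleiotropy-adjusted regression line).
    """
    h = h.single()
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("heterogeneity undefined for J < 2")
    if isinstance(fit, MRResults):
        if fit.method == "egger":
            return fit.q
        est = fit.estimate
    else:
        est = float(fit)
    wr = wald_ratios(h)
    wr = wr[wr["valid"]]
    q = float(np.sum(wr["weight"] * (wr["ratio"] - est) ** 2))
    df = len(wr) - 1
    return QBlock(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def leave_one_out(h: HarmonizedSet, model: str = "multiplicative-random") -> list[MRResults]:
    """J IVW fits, each omitting one instrument, labeled by the omitted rsID."""
    h = h.single()
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 instruments")
    fits = []
    for j in range(h.n_snp):
        keep = np.ones(h.n_snp, dtype=bool)
        keep[j] = False
        sub = h.subset(keep)
        fit = (ivw(sub, model=model) if sub.n_snp >= 2
               else ivw(sub, model="fixed"))
        fit.extra["omitted"] = h.snp_ids[j]
        fits.append(fit)
    return fits


@dataclass
class PressoResults:
    """MR-PRESSO output: global test, outliers, corrected fit, distortion."""

    global_rss: float
    global_p: float
    outliers: list[str]
    outlier_p: pd.DataFrame
    raw_fit: MRResults
    corrected_fit: MRResults | None
    distortion_p: float | None
    n_sim: int
    seed: int | None


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> PressoResults:
    """Pleiotropy residual-sum-of-squares outlier test (MR-PRESSO).

    The observed weighted RSS about leave-one-out IVW predictions is
    compared to a parametric null in which beta_X and beta_Y are redrawn
    from their sampling distributions around the no-pleiotropy fit
    (global test).  Per-SNP observed squared residuals are compared to
    their simulated distributions, Bonferroni-corrected at
    ``outlier_alpha``/J; the corrected fit re-runs IVW without flagged
    outliers, and a distortion p compares the corrected-vs-raw estimate
    shift to the shift from removing random same-size subsets.
    The observed leave-one-out slopes are reused across simulations
    rather than re-estimated per draw.
    """
    h = h.single()
    if h.n_snp < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {h.n_snp}")
    rng = np.random.default_rng(seed)
    J = h.n_snp
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    by, sy = h.beta_out, h.se_out
    w = 1.0 / sy**2

    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    est_loo = (s_xy - w * bx * by) / (s_xx - w * bx**2)

    obs_res2 = w * (by - est_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(est_loo * bx, sy, size=(n_sim, J))
    sim_res2 = w * (by_sim - est_loo * bx_sim) ** 2
    rss_sim = sim_res2.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_per = (1 + np.sum(sim_res2 >= obs_res2, axis=0)) / (n_sim + 1)
    flagged = p_per < outlier_alpha / J
    outliers = [s for s, f in zip(h.snp_ids, flagged) if f]
    outlier_tbl = pd.DataFrame({"snp_id": h.snp_ids, "rss_p": p_per, "outlier": flagged})

    raw_fit = ivw(h)
    corrected = None
    distortion_p = None
    if outliers and len(outliers) < J - 1:
        corrected = ivw(h.subset(~flagged))
        corrected.method = "presso-corrected"
        obs_shift = abs(corrected.estimate - raw_fit.estimate)
        k = len(outliers)
        shifts = np.empty(n_sim)
        idx = np.arange(J)
        for i in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            keep = np.setdiff1d(idx, drop)
            shifts[i] = abs(np.sum(w[keep] * bx[keep] * by[keep])
                            / np.sum(w[keep] * bx[keep] ** 2) - raw_fit.estimate)
        distortion_p = float((1 + np.sum(shifts >= obs_shift)) / (n_sim + 1))
    return PressoResults(
        global_rss=rss_obs, global_p=global_p, outliers=outliers,
        outlier_p=outlier_tbl, raw_fit=raw_fit, corrected_fit=corrected,
        distortion_p=distortion_p, n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# model class


class UnivariableMR:
    """Univariable two-sample MR model for one exposure-outcome pair.

    Parameters
    ----------
    harmonized : HarmonizedSet
        A single-exposure harmonized instrument set.

    ``fit(method=...)`` dispatches to the estimator functions above and
    returns :class:`MRResults`.  Diagnostics (``wald_ratios``,
    ``instrument_strength``, ``leave_one_out``, ``mr_presso``,
    ``funnel_data``) hang off the model.
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.harmonized = harmonized.single()

    @classmethod
    def from_tables(cls, exposure, outcome, p_threshold: float = 5e-8,
                    ld=None, clump_r2: float = 0.001, clump_kb: float = 10_000.0,
                    outcome_p_exclude: float | None = 5e-8,
                    palindrome_window=(0.42, 0.58)) -> "UnivariableMR":
        """Select instruments from ``exposure``, harmonize against ``outcome``."""
        from .sumstats import exclude_outcome_significant, harmonize, select_instruments

        snps = select_instruments(exposure, p_threshold=p_threshold, ld=ld,
                                  clump_r2=clump_r2, clump_kb=clump_kb)
        h = harmonize(exposure, outcome, snps, palindrome_window=palindrome_window)
        if outcome_p_exclude is not None:
            h = exclude_outcome_significant(h, outcome_p_exclude)
        return cls(h)

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        method = method.replace("_", "-")
        if method in ("ivw", "ivw-mre"):
            return ivw(self.harmonized, model=kwargs.pop("model", "multiplicative-random"))
        if method == "ivw-fe":
            return ivw(self.harmonized, model="fixed")
        if method == "egger":
            return mr_egger(self.harmonized)
        if method == "weighted-median":
            return weighted_median(self.harmonized, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int | None = None, n_boot: int = 1000) -> list[MRResults]:
        """IVW (random effects) plus the Egger and weighted-median sensitivity fits."""
        fits = [self.fit("ivw")]
        if self.harmonized.n_snp >= 3:
            fits.append(self.fit("egger"))
            fits.append(self.fit("weighted-median", seed=seed, n_boot=n_boot))
        return fits

    def wald_ratios(self, second_order: bool = False) -> pd.DataFrame:
        return wald_ratios(self.harmonized, second_order=second_order)

    def instrument_strength(self) -> dict:
        return instrument_strength(self.harmonized)

    def leave_one_out(self, model: str = "multiplicative-random") -> list[MRResults]:
        return leave_one_out(self.harmonized, model=model)

    def mr_presso(self, n_sim: int = 1000, seed: int | None = None,
                  outlier_alpha: float = 0.05) -> PressoResults:
        return mr_presso(self.harmonized, n_sim=n_sim, seed=seed,
                         outlier_alpha=outlier_alpha)

    def funnel_data(self) -> pd.DataFrame:
        """Per-SNP (ratio, precision) pairs underlying a funnel plot."""
        wr = self.wald_ratios()
        wr = wr[wr["valid"]]
        return pd.DataFrame({"snp_id": wr["snp_id"], "ratio": wr["ratio"],
                             "precision": 1.0 / wr["ratio_se"]})
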