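"""Multivariable two-sample MR (MVMR).

Regresses outcome betas jointly on the J x K matrix of exposure betas
(weights 1/se_Y^2, no intercept), so each coefficient is the effect of
that exposure conditional on the others.  In two-step mediation this
supplies the b path (mediator -> outcome adjusted for exposure) and the
direct effect c' (exposure -> outcome adjusted for mediators).  The
Egger variant frees the intercept as a directional-pleiotropy check.

Conditional instrument strength uses the Q-statistic formulation: for
exposure k, the weighted residual sum of squares of its instrument betas
regressed on all other exposures' betas, divided by J-K.  Cross-trait
sampling covariance is taken as zero (non-overlapping two-sample
design), an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CollinearityError, UnderdeterminedError
from .sumstats import HarmonizedSet
from .uvmr import Z95, QBlock, _wls

_RCOND = 1e-10


@dataclass
class MVMRResults:
    """Per-exposure conditional estimates from one MVMR regression."""

    method: str
    exposure_ids: list[str]
    outcome: str
    estimates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n_snp: int
    scales: list[str]
    outcome_scale: str
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: QBlock | None = None
    conditional_f: dict | None = None
    extra: dict = field(default_factory=dict)

    def __getitem__(self, exposure: str):
        """Estimate/SE/CI/p for one exposure as a dict.

        ``scale`` is the outcome scale: each coefficient is an effect on
        the outcome per unit of that exposure.
        """
        k = self.exposure_ids.index(exposure)
        return {
            "estimate": float(self.estimates[k]), "se": float(self.se[k]),
            "ci_low": float(self.ci_low[k]), "ci_high": float(self.ci_high[k]),
            "pvalue": float(self.pvalues[k]), "scale": self.outcome_scale,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposure_ids, "outcome": self.outcome,
            "method": self.method, "estimate": self.estimates, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalues, "n_snp": self.n_snp,
        })

    def summary(self) -> str:
        lines = [f"{'MVMR results':^72}", "=" * 72,
                 f"outcome: {self.outcome}   method: {self.method}   "
                 f"instruments: {self.n_snp}   outcome scale: {self.outcome_scale}",
                 "-" * 72,
                 f"{'exposure':<22}{'estimate':>10}{'se':>9}{'95% CI':>22}{'p':>9}"]
        for k, ex in enumerate(self.exposure_ids):
            ci = f"({self.ci_low[k]:.4f}, {self.ci_high[k]:.4f})"
            lines.append(f"{ex:<22}{self.estimates[k]:>10.4f}{self.se[k]:>9.4f}"
                         f"{ci:>22}{self.pvalues[k]:>9.3g}")
        if self.intercept is not None:
            lines.append("-" * 72)
            lines.append(f"intercept {self.intercept:.4f}  se {self.intercept_se:.4f}  "
                         f"p {self.intercept_p:.3g}")
        if self.q is not None:
            lines.append(f"Q {self.q.q:.3f}  df {self.q.df}  p {self.q.pvalue:.3g}")
        if self.conditional_f is not None:
            fs = "  ".join(f"{k}: {v:.1f}" for k, v in self.conditional_f.items())
            lines.append(f"conditional F: {fs}")
        lines.append("=" * 72)
        return "\n".join(lines)


def _check_rank(X: np.ndarray, w: np.ndarray):
    Xw = X * np.sqrt(w)[:, None]
    sv = np.linalg.svd(Xw, compute_uv=False)
    if sv[-1] <= _RCOND * sv[0]:
        raise CollinearityError(
            "exposure beta matrix is rank deficient (collinear exposures)")


def mvmr_ivw(h: HarmonizedSet) -> MVMRResults:
    """Multivariable IVW: zero-intercept WLS of beta_Y on the exposure betas.

    Requires J > K.  SE dispersion is floored at 1 (multiplicative
    random-effects behaviour); p-values are two-sided normal.  With K=1
    and dispersion <= 1 this reduces exactly to fixed-effect IVW.
    """
    J, K = h.n_snp, h.n_exposures
    if J <= K:
        raise UnderdeterminedError(f"MVMR-IVW needs J > K exposures; J={J}, K={K}")
    X = h.beta_exp
    w = 1.0 / h.se_out**2
    _check_rank(X, w)
    coef, cov_u, rss_w, dof = _wls(X, h.beta_out, w)
    disp = max(1.0, rss_w / dof)
    se = np.sqrt(np.diag(cov_u) * disp)
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    qblock = QBlock(q=rss_w, df=dof, pvalue=float(stats.chi2.sf(rss_w, dof)))
    return MVMRResults(
        method="mvmr-ivw", exposure_ids=list(h.exposure_ids), outcome=h.outcome_id,
        estimates=coef, se=se, ci_low=coef - Z95 * se, ci_high=coef + Z95 * se,
        pvalues=p, n_snp=J, scales=list(h.exposure_scales),
        outcome_scale=h.outcome_scale, q=qblock)


def mvmr_egger(h: HarmonizedSet) -> MVMRResults:
    """MVMR-Egger: the same regression with a free intercept.

    Rows are first oriented so the first-listed exposure's betas are
    non-negative.  The intercept test (t, J-K-1 df) assesses directional
    pleiotropy; requires J > K+1.
    """
    J, K = h.n_snp, h.n_exposures
    if J <= K + 1:
        raise UnderdeterminedError(f"MVMR-Egger needs J > K+1; J={J}, K={K}")
    sign = np.where(h.beta_exp[:, 0] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(J), h.beta_exp * sign[:, None]])
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2
    _check_rank(X, w)
    coef, cov_u, rss_w, dof = _wls(X, y, w)
    disp = max(1.0, rss_w / dof)
    se = np.sqrt(np.diag(cov_u) * disp)
    tcrit = stats.t.ppf(0.975, dof)
    p = 2.0 * stats.t.sf(np.abs(coef / se), dof)
    qblock = QBlock(q=rss_w, df=dof, pvalue=float(stats.chi2.sf(rss_w, dof)))
    return MVMRResults(
        method="mvmr-egger", exposure_ids=list(h.exposure_ids), outcome=h.outcome_id,
        estimates=coef[1:], se=se[1:], ci_low=coef[1:] - tcrit * se[1:],
        ci_high=coef[1:] + tcrit * se[1:], pvalues=p[1:], n_snp=J,
        scales=list(h.exposure_scales), outcome_scale=h.outcome_scale,
        intercept=float(coef[0]), intercept_se=float(se[0]),
        intercept_p=float(p[0]), q=qblock)


def conditional_f(h: HarmonizedSet) -> dict[str, float]:
    """Conditional F statistic per exposure.

    For exposure k, regress its instrument betas on all other exposures'
    betas (weights 1/se_xk^2, no intercept); the conditional F is the
    weighted residual Q statistic divided by J-K.  Instruments explaining
    an exposure only through co-exposures give F near zero.  With a single
    exposure this falls back to the marginal mean F with a log note.
    """
    import logging

    J, K = h.n_snp, h.n_exposures
    if K < 2:
        logging.getLogger(__name__).info(
            "conditional F with K=1 falls back to the marginal mean F")
        f = (h.beta_exp[:, 0] / h.se_exp[:, 0]) ** 2
        return {h.exposure_ids[0]: float(f.mean())}
    if J <= K:
        raise UnderdeterminedError(f"conditional F needs J > K; J={J}, K={K}")
    out = {}
    for k in range(K):
        xk = h.beta_exp[:, k]
        others = np.delete(h.beta_exp, k, axis=1)
        w = 1.0 / h.se_exp[:, k] ** 2
        Xw = others * w[:, None]
        xtwx = others.T @ Xw
        try:
            coef = np.linalg.solve(xtwx, Xw.T @ xk)
            resid = xk - others @ coef
        except np.linalg.LinAlgError:
            resid = xk
        q_x = float(np.sum(w * resid**2))
        out[h.exposure_ids[k]] = q_x / (J - K)
    return out


class MultivariableMR:
    """MVMR model over a jointly-harmonized multi-exposure instrument set.

    ``fit(method='ivw'|'egger')`` returns :class:`MVMRResults`;
    ``conditional_f()`` reports conditional instrument strength.
    """

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures < 1:
            raise ValueError("MVMR needs at least one exposure")
        self.harmonized = harmonized

    def fit(self, method: str = "ivw", with_conditional_f: bool = True) -> MVMRResults:
        method = method.replace("_", "-")
        if method in ("ivw", "mvmr-ivw"):
            res = mvmr_ivw(self.harmonized)
        elif method in ("egger", "mvmr-egger"):
            res = mvmr_egger(self.harmonized)
        else:
            raise ValueError(f"unknown MVMR method {method!r}")
        if with_conditional_f:
            try:
                res.conditional_f = conditional_f(self.harmonized)
            except UnderdeterminedError:
                res.conditional_f = None
        return res

    def conditional_f(self) -> dict[str, float]:
        return conditional_f(self.harmonized)
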