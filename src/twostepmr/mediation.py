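"""Two-step MR mediation: decomposition of a total causal effect.

Notation (additive scales throughout; log-odds for binary outcomes):

* ``c``  — total effect of exposure on outcome (univariable IVW);
* ``a``  — total effect of exposure on a mediator (univariable IVW);
* ``b``  — effect of the mediator on the outcome adjusted for the
  exposure (MVMR);
* ``c'`` — direct effect of the exposure on the outcome adjusted for the
  mediator(s) (MVMR).

The indirect effect through one mediator is the product a*b (Sobel SE
sqrt(a^2 se_b^2 + b^2 se_a^2), or a seeded Monte-Carlo percentile
interval over products of independent normal draws); through a combined
mediator set it is the difference c - c'.  Proportion mediated is
indirect/total with a delta-method CI; it may legitimately fall outside
[0, 1] when paths have opposing signs, and is reported unclipped with a
sign-consistency flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyInstrumentError,
    ScaleMismatchError,
    UndefinedProportionError,
)
from .mvmr import MultivariableMR, MVMRResults
from .sumstats import (
    HarmonizedSet,
    SummaryStats,
    exclude_outcome_significant,
    harmonize,
    select_instruments,
)
from .uvmr import Z95, MRResults, UnivariableMR, ivw

logger = logging.getLogger(__name__)


@dataclass
class Estimate:
    """A point estimate with its standard error and scale tag."""

    value: float
    se: float
    scale: str = "sd"

    def __post_init__(self):
        if not (self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")

    @classmethod
    def from_results(cls, res) -> "Estimate":
        return cls(value=float(res.estimate), se=float(res.se), scale=res.scale)

    @classmethod
    def from_ci(cls, value: float, ci_low: float, ci_high: float,
                scale: str = "sd") -> "Estimate":
        """Recover the SE from a symmetric 95% interval."""
        return cls(value=value, se=(ci_high - ci_low) / (2 * Z95), scale=scale)


@dataclass
class MediationDecomposition:
    """One indirect-effect decomposition (product or difference method)."""

    mediators: list[str]
    method: str  # 'product' | 'difference'
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    mc_ci: tuple[float, float] | None = None
    sobel_z: float | None = None
    sobel_p: float | None = None
    direct: float | None = None
    total: float | None = None
    proportion: float | None = None
    proportion_ci: tuple[float, float] | None = None
    sign_consistent: bool | None = None
    scale: str = "sd"


def product_indirect(a: Estimate, b: Estimate, ci_method: str = "sobel",
                     n_draws: int = 100_000, seed: int | None = None,
                     mediator: str = "mediator") -> MediationDecomposition:
    """Product-method indirect effect a*b.

    Sobel SE = sqrt(a^2 se_b^2 + b^2 se_a^2); z = (a*b)/SE with a
    two-sided normal p.  ``ci_method='monte-carlo'`` additionally draws
    a* ~ N(a, se_a), b* ~ N(b, se_b) independently and reports the
    2.5/97.5 percentile interval of a*b* (seeded), which respects the
    product's skewness at moderate relative SEs.
    """
    indirect = a.value * b.value
    se = float(np.sqrt(a.value**2 * b.se**2 + b.value**2 * a.se**2))
    if se > 0:
        z = indirect / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = 0.0, 1.0
    ci = (indirect - Z95 * se, indirect + Z95 * se)
    mc_ci = None
    if ci_method == "monte-carlo":
        rng = np.random.default_rng(seed)
        prod = rng.normal(a.value, a.se, n_draws) * rng.normal(b.value, b.se, n_draws)
        mc_ci = tuple(np.percentile(prod, [2.5, 97.5]))
    elif ci_method != "sobel":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MediationDecomposition(
        mediators=[mediator], method="product", indirect=float(indirect),
        indirect_se=se, indirect_ci=ci, mc_ci=mc_ci, sobel_z=float(z),
        sobel_p=p, scale=b.scale)


def difference_indirect(c: Estimate, c_prime: Estimate,
                        mediators: Sequence[str] = ("combined",)) -> MediationDecomposition:
    """Difference-method indirect effect c - c'.

    The SE sqrt(se_c^2 + se_c'^2) ignores the (positive) correlation
    between the total and direct estimates, which share instruments; it
    is therefore conservative and flagged as an approximation.
    """
    if c.scale != c_prime.scale:
        raise ScaleMismatchError(
            f"total on {c.scale!r} but direct on {c_prime.scale!r}")
    indirect = c.value - c_prime.value
    se = float(np.sqrt(c.se**2 + c_prime.se**2))
    return MediationDecomposition(
        mediators=list(mediators), method="difference", indirect=float(indirect),
        indirect_se=se, indirect_ci=(indirect - Z95 * se, indirect + Z95 * se),
        direct=c_prime.value, total=c.value, scale=c.scale)


def proportion_mediated(indirect: Estimate, total: Estimate):
    """Proportion mediated indirect/total with a delta-method 95% CI.

    Treats the two estimates as independent normals (an approximation —
    they share instruments).  The proportion is reported unclipped; a
    ``sign_consistent`` flag marks whether indirect and total agree in
    sign (proportions outside [0,1] arise when they do not, or when the
    direct effect opposes the indirect one).
    """
    if total.value == 0:
        raise UndefinedProportionError("total effect is zero")
    prop = indirect.value / total.value
    var = (indirect.se**2 / total.value**2
           + indirect.value**2 * total.se**2 / total.value**4)
    se = float(np.sqrt(var))
    return {
        "proportion": float(prop), "se": se,
        "ci": (prop - Z95 * se, prop + Z95 * se),
        "sign_consistent": bool(indirect.value * total.value >= 0),
    }


# ---------------------------------------------------------------------------
# screening


@dataclass
class ScreenVerdict:
    mediator: str
    retained: bool
    reason: str | None  # 'criterion-1' | 'insufficient-instruments' | 'criterion-2'
    detail: dict = field(default_factory=dict)


def screen_mediators(
    exposure: SummaryStats,
    mediators: Mapping[str, SummaryStats],
    outcome: SummaryStats,
    alpha: float = 0.05,
    min_instruments: int = 2,
    p_threshold: float = 5e-8,
    mediator_p_threshold: float = 5e-8,
    association: str = "uvmr",
    ld=None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
    mediator_clump_r2: float = 0.01,
    mediator_clump_kb: float = 1_000.0,
) -> dict[str, ScreenVerdict]:
    """Screen candidate mediators for inclusion in the decomposition.

    A candidate is retained iff (1) the exposure causally associates with
    it (univariable IVW p < ``alpha``), (2) it associates with the
    outcome (``association``: 'uvmr' unadjusted, 'mvmr' exposure-adjusted,
    or 'either'), and it carries at least ``min_instruments`` of its own
    instruments jointly available in all tables — a single-instrument
    mediator is excluded because its MVMR contribution would rest on one
    variant.  Every exclusion carries a machine-readable reason.
    """
    if association not in ("uvmr", "mvmr", "either"):
        raise ValueError(f"unknown association mode {association!r}")
    verdicts: dict[str, ScreenVerdict] = {}
    for name, med in mediators.items():
        detail: dict = {}
        # criterion 1: exposure -> mediator
        try:
            model = UnivariableMR.from_tables(
                exposure, med, p_threshold=p_threshold, ld=ld,
                clump_r2=clump_r2, clump_kb=clump_kb, outcome_p_exclude=None)
            # single-instrument pairs fall back to the fixed-effect (Wald) fit
            a_fit = model.fit("ivw" if model.harmonized.n_snp >= 2 else "ivw-fe")
            detail["a_p"] = a_fit.pvalue
        except EmptyInstrumentError:
            verdicts[name] = ScreenVerdict(name, False, "criterion-1",
                                           {"error": "no exposure instruments"})
            continue
        if a_fit.pvalue >= alpha:
            verdicts[name] = ScreenVerdict(name, False, "criterion-1", detail)
            continue
        # joint instrument availability for the mediator's own instruments
        try:
            med_snps = select_instruments(
                med, p_threshold=mediator_p_threshold, ld=ld,
                clump_r2=mediator_clump_r2, clump_kb=mediator_clump_kb)
        except EmptyInstrumentError:
            med_snps = []
        exp_ids = set(exposure.df["snp_id"])
        out_ids = set(outcome.df["snp_id"])
        joint = [s for s in med_snps if s in exp_ids and s in out_ids]
        detail["n_joint_instruments"] = len(joint)
        if len(joint) < min_instruments:
            verdicts[name] = ScreenVerdict(name, False, "insufficient-instruments", detail)
            continue
        # criterion 2: mediator -> outcome
        ok_uv = ok_mv = None
        if association in ("uvmr", "either"):
            try:
                fit = UnivariableMR.from_tables(
                    med, outcome, p_threshold=mediator_p_threshold, ld=ld,
                    clump_r2=mediator_clump_r2, clump_kb=mediator_clump_kb,
                    outcome_p_exclude=None).fit("ivw")
                detail["b_uvmr_p"] = fit.pvalue
                ok_uv = fit.pvalue < alpha
            except EmptyInstrumentError:
                ok_uv = False
        if association in ("mvmr", "either"):
            try:
                h = _joint_harmonize(exposure, [med], outcome,
                                     exposure_snps=None, mediator_snps={med.trait_id: joint},
                                     p_threshold=p_threshold, ld=ld,
                                     clump_r2=clump_r2, clump_kb=clump_kb)
                fit = MultivariableMR(h).fit("ivw", with_conditional_f=False)
                p_b = fit[med.trait_id]["pvalue"]
                detail["b_mvmr_p"] = p_b
                ok_mv = p_b < alpha
            except Exception as exc:  # noqa: BLE001 - screening records, not raises
                detail["mvmr_error"] = str(exc)
                ok_mv = False
        checks = [x for x in (ok_uv, ok_mv) if x is not None]
        passed = any(checks) if association == "either" else all(checks)
        if not passed:
            verdicts[name] = ScreenVerdict(name, False, "criterion-2", detail)
            continue
        verdicts[name] = ScreenVerdict(name, True, None, detail)
    return verdicts


def _joint_harmonize(exposure, mediators, outcome, exposure_snps, mediator_snps,
                     p_threshold, ld, clump_r2, clump_kb,
                     outcome_p_exclude=None, palindrome_window=(0.42, 0.58)):
    """Union of per-trait selected instruments, intersected with availability.

    Each trait contributes its own selected instruments; the union is then
    harmonized jointly, which drops any SNP absent from a table (proxies
    are never searched).
    """
    if exposure_snps is None:
        exposure_snps = select_instruments(exposure, p_threshold=p_threshold,
                                           ld=ld, clump_r2=clump_r2, clump_kb=clump_kb)
    candidates = list(exposure_snps)
    seen = set(candidates)
    for med in mediators:
        for s in mediator_snps.get(med.trait_id, []):
            if s not in seen:
                candidates.append(s)
                seen.add(s)
    h = harmonize([exposure] + list(mediators), outcome, candidates,
                  palindrome_window=palindrome_window)
    if outcome_p_exclude is not None:
        h = exclude_outcome_significant(h, outcome_p_exclude)
    return h


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class MediationResults:
    """Full two-step decomposition for one exposure-outcome pair."""

    exposure: str
    outcome: str
    mediator_names: list[str]
    total: MRResults
    a_fits: dict[str, MRResults]
    pair_mvmr: dict[str, MVMRResults]
    combined_mvmr: MVMRResults | None
    per_mediator: dict[str, MediationDecomposition]
    combined: MediationDecomposition | None
    screening: dict[str, ScreenVerdict] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def c(self) -> float:
        return self.total.estimate

    def path(self, mediator: str) -> dict:
        """The (a, b, c, c') path estimates for one mediator."""
        mv = self.pair_mvmr[mediator]
        return {
            "a": Estimate.from_results(self.a_fits[mediator]),
            "b": Estimate(value=mv[mediator]["estimate"], se=mv[mediator]["se"],
                          scale=mv[mediator]["scale"]),
            "c": Estimate.from_results(self.total),
            "c_prime": Estimate(value=mv[self.exposure]["estimate"],
                                se=mv[self.exposure]["se"],
                                scale=mv[self.exposure]["scale"]),
        }

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per mediation pathway."""
        rows = []
        for name, frag in self.per_mediator.items():
            rows.append({
                "pathway": f"via {name}", "method": frag.method,
                "indirect": frag.indirect, "indirect_se": frag.indirect_se,
                "ci_low": frag.indirect_ci[0], "ci_high": frag.indirect_ci[1],
                "proportion": frag.proportion,
                "proportion_ci_low": None if frag.proportion_ci is None else frag.proportion_ci[0],
                "proportion_ci_high": None if frag.proportion_ci is None else frag.proportion_ci[1],
                "sign_consistent": frag.sign_consistent,
            })
        if self.combined is not None:
            frag = self.combined
            rows.append({
                "pathway": "via " + " + ".join(frag.mediators), "method": frag.method,
                "indirect": frag.indirect, "indirect_se": frag.indirect_se,
                "ci_low": frag.indirect_ci[0], "ci_high": frag.indirect_ci[1],
                "proportion": frag.proportion,
                "proportion_ci_low": None if frag.proportion_ci is None else frag.proportion_ci[0],
                "proportion_ci_high": None if frag.proportion_ci is None else frag.proportion_ci[1],
                "sign_consistent": frag.sign_consistent,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"{'Two-step MR mediation':^72}", "=" * 72,
                 f"exposure: {self.exposure}    outcome: {self.outcome}",
                 f"total effect c = {self.total.estimate:.4f} "
                 f"(se {self.total.se:.4f}, p {self.total.pvalue:.3g}, "
                 f"{self.total.n_snp} SNPs, scale {self.total.scale})",
                 "-" * 72]
        for name, frag in self.per_mediator.items():
            path = self.path(name)
            lines.append(
                f"via {name}: a={path['a'].value:.4f}  b={path['b'].value:.4f}  "
                f"indirect={frag.indirect:.4f} "
                f"({frag.indirect_ci[0]:.4f}, {frag.indirect_ci[1]:.4f})  "
                f"proportion={frag.proportion:.3f}")
        if self.combined is not None:
            frag = self.combined
            lines.append(
                f"via {' + '.join(frag.mediators)} (difference): "
                f"indirect={frag.indirect:.4f}  direct c'={frag.direct:.4f}  "
                f"proportion={frag.proportion:.3f}")
        lines.append("=" * 72)
        return "\n".join(lines)


class TwoStepMediation:
    """Two-step MR mediation model over summary-statistics tables.

    Parameters mirror the instrument-selection rules: genome-wide
    significance for the exposure with strict clumping, a configurable
    looser clumping for mediators, and exclusion of instruments directly
    associated with the outcome.

    ``fit()`` runs: instrument selection -> joint harmonization ->
    univariable IVW for the total effect c and each a path -> per-pair
    and combined MVMR for b and c' -> product-method decomposition per
    mediator and difference-method decomposition for the combined set.
    """

    def __init__(
        self,
        exposure: SummaryStats,
        mediators: Mapping[str, SummaryStats],
        outcome: SummaryStats,
        p_threshold: float = 5e-8,
        mediator_p_threshold: float = 5e-8,
        ld=None,
        clump_r2: float = 0.001,
        clump_kb: float = 10_000.0,
        mediator_clump_r2: float = 0.01,
        mediator_clump_kb: float = 1_000.0,
        outcome_p_exclude: float | None = 5e-8,
        palindrome_window: tuple[float, float] = (0.42, 0.58),
        screen: bool = False,
        screen_alpha: float = 0.05,
        min_instruments: int = 2,
    ):
        self.exposure = exposure
        # the mapping key is the authoritative mediator label throughout
        self.mediators = {
            name: (med if med.trait_id == name else replace(med, trait_id=name))
            for name, med in mediators.items()
        }
        self.outcome = outcome
        labels = [exposure.trait_id, outcome.trait_id, *self.mediators]
        if len(set(labels)) != len(labels):
            raise ValueError(f"trait labels must be unique, got {labels}")
        self.p_threshold = p_threshold
        self.mediator_p_threshold = mediator_p_threshold
        self.ld = ld
        self.clump_r2 = clump_r2
        self.clump_kb = clump_kb
        self.mediator_clump_r2 = mediator_clump_r2
        self.mediator_clump_kb = mediator_clump_kb
        self.outcome_p_exclude = outcome_p_exclude
        self.palindrome_window = palindrome_window
        self.screen = screen
        self.screen_alpha = screen_alpha
        self.min_instruments = min_instruments

    def fit(self, ci_method: str = "monte-carlo", n_draws: int = 100_000,
            seed: int | None = None) -> MediationResults:
        mediators = self.mediators
        screening = None
        if self.screen:
            screening = screen_mediators(
                self.exposure, mediators, self.outcome, alpha=self.screen_alpha,
                min_instruments=self.min_instruments,
                p_threshold=self.p_threshold,
                mediator_p_threshold=self.mediator_p_threshold, ld=self.ld,
                clump_r2=self.clump_r2, clump_kb=self.clump_kb,
                mediator_clump_r2=self.mediator_clump_r2,
                mediator_clump_kb=self.mediator_clump_kb)
            mediators = {k: v for k, v in mediators.items() if screening[k].retained}
            dropped = [k for k, v in screening.items() if not v.retained]
            if dropped:
                logger.info("screening excluded mediators: %s",
                            {k: screening[k].reason for k in dropped})

        exp_snps = select_instruments(
            self.exposure, p_threshold=self.p_threshold, ld=self.ld,
            clump_r2=self.clump_r2, clump_kb=self.clump_kb)
        med_snps = {}
        for name, med in mediators.items():
            med_snps[med.trait_id] = select_instruments(
                med, p_threshold=self.mediator_p_threshold, ld=self.ld,
                clump_r2=self.mediator_clump_r2, clump_kb=self.mediator_clump_kb)

        # total effect c: exposure instruments against the outcome
        h_c = harmonize(self.exposure, self.outcome, exp_snps,
                        palindrome_window=self.palindrome_window)
        if self.outcome_p_exclude is not None:
            h_c = exclude_outcome_significant(h_c, self.outcome_p_exclude)
        total = ivw(h_c)
        c_est = Estimate.from_results(total)

        a_fits: dict[str, MRResults] = {}
        pair_mvmr: dict[str, MVMRResults] = {}
        per_mediator: dict[str, MediationDecomposition] = {}
        med_list = list(mediators.items())
        ss = np.random.SeedSequence(seed) if seed is not None else None
        child_seeds = (iter(ss.generate_state(max(len(med_list), 1)).tolist())
                       if ss is not None else None)

        for name, med in med_list:
            # a: exposure -> mediator, exposure's own instruments
            h_a = harmonize(self.exposure, med, exp_snps,
                            palindrome_window=self.palindrome_window)
            a_fits[name] = ivw(h_a)
            # b, c': joint MVMR of exposure + this mediator on the outcome
            h_pair = _joint_harmonize(
                self.exposure, [med], self.outcome, exp_snps, med_snps,
                p_threshold=self.p_threshold, ld=self.ld,
                clump_r2=self.clump_r2, clump_kb=self.clump_kb,
                outcome_p_exclude=self.outcome_p_exclude,
                palindrome_window=self.palindrome_window)
            mv = MultivariableMR(h_pair).fit("ivw")
            pair_mvmr[name] = mv
            a = Estimate.from_results(a_fits[name])
            b = Estimate(value=mv[med.trait_id]["estimate"],
                         se=mv[med.trait_id]["se"], scale=mv[med.trait_id]["scale"])
            frag = product_indirect(
                a, b, ci_method=ci_method, n_draws=n_draws,
                seed=(next(child_seeds) % (2**31) if child_seeds is not None else None),
                mediator=name)
            frag.total = total.estimate
            frag.direct = mv[self.exposure.trait_id]["estimate"]
            prop = proportion_mediated(
                Estimate(frag.indirect, frag.indirect_se, scale=frag.scale), c_est)
            frag.proportion = prop["proportion"]
            frag.proportion_ci = prop["ci"]
            frag.sign_consistent = prop["sign_consistent"]
            per_mediator[name] = frag

        combined_mvmr = None
        combined = None
        if len(med_list) >= 1:
            h_all = _joint_harmonize(
                self.exposure, [m for _, m in med_list], self.outcome,
                exp_snps, med_snps, p_threshold=self.p_threshold, ld=self.ld,
                clump_r2=self.clump_r2, clump_kb=self.clump_kb,
                outcome_p_exclude=self.outcome_p_exclude,
                palindrome_window=self.palindrome_window)
            combined_mvmr = MultivariableMR(h_all).fit("ivw")
            cp = combined_mvmr[self.exposure.trait_id]
            combined = difference_indirect(
                c_est, Estimate(value=cp["estimate"], se=cp["se"], scale=cp["scale"]),
                mediators=[n for n, _ in med_list])
            prop = proportion_mediated(
                Estimate(combined.indirect, combined.indirect_se, scale=combined.scale),
                c_est)
            combined.proportion = prop["proportion"]
            combined.proportion_ci = prop["ci"]
            combined.sign_consistent = prop["sign_consistent"]

        return MediationResults(
            exposure=self.exposure.trait_id, outcome=self.outcome.trait_id,
            mediator_names=[n for n, _ in med_list], total=total, a_fits=a_fits,
            pair_mvmr=pair_mvmr, combined_mvmr=combined_mvmr,
            per_mediator=per_mediator, combined=combined, screening=screening,
            extra={} if combined_mvmr is None else {"combined_harmonized": h_all})


def decompose(exposure: SummaryStats, mediators: Mapping[str, SummaryStats],
              outcome: SummaryStats, **kwargs) -> MediationResults:
    """Run the full two-step decomposition (see :class:`TwoStepMediation`).

    Keyword arguments are split between the model constructor and
    ``fit`` (``ci_method``, ``n_draws``, ``seed``).
    """
    fit_kw = {k: kwargs.pop(k) for k in ("ci_method", "n_draws", "seed")
              if k in kwargs}
    return TwoStepMediation(exposure, mediators, outcome, **kwargs).fit(**fit_kw)
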