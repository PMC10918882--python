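"""Synthetic GWAS summary statistics under a known mediation DAG.

The generator emulates a two-sample design with three non-overlapping
GWAS — exposure X, mediator M, outcome Y — whose traits follow

    X = sum_j gamma_j G_j + e_X
    M = a X + sum_j alpha_j G_j + e_M
    Y = c' X + b M + sum_j delta_j G_j + e_Y

so the true per-SNP marginal effects are gamma_j on X,
a*gamma_j + alpha_j on M, and (c' + a*b)*gamma_j + b*alpha_j + delta_j
on Y.  ``alpha`` gives the mediator SNP effects not transmitted through
the exposure (these double as the mediator's own instruments), and
``delta`` is horizontal pleiotropy on the outcome (mean 0 = balanced,
nonzero mean = directional, violating the exclusion restriction).

Summary statistics are generated directly on the marginal-effect scale
(no individual-level genotypes) with independent SNPs: emitted
beta = truth + N(0, SE), SE = 1/sqrt(2 maf (1-maf) N) for a unit-SD
continuous trait, scaled by 1/sqrt(prevalence (1-prevalence)) on the
log-odds scale for a binary outcome (a linearized approximation).
Identical seeds give bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .sumstats import HarmonizedSet, SummaryStats, normal_p, write_sumstats

#: non-palindromic allele pair used for every simulated variant
_EA, _OA = "A", "G"

PRESETS = ("null", "strong-mediation", "directional-pleiotropy",
           "weak-instruments", "binary-outcome")


@dataclass
class SimulationConfig:
    """Generating parameters for one simulated three-GWAS dataset.

    Defaults are the package's reference study conditions: J=150
    instruments, GWAS of N=500,000 each, a = -0.3, b = 0.35, c' = -0.5,
    mediator-specific SNP effects of SD 0.03 (without them the mediator
    has no instruments of its own and MVMR is unidentified) and no
    outcome pleiotropy.
    """

    J: int = 150
    maf_range: tuple[float, float] = (0.1, 0.4)
    gamma_range: tuple[float, float] = (0.02, 0.10)
    a: float = -0.3
    b: float = 0.35
    c_prime: float = -0.5
    pleio_mediator: tuple[float, float] = (0.0, 0.03)  # (mean, sd)
    pleio_outcome: tuple[float, float] = (0.0, 0.0)
    n_exposure: float = 5e5
    n_mediator: float = 5e5
    n_outcome: float = 5e5
    outcome_type: str = "continuous"
    prevalence: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.J < 1:
            raise ConfigError("J must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        glo, ghi = self.gamma_range
        if not (0.0 < glo <= ghi):
            raise ConfigError("gamma_range must be positive")
        for fname in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, fname) <= 0:
                raise ConfigError(f"{fname} must be > 0")
        for fname in ("pleio_mediator", "pleio_outcome"):
            if getattr(self, fname)[1] < 0:
                raise ConfigError(f"{fname} sd must be >= 0")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigError("outcome_type must be 'continuous' or 'binary'")
        if self.outcome_type == "binary" and not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must be in (0,1)")


@dataclass
class SimulationTruth:
    """The generating DAG realisation paired with one emitted dataset."""

    gamma: np.ndarray          # SNP -> exposure
    alpha: np.ndarray          # SNP -> mediator, not via exposure
    delta: np.ndarray          # SNP -> outcome, not via exposure/mediator
    true_exposure: np.ndarray  # marginal effects actually generated from
    true_mediator: np.ndarray
    true_outcome: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def total_effect(self) -> float:
        """True total exposure->outcome effect c = c' + a*b."""
        cfg = self.config
        return cfg.c_prime + cfg.a * cfg.b

    @property
    def proportion_mediated(self) -> float:
        return self.config.a * self.config.b / self.total_effect

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        return json.dumps(d, indent=1)


def _table(trait_id, trait_type, chrom, pos, maf, truth, se, rng, n) -> SummaryStats:
    beta = truth + rng.normal(0.0, se)
    df = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(len(truth))],
        "chrom": chrom, "pos": pos,
        "effect_allele": _EA, "other_allele": _OA,
        "eaf": maf, "beta": beta, "se": se,
        "pvalue": normal_p(beta, se), "n": float(n),
    })
    return SummaryStats(trait_id=trait_id, trait_type=trait_type, df=df, n_total=float(n))


def simulate_mediation_gwas(config: SimulationConfig) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimulationTruth]:
    """Generate (exposure, mediator, outcome) tables plus the ground truth.

    Sampling noise is independent across the three tables (two-sample
    design, no overlap).  SNPs are placed on alternating chromosomes at
    20-Mb spacing so default clumping windows never couple them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.J
    maf = rng.uniform(*config.maf_range, J)
    gamma = rng.uniform(*config.gamma_range, J) * rng.choice([-1.0, 1.0], J)
    alpha = config.pleio_mediator[0] + config.pleio_mediator[1] * rng.standard_normal(J)
    # directional (nonzero-mean) pleiotropy acts on the exposure-increasing
    # allele, as pleiotropy-biased MR scenarios are conventionally posed;
    # the stored per-SNP delta already carries that orientation
    delta = np.sign(gamma) * (
        config.pleio_outcome[0] + config.pleio_outcome[1] * rng.standard_normal(J))

    true_x = gamma
    true_m = config.a * gamma + alpha
    true_y = (config.c_prime + config.a * config.b) * gamma + config.b * alpha + delta

    var_g = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_g * config.n_exposure)
    se_m = 1.0 / np.sqrt(var_g * config.n_mediator)
    se_y = 1.0 / np.sqrt(var_g * config.n_outcome)
    if config.outcome_type == "binary":
        se_y = se_y / np.sqrt(config.prevalence * (1.0 - config.prevalence))

    chrom = (np.arange(J) % 22) + 1
    pos = 1_000_000 + (np.arange(J) // 22) * 20_000_000

    exposure = _table("exposure", "continuous", chrom, pos, maf, true_x, se_x,
                      rng, config.n_exposure)
    mediator = _table("mediator", "continuous", chrom, pos, maf, true_m, se_m,
                      rng, config.n_mediator)
    outcome = _table("outcome", config.outcome_type, chrom, pos, maf, true_y, se_y,
                     rng, config.n_outcome)
    truth = SimulationTruth(gamma=gamma, alpha=alpha, delta=delta,
                            true_exposure=true_x, true_mediator=true_m,
                            true_outcome=true_y, config=config)
    return exposure, mediator, outcome, truth


def harmonized_from_truth(config: SimulationConfig) -> tuple[HarmonizedSet, SimulationTruth]:
    """One-exposure HarmonizedSet straight from the generator.

    Convenience for estimator calibration studies: skips table I/O and
    instrument selection, taking every simulated SNP as an instrument
    with the exposure table's orientation.
    """
    exposure, _, outcome, truth = simulate_mediation_gwas(config)
    return HarmonizedSet(
        snp_ids=exposure.df["snp_id"].tolist(),
        exposure_ids=[exposure.trait_id],
        outcome_id=outcome.trait_id,
        beta_exp=exposure.df["beta"].to_numpy()[:, None],
        se_exp=exposure.df["se"].to_numpy()[:, None],
        beta_out=outcome.df["beta"].to_numpy(),
        se_out=outcome.df["se"].to_numpy(),
        p_out=outcome.df["pvalue"].to_numpy(),
        exposure_scales=[exposure.scale],
        outcome_scale=outcome.scale,
    ), truth


def preset_config(preset: str) -> SimulationConfig:
    """The documented named scenarios, each with a fixed seed."""
    if preset == "null":
        return SimulationConfig(a=0.0, b=0.0, c_prime=0.0,
                                pleio_mediator=(0.0, 0.0), seed=101)
    if preset == "strong-mediation":
        return SimulationConfig(seed=102)
    if preset == "directional-pleiotropy":
        return SimulationConfig(pleio_outcome=(0.01, 0.005), seed=103)
    if preset == "weak-instruments":
        # gamma chosen so the mean F statistic sits near 5
        return SimulationConfig(gamma_range=(0.003, 0.007), seed=104)
    if preset == "binary-outcome":
        return SimulationConfig(outcome_type="binary", prevalence=0.1, seed=105)
    raise ConfigError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_fixture(preset: str, outdir) -> dict[str, Path]:
    """Write a preset's three TSV tables plus a truth JSON; deterministic."""
    config = preset_config(preset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, truth = simulate_mediation_gwas(config)
    paths = {}
    for name, table in (("exposure", exposure), ("mediator", mediator),
                        ("outcome", outcome)):
        paths[name] = outdir / f"{name}.tsv"
        write_sumstats(table, paths[name])
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths
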