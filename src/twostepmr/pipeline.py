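"""Configuration-driven orchestration and report rendering.

``run_pipeline`` executes the full workflow — mediator screening,
univariable MR with sensitivity diagnostics, multivariable MR, and the
two-step mediation decomposition — from a YAML/JSON configuration, and
writes a report bundle of TSV tables (display-rounded) plus a JSON file
carrying full-precision results and a run manifest recording every
parameter and seed.  Reverse-direction MR is expressed by a config that
swaps the exposure/outcome roles; there is no dedicated code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .mediation import TwoStepMediation
from .mvmr import MultivariableMR
from .sumstats import LDInfo, read_sumstats
from .uvmr import UnivariableMR, cochran_q

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for report tables)."""
    if x is None or not np.isfinite(x):
        return x
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def format_effect(estimate: float, ci_low: float, ci_high: float,
                  scale: str, ndigits: int = 2) -> str:
    """Display string: exp-transformed OR for log-odds, beta as-is otherwise.

    e.g. a log-odds -0.6162 with CI (-0.7985, -0.4308) renders as
    "0.54 (0.45, 0.65)".
    """
    if scale == "log-odds":
        estimate, ci_low, ci_high = np.exp([estimate, ci_low, ci_high])
    r = [round_half_away(v, ndigits) for v in (estimate, ci_low, ci_high)]
    fmt = f"{{:.{ndigits}f}}"
    return f"{fmt.format(r[0])} ({fmt.format(r[1])}, {fmt.format(r[2])})"


@dataclass
class TraitSpec:
    path: str
    trait_id: str | None = None
    trait_type: str = "continuous"
    column_map: dict | None = None

    def load(self):
        p = Path(self.path)
        if not p.exists():
            raise ConfigError(f"trait file does not exist: {self.path}")
        return read_sumstats(p, column_map=self.column_map,
                             trait_id=self.trait_id, trait_type=self.trait_type)


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (one schema for YAML and JSON)."""

    exposure: TraitSpec
    outcome: TraitSpec
    mediators: dict[str, TraitSpec] = field(default_factory=dict)
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    mediator_p_threshold: float = 5e-8
    mediator_clump_r2: float = 0.01
    mediator_clump_kb: float = 1_000.0
    outcome_p_exclude: float | None = 5e-8
    ld_path: str | None = None
    ivw_model: str = "multiplicative-random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    mc_draws: int = 100_000
    screen: bool = False
    screen_alpha: float = 0.05
    min_instruments: int = 2
    seed: int | None = None
    out_dir: str = "report"

    def __post_init__(self):
        if self.seed is None and (self.n_boot or self.presso_n_sim or self.mc_draws):
            raise ConfigError("seed is mandatory: the pipeline runs stochastic steps "
                              "(bootstrap, MR-PRESSO, Monte-Carlo CIs)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)

        def spec(entry, default_id=None):
            if isinstance(entry, str):
                entry = {"path": entry}
            entry = dict(entry)
            entry.setdefault("trait_id", entry.pop("id", default_id))
            return TraitSpec(**entry)

        try:
            exposure = spec(d.pop("exposure"), "exposure")
            outcome = spec(d.pop("outcome"), "outcome")
        except KeyError as exc:
            raise ConfigError(f"config missing required section {exc}") from exc
        meds = {}
        for m in d.pop("mediators", []):
            s = spec(m)
            name = s.trait_id or Path(s.path).stem
            s.trait_id = name
            meds[name] = s
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(exposure=exposure, outcome=outcome, mediators=meds, **d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset: one loader
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)


def _fits_frame(fits, extra_cols=None) -> pd.DataFrame:
    rows = []
    for f in fits:
        d = f.to_dict()
        d.update(f.extra if extra_cols is None else
                 {k: f.extra.get(k) for k in extra_cols})
        d["display"] = format_effect(f.estimate, f.ci_low, f.ci_high, f.scale)
        rows.append(d)
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full two-step analysis and write the report bundle.

    Returns a dict of in-memory DataFrames/objects; side effect is the
    bundle under ``config.out_dir``: uvmr.tsv, mvmr.tsv, mediation.tsv,
    heterogeneity.tsv, pleiotropy.tsv, instrument_strength.tsv,
    leave_one_out.tsv, funnel.tsv, presso.tsv, screening.tsv,
    results.json (full precision) and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ld = LDInfo.read(config.ld_path) if config.ld_path else None
    exposure = config.exposure.load()
    outcome = config.outcome.load()
    mediators = {name: s.load() for name, s in config.mediators.items()}

    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(s) % 2**31 for s in ss.generate_state(64))

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    model = TwoStepMediation(
        exposure, mediators, outcome,
        p_threshold=config.p_threshold, mediator_p_threshold=config.mediator_p_threshold,
        ld=ld, clump_r2=config.clump_r2, clump_kb=config.clump_kb,
        mediator_clump_r2=config.mediator_clump_r2,
        mediator_clump_kb=config.mediator_clump_kb,
        outcome_p_exclude=config.outcome_p_exclude, screen=config.screen,
        screen_alpha=config.screen_alpha, min_instruments=config.min_instruments)
    med_seed = next(seeds)
    results = stage("mediation", lambda: model.fit(
        ci_method="monte-carlo", n_draws=config.mc_draws, seed=med_seed))

    # univariable sensitivity suite on the exposure->outcome pair
    uv = stage("uvmr", lambda: UnivariableMR.from_tables(
        exposure, outcome, p_threshold=config.p_threshold, ld=ld,
        clump_r2=config.clump_r2, clump_kb=config.clump_kb,
        outcome_p_exclude=config.outcome_p_exclude))
    wm_seed = next(seeds)
    uv_fits = stage("uvmr", lambda: uv.fit_all(seed=wm_seed, n_boot=config.n_boot))
    uvmr_rows = [_fits_frame(uv_fits)]
    for name, fit in results.a_fits.items():
        uvmr_rows.append(_fits_frame([fit]))
    uvmr_tbl = pd.concat(uvmr_rows, ignore_index=True)

    het_rows, pleio_rows = [], []
    for f in uv_fits:
        if f.q is not None:
            het_rows.append({"exposure": f.exposure, "outcome": f.outcome,
                             "method": f.method, "q": f.q.q, "q_df": f.q.df,
                             "q_p": f.q.pvalue})
        if f.intercept is not None:
            pleio_rows.append({"exposure": f.exposure, "outcome": f.outcome,
                               "egger_intercept": f.intercept,
                               "intercept_se": f.intercept_se,
                               "intercept_p": f.intercept_p})

    strength = stage("diagnostics", uv.instrument_strength)
    loo = stage("diagnostics", uv.leave_one_out)
    funnel = stage("diagnostics", uv.funnel_data)
    presso = None
    if uv.harmonized.n_snp >= 4:
        presso_seed = next(seeds)
        presso = stage("presso", lambda: uv.mr_presso(
            n_sim=config.presso_n_sim, seed=presso_seed))

    mvmr_tbls = [mv.to_frame() for mv in results.pair_mvmr.values()]
    egger_mv = None
    if results.combined_mvmr is not None:
        mvmr_tbls.append(results.combined_mvmr.to_frame())
        h_all = results.extra.get("combined_harmonized")
        if h_all is not None and h_all.n_snp > h_all.n_exposures + 1:
            egger_mv = stage("mvmr-egger", lambda: MultivariableMR(h_all).fit("egger"))
    mvmr_tbl = (pd.concat(mvmr_tbls, ignore_index=True)
                if mvmr_tbls else pd.DataFrame())

    mediation_tbl = results.to_frame()
    if not mediation_tbl.empty:
        mediation_tbl["display"] = [
            format_effect(r.indirect, r.ci_low, r.ci_high, "sd")
            for r in mediation_tbl.itertuples()]

    # ---- write bundle
    def write(df, name):
        df.to_csv(out / name, sep="\t", index=False)

    write(uvmr_tbl, "uvmr.tsv")
    write(mvmr_tbl, "mvmr.tsv")
    write(mediation_tbl, "mediation.tsv")
    write(pd.DataFrame(het_rows), "heterogeneity.tsv")
    write(pd.DataFrame(pleio_rows), "pleiotropy.tsv")
    write(strength["per_snp"], "instrument_strength.tsv")
    write(_fits_frame(loo, extra_cols=["omitted"]), "leave_one_out.tsv")
    write(funnel, "funnel.tsv")
    if presso is not None:
        write(presso.outlier_p, "presso.tsv")
    if results.screening is not None:
        write(pd.DataFrame([{"mediator": v.mediator, "retained": v.retained,
                             "reason": v.reason} for v in results.screening.values()]),
              "screening.tsv")

    payload = {
        "total": results.total.to_dict(),
        "a_paths": {k: v.to_dict() for k, v in results.a_fits.items()},
        "uvmr": uvmr_tbl.drop(columns=["display"]).to_dict(orient="records"),
        "mvmr": mvmr_tbl.to_dict(orient="records"),
        "mediation": mediation_tbl.drop(columns=["display"], errors="ignore")
                                   .to_dict(orient="records"),
        "instrument_strength": {k: strength[k] for k in ("min", "mean", "max", "n_below_10")},
        "presso": None if presso is None else {
            "global_p": presso.global_p, "outliers": presso.outliers,
            "distortion_p": presso.distortion_p},
        "mvmr_egger_intercept": None if egger_mv is None else {
            "intercept": egger_mv.intercept, "se": egger_mv.intercept_se,
            "p": egger_mv.intercept_p},
    }
    (out / "results.json").write_text(json.dumps(payload, indent=1, default=_jsonify))

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "seeds": {"root": config.seed, "mediation_mc": med_seed,
                  "weighted_median_boot": wm_seed,
                  "presso": None if presso is None else presso.seed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_jsonify))
    logger.info("report bundle written to %s", out)
    return {
        "results": results, "uvmr": uvmr_tbl, "mvmr": mvmr_tbl,
        "mediation": mediation_tbl, "presso": presso, "strength": strength,
        "out_dir": out,
    }


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


def _config_dict(config: AnalysisConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)
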