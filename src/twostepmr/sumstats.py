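"""GWAS summary-statistics I/O, instrument selection and harmonization.

The on-disk dialect is a tab-separated table with header columns
``SNP CHR POS EA OA EAF BETA SE P N`` (aliases configurable through a
``column_map``).  ``SNP`` is an rsID, ``EA``/``OA`` the effect and other
allele, ``BETA`` the per-effect-allele association (SD units for
continuous traits, log-odds for binary traits), ``SE`` its standard
error, ``P`` the two-sided p-value and ``N`` the per-variant sample
size.  ``CHR``/``POS``/``EAF``/``N`` are optional; a missing ``P`` is
recomputed from beta/SE with a two-sided normal test, because tables
exported from different repositories vary in which columns they carry.

Variant matching across traits is by rsID only; positions are
informational.  Proxy SNPs are never searched: an instrument absent from
a table is dropped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyHarmonizationError,
    EmptyInstrumentError,
    EmptyTableError,
    SumStatsFormatError,
)

logger = logging.getLogger(__name__)

#: canonical file header -> internal column name
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
}
MANDATORY = ("SNP", "EA", "OA", "BETA", "SE")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str | None:
    """Reverse-strand complement of a simple allele, None if ambiguous."""
    if len(allele) == 1 and allele in _COMPLEMENT:
        return _COMPLEMENT[allele]
    return None  # indels / multi-base alleles have no strand ambiguity here


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants, whose strand is not inferable from alleles."""
    return _complement(ea) == oa


def normal_p(beta, se):
    """Two-sided normal p-value from an estimate and its SE, floored away from 0."""
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    p = 2.0 * stats.norm.sf(z)
    return np.maximum(p, 1e-300)


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``df`` holds one row per variant with internal column names
    (see :data:`CANONICAL_COLUMNS`); ``rejected`` records rows that
    failed validation together with a per-row reason.
    """

    trait_id: str
    trait_type: str  # 'continuous' | 'binary'
    df: pd.DataFrame
    n_total: float | None = None
    rejected: pd.DataFrame | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise SumStatsFormatError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        df = self.df.reset_index(drop=True).copy()
        # normalise dtypes so tables are comparable regardless of origin
        if "chrom" in df:
            df["chrom"] = df["chrom"].astype("string")
        for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
            if col in df:
                df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        self.df = df
        if self.df["snp_id"].duplicated().any():
            dups = self.df["snp_id"][self.df["snp_id"].duplicated()].tolist()
            raise SumStatsFormatError(f"duplicate snp_id values: {dups[:5]}")

    @property
    def scale(self) -> str:
        return "log-odds" if self.trait_type == "binary" else "sd"

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def lookup(self, snp_id: str):
        """Return the record for ``snp_id`` as a Series, or None."""
        hit = self.df[self.df["snp_id"] == snp_id]
        if hit.empty:
            return None
        return hit.iloc[0]

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("snp_id", drop=False)


@dataclass
class LDInfo:
    """Pairwise linkage-disequilibrium r-squared between variants.

    Stored sparsely as a dict over unordered snp_id pairs; absent pairs
    are taken as r2 = 0.  ``window_kb`` records the physical window the
    map covers.
    """

    r2: dict[frozenset, float] = field(default_factory=dict)
    window_kb: float = 10_000.0

    def get(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self.r2.get(frozenset((snp_a, snp_b)), 0.0)

    def set(self, snp_a: str, snp_b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {value}")
        if snp_a != snp_b:
            self.r2[frozenset((snp_a, snp_b))] = float(value)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame, window_kb: float = 10_000.0) -> "LDInfo":
        """Build from a three-column table (snp_a, snp_b, r2)."""
        info = cls(window_kb=window_kb)
        cols = list(df.columns[:3])
        for a, b, r in df[cols].itertuples(index=False):
            info.set(str(a), str(b), float(r))
        return info

    @classmethod
    def from_matrix(cls, df: pd.DataFrame, window_kb: float = 10_000.0) -> "LDInfo":
        """Build from a square matrix with snp_ids as header row and column."""
        info = cls(window_kb=window_kb)
        ids = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("LD matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if mat[i, j] != 0.0:
                    info.set(a, ids[j], mat[i, j])
        return info

    @classmethod
    def read(cls, path, window_kb: float = 10_000.0) -> "LDInfo":
        """Read either dialect (pair list or square matrix) from TSV."""
        df = pd.read_csv(path, sep="\t")
        first = df.columns[0].lower()
        if first in ("snp_a", "snp1", "snp_1") or df.shape[1] == 3:
            return cls.from_pairs(df, window_kb=window_kb)
        return cls.from_matrix(pd.read_csv(path, sep="\t", index_col=0), window_kb=window_kb)


# ---------------------------------------------------------------------------
# I/O


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None):
    """Map file header names onto canonical names; returns {file_col: internal}."""
    alias = {k.upper(): v.upper() for k, v in (column_map or {}).items()}
    resolved = {}
    for col in header:
        canon = alias.get(col.upper(), col.upper())
        if canon in CANONICAL_COLUMNS:
            resolved[col] = CANONICAL_COLUMNS[canon]
    for mand in MANDATORY:
        if CANONICAL_COLUMNS[mand] not in resolved.values():
            raise SumStatsFormatError(f"mandatory column {mand!r} missing from header {list(header)}")
    return resolved


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    n_total: float | None = None,
) -> SummaryStats:
    """Read a summary-statistics TSV into a validated :class:`SummaryStats`.

    Rows violating the per-variant invariants (SE <= 0, p outside (0,1],
    identical alleles, EAF outside (0,1), duplicate rsID) are rejected and
    kept, with a reason, in ``.rejected``.  A header-only file yields a
    valid empty table; a file with rows but zero parsable ones raises
    :class:`EmptyTableError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(raw.columns, column_map)
    df = raw[list(resolved)].rename(columns=resolved)

    for col in CANONICAL_COLUMNS.values():
        if col not in df.columns:
            df[col] = np.nan
    for col in ("eaf", "beta", "se", "pvalue", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["snp_id"] = df["snp_id"].astype(str).str.strip()

    reasons = pd.Series("", index=df.index)

    def flag(mask, reason):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = reason

    flag(df["snp_id"].isin(("", "nan")), "missing snp_id")
    flag(df["beta"].isna() | ~np.isfinite(df["beta"]), "unparsable beta")
    flag(df["se"].isna() | (df["se"] <= 0), "se not > 0")
    flag(df["effect_allele"] == df["other_allele"], "effect_allele == other_allele")
    flag(df["pvalue"].notna() & ((df["pvalue"] <= 0) | (df["pvalue"] > 1)), "pvalue outside (0,1]")
    flag(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "eaf outside (0,1)")
    flag(df["snp_id"].duplicated(), "duplicate snp_id")

    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""])
    if len(rejected):
        logger.info("%s: rejected %d rows (%s)", path, len(rejected),
                    rejected["reason"].value_counts().to_dict())
    good = df[reasons == ""].copy()
    if len(raw) > 0 and good.empty:
        raise EmptyTableError(f"{path}: zero parsable rows out of {len(raw)}")

    missing_p = good["pvalue"].isna()
    if missing_p.any():
        good.loc[missing_p, "pvalue"] = normal_p(good.loc[missing_p, "beta"],
                                                 good.loc[missing_p, "se"])

    if trait_id is None:
        trait_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if n_total is None and good["n"].notna().any():
        n_total = float(good["n"].max())
    return SummaryStats(trait_id=trait_id, trait_type=trait_type,
                        df=good[list(CANONICAL_COLUMNS.values())],
                        n_total=n_total, rejected=rejected)


def write_sumstats(table: SummaryStats, path) -> None:
    """Write the canonical TSV dialect; re-reading yields an equal table."""
    inv = {v: k for k, v in CANONICAL_COLUMNS.items()}
    out = table.df.rename(columns=inv)[list(CANONICAL_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(
    table: SummaryStats,
    p_threshold: float = 5e-8,
    ld: LDInfo | None = None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
) -> list[str]:
    """Select independent genome-wide-significant instruments.

    Keeps variants with p < ``p_threshold``, then greedily clumps: scanning
    in order of ascending p (ties broken by snp_id, so the result does not
    depend on input row order), a variant is kept unless it is correlated
    (r2 >= ``clump_r2``) with an already-kept variant lying within
    ``clump_kb`` kilobases on the same chromosome.  Variants without
    positions are window-checked permissively (treated as within-window).
    Without an LD map all significant variants are retained and an
    independence-assumed warning is logged — reference-panel LD is not
    bundled.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0,1)")
    if not (0.0 < clump_r2 <= 1.0):
        raise ValueError("clump_r2 must be in (0,1]")
    sig = table.df[table.df["pvalue"] < p_threshold]
    if sig.empty:
        raise EmptyInstrumentError(
            f"{table.trait_id}: no SNP passes p < {p_threshold:g}")
    sig = sig.sort_values(["pvalue", "snp_id"], kind="mergesort")
    if ld is None:
        logger.warning(
            "%s: no LD information supplied; assuming the %d significant "
            "SNPs are independent", table.trait_id, len(sig))
        return sig["snp_id"].tolist()

    kept: list[pd.Series] = []
    for _, row in sig.iterrows():
        clumped = False
        for krow in kept:
            if not _within_window(row, krow, clump_kb):
                continue
            if ld.get(row["snp_id"], krow["snp_id"]) >= clump_r2:
                clumped = True
                break
        if not clumped:
            kept.append(row)
    return [r["snp_id"] for r in kept]


def _within_window(a: pd.Series, b: pd.Series, clump_kb: float) -> bool:
    if pd.isna(a.get("pos")) or pd.isna(b.get("pos")):
        return True  # no positions: rely on r2 alone
    ca, cb = a.get("chrom"), b.get("chrom")
    if pd.notna(ca) and pd.notna(cb) and str(ca) != str(cb):
        return False
    return abs(float(a["pos"]) - float(b["pos"])) <= clump_kb * 1000.0


# ---------------------------------------------------------------------------
# Harmonization


@dataclass
class HarmonizedSet:
    """J instruments x (K exposures + outcome) with one allele orientation.

    ``beta_exp``/``se_exp`` are (J, K) arrays in the column order of
    ``exposure_ids``; the first exposure defines the reference orientation.
    ``orientation_log`` maps every candidate instrument to the action taken
    (``kept``, ``flipped``, ``dropped-missing``, ``dropped-palindromic``,
    ``dropped-mismatch``, ``dropped-outcome-significant``).
    """

    snp_ids: list[str]
    exposure_ids: list[str]
    outcome_id: str
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    p_out: np.ndarray | None = None
    exposure_scales: list[str] = field(default_factory=list)
    outcome_scale: str = "sd"
    orientation_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        if self.beta_exp.shape[0] == 1 and len(self.snp_ids) > 1:
            self.beta_exp = self.beta_exp.T
            self.se_exp = self.se_exp.T
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        if self.p_out is not None:
            self.p_out = np.asarray(self.p_out, dtype=float)
        if not self.exposure_scales:
            self.exposure_scales = ["sd"] * self.n_exposures
        J = len(self.snp_ids)
        if self.beta_exp.shape != (J, self.n_exposures) or self.beta_out.shape != (J,):
            raise ValueError("inconsistent HarmonizedSet dimensions")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exp.shape[1]

    def outcome_pvalues(self) -> np.ndarray:
        """Carried outcome p-values, else two-sided normal from beta/SE."""
        if self.p_out is not None:
            return self.p_out
        return normal_p(self.beta_out, self.se_out)

    def subset(self, index) -> "HarmonizedSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.snp_ids[i] for i in index]
        return HarmonizedSet(
            snp_ids=ids,
            exposure_ids=list(self.exposure_ids),
            outcome_id=self.outcome_id,
            beta_exp=self.beta_exp[index],
            se_exp=self.se_exp[index],
            beta_out=self.beta_out[index],
            se_out=self.se_out[index],
            p_out=None if self.p_out is None else self.p_out[index],
            exposure_scales=list(self.exposure_scales),
            outcome_scale=self.outcome_scale,
            orientation_log={s: self.orientation_log.get(s, "kept") for s in ids},
        )

    def single(self) -> "HarmonizedSet":
        if self.n_exposures != 1:
            raise ValueError("operation requires a single-exposure HarmonizedSet")
        return self


def _orient(rec: pd.Series, ref_ea: str, ref_oa: str, ref_eaf, window) -> tuple[int, str] | None:
    """Orientation of one record against the reference alleles.

    Returns (sign, action) where sign multiplies beta (+1 keep, -1 flip),
    or None when the record must be dropped, with the reason encoded by
    the caller.  Palindromic variants are resolved by EAF agreement when
    both frequencies lie outside the ambiguity ``window``, else dropped.
    """
    ea, oa = rec["effect_allele"], rec["other_allele"]
    cea, coa = _complement(ea), _complement(oa)
    if (ea, oa) == (ref_ea, ref_oa):
        sign, eaf = 1, rec["eaf"]
    elif (ea, oa) == (ref_oa, ref_ea):
        sign, eaf = -1, 1.0 - rec["eaf"] if pd.notna(rec["eaf"]) else np.nan
    elif (cea, coa) == (ref_ea, ref_oa):
        sign, eaf = 1, rec["eaf"]
    elif (cea, coa) == (ref_oa, ref_ea):
        sign, eaf = -1, 1.0 - rec["eaf"] if pd.notna(rec["eaf"]) else np.nan
    else:
        return None
    if is_palindromic(ea, oa):
        lo, hi = window
        if pd.isna(eaf) or pd.isna(ref_eaf):
            return None
        if lo <= eaf <= hi or lo <= ref_eaf <= hi:
            return None
        if (eaf < 0.5) != (ref_eaf < 0.5):  # strand flip inferred from EAF
            sign, eaf = -sign, 1.0 - eaf
    return sign, ("kept" if sign == 1 else "flipped")


def harmonize(
    exposures: SummaryStats | Iterable[SummaryStats],
    outcome: SummaryStats,
    instruments: Sequence[str],
    palindrome_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align instrument effects across exposure and outcome tables.

    The first exposure's record defines the reference effect/other allele
    per SNP.  Records with swapped alleles have beta negated and EAF mapped
    to 1-EAF; strand-complement matches are accepted; palindromic (A/T,
    C/G) variants are resolved by EAF when both EAFs lie outside
    ``palindrome_window``, otherwise dropped.  SNPs absent from any table
    are dropped and logged; proxies are never searched.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    else:
        exposures = list(exposures)
    if not instruments:
        raise EmptyInstrumentError("instrument list is empty")
    tables = exposures + [outcome]
    indexed = [t.indexed() for t in tables]

    log: dict[str, str] = {}
    rows = []
    for snp in instruments:
        recs = []
        missing = False
        for idx in indexed:
            if snp not in idx.index:
                missing = True
                break
            recs.append(idx.loc[snp])
        if missing:
            log[snp] = "dropped-missing"
            continue
        ref = recs[0]
        ref_ea, ref_oa, ref_eaf = ref["effect_allele"], ref["other_allele"], ref["eaf"]
        if is_palindromic(ref_ea, ref_oa):
            lo, hi = palindrome_window
            if pd.isna(ref_eaf) or lo <= ref_eaf <= hi:
                log[snp] = "dropped-palindromic"
                continue
        oriented = []
        ok = True
        for rec in recs:
            res = _orient(rec, ref_ea, ref_oa, ref_eaf, palindrome_window)
            if res is None:
                log[snp] = ("dropped-palindromic"
                            if is_palindromic(rec["effect_allele"], rec["other_allele"])
                            else "dropped-mismatch")
                ok = False
                break
            oriented.append(res)
        if not ok:
            continue
        signs = [s for s, _ in oriented]
        log[snp] = "flipped" if any(s == -1 for s in signs) else "kept"
        betas = [float(rec["beta"]) * s for rec, (s, _) in zip(recs, oriented)]
        ses = [float(rec["se"]) for rec in recs]
        p_y = recs[-1]["pvalue"]
        # a flipped outcome keeps its two-sided p
        rows.append((snp, betas[:-1], ses[:-1], betas[-1], ses[-1],
                     float(p_y) if pd.notna(p_y) else np.nan))

    dropped = {s: a for s, a in log.items() if a.startswith("dropped")}
    if dropped:
        logger.info("harmonize: dropped %d/%d instruments (%s); proxy SNPs are not searched",
                    len(dropped), len(instruments),
                    pd.Series(list(dropped.values())).value_counts().to_dict())
    if not rows:
        raise EmptyHarmonizationError("all instruments dropped during harmonization")

    snp_ids = [r[0] for r in rows]
    p_out = np.array([r[5] for r in rows])
    return HarmonizedSet(
        snp_ids=snp_ids,
        exposure_ids=[t.trait_id for t in exposures],
        outcome_id=outcome.trait_id,
        beta_exp=np.array([r[1] for r in rows], dtype=float),
        se_exp=np.array([r[2] for r in rows], dtype=float),
        beta_out=np.array([r[3] for r in rows], dtype=float),
        se_out=np.array([r[4] for r in rows], dtype=float),
        p_out=None if np.isnan(p_out).all() else p_out,
        exposure_scales=[t.scale for t in exposures],
        outcome_scale=outcome.scale,
        orientation_log=log,
    )


def exclude_outcome_significant(h: HarmonizedSet, p_threshold: float = 5e-8) -> HarmonizedSet:
    """Drop instruments directly associated with the outcome (p < threshold).

    Guards the exclusion-restriction assumption: a variant this strongly
    associated with the outcome plausibly acts through a pathway other
    than the exposure.
    """
    p = h.outcome_pvalues()
    keep = p >= p_threshold
    if not keep.any():
        raise EmptyHarmonizationError(
            f"all instruments outcome-significant at p < {p_threshold:g}")
    removed = [s for s, k in zip(h.snp_ids, keep) if not k]
    if removed:
        logger.info("excluded %d outcome-significant instruments: %s",
                    len(removed), removed[:10])
    out = h.subset(keep)
    for s in removed:
        out.orientation_log[s] = "dropped-outcome-significant"
    return out
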