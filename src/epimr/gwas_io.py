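"""GWAS summary-statistic data model, I/O, and exposure-outcome harmonization.

Summary statistics are held as one row per SNP with canonical columns
``snp, chrom, pos, ea, oa, eaf, beta, se, p, n`` (plus ``n_cases`` for binary
traits).  ``ea`` is the effect allele: ``beta`` is the per-allele effect of
``ea`` on the trait (years of age acceleration for the epigenetic clocks,
log(ml/min/1.73 m^2) for log-eGFR).  Harmonization aligns an exposure table
and an outcome table onto a single effect-allele frame per SNP so that the
Wald ratio Gamma_j / gamma_j is meaningful.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("epimr")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "n_cases"]
MANDATORY_COLUMNS = ["snp", "ea", "oa", "beta", "se", "p"]

# file headers use "chr"; in memory we use "chrom" to avoid the builtin
_FILE_TO_INTERNAL = {"chr": "chrom"}


class SummaryStatsError(ValueError):
    """Malformed summary-statistic input (missing columns, duplicate ids...)."""


@dataclass
class SummaryTable:
    """A GWAS summary-statistic table for one trait.

    ``df`` holds one row per SNP using the canonical columns; ``snp`` ids are
    unique.  ``trait_type`` is ``"continuous"`` or ``"binary"``.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "continuous"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SummaryStatsError(f"unknown trait_type {self.trait_type!r}")
        df = self.df
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        self.df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        dup = self.df["snp"][self.df["snp"].duplicated()]
        if len(dup):
            raise SummaryStatsError(f"duplicate snp ids: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snps(self) -> pd.Series:
        return self.df["snp"]

    def subset(self, snp_ids, provenance_note: str | None = None) -> "SummaryTable":
        """Return a new table restricted to ``snp_ids`` (order preserved)."""
        keep = self.df["snp"].isin(set(snp_ids))
        prov = list(self.provenance)
        if provenance_note:
            prov.append(provenance_note)
        return SummaryTable(self.df[keep].copy(), self.trait_label, self.trait_type, prov)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out = out.rename(columns={"chrom": "chr"})
        if out["n_cases"].isna().all():
            out = out.drop(columns=["n_cases"])
        out.to_csv(path, sep="\t", index=False)


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_type: str = "continuous",
    trait_label: str = "",
    sep: str = "\t",
) -> SummaryTable:
    """Read a delimited summary-statistic file into a validated SummaryTable.

    Parameters
    ----------
    column_map
        Mapping from canonical names (``snp``, ``chr``, ``pos``, ``ea``,
        ``oa``, ``eaf``, ``beta``, ``se``, ``p``, ``n``, ``n_cases``) to the
        header names used in the file, for non-canonical dialects such as
        CKDGen's (``Effect_allele``, ``Freq``...).  Unmapped canonical names
        are looked up verbatim.
    trait_type
        ``"continuous"`` or ``"binary"``.

    Rows failing row-level validation (non-numeric beta/se, se <= 0,
    p outside (0, 1], eaf outside [0, 1], invalid or identical alleles) are
    dropped and reported with their 1-based data line numbers.  A missing
    mandatory column or duplicated SNP id raises :class:`SummaryStatsError`.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "n_cases"]:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = _FILE_TO_INTERNAL.get(canonical, canonical)
    df = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"missing mandatory column(s) {missing} in {path} "
            f"(headers found: {list(raw.columns)}; supply a column_map)"
        )
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()

    for col in ("pos", "eaf", "beta", "se", "p", "n", "n_cases"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ea", "oa"):
        df[col] = df[col].astype(str).str.upper()
    df["snp"] = df["snp"].astype(str)

    bad = pd.Series(False, index=df.index)
    reasons = {}

    def _flag(mask, reason):
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad[mask] = True

    _flag(df["beta"].isna() | df["se"].isna(), "non-numeric beta/se")
    _flag(df["se"] <= 0, "se <= 0")
    _flag(df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1), "pvalue outside (0, 1]")
    if "eaf" in df.columns:
        _flag(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "eaf outside [0, 1]")
    _flag(~df["ea"].isin(VALID_ALLELES) | ~df["oa"].isin(VALID_ALLELES), "invalid allele")
    _flag(df["ea"] == df["oa"], "effect allele equals other allele")

    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [f"line {i + 2}: {df.loc[i, 'snp']} ({reasons[i]})" for i in df.index[bad]]
        msg = f"{path}: dropped {bad.sum()} invalid row(s): " + "; ".join(lines[:20])
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        df = df[~bad]

    dup = df["snp"][df["snp"].duplicated()]
    if len(dup):
        raise SummaryStatsError(f"{path}: duplicate snp ids: {sorted(set(dup))}")
    return SummaryTable(df.reset_index(drop=True), trait_label or str(path), trait_type)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = [
    "snp", "chrom", "pos", "ea", "oa",
    "beta_exp", "se_exp", "p_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "p_out", "eaf_out", "n_out",
    "palindromic", "allele_flipped", "dropped", "drop_reason",
]


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


@dataclass
class HarmonizedSet:
    """Exposure-outcome SNP pairs aligned onto one effect-allele frame.

    ``beta_exp``/``se_exp`` are the SNP-exposure associations (gamma_j), and
    ``beta_out``/``se_out`` the SNP-outcome associations (Gamma_j), both per
    copy of the shared effect allele ``ea``.  Dropped SNPs stay in ``df``
    with ``dropped`` set and a ``drop_reason``; estimators see only the
    retained rows (:attr:`retained`).
    """

    df: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""
    outcome_type: str = "continuous"

    def __post_init__(self) -> None:
        self.df = self.df[HARMONIZED_COLUMNS].reset_index(drop=True)

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[~self.df["dropped"]]

    @property
    def n_retained(self) -> int:
        return int((~self.df["dropped"]).sum())

    def __len__(self) -> int:
        return len(self.df)

    def arrays(self):
        """(gamma, se_gamma, Gamma, se_Gamma) for the retained SNPs."""
        r = self.retained
        return (
            r["beta_exp"].to_numpy(float),
            r["se_exp"].to_numpy(float),
            r["beta_out"].to_numpy(float),
            r["se_out"].to_numpy(float),
        )

    def drop_snps(self, snp_ids, reason: str) -> "HarmonizedSet":
        df = self.df.copy()
        mask = df["snp"].isin(set(snp_ids)) & ~df["dropped"]
        df.loc[mask, "dropped"] = True
        df.loc[mask, "drop_reason"] = reason
        return HarmonizedSet(df, self.exposure_label, self.outcome_label, self.outcome_type)

    def subset_retained(self, keep_mask) -> "HarmonizedSet":
        """New set whose retained SNPs are the current retained rows where
        ``keep_mask`` (aligned to :attr:`retained`) is True; others dropped."""
        r = self.retained
        drop_ids = r.loc[~np.asarray(keep_mask, bool), "snp"]
        return self.drop_snps(drop_ids, "subset")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_window: float = 0.08,
    orient_increasing: bool = True,
) -> HarmonizedSet:
    """Align outcome associations onto the exposure effect-allele frame.

    SNPs are matched by id.  Outcome alleles equal to the exposure's are kept
    as-is; swapped alleles flip the outcome beta sign and complement its
    frequency; for non-palindromic SNPs a strand flip (A<->T, C<->G) is also
    attempted before declaring "allele-mismatch".  Palindromic SNPs (A/T or
    C/G) cannot be resolved from allele labels: they are aligned by effect
    allele frequency when both frequencies lie outside
    ``[0.5 - w, 0.5 + w]`` and dropped as "palindromic-ambiguous" otherwise
    (including when either frequency is missing).  When
    ``orient_increasing`` every retained SNP is finally oriented so that
    ``beta_exp >= 0`` — the "toward increasing exposure" convention — by
    flipping both betas together.

    Dropped SNPs are retained in the output with their reason; SNPs present
    in only one table are omitted entirely (they were never matched).
    """
    if not 0 <= palindrome_eaf_window < 0.5:
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    exp = exposure.df.set_index("snp")
    out = outcome.df.set_index("snp")
    common = exp.index.intersection(out.index)
    if len(common) == 0:
        raise SummaryStatsError("no SNPs shared between exposure and outcome tables")

    rows = []
    w = palindrome_eaf_window
    for snp in common:
        e = exp.loc[snp]
        o = out.loc[snp]
        pal = _is_palindromic(e["ea"], e["oa"])
        beta_out, se_out, p_out, eaf_out, n_out = (
            o["beta"], o["se"], o["p"], o["eaf"], o["n"])
        flipped = False
        dropped = False
        reason = ""

        if (o["ea"], o["oa"]) == (e["ea"], e["oa"]):
            pass
        elif (o["ea"], o["oa"]) == (e["oa"], e["ea"]):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else np.nan
            flipped = True
        elif not pal and (COMPLEMENT.get(o["ea"]), COMPLEMENT.get(o["oa"])) == (e["ea"], e["oa"]):
            pass  # strand flip, same orientation
        elif not pal and (COMPLEMENT.get(o["ea"]), COMPLEMENT.get(o["oa"])) == (e["oa"], e["ea"]):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else np.nan
            flipped = True
        else:
            dropped, reason = True, "allele-mismatch"

        if not dropped and pal:
            fe, fo = e["eaf"], eaf_out
            if pd.isna(fe) or pd.isna(fo) or abs(fe - 0.5) <= w or abs(fo - 0.5) <= w:
                dropped, reason = True, "palindromic-ambiguous"
            elif (fe - 0.5) * (fo - 0.5) < 0:
                # frequencies disagree on which allele is minor: the outcome
                # is reported on the opposite strand orientation
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                flipped = not flipped

        rows.append({
            "snp": snp, "chrom": e["chrom"], "pos": e["pos"],
            "ea": e["ea"], "oa": e["oa"],
            "beta_exp": float(e["beta"]), "se_exp": float(e["se"]),
            "p_exp": float(e["p"]), "eaf_exp": e["eaf"], "n_exp": e["n"],
            "beta_out": float(beta_out), "se_out": float(se_out),
            "p_out": float(p_out), "eaf_out": eaf_out, "n_out": n_out,
            "palindromic": pal, "allele_flipped": flipped,
            "dropped": dropped, "drop_reason": reason,
        })

    df = pd.DataFrame(rows)
    if orient_increasing:
        flip = (~df["dropped"]) & (df["beta_exp"] < 0)
        df.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
        df.loc[flip, "eaf_exp"] = 1.0 - df.loc[flip, "eaf_exp"]
        df.loc[flip, "eaf_out"] = 1.0 - df.loc[flip, "eaf_out"]
        ea = df.loc[flip, "ea"].copy()
        df.loc[flip, "ea"] = df.loc[flip, "oa"]
        df.loc[flip, "oa"] = ea
    n_drop = int(df["dropped"].sum())
    if n_drop:
        logger.info("harmonize: dropped %d of %d matched SNPs", n_drop, len(df))
    return HarmonizedSet(df, exposure.trait_label, outcome.trait_label, outcome.trait_type)


def harmonized_from_arrays(
    beta_exp, se_exp, beta_out, se_out,
    n_exp=None, n_out=None, snp=None, eaf=None,
    exposure_label: str = "exposure", outcome_label: str = "outcome",
    outcome_type: str = "continuous",
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from aligned effect arrays.

    Convenience constructor for simulations and tests where allele
    bookkeeping is already settled.
    """
    beta_exp = np.asarray(beta_exp, float)
    J = beta_exp.size
    snp = [f"rs{i + 1}" for i in range(J)] if snp is None else list(snp)
    df = pd.DataFrame({
        "snp": snp, "chrom": "1", "pos": np.arange(J) * 1_000_000 + 1,
        "ea": "A", "oa": "G",
        "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, float),
        "p_exp": np.nan, "eaf_exp": np.nan if eaf is None else np.asarray(eaf, float),
        "n_exp": np.nan if n_exp is None else n_exp,
        "beta_out": np.asarray(beta_out, float), "se_out": np.asarray(se_out, float),
        "p_out": np.nan, "eaf_out": np.nan if eaf is None else np.asarray(eaf, float),
        "n_out": np.nan if n_out is None else n_out,
        "palindromic": False, "allele_flipped": False,
        "dropped": False, "drop_reason": "",
    })
    from scipy import stats

    df["p_exp"] = 2 * stats.norm.sf(np.abs(df["beta_exp"] / df["se_exp"]))
    df["p_out"] = 2 * stats.norm.sf(np.abs(df["beta_out"] / df["se_out"]))
    return HarmonizedSet(df, exposure_label, outcome_label, outcome_type)
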