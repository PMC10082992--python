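"""Genetic-instrument construction and diagnostics.

Covers the selection funnel applied to each GWAS before estimation:
significance filtering with greedy LD clumping, exclusion-list filtering
(stand-in for phenotype-database pleiotropy screens), dual-marker refinement
of kidney-function instruments (retaining creatinine-eGFR SNPs that also
track a second kidney marker), Steiger directionality filtering, and
instrument-strength statistics (per-SNP F, I^2_GX, variance explained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import HarmonizedSet, SummaryTable

logger = logging.getLogger("epimr")


class InstrumentError(ValueError):
    pass


@dataclass
class LDInfo:
    """Sparse pairwise LD (r^2) between SNPs.

    Absent pairs are treated as r^2 = 0 (with a debug log) because sparse LD
    inputs listing only correlated pairs are the norm.
    """

    r2_map: dict = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise InstrumentError(f"r2({a},{b}) = {r2} outside [0, 1]")
        self.r2_map[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self.r2_map.get(self._key(a, b))
        if val is None:
            logger.debug("LD pair (%s, %s) missing; treating r2 as 0", a, b)
            return 0.0
        return val

    @classmethod
    def from_tsv(cls, path) -> "LDInfo":
        """Read a 3-column TSV (snp_a, snp_b, r2), header optional."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 3:
            raise InstrumentError(f"{path}: expected 3 columns (snp_a, snp_b, r2)")
        df.columns = ["snp_a", "snp_b", "r2"] + list(df.columns[3:])
        info = cls()
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], pd.to_numeric(df["r2"])):
            info.set_r2(str(a), str(b), r2)
        return info

    def to_tsv(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self.r2_map.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)


def select_and_clump(
    table: SummaryTable,
    ld: LDInfo,
    p_threshold: float = 5e-8,
    window_kb: float = 500.0,
    r2_max: float = 0.1,
) -> SummaryTable:
    """Greedy p-value clumping to approximately independent significant SNPs.

    SNPs with p < ``p_threshold`` are sorted by ascending p-value (ties
    broken by (chrom, pos, snp) for determinism); the best remaining SNP is
    kept and every other SNP on the same chromosome within ``window_kb``
    kilobases with r^2 >= ``r2_max`` to it is discarded.  Discards are
    appended to the returned table's ``provenance``.
    """
    df = table.df
    qual = df[df["p"] < p_threshold].copy()
    if qual.empty:
        logger.warning("clumping: no SNP passes p < %g", p_threshold)
        return SummaryTable(qual, table.trait_label, table.trait_type,
                            list(table.provenance) + ["clump: empty (no significant SNPs)"])
    if qual["pos"].isna().any():
        missing = qual.loc[qual["pos"].isna(), "snp"].tolist()
        raise InstrumentError(f"positions required for clumping; missing for {missing[:10]}")
    order = qual.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")
    remaining = list(order.itertuples(index=False))
    kept, log = [], []
    window_bp = window_kb * 1000.0
    while remaining:
        best = remaining.pop(0)
        kept.append(best.snp)
        survivors = []
        for cand in remaining:
            if (cand.chrom == best.chrom
                    and abs(cand.pos - best.pos) <= window_bp
                    and ld.r2(cand.snp, best.snp) >= r2_max):
                log.append(f"clump: {cand.snp} discarded (r2 >= {r2_max} with {best.snp})")
            else:
                survivors.append(cand)
        remaining = survivors
    keep_mask = df["snp"].isin(kept) & (df["p"] < p_threshold)
    return SummaryTable(df[keep_mask].copy(), table.trait_label, table.trait_type,
                        list(table.provenance) + log)


def apply_exclusion_list(
    table: SummaryTable,
    excluded_snps,
    ld: LDInfo | None = None,
    r2_proxy: float = 0.8,
) -> SummaryTable:
    """Drop SNPs on an exclusion list, or in high LD (r^2 > ``r2_proxy``)
    with an excluded SNP.

    The exclusion list stands in for phenotype-database screens flagging
    variants robustly associated with confounders (blood pressure, diabetes,
    BMI, smoking...).
    """
    excluded = set(excluded_snps)
    if not excluded:
        return table
    ld = ld or LDInfo()
    log = []
    keep = []
    for row in table.df.itertuples(index=False):
        if row.snp in excluded:
            log.append(f"exclude: {row.snp} on exclusion list")
            continue
        proxy = next((e for e in sorted(excluded) if ld.r2(row.snp, e) > r2_proxy), None)
        if proxy is not None:
            log.append(f"exclude: {row.snp} in LD (r2 > {r2_proxy}) with excluded {proxy}")
            continue
        keep.append(row.snp)
    kept = table.df[table.df["snp"].isin(keep)].copy()
    return SummaryTable(kept, table.trait_label, table.trait_type,
                        list(table.provenance) + log)


def read_exclusion_list(path) -> set:
    """One SNP id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def dual_marker_refine(
    primary: SummaryTable,
    secondary: SummaryTable,
    n_index: int,
    require_direction: bool = True,
    expected_sign: str = "concordant",
) -> SummaryTable:
    """Refine a primary-trait instrument by a second marker of the same
    underlying physiology.

    Keeps primary SNPs whose secondary-trait association is Bonferroni
    significant (p < 0.05 / ``n_index``) and — when ``require_direction`` —
    directionally consistent: the secondary beta shares the primary beta's
    sign for a concordant marker (cystatin-based eGFR vs creatinine-based
    eGFR) or opposes it for an inverse marker (blood urea nitrogen, which
    rises as filtration falls).  SNPs absent from the secondary table are
    removed with reason "no-secondary-data".
    """
    if n_index <= 0:
        raise InstrumentError("n_index must be positive")
    if expected_sign not in ("concordant", "discordant"):
        raise InstrumentError("expected_sign must be 'concordant' or 'discordant'")
    threshold = 0.05 / n_index
    sec = secondary.df.set_index("snp")
    log, keep = [], []
    for row in primary.df.itertuples(index=False):
        if row.snp not in sec.index:
            log.append(f"dual-marker: {row.snp} removed (no-secondary-data)")
            continue
        s = sec.loc[row.snp]
        # secondary beta on the primary's effect-allele frame
        if (s["ea"], s["oa"]) == (row.ea, row.oa):
            beta_sec = s["beta"]
        elif (s["ea"], s["oa"]) == (row.oa, row.ea):
            beta_sec = -s["beta"]
        else:
            log.append(f"dual-marker: {row.snp} removed (allele-mismatch in secondary)")
            continue
        if s["p"] >= threshold:
            log.append(f"dual-marker: {row.snp} removed (secondary p = {s['p']:.3g} >= {threshold:.3g})")
            continue
        if require_direction:
            same = np.sign(beta_sec) == np.sign(row.beta)
            ok = same if expected_sign == "concordant" else not same
            if not ok:
                log.append(f"dual-marker: {row.snp} removed (sign not {expected_sign})")
                continue
        keep.append(row.snp)
    kept = primary.df[primary.df["snp"].isin(keep)].copy()
    return SummaryTable(kept, primary.trait_label, primary.trait_type,
                        list(primary.provenance) + log)


# ---------------------------------------------------------------------------
# Steiger filtering and instrument strength
# ---------------------------------------------------------------------------

def variance_explained(beta, se, n):
    """Per-SNP trait variance explained, r^2 = t^2 / (t^2 + n - 2)."""
    t2 = (np.asarray(beta, float) / np.asarray(se, float)) ** 2
    return t2 / (t2 + np.asarray(n, float) - 2.0)


def steiger_z(r2_exp, r2_out, n_exp, n_out):
    """Fisher-z comparison of |correlations| implied by the two r^2 values.

    z = (atanh r_exp - atanh r_out) / sqrt(1/(n_exp-3) + 1/(n_out-3));
    positive z favours the exposure as the causally upstream trait.
    """
    n_exp = np.asarray(n_exp, float)
    n_out = np.asarray(n_out, float)
    if np.any(n_exp <= 3) or np.any(n_out <= 3):
        raise InstrumentError("sample sizes must exceed 3 for the Fisher-z variance")
    r_exp = np.sqrt(np.clip(r2_exp, 0.0, 1.0 - 1e-15))
    r_out = np.sqrt(np.clip(r2_out, 0.0, 1.0 - 1e-15))
    denom = np.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    return (np.arctanh(r_exp) - np.arctanh(r_out)) / denom


@dataclass
class SteigerResult:
    """Per-SNP directionality diagnostics (r^2 in exposure vs outcome)."""

    df: pd.DataFrame  # snp, r2_exp, r2_out, direction_ok, steiger_z, steiger_p

    @property
    def n_direction_ok(self) -> int:
        return int(self.df["direction_ok"].sum())


def steiger_stats(h: HarmonizedSet) -> SteigerResult:
    r = h.retained
    if r["n_exp"].isna().any() or r["n_out"].isna().any():
        raise InstrumentError("Steiger filtering needs n_exp and n_out for every SNP")
    r2_exp = variance_explained(r["beta_exp"], r["se_exp"], r["n_exp"])
    r2_out = variance_explained(r["beta_out"], r["se_out"], r["n_out"])
    z = steiger_z(r2_exp, r2_out, r["n_exp"], r["n_out"])
    p = 2.0 * stats.norm.sf(np.abs(z))
    return SteigerResult(pd.DataFrame({
        "snp": r["snp"].to_numpy(),
        "r2_exp": np.asarray(r2_exp, float),
        "r2_out": np.asarray(r2_out, float),
        "direction_ok": np.asarray(r2_exp, float) > np.asarray(r2_out, float),
        "steiger_z": np.asarray(z, float),
        "steiger_p": p,
    }))


def steiger_filter(
    h: HarmonizedSet,
    mode: str = "point-estimate",
    alpha: float = 0.05,
) -> tuple[HarmonizedSet, SteigerResult]:
    """Remove SNPs that do not explain more variance in the exposure than in
    the outcome.

    ``mode="point-estimate"`` drops SNPs with r2_exp <= r2_out;
    ``mode="significance"`` additionally requires the Fisher-z test to reject
    at ``alpha`` (two-sided p < alpha with the correct direction).
    """
    if mode not in ("point-estimate", "significance"):
        raise InstrumentError("mode must be 'point-estimate' or 'significance'")
    res = steiger_stats(h)
    ok = res.df["direction_ok"].to_numpy()
    if mode == "significance":
        ok = ok & (res.df["steiger_p"].to_numpy() < alpha)
    drop_ids = res.df.loc[~ok, "snp"]
    return h.drop_snps(drop_ids, "steiger"), res


@dataclass
class StrengthStats:
    """Instrument-strength diagnostics.

    ``f_per_snp`` are per-SNP F statistics (beta/se)^2; ``i2_gx`` is the
    heterogeneity of the SNP-exposure effects used to judge the NOME
    assumption for MR-Egger, clamped to [0, 1]; ``r2_instrument`` sums the
    per-SNP exposure variance explained.
    """

    f_per_snp: np.ndarray
    f_mean: float
    f_min: float
    q_gx: float
    i2_gx: float | None
    r2_instrument: float | None

    @property
    def weak(self) -> bool:
        return self.f_mean < 10.0


def instrument_strength(h: HarmonizedSet) -> StrengthStats:
    g, se_g, _, _ = h.arrays()
    if g.size == 0:
        raise InstrumentError("empty instrument")
    f = (g / se_g) ** 2
    if g.size >= 2:
        v = 1.0 / se_g**2
        gbar = np.sum(v * g) / np.sum(v)
        q_gx = float(np.sum(v * (g - gbar) ** 2))
        i2 = max(0.0, (q_gx - (g.size - 1)) / q_gx) if q_gx > 0 else 0.0
    else:
        q_gx, i2 = 0.0, None
    n_exp = h.retained["n_exp"].to_numpy(float)
    if np.isnan(n_exp).any():
        r2 = None
    else:
        r2 = float(np.sum(variance_explained(g, se_g, n_exp)))
    return StrengthStats(f, float(f.mean()), float(f.min()), q_gx, i2, r2)
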