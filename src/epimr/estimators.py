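"""Summary-data MR estimators and sensitivity analyses.

Given a harmonized set of J SNP-exposure effects gamma_j (se_gamma_j) and
SNP-outcome effects Gamma_j (se_Gamma_j), the causal effect beta of the
exposure on the outcome is estimated by:

* per-SNP Wald ratios Gamma_j / gamma_j;
* inverse-variance-weighted (IVW) meta-analysis — weighted regression of
  Gamma on gamma through the origin, with a multiplicative random-effects
  standard error (residual overdispersion phi = Q/(J-1), floored at 1);
* MR-Egger — the same regression with an intercept; a nonzero intercept
  estimates mean directional pleiotropy and the slope remains consistent
  under the InSIDE assumption;
* the weighted median of the ratio estimates (consistent when >50% of the
  weight comes from valid instruments), with a parametric-bootstrap SE;
* MR-PRESSO — a simulation-based residual-sum-of-squares test that detects
  pleiotropic outlier SNPs and re-estimates without them.

Model selection between IVW and MR-Egger follows the Rücker framework:
MR-Egger is preferred only when the heterogeneity drop Q - Q' is significant
(chi^2_1, p < 0.05) AND the Egger intercept differs from zero (p < 0.1).
Leave-one-out re-estimation and the Steiger directionality test complete the
sensitivity suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import HarmonizedSet
from .instruments import InstrumentError, steiger_stats, steiger_z


class EstimationError(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with normal/t-theory inference.

    ``beta`` is in outcome units per exposure unit.  For MR-Egger the
    pleiotropy intercept and its test are attached; for multiplicative
    random-effects IVW the overdispersion phi = Q/(J-1) is recorded.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    snp_id: str | None = None
    overdispersion: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 and np.isfinite(self.se):
            raise EstimationError(f"{self.method}: nonpositive SE {self.se}")

    def to_dict(self) -> dict:
        d = {"method": self.method, "beta": self.beta, "se": self.se,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "pvalue": self.pvalue, "n_snps": self.n_snps}
        for k in ("snp_id", "overdispersion", "intercept", "intercept_se", "intercept_p"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def _normal_estimate(method, beta, se, n_snps, **extra) -> MREstimate:
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
    return MREstimate(method, float(beta), float(se),
                      float(beta - z * se), float(beta + z * se), float(p),
                      int(n_snps), **extra)


def _t_bounds(beta, se, df):
    tq = stats.t.ppf(0.975, df)
    return float(beta - tq * se), float(beta + tq * se)


# ---------------------------------------------------------------------------
# Wald ratios and IVW
# ---------------------------------------------------------------------------

def wald_ratios(h: HarmonizedSet) -> list[MREstimate]:
    """Per-SNP causal estimates Gamma_j / gamma_j with first-order delta SEs.

    The SE is se_Gamma_j / |gamma_j| — the leading term of the delta method;
    uncertainty in gamma_j is neglected (documented approximation).  SNPs
    with gamma_j = 0 are excluded with a warning.
    """
    r = h.retained
    out = []
    for row in r.itertuples(index=False):
        if row.beta_exp == 0:
            warnings.warn(f"wald_ratios: {row.snp} excluded (beta_exp = 0)", stacklevel=2)
            continue
        beta = row.beta_out / row.beta_exp
        se = row.se_out / abs(row.beta_exp)
        out.append(_normal_estimate("wald", beta, se, 1, snp_id=row.snp))
    return out


def ivw_arrays(g, seg, G, seG, random_effects: bool = True):
    """Vectorized IVW over one instance (1-D) or a batch (2-D, reps x J).

    Returns (beta, se, Q, phi) with phi = Q/(J-1) and — when
    ``random_effects`` — the SE inflated by sqrt(max(1, phi)).
    """
    g = np.atleast_2d(np.asarray(g, float))
    G = np.atleast_2d(np.asarray(G, float))
    seG = np.atleast_2d(np.asarray(seG, float))
    J = g.shape[1]
    w = 1.0 / seG**2
    s2 = np.sum(w * g * g, axis=1)
    beta = np.sum(w * g * G, axis=1) / s2
    se = 1.0 / np.sqrt(s2)
    Q = np.sum(w * (G - beta[:, None] * g) ** 2, axis=1)
    phi = Q / (J - 1) if J > 1 else np.full_like(Q, np.nan)
    if random_effects and J > 1:
        se = se * np.sqrt(np.maximum(1.0, phi))
    return beta, se, Q, phi


def ivw(h: HarmonizedSet, random_effects: bool = True, _allow_single: bool = False) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of Gamma on
    gamma through the origin with weights 1/se_Gamma^2.

    With ``random_effects`` (the default, the primary model here) the SE is
    multiplied by sqrt(max(1, Q/(J-1))) — multiplicative overdispersion with
    a floor at 1 so random effects never claim more precision than fixed.
    """
    g, seg, G, seG = h.arrays()
    J = g.size
    if J < 2 and not _allow_single:
        raise EstimationError("IVW needs >= 2 SNPs; use wald_ratios for a single SNP")
    if J == 0:
        raise EstimationError("empty instrument")
    beta, se, Q, phi = ivw_arrays(g, seg, G, seG, random_effects)
    label = "IVW-RE" if random_effects else "IVW-FE"
    return _normal_estimate(label, beta[0], se[0], J,
                            overdispersion=float(phi[0]) if J > 1 else None)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def _egger_orient(g, G):
    """Flip SNPs so every gamma_j >= 0 (both betas together)."""
    sign = np.where(g < 0, -1.0, 1.0)
    return g * sign, G * sign


def egger_arrays(g, G, seG):
    """Weighted regression Gamma = b0 + b1 * gamma, weights 1/se_Gamma^2.

    Returns (slope, intercept, se_slope, se_intercept, Qprime) with SEs from
    the unscaled normal equations (multiply by the residual factor for
    random-effects inference).  Inputs must already be oriented gamma >= 0.
    """
    w = 1.0 / np.asarray(seG, float) ** 2
    g = np.asarray(g, float)
    G = np.asarray(G, float)
    sw = w.sum()
    sx = np.sum(w * g)
    sxx = np.sum(w * g * g)
    sy = np.sum(w * G)
    sxy = np.sum(w * g * G)
    det = sw * sxx - sx * sx
    if det <= 0 or not np.isfinite(det):
        raise EstimationError("Egger design is singular (no spread in gamma)")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    resid = G - intercept - slope * g
    qprime = float(np.sum(w * resid**2))
    se_slope = np.sqrt(sw / det)
    se_intercept = np.sqrt(sxx / det)
    return float(slope), float(intercept), float(se_slope), float(se_intercept), qprime


def egger(h: HarmonizedSet, random_effects: bool = True) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope estimate, intercept estimate).

    SNPs are internally oriented so gamma_j >= 0 (flipping both betas), the
    convention under which the intercept estimates mean directional
    pleiotropy.  Inference uses the t distribution on J-2 df — small-J
    intercept tests are anticonservative under normal theory — and, with
    ``random_effects``, SEs inflated by sqrt(max(1, Q'/(J-2))).
    """
    g, seg, G, seG = h.arrays()
    J = g.size
    if J < 3:
        raise EstimationError("insufficient SNPs for Egger (need >= 3)")
    g, G = _egger_orient(g, G)
    slope, intercept, se_s, se_i, qprime = egger_arrays(g, G, seG)
    phi = qprime / (J - 2)
    if random_effects:
        infl = np.sqrt(max(1.0, phi))
        se_s, se_i = se_s * infl, se_i * infl
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_s, J - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_i, J - 2)
    lo, hi = _t_bounds(slope, se_s, J - 2)
    slope_est = MREstimate("MR-Egger", slope, se_s, lo, hi, float(p_slope), J,
                           overdispersion=phi, intercept=intercept,
                           intercept_se=se_i, intercept_p=float(p_int))
    lo_i, hi_i = _t_bounds(intercept, se_i, J - 2)
    int_est = MREstimate("MR-Egger intercept", intercept, se_i, lo_i, hi_i, float(p_int), J)
    return slope_est, int_est


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median(ratios, weights):
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, b))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | np.random.Generator | None = None) -> MREstimate:
    """Weighted median of the Wald ratios; consistent if valid instruments
    carry more than half the weight.

    Ratios are ordered ascending with normalized inverse-variance weights
    w_j from the ratio SEs; the estimate interpolates the ratio at
    cumulative weight 1/2 using midpoints p_j = (S_j - w_j/2)/sum(w).  The
    SE comes from a parametric bootstrap: gamma and Gamma resampled from
    normal distributions at their SEs, ``n_boot`` times.
    """
    g, seg, G, seG = h.arrays()
    J = g.size
    if J < 3:
        raise EstimationError("weighted median needs >= 3 SNPs")
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} < 100: bootstrap SE will be unstable", stacklevel=2)
    ratios = G / g
    w = 1.0 / (seG / np.abs(g)) ** 2
    est = _weighted_median(ratios, w)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gb = rng.normal(g, seg, size=(n_boot, J))
    Gb = rng.normal(G, seG, size=(n_boot, J))
    rb = Gb / gb
    wb = (np.abs(gb) / seG) ** 2
    order = np.argsort(rb, axis=1, kind="mergesort")
    rb = np.take_along_axis(rb, order, axis=1)
    wb = np.take_along_axis(wb, order, axis=1)
    wb = wb / wb.sum(axis=1, keepdims=True)
    cum = np.cumsum(wb, axis=1) - 0.5 * wb
    boots = np.array([np.interp(0.5, cum[i], rb[i]) for i in range(n_boot)])
    se = float(boots.std(ddof=1))
    return _normal_estimate("weighted-median", est, se, J)


# ---------------------------------------------------------------------------
# Heterogeneity and Rücker model selection
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityStats:
    """Cochran's Q (IVW) and Rücker's Q' (Egger) with the Q - Q' test.

    ``p_diff`` is P(chi^2_1 >= Q - Q'): a small value says the Egger
    intercept absorbs significant heterogeneity, i.e. directional pleiotropy
    makes MR-Egger the better-fitting model.
    """

    q: float
    q_prime: float
    df_q: int
    df_qp: int
    p_q: float
    p_qp: float
    p_diff: float


def heterogeneity(h: HarmonizedSet) -> HeterogeneityStats:
    g, seg, G, seG = h.arrays()
    J = g.size
    if J < 3:
        raise EstimationError("heterogeneity statistics need >= 3 SNPs")
    w = 1.0 / seG**2
    beta_ivw = np.sum(w * g * G) / np.sum(w * g * g)
    q = float(np.sum(w * (G - beta_ivw * g) ** 2))
    go, Go = _egger_orient(g, G)
    *_, qprime = egger_arrays(go, Go, seG)
    qprime = min(qprime, q)  # nesting can only reduce weighted RSS
    return HeterogeneityStats(
        q=q, q_prime=qprime, df_q=J - 1, df_qp=J - 2,
        p_q=float(stats.chi2.sf(q, J - 1)),
        p_qp=float(stats.chi2.sf(qprime, J - 2)),
        p_diff=float(stats.chi2.sf(max(q - qprime, 0.0), 1)),
    )


@dataclass
class ModelSelectionResult:
    """Outcome of the Rücker IVW / MR-Egger model choice."""

    chosen_method: str
    p_diff: float
    intercept_p: float
    ivw_estimate: MREstimate
    egger_estimate: MREstimate
    heterogeneity: HeterogeneityStats
    rationale: str

    @property
    def primary(self) -> MREstimate:
        return self.egger_estimate if self.chosen_method == "MR-Egger" else self.ivw_estimate


def rucker_select(h: HarmonizedSet, random_effects: bool = True) -> ModelSelectionResult:
    """Choose the primary model: MR-Egger iff the heterogeneity drop Q - Q'
    is significant (p < 0.05) AND the Egger intercept is nonzero (p < 0.1);
    otherwise multiplicative random-effects IVW."""
    est_ivw = ivw(h, random_effects=random_effects)
    est_egger, _ = egger(h, random_effects=random_effects)
    het = heterogeneity(h)
    use_egger = het.p_diff < 0.05 and est_egger.intercept_p < 0.1
    if use_egger:
        rationale = (f"Q - Q' = {het.q - het.q_prime:.3g} (p = {het.p_diff:.3g} < 0.05) and "
                     f"Egger intercept p = {est_egger.intercept_p:.3g} < 0.1: "
                     "directional pleiotropy detected, MR-Egger fits better")
    else:
        rationale = (f"Q - Q' p = {het.p_diff:.3g}, Egger intercept p = "
                     f"{est_egger.intercept_p:.3g}: no model switch, IVW retained")
    return ModelSelectionResult(
        "MR-Egger" if use_egger else "IVW",
        het.p_diff, float(est_egger.intercept_p), est_ivw, est_egger, het, rationale)


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    ``global_p`` is the empirical p of the observed leave-one-out residual
    sum of squares against its parametric-simulation null, computed as
    (1 + #{RSS* >= RSS_obs}) / (n_sim + 1) so it can never be exactly zero.
    ``outlier_p`` are per-SNP Bonferroni-adjusted empirical p-values;
    ``beta_corrected`` is IVW after removing the flagged outliers, and
    ``distortion_p`` tests whether the raw-vs-corrected shift exceeds what
    removing random same-sized subsets produces.
    """

    rss_obs: float
    global_p: float
    outlier_p: pd.Series = field(repr=False)
    outlier_ids: list = field(default_factory=list)
    beta_raw: MREstimate | None = None
    beta_corrected: MREstimate | None = None
    distortion_p: float | None = None
    n_sim: int = 0
    seed: int | None = None


def _loo_ivw_beta(g, G, w):
    """Leave-one-out fixed-effect IVW slopes, vectorized over rows."""
    num = np.sum(w * g * G, axis=-1, keepdims=True) - w * g * G
    den = np.sum(w * g * g, axis=-1, keepdims=True) - w * g * g
    return num / den


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int | np.random.Generator | None = None) -> PressoResult:
    """MR-PRESSO outlier detection and correction.

    For each SNP j the expected outcome effect is gamma_j * beta(-j), with
    beta(-j) the IVW slope excluding SNP j; the observed weighted residual
    sum RSS_obs is referred to a null distribution built by simulating
    Gamma*_j ~ N(gamma_j beta(-j), se_Gamma_j) and gamma*_j ~ N(gamma_j,
    se_gamma_j) ``n_sim`` times and recomputing RSS on each draw.  Per-SNP
    contributions give the outlier test (Bonferroni-adjusted by J); SNPs
    with adjusted p < ``outlier_alpha`` are removed for the corrected IVW,
    and the distortion test compares the induced shift against removal of
    random subsets of the same size.
    """
    g, seg, G, seG = h.arrays()
    J = g.size
    if J < 4:
        raise EstimationError("MR-PRESSO needs >= 4 SNPs")
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = 1.0 / seG**2

    beta_loo = np.atleast_1d(np.squeeze(_loo_ivw_beta(g[None, :], G[None, :], w[None, :])))
    obs_contrib = w * (G - g * beta_loo) ** 2
    rss_obs = float(obs_contrib.sum())

    g_sim = rng.normal(g, seg, size=(n_sim, J))
    G_sim = rng.normal(g * beta_loo, seG, size=(n_sim, J))
    beta_loo_sim = _loo_ivw_beta(g_sim, G_sim, w[None, :])
    sim_contrib = w[None, :] * (G_sim - g_sim * beta_loo_sim) ** 2
    rss_sim = sim_contrib.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_per_snp = (1 + np.sum(sim_contrib >= obs_contrib[None, :], axis=0)) / (n_sim + 1)
    outlier_p = pd.Series(np.minimum(p_per_snp * J, 1.0),
                          index=h.retained["snp"].to_numpy(), name="outlier_p")
    outlier_mask = outlier_p.to_numpy() < outlier_alpha
    outlier_ids = list(outlier_p.index[outlier_mask])

    beta_raw = ivw(h)
    beta_corrected = None
    distortion_p = None
    if outlier_ids:
        if outlier_mask.all():
            raise EstimationError("MR-PRESSO flagged every SNP: no SNPs remain")
        h_corr = h.drop_snps(outlier_ids, "mr-presso-outlier")
        beta_corrected = ivw(h_corr)
        k = len(outlier_ids)
        d_obs = beta_raw.beta - beta_corrected.beta
        idx = np.argsort(rng.random((n_sim, J)), axis=1)[:, :k]  # random k-subsets
        keep = np.ones((n_sim, J), bool)
        np.put_along_axis(keep, idx, False, axis=1)
        num = np.where(keep, w * g * G, 0.0).sum(axis=1)
        den = np.where(keep, w * g * g, 0.0).sum(axis=1)
        d_null = beta_raw.beta - num / den
        distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(rss_obs, global_p, outlier_p, outlier_ids,
                        beta_raw, beta_corrected, distortion_p, n_sim, seed_int)


# ---------------------------------------------------------------------------
# Steiger directionality and leave-one-out
# ---------------------------------------------------------------------------

@dataclass
class DirectionalityResult:
    """Aggregate Steiger directionality over the whole instrument."""

    r2_exp_total: float
    r2_out_total: float
    valid: bool
    steiger_z: float
    steiger_p: float
    per_snp: pd.DataFrame = field(repr=False)


def steiger_directionality(h: HarmonizedSet) -> DirectionalityResult:
    """Test whether the instrument explains more variance in the exposure
    than in the outcome (summed per-SNP r^2; "valid" = exposure upstream)."""
    res = steiger_stats(h)
    r = h.retained
    r2e = float(np.clip(res.df["r2_exp"].sum(), 0.0, 1.0 - 1e-12))
    r2o = float(np.clip(res.df["r2_out"].sum(), 0.0, 1.0 - 1e-12))
    z = float(steiger_z(r2e, r2o, r["n_exp"].mean(), r["n_out"].mean()))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DirectionalityResult(r2e, r2o, r2e > r2o, z, p, res.df)


_METHODS = {}


def _register_methods():
    _METHODS.update({"ivw": ivw, "egger": lambda h, **kw: egger(h, **kw)[0],
                     "weighted-median": weighted_median})


_register_methods()


def leave_one_out(h: HarmonizedSet, method: str = "ivw", **kwargs) -> list[tuple[str, MREstimate]]:
    """Re-estimate excluding each retained SNP in turn (same settings)."""
    if method not in _METHODS:
        raise EstimationError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    snps = h.retained["snp"].tolist()
    if len(snps) < 3:
        raise EstimationError("leave-one-out needs >= 3 SNPs")
    fn = _METHODS[method]
    return [(s, fn(h.drop_snps([s], "loo"), **kwargs)) for s in snps]
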