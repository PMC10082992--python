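"""Synthetic GWAS and cohort generator with known ground truth.

Generative model (continuous traits standardized to unit variance):

    X = sum_j gamma_j G_j + q U + e_x
    Y = beta_true X + sum_j alpha_j G_j + r U + e_y

with G_j ~ Binomial(2, f_j) biallelic dosages, U a standardized confounder,
and alpha_j horizontal-pleiotropy effects carried by a configurable
fraction of invalid SNPs (balanced, directional, or routed through a
heritable confounder to violate InSIDE).  Binary outcomes use a logistic
link whose intercept is solved numerically for the target case fraction.

Two-sample summary statistics come either from simulated individuals in two
disjoint pools (``mode="individual"``) or directly from the estimators'
asymptotic sampling distributions (``mode="asymptotic"``) — the latter is
what large replicate experiments use.  A mediation variant adds a mediator
trait M with its own instrument SNPs, and an individual-level cohort
generator emulates a biobank with creatinine/cystatin C biomarkers whose
derived eGFR carries a planted allele-score effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gwas_io import SummaryTable

__all__ = [
    "SimulationConfig", "SimulationTruth", "simulate_two_sample",
    "simulate_mediation", "simulate_individual", "asymptotic_draws",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults describe the study conditions emulated throughout: J = 50
    biallelic SNPs with minor-allele frequencies in (0.05, 0.5), two
    non-overlapping GWAS samples of 50,000, an instrument explaining 4% of
    the exposure variance (the upper end of what the epigenetic-clock
    instruments explain), no pleiotropy, and a null causal effect unless
    stated otherwise.
    """

    J: int = 50
    maf_range: tuple = (0.05, 0.5)
    n_exp: int = 50_000
    n_out: int = 50_000
    beta_true: float = 0.0
    h2_exposure: float = 0.04
    # horizontal pleiotropy
    prop_invalid: float = 0.0
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    correlated_pleiotropy: bool = False
    # unmeasured confounder X <- U -> Y
    confounder_q: float = 0.3
    confounder_r: float = 0.3
    # outcome
    outcome_type: str = "continuous"
    case_fraction: float | None = None
    # mediation (X -> M -> Y); mediator gets its own J_med instrument SNPs
    mediated_fraction: float | None = None
    J_med: int = 25
    h2_mediator: float = 0.04
    beta_xm: float = 0.5
    # LD structure for individual-level genotypes
    ld_block_size: int = 1
    ld_rho: float = 0.0
    # individual-level cohort
    n_cohort: int | None = None
    score_effect_log_egfr: float = -0.001
    # two-sample overlap (fraction of the exposure sample reused in outcome)
    overlap_fraction: float = 0.0
    mode: str = "asymptotic"

    def __post_init__(self) -> None:
        if self.J < 1:
            raise SimulationError("J must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.h2_exposure < 1:
            raise SimulationError("h2_exposure must lie in (0, 1)")
        if not 0 <= self.prop_invalid <= 1:
            raise SimulationError("prop_invalid must lie in [0, 1]")
        if self.outcome_type not in ("continuous", "binary"):
            raise SimulationError("outcome_type must be 'continuous' or 'binary'")
        if self.outcome_type == "binary":
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise SimulationError("binary outcomes need case_fraction in (0, 1)")
        if self.mediated_fraction is not None and not 0 <= self.mediated_fraction <= 1:
            raise SimulationError("mediated_fraction must lie in [0, 1]")
        if not 0 <= self.ld_rho < 1:
            raise SimulationError("ld_rho must lie in [0, 1)")
        if not 0 <= self.overlap_fraction <= 1:
            raise SimulationError("overlap_fraction must lie in [0, 1]")
        if self.mode not in ("asymptotic", "individual"):
            raise SimulationError("mode must be 'asymptotic' or 'individual'")
        if self.confounder_q**2 + self.h2_exposure >= 1:
            raise SimulationError("h2_exposure + confounder_q^2 must be < 1")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    maf: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray
    beta_true: float
    mediated_fraction: float | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "maf": self.maf.tolist(), "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(), "invalid": self.invalid.astype(int).tolist(),
            "beta_true": self.beta_true, "mediated_fraction": self.mediated_fraction,
            "seed": self.seed,
            "extras": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.extras.items()},
        }


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator, n_reps: int = 1):
    """Draw (maf, gamma, alpha, invalid) arrays of shape (n_reps, J)."""
    J = cfg.J
    f = rng.uniform(*cfg.maf_range, size=(n_reps, J))
    het = 2.0 * f * (1.0 - f)
    raw = rng.normal(size=(n_reps, J))
    # scale per replicate so the instrument explains exactly h2_exposure
    scale = np.sqrt(cfg.h2_exposure / np.sum(raw**2 * het, axis=1, keepdims=True))
    gamma = raw * scale
    n_invalid = int(round(cfg.prop_invalid * J))
    invalid = np.zeros((n_reps, J), bool)
    alpha = np.zeros((n_reps, J))
    if n_invalid:
        # first n_invalid of a per-replicate permutation
        order = np.argsort(rng.random((n_reps, J)), axis=1)
        idx = order[:, :n_invalid]
        np.put_along_axis(invalid, idx, True, axis=1)
        a = rng.normal(cfg.mean_alpha, max(cfg.sd_alpha, 1e-300), size=(n_reps, n_invalid))
        gsel = np.take_along_axis(gamma, idx, axis=1)
        if cfg.correlated_pleiotropy:
            # route pleiotropy through instrument strength: alpha grows with
            # gamma, violating InSIDE
            gbar = np.mean(np.abs(gamma), axis=1, keepdims=True)
            a = a * (gsel / gbar)
        else:
            # "directional" is defined on the exposure-increasing allele:
            # plant alpha relative to that orientation, else the sign-flip
            # that orients gamma >= 0 would rebalance the pleiotropy
            a = a * np.sign(gsel)
        np.put_along_axis(alpha, idx, a, axis=1)
    return f, gamma, alpha, invalid


def _marginal_outcome_effects(cfg, gamma, alpha):
    """True marginal SNP-outcome effects (independent SNPs)."""
    return cfg.beta_true * gamma + alpha


def _outcome_residual_sd(cfg, f, gamma, alpha):
    """Residual sd of Y targeting unit total variance (continuous)."""
    het = 2.0 * f * (1.0 - f)
    sigma_x2 = 1.0 - cfg.h2_exposure - cfg.confounder_q**2
    explained = (np.sum((cfg.beta_true * gamma + alpha) ** 2 * het, axis=-1)
                 + (cfg.beta_true * cfg.confounder_q + cfg.confounder_r) ** 2
                 + cfg.beta_true**2 * sigma_x2)
    if np.any(explained >= 0.95):
        raise SimulationError(
            "causal effect / pleiotropy explain >= 95% of outcome variance; "
            "infeasible standardized-outcome configuration")
    return np.sqrt(1.0 - explained)


def asymptotic_draws(cfg: SimulationConfig, n_reps: int, rng, nome: bool = False) -> tuple:
    """Summary statistics for ``n_reps`` independent replicates, drawn from
    the asymptotic sampling distributions of per-SNP regressions.

    Returns arrays ``(gamma_hat, se_gamma, Gamma_hat, se_Gamma)`` of shape
    (n_reps, J).  Standard errors use the unit-variance trait convention:
    se ~ sqrt((1 - b^2 h) / (n h)) with h = 2 f (1 - f) for continuous
    traits, and se ~ 1 / sqrt(n K (1 - K) h) for a binary outcome on the
    log-odds scale.  With ``nome`` the SNP-exposure effects are returned
    noise-free (no-measurement-error assumption).
    """
    rng = _as_rng(rng)
    f, gamma, alpha, _ = _draw_truth(cfg, rng, n_reps)
    het = 2.0 * f * (1.0 - f)
    Gamma_true = _marginal_outcome_effects(cfg, gamma, alpha)
    se_g = np.sqrt(np.clip(1.0 - gamma**2 * het, 0.05, None) / (cfg.n_exp * het))
    if cfg.outcome_type == "continuous":
        _outcome_residual_sd(cfg, f, gamma, alpha)  # feasibility check
        se_G = np.sqrt(np.clip(1.0 - Gamma_true**2 * het, 0.05, None) / (cfg.n_out * het))
    else:
        K = cfg.case_fraction
        se_G = 1.0 / np.sqrt(cfg.n_out * K * (1.0 - K) * het)
    gamma_hat = gamma if nome else rng.normal(gamma, se_g)
    Gamma_hat = rng.normal(Gamma_true, se_G)
    return gamma_hat, se_g, Gamma_hat, se_G


def _summary_table(snp, chrom, pos, eaf, beta, se, n, label, trait_type="continuous",
                   n_cases=None) -> SummaryTable:
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos, "ea": "A", "oa": "G",
        "eaf": eaf, "beta": beta, "se": se,
        "p": np.clip(p, np.finfo(float).tiny, 1.0), "n": n,
        "n_cases": np.nan if n_cases is None else n_cases,
    })
    return SummaryTable(df, label, trait_type)


# ---------------------------------------------------------------------------
# Genotype and individual-level machinery
# ---------------------------------------------------------------------------

def _draw_dosages(cfg: SimulationConfig, f: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n x J); optional equicorrelated LD blocks via a
    Gaussian copula at latent correlation ``ld_rho``."""
    J = f.size
    if cfg.ld_block_size <= 1 or cfg.ld_rho == 0.0:
        return rng.binomial(2, f, size=(n, J)).astype(float)
    G = np.empty((n, J))
    rho = cfg.ld_rho
    for start in range(0, J, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, J)
        b = stop - start
        shared = rng.normal(size=(n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.normal(size=(n, b))
        u = special.ndtr(z)
        for k, j in enumerate(range(start, stop)):
            pj = f[j]
            cdf = np.array([(1 - pj) ** 2, (1 - pj) ** 2 + 2 * pj * (1 - pj)])
            G[:, j] = np.searchsorted(cdf, u[:, k])
    return G


def _per_snp_linear(G: np.ndarray, y: np.ndarray):
    """Marginal OLS of y on each dosage column: (beta, se) arrays."""
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(Gc**2, axis=0)
    beta = Gc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    sigma2 = rss / (n - 2)
    return beta, np.sqrt(sigma2 / sxx)


def _per_snp_logistic(G: np.ndarray, y: np.ndarray):
    """Marginal logistic regression of y on each dosage column via Newton
    iterations (intercept + slope), vectorized over SNPs."""
    n, J = G.shape
    b0 = np.full(J, special.logit(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
    b1 = np.zeros(J)
    for _ in range(25):
        eta = b0[None, :] + G * b1[None, :]
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        s0 = r.sum(axis=0)
        s1 = np.sum(G * r, axis=0)
        i00 = w.sum(axis=0)
        i01 = np.sum(w * G, axis=0)
        i11 = np.sum(w * G * G, axis=0)
        det = i00 * i11 - i01**2
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        b0 += d0
        b1 += d1
        if np.max(np.abs(d1)) < 1e-10:
            break
    eta = b0[None, :] + G * b1[None, :]
    w = special.expit(eta) * (1.0 - special.expit(eta))
    i00 = w.sum(axis=0)
    i01 = np.sum(w * G, axis=0)
    i11 = np.sum(w * G * G, axis=0)
    se = np.sqrt(i00 / (i00 * i11 - i01**2))
    return b1, se


def _solve_logistic_intercept(eta_lin: np.ndarray, target_k: float) -> float:
    """Intercept c such that mean(expit(c + eta_lin)) = target_k."""
    def g(c):
        return special.expit(c + eta_lin).mean() - target_k

    lo, hi = -30.0, 30.0
    if g(lo) > 0 or g(hi) < 0:
        raise SimulationError("cannot reach target case fraction")
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def simulate_two_sample(cfg: SimulationConfig, seed=None):
    """Simulate one exposure GWAS and one outcome GWAS over the same SNPs.

    Returns ``(exposure_table, outcome_table, truth)``.  ``mode="asymptotic"``
    draws summary statistics from their sampling distributions;
    ``mode="individual"`` simulates the two participant pools (disjoint up
    to ``overlap_fraction``) and runs per-SNP regressions.
    """
    rng = _as_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    J = cfg.J
    snp = [f"rs{i + 1}" for i in range(J)]
    chrom = [str(i % 22 + 1) for i in range(J)]
    pos = [1_000_000 * (i // 22 + 1) + i for i in range(J)]

    if cfg.mode == "asymptotic":
        f, gamma, alpha, invalid = _draw_truth(cfg, rng, 1)
        f, gamma, alpha, invalid = f[0], gamma[0], alpha[0], invalid[0]
        het = 2.0 * f * (1.0 - f)
        Gamma_true = cfg.beta_true * gamma + alpha
        se_g = np.sqrt(np.clip(1.0 - gamma**2 * het, 0.05, None) / (cfg.n_exp * het))
        if cfg.outcome_type == "continuous":
            _outcome_residual_sd(cfg, f[None], gamma[None], alpha[None])
            se_G = np.sqrt(np.clip(1.0 - Gamma_true**2 * het, 0.05, None)
                           / (cfg.n_out * het))
            n_cases = None
        else:
            K = cfg.case_fraction
            se_G = 1.0 / np.sqrt(cfg.n_out * K * (1.0 - K) * het)
            n_cases = int(round(K * cfg.n_out))
        g_hat = rng.normal(gamma, se_g)
        G_hat = rng.normal(Gamma_true, se_G)
    else:
        f, gamma, alpha, invalid = _draw_truth(cfg, rng, 1)
        f, gamma, alpha, invalid = f[0], gamma[0], alpha[0], invalid[0]
        n_shared = int(round(cfg.overlap_fraction * min(cfg.n_exp, cfg.n_out)))
        G_exp = _draw_dosages(cfg, f, cfg.n_exp, rng)
        G_out_new = _draw_dosages(cfg, f, cfg.n_out - n_shared, rng)
        G_out = np.vstack([G_exp[:n_shared], G_out_new]) if n_shared else G_out_new

        sigma_x = np.sqrt(1.0 - cfg.h2_exposure - cfg.confounder_q**2)

        def latent(Gm, rng):
            n = Gm.shape[0]
            U = rng.normal(size=n)
            X = (Gm - 2 * f) @ gamma + cfg.confounder_q * U + rng.normal(0, sigma_x, n)
            return X, U

        X_exp, _ = latent(G_exp, rng)
        X_out, U_out = latent(G_out, rng)
        pleio = (G_out - 2 * f) @ alpha
        if cfg.outcome_type == "continuous":
            sd_y = _outcome_residual_sd(cfg, f[None], gamma[None], alpha[None])[0]
            Y = (cfg.beta_true * X_out + pleio + cfg.confounder_r * U_out
                 + rng.normal(0, sd_y, G_out.shape[0]))
            G_hat, se_G = _per_snp_linear(G_out, Y)
            n_cases = None
        else:
            eta_lin = cfg.beta_true * X_out + pleio + cfg.confounder_r * U_out
            c0 = _solve_logistic_intercept(eta_lin, cfg.case_fraction)
            Y = rng.binomial(1, special.expit(c0 + eta_lin)).astype(float)
            G_hat, se_G = _per_snp_logistic(G_out, Y)
            n_cases = int(Y.sum())
        g_hat, se_g = _per_snp_linear(G_exp, X_exp)

    exposure = _summary_table(snp, chrom, pos, f, g_hat, se_g, cfg.n_exp, "exposure")
    outcome = _summary_table(snp, chrom, pos, f, G_hat, se_G, cfg.n_out, "outcome",
                             cfg.outcome_type, n_cases)
    truth = SimulationTruth(f, gamma, alpha, invalid, cfg.beta_true,
                            cfg.mediated_fraction, seed_int)
    return exposure, outcome, truth


def simulate_mediation(cfg: SimulationConfig, seed=None):
    """Simulate summary statistics for an exposure -> mediator -> outcome
    system.

    The exposure has ``J`` instrument SNPs (gamma) and the mediator ``J_med``
    SNPs of its own (kappa); with mediated fraction m and total effect
    beta_true the paths are beta_xm (X -> M), beta_my = m * beta_true /
    beta_xm (M -> Y) and direct = (1 - m) * beta_true.  Returns
    ``(exposure_table, mediator_table, outcome_table, truth)`` over the
    union of SNPs, drawn in asymptotic mode.
    """
    if cfg.mediated_fraction is None:
        raise SimulationError("simulate_mediation requires mediated_fraction")
    rng = _as_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    m = cfg.mediated_fraction
    if cfg.beta_xm == 0:
        raise SimulationError("beta_xm must be nonzero")
    beta_my = m * cfg.beta_true / cfg.beta_xm
    beta_direct = (1.0 - m) * cfg.beta_true

    # exposure SNPs
    fx, gamma, _, _ = _draw_truth(cfg, rng, 1)
    fx, gamma = fx[0], gamma[0]
    # mediator-specific SNPs (reuse the machinery with a mediator-sized config)
    med_cfg = replace(cfg, J=cfg.J_med, h2_exposure=cfg.h2_mediator,
                      prop_invalid=0.0, mediated_fraction=None)
    fm, kappa, _, _ = _draw_truth(med_cfg, rng, 1)
    fm, kappa = fm[0], kappa[0]

    J_all = cfg.J + cfg.J_med
    f = np.concatenate([fx, fm])
    het = 2.0 * f * (1.0 - f)
    # true marginal effects on each trait over all SNPs
    b_exp = np.concatenate([gamma, np.zeros(cfg.J_med)])
    b_med = np.concatenate([gamma * cfg.beta_xm, kappa])
    b_out = np.concatenate([gamma * cfg.beta_true, kappa * beta_my])

    def draw(b_true, n):
        se = np.sqrt(np.clip(1.0 - b_true**2 * het, 0.05, None) / (n * het))
        return rng.normal(b_true, se), se

    snp = [f"rs{i + 1}" for i in range(J_all)]
    chrom = [str(i % 22 + 1) for i in range(J_all)]
    pos = [1_000_000 * (i // 22 + 1) + i for i in range(J_all)]
    bx, sx = draw(b_exp, cfg.n_exp)
    bm, sm = draw(b_med, cfg.n_exp)
    by, sy = draw(b_out, cfg.n_out)
    truth = SimulationTruth(
        f, b_exp, np.zeros(J_all), np.zeros(J_all, bool), cfg.beta_true,
        m, seed_int,
        extras={"beta_xm": cfg.beta_xm, "beta_my": beta_my,
                "beta_direct": beta_direct, "kappa": kappa,
                "exposure_snps": snp[:cfg.J], "mediator_snps": snp[cfg.J:]})
    return (
        _summary_table(snp, chrom, pos, f, bx, sx, cfg.n_exp, "exposure"),
        _summary_table(snp, chrom, pos, f, bm, sm, cfg.n_exp, "mediator"),
        _summary_table(snp, chrom, pos, f, by, sy, cfg.n_out, "outcome"),
        truth,
    )


# ---------------------------------------------------------------------------
# Individual-level cohort
# ---------------------------------------------------------------------------

_EGFR_BASE = 135.0


def _invert_ckd_epi(egfr, age, female, split, rng=None):
    """Solve (scr, scys) reproducing ``egfr`` exactly under the 2012
    combined equation; ``split`` in (0, 1) apportions the deficit between
    the creatinine and cystatin factors."""
    base = _EGFR_BASE * 0.995**age * np.where(female, 0.969, 1.0)
    logT = np.log(np.asarray(egfr, float) / base)
    log_c_cys = split * logT
    log_c_cr = logT - log_c_cys
    c_cys = np.exp(log_c_cys)
    c_cr = np.exp(log_c_cr)
    scys = np.where(c_cys >= 1.0, 0.8 * c_cys ** (-1.0 / 0.375),
                    0.8 * c_cys ** (-1.0 / 0.711))
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.248, -0.207)
    scr = np.where(c_cr >= 1.0, kappa * c_cr ** (1.0 / alpha),
                   kappa * c_cr ** (-1.0 / 0.601))
    return scr, scys


def simulate_individual(cfg: SimulationConfig, seed=None):
    """Simulate a biobank-style cohort for one-sample allele-score MR.

    Dosages are Binomial(2, f) (optionally block-correlated); log-eGFR is
    built from a planted effect of the standardized true-weight allele score
    (``score_effect_log_egfr`` per SD) plus age, sex, clinical-covariate and
    noise terms; serum creatinine and cystatin C are then solved so the
    2012 combined equation reproduces that eGFR exactly.  CKD follows the
    eGFR < 60 rule.  Returns ``(IndividualDataset, truth)``.
    """
    from .allele_score import IndividualDataset

    rng = _as_rng(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    n = cfg.n_cohort or cfg.n_out
    f, gamma, alpha, invalid = _draw_truth(cfg, rng, 1)
    f, gamma = f[0], gamma[0]
    G = _draw_dosages(cfg, f, n, rng)
    snp = [f"rs{i + 1}" for i in range(cfg.J)]

    raw_score = G @ gamma
    z_score = (raw_score - raw_score.mean()) / raw_score.std(ddof=0)

    age = rng.uniform(50.0, 65.0, n)
    female = rng.random(n) < 0.5
    bmi = rng.normal(27.4, 4.8, n)
    hypertension = (rng.random(n) < 0.30).astype(int)
    diabetes = (rng.random(n) < 0.05).astype(int)
    hyperchol = (rng.random(n) < 0.20).astype(int)
    tg = np.exp(rng.normal(np.log(1.5), 0.4, n))
    hdl = np.clip(rng.normal(1.45, 0.38, n), 0.4, None)
    ldl = np.clip(rng.normal(3.56, 0.87, n), 0.5, None)
    smoking = (rng.random(n) < 0.10).astype(int)
    pcs = rng.normal(size=(n, 10))

    log_egfr = (np.log(92.0)
                - 0.004 * (age - 57.5)
                - 0.01 * female
                - 0.002 * (bmi - 27.4)
                - 0.03 * hypertension
                - 0.05 * diabetes
                + cfg.score_effect_log_egfr * z_score
                + rng.normal(0.0, 0.22, n))
    egfr = np.exp(log_egfr)
    split = rng.uniform(0.4, 0.6, n)
    scr, scys = _invert_ckd_epi(egfr, age, female, split)

    ph = pd.DataFrame({
        "scr": scr, "scys": scys, "age": age,
        "sex": np.where(female, "female", "male"),
        "bmi": bmi, "hypertension": hypertension, "diabetes": diabetes,
        "hypercholesterolemia": hyperchol, "tg": tg, "hdl": hdl, "ldl": ldl,
        "smoking": smoking,
        **{f"pc{i + 1}": pcs[:, i] for i in range(10)},
    })
    dosages = pd.DataFrame(G, columns=snp)
    data = IndividualDataset(dosages, ph, {s: "A" for s in snp})
    truth = SimulationTruth(
        f, gamma, np.zeros(cfg.J), np.zeros(cfg.J, bool), cfg.beta_true,
        None, seed_int,
        extras={"score_effect_log_egfr": cfg.score_effect_log_egfr,
                "ckd_prevalence": float((egfr < 60).mean())})
    return data, truth
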