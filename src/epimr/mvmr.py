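"""Multivariable MR and difference-method mediation.

Conditioning the SNP-outcome effects on a mediator's SNP associations gives
the *direct* effect of the exposure; subtracting it from the univariable
(total) effect gives the *indirect* effect carried by the mediator, and
indirect/total the proportion mediated.  This is the "difference method":

    indirect = total - direct,    proportion = indirect / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimationError, MREstimate, _normal_estimate
from .gwas_io import HarmonizedSet, SummaryTable, harmonize

MV_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_med", "se_med", "beta_out", "se_out"]


@dataclass
class HarmonizedMVSet:
    """SNP associations with exposure (gamma), mediator (delta) and outcome
    (Gamma), all on one shared effect-allele orientation."""

    df: pd.DataFrame
    exposure_label: str = ""
    mediator_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.df = self.df[MV_COLUMNS].reset_index(drop=True)
        if (self.df[["se_exp", "se_med", "se_out"]] <= 0).any().any():
            raise EstimationError("all SEs in a multivariable set must be positive")

    def __len__(self) -> int:
        return len(self.df)

    def arrays(self):
        d = self.df
        return (d["beta_exp"].to_numpy(float), d["beta_med"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))


def harmonize_mv(exposure: SummaryTable, mediator: SummaryTable, outcome: SummaryTable,
                 **harmonize_kwargs) -> HarmonizedMVSet:
    """Build a multivariable set from three summary tables.

    The exposure-outcome and exposure-mediator pairs are harmonized onto the
    exposure's effect-allele frame; SNPs retained in both are kept.
    """
    ho = harmonize(exposure, outcome, **harmonize_kwargs)
    hm = harmonize(exposure, mediator, **harmonize_kwargs)
    ro = ho.retained.set_index("snp")
    rm = hm.retained.set_index("snp")
    common = ro.index.intersection(rm.index)
    if len(common) == 0:
        raise EstimationError("no SNPs shared across exposure, mediator, and outcome")
    # both pairs were oriented on the exposure frame (same orient rule), so
    # mediator betas align with the outcome rows by construction
    df = pd.DataFrame({
        "snp": common,
        "beta_exp": ro.loc[common, "beta_exp"].to_numpy(),
        "se_exp": ro.loc[common, "se_exp"].to_numpy(),
        "beta_med": rm.loc[common, "beta_out"].to_numpy(),
        "se_med": rm.loc[common, "se_out"].to_numpy(),
        "beta_out": ro.loc[common, "beta_out"].to_numpy(),
        "se_out": ro.loc[common, "se_out"].to_numpy(),
    })
    return HarmonizedMVSet(df, exposure.trait_label, mediator.trait_label, outcome.trait_label)


def mvmr_ivw(mv: HarmonizedMVSet) -> tuple[MREstimate, MREstimate]:
    """Multivariable IVW: weighted regression of Gamma on (gamma, delta)
    without intercept, weights 1/se_Gamma^2.

    Returns (exposure estimate, mediator estimate); the exposure coefficient
    is its *direct* effect conditional on the mediator.  SEs come from the
    weighted normal equations inflated by sqrt(max(1, RSS_w/(J-2))) —
    multiplicative overdispersion as in univariable IVW.
    """
    g, d, G, seG = mv.arrays()
    J = g.size
    if J < 3:
        raise EstimationError("multivariable IVW needs >= 3 SNPs")
    w = 1.0 / seG**2
    if np.allclose(d, 0.0):
        # degenerate reduction: no mediator signal at any SNP, the exposure
        # coefficient is exactly the univariable IVW slope
        s2 = np.sum(w * g * g)
        beta = float(np.sum(w * g * G) / s2)
        rss_w = float(np.sum(w * (G - beta * g) ** 2))
        se = float(np.sqrt(max(1.0, rss_w / (J - 2)) / s2))
        est_exp = _normal_estimate("MVMR-IVW", beta, se, J)
        est_med = MREstimate("MVMR-IVW (mediator)", 0.0, np.nan, np.nan,
                             np.nan, np.nan, J)
        return est_exp, est_med
    X = np.column_stack([g, d])
    XtW = X.T * w
    A = XtW @ X
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise EstimationError("mediator instrument collinear with exposure "
                              f"(condition number {cond:.3g})")
    coef = np.linalg.solve(A, XtW @ G)
    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    infl = max(1.0, rss_w / (J - 2))
    cov = np.linalg.inv(A) * infl
    ses = np.sqrt(np.diag(cov))
    est_exp = _normal_estimate("MVMR-IVW", coef[0], ses[0], J)
    est_med = _normal_estimate("MVMR-IVW (mediator)", coef[1], ses[1], J)
    return est_exp, est_med


@dataclass
class MediationResult:
    """Difference-method decomposition total = direct + indirect.

    ``proportion`` is indirect/total (None when |total| is below
    ``tol``); the indirect-effect SE assumes independence of the total and
    direct estimates (an approximation: the samples overlap), with a
    parametric-bootstrap alternative for the proportion CI.
    """

    total: float
    direct: float
    indirect: float
    proportion: float | None
    total_ci: tuple
    direct_ci: tuple
    indirect_se: float
    indirect_ci: tuple
    proportion_ci: tuple | None = None

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion

    def to_dict(self) -> dict:
        return {
            "total": self.total, "direct": self.direct, "indirect": self.indirect,
            "proportion": self.proportion, "proportion_pct": self.proportion_pct,
            "total_ci": list(self.total_ci), "direct_ci": list(self.direct_ci),
            "indirect_se": self.indirect_se, "indirect_ci": list(self.indirect_ci),
            "proportion_ci": None if self.proportion_ci is None else list(self.proportion_ci),
        }


def mediation_difference(total: MREstimate, direct: MREstimate, tol: float = 1e-12,
                         n_boot: int = 0,
                         seed: int | np.random.Generator | None = None) -> MediationResult:
    """Decompose a total effect into direct + indirect via the difference
    method.

    indirect = total.beta - direct.beta; its SE is
    sqrt(se_total^2 + se_direct^2) under the independence approximation.
    With ``n_boot`` > 0 a parametric bootstrap (independent normals around
    the two estimates) supplies a percentile CI for the proportion mediated.
    """
    z = stats.norm.ppf(0.975)
    indirect = total.beta - direct.beta
    se_ind = float(np.hypot(total.se, direct.se))
    proportion = None if abs(total.beta) <= tol else indirect / total.beta
    prop_ci = None
    if n_boot > 0 and proportion is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        tb = rng.normal(total.beta, total.se, n_boot)
        db = rng.normal(direct.beta, direct.se, n_boot)
        props = (tb - db) / tb
        prop_ci = tuple(np.percentile(props, [2.5, 97.5]))
    return MediationResult(
        total=total.beta, direct=direct.beta, indirect=indirect, proportion=proportion,
        total_ci=(total.ci_low, total.ci_high),
        direct_ci=(direct.ci_low, direct.ci_high),
        indirect_se=se_ind,
        indirect_ci=(indirect - z * se_ind, indirect + z * se_ind),
        proportion_ci=prop_ci,
    )
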