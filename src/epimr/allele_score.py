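"""One-sample allele-score MR on individual-level data.

Phenotype derivation (the 2012 combined creatinine-cystatin C estimating
equation for GFR and the eGFR < 60 ml/min/1.73 m^2 definition of chronic
kidney disease), weighted allele-score construction from genotype dosages,
and covariate-adjusted association models: linear regression for log-eGFR,
logistic regression for CKD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gwas_io import SummaryTable

logger = logging.getLogger("epimr")

#: Model 1 adjusts for demographics and ancestry; Model 2 adds clinical covariates.
MODEL1_COVARIATES = ["age", "sex"] + [f"pc{i}" for i in range(1, 11)]
MODEL2_EXTRA = ["hypertension", "diabetes", "hypercholesterolemia",
                "bmi", "tg", "hdl", "ldl", "smoking"]
CKD_EGFR_THRESHOLD = 60.0


class PhenotypeError(ValueError):
    pass


def ckd_epi_egfr(scr, scys, age, sex, race_black=None, apply_race_coefficient=False):
    """Estimated GFR (ml/min/1.73 m^2) from the 2012 combined
    creatinine-cystatin C equation.

    egfr = 135 * min(scr/k, 1)^a * max(scr/k, 1)^-0.601
               * min(scys/0.8, 1)^-0.375 * max(scys/0.8, 1)^-0.711
               * 0.995^age * (0.969 if female) [* 1.08 if Black]

    with k = 0.7 (female) / 0.9 (male) and a = -0.248 (female) / -0.207
    (male).  ``scr`` in mg/dL, ``scys`` in mg/L, ``age`` in years, ``sex``
    "male"/"female" (or 1 = female).  The race coefficient is off by
    default (configurable).
    """
    scr = np.asarray(scr, float)
    scys = np.asarray(scys, float)
    age = np.asarray(age, float)
    if np.any(scr <= 0) or np.any(scys <= 0):
        raise PhenotypeError("serum creatinine and cystatin C must be positive")
    if np.any(age < 18):
        raise PhenotypeError("equation is for adults (age >= 18)")
    female = _female_mask(sex, scr.shape)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.248, -0.207)
    r_cr = scr / kappa
    r_cys = scys / 0.8
    egfr = (135.0
            * np.minimum(r_cr, 1.0) ** alpha
            * np.maximum(r_cr, 1.0) ** -0.601
            * np.minimum(r_cys, 1.0) ** -0.375
            * np.maximum(r_cys, 1.0) ** -0.711
            * 0.995 ** age
            * np.where(female, 0.969, 1.0))
    if apply_race_coefficient:
        if race_black is None:
            raise PhenotypeError("race_black required when applying the race coefficient")
        egfr = egfr * np.where(np.asarray(race_black, bool), 1.08, 1.0)
    return egfr


def _female_mask(sex, shape):
    sex_arr = np.asarray(sex)
    if sex_arr.dtype.kind in "UO":
        female = np.char.lower(sex_arr.astype(str)) == "female"
    else:
        female = sex_arr.astype(bool)
    return np.broadcast_to(female, shape)


@dataclass
class IndividualDataset:
    """Genotype dosages plus phenotypes/covariates for one-sample MR.

    ``dosages`` has one column per SNP (values in [0, 2], additive coding of
    the counted allele); ``dosage_alleles`` maps SNP id -> counted allele.
    ``phenotypes`` carries scr (mg/dL), scys (mg/L), age, sex, the Model-2
    covariates, and pc1..pc10.  eGFR, log_egfr, and the CKD flag are derived
    on construction from the biomarkers.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    dosage_alleles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.dosages.to_numpy(float)
        if d.size and (d.min() < 0 or d.max() > 2):
            raise PhenotypeError("dosages must lie in [0, 2]")
        if len(self.dosages) != len(self.phenotypes):
            raise PhenotypeError("dosage and phenotype tables differ in length")
        ph = self.phenotypes
        if "egfr" not in ph.columns:
            ph = ph.copy()
            ph["egfr"] = ckd_epi_egfr(ph["scr"], ph["scys"], ph["age"], ph["sex"])
            ph["log_egfr"] = np.log(ph["egfr"])
            ph["ckd"] = (ph["egfr"] < CKD_EGFR_THRESHOLD).astype(int)
            self.phenotypes = ph

    def __len__(self) -> int:
        return len(self.phenotypes)

    @classmethod
    def from_files(cls, dosage_path, phenotype_path) -> "IndividualDataset":
        """Read a PLINK .raw-style dosage table (FID, IID, then SNP_A
        columns) or a plain TSV of SNP columns, plus a phenotype TSV."""
        dos = pd.read_csv(dosage_path, sep="\t")
        alleles = {}
        drop = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in dos.columns]
        dos = dos.drop(columns=drop)
        rename = {}
        for col in dos.columns:
            if "_" in col:  # PLINK convention: SNPID_countedallele
                snp, _, allele = col.rpartition("_")
                if allele in "ACGT":
                    rename[col] = snp
                    alleles[snp] = allele
        dos = dos.rename(columns=rename)
        ph = pd.read_csv(phenotype_path, sep="\t")
        return cls(dos, ph, alleles)


@dataclass
class AlleleScore:
    """Weighted allele score s_i = sum_j beta_j d_ij and its z-scored form."""

    raw: np.ndarray
    standardized: np.ndarray
    snps: list
    flipped: list = field(default_factory=list)


def build_allele_score(data: IndividualDataset, instrument: SummaryTable) -> AlleleScore:
    """Per-participant score: effect size times dosage, summed over the
    instrument's SNPs, then z-score standardized.

    A SNP whose counted dosage allele is the instrument's *other* allele is
    flipped via d -> 2 - d (logged); this leaves standardized scores exactly
    unchanged.  Missing SNPs or a zero-variance score raise.
    """
    missing = [s for s in instrument.snps if s not in data.dosages.columns]
    if missing:
        raise PhenotypeError(f"instrument SNPs absent from dosage matrix: {missing}")
    raw = np.zeros(len(data))
    flipped = []
    for row in instrument.df.itertuples(index=False):
        d = data.dosages[row.snp].to_numpy(float)
        counted = data.dosage_alleles.get(row.snp, row.ea)
        if counted == row.ea:
            pass
        elif counted == row.oa:
            d = 2.0 - d
            flipped.append(row.snp)
        else:
            raise PhenotypeError(
                f"{row.snp}: dosage counts allele {counted}, not in instrument pair "
                f"{row.ea}/{row.oa}")
        raw += row.beta * d
    if flipped:
        logger.info("allele score: flipped dosage orientation for %s", flipped)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise PhenotypeError("allele score has zero variance")
    z = (raw - raw.mean()) / sd
    return AlleleScore(raw, z, list(instrument.snps), flipped)


def rank_inverse_normal(x, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom-type offset); offered as an
    alternative reading of "standard normal transformed" scores."""
    x = np.asarray(x, float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


@dataclass
class AssociationResult:
    """Covariate-adjusted association of the allele score with an outcome.

    ``beta`` is per 1 SD of the score; for the binary outcome the estimate
    is also reported as an odds ratio (the model is logistic regression).
    """

    outcome: str
    model: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int
    odds_ratio: float | None = None
    or_ci: tuple | None = None


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # identify columns linearly dependent on their predecessors
        offending = []
        for k in range(1, X.shape[1]):
            sub = arr[:, : k + 1]
            if np.linalg.matrix_rank(sub) <= np.linalg.matrix_rank(arr[:, :k]):
                offending.append(X.columns[k])
        raise PhenotypeError(f"singular design matrix; offending column(s): {offending}")


def score_association(score: AlleleScore, data: IndividualDataset,
                      outcome: str = "log_egfr", model: int = 1) -> AssociationResult:
    """Regress the outcome on the standardized allele score with covariate
    adjustment.

    Model 1 adjusts for age, sex, and 10 ancestry principal components;
    Model 2 additionally for hypertension, diabetes, hypercholesterolemia,
    BMI, lipid measures (TG/HDL/LDL) and smoking.  log-eGFR uses ordinary
    least squares; CKD uses logistic regression with effects reported on the
    odds scale.
    """
    if outcome not in ("log_egfr", "ckd"):
        raise PhenotypeError("outcome must be 'log_egfr' or 'ckd'")
    if model not in (1, 2):
        raise PhenotypeError("model must be 1 or 2")
    ph = data.phenotypes
    covars = MODEL1_COVARIATES + (MODEL2_EXTRA if model == 2 else [])
    missing = [c for c in covars + [outcome] if c not in ph.columns]
    if missing:
        raise PhenotypeError(f"phenotype table lacks column(s): {missing}")
    X = ph[covars].copy()
    if X["sex"].dtype.kind in "UO":
        X["sex"] = (X["sex"].str.lower() == "female").astype(float)
    X.insert(0, "score", score.standardized)
    X.insert(0, "const", 1.0)
    _check_design(X)
    y = ph[outcome].to_numpy(float)
    if outcome == "log_egfr":
        fit = sm.OLS(y, X).fit()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception as exc:  # perfect separation and kin
                raise PhenotypeError(f"logistic fit failed: {exc}") from exc
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    z = stats.norm.ppf(0.975)
    lo, hi = beta - z * se, beta + z * se
    res = AssociationResult(outcome, model, beta, se, lo, hi,
                            float(fit.pvalues["score"]), int(len(y)))
    if outcome == "ckd":
        res.odds_ratio = float(np.exp(beta))
        res.or_ci = (float(np.exp(lo)), float(np.exp(hi)))
    return res
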