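"""Bidirectional analysis orchestration, effect scaling, FDR, and reports.

A run is organised as directions (e.g. "forward": epigenetic-clock
exposures against kidney outcomes; "reverse": kidney instruments against
clock outcomes).  Each exposure-outcome pair goes through instrument
construction, harmonization, Steiger filtering, Rücker model selection,
the sensitivity suite (weighted median, MR-PRESSO, leave-one-out), and
strength diagnostics; effects are rescaled to the reporting unit (e.g. per
5 years of age acceleration, odds scale for binary outcomes) and p-values
are Benjamini-Hochberg adjusted within the configured family (default: the
exposures of one outcome within one direction).  Identical config + seed
reproduce byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from . import instruments as instr
from .gwas_io import SummaryTable, harmonize, read_summary_stats

logger = logging.getLogger("epimr")


class PipelineError(RuntimeError):
    pass


def scale_effect(e: est.MREstimate, factor: float = 1.0,
                 odds_scale: bool = False) -> est.MREstimate:
    """Rescale an estimate to a reporting unit.

    ``factor`` multiplies beta, SE and CI (e.g. 5 to report per 5-year
    increase in a clock exposure); with ``odds_scale`` the scaled point and
    CI are exponentiated to odds ratios.  The p-value is unchanged by
    either operation.
    """
    if factor <= 0:
        raise PipelineError("scale factor must be positive")
    beta = e.beta * factor
    se = e.se * factor
    lo = e.ci_low * factor
    hi = e.ci_high * factor
    if odds_scale:
        beta, lo, hi = np.exp(beta), np.exp(lo), np.exp(hi)
    scaled = dataclasses.replace(e, beta=float(beta), se=float(se),
                                 ci_low=float(lo), ci_high=float(hi))
    return scaled


def fdr_adjust(pvalues, method: str = "BH") -> list:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = list(pvalues)
    if not p:
        return []
    if method != "BH":
        raise PipelineError("only BH adjustment is supported")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """One summary-statistics input: path plus reading options."""

    path: str
    trait_type: str = "continuous"
    column_map: dict = field(default_factory=dict)
    scale_factor: float = 1.0  # reporting multiple of the exposure unit


@dataclass
class DirectionConfig:
    name: str
    exposures: dict  # label -> DatasetSpec
    outcomes: dict   # label -> DatasetSpec


@dataclass
class AnalysisConfig:
    """Full configuration of a bidirectional run (YAML-loadable)."""

    directions: list
    seed: int
    output_dir: str = "."
    ld_path: str | None = None
    exclusion_path: str | None = None
    p_threshold: float = 5e-8
    window_kb: float = 500.0
    r2_max: float = 0.1
    palindrome_eaf_window: float = 0.08
    steiger_mode: str = "point-estimate"
    n_boot: int = 1000
    n_presso_sim: int = 1000
    run_presso: bool = True
    run_loo: bool = True
    fdr_family: str = "per-outcome"  # or "pooled"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise PipelineError("config must set a seed (reproducibility contract)")
        directions = []
        for d in raw.pop("directions"):
            directions.append(DirectionConfig(
                name=d["name"],
                exposures={k: DatasetSpec(**v) if isinstance(v, dict) else DatasetSpec(v)
                           for k, v in d["exposures"].items()},
                outcomes={k: DatasetSpec(**v) if isinstance(v, dict) else DatasetSpec(v)
                          for k, v in d["outcomes"].items()},
            ))
        return cls(directions=directions, **raw)

    def canonical_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-pair analysis
# ---------------------------------------------------------------------------

@dataclass
class PairResult:
    direction: str
    exposure: str
    outcome: str
    ok: bool
    error: str | None = None
    selection: est.ModelSelectionResult | None = None
    primary_scaled: est.MREstimate | None = None
    weighted_median: est.MREstimate | None = None
    presso: est.PressoResult | None = None
    strength: instr.StrengthStats | None = None
    directionality: est.DirectionalityResult | None = None
    loo: list = field(default_factory=list)
    n_snps: int = 0
    p_raw: float | None = None
    p_fdr: float | None = None

    def row(self) -> dict:
        r = {"direction": self.direction, "exposure": self.exposure,
             "outcome": self.outcome, "ok": self.ok, "error": self.error or "",
             "n_snps": self.n_snps}
        if self.ok:
            sel = self.selection
            pr = self.primary_scaled
            r.update({
                "primary_method": sel.chosen_method,
                "beta": pr.beta, "se": pr.se,
                "ci_low": pr.ci_low, "ci_high": pr.ci_high,
                "p": self.p_raw, "p_fdr": self.p_fdr,
                "nominal_sig": self.p_raw < 0.05,
                "fdr_sig": self.p_fdr < 0.05 if self.p_fdr is not None else None,
                "egger_intercept_p": sel.egger_estimate.intercept_p,
                "q": sel.heterogeneity.q, "q_prime": sel.heterogeneity.q_prime,
                "p_q_diff": sel.p_diff,
                "wm_beta": self.weighted_median.beta if self.weighted_median else np.nan,
                "wm_p": self.weighted_median.pvalue if self.weighted_median else np.nan,
                "presso_global_p": self.presso.global_p if self.presso else np.nan,
                "presso_n_outliers": len(self.presso.outlier_ids) if self.presso else 0,
                "f_mean": self.strength.f_mean,
                "i2_gx": self.strength.i2_gx if self.strength.i2_gx is not None else np.nan,
                "steiger_valid": self.directionality.valid,
                "steiger_p": self.directionality.steiger_p,
            })
        return r


def analyse_pair(exposure: SummaryTable, outcome: SummaryTable,
                 cfg: AnalysisConfig, seed: int,
                 ld: instr.LDInfo | None = None,
                 excluded: set | None = None,
                 scale_factor: float = 1.0) -> dict:
    """Run the full estimator/sensitivity suite for one harmonized pair."""
    ld = ld or instr.LDInfo()
    instrument = instr.select_and_clump(exposure, ld, cfg.p_threshold,
                                        cfg.window_kb, cfg.r2_max)
    if excluded:
        instrument = instr.apply_exclusion_list(instrument, excluded, ld)
    if len(instrument) == 0:
        raise PipelineError("no instrument SNPs pass the significance threshold")
    h = harmonize(instrument, outcome, cfg.palindrome_eaf_window)
    h, steiger_res = instr.steiger_filter(h, mode=cfg.steiger_mode)
    if h.n_retained < 3:
        raise PipelineError(f"only {h.n_retained} SNPs retained; need >= 3")
    rng = np.random.default_rng(seed)
    selection = est.rucker_select(h)
    wm = est.weighted_median(h, n_boot=cfg.n_boot, seed=rng)
    presso = None
    if cfg.run_presso and h.n_retained >= 4:
        presso = est.mr_presso(h, n_sim=cfg.n_presso_sim, seed=rng)
    strength = instr.instrument_strength(h)
    direction = est.steiger_directionality(h)
    loo = est.leave_one_out(h, "ivw") if cfg.run_loo else []
    odds = outcome.trait_type == "binary"
    primary_scaled = scale_effect(selection.primary, scale_factor, odds_scale=odds)
    return {"harmonized": h, "selection": selection, "weighted_median": wm,
            "presso": presso, "strength": strength, "directionality": direction,
            "loo": loo, "primary_scaled": primary_scaled,
            "steiger_per_snp": steiger_res}


@dataclass
class ResultsBundle:
    config_hash: str
    seed: int
    pairs: list  # PairResult
    version: str = ""

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([p.row() for p in self.pairs])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df = self.table()
        float_cols = df.select_dtypes("float").columns
        df[float_cols] = df[float_cols].round(10)  # stable text repr
        df.to_csv(outdir / "results.tsv", sep="\t", index=False)
        payload = {
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version,
            "pairs": [_jsonify(p.row()) for p in self.pairs],
        }
        (outdir / "results.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _jsonify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, float)):
            out[k] = None if not np.isfinite(v) else round(float(v), 10)
        elif isinstance(v, (np.bool_, bool)):
            out[k] = bool(v)
        elif isinstance(v, (np.integer, int)):
            out[k] = int(v)
        else:
            out[k] = v
    return out


def run_bidirectional(cfg: AnalysisConfig) -> ResultsBundle:
    """Execute every configured exposure-outcome pair and assemble reports.

    Failures are isolated: a pair whose inputs are missing or whose
    instrument collapses is marked failed and the run continues.  Per-pair
    seeds are split deterministically from the configured master seed.
    """
    from . import __version__

    ld = instr.LDInfo.from_tsv(cfg.ld_path) if cfg.ld_path else instr.LDInfo()
    excluded = instr.read_exclusion_list(cfg.exclusion_path) if cfg.exclusion_path else set()
    root = np.random.SeedSequence(cfg.seed)
    pairs = []
    fdr_groups: dict[tuple, list[int]] = {}
    pair_index = 0
    for direction in cfg.directions:
        for exp_label, exp_spec in direction.exposures.items():
            for out_label, out_spec in direction.outcomes.items():
                pair_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
                try:
                    exposure = read_summary_stats(exp_spec.path, exp_spec.column_map,
                                                  exp_spec.trait_type, exp_label)
                    outcome = read_summary_stats(out_spec.path, out_spec.column_map,
                                                 out_spec.trait_type, out_label)
                    res = analyse_pair(exposure, outcome, cfg, pair_seed, ld,
                                       excluded, exp_spec.scale_factor)
                    pr = PairResult(
                        direction.name, exp_label, out_label, True,
                        selection=res["selection"],
                        primary_scaled=res["primary_scaled"],
                        weighted_median=res["weighted_median"],
                        presso=res["presso"], strength=res["strength"],
                        directionality=res["directionality"], loo=res["loo"],
                        n_snps=res["harmonized"].n_retained,
                        p_raw=float(res["selection"].primary.pvalue))
                    if cfg.plots:
                        _pair_plots(res, Path(cfg.output_dir) / "plots",
                                    f"{direction.name}_{exp_label}_{out_label}")
                except Exception as exc:  # isolation contract
                    logger.warning("pair %s/%s -> %s failed: %s",
                                   direction.name, exp_label, out_label, exc)
                    pr = PairResult(direction.name, exp_label, out_label, False,
                                    error=str(exc))
                pairs.append(pr)
                key = (direction.name,) if cfg.fdr_family == "pooled" \
                    else (direction.name, out_label)
                fdr_groups.setdefault(key, []).append(pair_index)
                pair_index += 1

    for key, idxs in fdr_groups.items():
        ok_idx = [i for i in idxs if pairs[i].ok]
        if not ok_idx:
            continue
        adj = fdr_adjust([pairs[i].p_raw for i in ok_idx])
        for i, a in zip(ok_idx, adj):
            pairs[i].p_fdr = a

    bundle = ResultsBundle(cfg.config_hash, cfg.seed, pairs, __version__)
    bundle.write(cfg.output_dir)
    return bundle


# ---------------------------------------------------------------------------
# Plots (forest, funnel, leave-one-out)
# ---------------------------------------------------------------------------

def _pair_plots(res: dict, outdir: Path, stem: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    h = res["harmonized"]
    ratios = est.wald_ratios(h)

    fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * len(ratios))))
    ys = np.arange(len(ratios))
    ax.errorbar([r.beta for r in ratios], ys,
                xerr=1.96 * np.array([r.se for r in ratios]), fmt="o", ms=3)
    ax.axvline(res["selection"].primary.beta, color="crimson", lw=1)
    ax.set_yticks(ys, [r.snp_id for r in ratios], fontsize=6)
    ax.set_xlabel("per-SNP causal estimate")
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}_forest.svg", metadata={"Date": None})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter([r.beta for r in ratios], [1 / r.se for r in ratios], s=10)
    ax.axvline(res["selection"].primary.beta, color="crimson", lw=1)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("1 / SE")
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}_funnel.svg", metadata={"Date": None})
    plt.close(fig)

    if res["loo"]:
        fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * len(res["loo"]))))
        ys = np.arange(len(res["loo"]))
        ax.errorbar([e.beta for _, e in res["loo"]], ys,
                    xerr=1.96 * np.array([e.se for _, e in res["loo"]]),
                    fmt="o", ms=3)
        ax.set_yticks(ys, [s for s, _ in res["loo"]], fontsize=6)
        ax.set_xlabel("estimate excluding SNP")
        fig.tight_layout()
        fig.savefig(outdir / f"{stem}_loo.svg", metadata={"Date": None})
        plt.close(fig)
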