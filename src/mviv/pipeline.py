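"""End-to-end two-sample MR workflows on summary-statistics tables.

``mr_pipeline`` mirrors the standard applied workflow: genome-wide-significant
instrument selection, FIQT winner's-curse correction, distance/LD clumping,
optional per-SD standardisation, allele harmonisation, then the four
univariable estimators plus Cochran's Q. ``mvmr_pipeline`` is the
multivariable analogue: instruments associated with either exposure,
union-clumped, with the multivariable estimator suite and per-exposure
conditional F-statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from .errors import EmptyResultError
from .gwas import SummaryStats, read_sumstats
from .instruments import (
    HarmonisedSet, IdentityLD, LDProvider,
    clump, fiqt_correct, harmonise, select_instruments, standardise,
)

log = logging.getLogger("mviv")

__all__ = ["PipelineConfig", "mr_pipeline", "mvmr_pipeline"]


@dataclass
class PipelineConfig:
    """Stage thresholds of the applied workflow.

    ``standardise_divisor`` rescales the exposure betas/SEs to a per-SD
    scale when set (e.g. 0.6940093 for the published lifetime-smoking
    score); left off by default since the constant is trait-specific.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    standardise_divisor: float | None = None
    fiqt: bool = True
    fiqt_before_clump: bool = True
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if self.standardise_divisor is not None and self.standardise_divisor <= 0:
            raise ValueError("standardise_divisor must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _as_stats(obj, trait: str) -> SummaryStats:
    if isinstance(obj, SummaryStats):
        return obj
    return read_sumstats(obj, trait=trait)


def _process_exposure(stats_in: SummaryStats, config: PipelineConfig,
                      ld: LDProvider) -> SummaryStats:
    """select -> FIQT -> clump -> standardise on one exposure table."""
    out = select_instruments(stats_in, config.p_threshold)
    log.info("selection: %d/%d variants pass p < %g",
             len(out), len(stats_in), config.p_threshold)
    if config.fiqt and config.fiqt_before_clump:
        out = fiqt_correct(out)
    out = clump(out, config.clump_r2, config.clump_kb, ld)
    log.info("clumping (r2 >= %g within %d kb): %d retained",
             config.clump_r2, config.clump_kb, len(out))
    if config.fiqt and not config.fiqt_before_clump:
        out = fiqt_correct(out)
    if config.standardise_divisor is not None:
        out = standardise(out, config.standardise_divisor)
        log.info("standardised betas/SEs by %g", config.standardise_divisor)
    return out


def _run_uv_suite(h: HarmonisedSet, config: PipelineConfig) -> list[est.MRResult]:
    results = [est.ivw(h)]
    if len(h) >= 3:
        results.append(est.mr_egger(h))
        results.append(est.weighted_median(h, n_boot=config.n_boot, seed=config.seed))
        results.append(est.weighted_mode(
            h, bandwidth_factor=config.bandwidth_factor,
            n_boot=config.n_boot, seed=config.seed))
    if len(h) >= 2:
        q, df, qp = est.cochran_q(h, results[0].estimate)
        results[0].q_statistic, results[0].q_pvalue = q, qp
    return results


def mr_pipeline(
    exposure, outcome, config: PipelineConfig | None = None,
    ld: LDProvider | None = None,
):
    """Univariable two-sample MR from exposure and outcome summary statistics.

    ``exposure``/``outcome`` are :class:`SummaryStats` or paths to
    tab-delimited tables. Returns ``(results, provenance, harmonised_set)``;
    ``provenance`` counts the variants dropped at each stage.
    """
    config = config or PipelineConfig()
    ld = ld or IdentityLD()
    exp = _as_stats(exposure, "exposure")
    out = _as_stats(outcome, "outcome")
    exp = _process_exposure(exp, config, ld)
    h = harmonise(exp, out, palindromic_eaf_band=config.palindromic_eaf_band)
    log.info("harmonised set: %d variants (provenance %s)", len(h), h.provenance)
    results = _run_uv_suite(h, config)
    return results, dict(h.provenance), h


def mvmr_pipeline(
    exposure, covariate, outcome, config: PipelineConfig | None = None,
    ld: LDProvider | None = None,
):
    """Multivariable two-sample MR with one exposure and one covariate.

    Instruments are variants genome-wide significant for *either* exposure;
    the union is clumped jointly (ranking by the smaller of the two
    p-values). FIQT and standardisation apply to the primary exposure table;
    FIQT also applies to the covariate table (both are selected-on-
    significance exposures in the multivariable model, hence both are
    winner's-curse prone).
    """
    config = config or PipelineConfig()
    ld = ld or IdentityLD()
    exp = _as_stats(exposure, "exposure")
    cov = _as_stats(covariate, "covariate")
    out = _as_stats(outcome, "outcome")

    p_exp = exp.data.set_index("variant_id")["pvalue"]
    p_cov = cov.data.set_index("variant_id")["pvalue"]
    shared = p_exp.index.intersection(p_cov.index)
    p_min = pd.concat([p_exp.loc[shared], p_cov.loc[shared]], axis=1).min(axis=1)
    sig = p_min.index[p_min < config.p_threshold]
    if len(sig) == 0:
        raise EmptyResultError(
            f"no variants associated with either exposure at p < {config.p_threshold:g}"
        )
    keep = exp.data["variant_id"].isin(set(sig)).to_numpy()
    exp_sel = exp.subset(keep)
    exp_sel.meta["n_not_significant"] = int(len(exp) - keep.sum())
    # clump on the union, ranking variants by their best p across exposures
    rank = exp_sel.copy()
    rank.data["pvalue"] = p_min.loc[rank.data["variant_id"]].to_numpy()
    clumped = clump(rank, config.clump_r2, config.clump_kb, ld)
    kept_ids = set(clumped.data["variant_id"])
    exp_sel = exp_sel.subset(exp_sel.data["variant_id"].isin(kept_ids).to_numpy())
    exp_sel.meta["n_clumped"] = clumped.meta.get("n_clumped", 0)

    if config.fiqt:
        exp_sel = fiqt_correct(exp_sel)
        cov = fiqt_correct(cov)
    if config.standardise_divisor is not None:
        exp_sel = standardise(exp_sel, config.standardise_divisor)

    h = harmonise(exp_sel, out, others=[cov],
                  palindromic_eaf_band=config.palindromic_eaf_band)
    log.info("harmonised multivariable set: %d variants (provenance %s)",
             len(h), h.provenance)

    results = est.mv_ivw(h)
    n, k = len(h), 2
    if n > k + 1:
        results += est.mv_egger(h)
        results += est.mv_median(h, n_boot=config.n_boot, seed=config.seed)
        results += est.mv_mode(h, bandwidth_factor=config.bandwidth_factor,
                               n_boot=config.n_boot, seed=config.seed)
    return results, dict(h.provenance), h


def write_results(results, path: str | Path) -> None:
    """Tidy tab-delimited estimator table."""
    est.results_to_frame(results).to_csv(path, sep="\t", index=False,
                                         float_format="%.12g")


def write_provenance(provenance: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2))
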