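"""Monte-Carlo study runner for the three-strategy bias comparison.

One replicate draws three non-overlapping samples under the structural model
(:mod:`mviv.dgp`), estimates the variant-exposure associations ``B_x`` in
sample 1, the variant-covariate associations ``B_p`` in sample 2 and the
variant-outcome associations ``B_y`` in sample 3, then applies each
estimation strategy:

``uv_adjusted``
    univariable IVW on the exposure variants, ``B_x``/``B_y`` from
    covariate-adjusted regressions — collider bias pulls the estimate down.
``uv_unadjusted``
    univariable IVW, no covariate adjustment — the pleiotropy/confounding
    channel through the covariate pushes the estimate up.
``mv_adjusted``
    multivariable IVW of ``B_y`` on ``(B_x, B_p)`` over all variants, with
    adjusted ``B_x``/``B_y`` — conditioning on the covariate's genetic
    associations closes both channels.

The performance measure is the mean bias (estimate − true effect) with its
Monte-Carlo standard error ``sd/sqrt(reps)``. Replicate seeds are spawned
deterministically from the master seed, so results are independent of worker
count and scheduling.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dgp import DGPConfig, simulate_cohorts
from .estimators import ivw, mv_ivw
from .gwas import run_gwas
from .instruments import HarmonisedSet

__all__ = ["StrategySpec", "SimulationReport", "run_replicate", "run_study",
           "STANDARD_STRATEGIES"]


@dataclass(frozen=True)
class StrategySpec:
    """One estimation strategy in the comparison."""

    name: str
    adjust_gwas_for_covariate: bool
    snp_set: str        # "exposure_snps_only" | "all_snps"
    estimator: str      # "ivw" | "mv_ivw"

    def __post_init__(self):
        if self.snp_set not in ("exposure_snps_only", "all_snps"):
            raise ValueError(f"unknown snp_set {self.snp_set!r}")
        if self.estimator not in ("ivw", "mv_ivw"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


STANDARD_STRATEGIES: tuple[StrategySpec, ...] = (
    StrategySpec("uv_adjusted", True, "exposure_snps_only", "ivw"),
    StrategySpec("uv_unadjusted", False, "exposure_snps_only", "ivw"),
    StrategySpec("mv_adjusted", True, "all_snps", "mv_ivw"),
)


@dataclass
class SimulationReport:
    """Per-strategy bias summary with full provenance."""

    strategies: list[str]
    mean_bias: dict[str, float]
    mc_se: dict[str, float]
    sd: dict[str, float]
    quantiles: dict[str, dict[str, float]]
    reps: int
    n_failed: int
    true_effect: float
    config: dict
    seed: int
    runtime_seconds: float
    estimates: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategies,
                "mean_bias": [self.mean_bias[s] for s in self.strategies],
                "mc_se": [self.mc_se[s] for s in self.strategies],
                "sd": [self.sd[s] for s in self.strategies],
                "reps": self.reps,
            }
        )

    def to_json(self, path: str | Path, include_estimates: bool = False) -> None:
        payload = asdict(self)
        if not include_estimates:
            payload.pop("estimates")
        Path(path).write_text(json.dumps(payload, indent=2))


def run_replicate(
    config: DGPConfig,
    strategies: Sequence[StrategySpec] = STANDARD_STRATEGIES,
    seed: int | None = None,
    screen_p: float | None = None,
) -> dict[str, float]:
    """One replicate: simulate three samples, run the GWASs, apply each strategy.

    Instrument sets default to the known causal index sets (the first
    ``n_exposure_snps`` variants for the univariable strategies, all variants
    for the multivariable one); ``screen_p`` optionally adds a significance
    screen on ``B_x`` within each strategy's variant set as a sensitivity
    option.
    """
    cohorts = simulate_cohorts(config, seed=seed, require_three_samples=True)
    s_exp, s_cov, s_out = cohorts[0], cohorts[1], cohorts[2]

    need_adj = any(s.adjust_gwas_for_covariate for s in strategies)
    need_unadj = any(not s.adjust_gwas_for_covariate for s in strategies)
    gw = {}
    if need_adj:
        gw[("x", True)] = run_gwas(s_exp, "exposure", adjust_for_covariate=True)
        gw[("y", True)] = run_gwas(s_out, "outcome", adjust_for_covariate=True)
    if need_unadj:
        gw[("x", False)] = run_gwas(s_exp, "exposure", adjust_for_covariate=False)
        gw[("y", False)] = run_gwas(s_out, "outcome", adjust_for_covariate=False)
    if any(s.estimator == "mv_ivw" for s in strategies):
        gw["p"] = run_gwas(s_cov, "covariate", adjust_for_covariate=False)

    k = config.n_exposure_snps
    estimates: dict[str, float] = {}
    for strat in strategies:
        bx = gw[("x", strat.adjust_gwas_for_covariate)]
        by = gw[("y", strat.adjust_gwas_for_covariate)]
        idx = np.arange(k if strat.snp_set == "exposure_snps_only" else config.n_snps)
        if screen_p is not None:
            p = bx.data["pvalue"].to_numpy()[idx]
            idx = idx[p < screen_p]
        # samples are simulated on aligned variants, so the harmonised set is
        # assembled directly without allele harmonisation
        h = HarmonisedSet(
            variant_ids=list(bx.data["variant_id"].iloc[idx]),
            exposure_beta=bx.data["beta"].to_numpy()[idx],
            exposure_se=bx.data["se"].to_numpy()[idx],
            outcome_beta=by.data["beta"].to_numpy()[idx],
            outcome_se=by.data["se"].to_numpy()[idx],
            covariate_beta=gw["p"].data["beta"].to_numpy()[idx]
            if strat.estimator == "mv_ivw" else None,
            covariate_se=gw["p"].data["se"].to_numpy()[idx]
            if strat.estimator == "mv_ivw" else None,
        )
        if strat.estimator == "ivw":
            estimates[strat.name] = ivw(h).estimate
        else:
            estimates[strat.name] = mv_ivw(h)[0].estimate
    return estimates


def _replicate_safe(config, strategies, seed, screen_p):
    try:
        return run_replicate(config, strategies, seed, screen_p)
    except Exception as exc:  # recorded, not silently dropped
        return {"__error__": repr(exc)}


def run_study(
    config: DGPConfig,
    reps: int,
    seed: int = 0,
    workers: int = 1,
    strategies: Sequence[StrategySpec] = STANDARD_STRATEGIES,
    screen_p: float | None = None,
    keep_estimates: bool = True,
    max_failure_fraction: float = 0.05,
) -> SimulationReport:
    """Run ``reps`` independent replicates and summarise the bias per strategy.

    Per-replicate seeds are derived from ``seed`` via
    ``numpy.random.SeedSequence.generate_state``, so the report is invariant
    to ``workers``. More than ``max_failure_fraction`` failed replicates
    aborts with a diagnostic.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    t0 = time.perf_counter()
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint32)
    results = Parallel(n_jobs=workers)(
        delayed(_replicate_safe)(config, tuple(strategies), int(s), screen_p)
        for s in rep_seeds
    )
    failures = [r["__error__"] for r in results if "__error__" in r]
    if len(failures) > max_failure_fraction * reps:
        raise RuntimeError(
            f"{len(failures)}/{reps} replicates failed; first error: {failures[0]}"
        )
    ok = [r for r in results if "__error__" not in r]
    truth = config.exposure_effect_on_outcome
    names = [s.name for s in strategies]
    est = {n: np.array([r[n] for r in ok]) for n in names}
    qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    report = SimulationReport(
        strategies=names,
        mean_bias={n: float(np.mean(est[n] - truth)) for n in names},
        mc_se={n: float(np.std(est[n], ddof=1) / np.sqrt(len(ok))) for n in names},
        sd={n: float(np.std(est[n], ddof=1)) for n in names},
        quantiles={
            n: {f"q{q:g}": float(v) for q, v in zip(qs, np.percentile(est[n], qs))}
            for n in names
        },
        reps=len(ok),
        n_failed=len(failures),
        true_effect=float(truth),
        config=asdict(config),
        seed=seed,
        runtime_seconds=time.perf_counter() - t0,
        estimates={n: est[n].tolist() for n in names} if keep_estimates else {},
    )
    return report
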