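"""Data-generating processes for collider/pleiotropy bias studies.

This module is the synthetic-data backbone of the package. It provides

* :func:`simulate_cohorts` — individual-level cohorts under a
  "damned if you do, damned if you don't" structure: a covariate ``P`` that is
  simultaneously a collider (conditioning on it opens a back-door path between
  the exposure's genetic score and the outcome's confounders) and, under the
  default ``pleiotropic`` variant, a pleiotropy channel (the exposure's
  instruments reach the outcome through ``P``, bypassing the exposure).
* :func:`simulate_sumstats_fixture` — four variant-aligned GWAS
  summary-statistics tables (exposure adjusted/unadjusted, covariate, outcome)
  emulating the structure of real two-sample MR inputs: mixed allele
  orientations, palindromic variants, and winner's-curse-inflated top hits.

Model
-----
With ``m`` variants (the first ``k`` of which instrument the exposure),
per-variant allele frequencies ``p_j ~ N(maf_mean, maf_sd^2)`` clipped to
(0.01, 0.99), dosages ``SNP_j ~ Binomial(2, p_j)``, confounders
``C1, C2 ~ N(0, 1)`` and per-variant effects ``beta_j, gamma_j ~
N(snp_effect_mean, snp_effect_sd^2)``:

.. code-block:: text

    E = a1*C1 + sum_{j<=k} beta_j*SNP_j + e1
    P = a2*C2 + G_P + e2
    Y = theta*E + c1*C1 + c2*C2 + b*P + e3

where ``G_P`` depends on ``structure_variant``:

``printed``
    ``G_P = sum_{j>k} gamma_j*SNP_j`` — the covariate has its own, disjoint
    instrument set; it is a pure collider and induces no bias in either
    univariable strategy.
``pleiotropic`` (default)
    ``G_P = sum_{j<=k} beta_j*SNP_j + sum_{j>k} gamma_j*SNP_j`` — the
    exposure's genetic score itself feeds the covariate (a single genetic
    liability node with arrows to both exposure and covariate), so the
    covariate is both pleiotropic and a collider. This is the structure whose
    estimator biases the simulation study reproduces.

All randomness flows from ``seed`` through ``numpy.random.SeedSequence``
substreams: effects/frequencies are drawn once per call and shared across the
(non-overlapping) samples; each sample gets an independent substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DGPConfig",
    "CohortData",
    "simulate_cohorts",
    "simulate_sumstats_fixture",
    "variant_table",
]

STRUCTURE_VARIANTS = ("printed", "pleiotropic")

#: allele pairs cycled over when synthesising non-palindromic variants
_NONPALINDROMIC_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("G", "C"))


@dataclass(frozen=True)
class DGPConfig:
    """Parameters of the individual-level data-generating process.

    Defaults are the study conditions of the headline simulation: 100
    independent variants, the first 50 instrumenting the exposure, three
    non-overlapping samples of 250,000 individuals, unit structural
    coefficients and unit noise.
    """

    n_snps: int = 100
    n_exposure_snps: int = 50
    n_individuals: int = 250_000
    n_samples: int = 3
    maf_mean: float = 0.5
    maf_sd: float = 0.1
    snp_effect_mean: float = 0.1
    snp_effect_sd: float = 0.05
    confounder_effect_on_exposure: float = 1.0
    confounder_effect_on_covariate: float = 1.0
    exposure_effect_on_outcome: float = 1.0
    covariate_effect_on_outcome: float = 1.0
    confounder_effects_on_outcome: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 1.0
    structure_variant: str = "pleiotropic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_exposure_snps", "n_individuals", "n_samples"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_exposure_snps > self.n_snps:
            raise ValueError(
                f"n_exposure_snps ({self.n_exposure_snps}) exceeds n_snps ({self.n_snps})"
            )
        if self.structure_variant not in STRUCTURE_VARIANTS:
            raise ValueError(
                f"structure_variant must be one of {STRUCTURE_VARIANTS}, "
                f"got {self.structure_variant!r}"
            )
        numeric = (
            self.maf_mean, self.maf_sd, self.snp_effect_mean, self.snp_effect_sd,
            self.confounder_effect_on_exposure, self.confounder_effect_on_covariate,
            self.exposure_effect_on_outcome, self.covariate_effect_on_outcome,
            *self.confounder_effects_on_outcome, self.noise_sd,
        )
        if not all(math.isfinite(float(v)) for v in numeric):
            raise ValueError("all DGPConfig coefficients must be finite")
        if self.noise_sd < 0 or self.maf_sd < 0 or self.snp_effect_sd < 0:
            raise ValueError("scale parameters must be non-negative")

    def with_(self, **kwargs) -> "DGPConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class CohortData:
    """One simulated sample: dosages plus the phenotypes built from them.

    ``true_snp_effects_*`` record the per-variant coefficients actually drawn
    for this replicate, enabling closed-form variance/F-statistic oracles.
    """

    genotypes: np.ndarray            # (n, m) int8 dosages in {0,1,2}
    confounders: np.ndarray          # (n, 2) — C1, C2
    exposure: np.ndarray             # (n,)
    covariate: np.ndarray            # (n,)
    outcome: np.ndarray              # (n,)
    true_snp_effects_exposure: np.ndarray    # (m,)
    true_snp_effects_covariate: np.ndarray   # (m,)
    allele_frequencies: np.ndarray | None = None  # (m,) drawn p_j
    sample_label: str = "sample"

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def permuted(self, order: np.ndarray) -> "CohortData":
        """Reorder individuals; summary statistics are invariant to this."""
        return CohortData(
            genotypes=self.genotypes[order],
            confounders=self.confounders[order],
            exposure=self.exposure[order],
            covariate=self.covariate[order],
            outcome=self.outcome[order],
            true_snp_effects_exposure=self.true_snp_effects_exposure,
            true_snp_effects_covariate=self.true_snp_effects_covariate,
            allele_frequencies=self.allele_frequencies,
            sample_label=self.sample_label,
        )

    def to_frame(self) -> pd.DataFrame:
        """Rectangular table, one row per individual (debugging/IO)."""
        df = pd.DataFrame(
            {
                "C1": self.confounders[:, 0],
                "C2": self.confounders[:, 1],
                "exposure": self.exposure,
                "covariate": self.covariate,
                "outcome": self.outcome,
            }
        )
        snp_cols = pd.DataFrame(
            self.genotypes,
            columns=[f"snp{j + 1:04d}" for j in range(self.n_snps)],
            index=df.index,
        )
        return pd.concat([df, snp_cols], axis=1)

    def write_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_table(cls, path: str | Path, sample_label: str = "sample") -> "CohortData":
        df = pd.read_csv(path, sep="\t")
        snp_cols = [c for c in df.columns if c.startswith("snp")]
        m = len(snp_cols)
        return cls(
            genotypes=df[snp_cols].to_numpy(dtype=np.int8),
            confounders=df[["C1", "C2"]].to_numpy(dtype=float),
            exposure=df["exposure"].to_numpy(dtype=float),
            covariate=df["covariate"].to_numpy(dtype=float),
            outcome=df["outcome"].to_numpy(dtype=float),
            true_snp_effects_exposure=np.full(m, np.nan),
            true_snp_effects_covariate=np.full(m, np.nan),
            sample_label=sample_label,
        )


def _draw_effects(config: DGPConfig, rng: np.random.Generator):
    """Shared per-replicate draws: frequencies and per-variant effects."""
    m, k = config.n_snps, config.n_exposure_snps
    freqs = np.clip(
        rng.normal(config.maf_mean, config.maf_sd, size=m), 0.01, 0.99
    )
    beta = np.zeros(m)
    beta[:k] = rng.normal(config.snp_effect_mean, config.snp_effect_sd, size=k)
    gamma_own = rng.normal(config.snp_effect_mean, config.snp_effect_sd, size=m - k)
    gamma = np.zeros(m)
    gamma[k:] = gamma_own
    if config.structure_variant == "pleiotropic":
        # the exposure's genetic score feeds the covariate: same coefficients
        gamma[:k] = beta[:k]
    return freqs, beta, gamma


def _simulate_sample(
    config: DGPConfig,
    freqs: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    rng: np.random.Generator,
    label: str,
) -> CohortData:
    n = config.n_individuals
    genotypes = rng.binomial(2, freqs, size=(n, config.n_snps)).astype(np.int8)
    g = genotypes.astype(np.float64)
    c1 = rng.standard_normal(n)
    c2 = rng.standard_normal(n)
    exposure = (
        config.confounder_effect_on_exposure * c1
        + g @ beta
        + config.noise_sd * rng.standard_normal(n)
    )
    covariate = (
        config.confounder_effect_on_covariate * c2
        + g @ gamma
        + config.noise_sd * rng.standard_normal(n)
    )
    d1, d2 = config.confounder_effects_on_outcome
    outcome = (
        config.exposure_effect_on_outcome * exposure
        + d1 * c1
        + d2 * c2
        + config.covariate_effect_on_outcome * covariate
        + config.noise_sd * rng.standard_normal(n)
    )
    return CohortData(
        genotypes=genotypes,
        confounders=np.column_stack([c1, c2]),
        exposure=exposure,
        covariate=covariate,
        outcome=outcome,
        true_snp_effects_exposure=beta,
        true_snp_effects_covariate=gamma,
        allele_frequencies=freqs,
        sample_label=label,
    )


def simulate_cohorts(
    config: DGPConfig,
    seed: int | None = None,
    require_three_samples: bool = False,
) -> list[CohortData]:
    """Draw ``config.n_samples`` independent cohorts under the structural model.

    Per-variant allele frequencies and effect sizes are drawn once and shared
    across samples (the samples genotype the same variants); genotypes,
    confounders and noise are independent between samples, emulating
    non-overlapping estimation samples for a two-sample design.

    Parameters
    ----------
    config
        The process parameters; ``config.seed`` is used unless ``seed`` is given.
    seed
        Optional override of ``config.seed`` (used by the replicate runner to
        derive per-replicate substreams).
    require_three_samples
        Set by the three-sample two-sample-MR design; rejects configs with
        fewer than three samples.
    """
    if require_three_samples and config.n_samples < 3:
        raise ValueError(
            "the three-sample design needs n_samples >= 3, "
            f"got n_samples={config.n_samples}"
        )
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = root.spawn(config.n_samples + 1)
    freqs, beta, gamma = _draw_effects(config, np.random.default_rng(streams[0]))
    return [
        _simulate_sample(
            config, freqs, beta, gamma,
            np.random.default_rng(streams[i + 1]),
            label=f"sample{i + 1}",
        )
        for i in range(config.n_samples)
    ]


def variant_table(
    n_variants: int,
    n_palindromic: int = 0,
    chromosome: str = "1",
    spacing_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Deterministic synthetic variant annotation.

    Variants sit ``spacing_bp`` apart on one synthetic chromosome so that
    distance-based clumping behaves predictably; the first ``n_palindromic``
    variants get A/T or G/C pairs, the rest cycle through non-palindromic
    pairs. The counted (dosage) allele is the effect allele.
    """
    if n_palindromic > n_variants:
        raise ValueError("n_palindromic exceeds n_variants")
    ids = [f"rs{j + 1}" for j in range(n_variants)]
    eff, oth = [], []
    for j in range(n_variants):
        if j < n_palindromic:
            a, b = _PALINDROMIC_PAIRS[j % len(_PALINDROMIC_PAIRS)]
        else:
            a, b = _NONPALINDROMIC_PAIRS[j % len(_NONPALINDROMIC_PAIRS)]
        eff.append(a)
        oth.append(b)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chromosome,
            "position": spacing_bp * (1 + np.arange(n_variants)),
            "effect_allele": eff,
            "other_allele": oth,
        }
    )


def _norm_p_from_z(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_sumstats_fixture(
    n_variants: int,
    n_palindromic: int = 0,
    flip_fraction: float = 0.0,
    seed: int = 0,
    *,
    n_significant: int | None = None,
    true_effect: float = 0.5,
    winners_curse_fraction: float = 0.0,
    winners_curse_inflation: float = 1.4,
    palindromic_eaf: float = 0.5,
    gwas_n: int = 100_000,
):
    """Four variant-aligned summary-statistic tables for pipeline testing.

    Emulates the input structure of an applied two-sample MR analysis: two
    exposure GWASs differing only by covariate adjustment, one covariate GWAS
    and one outcome GWAS (log-odds scale), with a shared variant set, a
    controllable number of allele-orientation flips in the outcome table,
    palindromic variants, and winner's-curse-inflated top hits.

    Returns
    -------
    (exposure_adjusted, exposure_unadjusted, covariate, outcome)
        Four :class:`~mviv.gwas.SummaryStats`. Construction details that tests
        rely on live in each table's ``meta``: ``significant_ids`` (variants
        built to pass 5e-8), ``winners_curse_ids`` (exposure betas inflated by
        ``winners_curse_inflation``), ``flipped_ids`` (outcome records stored
        with swapped alleles, negated beta, reflected EAF) and
        ``palindromic_ids``.

    Notes
    -----
    * The outcome beta is ``true_effect`` times the *uninflated* exposure beta
      plus independent noise, so winner's curse biases naive ratio estimates
      upward exactly as selection-on-significance does in real data.
    * With ``flip_fraction=0`` and ``n_palindromic=0`` the harmonisation stage
      is the identity on this fixture; with ``flip_fraction=1`` harmonisation
      restores the unflipped outcome betas bit-exactly.
    """
    from .gwas import SummaryStats

    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must lie in [0, 1]")
    if n_palindromic > n_variants:
        raise ValueError("n_palindromic exceeds n_variants")
    if n_significant is None:
        n_significant = n_variants // 2
    if n_significant > n_variants:
        raise ValueError("n_significant exceeds n_variants")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = variant_table(n_variants, n_palindromic)
    eaf = rng.uniform(0.15, 0.85, size=n_variants)
    eaf[:n_palindromic] = palindromic_eaf

    # exposure z-scores: significant records strictly beyond the genome-wide
    # threshold (|z| > 5.45), the rest strictly inside it
    z = np.empty(n_variants)
    sig = np.zeros(n_variants, dtype=bool)
    sig_idx = rng.permutation(n_variants)[:n_significant]
    sig[sig_idx] = True
    z[sig] = rng.uniform(6.5, 12.0, size=n_significant)
    z[~sig] = rng.uniform(0.5, 4.0, size=n_variants - n_significant)
    z *= rng.choice([-1.0, 1.0], size=n_variants)

    se_exp = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * gwas_n)
    beta_exp = z * se_exp

    # winner's curse: inflate |beta| of a documented subset of the significant hits
    n_wc = int(round(winners_curse_fraction * n_significant))
    wc_idx = np.sort(sig_idx[:n_wc])
    beta_exp_obs = beta_exp.copy()
    beta_exp_obs[wc_idx] *= winners_curse_inflation

    def table(beta, se, trait, adjusted_for, extra_meta=None):
        df = base.copy()
        df["eaf"] = eaf
        df["beta"] = beta
        df["se"] = se
        df["pvalue"] = _norm_p_from_z(beta / se)
        df["n"] = gwas_n
        meta = {
            "significant_ids": list(base.variant_id[sig]),
            "winners_curse_ids": list(base.variant_id[wc_idx]),
            "palindromic_ids": list(base.variant_id[:n_palindromic]),
        }
        if extra_meta:
            meta.update(extra_meta)
        return SummaryStats(df, trait=trait, adjusted_for=adjusted_for, meta=meta)

    exposure_adjusted = table(beta_exp_obs, se_exp, "exposure", ("covariate",))
    # the unadjusted GWAS sees the same signal with small independent jitter
    jitter = rng.normal(0.0, 0.1, size=n_variants) * se_exp
    exposure_unadjusted = table(beta_exp_obs + jitter, se_exp, "exposure", ())

    beta_cov = rng.normal(0.0, 2.0, size=n_variants) * se_exp
    covariate = table(beta_cov, se_exp, "covariate", ())

    se_out = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * gwas_n)
    beta_out = true_effect * beta_exp + rng.normal(0.0, 1.0, size=n_variants) * se_out

    n_flip = int(round(flip_fraction * n_variants))
    flip_idx = np.sort(rng.permutation(n_variants)[:n_flip])
    out_df_beta = beta_out.copy()
    out = table(
        out_df_beta, se_out, "outcome", (),
        extra_meta={"flipped_ids": list(base.variant_id[flip_idx]),
                    "scale": "log-odds", "true_effect": true_effect},
    )
    # store the flipped records with swapped alleles / negated beta / reflected
    # EAF — exactly what harmonisation must undo
    d = out.data
    fl = np.zeros(n_variants, dtype=bool)
    fl[flip_idx] = True
    ea = d.loc[fl, "effect_allele"].copy()
    d.loc[fl, "effect_allele"] = d.loc[fl, "other_allele"].values
    d.loc[fl, "other_allele"] = ea.values
    d.loc[fl, "beta"] = -d.loc[fl, "beta"]
    d.loc[fl, "eaf"] = 1.0 - d.loc[fl, "eaf"]

    return exposure_adjusted, exposure_unadjusted, covariate, out
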