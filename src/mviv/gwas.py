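"""Per-variant association scans and the summary-statistics container.

:func:`run_gwas` regresses a trait on each dosage column by ordinary least
squares, optionally partialling out the covariate (Frisch–Waugh), producing
the ``B_x`` / ``B_y`` / ``B_p`` inputs every summary-data MR estimator
consumes. Standard errors are the homoscedastic t-based OLS errors, matching
standard GWAS software at these sample sizes.

:class:`SummaryStats` wraps a canonical-column DataFrame and round-trips a
GWAS-SSF-style tab-delimited layout, tolerating the common alias headers
(``SNP``/``BETA``/``SE``/``P`` …).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError
from . import dgp as _dgp

__all__ = ["SummaryStats", "run_gwas", "read_sumstats", "CANONICAL_COLUMNS"]

CANONICAL_COLUMNS = (
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)

#: on-disk GWAS-SSF-style header names, keyed by canonical column
_SSF_NAMES = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

_ALIASES = {
    "variant_id": {"variant_id", "snp", "rsid", "markername", "id", "variant"},
    "chromosome": {"chromosome", "chr", "chrom"},
    "position": {"base_pair_location", "position", "bp", "pos"},
    "effect_allele": {"effect_allele", "a1", "ea", "allele1"},
    "other_allele": {"other_allele", "a2", "oa", "nea", "allele2", "allele0"},
    "eaf": {"effect_allele_frequency", "eaf", "frq", "af", "freq"},
    "beta": {"beta", "b", "effect", "effect_size"},
    "se": {"standard_error", "se", "stderr"},
    "pvalue": {"p_value", "p", "pval", "pvalue", "p_val"},
    "n": {"n", "sample_size", "nobs"},
}


@dataclass
class SummaryStats:
    """Per-variant association records for one trait.

    ``data`` holds the canonical columns (:data:`CANONICAL_COLUMNS`).
    Monomorphic variants are kept as rows with ``NaN`` beta/se/p and are
    excluded by every downstream stage; their count is in
    ``meta['n_monomorphic']`` when produced by :func:`run_gwas`.
    """

    data: pd.DataFrame
    trait: str = ""
    adjusted_for: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"summary statistics missing column(s): {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SummaryStats":
        return SummaryStats(
            self.data.copy(), trait=self.trait,
            adjusted_for=self.adjusted_for, meta=dict(self.meta),
        )

    def subset(self, mask) -> "SummaryStats":
        """Row subset (boolean mask or positional indexer), order preserved."""
        out = self.copy()
        out.data = self.data.loc[np.asarray(mask)].reset_index(drop=True) \
            if np.asarray(mask).dtype == bool else \
            self.data.iloc[np.asarray(mask)].reset_index(drop=True)
        return out

    def validate(self, p_rtol: float = 1e-10) -> None:
        """Raise if the container invariants are violated.

        Checks uniqueness of variant ids, positive SEs, frequencies and
        p-values in range, and consistency of each p-value with ``beta/se``
        under the two-sided normal approximation (NaN-beta rows exempt).
        """
        d = self.data
        if d["variant_id"].duplicated().any():
            dup = d.loc[d["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r}")
        ok = d["beta"].notna().to_numpy()
        if (d.loc[ok, "se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if ((d.loc[ok, "pvalue"] < 0) | (d.loc[ok, "pvalue"] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if ((d["eaf"] <= 0) | (d["eaf"] >= 1)).any():
            raise ValueError("effect-allele frequencies must lie in (0, 1)")
        z = (d.loc[ok, "beta"] / d.loc[ok, "se"]).to_numpy()
        dof = self.meta.get("dof")
        if dof is not None:  # finite-sample GWAS output carries t-based p
            expected = 2.0 * stats.t.sf(np.abs(z), dof)
        else:
            expected = 2.0 * stats.norm.sf(np.abs(z))
        p = d.loc[ok, "pvalue"].to_numpy()
        denom = np.maximum(expected, np.finfo(float).tiny)
        if np.any(np.abs(p - expected) / denom > p_rtol + 1e-6):
            raise ValueError("p-values inconsistent with beta/se (normal approx.)")

    # ------------------------------------------------------------------ IO
    def write_tsv(self, path: str | Path) -> None:
        out = self.data.loc[:, list(CANONICAL_COLUMNS)].rename(columns=_SSF_NAMES)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path: str | Path, trait: str = "") -> "SummaryStats":
        return read_sumstats(path, trait=trait)


def read_sumstats(path: str | Path, trait: str = "") -> SummaryStats:
    """Read a tab-delimited summary-statistics table.

    Header matching is case-insensitive and tolerates the common alias names
    for each column; a missing required column raises :class:`SchemaError`
    naming it.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canonical, aliases in _ALIASES.items():
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is None:
            raise SchemaError(
                f"{path}: no column for {canonical!r} "
                f"(accepted headers: {sorted(aliases)})"
            )
        rename[hit] = canonical
    df = df.rename(columns=rename).loc[:, list(CANONICAL_COLUMNS)]
    df["chromosome"] = df["chromosome"].astype(str)
    return SummaryStats(df, trait=trait)


def run_gwas(
    cohort: "_dgp.CohortData",
    trait: str = "exposure",
    adjust_for_covariate: bool = False,
    maf_filter: float | None = None,
) -> SummaryStats:
    """Per-variant OLS association scan of ``trait`` on each dosage column.

    Parameters
    ----------
    cohort
        The individual-level sample.
    trait
        One of ``exposure``, ``covariate``, ``outcome``.
    adjust_for_covariate
        Include the covariate ``P`` as a regressor (invalid when the trait is
        the covariate itself). The per-variant coefficient and its t-based
        standard error are identical to those of the multi-column regression
        (Frisch–Waugh), computed here by residualising trait and dosages on
        the covariate.
    maf_filter
        Optional minor-allele-frequency threshold; no filter by default.

    Notes
    -----
    Monomorphic variants (zero dosage variance) yield ``NaN`` beta/se/p; the
    count is reported in ``meta['n_monomorphic']``.
    """
    if trait not in ("exposure", "covariate", "outcome"):
        raise ValueError(f"unknown trait {trait!r}")
    if adjust_for_covariate and trait == "covariate":
        raise ValueError("cannot adjust the covariate GWAS for the covariate itself")

    y = np.asarray(getattr(cohort, trait), dtype=float)
    g = cohort.genotypes.astype(np.float64)
    n, m = g.shape
    eaf = g.mean(axis=0) / 2.0

    y = y - y.mean()
    g = g - g.mean(axis=0)
    n_params = 2
    if adjust_for_covariate:
        c = np.asarray(cohort.covariate, dtype=float)
        c = c - c.mean()
        cc = float(c @ c)
        y = y - c * (float(c @ y) / cc)
        g = g - np.outer(c, (c @ g) / cc)
        n_params = 3

    gg = np.einsum("ij,ij->j", g, g)
    mono = gg <= 0.0
    gg_safe = np.where(mono, 1.0, gg)
    beta = (g.T @ y) / gg_safe
    yy = float(y @ y)
    dof = n - n_params
    rss = yy - beta**2 * gg_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[mono] = np.nan
    se[mono] = np.nan
    pvalue[mono] = np.nan

    df = _dgp.variant_table(m)
    df["eaf"] = eaf
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = pvalue
    df["n"] = n

    stats_out = SummaryStats(
        df,
        trait=trait,
        adjusted_for=("covariate",) if adjust_for_covariate else (),
        meta={
            "n_monomorphic": int(mono.sum()),
            "sample_label": cohort.sample_label,
            "dof": dof,
        },
    )
    if maf_filter is not None:
        maf = np.minimum(eaf, 1.0 - eaf)
        keep = maf >= maf_filter
        stats_out.meta["n_maf_filtered"] = int((~keep).sum())
        stats_out = stats_out.subset(keep)
    return stats_out
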