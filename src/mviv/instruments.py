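"""Instrument processing: selection, winner's-curse correction, clumping,
standardisation, and allele harmonisation.

The stages turn raw GWAS summary statistics into a :class:`HarmonisedSet`
ready for the MR estimators. The canonical order is

    select -> FIQT -> clump -> standardise -> harmonise

(selection must precede clumping; the winner's-curse correction is applied to
the exposure GWAS). Each stage only ever removes rows or edits betas, so the
retained variant set shrinks monotonically and every drop is counted in the
provenance.

FIQT (FDR inverse quantile transformation)
------------------------------------------
Winner's curse inflates the effect sizes of variants selected for
significance. FIQT shrinks each z-score by pushing its two-sided p-value
through Benjamini–Hochberg and mapping the adjusted p back to a z:
``z' = sign(z) * Phi^-1(1 - p_BH/2)``, ``beta' = z' * se`` with the SE
unchanged. Since ``p_BH >= p``, ``|z'| <= |z|`` always, with equality iff BH
left the p-value untouched. All p arithmetic is done in log space so
genome-wide-scale z-scores do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EmptyResultError, EmptySelectionError
from .gwas import SummaryStats

__all__ = [
    "HarmonisedSet",
    "LDProvider",
    "IdentityLD",
    "MatrixLD",
    "select_instruments",
    "fiqt_correct",
    "clump",
    "standardise",
    "harmonise",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: stages recorded in HarmonisedSet.provenance
PROVENANCE_STAGES = (
    "not_significant", "clumped", "palindromic_unresolvable",
    "allele_mismatch", "missing_in_outcome",
)


# --------------------------------------------------------------------------- LD
class LDProvider(Protocol):
    """Pairwise linkage-disequilibrium (r^2) lookup for clumping."""

    def r2(self, id1: str, id2: str) -> float: ...


class IdentityLD:
    """Independent variants: r^2 = 0 for every distinct pair."""

    def r2(self, id1: str, id2: str) -> float:
        return 1.0 if id1 == id2 else 0.0


class MatrixLD:
    """Explicit r^2 matrix over a fixed variant panel.

    Pairs with either variant absent from the panel get r^2 = 0.
    """

    def __init__(self, r2_matrix, variant_ids: Sequence[str]):
        self._m = np.asarray(r2_matrix, dtype=float)
        if self._m.shape != (len(variant_ids), len(variant_ids)):
            raise ValueError("r2 matrix shape does not match variant_ids")
        self._idx = {v: i for i, v in enumerate(variant_ids)}

    def r2(self, id1: str, id2: str) -> float:
        i, j = self._idx.get(id1), self._idx.get(id2)
        if i is None or j is None:
            return 1.0 if id1 == id2 else 0.0
        return float(self._m[i, j])


# ------------------------------------------------------------------- container
@dataclass
class HarmonisedSet:
    """Variant-aligned betas/SEs for exposure, outcome and (optionally) a
    covariate, with every retained variant's effect allele identical across
    the constituent tables."""

    variant_ids: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    covariate_beta: np.ndarray | None = None
    covariate_se: np.ndarray | None = None
    effect_allele: list[str] | None = None
    other_allele: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vecs = [self.exposure_beta, self.exposure_se,
                self.outcome_beta, self.outcome_se]
        if self.covariate_beta is not None:
            vecs += [self.covariate_beta, self.covariate_se]
        lengths = {len(self.variant_ids)} | {len(np.asarray(v)) for v in vecs}
        if len(lengths) != 1:
            raise ValueError(f"harmonised vectors disagree in length: {lengths}")
        if len(self.variant_ids) < 1:
            raise EmptyResultError("harmonised set is empty")
        for name in ("exposure_se", "outcome_se", "covariate_se"):
            v = getattr(self, name)
            if v is not None and np.any(np.asarray(v) <= 0):
                raise ValueError(f"{name} must be strictly positive")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return 1 if self.covariate_beta is None else 2

    def exposure_matrix(self) -> np.ndarray:
        """(n_snps, n_exposures) beta matrix; exposure first, then covariate."""
        if self.covariate_beta is None:
            return np.asarray(self.exposure_beta, float)[:, None]
        return np.column_stack([self.exposure_beta, self.covariate_beta])

    def subset(self, idx) -> "HarmonisedSet":
        idx = np.asarray(idx)
        pick = (lambda v: None if v is None else np.asarray(v)[idx])
        return HarmonisedSet(
            variant_ids=[self.variant_ids[i] for i in np.flatnonzero(idx)]
            if idx.dtype == bool else [self.variant_ids[i] for i in idx],
            exposure_beta=np.asarray(self.exposure_beta)[idx],
            exposure_se=np.asarray(self.exposure_se)[idx],
            outcome_beta=np.asarray(self.outcome_beta)[idx],
            outcome_se=np.asarray(self.outcome_se)[idx],
            covariate_beta=pick(self.covariate_beta),
            covariate_se=pick(self.covariate_se),
            effect_allele=None if self.effect_allele is None
            else list(np.asarray(self.effect_allele, object)[idx]),
            other_allele=None if self.other_allele is None
            else list(np.asarray(self.other_allele, object)[idx]),
            provenance=dict(self.provenance),
        )


# ----------------------------------------------------------------- operations
def select_instruments(stats_in: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Retain variants with ``pvalue < p_threshold`` (order preserved).

    Rows with missing p (monomorphic) are dropped and counted. An empty
    selection raises :class:`EmptySelectionError` naming the threshold.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    p = stats_in.data["pvalue"].to_numpy()
    keep = p < p_threshold  # NaN compares False
    if not keep.any():
        raise EmptySelectionError(
            f"no variants pass p < {p_threshold:g} "
            f"(min p = {np.nanmin(p) if len(p) else float('nan'):g})"
        )
    out = stats_in.subset(keep)
    out.meta["n_not_significant"] = int(len(stats_in) - keep.sum())
    return out


def _log_bh_adjust(logp: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up on natural-log p-values, in log space."""
    m = len(logp)
    order = np.argsort(logp, kind="stable")          # ascending p
    ranks = np.arange(1, m + 1)
    adj_sorted = logp[order] + np.log(m) - np.log(ranks)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 0.0)         # cap at p = 1
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def fiqt_correct(stats_in: SummaryStats) -> SummaryStats:
    """Winner's-curse shrinkage of betas via the FDR inverse quantile transform.

    The returned table carries the shrunken betas, unchanged SEs, and
    p-values recomputed from the shrunken z (numerically equal to the
    BH-adjusted p), so the beta/se/p consistency invariant is preserved.
    A single-record table is returned unchanged (BH with m=1 is the
    identity); ``p_BH = 1`` maps to ``z' = 0``.
    """
    out = stats_in.copy()
    d = out.data
    ok = d["beta"].notna().to_numpy()
    z = (d.loc[ok, "beta"] / d.loc[ok, "se"]).to_numpy()
    # natural-log two-sided p; logsf keeps precision where p underflows
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    logp_adj = _log_bh_adjust(logp)
    # z' = Phi^-1(1 - p_adj/2) = -Phi^-1(p_adj/2), evaluated from log(p_adj/2)
    z_new = -special.ndtri_exp(logp_adj - np.log(2.0))
    z_new = np.where(np.isfinite(z_new), z_new, np.abs(z))  # guard: p==0 keeps z
    beta_new = np.sign(z) * z_new * d.loc[ok, "se"].to_numpy()
    d.loc[ok, "beta"] = beta_new
    d.loc[ok, "pvalue"] = np.exp(logp_adj)
    out.meta["fiqt_applied"] = True
    out.meta.pop("dof", None)  # p now on the normal scale
    return out


def clump(
    stats_in: SummaryStats,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    ld: LDProvider | None = None,
) -> SummaryStats:
    """Greedy p-value clumping.

    Sort by ascending p (ties broken by ascending position then lexicographic
    id); iteratively keep the best remaining variant and discard every other
    variant on the same chromosome within ``window_kb`` kilobases whose r^2
    with it is at least ``r2_threshold``. With the default
    :class:`IdentityLD` provider (independent synthetic variants) nothing is
    ever discarded. Records with a missing position are excluded and counted.
    """
    if ld is None:
        ld = IdentityLD()
    d = stats_in.data
    has_pos = d["position"].notna().to_numpy() & d["pvalue"].notna().to_numpy()
    n_missing = int((~has_pos).sum())
    cand = d.loc[has_pos, ["variant_id", "chromosome", "position", "pvalue"]]
    order = cand.sort_values(
        ["pvalue", "position", "variant_id"], kind="stable"
    ).index.to_list()

    alive = dict.fromkeys(order, True)
    kept: list = []
    pos = d["position"]
    chrom = d["chromosome"]
    window_bp = window_kb * 1000
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        vi, ci, pi = d.at[i, "variant_id"], chrom[i], pos[i]
        for j in order:
            if j == i or not alive[j]:
                continue
            if chrom[j] == ci and abs(pos[j] - pi) <= window_bp:
                if ld.r2(vi, d.at[j, "variant_id"]) >= r2_threshold:
                    alive[j] = False
    keep_mask = d.index.isin(kept)
    out = stats_in.subset(keep_mask)
    out.meta["n_clumped"] = int(len(cand) - len(kept))
    out.meta["n_missing_position"] = n_missing
    return out


def standardise(stats_in: SummaryStats, divisor: float) -> SummaryStats:
    """Divide beta and SE by ``divisor`` (z-scores, hence p-values, unchanged).

    Used to put exposure effects on a per-SD scale, e.g. the published
    lifetime-smoking divisor 0.6940093.
    """
    if not divisor > 0:
        raise ValueError(f"divisor must be positive, got {divisor}")
    out = stats_in.copy()
    out.data["beta"] = out.data["beta"] / divisor
    out.data["se"] = out.data["se"] / divisor
    out.meta["standardise_divisor"] = divisor
    return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _orientation(ea_ref, oa_ref, ea, oa):
    """How a record's alleles relate to the reference pair.

    Returns ``'same'``, ``'flip'``, ``'palindromic'`` or ``'mismatch'``.
    Strand flips (complement pairs) are folded into same/flip.
    """
    if _is_palindromic(ea_ref, oa_ref) or _is_palindromic(ea, oa):
        if {ea, oa} == {ea_ref, oa_ref}:
            return "palindromic"
        return "mismatch"
    cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
    if (ea, oa) == (ea_ref, oa_ref) or (cea, coa) == (ea_ref, oa_ref):
        return "same"
    if (oa, ea) == (ea_ref, oa_ref) or (coa, cea) == (ea_ref, oa_ref):
        return "flip"
    return "mismatch"


def harmonise(
    exposure: SummaryStats,
    outcome: SummaryStats,
    others: Iterable[SummaryStats] = (),
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonisedSet:
    """Align outcome (and covariate) records to the exposure's effect alleles.

    Inner-joins on ``variant_id`` (exposure order preserved). Where a
    record's alleles are swapped relative to the exposure, its beta is
    negated and its EAF reflected. Palindromic (A/T, G/C) variants carry no
    strand information, so orientation is inferred from allele frequency:
    if both tables' EAFs are outside the ambiguity band
    ``palindromic_eaf_band``, same-side frequencies mean the records are
    already aligned and opposite-side frequencies mean a flip; any EAF inside
    the band makes the variant unresolvable and it is removed. Variants with
    incompatible allele pairs are removed. All drops are counted in the
    returned provenance.
    """
    others = list(others)
    lo, hi = palindromic_eaf_band
    exp = exposure.data.set_index("variant_id", drop=False)
    tables = [t.data.set_index("variant_id", drop=False) for t in [outcome, *others]]

    common = exp.index
    for t in tables:
        common = common.intersection(t.index)
    # preserve exposure row order
    common_set = set(common)
    ordered = [v for v in exposure.data["variant_id"] if v in common_set]
    if not ordered:
        raise EmptyResultError("no variants shared between exposure and outcome tables")

    prov = dict.fromkeys(PROVENANCE_STAGES, 0)
    prov["n_input"] = len(exposure)
    prov["missing_in_outcome"] = len(exposure) - len(ordered)

    kept_ids: list[str] = []
    aligned = {i: {"beta": [], "se": []} for i in range(len(tables))}
    for vid in ordered:
        e = exp.loc[vid]
        if not np.isfinite(e["beta"]):
            prov["allele_mismatch"] += 1  # unusable exposure record
            continue
        row_vals = []
        status = "ok"
        for t in tables:
            r = t.loc[vid]
            rel = _orientation(
                e["effect_allele"], e["other_allele"],
                r["effect_allele"], r["other_allele"],
            )
            if rel == "mismatch" or not np.isfinite(r["beta"]):
                status = "mismatch"
                break
            if rel == "palindromic":
                fe, fr = float(e["eaf"]), float(r["eaf"])
                if not (fe < lo or fe > hi) or not (fr < lo or fr > hi):
                    status = "palindromic"
                    break
                rel = "same" if (fe < 0.5) == (fr < 0.5) else "flip"
            if rel == "flip":
                row_vals.append((-float(r["beta"]), float(r["se"])))
            else:
                row_vals.append((float(r["beta"]), float(r["se"])))
        if status == "mismatch":
            prov["allele_mismatch"] += 1
            continue
        if status == "palindromic":
            prov["palindromic_unresolvable"] += 1
            continue
        kept_ids.append(vid)
        for i, (b, s) in enumerate(row_vals):
            aligned[i]["beta"].append(b)
            aligned[i]["se"].append(s)

    if not kept_ids:
        raise EmptyResultError(
            f"harmonisation removed every variant (provenance: {prov})"
        )
    prov["retained"] = len(kept_ids)
    # carry forward counts from upstream stages if present
    prov["not_significant"] = exposure.meta.get("n_not_significant", 0)
    prov["clumped"] = exposure.meta.get("n_clumped", 0)

    exp_kept = exp.loc[kept_ids]
    cov_beta = cov_se = None
    if others:
        cov_beta = np.asarray(aligned[1]["beta"])
        cov_se = np.asarray(aligned[1]["se"])
    return HarmonisedSet(
        variant_ids=kept_ids,
        exposure_beta=exp_kept["beta"].to_numpy(float),
        exposure_se=exp_kept["se"].to_numpy(float),
        outcome_beta=np.asarray(aligned[0]["beta"]),
        outcome_se=np.asarray(aligned[0]["se"]),
        covariate_beta=cov_beta,
        covariate_se=cov_se,
        effect_allele=list(exp_kept["effect_allele"]),
        other_allele=list(exp_kept["other_allele"]),
        provenance=prov,
    )
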