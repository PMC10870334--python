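"""Hierarchical diversity and differentiation statistics, bootstrap pairwise
FST, and PCA of genotypes.

Diversity statistics follow the Nei & Chesser (1983) bias-corrected
estimators as implemented by the standard hierarchical F-statistics
reporting tools.  Per locus l over s populations, with per-population
alternate-allele frequency p_il, called diploid sample sizes n_il
(harmonic mean ñ across populations) and observed heterozygote fraction
het_il:

    HO_l  = mean_i het_il
    HS_l  = ñ/(ñ-1) * (1 - mean_i(p_il² + q_il²) - HO_l/(2ñ))
    HT_l  = 1 - (p̄_l² + q̄_l²) + HS_l/(ñ s) - HO_l/(2 ñ s)
    DST_l = HT_l - HS_l
    DEST_l = s/(s-1) * (HT_l - HS_l)/(1 - HS_l)     (Jost's D)

with p̄ the unweighted mean of p_il.  Genome-wide values average the
per-locus components across loci; the ratios are then formed from the
averages (ratio-of-averages): FST = mean(DST)/mean(HT), FIS =
1 - mean(HO)/mean(HS), DEST from averaged components.  With a single
population DST = FST = 0 and DEST is undefined.  Negative estimates are
reported, never clamped.

Pairwise FST uses the Weir & Cockerham (1984) theta estimator as a
ratio of averages across loci, with a seeded bootstrap over loci for 95%
percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class DiversityTable:
    """Genome-wide Nei/Jost statistics for one group-set (one table row)."""

    groups: list[str]
    n_loci_used: int
    H_O: float
    H_S: float
    H_T: float
    D_ST: float
    F_ST: float
    F_IS: float
    D_EST: float | None  # None when a single population (undefined)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "n_loci_used": self.n_loci_used,
            "H_O": self.H_O,
            "H_S": self.H_S,
            "H_T": self.H_T,
            "D_ST": self.D_ST,
            "F_ST": self.F_ST,
            "F_IS": self.F_IS,
            "D_EST": self.D_EST,
        }


@dataclass
class PairwiseFstMatrix:
    groups: list[str]
    theta: np.ndarray  # symmetric, zero diagonal; NaN = unavailable
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool; True iff bootstrap 95% CI excludes 0


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray


def _per_pop_counts(calls: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-population called sizes, alt-allele frequencies and het fractions.

    Returns arrays of shape (n_groups, n_loci): n (called diploids),
    p (alt frequency among called), het (observed heterozygote fraction).
    Entries with zero called genotypes are NaN for p/het and 0 for n.
    """
    n_loci = calls.shape[1]
    n = np.zeros((n_groups, n_loci))
    p = np.full((n_groups, n_loci), np.nan)
    het = np.full((n_groups, n_loci), np.nan)
    for k in range(n_groups):
        sub = calls[codes == k]
        called = sub != MISSING
        nk = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pk = np.where(nk > 0, alt / np.maximum(2 * nk, 1), np.nan)
            hk = np.where(nk > 0, (sub == 1).sum(axis=0) / np.maximum(nk, 1), np.nan)
        n[k] = nk
        p[k] = pk
        het[k] = hk
    return n, p, het


def diversity_stats(
    g: GenotypeMatrix,
    pops: PopulationMap,
    groups: list[str] | None = None,
) -> DiversityTable:
    """Nei/Chesser hierarchical diversity statistics over `groups` as units.

    Loci for which any group has zero called genotypes are dropped.  With
    a single group the convention is D_ST = 0, F_ST = 0 and D_EST absent.
    """
    if groups is None:
        groups = pops.groups
    if not groups:
        raise ValueError("need at least one group")
    for grp in groups:
        if not pops.samples_in(grp):
            raise ValueError(f"group {grp!r} has no samples")
    _, codes = pops.group_indices(g.sample_ids, groups)
    s = len(groups)
    n, p, het = _per_pop_counts(g.calls, codes, s)
    with np.errstate(divide="ignore"):
        ntilde_all = s / np.where(n > 0, 1.0 / np.maximum(n, 1), np.inf).sum(axis=0)
    # the Nei/Chesser correction needs ntilde > 1: loci with an uncalled
    # group or a harmonic-mean called size of one are dropped
    usable = (n > 0).all(axis=0) & (ntilde_all > 1)
    if not usable.any():
        raise ValueError("no locus is called (in >1 copy) in every group")
    n, p, het = n[:, usable], p[:, usable], het[:, usable]
    q = 1.0 - p
    ntilde = ntilde_all[usable]
    ho_l = het.mean(axis=0)
    hom_exp = (p**2 + q**2).mean(axis=0)
    hs_l = ntilde / (ntilde - 1.0) * (1.0 - hom_exp - ho_l / (2.0 * ntilde))
    pbar = p.mean(axis=0)
    qbar = 1.0 - pbar
    ht_l = 1.0 - (pbar**2 + qbar**2) + hs_l / (ntilde * s) - ho_l / (2.0 * ntilde * s)
    ho, hs, ht = float(ho_l.mean()), float(hs_l.mean()), float(ht_l.mean())
    if s == 1:
        return DiversityTable(groups, int(usable.sum()), ho, hs, hs, 0.0, 0.0,
                              1.0 - ho / hs if hs != 0 else np.nan, None)
    dst = ht - hs
    fst = dst / ht if ht != 0 else np.nan
    fis = 1.0 - ho / hs if hs != 0 else np.nan
    dest = (s / (s - 1.0)) * dst / (1.0 - hs) if hs != 1.0 else np.nan
    return DiversityTable(groups, int(usable.sum()), ho, hs, ht, dst, fst, fis, dest)


def weir_cockerham_components(
    calls: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, a+b+c).

    Returns two arrays of length n_loci; theta over any locus set is
    sum(a)/sum(a+b+c).  Loci where fewer than two populations have called
    genotypes yield NaN components.
    """
    n, p, het = _per_pop_counts(calls, codes, n_groups)
    ok = n > 0
    r = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = np.where(ok, n, 0).sum(axis=0) / r
        sum_n2 = np.where(ok, n**2, 0).sum(axis=0)
        nc = (np.where(ok, n, 0).sum(axis=0) - sum_n2 / np.where(ok, n, np.nan).sum(axis=0)) / (r - 1.0)
        pbar = np.where(ok, n * p, 0).sum(axis=0) / (r * nbar)
        s2 = np.where(ok, n * (p - pbar) ** 2, 0).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = np.where(ok, n * het, 0).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0) * (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, a + b + c)
    return a, total


def _theta(a: np.ndarray, total: np.ndarray, idx: np.ndarray | None = None) -> float:
    if idx is not None:
        a, total = a[idx], total[idx]
    ok = ~np.isnan(total)
    denom = total[ok].sum()
    return float(a[ok].sum() / denom) if denom != 0 else np.nan


def pairwise_fst(
    g: GenotypeMatrix,
    pops: PopulationMap,
    n_boot: int = 100,
    seed: int = 0,
    groups: list[str] | None = None,
) -> PairwiseFstMatrix:
    """Pairwise Weir-Cockerham theta with a seeded bootstrap over loci.

    For each pair of groups theta is the ratio-of-averages across loci;
    `n_boot` bootstrap resamples of loci give a 95% percentile interval,
    and a pair is flagged significant iff that interval excludes 0.
    Pairs where a group has fewer than 2 samples are NaN.
    """
    if groups is None:
        groups = pops.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _, codes = pops.group_indices(g.sample_ids, groups)
    k = len(groups)
    theta = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    sig = np.zeros((k, k), dtype=bool)
    rng = np.random.default_rng(seed)
    # one fixed resampling plan shared by all pairs, for reproducibility
    boot_idx = rng.integers(0, g.n_loci, size=(n_boot, g.n_loci))
    for i, j in combinations(range(k), 2):
        if (codes == i).sum() < 2 or (codes == j).sum() < 2:
            theta[i, j] = theta[j, i] = np.nan
            lo[i, j] = lo[j, i] = hi[i, j] = hi[j, i] = np.nan
            continue
        pair_codes = np.full_like(codes, -1)
        pair_codes[codes == i] = 0
        pair_codes[codes == j] = 1
        a, total = weir_cockerham_components(g.calls, pair_codes, 2)
        t = _theta(a, total)
        boots = np.array([_theta(a, total, boot_idx[b]) for b in range(n_boot)])
        ql, qh = np.nanpercentile(boots, [2.5, 97.5])
        theta[i, j] = theta[j, i] = t
        lo[i, j] = lo[j, i] = ql
        hi[i, j] = hi[j, i] = qh
        sig[i, j] = sig[j, i] = bool(ql > 0 or qh < 0)
    return PairwiseFstMatrix(list(groups), theta, lo, hi, sig)


def pca_structure(g: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of standardized genotypes.

    Calls are centered by twice the pooled allele frequency and scaled by
    sqrt(2 p (1-p)); missing cells are imputed to the locus mean (0 after
    centering).  Monomorphic or fully-missing loci are excluded.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    if n_components > min(g.n_samples, g.n_loci):
        raise ValueError("n_components exceeds matrix rank bound")
    calls = g.calls.astype(float)
    called = g.calls != MISSING
    nk = called.sum(axis=0)
    alt = np.where(called, calls, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nk > 0, alt / np.maximum(2 * nk, 1), np.nan)
    keep = (nk > 0) & (p > 0) & (p < 1)
    if not keep.any():
        return PCAResult(
            list(g.sample_ids),
            np.zeros((g.n_samples, n_components)),
            np.zeros(n_components),
        )
    calls, p, called = calls[:, keep], p[keep], called[:, keep]
    x = (calls - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[~called] = 0.0
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    var = sv**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u[:, :n_components] * sv[:n_components]
    return PCAResult(list(g.sample_ids), scores, ratio[:n_components])
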