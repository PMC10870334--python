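"""Locus-level SNP filters used by the study.

Three filters with boundary semantics read literally from the protocol:

- call rate: keep loci genotyped in **at least** `min_fraction` of samples
  (inclusive, default 0.8);
- heterozygosity: drop loci whose observed heterozygote fraction among
  called genotypes is **above** `max_het` (strict, default 0.65) — such
  loci are potentially merged paralogs;
- minor allele frequency: keep loci with pooled MAF **>=** `min_maf`
  (removal is MAF < threshold, default 0.05).

``apply_study_filters`` chains them in protocol order: the "popgen" stage
is call rate then heterozygosity; the "abc" stage additionally removes
loci with zero called genotypes and then applies the MAF filter.  A locus
failing several criteria is counted once, under the first filter applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class FilterReport:
    """Accounting of loci removed by each filter step."""

    n_input_loci: int
    n_removed_missingness: int = 0
    n_removed_heterozygosity: int = 0
    n_removed_maf: int = 0
    n_removed_uncalled: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missingness
            + self.n_removed_heterozygosity
            + self.n_removed_maf
            + self.n_removed_uncalled
        )
        if self.n_input_loci != self.n_retained + removed:
            raise ValueError("filter report counts do not balance")
        if min(
            self.n_input_loci,
            self.n_removed_missingness,
            self.n_removed_heterozygosity,
            self.n_removed_maf,
            self.n_removed_uncalled,
            self.n_retained,
        ) < 0:
            raise ValueError("negative counts in filter report")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input_loci": self.n_input_loci,
            "n_removed_missingness": self.n_removed_missingness,
            "n_removed_heterozygosity": self.n_removed_heterozygosity,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_uncalled": self.n_removed_uncalled,
            "n_retained": self.n_retained,
        }


def _check_nonempty(g: GenotypeMatrix) -> None:
    if g.n_samples == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")


def filter_call_rate(
    g: GenotypeMatrix, min_fraction: float = 0.8
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci called in at least `min_fraction` of samples (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    _check_nonempty(g)
    called = (g.calls != MISSING).sum(axis=0)
    keep = called / g.n_samples >= min_fraction
    report = FilterReport(
        n_input_loci=g.n_loci,
        n_removed_missingness=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return g.take_loci(keep), report


def filter_locus_heterozygosity(
    g: GenotypeMatrix, max_het: float = 0.65
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci with observed heterozygote fraction strictly above `max_het`.

    The fraction is computed among called genotypes only, so missingness
    does not dilute the paralog signal.  Loci with zero called genotypes
    are removed with a warning.
    """
    if not 0 < max_het < 1:
        raise ValueError("max_het must be in (0, 1)")
    _check_nonempty(g)
    called = (g.calls != MISSING).sum(axis=0)
    hets = (g.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        het_frac = np.where(called > 0, hets / np.maximum(called, 1), np.nan)
    uncalled = called == 0
    if uncalled.any():
        warnings.warn(f"{int(uncalled.sum())} loci with zero called genotypes removed")
    keep = ~uncalled & (het_frac <= max_het)
    report = FilterReport(
        n_input_loci=g.n_loci,
        n_removed_heterozygosity=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return g.take_loci(keep), report


def pooled_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor allele frequency over all called alleles, pooled
    across samples.  Loci with zero called genotypes get MAF 0."""
    called = (g.calls != MISSING).sum(axis=0)
    alt = np.where(g.calls == MISSING, 0, g.calls).sum(axis=0)
    total = 2 * called
    minor = np.minimum(alt, total - alt)  # integer counts: exact boundaries
    return np.where(total > 0, minor / np.maximum(total, 1), 0.0)


def filter_maf(
    g: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci with pooled minor allele frequency >= `min_maf` (inclusive)."""
    if not 0 < min_maf < 0.5:
        raise ValueError("min_maf must be in (0, 0.5)")
    _check_nonempty(g)
    keep = pooled_maf(g) >= min_maf
    report = FilterReport(
        n_input_loci=g.n_loci,
        n_removed_maf=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return g.take_loci(keep), report


def filter_uncalled(g: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci with zero called genotypes (no sample carries a call)."""
    _check_nonempty(g)
    keep = (g.calls != MISSING).any(axis=0)
    report = FilterReport(
        n_input_loci=g.n_loci,
        n_removed_uncalled=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return g.take_loci(keep), report


def apply_study_filters(
    g: GenotypeMatrix,
    stage: str = "popgen",
    min_call_rate: float = 0.8,
    max_het: float = 0.65,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the study's filter chain.

    stage "popgen": call rate then heterozygosity.
    stage "abc": popgen filters, then zero-call removal, then MAF.
    The report chains counts; removals are attributed to the first filter
    that rejects a locus.
    """
    if stage not in ("popgen", "abc"):
        raise ValueError(f"unknown stage {stage!r}; expected 'popgen' or 'abc'")
    g1, r1 = filter_call_rate(g, min_call_rate)
    g2, r2 = filter_locus_heterozygosity(g1, max_het)
    removed_uncalled = 0
    removed_maf = 0
    out = g2
    if stage == "abc":
        out, r3 = filter_uncalled(out)
        removed_uncalled = r3.n_removed_uncalled
        out, r4 = filter_maf(out, min_maf)
        removed_maf = r4.n_removed_maf
    report = FilterReport(
        n_input_loci=g.n_loci,
        n_removed_missingness=r1.n_removed_missingness,
        n_removed_heterozygosity=r2.n_removed_heterozygosity,
        n_removed_uncalled=removed_uncalled,
        n_removed_maf=removed_maf,
        n_retained=out.n_loci,
    )
    return out, report
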