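"""ABC summary statistics: reduce genotypes + population map to a
fixed-order vector.

The 60-statistic default set mirrors the SNP-mode defaults of
reference-table ABC tools: per-population expected heterozygosity (5),
per-population proportion of within-population monomorphic loci (5),
pairwise Weir-Cockerham FST (10), pairwise Nei (1972) standard distance
(10), and the admixture statistic f3(T; A, B) for every target and
unordered donor pair (30).  f3 is computed without the within-population
bias correction: simulated and observed statistics are computed
identically, so any bias cancels in the ABC comparison.

Missing calls are excluded per locus per population; a locus uncalled in
a population is dropped from every statistic involving that population.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap
from .popgen_stats import _per_pop_counts, weir_cockerham_components


def summary_names(groups: list[str]) -> list[str]:
    names = [f"Hexp_{g}" for g in groups]
    names += [f"mono_{g}" for g in groups]
    names += [f"fst_{a}_{b}" for a, b in combinations(groups, 2)]
    names += [f"nei_{a}_{b}" for a, b in combinations(groups, 2)]
    for t in groups:
        others = [g for g in groups if g != t]
        names += [f"f3_{t}_{a}_{b}" for a, b in combinations(others, 2)]
    return names


SUMMARY_NAMES: list[str] = summary_names(["MC", "CIC", "CILL1", "CILL2", "CILL3"])


def compute_summaries(
    g: GenotypeMatrix, pops: PopulationMap, groups: list[str] | None = None
) -> pd.Series:
    """Summary-statistic vector, fixed order given the group list."""
    if groups is None:
        groups = pops.groups
    for grp in groups:
        if len(pops.samples_in(grp)) < 2:
            raise ValueError(f"group {grp!r} needs at least 2 samples")
    _, codes = pops.group_indices(g.sample_ids, groups)
    k = len(groups)
    n, p, _ = _per_pop_counts(g.calls, codes, k)
    called = n > 0
    q = 1.0 - p
    values: list[float] = []
    # per-pop expected heterozygosity, small-sample corrected: 2p(1-p) * 2n/(2n-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hexp = 2.0 * p * q * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0)
    for i in range(k):
        values.append(float(np.nanmean(np.where(called[i], hexp[i], np.nan))))
    # per-pop monomorphic proportion
    for i in range(k):
        mono = (p[i] == 0.0) | (p[i] == 1.0)
        values.append(float(mono[called[i]].mean()))
    # pairwise Weir-Cockerham FST (ratio of averages over loci)
    for i, j in combinations(range(k), 2):
        pair_codes = np.full_like(codes, -1)
        pair_codes[codes == i] = 0
        pair_codes[codes == j] = 1
        a, total = weir_cockerham_components(g.calls, pair_codes, 2)
        ok = ~np.isnan(total)
        denom = total[ok].sum()
        values.append(float(a[ok].sum() / denom) if denom != 0 else 0.0)
    # pairwise Nei standard distance
    for i, j in combinations(range(k), 2):
        both = called[i] & called[j]
        ji = (p[i] ** 2 + q[i] ** 2)[both].mean()
        jj = (p[j] ** 2 + q[j] ** 2)[both].mean()
        jij = (p[i] * p[j] + q[i] * q[j])[both].mean()
        values.append(float(-np.log(jij / np.sqrt(ji * jj))))
    # f3(T; A, B) over all targets and donor pairs
    for t in range(k):
        others = [o for o in range(k) if o != t]
        for a_, b_ in combinations(others, 2):
            use = called[t] & called[a_] & called[b_]
            f3 = ((p[t] - p[a_]) * (p[t] - p[b_]))[use].mean()
            values.append(float(f3))
    return pd.Series(values, index=summary_names(groups), dtype=float)


def summary_matrix(
    sims: list[tuple[int, dict, GenotypeMatrix]],
    pops: PopulationMap,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """One row per simulation: scenario id, parameter values, summaries.

    Parameter names are unioned across scenarios (NaN where a scenario
    lacks a parameter); summary columns are complete.
    """
    if not sims:
        raise ValueError("no simulations given")
    n_samples = {m.n_samples for _, _, m in sims}
    if len(n_samples) != 1:
        raise ValueError("inconsistent sample sizes across simulations")
    rows = []
    for sid, params, mat in sims:
        row = {"scenario": sid}
        row.update({f"param_{k}": v for k, v in params.items()})
        row.update(compute_summaries(mat, pops, groups).to_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    stat_cols = summary_names(groups if groups is not None else pops.groups)
    param_cols = sorted(c for c in df.columns if c.startswith("param_"))
    return df[["scenario"] + param_cols + stat_cols]


def observed_summaries_matched(
    g: GenotypeMatrix,
    pops: PopulationMap,
    n_loci: int,
    seed: int = 0,
    groups: list[str] | None = None,
) -> pd.Series:
    """Observed summary vector computed on a random subsample of `n_loci`
    loci (without replacement).

    ABC compares observed and simulated summaries, so both must be
    computed identically — including the number of loci, which sets the
    sampling noise of every statistic.  When the reference table is built
    from `n_loci`-locus simulations, the observed vector is computed on a
    seeded random subsample of the same size; if the dataset has at most
    `n_loci` loci it is used in full.
    """
    if g.n_loci > n_loci:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(g.n_loci, size=n_loci, replace=False))
        g = g.take_loci(idx)
    return compute_summaries(g, pops, groups)
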