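import numpy as np
import pytest

from lakelock.coalescent import (
    SampleConfig,
    SimConfig,
    SimulationError,
    default_popmap,
    drop_snp_mutation,
    simulate_dataset,
    simulate_genealogy,
)
from lakelock.popgen_stats import weir_cockerham_components
from lakelock.scenarios import get_scenario
from lakelock.snp_filters import pooled_maf


def panmictic_params(N=1000.0):
    """Scenario 1 with every split at time 0: a single population of size N
    (all population sizes equal, merges immediate)."""
    spec = get_scenario(1)
    params = {f"N_{p}": N for p in spec.populations}
    params.update(t_CILL1=0.0, t_CILL2=0.0, t_CILL3=0.0, t_root=0.0)
    return spec, params


def tiny_samples(per_pop=1):
    return SampleConfig(tuple((p, per_pop) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))


def test_pair_tmrca_matches_coalescent_expectation():
    """Two lineages in one population of size N coalesce after ~2N
    generations on average."""
    spec = get_scenario(1)
    params = {f"N_{p}": 500.0 for p in spec.populations}
    params.update(t_CILL1=0.0, t_CILL2=0.0, t_CILL3=0.0, t_root=0.0)
    sc = SampleConfig((("MC", 1), ("CIC", 1), ("CILL1", 1), ("CILL2", 1), ("CILL3", 1)))
    # 10 lineages panmictic; E[TMRCA] = 4N(1 - 1/n)
    tm = [simulate_genealogy(spec, params, sc, seed=i).tmrca for i in range(4000)]
    n = 10
    expected = 4 * 500.0 * (1 - 1 / n)
    assert np.mean(tm) == pytest.approx(expected, rel=0.05)


def test_total_tree_length_matches_closed_form():
    """E[total length] = 4N * sum_{i=1}^{n-1} 1/i for a panmictic sample."""
    spec, params = panmictic_params(N=1000.0)
    sc = tiny_samples(1)  # n = 10 lineages
    lengths = [
        simulate_genealogy(spec, params, sc, seed=10_000 + i).total_branch_length
        for i in range(4000)
    ]
    h9 = sum(1 / i for i in range(1, 10))
    assert np.mean(lengths) == pytest.approx(4 * 1000.0 * h9, rel=0.05)


def test_zero_time_splits_equal_panmixia():
    """Splits at t=0 merge immediately: TMRCA matches the one-population
    expectation even though lineages start in five demes."""
    spec, params = panmictic_params(N=800.0)
    sc = tiny_samples(2)  # 20 lineages
    tm = [simulate_genealogy(spec, params, sc, seed=i).tmrca for i in range(3000)]
    assert np.mean(tm) == pytest.approx(4 * 800.0 * (1 - 1 / 20), rel=0.06)


def test_length_weighted_sfs_follows_one_over_i_law():
    """Weighting each locus by its total tree length recovers the neutral
    site-frequency spectrum P(i) = (1/i) / H_{n-1}.  (Unweighted single-SNP
    conditioning gives E[L_i/L] instead, with a slight singleton excess.)"""
    spec, params = panmictic_params()
    sc = tiny_samples(1)  # n = 10
    h9 = sum(1 / i for i in range(1, 10))
    w = np.zeros(10)
    for i in range(8000):
        g = simulate_genealogy(spec, params, sc, seed=50_000 + i)
        d = int(drop_snp_mutation(g, seed=90_000 + i).sum())
        w[d] += g.total_branch_length
    obs = w[1:] / w.sum()
    expected = np.array([1 / i for i in range(1, 10)]) / h9
    assert np.abs(obs - expected).max() < 0.02
    assert w[0] == 0.0  # never monomorphic


def test_mutation_output_is_polymorphic():
    spec, params = panmictic_params()
    sc = tiny_samples(2)
    for i in range(50):
        g = simulate_genealogy(spec, params, sc, seed=i)
        d = drop_snp_mutation(g, seed=1000 + i)
        assert 0 < d.sum() < len(d)


def test_drift_fst_matches_expectation():
    """Two populations split t = 0.2 x 2N generations ago: multi-locus
    Weir-Cockerham FST ~ 1 - exp(-0.2)."""
    spec = get_scenario(1)
    N = 10_000.0
    t = 0.2 * 2 * N
    params = {f"N_{p}": N for p in spec.populations}
    params.update(t_CILL1=0.0, t_CILL2=0.0, t_CILL3=t, t_root=t)
    sc = SampleConfig((("MC", 2), ("CIC", 25), ("CILL1", 2), ("CILL2", 2), ("CILL3", 25)))
    mat = simulate_dataset(spec, params, sc, SimConfig(n_loci=3000, maf_threshold=0.0, seed=11))
    pops = default_popmap(sc)
    _, codes = pops.group_indices(mat.sample_ids, ["CIC", "CILL3"])
    a, tot = weir_cockerham_components(mat.calls, codes, 2)
    ok = ~np.isnan(tot)
    theta = a[ok].sum() / tot[ok].sum()
    assert theta == pytest.approx(1 - np.exp(-0.2), abs=0.025)


def test_fst_increases_with_split_time():
    """Older splits give monotonically larger expected pairwise FST."""
    spec = get_scenario(1)
    N = 10_000.0
    sc = SampleConfig((("MC", 2), ("CIC", 20), ("CILL1", 2), ("CILL2", 2), ("CILL3", 20)))
    pops = default_popmap(sc)
    thetas = []
    for k, frac in enumerate([0.05, 0.15, 0.4, 1.0]):
        t = frac * 2 * N
        params = {f"N_{p}": N for p in spec.populations}
        params.update(t_CILL1=0.0, t_CILL2=0.0, t_CILL3=t, t_root=t)
        mat = simulate_dataset(spec, params, sc, SimConfig(n_loci=1500, maf_threshold=0.0, seed=40 + k))
        _, codes = pops.group_indices(mat.sample_ids, ["CIC", "CILL3"])
        a, tot = weir_cockerham_components(mat.calls, codes, 2)
        ok = ~np.isnan(tot)
        thetas.append(a[ok].sum() / tot[ok].sum())
    assert thetas == sorted(thetas)


def test_maf_conditioning_never_below_threshold():
    spec, params = panmictic_params()
    sc = tiny_samples(4)
    mat = simulate_dataset(spec, params, sc, SimConfig(n_loci=300, maf_threshold=0.2, seed=5))
    assert (pooled_maf(mat) >= 0.2).all()


def test_same_seed_runs_are_identical():
    spec = get_scenario(7)
    from lakelock.scenarios import PriorSpec, draw_parameters

    params = draw_parameters(spec, PriorSpec(), seed=9)
    sc = tiny_samples(3)
    cfg = SimConfig(n_loci=80, maf_threshold=0.05, seed=123)
    a = simulate_dataset(spec, params, sc, cfg)
    b = simulate_dataset(spec, params, sc, cfg)
    assert a == b
    c = simulate_dataset(spec, params, sc, SimConfig(n_loci=80, maf_threshold=0.05, seed=124))
    assert c != a


def test_unreachable_maf_raises_simulation_error():
    spec, params = panmictic_params()
    sc = tiny_samples(4)
    with pytest.raises(SimulationError, match="MAF"):
        simulate_dataset(
            spec, params, sc,
            SimConfig(n_loci=5, maf_threshold=0.49, seed=3, max_redraws_per_locus=2),
        )


def test_constraint_violating_parameters_rejected():
    spec = get_scenario(1)
    params = {f"N_{p}": 100.0 for p in spec.populations}
    params.update(t_CILL1=500.0, t_CILL2=100.0, t_CILL3=200.0, t_root=1000.0)
    with pytest.raises(ValueError, match="constraints"):
        simulate_dataset(spec, params, tiny_samples(1), SimConfig(n_loci=2, seed=0))


def test_two_population_tmrca_matches_msprime():
    """Cross-check against an independent coalescent implementation:
    mean TMRCA of a two-population split model agrees with msprime."""
    msprime = pytest.importorskip("msprime")
    N, t = 5_000.0, 4_000.0
    spec = get_scenario(1)
    params = {f"N_{p}": N for p in spec.populations}
    params.update(t_CILL1=0.0, t_CILL2=0.0, t_CILL3=0.0, t_root=t)
    # MC vs the (instantly merged) island side: effectively 2 demes of size N
    sc = SampleConfig((("MC", 3), ("CIC", 3), ("CILL1", 1), ("CILL2", 1), ("CILL3", 1)))
    ours = [simulate_genealogy(spec, params, sc, seed=i).tmrca for i in range(2500)]

    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=N)
    dem.add_population(name="B", initial_size=N)
    dem.add_population(name="anc", initial_size=N)
    dem.add_population_split(time=t, derived=["A", "B"], ancestral="anc")
    theirs = []
    for i in range(800):
        ts = msprime.sim_ancestry(
            {"A": 3, "B": 6}, demography=dem, ploidy=2, random_seed=i + 1
        )
        tree = ts.first()
        theirs.append(tree.time(tree.root))
    assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.06)
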