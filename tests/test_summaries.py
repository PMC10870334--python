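import numpy as np
import pandas as pd
import pytest

from lakelock.genotype_io import GenotypeMatrix, PopulationMap
from lakelock.summaries import SUMMARY_NAMES, compute_summaries, summary_matrix, summary_names

from .conftest import random_instance
from .oracles import summaries_oracle, wc_theta_oracle


def test_summary_vector_layout():
    assert len(SUMMARY_NAMES) == 60
    assert SUMMARY_NAMES[:5] == [f"Hexp_{g}" for g in ("MC", "CIC", "CILL1", "CILL2", "CILL3")]
    assert sum(n.startswith("fst_") for n in SUMMARY_NAMES) == 10
    assert sum(n.startswith("nei_") for n in SUMMARY_NAMES) == 10
    assert sum(n.startswith("f3_") for n in SUMMARY_NAMES) == 30
    assert len(set(SUMMARY_NAMES)) == 60


def test_null_structure_statistics_near_zero():
    """Five arbitrary labels over one panmictic sample: differentiation
    statistics hover around zero.  Nei's D and f3 are computed without
    finite-sample correction, so they carry an O(1/2n) positive offset
    (~0.025 at 20 diploids/group); the tolerance covers bias plus noise,
    while the sample-size-corrected FST is held tighter."""
    rng = np.random.default_rng(2)
    p = rng.uniform(0.2, 0.8, size=800)
    n = 100
    calls = ((rng.random((n, 800)) < p).astype(np.int8)
             + (rng.random((n, 800)) < p).astype(np.int8))
    g = GenotypeMatrix([f"s{i}" for i in range(n)],
                       [f"c1:{j + 1}" for j in range(800)], calls)
    pops = PopulationMap({f"s{i}": f"P{i % 5}" for i in range(n)})
    s = compute_summaries(g, pops)
    for name, val in s.items():
        if name.startswith("fst_"):
            assert abs(val) < 0.02, name
        elif name.startswith(("nei_", "f3_")):
            assert abs(val) < 0.05, name


def test_admixed_target_gives_negative_f3(toy_fixtures):
    """A 50:50 admixed target between fixed-difference donors has
    f3(T; A, B) = (0.5-0)(0.5-1) = -0.25 per locus."""
    bundle = toy_fixtures["admixture_f3"]
    s = compute_summaries(bundle["genotypes"], bundle["popmap"])
    assert s["f3_T_A_B"] == pytest.approx(-0.25, abs=1e-12)
    assert s["f3_T_A_B"] < 0


@pytest.mark.parametrize("seed", [20, 21, 22, 23])
def test_summaries_match_scalar_oracle(seed):
    """Every statistic agrees with a scalar-loop oracle on random small
    instances (heterozygosity, monomorphic fraction, FST, Nei D, f3)."""
    g, pops, codes, k = random_instance(seed, max_pops=3, max_per_pop=5, max_loci=4)
    if k < 2:
        pytest.skip("need >= 2 groups for pairwise statistics")
    groups = pops.groups
    s = compute_summaries(g, pops)
    exp = summaries_oracle(g.calls.tolist(), codes.tolist(), k)
    for gi, grp in enumerate(groups):
        assert s[f"Hexp_{grp}"] == pytest.approx(exp[f"Hexp_{gi}"], abs=1e-12)
        assert s[f"mono_{grp}"] == pytest.approx(exp[f"mono_{gi}"], abs=1e-12)
    for a in range(k):
        for b in range(a + 1, k):
            assert s[f"nei_{groups[a]}_{groups[b]}"] == pytest.approx(
                exp[f"nei_{a}_{b}"], abs=1e-12
            )
            pair_codes = np.where(codes == a, 0, np.where(codes == b, 1, -1))
            assert s[f"fst_{groups[a]}_{groups[b]}"] == pytest.approx(
                wc_theta_oracle(g.calls.tolist(), pair_codes.tolist()), abs=1e-12
            )
    for name in s.index:
        if name.startswith("f3_"):
            t, a, b = name.split("_")[1:]
            gi = {grp: i for i, grp in enumerate(groups)}
            assert s[name] == pytest.approx(
                exp[f"f3_{gi[t]}_{gi[a]}_{gi[b]}"], abs=1e-12
            )


def test_invariance_to_relabelling_and_locus_order():
    """The summary vector ignores sample order within populations and
    locus order."""
    g, pops, codes, k = random_instance(31, max_pops=3)
    if k < 2:
        g, pops, codes, k = random_instance(33, max_pops=3)
    base = compute_summaries(g, pops)
    rng = np.random.default_rng(0)
    # shuffle loci
    perm = rng.permutation(g.n_loci)
    g_loci = g.take_loci(perm)
    assert compute_summaries(g_loci, pops).equals(base)
    # shuffle samples within populations
    order = []
    for grp in pops.groups:
        idx = [i for i, s in enumerate(g.sample_ids) if pops.assignments[s] == grp]
        order.extend(rng.permutation(idx).tolist())
    g_samp = g.take_samples(np.array(order))
    out = compute_summaries(g_samp, pops)
    assert np.allclose(out.to_numpy(), base.to_numpy())


def test_summary_matrix_rows_match_individual_calls():
    from lakelock.coalescent import SampleConfig, SimConfig, default_popmap, simulate_dataset
    from lakelock.scenarios import PriorSpec, draw_parameters, get_scenario

    spec = get_scenario(1)
    sc = SampleConfig(tuple((p, 3) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))
    pops = default_popmap(sc)
    sims = []
    for i in range(3):
        params = draw_parameters(spec, PriorSpec(), seed=i)
        mat = simulate_dataset(spec, params, sc, SimConfig(n_loci=40, seed=i))
        sims.append((1, params, mat))
    df = summary_matrix(sims, pops)
    assert len(df) == 3
    assert list(df["scenario"]) == [1, 1, 1]
    stat_cols = summary_names(list(pops.groups))
    assert df.columns.tolist()[-60:] == stat_cols
    for i, (_, params, mat) in enumerate(sims):
        expect = compute_summaries(mat, pops)
        assert np.allclose(df.loc[i, stat_cols].to_numpy(float), expect.to_numpy())
    # permuting the sims permutes rows only
    df2 = summary_matrix(sims[::-1], pops)
    assert np.allclose(
        df2[stat_cols].to_numpy(float), df[stat_cols].to_numpy(float)[::-1]
    )


def test_summary_matrix_rejects_inconsistent_sample_sizes():
    from lakelock.coalescent import SampleConfig, SimConfig, default_popmap, simulate_dataset
    from lakelock.scenarios import PriorSpec, draw_parameters, get_scenario

    spec = get_scenario(1)
    params = draw_parameters(spec, PriorSpec(), seed=0)
    sc3 = SampleConfig(tuple((p, 3) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))
    sc2 = SampleConfig(tuple((p, 2) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))
    m3 = simulate_dataset(spec, params, sc3, SimConfig(n_loci=20, seed=1))
    m2 = simulate_dataset(spec, params, sc2, SimConfig(n_loci=20, seed=2))
    with pytest.raises(ValueError, match="inconsistent sample sizes"):
        summary_matrix([(1, params, m3), (1, params, m2)], None)


def test_mean_fst_increases_with_divergence_time():
    """Mean simulated FST(CIC, CILL3) rises monotonically in t_CILL3."""
    from lakelock.coalescent import SampleConfig, SimConfig, default_popmap, simulate_dataset
    from lakelock.scenarios import get_scenario

    spec = get_scenario(1)
    sc = SampleConfig(tuple((p, 6) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))
    pops = default_popmap(sc)
    N = 5000.0
    means = []
    for k, t in enumerate([500.0, 2000.0, 8000.0, 30000.0]):
        vals = []
        for r in range(6):
            params = {f"N_{p}": N for p in spec.populations}
            params.update(t_CILL1=100.0, t_CILL2=200.0, t_CILL3=t, t_root=60000.0)
            mat = simulate_dataset(
                spec, params, sc, SimConfig(n_loci=250, seed=1000 * k + r)
            )
            vals.append(compute_summaries(mat, pops)["fst_CIC_CILL3"])
        means.append(np.mean(vals))
    assert means == sorted(means)


def test_group_with_one_sample_rejected():
    g, pops, _, _ = random_instance(40, max_pops=2)
    bad = PopulationMap({**pops.assignments, "extra": "LONER"})
    g2 = GenotypeMatrix(
        g.sample_ids + ["extra"],
        g.locus_ids,
        np.vstack([g.calls, np.ones((1, g.n_loci), dtype=np.int8)]),
    )
    with pytest.raises(ValueError, match="at least 2 samples"):
        compute_summaries(g2, bad)
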