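import numpy as np
import pandas as pd
import pytest

from lakelock.abc_rf import (
    GENERATIONS_PER_YEAR,
    ReferenceTable,
    build_reference_table,
    choose_model,
    error_rates,
    estimate_parameters,
)
from lakelock.coalescent import SampleConfig, SimConfig
from lakelock.scenarios import PriorSpec, enumerate_scenarios, get_scenario

STATS = ["s1", "s2", "s3"]


def fake_table(rng, centers, n_per=150, spread=1.0, params=None):
    """Reference table with Gaussian summary clouds per scenario id."""
    rows = []
    for sid, mu in centers.items():
        x = rng.normal(mu, spread, size=(n_per, len(STATS)))
        for r in range(n_per):
            row = {"scenario": sid}
            if params is not None:
                row.update({f"param_{k}": v(rng, x[r]) for k, v in params.items()})
            row.update(dict(zip(STATS, x[r])))
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows), STATS)


def small_sample_config():
    return SampleConfig(tuple((p, 3) for p in ("MC", "CIC", "CILL1", "CILL2", "CILL3")))


def test_build_reference_table_bookkeeping_and_determinism():
    specs = [get_scenario(1), get_scenario(13)]
    cfg = SimConfig(n_loci=30, maf_threshold=0.05, seed=5)
    t1 = build_reference_table(specs, PriorSpec(), small_sample_config(), 4, cfg)
    assert len(t1.df) == 8
    assert t1.df["scenario"].value_counts().to_dict() == {1: 4, 13: 4}
    # union of parameter columns, NaN where a scenario lacks the parameter
    assert t1.df["param_t_LL"].isna().sum() == 4
    t2 = build_reference_table(specs, PriorSpec(), small_sample_config(), 4, cfg)
    pd.testing.assert_frame_equal(t1.df, t2.df)


def test_reference_table_round_trips_through_tsv(tmp_path):
    t = build_reference_table(
        [get_scenario(2)], PriorSpec(), small_sample_config(), 3,
        SimConfig(n_loci=20, seed=1),
    )
    path = tmp_path / "table.tsv"
    t.save(path)
    back = ReferenceTable.load(path)
    assert back.stat_names == t.stat_names
    pd.testing.assert_frame_equal(back.df, t.df, check_exact=False, rtol=1e-12)


def test_votes_sum_to_one_and_winner_is_argmax():
    rng = np.random.default_rng(0)
    table = fake_table(rng, {1: [0, 0, 0], 2: [4, 4, 4], 3: [-4, 4, 0]})
    res = choose_model(table, np.array([4.1, 3.9, 4.0]), n_trees=100, seed=1)
    assert sum(res.votes.values()) == pytest.approx(1.0, abs=1e-9)
    assert res.selected_scenario == max(res.votes, key=res.votes.get)
    assert res.selected_scenario == 2
    assert res.votes[2] > 0.9
    assert res.posterior_probability > 0.8
    assert res.prior_error < 0.1


def test_indistinguishable_scenarios_split_votes():
    """Two scenarios with identical simulators: the prior error approaches
    the random-guess rate 0.5, and votes averaged over observed points are
    ~50/50 (votes at any single point are noisy: trees are correlated)."""
    rng = np.random.default_rng(3)
    table = fake_table(rng, {1: [0, 0, 0], 2: [0, 0, 0]}, n_per=300)
    votes1 = []
    for k in range(5):
        obs = rng.normal(0, 0.3, size=3)
        res = choose_model(table, obs, n_trees=200, seed=2 + k)
        votes1.append(res.votes[1])
        assert res.prior_error == pytest.approx(0.5, abs=0.07)
    assert np.mean(votes1) == pytest.approx(0.5, abs=0.2)


def test_choose_model_requires_two_scenarios():
    rng = np.random.default_rng(1)
    table = fake_table(rng, {1: [0, 0, 0]})
    with pytest.raises(ValueError, match="two scenarios"):
        choose_model(table, np.array([0.0, 0.0, 0.0]), n_trees=10, seed=0)


def test_estimates_recover_an_identifiable_parameter():
    """When a parameter is (noisily) encoded in a statistic, the QRF point
    estimate tracks it monotonically (rank correlation > 0.9) and the 95%
    interval brackets the point estimate."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(7)
    rows = []
    for _ in range(2500):
        theta = rng.uniform(0, 100)
        rows.append(
            {
                "scenario": 1,
                "param_t_x": theta,
                "s1": theta + rng.normal(0, 4),
                "s2": rng.normal(0, 1),
                "s3": rng.normal(0, 1),
            }
        )
    table = ReferenceTable(pd.DataFrame(rows), STATS)
    truths = np.linspace(10, 90, 9)
    points = []
    for tval in truths:
        obs = np.array([tval, 0.0, 0.0])
        est = estimate_parameters(table, obs, n_trees=100, seed=4)
        e = est.estimates["t_x"]
        assert e["q025"] <= e["point"] <= e["q975"]
        points.append(e["point"])
    rho = spearmanr(truths, points).statistic
    assert rho > 0.9
    assert np.abs(np.array(points) - truths).max() < 12


def test_constant_parameter_returned_exactly():
    rng = np.random.default_rng(9)
    rows = [
        {"scenario": 1, "param_t_x": 10.0, **dict(zip(STATS, rng.normal(size=3)))}
        for _ in range(50)
    ]
    table = ReferenceTable(pd.DataFrame(rows), STATS)
    est = estimate_parameters(table, np.zeros(3), n_trees=20, seed=0)
    assert est.estimates["t_x"] == {
        "point": 10.0, "q025": 10.0, "q975": 10.0,
        "point_years": 10.0, "q025_years": 10.0, "q975_years": 10.0,
    }


def test_years_conversion_is_identity():
    """One generation per year: the years fields equal the generations
    fields exactly."""
    assert GENERATIONS_PER_YEAR == 1.0
    rng = np.random.default_rng(11)
    rows = [
        {
            "scenario": 1,
            "param_t_x": rng.uniform(0, 100),
            "param_N_y": rng.uniform(0, 100),
            **dict(zip(STATS, rng.normal(size=3))),
        }
        for _ in range(200)
    ]
    table = ReferenceTable(pd.DataFrame(rows), STATS)
    est = estimate_parameters(table, np.zeros(3), n_trees=50, seed=1)
    e = est.estimates["t_x"]
    assert e["point_years"] == e["point"]
    assert e["q025_years"] == e["q025"] and e["q975_years"] == e["q975"]
    assert "point_years" not in est.estimates["N_y"]  # sizes are not times


def test_estimation_requires_single_scenario_table():
    rng = np.random.default_rng(13)
    table = fake_table(rng, {1: [0, 0, 0], 2: [3, 3, 3]})
    with pytest.raises(ValueError, match="single-scenario"):
        estimate_parameters(table, np.zeros(3), n_trees=10, seed=0)
    with pytest.raises(ValueError, match="unknown parameters"):
        estimate_parameters(
            table.for_scenario(1), np.zeros(3), n_trees=10, seed=0, params=["nope"]
        )


def test_error_rates_separable_and_random_cases():
    rng = np.random.default_rng(17)
    sep = fake_table(rng, {1: [0, 0, 0], 2: [8, 8, 8]}, n_per=200)
    rep = error_rates(sep, 1, observed=np.array([0.1, 0.0, -0.1]), n_pseudo=200,
                      n_trees=100, seed=3)
    assert rep.global_error < 0.02
    assert rep.local_error < 0.05
    same = fake_table(rng, {1: [0, 0, 0], 2: [0, 0, 0], 3: [0, 0, 0]}, n_per=200)
    rep2 = error_rates(same, 2, observed=np.array([0.0, 0.0, 0.0]), n_pseudo=200,
                       n_trees=100, seed=4)
    assert rep2.global_error == pytest.approx(2 / 3, abs=0.08)
    for rep_i in (rep, rep2):
        assert 0.0 <= rep_i.global_error <= 1.0
        assert 0.0 <= rep_i.local_error <= 1.0
        for v in rep_i.per_parameter_error.values():
            assert 0.0 <= v <= 1.0


def test_prior_error_decreases_with_training_size():
    """On a fixed hard scenario pair (0.8 sigma separation on one axis,
    Bayes error ~0.34), the out-of-bag error weakly decreases as the
    training set grows."""
    rng = np.random.default_rng(23)
    errors = []
    for n_per in (40, 250, 1500):
        table = fake_table(rng, {1: [0, 0, 0], 2: [0.8, 0, 0]}, n_per=n_per)
        res = choose_model(table, np.zeros(3), n_trees=200, seed=5)
        errors.append(res.prior_error)
    assert errors[2] <= errors[0] + 0.02
    assert errors[2] < 0.48


def test_scenario_one_training_rows_have_complete_parameters():
    t = build_reference_table(
        [get_scenario(1)], PriorSpec(), small_sample_config(), 5,
        SimConfig(n_loci=25, seed=8),
    )
    assert set(t.param_names) == {
        "N_MC", "N_CIC", "N_CILL1", "N_CILL2", "N_CILL3", "N_ANC",
        "t_CILL1", "t_CILL2", "t_CILL3", "t_root",
    }
    assert not t.df[[f"param_{p}" for p in t.param_names]].isna().any().any()
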