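"""Random-forest ABC: scenario choice, parameter estimation, error rates.

Model choice trains a classification forest on the reference table
(summary statistics, optionally augmented with linear-discriminant axes);
the *votes* for a scenario are the fraction of trees choosing it at the
observed point, and the winner's posterior probability is estimated as
1 minus the prediction of a regression forest trained on the out-of-bag
misclassification indicators (the ABC-RF construction).  The global
(prior) error rate is the classifier's out-of-bag misclassification rate;
the local (posterior) error re-weights out-of-bag errors by how often a
training simulation shares a leaf with the observed data.

Parameter estimation uses quantile regression forests: the point estimate
is the forest prediction at the observed statistics and the 95% interval
comes from weighted quantiles of the training responses, with weights
given by leaf co-occurrence with the observed point.  Times are reported
in generations and in years at one generation per year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalescent import SampleConfig, SimConfig, SimulationError, default_popmap, simulate_dataset
from .scenarios import PriorSpec, ScenarioSpec, draw_parameters
from .summaries import compute_summaries, summary_names

GENERATIONS_PER_YEAR = 1.0  # one-year life cycle: years = generations


@dataclass
class ReferenceTable:
    """ABC training set: (scenario id, parameters, summary statistics) rows.

    Parameter columns are prefixed ``param_`` and may be NaN for scenarios
    lacking that parameter; summary-statistic columns are complete.
    """

    df: pd.DataFrame
    stat_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.stat_names if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table lacks statistic columns {missing}")
        if self.df[self.stat_names].isna().any().any():
            raise ValueError("missing cells in summary-statistic columns")
        if "scenario" not in self.df.columns:
            raise ValueError("reference table lacks a 'scenario' column")

    @property
    def scenario_ids(self) -> list[int]:
        return sorted(self.df["scenario"].unique().tolist())

    @property
    def param_names(self) -> list[str]:
        return [
            c[len("param_"):]
            for c in self.df.columns
            if c.startswith("param_") and self.df[c].notna().all()
        ]

    def X(self) -> np.ndarray:
        return self.df[self.stat_names].to_numpy(float)

    def y(self) -> np.ndarray:
        return self.df["scenario"].to_numpy(int)

    def for_scenario(self, scenario_id: int) -> "ReferenceTable":
        sub = self.df[self.df["scenario"] == scenario_id].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no rows for scenario {scenario_id}")
        sub = sub.dropna(axis=1, how="all")
        return ReferenceTable(sub, self.stat_names, dict(self.metadata))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# metadata: " + json.dumps(self.metadata, default=str) + "\n")
            fh.write("# stats: " + json.dumps(self.stat_names) + "\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            meta_line = fh.readline()
            stats_line = fh.readline()
            df = pd.read_csv(fh, sep="\t")
        metadata = json.loads(meta_line.split(":", 1)[1])
        stat_names = json.loads(stats_line.split(":", 1)[1])
        return cls(df, stat_names, metadata)


@dataclass
class ModelChoiceResult:
    votes: dict[int, float]  # fraction of trees per scenario, sums to 1
    selected_scenario: int
    posterior_probability: float
    prior_error: float
    n_trees: int

    def to_dict(self) -> dict:
        return {
            "votes": {str(k): v for k, v in self.votes.items()},
            "selected_scenario": self.selected_scenario,
            "posterior_probability": self.posterior_probability,
            "prior_error": self.prior_error,
            "n_trees": self.n_trees,
        }


@dataclass
class ParamEstimateResult:
    """Per-parameter point estimate and central 95% interval.

    Time parameters are in generations; ``*_years`` fields convert at one
    generation per year.
    """

    scenario_id: int
    estimates: dict[str, dict[str, float]]
    n_trees: int
    generations_per_year: float = GENERATIONS_PER_YEAR

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "estimates": self.estimates,
            "n_trees": self.n_trees,
            "generations_per_year": self.generations_per_year,
        }


@dataclass
class ErrorReport:
    global_error: float
    local_error: float
    per_parameter_error: dict[str, float]
    n_pseudo_observed: int

    def to_dict(self) -> dict:
        return {
            "global_error": self.global_error,
            "local_error": self.local_error,
            "per_parameter_error": self.per_parameter_error,
            "n_pseudo_observed": self.n_pseudo_observed,
        }


def build_reference_table(
    scenarios: list[ScenarioSpec],
    priors: PriorSpec | None = None,
    samples: SampleConfig | None = None,
    n_per_scenario: int = 2000,
    sim_cfg: SimConfig | None = None,
    groups: list[str] | None = None,
) -> ReferenceTable:
    """Simulate `n_per_scenario` reference-table rows per scenario.

    Fully reproducible from ``sim_cfg.seed``: per-simulation seeds are
    spawned from a :class:`numpy.random.SeedSequence`.
    """
    if priors is None:
        priors = PriorSpec()
    if samples is None:
        samples = SampleConfig()
    if sim_cfg is None:
        sim_cfg = SimConfig()
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    pops = default_popmap(samples)
    if groups is None:
        groups = list(samples.populations)
    stat_names = summary_names(groups)
    children = np.random.SeedSequence(sim_cfg.seed).spawn(len(scenarios) * n_per_scenario)
    rows = []
    idx = 0
    for spec in scenarios:
        for draw in range(n_per_scenario):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            params = draw_parameters(spec, priors, rng)
            locus_seed = int(child.generate_state(1)[0]) % (2**31)
            try:
                mat = simulate_dataset(
                    spec,
                    params,
                    samples,
                    SimConfig(
                        n_loci=sim_cfg.n_loci,
                        maf_threshold=sim_cfg.maf_threshold,
                        seed=locus_seed,
                        max_redraws_per_locus=sim_cfg.max_redraws_per_locus,
                    ),
                )
            except SimulationError as exc:
                raise SimulationError(
                    f"scenario {spec.scenario_id}, draw {draw}: {exc}"
                ) from exc
            row = {"scenario": spec.scenario_id}
            row.update({f"param_{k}": v for k, v in params.items()})
            row.update(compute_summaries(mat, pops, groups).to_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    param_cols = sorted(c for c in df.columns if c.startswith("param_"))
    df = df[["scenario"] + param_cols + stat_names]
    metadata = {
        "priors": {"lower": priors.lower, "upper": priors.upper},
        "samples": dict(samples.n_per_pop),
        "seed": sim_cfg.seed,
        "n_loci": sim_cfg.n_loci,
        "maf_threshold": sim_cfg.maf_threshold,
        "n_per_scenario": n_per_scenario,
    }
    return ReferenceTable(df, stat_names, metadata)


def _as_vector(observed, stat_names: list[str]) -> np.ndarray:
    if isinstance(observed, pd.Series):
        missing = [s for s in stat_names if s not in observed.index]
        if missing:
            raise ValueError(f"observed vector lacks statistics {missing}")
        return observed[stat_names].to_numpy(float)
    arr = np.asarray(observed, float)
    if arr.shape != (len(stat_names),):
        raise ValueError("observed vector does not match table statistics")
    return arr


def _augment(X: np.ndarray, y: np.ndarray, obs: np.ndarray, use_lda: bool):
    if not use_lda or len(np.unique(y)) < 2:
        return X, obs
    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    return (
        np.hstack([X, lda.transform(X)]),
        np.hstack([obs, lda.transform(obs.reshape(1, -1))[0]]),
    )


def _oob_predictions(clf: RandomForestClassifier, y: np.ndarray):
    """Out-of-bag class predictions; samples never out of bag get NaN votes."""
    dec = clf.oob_decision_function_
    valid = ~np.isnan(dec).any(axis=1) & (dec.sum(axis=1) > 0)
    pred = np.full(len(y), -1, dtype=int)
    pred[valid] = clf.classes_[np.argmax(dec[valid], axis=1)]
    return pred, valid


def choose_model(
    table: ReferenceTable,
    observed,
    n_trees: int = 500,
    seed: int = 0,
    use_lda: bool = True,
) -> ModelChoiceResult:
    """Scenario choice by classification random forest.

    Ties on vote counts break to the lowest scenario id.
    """
    ids = table.scenario_ids
    if len(ids) < 2:
        raise ValueError("model choice needs at least two scenarios in the table")
    X = table.X()
    y = table.y()
    obs = _as_vector(observed, table.stat_names)
    Xa, obsa = _augment(X, y, obs, use_lda)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    )
    clf.fit(Xa, y)
    tree_votes = np.array(
        [clf.classes_[int(est.predict(obsa.reshape(1, -1))[0])] for est in clf.estimators_]
    )
    votes = {int(s): float((tree_votes == s).mean()) for s in ids}
    best = max(ids, key=lambda s: (votes[s], -s))  # argmax, ties -> lowest id
    oob_pred, valid = _oob_predictions(clf, y)
    err_ind = (oob_pred[valid] != y[valid]).astype(float)
    prior_error = float(err_ind.mean())
    reg = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed + 1, max_features="sqrt", n_jobs=1
    )
    reg.fit(Xa[valid], err_ind)
    p_err = float(reg.predict(obsa.reshape(1, -1))[0])
    posterior = float(np.clip(1.0 - p_err, 0.0, 1.0))
    return ModelChoiceResult(votes, int(best), posterior, prior_error, n_trees)


def _qrf_weights(rf: RandomForestRegressor, X: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Quantile-regression-forest weights: average over trees of the
    normalized leaf-membership indicator for the observed point."""
    leaves = rf.apply(X)
    obs_leaves = rf.apply(obs.reshape(1, -1))[0]
    w = np.zeros(X.shape[0])
    for t in range(leaves.shape[1]):
        mask = leaves[:, t] == obs_leaves[t]
        n_in = mask.sum()
        if n_in:
            w[mask] += 1.0 / n_in
    return w / leaves.shape[1]


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return float(v[np.searchsorted(cw, q, side="left").clip(0, len(v) - 1)])


def estimate_parameters(
    table_for_scenario: ReferenceTable,
    observed,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 5,
    params: list[str] | None = None,
) -> ParamEstimateResult:
    """Quantile-regression-forest estimates for one scenario's parameters.

    `params` restricts estimation to a subset of parameter names.
    """
    ids = table_for_scenario.scenario_ids
    if len(ids) != 1:
        raise ValueError("parameter estimation requires a single-scenario table")
    X = table_for_scenario.X()
    obs = _as_vector(observed, table_for_scenario.stat_names)
    names = table_for_scenario.param_names
    if params is not None:
        unknown = [p for p in params if p not in names]
        if unknown:
            raise ValueError(f"unknown parameters {unknown}")
        names = [n for n in names if n in params]
    estimates: dict[str, dict[str, float]] = {}
    for i, name in enumerate(names):
        yv = table_for_scenario.df[f"param_{name}"].to_numpy(float)
        if np.ptp(yv) == 0:
            point = lo = hi = float(yv[0])
        else:
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=seed + i,
                min_samples_leaf=min_samples_leaf,
                max_features=1 / 3,
                n_jobs=1,
            )
            rf.fit(X, yv)
            w = _qrf_weights(rf, X, obs)
            point = float(np.sum(w * yv) / w.sum())
            lo = _weighted_quantile(yv, w, 0.025)
            hi = _weighted_quantile(yv, w, 0.975)
        entry = {"point": point, "q025": lo, "q975": hi}
        if name.startswith("t_"):
            entry.update(
                point_years=point / GENERATIONS_PER_YEAR,
                q025_years=lo / GENERATIONS_PER_YEAR,
                q975_years=hi / GENERATIONS_PER_YEAR,
            )
        estimates[name] = entry
    return ParamEstimateResult(int(ids[0]), estimates, n_trees)


def error_rates(
    table: ReferenceTable,
    best_scenario: int,
    observed=None,
    n_pseudo: int = 1000,
    n_trees: int = 500,
    seed: int = 0,
    use_lda: bool = True,
) -> ErrorReport:
    """Global (prior) and local (posterior) error of scenario choice, plus
    per-parameter out-of-bag errors for the selected scenario.

    The global error is the classifier's out-of-bag misclassification rate
    over the whole prior.  The local error re-evaluates out-of-bag errors
    on `n_pseudo` pseudo-observed draws from the reference table weighted
    by leaf co-occurrence with the observed point (uniform draws when no
    observed vector is supplied).  Per-parameter errors are out-of-bag
    mean absolute errors normalized by the parameter's range in the table.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    X = table.X()
    y = table.y()
    if best_scenario not in table.scenario_ids:
        raise ValueError(f"scenario {best_scenario} absent from table")
    obs = None if observed is None else _as_vector(observed, table.stat_names)
    rng = np.random.default_rng(seed)
    Xa = X
    obsa = obs
    if len(np.unique(y)) >= 2:
        if obs is None:
            Xa, _ = _augment(X, y, X[0], use_lda)
        else:
            Xa, obsa = _augment(X, y, obs, use_lda)
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
        )
        clf.fit(Xa, y)
        oob_pred, valid = _oob_predictions(clf, y)
        err_ind = (oob_pred != y).astype(float)
        global_error = float(err_ind[valid].mean())
        # pseudo-observed sets for the local error: rows of the selected
        # scenario, weighted toward the observed point when available
        sel = np.flatnonzero((y == best_scenario) & valid)
        if obs is not None:
            w = _qrf_weights_cls(clf, Xa, obsa)[sel]
            w = w / w.sum() if w.sum() > 0 else np.full(len(sel), 1.0 / len(sel))
        else:
            w = np.full(len(sel), 1.0 / len(sel))
        draws = rng.choice(sel, size=n_pseudo, replace=True, p=w)
        local_error = float(err_ind[draws].mean())
    else:
        global_error = 0.0
        local_error = 0.0
    sub = table.for_scenario(best_scenario)
    per_param: dict[str, float] = {}
    Xs = sub.X()
    for i, name in enumerate(sub.param_names):
        yv = sub.df[f"param_{name}"].to_numpy(float)
        rng_span = np.ptp(yv)
        if rng_span == 0:
            per_param[name] = 0.0
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=seed + 100 + i,
            oob_score=True,
            bootstrap=True,
            min_samples_leaf=5,
            max_features=1 / 3,
            n_jobs=1,
        )
        rf.fit(Xs, yv)
        per_param[name] = float(np.mean(np.abs(rf.oob_prediction_ - yv)) / rng_span)
    return ErrorReport(global_error, local_error, per_param, n_pseudo)


def _qrf_weights_cls(clf: RandomForestClassifier, X: np.ndarray, obs: np.ndarray) -> np.ndarray:
    leaves = clf.apply(X)
    obs_leaves = clf.apply(obs.reshape(1, -1))[0]
    w = np.zeros(X.shape[0])
    for t in range(leaves.shape[1]):
        mask = leaves[:, t] == obs_leaves[t]
        n_in = mask.sum()
        if n_in:
            w[mask] += 1.0 / n_in
    return w / leaves.shape[1]
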