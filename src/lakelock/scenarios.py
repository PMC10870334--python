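"""The 18-scenario space of divergence/landlocking histories.

Five sampled populations: MC (mainland coastal), CIC (island coastal),
and three landlocked clusters CILL1, CILL2, CILL3 (CILL3 = Lake Huro).
Every scenario is a rooted divergence tree whose oldest event is the
MC-CIC split (the island was colonised by a diadromous ancestor), and the
scenarios differ in how many landlocking events (3, 2 or 1) founded the
three landlocked clusters and in the order of those events:

- scenarios 1-6: three independent landlocking events; each cluster
  diverges directly from CIC, in one of the 3! time orders.  Scenario 1
  has CILL3 (Huro) diverging first, then CILL2, then CILL1.
- scenarios 7-12: two landlocking events; one event founds a landlocked
  ancestor (ghost population LLANC with its own size) that later splits
  into two clusters, the third cluster diverges from CIC separately.
  3 pairings x 2 time orders of the two landlocking events.
- scenarios 13-18: a single landlocking event founds a landlocked
  ancestor that splits twice.  The ancestor branch is modelled as
  continuous with the last-remaining cluster's lineage (that cluster's
  size applies along it); 3 choices of first-diverging cluster x 2
  choices of which of the remaining clusters diverges second.

Events are *backward-in-time* merges ``(time_param, derived, ancestral)``:
at the event time all lineages of the derived population move into the
ancestral population.  Each population branch has a constant diploid
effective size ``N_<pop>``; times are in generations.  All parameters get
independent uniform priors (default 10^1 - 10^6), with per-scenario
ordering constraints enforced by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

SAMPLED_POPULATIONS = ("MC", "CIC", "CILL1", "CILL2", "CILL3")
ROOT_POP = "ANC"

ParamVector = dict  # name -> float


@dataclass(frozen=True)
class ScenarioSpec:
    """A rooted divergence history over sampled + ancestral populations."""

    scenario_id: int
    n_landlock_events: int
    populations: tuple[str, ...]  # sampled first, internal after
    events: tuple[tuple[str, str, str], ...]  # (time_param, derived, ancestral)
    constraints: tuple[tuple[str, str], ...]  # (greater, lesser): t_g >= t_l

    @property
    def sampled_populations(self) -> tuple[str, ...]:
        return SAMPLED_POPULATIONS

    @property
    def size_parameter_names(self) -> tuple[str, ...]:
        return tuple(f"N_{p}" for p in self.populations)

    @property
    def time_parameter_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t, _, _ in self.events:
            seen.setdefault(t, None)
        return tuple(seen)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.size_parameter_names + self.time_parameter_names


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors; times in generations, sizes in diploids."""

    lower: float = 10.0
    upper: float = 1e6
    per_parameter: tuple[tuple[str, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in [(self.lower, self.upper)] + [b for _, b in self.per_parameter]:
            if not lo < hi:
                raise ValueError("prior lower bound must be below upper bound")

    def bounds_for(self, name: str) -> tuple[float, float]:
        for n, b in self.per_parameter:
            if n == name:
                return b
        return (self.lower, self.upper)


def _root_events() -> list[tuple[str, str, str]]:
    return [("t_root", "CIC", ROOT_POP), ("t_root", "MC", ROOT_POP)]


def _three_event_scenarios(start_id: int) -> list[ScenarioSpec]:
    specs = []
    # order = (oldest, middle, youngest) divergence from CIC
    for k, order in enumerate(permutations(("CILL3", "CILL2", "CILL1"))):
        a, b, c = order
        events = [
            (f"t_{c}", c, "CIC"),
            (f"t_{b}", b, "CIC"),
            (f"t_{a}", a, "CIC"),
        ] + _root_events()
        constraints = [
            ("t_root", f"t_{a}"),
            (f"t_{a}", f"t_{b}"),
            (f"t_{b}", f"t_{c}"),
        ]
        specs.append(
            ScenarioSpec(
                scenario_id=start_id + k,
                n_landlock_events=3,
                populations=SAMPLED_POPULATIONS + (ROOT_POP,),
                events=tuple(events),
                constraints=tuple(constraints),
            )
        )
    return specs


def _two_event_scenarios(start_id: int) -> list[ScenarioSpec]:
    specs = []
    sid = start_id
    clusters = ("CILL1", "CILL2", "CILL3")
    for pair in combinations(clusters, 2):
        (single,) = tuple(set(clusters) - set(pair))
        a, b = pair
        t_pair = f"t_LL_{a}_{b}"
        t_split = f"t_split_{a}_{b}"
        t_single = f"t_{single}"
        events = [
            (t_split, a, "LLANC"),
            (t_split, b, "LLANC"),
            (t_pair, "LLANC", "CIC"),
            (t_single, single, "CIC"),
        ] + _root_events()
        base = [("t_root", t_pair), ("t_root", t_single), (t_pair, t_split)]
        for order in ((t_single, t_pair), (t_pair, t_single)):
            specs.append(
                ScenarioSpec(
                    scenario_id=sid,
                    n_landlock_events=2,
                    populations=SAMPLED_POPULATIONS + ("LLANC", ROOT_POP),
                    events=tuple(events),
                    constraints=tuple(base + [order]),
                )
            )
            sid += 1
    return specs


def _one_event_scenarios(start_id: int) -> list[ScenarioSpec]:
    specs = []
    sid = start_id
    clusters = ("CILL1", "CILL2", "CILL3")
    for first in clusters:
        rest = tuple(c for c in clusters if c != first)
        for second in rest:
            (cont,) = tuple(c for c in rest if c != second)
            # cont's lineage is the landlocked ancestor branch
            events = [
                (f"t_{second}", second, cont),
                (f"t_{first}", first, cont),
                ("t_LL", cont, "CIC"),
            ] + _root_events()
            constraints = [
                ("t_root", "t_LL"),
                ("t_LL", f"t_{first}"),
                (f"t_{first}", f"t_{second}"),
            ]
            specs.append(
                ScenarioSpec(
                    scenario_id=sid,
                    n_landlock_events=1,
                    populations=SAMPLED_POPULATIONS + (ROOT_POP,),
                    events=tuple(events),
                    constraints=tuple(constraints),
                )
            )
            sid += 1
    return specs


def enumerate_scenarios() -> list[ScenarioSpec]:
    """All 18 scenarios: ids 1-6 (three events), 7-12 (two), 13-18 (one)."""
    return (
        _three_event_scenarios(1)
        + _two_event_scenarios(7)
        + _one_event_scenarios(13)
    )


def get_scenario(scenario_id: int) -> ScenarioSpec:
    for s in enumerate_scenarios():
        if s.scenario_id == scenario_id:
            return s
    raise KeyError(f"no scenario with id {scenario_id}")


def validate_scenario(spec: ScenarioSpec) -> list[str]:
    """Return a list of violations; empty iff the scenario is well-formed."""
    violations: list[str] = []
    derived_counts: dict[str, int] = {}
    pops = set(spec.populations)
    for t, d, a in spec.events:
        if d not in pops or a not in pops:
            violations.append(f"event ({t}, {d}, {a}) references unknown population")
        derived_counts[d] = derived_counts.get(d, 0) + 1
    root = spec.populations[-1]
    for p in spec.populations:
        c = derived_counts.get(p, 0)
        if p == root:
            if c != 0:
                violations.append(f"root population {p} must never be derived")
        elif c != 1:
            violations.append(f"population {p} must be derived exactly once, got {c}")
    # connectivity / acyclicity of the merge graph: follow derived -> ancestral
    edges = {d: a for _, d, a in spec.events}
    for p in SAMPLED_POPULATIONS:
        seen = set()
        cur = p
        while cur in edges:
            if cur in seen:
                violations.append(f"cycle in event graph reachable from {p}: not a tree")
                break
            seen.add(cur)
            cur = edges[cur]
        else:
            if cur != root:
                violations.append(f"population {p} does not reach the root")
    # the root event must be the MC-CIC split (diadromous-ancestor assumption)
    root_merges = sorted(d for t, d, a in spec.events if a == root)
    if root_merges != ["CIC", "MC"]:
        violations.append(
            "root event is not the MC-CIC split (the island ancestor is assumed "
            "diadromous, so MC-CIC must be the earliest divergence)"
        )
    times = set(spec.time_parameter_names)
    order = {c for c in spec.constraints}
    for g_, l_ in order:
        if g_ not in times or l_ not in times:
            violations.append(f"constraint ({g_} >= {l_}) references unknown time parameter")
    # t_root must dominate every other time parameter transitively
    below: dict[str, set[str]] = {t: set() for t in times}
    for g_, l_ in order:
        if g_ in below and l_ in times:
            below[g_].add(l_)
    reach = set()
    stack = ["t_root"]
    while stack:
        cur = stack.pop()
        for nxt in below.get(cur, ()):  # pragma: no branch
            if nxt not in reach:
                reach.add(nxt)
                stack.append(nxt)
    missing = times - reach - {"t_root"}
    if missing:
        violations.append(
            f"t_root does not dominate time parameters {sorted(missing)}"
        )
    # constraint graph must be acyclic
    state: dict[str, int] = {}

    def dfs(node: str) -> bool:
        state[node] = 1
        for nxt in below.get(node, ()):
            if state.get(nxt) == 1 or (state.get(nxt) is None and dfs(nxt)):
                return True
        state[node] = 2
        return False

    for t in times:
        if state.get(t) is None and dfs(t):
            violations.append("constraint partial order contains a cycle")
            break
    return violations


def satisfies_constraints(spec: ScenarioSpec, params: ParamVector) -> bool:
    return all(params[g_] >= params[l_] for g_, l_ in spec.constraints)


def draw_parameters(
    spec: ScenarioSpec,
    priors: PriorSpec | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1_000_000,
) -> ParamVector:
    """Draw one parameter vector: independent uniforms, rejected until the
    scenario's time ordering holds.  Deterministic given the seed."""
    if priors is None:
        priors = PriorSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = spec.parameter_names
    bounds = [priors.bounds_for(n) for n in names]
    for _ in range(max_tries):
        draws = {n: rng.uniform(lo, hi) for n, (lo, hi) in zip(names, bounds)}
        if satisfies_constraints(spec, draws):
            return draws
    raise RuntimeError(
        f"scenario {spec.scenario_id}: ordering constraints unsatisfied after "
        f"{max_tries} draws; check priors against constraints"
    )


def scenario_to_text(spec: ScenarioSpec) -> str:
    """Declarative plain-text block for one scenario (see `scenarios export`)."""
    lines = [
        f"scenario {spec.scenario_id}",
        f"  landlock_events {spec.n_landlock_events}",
        "  populations " + " ".join(spec.populations),
    ]
    for t, d, a in spec.events:
        lines.append(f"  event {t} {d} {a}")
    for g_, l_ in spec.constraints:
        lines.append(f"  constraint {g_} >= {l_}")
    lines.append("end")
    return "\n".join(lines)


def scenarios_from_text(text: str) -> list[ScenarioSpec]:
    """Parse scenario blocks produced by :func:`scenario_to_text`."""
    specs: list[ScenarioSpec] = []
    cur: dict | None = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "scenario":
            cur = {"id": int(parts[1]), "events": [], "constraints": []}
        elif cur is None:
            raise ValueError(f"line {line_no}: content outside a scenario block")
        elif parts[0] == "landlock_events":
            cur["n"] = int(parts[1])
        elif parts[0] == "populations":
            cur["pops"] = tuple(parts[1:])
        elif parts[0] == "event":
            cur["events"].append((parts[1], parts[2], parts[3]))
        elif parts[0] == "constraint":
            if len(parts) != 4 or parts[2] != ">=":
                raise ValueError(f"line {line_no}: expected 'constraint A >= B'")
            cur["constraints"].append((parts[1], parts[3]))
        elif parts[0] == "end":
            specs.append(
                ScenarioSpec(
                    scenario_id=cur["id"],
                    n_landlock_events=cur["n"],
                    populations=cur["pops"],
                    events=tuple(cur["events"]),
                    constraints=tuple(cur["constraints"]),
                )
            )
            cur = None
        else:
            raise ValueError(f"line {line_no}: unknown directive {parts[0]!r}")
    if cur is not None:
        raise ValueError("unterminated scenario block")
    return specs
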