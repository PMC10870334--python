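"""Structured-coalescent simulation of biallelic SNP genotype matrices.

Each locus is an independent realisation of the structured coalescent
under a :class:`~lakelock.scenarios.ScenarioSpec` plus parameter vector:
backward in time, lineages within a population of diploid size N coalesce
with exponential waiting times at rate k(k-1)/2 / (2N); at each divergence
event the derived population's lineages move into the ancestral
population; the process continues past the root until a single lineage
remains.  One mutation is then placed on a branch chosen with probability
proportional to branch length, so every locus is polymorphic by
construction (the convention of SNP-mode ABC simulators, which sidesteps
a mutation-rate parameter for unlinked GBS SNPs).  Loci are redrawn until
the pooled-sample minor allele frequency reaches the configured
threshold.  Haploid lineages are paired consecutively within each
population into diploid genotypes (random mating).

The per-locus kernel is compiled with numba; simulation is exact in
continuous time, with times in generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotype_io import GenotypeMatrix
from .scenarios import SAMPLED_POPULATIONS, ParamVector, ScenarioSpec, satisfies_constraints


@dataclass(frozen=True)
class SampleConfig:
    """Number of diploid individuals sampled per population.

    Defaults are study-like: 169 individuals total with MC = 18; the
    per-cluster island counts are configurable placeholders.
    """

    n_per_pop: tuple[tuple[str, int], ...] = (
        ("MC", 18),
        ("CIC", 40),
        ("CILL1", 30),
        ("CILL2", 50),
        ("CILL3", 31),
    )

    def __post_init__(self) -> None:
        for pop, n in self.n_per_pop:
            if n < 1:
                raise ValueError(f"population {pop} needs at least 1 individual")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.n_per_pop)

    def count(self, pop: str) -> int:
        return dict(self.n_per_pop)[pop]

    @property
    def n_individuals(self) -> int:
        return sum(n for _, n in self.n_per_pop)

    @property
    def n_lineages(self) -> int:
        return 2 * self.n_individuals

    def sample_ids(self) -> list[str]:
        return [f"{pop}_{i:03d}" for pop, n in self.n_per_pop for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimConfig:
    n_loci: int = 2000
    maf_threshold: float = 0.05
    seed: int = 0
    max_redraws_per_locus: int = 10_000

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")


@dataclass
class Genealogy:
    """Rooted binary coalescent tree; branch lengths in generations.

    Nodes 0..n_leaves-1 are haploid leaf lineages (``leaf_pops`` gives
    the sampled population of each); internal nodes follow in coalescence
    order, the last being the root.
    """

    parent: np.ndarray
    node_time: np.ndarray
    n_leaves: int
    leaf_pops: np.ndarray  # population index per leaf
    populations: tuple[str, ...]

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_branch_length(self) -> float:
        v = np.arange(self.root)
        return float((self.node_time[self.parent[v]] - self.node_time[v]).sum())


class SimulationError(RuntimeError):
    pass


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _rng_unit(state):
    # uniform on (0, 1]
    return (np.float64(_rng_next(state) >> np.uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _rng_init(seed):
    # splitmix64 scrambles small integer seeds into a nonzero xorshift state
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x106689D45497FDB5)
    out = np.empty(1, np.uint64)
    out[0] = z
    return out


@njit(cache=True, fastmath=True)
def _simulate_tree_into(
    lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc, parent, ntime, members, counts, state
):
    """Fill preallocated parent/time arrays with one coalescent tree.

    ``parent``/``ntime`` have length 2*n_lin-1; ``members`` is a
    (n_pops, n_lin) scratch matrix and ``counts`` its per-population fill.
    """
    n_lin = lineage_pop0.shape[0]
    n_pops = pop_sizes.shape[0]
    counts[:] = 0
    for i in range(n_lin):
        p = lineage_pop0[i]
        members[p, counts[p]] = i
        counts[p] += 1
        parent[i] = -1
        ntime[i] = 0.0
    next_node = n_lin
    cur_time = 0.0
    n_ev = ev_time.shape[0]
    for e in range(n_ev + 1):
        epoch_end = ev_time[e] if e < n_ev else np.inf
        for p in range(n_pops):
            k = counts[p]
            if k < 2:
                continue
            t = cur_time
            four_n = 4.0 * pop_sizes[p]
            while k > 1:
                rate = k * (k - 1) / four_n  # k(k-1)/2 pairs x 1/(2N)
                t += -np.log(_rng_unit(state)) / rate
                if t > epoch_end:
                    break
                i = np.int64(_rng_next(state) % np.uint64(k))
                j = np.int64(_rng_next(state) % np.uint64(k - 1))
                if j >= i:
                    j += 1
                a = members[p, i]
                b = members[p, j]
                node = next_node
                next_node += 1
                parent[a] = node
                parent[b] = node
                parent[node] = -1
                ntime[node] = t
                members[p, i] = node
                members[p, j] = members[p, k - 1]
                k -= 1
            counts[p] = k
        if e < n_ev:
            d = ev_derived[e]
            anc = ev_anc[e]
            for x in range(counts[d]):
                members[anc, counts[anc]] = members[d, x]
                counts[anc] += 1
            counts[d] = 0
            cur_time = ev_time[e]


@njit(cache=True, fastmath=True)
def _place_mutation_into(parent, ntime, n_lin, derived, below, state):
    """Drop one mutation, branch chosen proportional to length; fill
    `derived` with the 0/1 allele per leaf.  Returns the derived count.

    Uses the invariant parent[v] > v (nodes created in time order): one
    descending pass over nodes marks the subtree below the chosen branch.
    """
    n_nodes = parent.shape[0]
    root = n_nodes - 1
    total = 0.0
    for v in range(root):
        total += ntime[parent[v]] - ntime[v]
    u = _rng_unit(state) * total
    chosen = root - 1
    acc = 0.0
    for v in range(root):
        acc += ntime[parent[v]] - ntime[v]
        if u <= acc:
            chosen = v
            break
    cnt = 0
    below[root] = 0
    for v in range(root - 1, -1, -1):
        if v == chosen:
            below[v] = 1
        elif below[parent[v]] == 1:
            below[v] = 1
        else:
            below[v] = 0
    for i in range(n_lin):
        derived[i] = below[i]
        cnt += below[i]
    return cnt


@njit(cache=True)
def _simulate_calls(
    lineage_pop0,
    pop_sizes,
    ev_time,
    ev_derived,
    ev_anc,
    n_loci,
    maf_threshold,
    max_redraws,
    seed,
):
    state = _rng_init(seed)
    n_lin = lineage_pop0.shape[0]
    n_pops = pop_sizes.shape[0]
    n_ind = n_lin // 2
    n_nodes = 2 * n_lin - 1
    parent = np.empty(n_nodes, np.int32)
    ntime = np.empty(n_nodes, np.float64)
    members = np.empty((n_pops, n_lin), np.int32)
    counts = np.empty(n_pops, np.int32)
    derived = np.empty(n_lin, np.uint8)
    below = np.empty(n_nodes, np.uint8)
    out = np.empty((n_ind, n_loci), np.int8)
    min_minor = maf_threshold * n_lin
    for locus in range(n_loci):
        ok = False
        for _ in range(max_redraws):
            _simulate_tree_into(
                lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc,
                parent, ntime, members, counts, state,
            )
            cnt = _place_mutation_into(parent, ntime, n_lin, derived, below, state)
            minor = cnt if 2 * cnt <= n_lin else n_lin - cnt
            if minor >= min_minor:
                for ind in range(n_ind):
                    out[ind, locus] = derived[2 * ind] + derived[2 * ind + 1]
                ok = True
                break
        if not ok:
            return out, locus
    return out, -1


def _compile(
    spec: ScenarioSpec, params: ParamVector, samples: SampleConfig
):
    """Lower a scenario + parameters + sample configuration to the numeric
    arrays consumed by the numba kernels."""
    if not satisfies_constraints(spec, params):
        raise ValueError(
            f"parameters violate scenario {spec.scenario_id} time-ordering constraints"
        )
    pop_index = {p: i for i, p in enumerate(spec.populations)}
    for pop in samples.populations:
        if pop not in pop_index:
            raise ValueError(f"sampled population {pop} absent from scenario")
    pop_sizes = np.array(
        [float(params[f"N_{p}"]) for p in spec.populations], dtype=np.float64
    )
    if (pop_sizes <= 0).any():
        raise ValueError("population sizes must be positive")
    ev = sorted(
        ((float(params[t]), pop_index[d], pop_index[a]) for t, d, a in spec.events),
        key=lambda x: x[0],
    )
    ev_time = np.array([e[0] for e in ev], dtype=np.float64)
    ev_derived = np.array([e[1] for e in ev], dtype=np.int32)
    ev_anc = np.array([e[2] for e in ev], dtype=np.int32)
    lineage_pop0 = np.repeat(
        [pop_index[p] for p, n in samples.n_per_pop],
        [2 * n for _, n in samples.n_per_pop],
    ).astype(np.int32)
    return lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc


def simulate_genealogy(
    spec: ScenarioSpec,
    params: ParamVector,
    samples: SampleConfig,
    seed: int = 0,
) -> Genealogy:
    """Simulate one locus genealogy under the structured coalescent."""
    lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc = _compile(
        spec, params, samples
    )
    state = _rng_init(int(seed) & 0xFFFFFFFF)
    n_lin = lineage_pop0.shape[0]
    n_nodes = 2 * n_lin - 1
    parent = np.empty(n_nodes, np.int32)
    ntime = np.empty(n_nodes, np.float64)
    members = np.empty((pop_sizes.shape[0], n_lin), np.int32)
    counts = np.empty(pop_sizes.shape[0], np.int32)
    _simulate_tree_into(
        lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc,
        parent, ntime, members, counts, state,
    )
    return Genealogy(
        parent=parent,
        node_time=ntime,
        n_leaves=n_lin,
        leaf_pops=lineage_pop0,
        populations=spec.populations,
    )


def drop_snp_mutation(tree: Genealogy, seed: int = 0) -> np.ndarray:
    """Place one mutation on the genealogy, branch chosen proportionally to
    its length; returns the 0/1 derived-allele vector over leaf lineages.
    The resulting site is polymorphic by construction."""
    if tree.n_leaves < 2:
        raise ValueError("tree must have at least 2 leaves")
    if tree.total_branch_length <= 0:
        raise ValueError("zero-length tree")
    state = _rng_init(int(seed) & 0xFFFFFFFF)
    derived = np.empty(tree.n_leaves, np.uint8)
    below = np.empty(len(tree.parent), np.uint8)
    _place_mutation_into(tree.parent, tree.node_time, tree.n_leaves, derived, below, state)
    return derived


def simulate_dataset(
    spec: ScenarioSpec,
    params: ParamVector,
    samples: SampleConfig,
    cfg: SimConfig,
) -> GenotypeMatrix:
    """Simulate a genotype matrix of `cfg.n_loci` independent SNP loci.

    Each locus is redrawn (new genealogy + mutation) until the pooled
    minor allele frequency reaches ``cfg.maf_threshold``; deterministic
    given ``cfg.seed``.
    """
    lineage_pop0, pop_sizes, ev_time, ev_derived, ev_anc = _compile(
        spec, params, samples
    )
    calls, failed = _simulate_calls(
        lineage_pop0,
        pop_sizes,
        ev_time,
        ev_derived,
        ev_anc,
        cfg.n_loci,
        cfg.maf_threshold,
        cfg.max_redraws_per_locus,
        int(cfg.seed) & 0xFFFFFFFF,
    )
    if failed >= 0:
        raise SimulationError(
            f"locus {failed}: MAF >= {cfg.maf_threshold} not reached within "
            f"{cfg.max_redraws_per_locus} redraws (pathological parameters?)"
        )
    locus_ids = [f"sim:{j + 1}" for j in range(cfg.n_loci)]
    return GenotypeMatrix(samples.sample_ids(), locus_ids, calls)


def default_popmap(samples: SampleConfig):
    """PopulationMap matching :meth:`SampleConfig.sample_ids`."""
    from .genotype_io import PopulationMap

    return PopulationMap(
        {f"{pop}_{i:03d}": pop for pop, n in samples.n_per_pop for i in range(1, n + 1)}
    )
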