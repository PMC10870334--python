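"""Synthetic study-like datasets and miniature test fixtures.

``generate_study_dataset`` emulates the post-genotyping product of the
study: ~169 diploid samples in five groups (MC, CIC, CILL1, CILL2,
CILL3), biallelic SNPs simulated under a landlocking scenario (default:
scenario 1, three independent landlocking events, with the reported
divergence-time estimates as truth and order-of-magnitude placeholder
effective sizes giving landlocked groups reduced heterozygosity), plus
independent per-genotype missingness.  The truth record (scenario,
parameters, seeds) is sufficient to regenerate the dataset byte for byte.

These are stand-ins for the deposited sequence data: they reproduce the
matrix shape, group structure and qualitative diversity ordering, not
the real site-frequency spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import SampleConfig, SimConfig, default_popmap, simulate_dataset
from .genotype_io import MISSING, GenotypeMatrix, PopulationMap, write_popmap, write_vcf
from .scenarios import get_scenario

#: scenario-1 truth: reported divergence-time estimates (generations) and
#: placeholder effective sizes (coastal 1e5, landlocked 1e4, labelled as such)
DEFAULT_TRUTH_PARAMS: dict[str, float] = {
    "N_MC": 1e5,
    "N_CIC": 1e5,
    "N_CILL1": 1e4,
    "N_CILL2": 1e4,
    "N_CILL3": 1e4,
    "N_ANC": 1e5,
    "t_CILL3": 179_163.0,
    "t_CILL2": 169_467.0,
    "t_CILL1": 156_273.0,
    "t_root": 340_000.0,
}


@dataclass(frozen=True)
class StudyEmulationConfig:
    scenario_id: int = 1
    params: tuple[tuple[str, float], ...] = tuple(DEFAULT_TRUTH_PARAMS.items())
    samples: SampleConfig = SampleConfig()
    n_loci: int = 2000  # full study scale is 21,135; 2,000 is the desk default
    missingness: float = 0.1
    maf_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness <= 0.2:
            raise ValueError("missingness must be in [0, 0.2]")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


def generate_study_dataset(
    cfg: StudyEmulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Simulate an observed-style dataset; optionally write VCF/popmap/truth.

    Missingness is applied after simulation, independently per genotype
    (so the missing rate is identical across genotype classes).
    """
    if cfg is None:
        cfg = StudyEmulationConfig()
    spec = get_scenario(cfg.scenario_id)
    params = cfg.param_dict
    mat = simulate_dataset(
        spec,
        params,
        cfg.samples,
        SimConfig(n_loci=cfg.n_loci, maf_threshold=cfg.maf_threshold, seed=cfg.seed),
    )
    if cfg.missingness > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        mask = rng.random(mat.calls.shape) < cfg.missingness
        calls = mat.calls.copy()
        calls[mask] = MISSING
        mat = GenotypeMatrix(mat.sample_ids, mat.locus_ids, calls)
    pops = default_popmap(cfg.samples)
    truth = {
        "scenario_id": cfg.scenario_id,
        "params": params,
        "samples": dict(cfg.samples.n_per_pop),
        "n_loci": cfg.n_loci,
        "missingness": cfg.missingness,
        "maf_threshold": cfg.maf_threshold,
        "seed": cfg.seed,
        "note": "synthetic stand-in for the study dataset; Ne values are placeholders",
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(mat, out / "observed.vcf")
        write_popmap(pops, out / "popmap.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return mat, pops, truth


def _matrix(sample_ids, rows) -> GenotypeMatrix:
    calls = np.array(rows, dtype=np.int8).T  # rows given per locus
    locus_ids = [f"toy:{j + 1}" for j in range(calls.shape[1])]
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def make_toy_fixtures() -> dict[str, dict]:
    """Deterministic miniature datasets with machine-readable expectations.

    Each entry holds ``genotypes``, ``popmap`` and an ``expected`` dict
    describing the property the fixture pins down.
    """
    fixtures: dict[str, dict] = {}

    # filter boundary: 100 samples; loci called in 79/80/81 samples
    n = 100
    samples = [f"s{i:03d}" for i in range(n)]
    rows = []
    for n_called in (79, 80, 81):
        row = [1] * n_called + [MISSING] * (n - n_called)
        rows.append(row)
    fixtures["call_rate_boundary"] = {
        "genotypes": _matrix(samples, rows),
        "popmap": PopulationMap({s: "P" for s in samples}),
        "expected": {
            "min_fraction": 0.8,
            "kept_loci": ["toy:2", "toy:3"],
            "removed_loci": ["toy:1"],
        },
    }

    # two populations fixed for opposite alleles at every locus
    sample_ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    rows = [[0, 0, 0, 0, 2, 2, 2, 2]] * 5
    fixtures["fixed_difference"] = {
        "genotypes": _matrix(sample_ids, rows),
        "popmap": PopulationMap(
            {s: ("A" if s.startswith("a") else "B") for s in sample_ids}
        ),
        "expected": {"fst": 1.0},
    }

    # 50:50 admixed target between fixed-difference donors: f3 = -0.25/locus
    sample_ids = (
        [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
    )
    rows = [[0] * 4 + [2] * 4 + [1] * 4] * 6
    popmap = {s: {"a": "A", "b": "B", "t": "T"}[s[0]] for s in sample_ids}
    fixtures["admixture_f3"] = {
        "genotypes": _matrix(sample_ids, rows),
        "popmap": PopulationMap(popmap),
        "expected": {"f3_T_A_B": -0.25},
    }

    # single population: degenerate hierarchical statistics
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    fixtures["single_population"] = {
        "genotypes": GenotypeMatrix(
            [f"x{i}" for i in range(10)], [f"sp:{j + 1}" for j in range(50)], calls
        ),
        "popmap": PopulationMap({f"x{i}": "only" for i in range(10)}),
        "expected": {"F_ST": 0.0, "D_ST": 0.0, "D_EST": None},
    }
    return fixtures


def write_toy_fixtures(out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, bundle in make_toy_fixtures().items():
        write_vcf(bundle["genotypes"], out / f"{name}.vcf")
        write_popmap(bundle["popmap"], out / f"{name}.popmap.tsv")
        (out / f"{name}.expected.json").write_text(
            json.dumps(bundle["expected"], indent=2)
        )
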