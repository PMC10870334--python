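"""End-to-end orchestration: filters -> diversity/FST/PCA -> ABC scenario
choice -> parameter estimation -> error rates.

A single :class:`PipelineConfig` drives the run; per-stage seeds are
derived from one master seed by fixed offsets and recorded in the
manifest, so identical configurations give identical numeric outputs.
All intermediates are persisted as plain text (VCF/TSV/JSON).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_rf, popgen_stats, snp_filters
from .coalescent import SampleConfig, SimConfig
from .genotype_io import read_popmap, read_vcf, write_popmap, write_vcf
from .scenarios import PriorSpec, enumerate_scenarios, get_scenario
from .summaries import observed_summaries_matched
from .synthetic import StudyEmulationConfig, generate_study_dataset

log = logging.getLogger("lakelock.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "lakelock_run"
    # input: either paths to observed data, or a synthetic configuration
    vcf: str | None = None
    popmap: str | None = None
    synthetic: StudyEmulationConfig | None = None
    # filters
    min_call_rate: float = 0.8
    max_het: float = 0.65
    min_maf: float = 0.05
    # popgen stage
    n_boot: int = 100
    pca_components: int = 2
    # ABC stage
    run_abc: bool = True
    n_per_scenario_choice: int = 2000
    n_per_scenario_estimation: int = 10_000
    train_n_loci: int = 500
    n_trees: int = 500
    n_pseudo: int = 1000
    prior_lower: float = 10.0
    prior_upper: float = 1e6
    seed: int = 1

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(master: int) -> dict[str, int]:
    return {
        "synthetic": master,
        "bootstrap": master + 1,
        "choice_table": master + 2,
        "choice_rf": master + 3,
        "estimation_table": master + 4,
        "estimation_rf": master + 5,
        "errors": master + 6,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in protocol order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {
        "config": json.loads(
            json.dumps(asdict(cfg), default=str, sort_keys=True)
        ),
        "config_hash": cfg.config_hash(),
        "seeds": seeds,
        "stages": {},
        "outputs": [],
    }
    stage = "input"
    try:
        t0 = time.time()
        if cfg.vcf is not None and cfg.popmap is not None:
            g = read_vcf(cfg.vcf)
            pops = read_popmap(cfg.popmap)
        else:
            syn = cfg.synthetic or StudyEmulationConfig(seed=seeds["synthetic"])
            g, pops, truth = generate_study_dataset(syn)
            write_vcf(g, out / "observed.vcf")
            write_popmap(pops, out / "popmap.tsv")
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
            manifest["outputs"] += ["observed.vcf", "popmap.tsv", "truth.json"]
        manifest["stages"]["input"] = {
            "n_samples": g.n_samples,
            "n_loci": g.n_loci,
            "elapsed_s": round(time.time() - t0, 3),
        }
        log.info("input: %d samples x %d loci", g.n_samples, g.n_loci)

        stage = "filters_popgen"
        t0 = time.time()
        g_pop, rep_pop = snp_filters.apply_study_filters(
            g, "popgen", cfg.min_call_rate, cfg.max_het, cfg.min_maf
        )
        write_vcf(g_pop, out / "filtered_popgen.vcf")
        (out / "filter_report_popgen.json").write_text(
            json.dumps(rep_pop.to_dict(), indent=2)
        )
        manifest["outputs"] += ["filtered_popgen.vcf", "filter_report_popgen.json"]
        manifest["stages"][stage] = {
            **rep_pop.to_dict(),
            "elapsed_s": round(time.time() - t0, 3),
        }

        stage = "popgen_stats"
        t0 = time.time()
        groups = pops.groups
        rows = []
        for grp in groups:
            d = popgen_stats.diversity_stats(g_pop, pops, [grp])
            rows.append({"group_set": grp, **{k: v for k, v in d.to_dict().items() if k != "groups"}})
        d_all = popgen_stats.diversity_stats(g_pop, pops, groups)
        rows.append(
            {"group_set": "all", **{k: v for k, v in d_all.to_dict().items() if k != "groups"}}
        )
        pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
        fst = popgen_stats.pairwise_fst(g_pop, pops, cfg.n_boot, seeds["bootstrap"])
        fst_df = pd.DataFrame(fst.theta, index=fst.groups, columns=fst.groups)
        fst_df.to_csv(out / "pairwise_fst.tsv", sep="\t")
        sig_df = pd.DataFrame(fst.significant, index=fst.groups, columns=fst.groups)
        sig_df.to_csv(out / "pairwise_fst_significant.tsv", sep="\t")
        pca = popgen_stats.pca_structure(g_pop, cfg.pca_components)
        pca_df = pd.DataFrame(
            pca.scores,
            index=pca.sample_ids,
            columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
        )
        pca_df.to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["outputs"] += [
            "diversity.tsv",
            "pairwise_fst.tsv",
            "pairwise_fst_significant.tsv",
            "pca_scores.tsv",
        ]
        manifest["stages"][stage] = {
            "n_loci_used": d_all.n_loci_used,
            "elapsed_s": round(time.time() - t0, 3),
        }

        if cfg.run_abc:
            stage = "abc_filters"
            t0 = time.time()
            g_abc, rep_abc = snp_filters.apply_study_filters(
                g, "abc", cfg.min_call_rate, cfg.max_het, cfg.min_maf
            )
            write_vcf(g_abc, out / "filtered_abc.vcf")
            (out / "filter_report_abc.json").write_text(
                json.dumps(rep_abc.to_dict(), indent=2)
            )
            manifest["outputs"] += ["filtered_abc.vcf", "filter_report_abc.json"]
            manifest["stages"][stage] = {
                **rep_abc.to_dict(),
                "elapsed_s": round(time.time() - t0, 3),
            }

            stage = "abc_choice"
            t0 = time.time()
            # match the observed vector's locus count (hence noise level)
            # to the reference-table simulations
            observed = observed_summaries_matched(
                g_abc, pops, cfg.train_n_loci, seeds["choice_table"], groups
            )
            observed.to_frame("value").to_csv(out / "observed_summaries.tsv", sep="\t")
            samples = SampleConfig(
                n_per_pop=tuple((grp, len(pops.samples_in(grp))) for grp in groups)
            )
            priors = PriorSpec(cfg.prior_lower, cfg.prior_upper)
            table = abc_rf.build_reference_table(
                enumerate_scenarios(),
                priors,
                samples,
                cfg.n_per_scenario_choice,
                SimConfig(
                    n_loci=cfg.train_n_loci,
                    maf_threshold=cfg.min_maf,
                    seed=seeds["choice_table"],
                ),
                groups=groups,
            )
            table.save(out / "reference_table_choice.tsv")
            choice = abc_rf.choose_model(
                table, observed, cfg.n_trees, seeds["choice_rf"]
            )
            (out / "model_choice.json").write_text(
                json.dumps(choice.to_dict(), indent=2)
            )
            manifest["outputs"] += [
                "observed_summaries.tsv",
                "reference_table_choice.tsv",
                "model_choice.json",
            ]
            manifest["stages"][stage] = {
                "selected_scenario": choice.selected_scenario,
                "posterior_probability": choice.posterior_probability,
                "prior_error": choice.prior_error,
                "n_rows": len(table.df),
                "elapsed_s": round(time.time() - t0, 3),
            }

            stage = "abc_estimation"
            t0 = time.time()
            est_table = abc_rf.build_reference_table(
                [get_scenario(choice.selected_scenario)],
                priors,
                samples,
                cfg.n_per_scenario_estimation,
                SimConfig(
                    n_loci=cfg.train_n_loci,
                    maf_threshold=cfg.min_maf,
                    seed=seeds["estimation_table"],
                ),
                groups=groups,
            )
            est = abc_rf.estimate_parameters(
                est_table, observed, cfg.n_trees, seeds["estimation_rf"]
            )
            (out / "param_estimates.json").write_text(
                json.dumps(est.to_dict(), indent=2)
            )
            manifest["outputs"] += ["param_estimates.json"]
            manifest["stages"][stage] = {
                "n_rows": len(est_table.df),
                "elapsed_s": round(time.time() - t0, 3),
            }

            stage = "abc_errors"
            t0 = time.time()
            errors = abc_rf.error_rates(
                table,
                choice.selected_scenario,
                observed,
                cfg.n_pseudo,
                cfg.n_trees,
                seeds["errors"],
            )
            (out / "error_report.json").write_text(
                json.dumps(errors.to_dict(), indent=2)
            )
            manifest["outputs"] += ["error_report.json"]
            manifest["stages"][stage] = {
                "global_error": errors.global_error,
                "local_error": errors.local_error,
                "elapsed_s": round(time.time() - t0, 3),
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (Path(cfg.out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest["outputs"].append("manifest.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report_human_readable(manifest: dict, out_dir: str | Path | None = None) -> str:
    """Render a plain-text report from a run directory's outputs."""
    out = Path(out_dir if out_dir is not None else manifest["config"]["out_dir"])
    lines = ["Landlocking-history analysis report", "=" * 36, ""]
    warn: list[str] = []

    def section(title: str):
        lines.append(title)
        lines.append("-" * len(title))

    div_path = out / "diversity.tsv"
    if div_path.exists():
        section("Diversity statistics (per group-set)")
        lines.append(div_path.read_text().rstrip())
        lines.append("")
    else:
        warn.append("diversity table missing")
    fst_path = out / "pairwise_fst.tsv"
    if fst_path.exists():
        section("Pairwise FST (Weir-Cockerham, bootstrap over loci)")
        lines.append(fst_path.read_text().rstrip())
        lines.append("")
    else:
        warn.append("pairwise FST missing")
    mc_path = out / "model_choice.json"
    if mc_path.exists():
        choice = json.loads(mc_path.read_text())
        section("Scenario choice (random-forest votes)")
        votes = sorted(choice["votes"].items(), key=lambda kv: -kv[1])
        width = 40
        for sid, v in votes:
            lines.append(f"scenario {sid:>2}: {'#' * int(round(v * width)):<{width}} {v:.3f}")
        lines.append(
            f"selected scenario {choice['selected_scenario']} "
            f"(posterior probability {choice['posterior_probability']:.3f}, "
            f"prior error {choice['prior_error']:.3f})"
        )
        lines.append("")
    else:
        warn.append("model choice missing")
    est_path = out / "param_estimates.json"
    if est_path.exists():
        est = json.loads(est_path.read_text())
        section(f"Parameter estimates (scenario {est['scenario_id']})")
        lines.append(
            f"{'parameter':<22}{'point':>14}{'2.5%':>14}{'97.5%':>14}{'years':>14}"
        )
        for name, e in est["estimates"].items():
            years = e.get("point_years", "")
            years_s = f"{years:,.0f}" if years != "" else "-"
            lines.append(
                f"{name:<22}{e['point']:>14,.0f}{e['q025']:>14,.0f}"
                f"{e['q975']:>14,.0f}{years_s:>14}"
            )
        lines.append("(years at one generation per year)")
        lines.append("")
    err_path = out / "error_report.json"
    if err_path.exists():
        err = json.loads(err_path.read_text())
        section("Error rates")
        lines.append(
            f"global (prior) error {err['global_error']:.3f}; "
            f"local (posterior) error {err['local_error']:.3f} "
            f"({err['n_pseudo_observed']} pseudo-observed sets)"
        )
        lines.append("")
    if warn:
        lines.append("WARNINGS: " + "; ".join(warn))
    text = "\n".join(lines)
    if out_dir is not None or (out / "manifest.json").exists():
        (out / "report.txt").write_text(text)
    return text
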