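"""End-to-end orchestration of the fine-mapping analysis.

Stages run in the study's workflow order: simulate (or ingest) the cohort,
sample QC and relatedness pruning, variant QC, ancestry estimation,
single-variant association, stepwise conditional modelling, Bayesian
fine-mapping, LD/haplotype analysis, the rare-variant burden test, and
assay quantification.  Every stage logs its input and output counts into a
run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ancestry, assay_quant, assoc, finemap_bayes, genio, ld_haplotype, qc, rare_kbac
from .synthetic_cohort import (
    SimulationConfig,
    build_study_pools,
    inject_missingness,
    make_ancestral_panel,
    simulate_aims,
    simulate_assay_tables,
    simulate_cohort,
)
from .types import GenotypeMatrix

log = logging.getLogger("locusfine")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    completed: bool = False

    def record(self, stage: str, n_samples_in: int, n_variants_in: int,
               n_samples_out: int, n_variants_out: int, **extra):
        self.stages.append(
            {
                "stage": stage,
                "samples_in": n_samples_in,
                "variants_in": n_variants_in,
                "samples_out": n_samples_out,
                "variants_out": n_variants_out,
                **extra,
            }
        )
        log.info("%s: %d samples, %d variants -> %d samples, %d variants",
                 stage, n_samples_in, n_variants_in, n_samples_out, n_variants_out)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


DEFAULT_CONFIG = {
    "n_variants": 57,
    "n_cases": 400,
    "n_controls": 360,
    "causal_index": 28,
    "causal_or": 0.81,
    "causal_raf": 0.30,
    "missing_rate": 0.02,
    "n_aims": 347,
    "rare_variant_count": 20,
    "rare_enrichment": 1.0,
    "pool_haplotypes": 10000,
    "finemap_level": 0.95,
    "kbac_perms": 1000,
    "assay_effect": 0.5,
    "assay_noise_sd": 3.0,
    "assay_lines": 10,
    "ibd_sample_cap": 2000,
    "skip_stages": "",
}


def run_pipeline(config: dict | None = None, outdir: str | Path = "locusfine_out",
                 seed: int = 0) -> RunManifest:
    """Run the full analysis on a simulated cohort; returns the manifest."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(filter(None, str(cfg.get("skip_stages", "")).split(",")))
    manifest = RunManifest(config=cfg, seed=seed)
    rng = np.random.default_rng(seed)

    try:
        # -- simulate -------------------------------------------------
        pools = build_study_pools(
            n_variants=int(cfg["n_variants"]),
            n_haplotypes=int(cfg["pool_haplotypes"]),
            seed=seed,
        )
        sim = SimulationConfig(
            n_cases=int(cfg["n_cases"]),
            n_controls=int(cfg["n_controls"]),
            causal_index=int(cfg["causal_index"]),
            causal_or=float(cfg["causal_or"]),
            causal_raf=float(cfg["causal_raf"]),
            missing_rate=float(cfg["missing_rate"]),
            n_aims=int(cfg["n_aims"]),
            rare_variant_count=int(cfg["rare_variant_count"]),
            rare_enrichment=float(cfg["rare_enrichment"]),
            seed=int(rng.integers(2**31)),
        )
        gm, samples_df = simulate_cohort(pools, sim)
        gm = inject_missingness(gm, sim.missing_rate, seed=int(rng.integers(2**31)))
        panel = make_ancestral_panel(sim.n_aims, seed=int(rng.integers(2**31)))
        aims = simulate_aims(gm.samples, panel, seed=int(rng.integers(2**31)))
        genio.write_ped_map(gm, outdir / "cohort.ped", outdir / "cohort.map")
        genio.write_vcf(gm, outdir / "cohort.vcf")
        manifest.record("simulate", 0, 0, gm.n_samples, gm.n_variants,
                        causal_variant=pools[0].variant_ids[sim.causal_index])

        # -- sample QC + relatedness ---------------------------------
        n_s, n_v = gm.n_samples, gm.n_variants
        if "sample_qc" not in skip:
            rep = qc.sample_qc(gm)
            if gm.n_samples <= int(cfg["ibd_sample_cap"]):
                kin = qc.estimate_ibd_all_pairs(gm)
                prune = qc.prune_related(gm, kin)
                rep.sample_fail.update(
                    {k: v for k, v in prune.sample_fail.items() if k not in rep.sample_fail}
                )
            gm = qc.apply_qc(gm, rep)
            keep = [s.id for s in gm.samples]
            aims = aims.subset(sample_idx=[i for i, s in enumerate(aims.samples) if s.id in set(keep)])
            rep.to_frame().to_csv(outdir / "sample_qc.tsv", sep="\t", index=False)
        manifest.record("sample_qc", n_s, n_v, gm.n_samples, gm.n_variants)

        # -- variant QC ----------------------------------------------
        n_s, n_v = gm.n_samples, gm.n_variants
        if "variant_qc" not in skip:
            rare_ids = [v.id for v in gm.variants if v.id.startswith("rare")]
            rep = qc.variant_qc(gm, exempt_maf=rare_ids)
            rep.to_frame().to_csv(outdir / "variant_qc.tsv", sep="\t", index=False)
            gm = qc.apply_qc(gm, rep)
        manifest.record("variant_qc", n_s, n_v, gm.n_samples, gm.n_variants)

        # -- ancestry -------------------------------------------------
        if "ancestry" not in skip:
            scores, props = ancestry.annotate_samples(gm, aims, panel)
            outliers = ancestry.flag_outliers(scores, np.zeros(len(scores)))
            keep_idx = np.nonzero(~outliers)[0]
            n_s = gm.n_samples
            gm = gm.subset(sample_idx=keep_idx)
            genio.write_phenotypes(gm.samples, outdir / "phenotypes.tsv")
            manifest.record("ancestry", n_s, gm.n_variants, gm.n_samples, gm.n_variants,
                            outliers_removed=int(outliers.sum()))
        covars = gm.admixture_covariates()

        # -- association ----------------------------------------------
        common_idx = [j for j, v in enumerate(gm.variants) if not v.id.startswith("rare")]
        gm_common = gm.subset(variant_idx=common_idx)
        results = assoc.scan_region(gm_common, covars, "additive")
        res_df = genio.write_results(results, outdir / "association.tsv")
        manifest.record("association", gm.n_samples, gm.n_variants,
                        gm.n_samples, len(results))

        # -- conditional ----------------------------------------------
        if "conditional" not in skip:
            signals, profile = assoc.stepwise_conditional(gm_common, covars)
            genio.write_results(signals, outdir / "signals.tsv")
            profile.to_csv(outdir / "conditioning_profile.tsv", sep="\t", index=False)
            manifest.record("conditional", gm.n_samples, len(results),
                            gm.n_samples, len(signals), n_signals=len(signals))

        # -- Bayesian fine-mapping ------------------------------------
        if "finemap" not in skip:
            cs = finemap_bayes.finemap_region(gm_common, covars,
                                              level=float(cfg["finemap_level"]))
            cs.to_frame(gm_common.positions()).to_csv(
                outdir / "credible_set.tsv", sep="\t", index=False
            )
            manifest.record("finemap", gm.n_samples, gm_common.n_variants,
                            gm.n_samples, cs.size, span_bp=cs.span_bp)

        # -- LD / haplotypes ------------------------------------------
        if "ld" not in skip:
            blocks = ld_haplotype.four_gamete_blocks(gm_common)
            pd.DataFrame(
                [
                    {
                        "start_idx": b.start_idx, "end_idx": b.end_idx,
                        "start_bp": b.start_bp, "end_bp": b.end_bp,
                        "haplotypes": ";".join(f"{h}:{f:.4f}" for h, f in b.haplotypes),
                    }
                    for b in blocks
                ]
            ).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
            windows, haps = ld_haplotype.sliding_window_hap_assoc(gm_common, covars)
            windows.to_csv(outdir / "hap_windows.tsv", sep="\t", index=False)
            haps.to_csv(outdir / "hap_effects.tsv", sep="\t", index=False)
            manifest.record("ld_haplotype", gm.n_samples, gm_common.n_variants,
                            gm.n_samples, len(blocks), n_windows=len(windows))

        # -- rare variants --------------------------------------------
        if "rare" not in skip:
            kb = rare_kbac.kbac_test(gm, n_perms=int(cfg["kbac_perms"]),
                                     seed=int(rng.integers(2**31)))
            pd.DataFrame(
                [
                    {
                        "statistic": kb.statistic, "p_perm": kb.p_perm,
                        "n_perms": kb.n_perms, "n_rare_variants": kb.n_rare_variants,
                        "note": kb.note,
                    }
                ]
            ).to_csv(outdir / "kbac.tsv", sep="\t", index=False)
            manifest.record("rare", gm.n_samples, gm.n_variants,
                            gm.n_samples, kb.n_rare_variants)

        # -- assays ---------------------------------------------------
        if "assay" not in skip:
            table = simulate_assay_tables(
                effect=float(cfg["assay_effect"]),
                noise_sd=float(cfg["assay_noise_sd"]),
                n_lines=int(cfg["assay_lines"]),
                seed=int(rng.integers(2**31)),
            )
            cmp = assay_quant.group_compare_timecourse(table, n_perms=2000,
                                                       seed=int(rng.integers(2**31)))
            assay_quant.add_percent_column(table).to_csv(
                outdir / "assay_internalization.tsv", sep="\t", index=False
            )
            cmp["per_timepoint"].assign(
                p_overall_two_sided=cmp["p_two_sided"]
            ).to_csv(outdir / "assay_compare.tsv", sep="\t", index=False)
            manifest.record("assay", len(table), 0, len(table), 0,
                            p_two_sided=cmp["p_two_sided"])

        # -- plot -----------------------------------------------------
        if "plot" not in skip:
            cs_path = outdir / "credible_set.tsv"
            cs_df = pd.read_csv(cs_path, sep="\t") if cs_path.exists() else None
            plot_region(res_df, gm_common, cs_df, outdir / "region.png")
        manifest.completed = True
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


def plot_region(results: pd.DataFrame, gm: GenotypeMatrix | None = None,
                credible: pd.DataFrame | None = None, path="region.png"):
    """Association and posterior-probability panels across the region.

    Genotyped and imputed variants are drawn in different colours;
    credible-set members are highlighted in green in the posterior panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if credible is not None else 1
    fig, axes = plt.subplots(n_panels, 1, figsize=(8, 3 * n_panels), squeeze=False)
    ax = axes[0][0]
    if len(results) == 0:
        ax.set_title("no results")
    else:
        if gm is not None and len(gm.variants) == len(results):
            pos = gm.positions() / 1e6
            genotyped = np.array([v.genotyped for v in gm.variants])
        else:
            pos = np.arange(len(results), dtype=float)
            genotyped = np.ones(len(results), dtype=bool)
        y = results["neglog10_p"].to_numpy()
        ax.scatter(pos[genotyped], y[genotyped], c="red", s=12, label="genotyped")
        if (~genotyped).any():
            ax.scatter(pos[~genotyped], y[~genotyped], c="blue", s=12, label="imputed")
        ax.set_ylabel(r"$-\log_{10}(p)$")
        ax.legend(loc="best", fontsize=7)
    if credible is not None:
        ax2 = axes[1][0]
        cpos = (credible["pos"] / 1e6) if "pos" in credible else np.arange(len(credible))
        member = credible["member"].astype(bool).to_numpy()
        ax2.scatter(cpos[~member], credible["posterior"][~member], c="gray", s=12)
        ax2.scatter(cpos[member], credible["posterior"][member], c="green", s=14,
                    label="credible set")
        ax2.set_ylabel("posterior")
        ax2.set_xlabel("position (Mb)")
        ax2.legend(loc="best", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
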