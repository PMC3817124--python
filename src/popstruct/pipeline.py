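"""End-to-end orchestration of the two analysis tiers.

Stage 1 ("worldwide-style", few markers shared between two platforms):
harmonize two cohorts, check MAF concordance, build a bootstrap NJ
consensus over labelled populations, assign subpopulations with
iterative-pruning PCA, and sweep admixture fits over K.

Stage 2 ("high-resolution", one merged dense matrix): marker QC,
cohort-bias screen, ipPCA assignment, outlier exclusion, admixture over
a small K range, and pairwise/per-SNP Fst reports.

Both stages run from a single structured config (YAML or dict), write
plain TSV/Newick artifacts plus a JSON run manifest with checksums,
seeds and wall-clock per stage, and are bit-reproducible given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import sweep_k
from .data import GenotypeMatrix
from .fst import pairwise_fst_matrix, rank_snps_by_fst, render_pairwise_table
from .harmonize import (
    batch_bias_test,
    filter_markers,
    intersect_and_harmonize,
    ld_prune,
    maf_concordance,
)
from .io import (
    read_matrix_tsv,
    read_plink_text,
    write_matrix_tsv,
    write_table_tsv,
)
from .ippca import IterativePruningPCA, serialize_cluster_tree
from .njtree import bootstrap_consensus, write_newick
from .simulate import (
    SimulationConfig,
    inject_outliers,
    plant_divergent_loci,
    simulate_subpopulations,
    split_platforms,
    write_planted_tsv,
    write_truth_tsv,
)

log = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: dict, outdir: Path):
        self.data = {
            "software": f"popstruct {__version__}",
            "config": config,
            "stages": {},
            "files": {},
        }
        self.outdir = outdir

    def stage(self, name: str, seconds: float, **info) -> None:
        self.data["stages"][name] = {"wall_clock_s": round(seconds, 3), **info}

    def finish(self) -> Path:
        for f in sorted(self.outdir.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                self.data["files"][f.name] = _sha256(f)
        out = self.outdir / "manifest.json"
        out.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return out


def _load_cohort(entry: dict) -> GenotypeMatrix:
    if "tsv" in entry:
        return read_matrix_tsv(entry["tsv"])
    return read_plink_text(entry["ped"], entry["map"])


def _sim_config(entry: dict) -> SimulationConfig:
    fields = {k: v for k, v in entry.items() if k in SimulationConfig.__dataclass_fields__}
    cfg = SimulationConfig(**fields)
    if cfg.admixture_alpha is not None:
        cfg.admixture_alpha = tuple(cfg.admixture_alpha)
    if isinstance(cfg.ancestral_maf_range, list):
        cfg.ancestral_maf_range = tuple(cfg.ancestral_maf_range)
    return cfg


def _simulate_dataset(entry: dict):
    """Simulate a structured dataset with optional planted loci/outliers.

    Region labels mirror the true subpopulation (outliers "Unknown"),
    playing the role of self-reported origin in reporting stages.
    """
    cfg = _sim_config(entry)
    gm, truth = simulate_subpopulations(cfg)
    if cfg.n_planted_loci:
        gm, truth = plant_divergent_loci(
            gm, truth, cfg.n_planted_loci, cfg.planted_delta, cfg.seed + 1
        )
    if cfg.n_outliers:
        gm, truth = inject_outliers(
            gm, truth, cfg.n_outliers, cfg.outlier_drift, cfg.seed + 2
        )
    region = truth.membership.reindex(gm.sample_ids).fillna("Unknown")
    gm.samples["region"] = region.to_numpy()
    return gm, truth


def run_stage1(config: dict, outdir) -> dict:
    """Harmonize -> MAF concordance -> NJ bootstrap -> ipPCA -> K sweep."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    c = config.get("stage1", config)
    seed = int(c.get("seed", 0))
    truth = None

    t0 = time.perf_counter()
    if "sim" in c:
        gm, truth = _simulate_dataset({**c["sim"], "seed": seed})
        split = c.get("split", {})
        cohort_a, cohort_b, _ = split_platforms(
            gm,
            overlap_fraction=float(split.get("overlap_fraction", 0.8)),
            flip_fraction=float(split.get("flip_fraction", 0.1)),
            ambiguous_fraction=float(split.get("ambiguous_fraction", 0.05)),
            per_cohort_missing=float(split.get("per_cohort_missing", 0.0)),
            seed=seed + 10,
        )
        write_truth_tsv(truth, outdir / "truth.tsv")
    else:
        cohort_a = _load_cohort(c["cohort_a"])
        cohort_b = _load_cohort(c["cohort_b"])
    manifest.stage("input", time.perf_counter() - t0)

    t0 = time.perf_counter()
    merged, report = intersect_and_harmonize(cohort_a, cohort_b)
    r, maf_table = maf_concordance(merged)
    write_matrix_tsv(merged, outdir / "merged.tsv")
    write_table_tsv(maf_table, outdir / "maf_concordance.tsv")
    write_table_tsv(
        pd.DataFrame(
            [
                {
                    "n_shared": report.n_shared,
                    "n_merged": report.n_merged,
                    "n_complemented": report.n_complemented,
                    "n_ambiguous_excluded": report.n_ambiguous_excluded,
                    "n_allele_mismatch_excluded": report.n_allele_mismatch_excluded,
                    "maf_correlation": r,
                }
            ]
        ),
        outdir / "harmonization_report.tsv",
    )
    manifest.stage(
        "harmonize",
        time.perf_counter() - t0,
        n_merged=report.n_merged,
        maf_correlation=round(r, 6),
    )

    tree_cfg = c.get("tree", {})
    if tree_cfg.get("enabled", True):
        t0 = time.perf_counter()
        grouping = pd.Series(
            merged.samples["region"].fillna("Unlabelled").to_numpy(),
            index=merged.sample_ids,
        )
        cons = bootstrap_consensus(
            merged,
            grouping,
            n_replicates=int(tree_cfg.get("replicates", 100)),
            seed=seed + 20,
            outgroup=tree_cfg.get("outgroup"),
        )
        write_newick(cons, outdir / "nj_consensus.nwk")
        manifest.stage("nj_tree", time.perf_counter() - t0)

    t0 = time.perf_counter()
    ip = c.get("ippca", {})
    model = IterativePruningPCA(
        threshold=float(ip.get("threshold", 0.21)),
        min_subpop_size=int(ip.get("min_subpop_size", 20)),
    )
    ctree = model.fit(merged, seed=seed + 30)
    serialize_cluster_tree(
        ctree,
        outdir / "ippca_tree.tsv",
        labels=pd.Series(
            merged.samples["region"].to_numpy(), index=merged.sample_ids
        ),
    )
    assign = ctree.subpop_assignment()
    write_table_tsv(
        assign.rename_axis("sample_id").reset_index(), outdir / "ippca_assignment.tsv"
    )
    manifest.stage(
        "ippca",
        time.perf_counter() - t0,
        n_subpops=len(ctree.subpopulations()),
        n_outliers=len(ctree.outlier_ids),
    )

    t0 = time.perf_counter()
    adm = c.get("admixture", {})
    results = sweep_k(
        merged,
        k_min=int(adm.get("k_min", 2)),
        k_max=int(adm.get("k_max", 10)),
        n_restarts=int(adm.get("restarts", 1)),
        max_iter=int(adm.get("max_iter", 500)),
        seed=seed + 40,
    )
    for res in results:
        write_table_tsv(
            res.q_frame().rename_axis("sample_id").reset_index(),
            outdir / f"admixture_Q_K{res.K}.tsv",
        )
    write_table_tsv(
        pd.DataFrame(
            [{"K": r.K, "loglik": r.loglik, "converged": r.converged} for r in results]
        ),
        outdir / "admixture_loglik.tsv",
    )
    manifest.stage("admixture", time.perf_counter() - t0)

    manifest_path = manifest.finish()
    return {"outdir": outdir, "manifest": manifest_path, "cluster_tree": ctree}


def run_stage2(config: dict, outdir) -> dict:
    """QC -> cohort bias -> ipPCA -> admixture -> Fst matrix and ranking."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, outdir)
    c = config.get("stage2", config)
    seed = int(c.get("seed", 0))
    truth = None

    t0 = time.perf_counter()
    if "sim" in c:
        gm, truth = _simulate_dataset({**c["sim"], "seed": seed})
        # alternate samples between two synthetic collection cohorts so the
        # bias screen has two groups to compare
        gm.samples["cohort"] = np.where(
            np.arange(gm.n_samples) % 2 == 0, "A", "B"
        )
        write_truth_tsv(truth, outdir / "truth.tsv")
        if truth.planted_loci:
            write_planted_tsv(truth, outdir / "planted_loci.tsv")
    else:
        gm = _load_cohort(c["input"])
    manifest.stage("input", time.perf_counter() - t0)

    t0 = time.perf_counter()
    qc = c.get("qc", {})
    gm_f, qrep = filter_markers(
        gm,
        hwe_p=float(qc.get("hwe_p", 1e-3)),
        missing_max=float(qc.get("missing_max", 0.05)),
    )
    gm_f, ldrep = ld_prune(
        gm_f,
        r2_max=float(qc.get("ld_r2", 0.5)),
        window=int(qc.get("ld_window", 50)),
        step=int(qc.get("ld_step", 5)),
    )
    write_table_tsv(
        pd.DataFrame(
            [
                {
                    "n_input": qrep.n_input,
                    "n_fail_hwe": qrep.n_fail_hwe,
                    "n_fail_missing": qrep.n_fail_missing,
                    "n_pruned_ld": ldrep.n_pruned_ld,
                    "n_pass": ldrep.n_pass,
                }
            ]
        ),
        outdir / "qc_report.tsv",
    )
    manifest.stage("qc", time.perf_counter() - t0, n_pass=ldrep.n_pass)

    cohorts = gm_f.samples["cohort"].dropna().unique()
    if len(cohorts) == 2:
        t0 = time.perf_counter()
        rows_a = (gm_f.samples["cohort"] == cohorts[0]).to_numpy()
        bias = batch_bias_test(
            gm_f.take_samples(rows_a),
            gm_f.take_samples(~rows_a),
            bonferroni_alpha=float(c.get("bonferroni_alpha", 1e-7)),
        )
        write_table_tsv(bias, outdir / "batch_bias.tsv")
        manifest.stage(
            "batch_bias",
            time.perf_counter() - t0,
            n_flagged=int(bias["flagged"].sum()),
        )

    t0 = time.perf_counter()
    ip = c.get("ippca", {})
    model = IterativePruningPCA(
        threshold=float(ip.get("threshold", 0.21)),
        min_subpop_size=int(ip.get("min_subpop_size", 20)),
    )
    ctree = model.fit(gm_f, seed=seed + 30)
    serialize_cluster_tree(
        ctree,
        outdir / "ippca_tree.tsv",
        labels=pd.Series(gm_f.samples["region"].to_numpy(), index=gm_f.sample_ids),
    )
    assign = ctree.subpop_assignment()
    write_table_tsv(
        assign.rename_axis("sample_id").reset_index(), outdir / "ippca_assignment.tsv"
    )
    manifest.stage(
        "ippca",
        time.perf_counter() - t0,
        n_subpops=len(ctree.subpopulations()),
        n_outliers=len(ctree.outlier_ids),
    )

    # outliers are excluded before admixture and Fst
    core = gm_f.select_samples(list(assign.index))

    t0 = time.perf_counter()
    adm = c.get("admixture", {})
    results = sweep_k(
        core,
        k_min=int(adm.get("k_min", 2)),
        k_max=int(adm.get("k_max", 4)),
        n_restarts=int(adm.get("restarts", 1)),
        max_iter=int(adm.get("max_iter", 500)),
        seed=seed + 40,
    )
    for res in results:
        write_table_tsv(
            res.q_frame().rename_axis("sample_id").reset_index(),
            outdir / f"admixture_Q_K{res.K}.tsv",
        )
    manifest.stage("admixture", time.perf_counter() - t0)

    t0 = time.perf_counter()
    fst_cfg = c.get("fst", {})
    report = pairwise_fst_matrix(
        core,
        assign,
        n_permutations=int(fst_cfg.get("permutations", 1023)),
        seed=seed + 50,
    )
    write_table_tsv(render_pairwise_table(report), outdir / "fst_matrix.tsv")
    write_table_tsv(
        pd.DataFrame(
            [
                {
                    "pop_x": p.pop_pair[0],
                    "pop_y": p.pop_pair[1],
                    "theta": p.theta_genomewide,
                    "p_value": p.p_value,
                    "n_permutations": p.n_permutations,
                }
                for p in report.pairs
            ]
        ),
        outdir / "fst_pairs.tsv",
    )
    rankings = rank_snps_by_fst(core, assign, top_n=int(fst_cfg.get("top_n", 200)))
    for (x, y), table in rankings.items():
        write_table_tsv(table, outdir / f"fst_rank_{x}_{y}.tsv")
    manifest.stage("fst", time.perf_counter() - t0)

    # region-by-subpopulation proportions (reporting only)
    region = pd.Series(gm_f.samples["region"].to_numpy(), index=gm_f.sample_ids)
    status = assign.reindex(gm_f.sample_ids).fillna("Outlier")
    prop = (
        pd.crosstab(region, status, normalize="index")
        .rename_axis("region")
        .reset_index()
    )
    write_table_tsv(prop, outdir / "region_proportions.tsv")

    manifest_path = manifest.finish()
    return {"outdir": outdir, "manifest": manifest_path, "cluster_tree": ctree}
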