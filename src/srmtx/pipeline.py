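"""End-to-end orchestration: simulate → srm → pls → enrich → ppi.

Each stage reads its inputs from files written by the previous stage (so the
on-disk contract is exercised), writes TSV/JSON outputs into a per-stage
subdirectory, and the run ends with a machine-readable manifest recording
input hashes, parameters, per-stage outputs and library versions.  A single
top-level seed deterministically derives every stage seed, so one integer
reproduces a run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from srmtx import expression, io, network, phenotype, pls, synthetic
from srmtx import enrichment as enrich_mod
from srmtx.config import RunConfig, spawn_seed
from srmtx.exceptions import PipelineValidationError

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _validate_region_names(
    mt: pd.DataFrame, centroids: pd.DataFrame, expr: pd.DataFrame
) -> None:
    mt_regions = list(mt.columns)
    cen_regions = list(centroids["region"])
    expr_regions = list(expr.index)
    problems = []
    if mt_regions != cen_regions:
        problems.append(
            f"MT columns vs centroids: {sorted(set(mt_regions) ^ set(cen_regions)) or 'order differs'}"
        )
    if expr_regions != cen_regions:
        problems.append(
            f"expression rows vs centroids: {sorted(set(expr_regions) ^ set(cen_regions)) or 'order differs'}"
        )
    if problems:
        raise PipelineValidationError(
            "region-name mismatch between inputs: " + "; ".join(problems)
        )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "input_hashes": {},
    }
    inputs_dir = outdir / "inputs"

    if "simulate" in config.stages:
        dataset = synthetic.generate_dataset(config.synthetic)
        paths = synthetic.write_dataset(dataset, inputs_dir)
        manifest["stages"]["simulate"] = {"outputs": sorted(paths)}

    required = [
        "subjects.tsv",
        "trait.tsv",
        "mt_matrix.tsv",
        "centroids.csv",
        "expression.tsv",
        "genesets.gmt",
        "ppi_edges.tsv",
    ]
    for name in required:
        path = inputs_dir / name
        if not path.exists():
            raise PipelineValidationError(
                f"missing input file {path} (needed before stage 'srm')"
            )
        manifest["input_hashes"][name] = _sha256(path)

    subjects = io.read_table(inputs_dir / "subjects.tsv")
    trait_raw = io.read_table(inputs_dir / "trait.tsv")
    mt = io.read_matrix_tsv(inputs_dir / "mt_matrix.tsv")
    centroids = pd.read_csv(inputs_dir / "centroids.csv")
    expr_raw = io.read_matrix_tsv(inputs_dir / "expression.tsv")
    _validate_region_names(mt, centroids, expr_raw)

    srm_dir = outdir / "srm"
    if "srm" in config.stages:
        srm_dir.mkdir(exist_ok=True)
        trait = phenotype.combine_and_transform_trait(trait_raw)
        ages = subjects.set_index("subject_id").loc[mt.index, "age"]
        age_fit = phenotype.fit_regional_age_model(mt, ages)
        if config.covariates:
            srm_map = phenotype.covariate_adjusted_srm(
                mt, trait, subjects, list(config.covariates),
                alpha=config.fdr_level, force_spearman=config.robust,
            )
        else:
            srm_map = phenotype.compute_srm(
                age_fit, trait, alpha=config.fdr_level,
                force_spearman=config.robust,
            )
        r2_global, p_global = phenotype.global_association(mt, trait, ages)
        qc = phenotype.euler_qc(subjects, mt)
        srm_map.to_csv(srm_dir / "srm_map.tsv", sep="\t", index=False)
        age_table = pd.DataFrame(
            {"region": age_fit.mt14.index, "mt14": age_fit.mt14.to_numpy(),
             "dmt": age_fit.dmt.to_numpy()}
        )
        age_table.to_csv(srm_dir / "age_model.tsv", sep="\t", index=False)
        io.write_json(
            {
                "global_r2": r2_global,
                "global_p": p_global,
                "euler_rho_before": qc.rho_before,
                "euler_p_before": qc.p_before,
                "euler_rho_after": qc.rho_after,
                "euler_p_after": qc.p_after,
                "n_excluded": int(qc.excluded.sum()),
            },
            srm_dir / "global.json",
        )
        manifest["stages"]["srm"] = {
            "outputs": ["srm_map.tsv", "age_model.tsv", "global.json"],
            "n_sig_fdr": int(srm_map["sig_fdr"].sum()),
        }

    pls_dir = outdir / "pls"
    if "pls" in config.stages:
        pls_dir.mkdir(exist_ok=True)
        srm_map = io.read_table(srm_dir / "srm_map.tsv")
        y = srm_map.set_index("region").loc[expr_raw.index, "r"].to_numpy()
        X = expression.normalize_expression(expr_raw)
        result = pls.fit_pls1(X, y)
        scheme = pls.spin_relabelings(
            centroids, config.n_perm_spin, spawn_seed(config.seed, "spin")
        )
        spin = pls.spin_pvalue(X, y, scheme)
        gene_stats = pls.bootstrap_gene_weights(
            X, y, n_boot=config.n_boot,
            seed=spawn_seed(config.seed, "bootstrap"), alpha=config.fdr_level,
        )
        pos, neg = pls.significant_gene_lists(gene_stats)
        gene_stats.to_csv(pls_dir / "pls_result.tsv", sep="\t", index=False)
        pd.DataFrame({"null_varexp": spin.null_varexp}).to_csv(
            pls_dir / "null_varexp.tsv", sep="\t", index=False
        )
        io.write_json(
            {
                "varexp": result.varexp,
                "spin_p": spin.p,
                "n_perm": config.n_perm_spin,
                "n_boot": config.n_boot,
                "n_positive": len(pos),
                "n_negative": len(neg),
                "seed": config.seed,
            },
            pls_dir / "pls_summary.json",
        )
        manifest["stages"]["pls"] = {
            "outputs": ["pls_result.tsv", "pls_summary.json", "null_varexp.tsv"],
            "varexp": result.varexp,
            "spin_p": spin.p,
        }

    enrich_dir = outdir / "enrich"
    if "enrich" in config.stages:
        enrich_dir.mkdir(exist_ok=True)
        gene_stats = io.read_table(pls_dir / "pls_result.tsv")
        pos, neg = pls.significant_gene_lists(gene_stats)
        universe = gene_stats["gene"].tolist()
        genesets = io.read_gmt(inputs_dir / "genesets.gmt")
        de_names = sorted(p.name for p in inputs_dir.glob("de_*.tsv"))
        de_tables = {
            name[3:-4]: io.read_table(inputs_dir / name) for name in de_names
        }
        target_lists = {
            name: genes
            for name, genes in (("positive", pos), ("negative", neg))
            if genes
        }
        skipped = sorted({"positive", "negative"} - set(target_lists))
        if skipped:
            log.warning("no significant genes in lists %s; enrichment skipped "
                        "for them", skipped)
        celltypes = {
            k: v for k, v in genesets.items()
            if not k.endswith("regulated_like")
        }
        de_sets = {
            k: v for k, v in genesets.items() if k.endswith("regulated_like")
        }
        if target_lists:
            ct_table = enrich_mod.celltype_enrichment(
                target_lists, celltypes, universe,
                n_perm=config.n_perm_enrich,
                seed=spawn_seed(config.seed, "enrichment"),
                alpha=config.fdr_level,
            )
        else:
            ct_table = pd.DataFrame()
        de_rows: list[dict] = []
        de_seed_rng = np.random.default_rng(spawn_seed(config.seed, "enrichment"))
        for tname, tgenes in sorted(target_lists.items()):
            for aname, agenes in sorted(de_sets.items()):
                res = enrich_mod.relabeling_enrichment(
                    tgenes, agenes, universe,
                    n_perm=config.n_perm_enrich,
                    seed=int(de_seed_rng.integers(0, 2**31 - 1)),
                    target_name=tname, annotation_name=aname,
                )
                de_rows.append(res.__dict__)
        de_table = pd.DataFrame(de_rows)
        if len(de_table):
            de_table["q"] = np.nan  # DE-list overlaps: raw permutation p
        enr = pd.concat([ct_table, de_table], ignore_index=True)
        enr.to_csv(enrich_dir / "enrichment.tsv", sep="\t", index=False)
        weights = gene_stats.set_index("gene")["weight"]
        de_corr = enrich_mod.weight_de_correlation(weights, de_tables)
        de_corr.to_csv(enrich_dir / "de_correlations.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "outputs": ["enrichment.tsv", "de_correlations.tsv"]
        }

    ppi_dir = outdir / "ppi"
    if "ppi" in config.stages:
        ppi_dir.mkdir(exist_ok=True)
        gene_stats = io.read_table(pls_dir / "pls_result.tsv")
        pos, _ = pls.significant_gene_lists(gene_stats)
        genesets = io.read_gmt(inputs_dir / "genesets.gmt")
        down = genesets.get("downregulated_like", set())
        # genes both positively weighted and transcriptionally downregulated
        target = sorted(set(pos) & down)
        target_name = "positive_and_downregulated"
        if len(target) < 2:
            target, target_name = pos, "positive"
        if len(target) < 2:
            log.warning("fewer than 2 significant genes; PPI test skipped")
            io.write_json({"skipped": "fewer than 2 significant genes"},
                          ppi_dir / "ppi_test.json")
            manifest["stages"]["ppi"] = {"outputs": ["ppi_test.json"],
                                         "p": None}
            io.write_json(manifest, outdir / "manifest.json")
            return manifest
        edges = io.read_table(inputs_dir / "ppi_edges.tsv")
        universe = gene_stats["gene"].tolist()
        graph = network.load_ppi(edges, universe=universe)
        result = network.induced_edge_test(
            graph, target, n_perm=config.n_perm_ppi,
            seed=spawn_seed(config.seed, "network"),
            universe=universe, name=target_name,
        )
        result.degrees.to_csv(ppi_dir / "degrees.tsv", sep="\t", index=False)
        io.write_json(
            {
                "geneset": result.name,
                "n_input": result.n_input,
                "n_mapped": result.n_mapped,
                "observed_edges": result.observed_edges,
                "null_mean": result.null_mean,
                "null_sd": result.null_sd,
                "p": result.p,
                "n_perm": result.n_perm,
                "component_sizes": network.connected_component_sizes(
                    graph, target
                ),
                "hubs": network.hub_ranking(graph, target, 4).to_dict("records"),
            },
            ppi_dir / "ppi_test.json",
        )
        manifest["stages"]["ppi"] = {
            "outputs": ["ppi_test.json", "degrees.tsv"],
            "p": result.p,
        }

    io.write_json(manifest, outdir / "manifest.json")
    return manifest
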