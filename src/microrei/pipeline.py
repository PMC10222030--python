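"""Stage orchestration: each stage reads upstream TSV/JSON outputs from
the run directory, computes its piece of the analysis and writes result
files plus a run log with package versions, seed and parameters."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, archetypes, boosting, community, interpret, io, metagenome
from . import network as net
from . import phenotype as pheno
from . import simulate as sim

STAGES = (
    "simulate",
    "phenotype",
    "community",
    "archetypes",
    "predict",
    "interpret",
    "network",
    "metagenome",
    "report",
)


class MissingUpstreamError(FileNotFoundError):
    pass


def _need(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise MissingUpstreamError(
            f"missing {path}: run the '{producer}' stage first"
        )
    return path


def _log(outdir: Path, stage: str, cfg: dict, extra: dict | None = None) -> None:
    io.write_json(
        {
            "stage": stage,
            "microrei_version": __version__,
            "numpy_version": np.__version__,
            "seed": cfg.get("seed"),
            "params": cfg.get(stage, {}),
            **(extra or {}),
        },
        outdir / f"log_{stage}.json",
    )


# --------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    s = cfg["simulate"]
    config = sim.CohortConfig(
        n_animals=s["n_animals"],
        n_asvs=s["n_asvs"],
        n_components=s["n_components"],
        module_sizes=tuple(s["module_sizes"]),
        within_module_assoc=s["within_module_assoc"],
        noise_sd=s["noise_sd"],
        n_days=s["n_days"],
        seed=cfg["seed"],
    )
    counts, truth = sim.simulate_community(config)
    records = sim.simulate_energy_records(truth, config)
    io.write_table(counts, outdir / "asv_counts.tsv", index_label="sample_id")
    records.to_csv(outdir / "energy_records.tsv", sep="\t", index=False)

    # synthetic taxonomy: genus named after the planted module
    genus = [
        f"Genus_module{m}" if m > 0 else "Genus_background"
        for m in truth.module_labels
    ]
    tax = pd.DataFrame(
        {
            "Domain": "Bacteria",
            "Phylum": "Synthetica",
            "Class": "Synthetia",
            "Order": "Synthetales",
            "Family": "Syntheticaceae",
            "Genus": genus,
        },
        index=pd.Index(counts.columns, name="asv_id"),
    )
    io.write_table(tax, outdir / "taxonomy.tsv", index_label="asv_id")

    g = s["genes"]
    gene_counts, groups, annotation, gene_truth = sim.simulate_gene_matrix(
        n_genes=g["n_genes"],
        group_sizes=tuple(g["group_sizes"]),
        effect=g["effect"],
        ordered_fraction=g["ordered_fraction"],
        seed=cfg["seed"],
    )
    io.write_table(gene_counts, outdir / "gene_counts.tsv", index_label="gene_id")
    groups.to_frame().to_csv(outdir / "gene_groups.tsv", sep="\t", index_label="animal_id")
    io.write_annotation_maps(
        annotation["gene2ko"], annotation["gene2cazy"], gene_counts.index, outdir / "gene_map.tsv"
    )
    io.write_pathways(annotation["pathway2kos"], outdir / "pathways.tsv")
    io.write_json(
        {
            "rei_true": truth.rei_true,
            "module_labels": truth.module_labels,
            "X_true": truth.X_true,
            "component_effects": list(config.component_effects),
            "ordered_gene_ids": gene_truth.ordered_gene_ids,
            "enriched_pathway_ids": gene_truth.enriched_pathway_ids,
        },
        outdir / "truth.json",
    )
    _log(outdir, "simulate", cfg)


def stage_phenotype(cfg: dict, outdir: Path) -> None:
    records = pd.read_csv(_need(outdir, "energy_records.tsv", "simulate"), sep="\t")
    p = cfg["phenotype"]
    result = pheno.fit_rei(
        records, dim_window=tuple(p["dim_window"]), smooth_window=p["smooth_window"]
    )
    groups = pheno.assign_groups(result.rei)
    out = pd.DataFrame({"rei": result.rei, "group": groups})
    io.write_table(out, outdir / "rei.tsv", index_label="animal_id")
    _log(outdir, "phenotype", cfg, {"coefficients": result.coefficients})


def stage_community(cfg: dict, outdir: Path) -> None:
    counts = io.read_asv_table(_need(outdir, "asv_counts.tsv", "simulate"))
    rei = io.read_metadata(_need(outdir, "rei.tsv", "phenotype"), require=("rei", "group"))
    c = cfg["community"]
    core = community.filter_core_asvs(counts, min_rel=c["min_rel"], min_prev=c["min_prev"])
    io.write_table(core.counts, outdir / "core_counts.tsv", index_label="sample_id")
    alpha = community.alpha_diversity_table(core.relative)
    io.write_table(alpha, outdir / "alpha_diversity.tsv", index_label="sample_id")
    groups = rei.loc[core.relative.index, "group"]
    beta = community.divergence(core.relative, groups)
    io.write_table(beta.to_frame(), outdir / "divergence.tsv", index_label="sample_id")
    D = community.bray_curtis_matrix(core.relative)
    f, p = community.permanova(D, groups, n_perm=c["n_perm"], seed=cfg["seed"])
    alpha_tests = {
        name: community.rank_group_tests(alpha[name], groups)
        for name in alpha.columns
    }
    io.write_json(
        {
            "n_asvs_total": counts.shape[1],
            "n_asvs_core": core.counts.shape[1],
            "permanova_F": f,
            "permanova_p": p,
            "alpha_group_tests": {
                k: {"H": v["H"], "p": v["p"]} for k, v in alpha_tests.items()
            },
        },
        outdir / "community_summary.json",
    )
    _log(outdir, "community", cfg)


def stage_archetypes(cfg: dict, outdir: Path) -> None:
    core = io.read_asv_table(_need(outdir, "core_counts.tsv", "community"))
    rel = community.relative_abundance(core)
    a = cfg["archetypes"]
    model = archetypes.ArchetypeGLRM(
        n_components=a["n_components"],
        max_iter=a["max_iter"],
        tol=a["tol"],
        random_state=cfg["seed"],
    ).fit(rel)
    alpha = io.read_metadata(_need(outdir, "alpha_diversity.tsv", "community"))
    predictors, lambdas = archetypes.engineer_predictors(model, alpha)
    io.write_table(predictors, outdir / "predictors.tsv", index_label="sample_id")
    io.write_table(
        pd.DataFrame(model.X_, index=rel.index,
                     columns=[f"Arch{j + 1}" for j in range(model.X_.shape[1])]),
        outdir / "glrm_X.tsv", index_label="sample_id",
    )
    io.write_table(
        pd.DataFrame(model.components_, columns=rel.columns,
                     index=[f"Arch{j + 1}" for j in range(model.components_.shape[0])]),
        outdir / "glrm_Y.tsv", index_label="component",
    )
    io.write_json(
        {
            "column_means": model.column_means_,
            "variance_shares": model.variance_shares_,
            "selected": model.selected_,
            "selected_names": [f"Arch{j + 1}" for j in model.selected_],
            "share_selected": float(model.variance_shares_[model.selected_].sum()),
            "lambdas": lambdas,
            "n_iter": model.n_iter_,
            "final_objective": model.objective_history_[-1],
        },
        outdir / "glrm_model.json",
    )
    _log(outdir, "archetypes", cfg)


def _load_predictors_and_target(outdir: Path):
    predictors = io.read_metadata(_need(outdir, "predictors.tsv", "archetypes"))
    rei = io.read_metadata(_need(outdir, "rei.tsv", "phenotype"), require=("rei",))
    predictors = predictors.loc[rei.index.intersection(predictors.index)]
    y = rei.loc[predictors.index, "rei"].astype(float)
    return predictors, y


def stage_predict(cfg: dict, outdir: Path) -> None:
    predictors, y = _load_predictors_and_target(outdir)
    p = cfg["predict"]
    split = boosting.split_data(len(y), seed=cfg["seed"])
    X = predictors.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    params = {
        "eta": p["eta"], "depth": p["depth"], "min_node": p["min_node"],
        "row_subsample": p["row_subsample"], "col_subsample": p["col_subsample"],
    }
    n_rounds = p["n_rounds"]
    if p.get("tune"):
        tuned = boosting.tune_sequential(
            X[split.train], yv[split.train], X[split.validation], yv[split.validation],
            n_rounds=p["tune_rounds"], seed=cfg["seed"],
        )
        n_rounds = tuned.pop("n_rounds")
        params = tuned
    model = boosting.GradientBoostedTreeRegressor(
        n_rounds=n_rounds, random_state=cfg["seed"], **params
    ).fit(predictors.iloc[split.train], yv[split.train],
          eval_set=(X[split.validation], yv[split.validation]))
    metrics = boosting.evaluate(model, X, yv, split)
    metrics.to_csv(outdir / "prediction_metrics.tsv", sep="\t", index=False)
    io.write_json(model.to_dict(), outdir / "gbm_model.json")
    io.write_json(
        {"train": split.train, "validation": split.validation, "test": split.test},
        outdir / "data_split.json",
    )
    pred = pd.DataFrame({"prediction": model.predict(X), "rei": yv}, index=predictors.index)
    io.write_table(pred, outdir / "predictions.tsv", index_label="animal_id")
    _log(outdir, "predict", cfg, {"params": {**params, "n_rounds": n_rounds}})


def stage_interpret(cfg: dict, outdir: Path) -> None:
    predictors, y = _load_predictors_and_target(outdir)
    model = boosting.GradientBoostedTreeRegressor.from_dict(
        io.read_json(_need(outdir, "gbm_model.json", "predict"))
    )
    i = cfg["interpret"]
    X = predictors.to_numpy(dtype=float)
    shap = interpret.tree_shap(model, X)
    shap_df = shap.to_frame()
    shap_df.index = predictors.index
    io.write_table(shap_df, outdir / "shap_values.tsv", index_label="animal_id")
    imp = interpret.shap_importance(shap)
    imp.to_csv(outdir / "shap_importance.tsv", sep="\t", index=False)

    profiles = interpret.ale_profiles(model, X, n_bins=i["n_bins"])
    rows = []
    for prof in profiles:
        for edge, eff in zip(prof.edges[1:], prof.effects):
            rows.append({"predictor": predictors.columns[prof.predictor],
                         "bin_edge": edge, "effect": eff})
    pd.DataFrame(rows).to_csv(outdir / "ale_profiles.tsv", sep="\t", index=False)
    ale_imp = interpret.ale_importance(
        profiles, highlight_threshold=i["ale_highlight"],
        feature_names=list(predictors.columns),
    )
    ale_imp.to_csv(outdir / "ale_importance.tsv", sep="\t", index=False)

    s = i["surrogate"]
    surrogate = interpret.SurrogateTree(
        max_inner_nodes=s["max_inner_nodes"], alpha=s["alpha"],
        n_perm=s["n_perm"], random_state=cfg["seed"],
    ).fit(predictors, model.predict(X))
    io.write_json(surrogate.to_dict(), outdir / "surrogate_tree.json")
    _log(outdir, "interpret", cfg, {"surrogate_fidelity_r2": surrogate.fidelity_r2_})


def stage_network(cfg: dict, outdir: Path) -> None:
    core = io.read_asv_table(_need(outdir, "core_counts.tsv", "community"))
    rel = community.relative_abundance(core)
    rei = io.read_metadata(_need(outdir, "rei.tsv", "phenotype"), require=("rei",))
    glrm_meta = io.read_json(_need(outdir, "glrm_model.json", "archetypes"))
    imp = pd.read_csv(_need(outdir, "shap_importance.tsv", "interpret"), sep="\t")
    n = cfg["network"]

    # strongly REI-associated components: top archetype predictors by
    # SHAP importance
    arch_names = [p for p in imp["predictor"] if p.startswith("Arch")]
    top = arch_names[: n["n_top_components"]]
    subset = [int(name[4:]) - 1 for name in top]

    a = cfg["archetypes"]
    model = archetypes.ArchetypeGLRM(
        n_components=a["n_components"], max_iter=a["max_iter"], tol=a["tol"],
        random_state=cfg["seed"],
    ).fit(rel)
    rec = model.reconstruct(subset=subset)
    keep = rec.std(axis=0) > 0
    rec = rec.loc[:, keep]
    Z = (rec - rec.mean(axis=0)) / rec.std(axis=0)

    fit = net.GraphicalLassoEBIC(n_lambda=n["n_lambda"], gamma=n["gamma"]).fit(Z)
    edges = pd.DataFrame(fit.edges_, columns=["asv_i", "asv_j", "partial_correlation"])
    edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)

    hubs = net.hub_scores(fit.partial_corr_)
    beta = net.asv_rei_coefficients(rec, rei["rei"].astype(float))
    modules = net.detect_modules(
        fit.partial_corr_, min_size=n["min_module_size"],
        deep_split=n["deep_split"], labels=list(Z.columns),
    )
    node_table = pd.DataFrame(
        {"hub_score": hubs, "rei_coefficient": beta.to_numpy(), "module": modules.to_numpy()},
        index=Z.columns,
    )
    io.write_table(node_table, outdir / "network_nodes.tsv", index_label="asv_id")

    mod_stats = net.module_rei_stats(Z, modules, rei["rei"].astype(float))
    mod_stats.to_csv(outdir / "module_rei.tsv", sep="\t", index=False)
    hub_r, hub_p = net.hub_rei_correlation(hubs, beta.to_numpy())
    io.write_json(
        {
            "selected_components": top,
            "lambda": fit.lambda_,
            "sparsity": fit.sparsity_,
            "n_edges": len(fit.edges_),
            "n_modules": int(len(mod_stats)),
            "hub_rei_r": hub_r,
            "hub_rei_p": hub_p,
        },
        outdir / "network_summary.json",
    )
    _log(outdir, "network", cfg)


def stage_metagenome(cfg: dict, outdir: Path) -> None:
    counts = io.read_gene_abundance(_need(outdir, "gene_counts.tsv", "simulate"))
    groups = io.read_metadata(_need(outdir, "gene_groups.tsv", "simulate"), require=("group",))["group"]
    maps = io.read_annotation_maps(_need(outdir, "gene_map.tsv", "simulate"))
    pathways = io.read_pathways(_need(outdir, "pathways.tsv", "simulate"))
    m = cfg["metagenome"]
    res = metagenome.run_metagenome_stage(
        counts, groups,
        {"gene2ko": maps["gene2ko"], "gene2cazy": maps["gene2cazy"], "pathway2kos": pathways},
        filter_q=m["filter_q"], ko_sig_p=m["ko_sig_p"], fdr=m["fdr"],
        n_perm=m["n_perm"], seed=cfg["seed"],
    )
    io.write_table(res["gene_results"], outdir / "gene_tests.tsv", index_label="gene_id")
    if len(res["cazy_results"]):
        io.write_table(res["cazy_results"], outdir / "cazy_tests.tsv", index_label="cazy_family")
    if len(res["ko_results"]):
        io.write_table(res["ko_results"], outdir / "ko_tests.tsv", index_label="ko")
    res["enrichment"].to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
    io.write_table(res["completeness"].to_frame(), outdir / "pathway_completeness.tsv",
                   index_label="pathway")
    io.write_json(
        {
            "n_genes_filtered": res["n_genes_filtered"],
            "n_significant_genes_fdr": int((res["gene_results"]["q"] <= m["fdr"]).sum()),
            "n_significant_cazy_fdr": int((res["cazy_results"]["q"] <= m["fdr"]).sum())
            if len(res["cazy_results"]) else 0,
            "n_significant_kos": len(res["significant_kos"]),
            "n_enriched_pathways": int(res["enrichment"]["enriched"].sum())
            if len(res["enrichment"]) else 0,
            "completeness_summary": res["completeness_summary"],
        },
        outdir / "metagenome_summary.json",
    )
    _log(outdir, "metagenome", cfg)


def stage_report(cfg: dict, outdir: Path) -> None:
    report = {}
    for name in (
        "community_summary.json",
        "glrm_model.json",
        "network_summary.json",
        "metagenome_summary.json",
    ):
        path = outdir / name
        if path.exists():
            report[name.replace(".json", "")] = io.read_json(path)
    metrics_path = outdir / "prediction_metrics.tsv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path, sep="\t")
        report["prediction"] = {
            row["subset"]: {"pearson_r": row["pearson_r"], "rmse": row["rmse"]}
            for _, row in metrics.iterrows()
        }
    interp_log = outdir / "log_interpret.json"
    if interp_log.exists():
        report["surrogate_fidelity_r2"] = io.read_json(interp_log).get("surrogate_fidelity_r2")
    io.write_json(report, outdir / "report.json")
    _log(outdir, "report", cfg)


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "phenotype": stage_phenotype,
    "community": stage_community,
    "archetypes": stage_archetypes,
    "predict": stage_predict,
    "interpret": stage_interpret,
    "network": stage_network,
    "metagenome": stage_metagenome,
    "report": stage_report,
}


def run_stage(stage: str, cfg: dict, outdir: str | Path) -> None:
    if stage not in STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    STAGE_FUNCS[stage](cfg, Path(outdir))


def run_all(cfg: dict, outdir: str | Path) -> None:
    for stage in STAGES:
        run_stage(stage, cfg, outdir)
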