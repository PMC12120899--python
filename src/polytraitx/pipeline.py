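"""End-to-end orchestration from a single YAML config.

Stage order: simulate (optional) -> normalize -> tau -> triads -> network ->
variants -> eqtl -> assoc.  Every stage writes TSV outputs plus an entry in
a machine-readable JSON run report; all floating-point output uses a fixed
format so identical config + seed gives byte-identical files.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import (
    association,
    coexpr_network,
    eqtl,
    expression,
    pan_tau,
    synthetic_data,
    triad_bias,
    variants,
)

__all__ = ["load_config", "validate_config", "run_pipeline"]

FLOAT_FMT = "%.10g"

DEFAULTS: dict[str, dict[str, Any]] = {
    "expression": {"min_value": 3.0, "rule": "all_reps", "mode": "log2p1", "low_expr_min": 1.0},
    "tau": {"tau_min": 0.9, "max_lines": 10, "mean_min": 10.0, "max_min": 50.0, "filter_mode": "max"},
    "triads": {"min_mean": 10.0, "rule": "nearest_ideal", "divergent_below": 0.5},
    "network": {
        "power": 12.0, "min_module_size": 30, "merge_cut_height": 0.25,
        "n_top_genes": 15000, "fdr": 0.05, "cut_height_quantile": 0.99,
    },
    "variants": {"max_missing": 0.95, "maf": 0.05, "hwe_p": 1e-6},
    "eqtl": {"alpha": 0.05, "cis_window": 3000, "min_genes": 3},
    "association": {"n_pcs": 3, "sig_threshold": 5e-7},
}

STAGE_DEPS: dict[str, set[str]] = {
    "normalize": set(),
    "tau": {"normalize"},
    "triads": {"normalize"},
    "network": {"normalize"},
    "variants": set(),
    "eqtl": {"normalize", "network", "variants"},
    "assoc": {"variants"},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _params(cfg: dict, stage: str) -> dict:
    out = dict(DEFAULTS[stage])
    out.update(cfg.get(stage) or {})
    return out


def validate_config(cfg: dict) -> list[str]:
    """Range/consistency checks; returns a list of violations (empty = ok)."""
    v: list[str] = []
    net = _params(cfg, "network")
    if not 0 < net["merge_cut_height"] < 1:
        v.append("network.merge_cut_height must lie in (0,1)")
    if net["power"] < 1:
        v.append("network.power must be >= 1")
    var = _params(cfg, "variants")
    for key in ("max_missing", "maf"):
        if not 0 <= var[key] <= 1:
            v.append(f"variants.{key} must lie in [0,1]")
    ass = _params(cfg, "association")
    if ass["n_pcs"] < 1:
        v.append("association.n_pcs must be >= 1")
    sim = cfg.get("simulate")
    if sim is not None:
        try:
            sc = synthetic_data.SimConfig(**sim)
        except (TypeError, ValueError) as err:
            v.append(f"simulate: {err}")
        else:
            if ass["n_pcs"] >= sc.n_accessions:
                v.append("association.n_pcs must be smaller than the number of accessions")
    else:
        inputs = cfg.get("inputs") or {}
        required = {"counts", "triads", "vcf", "gff3", "traits", "go_map"}
        missing = required - set(inputs)
        if missing:
            v.append(f"inputs missing: {sorted(missing)}")
        else:
            for k, p in inputs.items():
                if not Path(p).exists():
                    v.append(f"inputs.{k}: no such file {p}")
    exp = _params(cfg, "expression")
    if exp["rule"] not in ("all_reps", "mean"):
        v.append("expression.rule must be all_reps or mean")
    return v


def read_counts_tsv(path: str | Path) -> expression.ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    samples = list(values.columns)
    meta = pd.DataFrame(
        {
            "accession": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return expression.ExpressionMatrix(values=values, sample_meta=meta, state="raw")


def _expand_stages(stages: list[str] | None) -> set[str]:
    if stages is None:
        return set(STAGE_DEPS)
    want: set[str] = set()
    frontier = list(stages)
    while frontier:
        s = frontier.pop()
        if s in ("simulate", "run-all"):
            return set(STAGE_DEPS)
        if s not in STAGE_DEPS:
            raise ValueError(f"unknown stage {s!r}")
        if s not in want:
            want.add(s)
            frontier.extend(STAGE_DEPS[s])
    return want


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(
    cfg: dict,
    outdir: str | Path | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages (all by default); writes and returns the run report."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    want = _expand_stages(stages)
    out = Path(outdir or cfg.get("outdir", "polytraitx_run"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": {}, "seed": cfg.get("seed")}

    def stage_entry(name: str, t0: float, **info: Any) -> None:
        report["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3), **info}

    # --- simulate or load inputs -------------------------------------------
    t0 = time.perf_counter()
    if cfg.get("simulate") is not None:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg.get("seed", 1))
        sc = synthetic_data.SimConfig(**sim)
        ds = synthetic_data.generate_dataset(sc)
        paths = synthetic_data.write_dataset(ds, out / "inputs")
        counts = ds.counts
        triad_table = ds.triads[["triad_id", "gene_a", "gene_b", "gene_c"]]
        gm = ds.genotypes
        gene_models = ds.gene_models
        traits = ds.traits
        go_map = ds.go_map
        stage_entry("simulate", t0, config=asdict(sc), outputs={k: str(p) for k, p in paths.items()})
    else:
        inputs = cfg["inputs"]
        counts = read_counts_tsv(inputs["counts"])
        triad_table = pd.read_csv(inputs["triads"], sep="\t")
        gm = variants.read_vcf(inputs["vcf"])
        gene_models = variants.read_gff3(inputs["gff3"])
        traits = pd.read_csv(inputs["traits"], sep="\t")
        go_map = pd.read_csv(inputs["go_map"], sep="\t")
        stage_entry("load", t0, inputs={k: str(v) for k, v in inputs.items()})

    acc_expr = set(counts.accessions)
    acc_gm = set(gm.accessions)
    acc_tr = set(traits["accession"])
    if not (acc_expr == acc_gm == acc_tr):
        diff = sorted(acc_expr ^ acc_gm) + sorted(acc_expr ^ acc_tr)
        raise ValueError(f"inconsistent accession sets between inputs: {sorted(set(diff))}")

    means_counts = means_log = None
    net = None
    focal_module = None
    top: list[str] = []
    blup = None
    trait_vec = None
    gm_f = gm

    if want & {"network", "assoc"}:
        blup = association.compute_blup(traits)
        trait_vec = blup.blups

    # --- normalize ----------------------------------------------------------
    if "normalize" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "expression")
        counts_f = expression.filter_low_expressed(counts, p["low_expr_min"])
        factors = expression.size_factors(counts_f)
        norm_log = expression.normalize(counts_f, factors, mode=p["mode"])
        norm_counts = expression.normalize(counts_f, factors, mode="counts")
        expressed, totals = expression.call_expressed(norm_counts, p["min_value"], p["rule"])
        means_counts = expression.accession_means(norm_counts)
        means_log = expression.accession_means(norm_log)
        _write(norm_log.values.rename_axis("gene_id"), out / "normalized.tsv")
        _write(
            totals.rename("n_expressed").rename_axis("accession").to_frame(),
            out / "expressed_totals.tsv",
        )
        stage_entry(
            "normalize", t0,
            genes_in=int(counts.values.shape[0]), genes_kept=int(counts_f.values.shape[0]),
            expressed_all=int(totals["__all_accessions__"]),
            expressed_any=int(totals["__any_accession__"]),
        )

    # --- tau ----------------------------------------------------------------
    if "tau" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "tau")
        kept = pan_tau.variable_gene_filter(
            means_counts, p["mean_min"], p["max_min"], p["filter_mode"]
        )
        dom = pan_tau.dominant_genes(means_counts.loc[kept], p["tau_min"], p["max_lines"])
        dom_df = pd.DataFrame(
            [(d.gene_id, d.tau, d.dominance_set_size) for d in dom],
            columns=["gene_id", "tau", "dominance_set_size"],
        )
        _write(dom_df, out / "tau_dominant.tsv", index=False)
        stage_entry("tau", t0, filtered_genes=int(len(kept)), dominant_genes=int(len(dom_df)))

    # --- triads -------------------------------------------------------------
    if "triads" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "triads")
        calls = triad_bias.call_triads(means_counts, triad_table, p["min_mean"], p["rule"])
        summaries = triad_bias.summarize_all(calls, p["divergent_below"])
        _write(calls, out / "triad_calls.tsv", index=False)
        _write(summaries, out / "triad_summaries.tsv", index=False)
        klass = summaries["conservation_class"].value_counts()
        stage_entry(
            "triads", t0,
            eligible_triads=int(summaries.shape[0]),
            conserved=int(klass.get("conserved", 0)),
            intermediate=int(klass.get("intermediate", 0)),
            divergent=int(klass.get("divergent", 0)),
        )

    # --- network ------------------------------------------------------------
    if "network" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "network")
        k = min(p["n_top_genes"], means_log.shape[0])
        top = expression.top_variance_genes(means_log, k)
        ncfg = coexpr_network.NetworkConfig(
            power=p["power"], min_module_size=p["min_module_size"],
            merge_cut_height=p["merge_cut_height"], n_top_genes=k,
            cut_height_quantile=p["cut_height_quantile"],
        )
        net = coexpr_network.build_network(means_log.loc[top], trait_vec, ncfg)
        _write(net.labels.rename_axis("gene_id").to_frame(), out / "modules.tsv")
        _write(net.eigengenes.rename_axis("accession"), out / "eigengenes.tsv")
        enrich_sig = 0
        if net.module_trait is not None and len(net.module_trait):
            _write(net.module_trait.rename_axis("module"), out / "module_trait.tsv")
            _write(net.gene_stats, out / "gene_stats.tsv")
            focal_module = str(net.module_trait["r"].abs().idxmax())
            mod_genes = set(net.labels.index[net.labels == focal_module])
            universe = set(net.labels.index)
            enrich = coexpr_network.go_enrichment(mod_genes, universe, go_map, p["fdr"])
            _write(enrich, out / "go_enrichment.tsv", index=False)
            enrich_sig = int(enrich["significant"].sum()) if len(enrich) else 0
        assigned = net.labels[net.labels != "grey"]
        stage_entry(
            "network", t0, genes_used=int(k),
            n_modules=int(assigned.nunique()) if len(assigned) else 0,
            focal_module=focal_module, enriched_terms=enrich_sig,
        )

    # --- variants -----------------------------------------------------------
    if "variants" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "variants")
        gm_f, drops = variants.filter_snps(gm, p["max_missing"], p["maf"], p["hwe_p"])
        anno = variants.annotate_snps(gm_f, gene_models)
        dist = variants.ibs_distance(gm_f)
        newick = variants.nj_tree(dist)
        _write(anno, out / "snp_annotation.tsv")
        _write(dist.rename_axis("accession"), out / "ibs_distance.tsv")
        (out / "accessions.nwk").write_text(newick + "\n")
        region_counts = anno["region"].value_counts().to_dict()
        stage_entry(
            "variants", t0, snps_in=int(gm.n_snps), snps_kept=int(gm_f.n_snps),
            drops=drops, regions={k2: int(v) for k2, v in region_counts.items()},
        )

    # --- eqtl ---------------------------------------------------------------
    if "eqtl" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "eqtl")
        hits, thr = eqtl.eqtl_scan(gm_f, means_log.loc[top], p["alpha"])
        gene_feats = gene_models[gene_models["feature"] == "gene"].set_index("gene_id")
        spans = gene_feats.loc[:, ["chrom", "start", "end"]]
        hits = eqtl.annotate_cis_trans(hits, gm_f.snp_map, spans, p["cis_window"])
        _write(hits, out / "eqtl_hits.tsv", index=False)
        n_cis = int((hits["cis_trans"] == "cis").sum())
        module_hits = pd.DataFrame()
        pleio = pd.Series(dtype=int)
        if focal_module is not None:
            mod_genes = set(net.labels.index[net.labels == focal_module])
            module_hits, pleio = eqtl.module_eqtls(hits, mod_genes, p["min_genes"])
            _write(module_hits, out / "module_eqtls.tsv", index=False)
        stage_entry(
            "eqtl", t0, threshold=thr, n_hits=int(len(hits)), n_cis=n_cis,
            n_trans=int(len(hits)) - n_cis,
            module_eqtls=int(module_hits["snp_id"].nunique()) if len(module_hits) else 0,
            pleiotropic_snps=int(len(pleio)),
        )

    # --- association --------------------------------------------------------
    if "assoc" in want:
        t0 = time.perf_counter()
        p = _params(cfg, "association")
        K = association.kinship(gm_f)
        pcs = association.genotype_pcs(gm_f, p["n_pcs"])
        assoc = association.lmm_association(gm_f, trait_vec, K, pcs)
        sig = association.significant_snps(assoc, p["sig_threshold"])
        _write(trait_vec.rename("blup").rename_axis("accession").to_frame(), out / "blups.tsv")
        _write(K.rename_axis("accession"), out / "kinship.tsv")
        amap = gm_f.snp_map.loc[assoc.index]
        assoc_out = assoc.copy()
        assoc_out.insert(0, "chrom", amap["chrom"])
        assoc_out.insert(1, "pos", amap["pos"])
        _write(assoc_out.rename_axis("snp_id"), out / "association.tsv")
        hap_info: dict[str, Any] = {}
        if sig:
            groups, anova_p, incomplete = association.haplotype_groups(gm_f, sig, trait_vec)
            hap_df = pd.DataFrame(
                [
                    (g.group_id, "".join(str(a) for a in g.alleles), len(g.accessions),
                     g.trait_mean, g.trait_median, g.trait_q1, g.trait_q3)
                    for g in groups
                ],
                columns=["group", "alleles", "n_accessions", "mean", "median", "q1", "q3"],
            )
            _write(hap_df, out / "haplotypes.tsv", index=False)
            hap_info = {
                "n_groups": int(len(groups)), "anova_p": anova_p,
                "n_incomplete": len(incomplete),
            }
        stage_entry(
            "assoc", t0, sigma2_g=blup.sigma2_g, sigma2_e=blup.sigma2_e,
            n_significant=len(sig), significant=sig, **hap_info,
        )

    report["outdir"] = str(out)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
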