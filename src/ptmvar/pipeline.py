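"""End-to-end orchestration of the analysis stages.

Each stage is a pure function from an annotated cohort to result tables, so
stages can run standalone or chained; :func:`run_all` executes them in
dependency order and writes every output TSV with a header carrying the
tool version, configuration hash and seed, making runs byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confounders, context, disease, drugnet, io, motifs, resampling, selection
from .regions import (
    build_regions,
    cluster_maps,
    filter_by_support,
    frame_to_sites,
    region_masks,
    sites_to_frame,
    zone_maps,
)
from .synthetic import SimulationConfig, SyntheticCohort, generate_cohort, make_calibration_controls
from .variants import (
    annotate_variants,
    classify_rare,
    codon_degeneracy,
    filter_codon_conflicts,
    gc_window,
    nearest_recomb,
)

log = logging.getLogger("ptmvar")


@dataclass
class RunConfig:
    """Settings of one pipeline run (thresholds, sizes, seeds)."""

    rare_daf: float = 0.005
    min_pubs: int = 1
    n_bins: int = 100
    n_perm: int = 1000
    interaction_order: int = 2
    fdr_selection: float = 0.05
    fdr_disease_overlap: float = 0.01
    seed: int = 0
    restrict_to_ptm_proteins: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name in ("fdr_selection", "fdr_disease_overlap"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name}: must lie in (0, 1)")
        if self.rare_daf <= 0:
            raise ValueError("rare_daf: must be positive")


def annotate_cohort(cohort: SyntheticCohort, config: RunConfig | None = None):
    """Annotate a cohort's variants into the substitution feature frame.

    Runs region building, codon translation, the same-codon conflict
    filter, the rare/common split and all confounder features. Returns
    (subs, regions, masks, rejects).
    """
    config = config or RunConfig()
    lengths = cohort.protein_lengths
    sites = filter_by_support(cohort.ptm_sites(), config.min_pubs)
    regions = build_regions(sites, lengths)
    masks = region_masks(regions, lengths)
    zones = zone_maps(regions)

    subs, rejects = annotate_variants(cohort.variants, cohort.models)
    n0 = len(subs)
    subs = filter_codon_conflicts(subs)
    log.info("annotation: %d accepted, %d rejected, %d dropped by codon-conflict filter",
             n0, len(rejects), n0 - len(subs))
    subs = classify_rare(subs, config.rare_daf)

    gc, degen, cons, dis, reg, zone = [], [], [], [], [], []
    for rec in subs.itertuples(index=False):
        model = cohort.models[rec.protein]
        gc.append(gc_window(model.cds, rec.cds_offset))
        degen.append(codon_degeneracy(rec.ref_aa))
        cons.append(float(cohort.conservation[rec.protein][rec.residue_index - 1]))
        dis.append(bool(cohort.disorder_masks[rec.protein][rec.residue_index - 1]))
        reg.append(bool(masks[rec.protein][rec.residue_index - 1]))
        zone.append(zones.get(rec.protein, {}).get(rec.residue_index, ""))
    subs["gc_content"] = gc
    subs["codon_degeneracy"] = degen
    subs["conservation"] = cons
    subs["in_disorder"] = dis
    subs["in_ptm_region"] = reg
    subs["zone"] = zone
    recomb = np.empty(len(subs))
    for chrom, grp in subs.groupby("chrom"):
        track = cohort.recomb[cohort.recomb["chrom"] == chrom]
        recomb[grp.index] = nearest_recomb(grp["pos"].to_numpy(), track["pos"].to_numpy(), track["rate"].to_numpy())
    subs["recomb_rate"] = recomb
    if "depth" in subs.columns:
        subs = subs.rename(columns={"depth": "read_depth"})
    return subs, regions, masks, rejects


# ---------------------------------------------------------------------------
# stages


def run_selection(cohort, subs, masks, config: RunConfig):
    """Rare-fraction and Ka/Ks bin comparisons of PTM vs non-PTM sequence."""
    lengths = cohort.protein_lengths
    ptm_proteins = set(subs.loc[subs["in_ptm_region"], "protein"]) | {
        p for p, m in masks.items() if m.any()
    }
    used = subs[subs["protein"].isin(ptm_proteins)] if config.restrict_to_ptm_proteins else subs
    rate = (
        used.groupby("protein")["residue_index"].nunique()
        .reindex(sorted(ptm_proteins if config.restrict_to_ptm_proteins else lengths), fill_value=0)
    )
    rate = rate / pd.Series(lengths).reindex(rate.index)
    n_bins = min(config.n_bins, len(rate))
    bins = selection.bin_by_variation(rate, n_bins)
    rare_bins = selection.per_bin_rare_fraction(used, bins)
    rare_test = selection.paired_bin_test(rare_bins["ptm_value"], rare_bins["nonptm_value"], "greater")
    models_used = {p: cohort.models[p] for p in rate.index}
    masks_used = {p: masks[p] for p in rate.index}
    protein_sites = selection.protein_site_table(models_used, masks_used)
    kaks_bins = selection.per_bin_ka_ks(used, bins, protein_sites)
    kaks_test = selection.paired_bin_test(kaks_bins["ptm_value"], kaks_bins["nonptm_value"], "less")
    summaries = selection.stratified_summaries(used, protein_sites)
    return {
        "bins": bins,
        "rare_bins": rare_bins,
        "rare_test": rare_test,
        "kaks_bins": kaks_bins,
        "kaks_test": kaks_test,
        "summaries": summaries,
    }


def run_model(subs, config: RunConfig):
    """Confounder-adjusted logistic model with backward selection."""
    table = confounders.build_feature_table(subs)
    null_fit, alt_fit = confounders.fit_models(table, config.interaction_order)
    selected = confounders.backward_select(table, alt_fit)
    delta, df, p = confounders.lrt(null_fit, alt_fit)
    ranks = confounders.deviance_rank(table, null_fit, alt_fit)
    return {
        "table": table,
        "null_fit": null_fit,
        "alt_fit": alt_fit,
        "selected_fit": selected,
        "ptm_lrt": {"delta_deviance": delta, "df": df, "p": p},
        "deviance_table": ranks,
    }


def _residue_universe(cohort, proteins) -> pd.DataFrame:
    rows = []
    for protein in sorted(proteins):
        seq = cohort.proteins[protein]
        rows.append(pd.DataFrame({
            "protein": protein,
            "position": np.arange(1, len(seq) + 1),
            "aa": list(seq),
        }))
    return pd.concat(rows, ignore_index=True)


def run_permutations(cohort, subs, regions, config: RunConfig):
    """Amino-acid-weighted permutation tests of zones, types and clusters."""
    rng = np.random.default_rng(config.seed + 1)
    sites_df = cohort.sites
    zones = zone_maps(regions)
    clusters = cluster_maps(regions)
    rows = []

    def run_one(stratum, test_res, universe_res):
        test = resampling.residue_table(subs, test_res)
        background = resampling.residue_table(subs, universe_res)
        res = resampling.permutation_test(
            test, background, n_perm=config.n_perm, seed=rng, direction="greater"
        )
        rows.append({
            "stratum": stratum, "observed": res.observed, "expected_mean": res.expected_mean,
            "expected_sd": res.expected_sd, "p": res.p_value, "n_test_residues": res.n_test_residues,
        })

    ptm_types = ["all"] + sorted(sites_df["ptm_type"].unique())
    for ptm_type in ptm_types:
        typed = sites_df if ptm_type == "all" else sites_df[sites_df["ptm_type"] == ptm_type]
        if typed.empty:
            continue
        proteins = set(typed["protein"])
        universe = _residue_universe(cohort, proteins)
        di_keys = set(zip(typed["protein"], typed["position"]))
        zone_rows = {"DI": [], "N1": [], "N2": []}
        for protein in proteins:
            for pos, z in zones.get(protein, {}).items():
                zone_rows[z].append((protein, pos))
        for zone_name in ("DI", "N1", "N2"):
            if zone_name == "DI":
                keys = di_keys
            else:
                keys = set(zone_rows[zone_name])
            sel = universe[[k in keys for k in zip(universe["protein"], universe["position"])]]
            if sel.empty:
                continue
            run_one(f"{ptm_type}:{zone_name}", sel, universe)

    proteins = set(sites_df["protein"])
    universe = _residue_universe(cohort, proteins)
    keys_by_bin: dict[int, set] = {}
    for protein in proteins:
        for pos, b in clusters.get(protein, {}).items():
            keys_by_bin.setdefault(int(b), set()).add((protein, pos))
    for b in sorted(keys_by_bin):
        keys = keys_by_bin[b]
        sel = universe[[k in keys for k in zip(universe["protein"], universe["position"])]]
        label = f"cluster:{b}" if b < 5 else "cluster:5+"
        run_one(label, sel, universe)
    return pd.DataFrame(rows)


def run_motifs(cohort, subs, config: RunConfig):
    """PWM calibration, bound-site prediction, breakers and kinase tests."""
    rng = np.random.default_rng(config.seed + 2)
    phospho = cohort.sites[cohort.sites["ptm_type"] == "phospho"][["protein", "position"]]
    all_breakers, all_bound = [], []
    for pwm in cohort.pwms:
        positives, negatives = make_calibration_controls(pwm, cohort.config.aa_freqs, seed=rng)
        motifs.calibrate(pwm, positives, negatives)
        bound = motifs.predict_bound_sites(pwm, phospho, cohort.proteins)
        if bound.empty:
            continue
        bound["kinase"] = pwm.kinase
        all_bound.append(bound)
        br = motifs.find_breakers(pwm, bound)
        if not br.empty:
            all_breakers.append(br)
    bound_df = pd.concat(all_bound, ignore_index=True) if all_bound else pd.DataFrame(
        columns=["protein", "position", "window", "score", "kinase"])
    breakers = pd.concat(all_breakers, ignore_index=True) if all_breakers else pd.DataFrame(
        columns=["protein", "position", "kinase", "phosphosite", "offset", "wt_aa", "fold_change"])
    phospho_proteins = set(phospho["protein"])
    background = resampling.residue_table(subs, _residue_universe(cohort, phospho_proteins))
    kinase_tests = (
        motifs.kinase_level_tests(
            breakers, background, cohort.disease, n_perm=config.n_perm, seed=config.seed + 3
        )
        if not breakers.empty
        else pd.DataFrame()
    )
    disease_genes = set(cohort.disease["protein"])
    network, degree_test = motifs.build_network(
        bound_df.rename(columns={"position": "phosphosite"}), disease_genes
    ) if not bound_df.empty else (None, {"p": None})
    return {
        "bound": bound_df,
        "breakers": breakers,
        "kinase_tests": kinase_tests,
        "network": network,
        "degree_test": degree_test,
    }


def run_disease(cohort, regions, masks, config: RunConfig, cancer_genes: set[str] | None = None):
    """Disease enrichment tests and the per-gene hotspot model."""
    lengths = cohort.protein_lengths
    ptm_proteins = sorted({r.protein for r in regions})
    annotated = {p: np.zeros(lengths[p], dtype=bool) for p in ptm_proteins}
    counts = {p: np.zeros(lengths[p]) for p in ptm_proteins}
    for rec in cohort.disease.itertuples(index=False):
        if rec.protein in annotated and rec.residue_index <= lengths[rec.protein]:
            annotated[rec.protein][rec.residue_index - 1] = True
            counts[rec.protein][rec.residue_index - 1] += rec.n_records
    masks_sel = {p: masks[p] for p in ptm_proteins}
    disorder_sel = {p: cohort.disorder_masks[p] for p in ptm_proteins}
    fisher = disease.region_enrichment_fisher(annotated, masks_sel, disorder_sel)
    poisson = disease.region_enrichment_poisson(counts, masks_sel)
    central = [
        disease.central_residue_enrichment(annotated, cohort.sites, cohort.proteins, t)
        for t in sorted(cohort.sites["ptm_type"].unique())
    ]
    regions_by_protein: dict[str, list] = {}
    for r in regions:
        regions_by_protein.setdefault(r.protein, []).append(r)
    ad_results = []
    for protein in ptm_proteins:
        if counts[protein].sum() == 0:
            continue
        ad_results.append(
            disease.active_driver(
                protein, lengths[protein], counts[protein],
                regions_by_protein.get(protein, []), cohort.disorder_masks[protein],
            )
        )
    ad_table = disease.active_driver_table(ad_results)
    cancer = None
    if cancer_genes:
        significant = set(ad_table.loc[ad_table["gene_q"] < config.fdr_selection, "protein"])
        cancer = disease.cancer_gene_enrichment(significant, cancer_genes, set(ptm_proteins))
    return {
        "fisher": fisher,
        "poisson": poisson,
        "central": central,
        "active_driver": ad_results,
        "active_driver_table": ad_table,
        "cancer": cancer,
    }


def run_context(cohort, subs, config: RunConfig):
    """Gene-set LRTs, conservation-binned trend and disease overlap."""
    groups = context.run_group_tests(subs, cohort.gene_sets)
    cons_median = pd.Series(
        {p: float(np.median(v)) for p, v in cohort.conservation.items()}, name="conservation"
    )
    n_bins = min(100, max(3, len(cons_median) // 3))
    trend_table, r, p = context.binned_trend(subs, cons_median, n_bins=n_bins)
    disease_genes = set(cohort.disease["protein"])
    sig = groups[(groups["q"].notna()) & (groups["q"] < config.fdr_selection)]
    sig_sets = {g: cohort.gene_sets[g] for g in sig["group"]}
    overlap = context.disease_overlap(sig_sets, disease_genes, set(cohort.proteins))
    nodes, edges = context.enrichment_map_export(groups, cohort.gene_sets, config.fdr_selection)
    clouds = context.word_cloud_table(cohort.disease, set(cohort.proteins))
    return {
        "groups": groups,
        "trend_table": trend_table,
        "trend_r": r,
        "trend_p": p,
        "overlap": overlap,
        "map_nodes": nodes,
        "map_edges": edges,
        "word_cloud": clouds,
    }


def run_drugnet(cohort, disease_results, config: RunConfig):
    """Drug-enzyme-gene-disease network from hotspot-significant genes."""
    ad_table = disease_results["active_driver_table"]
    pad = set(ad_table.loc[ad_table["gene_q"] < config.fdr_selection, "protein"])
    region_rows = []
    for res in disease_results["active_driver"]:
        if res.protein not in pad:
            continue
        for (start, end), p in res.region_p.items():
            if p < config.fdr_selection:
                region_rows.append({"protein": res.protein, "start": start, "end": end})
    sig_regions = pd.DataFrame(region_rows, columns=["protein", "start", "end"])
    paths, dangling = drugnet.assemble(
        pad, sig_regions, cohort.site_enzymes, cohort.drug_targets, cohort.disease
    )
    pairs = drugnet.pair_summary(paths)
    graph = drugnet.to_graph(paths)
    return {"paths": paths, "pairs": pairs, "dangling": dangling, "graph": graph,
            "queries": drugnet.literature_query_list(pairs)}


# ---------------------------------------------------------------------------
# full run


def run_all(config: RunConfig, outdir, cohort: SyntheticCohort | None = None) -> dict:
    """Execute every stage in dependency order and write result tables."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = io.output_meta(asdict(config), config.seed)
    if cohort is None:
        cohort = generate_cohort(config.simulation)
    results: dict = {"cohort": cohort}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    subs, regions, masks, rejects = stage("annotate", annotate_cohort, cohort, config)
    results.update(subs=subs, regions=regions, masks=masks)
    io.write_tsv(sites_to_frame(frame_to_sites(cohort.sites)), outdir / "ptm_sites.tsv", meta)
    from .regions import regions_to_frame

    io.write_tsv(regions_to_frame(regions), outdir / "ptm_regions.tsv", meta)
    io.write_tsv(subs.drop(columns=["window"], errors="ignore"), outdir / "substitutions.tsv", meta)
    if len(rejects):
        io.write_tsv(rejects, outdir / "rejected_variants.tsv", meta)

    sel = stage("selection", run_selection, cohort, subs, masks, config)
    results["selection"] = sel
    io.write_tsv(sel["rare_bins"], outdir / "selection_rare_bins.tsv", meta)
    io.write_tsv(sel["kaks_bins"], outdir / "selection_kaks_bins.tsv", meta)
    io.write_tsv(sel["summaries"], outdir / "selection_summaries.tsv", meta)
    tests = pd.DataFrame([
        {"metric": "rare_fraction", "alternative": "ptm>non", "statistic": sel["rare_test"].statistic,
         "p": sel["rare_test"].p_value, "n_informative": sel["rare_test"].n_informative},
        {"metric": "ka_ks", "alternative": "ptm<non", "statistic": sel["kaks_test"].statistic,
         "p": sel["kaks_test"].p_value, "n_informative": sel["kaks_test"].n_informative},
    ])
    io.write_tsv(tests, outdir / "selection_tests.tsv", meta)

    model = stage("model", run_model, subs, config)
    results["model"] = model
    io.write_tsv(model["deviance_table"], outdir / "deviance_table.tsv", meta)
    lrt_df = pd.DataFrame([model["ptm_lrt"]])
    io.write_tsv(lrt_df, outdir / "ptm_lrt.tsv", meta)

    perm = stage("permute", run_permutations, cohort, subs, regions, config)
    results["permutations"] = perm
    io.write_tsv(perm, outdir / "permutation_tests.tsv", meta)

    mot = stage("motifs", run_motifs, cohort, subs, config)
    results["motifs"] = mot
    io.write_tsv(mot["breakers"], outdir / "motif_breakers.tsv", meta)
    if len(mot["kinase_tests"]):
        io.write_tsv(mot["kinase_tests"], outdir / "kinase_tests.tsv", meta)
    if mot["network"] is not None:
        edges = pd.DataFrame(
            [{"kinase": mot["network"].nodes[a]["name"], "substrate": mot["network"].nodes[b]["name"]}
             for a, b in mot["network"].edges()]
        )
        io.write_tsv(edges, outdir / "kinase_network_edges.tsv", meta)

    dis = stage("disease", run_disease, cohort, regions, masks, config)
    results["disease"] = dis
    enr_rows = [r.__dict__ for r in dis["fisher"]] + [dis["poisson"].__dict__] + [
        r.__dict__ for r in dis["central"]
    ]
    io.write_tsv(pd.DataFrame(enr_rows), outdir / "disease_enrichment.tsv", meta)
    io.write_tsv(dis["active_driver_table"], outdir / "active_driver.tsv", meta)

    ctx = stage("context", run_context, cohort, subs, config)
    results["context"] = ctx
    io.write_tsv(ctx["groups"], outdir / "group_tests.tsv", meta)
    io.write_tsv(ctx["trend_table"], outdir / "conservation_trend.tsv", meta)
    io.write_tsv(ctx["overlap"], outdir / "disease_overlap.tsv", meta)
    io.write_tsv(ctx["map_nodes"], outdir / "enrichment_map_nodes.tsv", meta)
    io.write_tsv(ctx["map_edges"], outdir / "enrichment_map_edges.tsv", meta)
    io.write_tsv(ctx["word_cloud"], outdir / "word_cloud.tsv", meta)

    dn = stage("drugnet", run_drugnet, cohort, dis, config)
    results["drugnet"] = dn
    io.write_tsv(dn["paths"], outdir / "drug_disease_paths.tsv", meta)
    io.write_tsv(dn["pairs"], outdir / "drug_disease_pairs.tsv", meta)
    io.write_tsv(dn["queries"], outdir / "literature_queries.tsv", meta)
    return results
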