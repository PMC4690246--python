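"""End-to-end orchestration: normalize -> SFP/DE fits per tissue ->
similarly-expressed gene set -> array clustering -> homologous tissues ->
silent/global/changed classification -> tau -> molecular evolution ->
genome windows -> enrichment -> eQTL summary, with a machine-readable run
manifest.

The data directory layout is the one `straindiff simulate` writes
(probes.tsv, mapping.tsv, samples.tsv, atlas_<strain>.tsv,
orthologs_{a,b}.fasta, genes.bed, go.tsv, eqtl.tsv); user-supplied files in
the same formats work identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import cluster as cluster_mod
from . import molevo, preprocess, snep, stats, windows
from .config import AnalysisConfig
from .io import (read_annotation, read_atlas, read_bed, read_eqtl_records,
                 read_fasta_pairs, read_probe_table, read_sample_sheet,
                 write_results)

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input {path}")
    return path


def run_pipeline(config: AnalysisConfig, data_dir: str | Path,
                 out_dir: str | Path,
                 strain_pair: tuple[str, str] = ("A", "B")) -> dict:
    """Run every stage on a data directory; returns the manifest dict.

    All stage outputs are written to ``out_dir``; the manifest (config echo,
    per-stage counts, output hashes) is written as ``manifest.json``.
    Re-running with identical inputs and config reproduces identical hashes.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sa, sb = strain_pair
    manifest: dict = {"config": config.to_dict(), "stages": [], "counts": {}}

    def stage(name: str, outputs: list[Path], **counts) -> None:
        manifest["stages"].append({
            "name": name,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })
        manifest["counts"].update(counts)
        log.info("stage %s done: %s", name, counts)

    # --- load + normalize ---------------------------------------------------
    table = read_probe_table(_require(data / "probes.tsv", "load"),
                             _require(data / "mapping.tsv", "load"), config)
    sheet = read_sample_sheet(_require(data / "samples.tsv", "load"))
    norm = preprocess.quantile_normalize(table.values)
    table = type(table)(values=norm, transcript=table.transcript)
    stage("normalize", [], n_probes=len(norm), n_arrays=norm.shape[1])

    # --- SNEP per tissue ----------------------------------------------------
    tissues = [t for t in sheet.tissues
               if sheet.arrays_for(sa, t) and sheet.arrays_for(sb, t)]
    if not tissues:
        raise ValueError(f"no tissue has arrays for both strains {strain_pair}")
    de_all, sfp_all = [], []
    for t in tissues:
        de, sfp = snep.run_snep(table, sheet, strain_pair, t, config)
        de_all.append(de)
        sfp_all.append(sfp)
    de_calls = pd.concat(de_all, ignore_index=True)
    sfp_calls = pd.concat(sfp_all, ignore_index=True)
    write_results(out / "de_calls.tsv", de_calls)
    write_results(out / "sfp_calls.tsv", sfp_calls)
    n_sfp = int(sfp_calls["is_sfp"].sum())
    stage("snep", [out / "de_calls.tsv", out / "sfp_calls.tsv"],
          n_tissues=len(tissues), n_de_calls=int(de_calls["is_de"].sum()),
          n_sfp_probes=n_sfp)

    # --- similarly-expressed genes + array clustering -----------------------
    meas = de_calls[de_calls["measurable"]]
    per_gene = meas.groupby("gene_id").agg(
        any_de=("is_de", "any"),
        max_expr=("expr_a", "max"), max_expr_b=("expr_b", "max"))
    high = per_gene[["max_expr", "max_expr_b"]].max(axis=1) > config.expr_threshold
    se_genes = set(per_gene.index[(~per_gene["any_de"]) & high])
    sfp_probe_ids = set(sfp_calls.loc[sfp_calls["is_sfp"], "probe_id"])

    keep_probes = (table.transcript.isin(se_genes)
                   & ~table.values.index.isin(list(sfp_probe_ids)))
    expr = (table.values[keep_probes]
            .groupby(table.transcript[keep_probes]).median())
    scaled = preprocess.z_scale_genes(expr)
    dist = cluster_mod.correlation_distance(scaled.T)
    dend = cluster_mod.ward_cluster(dist)
    assignment = cluster_mod.cut(dend, config.dendrogram_cut)
    homologous = cluster_mod.select_homologous(assignment, sheet, {sa, sb})
    assignment.rename_axis("array_id").reset_index().to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    write_results(out / "homologous.tsv",
                  pd.DataFrame(homologous, columns=["tissue", "cluster"]))
    stage("cluster", [out / "clusters.tsv", out / "homologous.tsv"],
          n_se_genes=len(se_genes), n_clusters=int(assignment.max()),
          n_homologous_tissues=len(homologous))

    # --- atlases: silent genes, classification, tau -------------------------
    atlas_a = read_atlas(_require(data / f"atlas_{sa}.tsv", "atlas"))
    atlas_b = read_atlas(_require(data / f"atlas_{sb}.tsv", "atlas"))
    silent_a = atlas_mod.detect_silent(atlas_a, atlas_b, config)
    silent_b = atlas_mod.detect_silent(atlas_b, atlas_a, config)
    hom_tissues = {t for t, _ in homologous} or set(tissues)
    de_hom = de_calls[de_calls["tissue"].isin(hom_tissues)]
    classes = atlas_mod.classify_de(de_hom, silent_a, silent_b, config,
                                    strain_pair)
    cls_df = pd.DataFrame(
        [(c.gene_id, c.de_class, ",".join(sorted(c.tissues_detected)))
         for c in classes],
        columns=["gene_id", "de_class", "tissues_detected"]).sort_values(
        "gene_id")
    write_results(out / "classification.tsv", cls_df)
    tau_tables = {}
    for s, atl in ((sa, atlas_a), (sb, atlas_b)):
        tt = atlas_mod.compute_tau_table(atl, config)
        tau_tables[s] = tt
        tt.reset_index().to_csv(out / f"tau_{s}.tsv", sep="\t", index=False,
                                float_format="%.10g")
    n_global = int(cls_df["de_class"].str.startswith("global").sum())
    n_changed = int((cls_df["de_class"] == "changed_tissues").sum())
    stage("classify",
          [out / "classification.tsv"] + [out / f"tau_{s}.tsv" for s in (sa, sb)],
          n_silent_a=len(silent_a), n_silent_b=len(silent_b),
          n_global=n_global, n_changed_tissues=n_changed)

    # --- molecular evolution ------------------------------------------------
    pairs = read_fasta_pairs(_require(data / "orthologs_a.fasta", "molevo"),
                             _require(data / "orthologs_b.fasta", "molevo"))
    evolution = molevo.classify_pairs(pairs, config)
    write_results(out / "evolution.tsv", evolution)
    stage("molevo", [out / "evolution.tsv"],
          n_ortholog_pairs=len(evolution),
          n_rapid=int((evolution["rate_class"] == "rapid").sum()))

    # --- genome windows -----------------------------------------------------
    loci = read_bed(_require(data / "genes.bed", "windows"))
    he_genes = set(per_gene.index[high])
    universe = {l.gene_id for l in loci}
    flag_genes = {c.gene_id for c in classes
                  if c.de_class.startswith("global")} & universe
    he_for_windows = (he_genes | flag_genes) & universe
    profile = windows.gene_index_windows(loci, he_for_windows, flag_genes,
                                         config.window_genes,
                                         config.step_genes)
    regions = windows.detect_clusters(profile, config) if len(profile) >= 4 else []
    write_results(out / "windows.tsv", profile)
    write_results(out / "clusters_genome.tsv",
                  pd.DataFrame([(r.chrom, r.start, r.end, r.n_windows)
                                for r in regions],
                               columns=["chrom", "start", "end", "n_windows"]))
    stage("windows", [out / "windows.tsv", out / "clusters_genome.tsv"],
          n_windows=len(profile), n_regions=len(regions))

    # --- enrichment ---------------------------------------------------------
    annotation = read_annotation(_require(data / "go.tsv", "enrich"))
    background = set(annotation)
    de_genes_flagged = ({c.gene_id for c in classes
                         if c.de_class != "similar"} & background)
    enrich = stats.fisher_enrichment(de_genes_flagged, background,
                                     annotation, config)
    enrich_df = pd.DataFrame(
        [(r.term, r.k, r.big_k, r.n, r.big_n, r.odds_ratio, r.p, r.enriched)
         for r in enrich],
        columns=["term", "k", "K", "n", "N", "odds_ratio", "p", "enriched"])
    write_results(out / "enrichment.tsv", enrich_df)
    stage("enrich", [out / "enrichment.tsv"],
          n_terms_tested=len(enrich_df),
          n_enriched=int(enrich_df["enriched"].sum()) if len(enrich_df) else 0)

    # --- eQTL summary -------------------------------------------------------
    eqtl_path = data / "eqtl.tsv"
    if eqtl_path.exists():
        records = read_eqtl_records(eqtl_path)
        loci_map = {l.gene_id: l for l in loci}
        tau_map = tau_tables[sb]["tau"].to_dict()
        summary, cohort = stats.summarize_eqtl(records, loci_map, tau_map,
                                               config)
        write_results(out / "eqtl_summary.tsv", summary)
        stage("eqtl", [out / "eqtl_summary.tsv"],
              n_eqtl_genes=int((summary["n_records"] > 0).sum()),
              n_well_explained=int((summary["group"] == "well_explained").sum()))
        manifest["eqtl_cohort"] = cohort

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
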