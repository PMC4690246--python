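"""Synthetic-data generation with planted ground truth for every pipeline
input: replicated probe sets with strain-specific SFP shifts and expression
differences, tissue atlases with controllable specificity and silent genes,
ortholog CDS pairs with tuned synonymous/non-synonymous divergence and
structural lesions, gene maps with planted clusters, annotation terms with
planted enrichment, and eQTL records with planted cis/trans structure.

One root seed drives everything; each sub-generator derives an independent
stream from (seed, stage tag), so stages are reproducible in isolation.
Defaults place gene levels around the expression threshold (baseline
N(8, 2) log2, probe affinities N(0, 1)) and use a negative SFP shift
(mismatches reduce hybridization).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import (GeneLocus, ProbeIntensityTable, SampleSheet, write_atlas,
                 write_bed, write_mapping, write_probe_table,
                 write_sample_sheet)
from .molevo import _codon_sites

_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]
_CODON_AA = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402
_CODON_AA = dict(_tbl.forward_table)

STRUCTURAL_CLASSES = ("no_ortholog", "orf_not_detected",
                      "different_protein_length", "amino_acid_substitution",
                      "same_protein_sequence")


def _rng(config: AnalysisConfig, tag: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31),
                                  zlib.crc32(tag.encode()) % (2 ** 31)])


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside every synthetic input."""
    sfp_probes: set[tuple[str, str]] = field(default_factory=set)
    de_genes: dict[tuple[str, str, tuple[str, str]], float] = field(default_factory=dict)
    true_expr: dict[tuple[str, str, str], float] = field(default_factory=dict)  # (gene, tissue, strain)
    silent_genes: dict[str, set[str]] = field(default_factory=dict)
    changed_genes: dict[str, tuple[str, float]] = field(default_factory=dict)  # gene -> (tissue, shift)
    tau_targets: dict[str, str] = field(default_factory=dict)  # broad / specific
    ortholog_classes: dict[str, str] = field(default_factory=dict)
    target_ratios: dict[str, float] = field(default_factory=dict)
    planted_clusters: list[tuple[str, int, int, str]] = field(default_factory=list)
    enriched_terms: set[str] = field(default_factory=set)
    eqtl_truth: dict[str, tuple[bool, tuple[float, ...]]] = field(default_factory=dict)


def simulate_probe_experiment(config: AnalysisConfig, n_genes: int = 1000,
                              probes_per_gene: int = 11,
                              replicates: dict[str, int] | None = None,
                              sfp_fraction: float = 0.1,
                              sfp_shift: float = -2.0,
                              sfp_shift_sd: float = 0.5,
                              de_fraction: float = 0.1,
                              de_shift: float = 2.0,
                              noise_sd: float = 0.25,
                              tissues: tuple[str, ...] = ("t1",),
                              gene_levels: dict | None = None,
                              ) -> tuple[ProbeIntensityTable, SampleSheet, SimTruth]:
    """Replicated two-strain probe-level experiment with planted SFPs and DE.

    Model per probe p, strain s, replicate r:
    ``y = level(gene, tissue, s) + a_p + sigma_p*1[s=B, p SFP] + eps`` with
    ``eps ~ N(0, noise_sd^2)`` and probe affinities ``a_p ~ N(0, 1)`` drawn
    once per probe. ``level`` is the gene baseline (N(8, 2) plus a per-tissue
    program when several tissues are simulated) shifted by ``+/- de_shift``
    in strain B for DE genes; pass ``gene_levels`` (a map
    (gene, tissue, strain) -> log2 level) to override levels entirely.
    SFP shifts are per-probe, ``sigma_p ~ N(sfp_shift, sfp_shift_sd^2)``.
    """
    if probes_per_gene < 3:
        raise ValueError("probes_per_gene must be >= 3")
    replicates = replicates or {"A": 3, "B": 3}
    strains = list(replicates)
    if len(strains) != 2:
        raise ValueError("exactly two strains required")
    sa, sb = strains
    rng = _rng(config, "probe_experiment")
    truth = SimTruth()

    genes = [f"g{i:05d}" for i in range(n_genes)]
    probe_ids = [f"{g}_p{j}" for g in genes for j in range(probes_per_gene)]
    n_probes = len(probe_ids)
    affinity = rng.normal(0.0, 1.0, n_probes)

    if gene_levels is None:
        base = rng.normal(8.0, 2.0, n_genes)
        tissue_fx = (rng.normal(0.0, 1.0, (n_genes, len(tissues)))
                     if len(tissues) > 1 else np.zeros((n_genes, 1)))
        is_de = rng.random(n_genes) < de_fraction
        sign = rng.choice([-1.0, 1.0], n_genes)
        affected = np.ones((n_genes, len(tissues)), dtype=bool)
        if len(tissues) > 1:
            affected = rng.random((n_genes, len(tissues))) < 0.5
            none = ~affected.any(axis=1)
            affected[none, rng.integers(0, len(tissues), int(none.sum()))] = True
        levels = {}
        for gi, g in enumerate(genes):
            for ti, t in enumerate(tissues):
                lvl = base[gi] + tissue_fx[gi, ti]
                levels[(g, t, sa)] = lvl
                d = sign[gi] * de_shift if (is_de[gi] and affected[gi, ti]) else 0.0
                levels[(g, t, sb)] = lvl + d
                if d != 0.0:
                    truth.de_genes[(g, t, (sa, sb))] = d
        gene_levels = levels
    truth.true_expr = dict(gene_levels)

    sfp_mask = rng.random(n_probes) < sfp_fraction
    sfp_sigma = rng.normal(sfp_shift, sfp_shift_sd, n_probes)
    truth.sfp_probes = {(probe_ids[i], sb) for i in np.flatnonzero(sfp_mask)}

    rows_sheet = []
    cols = {}
    for t in tissues:
        for s in strains:
            for r in range(1, replicates[s] + 1):
                arr = f"{s}_{t}_r{r}"
                rows_sheet.append((arr, s, t, r))
                lvl = np.array([gene_levels[(g, t, s)] for g in genes])
                signal = np.repeat(lvl, probes_per_gene) + affinity
                if s == sb:
                    signal = signal + np.where(sfp_mask, sfp_sigma, 0.0)
                noise = rng.normal(0.0, noise_sd, n_probes) if noise_sd > 0 else 0.0
                cols[arr] = signal + noise
    values = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    transcript = pd.Series(np.repeat(genes, probes_per_gene),
                           index=values.index, name="transcript")
    sheet = SampleSheet(pd.DataFrame(rows_sheet, columns=["array_id", "strain",
                                                          "tissue", "replicate"]))
    return ProbeIntensityTable(values, transcript), sheet, truth


def simulate_atlas(config: AnalysisConfig, strains: tuple[str, str] = ("A", "B"),
                   n_tissues: dict[str, int] | None = None, n_genes: int = 400,
                   silent_fraction: float = 0.1,
                   changed_tissue_fraction: float = 0.1,
                   tau_mixture: dict[str, float] | None = None,
                   n_homologous: int = 5, noise_sd: float = 0.25,
                   changed_shift: float = -3.0,
                   ) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Per-strain gene x tissue atlases with planted silent, changed-tissues,
    specific and broad genes.

    The first ``n_homologous`` tissues share names across strains
    (homologous set); the remaining tissues are strain-specific, so tissue
    sets may differ across strains. Silent genes have all values clamped at
    or below the expression threshold in their designated strain and a
    highly expressed tissue in the other strain. Specific genes target
    tau >= 0.8 (one dominant tissue), broad genes tau <= 0.3.

    The noise-free per-tissue levels are the biological truth shared by any
    downstream experiment (recorded in ``truth.true_expr`` for the
    homologous tissues); ``noise_sd`` is atlas measurement noise added on
    top of them in the emitted matrices.
    """
    if silent_fraction + changed_tissue_fraction > 1:
        raise ValueError("silent_fraction + changed_tissue_fraction must be <= 1")
    n_tissues = n_tissues or {s: 8 for s in strains}
    tau_mixture = tau_mixture or {"broad": 0.5, "specific": 0.5}
    if any(n_tissues[s] < max(2, n_homologous) for s in strains):
        raise ValueError("each strain needs >= max(2, n_homologous) tissues")
    rng = _rng(config, "atlas")
    truth = SimTruth()
    sa, sb = strains
    tissue_names = {
        s: ([f"h{i+1}" for i in range(n_homologous)]
            + [f"{s}_x{i+1}" for i in range(n_tissues[s] - n_homologous)])
        for s in strains}

    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_silent = int(round(n_genes * silent_fraction))
    n_changed = int(round(n_genes * changed_tissue_fraction))
    roles = (["silent"] * n_silent + ["changed"] * n_changed
             + ["expressed"] * (n_genes - n_silent - n_changed))
    rng.shuffle(roles)
    p_specific = tau_mixture.get("specific", 0.5) / max(
        sum(tau_mixture.values()), 1e-12)

    truth.silent_genes = {s: set() for s in strains}
    mats = {s: np.zeros((n_genes, n_tissues[s])) for s in strains}

    def expressed_profile(n_t: int, kind: str, dominant: int) -> np.ndarray:
        if kind == "broad":
            return rng.normal(10.0, 0.3, n_t)
        prof = np.clip(rng.normal(1.2, 0.4, n_t), 0.0, None)
        prof[dominant] = rng.normal(12.0, 0.5)
        return prof

    for gi, (g, role) in enumerate(zip(genes, roles)):
        kind = "specific" if rng.random() < p_specific else "broad"
        truth.tau_targets[g] = kind
        if role == "silent":
            silent_in = strains[gi % 2]
            other = sb if silent_in == sa else sa
            truth.silent_genes[silent_in].add(g)
            mats[silent_in][gi] = np.minimum(
                np.clip(rng.normal(4.0, 0.8, n_tissues[silent_in]), 0.0, None),
                config.expr_threshold)
            mats[other][gi] = expressed_profile(
                n_tissues[other], kind, int(rng.integers(0, n_tissues[other])))
            continue
        dominant = int(rng.integers(0, n_homologous)) if role == "changed" else \
            int(rng.integers(0, min(n_tissues[sa], n_tissues[sb])))
        prof_a = expressed_profile(n_tissues[sa], kind, dominant)
        prof_b = prof_a[:n_homologous].tolist() + list(
            expressed_profile(n_tissues[sb], kind, dominant)[n_homologous:])
        prof_b = np.asarray(prof_b[:n_tissues[sb]])
        if prof_b.size < n_tissues[sb]:
            prof_b = np.concatenate([prof_b, expressed_profile(
                n_tissues[sb], kind, dominant)[prof_b.size:]])
        if role == "changed":
            # shift one homologous tissue in strain B; keep the gene expressed
            t_idx = dominant if kind == "specific" else int(
                rng.integers(0, n_homologous))
            prof_b = prof_b.copy()
            prof_b[t_idx] = max(prof_b[t_idx] + changed_shift, 0.0)
            truth.changed_genes[g] = (tissue_names[sb][t_idx], changed_shift)
        mats[sa][gi] = prof_a
        mats[sb][gi] = prof_b

    gene_pos = {g: i for i, g in enumerate(genes)}
    for s in strains:
        for t_idx in range(n_homologous):
            t = tissue_names[s][t_idx]
            for g in genes:
                truth.true_expr[(g, t, s)] = float(mats[s][gene_pos[g], t_idx])
    noisy = {}
    for s in strains:
        m = mats[s].copy()
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, m.shape)
            # re-clamp silent rows so the invariant holds exactly
            for g in truth.silent_genes[s]:
                m[gene_pos[g]] = np.minimum(m[gene_pos[g]],
                                            config.expr_threshold)
        noisy[s] = m
    atlases = {s: pd.DataFrame(np.clip(noisy[s], 0.0, None),
                               index=pd.Index(genes, name="gene_id"),
                               columns=tissue_names[s])
               for s in strains}
    return atlases, truth


def _mutate_synonymous(rng, codons: list[str], idx: int) -> bool:
    c = codons[idx]
    aa = _CODON_AA.get(c)
    alts = [c[:2] + nt for nt in "ACGT"
            if nt != c[2] and _CODON_AA.get(c[:2] + nt) == aa]
    if not alts:
        return False
    codons[idx] = alts[int(rng.integers(0, len(alts)))]
    return True


def _mutate_nonsynonymous(rng, codons: list[str], idx: int) -> bool:
    c = codons[idx]
    aa = _CODON_AA.get(c)
    alts = []
    for pos in (0, 1):
        for nt in "ACGT":
            if nt == c[pos]:
                continue
            alt = c[:pos] + nt + c[pos + 1:]
            if alt in _CODON_AA and _CODON_AA[alt] != aa:
                alts.append(alt)
    if not alts:
        return False
    codons[idx] = alts[int(rng.integers(0, len(alts)))]
    return True


def simulate_ortholog_pairs(config: AnalysisConfig, n_pairs: int = 100,
                            class_mix: dict[str, float] | None = None,
                            target_kaks: tuple[float, ...] = (0.3, 1.0, 1.5),
                            cds_len_codons: int = 300,
                            syn_prop: float = 0.05,
                            ) -> tuple[list[tuple[str, str]],
                                       list[tuple[str, str]], SimTruth]:
    """Paired CDS records with planted structural classes and Ka/Ks targets.

    Same-protein pairs differ only at synonymous positions; different-
    protein-length pairs carry a 1-bp frameshift deletion or an in-frame
    premature stop; amino-acid-substitution pairs are tuned so the NG86
    estimate lands near the cycled ``target_kaks`` values (raw synonymous
    difference proportion ``syn_prop``).
    """
    if cds_len_codons < 100:
        raise ValueError("cds_len_codons must be >= 100 for the JC correction")
    if any(r <= 0 for r in target_kaks):
        raise ValueError("target Ka/Ks ratios must be positive")
    class_mix = class_mix or {c: 0.2 for c in STRUCTURAL_CLASSES}
    total = sum(class_mix.values())
    rng = _rng(config, "orthologs")
    truth = SimTruth()
    classes = rng.choice(list(class_mix), size=n_pairs,
                         p=[v / total for v in class_mix.values()])
    rec_a, rec_b = [], []
    n_aa = 0
    for i in range(n_pairs):
        gene = f"g{i:05d}"
        cls = str(classes[i])
        truth.ortholog_classes[gene] = cls
        body = [str(_SENSE_CODONS[j]) for j in
                rng.integers(0, len(_SENSE_CODONS), cds_len_codons - 2)]
        codons_a = ["ATG"] + body + ["TAA"]
        seq_a = "".join(codons_a)
        codons_b = list(codons_a)
        if cls == "no_ortholog":
            seq_b = "".join(["ATG"] + [str(_SENSE_CODONS[j]) for j in
                                       rng.integers(0, len(_SENSE_CODONS),
                                                    cds_len_codons - 2)]
                            + ["TAA"])
        elif cls == "orf_not_detected":
            codons_b[0] = "ATT"
            seq_b = "".join(codons_b)
        elif cls == "different_protein_length":
            if rng.random() < 0.5:
                s = "".join(codons_b)
                cut = 3 * (cds_len_codons // 2)
                seq_b = s[:cut] + s[cut + 1:]  # 1-bp deletion mid-CDS
            else:
                codons_b[cds_len_codons // 2] = "TAA"  # premature stop
                seq_b = "".join(codons_b)
        else:
            n_codons = len(codons_b)
            n_syn = int(round(syn_prop * n_codons))
            if syn_prop > 0:
                n_syn = max(1, n_syn)
            order = rng.permutation(np.arange(1, n_codons - 1))
            placed = 0
            ptr = 0
            while placed < n_syn and ptr < len(order):
                placed += _mutate_synonymous(rng, codons_b, int(order[ptr]))
                ptr += 1
            if cls == "amino_acid_substitution":
                ratio = float(target_kaks[n_aa % len(target_kaks)])
                truth.target_ratios[gene] = ratio
                n_aa += 1
                # pick the non-synonymous count so pn/ps hits the target:
                # nd = ratio * (sd / S_sites) * N_sites for this sequence
                s_sites = sum(_codon_sites(c)[0] for c in codons_a[:-1])
                n_sites = 3 * (len(codons_a) - 1) - s_sites
                n_non = max(1, int(round(
                    ratio * max(placed, 1) / s_sites * n_sites)))
                placed_n = 0
                while placed_n < n_non and ptr < len(order):
                    placed_n += _mutate_nonsynonymous(rng, codons_b, int(order[ptr]))
                    ptr += 1
            seq_b = "".join(codons_b)
        rec_a.append((gene, seq_a))
        rec_b.append((gene, seq_b))
    return rec_a, rec_b, truth


def simulate_genome(config: AnalysisConfig, n_genes: int = 2000,
                    chrom_sizes: dict[str, int] | None = None,
                    cluster_spec: list[tuple[str, int, int, float]] | None = None,
                    he_fraction: float = 0.7,
                    background_flag_rate: float = 0.02,
                    ) -> tuple[list[GeneLocus], set[str], set[str], SimTruth]:
    """Gene coordinates with optional planted high-flag-density windows.

    Returns (loci, highly-expressed set, flagged set, truth). Flags are
    drawn only among highly expressed genes: Bernoulli(background rate)
    outside planted windows, Bernoulli(window rate) inside.
    """
    chrom_sizes = chrom_sizes or {"chr1": 20_000_000, "chr2": 15_000_000}
    cluster_spec = cluster_spec or []
    for chrom, start, end, _rate in cluster_spec:
        if chrom not in chrom_sizes or not (0 <= start < end <= chrom_sizes[chrom]):
            raise ValueError(f"planted window ({chrom}, {start}, {end}) "
                             "outside chromosome")
    rng = _rng(config, "genome")
    truth = SimTruth()
    total = sum(chrom_sizes.values())
    loci: list[GeneLocus] = []
    he: set[str] = set()
    flagged: set[str] = set()
    counts = rng.multinomial(n_genes, [v / total for v in chrom_sizes.values()])
    gi = 0
    for (chrom, size), k in zip(chrom_sizes.items(), counts):
        starts = np.sort(rng.integers(0, size - 5000, k))
        for s in starts:
            gene = f"g{gi:05d}"
            gi += 1
            end = int(min(s + int(rng.integers(500, 5000)), size))
            loci.append(GeneLocus(gene, chrom, int(s), end))
            if rng.random() >= he_fraction:
                continue
            he.add(gene)
            rate = background_flag_rate
            for c, ws, we, wrate in cluster_spec:
                if c == chrom and ws <= s < we:
                    rate = wrate
            if rng.random() < rate:
                flagged.add(gene)
    truth.planted_clusters = [(c, s, e, "flag") for c, s, e, _ in cluster_spec]
    return loci, he, flagged, truth


def simulate_go(config: AnalysisConfig, n_genes: int = 2000, n_terms: int = 50,
                enriched: list[tuple[str, float]] | None = None,
                n_flagged: int = 50,
                term_size: tuple[int, int] = (10, 60),
                gene_ids: list[str] | None = None,
                flagged_genes: set[str] | None = None,
                ) -> tuple[dict[str, set[str]], set[str], set[str], SimTruth]:
    """Annotation map with planted term enrichment.

    Enriched terms sample their member genes with weight ``odds_ratio`` on
    flagged genes versus 1 on the rest; other terms sample uniformly.
    Returns (annotation, flagged set, background set, truth). Pass
    ``gene_ids``/``flagged_genes`` to plant enrichment on an existing gene
    universe (e.g. a DE gene list) instead of a fresh one.
    """
    enriched = enriched or []
    rng = _rng(config, "go")
    truth = SimTruth()
    genes = np.array(gene_ids if gene_ids is not None
                     else [f"g{i:05d}" for i in range(n_genes)])
    flagged = (set(flagged_genes) if flagged_genes is not None
               else set(rng.choice(genes, size=n_flagged, replace=False)))
    ann: dict[str, set[str]] = {}
    enriched_map = dict(enriched)
    truth.enriched_terms = set(enriched_map)
    flag_mask = np.isin(genes, list(flagged))
    for ti in range(n_terms):
        term = f"TERM:{ti:04d}"
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        w = np.where(flag_mask, enriched_map.get(term, 1.0), 1.0)
        members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
        for g in members:
            ann.setdefault(str(g), set()).add(term)
    return ann, flagged, set(genes), truth


def simulate_eqtl_records(config: AnalysisConfig, n_genes: int = 200,
                          group_mix: dict[str, float] | None = None,
                          loci: dict[str, GeneLocus] | None = None,
                          ) -> tuple[pd.DataFrame, dict[str, GeneLocus], SimTruth]:
    """Per-gene eQTL records with planted group structure.

    Group ``well_explained_cis`` genes get one cis record (interval
    overlapping the gene) plus a moderate trans record so the summed
    variance explained strictly exceeds 80 %; group ``unexplained_no_cis``
    genes get 0-2 small distant trans records summing below 40 % (and a
    high tissue-specificity target, recorded in the truth).
    """
    group_mix = group_mix or {"well_explained_cis": 0.5,
                              "unexplained_no_cis": 0.5}
    rng = _rng(config, "eqtl")
    truth = SimTruth()
    chrom, size = "chr1", 30_000_000
    if loci is None:
        starts = np.sort(rng.integers(0, size - 10_000, n_genes))
        loci = {f"g{i:05d}": GeneLocus(f"g{i:05d}", chrom, int(s), int(s) + 3000)
                for i, s in enumerate(starts)}
    total = sum(group_mix.values())
    groups = rng.choice(list(group_mix), size=len(loci),
                        p=[v / total for v in group_mix.values()])
    rows = []
    for (gene, locus), grp in zip(sorted(loci.items()), groups):
        if grp == "well_explained_cis":
            cis_var = float(rng.uniform(70, 90))
            trans_var = float(rng.uniform(15, 25))
            rows.append((gene, locus.chrom, max(0, locus.start - 50_000),
                         locus.end + 50_000, cis_var))
            rows.append((gene, "chrT", 1_000_000, 2_000_000, trans_var))
            truth.eqtl_truth[gene] = (True, (cis_var, trans_var))
        else:
            k = int(rng.integers(0, 3))
            fr = tuple(float(rng.uniform(5, 15)) for _ in range(k))
            for v in fr:
                rows.append((gene, "chrT", 5_000_000, 6_000_000, v))
            truth.eqtl_truth[gene] = (False, fr)
    records = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                          "var_explained"])
    return records, loci, truth


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_dataset(config: AnalysisConfig, out_dir: str | Path,
                  n_genes: int = 300, probes_per_gene: int = 8,
                  replicates: dict[str, int] | None = None,
                  n_homologous: int = 5,
                  noise_sd: float = 0.25) -> SimTruth:
    """Generate and write one coordinated synthetic dataset for the full
    pipeline: atlases define each gene's per-tissue levels, the probe-level
    experiment realizes the homologous tissues of those atlases, and gene
    maps, ortholog pairs, annotations and eQTL records share the gene ids.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    replicates = replicates or {"A": 3, "B": 3}

    atlases, truth = simulate_atlas(config, n_genes=n_genes,
                                    n_homologous=n_homologous,
                                    noise_sd=noise_sd)
    genes = list(atlases["A"].index)
    homologous = [f"h{i+1}" for i in range(n_homologous)]
    # biological levels: the atlases' noise-free profiles plus a small
    # inter-strain scatter (well below the fold threshold)
    rng = _rng(config, "dataset")
    levels = dict(truth.true_expr)
    for g in genes:
        for t in homologous:
            levels[(g, t, "B")] = max(
                0.0, levels[(g, t, "B")] + float(rng.normal(0.0, 0.1)))
    table, sheet, ptruth = simulate_probe_experiment(
        config, n_genes=n_genes, probes_per_gene=probes_per_gene,
        replicates=replicates, noise_sd=noise_sd,
        tissues=tuple(homologous), gene_levels=levels)
    truth.sfp_probes = ptruth.sfp_probes
    truth.true_expr = ptruth.true_expr
    # DE truth for the pair follows from the planted changed-tissue shifts
    for g, (t, shift) in truth.changed_genes.items():
        truth.de_genes[(g, t, ("A", "B"))] = shift

    rec_a, rec_b, otruth = simulate_ortholog_pairs(config, n_pairs=n_genes,
                                                   cds_len_codons=120)
    truth.ortholog_classes = otruth.ortholog_classes
    truth.target_ratios = otruth.target_ratios

    loci, he, flg, gtruth = simulate_genome(config, n_genes=n_genes)
    truth.planted_clusters = gtruth.planted_clusters
    # remap genome gene ids onto the dataset's genes (same count by
    # construction when n_genes matches; otherwise truncate)
    loci = loci[:n_genes]
    loci = [GeneLocus(g, l.chrom, l.start, l.end)
            for g, l in zip(genes, loci)]

    de_like = set().union(*truth.silent_genes.values()) | set(truth.changed_genes)
    ann, go_flagged, go_background, gotruth = simulate_go(
        config, n_terms=20, enriched=[("TERM:0000", 10.0)],
        gene_ids=genes, flagged_genes=de_like)
    truth.enriched_terms = gotruth.enriched_terms

    loci_map = {l.gene_id: l for l in loci}
    records, _, etruth = simulate_eqtl_records(config, loci=loci_map)
    truth.eqtl_truth = etruth.eqtl_truth

    write_probe_table(out / "probes.tsv", table)
    write_mapping(out / "mapping.tsv", table.transcript)
    write_sample_sheet(out / "samples.tsv", sheet)
    for s, atlas in atlases.items():
        write_atlas(out / f"atlas_{s}.tsv", atlas)
    write_fasta(out / "orthologs_a.fasta", rec_a)
    write_fasta(out / "orthologs_b.fasta", rec_b)
    write_bed(out / "genes.bed", loci)
    with open(out / "go.tsv", "w") as fh:
        for g in sorted(ann):
            for term in sorted(ann[g]):
                fh.write(f"{g}\t{term}\n")
    records.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")

    pd.DataFrame(sorted((s, g) for s, gs in truth.silent_genes.items()
                        for g in gs),
                 columns=["strain", "gene_id"]).to_csv(
        out / "truth" / "silent.tsv", sep="\t", index=False)
    pd.DataFrame(sorted((g, t, s) for (g, t, _pair), s
                        in truth.de_genes.items()),
                 columns=["gene_id", "tissue", "shift"]).to_csv(
        out / "truth" / "de.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.sfp_probes),
                 columns=["probe_id", "strain"]).to_csv(
        out / "truth" / "sfp.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.ortholog_classes.items()),
                 columns=["gene_id", "structural_class"]).to_csv(
        out / "truth" / "orthologs.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.tau_targets.items()),
                 columns=["gene_id", "tau_class"]).to_csv(
        out / "truth" / "tau.tsv", sep="\t", index=False)
    return truth
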