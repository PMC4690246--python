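"""Molecular-evolution classification of ortholog pairs.

Ortholog CDS pairs are classified into five structural types by a first-
match cascade: (1) no ortholog (alignment coverage < 0.8), (2) ORF not
detected (no start codon), (3) different protein length (frameshift,
premature stop, stop-codon loss, or a length change), (4) amino acid
substitution, (5) same protein sequence. For same-length pairs, Ka/Ks is
estimated by the Nei-Gojobori (1986) pathway method with Jukes-Cantor
correction, and pairs are binned into conserved (< 0.75), neutral
(0.75 <= ratio < 1.25) and rapid (>= 1.25) rate classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .config import AnalysisConfig
from .io import ValidationError

log = logging.getLogger(__name__)

STRUCTURAL_CLASSES = ("no_ortholog", "orf_not_detected",
                      "different_protein_length", "amino_acid_substitution",
                      "same_protein_sequence")

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)
_NUCS = "ACGT"


@dataclass
class OrthologAlignment:
    """Alignment-derived features of a query CDS against its putative
    ortholog."""
    gene_id: str
    coverage: float             # fraction of the query aligned/identical
    target_cds: str | None
    has_start: bool
    frameshift: bool
    premature_stop: bool
    stop_lost: bool
    protein_identical: bool = False  # target protein == query protein


@dataclass
class OrthologEvolution:
    gene_id: str
    structural_class: str
    ka: float | None
    ks: float | None
    ratio: float | None
    rate_class: str  # conserved / neutral / rapid / undefined
    saturated: bool = False


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def pair_alignment(gene_id: str, cds_query: str, cds_target: str
                   ) -> OrthologAlignment:
    """Derive structural features for a CDS pair.

    Coverage is edit-distance identity of the target against the query
    (1 - distance/|query|), a proxy for the fraction of the query matched.
    Frame integrity is judged from the target alone: a length difference
    that is not a multiple of 3 (or a target length not a multiple of 3) is
    a frameshift; an internal stop in the target translation is a premature
    stop; a missing terminal stop codon is a lost stop.
    """
    cds_query = cds_query.upper()
    cds_target = cds_target.upper()
    if not cds_target:
        return OrthologAlignment(gene_id, 0.0, None, False, False, False, False)
    dist = edlib.align(cds_target, cds_query, task="distance")["editDistance"]
    coverage = max(0.0, 1.0 - dist / max(len(cds_query), 1))
    has_start = cds_target.startswith("ATG")
    frameshift = (len(cds_target) % 3 != 0
                  or (len(cds_target) - len(cds_query)) % 3 != 0)
    prot = _translate(cds_target)
    premature_stop = "*" in prot[:-1]
    stop_lost = not prot.endswith("*")
    return OrthologAlignment(gene_id, coverage, cds_target, has_start,
                             frameshift, premature_stop, stop_lost,
                             protein_identical=prot == _translate(cds_query))


def classify_ortholog_pair(aln: OrthologAlignment, query_protein_len: int,
                           min_coverage: float = 0.8) -> str:
    """First-matching-rule cascade over the five structural types.

    ``query_protein_len`` counts residues including the terminal stop symbol
    convention used by :func:`pair_alignment` (translated length).
    """
    if aln.coverage < min_coverage:
        return "no_ortholog"
    if aln.target_cds is None:
        raise ValidationError(
            f"gene {aln.gene_id!r}: coverage >= {min_coverage} but no target CDS")
    if not aln.has_start:
        return "orf_not_detected"
    target_len = len(_translate(aln.target_cds))
    if (aln.frameshift or aln.premature_stop or aln.stop_lost
            or target_len != query_protein_len):
        return "different_protein_length"
    if aln.protein_identical:
        return "same_protein_sequence"
    return "amino_acid_substitution"


def classify_pairs(pairs: list[tuple[str, str, str]],
                   config: AnalysisConfig) -> pd.DataFrame:
    """Classify a list of (gene_id, cds_a, cds_b) pairs and compute Ka/Ks
    where defined (same-length coding pairs without structural lesions)."""
    rows = []
    for gene, cds_a, cds_b in pairs:
        aln = pair_alignment(gene, cds_a, cds_b)
        cls = classify_ortholog_pair(aln, len(_translate(cds_a)))
        ka = ks = ratio = None
        rate = "undefined"
        saturated = False
        if cls in ("amino_acid_substitution", "same_protein_sequence"):
            core_a = _strip_stop(cds_a)
            core_b = _strip_stop(cds_b)
            if len(core_a) == len(core_b):
                ka, ks, ratio, saturated = compute_ka_ks(core_a, core_b)
                rate = rate_class(ratio, config)
        rows.append((gene, cls, ka, ks, ratio, rate, saturated))
    return pd.DataFrame(rows, columns=["gene_id", "structural_class", "ka",
                                       "ks", "ratio", "rate_class",
                                       "saturated"])


def _strip_stop(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    cds = cds[:usable]
    if cds[-3:] in _STOPS:
        cds = cds[:-3]
    return cds


def rate_class(ratio: float | None, config: AnalysisConfig) -> str:
    if ratio is None:
        return "undefined"
    if ratio < config.kaks_conserved:
        return "conserved"
    if ratio < config.kaks_rapid:
        return "neutral"
    return "rapid"


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Per position, the fraction of the three possible substitutions that are
    synonymous; changes creating stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE.get(codon)
    if aa is None:
        raise ValidationError(f"stop or invalid codon {codon!r} in CDS")
    syn = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            alt_codon = codon[:pos] + alt + codon[pos + 1:]
            if _CODON_TABLE.get(alt_codon) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    All shortest mutational pathways are weighted equally; pathways passing
    through a stop codon are excluded (unless every pathway does).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and len(diff_pos) > 1 and nxt != c2:
                blocked = True
                break
            if _CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every pathway passes a stop; fall back to all pathways
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p <= 0:
        return 0.0, False
    if p >= 0.75:
        return p, True  # saturated: uncorrected proportion returned
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0)), False


def compute_ka_ks(cds_a: str, cds_b: str
                  ) -> tuple[float, float, float | None, bool]:
    """NG86 Ka/Ks for two in-frame, equal-length CDS (no internal stops).

    Codons containing gaps or ambiguity codes are excluded pairwise. Site
    counts are averaged over both sequences; substitution differences are
    counted over all shortest mutational pathways with equal weights.
    Jukes-Cantor correction is applied when the raw proportion is < 0.75;
    otherwise the uncorrected proportion is returned with a saturation flag.
    The ratio is None when Ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValidationError("compute_ka_ks: sequences differ in length")
    if len(cds_a) % 3:
        raise ValidationError("compute_ka_ks: length not a multiple of 3")
    s_sites_a = s_sites_b = n_sites_a = n_sites_b = 0.0
    sd = nd = 0.0
    n_used = 0
    for i in range(0, len(cds_a), 3):
        c1, c2 = cds_a[i:i + 3], cds_b[i:i + 3]
        if set(c1 + c2) - set(_NUCS):
            continue  # gap or ambiguity: exclude the codon pair
        sa, na = _codon_sites(c1)
        sb, nb = _codon_sites(c2)
        s_sites_a += sa
        n_sites_a += na
        s_sites_b += sb
        n_sites_b += nb
        dsd, dnd = _codon_differences(c1, c2)
        sd += dsd
        nd += dnd
        n_used += 1
    if n_used == 0:
        raise ValidationError("compute_ka_ks: no usable codons")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = (n_sites_a + n_sites_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jukes_cantor(ps)
    ka, sat_n = _jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio, sat_s or sat_n


def summarize_evolution(evolution: pd.DataFrame,
                        gene_categories: dict[str, str]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency tables of structural class x category and rate class x
    category (counts; column proportions sum to 1 over non-empty columns)."""
    cats = pd.Series(gene_categories, name="category")
    if cats.index.has_duplicates or evolution["gene_id"].duplicated().any():
        raise ValidationError("a gene appears in two categories")
    df = evolution.set_index("gene_id").join(cats, how="inner")
    struct = pd.crosstab(df["structural_class"], df["category"])
    rates = pd.crosstab(df.loc[df["rate_class"] != "undefined", "rate_class"],
                        df.loc[df["rate_class"] != "undefined", "category"])
    return struct, rates
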