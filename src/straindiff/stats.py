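"""Downstream statistics: annotation-term enrichment, three-strain DE
pattern classification with the expected-vs-observed three-way test, and
eQTL variance-explained summaries.

Enrichment is a one-sided (greater) Fisher / hypergeometric test per term,
restricted to terms carried by strictly more than ``go_min_genes``
background genes, reported at raw p < ``enrich_alpha`` (no multiplicity
correction by default, matching the analysis style this pipeline
reproduces). The three-way test is two-sided by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .io import GeneLocus, ValidationError

THREE_STRAIN_PATTERNS = ("three_way", "common_ji", "indica_indica",
                         "similar", "inconsistent")


def hypergeom_tail_p(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n): one-sided enrichment p."""
    return float(sps.hypergeom.sf(k - 1, big_n, big_k, n))


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric pmf over tables at most as
    probable as the observed one (same margins)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell in 2x2 table")
    big_n = a + b + c + d
    big_k = a + b
    n = a + c
    lo = max(0, n - (big_n - big_k))
    hi = min(n, big_k)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, big_n, big_k, n)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


@dataclass
class EnrichmentResult:
    term: str
    k: int          # flagged genes with term
    big_k: int      # background genes with term
    n: int          # flagged genes
    big_n: int      # background genes
    odds_ratio: float
    p: float
    enriched: bool


def fisher_enrichment(flagged: set[str], background: set[str],
                      annotation: dict[str, set[str]],
                      config: AnalysisConfig) -> list[EnrichmentResult]:
    """One-sided term enrichment of ``flagged`` within ``background``.

    Terms are tested only when strictly more than ``config.go_min_genes``
    background genes carry them; results sorted by p.
    """
    if not background:
        raise ValidationError("empty background gene set")
    if not flagged <= background:
        raise ValidationError("flagged genes must be a subset of background")
    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    big_n, n = len(background), len(flagged)
    out = []
    for term, genes in term_genes.items():
        big_k = len(genes)
        if big_k <= config.go_min_genes:
            continue
        k = len(genes & flagged)
        p = hypergeom_tail_p(k, big_k, n, big_n)
        b, c, d = big_k - k, n - k, big_n - big_k - n + k
        odds = float("inf") if b * c == 0 and k * d > 0 else (
            (k * d) / (b * c) if b * c else float("nan"))
        out.append(EnrichmentResult(term, k, big_k, n, big_n, odds, p,
                                    p < config.enrich_alpha))
    out.sort(key=lambda r: (r.p, r.term))
    return out


def _pattern(nm: bool, nz: bool, mz: bool) -> str:
    if nm and nz and mz:
        return "three_way"
    if nm and nz and not mz:
        return "common_ji"
    if mz and (nm != nz):
        return "indica_indica"
    if not (nm or nz or mz):
        return "similar"
    return "inconsistent"


def classify_three_strain(de_nm: pd.DataFrame, de_nz: pd.DataFrame,
                          de_mz: pd.DataFrame, tissue: str,
                          config: AnalysisConfig,
                          silent: set[str] | None = None) -> pd.DataFrame:
    """Per-gene DE pattern among three strains for one tissue.

    The three inputs are pairwise DE tables (japonica-M, japonica-Z, M-Z).
    Genes not highly expressed in any of the three strains, and silent
    genes, are dropped before classification; the remaining genes partition
    into the five patterns.
    """
    silent = silent or set()
    tabs = []
    for name, df in (("nm", de_nm), ("nz", de_nz), ("mz", de_mz)):
        sub = df[df["tissue"] == tissue].set_index("gene_id")
        tabs.append(sub.add_prefix(name + "_"))
    merged = tabs[0].join(tabs[1], how="inner").join(tabs[2], how="inner")
    if len(merged) == 0:
        raise ValidationError(
            f"no shared genes across the three DE tables for tissue {tissue!r}")
    expr_cols = [c for c in merged.columns if c.endswith(("expr_a", "expr_b"))]
    high = merged[expr_cols].max(axis=1) > config.expr_threshold
    measurable = (merged["nm_measurable"] & merged["nz_measurable"]
                  & merged["mz_measurable"])
    keep = high & measurable & ~merged.index.isin(list(silent))
    merged = merged[keep]
    pattern = [
        _pattern(bool(r.nm_is_de), bool(r.nz_is_de), bool(r.mz_is_de))
        for r in merged.itertuples()
    ]
    return pd.DataFrame({
        "gene_id": merged.index,
        "tissue": tissue,
        "nm_de": merged["nm_is_de"].to_numpy(dtype=bool),
        "nz_de": merged["nz_is_de"].to_numpy(dtype=bool),
        "mz_de": merged["mz_is_de"].to_numpy(dtype=bool),
        "pattern": pattern,
    })


def expected_threeway(common_ji: int, mzde: int, highly_expressed: int) -> float:
    """Expected three-way DE count under proportional mixing.

    Assumes the proportion of three-way DE genes among common DE genes
    equals the proportion of M-Z DE genes among highly expressed genes.
    """
    if highly_expressed <= 0:
        raise ValidationError("highly_expressed must be positive")
    if mzde > highly_expressed:
        raise ValidationError("mzde cannot exceed highly_expressed")
    return common_ji * mzde / highly_expressed


def threeway_test(observed: int, common_ji: int, mzde: int,
                  highly_expressed: int, alternative: str = "two-sided"
                  ) -> float:
    """Fisher's exact test of the observed three-way count against the
    proportional-mixing expectation."""
    if observed > common_ji:
        raise ValidationError("observed cannot exceed common_ji")
    table = [[observed, common_ji - observed],
             [mzde, highly_expressed - mzde]]
    if alternative == "two-sided":
        return fisher_two_sided_p(table)
    if alternative == "greater":
        return hypergeom_tail_p(observed, common_ji, observed + mzde,
                                common_ji + highly_expressed)
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class EqtlGeneSummary:
    gene_id: str
    n_records: int
    sum_explained: float   # percent
    has_cis: bool
    group: str             # well_explained / unexplained / intermediate


def _overlaps(locus: GeneLocus, chrom: str, start: int, end: int,
              margin: int) -> bool:
    return (chrom == locus.chrom
            and start < locus.end + margin
            and end > max(0, locus.start - margin))


def summarize_eqtl(records: pd.DataFrame, loci: dict[str, GeneLocus],
                   tau: dict[str, float] | None,
                   config: AnalysisConfig,
                   gene_class: dict[str, str] | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-gene eQTL summaries plus cohort statistics.

    ``records`` columns: gene_id, chrom, start, end, var_explained (percent).
    A record is cis when its interval overlaps the gene body expanded by
    ``config.cis_margin_bp``. ``sum_explained`` is the simple summation of
    variance explained over all records of a gene. Groups: strictly >
    ``eqtl_high`` -> well_explained, strictly < ``eqtl_low`` -> unexplained,
    else intermediate. Cohort stats (mean +/- sd of the sums, overall and
    cis-only) are reported per supplied gene class.
    """
    rows = []
    genes_seen = []
    for gene, sub in records.groupby("gene_id", sort=True):
        locus = loci.get(gene)
        if locus is None:
            continue  # unknown gene: skipped (warning left to callers' logs)
        genes_seen.append(gene)
        total = float(sub["var_explained"].sum())
        has_cis = any(
            _overlaps(locus, r.chrom, int(r.start), int(r.end),
                      config.cis_margin_bp)
            for r in sub.itertuples())
        if total > config.eqtl_high:
            group = "well_explained"
        elif total < config.eqtl_low:
            group = "unexplained"
        else:
            group = "intermediate"
        rows.append((gene, len(sub), total, has_cis, group,
                     float("nan") if tau is None else tau.get(gene, float("nan"))))
    # genes with loci but no records: sum 0, unexplained
    for gene, locus in loci.items():
        if gene not in set(genes_seen):
            rows.append((gene, 0, 0.0, False, "unexplained",
                         float("nan") if tau is None else tau.get(gene, float("nan"))))
    summary = pd.DataFrame(rows, columns=["gene_id", "n_records",
                                          "sum_explained", "has_cis",
                                          "group", "tau"])
    cohort: dict = {}
    classes = ({"all": set(summary["gene_id"])} if gene_class is None else
               {c: {g for g, cc in gene_class.items() if cc == c}
                for c in sorted(set(gene_class.values()))})
    for cname, members in classes.items():
        sub = summary[summary["gene_id"].isin(members)
                      & (summary["n_records"] > 0)]
        cis = sub[sub["has_cis"]]
        cohort[cname] = {
            "n": int(len(sub)),
            "mean_explained": float(sub["sum_explained"].mean()) if len(sub) else float("nan"),
            "sd_explained": float(sub["sum_explained"].std(ddof=1)) if len(sub) > 1 else float("nan"),
            "n_cis": int(len(cis)),
            "mean_explained_cis": float(cis["sum_explained"].mean()) if len(cis) else float("nan"),
            "sd_explained_cis": float(cis["sum_explained"].std(ddof=1)) if len(cis) > 1 else float("nan"),
        }
    return summary, cohort
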