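"""Tissue-atlas analysis: silent genes, global vs changed-tissues DE
classification, the tissue-specificity index tau, and atlas-based summaries.

A strain's atlas is a gene x tissue matrix of log2 expression values
(SFP-excluded probe-set medians). A gene is *silent* in a strain when its
log2 value does not exceed the expression threshold in any atlas tissue of
that strain while being highly expressed in at least one tissue of the other
strain. Silent genes are *global* DE genes: the difference holds in every
tissue. DE genes detected between homologous tissues that are silent in
neither strain are *changed-tissues* DE genes: expressed in both strains but
differentially in some tissues.

The tissue-specificity index tau is

    tau = sum_i (1 - x_i) / (N - 1),   x_i = value_i / max_i(value_i),

0 for uniform expression and 1 for single-tissue expression. Values are
clamped at 0 from below before normalization (log2 scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ValidationError

log = logging.getLogger(__name__)


@dataclass
class TauResult:
    gene_id: str
    tau: float
    n_tissues: int
    max_tissue: str
    eligible: bool  # max value > expr_threshold


@dataclass
class DEClassification:
    gene_id: str
    strain_pair: tuple[str, str]
    de_class: str  # global_silent_in_A / global_silent_in_B / changed_tissues / similar
    tissues_detected: frozenset[str]
    direction: dict[str, str]


def detect_silent(atlas_self: pd.DataFrame, atlas_other: pd.DataFrame,
                  config: AnalysisConfig) -> set[str]:
    """Genes silent in ``atlas_self`` but expressed in ``atlas_other``.

    A gene qualifies iff its maximum over the self atlas is <= expr_threshold
    ("did not exceed") AND its maximum over the other strain's atlas is
    strictly > expr_threshold.
    """
    shared = atlas_self.index.intersection(atlas_other.index)
    if shared.empty:
        raise ValidationError("detect_silent: no shared genes between atlases")
    low_self = atlas_self.loc[shared].max(axis=1) <= config.expr_threshold
    high_other = atlas_other.loc[shared].max(axis=1) > config.expr_threshold
    return set(shared[low_self & high_other])


def classify_de(de_calls: pd.DataFrame, silent_a: set[str], silent_b: set[str],
                config: AnalysisConfig,
                strain_pair: tuple[str, str] = ("A", "B")
                ) -> list[DEClassification]:
    """Classify genes into global / changed-tissues / similar.

    ``de_calls`` holds per (gene, tissue) DE rows over the homologous tissue
    set. Any silent-set member is global regardless of its per-tissue calls
    (the atlas adds silent genes the per-tissue tests can miss); DE-detected
    non-silent genes are changed-tissues; everything else is similar.
    """
    both = silent_a & silent_b
    if both:
        raise ValidationError(
            f"{len(both)} genes silent in both strains (e.g. "
            f"{sorted(both)[0]!r}); outside the highly-expressed universe"
        )
    out: list[DEClassification] = []
    grouped = de_calls.groupby("gene_id", sort=False)
    de_genes = set(de_calls["gene_id"])
    for gene in de_genes | silent_a | silent_b:
        if gene in silent_a:
            cls = f"global_silent_in_{strain_pair[0]}"
        elif gene in silent_b:
            cls = f"global_silent_in_{strain_pair[1]}"
        else:
            cls = "similar"
        tissues: frozenset[str] = frozenset()
        direction: dict[str, str] = {}
        if gene in de_genes:
            rows = grouped.get_group(gene)
            hit = rows[rows["is_de"]]
            if len(hit) and cls == "similar":
                cls = "changed_tissues"
            if len(hit):
                tissues = frozenset(hit["tissue"])
                direction = dict(zip(hit["tissue"], hit["direction"]))
        out.append(DEClassification(gene, strain_pair, cls, tissues, direction))
    return out


def compute_tau(values, config: AnalysisConfig,
                gene_id: str = "", tissue_names=None) -> TauResult:
    """Tissue-specificity index for one gene's tissue vector.

    Negative values are clamped to 0. An all-zero vector has undefined tau
    (returned as NaN, eligible False).
    """
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    n = v.size
    if n < 2:
        raise ValueError("compute_tau needs >= 2 tissues")
    vmax = float(v.max())
    if tissue_names is None:
        tissue_names = [f"t{i}" for i in range(n)]
    if vmax <= 0:
        return TauResult(gene_id, float("nan"), n, "", False)
    x = v / vmax
    tau = float(np.sum(1.0 - x) / (n - 1))
    imax = int(np.argmax(v))  # ties -> first tissue in order
    return TauResult(gene_id, tau, n, str(tissue_names[imax]),
                     vmax > config.expr_threshold)


def compute_tau_table(atlas: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Vectorized tau over a whole atlas; one row per gene."""
    v = np.clip(atlas.to_numpy(dtype=float), 0.0, None)
    n = v.shape[1]
    vmax = v.max(axis=1)
    safe = np.where(vmax > 0, vmax, 1.0)
    tau = (1.0 - v / safe[:, None]).sum(axis=1) / (n - 1)
    tau = np.where(vmax > 0, tau, np.nan)
    return pd.DataFrame({
        "gene_id": atlas.index,
        "tau": tau,
        "n_tissues": n,
        "max_tissue": atlas.columns.to_numpy()[np.argmax(v, axis=1)],
        "eligible": vmax > config.expr_threshold,
    }).set_index("gene_id")


def tau_window_profile(tau_results: pd.DataFrame, flag_set: set[str],
                       window: float = 0.1, step: float = 0.05) -> pd.DataFrame:
    """Percent of flagged genes in sliding tau windows over [0, 1].

    Only eligible genes are binned; empty windows emit no row.
    """
    elig = tau_results[tau_results["eligible"]]
    tau = elig["tau"].to_numpy()
    flagged = elig.index.isin(list(flag_set))
    rows = []
    start = 0.0
    while start < 1.0 - 1e-12:
        hi = start + window
        inside = (tau >= start) & (tau < hi if hi < 1.0 else tau <= 1.0)
        if inside.sum():
            rows.append((start + window / 2.0, int(inside.sum()),
                         100.0 * flagged[inside].mean()))
        start += step
    return pd.DataFrame(rows, columns=["window_center", "n_genes", "pct_flagged"])


def specific_gene_regression(points, exclude: set[int] | None = None
                             ) -> tuple[float, float]:
    """Least-squares line through the origin for (x, y) count pairs.

    slope = sum(xy)/sum(x^2); R^2 uses the uncentered through-origin
    convention 1 - SS_res / sum(y^2). Optional index-based exclusion of
    outlier points.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if exclude:
        pts = [p for i, p in enumerate(pts) if i not in exclude]
    if len(pts) < 2:
        raise ValueError("regression needs >= 2 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x values are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    ss_res = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 if syy == 0 else 1.0 - ss_res / syy
    return slope, r2


def atlas_highest(atlas: pd.DataFrame) -> pd.Series:
    """Tissue of maximum expression per gene (ties -> first tissue, logged)."""
    v = atlas.to_numpy(dtype=float)
    imax = np.argmax(v, axis=1)
    n_max = (v == v.max(axis=1, keepdims=True)).sum(axis=1)
    ties = n_max > 1
    if ties.any():
        log.info("atlas_highest: %d genes with tied maxima; first tissue kept",
                 int(ties.sum()))
    return pd.Series(atlas.columns.to_numpy()[imax], index=atlas.index,
                     name="max_tissue")


def relative_expression(atlas: pd.DataFrame, gene: str, tissue: str) -> float:
    """Expression in one tissue as percent of the gene's atlas maximum."""
    row = atlas.loc[gene]
    vmax = float(row.max())
    if vmax <= 0:
        raise ValueError(f"gene {gene!r}: atlas maximum is not positive")
    return 100.0 * float(row[tissue]) / vmax
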