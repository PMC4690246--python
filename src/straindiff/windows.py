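"""Sliding-window gene-density and flag-ratio profiles along chromosomes,
and cluster detection by the quartile rule.

Two window geometries are supported: fixed base-pair windows (default 1 Mb,
step 0.1 Mb) counting mapped genes, and gene-index windows (default 100
mapped genes, step 10) tracking the ratio of flagged genes to highly
expressed genes. A window is part of a cluster when its ratio exceeds
``cluster_ratio_factor`` times the third quartile of all window ratios and
its highly-expressed count exceeds the first quartile of highly-expressed
counts; overlapping flagged windows merge into maximal regions. A gene
belongs to a window iff its start coordinate lies in the half-open window
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import GeneLocus, ValidationError


@dataclass(frozen=True)
class ClusterRegion:
    chrom: str
    start: int
    end: int
    n_windows: int


def _by_chrom(loci: list[GeneLocus]) -> dict[str, list[GeneLocus]]:
    out: dict[str, list[GeneLocus]] = {}
    for l in loci:
        out.setdefault(l.chrom, []).append(l)
    for chrom in out:
        out[chrom].sort(key=lambda l: (l.start, l.gene_id))
    return out


def bp_windows(loci: list[GeneLocus], chrom_sizes: dict[str, int],
               window_bp: int, step_bp: int,
               flagged: set[str] | None = None) -> pd.DataFrame:
    """Gene counts in overlapping bp windows [k*step, k*step + window)."""
    flagged = flagged or set()
    rows = []
    grouped = _by_chrom(loci)
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        genes = grouped.get(chrom, [])
        for g in genes:
            if g.start >= size:
                raise ValidationError(
                    f"gene {g.gene_id!r} at {g.start} beyond {chrom} size {size}")
        starts = np.array([g.start for g in genes], dtype=int)
        is_flag = np.array([g.gene_id in flagged for g in genes], dtype=bool)
        w_start = 0
        while w_start < size:
            w_end = w_start + window_bp
            inside = (starts >= w_start) & (starts < w_end)
            rows.append((chrom, w_start, w_end, int(inside.sum()),
                         int(is_flag[inside].sum())))
            w_start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_mapped",
                                       "n_flagged"])


def gene_index_windows(loci: list[GeneLocus], highly_expressed: set[str],
                       flagged: set[str], window_genes: int,
                       step_genes: int) -> pd.DataFrame:
    """Flag ratios per ``window_genes`` mapped genes, per chromosome.

    Trailing windows with fewer than ``window_genes`` genes are dropped.
    ``ratio`` is n_flagged / n_highly_expressed (NaN when the window has no
    highly expressed genes). Requires flagged to be a subset of
    highly_expressed.
    """
    extra = flagged - highly_expressed
    if extra:
        raise ValidationError(
            f"{len(extra)} flagged genes not in the highly-expressed set "
            f"(e.g. {sorted(extra)[0]!r})")
    rows = []
    for chrom, genes in sorted(_by_chrom(loci).items()):
        ids = [g.gene_id for g in genes]
        he = np.array([g in highly_expressed for g in ids], dtype=int)
        fl = np.array([g in flagged for g in ids], dtype=int)
        che = np.concatenate([[0], np.cumsum(he)])
        cfl = np.concatenate([[0], np.cumsum(fl)])
        i = 0
        while i + window_genes <= len(genes):
            j = i + window_genes
            n_he = int(che[j] - che[i])
            n_fl = int(cfl[j] - cfl[i])
            rows.append((chrom, genes[i].start, genes[j - 1].end, window_genes,
                         n_he, n_fl,
                         n_fl / n_he if n_he else float("nan")))
            i += step_genes
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_mapped",
                                       "n_highly_expressed", "n_flagged",
                                       "ratio"])


def detect_clusters(profile: pd.DataFrame,
                    config: AnalysisConfig) -> list[ClusterRegion]:
    """Flag windows by the quartile rule and merge overlaps into regions.

    A window is flagged iff ratio > cluster_ratio_factor * Q3(ratios) and
    n_highly_expressed > Q1(highly-expressed counts); quartiles use linear
    interpolation between order statistics. Needs >= 4 windows.
    """
    if len(profile) < 4:
        raise ValueError("detect_clusters needs >= 4 windows")
    ratios = profile["ratio"].to_numpy(dtype=float)
    he = profile["n_highly_expressed"].to_numpy(dtype=float)
    defined = ~np.isnan(ratios)
    q3 = float(np.percentile(ratios[defined], 75)) if defined.any() else 0.0
    q1_he = float(np.percentile(he, 25))
    hit = defined & (ratios > config.cluster_ratio_factor * q3) & (he > q1_he)

    regions: list[ClusterRegion] = []
    cur = None
    for idx in np.flatnonzero(hit):
        row = profile.iloc[idx]
        if (cur is not None and row["chrom"] == cur[0]
                and row["start"] <= cur[2]):
            cur = (cur[0], cur[1], max(cur[2], int(row["end"])), cur[3] + 1)
        else:
            if cur is not None:
                regions.append(ClusterRegion(*cur))
            cur = (row["chrom"], int(row["start"]), int(row["end"]), 1)
    if cur is not None:
        regions.append(ClusterRegion(*cur))
    return regions
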