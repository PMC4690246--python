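"""Analysis configuration: every threshold the pipeline applies, in one place.

All intensities are log2-scale throughout the package. ``expr_threshold`` is
the "highly expressed" cutoff (strictly greater than), ``fold_threshold`` the
linear fold-change cutoff (strictly greater than), and the alpha values are
raw, uncorrected test levels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and tuning knobs shared by every pipeline stage.

    Attributes
    ----------
    expr_threshold:
        log2 intensity above which a gene counts as highly expressed
        (strict ``>``; a value of exactly ``expr_threshold`` is *not*
        expressed — "did not exceed" semantics for silent calls).
    fold_threshold:
        Linear fold change a DE call must strictly exceed.
    de_alpha, sfp_alpha:
        Test levels for the transcript-level DE test and the per-probe
        SFP test (two-sided, uncorrected).
    tau_specific:
        Tissue-specificity index above which a gene counts as
        tissue-specifically expressed.
    kaks_conserved, kaks_rapid:
        Ka/Ks class boundaries: conserved < 0.75 <= neutral < 1.25 <= rapid.
    window_bp, step_bp, window_genes, step_genes:
        Sliding-window geometry for genome-distribution profiles.
    cluster_ratio_factor:
        A window is a candidate cluster when its flagged/highly-expressed
        ratio exceeds this multiple of the third quartile of all ratios.
    dendrogram_cut:
        Height at which the array dendrogram is cut into clusters.
    go_min_genes:
        Annotation terms are tested only when strictly more than this many
        background genes carry the term.
    enrich_alpha:
        Enrichment significance level (raw p).
    eqtl_high, eqtl_low:
        Percent summed variance-explained cutoffs separating the
        well-explained (> high) and unexplained (< low) gene groups.
    rel_expr_cap:
        Percent-of-atlas-maximum cap used when asking whether differential
        expression occurred in a gene's highest-expression tissue.
    cis_margin_bp:
        An eQTL counts as cis when its interval overlaps the gene body
        expanded by this margin.
    already_log2:
        If false, input intensities are log2-transformed (floored at 0)
        on read.
    seed:
        Root seed for every stochastic component.
    """

    expr_threshold: float = 7.0
    fold_threshold: float = 2.5
    de_alpha: float = 0.05
    sfp_alpha: float = 0.001
    tau_specific: float = 0.8
    kaks_conserved: float = 0.75
    kaks_rapid: float = 1.25
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    window_genes: int = 100
    step_genes: int = 10
    cluster_ratio_factor: float = 3.0
    dendrogram_cut: float = 0.75
    go_min_genes: int = 5
    enrich_alpha: float = 0.01
    eqtl_high: float = 80.0
    eqtl_low: float = 40.0
    rel_expr_cap: float = 95.0
    cis_margin_bp: int = 1_000_000
    already_log2: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "expr_threshold fold_threshold de_alpha sfp_alpha tau_specific "
            "kaks_conserved kaks_rapid window_bp step_bp window_genes "
            "step_genes cluster_ratio_factor dendrogram_cut go_min_genes "
            "enrich_alpha eqtl_high eqtl_low rel_expr_cap"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.kaks_conserved >= self.kaks_rapid:
            raise ValueError("kaks_conserved must be < kaks_rapid")
        if self.eqtl_low >= self.eqtl_high:
            raise ValueError("eqtl_low must be < eqtl_high")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
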