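"""Readers, writers and shared domain types for the pipeline's tabular and
sequence formats.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines. Gene
coordinates follow the BED convention (0-based, half-open) everywhere,
including outputs. Intensity tables are log2 scale; raw-scale input is only
converted when the config says ``already_log2: false``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import AnalysisConfig

log = logging.getLogger(__name__)

MAPPING_COLUMNS = ["AffyID", "ProbeNumber", "NewTranscriptName", "NewProbeNumber"]


class FormatError(ValueError):
    """Malformed file structure (bad header, non-numeric cell, bad record)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class ProbeIntensityTable:
    """Probe x array matrix of log2 intensities with probe -> transcript
    grouping.

    ``values`` is indexed by probe_id with one column per array_id;
    ``transcript`` maps each probe_id to its transcript group. Every
    transcript group has >= 3 probes (smaller sets are dropped on read:
    transcripts targeted by fewer than three unique probes are not
    analyzable).
    """

    values: pd.DataFrame
    transcript: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe_id in intensity table")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate array_id in intensity table")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite intensity values")
        if not self.values.index.equals(self.transcript.index):
            raise ValidationError("probe ids of values and transcript mapping differ")
        sizes = self.transcript.value_counts()
        small = sizes[sizes < 3]
        if len(small):
            raise ValidationError(
                f"{len(small)} transcript groups with < 3 probes (e.g. "
                f"{small.index[0]!r}); drop them before constructing the table"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def array_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def transcripts(self) -> list[str]:
        return list(dict.fromkeys(self.transcript))

    def groups(self):
        """Yield (transcript_id, probe index array into values.values)."""
        codes, uniques = pd.factorize(self.transcript.to_numpy())
        order = np.argsort(codes, kind="stable")
        bounds = np.searchsorted(codes[order], np.arange(len(uniques) + 1))
        for i, t in enumerate(uniques):
            yield t, order[bounds[i]:bounds[i + 1]]


@dataclass
class SampleSheet:
    """array -> (strain, tissue, replicate) assignment."""

    frame: pd.DataFrame  # columns: array_id, strain, tissue, replicate

    def __post_init__(self) -> None:
        need = ["array_id", "strain", "tissue", "replicate"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns {missing}")
        if self.frame["array_id"].duplicated().any():
            raise ValidationError("duplicate array_id in sample sheet")
        key = self.frame[["strain", "tissue", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (strain, tissue, replicate) in sample sheet")
        if (self.frame["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive")

    def arrays_for(self, strain: str, tissue: str) -> list[str]:
        f = self.frame
        sel = f[(f["strain"] == strain) & (f["tissue"] == tissue)]
        return sel.sort_values("replicate")["array_id"].tolist()

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.frame["strain"]))

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.frame["tissue"]))


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read the probe -> transcript mapping table.

    Columns AffyID, ProbeNumber, NewTranscriptName, NewProbeNumber; a header
    row is accepted but not required (detected from the first line). The
    probe key matched against intensity-table probe ids is
    ``{AffyID}_{ProbeNumber}``.
    """
    first = pd.read_csv(path, sep="\t", comment="#", header=None, nrows=1)
    has_header = str(first.iloc[0, 0]).strip() == "AffyID"
    df = _read_tsv(path, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise FormatError(
            f"mapping table {path}: expected 4 columns {MAPPING_COLUMNS}, "
            f"got {df.shape[1]}"
        )
    df = df.iloc[:, :4]
    df.columns = MAPPING_COLUMNS
    df["probe_key"] = df["AffyID"].astype(str) + "_" + df["ProbeNumber"].astype(str)
    return df


def read_probe_table(path: str | Path, mapping_path: str | Path,
                     config: AnalysisConfig | None = None) -> ProbeIntensityTable:
    """Read a probe x array intensity TSV plus its probe -> transcript mapping.

    First column is the probe id; the header row carries array ids. Probes
    without a mapping entry are dropped (count logged), then transcript
    groups left with < 3 probes are dropped (count logged).
    """
    config = config or AnalysisConfig()
    df = _read_tsv(path, index_col=0)
    df.index.name = "probe_id"
    if df.columns.size == 0:
        raise FormatError(f"{path}: no array columns in header")
    if df.columns.str.match(r"^Unnamed").any():
        raise FormatError(f"{path}: malformed header (unnamed columns)")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
    if df.isna().any().any():
        cell = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at row {df.index[cell[0]]!r}, "
            f"column {df.columns[cell[1]]!r}"
        )
    if not config.already_log2:
        df = np.log2(df.clip(lower=1.0))

    mapping = read_mapping(mapping_path)
    probe_to_transcript = mapping.set_index("probe_key")["NewTranscriptName"]
    probe_to_transcript = probe_to_transcript[~probe_to_transcript.index.duplicated()]

    n_in = len(df)
    mapped = df.index.intersection(probe_to_transcript.index)
    n_unmapped = n_in - len(mapped)
    if n_unmapped:
        log.info("read_probe_table: dropped %d/%d probes lacking a mapping entry",
                 n_unmapped, n_in)
    df = df.loc[mapped]
    transcript = probe_to_transcript.loc[mapped].astype(str)

    sizes = transcript.value_counts()
    keep_t = sizes[sizes >= 3].index
    small = sizes.index.difference(keep_t)
    if len(small):
        log.info("read_probe_table: dropped %d transcripts with < 3 probes "
                 "(%d probes)", len(small), int(sizes[small].sum()))
    keep = transcript.isin(keep_t)
    values = df.loc[keep]
    values.index.name = "probe_id"
    transcript = transcript[keep]
    transcript.index.name = "probe_id"
    return ProbeIntensityTable(values=values, transcript=transcript)


def write_probe_table(path: str | Path, table: ProbeIntensityTable) -> None:
    out = table.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_mapping(path: str | Path, transcript: pd.Series) -> None:
    """Write a minimal mapping table for probe ids of the form ``{affy}_{n}``."""
    affy, num = zip(*(p.rsplit("_", 1) for p in transcript.index))
    df = pd.DataFrame({
        "AffyID": affy,
        "ProbeNumber": num,
        "NewTranscriptName": transcript.to_numpy(),
        "NewProbeNumber": num,
    })
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(_read_tsv(path, dtype={"array_id": str, "strain": str,
                                              "tissue": str}))


def write_sample_sheet(path: str | Path, sheet: SampleSheet) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Read BED4 (chrom, start, end, gene_id); 0-based half-open."""
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 needs 4 columns")
            chrom, start, end, gene = parts[:4]
            locus = GeneLocus(gene, chrom, int(start), int(end))
            if gene in seen:
                raise ValidationError(f"{path}:{ln}: duplicated gene id {gene!r}")
            seen.add(gene)
            loci.append(locus)
    return loci


def write_bed(path: str | Path, loci: list[GeneLocus]) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene_id}\n")


def read_fasta_pairs(path_a: str | Path, path_b: str | Path
                     ) -> list[tuple[str, str, str]]:
    """Pair FASTA records across two files by identical ids.

    Returns (gene_id, cds_a, cds_b) for the shared ids, in file-A order;
    unmatched ids on either side are reported via logging.
    """
    a = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path_a), "fasta")}
    b = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path_b), "fasta")}
    only_a = [k for k in a if k not in b]
    only_b = [k for k in b if k not in a]
    if only_a:
        log.warning("read_fasta_pairs: %d ids only in %s (e.g. %r)",
                    len(only_a), path_a, only_a[0])
    if only_b:
        log.warning("read_fasta_pairs: %d ids only in %s (e.g. %r)",
                    len(only_b), path_b, only_b[0])
    return [(k, a[k], b[k]) for k in a if k in b]


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read gene<TAB>term lines into a gene -> set-of-terms map."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected gene<TAB>term")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def read_eqtl_records(path: str | Path) -> pd.DataFrame:
    """Read per-gene eQTL records: gene_id, chrom, start, end, var_explained
    (percent)."""
    df = _read_tsv(path, dtype={"gene_id": str, "chrom": str})
    need = ["gene_id", "chrom", "start", "end", "var_explained"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: eQTL table missing columns {missing}")
    if (df["var_explained"] < 0).any():
        raise ValidationError(f"{path}: negative var_explained")
    return df


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue atlas matrix (first column gene_id)."""
    df = _read_tsv(path, index_col=0)
    if not np.isfinite(df.to_numpy()).all():
        raise ValidationError(f"{path}: non-finite atlas values")
    return df


def write_atlas(path: str | Path, atlas: pd.DataFrame) -> None:
    out = atlas.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_results(path: str | Path, table: pd.DataFrame) -> None:
    """Write a results table with a stable column order and no index."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
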