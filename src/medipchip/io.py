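"""Readers and writers for the on-disk formats used throughout the pipeline.

All genomic intervals are 0-based, half-open (BED convention); a region's
size is always ``end - start``.  Tables are tab-separated UTF-8 with a header
row and ``.`` for missing values.  FASTA output is wrapped at 60 columns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

DESIGN_COLUMNS = ["chrom", "start", "end", "probe_id", "gc", "promoter_id", "gene_symbol"]

#: Column order of the published intersection-DMR tables.
DMR_TABLE_COLUMNS = ["Gene Symbol", "Significance", "Chr", "Start", "End", "Region size(bp)"]

#: Permitted probe length range for NimbleGen-style promoter tiling designs.
PROBE_LEN_RANGE = (50, 75)


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


# ---------------------------------------------------------------------------
# Probe designs
# ---------------------------------------------------------------------------

@dataclass
class ProbeDesign:
    """Genomic layout of a promoter tiling array.

    ``probes`` has columns chrom, start, end, probe_id, gc, promoter_id,
    gene_symbol and is sorted by (chrom, start).  One promoter is tiled by a
    contiguous block of probes covering the window around its TSS.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes.reset_index(drop=True)
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"probe design missing columns: {missing}")
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            pid = bad.iloc[0]["probe_id"]
            raise FormatError(f"probe {pid!r} has start >= end")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        if not df.sort_values(["chrom", "start"], kind="mergesort").equals(df):
            log.warning("probe design not sorted by (chrom, start); sorting")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        lengths = df["end"] - df["start"]
        lo, hi = PROBE_LEN_RANGE
        n_odd = int(((lengths < lo) | (lengths > hi)).sum())
        if n_odd:
            log.warning("%d probes outside the %d-%d nt length range", n_odd, lo, hi)
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise FormatError("probe GC fraction outside [0, 1]")
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    def midpoints(self) -> np.ndarray:
        p = self.probes
        return ((p["start"].to_numpy() + p["end"].to_numpy()) // 2).astype(np.int64)

    def promoter_bounds(self) -> pd.DataFrame:
        """Tiled extent of each promoter: (chrom, start, end, gene_symbol)."""
        g = self.probes.groupby("promoter_id", sort=False)
        out = g.agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            gene_symbol=("gene_symbol", "first"),
        )
        return out

    def chromosomes(self) -> list[str]:
        return sorted(self.probes["chrom"].unique().tolist())


def read_design(path: str | Path) -> ProbeDesign:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_symbol": str}, na_values=["."])
    return ProbeDesign(df[DESIGN_COLUMNS] if set(DESIGN_COLUMNS) <= set(df.columns) else df)


def write_design(design: ProbeDesign, path: str | Path) -> None:
    design.probes[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# Comparative two-channel arrays
# ---------------------------------------------------------------------------

@dataclass
class ComparativeArray:
    """One paired hybridization: treated and control channel intensities.

    ``data`` is indexed by probe_id with float columns ``treated`` and
    ``control`` (raw linear-scale intensities, strictly positive).
    """

    comparison_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("treated", "control"):
            if col not in self.data.columns:
                raise FormatError(f"intensity table lacks column {col!r}")
        nonpos = self.data[(self.data["treated"] <= 0) | (self.data["control"] <= 0)]
        if len(nonpos):
            raise FormatError(
                f"nonpositive intensity for probe {nonpos.index[0]!r} "
                f"in comparison {self.comparison_id}"
            )

    def matches_design(self, design: ProbeDesign) -> bool:
        return set(self.data.index) == set(design.probe_ids)


def read_intensities(path: str | Path, comparison_id: str | None = None) -> ComparativeArray:
    df = pd.read_csv(path, sep="\t").set_index("probe_id")
    df = df.rename(columns={"cy5_treated": "treated", "cy3_control": "control"})
    cid = comparison_id or Path(path).stem
    return ComparativeArray(cid, df[["treated", "control"]].astype(float))


def write_intensities(array: ComparativeArray, path: str | Path) -> None:
    out = array.data.rename(columns={"treated": "cy5_treated", "control": "cy3_control"})
    out = out[["cy3_control", "cy5_treated"]]
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with treatment and batch factors."""

    values: pd.DataFrame                     # genes x samples, log2 scale
    treatment: pd.Series                     # sample -> treatment label
    batch: pd.Series                         # sample -> batch label

    def __post_init__(self) -> None:
        samples = self.values.columns
        for name, factor in (("treatment", self.treatment), ("batch", self.batch)):
            missing = samples.difference(factor.index)
            if len(missing):
                raise FormatError(f"samples missing a {name} label: {list(missing)}")
            if factor.loc[samples].isna().any():
                raise FormatError(f"NA {name} label")
        counts = self.treatment.loc[samples].value_counts()
        if (counts < 2).any():
            raise FormatError("each treatment level needs >= 2 samples")
        self.treatment = self.treatment.loc[samples]
        self.batch = self.batch.loc[samples]


def read_expression(matrix_path: str | Path, sample_sheet_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str).set_index("sample")
    return ExpressionMatrix(values, sheet["treatment"], sheet["batch"])


def write_expression(mat: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path) -> None:
    mat.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    sheet = pd.DataFrame({"treatment": mat.treatment, "batch": mat.batch})
    sheet.to_csv(sample_sheet_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# DMR tables (published-table layout) and BED/FASTA export
# ---------------------------------------------------------------------------

@dataclass
class DmrRecord:
    gene_symbol: str
    chrom: str
    start: int
    end: int
    p_value: float
    analysis_mode: str = "intersection"      # intersection | average | single
    stage_label: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"DMR {self.gene_symbol}: start >= end")

    @property
    def region_size(self) -> int:
        return self.end - self.start


def dmr_records_to_frame(records: Iterable[DmrRecord]) -> pd.DataFrame:
    rows = [
        {
            "Gene Symbol": r.gene_symbol,
            "Significance": r.p_value,
            "Chr": r.chrom,
            "Start": r.start,
            "End": r.end,
            "Region size(bp)": r.region_size,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DMR_TABLE_COLUMNS)


def write_dmr_table(records: list[DmrRecord], path: str | Path,
                    bed_path: str | Path | None = None) -> None:
    """Write a DMR table in the published column order, plus a companion BED.

    The BED file (``<path stem>.bed`` unless given) carries identical
    intervals with the gene symbol as the name field.
    """
    path = Path(path)
    dmr_records_to_frame(records).to_csv(path, sep="\t", index=False)
    bed_path = Path(bed_path) if bed_path is not None else path.with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_symbol}\n")


def read_dmr_table(path: str | Path) -> list[DmrRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    records = []
    for _, row in df.iterrows():
        rec = DmrRecord(
            gene_symbol=str(row["Gene Symbol"]),
            chrom=str(row["Chr"]),
            start=int(row["Start"]),
            end=int(row["End"]),
            p_value=float(row["Significance"]),
        )
        if "Region size(bp)" in df.columns and int(row["Region size(bp)"]) != rec.region_size:
            log.warning("DMR %s: printed size %s != end-start %d",
                        rec.gene_symbol, row["Region size(bp)"], rec.region_size)
        records.append(rec)
    return records


_DMR_ID_RE = re.compile(r"^(?P<gene>.+)\|(?P<chrom>[^:|]+):(?P<start>\d+)-(?P<end>\d+)$")


def dmr_fasta_id(record: DmrRecord) -> str:
    return f"{record.gene_symbol}|{record.chrom}:{record.start}-{record.end}"


def parse_dmr_fasta_id(identifier: str) -> tuple[str, str, int, int]:
    m = _DMR_ID_RE.match(identifier)
    if m is None:
        raise FormatError(f"not a DMR FASTA id: {identifier!r}")
    return m["gene"], m["chrom"], int(m["start"]), int(m["end"])


def export_dmr_fasta(records: list[DmrRecord], genome: Mapping[str, str],
                     path: str | Path | None = None) -> list[SeqRecord]:
    """Extract each DMR's sequence for downstream motif tools (GLAM2/MEME).

    ``genome`` maps contig name to sequence string (load a FASTA with
    :func:`read_fasta`).  Record ids are ``gene|chrom:start-end``.
    """
    out: list[SeqRecord] = []
    for r in records:
        if r.chrom not in genome:
            raise FormatError(f"DMR {r.gene_symbol}: contig {r.chrom!r} not in genome")
        seq = genome[r.chrom]
        if r.end > len(seq):
            raise FormatError(
                f"DMR {r.gene_symbol}: interval {r.start}-{r.end} outside contig "
                f"{r.chrom!r} (length {len(seq)})"
            )
        out.append(SeqRecord(Seq(seq[r.start:r.end]), id=dmr_fasta_id(r), description=""))
    if path is not None:
        write_fasta(out, path)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def builtin_dmr_table() -> Path:
    """Path to the shipped published E13 germ-cell intersection-DMR table."""
    return Path(__file__).parent / "data" / "e13_pgc_intersection_dmrs.tsv"
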