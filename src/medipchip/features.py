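"""Genomic features of called DMRs: CpG density and chromosome distribution.

The CpG density of a region is the number of CG dinucleotides per 100 bp.
CG cannot overlap itself, so counting every position i with seq[i:i+2] ==
"CG" equals non-overlapping counting.  The denominator is the region length
in bp (not length - 1); the difference is negligible and this matches the
per-bp usage of "CpG/100bp".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DmrRecord, ProbeDesign


@dataclass
class CpGDensity:
    region_id: str
    cpg_count: int
    length: int

    @property
    def density(self) -> float:
        """CpG sites per 100 bp."""
        return 100.0 * self.cpg_count / self.length


def cpg_density(seq: str, region_id: str = ".") -> CpGDensity:
    """Count CG dinucleotides in a sequence (case-insensitive; N never matches)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = seq.upper()
    if set(s) - set("ACGTN"):
        raise ValueError("sequence contains letters outside {A,C,G,T,N}")
    return CpGDensity(region_id, s.count("CG"), len(s))


def dmr_cpg_table(records: list[DmrRecord], genome: dict[str, str]) -> pd.DataFrame:
    """Per-DMR CpG count, length and density (CpG/100bp)."""
    rows = []
    for r in records:
        d = cpg_density(genome[r.chrom][r.start:r.end], r.gene_symbol)
        rows.append({"gene_symbol": r.gene_symbol, "chrom": r.chrom,
                     "start": r.start, "end": r.end,
                     "cpg_count": d.cpg_count, "length": d.length,
                     "density": d.density})
    return pd.DataFrame(rows)


def density_histogram(densities: list[float] | np.ndarray,
                      bin_width: float = 1.0) -> pd.DataFrame:
    """Counts per [k*w, (k+1)*w) density bin, plus the mean density.

    The mean is attached as a DataFrame attribute ``mean_density``.
    """
    d = np.asarray(densities, dtype=float)
    if len(d) == 0:
        out = pd.DataFrame(columns=["bin_start", "bin_end", "count"])
        out.attrs["mean_density"] = float("nan")
        return out
    k = np.floor(d / bin_width).astype(int)
    idx = np.arange(k.min(), k.max() + 1)
    counts = pd.Series(k).value_counts().reindex(idx, fill_value=0).sort_index()
    out = pd.DataFrame({"bin_start": idx * bin_width,
                        "bin_end": (idx + 1) * bin_width,
                        "count": counts.to_numpy()})
    out.attrs["mean_density"] = float(d.mean())
    return out


def chromosome_distribution(records: list[DmrRecord],
                            design: ProbeDesign | None = None,
                            chromosomes: list[str] | None = None) -> pd.Series:
    """DMR count per chromosome, zero-filled over the design's chromosomes."""
    if chromosomes is None:
        chromosomes = design.chromosomes() if design is not None else []
    counts: dict[str, int] = {c: 0 for c in chromosomes}
    for r in records:
        counts[r.chrom] = counts.get(r.chrom, 0) + 1
    out = pd.Series(counts, name="n_dmr").sort_index()
    out.index.name = "chrom"
    return out
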