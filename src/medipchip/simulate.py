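"""Synthetic two-color promoter tiling-array experiments with known truth.

The generator emulates a NimbleGen-style promoter methylation array: each
promoter is tiled from 3,880 bp upstream to 970 bp downstream of its TSS with
50-75 nt probes at a median spacing of 100 bp, and an experiment consists of
three paired treatment-vs-control comparative hybridizations.  Differential
methylation is planted as an additive shift (in M units, i.e. log2 ratio) on
probes inside chosen promoter subregions of >= 600 bp, and a smooth
GC-by-intensity dye bias is injected so that the normalization stage has
something real to remove.  Every generator is a pure function of its
configuration and seed, and everything planted is recorded in a ground-truth
manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import ComparativeArray, ExpressionMatrix, ProbeDesign

log = logging.getLogger(__name__)

#: Gap left between consecutive promoter tiles on a simulated chromosome.
_TILE_GAP = 5000


@dataclass
class SimConfig:
    """Parameters of a simulated MeDIP-chip experiment.

    Lengths are bp; ``effect_size`` is the planted methylation difference in
    M units (log2 ratio); ``noise_sd`` is the per-channel log2 intensity
    noise; ``gc_bias_amplitude`` scales the injected dye bias.
    """

    n_promoters: int = 200
    n_chromosomes: int = 20
    upstream_bp: int = 3880
    downstream_bp: int = 970
    probe_len_range: tuple[int, int] = (50, 75)
    probe_spacing_bp: int = 100
    n_comparisons: int = 3
    dmr_fraction: float = 0.1
    dmr_len_range: tuple[int, int] = (600, 1200)
    effect_size: float = 1.0
    gc_bias_amplitude: float = 0.3
    noise_sd: float = 0.2
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters <= 0:
            raise ValueError("n_promoters must be positive")
        if not 0.0 <= self.dmr_fraction <= 1.0:
            raise ValueError("dmr_fraction must lie in [0, 1]")
        if self.upstream_bp + self.downstream_bp < self.dmr_len_range[1]:
            raise ValueError("promoter window shorter than the longest planted DMR")
        if self.probe_spacing_bp < self.probe_len_range[1]:
            log.warning("probe spacing %d < max probe length %d: probes may overlap",
                        self.probe_spacing_bp, self.probe_len_range[1])

    @property
    def window_bp(self) -> int:
        return self.upstream_bp + self.downstream_bp


@dataclass
class GroundTruthManifest:
    """Everything planted by a generator, sufficient to score calls against.

    ``planted_dmrs`` columns: promoter_id, gene_symbol, chrom, start, end,
    effect_size.  ``planted_de_genes`` columns: gene_id, fold_change,
    direction.  ``batch_assignments`` maps sample -> batch.
    """

    planted_dmrs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["promoter_id", "gene_symbol", "chrom", "start", "end", "effect_size"]))
    planted_de_genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "fold_change", "direction"]))
    batch_assignments: dict[str, str] = field(default_factory=dict)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.planted_dmrs.to_csv(prefix.with_suffix(".dmrs.tsv"), sep="\t", index=False)
        self.planted_de_genes.to_csv(prefix.with_suffix(".de.tsv"), sep="\t", index=False)
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump({"batch_assignments": self.batch_assignments}, fh, indent=1)

    @classmethod
    def read(cls, prefix: str | Path) -> "GroundTruthManifest":
        prefix = Path(prefix)
        dmrs = pd.read_csv(prefix.with_suffix(".dmrs.tsv"), sep="\t",
                           dtype={"chrom": str, "promoter_id": str})
        de = pd.read_csv(prefix.with_suffix(".de.tsv"), sep="\t", dtype={"gene_id": str})
        with open(prefix.with_suffix(".json")) as fh:
            batches = json.load(fh)["batch_assignments"]
        return cls(dmrs, de, batches)


# ---------------------------------------------------------------------------
# Probe design
# ---------------------------------------------------------------------------

def generate_design(cfg: SimConfig) -> ProbeDesign:
    """Tile every promoter window with probes at the configured spacing.

    Promoters are assigned round-robin to chromosomes and laid out left to
    right with a fixed gap between tiles.  Probe starts advance by the median
    spacing; a probe is placed only if it fits inside the promoter window, so
    a 4,850 bp window at 100 bp spacing carries 48-49 probes depending on the
    drawn length of the last one.  GC content is drawn per probe from a
    Beta-shaped distribution spanning 0.25-0.75.
    """
    rng = np.random.default_rng(cfg.seed)
    lo_len, hi_len = cfg.probe_len_range
    span = cfg.window_bp
    rows: list[tuple] = []
    # running right edge per chromosome
    cursor = {f"chr{c + 1}": _TILE_GAP for c in range(cfg.n_chromosomes)}
    for p in range(cfg.n_promoters):
        chrom = f"chr{p % cfg.n_chromosomes + 1}"
        win_start = cursor[chrom]
        win_end = win_start + span
        cursor[chrom] = win_end + _TILE_GAP
        promoter_id = f"P{p:05d}"
        gene = f"Gene{p:05d}"
        k = 0
        for off in range(0, span, cfg.probe_spacing_bp):
            length = int(rng.integers(lo_len, hi_len + 1))
            start = win_start + off
            if start + length > win_end:
                continue
            gc = 0.25 + 0.5 * rng.beta(2.0, 2.0)
            rows.append((chrom, start, start + length, f"{promoter_id}_{k:03d}",
                         round(float(gc), 4), promoter_id, gene))
            k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "gc",
                                     "promoter_id", "gene_symbol"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ProbeDesign(df)


# ---------------------------------------------------------------------------
# MeDIP comparative hybridizations
# ---------------------------------------------------------------------------

def _dye_bias(gc: np.ndarray, a_level: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth additive M bias: stronger at high mean intensity, signed by GC.

    b(GC, A) = amplitude * (GC - 0.5) * sigmoid(A - 10).  Any smooth form the
    GC-grouped loess can cancel would do; this one is monotone in both
    arguments and easy to test against.
    """
    s = 1.0 / (1.0 + np.exp(-(a_level - 10.0)))
    return amplitude * (gc - 0.5) * s


def generate_medip_experiment(
    design: ProbeDesign, cfg: SimConfig
) -> tuple[list[ComparativeArray], GroundTruthManifest]:
    """Simulate paired comparative hybridizations over a probe design.

    Each probe has a fixed baseline log2 intensity shared by both channels;
    per-channel Gaussian noise and a GC/intensity dye bias (split antisym-
    metrically between channels so it appears in M, not A) are added, and the
    treated channel gains ``effect_size`` log2 units on probes whose midpoint
    falls inside a planted DMR.  Exactly round(dmr_fraction * n_promoters)
    promoters receive one DMR each, placed uniformly inside the tiled window.
    """
    if len(design) == 0:
        raise ValueError("empty probe design")
    if cfg.effect_size == 0 and cfg.dmr_fraction > 0:
        warnings.warn("effect_size=0 with dmr_fraction>0: planted DMRs carry no signal")
    rng = np.random.default_rng(cfg.seed + 1)
    probes = design.probes
    n = len(probes)
    mids = design.midpoints()
    gc = probes["gc"].to_numpy()

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    # plant DMRs
    bounds = design.promoter_bounds()
    n_dmr = int(round(cfg.dmr_fraction * len(bounds)))
    chosen = rng.choice(bounds.index.to_numpy(), size=n_dmr, replace=False)
    dmr_rows = []
    in_dmr = np.zeros(n, dtype=bool)
    pid_arr = probes["promoter_id"].to_numpy()
    lo_len, hi_len = cfg.dmr_len_range
    for pid in sorted(chosen):
        b = bounds.loc[pid]
        length = int(rng.integers(lo_len, min(hi_len, b.end - b.start) + 1))
        start = int(rng.integers(b.start, b.end - length + 1))
        end = start + length
        dmr_rows.append({"promoter_id": pid, "gene_symbol": b.gene_symbol,
                         "chrom": b.chrom, "start": start, "end": end,
                         "effect_size": cfg.effect_size})
        in_dmr |= (pid_arr == pid) & (mids >= start) & (mids < end)

    arrays: list[ComparativeArray] = []
    for c in range(cfg.n_comparisons):
        noise_t = rng.normal(0.0, cfg.noise_sd, size=n)
        noise_c = rng.normal(0.0, cfg.noise_sd, size=n)
        bias = _dye_bias(gc, baseline, cfg.gc_bias_amplitude)
        log_t = baseline + noise_t + bias / 2.0 + np.where(in_dmr, cfg.effect_size, 0.0)
        log_c = baseline + noise_c - bias / 2.0
        data = pd.DataFrame(
            {"treated": np.exp2(log_t), "control": np.exp2(log_c)},
            index=pd.Index(probes["probe_id"], name="probe_id"),
        )
        arrays.append(ComparativeArray(f"C{c + 1}", data))

    manifest = GroundTruthManifest(
        planted_dmrs=pd.DataFrame(
            dmr_rows, columns=["promoter_id", "gene_symbol", "chrom", "start",
                               "end", "effect_size"]),
    )
    return arrays, manifest


# ---------------------------------------------------------------------------
# Sequences with controlled CpG density
# ---------------------------------------------------------------------------

def generate_sequences(
    regions: list[tuple[str, int, int]], cpg_per_100bp: float, seed: int
) -> list[SeqRecord]:
    """Random sequences with a controlled CpG dinucleotide density.

    ``regions`` are (name, start, end) intervals; each output sequence has
    length end-start and contains round(density * length / 100) CG
    dinucleotides, planted at random non-adjacent positions with all
    accidental CGs in the background removed.  Density is CpG per 100 bp and
    must lie in [0, 50] (50/100 bp, i.e. "CGCG...", is the physical maximum).
    """
    if not 0.0 <= cpg_per_100bp <= 50.0:
        raise ValueError("cpg_per_100bp must lie in [0, 50]")
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ACGT", dtype="S1")
    records: list[SeqRecord] = []
    for name, start, end in regions:
        length = end - start
        if length <= 0:
            raise ValueError(f"region {name!r} has nonpositive length")
        seq = rng.choice(letters, size=length)
        target = int(round(cpg_per_100bp * length / 100.0))
        planted: set[int] = set()
        if target > 0:
            # candidate start positions spaced >= 2 apart so planted CGs
            # cannot overlap; choose among even offsets for simplicity
            slots = np.arange(0, length - 1, 2)
            if target > len(slots):
                raise ValueError(f"region {name!r} too short for target CpG count")
            pos = rng.choice(slots, size=target, replace=False)
            seq[pos] = b"C"
            seq[pos + 1] = b"G"
            planted = set(int(i) for i in pos)
        # destroy background CGs (never touches a planted pair: a planted
        # position holds 'C', so it can never be the 'G' of another CG)
        s = seq.tobytes()
        i = s.find(b"CG")
        while i != -1:
            if i not in planted:
                seq[i + 1] = b"A"
                s = seq.tobytes()
            i = s.find(b"CG", i + 1)
        records.append(SeqRecord(Seq(seq.tobytes().decode()), id=str(name), description=""))
    return records


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int = 2000,
    samples_per_group: int = 3,
    n_batches: int = 3,
    de_fraction: float = 0.05,
    fc_range: tuple[float, float] = (1.5, 4.0),
    batch_sd: float = 0.4,
    noise_sd: float = 0.15,
    baseline_log2_range: tuple[float, float] = (6.0, 11.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """Simulate a log2 expression matrix with planted DE genes and batches.

    The design mirrors a three-replicates-per-treatment experiment whose
    biological replicates were prepared on different dates: samples are
    assigned to batches in a balanced way (each batch holds one control and
    one treated sample when ``n_batches == samples_per_group``), and every
    gene receives an additive N(0, batch_sd) offset per batch.  Planted DE
    genes are shifted by +/- log2(fc) in the treated group, fc drawn
    uniformly from ``fc_range``.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")
    n_samples = 2 * samples_per_group
    if n_samples % n_batches:
        raise ValueError("n_batches must divide the total sample count")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"Ctrl{i + 1}" for i in range(samples_per_group)] + \
              [f"Trt{i + 1}" for i in range(samples_per_group)]
    treatment = pd.Series(["control"] * samples_per_group + ["treated"] * samples_per_group,
                          index=samples, name="treatment")
    # balanced batches: replicate i of each group was prepared together
    batch_ids = [f"B{i % n_batches + 1}" for i in range(samples_per_group)] * 2
    batch = pd.Series(batch_ids, index=samples, name="batch")

    base = rng.uniform(*baseline_log2_range, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    fc = rng.uniform(*fc_range, size=n_de)
    up = rng.random(n_de) < 0.5
    shift = np.zeros(n_genes)
    shift[de_idx] = np.where(up, 1.0, -1.0) * np.log2(fc)

    batch_levels = sorted(set(batch_ids))
    batch_offsets = rng.normal(0.0, batch_sd, size=(n_genes, len(batch_levels)))
    col_batch = np.array([batch_levels.index(b) for b in batch_ids])
    treated_mask = (treatment.values == "treated").astype(float)

    values = (
        base[:, None]
        + shift[:, None] * treated_mask[None, :]
        + batch_offsets[:, col_batch]
        + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    )
    mat = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                           treatment, batch)
    manifest = GroundTruthManifest(
        planted_de_genes=pd.DataFrame({
            "gene_id": np.array(genes)[de_idx],
            "fold_change": fc,
            "direction": np.where(up, "up", "down"),
        }).sort_values("gene_id").reset_index(drop=True),
        batch_assignments=dict(zip(samples, batch_ids)),
    )
    return mat, manifest
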