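"""Significance and DMR calling on smoothed MeDIP tiling signal.

Smoothed probe M values are compared to an empirical normal null scaled to
the experimental mean and standard deviation of the signal; each probe gets
a Z-score and a two-sided p-value.  Probes below the cutoff (p < 1e-4 by
default, strict) are merged into sites (maximal runs of consecutive
significant probes within one promoter tile) and sites into per-promoter
DMRs.  Replicate comparisons are combined either by requiring a significant,
overlapping site in every comparison (intersection analysis) or by testing
the per-probe mean signal across comparisons (average analysis).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DmrRecord
from .normalize import SmoothedSignal

DEFAULT_P_CUTOFF = 1e-4


@dataclass
class NullModel:
    """Empirical normal null: mean and SD of the defined smoothed M values."""

    mu: float
    sigma: float
    n: int


@dataclass
class Site:
    """Maximal run of consecutive significant probes within one promoter."""

    chrom: str
    start: int
    end: int
    promoter_id: str
    gene_symbol: str
    probe_ids: list[str]
    min_p: float
    direction: int          # +1 hyper-, -1 hypomethylated (sign of mean z)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Site") -> bool:
        # sites live inside promoter tiles, which are disjoint; an overlap
        # across tiles is therefore also a promoter match
        return (self.promoter_id == other.promoter_id
                and self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class DmrCall:
    """A called DMR: the union of all sites within one promoter tile."""

    gene_symbol: str
    promoter_id: str
    chrom: str
    start: int
    end: int
    p_value: float
    direction: int
    analysis_mode: str
    sites: list[Site] = field(default_factory=list)
    comparison_support: dict[str, bool] = field(default_factory=dict)

    @property
    def region_size(self) -> int:
        return self.end - self.start

    def to_record(self, stage_label: str = ".") -> DmrRecord:
        return DmrRecord(self.gene_symbol, self.chrom, self.start, self.end,
                         self.p_value, self.analysis_mode, stage_label)


def fit_null(signal: SmoothedSignal) -> NullModel:
    """Fit the empirical null from all defined smoothed values (sample SD)."""
    vals = signal.defined()["m_smoothed"].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two defined smoothed values")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate signal: zero standard deviation")
    return NullModel(mu, sigma, len(vals))


def probe_significance(signal: SmoothedSignal, null: NullModel) -> pd.DataFrame:
    """Z-score and two-sided normal p-value per defined probe.

    Probes with no smoothed value are omitted.  p = 2 * (1 - Phi(|z|)).
    """
    d = signal.defined()
    z = (d["m_smoothed"].to_numpy(dtype=float) - null.mu) / null.sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"z": z, "p": p}, index=d.index)


def call_sites(sigs: pd.DataFrame, signal: SmoothedSignal,
               p_cutoff: float = DEFAULT_P_CUTOFF) -> list[Site]:
    """Merge consecutive significant probes into sites.

    Significance is strict (p < cutoff).  A run breaks at promoter-tile
    boundaries and at any intervening design probe that is undefined or not
    significant.  The site interval is the union of the member probes'
    smoothing windows, so a single significant probe yields a site exactly
    one window long.
    """
    df = signal.data.join(sigs, how="left")
    sig_mask = (df["p"] < p_cutoff).fillna(False).to_numpy()
    sites: list[Site] = []
    promoters = df["promoter_id"].to_numpy()
    for key, sub_idx in df.groupby("promoter_id", sort=False).indices.items():
        sub_idx = np.sort(sub_idx)
        run: list[int] = []
        for i in itertools.chain(sub_idx, [-1]):
            if i != -1 and sig_mask[i]:
                run.append(i)
                continue
            if run:
                rows = df.iloc[run]
                zmean = float(rows["z"].mean())
                sites.append(Site(
                    chrom=str(rows["chrom"].iloc[0]),
                    start=int(rows["win_start"].min()),
                    end=int(rows["win_end"].max()),
                    promoter_id=str(key),
                    gene_symbol=str(rows["gene_symbol"].iloc[0]),
                    probe_ids=list(rows.index),
                    min_p=float(rows["p"].min()),
                    direction=1 if zmean >= 0 else -1,
                ))
                run = []
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites


def merge_sites_to_dmrs(sites: list[Site], analysis_mode: str = "single") -> list[DmrCall]:
    """All sites of one promoter tile merge into a single DMR.

    The DMR interval is the union span of its sites; its p-value the minimum
    member p; its direction the direction of the most significant site.
    """
    by_promoter: dict[str, list[Site]] = {}
    for s in sites:
        by_promoter.setdefault(s.promoter_id, []).append(s)
    calls = []
    for pid, group in by_promoter.items():
        best = min(group, key=lambda s: s.min_p)
        calls.append(DmrCall(
            gene_symbol=group[0].gene_symbol,
            promoter_id=pid,
            chrom=group[0].chrom,
            start=min(s.start for s in group),
            end=max(s.end for s in group),
            p_value=best.min_p,
            direction=best.direction,
            analysis_mode=analysis_mode,
            sites=sorted(group, key=lambda s: s.start),
        ))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def single_comparison_dmrs(signal: SmoothedSignal,
                           p_cutoff: float = DEFAULT_P_CUTOFF) -> list[DmrCall]:
    """Null fit -> probe significance -> sites -> DMRs for one analysis set."""
    null = fit_null(signal)
    sigs = probe_significance(signal, null)
    return merge_sites_to_dmrs(call_sites(sigs, signal, p_cutoff), "single")


# ---------------------------------------------------------------------------
# Replicate combination
# ---------------------------------------------------------------------------

def pairwise_shared_site_counts(per_comparison_sites: dict[str, list[Site]]
                                ) -> dict[str, int]:
    """Count overlapping site pairs for every pair of comparisons.

    The count for pair (i, j) is the number of (site_i, site_j) pairs whose
    intervals overlap — the reproducible sites shared by the two replicate
    hybridizations.
    """
    out: dict[str, int] = {}
    for (ai, sa), (aj, sb) in itertools.combinations(per_comparison_sites.items(), 2):
        n = sum(1 for x in sa for y in sb if x.overlaps(y))
        out[f"{ai}-{aj}"] = n
    return out


def intersection_analysis(per_comparison_sites: dict[str, list[Site]],
                          ) -> tuple[list[DmrCall], dict[str, int]]:
    """Retain only DMRs significant in every replicate comparison.

    A candidate promoter is kept iff every comparison has at least one
    significant site there and the sites of every pair of comparisons
    overlap as regions (smoothing shifts site edges between replicates, so
    region overlap rather than probe identity is required).  The reported
    interval is the union span over all supporting comparisons; the p-value
    is the worst (largest) of the per-comparison minima, i.e. the evidence
    every replicate attains.
    """
    if len(per_comparison_sites) < 2:
        raise ValueError("intersection analysis needs >= 2 comparisons")
    shared = pairwise_shared_site_counts(per_comparison_sites)
    promoters: dict[str, dict[str, list[Site]]] = {}
    for cid, sites in per_comparison_sites.items():
        for s in sites:
            promoters.setdefault(s.promoter_id, {}).setdefault(cid, []).append(s)
    calls: list[DmrCall] = []
    all_cids = list(per_comparison_sites)
    for pid, by_cid in promoters.items():
        if set(by_cid) != set(all_cids):
            continue
        ok = all(
            any(x.overlaps(y) for x in by_cid[ci] for y in by_cid[cj])
            for ci, cj in itertools.combinations(all_cids, 2)
        )
        if not ok:
            continue
        sites = [s for group in by_cid.values() for s in group]
        worst_p = max(min(s.min_p for s in group) for group in by_cid.values())
        best = min(sites, key=lambda s: s.min_p)
        calls.append(DmrCall(
            gene_symbol=sites[0].gene_symbol,
            promoter_id=pid,
            chrom=sites[0].chrom,
            start=min(s.start for s in sites),
            end=max(s.end for s in sites),
            p_value=worst_p,
            direction=best.direction,
            analysis_mode="intersection",
            sites=sorted(sites, key=lambda s: s.start),
            comparison_support={cid: True for cid in all_cids},
        ))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls, shared


def average_signal(per_comparison_signals: list[SmoothedSignal]) -> SmoothedSignal:
    """Per-probe mean of smoothed M across comparisons.

    Only probes defined in every comparison keep a value; support is the
    minimum across comparisons.
    """
    if not per_comparison_signals:
        raise ValueError("no signals")
    ref = per_comparison_signals[0].data
    for s in per_comparison_signals[1:]:
        if not ref.index.equals(s.data.index):
            raise ValueError("probe sets differ across comparisons")
    m = np.column_stack([s.data["m_smoothed"].to_numpy(dtype=float)
                         for s in per_comparison_signals])
    sup = np.column_stack([s.data["n_support"].to_numpy()
                           for s in per_comparison_signals])
    out = ref.copy()
    out["m_smoothed"] = np.where(np.isnan(m).any(axis=1), np.nan, m.mean(axis=1))
    out["n_support"] = sup.min(axis=1)
    return SmoothedSignal("average", out)


def average_analysis(per_comparison_signals: list[SmoothedSignal],
                     p_cutoff: float = DEFAULT_P_CUTOFF) -> list[DmrCall]:
    """DMR calling on the across-comparison mean signal (permissive mode)."""
    avg = average_signal(per_comparison_signals)
    null = fit_null(avg)
    sigs = probe_significance(avg, null)
    calls = merge_sites_to_dmrs(call_sites(sigs, avg, p_cutoff), "average")
    return calls


def overlap_dmr_sets(a: list[DmrCall] | list[DmrRecord],
                     b: list[DmrCall] | list[DmrRecord]) -> list[str]:
    """Gene symbols present in both DMR lists (promoter-level identity)."""
    ga = {x.gene_symbol for x in a}
    gb = {x.gene_symbol for x in b}
    return sorted(ga & gb)


def calls_to_records(calls: list[DmrCall], stage_label: str = ".") -> list[DmrRecord]:
    return [c.to_record(stage_label) for c in calls]
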