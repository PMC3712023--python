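"""End-to-end orchestration of the MeDIP-chip DMR pipeline.

Raw comparative arrays are normalized (MA -> GC-grouped loess -> A-quantile),
smoothed per comparison with the 600 bp windowed median, and combined by the
intersection or average rule.  This is the surface the examples and the CLI
drive; each stage remains importable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dmr import (DEFAULT_P_CUTOFF, DmrCall, Site, average_analysis, call_sites,
                  fit_null, intersection_analysis, merge_sites_to_dmrs,
                  probe_significance)
from .io import ComparativeArray, ProbeDesign
from .normalize import (NormalizationParams, SmoothedSignal, normalize_experiment,
                        window_median_smooth)


@dataclass
class MedipResult:
    """Everything the pipeline produced for one stage (e.g. E13 or E16)."""

    mode: str
    calls: list[DmrCall]
    per_comparison_sites: dict[str, list[Site]] = field(default_factory=dict)
    per_comparison_signals: dict[str, SmoothedSignal] = field(default_factory=dict)
    pairwise_shared_sites: dict[str, int] = field(default_factory=dict)
    per_comparison_dmrs: dict[str, list[DmrCall]] = field(default_factory=dict)

    def summary(self) -> dict:
        per_chrom: dict[str, int] = {}
        for c in self.calls:
            per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
        return {
            "mode": self.mode,
            "n_dmrs": len(self.calls),
            "n_sites": {cid: len(s) for cid, s in self.per_comparison_sites.items()},
            "pairwise_shared_sites": self.pairwise_shared_sites,
            "dmrs_per_chromosome": dict(sorted(per_chrom.items())),
        }


def smooth_per_comparison(arrays: list[ComparativeArray], design: ProbeDesign,
                          params: NormalizationParams | None = None
                          ) -> dict[str, SmoothedSignal]:
    """Normalize jointly, then smooth each comparison as its own analysis set."""
    params = params or NormalizationParams()
    mas = normalize_experiment(arrays, design, params)
    return {ma.array_id: window_median_smooth([ma], design, params,
                                              analysis_id=ma.array_id)
            for ma in mas}


def run_medip_pipeline(arrays: list[ComparativeArray], design: ProbeDesign,
                       params: NormalizationParams | None = None,
                       mode: str = "intersection",
                       p_cutoff: float = DEFAULT_P_CUTOFF) -> MedipResult:
    """Run normalization, smoothing, significance and DMR calling.

    mode 'intersection': per-comparison nulls and site calls, then the
    all-comparisons overlap rule.  mode 'average': DMR calling on the
    per-probe mean of the per-comparison smoothed signals.  mode 'single':
    one analysis set pooling nothing (first array only).
    """
    params = params or NormalizationParams()
    signals = smooth_per_comparison(arrays, design, params)
    per_sites: dict[str, list[Site]] = {}
    per_dmrs: dict[str, list[DmrCall]] = {}
    for cid, sig in signals.items():
        null = fit_null(sig)
        sigs = probe_significance(sig, null)
        sites = call_sites(sigs, sig, p_cutoff)
        per_sites[cid] = sites
        per_dmrs[cid] = merge_sites_to_dmrs(sites, "single")

    if mode == "intersection":
        calls, shared = intersection_analysis(per_sites)
    elif mode == "average":
        calls = average_analysis(list(signals.values()), p_cutoff)
        from .dmr import pairwise_shared_site_counts
        shared = pairwise_shared_site_counts(per_sites)
    elif mode == "single":
        first = next(iter(signals))
        calls, shared = per_dmrs[first], {}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MedipResult(mode, calls, per_sites, signals, shared, per_dmrs)


def calls_table(calls: list[DmrCall]) -> pd.DataFrame:
    rows = [{
        "gene_symbol": c.gene_symbol, "promoter_id": c.promoter_id,
        "chrom": c.chrom, "start": c.start, "end": c.end,
        "region_size": c.region_size, "p_value": c.p_value,
        "direction": "hyper" if c.direction > 0 else "hypo",
        "n_sites": len(c.sites), "analysis_mode": c.analysis_mode,
    } for c in calls]
    return pd.DataFrame(rows, columns=["gene_symbol", "promoter_id", "chrom",
                                       "start", "end", "region_size", "p_value",
                                       "direction", "n_sites", "analysis_mode"])
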