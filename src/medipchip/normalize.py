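"""Within- and between-array normalization for two-color MeDIP tiling data.

The chain is fixed: raw channels -> MA conversion -> GC-grouped loess of M on
A within each array -> A-quantile normalization across arrays -> 600 bp
windowed-median smoothing of M with a minimum-probe-support rule.  M is the
log2 treated/control ratio and A the mean log2 intensity, the universal
two-color convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ComparativeArray, FormatError, ProbeDesign

log = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    """Tunables of the normalization chain.

    ``window_bp`` (600) and ``min_probes`` (3) are the windowed-median
    constants of the published procedure; ``n_gc_groups`` and ``loess_span``
    are not fixed by it and default to common two-color practice.
    """

    n_gc_groups: int = 10
    loess_span: float = 0.3
    window_bp: int = 600
    min_probes: int = 3
    min_group_size: int = 10     # GC groups smaller than this merge/skip

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class MAProfile:
    """Per-probe M (log ratio) and A (average log intensity) for one array."""

    array_id: str
    data: pd.DataFrame        # index probe_id, columns m, a

    def copy(self) -> "MAProfile":
        return MAProfile(self.array_id, self.data.copy())


@dataclass
class SmoothedSignal:
    """Windowed-median M per probe for one analysis set.

    ``data`` columns: probe_id (index), chrom, promoter_id, win_start,
    win_end, m_smoothed (NaN where the window held fewer than ``min_probes``
    design probes), n_support.
    """

    analysis_id: str
    data: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        return self.data[self.data["m_smoothed"].notna()]


def compute_ma(array: ComparativeArray) -> MAProfile:
    """Convert raw two-channel intensities to M/A values.

    M = log2(treated) - log2(control); A = (log2(treated) + log2(control))/2.
    """
    t = array.data["treated"].to_numpy(dtype=float)
    c = array.data["control"].to_numpy(dtype=float)
    bad = ~(np.isfinite(t) & np.isfinite(c) & (t > 0) & (c > 0))
    if bad.any():
        probe = array.data.index[np.flatnonzero(bad)[0]]
        raise FormatError(f"nonpositive or nonfinite intensity at probe {probe!r}")
    lt, lc = np.log2(t), np.log2(c)
    df = pd.DataFrame({"m": lt - lc, "a": (lt + lc) / 2.0}, index=array.data.index)
    return MAProfile(array.comparison_id, df)


# ---------------------------------------------------------------------------
# GC-grouped loess
# ---------------------------------------------------------------------------

def _gc_bins(gc: np.ndarray, n_groups: int, min_size: int) -> np.ndarray:
    """Quantile-bin GC values, merging undersized bins into their neighbor."""
    qs = np.quantile(gc, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(qs)
    bins = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    # merge small bins leftward (or rightward for the first bin)
    labels = np.unique(bins)
    counts = {int(b): int((bins == b).sum()) for b in labels}
    for b in sorted(counts):
        if counts[b] < min_size:
            neighbors = [x for x in sorted(counts) if x != b]
            if not neighbors:
                break
            tgt = max([x for x in neighbors if x < b], default=min(neighbors))
            bins[bins == b] = tgt
            counts[tgt] += counts.pop(b)
    return bins


def gc_group_loess(ma: MAProfile, design: ProbeDesign,
                   params: NormalizationParams | None = None) -> MAProfile:
    """Remove intensity- and GC-dependent dye bias within one array.

    Probes are split into GC-content quantile groups and, within each group,
    the loess fit of M on A is subtracted, producing a bias curve specific to
    each GC group.  Groups still smaller than ``min_group_size`` after
    merging are left uncorrected with a warning.
    """
    params = params or NormalizationParams()
    gc = design.probes.set_index("probe_id")["gc"].reindex(ma.data.index)
    if gc.isna().any():
        raise FormatError("probes without a GC value in the design")
    bins = _gc_bins(gc.to_numpy(), params.n_gc_groups, params.min_group_size)
    m = ma.data["m"].to_numpy(dtype=float).copy()
    a = ma.data["a"].to_numpy(dtype=float)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        if len(idx) < params.min_group_size:
            log.warning("GC group %d has %d probes; skipping loess", b, len(idx))
            continue
        aa, mm = a[idx], m[idx]
        delta = 0.01 * (aa.max() - aa.min())
        fit = lowess(mm, aa, frac=params.loess_span, it=2, delta=delta,
                     return_sorted=False)
        m[idx] = mm - fit
    out = ma.data.copy()
    out["m"] = m
    return MAProfile(ma.array_id, out)


# ---------------------------------------------------------------------------
# A-quantile normalization
# ---------------------------------------------------------------------------

def a_quantile_normalize(mas: list[MAProfile]) -> list[MAProfile]:
    """Force identical A distributions across arrays; M is untouched.

    Rank k on every array is mapped to the mean of the arrays' k-th order
    statistics (the standard quantile-normalization construction).
    """
    if len(mas) < 2:
        raise ValueError("need at least two arrays")
    ref_index = mas[0].data.index
    for ma in mas[1:]:
        if not ref_index.sort_values().equals(ma.data.index.sort_values()):
            raise FormatError(f"array {ma.array_id}: probe set differs")
    a_mat = np.column_stack([ma.data["a"].reindex(ref_index).to_numpy() for ma in mas])
    order = np.argsort(a_mat, axis=0, kind="mergesort")
    sorted_a = np.take_along_axis(a_mat, order, axis=0)
    mean_quantiles = sorted_a.mean(axis=1)
    out = []
    for j, ma in enumerate(mas):
        new_a = np.empty(len(ref_index))
        new_a[order[:, j]] = mean_quantiles
        df = ma.data.reindex(ref_index).copy()
        df["a"] = new_a
        out.append(MAProfile(ma.array_id, df))
    return out


# ---------------------------------------------------------------------------
# Windowed-median smoothing
# ---------------------------------------------------------------------------

def window_median_smooth(mas: list[MAProfile], design: ProbeDesign,
                         params: NormalizationParams | None = None,
                         analysis_id: str | None = None) -> SmoothedSignal:
    """Replace each probe's M with the median over a 600 bp window.

    The window is centered on the probe midpoint, [mid - w/2, mid + w/2), and
    pools the M values of every design probe of the same promoter tile whose
    midpoint falls in the window, across all arrays in ``mas`` (the analysis
    set).  If fewer than ``min_probes`` distinct design probes support the
    window, no value is assigned.  Windows never pool across promoter tiles
    or chromosomes.
    """
    params = params or NormalizationParams()
    probes = design.probes
    order = pd.Index(probes["probe_id"])
    m_mat = np.column_stack([ma.data["m"].reindex(order).to_numpy() for ma in mas])
    mids = design.midpoints()
    half = params.window_bp // 2
    n = len(probes)
    m_sm = np.full(n, np.nan)
    n_sup = np.zeros(n, dtype=np.int64)
    grouped = probes.groupby("promoter_id", sort=False).indices
    for _, idx in grouped.items():
        idx = np.sort(idx)
        pm = mids[idx]          # already position-sorted within a promoter
        block = m_mat[idx]
        lo = np.searchsorted(pm, pm - half, side="left")
        hi = np.searchsorted(pm, pm + half, side="left")
        support = hi - lo
        for j in range(len(idx)):
            if support[j] < params.min_probes:
                continue
            vals = block[lo[j]:hi[j]].ravel()
            m_sm[idx[j]] = np.median(vals)
        n_sup[idx] = support
    data = pd.DataFrame({
        "chrom": probes["chrom"].to_numpy(),
        "promoter_id": probes["promoter_id"].to_numpy(),
        "gene_symbol": probes["gene_symbol"].to_numpy(),
        "win_start": mids - half,
        "win_end": mids + half,
        "m_smoothed": m_sm,
        "n_support": n_sup,
    }, index=pd.Index(order, name="probe_id"))
    aid = analysis_id or "+".join(ma.array_id for ma in mas)
    return SmoothedSignal(aid, data)


def window_median_smooth_per_array(mas: list[MAProfile], design: ProbeDesign,
                                   params: NormalizationParams | None = None
                                   ) -> list[SmoothedSignal]:
    """Per-array smoothing mode: one smoothed profile per input array."""
    return [window_median_smooth([ma], design, params, analysis_id=ma.array_id)
            for ma in mas]


def normalize_experiment(arrays: list[ComparativeArray], design: ProbeDesign,
                         params: NormalizationParams | None = None) -> list[MAProfile]:
    """MA conversion + per-array GC-grouped loess + across-array A-quantile."""
    params = params or NormalizationParams()
    mas = [gc_group_loess(compute_ma(arr), design, params) for arr in arrays]
    if len(mas) >= 2:
        mas = a_quantile_normalize(mas)
    return mas


def write_smoothed(signal: SmoothedSignal, path) -> None:
    signal.data.to_csv(path, sep="\t", index_label="probe_id", na_rep=".")


def read_smoothed(path, analysis_id: str | None = None) -> SmoothedSignal:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["."],
                     dtype={"chrom": str, "promoter_id": str})
    return SmoothedSignal(analysis_id or str(path), df)
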