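"""Differential expression with a two-way fixed-effects ANOVA and the
three-part selection rule.

Each gene's log2 signal is modeled additively as treatment + batch (no
interaction); the treatment factor is tested with a type-II F-test, which for
balanced designs coincides with the classical method-of-moments two-way
ANOVA.  Batch effects are estimated as marginal-mean deviations.  A gene is
selected when, jointly and strictly: treatment p < 0.05, unlogged fold
change > 1.2, and the difference of unlogged group means > 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class DeThresholds:
    p: float = 0.05
    fold_change: float = 1.2
    min_diff_unlogged: float = 10.0


def _dummies(factor: pd.Series) -> np.ndarray:
    levels = sorted(factor.unique())
    return np.column_stack([(factor.values == lv).astype(float) for lv in levels[1:]])


def _residual_projector(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return np.eye(x.shape[0]) - q @ q.T


def two_way_anova(mat: ExpressionMatrix) -> pd.Series:
    """Treatment-factor p-value per gene from the additive two-way ANOVA.

    Computed for all genes at once: with a common design across genes, the
    treatment sum of squares is RSS(batch-only model) - RSS(full additive
    model), the type-II decomposition, and F = (SS_t / df_t) / (RSS_full /
    df_res).  For balanced designs this equals the classical two-way ANOVA.
    """
    y = mat.values.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("nonfinite expression values")
    n = y.shape[1]
    treat = _dummies(mat.treatment)
    batch = _dummies(mat.batch)
    if treat.shape[1] < 1 or batch.shape[1] < 1:
        raise ValueError("each factor needs >= 2 levels")
    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept, treat, batch])
    x_red = np.column_stack([intercept, batch])
    df_t = treat.shape[1]
    df_res = n - np.linalg.matrix_rank(x_full)
    if df_res < 1:
        raise ValueError("zero residual degrees of freedom")
    m_full = _residual_projector(x_full)
    m_red = _residual_projector(x_red)
    rss_full = np.einsum("gs,gs->g", y @ m_full, y)
    rss_red = np.einsum("gs,gs->g", y @ m_red, y)
    ss_t = np.maximum(rss_red - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_t / df_t) / (rss_full / df_res)
    p = stats.f.sf(f, df_t, df_res)
    p = np.where(np.isfinite(f), p, 1.0)
    return pd.Series(p, index=mat.values.index, name="p_treatment")


def estimate_batch_effects(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene batch offsets by the method of moments (marginal means).

    Each batch effect is the batch marginal mean minus the grand mean, the
    classical moments estimator for the additive model under a (near-)
    balanced design.
    """
    y = mat.values
    grand = y.mean(axis=1)
    out = {}
    for level in sorted(mat.batch.unique()):
        cols = mat.batch.index[mat.batch == level]
        out[level] = y[cols].mean(axis=1) - grand
    return pd.DataFrame(out)


def remove_batch_effects(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the moments batch-effect estimates from every sample."""
    effects = estimate_batch_effects(mat)
    corrected = mat.values.copy()
    for sample in corrected.columns:
        corrected[sample] = corrected[sample] - effects[mat.batch[sample]]
    return ExpressionMatrix(corrected, mat.treatment, mat.batch)


def fold_change_and_diff(mat: ExpressionMatrix,
                         treated_level: str = "treated") -> pd.DataFrame:
    """Unlogged fold change, unlogged mean difference and direction per gene.

    Group means are taken on the log2 scale and unlogged (2^mean, the
    geometric mean of signals); fold change is the larger of the ratio and
    its reciprocal, with direction 'up' when treated > control.
    """
    levels = sorted(mat.treatment.unique())
    if treated_level not in levels or len(levels) != 2:
        raise ValueError("need exactly two treatment levels incl. " + treated_level)
    control_level = next(lv for lv in levels if lv != treated_level)
    y = mat.values
    if not np.isfinite(y.to_numpy()).all():
        raise ValueError("nonfinite expression values")
    mean_t = np.exp2(y[mat.treatment.index[mat.treatment == treated_level]].mean(axis=1))
    mean_c = np.exp2(y[mat.treatment.index[mat.treatment == control_level]].mean(axis=1))
    ratio = mean_t / mean_c
    fc = np.maximum(ratio, 1.0 / ratio)
    return pd.DataFrame({
        "fold_change": fc,
        "mean_diff_unlogged": (mean_t - mean_c).abs(),
        "direction": np.where(ratio >= 1.0, "up", "down"),
    })


def de_analysis(mat: ExpressionMatrix,
                thresholds: DeThresholds | None = None,
                treated_level: str = "treated") -> pd.DataFrame:
    """Full per-gene DE table: ANOVA p, fold change, difference, selection."""
    thresholds = thresholds or DeThresholds()
    res = fold_change_and_diff(mat, treated_level)
    res.insert(0, "p_treatment", two_way_anova(mat))
    return select_differential(res, thresholds)


def select_differential(results: pd.DataFrame,
                        thresholds: DeThresholds | None = None) -> pd.DataFrame:
    """Apply the three-part rule: p, fold change and unlogged difference.

    All three criteria are strict inequalities, so a gene at exactly the
    fold-change threshold is rejected; a relative tie-guard of 1e-9 absorbs
    the floating-point error of the log2/unlog round trip so that an exact
    1.2-fold gene never sneaks past ">1.2".
    """
    t = thresholds or DeThresholds()
    eps = 1e-9
    out = results.copy()
    out["selected"] = (
        (out["p_treatment"] < t.p)
        & (out["fold_change"] > t.fold_change * (1 + eps))
        & (out["mean_diff_unlogged"] > t.min_diff_unlogged * (1 + eps))
    )
    return out


def overlap_gene_lists(a: list[str] | pd.Index, b: list[str] | pd.Index) -> list[str]:
    """Genes common to two DE lists."""
    return sorted(set(a) & set(b))


def tally_categories(selected: pd.DataFrame,
                     category_map: dict[str, str] | pd.Series | None = None
                     ) -> pd.DataFrame:
    """Count selected genes per functional category, split by direction.

    Genes absent from ``category_map`` (or all genes when no map is given)
    are tallied as 'unknown'.
    """
    cmap = pd.Series(category_map, dtype=object) if category_map is not None else pd.Series(dtype=object)
    sel = selected[selected["selected"]] if "selected" in selected.columns else selected
    cats = sel.index.map(lambda g: cmap.get(g, "unknown"))
    tab = pd.crosstab(cats, sel["direction"])
    tab.index.name = "category"
    for col in ("up", "down"):
        if col not in tab.columns:
            tab[col] = 0
    tab["total"] = tab["up"] + tab["down"]
    return tab[["up", "down", "total"]]


def de_summary(results_by_stage: dict[str, pd.DataFrame]) -> dict:
    """Counts per stage plus pairwise common-gene lists (promoter identity)."""
    out: dict = {"n_selected": {}, "common": {}}
    sel = {k: df.index[df["selected"]] for k, df in results_by_stage.items()}
    for k, idx in sel.items():
        out["n_selected"][k] = int(len(idx))
    keys = list(sel)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            common = overlap_gene_lists(sel[keys[i]], sel[keys[j]])
            out["common"][f"{keys[i]}&{keys[j]}"] = common
    return out
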