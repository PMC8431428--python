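"""Pairwise differential expression on count matrices.

A self-contained negative-binomial Wald procedure: median-of-ratios size
factors, method-of-moments dispersion, a delta-method Wald test on the
log2 fold change, Benjamini-Hochberg adjustment, and three-valued DEG
calling at |log2FC| ≥ τ and adjusted p < α.

Direction convention: a comparison named ``"A vs B"`` reports
``log2fc = log2(B/A)``, so for hybrid-parent comparisons with the hybrid
as B, "up" means higher in the hybrid.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_MIN = 1e-8


def estimate_size_factors(
    counts: pd.DataFrame, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios library-size factors.

    For each sample s, the factor is the median over genes g (with
    all-positive counts) of counts[g, s] / geometric-mean_g, where the
    geometric mean is taken across samples.

    Parameters
    ----------
    counts
        Genes × samples non-negative integer matrix.
    allow_pseudo_reference
        If no gene has all-positive counts, fall back to computing each
        gene's geometric mean over its positive entries only (and the
        median over genes positive in that sample).  Off by default.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any():
        sub = mat[all_positive]
        geo = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geo[:, None], axis=0)
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(mat > 0, mat / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; "
            "re-run with allow_pseudo_reference=True to use a "
            "positive-entries-only reference"
        )
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_columns(
    design: pd.DataFrame,
    group: str,
    time_point: Optional[str],
) -> list:
    sel = design["genotype"] == group
    if time_point is not None:
        sel &= design["time_point"] == time_point
    cols = design.loc[sel, "sample_id"].tolist()
    if not cols:
        raise ValueError(f"no samples for group {group!r}"
                         + (f" at time point {time_point!r}" if time_point else ""))
    return cols


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    size_factors: Optional[pd.Series] = None,
    time_point: Optional[str] = None,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion for a two-group contrast.

    Normalised counts are pooled across both groups after centring each
    group on its own mean; with pooled within-group variance s² and grand
    mean μ̄, the estimate is ``α = max((s² − μ̄)/μ̄², α_min)``.  Genes with
    μ̄ = 0 get ``α_min``.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    cols_a = _group_columns(design, group_a, time_point)
    cols_b = _group_columns(design, group_b, time_point)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need >= 2 replicates")
    norm = counts[cols_a + cols_b].to_numpy(dtype=float) / size_factors[
        cols_a + cols_b
    ].to_numpy()
    na, nb = len(cols_a), len(cols_b)
    a, b = norm[:, :na], norm[:, na:]
    resid = np.concatenate(
        [a - a.mean(axis=1, keepdims=True), b - b.mean(axis=1, keepdims=True)], axis=1
    )
    s2 = (resid ** 2).sum(axis=1) / (na + nb - 2)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (s2 - mu) / mu ** 2, alpha_min)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    size_factors: Optional[pd.Series] = None,
    dispersion: Optional[pd.Series] = None,
    time_point: Optional[str] = None,
) -> pd.DataFrame:
    """Wald test of group B over group A on normalised counts.

    Per gene: group means m_A, m_B of normalised counts; if either mean
    is zero a pseudo-count of 0.5 is added to both before the ratio, so
    ``log2fc = log2((m_B + 0.5z)/(m_A + 0.5z))`` with z ∈ {0, 1}.  The
    standard error comes from the NB delta method,
    ``Var(m) ≈ (Σ_s μ/L_s + α μ² n)/n²`` at the fitted group mean, and
    the two-sided p-value from a standard normal reference.  Genes with
    all-zero counts in both groups are reported with log2fc 0 and p 1.

    Returns a DataFrame with columns base_mean, log2fc, se, wald_stat,
    p_value, p_adj (BH across all genes of the comparison).
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(
            counts, design, group_a, group_b, size_factors, time_point
        )
    cols_a = _group_columns(design, group_a, time_point)
    cols_b = _group_columns(design, group_b, time_point)
    if set(cols_a) & set(cols_b):
        raise ValueError("groups must be disjoint")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need >= 2 replicates")

    lf_a = size_factors[cols_a].to_numpy()
    lf_b = size_factors[cols_b].to_numpy()
    norm_a = counts[cols_a].to_numpy(dtype=float) / lf_a
    norm_b = counts[cols_b].to_numpy(dtype=float) / lf_b
    m_a = norm_a.mean(axis=1)
    m_b = norm_b.mean(axis=1)
    alpha = dispersion.to_numpy(dtype=float)
    na, nb = len(cols_a), len(cols_b)

    z = ((m_a == 0) | (m_b == 0)).astype(float)
    m_a_adj = m_a + 0.5 * z
    m_b_adj = m_b + 0.5 * z
    log2fc = np.log2(m_b_adj / m_a_adj)

    # delta-method variance of each group mean at the (adjusted) fitted mean
    def mean_var(mu: np.ndarray, lf: np.ndarray, n: int) -> np.ndarray:
        return (mu[:, None] / lf[None, :]).sum(axis=1) / n ** 2 + alpha * mu ** 2 / n

    var_a = mean_var(m_a_adj, lf_a, na)
    var_b = mean_var(m_b_adj, lf_b, nb)
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_a / (m_a_adj ** 2 * ln2sq) + var_b / (m_b_adj ** 2 * ln2sq))
        wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    degenerate = (m_a == 0) & (m_b == 0)
    log2fc[degenerate] = 0.0
    wald[degenerate] = 0.0
    p[degenerate] = 1.0
    se[degenerate] = np.nan

    base_mean = np.concatenate([norm_a, norm_b], axis=1).mean(axis=1)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_stat": wald,
            "p_value": p,
        },
        index=counts.index,
    )
    out["p_adj"] = adjust_bh(out["p_value"].to_numpy())
    return out


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``q_(i) = min_{j >= i} p_(j) · m / j``, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_degs(
    de: pd.DataFrame, alpha: float = 0.05, tau: float = 1.0
) -> pd.Series:
    """Three-valued DEG call: up / down / ns.

    up ⇔ p_adj < α and log2fc ≥ τ; down ⇔ p_adj < α and log2fc ≤ −τ.
    """
    up = (de["p_adj"] < alpha) & (de["log2fc"] >= tau)
    down = (de["p_adj"] < alpha) & (de["log2fc"] <= -tau)
    call = pd.Series("ns", index=de.index, name="call")
    call[up] = "up"
    call[down] = "down"
    return call


def deg_summary(call: pd.Series) -> Tuple[int, int, int]:
    """(n_up, n_down, n_total_deg) for a call vector."""
    n_up = int((call == "up").sum())
    n_down = int((call == "down").sum())
    return n_up, n_down, n_up + n_down


def de_comparison(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    tau: float = 1.0,
    time_point: Optional[str] = None,
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Full "A vs B" comparison: test, adjust and call in one table."""
    de = nb_wald_test(
        counts, design, group_a, group_b,
        size_factors=size_factors, time_point=time_point,
    )
    de["call"] = call_degs(de, alpha=alpha, tau=tau)
    return de
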