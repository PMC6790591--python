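"""Score post-processing: chi-squared p-values, Storey q-values, Bonferroni
adjustment, and score-based plotting filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class PostError(ValueError):
    pass


def chi2_pvalue(score, df: int):
    """Upper-tail chi-squared probability ``P(X2_df >= score)``.

    Accepts scalars or arrays; negative scores are an error (NaN propagates).
    """
    score_arr = np.asarray(score, dtype=float)
    if df < 1:
        raise PostError("df must be >= 1")
    with np.errstate(invalid="ignore"):
        if np.any(score_arr[~np.isnan(score_arr)] < 0):
            raise PostError("chi-squared score must be nonnegative")
    out = stats.chi2.sf(score_arr, df)
    return float(out) if np.isscalar(score) else out


def estimate_pi0(p: np.ndarray) -> float:
    """Estimate the proportion of true nulls.

    Lambda-grid {0.05, 0.10, ..., 0.95} with ``pi0(lambda) =
    #{p > lambda} / (m (1 - lambda))``, extrapolated to lambda = 1 by a cubic
    polynomial smoother; for fewer than 100 p-values the plug-in at
    lambda = 0.5 is used instead.  Clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 100:
        pi0 = np.mean(p > 0.5) / 0.5
    else:
        lam = np.arange(0.05, 0.951, 0.05)
        pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, 1.0))
    return float(min(max(pi0, 1.0 / m if m else 1e-8), 1.0))


def storey_qvalues(p, pi0: float | None = None):
    """Storey q-values.

    ``q_i = pi0 * min_{p_(j) >= p_(i)} (m p_(j) / j)`` over the order
    statistics; ties share the minimum.  Returns ``(q, pi0)``.  ``pi0`` may
    be forced (e.g. 1.0 reduces q to Benjamini-Hochberg adjusted p).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise PostError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PostError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise PostError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def bonferroni(p, m: int | None = None):
    """Family-wise adjusted p-values ``min(1, m p)``.

    ``m`` defaults to ``len(p)`` but may exceed it when only a filtered
    subset of a larger test family is supplied.
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise PostError("m must be at least the number of p-values supplied")
    return np.minimum(1.0, m * p)


def attach_pvalues(scores: pd.DataFrame, m: int | None = None,
                   per_env: bool = True) -> pd.DataFrame:
    """Extend a scan result table with p_G, p_Wald, q_G, q_Wald and p_bonf.

    By default the multiple-testing family is counted per environmental
    variable (matching per-variable Manhattan plots); ``per_env=False``
    corrects across the full indicator x env product.  Rows whose fit was
    skipped or degenerate get NaN everywhere.
    """
    out = scores.copy()
    usable = scores["status"].isin(["converged", "separated"]) & \
        np.isfinite(scores["G"].to_numpy(dtype=float))
    for col in ("p_G", "p_Wald", "q_G", "q_Wald", "p_bonf"):
        out[col] = np.nan
    out["pi0_G"] = np.nan

    groups = scores.groupby("env").groups.items() if per_env else \
        [("__all__", scores.index)]
    for _, idx in groups:
        idx = pd.Index(idx)
        sel = idx[usable.loc[idx]]
        if len(sel) == 0:
            continue
        df_counts = scores.loc[sel, "df"].to_numpy(dtype=int)
        if np.unique(df_counts).size != 1:
            raise PostError("mixed df within one correction family")
        df = int(df_counts[0])
        g = np.clip(scores.loc[sel, "G"].to_numpy(dtype=float), 0.0, None)
        w = np.clip(scores.loc[sel, "Wald"].to_numpy(dtype=float), 0.0, None)
        p_g = chi2_pvalue(g, df)
        p_w = chi2_pvalue(w, df)
        m_eff = m if m is not None else len(sel)
        q_g, pi0 = storey_qvalues(p_g)
        q_w, _ = storey_qvalues(p_w)
        out.loc[sel, "p_G"] = p_g
        out.loc[sel, "p_Wald"] = p_w
        out.loc[sel, "q_G"] = q_g
        out.loc[sel, "q_Wald"] = q_w
        out.loc[sel, "p_bonf"] = bonferroni(p_g, m_eff)
        out.loc[sel, "pi0_G"] = pi0
    return out


def filter_for_plot(rt: pd.DataFrame, score_min: float = 6.0) -> pd.DataFrame:
    """Rows whose best score exceeds ``score_min`` (strict); input untouched."""
    g = rt["G"].to_numpy(dtype=float)
    w = rt["Wald"].to_numpy(dtype=float)
    best = np.fmax(g, w)  # fmax ignores NaN on one side
    keep = np.nan_to_num(best, nan=-np.inf) > score_min
    return rt.loc[keep].copy()
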