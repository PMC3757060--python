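"""Two-group differential expression with an empirical-Bayes moderated t.

Per feature the statistic is log2FC / (s_tilde * sqrt(1/n1 + 1/n2)) where
s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d) shrinks the pooled within-group
variance s^2 (d residual df) toward a common prior variance s0^2 with prior
df d0.  The hyperparameters (d0, s0^2) are estimated from the marginal
distribution of s^2 across features by moment matching on log s^2: under the
model s^2 ~ s0^2 * F(d, d0), so log s^2 has mean and variance expressible
through digamma/trigamma functions of d/2 and d0/2, which are inverted
numerically.  The moderated t is referred to a t distribution on d0 + d
degrees of freedom (a normal when d0 is estimated infinite).

Direction convention: log2FC = mean(high) - mean(low), so a negative value
means "down in the high-proliferative group".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ("log2fc", "t", "p", "fdr", "direction", "mean_high", "mean_low")


# ---------------------------------------------------------------------------
# variance filter

def variance_filter(mat: ExpressionMatrix, keep_fraction: float) -> ExpressionMatrix:
    """Keep the ceil(keep_fraction * n) features of largest across-sample variance.

    Ties at the cut are broken by feature id (lexicographically smaller wins)
    so the filter is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    n = len(mat.feature_ids)
    if n == 0:
        raise ValueError("empty expression matrix")
    variances = mat.values.var(axis=1, ddof=1)
    order = sorted(mat.feature_ids, key=lambda f: (-variances[f], f))
    n_keep = int(np.ceil(keep_fraction * n))
    kept = sorted(order[:n_keep], key=mat.feature_ids.index)
    logger.info("filter=variance before=%d after=%d keep_fraction=%s",
                n, n_keep, keep_fraction)
    return mat.subset(kept)


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameters

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-F marginal of the sample variances.

    Matches the first two moments of log s^2.  Returns d0 = inf when the
    observed spread of log s^2 is no larger than expected from the sampling
    noise alone (no feature-to-feature variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2)) if len(s2) else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


# ---------------------------------------------------------------------------
# moderated t

def _shrink_and_test(lfc, s2, df, n1, n2, d0, s02):
    """Moderated t and two-sided p given hyperparameters (helper, testable)."""
    lfc = np.asarray(lfc, float)
    s2 = np.asarray(s2, float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # identical means with zero variance everywhere: no evidence, p = 1
    p = np.where((se == 0) & (lfc == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where((se == 0) & (lfc != 0), np.inf * np.sign(lfc), t)
    p = np.where((se == 0) & (lfc != 0), 0.0, p)
    return t, p, df_total


def moderated_t(mat: ExpressionMatrix) -> pd.DataFrame:
    """Moderated two-group test for every feature; returns the DE table.

    Columns: log2fc, t, p, fdr (BH), direction (up/down by log2FC sign),
    mean_high, mean_low.  A single-feature matrix cannot support variance
    shrinkage and falls back to the ordinary two-sample t (d0 = 0).
    """
    high = mat.values[mat.samples_of("high")].to_numpy()
    low = mat.values[mat.samples_of("low")].to_numpy()
    n1, n2 = high.shape[1], low.shape[1]
    df = n1 + n2 - 2
    mean_h, mean_l = high.mean(axis=1), low.mean(axis=1)
    lfc = mean_h - mean_l
    ss = ((high - mean_h[:, None]) ** 2).sum(axis=1) + \
         ((low - mean_l[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if len(lfc) < 2:
        d0, s02 = 0.0, 0.0
        s2_shrunk = s2
        t_stat, p, _ = _shrink_and_test(lfc, s2, df, n1, n2, 0.0, 0.0)
    else:
        d0, s02 = fit_f_dist(s2, df)
        t_stat, p, _ = _shrink_and_test(lfc, s2, df, n1, n2, d0, s02)
    logger.info("moderated_t features=%d d0=%s s02=%s", len(lfc), d0, s02)

    table = pd.DataFrame({
        "log2fc": lfc,
        "t": t_stat,
        "p": p,
        "fdr": bh_fdr(p),
        "direction": np.where(lfc >= 0, "up", "down"),
        "mean_high": mean_h,
        "mean_low": mean_l,
    }, index=mat.values.index)
    table.index.name = "feature"
    return table


# ---------------------------------------------------------------------------
# BH and filtering

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def filter_de(table: pd.DataFrame, p_kind: str, p_max: float,
              abs_lfc_min: float) -> pd.DataFrame:
    """Apply the printed filter operators: p-quantity strictly <, |log2FC| >=."""
    if p_kind not in ("fdr", "raw"):
        raise ValueError("p_kind must be 'fdr' or 'raw'")
    col = "fdr" if p_kind == "fdr" else "p"
    kept = table[(table[col] < p_max) & (table["log2fc"].abs() >= abs_lfc_min)]
    logger.info("filter=de kind=%s p_max=%s lfc_min=%s before=%d after=%d",
                p_kind, p_max, abs_lfc_min, len(table), len(kept))
    return kept
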