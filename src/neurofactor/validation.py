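"""Converging-evidence utilities.

Factor scores recovered from activation can be checked against external,
imaging-free characterizations of the same words: behavioural ratings,
corpus-derived similarity values, letter counts, or log word frequencies.
The checks are plain Pearson correlations over the word set, plus a
stepwise regression that asks whether word frequency explains activation at
a location beyond what word length already explains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "convergent_correlation",
    "correlation_report",
    "stepwise_frequency_check",
]


def convergent_correlation(factor_scores: np.ndarray, external: np.ndarray) -> float:
    """Pearson correlation between per-word factor scores and an external
    per-word measure."""
    f = np.asarray(factor_scores, dtype=float)
    e = np.asarray(external, dtype=float)
    if f.shape != e.shape or f.ndim != 1:
        raise ValueError("need two aligned per-word vectors")
    if not (np.isfinite(f).all() and np.isfinite(e).all()):
        raise ValueError("non-finite values in input")
    if f.std() == 0 or e.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.corrcoef(f, e)[0, 1])


def correlation_report(
    factor_scores: pd.DataFrame, external: pd.DataFrame
) -> pd.DataFrame:
    """Correlation of every factor column with every external column.

    Both frames must share a ``word`` column; rows are aligned on it.
    """
    merged = factor_scores.merge(external, on="word", suffixes=("_factor", "_ext"))
    fcols = [c for c in factor_scores.columns if c != "word"]
    ecols = [c for c in external.columns if c != "word"]
    rows = []
    for fc in fcols:
        fc_m = fc if fc in merged.columns else f"{fc}_factor"
        for ec in ecols:
            ec_m = ec if ec in merged.columns else f"{ec}_ext"
            rows.append(
                {
                    "factor": fc,
                    "external": ec,
                    "r": convergent_correlation(
                        merged[fc_m].to_numpy(), merged[ec_m].to_numpy()
                    ),
                }
            )
    return pd.DataFrame(rows)


def stepwise_frequency_check(
    activation: np.ndarray,
    word_length: np.ndarray,
    log_frequency: np.ndarray,
) -> dict[str, float]:
    """Does log word frequency add explanatory power beyond word length?

    Step 1 regresses the per-word mean activation of a location on word
    length; step 2 adds log frequency. Returns the step-1 R^2, the R^2
    increment, and the incremental F statistic with (1, n - 3) degrees of
    freedom and its p-value.
    """
    y = np.asarray(activation, dtype=float)
    wl = np.asarray(word_length, dtype=float)
    lf = np.asarray(log_frequency, dtype=float)
    n = len(y)
    if not (len(wl) == len(lf) == n):
        raise ValueError("all three vectors must be aligned")
    if np.corrcoef(wl, lf)[0, 1] ** 2 > 1 - 1e-10:
        raise ValueError("word length and log frequency are collinear")
    step1 = sm.OLS(y, sm.add_constant(wl)).fit()
    step2 = sm.OLS(y, sm.add_constant(np.column_stack([wl, lf]))).fit()
    r2_1, r2_2 = step1.rsquared, step2.rsquared
    delta = r2_2 - r2_1
    df_resid = n - 3
    if 1 - r2_2 <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = delta / ((1 - r2_2) / df_resid)
        p = float(stats.f.sf(f_stat, 1, df_resid))
    return {
        "r2_step1": float(r2_1),
        "delta_r2": float(delta),
        "f_stat": float(f_stat),
        "p_value": float(p),
        "df_denom": float(df_resid),
    }
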