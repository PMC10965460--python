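"""Sullivan health expectancy: prevalence estimation and prevalence-weighted
life-table person-years.

The Sullivan method combines a period life table with cross-sectional
disease prevalence: person-years lived in each age interval are discounted
by the proportion of the interval's population living with the condition,

    HALE(x) = (1/l_x) * sum_{y >= x} (1 - pi_y) * L_y,

so HALE is the expected remaining years lived free of the condition for a
survivor to exact age x, and HALE/LE is the healthy fraction of remaining
life.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "estimate_prevalence",
    "add_prevalence_ci",
    "age_standardize_prevalence",
    "sullivan_hale",
    "hale_le_ratio",
]


def estimate_prevalence(n: int, cases: int, alpha: float = 0.05,
                        method: str = "wilson") -> tuple[float, tuple[float, float]]:
    """Prevalence point estimate with a binomial confidence interval.

    Wilson score interval by default (well behaved at the 0/1 boundaries);
    ``method='wald'`` gives the normal-approximation interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= cases <= n:
        raise ValueError("cases must lie in [0, n]")
    if method not in ("wilson", "wald"):
        raise ValueError("method must be 'wilson' or 'wald'")
    p = cases / n
    lo, hi = proportion_confint(cases, n, alpha=alpha,
                                method="normal" if method == "wald" else "wilson")
    return p, (float(lo), float(hi))


def add_prevalence_ci(prev: pd.DataFrame, alpha: float = 0.05,
                      method: str = "wilson") -> pd.DataFrame:
    """Attach prevalence, ci_low and ci_high columns to an (n, cases) table.

    Intervals with no observations (n = 0, e.g. age bands above the oldest
    enrolment age) get NaN estimates and are treated as unobserved downstream.
    """
    out = prev.copy()
    est = [estimate_prevalence(int(n), int(c), alpha=alpha, method=method)
           if n > 0 else (np.nan, (np.nan, np.nan))
           for n, c in zip(out["n"], out["cases"])]
    out["prevalence"] = [p for p, _ in est]
    out["ci_low"] = [ci[0] for _, ci in est]
    out["ci_high"] = [ci[1] for _, ci in est]
    return out


def age_standardize_prevalence(prev: pd.DataFrame, standard_weights) -> float:
    """Directly standardised prevalence: sum(w_g p_g) / sum(w_g).

    ``standard_weights`` are the standard population's counts (or any
    non-negative weights) aligned with the rows of ``prev``, e.g. census
    population by the same age bands.
    """
    w = np.asarray(standard_weights, dtype=float)
    if "prevalence" in prev.columns:
        p = prev["prevalence"].to_numpy(dtype=float)
    else:
        p = (prev["cases"] / prev["n"]).to_numpy(dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights must align with the prevalence intervals")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    return float(np.sum(w * p) / w.sum())


def _aligned_prevalence(table: pd.DataFrame, prev: pd.DataFrame) -> np.ndarray:
    """Per-life-table-interval prevalence, carrying the last observed group
    forward into older intervals (the terminal interval in particular)."""
    t_starts = table["age_start"].to_numpy(dtype=float)
    p = prev.sort_values("age_start")
    if "prevalence" in p.columns:
        vals = p["prevalence"].to_numpy(dtype=float)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (p["cases"] / p["n"]).to_numpy(dtype=float)
    observed = ~np.isnan(vals)          # NaN rows are unobserved age bands
    if not observed.any():
        raise ValueError("no observed prevalence intervals")
    p_starts = p["age_start"].to_numpy(dtype=float)[observed]
    p_vals = vals[observed]
    if np.any((p_vals < 0) | (p_vals > 1)):
        raise ValueError("prevalence outside [0, 1]")

    out = np.empty(len(t_starts))
    for i, s in enumerate(t_starts):
        match = np.isclose(p_starts, s)
        if match.any():
            out[i] = p_vals[match.argmax()]
        elif s > p_starts[-1]:
            out[i] = p_vals[-1]        # carried forward beyond oldest observed
        else:
            raise ValueError(f"no prevalence interval starting at age {s}")
    return out


def sullivan_hale(table: pd.DataFrame, prev: pd.DataFrame,
                  start_ages=None) -> pd.DataFrame:
    """Sullivan LE/HALE from a Chiang life table and an age-banded prevalence.

    Parameters
    ----------
    table : DataFrame
        Abridged life table (``build_abridged_life_table`` output).
    prev : DataFrame
        Age-banded prevalence with ``age_start`` and either a ``prevalence``
        column or ``n``/``cases``. Intervals must line up with the life
        table; ages above the oldest observed band reuse its prevalence.
    start_ages : sequence of float, optional
        Interval starts to report (default: every life-table interval).

    Returns
    -------
    DataFrame with columns ``age_group, LE, HALE, ratio_pct`` — remaining
    life expectancy, health-adjusted life expectancy and the percentage of
    remaining life lived disease-free, per starting age.
    """
    pi = _aligned_prevalence(table, prev)
    L = table["L"].to_numpy(dtype=float)
    l = table["l"].to_numpy(dtype=float)
    e = table["e"].to_numpy(dtype=float)
    starts = table["age_start"].to_numpy(dtype=float)
    healthy_L = (1.0 - pi) * L
    tail = np.cumsum(healthy_L[::-1])[::-1]

    if start_ages is None:
        start_ages = starts
    rows = []
    for age in start_ages:
        match = np.isclose(starts, age)
        if not match.any():
            raise ValueError(f"start age {age} is not a life-table interval start")
        i = int(match.argmax())
        if l[i] <= 0:
            raise ValueError(f"no survivors at age {age}")
        hale = tail[i] / l[i]
        rows.append((starts[i], e[i], hale, hale_le_ratio(e[i], hale)))
    return pd.DataFrame(rows, columns=["age_group", "LE", "HALE", "ratio_pct"])


def hale_le_ratio(le: float, hale: float) -> float:
    """HALE as a percentage of LE."""
    if le <= 0:
        raise ValueError("LE must be positive")
    if not 0 <= hale <= le + 1e-12:
        raise ValueError("HALE must lie in [0, LE]")
    return 100.0 * hale / le
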