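"""Chiang abridged (current) life tables from age-grouped deaths and exposure.

Columns follow the conventional demographic notation: central death rate m,
conditional probability of dying q, separation fraction a (mean fraction of
the interval lived by those dying in it), survivors l, life-table deaths d,
person-years lived L, cumulated person-years T and expectation of life e.
The terminal interval is open-ended: everyone alive there eventually dies in
it (q = 1) and person-years are l/m, the exponential-tail closure.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

__all__ = ["build_abridged_life_table", "life_expectancy_at", "default_age_intervals"]

LIFETABLE_COLUMNS = ["age_start", "age_width", "population", "deaths",
                     "m", "q", "a", "l", "d", "L", "T", "e"]


def default_age_intervals(start: float = 65.0, width: float = 5.0,
                          terminal: float = 85.0) -> list[tuple[float, float]]:
    """5-year bands from ``start`` with an open-ended terminal interval."""
    starts = np.arange(start, terminal, width)
    iv = [(float(s), float(width)) for s in starts]
    iv.append((float(terminal), np.inf))
    return iv


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    for col in ("age_start", "age_width", "population", "deaths"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    c = counts.sort_values("age_start").reset_index(drop=True)
    widths = c["age_width"].to_numpy(dtype=float)
    starts = c["age_start"].to_numpy(dtype=float)
    open_ended = ~np.isfinite(widths)
    if open_ended.sum() != 1 or not open_ended[-1]:
        raise ValueError("exactly the last interval must be open-ended "
                         "(age_width inf or NaN)")
    if len(c) > 1 and not np.allclose(starts[1:], starts[:-1] + widths[:-1]):
        raise ValueError("age intervals must be contiguous and non-overlapping")
    if (c["deaths"] < 0).any() or (c["population"] < 0).any():
        raise ValueError("negative counts")
    if ((c["deaths"] > 0) & (c["population"] <= 0)).any():
        raise ValueError("deaths recorded in an interval with no population")
    return c


def build_abridged_life_table(counts: pd.DataFrame, radix: float = 100_000,
                              a_defaults=0.5) -> pd.DataFrame:
    """Build a Chiang abridged life table from an age-grouped count table.

    Parameters
    ----------
    counts : DataFrame
        Columns ``age_start``, ``age_width`` (inf/NaN for the terminal
        open-ended interval), ``population`` (mid-period population or
        person-years) and ``deaths``.
    radix : float
        Starting cohort size l at the first age; the expectation-of-life
        column is invariant to it.
    a_defaults : float or sequence
        Separation fraction(s) a. A scalar applies to every interval
        (0.5 is standard Chiang practice for ages 5 and above); a sequence
        gives one value per interval, e.g. to use infant-mortality fractions
        in a full table.

    Returns
    -------
    DataFrame with the input columns plus ``m, q, a, l, d, L, T, e``, one
    row per age interval.

    Notes
    -----
    The interior Chiang conversion is q = n m / (1 + n (1 - a) m), capped at
    one; the terminal interval has q = 1 and L = l/m, which requires a
    positive terminal death rate (a terminal interval with survivors but no
    deaths leaves remaining lifetime undefined and raises).
    """
    c = _validate_counts(counts)
    k = len(c)
    if radix <= 0:
        raise ValueError("radix must be positive")
    if isinstance(a_defaults, numbers.Number):
        a = np.full(k, float(a_defaults))
    else:
        a = np.asarray(a_defaults, dtype=float)
        if a.shape != (k,):
            raise ValueError("a_defaults must be scalar or one value per interval")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("separation fractions must lie in [0, 1]")

    n = c["age_width"].to_numpy(dtype=float)
    pop = c["population"].to_numpy(dtype=float)
    dth = c["deaths"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(pop > 0, dth / pop, 0.0)

    q = np.empty(k)
    q[:-1] = np.minimum(n[:-1] * m[:-1] / (1.0 + n[:-1] * (1.0 - a[:-1]) * m[:-1]), 1.0)
    q[-1] = 1.0

    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q

    L = np.empty(k)
    L[:-1] = n[:-1] * l[1:] + a[:-1] * n[:-1] * d[:-1]
    if l[-1] > 0 and m[-1] <= 0:
        raise ValueError("terminal interval has survivors but no deaths: "
                         "terminal person-years l/m are undefined")
    L[-1] = l[-1] / m[-1] if l[-1] > 0 else 0.0

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, np.nan)

    out = c.copy()
    out["m"], out["q"], out["a"], out["l"] = m, q, a, l
    out["d"], out["L"], out["T"], out["e"] = d, L, T, e
    return out[LIFETABLE_COLUMNS]


def life_expectancy_at(table: pd.DataFrame, age: float) -> float:
    """Expectation of life e at an exact age equal to an interval start."""
    starts = table["age_start"].to_numpy(dtype=float)
    match = np.isclose(starts, age)
    if not match.any():
        raise ValueError(f"age {age} is not an interval boundary of the table")
    return float(table.loc[match, "e"].iloc[0])
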