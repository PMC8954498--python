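"""Disproportionality statistics over the drug–event contingency table.

For each (ingredient, preferred term) pair the 2x2 cell is

====================  =========  ===============
..                     drug X     all other drugs
event Y                a          b
all other events       c          d
====================  =========  ===============

counted in *reports* (distinct case identifiers): a case mentioning a pair
several times contributes once.  N = a+b+c+d is the total number of
deduplicated reports and is identical across all cells of one table.

The statistics are the classical frequentist pair measures:

* PRR  = [a/(a+c)] / [b/(b+d)], 95% CI
  exp(ln PRR ± 1.96 sqrt(1/a − 1/(a+c) + 1/b − 1/(b+d)))
* ROR  = ad/bc, 95% CI exp(ln ROR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))
* Yates-corrected chi-squared
  N (max(0, |ad−bc| − N/2))² / [(a+c)(a+b)(b+d)(c+d)]
  (the continuity correction is clamped at zero so an exactly proportional
  table scores 0 rather than a spurious positive value)
* information component IC = log2((a+0.5)/(a_exp+0.5)) with
  a_exp = (a+b)(a+c)/N and the closed-form credibility bounds
  IC025 = IC − 3.3 (a+0.5)^−1/2 − 2 (a+0.5)^−3/2,
  IC975 = IC + 2.4 (a+0.5)^−1/2 − 0.5 (a+0.5)^−3/2.

Ratio statistics are undefined on zero cells; they are returned null with a
reason code rather than silently corrected (an opt-in ``continuity``
constant adds a Haldane-style offset for users who want finite estimates).
The IC is total for every a ≥ 0 thanks to the +0.5 shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.96

REASON_OK = ""
REASON_ZERO_CELL = "zero-cell"
REASON_ZERO_MARGINAL = "zero-marginal"


@dataclass
class SignalScores:
    """All pair statistics for one contingency cell."""

    a: int
    b: int
    c: int
    d: int
    n: int
    prr: float | None
    prr_lo: float | None
    prr_hi: float | None
    prr_reason: str
    ror: float | None
    ror_lo: float | None
    ror_hi: float | None
    ror_reason: str
    chi2_yates: float | None
    chi2_reason: str
    a_exp: float
    ic: float
    ic025: float
    ic975: float


# ------------------------------------------------------------------ vector ops

def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def prr_arrays(a, b, c, d, continuity: float = 0.0):
    """PRR point and 95% CI; invalid cells -> NaN plus a reason array."""
    a, b, c, d = (_as_float(x) + continuity for x in (a, b, c, d))
    valid = (a > 0) & (b > 0) & (a + c > 0) & (b + d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        point = np.where(valid, (a / (a + c)) / (b / (b + d)), np.nan)
        se = np.sqrt(np.where(valid, 1 / a - 1 / (a + c) + 1 / b - 1 / (b + d), np.nan))
        lo = np.exp(np.log(point) - Z95 * se)
        hi = np.exp(np.log(point) + Z95 * se)
    reason = np.where(valid, REASON_OK, REASON_ZERO_CELL)
    return point, lo, hi, reason


def ror_arrays(a, b, c, d, continuity: float = 0.0):
    """ROR point and 95% CI; any zero cell -> NaN plus a reason array."""
    a, b, c, d = (_as_float(x) + continuity for x in (a, b, c, d))
    valid = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        point = np.where(valid, (a * d) / (b * c), np.nan)
        se = np.sqrt(np.where(valid, 1 / a + 1 / b + 1 / c + 1 / d, np.nan))
        lo = np.exp(np.log(point) - Z95 * se)
        hi = np.exp(np.log(point) + Z95 * se)
    reason = np.where(valid, REASON_OK, REASON_ZERO_CELL)
    return point, lo, hi, reason


def chi2_yates_arrays(a, b, c, d):
    """Yates-corrected chi-squared with the correction clamped at zero."""
    a, b, c, d = (_as_float(x) for x in (a, b, c, d))
    n = a + b + c + d
    m1, m2, m3, m4 = a + c, a + b, b + d, c + d
    valid = (m1 > 0) & (m2 > 0) & (m3 > 0) & (m4 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.abs(a * d - b * c) - n / 2.0
        diff = np.where(diff > 0, diff, 0.0)
        stat = np.where(valid, n * diff ** 2 / (m1 * m2 * m3 * m4), np.nan)
    reason = np.where(valid, REASON_OK, REASON_ZERO_MARGINAL)
    return stat, reason


def ic_arrays(a, b, c, d):
    """Information component with closed-form 2.5%/97.5% bounds; total."""
    a, b, c, d = (_as_float(x) for x in (a, b, c, d))
    n = a + b + c + d
    a_exp = (a + b) * (a + c) / n
    ic = np.log2((a + 0.5) / (a_exp + 0.5))
    s = a + 0.5
    ic025 = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
    ic975 = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
    return ic, ic025, ic975, a_exp


# ----------------------------------------------------------------- scalar API

def _scalar(x) -> float | None:
    v = float(x)
    return None if np.isnan(v) else v


def signal_scores(a: int, b: int, c: int, d: int,
                  continuity: float = 0.0) -> SignalScores:
    """All statistics for a single (a, b, c, d) cell."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    aa = np.array([a]); bb = np.array([b]); cc = np.array([c]); dd = np.array([d])
    prr, prr_lo, prr_hi, prr_r = prr_arrays(aa, bb, cc, dd, continuity)
    ror, ror_lo, ror_hi, ror_r = ror_arrays(aa, bb, cc, dd, continuity)
    chi2, chi2_r = chi2_yates_arrays(aa, bb, cc, dd)
    ic, ic025, ic975, a_exp = ic_arrays(aa, bb, cc, dd)
    return SignalScores(
        a=a, b=b, c=c, d=d, n=a + b + c + d,
        prr=_scalar(prr[0]), prr_lo=_scalar(prr_lo[0]), prr_hi=_scalar(prr_hi[0]),
        prr_reason=str(prr_r[0]),
        ror=_scalar(ror[0]), ror_lo=_scalar(ror_lo[0]), ror_hi=_scalar(ror_hi[0]),
        ror_reason=str(ror_r[0]),
        chi2_yates=_scalar(chi2[0]), chi2_reason=str(chi2_r[0]),
        a_exp=float(a_exp[0]), ic=float(ic[0]),
        ic025=float(ic025[0]), ic975=float(ic975[0]),
    )


def prr(a, b, c, d, continuity: float = 0.0):
    """(point, lo, hi) for the proportional reporting ratio; None on zero cells."""
    s = signal_scores(a, b, c, d, continuity)
    return s.prr, s.prr_lo, s.prr_hi


def ror(a, b, c, d, continuity: float = 0.0):
    """(point, lo, hi) for the reporting odds ratio; None on zero cells."""
    s = signal_scores(a, b, c, d, continuity)
    return s.ror, s.ror_lo, s.ror_hi


def chi2_yates(a, b, c, d):
    """The clamped Yates-corrected chi-squared; None on a zero marginal."""
    return signal_scores(a, b, c, d).chi2_yates


def ic(a, b, c, d):
    """(ic, ic025, ic975, a_exp); defined for every a >= 0."""
    s = signal_scores(a, b, c, d)
    return s.ic, s.ic025, s.ic975, s.a_exp


# ------------------------------------------------------------ table operations

def build_contingency(pairs: pd.DataFrame, n_total: int | None = None) -> pd.DataFrame:
    """Contingency cells from deduplicated (primaryid, ingredient, pt) triples.

    ``pairs`` needs columns ``primaryid``, ``ingredient_rxaui`` and ``pt``;
    repeats of a pair within one case collapse before counting.  ``n_total``
    is the size of the report universe (defaults to the number of distinct
    primaryids present in ``pairs``; pass the deduplicated DEMO count when
    cases without mapped drugs or reactions should still count toward N).
    """
    cols = ["primaryid", "ingredient_rxaui", "pt"]
    if pairs.empty:
        return pd.DataFrame(columns=["ingredient_rxaui", "pt", "a", "b", "c", "d", "n"])
    triples = pairs[cols].dropna().drop_duplicates()
    n = int(n_total) if n_total is not None else triples["primaryid"].nunique()
    a = (triples.groupby(["ingredient_rxaui", "pt"])["primaryid"]
         .nunique().rename("a").reset_index())
    n_x = (triples[["primaryid", "ingredient_rxaui"]].drop_duplicates()
           .groupby("ingredient_rxaui").size().rename("n_drug"))
    n_y = (triples[["primaryid", "pt"]].drop_duplicates()
           .groupby("pt").size().rename("n_event"))
    cells = a.join(n_x, on="ingredient_rxaui").join(n_y, on="pt")
    cells["b"] = cells["n_event"] - cells["a"]
    cells["c"] = cells["n_drug"] - cells["a"]
    cells["d"] = n - cells["a"] - cells["b"] - cells["c"]
    cells["n"] = n
    out = cells[["ingredient_rxaui", "pt", "a", "b", "c", "d", "n"]].copy()
    for col in ("a", "b", "c", "d", "n"):
        out[col] = out[col].astype(np.int64)
    return out.sort_values(["ingredient_rxaui", "pt"]).reset_index(drop=True)


def proportionate_analysis(cells: pd.DataFrame,
                           continuity: float = 0.0) -> pd.DataFrame:
    """One row of SignalScores per contingency cell (row count preserved)."""
    out = cells.reset_index(drop=True).copy()
    if out.empty:
        for col in ("prr", "prr_lo", "prr_hi", "ror", "ror_lo", "ror_hi",
                    "chi2_yates", "a_exp", "ic", "ic025", "ic975"):
            out[col] = pd.Series(dtype=float)
        for col in ("prr_reason", "ror_reason", "chi2_reason"):
            out[col] = pd.Series(dtype=object)
        return out
    a, b, c, d = (out[k].to_numpy() for k in ("a", "b", "c", "d"))
    out["prr"], out["prr_lo"], out["prr_hi"], out["prr_reason"] = \
        prr_arrays(a, b, c, d, continuity)
    out["ror"], out["ror_lo"], out["ror_hi"], out["ror_reason"] = \
        ror_arrays(a, b, c, d, continuity)
    out["chi2_yates"], out["chi2_reason"] = chi2_yates_arrays(a, b, c, d)
    out["ic"], out["ic025"], out["ic975"], out["a_exp"] = ic_arrays(a, b, c, d)
    return out
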