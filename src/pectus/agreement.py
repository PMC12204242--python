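"""Observer-agreement protocol: error rules, chi-square, ICC, Bland-Altman.

The measurement-error rule: three observers measure each index for each
patient; a case is an error when any observer deviates from the three-
observer mean by more than 10 % of that mean.  Flagged cases are corrected
by replacing the most deviant reading with a fourth, independent observer's
value, and the rule is re-evaluated on the corrected triple.  The automatic
(AI) measurement is an error when it deviates from the (pre- or post-
correction) manual mean by more than the same fraction.

Errors are counted per case — one patient x index combination — so with
three indices and ``n`` patients the pooled denominator is ``3 n``.

Agreement between the corrected manual mean and the automatic value is
summarized per index by the intraclass correlation (two-way random effects,
absolute agreement, single measures) and by Bland-Altman bias and 95 %
limits of agreement on percent differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import DataError, ParameterError

__all__ = [
    "INDEX_NAMES", "ERROR_THRESHOLD",
    "dice", "iou", "ErrorFlag", "flag_error", "fourth_person_correction",
    "ai_error", "error_rate_report", "pooled_error_rate", "pearson_chi2",
    "icc_single", "bland_altman", "BlandAltman", "agreement_report",
    "simulate_observer_table",
]

INDEX_NAMES = ("haller", "correction", "asymmetry")
ERROR_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# Mask overlap metrics
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks agree (1.0)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; two empty masks agree (1.0)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


# ---------------------------------------------------------------------------
# The 10 %-of-mean error rule
# ---------------------------------------------------------------------------

class ErrorFlag(NamedTuple):
    is_error: bool
    worst_observer: int  # 1-based; the most deviant of the three
    tie: bool            # deviation tie broken toward the lowest observer


def flag_error(values: Sequence[float],
               threshold: float = ERROR_THRESHOLD) -> ErrorFlag:
    """Apply the deviation-from-mean rule to a triple of observer readings."""
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise ParameterError(f"expected exactly 3 observer values, got {v.shape}")
    if (v <= 0).any():
        raise ParameterError(f"observer values must be positive, got {v.tolist()}")
    m = v.mean()
    dev = np.abs(v - m)
    worst = int(np.argmin(np.where(dev == dev.max(), np.arange(3), 3)))
    tie = int((dev == dev.max()).sum()) > 1
    return ErrorFlag(bool(dev.max() > threshold * m), worst + 1, tie)


def fourth_person_correction(row: pd.Series | dict,
                             threshold: float = ERROR_THRESHOLD) -> tuple:
    """Corrected observer triple for one table row.

    Unflagged rows pass through unchanged.  On a flagged row the most
    deviant reading is replaced by the fourth observer's value; the
    replacement may itself leave the row in error (counted post-correction).
    Returns ``(corrected_triple, was_corrected)``.
    """
    triple = [float(row[k]) for k in ("obs1", "obs2", "obs3")]
    flag = flag_error(triple, threshold)
    if not flag.is_error:
        return tuple(triple), False
    obs4 = row.get("obs4") if isinstance(row, dict) else row.get("obs4", None)
    if obs4 is None or (isinstance(obs4, float) and np.isnan(obs4)):
        ident = {k: row[k] for k in ("patient_id", "index_name") if k in row}
        raise DataError(f"flagged row {ident} has no fourth-observer value")
    triple[flag.worst_observer - 1] = float(obs4)
    return tuple(triple), True


def ai_error(ai: float, manual_triple: Sequence[float],
             threshold: float = ERROR_THRESHOLD) -> bool:
    """Whether the automatic value deviates > threshold from the manual mean."""
    v = np.asarray(manual_triple, dtype=float)
    if (v <= 0).any() or not ai > 0:
        raise ParameterError("measurements must be positive")
    m = v.mean()
    return bool(abs(ai - m) > threshold * m)


# ---------------------------------------------------------------------------
# Table-level reporting
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("patient_id", "index_name", "obs1", "obs2", "obs3", "ai")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"observer table lacks columns {missing}")
    bad = set(table["index_name"]) - set(INDEX_NAMES)
    if bad:
        raise DataError(f"unknown index names {sorted(bad)}")
    dup = table.duplicated(subset=["patient_id", "index_name"])
    if dup.any():
        raise DataError("observer table has duplicate patient x index rows")
    return table


def error_rate_report(table: pd.DataFrame,
                      threshold: float = ERROR_THRESHOLD) -> dict:
    """Per-index and pooled error counts/rates, manual and AI, pre/post.

    Denominators are the per-index case counts; the pooled denominator is
    their sum.  Rates are percentages rounded to one decimal.
    """
    table = _validate_table(table)
    counts: dict[str, dict[str, int]] = {}
    denoms: dict[str, int] = {}
    for index_name, group in table.groupby("index_name", sort=False):
        c = {"manual_pre": 0, "manual_post": 0, "ai_pre": 0, "ai_post": 0}
        for _, row in group.iterrows():
            triple = [row.obs1, row.obs2, row.obs3]
            pre = flag_error(triple, threshold)
            corrected, _ = fourth_person_correction(row, threshold) if pre.is_error \
                else (tuple(triple), False)
            post = flag_error(corrected, threshold)
            c["manual_pre"] += pre.is_error
            c["manual_post"] += post.is_error
            c["ai_pre"] += ai_error(row.ai, triple, threshold)
            c["ai_post"] += ai_error(row.ai, corrected, threshold)
        counts[index_name] = c
        denoms[index_name] = len(group)
    pooled = {k: sum(c[k] for c in counts.values())
              for k in ("manual_pre", "manual_post", "ai_pre", "ai_post")}
    pooled_n = sum(denoms.values())
    rates = {
        name: {k: round(100.0 * v / denoms[name], 1) for k, v in c.items()}
        for name, c in counts.items()
    }
    rates["total"] = {k: round(100.0 * v / pooled_n, 1) for k, v in pooled.items()}
    return {
        "counts": counts,
        "denominators": denoms,
        "pooled_counts": pooled,
        "pooled_denominator": pooled_n,
        "rates_pct": rates,
        "threshold": threshold,
    }


def pooled_error_rate(counts: Sequence[int], denominators: Sequence[int]) -> float:
    """Pooled percentage from per-index error counts, one decimal place."""
    counts = np.asarray(counts, dtype=int)
    denoms = np.asarray(denominators, dtype=int)
    if counts.shape != denoms.shape or (denoms <= 0).any():
        raise ParameterError("counts and positive denominators must align")
    if (counts > denoms).any():
        raise ParameterError("error count exceeds its denominator")
    return round(100.0 * counts.sum() / denoms.sum(), 1)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def pearson_chi2(table2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table via the closed form.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1; the Yates
    option subtracts n/2 from \\|ad - bc\\| before squaring.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ParameterError("need a 2x2 table of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ParameterError("2x2 table has a zero margin")
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    statistic = n * det**2 / margins
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def icc_single(ratings: np.ndarray) -> tuple[float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is (cases, raters).  Returns (icc, p) from the F test; a
    table with zero between-case variance is degenerate and returns NaNs.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 5 or r.shape[1] < 2:
        raise ParameterError("need >= 5 cases and >= 2 raters")
    if np.ptp(r.mean(axis=1)) == 0:
        return float("nan"), float("nan")
    n_cases, n_raters = r.shape
    df = pd.DataFrame({
        "case": np.repeat(np.arange(n_cases), n_raters),
        "rater": np.tile(np.arange(n_raters), n_cases),
        "score": r.ravel(),
    })
    import warnings

    with warnings.catch_warnings():
        # perfect-agreement tables yield infinite F ratios inside pingouin
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(df, targets="case", raters="rater",
                                 ratings="score").set_index("Type")
    # Two-way random effects, absolute agreement, single measures; the label
    # changed across pingouin releases.
    label = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
    row = res.loc[label]
    return float(row["ICC"]), float(row["pval"])


@dataclass
class BlandAltman:
    """Bias and 95 % limits of agreement, with the per-pair plot data."""

    bias: float
    lo: float
    hi: float
    relative: bool
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(x: Sequence[float], y: Sequence[float],
                 relative: bool = True) -> BlandAltman:
    """Bland-Altman agreement between reference ``x`` and method ``y``.

    With ``relative`` (the default) differences are percent of the pair
    mean, ``100 (y - x) / ((x + y)/2)``; otherwise raw differences.  Limits
    are bias ± 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d and paired")
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    if (x <= 0).any() or (y <= 0).any():
        raise ParameterError("paired values must be positive")
    means = (x + y) / 2.0
    if relative:
        diffs = 100.0 * (y - x) / means
    else:
        diffs = y - x
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if x.size > 1 else 0.0
    return BlandAltman(bias=bias, lo=bias - 1.96 * sd, hi=bias + 1.96 * sd,
                       relative=relative, means=means, diffs=diffs)


def agreement_report(table: pd.DataFrame,
                     threshold: float = ERROR_THRESHOLD) -> dict:
    """Full agreement summary of an observer table.

    Combines the error-rate section with, per index: pre-vs-post chi-square
    for manual and AI error counts, manual-vs-AI chi-square, ICC(2,1)
    between the corrected manual mean and the AI value, and Bland-Altman
    bias/limits on the percent scale.
    """
    table = _validate_table(table)
    report = {"errors": error_rate_report(table, threshold)}
    err = report["errors"]

    def chi2_pair(k1: str, k2: str, name: str) -> dict:
        c = err["counts"][name] if name in err["counts"] else err["pooled_counts"]
        n = err["denominators"].get(name, err["pooled_denominator"])
        t = [[c[k1], n - c[k1]], [c[k2], n - c[k2]]]
        try:
            s, p = pearson_chi2(t)
        except ParameterError:
            return {"statistic": None, "p": None}
        return {"statistic": s, "p": p}

    comparisons = {}
    for name in list(err["counts"]) + ["total"]:
        comparisons[name] = {
            "manual_pre_vs_post": chi2_pair("manual_pre", "manual_post", name),
            "ai_pre_vs_post": chi2_pair("ai_pre", "ai_post", name),
            "manual_vs_ai_pre": chi2_pair("manual_pre", "ai_pre", name),
            "manual_vs_ai_post": chi2_pair("manual_post", "ai_post", name),
        }
    report["chi_square"] = comparisons

    icc_section, ba_section = {}, {}
    for index_name, group in table.groupby("index_name", sort=False):
        corrected = np.array([
            fourth_person_correction(row, threshold)[0]
            for _, row in group.iterrows()
        ])
        manual_mean = corrected.mean(axis=1)
        ai_vals = group["ai"].to_numpy(dtype=float)
        if len(group) >= 5:
            icc, p = icc_single(np.column_stack([manual_mean, ai_vals]))
            icc_section[index_name] = {"icc": icc, "p": p}
        ba = bland_altman(manual_mean, ai_vals, relative=True)
        ba_section[index_name] = {"bias_pct": ba.bias, "lo_pct": ba.lo,
                                  "hi_pct": ba.hi}
    report["icc"] = icc_section
    report["bland_altman"] = ba_section
    return report


# ---------------------------------------------------------------------------
# Synthetic observer tables
# ---------------------------------------------------------------------------

def simulate_observer_table(n_patients: int = 164, seed: int = 0,
                            observer_cv: float = 0.05,
                            ai_cv: float = 0.04) -> pd.DataFrame:
    """A plausible observer table for protocol demonstrations and tests.

    True index values are drawn per patient from clinically plausible ranges
    (Haller 2.2-6, correction 10-45 %, asymmetry 0.9-1.3); observers read
    the truth with multiplicative noise of coefficient of variation
    ``observer_cv`` (the fourth observer at half that, emulating the senior
    referee), and the automatic method with ``ai_cv``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ranges = {"haller": (2.2, 6.0), "correction": (10.0, 45.0),
              "asymmetry": (0.9, 1.3)}
    for pid in range(n_patients):
        for index_name in INDEX_NAMES:
            lo, hi = ranges[index_name]
            truth = rng.uniform(lo, hi)
            obs = truth * (1 + rng.normal(0, observer_cv, 3))
            obs4 = truth * (1 + rng.normal(0, observer_cv / 2))
            ai = truth * (1 + rng.normal(0, ai_cv))
            rows.append({
                "patient_id": f"P{pid:04d}", "index_name": index_name,
                "obs1": abs(obs[0]), "obs2": abs(obs[1]), "obs3": abs(obs[2]),
                "obs4": abs(obs4), "ai": abs(ai),
            })
    return pd.DataFrame(rows)
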