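"""Phenotype comparisons between hatchery- and wild-born offspring.

Run timing (two-sample Kolmogorov-Smirnov by return year), age
composition (2-df chi-square on pooled age classes {3+4, 5, 6} by brood
year), freshwater age (Fisher's exact test on the 1-vs-2 lake-year 2x2
table), and size at age (per-brood-year OLS of mid-eye-to-fork length on
origin, sex and scale age as an ordered factor).  Families of p-values
are adjusted by the Holm step-down procedure.  These analyses consume
only strict-threshold assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "SizeAtAgeModel",
    "ks_run_timing",
    "age_composition_test",
    "freshwater_age_test",
    "size_at_age_fit",
    "holm_bonferroni",
    "broodstock_date_subset",
]

SCALE_AGE_LEVELS = ["1.2", "2.2", "1.3", "2.3"]  # ordered by total age, then lake years


@dataclass
class TestResult:
    name: str
    stratum: str
    statistic: float
    df: int | None
    p_raw: float
    p_adj: float | None = None
    n_hatchery: int = 0
    n_wild: int = 0
    extra: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class SizeAtAgeModel:
    brood_year: int
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    origin_p: float
    residual_sigma: float
    n: int
    diagnostics: dict = field(default_factory=dict)


def ks_run_timing(doy_hatchery, doy_wild, stratum: str = "") -> TestResult:
    """Two-sided two-sample KS test on return day of year.

    Reports D, the p-value (exact enumeration when min(n) <= 10, else
    asymptotic), and the median difference delta (negative = hatchery
    median earlier).
    """
    h = np.asarray(doy_hatchery, dtype=float)
    w = np.asarray(doy_wild, dtype=float)
    if len(h) == 0 or len(w) == 0:
        raise ValueError("both origin groups must be non-empty")
    method = "exact" if min(len(h), len(w)) <= 10 else "asymp"
    res = stats.ks_2samp(h, w, alternative="two-sided", method=method)
    delta = float(np.median(h) - np.median(w))
    return TestResult(
        name="ks_run_timing", stratum=stratum,
        statistic=float(res.statistic), df=None, p_raw=float(res.pvalue),
        n_hatchery=len(h), n_wild=len(w),
        extra={"delta_days": delta, "method": method},
    )


def age_composition_test(
    ages_hatchery, ages_wild, pool_classes: tuple[int, ...] = (3, 4), stratum: str = ""
) -> TestResult:
    """Chi-square homogeneity test of total-age composition.

    Rare young classes are pooled (default ages 3 and 4), leaving the
    classes {3+4, 5, 6} and 2 degrees of freedom.
    """
    h = np.asarray(ages_hatchery, dtype=int)
    w = np.asarray(ages_wild, dtype=int)
    for a in np.concatenate([h, w]):
        if a not in (3, 4, 5, 6):
            raise ValueError(f"total age {a} outside 3-6")
    classes = [tuple(sorted(pool_classes))] + [(a,) for a in (5, 6) if a not in pool_classes]

    def tally(x):
        return [int(np.isin(x, cls).sum()) for cls in classes]

    table = np.array([tally(h), tally(w)])
    col_zero = np.flatnonzero(table.sum(axis=0) == 0)
    if len(col_zero):
        raise ValueError(f"expected count of 0 in age class {classes[col_zero[0]]}")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("one origin group is empty")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        name="age_composition_chi2", stratum=stratum,
        statistic=float(chi2), df=int(dof), p_raw=float(p),
        n_hatchery=len(h), n_wild=len(w),
        extra={"classes": classes, "table": table.tolist()},
    )


def freshwater_age_test(fw_hatchery, fw_wild, stratum: str = "") -> TestResult:
    """Two-sided Fisher's exact test on the freshwater-age (1 vs 2) table."""
    h = np.asarray(fw_hatchery, dtype=int)
    w = np.asarray(fw_wild, dtype=int)
    for a in np.concatenate([h, w]):
        if a not in (1, 2):
            raise ValueError(f"freshwater age {a} outside {{1, 2}}")
    table = np.array(
        [[int((h == 1).sum()), int((h == 2).sum())],
         [int((w == 1).sum()), int((w == 2).sum())]]
    )
    note = ""
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p, odds, note = 1.0, float("nan"), "empty margin"
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        name="freshwater_age_fisher", stratum=stratum,
        statistic=float(odds) if np.isfinite(odds) else float("nan"),
        df=1, p_raw=float(p), n_hatchery=len(h), n_wild=len(w),
        extra={"table": table.tolist()}, note=note,
    )


def size_at_age_fit(
    records: pd.DataFrame,
    brood_year: int | None = None,
    scale_age_levels: list[str] | None = None,
) -> SizeAtAgeModel:
    """OLS of MEFL on origin, sex, and scale age (ordered factor).

    ``records`` needs columns mefl_mm, origin (hatchery/wild), sex (F/M)
    and scale_age restricted to the levels found in both origins (default
    1.2, 2.2, 1.3, 2.3).  One brood year per fit.  Raises on a
    rank-deficient design, naming the collinear term.
    """
    levels = scale_age_levels or SCALE_AGE_LEVELS
    df = records[records["scale_age"].isin(levels)].copy()
    if df.empty or df["origin"].nunique() < 2:
        raise ValueError("need records from both origins")
    y = df["mefl_mm"].to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": 1.0}, index=df.index)
    X["origin[hatchery]"] = (df["origin"] == "hatchery").astype(float)
    X["sex[M]"] = (df["sex"] == "M").astype(float)
    present = [lv for lv in levels if (df["scale_age"] == lv).any()]
    for lv in present[1:]:  # treatment contrasts over the ordered levels
        X[f"scale_age[{lv}]"] = (df["scale_age"] == lv).astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for c in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X.to_numpy()[:, :c]) < c:
                raise ValueError(f"design matrix rank-deficient at term {X.columns[c - 1]!r}")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    diagnostics = {
        "resid_skew": float(stats.skew(resid)),
        "resid_kurtosis": float(stats.kurtosis(resid)),
        "shapiro_p": float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else float("nan"),
    }
    return SizeAtAgeModel(
        brood_year=int(brood_year) if brood_year is not None else -1,
        coefficients={k: float(v) for k, v in fit.params.items()},
        std_errors={k: float(v) for k, v in fit.bse.items()},
        origin_p=float(fit.pvalues["origin[hatchery]"]),
        residual_sigma=float(np.sqrt(fit.scale)),
        n=int(fit.nobs),
        diagnostics=diagnostics,
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def broodstock_date_subset(
    assignments: pd.DataFrame,
    registry: pd.DataFrame,
    brood_year: int,
    collection_window: tuple[int, int],
) -> list[str]:
    """Wild-born offspring with >= 1 assigned parent returning inside the
    2-day broodstock collection window for that brood year."""
    lo, hi = collection_window
    reg = registry.set_index("id")
    sub = assignments[assignments["brood_year"] == brood_year]
    out = []
    for rec in sub.itertuples(index=False):
        parents = [p for p in (rec.dam_id, rec.sire_id) if p]
        if not parents:
            continue
        if any(reg.at[p, "is_broodstock"] for p in parents if p in reg.index):
            continue  # hatchery-born
        if any(
            lo <= int(reg.at[p, "return_doy"]) <= hi for p in parents if p in reg.index
        ):
            out.append(rec.offspring_id)
    return out
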