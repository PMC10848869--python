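"""Relative productivity of hatchery vs wild spawners.

Productivity is the mean number of returning adult offspring assigned to
a spawner (per brood year and sex); relative productivity (RP) is the
hatchery mean divided by the wild mean, reported for females.  The 95%
confidence interval treats each assigned offspring as hatchery-parented
with probability p(w) = Nh*w / (Nh*w + Nw) and profiles the binomial
log-likelihood: the CI is the set of w whose deviance from the MLE is
within the chi-square(1) critical value.  A parametric-bootstrap CI is
provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ParentCount",
    "RPEstimate",
    "count_offspring",
    "relative_productivity",
    "rp_confidence_interval",
    "rp_bootstrap_ci",
    "rp_estimate",
    "expected_wild_contribution",
    "threshold_sensitivity",
]


@dataclass
class ParentCount:
    parent_id: str
    sex: str
    origin: str
    brood_year: int
    n_offspring: int
    included: bool = True
    reason: str = ""


@dataclass
class RPEstimate:
    brood_year: int
    n_dams_h: int
    n_dams_w: int
    offspring_h: int
    offspring_w: int
    w_hat: float
    ci_lo: float
    ci_hi: float
    alpha: float


def count_offspring(
    assignments: pd.DataFrame,
    registry: pd.DataFrame,
    brood_year: int,
    sex: str = "F",
    threshold: float | None = None,
    excluded_parents: dict[str, str] | None = None,
) -> list[ParentCount]:
    """Per-parent accepted-offspring counts for one brood year and sex.

    Spawners of that brood year (every registered adult of that return
    year, split into broodstock = hatchery and the rest = wild) each
    receive a count, zero included.  A dyad is counted when its LOD meets
    ``threshold`` (None = no threshold, the no-cutoff sensitivity run).
    Parents named in ``excluded_parents`` (e.g. genotype-completeness
    failures) are carried with ``included=False`` and receive no counts.
    """
    excluded_parents = excluded_parents or {}
    spawners = registry[registry["return_year"] == brood_year]
    # sex: reconciled slot usage determines the role; registry sex selects
    # the denominator population (jacks count as male spawners)
    sex_col = spawners["sex_field"].replace({"J": "M"})
    spawners = spawners[sex_col == sex]

    slot = "dam_id" if sex == "F" else "sire_id"
    lod_col = "dam_lod" if sex == "F" else "sire_lod"
    acc = assignments[assignments[slot].notna() & (assignments["brood_year"] == brood_year)]
    if threshold is not None:
        acc = acc[acc[lod_col] >= threshold]
    tallies = acc[slot].value_counts().to_dict()

    out = []
    for rec in spawners.itertuples(index=False):
        origin = "hatchery" if rec.is_broodstock else "wild"
        if rec.id in excluded_parents:
            out.append(
                ParentCount(rec.id, sex, origin, brood_year, 0, included=False,
                            reason=excluded_parents[rec.id])
            )
        else:
            out.append(
                ParentCount(rec.id, sex, origin, brood_year, int(tallies.get(rec.id, 0)))
            )
    return out


def relative_productivity(
    offspring_h: float, n_dams_h: int, offspring_w: float, n_dams_w: int
) -> float:
    """RP = (hatchery offspring per dam) / (wild offspring per dam).

    Returns inf (flagged by the caller) when wild offspring are zero.
    """
    if n_dams_h < 1 or n_dams_w < 1:
        raise ValueError("need at least one dam in each group")
    if offspring_w == 0:
        return float("inf")
    return (offspring_h / n_dams_h) / (offspring_w / n_dams_w)


def _profile_loglik(w: float, oh: int, nh: int, ow: int, nw: int) -> float:
    p = nh * w / (nh * w + nw)
    ll = 0.0
    if oh:
        ll += oh * np.log(p)
    if ow:
        ll += ow * np.log1p(-p)
    return ll


def rp_confidence_interval(
    offspring_h: int, n_dams_h: int, offspring_w: int, n_dams_w: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Profile-likelihood CI for relative productivity.

    Endpoints solve 2*[lnL(w_hat) - lnL(w)] = chi2(1, 1-alpha), located
    by bracketed root-finding to |2*dlnL - crit| < 1e-8.  With zero
    hatchery offspring the interval is one-sided from 0.
    """
    oh, nh, ow, nw = offspring_h, n_dams_h, offspring_w, n_dams_w
    if oh + ow < 1:
        raise ValueError("no assigned offspring")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    if ow == 0:
        w_hat = float("inf")
    else:
        w_hat = relative_productivity(oh, nh, ow, nw)
    ll_hat = (
        _profile_loglik(w_hat, oh, nh, ow, nw)
        if np.isfinite(w_hat) and w_hat > 0
        else (oh * np.log(oh / (oh + ow)) if oh else 0.0) + (ow * np.log(ow / (oh + ow)) if ow else 0.0)
    )

    def dev(w: float) -> float:
        return 2.0 * (ll_hat - _profile_loglik(w, oh, nh, ow, nw)) - crit

    lo_bracket = 1e-12
    if oh == 0:
        lo = 0.0
    else:
        lo = float(optimize.brentq(dev, lo_bracket, w_hat, xtol=1e-12, rtol=1e-14))
    if ow == 0:
        hi = float("inf")
    else:
        upper = max(w_hat * 2, 1.0)
        while dev(upper) < 0:
            upper *= 2
        hi = float(optimize.brentq(dev, max(w_hat, lo_bracket), upper, xtol=1e-12, rtol=1e-14))
    return lo, hi


def rp_bootstrap_ci(
    counts_h: np.ndarray, counts_w: np.ndarray, alpha: float = 0.05,
    n_boot: int = 2000, seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI over per-dam counts (cross-check oracle)."""
    rng = np.random.default_rng(seed)
    ch = np.asarray(counts_h)
    cw = np.asarray(counts_w)
    reps = []
    for _ in range(n_boot):
        mh = rng.choice(ch, size=len(ch)).mean()
        mw = rng.choice(cw, size=len(cw)).mean()
        if mw > 0:
            reps.append(mh / mw)
    return tuple(np.quantile(reps, [alpha / 2, 1 - alpha / 2]))


def rp_estimate(
    counts_h: list[ParentCount], counts_w: list[ParentCount], alpha: float = 0.05
) -> RPEstimate:
    """RP point estimate and profile-likelihood CI from per-parent counts."""
    inc_h = [c for c in counts_h if c.included]
    inc_w = [c for c in counts_w if c.included]
    if not inc_h or not inc_w:
        raise ValueError("a brood year needs at least one included dam per group")
    nh, nw = len(inc_h), len(inc_w)
    oh = sum(c.n_offspring for c in inc_h)
    ow = sum(c.n_offspring for c in inc_w)
    w_hat = relative_productivity(oh, nh, ow, nw)
    lo, hi = rp_confidence_interval(oh, nh, ow, nw, alpha=alpha)
    return RPEstimate(
        brood_year=inc_h[0].brood_year,
        n_dams_h=nh, n_dams_w=nw, offspring_h=oh, offspring_w=ow,
        w_hat=w_hat, ci_lo=lo, ci_hi=hi, alpha=alpha,
    )


def expected_wild_contribution(n_females: int, offspring_w: int, n_dams_w: int) -> int:
    """Adults the broodstock females would have produced spawning in the
    wild: n_females times the wild per-dam mean, to the nearest integer."""
    if n_dams_w < 1:
        raise ValueError("n_dams_w must be >= 1")
    return int(round(n_females * offspring_w / n_dams_w))


def threshold_sensitivity(
    assignments: pd.DataFrame,
    registry: pd.DataFrame,
    brood_year: int,
    threshold: float,
    alpha: float = 0.05,
    excluded_parents: dict[str, str] | None = None,
) -> pd.DataFrame:
    """RP with the acceptance threshold vs with no LOD cutoff.

    Returns a two-row frame with the paired estimates and their absolute
    and relative difference; a non-finite thresholded RP is flagged.
    """
    rows = []
    for label, thr in (("no_threshold", None), ("lod_accept", threshold)):
        ch = count_offspring(assignments, registry, brood_year, "F", thr, excluded_parents)
        cw = [c for c in ch if c.origin == "wild"]
        chh = [c for c in ch if c.origin == "hatchery"]
        est = rp_estimate(chh, cw, alpha=alpha)
        rows.append({"mode": label, "brood_year": brood_year, "rp": est.w_hat,
                     "ci_lo": est.ci_lo, "ci_hi": est.ci_hi,
                     "offspring_h": est.offspring_h, "offspring_w": est.offspring_w})
    df = pd.DataFrame(rows)
    base, thr_rp = df.loc[0, "rp"], df.loc[1, "rp"]
    df["abs_diff"] = abs(thr_rp - base)
    df["rel_diff"] = abs(thr_rp - base) / base if np.isfinite(base) and base > 0 else np.nan
    df["flagged"] = ~np.isfinite(df["rp"])
    return df
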