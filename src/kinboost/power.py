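"""Assignment-power calibration by kin-pair simulation.

LOD distributions are simulated from the panel allele frequencies for
parent-offspring (PO), unrelated (U), and avuncular (AV) dyads, with the
same mistyping model used by the assignment likelihood.  From the PO and
U distributions the false-negative rate FNR(t) = P(PO LOD < t) and
false-positive rate FPR(t) = P(U LOD >= t) are estimated for any
threshold t, and the acceptance threshold is chosen as the smallest t
whose estimated FPR meets a target.  For tail FPRs below the Monte-Carlo
resolution an importance-sampling estimator is provided: U-tail
probabilities are computed from PO draws reweighted by the per-dyad
likelihood ratio, P_U(LOD >= t) = E_PO[ exp(-LOD) 1{LOD >= t} ].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .likelihood import LikelihoodTables, build_tables
from .panel import PanelConfig

__all__ = [
    "PowerResult",
    "ThresholdReport",
    "simulate_dyad_lods",
    "estimate_rates",
    "choose_threshold",
]

RELATIONSHIPS = ("PO", "U", "AV")


@dataclass
class PowerResult:
    relationship: str
    lod_samples: np.ndarray
    n: int
    eps: float
    weights: np.ndarray | None = None  # importance weights for U-tail estimation


@dataclass
class ThresholdReport:
    threshold: float
    fnr: float
    fpr: float
    fnr_ci: tuple[float, float]
    fpr_ci: tuple[float, float]
    fpr_av: float | None = None


def _hw_draw(rng, freqs: np.ndarray, n: int) -> np.ndarray:
    """(n, 2) allele draws from Hardy-Weinberg proportions."""
    return rng.choice(len(freqs), size=(n, 2), p=freqs)


def _codes(pairs: np.ndarray) -> np.ndarray:
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    return hi * (hi + 1) // 2 + lo


def _mistype(rng, pairs: np.ndarray, freqs: np.ndarray, eps: float) -> np.ndarray:
    if eps <= 0:
        return pairs
    hit = rng.random(len(pairs)) < eps
    n_hit = int(hit.sum())
    if n_hit:
        pairs = pairs.copy()
        pairs[hit] = _hw_draw(rng, freqs, n_hit)
    return pairs


def simulate_dyad_lods(
    panel: PanelConfig,
    relationship: str,
    n: int,
    eps: float | None = None,
    seed: int = 0,
    importance: bool = False,
) -> PowerResult:
    """Simulate n dyads of the given relationship and score their LODs.

    PO: offspring of a Hardy-Weinberg parent with a Hardy-Weinberg mate.
    U: two independent Hardy-Weinberg genotypes.
    AV: aunt/uncle-nibling via shared grandparents (two full sibs; one
    sib's offspring against the other sib).
    With ``importance=True`` (PO draws reweighted toward the U null) the
    result carries per-sample weights exp(-LOD) for tail-FPR estimation.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship: {relationship!r}; expected one of {RELATIONSHIPS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tables = build_tables(panel, eps)
    e = tables.eps
    L = panel.n_loci
    lod = np.zeros(n)
    for l, locus in enumerate(panel.loci):
        freqs = locus.freqs
        sim_rel = "PO" if importance else relationship
        if sim_rel == "U":
            g1 = _hw_draw(rng, freqs, n)
            g2 = _hw_draw(rng, freqs, n)
        elif sim_rel == "PO":
            parent = _hw_draw(rng, freqs, n)
            transmitted = parent[np.arange(n), rng.integers(0, 2, n)]
            mate = rng.choice(len(freqs), size=n, p=freqs)
            g1 = np.column_stack([transmitted, mate])  # offspring
            g2 = parent
        else:  # AV
            gp1 = _hw_draw(rng, freqs, n)
            gp2 = _hw_draw(rng, freqs, n)
            def sib():
                a = gp1[np.arange(n), rng.integers(0, 2, n)]
                b = gp2[np.arange(n), rng.integers(0, 2, n)]
                return np.column_stack([a, b])
            s1, s2 = sib(), sib()
            transmitted = s1[np.arange(n), rng.integers(0, 2, n)]
            mate = rng.choice(len(freqs), size=n, p=freqs)
            g1 = np.column_stack([transmitted, mate])  # nibling
            g2 = s2  # aunt/uncle as candidate parent
        g1 = _mistype(rng, g1, freqs, e)
        g2 = _mistype(rng, g2, freqs, e)
        lod += tables.log_lr[l][_codes(g1), _codes(g2)]
    weights = np.exp(-lod) if importance else None
    return PowerResult(relationship=relationship, lod_samples=lod, n=n, eps=e, weights=weights)


def _fpr_at(u: PowerResult, threshold: float) -> float:
    if u.weights is not None:
        return float(np.mean(u.weights * (u.lod_samples >= threshold)))
    return float(np.mean(u.lod_samples >= threshold))


def estimate_rates(
    po: PowerResult, u: PowerResult, threshold: float, av: PowerResult | None = None
) -> ThresholdReport:
    """Empirical FNR/FPR at a threshold, with Wilson 95% intervals."""
    if po.n == 0 or u.n == 0:
        raise ValueError("empty LOD samples")
    if po.eps != u.eps:
        raise ValueError("PO and U results use different error rates")
    fn = int(np.sum(po.lod_samples < threshold))
    fnr = fn / po.n
    fnr_ci = proportion_confint(fn, po.n, alpha=0.05, method="wilson")
    fpr = _fpr_at(u, threshold)
    if u.weights is None:
        fp = int(np.sum(u.lod_samples >= threshold))
        fpr_ci = proportion_confint(fp, u.n, alpha=0.05, method="wilson")
    else:
        contrib = u.weights * (u.lod_samples >= threshold)
        se = float(np.std(contrib, ddof=1) / np.sqrt(u.n))
        fpr_ci = (max(0.0, fpr - 1.96 * se), fpr + 1.96 * se)
    fpr_av = _fpr_at(av, threshold) if av is not None else None
    return ThresholdReport(
        threshold=float(threshold),
        fnr=float(fnr),
        fpr=float(fpr),
        fnr_ci=(float(fnr_ci[0]), float(fnr_ci[1])),
        fpr_ci=(float(fpr_ci[0]), float(fpr_ci[1])),
        fpr_av=fpr_av,
    )


def choose_threshold(
    po: PowerResult, u: PowerResult, target_fpr: float, av: PowerResult | None = None
) -> ThresholdReport:
    """Smallest threshold whose estimated FPR is <= the target."""
    if not 0.0 < target_fpr <= 1.0:
        raise ValueError("target_fpr must be in (0, 1]")
    if u.weights is None and target_fpr < 1.0 / u.n:
        raise ValueError(
            f"target FPR {target_fpr} below Monte-Carlo resolution 1/{u.n}; "
            "increase n or use an importance-sampled U result"
        )
    candidates = np.unique(u.lod_samples)
    chosen = None
    for t in candidates:  # ascending; FPR(t) is nonincreasing in t
        if _fpr_at(u, t) <= target_fpr:
            chosen = float(t)
            break
    if chosen is None:
        chosen = float(np.nextafter(candidates[-1], np.inf))
    return estimate_rates(po, u, chosen, av=av)
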