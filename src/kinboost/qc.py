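"""Locus and individual screening.

Hardy-Weinberg chi-square tests with F_IS per sample year (persistent
positive F_IS across years flags likely null alleles), Monte-Carlo
permutation tests for pairwise linkage within years with Fisher's-method
pooling across years, and the genotype-completeness filters applied to
offspring and candidate parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .panel import code_to_pair, geno_code, n_geno_codes

__all__ = [
    "LocusQCResult",
    "PairLDResult",
    "hwe_test",
    "hwe_scan",
    "null_allele_screen",
    "ld_pair_test",
    "filter_individuals",
    "qc_report",
]


@dataclass
class LocusQCResult:
    locus: str
    year: str  # a year label or "pooled"
    chi2: float
    df: int
    p_raw: float
    f_is: float  # NaN when undefined (monomorphic)
    n_genotyped: int
    monomorphic: bool = False


@dataclass
class PairLDResult:
    locus_a: str
    locus_b: str
    year: str
    p_raw: float
    note: str = ""


def hwe_test(genotype_counts, locus: str = "", year: str = "pooled") -> LocusQCResult:
    """Hardy-Weinberg chi-square test and F_IS from genotype counts.

    ``genotype_counts`` maps unordered allele pairs (tuples of allele
    indices) to counts.  Allele frequencies are estimated from the
    sample; all k(k+1)/2 genotype classes enter the chi-square with
    df = k(k-1)/2 (no pooling of rare classes: the screen is advisory).
    A monomorphic locus yields chi2 = 0 and an undefined (NaN) F_IS.
    """
    counts: dict[tuple[int, int], float] = {}
    for pair, c in genotype_counts.items():
        if c == 0:
            continue
        a, b = sorted(pair)
        counts[(a, b)] = counts.get((a, b), 0) + c
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("no non-missing genotypes")
    alleles = sorted({a for pair in counts for a in pair})
    k = len(alleles)
    if k == 1:
        return LocusQCResult(locus, year, 0.0, 0, 1.0, float("nan"), int(n), monomorphic=True)
    remap = {a: i for i, a in enumerate(alleles)}
    freqs = np.zeros(k)
    for (a, b), c in counts.items():
        freqs[remap[a]] += c
        freqs[remap[b]] += c
    freqs /= 2.0 * n

    chi2 = 0.0
    het_obs = 0.0
    for j in range(k):
        for i in range(j + 1):
            exp_p = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
            obs = counts.get((alleles[i], alleles[j]), 0)
            exp = exp_p * n
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
            if i != j:
                het_obs += obs
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    he = 1.0 - float(np.sum(freqs**2))
    f_is = 1.0 - (het_obs / n) / he
    return LocusQCResult(locus, year, float(chi2), df, p, float(f_is), int(n))


def _locus_counts(gt: GenotypeTable, locus_index: int, rows: np.ndarray) -> dict:
    al = gt.alleles[rows, locus_index]
    ok = al[:, 0] >= 0
    counts: dict[tuple[int, int], int] = {}
    for a, b in al[ok]:
        key = (int(min(a, b)), int(max(a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def hwe_scan(gt: GenotypeTable, years: pd.Series) -> list[LocusQCResult]:
    """Per-locus, per-year Hardy-Weinberg tests for a genotype table.

    ``years`` maps individual id -> sample year (e.g. return year).
    """
    yr = years.reindex(gt.ids).to_numpy()
    results = []
    for y in sorted(pd.unique(yr[~pd.isna(yr)])):
        rows = np.flatnonzero(yr == y)
        for l, locus in enumerate(gt.panel.loci):
            counts = _locus_counts(gt, l, rows)
            if counts:
                results.append(hwe_test(counts, locus=locus.name, year=str(int(y))))
    return results


def null_allele_screen(per_year_results: list[LocusQCResult], p_threshold: float = 0.01) -> bool:
    """Flag a locus whose F_IS is positive in every year with at least one
    year significant at ``p_threshold`` — the signature of a segregating
    null allele."""
    if len(per_year_results) < 2:
        raise ValueError("null-allele screen needs results from >= 2 years")
    f = np.array([r.f_is for r in per_year_results])
    p = np.array([r.p_raw for r in per_year_results])
    if np.isnan(f).any():
        return False
    return bool((f > 0).all() and (p < p_threshold).any())


def _g_statistic(table: np.ndarray) -> float:
    t = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = t.sum()
    if n == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / exp), 0.0)
    return 2.0 * float(terms.sum())


def _permutation_p(codes_a, codes_b, n_permutations: int, rng) -> float:
    """Monte-Carlo permutation p-value (add-one rule) of the genotypic
    contingency-table G statistic."""
    na = int(codes_a.max()) + 1
    nb = int(codes_b.max()) + 1

    def gstat(b):
        table = np.bincount(codes_a * nb + b, minlength=na * nb).reshape(na, nb)
        return _g_statistic(table)

    obs = gstat(codes_b)
    b = codes_b.copy()
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(b)
        if gstat(b) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def ld_pair_test(
    gt: GenotypeTable,
    locus_a: str,
    locus_b: str,
    years: pd.Series,
    year: str | int = "pooled",
    n_permutations: int = 1000,
    seed: int = 0,
) -> PairLDResult:
    """Test for non-random association of genotypes at two loci.

    Within a year the p-value is a Monte-Carlo permutation p of the
    genotypic contingency-table G statistic (one locus's genotypes
    shuffled within the year, add-one rule so p >= 1/(n+1)).  The pooled
    test combines per-year p-values by Fisher's method.
    """
    rng = np.random.default_rng(seed)
    la = gt.panel.names.index(locus_a)
    lb = gt.panel.names.index(locus_b)
    codes = gt.codes()
    yr = years.reindex(gt.ids).to_numpy()

    def one_year(y) -> PairLDResult:
        rows = np.flatnonzero((yr == y) & (codes[:, la] >= 0) & (codes[:, lb] >= 0))
        ca, cb = codes[rows, la], codes[rows, lb]
        if len(rows) == 0 or len(np.unique(ca)) < 2 or len(np.unique(cb)) < 2:
            return PairLDResult(locus_a, locus_b, str(y), 1.0, note="monomorphic in stratum")
        p = _permutation_p(ca.astype(np.int64), cb.astype(np.int64), n_permutations, rng)
        return PairLDResult(locus_a, locus_b, str(y), p, note="permutation G-test")

    if year != "pooled":
        return one_year(int(year))
    per_year = [one_year(int(y)) for y in sorted(pd.unique(yr[~pd.isna(yr)]))]
    ps = [r.p_raw for r in per_year]
    if len(ps) == 1:
        pooled = ps[0]
    else:
        stat = -2.0 * np.sum(np.log(ps))
        pooled = float(stats.chi2.sf(stat, 2 * len(ps)))
    return PairLDResult(locus_a, locus_b, "pooled", pooled, note="Fisher's method over years")


def filter_individuals(
    gt: GenotypeTable,
    role: str,
    min_loci: int = 40,
    max_missing_str: int = 5,
    max_missing_snp: int = 22,
    ids: list[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Apply the genotype-completeness filters.

    Everyone needs >= ``min_loci`` genotyped loci.  Candidate parents are
    additionally excluded when missing >= ``max_missing_str`` STRs or
    >= ``max_missing_snp`` SNPs.  Returns (kept ids, excluded id -> reason).
    """
    if role not in ("offspring", "parent"):
        raise ValueError(f"unknown role: {role}")
    if ids is None:
        ids = list(gt.ids)
    rows = np.array([gt.row(i) for i in ids], dtype=int)
    miss = gt.missing_mask()[rows]
    n_typed = (~miss).sum(axis=1)
    str_missing = miss[:, gt.panel.str_indices].sum(axis=1)
    snp_missing = miss[:, gt.panel.snp_indices].sum(axis=1)

    kept: list[str] = []
    excluded: dict[str, str] = {}
    for i, ind in enumerate(ids):
        if n_typed[i] < min_loci:
            excluded[ind] = f"fewer than {min_loci} genotyped loci ({n_typed[i]})"
        elif role == "parent" and str_missing[i] >= max_missing_str:
            excluded[ind] = f"missing >= {max_missing_str} STRs ({str_missing[i]})"
        elif role == "parent" and snp_missing[i] >= max_missing_snp:
            excluded[ind] = f"missing >= {max_missing_snp} SNPs ({snp_missing[i]})"
        else:
            kept.append(ind)
    return kept, excluded


def qc_report(results: list[LocusQCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus for r in results],
            "year": [r.year for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "f_is": [r.f_is for r in results],
            "n_genotyped": [r.n_genotyped for r in results],
        }
    )
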