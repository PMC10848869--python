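"""Synthetic populations with overlapping generations and hatchery crosses.

The simulator emulates a small sockeye salmon system sampled exhaustively
at a weir: every returning adult is registered (year, field sex, run day,
length, optional scale age) and genotyped on a mixed SNP/STR panel.  A few
brood years are supplemented: ~30 females and ~15 males are removed as
broodstock and crossed 2:1 (two dams per sire), and their offspring return
3-6 years later alongside wild-born fish.  Wild per-dam productivity sits
near or below one returning adult; hatchery per-dam productivity is an
order of magnitude higher.  Offspring counts per dam are negative binomial
(heavy-tailed, most wild dams produce zero returning adults), total age is
3-6 with hatchery fish skewed younger, and hatchery fish are more likely
to leave the lake after one winter rather than two.

Ground truth (the full pedigree) is returned alongside the registry so the
parentage machinery can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable
from .panel import PanelConfig

__all__ = [
    "SimConfig",
    "ConfigError",
    "PedigreeError",
    "simulate_population",
    "simulate_genotypes",
    "apply_sex_misid",
    "write_fixture",
    "read_fixture",
    "broodstock_window",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PedigreeError(ValueError):
    """Pedigree references an unknown individual."""


def _default_run_sizes() -> dict[int, int]:
    # 2011-2019 follow weir counts observed in a small supplemented sockeye
    # system; 2008-2010 are unsupplemented seed years inside the same range.
    return {
        2008: 2400, 2009: 1800, 2010: 2200,
        2011: 2423, 2012: 1556, 2013: 2060,
        2014: 3443, 2015: 4720, 2016: 2519,
        2017: 3663, 2018: 923, 2019: 1106,
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults reproduce the structure of the supplemented system: 12
    return years, 3 supplemented brood years with a 30-dam/15-sire 2:1
    broodstock design, wild mean productivity below replacement and
    hatchery productivity roughly 20x higher, ages 3-6 (hatchery skewed
    young), and 5% field sex misidentification.
    """

    run_sizes: dict[int, int] = field(default_factory=_default_run_sizes)
    female_fraction: float = 0.5
    jack_fraction: float = 0.05  # fraction of males maturing as age-3 jacks
    brood_years_supplemented: tuple[int, ...] = (2011, 2012, 2013)
    n_broodstock_dams: int = 30
    n_broodstock_sires: int = 15
    cross_ratio: int = 2  # dams per sire
    prespawn_failure: float = 0.1
    hatchery_mean_offspring: float = 17.0
    hatchery_dispersion: float | None = 1.5  # NB size parameter; None = deterministic
    wild_mean_offspring: float = 0.8
    wild_dispersion: float | None = 0.3
    age_dist_wild: dict[int, float] = field(
        default_factory=lambda: {3: 0.01, 4: 0.06, 5: 0.45, 6: 0.48}
    )
    age_dist_hatchery: dict[int, float] = field(
        default_factory=lambda: {3: 0.005, 4: 0.16, 5: 0.75, 6: 0.085}
    )
    fw1_prob_wild: float = 0.25
    fw1_prob_hatchery: float = 0.75
    run_day_mean: float = 200.0
    run_day_sd: float = 12.0
    length_mean: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("F", 3): 390.0, ("F", 4): 480.0, ("F", 5): 530.0, ("F", 6): 560.0,
            ("M", 3): 360.0, ("M", 4): 500.0, ("M", 5): 550.0, ("M", 6): 580.0,
        }
    )
    length_sd: float = 30.0
    scale_sample_frac: float = 0.12
    sex_misid_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "female_fraction", "jack_fraction", "prespawn_failure",
            "fw1_prob_wild", "fw1_prob_hatchery", "scale_sample_frac",
            "sex_misid_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if any(n <= 0 for n in self.run_sizes.values()):
            raise ConfigError("run sizes must be positive")
        for label, dist in (("wild", self.age_dist_wild), ("hatchery", self.age_dist_hatchery)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"age_dist_{label} does not sum to 1")
            if any(a not in (3, 4, 5, 6) for a in dist):
                raise ConfigError(f"age_dist_{label} has ages outside 3-6")
        if self.wild_mean_offspring < 0 or self.hatchery_mean_offspring < 0:
            raise ConfigError("offspring means must be non-negative")
        if self.n_broodstock_dams < 0 or self.n_broodstock_sires < 0 or self.cross_ratio < 1:
            raise ConfigError("invalid broodstock design")

    @property
    def years(self) -> list[int]:
        return sorted(self.run_sizes)


def _draw_counts(rng, mean: float, dispersion: float | None, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if mean == 0:
        return np.zeros(n, dtype=int)
    if dispersion is None:
        return np.full(n, int(round(mean)), dtype=int)
    # negative binomial parameterised by mean and size k: p = k / (k + mu)
    k = dispersion
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=n)


def _draw_ages(rng, dist: dict[int, float], n: int) -> np.ndarray:
    ages = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[a] for a in ages])
    return rng.choice(ages, size=n, p=probs)


def simulate_population(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full multi-year run and its true pedigree.

    Returns ``(registry, truth)``.  ``registry`` has one row per returning
    adult (columns id, return_year, sex_true, sex_field, origin_true,
    total_age, fw_age, return_doy, mefl_mm, scale_age, is_broodstock).
    ``truth`` maps pedigreed offspring to their true dam, sire, brood year
    and origin; fish whose parents predate the simulation are founders and
    carry no truth row.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pending: dict[int, list[dict]] = {}
    registry_rows: list[dict] = []
    truth_rows: list[dict] = []

    for year in cfg.years:
        target = cfg.run_sizes[year]
        offspring = pending.pop(year, [])
        n_founders = max(0, target - len(offspring))

        specs: list[dict] = []
        for rec in offspring:
            specs.append(dict(rec, founder=False))
        for _ in range(n_founders):
            specs.append(dict(founder=True))

        rng.shuffle(specs)
        year_rows: list[dict] = []
        for i, sp in enumerate(specs):
            ind_id = f"{year}_{i:05d}"
            if sp["founder"]:
                sex = "F" if rng.random() < cfg.female_fraction else "M"
                if sex == "M" and rng.random() < cfg.jack_fraction:
                    age = 3
                else:
                    age = int(_draw_ages(rng, cfg.age_dist_wild, 1)[0])
                origin = "wild"
            else:
                sex = "F" if rng.random() < 0.5 else "M"
                age = sp["total_age"]
                origin = sp["origin"]
                truth_rows.append(
                    {
                        "offspring_id": ind_id,
                        "dam_id": sp["dam_id"],
                        "sire_id": sp["sire_id"],
                        "brood_year": sp["brood_year"],
                        "origin": origin,
                    }
                )
            is_jack = sex == "M" and age == 3
            if age == 3:
                fw = 1
            else:
                p1 = cfg.fw1_prob_hatchery if origin == "hatchery" else cfg.fw1_prob_wild
                fw = 1 if rng.random() < p1 else 2
            doy = int(np.clip(round(rng.normal(cfg.run_day_mean, cfg.run_day_sd)), 140, 300))
            mefl = rng.normal(cfg.length_mean[(sex, age)], cfg.length_sd)
            if is_jack:
                mefl = min(mefl, 400.0)
            scale = f"{fw}.{age - fw - 1}" if rng.random() < cfg.scale_sample_frac else None
            year_rows.append(
                {
                    "id": ind_id,
                    "return_year": year,
                    "sex_true": sex,
                    "sex_field": "J" if is_jack else sex,
                    "origin_true": origin,
                    "total_age": age,
                    "fw_age": fw,
                    "return_doy": doy,
                    "mefl_mm": round(float(mefl), 1),
                    "scale_age": scale,
                    "is_broodstock": False,
                }
            )

        # --- broodstock selection (supplemented brood years only) -------
        if year in cfg.brood_years_supplemented:
            females = [r for r in year_rows if r["sex_true"] == "F"]
            males = [r for r in year_rows if r["sex_true"] == "M" and r["sex_field"] != "J"]
            if len(females) < cfg.n_broodstock_dams or len(males) < cfg.n_broodstock_sires:
                raise ConfigError(f"run in {year} too small for broodstock targets")
            dams = list(rng.choice(len(females), size=cfg.n_broodstock_dams, replace=False))
            sires = list(rng.choice(len(males), size=cfg.n_broodstock_sires, replace=False))
            window = (int(round(cfg.run_day_mean)) - 1, int(round(cfg.run_day_mean)))
            for idx in dams:
                females[idx]["is_broodstock"] = True
                females[idx]["return_doy"] = int(rng.choice(window))
            for idx in sires:
                males[idx]["is_broodstock"] = True
                males[idx]["return_doy"] = int(rng.choice(window))

        registry_rows.extend(year_rows)

        # --- reproduction from this year's spawners ---------------------
        spawners = [r for r in year_rows if not r["is_broodstock"]]
        wild_dams = [r["id"] for r in spawners if r["sex_true"] == "F"]
        wild_sires = [r["id"] for r in spawners if r["sex_true"] == "M"]
        if wild_dams and wild_sires and cfg.wild_mean_offspring > 0:
            counts = _draw_counts(rng, cfg.wild_mean_offspring, cfg.wild_dispersion, len(wild_dams))
            for dam, c in zip(wild_dams, counts):
                if c == 0:
                    continue
                sires_for = rng.choice(wild_sires, size=c)
                ages = _draw_ages(rng, cfg.age_dist_wild, c)
                for sire, age in zip(sires_for, ages):
                    ry = year + int(age)
                    if ry in cfg.run_sizes:
                        pending.setdefault(ry, []).append(
                            {
                                "dam_id": dam,
                                "sire_id": str(sire),
                                "brood_year": year,
                                "origin": "wild",
                                "total_age": int(age),
                            }
                        )

        if year in cfg.brood_years_supplemented:
            bs_dams = [r["id"] for r in year_rows if r["is_broodstock"] and r["sex_true"] == "F"]
            bs_sires = [r["id"] for r in year_rows if r["is_broodstock"] and r["sex_true"] == "M"]
            spawned_dams = [d for d in bs_dams if rng.random() >= cfg.prespawn_failure]
            spawned_sires = [s for s in bs_sires if rng.random() >= cfg.prespawn_failure]
            if spawned_dams and spawned_sires:
                counts = _draw_counts(
                    rng, cfg.hatchery_mean_offspring, cfg.hatchery_dispersion, len(spawned_dams)
                )
                for i, (dam, c) in enumerate(zip(spawned_dams, counts)):
                    sire = spawned_sires[min(i // cfg.cross_ratio, len(spawned_sires) - 1)]
                    ages = _draw_ages(rng, cfg.age_dist_hatchery, int(c))
                    for age in ages:
                        ry = year + int(age)
                        if ry in cfg.run_sizes:
                            pending.setdefault(ry, []).append(
                                {
                                    "dam_id": dam,
                                    "sire_id": sire,
                                    "brood_year": year,
                                    "origin": "hatchery",
                                    "total_age": int(age),
                                }
                            )

    registry = pd.DataFrame(registry_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["offspring_id", "dam_id", "sire_id", "brood_year", "origin"]
    )
    # drop truth rows for offspring that never returned inside the horizon
    truth = truth[truth["offspring_id"].isin(registry["id"])].reset_index(drop=True)
    if cfg.sex_misid_rate > 0:
        registry = apply_sex_misid(registry, cfg.sex_misid_rate, seed=rng.integers(2**31))
    return registry, truth


def apply_sex_misid(registry: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Flip field sex (F <-> M) for a Binomial(n, rate) subset.

    True sex is untouched.  Jacks keep their 'J' field label: the jack
    phenotype is morphologically unambiguous.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate={rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = registry.copy()
    eligible = out["sex_field"].isin(["F", "M"]).to_numpy()
    flip = eligible & (rng.random(len(out)) < rate)
    flipped = out.loc[flip, "sex_field"].map({"F": "M", "M": "F"})
    out.loc[flip, "sex_field"] = flipped
    return out


def simulate_genotypes(
    registry: pd.DataFrame, truth: pd.DataFrame, panel: PanelConfig, seed: int
) -> GenotypeTable:
    """Draw genotypes down the pedigree.

    Founders (individuals without a truth row) are Hardy-Weinberg draws at
    the panel frequencies; offspring inherit one allele per parent
    uniformly.  Null alleles (if configured) segregate as an invisible
    extra allele: visible/null heterozygotes are recorded as homozygous
    for the visible allele, null homozygotes as missing.  Each observed
    genotype is then independently replaced with probability eps by a
    Hardy-Weinberg random genotype, and finally dropped with the locus's
    missingness rate.
    """
    rng = np.random.default_rng(seed)
    ids = list(registry["id"])
    rowmap = {i: k for k, i in enumerate(ids)}
    n, L = len(ids), panel.n_loci

    dam_row = np.full(n, -1, dtype=int)
    sire_row = np.full(n, -1, dtype=int)
    for rec in truth.itertuples(index=False):
        if rec.offspring_id not in rowmap:
            continue
        if rec.dam_id not in rowmap or rec.sire_id not in rowmap:
            raise PedigreeError(f"offspring {rec.offspring_id} references unknown parent")
        r = rowmap[rec.offspring_id]
        dam_row[r] = rowmap[rec.dam_id]
        sire_row[r] = rowmap[rec.sire_id]

    years = registry["return_year"].to_numpy()
    true_al = np.full((n, L, 2), MISSING, dtype=np.int16)
    cols = np.arange(L)
    for year in sorted(set(years)):
        rows = np.flatnonzero(years == year)
        fdr = rows[dam_row[rows] < 0]
        off = rows[dam_row[rows] >= 0]
        for l, locus in enumerate(panel.loci):
            k, nu = locus.n_alleles, locus.null_allele_freq
            if nu > 0:
                ext = np.append(locus.freqs * (1.0 - nu), nu)
            else:
                ext = locus.freqs
            if len(fdr):
                true_al[fdr, l, :] = rng.choice(len(ext), size=(len(fdr), 2), p=ext)
        if len(off):
            pick_d = rng.integers(0, 2, size=(len(off), L))
            pick_s = rng.integers(0, 2, size=(len(off), L))
            true_al[off, :, 0] = true_al[dam_row[off][:, None], cols[None, :], pick_d]
            true_al[off, :, 1] = true_al[sire_row[off][:, None], cols[None, :], pick_s]

    obs = true_al.copy()
    for l, locus in enumerate(panel.loci):
        k = locus.n_alleles
        if locus.null_allele_freq > 0:
            null0 = obs[:, l, 0] == k
            null1 = obs[:, l, 1] == k
            both = null0 & null1
            obs[null0 & ~both, l, 0] = obs[null0 & ~both, l, 1]
            obs[null1 & ~both, l, 1] = obs[null1 & ~both, l, 0]
            obs[both, l, :] = MISSING
        eps = panel.error_rate
        if eps > 0:
            present = obs[:, l, 0] != MISSING
            err = present & (rng.random(n) < eps)
            n_err = int(err.sum())
            if n_err:
                obs[err, l, :] = rng.choice(k, size=(n_err, 2), p=locus.freqs)
        if locus.missing_rate > 0:
            miss = rng.random(n) < locus.missing_rate
            obs[miss, l, :] = MISSING
    return GenotypeTable(ids, panel, obs)


def broodstock_window(registry: pd.DataFrame, brood_year: int) -> tuple[int, int]:
    """The 2-day broodstock collection window, recovered from the registry."""
    bs = registry[(registry["return_year"] == brood_year) & registry["is_broodstock"]]
    if bs.empty:
        raise ValueError(f"no broodstock in {brood_year}")
    return int(bs["return_doy"].min()), int(bs["return_doy"].max())


# ---------------------------------------------------------------------------
# fixture round-trip
# ---------------------------------------------------------------------------
REGISTRY_COLUMNS = [
    "id", "return_year", "sex_true", "sex_field", "origin_true", "total_age",
    "fw_age", "return_doy", "mefl_mm", "scale_age", "is_broodstock",
]


def write_fixture(
    registry: pd.DataFrame,
    truth: pd.DataFrame,
    genotypes: GenotypeTable,
    directory: str | Path,
) -> dict[str, Path]:
    """Write individuals.tsv, truth.tsv, genotypes.tsv and panel.yaml."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": d / "individuals.tsv",
        "truth": d / "truth.tsv",
        "genotypes": d / "genotypes.tsv",
        "panel": d / "panel.yaml",
    }
    reg = registry.reindex(columns=REGISTRY_COLUMNS)
    reg.to_csv(paths["individuals"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    genotypes.write_tsv(paths["genotypes"])
    genotypes.panel.to_yaml(paths["panel"])
    return paths


def read_fixture(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeTable]:
    d = Path(directory)
    panel = PanelConfig.from_yaml(d / "panel.yaml")
    registry = pd.read_csv(
        d / "individuals.tsv", sep="\t",
        dtype={"id": str, "scale_age": str}, keep_default_na=True,
    )
    if len(registry):
        registry["scale_age"] = registry["scale_age"].where(registry["scale_age"].notna(), None)
    truth = pd.read_csv(
        d / "truth.tsv", sep="\t",
        dtype={"offspring_id": str, "dam_id": str, "sire_id": str},
    )
    genotypes = GenotypeTable.read_tsv(d / "genotypes.tsv", panel)
    return registry, truth, genotypes
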