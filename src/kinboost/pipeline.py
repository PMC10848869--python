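"""End-to-end orchestration: simulate -> QC -> power -> assign -> RP -> phenotypes.

A single :class:`RunConfig` (YAML-serialisable) drives every stage with
explicit per-stage seeds; ``run_all`` writes all stage tables, a run
manifest, and human-readable summary tables (run sizes with the
candidate-parent Nmax, relative productivity with CIs, age-composition
and freshwater-age tests) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phenotypes as ph
from . import productivity as rp
from .genotypes import GenotypeTable
from .likelihood import build_tables
from .panel import PanelConfig, default_panel
from .parentage import assign_parentage, compute_nmax, reconcile_sex
from .power import choose_threshold, simulate_dyad_lods
from .qc import filter_individuals, hwe_scan, null_allele_screen, qc_report
from .simulate import SimConfig, broodstock_window, read_fixture, simulate_genotypes, simulate_population, write_fixture

log = logging.getLogger("kinboost")

__all__ = ["RunConfig", "run_all", "report_tables", "format_rp", "format_ci"]


@dataclass
class RunConfig:
    """Full pipeline configuration (fixture mode or data mode)."""

    data_dir: str | None = None  # data mode: directory of fixture-format tables
    sim: SimConfig | None = None  # fixture mode: simulate this population
    eps: float = 0.005
    lod_accept: float = 4.5
    lod_strict: float = 9.0
    calibrate: bool = False  # replace lod_accept by a calibrated threshold
    target_fpr: float = 2.5e-4
    power_n: int = 20000
    min_loci: int = 40
    max_missing_str: int = 5
    max_missing_snp: int = 22
    max_dyad_mismatch: int = 2
    max_triad_mismatch: int = 3
    alpha: float = 0.05
    seeds: dict[str, int] = field(
        default_factory=lambda: {"sim": 1, "genotypes": 2, "power": 3, "sex": 4}
    )

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        if self.sim is not None:
            sim = asdict(self.sim)
            sim["length_mean"] = {f"{k[0]}:{k[1]}": v for k, v in self.sim.length_mean.items()}
            doc["sim"] = sim
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sim = doc.pop("sim", None)
        cfg = cls(**{k: v for k, v in doc.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            if "length_mean" in sim:
                sim["length_mean"] = {
                    (k.split(":")[0], int(k.split(":")[1])): v
                    for k, v in sim["length_mean"].items()
                }
            if "run_sizes" in sim:
                sim["run_sizes"] = {int(k): int(v) for k, v in sim["run_sizes"].items()}
            for key in ("brood_years_supplemented",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            for dk in ("age_dist_wild", "age_dist_hatchery"):
                if dk in sim:
                    sim[dk] = {int(k): float(v) for k, v in sim[dk].items()}
            cfg.sim = SimConfig(**sim)
        return cfg


def _stage(name):
    t0 = time.time()
    log.info("stage %s ...", name)
    return lambda: log.info("stage %s done (%.1f s)", name, time.time() - t0)


def run_all(cfg: RunConfig, outdir: str | Path, panel: PanelConfig | None = None) -> dict:
    """Run every stage; returns the report bundle (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    # ---- inputs --------------------------------------------------------
    done = _stage("inputs")
    if cfg.data_dir is not None:
        d = Path(cfg.data_dir)
        if not d.exists():
            raise FileNotFoundError(f"data directory not found: {d}")
        registry, truth, gt = read_fixture(d)
        panel = gt.panel
    else:
        sim = cfg.sim or SimConfig()
        sim.seed = cfg.seeds.get("sim", sim.seed)
        panel = panel or default_panel(error_rate=cfg.eps)
        registry, truth = simulate_population(sim)
        gt = simulate_genotypes(registry, truth, panel, seed=cfg.seeds.get("genotypes", 0))
        write_fixture(registry, truth, gt, out / "fixture")
    done()

    years = registry.set_index("id")["return_year"]
    run_sizes = registry.groupby("return_year").size().to_dict()
    brood_years = sorted(
        registry.loc[registry["is_broodstock"], "return_year"].unique().tolist()
    )

    # ---- QC ------------------------------------------------------------
    done = _stage("qc")
    hwe = hwe_scan(gt, years)
    qdf = qc_report(hwe)
    qdf.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    null_flags = {}
    for locus in panel.names:
        per_year = [r for r in hwe if r.locus == locus]
        if len(per_year) >= 2:
            null_flags[locus] = null_allele_screen(per_year)
    done()

    # ---- power & thresholds -------------------------------------------
    done = _stage("power")
    po = simulate_dyad_lods(panel, "PO", cfg.power_n, cfg.eps, seed=cfg.seeds.get("power", 0))
    u = simulate_dyad_lods(panel, "U", cfg.power_n, cfg.eps, seed=cfg.seeds.get("power", 0) + 1)
    target = max(cfg.target_fpr, 1.0 / cfg.power_n)
    thr_report = choose_threshold(po, u, target_fpr=target)
    lod_accept = thr_report.threshold if cfg.calibrate else cfg.lod_accept
    lod_strict = cfg.lod_strict
    pd.DataFrame(
        {
            "relationship": ["PO", "U"],
            "n": [po.n, u.n],
            "median_lod": [float(np.median(po.lod_samples)), float(np.median(u.lod_samples))],
        }
    ).to_csv(out / "power_report.tsv", sep="\t", index=False)
    done()

    # ---- assignment ----------------------------------------------------
    done = _stage("assign")
    tables = build_tables(panel, cfg.eps)
    min_ret = min(run_sizes) + 3
    assignments = []
    for ry in sorted(y for y in run_sizes if y >= min_ret):
        assignments.append(
            assign_parentage(
                gt, registry, ry, tables=tables,
                max_dyad_mismatch=cfg.max_dyad_mismatch,
                max_triad_mismatch=cfg.max_triad_mismatch,
                min_loci=cfg.min_loci,
                max_missing_str=cfg.max_missing_str,
                max_missing_snp=cfg.max_missing_snp,
            )
        )
    assignments = pd.concat(assignments, ignore_index=True)
    assignments = reconcile_sex(assignments, registry, seed=cfg.seeds.get("sex", 0))
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    done()

    # ---- productivity --------------------------------------------------
    done = _stage("productivity")
    _, parent_excl = filter_individuals(
        gt, "parent", min_loci=cfg.min_loci,
        max_missing_str=cfg.max_missing_str, max_missing_snp=cfg.max_missing_snp,
    )
    rp_rows = []
    for by in brood_years:
        counts = rp.count_offspring(
            assignments, registry, by, "F", threshold=lod_accept, excluded_parents=parent_excl
        )
        ch = [c for c in counts if c.origin == "hatchery"]
        cw = [c for c in counts if c.origin == "wild"]
        est = rp.rp_estimate(ch, cw, alpha=cfg.alpha)
        n_females = sum(1 for c in ch)
        rp_rows.append(
            {
                "brood_year": by,
                "dams_h": est.n_dams_h, "offspring_h": est.offspring_h,
                "dams_w": est.n_dams_w, "offspring_w": est.offspring_w,
                "rp": est.w_hat, "ci_lo": est.ci_lo, "ci_hi": est.ci_hi,
                "expected_wild_contribution": rp.expected_wild_contribution(
                    n_females, est.offspring_w, est.n_dams_w
                ),
            }
        )
    rp_table = pd.DataFrame(rp_rows)
    rp_table.to_csv(out / "rp_table.tsv", sep="\t", index=False)
    sensitivity = pd.concat(
        [
            rp.threshold_sensitivity(
                assignments, registry, by, lod_accept, excluded_parents=parent_excl
            )
            for by in brood_years
        ],
        ignore_index=True,
    ) if brood_years else pd.DataFrame()
    if len(sensitivity):
        sensitivity.to_csv(out / "rp_threshold_sensitivity.tsv", sep="\t", index=False)
    done()

    # ---- nmax table (weir-count analog of the candidate-parent cap) ----
    nmax_rows = []
    for ry in sorted(run_sizes):
        try:
            spec = compute_nmax(run_sizes, ry)
            nmax_rows.append({"return_year": ry, "nmax": spec.nmax})
        except ValueError:
            continue
    nmax_table = pd.DataFrame(nmax_rows)
    nmax_table.to_csv(out / "nmax_table.tsv", sep="\t", index=False)

    # ---- phenotypes (strict threshold) ---------------------------------
    done = _stage("phenotypes")
    reg_ix = registry.set_index("id")
    strict = assignments[
        (assignments["dam_lod"].fillna(-np.inf) >= lod_strict)
        | (assignments["sire_lod"].fillna(-np.inf) >= lod_strict)
    ].copy()
    strict = strict[strict["brood_year"].isin(brood_years)]
    pheno = strict.merge(
        registry[["id", "return_year", "sex_field", "return_doy", "mefl_mm", "scale_age", "total_age"]]
        .rename(columns={"id": "offspring_id", "return_year": "offspring_return_year"}),
        on="offspring_id", how="left",
    )
    dam_bs = pheno["dam_id"].map(reg_ix["is_broodstock"]).astype("boolean").fillna(False)
    sire_bs = pheno["sire_id"].map(reg_ix["is_broodstock"]).astype("boolean").fillna(False)
    pheno["origin"] = np.where(dam_bs | sire_bs, "hatchery", "wild")
    pheno["age_from_parentage"] = (
        pheno["offspring_return_year"].astype(int) - pheno["brood_year"].astype(int)
    )
    results: list[ph.TestResult] = []
    # run timing by return year
    for ry, sub in pheno.groupby("offspring_return_year"):
        h = sub.loc[sub["origin"] == "hatchery", "return_doy"].dropna()
        w = sub.loc[sub["origin"] == "wild", "return_doy"].dropna()
        if len(h) and len(w):
            results.append(ph.ks_run_timing(h, w, stratum=f"return_{ry}"))
    _adjust(results, "ks_run_timing")
    # age composition by brood year
    age_res = []
    for by, sub in pheno.groupby("brood_year"):
        h = sub.loc[sub["origin"] == "hatchery", "age_from_parentage"]
        w = sub.loc[sub["origin"] == "wild", "age_from_parentage"]
        if len(h) and len(w):
            try:
                age_res.append(ph.age_composition_test(h, w, stratum=f"brood_{by}"))
            except ValueError as exc:
                log.warning("age composition %s skipped: %s", by, exc)
    _adjust(age_res, "age_composition_chi2")
    results.extend(age_res)
    # freshwater age (scale subsample agreeing with parentage age)
    fw_res = []
    scale_ok = pheno[pheno["scale_age"].notna()].copy()
    if len(scale_ok):
        scale_total = scale_ok["scale_age"].str.split(".", expand=True).astype(int).sum(axis=1) + 1
        scale_ok = scale_ok[scale_total == scale_ok["age_from_parentage"]]
        scale_ok["fw"] = scale_ok["scale_age"].str.split(".").str[0].astype(int)
        strata = [(f"brood_{by}", sub) for by, sub in scale_ok.groupby("brood_year")]
        strata.append(("pooled", scale_ok))
        for label, sub in strata:
            h = sub.loc[sub["origin"] == "hatchery", "fw"]
            w = sub.loc[sub["origin"] == "wild", "fw"]
            if len(h) and len(w):
                fw_res.append(ph.freshwater_age_test(h, w, stratum=label))
    _adjust(fw_res, "freshwater_age_fisher")
    results.extend(fw_res)
    # size at age per brood year
    size_rows = []
    for by, sub in scale_ok.groupby("brood_year") if len(scale_ok) else []:
        df = sub.rename(columns={"sex_field": "sex"})[
            ["mefl_mm", "origin", "sex", "scale_age"]
        ].dropna()
        df = df[df["sex"].isin(["F", "M"])]
        try:
            model = ph.size_at_age_fit(df, brood_year=by)
            size_rows.append(
                {"brood_year": by, "n": model.n,
                 "beta_origin": model.coefficients.get("origin[hatchery]"),
                 "origin_p": model.origin_p, "sigma": model.residual_sigma}
            )
        except ValueError as exc:
            log.warning("size-at-age %s skipped: %s", by, exc)
    size_table = pd.DataFrame(size_rows)
    if len(size_table):
        size_table.to_csv(out / "size_at_age_coefs.tsv", sep="\t", index=False)
    pheno_table = pd.DataFrame(
        {
            "test": [r.name for r in results],
            "stratum": [r.stratum for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "n_hatchery": [r.n_hatchery for r in results],
            "n_wild": [r.n_wild for r in results],
        }
    )
    pheno_table.to_csv(out / "phenotype_report.tsv", sep="\t", index=False)
    done()

    # ---- manifest ------------------------------------------------------
    manifest = {
        "seeds": cfg.seeds,
        "lod_accept": float(lod_accept),
        "lod_strict": float(lod_strict),
        "calibrated_threshold": float(thr_report.threshold),
        "calibration_fnr": thr_report.fnr,
        "calibration_fpr": thr_report.fpr,
        "null_allele_flags": {k: bool(v) for k, v in null_flags.items() if v},
        "n_individuals": int(len(registry)),
        "n_assigned": int(
            (assignments["dam_id"].notna() | assignments["sire_id"].notna()).sum()
        ),
        "tables": sorted(p.name for p in out.glob("*.tsv")),
        "digest": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "registry": registry,
        "truth": truth,
        "assignments": assignments,
        "rp_table": rp_table,
        "nmax_table": nmax_table,
        "phenotype_table": pheno_table,
        "size_at_age": size_table,
        "manifest": manifest,
        "threshold_report": thr_report,
    }


def _adjust(results: list, name: str) -> None:
    sub = [r for r in results if r.name == name]
    if not sub:
        return
    adj = ph.holm_bonferroni([r.p_raw for r in sub])
    for r, a in zip(sub, adj):
        r.p_adj = float(a)


# ---------------------------------------------------------------------------
# formatting to the precision used in the study tables
# ---------------------------------------------------------------------------
def format_ci(lo: float, hi: float) -> str:
    if not np.isfinite(hi):
        return f"({lo:.1f}–inf)"
    return f"({lo:.1f}–{hi:.1f})"


def format_rp(rp_value: float, lo: float, hi: float) -> str:
    if not np.isfinite(rp_value):
        return "—"
    return f"{rp_value:.1f} {format_ci(lo, hi)}"


def report_tables(bundle: dict) -> str:
    """Human-readable summary of the report bundle."""
    lines = ["Relative productivity (females) by brood year"]
    rpt = bundle["rp_table"]
    if rpt.empty:
        lines.append("  —")
    for rec in rpt.itertuples(index=False):
        lines.append(
            f"  {rec.brood_year}: dams {rec.dams_h}H/{rec.dams_w}W, "
            f"offspring {rec.offspring_h}H/{rec.offspring_w}W, "
            f"RP {format_rp(rec.rp, rec.ci_lo, rec.ci_hi)}"
        )
    lines.append("Phenotype tests (Holm-adjusted)")
    for rec in bundle["phenotype_table"].itertuples(index=False):
        stat = f"{rec.statistic:.2f}" if np.isfinite(rec.statistic) else "—"
        lines.append(
            f"  {rec.test} [{rec.stratum}]: stat={stat} p_adj={rec.p_adj:.4g}"
            if rec.p_adj is not None and np.isfinite(rec.p_adj)
            else f"  {rec.test} [{rec.stratum}]: stat={stat} p={rec.p_raw:.4g}"
        )
    return "\n".join(lines)
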