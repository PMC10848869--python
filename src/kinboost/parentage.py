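"""Likelihood-based parent-offspring assignment.

Each returning adult is compared against every candidate parent that
spawned 3-6 years earlier.  Per-dyad LOD scores (natural-log likelihood
ratio of parent-offspring vs unrelated, genotyping error folded in) are
computed over the shared non-missing loci; dyads exceeding the Mendelian
mismatch limit are discarded; the best-supported dam-sire pair (the triad
maximising the joint likelihood, with both candidates from the same brood
year) is reported when one exists, otherwise the single best dyad.
Acceptance thresholds on the LOD are applied downstream, so the weaker
(productivity) and stricter (phenotype) thresholds can share one
assignment pass.  Field sex is unreliable, so candidates of any field sex
may enter either parent slot and apparent same-sex pairs are reconciled
afterwards from mate evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .likelihood import LikelihoodTables, build_tables, transmission_prob
from .panel import PanelConfig
from .qc import filter_individuals

__all__ = [
    "DyadLikelihood",
    "NmaxSpec",
    "lod_dyad",
    "compute_nmax",
    "assign_parentage",
    "reconcile_sex",
    "transmission_prob",
]

PARENT_YEAR_LAGS = range(3, 7)  # parents spawned 3-6 years before the return year


@dataclass
class DyadLikelihood:
    offspring_id: str
    candidate_id: str
    lod: float
    n_loci_used: int
    n_mismatch: int


@dataclass
class NmaxSpec:
    """Candidate-parent population-size parameter derived from weir counts:
    half the summed counts over the four parent years, plus 5%, rounded up
    to the nearest five."""

    return_year: int
    parent_years: tuple[int, ...]
    weir_counts: dict[int, int]
    nmax: int


def compute_nmax(weir_counts: dict[int, int], return_year: int) -> NmaxSpec:
    parent_years = tuple(return_year - lag for lag in sorted(PARENT_YEAR_LAGS, reverse=True))
    missing = [y for y in parent_years if y not in weir_counts]
    if missing:
        raise ValueError(f"missing weir counts for parent years {missing}")
    total = sum(weir_counts[y] for y in parent_years)
    nmax = int(math.ceil((total / 2.0) * 1.05 / 5.0) * 5)
    return NmaxSpec(
        return_year=return_year,
        parent_years=parent_years,
        weir_counts={y: weir_counts[y] for y in parent_years},
        nmax=nmax,
    )


def lod_dyad(
    gt: GenotypeTable,
    offspring_id: str,
    candidate_id: str,
    tables: LikelihoodTables | None = None,
    eps: float | None = None,
) -> DyadLikelihood:
    """LOD for one candidate dyad, summed over shared non-missing loci."""
    if tables is None:
        tables = build_tables(gt.panel, eps)
    codes = gt.codes()
    o = codes[[gt.row(offspring_id)]]
    c = codes[[gt.row(candidate_id)]]
    lod, nmis, nloci = tables.dyad_scores(o, c)
    if nloci[0, 0] < 1:
        raise ValueError(f"no shared genotyped loci for ({offspring_id}, {candidate_id})")
    return DyadLikelihood(
        offspring_id=offspring_id,
        candidate_id=candidate_id,
        lod=float(lod[0, 0]),
        n_loci_used=int(nloci[0, 0]),
        n_mismatch=int(nmis[0, 0]),
    )


ASSIGNMENT_COLUMNS = [
    "offspring_id", "return_year", "brood_year",
    "dam_id", "sire_id", "dam_lod", "sire_lod",
    "dam_mismatch", "sire_mismatch", "triad_mismatch", "triad_lod",
    "n_candidates", "sex_resolution",
]


def assign_parentage(
    gt: GenotypeTable,
    registry: pd.DataFrame,
    return_year: int,
    tables: LikelihoodTables | None = None,
    eps: float | None = None,
    max_dyad_mismatch: int = 2,
    max_triad_mismatch: int = 3,
    min_loci: int = 40,
    max_missing_str: int = 5,
    max_missing_snp: int = 22,
    top_k: int = 20,
) -> pd.DataFrame:
    """Assign parents to all offspring returning in one year.

    Returns one row per offspring that passed the completeness filter,
    with dam/sire slots (field-sex informed; 'J' candidates enter the
    sire slot), per-dyad LODs and mismatch counts, and triad statistics
    when a dam-sire pair was found.  Offspring may be unassigned (both
    slots empty).  Threshold acceptance is applied by the caller.
    """
    if tables is None:
        tables = build_tables(gt.panel, eps)
    reg = registry.set_index("id")
    in_gt = set(gt.ids)

    off_ids = [
        i for i in registry.loc[registry["return_year"] == return_year, "id"] if i in in_gt
    ]
    cand_years = [return_year - lag for lag in PARENT_YEAR_LAGS]
    cand_ids = [
        i
        for i in registry.loc[registry["return_year"].isin(cand_years), "id"]
        if i in in_gt
    ]
    off_kept, _ = filter_individuals(gt, "offspring", min_loci=min_loci, ids=off_ids)
    cand_kept, _ = filter_individuals(
        gt, "parent", min_loci=min_loci,
        max_missing_str=max_missing_str, max_missing_snp=max_missing_snp, ids=cand_ids,
    )

    rows: list[dict] = []
    if not off_kept:
        return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    if not cand_kept:
        for o in off_kept:
            rows.append(_empty_record(o, return_year, 0))
        return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)

    codes = gt.codes()
    o_rows = np.array([gt.row(i) for i in off_kept])
    c_rows = np.array([gt.row(i) for i in cand_kept])
    cand_year = reg.loc[cand_kept, "return_year"].to_numpy()
    cand_sex = reg.loc[cand_kept, "sex_field"].to_numpy()
    cand_arr = np.asarray(cand_kept)

    # offspring are processed in blocks so the dyad matrices stay small
    block = max(1, min(len(off_kept), int(4_000_000 // max(1, len(cand_kept)))))
    for start in range(0, len(off_kept), block):
        stop = min(start + block, len(off_kept))
        lod, nmis, nloci = tables.dyad_scores(codes[o_rows[start:stop]], codes[c_rows])
        valid = (nmis <= max_dyad_mismatch) & (nloci >= 1)

        # gather candidate triad pairs across the block, then score in bulk
        pair_meta: list[tuple[int, int, int]] = []  # (local offspring idx, cand a, cand b)
        single_best: dict[int, int | None] = {}
        for oi in range(stop - start):
            ok = np.flatnonzero(valid[oi])
            if len(ok) == 0:
                single_best[oi] = None
                continue
            # deterministic order: LOD desc, then more loci, then id
            order = sorted(ok, key=lambda j: (-lod[oi, j], -nloci[oi, j], cand_arr[j]))
            single_best[oi] = order[0]
            top = order[: min(top_k, len(order))]
            for a in range(len(top)):
                for b in range(a + 1, len(top)):
                    ja, jb = top[a], top[b]
                    if cand_year[ja] == cand_year[jb]:  # spawning pair must co-occur
                        pair_meta.append((oi, ja, jb))

        triad_lod_all = np.zeros(0)
        triad_mis_all = np.zeros(0, dtype=int)
        if pair_meta:
            om = np.array([m[0] for m in pair_meta])
            am = np.array([m[1] for m in pair_meta])
            bm = np.array([m[2] for m in pair_meta])
            triad_lod_all, triad_mis_all = tables.triad_scores(
                codes[o_rows[start + om]], codes[c_rows[am]], codes[c_rows[bm]]
            )
        pairs_by_off: dict[int, list[int]] = {}
        for idx, (oi, _, _) in enumerate(pair_meta):
            pairs_by_off.setdefault(oi, []).append(idx)

        for oi in range(stop - start):
            off_id = off_kept[start + oi]
            n_cand = int(valid[oi].sum())
            best_pair = None
            if oi in pairs_by_off:
                cands = [
                    idx for idx in pairs_by_off[oi] if triad_mis_all[idx] <= max_triad_mismatch
                ]
                if cands:
                    # deterministic tie-break: lexicographically smallest id pair
                    best_pair = min(
                        cands,
                        key=lambda idx: (
                            -triad_lod_all[idx],
                            cand_arr[pair_meta[idx][1]],
                            cand_arr[pair_meta[idx][2]],
                        ),
                    )
            if best_pair is not None:
                _, ja, jb = pair_meta[best_pair]
                rec = _slot_pair(
                    off_id, return_year, cand_arr, cand_sex, cand_year,
                    ja, jb, lod[oi], nmis[oi],
                    float(triad_lod_all[best_pair]), int(triad_mis_all[best_pair]), n_cand,
                )
            elif single_best[oi] is not None:
                j = single_best[oi]
                rec = _slot_single(
                    off_id, return_year, cand_arr, cand_sex, cand_year, j,
                    lod[oi], nmis[oi], n_cand,
                )
            else:
                rec = _empty_record(off_id, return_year, n_cand)
            rows.append(rec)
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def _empty_record(off_id: str, return_year: int, n_cand: int) -> dict:
    return {
        "offspring_id": off_id, "return_year": return_year, "brood_year": pd.NA,
        "dam_id": None, "sire_id": None, "dam_lod": np.nan, "sire_lod": np.nan,
        "dam_mismatch": pd.NA, "sire_mismatch": pd.NA,
        "triad_mismatch": pd.NA, "triad_lod": np.nan,
        "n_candidates": n_cand, "sex_resolution": "",
    }


def _slot_pair(off_id, return_year, cand_arr, cand_sex, cand_year, ja, jb, lods, nmis,
               triad_lod, triad_mis, n_cand) -> dict:
    sa, sb = cand_sex[ja], cand_sex[jb]
    # female-labelled candidate takes the dam slot; jacks are male
    if sa == "F" and sb != "F":
        dam, sire = ja, jb
    elif sb == "F" and sa != "F":
        dam, sire = jb, ja
    else:  # same-sex pair by field labels; order deterministically, fix later
        dam, sire = (ja, jb) if cand_arr[ja] < cand_arr[jb] else (jb, ja)
    return {
        "offspring_id": off_id, "return_year": return_year,
        "brood_year": int(cand_year[dam]),
        "dam_id": cand_arr[dam], "sire_id": cand_arr[sire],
        "dam_lod": float(lods[dam]), "sire_lod": float(lods[sire]),
        "dam_mismatch": int(nmis[dam]), "sire_mismatch": int(nmis[sire]),
        "triad_mismatch": triad_mis, "triad_lod": triad_lod,
        "n_candidates": n_cand,
        "sex_resolution": "",
    }


def _slot_single(off_id, return_year, cand_arr, cand_sex, cand_year, j, lods, nmis, n_cand) -> dict:
    rec = _empty_record(off_id, return_year, n_cand)
    rec["brood_year"] = int(cand_year[j])
    if cand_sex[j] == "F":
        rec.update(dam_id=cand_arr[j], dam_lod=float(lods[j]), dam_mismatch=int(nmis[j]))
    else:
        rec.update(sire_id=cand_arr[j], sire_lod=float(lods[j]), sire_mismatch=int(nmis[j]))
    return rec


def reconcile_sex(
    assignments: pd.DataFrame, registry: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Resolve triads whose two parents share a field sex label.

    Rules, in order: (1) if exactly one member's field sex is corroborated
    by its other mates (a mate of opposite working sex elsewhere), flip
    the other member; (2) if both are monogamous (no other mates), assign
    dam/sire randomly but consistently; (3) if mate evidence corroborates
    both (they really are the same sex), drop the lower-LOD parent.
    The resolution path is recorded per assignment.
    """
    rng = np.random.default_rng(seed)
    out = assignments.copy()
    sex_field = registry.set_index("id")["sex_field"].to_dict()

    def working(s):  # jacks are male
        return "M" if s == "J" else s

    # mate map over all triads
    mates: dict[str, set[str]] = {}
    for rec in out.itertuples(index=False):
        if rec.dam_id and rec.sire_id:
            mates.setdefault(rec.dam_id, set()).add(rec.sire_id)
            mates.setdefault(rec.sire_id, set()).add(rec.dam_id)

    # resolved working sex per individual id (may be flipped below)
    resolved: dict[str, str] = {}

    def evidence(ind: str, partner: str) -> bool:
        """True if some other mate of `ind` has the opposite field sex,
        corroborating `ind`'s own field label."""
        others = mates.get(ind, set()) - {partner}
        own = working(sex_field.get(ind, ""))
        opp = "M" if own == "F" else "F"
        return any(working(sex_field.get(m, "")) == opp for m in others)

    for idx in out.index:
        dam, sire = out.at[idx, "dam_id"], out.at[idx, "sire_id"]
        if not dam or not sire:
            continue
        sd = resolved.get(dam, working(sex_field.get(dam, "")))
        ss = resolved.get(sire, working(sex_field.get(sire, "")))
        if sd == "F" and ss == "M":
            continue
        if sd == "M" and ss == "F":
            out.loc[idx, ["dam_id", "sire_id"]] = [sire, dam]
            out.loc[idx, ["dam_lod", "sire_lod"]] = [
                out.at[idx, "sire_lod"], out.at[idx, "dam_lod"]
            ]
            out.loc[idx, ["dam_mismatch", "sire_mismatch"]] = [
                out.at[idx, "sire_mismatch"], out.at[idx, "dam_mismatch"]
            ]
            out.at[idx, "sex_resolution"] = "slots swapped to match field sex"
            continue
        # same working sex
        ev_dam = evidence(dam, sire)
        ev_sire = evidence(sire, dam)
        if ev_dam and not ev_sire:
            # dam's label corroborated; the sire-slot member's label flips
            resolved[sire] = "M" if sd == "F" else "F"
            note = f"{sire} relabeled by mate parsimony"
        elif ev_sire and not ev_dam:
            resolved[dam] = "M" if ss == "F" else "F"
            note = f"{dam} relabeled by mate parsimony"
        elif not ev_dam and not ev_sire:
            # monogamous pair: random but valid partition
            if rng.random() < 0.5:
                out.loc[idx, ["dam_id", "sire_id"]] = [sire, dam]
                out.loc[idx, ["dam_lod", "sire_lod"]] = [
                    out.at[idx, "sire_lod"], out.at[idx, "dam_lod"]
                ]
                out.loc[idx, ["dam_mismatch", "sire_mismatch"]] = [
                    out.at[idx, "sire_mismatch"], out.at[idx, "dam_mismatch"]
                ]
            note = "monogamous same-sex pair: sexes assigned randomly"
        else:
            # both corroborated: truly same sex, drop the lower-LOD parent
            if out.at[idx, "dam_lod"] >= out.at[idx, "sire_lod"]:
                out.at[idx, "sire_id"] = None
                out.at[idx, "sire_lod"] = np.nan
                out.at[idx, "sire_mismatch"] = pd.NA
                note = "conflicting mate evidence: lower-LOD sire dropped"
            else:
                out.at[idx, "dam_id"] = None
                out.at[idx, "dam_lod"] = np.nan
                out.at[idx, "dam_mismatch"] = pd.NA
                note = "conflicting mate evidence: lower-LOD dam dropped"
            out.at[idx, "triad_mismatch"] = pd.NA
            out.at[idx, "triad_lod"] = np.nan
        # if the dam slot now holds the male label, swap slots
        dam2, sire2 = out.at[idx, "dam_id"], out.at[idx, "sire_id"]
        if dam2 and sire2:
            wd = resolved.get(dam2, working(sex_field.get(dam2, "")))
            if wd == "M" or resolved.get(sire2) == "F":
                out.loc[idx, ["dam_id", "sire_id"]] = [sire2, dam2]
                out.loc[idx, ["dam_lod", "sire_lod"]] = [
                    out.at[idx, "sire_lod"], out.at[idx, "dam_lod"]
                ]
                out.loc[idx, ["dam_mismatch", "sire_mismatch"]] = [
                    out.at[idx, "sire_mismatch"], out.at[idx, "dam_mismatch"]
                ]
        out.at[idx, "sex_resolution"] = note
    return out
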