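import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import founders_registry
from kinboost.genotypes import GenotypeTable
from kinboost.likelihood import build_tables, hw_probs, transmission_matrix, transmission_prob
from kinboost.panel import Locus, PanelConfig, code_to_pair, geno_code, n_geno_codes
from kinboost.parentage import assign_parentage, compute_nmax, lod_dyad, reconcile_sex


# ---------------------------------------------------------------------------
# brute-force oracle: dyad likelihood by full enumeration over true genotypes
# ---------------------------------------------------------------------------
def brute_force_lod(panel, eps, obs_o_codes, obs_p_codes):
    """Enumerate the mistyping model directly, per locus, and sum lods."""
    total = 0.0
    for l, locus in enumerate(panel.loci):
        o_obs, p_obs = obs_o_codes[l], obs_p_codes[l]
        if o_obs < 0 or p_obs < 0:
            continue
        freqs = locus.freqs
        hw = hw_probs(freqs)
        T = transmission_matrix(freqs)
        G = len(hw)

        def p_obs_given_true(obs, true):
            return (1 - eps) * (obs == true) + eps * hw[obs]

        l_po = 0.0
        l_u = 0.0
        for ot in range(G):
            for pt in range(G):
                joint_po = hw[pt] * T[ot, pt]
                joint_u = hw[pt] * hw[ot]
                w = p_obs_given_true(o_obs, ot) * p_obs_given_true(p_obs, pt)
                l_po += w * joint_po
                l_u += w * joint_u
        total += np.log(l_po / l_u)
    return total


class TestTransmission:
    def test_homozygous_parent(self):
        po, u = transmission_prob((0, 0), (0, 0), [0.5, 0.5])
        assert po == pytest.approx(0.5)
        assert u == pytest.approx(0.25)

    def test_uninformative_het_parent(self):
        po, u = transmission_prob((0, 0), (0, 1), [0.5, 0.5])
        assert po == pytest.approx(u) == pytest.approx(0.25)

    def test_opposing_homozygotes(self):
        po, _ = transmission_prob((0, 0), (1, 1), [0.5, 0.5])
        assert po == 0.0

    def test_allele_outside_panel(self):
        with pytest.raises(ValueError, match="absent"):
            transmission_prob((0, 2), (0, 0), [0.5, 0.5])


class TestDyadLod:
    def _gt(self, panel, rows):
        alleles = np.array(rows, dtype=np.int16)
        ids = [f"i{k}" for k in range(len(rows))]
        return GenotypeTable(ids, panel, alleles)

    def test_single_snp_matching_homozygotes(self):
        panel = PanelConfig([Locus("S", "SNP", (0.5, 0.5))], error_rate=0.0)
        gt = self._gt(panel, [[[0, 0]], [[0, 0]]])
        d = lod_dyad(gt, "i0", "i1", eps=0.0)
        assert d.lod == pytest.approx(np.log(2.0))
        assert d.n_mismatch == 0 and d.n_loci_used == 1

    def test_opposing_homozygotes_with_error_finite_negative(self):
        panel = PanelConfig([Locus("S", "SNP", (0.5, 0.5))], error_rate=0.005)
        gt = self._gt(panel, [[[0, 0]], [[1, 1]]])
        d = lod_dyad(gt, "i0", "i1", eps=0.005)
        assert np.isfinite(d.lod) and d.lod < 0
        assert d.n_mismatch == 1

    def test_no_shared_loci_errors(self):
        panel = PanelConfig([Locus("S", "SNP", (0.5, 0.5))], error_rate=0.0)
        gt = self._gt(panel, [[[-1, -1]], [[0, 0]]])
        with pytest.raises(ValueError, match="no shared"):
            lod_dyad(gt, "i0", "i1", eps=0.0)

    @pytest.mark.parametrize("eps", [0.005, 0.02])
    def test_lod_matches_brute_force_enumeration(self, eps):
        """Panel LOD equals the exhaustive-enumeration oracle to 1e-10."""
        panel = PanelConfig(
            [
                Locus("S1", "SNP", (0.3, 0.7)),
                Locus("T1", "STR", (0.5, 0.3, 0.2)),
                Locus("S2", "SNP", (0.9, 0.1)),
            ],
            error_rate=eps,
        )
        tables = build_tables(panel, eps)
        sizes = [n_geno_codes(l.n_alleles) for l in panel.loci]
        # all genotype configurations at every locus, incl. one missing slot
        configs = list(itertools.product(*[list(range(s)) + [-1] for s in sizes]))
        rng = np.random.default_rng(0)
        chosen = rng.choice(len(configs), size=40, replace=False)
        for ci in chosen:
            for cj in chosen[:10]:
                o_codes = np.array(configs[ci])[None, :]
                p_codes = np.array(configs[cj])[None, :]
                lod, _, nloci = tables.dyad_scores(o_codes, p_codes)
                if nloci[0, 0] == 0:
                    continue
                expected = brute_force_lod(panel, eps, configs[ci], configs[cj])
                assert lod[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_lod_additivity_and_missing_locus_neutrality(self):
        eps = 0.005
        p2 = PanelConfig(
            [Locus("S1", "SNP", (0.3, 0.7)), Locus("T1", "STR", (0.5, 0.3, 0.2))],
            error_rate=eps,
        )
        t2 = build_tables(p2, eps)
        o = np.array([[0, 3]])
        c = np.array([[2, 3]])
        lod2, _, _ = t2.dyad_scores(o, c)
        # per-locus single panels
        total = 0.0
        for l, locus in enumerate(p2.loci):
            p1 = PanelConfig([locus], error_rate=eps)
            t1 = build_tables(p1, eps)
            lod1, _, _ = t1.dyad_scores(o[:, [l]], c[:, [l]])
            total += lod1[0, 0]
        assert lod2[0, 0] == pytest.approx(total, abs=1e-12)
        # locus missing in one member changes nothing
        o_miss = np.array([[0, -1]])
        lod_m, _, nl = t2.dyad_scores(o_miss, c)
        lod_s, _, _ = t2.dyad_scores(o[:, [0]], c[:, [0]])
        assert lod_m[0, 0] == pytest.approx(lod_s[0, 0])
        assert nl[0, 0] == 1

    def test_matching_informative_locus_increases_lod(self):
        eps = 0.005
        locus = Locus("S", "SNP", (0.2, 0.8))
        p1 = build_tables(PanelConfig([locus], error_rate=eps), eps)
        # matching rare-homozygote pair is informative and positive
        code = geno_code(0, 0)
        lr = p1.log_lr[0][code, code]
        assert lr > 0


class TestNmax:
    def test_weir_rule_2018(self):
        spec = compute_nmax({2012: 1556, 2013: 2060, 2014: 3443, 2015: 4720}, 2018)
        assert spec.nmax == 6185
        assert spec.parent_years == (2012, 2013, 2014, 2015)

    def test_weir_rule_2019(self):
        spec = compute_nmax(
            {2013: 2060, 2014: 3443, 2015: 4720, 2016: 2519}, 2019
        )
        assert spec.nmax == 6690

    def test_zero_counts(self):
        assert compute_nmax({y: 0 for y in range(2012, 2016)}, 2018).nmax == 0

    def test_missing_year_errors(self):
        with pytest.raises(ValueError, match="missing weir counts"):
            compute_nmax({2013: 100, 2014: 100, 2015: 100}, 2018)


class TestAssignment:
    def test_mismatch_limit_rejects_regardless_of_lod(self, clean_panel):
        """A candidate with 3 mismatching loci is excluded by the limit."""
        rng = np.random.default_rng(3)
        L = clean_panel.n_loci
        parent = np.stack([rng.integers(0, 2, L), rng.integers(0, 2, L)], axis=1)
        child = parent.copy()
        # force 3 opposing-homozygote loci at SNPs
        snps = clean_panel.snp_indices[:3]
        parent[snps] = 0
        child[snps] = 1
        alleles = np.stack([child, parent]).astype(np.int16)
        reg = pd.DataFrame(
            {
                "id": ["2016_00000", "2012_00000"],
                "return_year": [2016, 2012],
                "sex_field": ["F", "F"],
                "is_broodstock": False,
            }
        )
        gt = GenotypeTable(["2016_00000", "2012_00000"], clean_panel, alleles)
        asg = assign_parentage(gt, reg, 2016, eps=0.005, min_loci=40)
        assert len(asg) == 1
        assert asg.iloc[0]["dam_id"] is None and asg.iloc[0]["sire_id"] is None

    def test_empty_candidate_set(self, clean_panel):
        reg = founders_registry(5, year=2016)
        alleles = np.zeros((5, clean_panel.n_loci, 2), dtype=np.int16)
        gt = GenotypeTable(list(reg["id"]), clean_panel, alleles)
        asg = assign_parentage(gt, reg, 2016, eps=0.005)
        assert len(asg) == 5
        assert asg["dam_id"].isna().all() or (asg["dam_id"] == None).all()  # noqa: E711


def _triad_frame(rows):
    cols = ["offspring_id", "return_year", "brood_year", "dam_id", "sire_id",
            "dam_lod", "sire_lod", "dam_mismatch", "sire_mismatch",
            "triad_mismatch", "triad_lod", "n_candidates", "sex_resolution"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df:
            df[c] = None
    return df[cols]


def _reg(ids_sex):
    return pd.DataFrame(
        {
            "id": list(ids_sex),
            "return_year": 2012,
            "sex_field": [ids_sex[i] for i in ids_sex],
            "is_broodstock": False,
            "return_doy": 200,
        }
    )


class TestSexReconciliation:
    def test_mate_parsimony_relabels_partner(self):
        # P1 "F" also mates with a known male elsewhere -> P2 becomes the male
        reg = _reg({"P1": "F", "P2": "F", "P3": "M"})
        asg = _triad_frame(
            [
                {"offspring_id": "O1", "dam_id": "P1", "sire_id": "P2",
                 "dam_lod": 10.0, "sire_lod": 9.0},
                {"offspring_id": "O2", "dam_id": "P1", "sire_id": "P3",
                 "dam_lod": 11.0, "sire_lod": 12.0},
            ]
        )
        out = reconcile_sex(asg, reg, seed=0)
        row = out[out["offspring_id"] == "O1"].iloc[0]
        assert row["dam_id"] == "P1" and row["sire_id"] == "P2"
        assert "relabeled" in row["sex_resolution"]

    def test_monogamous_pair_random_but_partitioned(self):
        reg = _reg({"P1": "F", "P2": "F"})
        asg = _triad_frame(
            [{"offspring_id": "O1", "dam_id": "P1", "sire_id": "P2",
              "dam_lod": 10.0, "sire_lod": 9.0}]
        )
        for seed in range(5):
            out = reconcile_sex(asg.copy(), reg, seed=seed)
            row = out.iloc[0]
            assert {row["dam_id"], row["sire_id"]} == {"P1", "P2"}
            assert "randomly" in row["sex_resolution"]

    def test_conflicting_evidence_drops_lower_lod(self):
        # both focal parents corroborated female by their other (male) mates
        reg = _reg({"P1": "F", "P2": "F", "M1": "M", "M2": "M"})
        asg = _triad_frame(
            [
                {"offspring_id": "O1", "dam_id": "P1", "sire_id": "P2",
                 "dam_lod": 12.0, "sire_lod": 7.0},
                {"offspring_id": "O2", "dam_id": "P1", "sire_id": "M1",
                 "dam_lod": 10.0, "sire_lod": 10.0},
                {"offspring_id": "O3", "dam_id": "P2", "sire_id": "M2",
                 "dam_lod": 10.0, "sire_lod": 10.0},
            ]
        )
        out = reconcile_sex(asg, reg, seed=0)
        row = out[out["offspring_id"] == "O1"].iloc[0]
        assert row["dam_id"] == "P1"
        assert row["sire_id"] is None
        assert "dropped" in row["sex_resolution"]
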