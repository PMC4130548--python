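"""Synthetic-data generators: pedigree structure, kinship, gene dropping,
phenotype model, aCGH signal model, strata and variant tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foundercnv import simulate as S
from foundercnv.filters import select_set_variants


class TestSimulatePedigree:
    def test_one_generation_returns_exactly_the_founders(self):
        ped = S.simulate_pedigree(16, 1, seed=1)
        assert len(ped) == 16
        assert all(ind.is_founder for ind in ped.individuals)

    def test_seed_determinism(self):
        a = S.simulate_pedigree(4, 2, seed=7)
        b = S.simulate_pedigree(4, 2, seed=7)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_different_seed_differs(self):
        a = S.simulate_pedigree(8, 3, seed=1)
        b = S.simulate_pedigree(8, 3, seed=2)
        assert not a.to_dataframe().equals(b.to_dataframe())

    def test_deep_pedigree_parent_links_are_valid(self):
        # full-scale founder population: every non-founder has two parents
        # of opposite sex from strictly earlier generations
        ped = S.simulate_pedigree(64, 13, offspring_rate=1.1, seed=3)
        index = {ind.iid: ind for ind in ped.individuals}
        n_checked = 0
        for ind in ped.individuals:
            if ind.is_founder:
                continue
            father, mother = index[ind.father], index[ind.mother]
            assert father.sex == "male" and mother.sex == "female"
            assert father.generation < ind.generation
            assert mother.generation < ind.generation
            n_checked += 1
        assert n_checked > 0

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            S.simulate_pedigree(1, 3, seed=0)
        with pytest.raises(ValueError):
            S.simulate_pedigree(8, 0, seed=0)
        with pytest.raises(ValueError):
            S.simulate_pedigree(8, 3, offspring_rate=-1.0, seed=0)


class TestComputeKinship:
    def test_trio_closed_form(self, trio):
        kin = S.compute_kinship(trio)
        assert kin.phi("kid", "mom") == pytest.approx(0.25)
        assert kin.phi("kid", "dad") == pytest.approx(0.25)
        assert kin.phi("kid", "kid") == pytest.approx(0.5)
        assert kin.phi("dad", "mom") == 0.0

    def test_child_of_full_sibs(self, sib_mating_pedigree):
        kin = S.compute_kinship(sib_mating_pedigree)
        assert kin.phi("bro", "sis") == pytest.approx(0.25)
        # phi_ii = (1 + f)/2 with f = 1/4 for an offspring of full sibs
        assert kin.phi("inbred", "inbred") == pytest.approx(0.625)

    def test_matches_gene_dropping_ibd_estimate(self):
        """2*phi equals expected IBD allele sharing, estimated by dropping
        unique founder allele labels through the pedigree 200k times."""
        ped = S.simulate_pedigree(10, 3, offspring_rate=1.5, seed=5)
        members = ped.topo_order()[:30]
        sub = S.Pedigree(list(ped.individuals))  # keep full pedigree for drops
        kin = S.compute_kinship(sub)
        pos = {iid: k for k, iid in enumerate(kin.ids)}

        n_reps = 200_000
        rng = np.random.default_rng(42)
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        label = 0
        for ind in sub.topo_order():
            if ind.is_founder:
                haps[ind.iid] = (
                    np.full(n_reps, label), np.full(n_reps, label + 1)
                )
                label += 2
            else:
                pick_f = rng.integers(2, size=n_reps)
                pick_m = rng.integers(2, size=n_reps)
                fa, mo = haps[ind.father], haps[ind.mother]
                haps[ind.iid] = (
                    np.where(pick_f == 0, fa[0], fa[1]),
                    np.where(pick_m == 0, mo[0], mo[1]),
                )

        rng_pairs = np.random.default_rng(7)
        pairs = [tuple(rng_pairs.choice(len(members), 2, replace=False)) for _ in range(12)]
        for i, j in pairs:
            a, b = members[i].iid, members[j].iid
            ha, hb = haps[a], haps[b]
            share = sum(
                (ha[u] == hb[v]).mean() for u in range(2) for v in range(2)
            ) / 4.0
            # phi = P(random allele of a IBD to random allele of b)
            se = np.sqrt(share * (1 - share) / n_reps) * 2  # 4 hap pairs, conservative
            assert abs(share - kin.matrix[pos[a], pos[b]]) < max(3 * se, 0.004)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_kinship_bounds_and_symmetry(self, seed):
        ped = S.simulate_pedigree(6, 3, offspring_rate=1.2, seed=seed)
        kin = S.compute_kinship(ped)
        m = kin.matrix
        assert np.allclose(m, m.T)
        assert (m >= 0).all() and (m <= 1).all()
        assert (np.diag(m) >= 0.5 - 1e-12).all()
        # 2*Phi is an additive relationship matrix: positive semi-definite
        assert np.linalg.eigvalsh(2 * m).min() > -1e-8


class TestDropBiallelicGenotypes:
    def test_fixed_frequencies(self, trio):
        assert (S.drop_biallelic_genotypes(trio, 0.0, seed=1) == 0).all()
        assert (S.drop_biallelic_genotypes(trio, 1.0, seed=1) == 2).all()

    def test_founder_frequency_is_unbiased(self):
        ped = S.simulate_pedigree(64, 1, seed=0)
        n_reps = 10_000
        freqs = np.empty(n_reps)
        for b in range(n_reps):
            g = S.drop_biallelic_genotypes(ped, 0.2, seed=b)
            freqs[b] = g.sum() / (2 * len(ped))
        se = np.sqrt(0.2 * 0.8 / (2 * 64 * n_reps))
        assert abs(freqs.mean() - 0.2) < 3 * se

    def test_mendelian_consistency(self):
        ped = S.simulate_pedigree(10, 3, offspring_rate=1.5, seed=3)
        _, haps = S.drop_biallelic_genotypes(ped, 0.4, seed=9, return_haplotypes=True)
        for ind in ped.individuals:
            if ind.is_founder:
                continue
            assert haps.loc[ind.iid, "hap_pat"] in set(haps.loc[ind.father])
            assert haps.loc[ind.iid, "hap_mat"] in set(haps.loc[ind.mother])

    def test_seed_determinism(self, trio):
        a = S.drop_biallelic_genotypes(trio, 0.5, seed=4)
        b = S.drop_biallelic_genotypes(trio, 0.5, seed=4)
        assert a.equals(b)


class TestAssignPhenotypes:
    def test_labels_partition_and_determinism(self):
        ped = S.simulate_pedigree(20, 2, seed=0)
        g = S.drop_biallelic_genotypes(ped, 0.3, seed=1)
        a = S.assign_phenotypes(ped, g, 0.25, 1.0, seed=2)
        b = S.assign_phenotypes(ped, g, 0.25, 1.0, seed=2)
        assert a.equals(b)
        assert set(a.unique()) <= {"asthma", "control", "unknown"}

    def test_risk_allele_enriched_in_cases(self):
        # large unrelated cohort, strong effect, no familial term:
        # carrier frequency must be visibly higher among cases
        ped = S.simulate_pedigree(4000, 1, seed=0)
        g = S.drop_biallelic_genotypes(ped, 0.2, seed=1)
        ph = S.assign_phenotypes(ped, g, 0.2, 3.0, seed=2, familial_sd=0.0)
        f_case = g[ph == "asthma"].mean() / 2
        f_ctrl = g[ph == "control"].mean() / 2
        assert f_case > f_ctrl + 0.03

    def test_null_or_leaves_genotype_balanced(self):
        ped = S.simulate_pedigree(4000, 1, seed=3)
        g = S.drop_biallelic_genotypes(ped, 0.2, seed=4)
        ph = S.assign_phenotypes(ped, g, 0.3, 1.0, seed=5, familial_sd=0.0)
        f_case = g[ph == "asthma"].mean() / 2
        f_ctrl = g[ph == "control"].mean() / 2
        assert abs(f_case - f_ctrl) < 0.02


class TestSimulateAcghProbes:
    def _truth(self, cn_values, ids=None):
        ids = ids or [f"s{i}" for i in range(len(cn_values))]
        loci = pd.DataFrame(
            [{"locus_id": "L1", "chrom": "chr1", "start": 100, "end": 1100,
              "allele_type": "deletion", "founder_freq": 0.0}]
        )
        return S.SimulatedCnvTruth(loci, pd.DataFrame({"L1": cn_values}, index=ids))

    def test_zero_noise_log2_is_exact(self):
        truth = self._truth([2, 1, 4])
        probes = S.simulate_acgh_probes(truth, probes_per_locus=5, noise_sd=0.0, seed=0)
        by_sample = probes.groupby("sample")["log2_ratio"].median()
        assert by_sample["s0"] == 0.0
        assert by_sample["s1"] == -1.0
        assert by_sample["s2"] == 1.0

    def test_zero_copy_uses_finite_floor(self):
        probes = S.simulate_acgh_probes(self._truth([0]), 3, 0.0, seed=0)
        expected = np.log2(S.CN_ZERO_FLOOR / 2)
        assert probes["log2_ratio"].unique() == pytest.approx([expected])

    def test_median_concentrates_with_noise(self):
        # CN 3 vs reference 2 at noise 0.1 with 10 probes: the per-sample
        # median log2 lands within 0.1 of log2(1.5) in >=95% of replicates
        truth = self._truth([3] * 1000)
        probes = S.simulate_acgh_probes(truth, 10, 0.1, seed=11)
        med = probes.groupby("sample")["log2_ratio"].median()
        frac = (np.abs(med - np.log2(1.5)) < 0.1).mean()
        assert frac >= 0.95

    def test_determinism(self):
        truth = self._truth([2, 1])
        a = S.simulate_acgh_probes(truth, 4, 0.2, seed=5)
        b = S.simulate_acgh_probes(truth, 4, 0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateStrata:
    def test_zero_frequency_gives_zero_cells(self):
        (t,) = S.simulate_strata([(100, 80, 0.0, 0.0)], seed=0)
        assert t.case_carrier == 0 and t.control_carrier == 0
        assert t.case_noncarrier == 200 and t.control_noncarrier == 160

    def test_binomial_mean(self):
        n_reps = 5000
        counts = np.empty(n_reps)
        for b in range(n_reps):
            (t,) = S.simulate_strata([(189, 172, 0.019, 0.015)], seed=b)
            counts[b] = t.case_carrier
        expected = 2 * 189 * 0.019
        se = np.sqrt(2 * 189 * 0.019 * 0.981 / n_reps)
        assert abs(counts.mean() - expected) < 3 * se

    def test_determinism(self):
        a = S.simulate_strata([(50, 50, 0.1, 0.1)], seed=3)
        b = S.simulate_strata([(50, 50, 0.1, 0.1)], seed=3)
        assert a[0] == b[0]


class TestSimulateVariantTable:
    def test_all_synonymous_yields_empty_qualifying_set(self):
        records, _, _ = S.simulate_variant_table(
            20, 50, 50, class_mix={"synonymous": 1.0}, seed=0
        )
        assert select_set_variants(records, "TX1", mode="rare_conserved") == []

    def test_high_missingness_excludes_everything(self):
        records, _, _ = S.simulate_variant_table(10, 200, 200, missingness_rate=0.5, seed=1)
        assert select_set_variants(records, "TX1", mode="rare_conserved") == []
        assert select_set_variants(records, "TX1", mode="all_protein_altering") == []

    def test_control_enrichment_plants_excess_control_alleles(self):
        records, case_ids, control_ids = S.simulate_variant_table(
            40, 800, 800, control_enrichment=10.0, base_allele_freq=0.002, seed=2
        )
        kept = select_set_variants(records, "TX1", mode="rare_conserved")
        case_alleles = sum(
            sum(r.genotypes[s] or 0 for s in case_ids) for r in kept
        )
        ctrl_alleles = sum(
            sum(r.genotypes[s] or 0 for s in control_ids) for r in kept
        )
        assert ctrl_alleles > 3 * max(case_alleles, 1)
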