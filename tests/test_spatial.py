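"""Spatial / diversity statistics: exhaustive small-case oracles, closed
forms and permutation-test properties."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amplimhc.reference_data import NGS_COUNTS, SSCP_COUNTS
from amplimhc.spatial import (
    allele_frequency_summary,
    allelic_richness,
    genetic_distance_individuals,
    geo_distance_matrix,
    mantel,
    microsat_summary,
    paired_t_test,
    partial_mantel,
    private_alleles,
)

TOY = {"A": {"1", "2"}, "B": {"2", "3"}, "C": {"3", "4"}}
ONE_GROUP = {"A": "g", "B": "g", "C": "g"}


class TestAllelicRichness:
    def test_g1_equals_mean_allele_count(self):
        res = allelic_richness(TOY, ONE_GROUP, g=1, n_reps=4000, seed=0)[0]
        assert res.mean_richness == pytest.approx(2.0, abs=0.05)

    def test_exact_enumeration_matches_hand_value(self):
        res = allelic_richness(TOY, ONE_GROUP, g=2, exact=True)[0]
        # subsets {A,B}->3, {A,C}->4, {B,C}->3 alleles: mean 10/3
        assert res.mean_richness == pytest.approx(10 / 3)
        assert res.n_replicates == 3

    def test_resampling_converges_to_exact(self):
        exact = allelic_richness(TOY, ONE_GROUP, g=2, exact=True)[0]
        mc = allelic_richness(TOY, ONE_GROUP, g=2, n_reps=8000, seed=1)[0]
        assert mc.mean_richness == pytest.approx(exact.mean_richness, abs=0.05)

    def test_full_group_draw_has_zero_sd(self):
        res = allelic_richness(TOY, ONE_GROUP, g=3, n_reps=100, seed=2)[0]
        assert res.mean_richness == 4 and res.sd_richness == 0

    def test_mean_nondecreasing_in_g(self, study_truth):
        groups = {i: "all" for i in study_truth.genotypes}
        means = [
            allelic_richness(study_truth.genotypes, groups, g=g, n_reps=300, seed=3)[0].mean_richness
            for g in (2, 5, 10, 20)
        ]
        assert means == sorted(means)

    def test_oversized_g_rejected(self):
        with pytest.raises(ValueError):
            allelic_richness(TOY, ONE_GROUP, g=5, n_reps=10, seed=0)


class TestPrivateAlleles:
    def test_shared_allele_not_private(self):
        groups = {"A": "g1", "B": "g2", "C": "g2"}
        priv = private_alleles(TOY, groups)
        assert "2" not in priv["g1"] and "2" not in priv["g2"]

    def test_single_biome_carriers_are_private(self):
        geno = {"A": {"x"}, "B": {"x"}, "C": {"y"}}
        groups = {"A": "g1", "B": "g1", "C": "g2"}
        priv = private_alleles(geno, groups)
        assert priv == {"g1": {"x"}, "g2": {"y"}}

    def test_private_plus_shared_partitions_alleles(self, study_truth):
        priv = private_alleles(study_truth.genotypes, study_truth.biome_of)
        n_private = sum(len(v) for v in priv.values())
        all_alleles = set().union(*study_truth.genotypes.values())
        carriers = {
            a: {study_truth.biome_of[i] for i, g in study_truth.genotypes.items() if a in g}
            for a in all_alleles
        }
        n_shared = sum(1 for v in carriers.values() if len(v) > 1)
        assert n_private + n_shared == len(all_alleles)


class TestFrequencySummary:
    def test_published_catalog_thresholds(self):
        geno = {f"i{k}": set() for k in range(65)}
        for k in range(37):
            geno[f"i{k}"].add("common")
        for k in range(7):
            geno[f"i{k}"].add("borderline_in")
        for k in range(6):
            geno[f"i{k}"].add("borderline_out")
        for k in range(2):
            geno[f"i{k}"].add("rare")
        df = allele_frequency_summary(geno).set_index("allele")
        assert df.at["common", "frequency"] == pytest.approx(37 / 65)
        assert round(df.at["common", "frequency"], 3) == 0.569
        assert df.at["borderline_in", "frequent"]  # 7/65 = 0.108 > 0.10
        assert not df.at["borderline_out", "frequent"]  # 6/65 = 0.092
        assert df.at["rare", "rare"] and not df.at["common", "rare"]


class TestMicrosatSummary:
    def test_heterozygosity_closed_forms(self):
        tab = pd.DataFrame(
            {"L1_1": [150, 150, 152, 152], "L1_2": [152, 152, 150, 150],
             "L2_1": [160, 160, 160, 160], "L2_2": [160, 160, 160, 160]},
            index=["a", "b", "c", "d"],
        )
        groups = {k: "g" for k in tab.index}
        s = microsat_summary(tab, groups).set_index("locus")
        assert s.at["L1", "He"] == pytest.approx(0.5)
        assert s.at["L1", "Ho"] == 1.0
        assert s.at["L2", "He"] == 0 and s.at["L2", "Ho"] == 0
        assert s.at["L2", "Na"] == 1

    def test_private_microsat_alleles(self):
        tab = pd.DataFrame(
            {"L1_1": [150, 154], "L1_2": [150, 154]}, index=["a", "b"]
        )
        s = microsat_summary(tab, {"a": "g1", "b": "g2"})
        assert (s.private == 1).all()


class TestGeoDistance:
    def test_equator_degree_is_111km(self):
        d = geo_distance_matrix({"a": (0.0, 0.0), "b": (0.0, 1.0)}, log10=False)
        assert d.loc["a", "b"] == pytest.approx(111.2, abs=0.3)

    def test_symmetry_zero_diagonal_and_log_floor(self):
        d = geo_distance_matrix({"a": (1.0, 1.0), "b": (1.0, 1.0), "c": (2.0, 2.0)})
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert d.loc["a", "b"] == -1.0  # co-located pair floored at 0.1 km

    def test_invalid_coordinates_name_individual(self):
        with pytest.raises(ValueError, match="bad_ind"):
            geo_distance_matrix({"bad_ind": (99.0, 0.0), "b": (0.0, 0.0)})

    def test_planar_close_to_haversine_at_small_scale(self):
        coords = {"a": (-10.0, -50.0), "b": (-10.5, -50.5)}
        h = geo_distance_matrix(coords, mode="haversine", log10=False)
        p = geo_distance_matrix(coords, mode="planar", log10=False)
        assert h.loc["a", "b"] == pytest.approx(p.loc["a", "b"], rel=0.01)


class TestGeneticDistance:
    def test_presence_mismatch_examples(self):
        d = genetic_distance_individuals(
            {"x": {"1", "2", "3"}, "y": {"2", "3", "4"}, "z": {"1", "2", "3"}}
        )
        assert d.loc["x", "y"] == pytest.approx(1 / 3)
        assert d.loc["x", "z"] == 0

    def test_disjoint_sets_are_maximally_distant(self):
        d = genetic_distance_individuals({"x": {"1"}, "y": {"2"}})
        assert d.loc["x", "y"] == 1

    def test_microsat_allele_sharing(self):
        tab = pd.DataFrame(
            {"L1_1": [150, 150], "L1_2": [152, 154],
             "L2_1": [160, 162], "L2_2": [160, 164]},
            index=["x", "y"],
        )
        d = genetic_distance_individuals(tab, kind="microsat_allele_sharing")
        # L1 shares one allele (0.5 unshared), L2 shares none (1.0)
        assert d.loc["x", "y"] == pytest.approx(0.75)


def brute_force_exact_mantel(a, b):
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(a[iu], b[np.ix_(p, p)][iu])[0, 1]
        total += 1
        hits += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, hits / total


def random_distance_matrix(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = random_distance_matrix(rng, 6)
        res = mantel(a, a, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_on_4x4(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = random_distance_matrix(rng, 4)
            b = random_distance_matrix(rng, 4)
            res = mantel(a, b, exact=True)
            r_exp, p_exp = brute_force_exact_mantel(a, b)
            assert res.r == pytest.approx(r_exp)
            assert res.p_value == pytest.approx(p_exp)

    def test_permutation_p_consistent_with_exact(self):
        rng = np.random.default_rng(2)
        a = random_distance_matrix(rng, 5)
        b = a + 0.1 * random_distance_matrix(rng, 5)
        exact = mantel(a, b, exact=True)
        mc = mantel(a, b, n_perm=2000, seed=3)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_p_never_zero_and_seeded(self):
        rng = np.random.default_rng(3)
        a = random_distance_matrix(rng, 10)
        b = a.copy()
        r1 = mantel(a, b, n_perm=500, seed=7)
        r2 = mantel(a, b, n_perm=500, seed=7)
        assert r1.p_value > 0 and r1.p_value == r2.p_value

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        a = random_distance_matrix(rng, 7)
        b = random_distance_matrix(rng, 7)
        p = rng.permutation(7)
        res1 = mantel(a, b, n_perm=200, seed=5)
        res2 = mantel(a[np.ix_(p, p)], b[np.ix_(p, p)], n_perm=200, seed=5)
        assert res1.r == pytest.approx(res2.r)

    def test_constant_matrix_reported_undefined(self):
        a = np.zeros((4, 4))
        rng = np.random.default_rng(5)
        res = mantel(a, random_distance_matrix(rng, 4), n_perm=10, seed=0)
        assert math.isnan(res.r)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(60):
            a = random_distance_matrix(rng, 8)
            b = random_distance_matrix(rng, 8)
            ps.append(mantel(a, b, n_perm=200, seed=int(rng.integers(2**31))).p_value)
        assert 0.3 < np.mean(ps) < 0.7

    def test_r_matches_scikit_bio(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        rng = np.random.default_rng(7)
        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10)
        ours = mantel(a, b, n_perm=99, seed=0)
        theirs = skbio_mantel(a, b, method="pearson", permutations=0)[0]
        assert ours.r == pytest.approx(theirs)


class TestPartialMantel:
    def test_constant_conditioning_reduces_to_simple(self):
        rng = np.random.default_rng(8)
        a = random_distance_matrix(rng, 6)
        b = random_distance_matrix(rng, 6)
        c = np.ones((6, 6)) - np.eye(6)
        simple = mantel(a, b, n_perm=200, seed=9)
        part = partial_mantel(a, b, c, n_perm=200, seed=9)
        assert part.r == pytest.approx(simple.r)

    def test_matches_closed_form_partial_correlation(self):
        rng = np.random.default_rng(9)
        a = random_distance_matrix(rng, 8)
        b = random_distance_matrix(rng, 8)
        c = random_distance_matrix(rng, 8)
        iu = np.triu_indices(8, k=1)
        rab = np.corrcoef(a[iu], b[iu])[0, 1]
        rac = np.corrcoef(a[iu], c[iu])[0, 1]
        rbc = np.corrcoef(b[iu], c[iu])[0, 1]
        expected = (rab - rac * rbc) / math.sqrt((1 - rac**2) * (1 - rbc**2))
        res = partial_mantel(a, b, c, n_perm=50, seed=0)
        assert res.r == pytest.approx(expected, abs=1e-9)

    def test_orthogonal_predictor_not_significant(self):
        rng = np.random.default_rng(10)
        c = random_distance_matrix(rng, 12)
        a = 2 * c + 0.01 * random_distance_matrix(rng, 12)  # a is driven by c
        b = random_distance_matrix(rng, 12)  # independent predictor
        res = partial_mantel(a, b, c, n_perm=500, seed=11)
        assert abs(res.r) < 0.35 and res.p_value > 0.05


class TestPairedT:
    def test_method_comparison_columns(self):
        res = paired_t_test(list(SSCP_COUNTS), list(NGS_COUNTS))
        assert res.df == 9
        assert round(res.t, 3) == 3.772
        assert round(res.p_value, 3) == 0.004

    def test_equal_samples_degenerate(self):
        res = paired_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p_value == 1

    def test_hand_computed_case(self):
        x, y = [1, 2, 3, 4], [2, 4, 3, 6]
        d = np.array(y) - np.array(x)
        t_exp = d.mean() / (d.std(ddof=1) / 2)
        res = paired_t_test(x, y)
        assert res.t == pytest.approx(t_exp)
        assert res.p_value == pytest.approx(2 * stats.t.sf(t_exp, df=3))
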