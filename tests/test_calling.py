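"""Variant classification and allele calling, checked against hand-worked
examples and an independent brute-force implementation of the rules."""

import itertools
import math

import numpy as np
import pytest

from oracles import brute_force_labels

from amplimhc.calling import (
    ARTIFACT_LABELS,
    Variant,
    classify_within_amplicon,
    cluster_variants,
    cross_individual_consolidate,
    cross_replicate_classify,
    detect_chimera,
    estimate_min_loci,
    name_alleles,
)

A = "ACGT" * 12  # 48 bp toy sequences keep the chimera scans cheap


def mutate(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


class TestClusterVariants:
    def test_identical_reads_form_one_variant(self):
        vs = cluster_variants(["ACGT"] * 10)
        assert len(vs) == 1 and vs[0].count == 10 and vs[0].rank == 1

    def test_ranking_and_singleton_label(self):
        vs = cluster_variants(["AAAA"] * 5 + ["CCCC"] * 3 + ["GGGG"])
        assert [(v.sequence, v.count) for v in vs] == [
            ("AAAA", 5), ("CCCC", 3), ("GGGG", 1)
        ]
        assert vs[2].label == "singleton_artifact"
        assert vs[0].label is None is vs[1].label

    def test_ties_break_lexicographically(self):
        vs = cluster_variants(["TTTT", "AAAA", "TTTT", "AAAA"])
        assert [v.sequence for v in vs] == ["AAAA", "TTTT"]

    def test_empty_amplicon(self):
        assert cluster_variants([]) == []


class TestDetectChimera:
    p1 = A
    p2 = mutate(mutate(A, 5, "T"), 40, "G")  # A[5]='C'->'T', A[40]='A'->'G'

    def test_constructed_recombinant_found(self):
        cand = self.p1[:20] + self.p2[20:]
        ok, pair, bp = detect_chimera(cand, [self.p1, self.p2])
        assert ok and set(pair) == {self.p1, self.p2}
        # breakpoint consistent: candidate == p1[:bp] + p2[bp:]
        assert cand == pair[0][:bp] + pair[1][bp:]

    def test_identical_to_parent_is_not_chimera(self):
        ok, _, _ = detect_chimera(self.p1, [self.p1, self.p2])
        assert not ok

    def test_matches_exhaustive_breakpoint_scan(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(300):
            seqs = [
                "".join(rng.choice(list(bases), size=12)) for _ in range(3)
            ]
            p1, p2, cand = seqs
            ok, _, _ = detect_chimera(cand, [p1, p2])
            brute = any(
                cand == pa[:b] + pb[b:] and cand not in (pa, pb)
                for pa, pb in itertools.permutations([p1, p2], 2)
                for b in range(1, len(cand))
            )
            assert ok == brute


class TestClassifyWithinAmplicon:
    def test_low_count_one_bp_neighbour(self):
        top = Variant(A, 500, 1)
        low = Variant(mutate(A, 10, "G" if A[10] != "G" else "C"), 3, 2)
        classify_within_amplicon([top, low])
        assert low.label == "one_bp_diff" and top.label == "gt_one_bp_diff"

    def test_chimera_test_precedes_one_bp_test(self):
        p1 = A
        p2 = mutate(mutate(A, 4, "T" if A[4] != "T" else "G"), 44, "A" if A[44] != "A" else "C")
        chim = p1[:20] + p2[20:]  # 1 bp from p1 AND a recombinant
        vs = [Variant(p1, 500, 1), Variant(p2, 400, 2), Variant(chim, 5, 3)]
        classify_within_amplicon(vs)
        assert vs[2].label == "chimera"

    def test_distant_variant_is_gt_one_bp(self):
        far = A
        for pos in (3, 9, 15, 21, 27):
            far = mutate(far, pos, "C" if A[pos] != "C" else "G")
        vs = [Variant(A, 500, 1), Variant(far, 4, 2)]
        classify_within_amplicon(vs)
        assert vs[1].label == "gt_one_bp_diff"

    def test_comparable_counts_not_artifact_labelled(self):
        # two co-amplified alleles 1 bp apart with similar counts: neither is
        # explicable as an error of the other
        sib = mutate(A, 30, "A" if A[30] != "A" else "T")
        vs = [Variant(A, 30, 1), Variant(sib, 20, 2)]
        classify_within_amplicon(vs)
        assert vs[1].label == "gt_one_bp_diff"


class TestCrossReplicate:
    def test_present_in_both_above_artifacts_is_putative(self):
        err = mutate(A, 7, "C" if A[7] != "C" else "T")
        rep1 = classify_within_amplicon(cluster_variants([A] * 100 + [err] * 2))
        rep2 = classify_within_amplicon(cluster_variants([A] * 90 + [err]))
        labels = cross_replicate_classify(rep1, rep2)
        assert labels[A] == "putative_allele"
        assert labels[err] == "artifact"

    def test_single_replicate_but_recurrent_is_unclassified(self):
        other = mutate(mutate(A, 1, "T" if A[1] != "T" else "G"),
                       30, "C" if A[30] != "C" else "G")
        rep1 = classify_within_amplicon(cluster_variants([A] * 100 + [other] * 10))
        rep2 = classify_within_amplicon(cluster_variants([A] * 100))
        labels = cross_replicate_classify(rep1, rep2, seen_elsewhere={other})
        assert labels[other] == "unclassified"

    def test_single_replicate_seen_nowhere_is_artifact(self):
        other = mutate(mutate(A, 1, "T" if A[1] != "T" else "G"),
                       30, "C" if A[30] != "C" else "G")
        rep1 = classify_within_amplicon(cluster_variants([A] * 100 + [other] * 10))
        rep2 = classify_within_amplicon(cluster_variants([A] * 100))
        labels = cross_replicate_classify(rep1, rep2, seen_elsewhere=set())
        assert labels[other] == "artifact"


class TestConsolidateAndNaming:
    def test_majority_putative_is_plain_allele(self):
        labels = {
            "i1": {A: "putative_allele"},
            "i2": {A: "putative_allele"},
            "i3": {A: "putative_allele"},
            "i4": {A: "unclassified"},
        }
        info, genotypes = cross_individual_consolidate(labels)
        assert A in info and not info[A]["low_amp"]
        assert genotypes["i4"] == {A}

    def test_mostly_unclassified_flagged_low_amplification(self):
        labels = {f"i{k}": {A: "unclassified"} for k in range(4)}
        labels["i9"] = {A: "putative_allele"}
        info, _ = cross_individual_consolidate(labels)
        assert info[A]["low_amp"]

    def test_single_occurrence_not_validated(self):
        info, _ = cross_individual_consolidate({"i1": {A: "unclassified"}})
        assert A not in info

    def test_letter_suffixes_for_synonymous_alleles(self):
        # four sequences with identical translation (third-position changes)
        base = "CTTCGTGGG"  # L R G
        variants = {
            "CTACGTGGG": 400, "CTCCGTGGG": 300, "CTGCGTGGG": 200, base: 100,
        }
        unique = "ATGAAATTT"
        info = {
            s: {"discovery": i, "coverage": c, "carriers": ["i1"], "low_amp": False,
                "n_putative": 1, "n_unclassified": 0}
            for i, (s, c) in enumerate({**variants, unique: 50}.items())
        }
        catalog = name_alleles(info, n_individuals=1, prefix="X*")
        names = {a.sequence: a.name for a in catalog.alleles}
        syn_names = sorted(names[s] for s in variants)
        assert syn_names == ["X*01a", "X*01b", "X*01c", "X*01d"]
        # suffix order follows coverage
        assert names["CTACGTGGG"] == "X*01a" and names[base] == "X*01d"
        assert names[unique] == "X*02"

    @pytest.mark.parametrize("max_count,expected", [(13, 7), (2, 1), (5, 3)])
    def test_min_loci_bound(self, max_count, expected):
        genotypes = {"ind": {f"a{k}" for k in range(max_count)}, "other": {"a0"}}
        assert estimate_min_loci(genotypes) == expected

    def test_min_loci_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            estimate_min_loci({})


class TestBruteForceOracle:
    def test_labels_match_brute_force_on_small_amplicons(self):
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for trial in range(150):
            # a small pool of related sequences: a root, mutants, recombinants
            root = "".join(rng.choice(list(bases), size=15))
            seqs = {root}
            while len(seqs) < 6:
                s = rng.choice(sorted(seqs))
                kind = rng.random()
                if kind < 0.5:
                    pos = int(rng.integers(15))
                    s = s[:pos] + bases[rng.integers(4)] + s[pos + 1 :]
                elif kind < 0.8 and len(seqs) >= 2:
                    t = rng.choice(sorted(seqs))
                    b = int(rng.integers(1, 15))
                    s = s[:b] + t[b:]
                else:
                    pos = int(rng.integers(15))
                    s = s[:pos] + s[pos + 1 :] if rng.random() < 0.5 else s[:pos] + bases[rng.integers(4)] + s[pos:]
                seqs.add(s)
            seqs = sorted(seqs)
            counts1 = {s: int(rng.integers(1, 200)) for s in rng.choice(seqs, size=int(rng.integers(2, 7)), replace=False)}
            counts2 = {s: int(rng.integers(1, 200)) for s in rng.choice(seqs, size=int(rng.integers(2, 7)), replace=False)}
            elsewhere = set(rng.choice(seqs, size=2, replace=False))
            rep1 = classify_within_amplicon(
                cluster_variants([s for s, c in counts1.items() for _ in range(c)])
            )
            rep2 = classify_within_amplicon(
                cluster_variants([s for s, c in counts2.items() for _ in range(c)])
            )
            got = cross_replicate_classify(rep1, rep2, elsewhere)
            expected = brute_force_labels(counts1, counts2, elsewhere)
            assert got == expected, f"trial {trial}"


class TestPipelineInvariants:
    def test_label_totality_and_exclusivity(self, noisy_run):
        audit = noisy_run["audit"]
        assert audit.within_label.isin(
            {"singleton_artifact", "chimera", "one_bp_diff", "gt_one_bp_diff"}
        ).all()
        assert audit.replicate_label.isin(
            {"putative_allele", "unclassified", "artifact"}
        ).all()

    def test_no_putative_outranked_by_artifact(self, noisy_run):
        audit = noisy_run["audit"]
        for (_, _), grp in audit.groupby(["individual", "replicate"]):
            art_max = grp.loc[grp.within_label.isin(ARTIFACT_LABELS), "count"].max()
            if math.isnan(art_max):
                continue
            putative = grp[grp.replicate_label == "putative_allele"]
            assert (putative["count"] > art_max).all()
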