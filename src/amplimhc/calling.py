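"""Replicate-validated variant classification and allele calling.

Within each amplicon, identity clusters of QC-passed inserts ("variants")
are ranked by read count and screened against the more frequent variants:
single-breakpoint recombinants of two more-frequent parents are chimeras,
variants one edit away from a more-frequent variant are presumptive
polymerase/sequencing errors ("1 bp diff"), and singletons are artifacts
outright. A variant becomes a putative allele only if it occurs in both
independent replicate amplicons of an individual and outnumbers every
artifact-labelled variant in each replicate; recurrent variants that fail
the replicate rule but cannot be explained as artifacts are held as
"unclassified" and can be rescued across individuals as putative alleles
with low amplification efficiency.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .codons import translate
from .qc import Amplicon

__all__ = [
    "Variant",
    "AlleleRecord",
    "AlleleCatalog",
    "ARTIFACT_LABELS",
    "cluster_variants",
    "detect_chimera",
    "classify_within_amplicon",
    "cross_replicate_classify",
    "cross_individual_consolidate",
    "call_genotypes",
    "name_alleles",
    "estimate_min_loci",
]

#: within-amplicon labels that mark a variant as a presumptive artifact
ARTIFACT_LABELS = frozenset({"singleton_artifact", "chimera", "one_bp_diff"})

WITHIN_LABELS = frozenset({"singleton_artifact", "chimera", "one_bp_diff", "gt_one_bp_diff"})
REPLICATE_LABELS = frozenset({"putative_allele", "unclassified", "artifact"})


@dataclass
class Variant:
    sequence: str
    count: int
    rank: int = 0
    label: str | None = None  # within-amplicon label
    chimera_parents: tuple[str, str] | None = None
    chimera_breakpoint: int | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("variant count must be >= 1")


def cluster_variants(amplicon: Amplicon | list[str]) -> list[Variant]:
    """Identity clusters of an amplicon's inserts, ranked by read count.

    Ties are broken lexicographically by sequence. Count-1 variants are
    labelled ``singleton_artifact`` immediately.
    """
    inserts = amplicon.inserts if isinstance(amplicon, Amplicon) else amplicon
    counts = Counter(inserts)
    variants = [
        Variant(sequence=s, count=c) for s, c in counts.items()
    ]
    variants.sort(key=lambda v: (-v.count, v.sequence))
    for rank, v in enumerate(variants, start=1):
        v.rank = rank
        if v.count == 1:
            v.label = "singleton_artifact"
    return variants


def detect_chimera(
    candidate: str, parents: list[Variant] | list[str]
) -> tuple[bool, tuple[str, str] | None, int | None]:
    """Test whether ``candidate`` is a single-breakpoint recombinant of two
    distinct, more frequent parental variants.

    Every ordered parent pair and every internal breakpoint b (0 < b < len)
    is searched: a hit means candidate == P1[:b] + P2[b:] with the candidate
    identical to neither parent. Returns (is_chimera, (p1, p2), breakpoint).
    """
    seqs = [p.sequence if isinstance(p, Variant) else p for p in parents]
    for p1 in seqs:
        if p1 == candidate:
            continue
        # longest common prefix with p1
        lp = 0
        for a, b in zip(candidate, p1):
            if a != b:
                break
            lp += 1
        if lp == 0:
            continue
        for p2 in seqs:
            if p2 == candidate or p2 == p1 or len(p2) != len(candidate):
                continue
            # longest common suffix with p2
            ls = 0
            for a, b in zip(reversed(candidate), reversed(p2)):
                if a != b:
                    break
                ls += 1
            b_min = max(1, len(candidate) - ls)
            b_max = min(lp, len(candidate) - 1)
            if b_min <= b_max:
                return True, (p1, p2), b_min
    return False, None, None


def _edit_distance(s1: str, s2: str) -> int:
    return edlib.align(s1, s2)["editDistance"]


def classify_within_amplicon(
    variants: list[Variant], artifact_ratio: float = 1.0 / 3.0
) -> list[Variant]:
    """Assign the within-amplicon label to every non-singleton variant.

    Each variant is compared against the clearly more frequent variants —
    those whose count makes an artifactual origin plausible, i.e. variants
    at least ``1/artifact_ratio`` times more frequent (errors and chimeras
    arise from their parent templates at per-read rates far below this,
    whereas co-amplified alleles of one individual have comparable counts).
    The chimera test runs first, then the 1-edit test (Levenshtein; single
    substitutions and single-base indels count equally); otherwise the
    variant is ``gt_one_bp_diff``. Variants with no comparison partners
    (in particular the rank-1 variant) are ``gt_one_bp_diff`` vacuously.
    Genuine alleles with low amplification efficiency that do fall below the
    ratio are recoverable later through the cross-individual rescue.
    """
    for v in variants:
        if v.label == "singleton_artifact":
            continue
        more_frequent = [u for u in variants if v.count <= artifact_ratio * u.count]
        is_chim, pair, bp = detect_chimera(v.sequence, more_frequent)
        if is_chim:
            v.label = "chimera"
            v.chimera_parents = pair
            v.chimera_breakpoint = bp
            continue
        if more_frequent and min(
            _edit_distance(v.sequence, u.sequence) for u in more_frequent
        ) == 1:
            v.label = "one_bp_diff"
        else:
            v.label = "gt_one_bp_diff"
    return variants


def cross_replicate_classify(
    rep1: list[Variant],
    rep2: list[Variant],
    seen_elsewhere: set[str] | None = None,
) -> dict[str, str]:
    """Replicate-level label for every sequence seen in either replicate.

    putative_allele: present in both replicates and, in each, more frequent
    than every artifact-labelled variant there (an artifact-labelled variant
    can never exceed its own count, so it self-excludes).

    unclassified: fails the putative rule (single replicate, or outranked by
    an artifact) but recurs in other individuals (``seen_elsewhere``) and is
    not explicable as an artifact (never labelled chimera, 1-bp-diff or
    singleton where it occurs).

    artifact: everything else.
    """
    seen_elsewhere = seen_elsewhere or set()
    by_seq1 = {v.sequence: v for v in rep1}
    by_seq2 = {v.sequence: v for v in rep2}
    art_max1 = max((v.count for v in rep1 if v.label in ARTIFACT_LABELS), default=0)
    art_max2 = max((v.count for v in rep2 if v.label in ARTIFACT_LABELS), default=0)
    out: dict[str, str] = {}
    for seq in set(by_seq1) | set(by_seq2):
        v1, v2 = by_seq1.get(seq), by_seq2.get(seq)
        if (
            v1 is not None
            and v2 is not None
            and v1.count > art_max1
            and v2.count > art_max2
        ):
            out[seq] = "putative_allele"
            continue
        labels = {v.label for v in (v1, v2) if v is not None}
        if labels <= {"gt_one_bp_diff"} and seq in seen_elsewhere:
            out[seq] = "unclassified"
        else:
            out[seq] = "artifact"
    return out


@dataclass
class AlleleRecord:
    name: str
    sequence: str
    coverage: int
    n_individuals: int
    frequency: float
    low_amplification_efficiency: bool = False
    has_stop: bool = False


@dataclass
class AlleleCatalog:
    alleles: list[AlleleRecord] = field(default_factory=list)
    #: amino-acid sequence -> member nucleotide allele names
    aa_groups: dict[str, list[str]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.alleles])


def cross_individual_consolidate(
    labels_by_individual: dict[str, dict[str, str]],
    counts_by_individual: dict[str, dict[str, int]] | None = None,
) -> tuple[dict[str, dict], dict[str, set[str]]]:
    """Resolve per-individual labels into the validated allele set.

    A sequence is validated if it is a putative allele in at least one
    individual, or if it is unclassified in several individuals (recurrence
    across individuals rescues it, flagged ``low_amplification_efficiency``
    whenever unclassified calls outnumber putative ones). Either way a
    validated allele was seen in two independent reactions of one individual
    or in two distinct individuals.

    Returns (allele_info, genotypes): allele_info maps sequence -> dict with
    keys n_putative, n_unclassified, coverage, carriers, low_amp; genotypes
    maps individual -> set of validated sequences carried (label putative or
    unclassified there).
    """
    tally: dict[str, dict[str, int]] = defaultdict(lambda: {"putative": 0, "unclassified": 0})
    discovery: dict[str, int] = {}
    for order, (ind, labels) in enumerate(labels_by_individual.items()):
        for seq, label in labels.items():
            if label == "putative_allele":
                tally[seq]["putative"] += 1
            elif label == "unclassified":
                tally[seq]["unclassified"] += 1
            if label in ("putative_allele", "unclassified"):
                discovery.setdefault(seq, order)
    allele_info: dict[str, dict] = {}
    for seq, t in tally.items():
        validated = t["putative"] >= 1 or t["unclassified"] >= 2
        if not validated:
            continue
        low_amp = t["unclassified"] > t["putative"]
        carriers = [
            ind
            for ind, labels in labels_by_individual.items()
            if labels.get(seq) in ("putative_allele", "unclassified")
        ]
        coverage = 0
        if counts_by_individual:
            coverage = sum(counts_by_individual.get(ind, {}).get(seq, 0) for ind in carriers)
        allele_info[seq] = {
            "n_putative": t["putative"],
            "n_unclassified": t["unclassified"],
            "carriers": carriers,
            "coverage": coverage,
            "low_amp": low_amp,
            "discovery": discovery[seq],
        }
    genotypes = {
        ind: {seq for seq, lab in labels.items() if seq in allele_info and lab in ("putative_allele", "unclassified")}
        for ind, labels in labels_by_individual.items()
    }
    return allele_info, genotypes


def name_alleles(
    allele_info: dict[str, dict], n_individuals: int, prefix: str = "TateDRB*"
) -> AlleleCatalog:
    """Name validated alleles by discovery order; nucleotide alleles sharing
    a translation share a serial number and get coverage-ordered letter
    suffixes (a, b, c, ...)."""
    ordered = sorted(
        allele_info.items(), key=lambda kv: (kv[1]["discovery"], -kv[1]["coverage"], kv[0])
    )
    groups: dict[str, list[str]] = {}
    group_order: list[str] = []
    for seq, _ in ordered:
        aa = translate(seq)
        if aa not in groups:
            groups[aa] = []
            group_order.append(aa)
        groups[aa].append(seq)
    width = max(2, len(str(len(group_order))))
    catalog = AlleleCatalog()
    for num, aa in enumerate(group_order, start=1):
        members = sorted(groups[aa], key=lambda s: (-allele_info[s]["coverage"], s))
        for k, seq in enumerate(members):
            suffix = chr(ord("a") + k) if len(members) > 1 else ""
            info = allele_info[seq]
            catalog.alleles.append(
                AlleleRecord(
                    name=f"{prefix}{num:0{width}d}{suffix}",
                    sequence=seq,
                    coverage=info["coverage"],
                    n_individuals=len(info["carriers"]),
                    frequency=len(info["carriers"]) / n_individuals,
                    low_amplification_efficiency=info["low_amp"],
                    has_stop="*" in translate(seq),
                )
            )
        catalog.aa_groups[aa] = [
            a.name for a in catalog.alleles if translate(a.sequence) == aa
        ]
    return catalog


def estimate_min_loci(genotypes: dict[str, set[str]] | pd.DataFrame) -> int:
    """Lower bound on the number of amplified loci: half the maximum
    per-individual allele count, rounded up."""
    if isinstance(genotypes, pd.DataFrame):
        counts = genotypes.sum(axis=1)
        if counts.empty:
            raise ValueError("empty genotype matrix")
        return math.ceil(counts.max() / 2)
    if not genotypes:
        raise ValueError("empty genotype matrix")
    return math.ceil(max(len(v) for v in genotypes.values()) / 2)


def call_genotypes(
    amplicons: dict[tuple[str, int], Amplicon],
    min_coverage: int = 110,
    prefix: str = "TateDRB*",
    artifact_ratio: float = 1.0 / 3.0,
) -> tuple[AlleleCatalog, pd.DataFrame, pd.DataFrame]:
    """Run the whole classification workflow over all individuals.

    Individuals lacking either replicate, or with fewer than ``min_coverage``
    QC-passed reads in either replicate, are excluded from genotyping (their
    variants still inform the cross-individual occurrence checks).

    Returns (catalog, genotype_matrix, audit): the genotype matrix is a
    presence/absence DataFrame (individuals x allele names) over genotyped
    individuals; audit records every variant with its labels and evidence.
    """
    individuals = sorted({ind for ind, _ in amplicons})
    variants_by_ind: dict[str, dict[int, list[Variant]]] = {}
    for ind in individuals:
        reps = {}
        for rep in (1, 2):
            amp = amplicons.get((ind, rep))
            if amp is not None and amp.inserts:
                reps[rep] = classify_within_amplicon(cluster_variants(amp), artifact_ratio)
        variants_by_ind[ind] = reps

    occurrences: dict[str, set[str]] = defaultdict(set)
    for ind, reps in variants_by_ind.items():
        for vs in reps.values():
            for v in vs:
                occurrences[v.sequence].add(ind)

    genotypable = [
        ind
        for ind in individuals
        if set(variants_by_ind[ind]) == {1, 2}
        and all(
            sum(v.count for v in variants_by_ind[ind][rep]) >= min_coverage
            for rep in (1, 2)
        )
    ]

    labels_by_individual: dict[str, dict[str, str]] = {}
    counts_by_individual: dict[str, dict[str, int]] = {}
    audit_rows = []
    for ind in genotypable:
        rep1, rep2 = variants_by_ind[ind][1], variants_by_ind[ind][2]
        seen_elsewhere = {
            v.sequence
            for vs in (rep1, rep2)
            for v in vs
            if len(occurrences[v.sequence] - {ind}) > 0
        }
        labels = cross_replicate_classify(rep1, rep2, seen_elsewhere)
        labels_by_individual[ind] = labels
        counts = defaultdict(int)
        for vs, rep in ((rep1, 1), (rep2, 2)):
            for v in vs:
                counts[v.sequence] += v.count
                audit_rows.append(
                    {
                        "individual": ind,
                        "replicate": rep,
                        "sequence": v.sequence,
                        "count": v.count,
                        "rank": v.rank,
                        "within_label": v.label,
                        "replicate_label": labels[v.sequence],
                        "chimera_parents": ";".join(v.chimera_parents or ()),
                        "has_stop": "*" in translate(v.sequence) if len(v.sequence) % 3 == 0 else None,
                    }
                )
        counts_by_individual[ind] = dict(counts)

    allele_info, genotypes = cross_individual_consolidate(
        labels_by_individual, counts_by_individual
    )
    catalog = name_alleles(allele_info, n_individuals=len(genotypable), prefix=prefix)
    name_of = {a.sequence: a.name for a in catalog.alleles}
    matrix = pd.DataFrame(
        0, index=genotypable, columns=[a.name for a in catalog.alleles], dtype=int
    )
    for ind in genotypable:
        for seq in genotypes[ind]:
            matrix.at[ind, name_of[seq]] = 1
    audit = pd.DataFrame(audit_rows)
    return catalog, matrix, audit
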