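"""Ground-truthed synthetic data with the statistical structure of a
multi-locus MHC class II DRB exon-2 amplicon survey.

The generator produces (1) an allele pool over several duplicated loci whose
nonsynonymous variation is concentrated in antigen-binding-site (ABS)
codons, including whole-codon indel alleles and synonymous sibling alleles;
(2) biome-structured multi-allele genotypes with private alleles and
coordinates; (3) two replicate 454-style amplicons per individual with
per-base substitution errors, homopolymer-length indels, PCR chimeras and
Phred qualities; and (4) a diploid microsatellite table with configurable
between-biome divergence. Every read is tracked in a truth table so the
downstream pipeline can be validated end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import (
    BASES,
    CODON_TO_AA,
    DEFAULT_ABS_MASK,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
    translate,
)
from .qc import revcomp
from .selection import CodonAlignment

__all__ = [
    "AllelePool",
    "BiomeSpec",
    "TruthGenotypes",
    "ReadSimConfig",
    "DEFAULT_BIOMES",
    "FWD_PRIMER",
    "REV_PRIMER",
    "generate_allele_pool",
    "assign_genotypes",
    "make_mid_table",
    "simulate_amplicon_reads",
    "simulate_microsatellites",
]

# fusion-primer parts (10-base MIDs are generated; the rest is fixed)
FWD_ADAPTOR = "CGTATCGCCTCCCTCGCGCCA"
REV_ADAPTOR = "CTATGCGCCTTGCCAGCCCGC"
KEY = "TCAG"
FWD_PRIMER = "GAGTGTCATTTYGAGAACGGGACSGAG"  # contains IUPAC Y and S
REV_PRIMER = "TCGCCGCTGCACTGTGAACGTCTC"

# concrete bases emitted for the degenerate primer positions
_FWD_PRIMER_EMIT = FWD_PRIMER.replace("Y", "T").replace("S", "G")


# ---------------------------------------------------------------------------
# allele pool


@dataclass
class AllelePool:
    """Named nucleotide alleles over duplicated loci, plus their common
    codon alignment (whole-codon indels only)."""

    names: list[str]
    seq_of: dict[str, str]
    locus_of: dict[str, int]
    abs_mask: frozenset[int]
    aligned_of: dict[str, str]
    n_codons: int = 65

    def alignment(self) -> CodonAlignment:
        """Codon alignment of the pool with the ABS mask lifted onto the
        alignment coordinates (an insertion column shifts later codons)."""
        aligned_len = len(next(iter(self.aligned_of.values()))) // 3
        if aligned_len == self.n_codons:
            mask = self.abs_mask
        else:  # one insertion column at self._insertion_codon
            ins = self._insertion_codon
            mask = frozenset(i if i < ins else i + 1 for i in self.abs_mask)
        return CodonAlignment(
            names=list(self.names),
            seqs=[self.aligned_of[n] for n in self.names],
            abs_mask=mask,
        )

    _insertion_codon: int = 5


def _random_sense_codon(rng: np.random.Generator) -> str:
    return SENSE_CODONS[rng.integers(len(SENSE_CODONS))]


def _mutate(
    codons: list[str],
    n_mut: int,
    abs_mask: frozenset[int],
    rng: np.random.Generator,
    abs_nonsyn_enrichment: float,
    nonabs_omega: float,
    max_tries: int = 10_000,
) -> list[str]:
    """Apply ``n_mut`` accepted single-base substitutions.

    Proposals are uniform over (codon, position, base); stop-creating changes
    are rejected. Synonymous changes are accepted with probability 0.5,
    nonsynonymous changes at ABS codons with 0.5 * enrichment (capped at 1)
    and nonsynonymous changes elsewhere with 0.5 * nonabs_omega — this is
    what concentrates amino-acid variation in the binding sites.
    """
    out = list(codons)
    accepted = 0
    for _ in range(max_tries):
        if accepted >= n_mut:
            return out
        ci = int(rng.integers(len(out)))
        pos = int(rng.integers(3))
        cur = out[ci]
        base = BASES[rng.integers(4)]
        if base == cur[pos]:
            continue
        alt = cur[:pos] + base + cur[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        if CODON_TO_AA[alt] == CODON_TO_AA[cur]:
            p = 0.5
        elif (ci + 1) in abs_mask:
            p = min(1.0, 0.5 * abs_nonsyn_enrichment)
        else:
            p = 0.5 * nonabs_omega
        if rng.random() < p:
            out[ci] = alt
            accepted += 1
    raise RuntimeError(f"could not place {n_mut} stop-free mutations in {max_tries} proposals")


def _synonymous_variant(
    seq: str,
    existing: set[str],
    rng: np.random.Generator,
    excluded_codons: frozenset[int] = frozenset(),
) -> str | None:
    """A single-base synonymous variant of ``seq`` not already in use.

    ``excluded_codons`` (1-based) are never touched, so siblings stay
    distinct even if those codons are later deleted.
    """
    cods = codons_of(seq)
    order = rng.permutation(len(cods))
    for ci in order:
        if (ci + 1) in excluded_codons:
            continue
        cur = cods[ci]
        for pos in rng.permutation(3):
            for base in BASES:
                if base == cur[pos]:
                    continue
                alt = cur[:pos] + base + cur[pos + 1 :]
                if alt in STOP_CODONS or CODON_TO_AA[alt] != CODON_TO_AA[cur]:
                    continue
                cand = "".join(cods[:ci] + [alt] + cods[ci + 1 :])
                if cand not in existing:
                    return cand
    return None


def generate_allele_pool(
    n_loci: int = 7,
    alleles_per_locus: int = 10,
    abs_mask: frozenset[int] = DEFAULT_ABS_MASK,
    seed: int | None = None,
    n_codons: int = 65,
    abs_nonsyn_enrichment: float = 5.0,
    nonabs_omega: float = 0.5,
    locus_mutations: int = 15,
    allele_mutations: int = 6,
    n_synonymous: int = 10,
    n_insertion_alleles: int = 1,
    n_deletion_alleles: int = 13,
    insertion_codon: int = 5,
    deletion_codon: int = 57,
    max_retries: int = 200,
) -> AllelePool:
    """Generate a stop-free allele pool of ``n_loci * alleles_per_locus``
    distinct nucleotide sequences.

    ``n_synonymous`` alleles are synonymous single-base siblings of another
    allele at the same locus, so the pool collapses to
    ``total - n_synonymous`` amino-acid alleles. ``n_insertion_alleles`` /
    ``n_deletion_alleles`` alleles carry one whole-codon indel at a fixed
    position (siblings move together so the amino-acid arithmetic holds).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    total = n_loci * alleles_per_locus
    if not all(1 <= i <= n_codons for i in abs_mask):
        raise ValueError("abs_mask outside 1..n_codons")
    if n_synonymous > total - n_loci:
        raise ValueError("too many synonymous siblings requested")
    rng = np.random.default_rng(seed)
    ancestor = [_random_sense_codon(rng) for _ in range(n_codons)]

    mut = dict(
        abs_mask=abs_mask,
        rng=rng,
        abs_nonsyn_enrichment=abs_nonsyn_enrichment,
        nonabs_omega=nonabs_omega,
    )
    seqs: list[str] = []
    locus_idx: list[int] = []
    translations: set[str] = set()
    for locus in range(n_loci):
        locus_anc = _mutate(ancestor, locus_mutations, **mut)
        made = 0
        tries = 0
        while made < alleles_per_locus:
            tries += 1
            if tries > max_retries * alleles_per_locus:
                raise RuntimeError(
                    f"locus {locus}: could not generate {alleles_per_locus} "
                    f"distinct stop-free alleles after {tries} attempts"
                )
            cand = "".join(_mutate(locus_anc, allele_mutations, **mut))
            if cand in seqs or translate(cand) in translations:
                continue
            seqs.append(cand)
            translations.add(translate(cand))
            locus_idx.append(locus)
            made += 1

    # convert the chosen alleles into synonymous siblings of a same-locus source
    existing = set(seqs)
    sibling_of: dict[int, int] = {}
    used_as_source: set[int] = set()
    if n_synonymous:
        convertible = list(rng.permutation(total))
        converted = 0
        for k in convertible:
            if converted >= n_synonymous:
                break
            if k in sibling_of or k in used_as_source:
                continue
            sources = [
                j for j in range(total)
                if j != k and locus_idx[j] == locus_idx[k] and j not in sibling_of
            ]
            if not sources:
                continue
            src = int(sources[rng.integers(len(sources))])
            cand = _synonymous_variant(
                seqs[src], existing, rng,
                excluded_codons=frozenset({deletion_codon} if n_deletion_alleles else ()),
            )
            if cand is None:
                continue
            existing.discard(seqs[k])
            seqs[k] = cand
            existing.add(cand)
            sibling_of[k] = src
            used_as_source.add(src)
            converted += 1
        if converted < n_synonymous:
            raise RuntimeError("could not place all synonymous siblings")

    # amino-acid groups (sibling sets) for indel placement
    groups: dict[int, list[int]] = {}
    for k in range(total):
        root = sibling_of.get(k, k)
        groups.setdefault(root, []).append(k)

    def _pick_groups(n_alleles: int, taken: set[int]) -> list[int]:
        """Greedy choice of aa-groups whose member counts sum to n_alleles."""
        chosen: list[int] = []
        remaining = n_alleles
        roots = sorted(groups, key=lambda r: -len(groups[r]))
        for r in roots:
            if r in taken:
                continue
            if len(groups[r]) <= remaining and len(groups[r]) > 1:
                chosen.append(r)
                remaining -= len(groups[r])
        singles = [r for r in roots if len(groups[r]) == 1 and r not in taken]
        rng.shuffle(singles)
        chosen.extend(singles[:remaining])
        if sum(len(groups[r]) for r in chosen) != n_alleles:
            raise RuntimeError("cannot satisfy indel-allele counts with whole sibling groups")
        return chosen

    taken: set[int] = set()
    ins_members: set[int] = set()
    del_members: set[int] = set()
    if n_insertion_alleles:
        ins_roots = _pick_groups(n_insertion_alleles, taken)
        taken.update(ins_roots)
        ins_members = {k for r in ins_roots for k in groups[r]}
    if n_deletion_alleles:
        del_roots = _pick_groups(n_deletion_alleles, taken)
        taken.update(del_roots)
        del_members = {k for r in del_roots for k in groups[r]}

    inserted_codon = _random_sense_codon(rng)
    names = [f"SIM{k + 1:03d}" for k in range(total)]
    seq_of: dict[str, str] = {}
    aligned_of: dict[str, str] = {}
    has_insertion_col = bool(ins_members)
    for k, name in enumerate(names):
        cods = codons_of(seqs[k])
        aligned = list(cods)
        if k in del_members:
            aligned[deletion_codon - 1] = "---"
            cods = cods[: deletion_codon - 1] + cods[deletion_codon:]
        if has_insertion_col:
            col = inserted_codon if k in ins_members else "---"
            aligned = aligned[: insertion_codon - 1] + [col] + aligned[insertion_codon - 1 :]
        if k in ins_members:
            cods = cods[: insertion_codon - 1] + [inserted_codon] + cods[insertion_codon - 1 :]
        seq_of[name] = "".join(cods)
        aligned_of[name] = "".join(aligned)

    if len(set(seq_of.values())) != total:
        raise RuntimeError("indel placement collapsed two alleles; re-run with another seed")

    pool = AllelePool(
        names=names,
        seq_of=seq_of,
        locus_of={names[k]: locus_idx[k] for k in range(total)},
        abs_mask=frozenset(abs_mask),
        aligned_of=aligned_of,
        n_codons=n_codons,
    )
    pool._insertion_codon = insertion_codon
    return pool


# ---------------------------------------------------------------------------
# genotypes / metadata


@dataclass
class BiomeSpec:
    name: str
    n_individuals: int
    n_private: int
    bbox: tuple[float, float, float, float]  # lat_min, lat_max, lon_min, lon_max


#: the five-biome sampling structure of the emulated survey (genotyped sizes)
DEFAULT_BIOMES: tuple[BiomeSpec, ...] = (
    BiomeSpec("Atlantic_forest", 29, 12, (-25.0, -5.0, -50.0, -35.0)),
    BiomeSpec("Amazon_forest", 9, 11, (-10.0, 3.0, -70.0, -50.0)),
    BiomeSpec("Cerrado", 16, 5, (-20.0, -5.0, -55.0, -45.0)),
    BiomeSpec("Caatinga", 3, 3, (-15.0, -3.0, -44.0, -36.0)),
    BiomeSpec("Pantanal", 8, 2, (-22.0, -15.0, -59.0, -55.0)),
)


@dataclass
class TruthGenotypes:
    genotypes: dict[str, set[str]]  # individual -> allele names
    biome_of: dict[str, str]
    coords: dict[str, tuple[float, float]]  # (lat, lon)
    private_of: dict[str, set[str]] = field(default_factory=dict)  # biome -> alleles


def _unique_codes(names: list[str]) -> dict[str, str]:
    """Short distinct uppercase codes for individual-id prefixes."""
    codes: dict[str, str] = {}
    used: set[str] = set()
    for i, name in enumerate(names):
        candidates = ["".join(w[0] for w in name.split("_")).upper(), name[:2].upper(), name[:3].upper(), f"B{i + 1}"]
        code = next(c for c in candidates if len(c) >= 2 and c not in used)
        codes[name] = code
        used.add(code)
    return codes


def assign_genotypes(
    pool: AllelePool,
    biomes: tuple[BiomeSpec, ...] = DEFAULT_BIOMES,
    seed: int | None = None,
    min_alleles: int = 2,
    max_alleles: int = 13,
    n_top_common: int = 5,
) -> TruthGenotypes:
    """Draw biome-structured per-individual allele sets.

    Each biome gets its configured count of designated private alleles
    (guaranteed carried there and nowhere else); all remaining alleles are
    common and guaranteed to occur in at least two biomes, so the planted
    private split is recoverable exactly from the truth. ``n_top_common``
    alleles get boosted weight everywhere, emulating a handful of
    range-wide high-frequency alleles.
    """
    rng = np.random.default_rng(seed)
    n_private_total = sum(b.n_private for b in biomes)
    if n_private_total > len(pool.names):
        raise ValueError("more private alleles requested than pool size")
    order = list(rng.permutation(len(pool.names)))
    alleles = [pool.names[i] for i in order]
    private_of: dict[str, set[str]] = {}
    cursor = 0
    for b in biomes:
        private_of[b.name] = set(alleles[cursor : cursor + b.n_private])
        cursor += b.n_private
    common = alleles[cursor:]
    if len(biomes) > 1 and not common:
        raise ValueError("no common alleles left; reduce private counts")
    top_common = set(common[:n_top_common])

    genotypes: dict[str, set[str]] = {}
    biome_of: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    inds_of_biome: dict[str, list[str]] = {}
    codes = _unique_codes([b.name for b in biomes])
    for b in biomes:
        avail = common + sorted(private_of[b.name])
        weights = rng.gamma(0.5, size=len(avail))
        for i, a in enumerate(avail):
            if a in top_common:
                weights[i] *= 10.0
        weights /= weights.sum()
        code = codes[b.name]
        lat_min, lat_max, lon_min, lon_max = b.bbox
        inds = []
        for i in range(b.n_individuals):
            ind = f"{code}{i + 1:02d}"
            k = int(rng.integers(min_alleles, max_alleles + 1))
            k = min(k, len(avail))
            chosen = rng.choice(len(avail), size=k, replace=False, p=weights)
            genotypes[ind] = {avail[j] for j in chosen}
            biome_of[ind] = b.name
            coords[ind] = (
                float(rng.uniform(lat_min, lat_max)),
                float(rng.uniform(lon_min, lon_max)),
            )
            inds.append(ind)
        inds_of_biome[b.name] = inds

    common_set = set(common)

    def _plant(allele: str, biome: str, force: bool = True) -> bool:
        cands = [i for i in inds_of_biome[biome] if allele not in genotypes[i]]
        cands.sort(key=lambda i: len(genotypes[i]))
        for ind in cands:
            if len(genotypes[ind]) < max_alleles:
                genotypes[ind].add(allele)
                return True
        if not force or not cands:
            return False
        # all individuals full: swap out a common allele that stays carried
        # in >= 2 biomes without this individual
        ind = cands[0]
        removable = [
            a
            for a in sorted(genotypes[ind])
            if a in common_set
            and len({biome_of[i2] for i2, g in genotypes.items() if a in g and i2 != ind}) >= 2
        ]
        if not removable:
            raise RuntimeError(f"cannot plant {allele} in {biome}")
        genotypes[ind].discard(removable[0])
        genotypes[ind].add(allele)
        return True

    # guarantee every private allele is carried in its biome
    for b in biomes:
        for a in sorted(private_of[b.name]):
            if not any(a in genotypes[i] for i in inds_of_biome[b.name]):
                _plant(a, b.name)
    # guarantee every *carried* common allele occurs in >= 2 biomes (so it
    # never masquerades as private); uncarried alleles simply stay absent
    if len(biomes) > 1:
        for a in common:
            present = {biome_of[i] for i, g in genotypes.items() if a in g}
            if len(present) != 1:
                continue
            need = [b.name for b in biomes if b.name not in present]
            rng.shuffle(need)
            planted = any(_plant(a, target, force=False) for target in need)
            if not planted:
                # capacity exhausted: withdraw the allele instead, provided
                # its carriers keep the minimum allele count
                carriers = [i for i, g in genotypes.items() if a in g]
                if all(len(genotypes[i]) > min_alleles for i in carriers):
                    for i in carriers:
                        genotypes[i].discard(a)
                else:
                    _plant(a, need[0])  # forced, may swap another allele out

    return TruthGenotypes(genotypes, biome_of, coords, private_of)


# ---------------------------------------------------------------------------
# reads


def make_mid_table(
    individuals: list[str], mid_length: int = 10, seed: int = 20150
) -> dict[tuple[str, int], tuple[str, str]]:
    """Deterministic 10-base MID barcodes: a unique (forward, reverse) pair
    per (individual, replicate), pairwise Hamming distance >= 3 among MIDs."""
    rng = np.random.default_rng(seed)
    need = 2 * len(individuals)
    n_side = int(np.ceil(np.sqrt(need))) + 1
    mids: list[str] = []
    while len(mids) < 2 * n_side:
        cand = "".join(BASES[i] for i in rng.integers(4, size=mid_length))
        if any(c * 3 in cand for c in BASES):
            continue
        if all(sum(a != b for a, b in zip(cand, m)) >= 3 for m in mids):
            mids.append(cand)
    fwd, rev = mids[:n_side], mids[n_side : 2 * n_side]
    combos = list(itertools.product(fwd, rev))
    table: dict[tuple[str, int], tuple[str, str]] = {}
    for i, ind in enumerate(individuals):
        table[(ind, 1)] = combos[2 * i]
        table[(ind, 2)] = combos[2 * i + 1]
    return table


@dataclass
class ReadSimConfig:
    substitution_rate: float = 2e-3  # per base, whole read
    homopolymer_indel_rate: float = 5e-4  # per run base, insert only
    chimera_rate: float = 0.03  # per read
    coverage: tuple[int, int, str] = (110, 5344, "uniform")  # per amplicon
    low_quality_read_fraction: float = 0.02
    revcomp_fraction: float = 0.5
    amplification_weights: dict[str, float] | None = None  # allele -> weight
    mid_length: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (
            self.substitution_rate,
            self.homopolymer_indel_rate,
            self.chimera_rate,
            self.low_quality_read_fraction,
            self.revcomp_fraction,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.coverage[0] < 1 or self.coverage[1] < self.coverage[0]:
            raise ValueError("coverage bounds invalid")


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs with length >= 2."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_homopolymer_indels(
    insert: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate == 0.0:
        return insert, 0
    events = 0
    out = insert
    # iterate runs right-to-left so earlier coordinates stay valid
    for start, length in reversed(_homopolymer_runs(insert)):
        if rng.random() < min(0.5, rate * length):
            events += 1
            if rng.random() < 0.5:
                out = out[:start] + insert[start] + out[start:]
            else:
                out = out[:start] + out[start + 1 :]
    return out, events


def _apply_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode(), len(hits)


def _frameshifting(insert: str, source: str) -> bool:
    """Whether the realized insert carries a frame-breaking indel relative
    to its source template (codon-multiple gaps are tolerated). Uses the
    same gapped-alignment criterion as the QC frame filter."""
    from .qc import frame_filter

    return not frame_filter(insert, reference_length=len(source), reference=source)


def simulate_amplicon_reads(
    truth: TruthGenotypes,
    pool: AllelePool,
    cfg: ReadSimConfig,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, dict[tuple[str, int], tuple[str, str]]]:
    """Simulate two replicate amplicons per individual.

    Returns (reads, truth_table, mid_table): ``reads`` is a list of
    (read_id, sequence, phred33-quality string); the truth table records for
    every read its individual, replicate, source allele(s), error counts,
    chimera status and whether it carries a frame-shifting error.
    """
    rng = np.random.default_rng(cfg.seed)
    individuals = sorted(truth.genotypes)
    mid_table = make_mid_table(individuals, cfg.mid_length)
    cov_min, cov_max, law = cfg.coverage
    if law != "uniform":
        raise ValueError(f"unsupported coverage law {law!r}")

    reads: list[tuple[str, str, str]] = []
    rows: list[dict] = []
    counter = 0
    for ind in individuals:
        alleles = sorted(truth.genotypes[ind])
        w = np.array(
            [
                (cfg.amplification_weights or {}).get(a, 1.0)
                for a in alleles
            ],
            dtype=float,
        )
        w /= w.sum()
        for rep in (1, 2):
            mid_f, mid_r = mid_table[(ind, rep)]
            prefix = FWD_ADAPTOR + KEY + mid_f + _FWD_PRIMER_EMIT
            suffix = revcomp(REV_PRIMER) + revcomp(mid_r) + revcomp(KEY) + revcomp(REV_ADAPTOR)
            n_reads = int(rng.integers(cov_min, cov_max + 1))
            for _ in range(n_reads):
                counter += 1
                rid = f"r{counter:07d}"
                is_chimera = False
                p1 = p2 = ""
                bp = -1
                if len(alleles) >= 2 and rng.random() < cfg.chimera_rate:
                    is_chimera = True
                    i1, i2 = rng.choice(len(alleles), size=2, replace=False)
                    p1, p2 = alleles[int(i1)], alleles[int(i2)]
                    s1, s2 = pool.seq_of[p1], pool.seq_of[p2]
                    bp = int(rng.integers(1, min(len(s1), len(s2))))
                    insert = s1[:bp] + s2[bp:]
                    source = insert
                    allele = ""
                else:
                    allele = alleles[int(rng.choice(len(alleles), p=w))]
                    insert = pool.seq_of[allele]
                    source = insert
                insert, n_indels = _apply_homopolymer_indels(
                    insert, cfg.homopolymer_indel_rate, rng
                )
                frameshift = _frameshifting(insert, source) if n_indels else False
                seq = prefix + insert + suffix
                seq, n_subs = _apply_substitutions(seq, cfg.substitution_rate, rng)
                low_q = rng.random() < cfg.low_quality_read_fraction
                mu, sd = (12, 6) if low_q else (33, 4)
                quals = np.clip(rng.normal(mu, sd, size=len(seq)), 2, 40)
                qual_str = (quals.astype(np.uint8) + 33).tobytes().decode("ascii")
                if rng.random() < cfg.revcomp_fraction:
                    seq = revcomp(seq)
                    qual_str = qual_str[::-1]
                reads.append((rid, seq, qual_str))
                rows.append(
                    {
                        "read_id": rid,
                        "individual": ind,
                        "replicate": rep,
                        "allele": allele,
                        "is_chimera": is_chimera,
                        "parent1": p1,
                        "parent2": p2,
                        "breakpoint": bp,
                        "n_substitutions": n_subs,
                        "n_indels": n_indels,
                        "frameshift": frameshift,
                        "low_quality": low_q,
                    }
                )
    return reads, pd.DataFrame(rows), mid_table


# ---------------------------------------------------------------------------
# microsatellites


def simulate_microsatellites(
    truth: TruthGenotypes,
    n_loci: int = 8,
    allele_range: tuple[int, int] = (4, 12),
    fst_like_divergence: float = 0.1,
    missing_rate: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Diploid genotypes at ``n_loci`` microsatellite loci with
    Balding–Nichols-style between-biome frequency divergence.

    Returns a DataFrame indexed by individual with columns
    ``L<k>_1 / L<k>_2`` holding integer repeat alleles (NaN = missing).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 <= fst_like_divergence < 1.0:
        raise ValueError("fst_like_divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    individuals = sorted(truth.genotypes)
    biomes = sorted(set(truth.biome_of.values()))
    data: dict[str, list] = {}
    for k in range(n_loci):
        n_alleles = int(rng.integers(allele_range[0], allele_range[1] + 1))
        allele_sizes = 150 + 2 * np.arange(n_alleles)
        p_global = rng.dirichlet(np.ones(n_alleles))
        p_biome = {}
        for b in biomes:
            if fst_like_divergence == 0.0:
                p_biome[b] = p_global
            else:
                f = fst_like_divergence
                p_biome[b] = rng.dirichlet(p_global * (1.0 - f) / f)
        col1, col2 = [], []
        for ind in individuals:
            p = p_biome[truth.biome_of[ind]]
            a1, a2 = rng.choice(allele_sizes, size=2, p=p)
            if rng.random() < missing_rate:
                col1.append(np.nan)
                col2.append(np.nan)
            else:
                col1.append(int(a1))
                col2.append(int(a2))
        data[f"L{k + 1}_1"] = col1
        data[f"L{k + 1}_2"] = col2
    return pd.DataFrame(data, index=individuals)
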