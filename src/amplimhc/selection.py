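"""Molecular-evolution statistics on a validated MHC allele set.

Implements the classical immunogenetics toolkit for a codon alignment of
DRB exon-2 alleles: Nei–Gojobori (1986) synonymous / nonsynonymous
substitution counting with Jukes–Cantor multiple-hit correction and a
codon-bootstrap Z-test for positive selection, Kimura two-parameter and
Poisson-corrected distances, site-class tallies (invariable / singleton /
parsimony-informative) and nucleotide diversity, all computable over the
full fragment, over the antigen-binding-site (ABS) codons only, or over the
non-ABS remainder.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

from .codons import (
    BASES,
    CODON_TO_AA,
    DEFAULT_ABS_MASK,
    STOP_CODONS,
    codons_of,
    translate,
)

__all__ = [
    "CodonAlignment",
    "NeiGojoboriCounts",
    "SelectionTest",
    "translate_and_collapse",
    "count_site_classes",
    "nei_gojobori_pair",
    "mean_dn_ds",
    "k2p_distance",
    "poisson_aa_distance",
    "nucleotide_diversity",
    "group_divergence_table",
    "codon_align",
    "lift_mask",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CodonAlignment:
    """A frame-1 codon alignment with an antigen-binding-site mask.

    ``abs_mask`` holds 1-based codon indices; gaps, if any, must occupy whole
    codons ('---').
    """

    names: list[str]
    seqs: list[str]
    abs_mask: frozenset[int] = field(default_factory=lambda: DEFAULT_ABS_MASK)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise ValueError("names and seqs differ in length")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("alignment is ragged")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length is not a multiple of 3")
        self.seqs = [s.upper() for s in self.seqs]
        n = self.n_codons
        if any(i < 1 or i > n for i in self.abs_mask):
            raise ValueError("abs_mask index outside the alignment")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    @property
    def non_abs(self) -> frozenset[int]:
        return frozenset(range(1, self.n_codons + 1)) - self.abs_mask

    def codon_columns(self, mask: frozenset[int] | None = None) -> list[int]:
        """Sorted 1-based codon indices selected by ``mask`` (None = all)."""
        idx = mask if mask is not None else frozenset(range(1, self.n_codons + 1))
        return sorted(idx)

    def site_indices(self, mask: frozenset[int] | None = None) -> list[int]:
        """0-based nucleotide positions covered by the codon ``mask``."""
        out: list[int] = []
        for c in self.codon_columns(mask):
            out.extend(range(3 * (c - 1), 3 * c))
        return out


@dataclass
class NeiGojoboriCounts:
    S: float  # potential synonymous sites
    N: float  # potential nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else np.nan

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else np.nan

    @staticmethod
    def _jc(p: float) -> float:
        if np.isnan(p) or p >= 0.75:
            return np.nan
        return -0.75 * np.log1p(-(4.0 / 3.0) * p)

    @property
    def dS(self) -> float:
        return self._jc(self.pS)

    @property
    def dN(self) -> float:
        return self._jc(self.pN)


@dataclass
class SelectionTest:
    dN: float
    dS: float
    se_dN: float
    se_dS: float
    z: float
    p_value: float
    n_boot: int
    mask: tuple[int, ...]

    @property
    def ratio(self) -> float:
        return self.dN / self.dS if self.dS > 0 else np.inf


# ---------------------------------------------------------------------------
# translation / collapsing


def translate_and_collapse(alleles: dict[str, str]) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Collapse nucleotide alleles to distinct amino-acid alleles.

    Returns ``(translation_of, members)`` where ``translation_of`` maps each
    usable nucleotide allele name to its amino-acid sequence and ``members``
    maps each distinct amino-acid sequence to the nucleotide allele names
    that encode it. Sequences with an internal stop codon are excluded with
    a warning.
    """
    translation_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for name, seq in alleles.items():
        aa = translate(seq)
        if "*" in aa:
            warnings.warn(f"allele {name} contains a stop codon; excluded from amino-acid set")
            continue
        translation_of[name] = aa
        members.setdefault(aa, []).append(name)
    return translation_of, members


# ---------------------------------------------------------------------------
# site classes


def count_site_classes(aln: CodonAlignment | list[str]) -> dict[str, int]:
    """Tally invariable, singleton and parsimony-informative sites.

    Columns containing a gap or ambiguity in any sequence are excluded from
    the compared sites. A variable column is parsimony-informative when at
    least two states each occur in at least two sequences; otherwise it is a
    singleton site.
    """
    seqs = aln.seqs if isinstance(aln, CodonAlignment) else [s.upper() for s in aln]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    counts = {"compared": 0, "invariable": 0, "variable": 0, "singleton": 0, "parsimony_informative": 0}
    for j in range(length):
        col = [s[j] for s in seqs]
        if any(b not in BASES for b in col):
            continue
        counts["compared"] += 1
        tally = {b: col.count(b) for b in set(col)}
        if len(tally) == 1:
            counts["invariable"] += 1
            continue
        counts["variable"] += 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            counts["parsimony_informative"] += 1
        else:
            counts["singleton"] += 1
    return counts


# ---------------------------------------------------------------------------
# Nei–Gojobori


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Potential synonymous sites in a sense codon (0..3): each position
    contributes the fraction of its three possible changes that are
    synonymous. Changes to stop codons count as nonsynonymous so that
    (syn sites) + (nonsyn sites) = 3 exactly.
    """
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                syn += 1.0
    return syn / 3.0


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two sense codons,
    averaged over all minimal mutational pathways that avoid stop codons.

    If every pathway passes through a stop codon, all pathways are used
    (standard fallback).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                # classify against translation where defined; stop steps are
                # nonsynonymous by convention
                nd += 1
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return sd_mean, nd_mean


def _usable(codon: str) -> bool:
    return all(b in BASES for b in codon) and codon not in STOP_CODONS


def nei_gojobori_pair(
    seq1: str, seq2: str, mask: frozenset[int] | None = None
) -> NeiGojoboriCounts:
    """Nei–Gojobori (1986) counts for one pair of frame-1 codon sequences.

    ``mask`` restricts the computation to the given 1-based codon indices.
    Codons containing gaps, ambiguity codes or stops in either sequence are
    skipped pairwise.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    cods1, cods2 = codons_of(seq1.upper()), codons_of(seq2.upper())
    S = N = Sd = Nd = 0.0
    for idx, (a, b) in enumerate(zip(cods1, cods2), start=1):
        if mask is not None and idx not in mask:
            continue
        if not (_usable(a) and _usable(b)):
            continue
        fa, fb = _syn_sites(a), _syn_sites(b)
        S += (fa + fb) / 2.0
        N += 3.0 - (fa + fb) / 2.0
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    return NeiGojoboriCounts(S=S, N=N, Sd=Sd, Nd=Nd)


def _pair_codon_arrays(
    aln: CodonAlignment, mask: frozenset[int] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-(pair, codon-column) Sd, Nd, S, N arrays for bootstrap resampling."""
    cols = aln.codon_columns(mask)
    codon_rows = [codons_of(s) for s in aln.seqs]
    n = len(aln.seqs)
    pairs = list(itertools.combinations(range(n), 2))
    shape = (len(pairs), len(cols))
    sd = np.zeros(shape)
    nd = np.zeros(shape)
    ss = np.zeros(shape)
    nn = np.zeros(shape)
    for pi, (i, j) in enumerate(pairs):
        for cj, col in enumerate(cols):
            a, b = codon_rows[i][col - 1], codon_rows[j][col - 1]
            if not (_usable(a) and _usable(b)):
                continue
            f = (_syn_sites(a) + _syn_sites(b)) / 2.0
            ss[pi, cj] = f
            nn[pi, cj] = 3.0 - f
            d = _pathway_counts(a, b)
            sd[pi, cj], nd[pi, cj] = d
    return sd, nd, ss, nn


def _mean_rates(sd, nd, ss, nn) -> tuple[float, float]:
    """Mean pairwise JC-corrected dN and dS from per-pair column sums."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = sd.sum(axis=1) / ss.sum(axis=1)
        pN = nd.sum(axis=1) / nn.sum(axis=1)
        dS = np.where(pS < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * pS), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * pN), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN resamples
        return float(np.nanmean(dN)), float(np.nanmean(dS))


def mean_dn_ds(
    aln: CodonAlignment,
    mask: frozenset[int] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SelectionTest:
    """Average pairwise dN and dS with a codon-bootstrap Z-test.

    The codon columns inside ``mask`` are resampled with replacement
    ``n_boot`` times; bootstrap standard errors feed the two-tailed Z-test
    of the neutral null dN = dS.
    """
    if len(aln.seqs) < 2:
        raise ValueError("need at least two sequences")
    cols = aln.codon_columns(mask)
    if len(cols) < 2:
        warnings.warn("mask too small for bootstrap variance; p undefined")
    sd, nd, ss, nn = _pair_codon_arrays(aln, mask)
    dN, dS = _mean_rates(sd, nd, ss, nn)
    rng = np.random.default_rng(seed)
    k = sd.shape[1]
    boot_dN = np.empty(n_boot)
    boot_dS = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        boot_dN[b], boot_dS[b] = _mean_rates(sd[:, idx], nd[:, idx], ss[:, idx], nn[:, idx])
    se_dN = float(np.nanstd(boot_dN, ddof=1))
    se_dS = float(np.nanstd(boot_dS, ddof=1))
    var = se_dN**2 + se_dS**2
    if var > 0 and np.isfinite(dN) and np.isfinite(dS):
        z = (dN - dS) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = np.nan, np.nan
    return SelectionTest(
        dN=dN, dS=dS, se_dN=se_dN, se_dS=se_dS, z=float(z), p_value=p,
        n_boot=n_boot, mask=tuple(cols),
    )


# ---------------------------------------------------------------------------
# distances


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def k2p_distance(s1: str, s2: str, sites: list[int] | None = None) -> float:
    """Kimura two-parameter distance; gap/ambiguous positions pairwise-deleted.

    Returns NaN when the logarithms are undefined (saturation).
    """
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    s1, s2 = s1.upper(), s2.upper()
    idx = sites if sites is not None else range(len(s1))
    n = ts = tv = 0
    for j in idx:
        a, b = s1[j], s2[j]
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a != b:
            if frozenset((a, b)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        return np.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return np.nan
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def poisson_aa_distance(a1: str, a2: str, sites: list[int] | None = None) -> float:
    """Poisson-corrected amino-acid distance, d = -ln(1 - p)."""
    if len(a1) != len(a2):
        raise ValueError("sequences differ in length")
    idx = sites if sites is not None else range(len(a1))
    n = diff = 0
    for j in idx:
        x, y = a1[j], a2[j]
        if x in "-X*" or y in "-X*":
            continue
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        return np.nan
    p = diff / n
    if p >= 1.0:
        return np.nan
    return float(-np.log1p(-p))


# ---------------------------------------------------------------------------
# diversity


def nucleotide_diversity(
    seqs: list[str], sites: list[int] | None = None
) -> tuple[float, float]:
    """Nucleotide diversity over unique alleles (unweighted by carriers).

    Returns (pi, sd): pi is the mean pairwise proportion of differing sites
    (pairwise deletion of gaps/ambiguities, restricted to ``sites`` when
    given); sd is from Nei's (1987) variance estimator for mean pairwise
    diversity.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    seqs = [s.upper() for s in seqs]
    idx = list(sites) if sites is not None else list(range(len(seqs[0])))
    props = []
    for s1, s2 in itertools.combinations(seqs, 2):
        n = diff = 0
        for j in idx:
            a, b = s1[j], s2[j]
            if a not in BASES or b not in BASES:
                continue
            n += 1
            if a != b:
                diff += 1
        if n:
            props.append(diff / n)
    pi = float(np.mean(props))
    n_seq = len(seqs)
    L = len(idx)
    var = ((n_seq + 1.0) / (3.0 * (n_seq - 1.0) * L)) * pi + (
        2.0 * (n_seq**2 + n_seq + 3.0) / (9.0 * n_seq * (n_seq - 1.0))
    ) * pi**2
    return pi, float(np.sqrt(var))


def group_divergence_table(
    aln: CodonAlignment, groups: dict[str, list[str]]
) -> "pd.DataFrame":
    """Mean pairwise K2P (nucleotide) and Poisson (amino acid) divergence per
    group, partitioned into all / ABS / non-ABS sites.

    ``groups`` maps a group label to allele names present in the alignment.
    Singleton groups are reported as NaN.
    """
    import pandas as pd

    by_name = dict(zip(aln.names, aln.seqs))
    partitions = {"all": None, "abs": aln.abs_mask, "non_abs": aln.non_abs}
    rows = []
    for label, members in groups.items():
        seqs = [by_name[m] for m in members if m in by_name]
        row: dict[str, float | str | int] = {"group": label, "n_alleles": len(seqs)}
        for part, mask in partitions.items():
            nt_sites = aln.site_indices(mask) if mask is not None else None
            aa_sites = [c - 1 for c in aln.codon_columns(mask)] if mask is not None else None
            if len(seqs) < 2:
                row[f"k2p_{part}"] = row[f"k2p_{part}_se"] = np.nan
                row[f"poisson_{part}"] = row[f"poisson_{part}_se"] = np.nan
                continue
            k2p = [
                k2p_distance(a, b, nt_sites)
                for a, b in itertools.combinations(seqs, 2)
            ]
            aas = [translate(s) for s in seqs]
            poi = [
                poisson_aa_distance(a, b, aa_sites)
                for a, b in itertools.combinations(aas, 2)
            ]
            for key, vals in (("k2p", k2p), ("poisson", poi)):
                arr = np.asarray(vals, dtype=float)
                row[f"{key}_{part}"] = float(np.nanmean(arr))
                m = np.isfinite(arr).sum()
                row[f"{key}_{part}_se"] = (
                    float(np.nanstd(arr, ddof=1) / np.sqrt(m)) if m > 1 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon-aware alignment of near-identical fragments


def codon_align(alleles: dict[str, str]) -> dict[str, str]:
    """Align same-fragment alleles that differ by whole-codon indels.

    Each sequence is aligned at the codon level (Needleman–Wunsch over codon
    tokens) against the longest allele, so gaps always occupy whole codons.
    Sequences longer than the chosen reference are not supported; use an
    external aligner for such inputs.
    """
    if not alleles:
        return {}
    ref_name = max(alleles, key=lambda k: len(alleles[k]))
    ref = codons_of(alleles[ref_name].upper())
    out: dict[str, str] = {}
    for name, seq in alleles.items():
        cods = codons_of(seq.upper())
        if len(cods) > len(ref):
            raise ValueError(f"{name} longer than reference {ref_name}; align externally")
        out[name] = "".join(_codon_nw(cods, ref))
    return out


def lift_mask(aligned_seqs: list[str], mask: frozenset[int]) -> frozenset[int]:
    """Map a codon mask defined on the ungapped canonical frame onto
    alignment coordinates.

    Codon columns in which most sequences are gapped are treated as
    insertion columns (absent from the canonical frame); the remaining
    columns, in order, correspond to canonical codons 1, 2, ...
    """
    n_codons = len(aligned_seqs[0]) // 3
    canonical: list[int] = []
    half = len(aligned_seqs) / 2.0
    for c in range(1, n_codons + 1):
        gapped = sum(1 for s in aligned_seqs if s[3 * (c - 1) : 3 * c] == "---")
        if gapped <= half:
            canonical.append(c)
    out = set()
    for i in mask:
        if i <= len(canonical):
            out.add(canonical[i - 1])
    return frozenset(out)


def _codon_nw(query: list[str], ref: list[str]) -> list[str]:
    """Global codon-token alignment of query onto ref; returns query padded
    with '---' to len(ref). Only deletions in the query are allowed."""
    nq, nr = len(query), len(ref)
    gap = -4.0
    score = np.full((nq + 1, nr + 1), -np.inf)
    ptr = np.zeros((nq + 1, nr + 1), dtype=np.int8)  # 1=diag, 2=gap-in-query
    score[0, : nr - nq + 1] = np.arange(nr - nq + 1) * gap
    for i in range(1, nq + 1):
        for j in range(max(1, i), nr - nq + i + 1):
            match = sum(a == b for a, b in zip(query[i - 1], ref[j - 1]))
            diag = score[i - 1, j - 1] + match
            skip = score[i, j - 1] + gap
            if diag >= skip:
                score[i, j], ptr[i, j] = diag, 1
            else:
                score[i, j], ptr[i, j] = skip, 2
    aligned: list[str] = []
    i, j = nq, nr
    while j > 0:
        if i > 0 and ptr[i, j] == 1:
            aligned.append(query[i - 1])
            i -= 1
            j -= 1
        else:
            aligned.append("---")
            j -= 1
    aligned.reverse()
    return aligned
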