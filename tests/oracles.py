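"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive every rule from first principles (exhaustive
enumeration, direct transcription of definitions) and share no code with the
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from amplimhc.codons import CODON_TO_AA


# ---------------------------------------------------------------------------
# Nei–Gojobori pathway enumeration


def brute_force_ng_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by enumerating every minimal
    mutational pathway, skipping pathways through stop codons (falling back
    to all pathways when every one is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt not in CODON_TO_AA:
                stop = True
                nd += 1
            elif cur not in CODON_TO_AA:
                nd += 1
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop else valid).append((sd, nd))
    paths = valid or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def brute_force_syn_sites(codon: str) -> float:
    """Potential synonymous sites of a sense codon; stop targets count as
    nonsynonymous."""
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in CODON_TO_AA and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                syn += 1
    return syn / 3.0


# ---------------------------------------------------------------------------
# Mantel exact permutation


def brute_force_exact_mantel(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(a[iu], b[np.ix_(p, p)][iu])[0, 1]
        total += 1
        hits += abs(r) >= abs(r_obs) - 1e-12
    return float(r_obs), hits / total


# ---------------------------------------------------------------------------
# rarefaction by exhaustive subset enumeration


def brute_force_rarefaction(genotypes: dict[str, set[str]], g: int) -> tuple[float, float]:
    inds = sorted(genotypes)
    vals = [
        len(set().union(*(genotypes[i] for i in sub)))
        for sub in itertools.combinations(inds, g)
    ]
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# the complete variant-classification rules, re-transcribed


def _levenshtein(s1: str, s2: str) -> int:
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, 1):
        cur = [i]
        for j, b in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def brute_force_labels(
    rep1_counts: dict[str, int],
    rep2_counts: dict[str, int],
    seen_elsewhere: set[str],
    ratio: float = 1.0 / 3.0,
) -> dict[str, str]:
    """Replicate-level labels for every sequence, straight from the rules."""

    def within(counts):
        labels = {}
        for seq, c in counts.items():
            if c == 1:
                labels[seq] = "singleton_artifact"
                continue
            parents = [s for s, cc in counts.items() if c <= ratio * cc]
            chim = any(
                seq == pa[:b] + pb[b:] and seq not in (pa, pb)
                for pa, pb in itertools.permutations(parents, 2)
                for b in range(1, len(seq))
            )
            if chim:
                labels[seq] = "chimera"
            elif parents and min(_levenshtein(seq, p) for p in parents) == 1:
                labels[seq] = "one_bp_diff"
            else:
                labels[seq] = "gt_one_bp_diff"
        return labels

    art = frozenset({"singleton_artifact", "chimera", "one_bp_diff"})
    l1, l2 = within(rep1_counts), within(rep2_counts)
    am1 = max((c for s, c in rep1_counts.items() if l1[s] in art), default=0)
    am2 = max((c for s, c in rep2_counts.items() if l2[s] in art), default=0)
    out = {}
    for seq in set(rep1_counts) | set(rep2_counts):
        if (
            seq in rep1_counts
            and seq in rep2_counts
            and rep1_counts[seq] > am1
            and rep2_counts[seq] > am2
        ):
            out[seq] = "putative_allele"
            continue
        labs = {l1.get(seq), l2.get(seq)} - {None}
        if labs <= {"gt_one_bp_diff"} and seq in seen_elsewhere:
            out[seq] = "unclassified"
        else:
            out[seq] = "artifact"
    return out
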