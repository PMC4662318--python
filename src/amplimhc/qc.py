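"""Demultiplexing and read-level quality control for pooled amplicon reads.

Reads are assigned to (individual, replicate) amplicons by exact MID-barcode
match and exact (IUPAC-degeneracy-aware) primer match, then filtered by a
fixed rule order so every rejected read carries exactly one reason:

    length -> MID -> primer -> quality -> frame

The frame filter removes reads whose insert carries a frame-shifting indel
(anything other than whole-codon gaps against the amplicon consensus), the
hallmark artifact of pyrosequencing homopolymer miscalls.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

__all__ = [
    "QualityRead",
    "Amplicon",
    "REJECT_REASONS",
    "demultiplex",
    "quality_filter",
    "frame_filter",
    "run_qc",
]

REJECT_REASONS = ("too_short", "bad_mid", "bad_primer", "low_quality", "frame_violation")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(primer: str) -> str:
    """Regex matching a primer exactly, honoring IUPAC degeneracy codes."""
    parts = []
    for b in primer.upper():
        opts = IUPAC.get(b)
        if opts is None:
            raise ValueError(f"invalid primer base {b!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


@dataclass
class QualityRead:
    """One sequencing read with per-base Phred scores and its QC fate."""

    read_id: str
    sequence: str
    scores: list[int]
    assigned_to: tuple[str, int] | None = None
    reject_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.scores):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class Amplicon:
    """All trimmed inserts assigned to one (individual, replicate) PCR."""

    individual: str
    replicate: int
    inserts: list[str] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2):
            raise ValueError("replicate must be 1 or 2")


def quality_filter(read: QualityRead, q_threshold: int = 20, min_fraction: float = 0.95) -> bool:
    """Pass iff the fraction of bases with Q strictly above ``q_threshold``
    is at least ``min_fraction``."""
    if not read.scores:
        raise ValueError(f"{read.read_id}: empty read")
    good = sum(1 for q in read.scores if q > q_threshold)
    return good / len(read.scores) >= min_fraction


def _frame_aligner() -> Align.PairwiseAligner:
    # substitutions are cheap relative to gaps so that sequence divergence
    # between co-amplified alleles is never explained away with spurious
    # 1-bp indels; real homopolymer indels still must appear as gaps
    # because they change the sequence length locally
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _frame_aligner()


@lru_cache(maxsize=65536)
def _gap_runs_codon_sized(insert: str, reference: str) -> bool:
    """True iff every indel run in the optimal gapped alignment of insert
    against reference has a length that is a multiple of 3."""
    aln = _ALIGNER.align(insert, reference)[0]
    q_blocks, t_blocks = aln.aligned
    if len(q_blocks) == 0:
        return False
    # leading/trailing gaps
    lead = max(q_blocks[0][0], t_blocks[0][0])
    trail = max(len(insert) - q_blocks[-1][1], len(reference) - t_blocks[-1][1])
    if lead % 3 or trail % 3:
        return False
    for k in range(len(q_blocks) - 1):
        q_gap = q_blocks[k + 1][0] - q_blocks[k][1]
        t_gap = t_blocks[k + 1][0] - t_blocks[k][1]
        if q_gap % 3 or t_gap % 3:
            return False
    return True


def frame_filter(
    insert: str, reference_length: int = 195, reference: str | None = None
) -> bool:
    """Pass iff the insert is compatible with an intact reading frame.

    The length difference from ``reference_length`` must be a multiple of 3
    and, when a ``reference`` (amplicon consensus) is supplied, the gapped
    alignment against it must place all indels in runs of whole codons.
    """
    if (len(insert) - reference_length) % 3:
        return False
    if reference is None or insert == reference:
        return True
    if len(insert) == len(reference) and sum(
        a != b for a, b in zip(insert, reference)
    ) <= 2:
        return True  # pure near-identity, no indel possible at this cost
    return _gap_runs_codon_sized(insert, reference)


class _Demuxer:
    """Compiled matching machinery for one MID table + primer pair."""

    def __init__(
        self,
        mid_table: dict[tuple[str, int], tuple[str, str]],
        primers: tuple[str, str],
        key: str = "TCAG",
    ) -> None:
        seen: dict[tuple[str, str], tuple[str, int]] = {}
        for sample, pair in mid_table.items():
            if pair in seen:
                raise ValueError(
                    f"duplicate MID pair {pair} for {sample} and {seen[pair]}"
                )
            seen[pair] = sample
        self.sample_of = seen
        self.key = key.upper()
        fwd_primer, rev_primer = primers
        self.fwd_mids = sorted({p[0] for p in seen})
        self.rev_mids = sorted({p[1] for p in seen})
        self.mid_len = len(self.fwd_mids[0])
        self.fwd_re = re.compile(
            self.key + f"(?P<mid>[ACGT]{{{self.mid_len}}})" + iupac_regex(fwd_primer)
        )
        # reverse structure at the 3' end: rc(primer) + rc(mid) + rc(key)
        self.rev_re = re.compile(
            iupac_regex(revcomp(rev_primer))
            + f"(?P<mid>[ACGT]{{{self.mid_len}}})"
            + revcomp(self.key)
        )
        self.fwd_mid_set = set(self.fwd_mids)
        self.rev_mid_set = set(self.rev_mids)

    def match(self, seq: str) -> tuple[tuple[str, int] | None, str | None, str]:
        """Try both orientations; returns (sample, insert, fail_reason).

        fail_reason distinguishes bad_mid (no known MID pair located) from
        bad_primer (MIDs present but a primer region does not match).
        """
        reason = "bad_mid"
        for oriented in (seq, revcomp(seq)):
            m_f = self.fwd_re.search(oriented)
            m_r = self.rev_re.search(oriented)
            if m_f and m_r and m_r.start() > m_f.end():
                mid_f, mid_r_rc = m_f.group("mid"), m_r.group("mid")
                pair = (mid_f, revcomp(mid_r_rc))
                sample = self.sample_of.get(pair)
                if sample is not None:
                    return sample, oriented[m_f.end() : m_r.start()], ""
                continue  # structure found but unknown combination
            # distinguish: are both MIDs locatable next to the key at all?
            if self._mids_present(oriented):
                reason = "bad_primer"
        return None, None, reason

    def _mids_present(self, seq: str) -> bool:
        k, m = self.key, self.mid_len
        i = seq.find(k)
        fwd_ok = False
        while i != -1:
            if seq[i + len(k) : i + len(k) + m] in self.fwd_mid_set:
                fwd_ok = True
                break
            i = seq.find(k, i + 1)
        if not fwd_ok:
            return False
        rk = revcomp(k)
        j = seq.find(rk)
        while j != -1:
            if revcomp(seq[j - m : j]) in self.rev_mid_set:
                return True
            j = seq.find(rk, j + 1)
        return False


def demultiplex(
    reads: list[QualityRead],
    mid_table: dict[tuple[str, int], tuple[str, str]],
    primers: tuple[str, str],
    length_min: int = 280,
    key: str = "TCAG",
) -> tuple[dict[tuple[str, int], Amplicon], list[tuple[str, str]]]:
    """Assign reads to amplicons by length, MID and primer rules.

    ``mid_table`` maps (individual, replicate) -> (forward MID, reverse MID);
    duplicate MID pairs fail before any read is processed. Returns the
    amplicon map and a reject log of (read_id, reason).
    """
    demux = _Demuxer(mid_table, primers, key)
    amplicons: dict[tuple[str, int], Amplicon] = {}
    rejects: list[tuple[str, str]] = []
    for read in reads:
        if len(read.sequence) < length_min:
            read.reject_reason = "too_short"
            rejects.append((read.read_id, "too_short"))
            continue
        sample, insert, reason = demux.match(read.sequence.upper())
        if sample is None:
            read.reject_reason = reason
            rejects.append((read.read_id, reason))
            continue
        read.assigned_to = sample
        amp = amplicons.setdefault(sample, Amplicon(sample[0], sample[1]))
        amp.inserts.append(insert)
        amp.read_ids.append(read.read_id)
    return amplicons, rejects


def run_qc(
    reads: list[QualityRead],
    mid_table: dict[tuple[str, int], tuple[str, str]],
    primers: tuple[str, str],
    length_min: int = 280,
    q_threshold: int = 20,
    min_fraction: float = 0.95,
    reference_length: int = 195,
    key: str = "TCAG",
) -> tuple[dict[tuple[str, int], Amplicon], list[tuple[str, str]]]:
    """Full read-level QC in fixed rule order: length, MID, primer, quality,
    frame. Returns passing amplicons and the reject log; assigned + rejected
    always partitions the input."""
    quality_ok = []
    rejects: list[tuple[str, str]] = []
    # quality is rule 4, but it is read-intrinsic; apply it after demux so the
    # earlier rules (length/MID/primer) take precedence in the reject reason
    amplicons, demux_rejects = demultiplex(reads, mid_table, primers, length_min, key)
    rejects.extend(demux_rejects)
    scores_of = {r.read_id: r for r in reads}
    filtered: dict[tuple[str, int], Amplicon] = {}
    for sample, amp in amplicons.items():
        kept_pairs = []
        for rid, ins in zip(amp.read_ids, amp.inserts):
            read = scores_of[rid]
            if not quality_filter(read, q_threshold, min_fraction):
                read.reject_reason = "low_quality"
                read.assigned_to = None
                rejects.append((rid, "low_quality"))
            else:
                kept_pairs.append((rid, ins))
        if not kept_pairs:
            continue
        # consensus for the frame check: the most common insert (modal exact
        # sequence) in this amplicon
        counts = Counter(ins for _, ins in kept_pairs)
        consensus = max(counts, key=lambda s: (counts[s], s))
        out = Amplicon(sample[0], sample[1])
        for rid, ins in kept_pairs:
            if frame_filter(ins, reference_length, consensus):
                out.inserts.append(ins)
                out.read_ids.append(rid)
            else:
                read = scores_of[rid]
                read.reject_reason = "frame_violation"
                read.assigned_to = None
                rejects.append((rid, "frame_violation"))
        if out.inserts:
            filtered[sample] = out
    return filtered, rejects
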