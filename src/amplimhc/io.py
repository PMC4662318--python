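"""File formats and run configuration.

FASTA/FASTQ (Sanger Phred+33) round-tripping is delegated to Biopython;
tabular artifacts are plain TSV whose first line is a comment naming the
producing stage, the config hash and the seed, so every output is traceable
to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import DEFAULT_ABS_MASK
from .qc import QualityRead
from .simulate import DEFAULT_BIOMES

__all__ = [
    "RunConfig",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]


def read_fastq(path: str | Path) -> list[QualityRead]:
    """Read a Phred+33 FASTQ into QualityRead objects (uppercased, logged)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            QualityRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                scores=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]]) -> Path:
    """Write (id, sequence, quality-string) triples as Phred+33 FASTQ."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def write_table(
    path: str | Path, df: pd.DataFrame, stage: str, config_hash: str = "-", seed: int | str = "-"
) -> Path:
    """TSV with a provenance comment header (stage, config hash, seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage}\tconfig={config_hash}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default, in one place.

    Round-trips losslessly through YAML via :meth:`to_yaml`/:meth:`from_yaml`.
    """

    seed: int = 1
    # allele pool
    n_loci: int = 7
    alleles_per_locus: int = 10
    abs_mask: list[int] = field(default_factory=lambda: sorted(DEFAULT_ABS_MASK))
    n_synonymous: int = 10
    n_insertion_alleles: int = 1
    n_deletion_alleles: int = 13
    abs_nonsyn_enrichment: float = 5.0
    nonabs_omega: float = 0.5
    locus_mutations: int = 15
    allele_mutations: int = 6
    # genotypes / biomes
    biomes: list[dict] = field(
        default_factory=lambda: [asdict(b) for b in DEFAULT_BIOMES]
    )
    min_alleles: int = 2
    max_alleles: int = 13
    # read simulation
    substitution_rate: float = 2e-3
    homopolymer_indel_rate: float = 5e-4
    chimera_rate: float = 0.03
    coverage_min: int = 110
    coverage_max: int = 5344
    low_quality_read_fraction: float = 0.02
    revcomp_fraction: float = 0.5
    # microsatellites
    microsat_loci: int = 8
    microsat_divergence: float = 0.1
    microsat_missing_rate: float = 0.02
    # read QC
    length_min: int = 280
    q_threshold: int = 20
    min_quality_fraction: float = 0.95
    reference_length: int = 195
    # allele calling
    min_coverage: int = 110
    allele_prefix: str = "TateDRB*"
    # selection statistics
    n_bootstrap: int = 1000
    # spatial statistics
    n_permutations: int = 1000
    rarefaction_reps: int = 10000

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for b in data.get("biomes", []):
            b["bbox"] = tuple(b["bbox"])
        return cls(**data)
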