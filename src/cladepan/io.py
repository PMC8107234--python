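"""On-disk artifacts: FASTA, Newick files, Rtab-style matrices, quality tables.

All tabular outputs are plain TSV; matrices follow the Rtab convention of
pangenome tools (one row per gene family, one column per genome). Sequence
parsing goes through Biopython with a thin layer that enforces the
package's normalisation rules (uppercase, IUPAC ambiguity codes collapsed
to N for nucleotides, duplicate-ID detection).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .tree import PhyloTree

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN")


@dataclass
class Quality:
    completeness: float
    contamination: float
    heterogeneity: float


@dataclass
class GenomeRecord:
    """One assembly: contigs plus (optionally) proteome, 16S genes, quality."""

    genome_id: str
    label: str = ""
    contigs: list[tuple[str, str]] = field(default_factory=list)
    proteins: list[tuple[str, str]] = field(default_factory=list)
    rrna_16s: list[tuple[str, str]] = field(default_factory=list)
    quality: Optional[Quality] = None

    @property
    def genome_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class ManifestEntry:
    genome_id: str
    label: str = ""
    genome_path: Optional[str] = None
    proteome_path: Optional[str] = None
    rrna_path: Optional[str] = None


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    outgroup_id: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [e.genome_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in manifest")
        if self.outgroup_id is not None and self.outgroup_id not in ids:
            raise ValueError(f"outgroup {self.outgroup_id!r} not in manifest")

    @property
    def genome_ids(self) -> list[str]:
        return [e.genome_id for e in self.entries]


# ------------------------------------------------------------------- FASTA
def read_genome_fasta(path: str | Path, kind: str = "nucleotide") -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs in file order.

    Sequences are uppercased; for ``kind="nucleotide"`` any character
    outside {A,C,G,T,N} (ambiguity codes, gaps) is mapped to N.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if kind == "nucleotide":
            seq = "".join(c if c in NUCLEOTIDE_ALPHABET else "N" for c in seq)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------- matrices
def write_matrix_table(frame: pd.DataFrame, path: str | Path, index_name: str = "family") -> None:
    """Write a families × genomes count matrix as an Rtab-style TSV."""
    if frame.shape[0] == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return frame


# ------------------------------------------------------------------- newick
def read_newick(path: str | Path) -> PhyloTree:
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(tree.to_newick() + "\n")


# ------------------------------------------------------------ quality table
def read_quality_table(path: str | Path) -> dict[str, Quality]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"genome_id", "completeness", "contamination", "heterogeneity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"quality table missing columns: {sorted(missing)}")
    return {
        row.genome_id: Quality(row.completeness, row.contamination, row.heterogeneity)
        for row in frame.itertuples()
    }


def filter_quality(
    genomes: list[GenomeRecord],
    min_completeness: float = 95.0,
    max_contamination: float = 5.0,
    max_heterogeneity: float = 5.0,
) -> tuple[list[GenomeRecord], list[tuple[GenomeRecord, str]]]:
    """Partition genomes into high-quality drafts and rejects.

    A genome is retained iff completeness ≥ ``min_completeness`` AND
    contamination < ``max_contamination`` AND heterogeneity <
    ``max_heterogeneity`` (inclusive lower bound, strict upper bounds).
    Genomes without quality metrics are retained with a warning — closed
    genomes typically skip draft QC.
    """
    retained: list[GenomeRecord] = []
    rejected: list[tuple[GenomeRecord, str]] = []
    for g in genomes:
        q = g.quality
        if q is None:
            warnings.warn(f"genome {g.genome_id} has no quality metrics; retained")
            retained.append(g)
            continue
        if q.completeness < min_completeness:
            rejected.append((g, "completeness"))
        elif q.contamination >= max_contamination:
            rejected.append((g, "contamination"))
        elif q.heterogeneity >= max_heterogeneity:
            rejected.append((g, "heterogeneity"))
        else:
            retained.append(g)
    return retained, rejected


# ------------------------------------------------------------- manifest IO
def load_genomes(manifest: DatasetManifest, quality: Optional[dict[str, Quality]] = None) -> list[GenomeRecord]:
    """Materialise GenomeRecords from the files a manifest points to."""
    records = []
    for entry in manifest.entries:
        rec = GenomeRecord(genome_id=entry.genome_id, label=entry.label)
        if entry.genome_path:
            rec.contigs = read_genome_fasta(entry.genome_path, "nucleotide")
        if entry.proteome_path:
            rec.proteins = read_genome_fasta(entry.proteome_path, "protein")
        if entry.rrna_path:
            rec.rrna_16s = read_genome_fasta(entry.rrna_path, "nucleotide")
        if quality and entry.genome_id in quality:
            rec.quality = quality[entry.genome_id]
        records.append(rec)
    return records
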