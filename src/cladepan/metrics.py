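"""Pairwise genome metrics: ANI, TETRA, AAI and 16S identity.

The species criterion thresholds three whole-genome signals at once:

* **ANI** — fragment-based average nucleotide identity in the Goris
  tradition: the query genome is cut into consecutive 1020-nt fragments,
  each fragment is located in the subject by shared 16-mers and aligned;
  fragments aligning at ≥30% identity over ≥70% of their length are kept
  and their mean identity is the directional ANI; the reported value
  averages both directions.
* **TETRA** — Pearson correlation of tetranucleotide z-score signatures,
  with the expected count of each 4-mer given by the maximal-order Markov
  model over its 3-mer/2-mer constituents (both strands counted).
* **AAI** — mean identity over reciprocal-best-hit protein pairs, hits
  requiring ≥30% identity and ≥70% coverage of the shorter protein.

Undefined values (no alignable fragments, no RBH pairs) are recorded as
missing and always fail threshold tests downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .alignment import global_identity, infix_identity
from .io import GenomeRecord

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

ANI_FRAGMENT = 1020
ANI_SEED_K = 16
ANI_BAND = 64
ANI_MIN_IDENTITY = 0.30
ANI_MIN_COVERAGE = 0.70
AAI_SEED_K = 5
AAI_MIN_IDENTITY = 0.30
AAI_MIN_COVERAGE = 0.70


# =====================================================================
# TETRA
# =====================================================================
@dataclass
class TetraProfile:
    """256 tetranucleotide z-scores in lexicographic (A<C<G<T) order."""

    z: np.ndarray

    def __post_init__(self) -> None:
        assert self.z.shape == (256,)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def _count_kmers(codes: np.ndarray, k: int, out: np.ndarray) -> None:
    n = len(codes) - k + 1
    if n <= 0:
        return
    word = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        word = word * 4 + codes[i : i + n]
        ok &= codes[i : i + n] < 4
    word[~ok] = 0
    counts = np.bincount(word[ok], minlength=4**k)
    out += counts


def kmer_counts(contigs: Iterable[str], k: int) -> np.ndarray:
    """Counts of all k-mers over every contig and its reverse complement,
    windows not crossing contig ends, windows containing N skipped."""
    out = np.zeros(4**k, dtype=np.int64)
    for seq in contigs:
        codes = _encode(seq)
        _count_kmers(codes, k, out)
        _count_kmers(_revcomp_codes(codes), k, out)
    return out


def compute_tetra_profile(genome: GenomeRecord) -> TetraProfile:
    """Teeling-style z-scores: observed 4-mer counts against the
    maximal-order Markov expectation from 3-mer and 2-mer counts."""
    if not genome.contigs:
        raise ValueError(f"genome {genome.genome_id} has no contigs")
    if genome.genome_length < 50_000:
        logger.warning(
            "genome %s is %d bp (<50 kb); TETRA signature will be noisy",
            genome.genome_id,
            genome.genome_length,
        )
    seqs = [s for _, s in genome.contigs]
    o4 = kmer_counts(seqs, 4).astype(float)
    o3 = kmer_counts(seqs, 3).astype(float)
    o2 = kmer_counts(seqs, 2).astype(float)

    idx = np.arange(256)
    pref = idx >> 2  # n1n2n3
    suf = idx & 0x3F  # n2n3n4
    mid = (idx >> 2) & 0xF  # n2n3

    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(o2[mid] > 0, o3[pref] * o3[suf] / o2[mid], 0.0)
        v = np.where(
            o2[mid] > 0,
            e * (o2[mid] - o3[pref]) * (o2[mid] - o3[suf]) / o2[mid] ** 2,
            0.0,
        )
        z = np.where(v > 0, (o4 - e) / np.sqrt(v), 0.0)
    return TetraProfile(z)


def tetra_correlation(p1: TetraProfile, p2: TetraProfile) -> float:
    """Pearson correlation of two tetranucleotide signatures."""
    z1, z2 = p1.z, p2.z
    if np.std(z1) == 0 or np.std(z2) == 0:
        raise ValueError("zero-variance tetranucleotide profile")
    return float(np.corrcoef(z1, z2)[0, 1])


# =====================================================================
# ANI
# =====================================================================
class _GenomeIndex:
    """Concatenated contigs plus a 16-mer position index for seeding."""

    def __init__(self, genome: GenomeRecord, k: int = ANI_SEED_K):
        spacer = "N" * (k + 4)
        self.sequence = spacer.join(s for _, s in genome.contigs)
        self.k = k
        index: dict[str, list[int]] = {}
        seq = self.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append(i)
        self.index = index


def _fragments(genome: GenomeRecord, size: int = ANI_FRAGMENT) -> list[str]:
    frags = []
    for _, seq in genome.contigs:
        for i in range(0, len(seq) - size + 1, size):
            frags.append(seq[i : i + size])
    return frags


def _map_fragment(fragment: str, target: _GenomeIndex, band: int = ANI_BAND) -> Optional[float]:
    """Locate a fragment by modal shared-16-mer diagonal, then align
    banded around it; returns the identity fraction or None."""
    k = target.k
    votes: Counter[int] = Counter()
    offsets: dict[int, list[int]] = {}
    for off in range(0, len(fragment) - k + 1, k + 1):
        kmer = fragment[off : off + k]
        positions = target.index.get(kmer)
        if positions:
            for p in positions:
                diag = p - off
                votes[diag] += 1
                offsets.setdefault(diag, []).append(off)
    if not votes:
        return None
    diag = min((d for d, c in votes.items() if c == max(votes.values())))
    # homologous-span check: the modal diagonal must be supported across
    # >=70% of the fragment, the seed-level analogue of the classic
    # local-alignment coverage rule (rejects fragments straddling
    # rearrangement or gene gain/loss breakpoints)
    supp = offsets[diag]
    span = (max(supp) + k - min(supp)) + 2 * band
    if span < len(fragment) * ANI_MIN_COVERAGE:
        return None
    lo = max(diag - band, 0)
    hi = min(diag + len(fragment) + band, len(target.sequence))
    window = target.sequence[lo:hi]
    if len(window) < len(fragment) * ANI_MIN_COVERAGE:
        return None
    max_dist = int(len(fragment) * (1 - ANI_MIN_IDENTITY)) + 2 * band
    hit = infix_identity(fragment, window, max_dist=max_dist)
    if hit is None:
        return None
    identity, columns = hit
    if identity < ANI_MIN_IDENTITY or len(fragment) / columns < ANI_MIN_COVERAGE:
        return None
    return identity


def _directional_ani(query: GenomeRecord, target: _GenomeIndex) -> tuple[Optional[float], int]:
    identities = []
    for frag in _fragments(query):
        ident = _map_fragment(frag, target)
        if ident is not None:
            identities.append(ident)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def compute_ani(
    g1: GenomeRecord, g2: GenomeRecord, _idx1: Optional[_GenomeIndex] = None, _idx2: Optional[_GenomeIndex] = None
) -> tuple[Optional[float], int]:
    """Two-way fragment ANI in percent, plus total retained fragments."""
    for g in (g1, g2):
        if g.genome_length < 10_000:
            raise ValueError(f"genome {g.genome_id} shorter than 10 kb")
    idx1 = _idx1 or _GenomeIndex(g1)
    idx2 = _idx2 or _GenomeIndex(g2)
    a12, n12 = _directional_ani(g1, idx2)
    a21, n21 = _directional_ani(g2, idx1)
    parts = [a for a in (a12, a21) if a is not None]
    if not parts:
        return None, 0
    return 100.0 * float(np.mean(parts)), n12 + n21


# =====================================================================
# AAI
# =====================================================================
class _ProteomeIndex:
    def __init__(self, proteins: list[tuple[str, str]], k: int = AAI_SEED_K):
        self.proteins = proteins
        self.k = k
        index: dict[str, list[int]] = {}
        for pi, (_, seq) in enumerate(proteins):
            for i in range(0, len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append(pi)
        self.index = index


def _best_hit(seq: str, target: _ProteomeIndex, top: int = 5) -> Optional[tuple[int, float]]:
    k = target.k
    votes: Counter[int] = Counter()
    for i in range(0, len(seq) - k + 1, 3):
        for pi in target.index.get(seq[i : i + k], ()):
            votes[pi] += 1
    if not votes:
        return None
    candidates = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    best: Optional[tuple[int, float]] = None
    for pi, _ in candidates:
        tseq = target.proteins[pi][1]
        if min(len(seq), len(tseq)) / max(len(seq), len(tseq)) < AAI_MIN_COVERAGE:
            continue
        identity, _cols = global_identity(seq, tseq)
        if identity < AAI_MIN_IDENTITY:
            continue
        if best is None or identity > best[1]:
            best = (pi, identity)
    return best


def compute_aai(
    g1: GenomeRecord, g2: GenomeRecord, _idx1: Optional[_ProteomeIndex] = None, _idx2: Optional[_ProteomeIndex] = None
) -> tuple[Optional[float], int]:
    """Reciprocal-best-hit AAI in percent, plus the RBH pair count."""
    if not g1.proteins or not g2.proteins:
        raise ValueError("both genomes need proteomes for AAI")
    idx1 = _idx1 or _ProteomeIndex(g1.proteins)
    idx2 = _idx2 or _ProteomeIndex(g2.proteins)
    fwd: dict[int, tuple[int, float]] = {}
    for qi, (_, seq) in enumerate(g1.proteins):
        hit = _best_hit(seq, idx2)
        if hit is not None:
            fwd[qi] = hit
    identities = []
    for qi, (ti, ident) in fwd.items():
        back = _best_hit(g2.proteins[ti][1], idx1)
        if back is not None and back[0] == qi:
            identities.append((ident + back[1]) / 2.0)
    if not identities:
        return None, 0
    return 100.0 * float(np.mean(identities)), len(identities)


# =====================================================================
# 16S marker identity
# =====================================================================
def marker_identity(s1: str, s2: str) -> tuple[float, float, float]:
    """Global alignment with free end gaps.

    Returns (identity %, query coverage %, target coverage %); identity is
    matches over aligned columns excluding terminal overhangs, coverage is
    each sequence's aligned span over its length.
    """
    if not s1 or not s2:
        raise ValueError("empty marker sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    aln = aligner.align(s1, s2)[0]
    qb, tb = aln.aligned  # blocks in s1 and s2 coordinates
    matches = 0
    columns = 0
    for bi, ((q0, q1), (t0, t1)) in enumerate(zip(qb, tb)):
        matches += sum(1 for a, b in zip(s1[q0:q1], s2[t0:t1]) if a == b)
        columns += q1 - q0
        if bi:
            columns += (q0 - qb[bi - 1][1]) + (t0 - tb[bi - 1][1])
    if columns == 0:
        return 0.0, 0.0, 0.0
    cov_q = 100.0 * (qb[-1][1] - qb[0][0]) / len(s1)
    cov_t = 100.0 * (tb[-1][1] - tb[0][0]) / len(s2)
    return 100.0 * matches / columns, cov_q, cov_t


# =====================================================================
# all-pairs driver
# =====================================================================
@dataclass
class PairMetrics:
    ani: Optional[float] = None
    ani_fragments: int = 0
    tetra: Optional[float] = None
    aai: Optional[float] = None
    rbh_pairs: int = 0


class PairwiseMetricTable:
    """Symmetric per-pair store of ANI/TETRA/AAI values."""

    COLUMNS = ["genome_a", "genome_b", "ani", "ani_fragments", "tetra", "aai", "rbh_pairs"]

    def __init__(self, genomes: Optional[list[str]] = None):
        self.genomes: list[str] = list(genomes or [])
        self._data: dict[tuple[str, str], PairMetrics] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, metrics: PairMetrics) -> None:
        self._data[self._key(a, b)] = metrics

    def get(self, a: str, b: str) -> Optional[PairMetrics]:
        if a == b:
            return PairMetrics(ani=100.0, tetra=1.0, aai=100.0)
        return self._data.get(self._key(a, b))

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), m in sorted(self._data.items()):
            rows.append([a, b, m.ani, m.ani_fragments, m.tetra, m.aai, m.rbh_pairs])
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        # %.17g keeps the cache lossless: resuming reproduces exact floats
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairwiseMetricTable":
        frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        table = cls()
        names = set()
        for row in frame.itertuples():
            names.update([row.genome_a, row.genome_b])
            table.set(
                row.genome_a,
                row.genome_b,
                PairMetrics(
                    ani=None if pd.isna(row.ani) else float(row.ani),
                    ani_fragments=int(row.ani_fragments),
                    tetra=None if pd.isna(row.tetra) else float(row.tetra),
                    aai=None if pd.isna(row.aai) else float(row.aai),
                    rbh_pairs=int(row.rbh_pairs),
                ),
            )
        table.genomes = sorted(names)
        return table


def compute_all_pairs(
    records: list[GenomeRecord],
    cache_path: Optional[str | Path] = None,
) -> PairwiseMetricTable:
    """All unordered pairs of ANI, TETRA and AAI; resumable via a TSV cache."""
    if len(records) < 2:
        raise ValueError("need at least two genomes")
    records = sorted(records, key=lambda r: r.genome_id)
    ids = [r.genome_id for r in records]

    table = PairwiseMetricTable(ids)
    cached = 0
    if cache_path is not None and Path(cache_path).exists():
        prior = PairwiseMetricTable.from_tsv(cache_path)
        for a, b in prior.pairs():
            if a in ids and b in ids:
                table.set(a, b, prior.get(a, b))
                cached += 1

    profiles = {r.genome_id: compute_tetra_profile(r) for r in records}
    genome_idx: dict[str, _GenomeIndex] = {}
    prot_idx: dict[str, _ProteomeIndex] = {}

    def gidx(r: GenomeRecord) -> _GenomeIndex:
        if r.genome_id not in genome_idx:
            genome_idx[r.genome_id] = _GenomeIndex(r)
        return genome_idx[r.genome_id]

    def pidx(r: GenomeRecord) -> _ProteomeIndex:
        if r.genome_id not in prot_idx:
            prot_idx[r.genome_id] = _ProteomeIndex(r.proteins)
        return prot_idx[r.genome_id]

    computed = 0
    for i, r1 in enumerate(records):
        for r2 in records[i + 1 :]:
            if table.get(r1.genome_id, r2.genome_id) is not None:
                continue
            ani, nfrag = compute_ani(r1, r2, gidx(r1), gidx(r2))
            tetra = tetra_correlation(profiles[r1.genome_id], profiles[r2.genome_id])
            if r1.proteins and r2.proteins:
                aai, nrbh = compute_aai(r1, r2, pidx(r1), pidx(r2))
            else:
                aai, nrbh = None, 0
            table.set(r1.genome_id, r2.genome_id, PairMetrics(ani, nfrag, tetra, aai, nrbh))
            computed += 1
    logger.info("pairwise metrics: %d cached, %d computed", cached, computed)

    if cache_path is not None and computed:
        table.to_tsv(cache_path)
    return table
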