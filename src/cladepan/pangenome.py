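"""Pangenome construction, partition, rarefaction and openness.

Orthogroups come from a deterministic greedy clustering (CD-HIT style:
proteins sorted by length, each joining the first cluster whose
representative it matches at ≥80% identity over ≥80% of the shorter
sequence). The occurrence matrix is partitioned into core (100% of
genomes), soft-core (≥95%), shell (≥15%) and cloud, and rarefaction
curves over random genome orderings feed a power-law fit of the
new-genes-per-genome curve, Δn(N) = κ·N^−α: α < 1 diagnoses an open
pangenome (the collection keeps yielding new families), α > 1 a closed
one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import global_identity

logger = logging.getLogger(__name__)

IDENTITY_MIN = 0.8
COVERAGE_MIN = 0.8
_SEED_K = 5


@dataclass
class OrthogroupMatrix:
    """Gene families × genomes occurrence counts."""

    counts: pd.DataFrame  # index: family IDs, columns: genome IDs, int counts
    representatives: dict[str, str]  # family ID -> representative gene ID
    members: Optional[dict[str, list[tuple[str, str]]]] = None  # family -> (genome, gene)

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("orthogroup matrix contains an all-zero family row")

    @property
    def n_families(self) -> int:
        return self.counts.shape[0]

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)


@dataclass
class PangenomeSummary:
    core: int
    soft_core: int
    shell: int
    cloud: int
    total: int
    soft_min: float
    shell_min: float

    def as_dict(self) -> dict[str, int]:
        return {
            "core": self.core,
            "soft_core": self.soft_core,
            "shell": self.shell,
            "cloud": self.cloud,
            "total": self.total,
        }


@dataclass
class OpennessFit:
    kappa: float
    alpha: float
    open: bool
    n_permutations: int
    seed: int


@dataclass
class RarefactionCurves:
    """Median and 95% band of pan/core/new-family counts per sample size."""

    n: np.ndarray  # 1..N_max
    pan_median: np.ndarray
    pan_lo: np.ndarray
    pan_hi: np.ndarray
    core_median: np.ndarray
    core_lo: np.ndarray
    core_hi: np.ndarray
    new_median: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.n,
                "pan_median": self.pan_median,
                "pan_lo": self.pan_lo,
                "pan_hi": self.pan_hi,
                "core_median": self.core_median,
                "core_lo": self.core_lo,
                "core_hi": self.core_hi,
                "new_median": self.new_median,
            }
        )


# ---------------------------------------------------------------- clustering
def cluster_orthogroups(
    proteomes: dict[str, list[tuple[str, str]]],
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
) -> OrthogroupMatrix:
    """Greedy length-sorted protein clustering into gene families.

    Deterministic and invariant to input order: proteins are globally
    sorted by length (descending) then genome and gene ID before the
    greedy sweep, and candidate clusters are tried in founding order.
    """
    if not proteomes:
        raise ValueError("no proteomes supplied")
    entries = []
    for genome_id in sorted(proteomes):
        for gene_id, seq in proteomes[genome_id]:
            entries.append((genome_id, gene_id, seq))
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))

    reps: list[str] = []  # representative sequences per cluster
    rep_ids: list[str] = []
    members: list[list[tuple[str, str]]] = []
    index: dict[str, set[int]] = {}

    def _add_to_index(seq: str, ci: int) -> None:
        for i in range(0, len(seq) - _SEED_K + 1, 2):
            index.setdefault(seq[i : i + _SEED_K], set()).add(ci)

    for genome_id, gene_id, seq in entries:
        votes: Counter[int] = Counter()
        for i in range(0, len(seq) - _SEED_K + 1, 3):
            for ci in index.get(seq[i : i + _SEED_K], ()):
                votes[ci] += 1
        placed = False
        for ci in sorted(votes):
            rep = reps[ci]
            shorter = min(len(seq), len(rep))
            if shorter / max(len(seq), len(rep)) < coverage_min:
                continue
            identity, _ = global_identity(seq, rep)
            if identity >= identity_min:
                members[ci].append((genome_id, gene_id))
                placed = True
                break
        if not placed:
            ci = len(reps)
            reps.append(seq)
            rep_ids.append(f"{genome_id}|{gene_id}" if "|" not in gene_id else gene_id)
            members.append([(genome_id, gene_id)])
            _add_to_index(seq, ci)

    genomes = sorted(proteomes)
    fam_ids = [f"OG{i + 1:06d}" for i in range(len(reps))]
    counts = np.zeros((len(reps), len(genomes)), dtype=int)
    col = {g: j for j, g in enumerate(genomes)}
    for ci, mem in enumerate(members):
        for genome_id, _gene in mem:
            counts[ci, col[genome_id]] += 1
    frame = pd.DataFrame(counts, index=fam_ids, columns=genomes)
    member_map = {fid: members[ci] for ci, fid in enumerate(fam_ids)}
    return OrthogroupMatrix(frame, dict(zip(fam_ids, rep_ids)), member_map)


# ------------------------------------------------------------------ partition
def categorize(matrix: OrthogroupMatrix, soft_min: float = 0.95, shell_min: float = 0.15) -> PangenomeSummary:
    """Partition families into core / soft-core / shell / cloud.

    Core is presence in strictly all genomes; soft-core ≥ ``soft_min``,
    shell ≥ ``shell_min``, cloud below that.
    """
    presence = matrix.presence().to_numpy()
    n_genomes = presence.shape[1]
    frac = presence.sum(axis=1) / n_genomes
    core = int((frac == 1.0).sum())
    soft = int(((frac >= soft_min) & (frac < 1.0)).sum())
    shell = int(((frac >= shell_min) & (frac < soft_min)).sum())
    cloud = int((frac < shell_min).sum())
    return PangenomeSummary(core, soft, shell, cloud, matrix.n_families, soft_min, shell_min)


# ----------------------------------------------------------------- rarefaction
def rarefaction(
    matrix: OrthogroupMatrix, n_permutations: int = 1000, seed: int = 0, keep_permutations: bool = False
) -> RarefactionCurves:
    """Pan/core/new-family counts over random genome orderings.

    With ``keep_permutations`` the per-permutation pan/core trajectories
    are attached as ``curves.pan_raw`` / ``curves.core_raw``.
    """
    presence = matrix.presence().to_numpy(dtype=bool)  # families × genomes
    n_fam, n_genomes = presence.shape
    if n_genomes < 2:
        raise ValueError("rarefaction needs at least two genomes")
    rng = np.random.default_rng(seed)
    pan = np.empty((n_permutations, n_genomes), dtype=np.int64)
    core = np.empty_like(pan)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        cols = presence[:, order]
        seen = np.logical_or.accumulate(cols, axis=1)
        shared = np.logical_and.accumulate(cols, axis=1)
        pan[p] = seen.sum(axis=0)
        core[p] = shared.sum(axis=0)
    new = np.diff(pan, axis=1, prepend=0)

    def q(a, v):
        return np.quantile(a, v, axis=0, method="lower")

    curves = RarefactionCurves(
        n=np.arange(1, n_genomes + 1),
        pan_median=np.median(pan, axis=0),
        pan_lo=q(pan, 0.025),
        pan_hi=q(pan, 0.975),
        core_median=np.median(core, axis=0),
        core_lo=q(core, 0.025),
        core_hi=q(core, 0.975),
        new_median=np.median(new, axis=0),
        n_permutations=n_permutations,
        seed=seed,
    )
    if keep_permutations:
        curves.pan_raw = pan
        curves.core_raw = core
    return curves


# -------------------------------------------------------------------- openness
def fit_openness(curves: RarefactionCurves) -> OpennessFit:
    """Power-law fit of the median new-genes curve, Δn(N) = κ·N^−α.

    Least squares on log Δn vs log N over N ≥ 2 (the first genome's whole
    repertoire is not a discovery rate); zero medians are excluded from
    the log fit.
    """
    n = curves.n
    dn = curves.new_median.astype(float)
    mask = (n >= 2) & (dn > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 positive new-gene medians at N >= 2; fit undefined")
    slope, intercept = np.polyfit(np.log(n[mask]), np.log(dn[mask]), 1)
    alpha = -float(slope)
    kappa = float(np.exp(intercept))
    return OpennessFit(kappa, alpha, alpha < 1.0, curves.n_permutations, curves.seed)


def per_genome_rates(curves: RarefactionCurves, fit: OpennessFit) -> tuple[float, float]:
    """(new families gained per genome at N_max, core families lost per genome)."""
    n_max = int(curves.n[-1])
    if n_max < 3:
        raise ValueError("need at least 3 genomes")
    pan_gain = fit.kappa * n_max ** (-fit.alpha)
    core_loss = (curves.core_median[1] - curves.core_median[-1]) / (n_max - 2)
    return float(pan_gain), float(core_loss)


# ------------------------------------------------------------------- histogram
def frequency_histogram(
    matrix: OrthogroupMatrix, window: Optional[tuple[int, int]] = None
) -> tuple[pd.Series, float]:
    """Families binned by the number of genomes carrying them.

    Returns the histogram and the mean bin height over an "accessory"
    window of genome counts (by default 50–200 scaled proportionally to
    the dataset size, the convention used for ~224-genome collections).
    """
    presence = matrix.presence().to_numpy()
    n_genomes = presence.shape[1]
    freq = presence.sum(axis=1)
    hist = pd.Series(freq).value_counts().reindex(range(1, n_genomes + 1), fill_value=0)
    hist.index.name = "n_genomes"
    if window is None:
        lo = max(1, round(50 / 224 * n_genomes))
        hi = max(lo, round(200 / 224 * n_genomes))
    else:
        lo, hi = window
    windowed = hist.loc[lo:hi]
    mean_shared = float(windowed.mean()) if len(windowed) else 0.0
    return hist, mean_shared


# ---------------------------------------------------------- module completeness
def module_completeness(
    annotations: dict[str, set[str]],
    modules: dict[str, set[str]],
    matrix: OrthogroupMatrix,
    genome_subset: Optional[Sequence[str]] = None,
    min_completeness: float = 50.0,
) -> pd.Series:
    """Per-module % of required steps covered by the subset's core families.

    A step counts as covered when some family present in *every* genome of
    the subset is annotated with it; modules under ``min_completeness`` are
    dropped (the usual reporting convention).
    """
    if not annotations or not modules:
        raise ValueError("annotation and module maps must be non-empty")
    subset = list(genome_subset) if genome_subset is not None else matrix.genomes
    presence = matrix.presence()[subset]
    core_families = presence.index[presence.all(axis=1)]
    covered_steps: set[str] = set()
    for fam in core_families:
        covered_steps |= annotations.get(fam, set())
    out = {}
    for module, steps in modules.items():
        if not steps:
            raise ValueError(f"module {module!r} has no required steps")
        pct = 100.0 * len(steps & covered_steps) / len(steps)
        if pct >= min_completeness:
            out[module] = pct
    return pd.Series(out, dtype=float).sort_index()
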