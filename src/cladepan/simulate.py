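"""Synthetic genus-scale datasets with full ground truth.

The generator emulates the statistical structure a genomic-species analysis
assumes: several species whose strains are ~1% nucleotide-divergent,
species separated by ≥5% divergence, gene repertoires evolving by Poisson
gain/loss along a known tree, proteins obtained by translation (so amino
acid identity stays coherently coupled to nucleotide identity), and a
slowly evolving 16S-like marker shared by every genome.

Sequence evolution is Jukes–Cantor per branch: each site is substituted
with probability 3/4·(1−exp(−4t/3)) to a uniformly chosen different base,
which is the exact JC transition kernel and therefore composes correctly
along root-to-leaf paths. There is no rate heterogeneity, no indels and no
intergenic DNA — the generator targets controlled identity levels, not
assembly realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .io import (
    DatasetManifest,
    GenomeRecord,
    ManifestEntry,
    Quality,
    write_fasta,
    write_newick,
)
from .tree import Node, PhyloTree

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Seq import Seq

    table = {}
    for i in "ACGT":
        for j in "ACGT":
            for k in "ACGT":
                codon = i + j + k
                table[codon] = str(Seq(codon).translate())
    return table


@dataclass
class SimulationConfig:
    """Knobs of the synthetic clade; the defaults are the study conditions."""

    seed: int = 0
    n_species: int = 8
    strains_per_species: Union[int, list[int]] = 3
    tree_depth: float = 0.12  # expected substitutions/site, root -> tip
    intra_species_divergence: float = 0.01  # pairwise, among strains of one species
    root_family_count: int = 2000
    gain_rate: float = 300.0  # expected gains per unit branch length
    loss_rate: float = 100.0
    mean_gene_length: int = 900  # nt
    marker_length: int = 1550  # nt, 16S-like
    marker_rate_scale: float = 0.05
    novel_pool: Union[str, int] = "infinite"
    composition_bias: float = 0.3  # log-normal spread of order-3 Markov transitions
    species_split_depth_frac: float = 0.7  # splits confined to the top of the tree
    include_outgroup: bool = False
    outgroup_branch: float = 0.1

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.intra_species_divergence >= self.tree_depth:
            raise ValueError("intra_species_divergence must be < tree_depth")
        for rate in (self.gain_rate, self.loss_rate, self.marker_rate_scale):
            if rate < 0:
                raise ValueError("rates must be non-negative")

    def strains_for(self, species_index: int) -> int:
        if isinstance(self.strains_per_species, int):
            return self.strains_per_species
        return self.strains_per_species[species_index]


@dataclass
class GroundTruth:
    tree: PhyloTree
    species_of: dict[str, int]
    node_families: dict[str, frozenset[str]]
    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]]  # child -> (gained, lost)
    config: SimulationConfig = field(repr=False, default=None)


def _jc_prob(t: float) -> float:
    """Probability a site differs after branch length t (JC69)."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def simulate_species_tree(config: SimulationConfig) -> PhyloTree:
    """Pure-birth species topology, ultrametric, expanded into strain leaves.

    Species splits are confined to the upper ``species_split_depth_frac`` of
    the species-tree depth, which bounds the minimum inter-species
    divergence away from the intra-species level — the separability regime
    the triple-condition species criterion assumes. Strain leaves attach in
    a star at half the intra-species divergence, so strains of one species
    are pairwise ``intra_species_divergence`` apart.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    n = config.n_species
    species_depth = config.tree_depth - config.intra_species_divergence / 2.0
    if config.strains_per_species == 1 or config.strains_per_species == [1] * n:
        species_depth = config.tree_depth

    root = Node()
    root.add(Node())
    root.add(Node())
    active: list[tuple[Node, float]] = [(root.children[0], 0.0), (root.children[1], 0.0)]
    # root splits at depth 0; later splits hit a random surviving lineage
    extra_depths = np.sort(rng.uniform(0.0, config.species_split_depth_frac * species_depth, n - 2))
    for depth in extra_depths:
        idx = int(rng.integers(len(active)))
        lineage, start = active.pop(idx)
        lineage.length = depth - start
        a, b = Node(), Node()
        lineage.add(a)
        lineage.add(b)
        active.append((a, depth))
        active.append((b, depth))

    species_nodes = []
    for lineage, start in active:
        lineage.length = species_depth - start
        species_nodes.append(lineage)
    # deterministic species numbering: shuffle-free, left-to-right preorder
    tree = PhyloTree(root, rooted=True)
    ordered = [n for n in tree.preorder() if n in species_nodes]

    for si, node in enumerate(ordered):
        k = config.strains_for(si)
        if k == 1:
            node.name = f"S{si + 1:02d}_01"
        else:
            for gi in range(k):
                leaf = Node(f"S{si + 1:02d}_{gi + 1:02d}", config.intra_species_divergence / 2.0)
                node.add(leaf)

    if config.include_outgroup:
        new_root = Node()
        root.length = config.outgroup_branch
        new_root.add(root)
        new_root.add(Node("OUTG_01", config.outgroup_branch + config.tree_depth))
        tree = PhyloTree(new_root, rooted=True)

    tree.label_internals()
    return tree


def species_map(tree: PhyloTree) -> dict[str, int]:
    out = {}
    for name in tree.leaf_names():
        if name.startswith("OUTG"):
            out[name] = -1
        else:
            out[name] = int(name[1:3])
    return out


def simulate_gene_content(tree: PhyloTree, config: SimulationConfig) -> GroundTruth:
    """Poisson gain/loss of gene families along every branch.

    Gains draw globally fresh family IDs under ``novel_pool="infinite"``
    (an open pangenome by construction) or uniformly from the absent part
    of a fixed catalogue under a finite pool (a closing pangenome). Losses
    remove uniformly chosen present families, capped at the number present.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    counter = config.root_family_count
    pool: Optional[list[str]] = None
    if config.novel_pool != "infinite":
        pool_size = int(config.novel_pool)
        if pool_size < config.root_family_count:
            raise ValueError("finite pool smaller than root family count")
        pool = [f"F{i + 1:06d}" for i in range(pool_size)]

    root_set = frozenset(f"F{i + 1:06d}" for i in range(config.root_family_count))
    node_families: dict[str, frozenset[str]] = {tree.root.name: root_set}
    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]] = {}

    for parent, child in tree.branches():
        present = set(node_families[parent.name])
        t = child.length or 0.0
        n_loss = min(int(rng.poisson(config.loss_rate * t)), len(present))
        lost = set(rng.choice(sorted(present), size=n_loss, replace=False)) if n_loss else set()
        present -= lost
        n_gain = int(rng.poisson(config.gain_rate * t))
        gained: set[str] = set()
        if n_gain:
            if pool is None:
                for _ in range(n_gain):
                    counter += 1
                    gained.add(f"F{counter:06d}")
            else:
                absent = sorted(set(pool) - present)
                n_gain = min(n_gain, len(absent))
                gained = set(rng.choice(absent, size=n_gain, replace=False)) if n_gain else set()
        present |= gained
        node_families[child.name] = frozenset(present)
        branch_events[child.name] = (frozenset(gained), frozenset(lost))

    return GroundTruth(tree, species_map(tree), node_families, branch_events, config)


def _markov_chain(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Cumulative transition probabilities of a genus-wide order-3 chain.

    Real bacterial genomes carry compositional structure beyond what their
    3-mer frequencies predict; this is exactly the signal tetranucleotide
    z-scores read, and it is what makes same-species signatures correlate
    near 1. Drawing transition probabilities with a log-normal spread
    (``composition_bias``) reproduces z-score magnitudes in the ±20 range
    typical of bacteria; sigma=0 degrades to i.i.d. uniform sequence.
    """
    probs = np.exp(sigma * rng.normal(size=(64, 4)))
    probs /= probs.sum(axis=1, keepdims=True)
    return probs.cumsum(axis=1)


def _chain_sequence(rng: np.random.Generator, cum: np.ndarray, length: int) -> np.ndarray:
    out = np.empty(length, dtype=np.uint8)
    out[:3] = rng.integers(0, 4, size=3)
    ctx = int(out[0]) * 16 + int(out[1]) * 4 + int(out[2])
    draws = rng.random(length)
    for i in range(3, length):
        base = int(np.searchsorted(cum[ctx], draws[i], side="right"))
        base = min(base, 3)
        out[i] = base
        ctx = ((ctx * 4) & 63) + base
    return out


def _random_coding_sequence(rng: np.random.Generator, cum: np.ndarray, length: int) -> np.ndarray:
    seq = _chain_sequence(rng, cum, length)
    _fix_stops(seq)
    return seq


def _fix_stops(seq: np.ndarray) -> None:
    # A,C,G,T = 0,1,2,3; stops TAA/TAG/TGA get third base -> C (Tyr/Cys)
    codons = seq[: 3 * (len(seq) // 3)].reshape(-1, 3)
    c0, c1, c2 = codons[:, 0], codons[:, 1], codons[:, 2]
    stop = (c0 == 3) & (((c1 == 0) & ((c2 == 0) | (c2 == 2))) | ((c1 == 2) & (c2 == 0)))
    codons[stop, 2] = 1


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator, coding: bool = True) -> np.ndarray:
    p = _jc_prob(t)
    out = seq.copy()
    if p > 0:
        mask = rng.random(len(seq)) < p
        n = int(mask.sum())
        if n:
            out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    if coding:
        _fix_stops(out)
    return out


def seq_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def translate(nt: str) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    return "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))


def simulate_sequences(truth: GroundTruth, config: SimulationConfig) -> list[GenomeRecord]:
    """Evolve per-family nucleotide sequences and the 16S-like marker.

    Family lengths are 300 + 3·Geometric nt (mean ≈ ``mean_gene_length``);
    a family gained on a branch starts from the family's base sequence at
    the child node. Leaf genomes concatenate their family sequences into
    1–10 contigs; proteins are direct translations (stop codons re-mapped
    to sense codons so translations are full-length).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 303]))
    tree = truth.tree
    mean_extra_codons = max((config.mean_gene_length - 300) / 3.0, 1.0)
    p_geom = 1.0 / mean_extra_codons

    chain = _markov_chain(rng, config.composition_bias)
    base_seqs: dict[str, np.ndarray] = {}

    def base_seq(fid: str) -> np.ndarray:
        if fid not in base_seqs:
            length = 300 + 3 * int(rng.geometric(p_geom))
            base_seqs[fid] = _random_coding_sequence(rng, chain, length)
        return base_seqs[fid]

    for fid in sorted(truth.node_families[tree.root.name]):
        base_seq(fid)
    marker_root = _chain_sequence(rng, chain, config.marker_length)

    records: list[GenomeRecord] = []
    # DFS carrying the parent's family sequences and marker
    root_state = ({f: base_seq(f) for f in sorted(truth.node_families[tree.root.name])}, marker_root)
    stack: list[tuple[Node, dict[str, np.ndarray], np.ndarray]] = [
        (tree.root, root_state[0], root_state[1])
    ]
    leaf_payload: dict[str, tuple[dict[str, np.ndarray], np.ndarray]] = {}
    while stack:
        node, seqs, marker = stack.pop()
        if node.is_leaf:
            leaf_payload[node.name] = (seqs, marker)
            continue
        for child in reversed(node.children):
            t = child.length or 0.0
            child_seqs: dict[str, np.ndarray] = {}
            for fid in sorted(truth.node_families[child.name]):
                if fid in seqs:
                    child_seqs[fid] = _mutate(seqs[fid], t, rng)
                else:
                    child_seqs[fid] = base_seq(fid)
            child_marker = _mutate(marker, t * config.marker_rate_scale, rng, coding=False)
            stack.append((child, child_seqs, child_marker))

    for leaf in tree.leaf_names():
        seqs, marker = leaf_payload[leaf]
        fids = sorted(seqs)
        genome_nt = "".join(seq_to_str(seqs[f]) for f in fids)
        n_contigs = int(rng.integers(1, 11))
        n_contigs = min(n_contigs, max(len(fids), 1))
        # split at gene boundaries into roughly equal contigs
        bounds = np.linspace(0, len(fids), n_contigs + 1).astype(int)
        offsets = np.cumsum([0] + [len(seqs[f]) for f in fids])
        contigs = []
        for ci in range(n_contigs):
            lo, hi = offsets[bounds[ci]], offsets[bounds[ci + 1]]
            if hi > lo:
                contigs.append((f"{leaf}_c{ci + 1}", genome_nt[lo:hi]))
        proteins = [(f"{leaf}|{f}", translate(seq_to_str(seqs[f]))) for f in fids]
        records.append(
            GenomeRecord(
                genome_id=leaf,
                label=f"species_{truth.species_of[leaf]}" if truth.species_of[leaf] > 0 else "outgroup",
                contigs=contigs,
                proteins=proteins,
                rrna_16s=[(f"{leaf}_16S", seq_to_str(marker))],
                quality=Quality(100.0, 0.0, 0.0),
            )
        )
    return records


def simulate_clade(config: SimulationConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Tree → gene content → sequences, as one deterministic pipeline."""
    tree = simulate_species_tree(config)
    truth = simulate_gene_content(tree, config)
    records = simulate_sequences(truth, config)
    return records, truth


def emit_dataset(records: list[GenomeRecord], truth: GroundTruth, out_dir: str | Path) -> DatasetManifest:
    """Write the dataset and its ground truth as plain-text files."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "proteomes").mkdir(exist_ok=True)
    (out / "markers").mkdir(exist_ok=True)

    entries = []
    for rec in records:
        gpath = out / "genomes" / f"{rec.genome_id}.fna"
        ppath = out / "proteomes" / f"{rec.genome_id}.faa"
        mpath = out / "markers" / f"{rec.genome_id}.16S.fna"
        write_fasta(rec.contigs, gpath)
        write_fasta(rec.proteins, ppath)
        write_fasta(rec.rrna_16s, mpath)
        entries.append(
            ManifestEntry(rec.genome_id, rec.label, str(gpath), str(ppath), str(mpath))
        )

    with open(out / "quality.tsv", "w") as fh:
        fh.write("genome_id\tcompleteness\tcontamination\theterogeneity\n")
        for rec in records:
            q = rec.quality
            fh.write(f"{rec.genome_id}\t{q.completeness}\t{q.contamination}\t{q.heterogeneity}\n")

    write_newick(truth.tree, out / "tree.nwk")

    with open(out / "truth_species.tsv", "w") as fh:
        fh.write("genome_id\tspecies\n")
        for gid in sorted(truth.species_of):
            fh.write(f"{gid}\t{truth.species_of[gid]}\n")

    with open(out / "truth_events.tsv", "w") as fh:
        fh.write("child\tgained\tlost\n")
        for child in sorted(truth.branch_events):
            gained, lost = truth.branch_events[child]
            fh.write(f"{child}\t{','.join(sorted(gained))}\t{','.join(sorted(lost))}\n")

    outgroup = next((r.genome_id for r in records if r.genome_id.startswith("OUTG")), None)
    manifest = DatasetManifest(entries, outgroup_id=outgroup)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "outgroup_id": outgroup,
                "genomes": [
                    {
                        "genome_id": e.genome_id,
                        "label": e.label,
                        "genome_path": e.genome_path,
                        "proteome_path": e.proteome_path,
                        "rrna_path": e.rrna_path,
                    }
                    for e in entries
                ],
            },
            fh,
            sort_keys=False,
        )
    return manifest


def load_manifest(path: str | Path) -> DatasetManifest:
    data = yaml.safe_load(Path(path).read_text())
    entries = [
        ManifestEntry(
            d["genome_id"],
            d.get("label", ""),
            d.get("genome_path"),
            d.get("proteome_path"),
            d.get("rrna_path"),
        )
        for d in data["genomes"]
    ]
    return DatasetManifest(entries, outgroup_id=data.get("outgroup_id"))
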