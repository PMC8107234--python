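"""Genomic species delineation by the triple-condition criterion.

Two genomes belong to the same genomic species when simultaneously
ANI > 95%, TETRA > 0.99 and AAI > 95% (strict inequalities). Species
clusters are the connected components of the resulting graph; pairs inside
a component that fail the criterion (near-threshold intransitivity) are
surfaced, never silently merged or split. Inter-cluster pairs passing some
but not all criteria are reported as "gray zones", together with the share
of pairs falling in the sparsely populated 83–95% ANI discontinuity zone.

Cluster naming follows type-strain membership first, then full-length 16S
identity (≥99% at ≥80% mutual coverage, sequences >1400 nt), then falls
back to deterministic "unknown group" letters.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .metrics import PairwiseMetricTable, marker_identity

logger = logging.getLogger(__name__)

CRITERIA = ("ANI", "TETRA", "AAI")


@dataclass
class SpeciesThresholds:
    ani_min: float = 95.0
    tetra_min: float = 0.99
    aai_min: float = 95.0
    marker_identity_min: float = 99.0
    marker_coverage_min: float = 80.0
    marker_length_min: int = 1400


@dataclass
class SpeciesCluster:
    cluster_id: int
    members: frozenset[str]
    representative: str
    name: str = ""
    evidence: str = "unnamed"
    incomplete_pairs: list[tuple[str, str]] = field(default_factory=list)
    gray_zone_partners: list[tuple[int, frozenset[str]]] = field(default_factory=list)


def criteria_passed(metrics, th: SpeciesThresholds) -> frozenset[str]:
    passed = set()
    if metrics.ani is not None and metrics.ani > th.ani_min:
        passed.add("ANI")
    if metrics.tetra is not None and metrics.tetra > th.tetra_min:
        passed.add("TETRA")
    if metrics.aai is not None and metrics.aai > th.aai_min:
        passed.add("AAI")
    return frozenset(passed)


def build_species_graph(table: PairwiseMetricTable, th: Optional[SpeciesThresholds] = None) -> nx.Graph:
    """Graph over genomes with an edge wherever all three criteria pass.

    Non-edges carry the subset of criteria the pair did pass; missing pairs
    are treated as no-edge and logged.
    """
    th = th or SpeciesThresholds()
    graph = nx.Graph()
    graph.add_nodes_from(table.genomes)
    graph.graph["passed"] = passed_map = {}
    for a, b in itertools.combinations(sorted(table.genomes), 2):
        metrics = table.get(a, b)
        if metrics is None:
            logger.warning("missing metric pair (%s, %s); treated as no edge", a, b)
            passed_map[(a, b)] = frozenset()
            continue
        passed = criteria_passed(metrics, th)
        passed_map[(a, b)] = passed
        if passed == frozenset(CRITERIA):
            graph.add_edge(a, b)
        for name, value, bound in (
            ("ANI", metrics.ani, th.ani_min),
            ("TETRA", metrics.tetra, th.tetra_min),
            ("AAI", metrics.aai, th.aai_min),
        ):
            if value is not None and value == bound:
                logger.warning("pair (%s, %s) sits exactly on the %s threshold", a, b, name)
    return graph


def cluster_species(graph: nx.Graph) -> list[SpeciesCluster]:
    """Connected components, ordered by size (desc) then representative ID."""
    passed_map = graph.graph.get("passed", {})
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    clusters = []
    for i, members in enumerate(components, start=1):
        incomplete = []
        for a, b in itertools.combinations(members, 2):
            if not graph.has_edge(a, b):
                incomplete.append((a, b))
        clusters.append(
            SpeciesCluster(
                cluster_id=i,
                members=frozenset(members),
                representative=min(members),
                incomplete_pairs=incomplete,
            )
        )
    return clusters


@dataclass
class GrayZoneReport:
    pairs: list[tuple[str, str, int, int, frozenset[str]]]  # a, b, cluster_a, cluster_b, passed
    discontinuity_fraction: float
    n_pairs_total: int


def flag_gray_zones(
    table: PairwiseMetricTable,
    clusters: list[SpeciesCluster],
    th: Optional[SpeciesThresholds] = None,
    ani_zone: tuple[float, float] = (83.0, 95.0),
) -> GrayZoneReport:
    """Inter-cluster pairs passing ≥1 but not all criteria, plus the
    fraction of all pairs inside the ANI discontinuity zone."""
    th = th or SpeciesThresholds()
    cluster_of = {}
    for c in clusters:
        for m in c.members:
            cluster_of[m] = c.cluster_id
    gray = []
    in_zone = 0
    total = 0
    for a, b in itertools.combinations(sorted(table.genomes), 2):
        metrics = table.get(a, b)
        total += 1
        if metrics is None:
            continue
        if metrics.ani is not None and ani_zone[0] <= metrics.ani <= ani_zone[1]:
            in_zone += 1
        if cluster_of.get(a) == cluster_of.get(b):
            continue
        passed = criteria_passed(metrics, th)
        if 0 < len(passed) < len(CRITERIA):
            gray.append((a, b, cluster_of[a], cluster_of[b], passed))
    for c in clusters:
        partners: dict[int, frozenset[str]] = {}
        for a, b, ca, cb, passed in gray:
            if ca == c.cluster_id:
                partners[cb] = passed
            elif cb == c.cluster_id:
                partners[ca] = passed
        c.gray_zone_partners = sorted(partners.items())
    fraction = in_zone / total if total else 0.0
    return GrayZoneReport(gray, fraction, total)


@dataclass
class Reference:
    """A named anchor: a type-strain genome and/or its 16S sequence."""

    name: str
    type_strain_id: Optional[str] = None
    rrna_sequence: Optional[str] = None


def assign_names(
    clusters: list[SpeciesCluster],
    references: list[Reference],
    markers: Optional[dict[str, list[tuple[str, str]]]] = None,
    th: Optional[SpeciesThresholds] = None,
) -> list[SpeciesCluster]:
    """Name clusters by type-strain membership, then 16S match, else letters.

    A cluster containing two type strains carries both names joined by
    "/" (a reported merge). 16S evidence requires a member sequence longer
    than ``marker_length_min`` matching a reference at
    ≥ ``marker_identity_min`` with both coverages ≥ ``marker_coverage_min``.
    """
    th = th or SpeciesThresholds()
    markers = markers or {}
    letters = iter(
        list(string.ascii_uppercase)
        + ["".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2)]
    )
    for cluster in clusters:
        type_names = [
            ref.name for ref in references if ref.type_strain_id and ref.type_strain_id in cluster.members
        ]
        if type_names:
            cluster.name = "/".join(type_names)
            cluster.evidence = "type_strain"
            if len(type_names) > 1:
                logger.warning(
                    "cluster %d merges type strains: %s", cluster.cluster_id, cluster.name
                )
            continue
        marker_name = None
        best = 0.0
        for member in sorted(cluster.members):
            for _sid, seq in markers.get(member, []):
                if len(seq) <= th.marker_length_min:
                    continue
                for ref in references:
                    if not ref.rrna_sequence:
                        continue
                    ident, cov_q, cov_t = marker_identity(seq, ref.rrna_sequence)
                    if (
                        ident >= th.marker_identity_min
                        and cov_q >= th.marker_coverage_min
                        and cov_t >= th.marker_coverage_min
                        and ident > best
                    ):
                        best = ident
                        marker_name = ref.name
        if marker_name:
            cluster.name = marker_name
            cluster.evidence = "marker_match"
        else:
            cluster.name = f"unknown group {next(letters)}"
            cluster.evidence = "unnamed"
    return clusters


def delineate(
    table: PairwiseMetricTable,
    th: Optional[SpeciesThresholds] = None,
    references: Optional[list[Reference]] = None,
    markers: Optional[dict[str, list[tuple[str, str]]]] = None,
) -> tuple[list[SpeciesCluster], GrayZoneReport]:
    """Full delineation: graph → components → gray zones → names."""
    th = th or SpeciesThresholds()
    graph = build_species_graph(table, th)
    clusters = cluster_species(graph)
    report = flag_gray_zones(table, clusters, th)
    assign_names(clusters, references or [], markers, th)
    return clusters, report
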