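"""End-to-end orchestration: dataset → metrics → species → pangenome → tree → gain/loss.

Every stage writes plain TSV artifacts (with ``#`` provenance headers
recording the seed and thresholds) into the run directory and is skipped
when its outputs already exist, so a run is resumable and a re-run of a
complete directory is a no-op. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as cio
from .delineate import SpeciesThresholds, delineate
from .gainloss import PenaltyConfig, branch_summary, wagner_parsimony
from .metrics import PairwiseMetricTable, compute_all_pairs
from .pangenome import (
    OrthogroupMatrix,
    categorize,
    cluster_orthogroups,
    fit_openness,
    frequency_histogram,
    per_genome_rates,
    rarefaction,
)
from .phylogeny import family_distance_matrix, neighbor_joining, root_with_outgroup, single_copy_core
from .simulate import SimulationConfig, emit_dataset, load_manifest, simulate_clade
from .tree import PhyloTree

logger = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "delineate", "pangenome", "tree", "gainloss", "report")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    manifest_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    thresholds: SpeciesThresholds = field(default_factory=SpeciesThresholds)
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)
    n_permutations: int = 1000
    soft_min: float = 0.95
    shell_min: float = 0.15
    tree_path: Optional[str] = None  # externally supplied rooted tree
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulation", None)
        th = data.pop("thresholds", None)
        pen = data.pop("penalties", None)
        config = cls(**data)
        if sim:
            config.simulation = SimulationConfig(**sim)
        if th:
            config.thresholds = SpeciesThresholds(**th)
        if pen:
            config.penalties = PenaltyConfig(**pen)
        return config


def _header(config: PipelineConfig, stage: str) -> str:
    return f"# cladepan stage={stage} seed={config.seed}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, stage: str, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config, stage))
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6f")


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.status: dict[str, str] = {}
        self._records = None
        self._manifest = None

    # ------------------------------------------------------------ dataset
    def _load_records(self):
        if self._records is not None:
            return self._records
        cfg = self.config
        if cfg.simulation is not None:
            manifest_file = self.out / "dataset" / "manifest.yaml"
            if not manifest_file.exists():
                records, truth = simulate_clade(cfg.simulation)
                emit_dataset(records, truth, self.out / "dataset")
            self._manifest = load_manifest(manifest_file)
        elif cfg.manifest_path:
            self._manifest = load_manifest(cfg.manifest_path)
        else:
            raise ValueError("config needs either a simulation block or a manifest_path")
        quality = None
        qpath = Path(self._manifest.entries[0].genome_path).parent.parent / "quality.tsv"
        if qpath.exists():
            quality = cio.read_quality_table(qpath)
        records = cio.load_genomes(self._manifest, quality)
        retained, rejected = cio.filter_quality(records)
        for rec, reason in rejected:
            logger.info("quality filter rejected %s (%s)", rec.genome_id, reason)
        self._records = retained
        return retained

    # ------------------------------------------------------------- stages
    def stage_simulate(self) -> None:
        if self.config.simulation is None:
            self.status["simulate"] = "skipped (external manifest)"
            return
        marker = self.out / "dataset" / "manifest.yaml"
        if marker.exists():
            self.status["simulate"] = "cached"
            return
        self._load_records()
        self.status["simulate"] = "done"

    def stage_metrics(self) -> PairwiseMetricTable:
        path = self.out / "metrics.tsv"
        if path.exists():
            self.status["metrics"] = "cached"
            return PairwiseMetricTable.from_tsv(path)
        records = self._load_records()
        table = compute_all_pairs(records)
        with open(path, "w") as fh:
            fh.write(_header(self.config, "metrics"))
        table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f", mode="a")
        self.status["metrics"] = "done"
        return table

    def stage_delineate(self, table: PairwiseMetricTable) -> pd.DataFrame:
        path = self.out / "clusters.tsv"
        if path.exists():
            self.status["delineate"] = "cached"
            return pd.read_csv(path, sep="\t", comment="#")
        clusters, gray = delineate(table, self.config.thresholds, references=[])
        rows = [
            [c.cluster_id, member, c.name, c.evidence]
            for c in clusters
            for member in sorted(c.members)
        ]
        frame = pd.DataFrame(rows, columns=["cluster_id", "genome_id", "name", "evidence"])
        _write_tsv(frame, path, self.config, "delineate")
        gray_rows = [[a, b, ca, cb, "+".join(sorted(p))] for a, b, ca, cb, p in gray.pairs]
        gray_frame = pd.DataFrame(
            gray_rows, columns=["genome_a", "genome_b", "cluster_a", "cluster_b", "criteria_passed"]
        )
        with open(self.out / "grayzones.tsv", "w") as fh:
            fh.write(_header(self.config, "delineate"))
            fh.write(f"# ani_discontinuity_fraction={gray.discontinuity_fraction:.6f}\n")
            gray_frame.to_csv(fh, sep="\t", index=False)
        self.status["delineate"] = "done"
        return frame

    def stage_pangenome(self) -> OrthogroupMatrix:
        matrix_path = self.out / "pangenome" / "gene_content.Rtab"
        if matrix_path.exists():
            self.status["pangenome"] = "cached"
            frame = cio.read_matrix_table(matrix_path)
            return OrthogroupMatrix(frame, {})
        records = self._load_records()
        proteomes = {r.genome_id: r.proteins for r in records}
        matrix = cluster_orthogroups(proteomes)
        cio.write_matrix_table(matrix.counts, matrix_path)

        summary = categorize(matrix, self.config.soft_min, self.config.shell_min)
        _write_tsv(
            pd.DataFrame([summary.as_dict()]),
            self.out / "pangenome" / "summary.tsv",
            self.config,
            "pangenome",
        )
        curves = rarefaction(matrix, self.config.n_permutations, seed=self.config.seed)
        _write_tsv(curves.to_frame(), self.out / "pangenome" / "curves.tsv", self.config, "pangenome")
        hist, mean_shared = frequency_histogram(matrix)
        _write_tsv(
            hist.rename("n_families").reset_index(),
            self.out / "pangenome" / "gene_frequency.tsv",
            self.config,
            "pangenome",
        )
        try:
            fit = fit_openness(curves)
            pan_gain, core_loss = per_genome_rates(curves, fit)
            openness = pd.DataFrame(
                [
                    {
                        "kappa": fit.kappa,
                        "alpha": fit.alpha,
                        "open": fit.open,
                        "pan_gain_per_genome": pan_gain,
                        "core_loss_per_genome": core_loss,
                        "mean_shared_accessory": mean_shared,
                        "n_permutations": fit.n_permutations,
                    }
                ]
            )
            _write_tsv(openness, self.out / "pangenome" / "openness.tsv", self.config, "pangenome")
        except ValueError as exc:
            logger.warning("openness fit unavailable: %s", exc)
        if self.config.make_plots:
            self._plot_pangenome(curves, hist)
        self.status["pangenome"] = "done"
        return matrix

    def _plot_pangenome(self, curves, hist) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        axes[0].plot(curves.n, curves.pan_median, color="tab:blue")
        axes[0].fill_between(curves.n, curves.pan_lo, curves.pan_hi, alpha=0.3)
        axes[0].set(title="pan genome", xlabel="genomes sampled", ylabel="families")
        axes[1].plot(curves.n, curves.core_median, color="tab:red")
        axes[1].fill_between(curves.n, curves.core_lo, curves.core_hi, alpha=0.3, color="tab:red")
        axes[1].set(title="core genome", xlabel="genomes sampled")
        axes[2].bar(hist.index, hist.to_numpy(), color="tab:gray")
        axes[2].set(title="family frequency", xlabel="genomes containing family")
        fig.tight_layout()
        fig.savefig(self.out / "pangenome" / "curves.png", dpi=120)
        plt.close(fig)

    def stage_tree(self, matrix: OrthogroupMatrix) -> PhyloTree:
        rooted_path = self.out / "tree" / "rooted.nwk"
        if rooted_path.exists():
            self.status["tree"] = "cached"
            return cio.read_newick(rooted_path)
        if self.config.tree_path:
            tree = cio.read_newick(self.config.tree_path)
            cio.write_newick(tree, rooted_path)
            self.status["tree"] = "external"
            return tree
        records = self._load_records()
        # the tree needs families spanning the outgroup too, so cluster
        # again at a permissive homology threshold (OrthoFinder-grade
        # sensitivity) rather than the pangenome's within-genus 80%
        proteomes = {r.genome_id: r.proteins for r in records}
        matrix = cluster_orthogroups(proteomes, identity_min=0.4, coverage_min=0.5)
        families = single_copy_core(matrix)
        gene_seq = {
            r.genome_id: {gid: seq for gid, seq in r.proteins} for r in records
        }
        sequences: dict[str, dict[str, str]] = {g: {} for g in matrix.genomes}
        for fam in families:
            for genome_id, gene_id in matrix.members[fam]:
                sequences[genome_id][fam] = gene_seq[genome_id][gene_id]
        dist = family_distance_matrix(families, sequences)
        _write_tsv(dist, self.out / "tree" / "distances.tsv", self.config, "tree", index=True)
        nj = neighbor_joining(dist)
        cio.write_newick(nj, self.out / "tree" / "nj.nwk")
        outgroup = self._manifest.outgroup_id if self._manifest else None
        if outgroup is None:
            raise ValueError(
                "rooting needs an outgroup in the manifest or a tree_path in the config; "
                "run the tree stage with one of those"
            )
        rooted = root_with_outgroup(nj, outgroup)
        cio.write_newick(rooted, rooted_path)
        self.status["tree"] = "done"
        return rooted

    def stage_gainloss(self, tree: PhyloTree, matrix: OrthogroupMatrix) -> pd.DataFrame:
        path = self.out / "gainloss" / "branches.tsv"
        if path.exists():
            self.status["gainloss"] = "cached"
            return pd.read_csv(path, sep="\t", comment="#")
        recon = wagner_parsimony(tree, matrix, self.config.penalties)
        summary = branch_summary(recon)
        _write_tsv(summary, path, self.config, "gainloss")
        root_fams = sorted(recon.branch_gains[tree.root.name])
        (self.out / "gainloss" / "root_families.txt").write_text("\n".join(root_fams) + "\n")
        self.status["gainloss"] = "done"
        return summary

    def stage_report(self) -> str:
        lines = ["# cladepan run report", "", f"seed: {self.config.seed}", ""]
        lines.append("## stage status")
        for stage in STAGES:
            lines.append(f"- {stage}: {self.status.get(stage, 'not run')}")
        clusters_path = self.out / "clusters.tsv"
        if clusters_path.exists():
            clusters = pd.read_csv(clusters_path, sep="\t", comment="#")
            lines += [
                "",
                "## genomic species",
                f"- genomes: {clusters['genome_id'].nunique()}",
                f"- species clusters: {clusters['cluster_id'].nunique()}",
            ]
        else:
            lines += ["", "## genomic species", "- not run"]
        openness_path = self.out / "pangenome" / "openness.tsv"
        if openness_path.exists():
            fit = pd.read_csv(openness_path, sep="\t", comment="#").iloc[0]
            verdict = "open" if bool(fit["open"]) else "closed"
            lines += [
                "",
                "## pangenome",
                f"- power-law alpha: {fit['alpha']:.3f} ({verdict} pangenome)",
                f"- new families per added genome at N_max: {fit['pan_gain_per_genome']:.2f}",
                f"- core families lost per added genome: {fit['core_loss_per_genome']:.3f}",
            ]
        else:
            lines += ["", "## pangenome", "- not run"]
        branches_path = self.out / "gainloss" / "branches.tsv"
        if branches_path.exists():
            branches = pd.read_csv(branches_path, sep="\t", comment="#")
            root_row = branches[branches["parent"] == "-"].iloc[0]
            lines += [
                "",
                "## gene gain/loss",
                f"- inferred root repertoire: {int(root_row['present_child'])} families",
                f"- total gains on branches: {int(branches[branches['parent'] != '-']['gained'].sum())}",
                f"- total losses on branches: {int(branches['lost'].sum())}",
            ]
        else:
            lines += ["", "## gene gain/loss", "- not run"]
        text = "\n".join(lines) + "\n"
        (self.out / "report.md").write_text(text)
        self.status["report"] = "done"
        return text


def run(config: PipelineConfig, stages: Optional[list[str]] = None) -> Pipeline:
    """Execute the requested stages (default: all) in dependency order."""
    wanted = list(stages) if stages else list(STAGES)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    pipe = Pipeline(config)
    table = None
    matrix = None
    tree = None
    if "simulate" in wanted:
        pipe.stage_simulate()
    if "metrics" in wanted or "delineate" in wanted:
        table = pipe.stage_metrics()
    if "delineate" in wanted:
        pipe.stage_delineate(table)
    if "pangenome" in wanted or "tree" in wanted or "gainloss" in wanted:
        matrix = pipe.stage_pangenome()
    if "tree" in wanted or "gainloss" in wanted:
        tree = pipe.stage_tree(matrix)
    if "gainloss" in wanted:
        pipe.stage_gainloss(tree, matrix)
    if "report" in wanted:
        pipe.stage_report()
    return pipe
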