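"""End-to-end orchestration: simulate/load -> markers -> consensus -> SNPs
-> diversity -> tree -> dRFLP screen -> statistics, with plain-text
artifacts and a JSON run report.

Every stage writes inspectable TSV/FASTA/JSON/newick intermediates into
the output directory, and the fully-resolved configuration (seed included)
is serialized alongside them for provenance. Running stages through the
CLI subcommands or through :func:`run_pipeline` produces identical
artifacts for the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import (
    GelModel, PrimerPair, ScanParams, Scoring,
    build_marker_matrix, call_consensus, default_enzyme_library,
    diversity_report, kruskal_wallis, normalize, pca, plsda_vip,
    progressive_msa, read_enzyme_table, read_fasta, screen_enzymes,
    simulate_populations, snp_table, study_config, top_markers,
    write_fasta, write_marker_table,
)
from .io_formats import PopulationSet, write_population_map
from .phylo import bootstrap_tree
from .restriction import digest, render_gel
from .synthetic import STUDY_REGIONS, TR10_MOTIF, _TR2_MOTIF

log = logging.getLogger("mitomarkers")

_ALL_STAGES = ("simulate", "markers", "consensus", "diversity", "tree",
               "screen", "stats")


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration.

    Either ``input_fasta`` (+ optional ``population_map``) or the built-in
    simulator (``simulate=True``) provides the sequences.
    """

    out_dir: str
    seed: int = 1
    stages: tuple[str, ...] = _ALL_STAGES
    input_fasta: str | None = None
    population_map: str | None = None
    enzyme_table: str | None = None       # None -> REBASE-derived default
    region_map: Mapping[str, str] = field(default_factory=lambda: dict(STUDY_REGIONS))
    tr_motifs: Mapping[str, str] = field(
        default_factory=lambda: {"TR2": _TR2_MOTIF, "TR10": TR10_MOTIF})
    noise_rate: float = 0.005
    scan: ScanParams = field(default_factory=ScanParams)
    gel: GelModel = field(default_factory=GelModel)
    scoring: Scoring = field(default_factory=Scoring)
    bootstrap_reps: int = 1000
    max_enzyme_set_size: int = 2
    n_top_markers: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.input_fasta is None and "simulate" not in self.stages and self.stages:
            needs_seqs = set(self.stages) - {"stats"}
            if needs_seqs:
                raise ValueError("no input FASTA and simulate stage disabled")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, typ in (("scan", ScanParams), ("gel", GelModel),
                         ("scoring", Scoring)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        raw["stages"] = list(self.stages)
        raw["region_map"] = dict(self.region_map)
        raw["tr_motifs"] = dict(self.tr_motifs)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report
    dict (also written as ``report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    artifacts: list[str] = ["config.yaml"]
    stages = set(config.stages)
    if not stages:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report

    pop_set: PopulationSet | None = None
    truth = None
    ssr_primers: dict[str, PrimerPair] = {}

    if "simulate" in stages:
        log.info("simulate: seed=%s noise=%s", config.seed, config.noise_rate)
        sim = study_config(config.seed, noise_rate=config.noise_rate)
        pop_set, truth = simulate_populations(sim)
        write_fasta(pop_set, out / "sequences.fasta")
        write_population_map(pop_set, out / "populations.tsv")
        truth.to_json(out / "truth.json")
        artifacts += ["sequences.fasta", "populations.tsv", "truth.json"]
        ssr_primers = ssr_primer_pairs(sim)
        lengths = [len(s) for s in pop_set]
        report["simulate"] = {
            "n_individuals": len(pop_set),
            "n_populations": len(pop_set.populations),
            "length_min_bp": min(lengths),
            "length_max_bp": max(lengths),
        }
    elif config.input_fasta:
        pop_set = read_fasta(config.input_fasta, config.population_map)

    needs_markers = "markers" in stages or "stats" in stages
    marker_table = None
    if needs_markers and pop_set is not None:
        log.info("markers: scanning %d sequences", len(pop_set))
        marker_table = build_marker_matrix(pop_set, dict(config.tr_motifs),
                                           ssr_primers or None, config.scan)
        write_marker_table(marker_table, out / "marker_matrix.tsv")
        artifacts.append("marker_matrix.tsv")
        if "TR10" in marker_table.markers:
            tr10 = marker_table.values["TR10"]
            report["markers"] = {
                "tr10_copy_min": float(tr10.min()),
                "tr10_copy_max": float(tr10.max()),
            }

    needs_consensus = stages & {"consensus", "diversity", "tree", "screen"}
    div = None
    if needs_consensus and pop_set is not None:
        log.info("consensus/diversity: aligning %d populations",
                 len(pop_set.populations))
        div = diversity_report(pop_set, config.region_map, config.scoring)
        with open(out / "consensus.fasta", "w") as fh:
            for cons in div.consensuses.values():
                fh.write(f">{cons.population}\n{cons.residues}\n")
        snps = snp_table(div.consensus_msa)
        snps.to_tsv(out / "snp_table.tsv")
        artifacts += ["consensus.fasta", "snp_table.tsv"]
        report["consensus"] = {
            "n_snp_rows": len(snps),
            "n_private_rows": len(snps.private_rows()),
        }

    if "diversity" in stages and div is not None:
        div.similarity.to_tsv(out / "similarity_matrix.tsv")
        div.similarity.edge_list().to_csv(out / "similarity_edges.tsv",
                                          sep="\t", index=False)
        artifacts += ["similarity_matrix.tsv", "similarity_edges.tsv"]
        best, worst = div.similarity.extremes()
        report["diversity"] = {
            "inter_population_pi_percent": div.inter.percent,
            "intra_population_pi_percent": {
                pop: est.percent for pop, est in div.intra.items()},
            "regional_pi_percent": {
                region: est.percent for region, est in div.regional.items()},
            "similarity_max": {"pair": [best[0], best[1]], "value": round(best[2], 4)},
            "similarity_min": {"pair": [worst[0], worst[1]], "value": round(worst[2], 4)},
        }

    if "tree" in stages and div is not None:
        log.info("tree: TN93 + UPGMA, %d bootstrap replicates",
                 config.bootstrap_reps)
        tree = bootstrap_tree(div.consensus_msa, reps=config.bootstrap_reps,
                              seed=config.seed)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        artifacts.append("tree.nwk")
        report["tree"] = {
            "newick": tree.to_newick(),
            "supports": {"+".join(sorted(n.leaves())): round(n.support, 1)
                         for n in tree.internal_nodes()},
        }

    if "screen" in stages and div is not None:
        library = (read_enzyme_table(config.enzyme_table)
                   if config.enzyme_table else default_enzyme_library())
        log.info("screen: %d enzymes, sets up to size %d", len(library),
                 config.max_enzyme_set_size)
        consensuses = list(div.consensuses.values())
        entries = screen_enzymes(consensuses, library, config.gel,
                                 config.max_enzyme_set_size)
        with open(out / "screen_results.tsv", "w") as fh:
            fh.write("enzymes\tscore\tn_pairs\ttotal_sites\tfull_discrimination\n")
            for e in entries[:200]:
                fh.write(f"{'+'.join(e.enzymes)}\t{e.score}\t{e.n_pairs}\t"
                         f"{e.total_sites}\t{int(e.full_discrimination)}\n")
        artifacts.append("screen_results.tsv")
        flagged = [e for e in entries if e.full_discrimination]
        target = tuple(sorted(("HpyCH4IV", "Tsp45I")))
        target_entry = next((e for e in entries if e.enzymes == target), None)
        if target_entry is not None:
            pats = [digest(c, [e for e in library if e.name in target],
                           ambiguity="strict") for c in consensuses]
            (out / "gel_double_digest.txt").write_text(
                render_gel(pats, config.gel, path=str(out / "gel_double_digest.png")))
            artifacts += ["gel_double_digest.txt", "gel_double_digest.png"]
        report["screen"] = {
            "library_size": len(library),
            "n_flagged_sets": len(flagged),
            "best_set": list(entries[0].enzymes) if entries else [],
            "hpych4iv_tsp45i_full": bool(target_entry and
                                         target_entry.full_discrimination),
            "hpych4iv_tsp45i_distinct_patterns": (
                _distinct_patterns(target_entry, config.gel)
                if target_entry else None),
        }

    if "stats" in stages and marker_table is not None:
        log.info("stats: %d markers", len(marker_table.markers))
        norm = normalize(marker_table)
        kw = kruskal_wallis(norm)
        vip = plsda_vip(norm)
        top = top_markers(kw, vip, config.n_top_markers)
        top_table = norm.values[top]
        pca_res = pca(NormalizedView(top_table, norm.groups), collapse_groups=True)
        stats_tsv = kw.table.copy()
        stats_tsv["VIP"] = vip.vip
        stats_tsv.to_csv(out / "marker_stats.tsv", sep="\t")
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca_res.group_scores.to_csv(out / "pca_group_scores.tsv", sep="\t")
        artifacts += ["marker_stats.tsv", "pca_scores.tsv", "pca_group_scores.tsv"]
        report["stats"] = {
            "top_markers": top,
            "pc1_variance_pct": round(float(pca_res.variance_pct[0]), 1),
            "pc2_variance_pct": round(float(pca_res.variance_pct[1]), 1),
            "kruskal_significant": [
                m for m in kw.table.index if kw.table.loc[m, "p"] <= 0.05],
        }

    # config.yaml embeds the run-specific output path; PNGs are renderings
    # of hashed text artifacts — neither belongs in the determinism surface
    report["artifacts"] = {
        name: _sha256(out / name) for name in artifacts
        if (out / name).exists() and not name.endswith(".png")
        and name != "config.yaml"}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _distinct_patterns(entry, gel: GelModel) -> int:
    from .restriction import visible_bands

    seen = set()
    for pat in entry.patterns:
        bands = tuple(round(b, 1) for b in visible_bands(pat, gel))
        seen.add(bands)
    return len(seen)


@dataclass
class NormalizedView:
    """A column subset of a NormalizedMatrix, for downstream PCA."""

    values: object
    groups: object


def ssr_primer_pairs(sim_config) -> dict[str, PrimerPair]:
    """Primer pairs flanking each simulated SSR locus, read off the
    realized template (20-mers ending 20 bp before / starting 20 bp after
    the insertion point)."""
    from .iupac import reverse_complement
    from .synthetic import _draw_template

    template = _draw_template(sim_config,
                              np.random.default_rng([sim_config.seed, 1]))
    pairs = {}
    for locus in sim_config.ssr_loci:
        p = locus.position
        forward = template[p - 40:p - 20]
        reverse = reverse_complement(template[p + 20:p + 40])
        pairs[locus.name] = PrimerPair(forward, reverse, max_mismatches=1)
    return pairs
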