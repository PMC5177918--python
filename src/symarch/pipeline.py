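"""Stage orchestration and report assembly.

Wires the analysis stages into a single configurable run and assembles the
side-by-side genome-comparison table (assembly metrics, gene architecture,
splice-site predominance, gene density) from per-genome reports. Stage
parameters come from a YAML/JSON-style mapping; every executed stage writes
a TSV and a sibling JSON under the output directory, and the run report
records provenance (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .enrichment import (
    DomainCountMatrix,
    ScreenConfig,
    enrichment_screen,
    records_to_frame,
)
from .errors import ConfigError
from .evolution import SyntenyConfig, TreeConfig, collapse_low_support, \
    find_collinear_blocks, species_specific_clades
from .model import read_fasta, read_gff3, read_newick
from .orientation import OrientationConfig, orientation_result_for_genome
from .stats import AssemblyReport, GeneStatsReport, assembly_report, gene_statistics
from .util import round_half_away


@dataclass
class RunReport:
    summaries: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (set, frozenset, tuple)):
                return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
            return str(o)

        with open(path, "w") as fh:
            json.dump(
                {"summaries": self.summaries, "provenance": self.provenance},
                fh, indent=2, default=default,
            )


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_STAGES = ("stats", "orient", "enrich", "synteny", "clades")


def validate_config(config: Mapping) -> None:
    """Check stage names and referenced input paths before any execution."""
    unknown = set(config) - set(_STAGES) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    path_keys = ("fasta", "gff", "counts", "newick", "pairs")
    for stage, params in config.items():
        if stage in ("seed", "out_dir") or not isinstance(params, Mapping):
            continue
        for key in path_keys:
            if key in params and not Path(params[key]).exists():
                raise ConfigError(f"{stage}.{key}: no such file {params[key]!r}")


def run_pipeline(config: Mapping, out_dir: str | Path) -> RunReport:
    """Execute the configured stages in dependency order.

    Recognized sections: ``stats`` (fasta, gff, min_gap_n), ``orient``
    (fasta, gff, window, step), ``enrich`` (counts TSV, in_group, out_group,
    fdr, sidedness), ``synteny`` (pairs TSV plus order files), ``clades``
    (newick, collapse threshold). Stages toggle by presence. Validation
    errors precede any execution; a stage failure aborts with the stage
    name.
    """
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        provenance={
            "version": __version__,
            "config_hash": config_hash(config),
            "seed": str(config.get("seed", "")),
        }
    )

    genome_cache: dict[tuple[str, str], Any] = {}

    def load_genome(params: Mapping):
        key = (str(params["fasta"]), str(params["gff"]))
        if key not in genome_cache:
            scaffolds = read_fasta(params["fasta"])
            genome_cache[key] = read_gff3(params["gff"], scaffolds)
        return genome_cache[key]

    stage = "validate"
    try:
        if "stats" in config:
            stage = "stats"
            params = config["stats"]
            genome = load_genome(params)
            asm = assembly_report(genome.scaffolds,
                                  min_gap_n=int(params.get("min_gap_n", 10)))
            gstats = gene_statistics(genome)
            report.summaries["assembly"] = asm
            report.summaries["genes"] = gstats
            make_table1({params.get("label", "genome"): (asm, gstats)}).to_csv(
                out_dir / "table1.tsv", sep="\t"
            )
        if "orient" in config:
            stage = "orient"
            params = config["orient"]
            genome = load_genome(params)
            cfg = OrientationConfig(
                window=int(params.get("window", 10)),
                step=int(params.get("step", 10)),
            )
            res = orientation_result_for_genome(genome, cfg)
            report.summaries["orientation"] = res
            pd.DataFrame({"changes": res.per_window_changes}).to_csv(
                out_dir / "orientation_windows.tsv", sep="\t", index_label="window"
            )
        if "enrich" in config:
            stage = "enrich"
            params = config["enrich"]
            matrix = DomainCountMatrix.from_tsv(params["counts"])
            cfg = ScreenConfig(
                in_group=tuple(params["in_group"]),
                out_group=tuple(params["out_group"]),
                fdr_threshold=float(params.get("fdr", 0.001)),
                sidedness=params.get("sidedness", "greater"),
            )
            enriched, records = enrichment_screen(matrix, cfg)
            report.summaries["enrichment"] = {
                "n_enriched": len(enriched),
                "enriched": sorted(enriched),
                "fdr_threshold": cfg.fdr_threshold,
                "sidedness": cfg.sidedness,
            }
            records_to_frame(records).to_csv(
                out_dir / "enrichment.tsv", sep="\t", index=False
            )
        if "synteny" in config:
            stage = "synteny"
            params = config["synteny"]
            pairs_df = pd.read_csv(params["pairs"], sep="\t")
            order_a = pairs_df["gene_a"].drop_duplicates().tolist() \
                if "order_a" not in params else list(params["order_a"])
            order_b = pairs_df["gene_b"].drop_duplicates().tolist() \
                if "order_b" not in params else list(params["order_b"])
            cfg = SyntenyConfig(
                min_block_genes=int(params.get("min_block_genes", 5)),
                max_gap_genes=int(params.get("max_gap_genes", 25)),
            )
            blocks, hist = find_collinear_blocks(
                order_a, order_b,
                list(pairs_df.itertuples(index=False, name=None)), cfg,
            )
            report.summaries["synteny"] = {
                "n_blocks": len(blocks),
                "size_histogram": hist,
            }
            pd.DataFrame(
                [
                    {
                        "scaffold_a": b.scaffold_a,
                        "scaffold_b": b.scaffold_b,
                        "size": b.size,
                        "orientation": b.orientation,
                        "anchors": ";".join(f"{a}|{c}" for a, c in b.anchors),
                    }
                    for b in blocks
                ]
            ).to_csv(out_dir / "synteny_blocks.tsv", sep="\t", index=False)
        if "clades" in config:
            stage = "clades"
            params = config["clades"]
            stree = read_newick(params["newick"])
            cfg = TreeConfig(
                support_collapse_threshold=int(params.get("collapse", 50)),
                min_clade_size=int(params.get("min_clade_size", 2)),
            )
            collapsed = collapse_low_support(stree, cfg)
            counts, members = species_specific_clades(collapsed, cfg)
            report.summaries["clades"] = {
                "counts": counts,
                "members": {sp: [sorted(c) for c in cl] for sp, cl in members.items()},
            }
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"stage {stage!r} failed: {exc}") from exc

    report.to_json(out_dir / "run_report.json")
    return report


TABLE1_ROWS = (
    "Total scaffold length (bp)",
    "Scaffold N50 (bp)",
    "Total contig length (bp)",
    "Contig N50 (bp)",
    "GC content, N excluded (%)",
    "Number of genes",
    "Mean gene length (bp)",
    "Mean coding region length (bp)",
    "Number of exons per gene",
    "Mean exon length (bp)",
    "Total exon length (Mb)",
    "Genes with introns (%)",
    "Mean intron length (bp)",
    "Total intron length (Mb)",
    "Predominant donor splice dinucleotides",
    "Predominant acceptor splice dinucleotides",
    "Mean intergenic length (bp)",
    "Gene density (genes/Mb)",
)


def make_table1(
    reports: Mapping[str, tuple[AssemblyReport, GeneStatsReport]]
) -> pd.DataFrame:
    """Side-by-side genome comparison table with a fixed row layout."""
    cols: dict[str, list] = {}
    for label, (asm, genes) in reports.items():
        donor = "/".join(genes.donor_dinucleotide_freqs)  # frequency order
        acceptor = "/".join(genes.acceptor_dinucleotide_freqs)
        cols[label] = [
            asm.total_scaffold_bp,
            asm.scaffold_n50_bp,
            asm.total_contig_bp,
            asm.contig_n50_bp,
            round_half_away(asm.gc_percent_n_excluded, 1),
            genes.n_genes,
            round_half_away(genes.mean_gene_length_bp, 0),
            round_half_away(genes.mean_coding_length_bp, 0),
            round_half_away(genes.exons_per_gene, 1),
            round_half_away(genes.mean_exon_length_bp, 1),
            round_half_away(genes.total_exon_mb, 1),
            round_half_away(genes.percent_genes_with_introns, 1),
            round_half_away(genes.mean_intron_length_bp, 1),
            round_half_away(genes.total_intron_mb, 1),
            donor,
            acceptor,
            round_half_away(genes.mean_intergenic_bp, 0),
            round_half_away(genes.gene_density_per_mb, 0),
        ]
    return pd.DataFrame(cols, index=list(TABLE1_ROWS))
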