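"""Pipeline orchestration: run all stages on one dataset and write a report.

One :class:`RunConfig` drives everything: distance matrices and the
divergence summary table, mismatch histograms and barcoding-gap verdicts,
diagnostic site tables, and assignment of flagged query specimens.  A JSON
manifest records package/library versions, parameters, and a checksum of
every input and output file, so identical inputs and configuration yield
byte-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

from . import __version__
from .alignment_io import (
    AlignedLocus,
    Dataset,
    SpecimenRecord,
    build_dataset,
    read_fasta_alignment,
    read_metadata,
)
from . import distance as dist
from . import diagnostics as diag
from . import gap_analysis as gap

logger = logging.getLogger(__name__)

ALL_STAGES = ("distances", "gap", "diagnose", "assign")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs, grouping choice, thresholds and output location for one run."""

    fasta_paths: dict[str, Path]          # locus name -> aligned FASTA
    metadata_path: Path
    outdir: Path
    grouping: Literal["form", "species"] = "form"
    bin_width: float = 0.005
    min_variant_carriers: int = 2
    sd_estimator: dist.SDEstimator = "sample"
    query_ids: list[str] = field(default_factory=list)
    make_plots: bool = False

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [self.metadata_path, *self.fasta_paths.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"input path(s) do not exist: {missing}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_run_dataset(config: RunConfig) -> Dataset:
    """Read all inputs; with ``grouping="species"`` form labels are dropped."""
    specimens = read_metadata(config.metadata_path)
    if config.grouping == "species":
        specimens = [
            SpecimenRecord(s.specimen_id, s.species, "") for s in specimens
        ]
    loci = [
        read_fasta_alignment(path, name) for name, path in config.fasta_paths.items()
    ]
    return build_dataset(loci, specimens)


def run_pipeline(
    config: RunConfig, stages: Sequence[str] = ALL_STAGES
) -> dict:
    """Run the requested stages and return the manifest (also written to disk).

    Any stage failure aborts with a stage-named :class:`PipelineError`; a
    ``FAILED`` marker naming the stage is left in the output directory next
    to whatever was already flushed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        dataset = load_run_dataset(config)
        matrices: dict[str, dist.DistanceMatrix] = {}
        for name, locus in dataset.loci.items():
            if len(locus) >= 2:
                matrices[name] = dist.distance_matrix(locus)
            else:
                warnings.warn(f"locus {name!r}: <2 sequences, skipped", stacklevel=2)

        if "distances" in stages:
            stage = "distances"
            ddir = outdir / "distances"
            ddir.mkdir(exist_ok=True)
            for name, matrix in matrices.items():
                dist.write_phylip(matrix, ddir / f"{name}.dist")
                outputs[f"distances/{name}.dist"] = ddir / f"{name}.dist"
                dist.write_long_tsv(matrix, ddir / f"{name}.pairs.tsv")
                outputs[f"distances/{name}.pairs.tsv"] = ddir / f"{name}.pairs.tsv"
            summaries = dist.all_group_summaries(dataset, config.sd_estimator)
            dist.summaries_to_frame(summaries).to_csv(
                outdir / "summaries_long.tsv", sep="\t", index=False, float_format="%.6f"
            )
            outputs["summaries_long.tsv"] = outdir / "summaries_long.tsv"
            dist.write_summary_table(summaries, outdir / "summary_table.tsv")
            outputs["summary_table.tsv"] = outdir / "summary_table.tsv"

        if "gap" in stages:
            stage = "gap"
            histograms: list[gap.MismatchHistogram] = []
            gap_results: list[gap.GapResult] = []
            group_of = dataset.group_of
            for name, matrix in matrices.items():
                hists = gap.mismatch_distribution(
                    matrix, dataset.specimens, config.bin_width
                )
                histograms.extend(hists)
                sizes: dict[str, int] = {}
                for sid in matrix.specimen_ids:
                    g = group_of[sid]
                    sizes[g] = sizes.get(g, 0) + 1
                eligible = [g for g in dataset.groups if sizes.get(g, 0) >= 2]
                for ga, gb in combinations(eligible, 2):
                    gap_results.append(
                        gap.barcoding_gap(matrix, dataset.specimens, ga, gb)
                    )
                if config.make_plots:
                    plot = outdir / f"mismatch_{name}.png"
                    gap.plot_mismatch(hists, plot, title=name)
                    outputs[f"mismatch_{name}.png"] = plot
            gap.write_histograms(histograms, outdir / "histograms.tsv")
            outputs["histograms.tsv"] = outdir / "histograms.tsv"
            gap.gap_results_to_frame(gap_results).to_csv(
                outdir / "gap_results.tsv", sep="\t", index=False, float_format="%.6f"
            )
            outputs["gap_results.tsv"] = outdir / "gap_results.tsv"

        tables: dict[str, diag.DiagnosticSiteTable] = {}
        if "diagnose" in stages or "assign" in stages:
            stage = "diagnose"
            reference = dataset.specimens
            queries = set(config.query_ids)
            if queries:
                reference = [
                    s for s in dataset.specimens if s.specimen_id not in queries
                ]
            sdir = outdir / "diagnostics"
            sdir.mkdir(exist_ok=True)
            for name, locus in dataset.loci.items():
                ref_locus = AlignedLocus(
                    locus_name=name,
                    length=locus.length,
                    sequences={
                        sid: seq
                        for sid, seq in locus.sequences.items()
                        if sid not in queries
                    },
                )
                ref_groups = {
                    s.group for s in reference if s.specimen_id in ref_locus.sequences
                }
                if len(ref_groups) < 2:
                    warnings.warn(
                        f"locus {name!r}: <2 groups after removing queries; "
                        "diagnostics skipped",
                        stacklevel=2,
                    )
                    continue
                table = diag.classify_sites(
                    ref_locus, reference, config.min_variant_carriers
                )
                tables[name] = table
                if "diagnose" in stages:
                    diag.write_site_table(table, sdir / f"{name}.sites.tsv")
                    outputs[f"diagnostics/{name}.sites.tsv"] = sdir / f"{name}.sites.tsv"
                    render = diag.render_site_alignment(table, ref_locus, reference)
                    (sdir / f"{name}.render.txt").write_text(render + "\n")
                    outputs[f"diagnostics/{name}.render.txt"] = sdir / f"{name}.render.txt"

        if "assign" in stages and config.query_ids:
            stage = "assign"
            rows = []
            for name, table in tables.items():
                locus = dataset.loci[name]
                for qid in config.query_ids:
                    if qid not in locus.sequences:
                        continue
                    res = diag.assign_specimen(locus.sequences[qid], table)
                    rows.append(
                        (
                            name,
                            qid,
                            res.group if res.assigned else "UNASSIGNED",
                            json.dumps(dict(res.tally), sort_keys=True),
                        )
                    )
            import pandas as pd

            pd.DataFrame(
                rows, columns=["locus", "query", "assigned_group", "tally"]
            ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
            outputs["assignments.tsv"] = outdir / "assignments.tsv"

        stage = "manifest"
        manifest = _build_manifest(config, outputs)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _build_manifest(config: RunConfig, outputs: dict[str, Path]) -> dict:
    import numpy
    import pandas

    return {
        "neodiag_version": __version__,
        "library_versions": {"numpy": numpy.__version__, "pandas": pandas.__version__},
        "parameters": {
            "grouping": config.grouping,
            "bin_width": config.bin_width,
            "min_variant_carriers": config.min_variant_carriers,
            "sd_estimator": config.sd_estimator,
            "query_ids": list(config.query_ids),
        },
        "inputs": {
            "metadata": {
                "path": str(config.metadata_path),
                "sha256": _sha256(Path(config.metadata_path)),
            },
            "fasta": {
                name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in config.fasta_paths.items()
            },
        },
        "outputs": {
            rel: {"path": str(p), "sha256": _sha256(p)} for rel, p in outputs.items()
        },
    }
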