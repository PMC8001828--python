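"""End-to-end orchestration: fixture generation, filtering, scoring, reports.

A :class:`RunConfig` names the inputs (a design plus either detection tables
on disk or synthetic-generation parameters) and the thresholds; ``run_pipeline``
executes background subtraction -> contaminant removal -> Venn comparison ->
three-criteria candidate selection -> spectral-count scoring, and optionally
PLA image quantification, writing every report as TSV/JSON with a provenance
header (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import __version__
from .core import (
    ContaminantPolicy,
    DetectionTable,
    ExperimentDesign,
    SegmentRole,
    load_design,
    study_design,
)
from .filtering import (
    FilterTrace,
    carboxylase_qc,
    mark_control_background,
    presence_set,
    remove_contaminants,
    select_segment_candidates,
    venn_partition,
)
from .scoring import ScoringParams, export_network, score_table, tier_candidates, write_interaction_files
from .simulate import generate_interactome, simulate_detection_tables, write_fixture


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data inconsistent with the design (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable for provenance hashing."""

    design_path: Optional[Path] = None  # None -> built-in five-line study design
    table_path: Optional[Path] = None  # None -> simulate from synthetic params
    synthetic: Optional[Mapping] = None  # kwargs for generate_interactome
    seed: int = 0
    out_dir: Path = Path("segbioid-out")
    network_threshold: float = 0.6
    pooled_controls: bool = False
    min_unique_peptides: int = 1
    nucleus_image: Optional[Path] = None
    signal_image: Optional[Path] = None

    def config_hash(self) -> str:
        doc = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(self).items()
            if v is not None
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> tuple[ExperimentDesign, DetectionTable]:
    if config.design_path is not None:
        if not Path(config.design_path).exists():
            raise ConfigError(f"design file not found: {config.design_path}")
        design = load_design(config.design_path)
    else:
        design = study_design()
    if config.table_path is not None:
        if not Path(config.table_path).exists():
            raise ConfigError(f"detection table not found: {config.table_path}")
        table = DetectionTable.from_tsv(config.table_path)
    else:
        truth = generate_interactome(seed=config.seed, **(config.synthetic or {}))
        table = simulate_detection_tables(truth, design, seed=config.seed)
    return design, table


def _header(config: RunConfig, stage: str) -> list[str]:
    return [
        f"segbioid {__version__}",
        f"stage={stage}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]


@dataclass
class ReportBundle:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    candidate_lists: dict = field(default_factory=dict)  # segment name -> CandidateList
    venn: Optional[object] = None
    background: set = field(default_factory=set)
    removed_contaminants: set = field(default_factory=set)
    qc_passed: Optional[bool] = None
    scored: list = field(default_factory=list)
    files: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full candidate-identification analysis and write reports."""
    design, table = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    trace = FilterTrace()
    policy = ContaminantPolicy()

    # stage 1: QC + background subtraction + contaminant removal
    qc = carboxylase_qc(table, design, policy)
    bundle.qc_passed = qc.passed
    qc.frame.to_csv(out / "carboxylase_qc.tsv", sep="\t", index=False)

    try:
        background = mark_control_background(
            table,
            design,
            pooled=config.pooled_controls,
            min_unique_peptides=config.min_unique_peptides,
            trace=trace,
        )
    except ValueError as exc:
        raise DataError(f"control subtraction failed: {exc}") from exc
    bundle.background = background
    filtered = table.drop_genes(background)
    filtered, removed = remove_contaminants(filtered, policy, trace=trace)
    bundle.removed_contaminants = removed

    # stage 2: Venn comparison of filtered presence sets (>=1 replicate)
    pos_line = design.positive_control_line
    exp_lines = design.experimental_lines
    if len(exp_lines) != 2:
        raise DataError(
            f"design must name exactly 2 experimental lines for the mutually "
            f"exclusive comparison, got {exp_lines}"
        )
    sets = [
        presence_set(filtered, line, 1, config.min_unique_peptides)
        for line in (pos_line, *exp_lines)
    ]
    venn = venn_partition(*sets, labels=(pos_line, *exp_lines))
    bundle.venn = venn
    venn.summary_frame().to_csv(out / "venn_summary.tsv", sep="\t", index=False)

    # stage 3: three-criteria candidate selection for each experimental segment
    seg_a = design.segment_of(exp_lines[0])
    seg_b = design.segment_of(exp_lines[1])
    for target, partner in ((seg_a, seg_b), (seg_b, seg_a)):
        try:
            candidates = select_segment_candidates(
                filtered, design, target, partner,
                trace=trace, min_unique_peptides=config.min_unique_peptides,
            )
        except ValueError as exc:
            raise DataError(f"candidate selection failed for {target.name}: {exc}") from exc
        bundle.candidate_lists[target.name] = candidates
        fname = out / f"candidates_{target.name.replace(' ', '_')}.tsv"
        candidates.to_tsv(fname, header_lines=_header(config, f"candidates:{target.name}"))
        bundle.files[f"candidates:{target.name}"] = fname

    trace.to_tsv(out / "filter_trace.tsv")

    # stage 4: spectral-count scoring + exports (uses the unfiltered counts,
    # controls inform the background rate)
    scored = score_table(table, design, ScoringParams())
    bundle.scored = scored
    tiers = tier_candidates(scored)
    with open(out / "score_tiers.tsv", "w") as fh:
        fh.write("bait\tprey\tscore\ttier\n")
        for si in scored:
            fh.write(f"{si.bait}\t{si.prey}\t{si.score:.6f}\t{si.tier}\n")
    export_network(scored, config.network_threshold, out / "network_edges.tsv")
    saint_paths = write_interaction_files(table, design, out / "saint_input")
    bundle.files.update(
        {
            "venn": out / "venn_summary.tsv",
            "trace": out / "filter_trace.tsv",
            "tiers": out / "score_tiers.tsv",
            "network": out / "network_edges.tsv",
            **{f"saint_{k}": v for k, v in saint_paths.items()},
        }
    )

    # stage 5 (optional): PLA image quantification
    if config.nucleus_image is not None and config.signal_image is not None:
        import tifffile

        from .pla import count_nuclear_foci, detect_foci, segment_nuclei, summarize_foci

        nuc = tifffile.imread(config.nucleus_image)
        sig = tifffile.imread(config.signal_image)
        mask = segment_nuclei(nuc)
        foci = detect_foci(sig)
        counts, extra = count_nuclear_foci(mask, foci)
        if mask.n_nuclei >= 2:
            summary = summarize_foci(list(counts.values()), extranuclear=extra).as_dict()
        else:
            summary = {"n_cells": mask.n_nuclei, "extranuclear": extra}
        pla_path = out / "pla_summary.json"
        pla_path.write_text(json.dumps(summary, indent=2))
        bundle.files["pla"] = pla_path

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_input_genes": len(table),
        "n_background": len(background),
        "n_contaminants_removed": len(removed),
        "qc_passed": bundle.qc_passed,
        "candidates": {name: cl.genes for name, cl in bundle.candidate_lists.items()},
        "venn_counts": venn.counts(),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    bundle.files["summary"] = out / "run_summary.json"
    return bundle


def make_fixture(config: RunConfig) -> dict[str, Path]:
    """Write a synthetic fixture (tables, truth, images) to the output directory."""
    design = load_design(config.design_path) if config.design_path else study_design()
    truth = generate_interactome(seed=config.seed, **(config.synthetic or {}))
    return write_fixture(config.out_dir, design, truth=truth, seed=config.seed)
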