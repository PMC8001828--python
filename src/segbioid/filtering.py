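"""Replicate-aware candidate filtering for segmented-bait proximity labeling.

The procedure mirrors how segmented BioID2 screens separate true interactors
from background:

1. **Background subtraction** — any protein identified in at least
   ``control_min_reps`` replicates *within* a single negative-control line
   (parental cells or the nuclear-targeted ligase alone) is nonspecific and
   subtracted from every experimental comparison.
2. **Contaminant removal** — keratins (gene prefix ``KRT``) and any other
   configured contaminant families are dropped as sample-prep artefacts.
3. **Venn partitioning** — the filtered presence sets of the full-length bait
   and the two mutually exclusive segments are compared; proteins shared by
   both segments are structural false positives because no residue can be
   present in both.
4. **Three-criteria selection** — a segment-specific candidate must be
   (i) absent from *every* replicate of the mutually exclusive partner
   segment, (ii) present in at least one replicate of the full-length
   positive control, and (iii) present in all ``final_required_reps``
   replicates of its own segment's line.

Every stage logs per-protein outcomes into a :class:`FilterTrace` so the full
provenance of a candidate list is reconstructable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .core import (
    BaitSegment,
    ContaminantPolicy,
    DetectionTable,
    ExperimentDesign,
    are_mutually_exclusive,
)

__all__ = [
    "FilterTrace",
    "VennPartition",
    "CandidateList",
    "mark_control_background",
    "remove_contaminants",
    "presence_set",
    "venn_partition",
    "select_segment_candidates",
    "carboxylase_qc",
    "CarboxylaseQC",
]


@dataclass
class FilterTrace:
    """Ordered per-protein record of every filter decision."""

    records: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (stage, gene, outcome, evidence)

    def log(self, stage: str, gene: str, outcome: str, evidence: str = "") -> None:
        self.records.append((stage, gene, outcome, evidence))

    def stage_counts(self) -> pd.DataFrame:
        df = self.frame
        if df.empty:
            return pd.DataFrame(columns=["stage", "outcome", "n"])
        return df.groupby(["stage", "outcome"]).size().rename("n").reset_index()

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["stage", "gene", "outcome", "evidence"])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


_REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint regions of a three-set comparison.

    Region keys name the sets they intersect: ``AB`` is (A ∩ B) \\ C, ``ABC``
    the triple intersection, and so on. Percentages are relative to
    ``|A ∪ B ∪ C|``.
    """

    labels: tuple[str, str, str]
    regions: dict[str, frozenset[str]]

    @classmethod
    def from_sets(
        cls,
        set_a: Iterable[str],
        set_b: Iterable[str],
        set_c: Iterable[str],
        labels: tuple[str, str, str] = ("A", "B", "C"),
    ) -> "VennPartition":
        a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
        regions = {
            "A_only": a - b - c,
            "B_only": b - a - c,
            "C_only": c - a - b,
            "AB": (a & b) - c,
            "AC": (a & c) - b,
            "BC": (b & c) - a,
            "ABC": a & b & c,
        }
        return cls(labels=tuple(labels), regions=regions)

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in _REGIONS}

    def percentages(self) -> dict[str, float]:
        total = self.union_size
        if total == 0:
            return {k: 0.0 for k in _REGIONS}
        return {k: 100.0 * len(self.regions[k]) / total for k in _REGIONS}

    def summary_frame(self) -> pd.DataFrame:
        counts, pcts = self.counts(), self.percentages()
        return pd.DataFrame(
            {
                "region": list(_REGIONS),
                "count": [counts[k] for k in _REGIONS],
                "pct_of_union": [round(pcts[k], 2) for k in _REGIONS],
                "members": [";".join(sorted(self.regions[k])) for k in _REGIONS],
            }
        )


@dataclass(frozen=True)
class CandidateList:
    """Final segment-specific candidates with per-replicate evidence."""

    segment: str
    frame: pd.DataFrame  # gene, accession, replicate vectors, criteria flags
    control_min_reps: int
    final_required_reps: int

    @property
    def genes(self) -> list[str]:
        return self.frame["gene"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False)


def mark_control_background(
    table: DetectionTable,
    design: ExperimentDesign,
    pooled: bool = False,
    min_unique_peptides: int = 1,
    trace: Optional[FilterTrace] = None,
) -> set[str]:
    """Proteins to subtract as nonspecific background.

    Default (per-line) rule: a protein is background when detected in at least
    ``design.control_min_reps`` replicates *within* at least one
    negative-control line. A protein seen once in each of two control lines is
    therefore not background, while one seen in 1 parental + 3 ligase-control
    replicates is (the ligase-control line alone crosses the threshold).

    ``pooled=True`` switches to counting detections across all control lines
    together; this is stricter and off by default.
    """
    controls = design.negative_control_lines
    missing = [c for c in controls if c not in table.cell_lines]
    if missing and len(table.frame):
        raise ValueError(f"negative-control line(s) absent from table: {missing}")
    background: set[str] = set()
    evidence: dict[str, list[str]] = {}
    if pooled:
        totals: dict[str, int] = {}
        for line in controls:
            for gene, n in table.detection_counts(line, min_unique_peptides).items():
                totals[gene] = totals.get(gene, 0) + int(n)
                evidence.setdefault(gene, []).append(f"{line}:{n}")
        background = {g for g, n in totals.items() if n >= design.control_min_reps}
    else:
        for line in controls:
            counts = table.detection_counts(line, min_unique_peptides)
            for gene, n in counts.items():
                evidence.setdefault(gene, []).append(f"{line}:{n}")
                if int(n) >= design.control_min_reps:
                    background.add(gene)
    if trace is not None:
        for gene in sorted(set(table.genes)):
            outcome = "background" if gene in background else "kept"
            trace.log("control_subtraction", gene, outcome, ",".join(evidence.get(gene, [])))
    return background


def remove_contaminants(
    table: DetectionTable,
    policy: ContaminantPolicy = ContaminantPolicy(),
    trace: Optional[FilterTrace] = None,
) -> tuple[DetectionTable, set[str]]:
    """Drop contaminant-family proteins (keratins by default) from the table."""
    removed = {g for g in table.genes if policy.is_contaminant(g)}
    if trace is not None:
        for gene in table.genes:
            trace.log(
                "contaminant_removal",
                gene,
                "removed" if gene in removed else "kept",
                "prefix_match" if gene in removed else "",
            )
    return table.drop_genes(removed), removed


def presence_set(
    table: DetectionTable,
    line: str,
    min_reps: int,
    min_unique_peptides: int = 1,
) -> set[str]:
    """Proteins detected in at least ``min_reps`` replicates of *line*."""
    if min_reps < 1:
        raise ValueError(f"min_reps must be >= 1, got {min_reps}")
    if line not in table.cell_lines:
        if len(table.frame) == 0:
            return set()
        raise ValueError(f"unknown cell line {line!r}; table has {table.cell_lines}")
    counts = table.detection_counts(line, min_unique_peptides)
    return set(counts[counts >= min_reps].index)


def venn_partition(
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Iterable[str],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Partition three presence sets into the seven standard disjoint regions."""
    return VennPartition.from_sets(set_a, set_b, set_c, labels)


def select_segment_candidates(
    table: DetectionTable,
    design: ExperimentDesign,
    target_segment: BaitSegment,
    exclusive_partner: BaitSegment,
    trace: Optional[FilterTrace] = None,
    min_unique_peptides: int = 1,
) -> CandidateList:
    """Apply the three-criteria selection for one segment.

    ``table`` must already be background-subtracted and contaminant-free. A
    protein becomes a candidate iff it is (1) absent from every replicate of
    the partner segment's line, (2) present in >= 1 replicate of the
    positive-control line, and (3) present in all ``final_required_reps``
    replicates of the target segment's line.
    """
    if not are_mutually_exclusive(target_segment, exclusive_partner):
        raise ValueError(
            f"segments {target_segment.name!r} and {exclusive_partner.name!r} overlap "
            "in residues; the exclusion criterion requires mutually exclusive segments"
        )
    target_line = design.line_for_segment(target_segment)
    partner_line = design.line_for_segment(exclusive_partner)
    positive_line = design.positive_control_line

    need = design.final_required_reps
    target_counts = table.detection_counts(target_line, min_unique_peptides)
    partner_counts = table.detection_counts(partner_line, min_unique_peptides)
    positive_counts = table.detection_counts(positive_line, min_unique_peptides)

    rows = []
    stage = f"criteria[{target_segment.name}]"
    for gene in table.genes:
        n_target = int(target_counts.get(gene, 0))
        n_partner = int(partner_counts.get(gene, 0))
        n_positive = int(positive_counts.get(gene, 0))
        c1 = n_partner == 0
        c2 = n_positive >= 1
        c3 = n_target >= need
        ok = c1 and c2 and c3
        if trace is not None:
            trace.log(
                stage,
                gene,
                "candidate" if ok else "rejected",
                f"target={n_target}/{need} partner={n_partner} positive={n_positive}",
            )
        if ok:
            rows.append(
                {
                    "gene": gene,
                    "accession": table.accession_of(gene),
                    "target_replicates": _vector(table, gene, target_line, design),
                    "positive_replicates": _vector(table, gene, positive_line, design),
                    "partner_replicates": _vector(table, gene, partner_line, design),
                    "absent_from_partner": c1,
                    "in_positive_control": c2,
                    "in_all_target_replicates": c3,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "accession",
            "target_replicates",
            "positive_replicates",
            "partner_replicates",
            "absent_from_partner",
            "in_positive_control",
            "in_all_target_replicates",
        ],
    )
    frame = frame.sort_values(["gene", "accession"]).reset_index(drop=True)
    return CandidateList(
        segment=target_segment.name,
        frame=frame,
        control_min_reps=design.control_min_reps,
        final_required_reps=design.final_required_reps,
    )


def _vector(table: DetectionTable, gene: str, line: str, design: ExperimentDesign) -> str:
    hits = table.replicate_hits(gene, line)
    return "".join("1" if r in hits else "0" for r in design.replicate_labels)


@dataclass(frozen=True)
class CarboxylaseQC:
    """Per-sample detection of endogenously biotinylated carboxylases."""

    frame: pd.DataFrame  # cell_line, replicate, carboxylases detected, pass flag
    passed: bool

    def failures(self) -> pd.DataFrame:
        return self.frame[~self.frame["sample_pass"]]


def carboxylase_qc(
    table: DetectionTable,
    design: ExperimentDesign,
    policy: ContaminantPolicy = ContaminantPolicy(),
) -> CarboxylaseQC:
    """Check that every sample captured at least one carboxylase.

    Naturally biotinylated carboxylases (PC, ACACA, ACACB, PCCA, MCCC1) should
    appear in every streptavidin pulldown; a sample with none indicates failed
    biotin capture.
    """
    if not policy.carboxylase_genes:
        raise ValueError("carboxylase QC set must be non-empty")
    carbox_by_gene: dict[str, str] = {}
    for gene in table.genes:
        canon = policy.canonical_carboxylase(gene)
        if canon is not None:
            carbox_by_gene[gene] = canon
    rows = []
    for line in design.cell_lines:
        for rep in design.replicate_labels:
            found = sorted(
                {
                    canon
                    for gene, canon in carbox_by_gene.items()
                    if rep in table.replicate_hits(gene, line)
                }
            )
            rows.append(
                {
                    "cell_line": line,
                    "replicate": rep,
                    "carboxylases": ";".join(found),
                    "n_detected": len(found),
                    "sample_pass": len(found) >= 1,
                }
            )
    frame = pd.DataFrame(rows)
    return CarboxylaseQC(frame=frame, passed=bool(frame["sample_pass"].all()))
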