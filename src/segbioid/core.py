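"""Domain types and construct geometry shared by every pipeline stage.

The central objects are :class:`BaitSegment` (a contiguous residue range of the
bait protein fused to the BioID2 ligase), :class:`ExperimentDesign` (which cell
line carries which construct, replicate counts, filtering thresholds) and
:class:`DetectionTable` (the proteins x (cell line, replicate) presence /
spectral-count matrix that the whole analysis consumes).

Residue coordinates are 1-based and inclusive throughout: a segment spanning
residues 1-609 covers 609 amino acids and 1827 coding nucleotides.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "SegmentRole",
    "BaitSegment",
    "ContaminantPolicy",
    "ExperimentDesign",
    "DetectionTable",
    "define_segment",
    "segment_length_bp",
    "are_mutually_exclusive",
    "study_design",
    "load_design",
    "save_design",
    "TABLE_COLUMNS",
]


class SegmentRole(str, enum.Enum):
    """Role of a construct in the experimental design."""

    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"
    EXPERIMENTAL = "experimental"


@dataclass(frozen=True)
class BaitSegment:
    """A contiguous residue range of the bait protein fused to the ligase.

    Parameters
    ----------
    name:
        Short construct label (e.g. ``"Ku70 vWA"``).
    start_res, end_res:
        1-based inclusive residue bounds.
    role:
        Whether the construct serves as a negative control, the full-length
        positive control, or an experimental segment.
    nls_appended:
        True when an exogenous nuclear localization signal was fused to the
        construct (the vWA segment lacks the intrinsic Ku70 NLS).
    """

    name: str
    start_res: int
    end_res: int
    role: SegmentRole
    nls_appended: bool = False

    def __post_init__(self) -> None:
        if self.start_res < 1:
            raise ValueError(
                f"segment {self.name!r}: start_res must be >= 1, got {self.start_res}"
            )
        if self.end_res < self.start_res:
            raise ValueError(
                f"segment {self.name!r}: end_res ({self.end_res}) precedes "
                f"start_res ({self.start_res})"
            )

    @property
    def n_residues(self) -> int:
        return self.end_res - self.start_res + 1

    def overlaps(self, other: "BaitSegment") -> bool:
        return self.start_res <= other.end_res and other.start_res <= self.end_res


def define_segment(
    name: str,
    start_res: int,
    end_res: int,
    role: SegmentRole | str,
    nls_appended: bool = False,
) -> BaitSegment:
    """Validate and build a :class:`BaitSegment` (1-based inclusive bounds)."""
    return BaitSegment(name, int(start_res), int(end_res), SegmentRole(role), nls_appended)


def segment_length_bp(segment: BaitSegment) -> int:
    """Coding-sequence length of the segment in nucleotides (3 bp per codon)."""
    return 3 * segment.n_residues


def are_mutually_exclusive(segment_a: BaitSegment, segment_b: BaitSegment) -> bool:
    """True iff the two residue ranges share no position.

    Mutually exclusive segments of the same bait cannot both harbour a
    residue-level binding site, which is what licenses the shared-candidate
    subtraction between the vWA and ``Δ``vWA lists.
    """
    return not segment_a.overlaps(segment_b)


# Endogenously biotinylated carboxylases; their detection is an innate positive
# control that biotinylated proteins were captured at all.
_CARBOXYLASES = frozenset({"PC", "ACACA", "ACACB", "PCCA", "MCCC1"})
# Nonstandard alias seen in the literature for MCCC1.
_CARBOXYLASE_ALIASES = {"MCCCA": "MCCC1"}


@dataclass(frozen=True)
class ContaminantPolicy:
    """Which gene names are treated as contaminants or QC markers."""

    gene_prefixes: tuple[str, ...] = ("KRT",)
    carboxylase_genes: frozenset[str] = _CARBOXYLASES
    carboxylase_aliases: Mapping[str, str] = field(
        default_factory=lambda: dict(_CARBOXYLASE_ALIASES)
    )

    def __post_init__(self) -> None:
        if not self.gene_prefixes or any(not p for p in self.gene_prefixes):
            raise ValueError("gene_prefixes must be non-empty strings")

    def is_contaminant(self, gene: str) -> bool:
        g = gene.upper()
        return any(g.startswith(p.upper()) for p in self.gene_prefixes)

    def canonical_carboxylase(self, gene: str) -> Optional[str]:
        g = gene.upper()
        g = self.carboxylase_aliases.get(g, g)
        return g if g in self.carboxylase_genes else None


@dataclass(frozen=True)
class ExperimentDesign:
    """Cell-line layout, replicate counts and filtering thresholds.

    ``cell_lines`` maps each cell-line label to the name of the segment it
    expresses, or ``None`` for the untransfected parental line. Exactly one
    segment must carry the positive-control role and at least one line must be
    a negative control (parental or a negative-control construct).
    """

    segments: tuple[BaitSegment, ...]
    cell_lines: Mapping[str, Optional[str]]
    replicates_per_line: int = 3
    control_min_reps: int = 2
    final_required_reps: int = 3

    def __post_init__(self) -> None:
        by_name = {s.name: s for s in self.segments}
        if len(by_name) != len(self.segments):
            raise ValueError("segment names must be unique")
        n_pos = sum(1 for s in self.segments if s.role is SegmentRole.POSITIVE_CONTROL)
        if n_pos != 1:
            raise ValueError(f"design requires exactly one positive-control segment, got {n_pos}")
        for line, seg in self.cell_lines.items():
            if seg is not None and seg not in by_name:
                raise ValueError(f"cell line {line!r} references unknown segment {seg!r}")
        if not self.negative_control_lines:
            raise ValueError("design requires at least one negative-control line")
        for attr in ("control_min_reps", "final_required_reps"):
            v = getattr(self, attr)
            if not 1 <= v <= self.replicates_per_line:
                raise ValueError(
                    f"{attr} must be in [1, replicates_per_line={self.replicates_per_line}], got {v}"
                )

    # -- line classification -------------------------------------------------

    def segment_of(self, line: str) -> Optional[BaitSegment]:
        seg_name = self.cell_lines[line]
        if seg_name is None:
            return None
        return next(s for s in self.segments if s.name == seg_name)

    def _lines_with_role(self, role: SegmentRole) -> list[str]:
        return [
            line
            for line, seg in self.cell_lines.items()
            if seg is not None and self.segment_of(line).role is role
        ]

    @property
    def negative_control_lines(self) -> list[str]:
        parental = [line for line, seg in self.cell_lines.items() if seg is None]
        return parental + self._lines_with_role(SegmentRole.NEGATIVE_CONTROL)

    @property
    def positive_control_line(self) -> str:
        lines = self._lines_with_role(SegmentRole.POSITIVE_CONTROL)
        if not lines:
            raise ValueError("no cell line expresses the positive-control segment")
        return lines[0]

    @property
    def experimental_lines(self) -> list[str]:
        return self._lines_with_role(SegmentRole.EXPERIMENTAL)

    def line_for_segment(self, segment: BaitSegment | str) -> str:
        name = segment.name if isinstance(segment, BaitSegment) else segment
        for line, seg in self.cell_lines.items():
            if seg == name:
                return line
        raise KeyError(f"no cell line expresses segment {name!r}")

    @property
    def replicate_labels(self) -> list[int]:
        return list(range(1, self.replicates_per_line + 1))


def study_design() -> ExperimentDesign:
    """The five-line Ku70 segmentation design.

    Parental HEK293 and the nuclear-targeted ligase (NLS-BioID2) are negative
    controls, full-length Ku70 is the positive control, and the vWA (residues
    1-250) and ``Δ``vWA (251-609) constructs are the mutually exclusive
    experimental pair.
    """
    segments = (
        define_segment("NLS", 539, 556, SegmentRole.NEGATIVE_CONTROL),
        define_segment("Ku70", 1, 609, SegmentRole.POSITIVE_CONTROL),
        define_segment("Ku70 vWA", 1, 250, SegmentRole.EXPERIMENTAL, nls_appended=True),
        define_segment("Ku70 dvWA", 251, 609, SegmentRole.EXPERIMENTAL),
    )
    cell_lines = {
        "HEK293": None,
        "NLS-BioID2": "NLS",
        "Ku70-BioID2": "Ku70",
        "Ku70-vWA-BioID2": "Ku70 vWA",
        "Ku70-dvWA-BioID2": "Ku70 dvWA",
    }
    return ExperimentDesign(segments=segments, cell_lines=cell_lines)


TABLE_COLUMNS = ["accession", "gene", "cell_line", "replicate", "unique_peptides", "spectral_count"]


class DetectionTable:
    """Sparse per-replicate protein identification table.

    One row per (protein, cell line, replicate) in which the protein was
    identified; absence of a row means not detected. A stored row must have
    ``unique_peptides >= 1`` and ``spectral_count >= 1`` (identification
    upstream requires at least one unique peptide, and a detected protein has
    at least one spectrum). Rows with both fields zero are silently dropped on
    construction; inconsistent rows (one zero, one positive) are rejected.

    Set logic is gene-level: duplicate gene names across accessions collapse to
    a single record per replicate, keeping the maximum evidence and the
    lexicographically smallest accession among the best rows.
    """

    def __init__(self, rows: pd.DataFrame):
        df = rows.copy()
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"detection table missing columns: {missing}")
        df = df[TABLE_COLUMNS]
        df["unique_peptides"] = df["unique_peptides"].astype(int)
        df["spectral_count"] = df["spectral_count"].astype(int)
        if (df["unique_peptides"] < 0).any() or (df["spectral_count"] < 0).any():
            raise ValueError("unique_peptides and spectral_count must be non-negative")
        undetected = (df["unique_peptides"] == 0) & (df["spectral_count"] == 0)
        df = df[~undetected]
        bad = (df["unique_peptides"] == 0) ^ (df["spectral_count"] == 0)
        if bad.any():
            raise ValueError(
                "inconsistent rows: a detected protein needs unique_peptides >= 1 "
                "and spectral_count >= 1"
            )
        # gene-level collapse: best evidence per (gene, line, replicate)
        df = df.sort_values(
            ["gene", "cell_line", "replicate", "unique_peptides", "spectral_count", "accession"],
            ascending=[True, True, True, False, False, True],
        )
        df = df.drop_duplicates(subset=["gene", "cell_line", "replicate"], keep="first")
        dup = df.duplicated(subset=["cell_line", "replicate", "gene"])
        if dup.any():  # pragma: no cover - defensive
            raise ValueError("replicate labels must be unique within a cell line")
        self._df = df.reset_index(drop=True)

    # -- construction / IO ---------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "DetectionTable":
        return cls(pd.DataFrame.from_records(list(records), columns=TABLE_COLUMNS))

    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "DetectionTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying tidy DataFrame (sorted, gene-collapsed)."""
        return self._df

    # -- queries -------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self._df["gene"].unique())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self._df["cell_line"].unique())

    def accession_of(self, gene: str) -> str:
        sub = self._df[self._df["gene"] == gene]
        if sub.empty:
            raise KeyError(gene)
        return sub["accession"].min()

    def replicate_hits(self, gene: str, line: str) -> set[int]:
        """Replicate labels of the given line in which the gene was detected."""
        sub = self._df[(self._df["gene"] == gene) & (self._df["cell_line"] == line)]
        return set(sub["replicate"].tolist())

    def n_replicates_detected(self, gene: str, line: str) -> int:
        return len(self.replicate_hits(gene, line))

    def detection_counts(self, line: str, min_unique_peptides: int = 1) -> pd.Series:
        """Per-gene number of replicates of *line* meeting the peptide cutoff."""
        sub = self._df[
            (self._df["cell_line"] == line)
            & (self._df["unique_peptides"] >= min_unique_peptides)
        ]
        return sub.groupby("gene")["replicate"].nunique()

    def spectral_counts(self, gene: str, line: str, replicates: Sequence[int]) -> list[int]:
        """Spectral counts over the given replicate labels, 0 where absent."""
        sub = self._df[(self._df["gene"] == gene) & (self._df["cell_line"] == line)]
        by_rep = dict(zip(sub["replicate"], sub["spectral_count"]))
        return [int(by_rep.get(r, 0)) for r in replicates]

    def drop_genes(self, genes: Iterable[str]) -> "DetectionTable":
        genes = set(genes)
        return DetectionTable(self._df[~self._df["gene"].isin(genes)])

    def restrict_lines(self, lines: Iterable[str]) -> "DetectionTable":
        lines = set(lines)
        return DetectionTable(self._df[self._df["cell_line"].isin(lines)])

    def __len__(self) -> int:
        return len(self._df["gene"].unique())

    def __repr__(self) -> str:
        return (
            f"DetectionTable({len(self)} genes, {len(self.cell_lines)} cell lines, "
            f"{len(self._df)} detection records)"
        )


# -- design (de)serialization ------------------------------------------------


def save_design(design: ExperimentDesign, path: str | Path) -> None:
    doc = {
        "replicates_per_line": design.replicates_per_line,
        "control_min_reps": design.control_min_reps,
        "final_required_reps": design.final_required_reps,
        "segments": {
            s.name: {
                "start_res": s.start_res,
                "end_res": s.end_res,
                "role": s.role.value,
                "nls_appended": s.nls_appended,
            }
            for s in design.segments
        },
        "cell_lines": dict(design.cell_lines),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment design from a YAML file written by :func:`save_design`."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        segments = tuple(
            define_segment(
                name,
                spec["start_res"],
                spec["end_res"],
                spec["role"],
                bool(spec.get("nls_appended", False)),
            )
            for name, spec in doc["segments"].items()
        )
        return ExperimentDesign(
            segments=segments,
            cell_lines=dict(doc["cell_lines"]),
            replicates_per_line=int(doc.get("replicates_per_line", 3)),
            control_min_reps=int(doc.get("control_min_reps", 2)),
            final_required_reps=int(doc.get("final_required_reps", 3)),
        )
    except KeyError as exc:
        raise ValueError(f"design file {path} is missing key {exc}") from exc
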