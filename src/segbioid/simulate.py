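"""Synthetic detection tables and microscopy images with known ground truth.

The generator plants an interactome with the detection structure a segmented
BioID2 screen exhibits: domain-specific interactors that can only be labeled
by constructs carrying the relevant residues, heterodimer-partner-mediated
interactors that survive the domain deletion, promiscuous background present
in every line including controls, always-detected endogenously biotinylated
carboxylases, and sporadic keratin contaminants. Detection is Bernoulli per
replicate and spectral counts are zero-truncated Poisson given detection, the
simplest emission consistent with count data.

A single global seed drives independent per-stream child seeds (tables vs
images), so each artefact is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DetectionTable, ExperimentDesign, SegmentRole, TABLE_COLUMNS

__all__ = [
    "CLASSES",
    "PlantedProtein",
    "PlantedInteractome",
    "SyntheticImageTruth",
    "generate_interactome",
    "simulate_detection_tables",
    "add_scripted_protein",
    "generate_pla_image",
    "write_fixture",
]

# protein classes and the construct roles whose lines can detect them;
# None entries are resolved per design below.
CLASSES = (
    "vwa_specific",
    "non_vwa_specific",
    "heterodimer_mediated",
    "shared_background",
    "carboxylase",
    "keratin",
)

# Realistic defaults for the stated world: specific interactors are labeled in
# most replicates of a compatible line, background is common everywhere,
# keratins are sporadic sample-prep contaminants, carboxylases are certain.
DEFAULT_DETECTION_PROBS: dict[str, float] = {
    "vwa_specific": 0.85,
    "non_vwa_specific": 0.85,
    "heterodimer_mediated": 0.85,
    "shared_background": 0.7,
    "carboxylase": 1.0,
    "keratin": 0.2,
}

DEFAULT_COUNT_MEANS: dict[str, float] = {
    "vwa_specific": 10.0,
    "non_vwa_specific": 10.0,
    "heterodimer_mediated": 10.0,
    "shared_background": 5.0,
    "carboxylase": 20.0,
    "keratin": 2.0,
}

# Planted class sizes default to the study's candidate-list scale: 11 vWA-domain
# interactors and 7 interactors outside the vWA domain (of which 3 are mediated
# by the retained heterodimerization surface).
DEFAULT_N_PER_CLASS: dict[str, int] = {
    "vwa_specific": 11,
    "non_vwa_specific": 4,
    "heterodimer_mediated": 3,
    "shared_background": 100,
    "carboxylase": 5,
    "keratin": 20,
}

_CARBOXYLASE_GENES = ("PC", "ACACA", "ACACB", "PCCA", "MCCC1")


@dataclass(frozen=True)
class PlantedProtein:
    accession: str
    gene: str
    label: str
    detection_prob: float
    count_mean: float
    # optional per-line scripted replicate pattern (line -> tuple of bools),
    # overriding the stochastic model for that line
    scripted: Optional[Mapping[str, tuple[bool, ...]]] = None


@dataclass(frozen=True)
class PlantedInteractome:
    """Ground-truth interactome with per-class detection parameters."""

    proteins: tuple[PlantedProtein, ...]
    seed: int

    def members(self, label: str) -> list[str]:
        return sorted(p.gene for p in self.proteins if p.label == label)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [p.gene for p in self.proteins],
                "accession": [p.accession for p in self.proteins],
                "class": [p.label for p in self.proteins],
            }
        ).sort_values("gene").reset_index(drop=True)


def _compatible_roles(label: str) -> Optional[set]:
    """Which construct roles can biotinylate a protein of this class.

    ``None`` means every line including the controls (parental line has no
    construct but still picks up streptavidin-bead background and endogenously
    biotinylated proteins).
    """
    if label == "vwa_specific":
        return {"vwa"}
    if label in ("non_vwa_specific", "heterodimer_mediated"):
        return {"dvwa"}
    return None  # compatible with all lines


def _line_kind(design: ExperimentDesign, line: str) -> str:
    seg = design.segment_of(line)
    if seg is None:
        return "parental"
    if seg.role is SegmentRole.NEGATIVE_CONTROL:
        return "control"
    if seg.role is SegmentRole.POSITIVE_CONTROL:
        return "full"
    # experimental segments: classify by whether the range covers residue 1
    # (the vWA-containing segment) or excludes it
    return "vwa" if seg.start_res == 1 else "dvwa"


def detection_probability(protein: PlantedProtein, design: ExperimentDesign, line: str) -> float:
    """Per-replicate detection probability of *protein* in *line* (0 if incompatible)."""
    kind = _line_kind(design, line)
    roles = _compatible_roles(protein.label)
    if roles is None:
        return protein.detection_prob
    # domain-specific interactors: compatible with the full-length bait and the
    # segment retaining their site; never with controls or the other segment
    if kind == "full" or kind in roles:
        return protein.detection_prob
    return 0.0


def generate_interactome(
    n_per_class: Optional[Mapping[str, int]] = None,
    detection_probs: Optional[Mapping[str, float]] = None,
    count_means: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> PlantedInteractome:
    """Build a reproducible planted interactome.

    Parameters are per-class; unspecified classes fall back to the defaults
    above. Carboxylases use the five real gene symbols (detection probability
    forced to 1); keratin contaminants get KRT-prefixed synthetic symbols so
    the contaminant filter applies to them.
    """
    sizes = dict(DEFAULT_N_PER_CLASS)
    sizes.update(n_per_class or {})
    probs = dict(DEFAULT_DETECTION_PROBS)
    probs.update(detection_probs or {})
    means = dict(DEFAULT_COUNT_MEANS)
    means.update(count_means or {})

    for label, n in sizes.items():
        if label not in CLASSES:
            raise ValueError(f"unknown protein class {label!r}")
        if n < 0:
            raise ValueError(f"class size must be >= 0, got {label}={n}")
    for label, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"detection probability must be in [0,1], got {label}={p}")
    for label, m in means.items():
        if m <= 0:
            raise ValueError(f"count mean must be positive, got {label}={m}")

    prefixes = {
        "vwa_specific": "VWAI",
        "non_vwa_specific": "CTRI",
        "heterodimer_mediated": "HDMI",
        "shared_background": "BKG",
        "keratin": "KRT9",
    }
    proteins: list[PlantedProtein] = []
    idx = 0
    for label in CLASSES:
        for i in range(sizes[label]):
            idx += 1
            if label == "carboxylase":
                gene = (
                    _CARBOXYLASE_GENES[i]
                    if i < len(_CARBOXYLASE_GENES)
                    else f"CARB{i + 1:02d}"
                )
                p = 1.0
            else:
                gene = f"{prefixes[label]}{i + 1:03d}"
                p = probs[label]
            proteins.append(
                PlantedProtein(
                    accession=f"SYN{idx:05d}",
                    gene=gene,
                    label=label,
                    detection_prob=p,
                    count_mean=means[label],
                )
            )
    return PlantedInteractome(proteins=tuple(proteins), seed=int(seed))


def add_scripted_protein(
    truth: PlantedInteractome,
    gene: str,
    pattern: Mapping[str, Sequence[bool]],
    label: str = "shared_background",
    count_mean: float = 5.0,
) -> PlantedInteractome:
    """Return a new interactome with one deterministically detected protein.

    ``pattern`` maps cell-line label to per-replicate detection flags; lines
    not listed are never detected. Used to plant fixed evidence patterns, e.g.
    a known interactor detected in 1 parental + 3 ligase-control replicates
    that the background subtraction must remove.
    """
    prot = PlantedProtein(
        accession=f"SYN9{len(truth.proteins):04d}",
        gene=gene,
        label=label,
        detection_prob=0.0,
        count_mean=float(count_mean),
        scripted={line: tuple(bool(b) for b in flags) for line, flags in pattern.items()},
    )
    return PlantedInteractome(proteins=truth.proteins + (prot,), seed=truth.seed)


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Draw zero-truncated Poisson variates by resampling zeros."""
    draws = rng.poisson(mean, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(mean, size=int(zeros.sum()))


def simulate_detection_tables(
    truth: PlantedInteractome,
    design: ExperimentDesign,
    seed: Optional[int] = None,
) -> DetectionTable:
    """Emit a detection table from the planted interactome.

    Detection is Bernoulli(p) per replicate with p the protein's probability in
    that line (0 when incompatible); spectral counts are zero-truncated
    Poisson(count_mean) given detection; unique peptide counts are 1 plus a
    Poisson(1) excess. Carboxylases are detected in every sample.
    """
    seed = truth.seed if seed is None else int(seed)
    rng = np.random.default_rng([seed, 0x7AB1E])
    reps = design.replicate_labels
    records: list[tuple] = []
    for prot in truth.proteins:
        for line in design.cell_lines:
            if prot.scripted is not None:
                flags = prot.scripted.get(line, ())
                detected = [
                    bool(flags[i]) if i < len(flags) else False for i in range(len(reps))
                ]
            else:
                p = detection_probability(prot, design, line)
                if p == 0.0:
                    continue
                detected = list(rng.random(len(reps)) < p)
            n_hit = int(sum(detected))
            if n_hit == 0:
                continue
            counts = _zero_truncated_poisson(rng, prot.count_mean, n_hit)
            peptides = 1 + rng.poisson(1.0, size=n_hit)
            k = 0
            for rep, hit in zip(reps, detected):
                if hit:
                    records.append(
                        (prot.accession, prot.gene, line, rep, int(peptides[k]), int(counts[k]))
                    )
                    k += 1
    return DetectionTable(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS))


# -- synthetic two-channel PLA images ----------------------------------------


@dataclass(frozen=True)
class SyntheticImageTruth:
    """Planted geometry behind a synthetic nucleus/PLA image pair."""

    nuclei: tuple[tuple[tuple[float, float], float], ...]  # ((row, col), radius)
    foci: tuple[tuple[tuple[float, float], float, Optional[int]], ...]  # (..., parent idx)
    background: float
    noise_scale: float

    @property
    def foci_per_nucleus(self) -> list[int]:
        counts = [0] * len(self.nuclei)
        for _, _, parent in self.foci:
            if parent is not None:
                counts[parent] += 1
        return counts

    @property
    def n_extranuclear(self) -> int:
        return sum(1 for _, _, parent in self.foci if parent is None)


@dataclass(frozen=True)
class PlaImageParams:
    """Tunable geometry for the image generator (pixel units, 0-255 intensity)."""

    n_nuclei: int = 10
    nucleus_radius: float = 18.0
    focus_radius: float = 2.0
    foci_mean_per_nucleus: float = 5.0
    n_extranuclear_foci: int = 0
    background: float = 10.0
    nucleus_intensity: float = 180.0
    focus_intensity: float = 220.0
    noise_scale: float = 0.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_pla_image(
    params: PlaImageParams = PlaImageParams(),
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticImageTruth]:
    """Render a (nucleus channel, signal channel, truth) triple.

    Nuclei are non-overlapping bright disks in the nucleus channel; PLA foci
    are small disks in the signal channel, each placed fully inside its parent
    nucleus (per-nucleus counts Poisson-distributed), with optional
    extranuclear foci and additive Gaussian noise. Both channels are 8-bit.
    """
    if image_shape[0] < 64 or image_shape[1] < 64:
        raise ValueError(f"image dimensions must be >= 64x64, got {image_shape}")
    if params.focus_radius < 1 or params.nucleus_radius < 1:
        raise ValueError("radii must be >= 1 pixel")
    if params.focus_radius >= params.nucleus_radius:
        raise ValueError(
            f"focus radius ({params.focus_radius}) must be smaller than nucleus "
            f"radius ({params.nucleus_radius})"
        )
    rng = np.random.default_rng([int(seed), 0x1AB2E])
    h, w = image_shape
    margin = params.nucleus_radius + 2

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < params.n_nuclei:
        attempts += 1
        if attempts > 10000 * max(params.n_nuclei, 1):
            raise RuntimeError("could not place non-overlapping nuclei; reduce count or radius")
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(
            math.hypot(c[0] - o[0], c[1] - o[1]) > 2 * params.nucleus_radius + 3 for o in centers
        ):
            centers.append(c)

    nuclei = tuple((c, params.nucleus_radius) for c in centers)
    foci: list[tuple[tuple[float, float], float, Optional[int]]] = []
    # PLA puncta are discrete: keep planted foci separated so each remains its
    # own connected component in the rendered channel
    min_sep = 2 * params.focus_radius + 1

    def _separated(fc: tuple[float, float]) -> bool:
        return all(math.hypot(fc[0] - o[0], fc[1] - o[1]) > min_sep for o, _, _ in foci)

    for i, (c, r) in enumerate(nuclei):
        n_foci = int(rng.poisson(params.foci_mean_per_nucleus))
        for _ in range(n_foci):
            for _attempt in range(1000):
                # place fully inside the nuclear disk
                rho = (r - params.focus_radius - 1) * math.sqrt(rng.random())
                theta = rng.uniform(0, 2 * math.pi)
                fc = (c[0] + rho * math.cos(theta), c[1] + rho * math.sin(theta))
                if _separated(fc):
                    foci.append((fc, params.focus_radius, i))
                    break
            else:
                raise RuntimeError(
                    "could not place non-overlapping foci inside a nucleus; "
                    "reduce foci_mean_per_nucleus or focus_radius"
                )
    for _ in range(params.n_extranuclear_foci):
        while True:
            fc = (rng.uniform(2, h - 2), rng.uniform(2, w - 2))
            if _separated(fc) and all(
                math.hypot(fc[0] - c[0], fc[1] - c[1]) > r + params.focus_radius + 2
                for c, r in nuclei
            ):
                foci.append((fc, params.focus_radius, None))
                break

    nucleus_img = np.full(image_shape, params.background, dtype=float)
    for c, r in nuclei:
        nucleus_img[_disk_mask(image_shape, c, r)] = params.nucleus_intensity
    signal_img = np.full(image_shape, params.background, dtype=float)
    for fc, fr, _ in foci:
        signal_img[_disk_mask(image_shape, fc, fr)] = params.focus_intensity

    if params.noise_scale > 0:
        nucleus_img += rng.normal(0, params.noise_scale, image_shape)
        signal_img += rng.normal(0, params.noise_scale, image_shape)

    truth = SyntheticImageTruth(
        nuclei=nuclei,
        foci=tuple(foci),
        background=params.background,
        noise_scale=params.noise_scale,
    )
    to_u8 = lambda a: np.clip(np.rint(a), 0, 255).astype(np.uint8)
    return to_u8(nucleus_img), to_u8(signal_img), truth


def write_fixture(
    out_dir: str | Path,
    design: ExperimentDesign,
    truth: Optional[PlantedInteractome] = None,
    seed: int = 0,
    images: bool = True,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: detection TSV, truth TSV, image pair.

    Returns a mapping of artefact name to path. The detection table uses the
    same TSV dialect :class:`~segbioid.core.DetectionTable` reads back.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = generate_interactome(seed=seed)
    table = simulate_detection_tables(truth, design, seed=seed)
    paths = {
        "detections": out / "detections.tsv",
        "truth": out / "truth.tsv",
    }
    table.to_tsv(paths["detections"], header_lines=[f"seed={seed}"])
    truth.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    if images:
        nuc, sig, _ = generate_pla_image(seed=seed)
        paths["nucleus_image"] = out / "nucleus.tif"
        paths["signal_image"] = out / "pla.tif"
        tifffile.imwrite(paths["nucleus_image"], nuc)
        tifffile.imwrite(paths["signal_image"], sig)
    return paths
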