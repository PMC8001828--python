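"""Spectral-count confidence scoring of bait-prey pairs.

This is a deliberately simple, fully documented SAINT-style score, not a
re-implementation of SAINTexpress: each prey's replicate spectral counts in a
bait line are modeled as Poisson draws from either a true-interaction rate
``lambda_true`` (the bait-line mean, floored at the background rate) or a
background rate ``lambda_false`` (pooled control mean plus a pseudocount).
The score is the posterior probability of the true-interaction component
given all replicates jointly:

    score = p * L_true / (p * L_true + (1 - p) * L_false)

with ``L`` the product of replicate Poisson likelihoods and ``p`` the prior
(0.5, indifference, by default). Because the joint log-likelihood ratio is a
nondecreasing function of the bait count total, the score is monotone in the
counts and symmetric under replicate permutation. Preys with no enrichment
over controls score exactly the prior.

The module also writes the whitespace-delimited bait / prey / interaction
files the reference SAINTexpress tool consumes, so real data can be handed to
it unchanged, and exports thresholded edge lists for network viewers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DetectionTable, ExperimentDesign, SegmentRole

__all__ = [
    "ScoringParams",
    "ScoredInteraction",
    "score_prey",
    "score_table",
    "tier_candidates",
    "export_network",
    "write_interaction_files",
    "TIER_THRESHOLDS",
]

TIER_THRESHOLDS = (0.6, 0.9, 0.99)


@dataclass(frozen=True)
class ScoringParams:
    """Tunables of the two-component Poisson posterior."""

    pseudocount: float = 0.5  # added to the pooled control mean; avoids a zero rate
    prior_true: float = 0.5  # prior probability of a true interaction

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0 < self.prior_true < 1:
            raise ValueError("prior_true must be in (0, 1)")


@dataclass(frozen=True)
class ScoredInteraction:
    prey: str
    bait: str
    bait_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    score: float
    tier: str  # "none", ">=0.6", ">=0.9", ">=0.99"


def _validate_counts(counts: Sequence[int], what: str) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError(f"{what} must be integers, got {counts}")
        arr = np.rint(arr).astype(int)
    if (arr < 0).any():
        raise ValueError(f"{what} must be non-negative, got {counts}")
    return arr.astype(int)


def score_prey(
    bait_counts: Sequence[int],
    control_counts: Sequence[int],
    params: ScoringParams = ScoringParams(),
) -> float:
    """Posterior probability in [0, 1] that the prey is a true interactor.

    ``lambda_false`` is the pooled control mean plus the pseudocount;
    ``lambda_true`` is the bait-replicate mean, floored at ``lambda_false`` so
    depletion is never treated as evidence for interaction. When the bait mean
    does not exceed background the score equals the prior exactly.
    """
    bait = _validate_counts(bait_counts, "bait counts")
    if bait.size < 1:
        raise ValueError("need at least one bait replicate")
    controls = _validate_counts(control_counts, "control counts")

    lam_false = (controls.mean() if controls.size else 0.0) + params.pseudocount
    lam_true = max(float(bait.mean()), lam_false)
    # joint log-likelihood ratio over replicates; the x! terms cancel
    total = int(bait.sum())
    n = bait.size
    log_lr = -n * (lam_true - lam_false) + total * math.log(lam_true / lam_false)
    log_prior_odds = math.log(params.prior_true / (1.0 - params.prior_true))
    log_odds = log_prior_odds + log_lr
    # stable logistic
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    e = math.exp(log_odds)
    return e / (1.0 + e)


def _tier_label(score: float, thresholds: Sequence[float] = TIER_THRESHOLDS) -> str:
    label = "none"
    for t in sorted(thresholds):
        if score >= t:
            label = f">={t:g}"
    return label


def score_table(
    table: DetectionTable,
    design: ExperimentDesign,
    params: ScoringParams = ScoringParams(),
    bait_lines: Optional[Sequence[str]] = None,
) -> list[ScoredInteraction]:
    """Score every detected prey against each bait line.

    Controls are all negative-control lines pooled. By default the scored
    baits are the experimental segment lines.
    """
    controls = design.negative_control_lines
    baits = list(bait_lines) if bait_lines is not None else design.experimental_lines
    reps = design.replicate_labels
    out: list[ScoredInteraction] = []
    for bait_line in baits:
        seg = design.segment_of(bait_line)
        bait_name = seg.name if seg is not None else bait_line
        for gene in table.genes:
            bait_counts = tuple(table.spectral_counts(gene, bait_line, reps))
            if sum(bait_counts) == 0:
                continue
            control_counts: tuple[int, ...] = tuple(
                c for line in controls for c in table.spectral_counts(gene, line, reps)
            )
            s = score_prey(bait_counts, control_counts, params)
            out.append(
                ScoredInteraction(
                    prey=gene,
                    bait=bait_name,
                    bait_counts=bait_counts,
                    control_counts=control_counts,
                    score=s,
                    tier=_tier_label(s),
                )
            )
    out.sort(key=lambda si: (si.bait, -si.score, si.prey))
    return out


def tier_candidates(
    scored: Iterable[ScoredInteraction],
    thresholds: Sequence[float] = TIER_THRESHOLDS,
) -> dict[float, list[ScoredInteraction]]:
    """Nested confidence tiers: each higher threshold's list is a subset of the lower's."""
    ts = sorted(set(float(t) for t in thresholds))
    if any(not 0 <= t <= 1 for t in ts):
        raise ValueError(f"thresholds must be in [0, 1], got {thresholds}")
    scored = list(scored)
    return {
        t: [si for si in scored if si.score >= t]
        for t in ts
    }


def export_network(
    scored: Iterable[ScoredInteraction],
    threshold: float,
    path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Bait->prey edge list above a score threshold, for graph viewers.

    Deterministic ordering (bait, then prey); written as TSV with columns
    source, target, score when a path is given.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    edges = sorted(
        ((si.bait, si.prey, si.score) for si in scored if si.score >= threshold),
        key=lambda e: (e[0], e[1]),
    )
    df = pd.DataFrame(edges, columns=["source", "target", "score"])
    df["score"] = df["score"].map(lambda s: f"{s:.6f}") if len(df) else df["score"]
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def write_interaction_files(
    table: DetectionTable,
    design: ExperimentDesign,
    output_dir: str | Path,
    bait_lines: Optional[Sequence[str]] = None,
    control_lines: Optional[Sequence[str]] = None,
) -> dict[str, Path]:
    """Write SAINT-format bait / prey / interaction files.

    * ``bait.txt`` — one row per IP (cell line x replicate): IP id, bait id,
      ``T`` for test purifications and ``C`` for controls.
    * ``prey.txt`` — prey id, sequence-length placeholder, gene name.
    * ``inter.txt`` — IP id, bait id, prey id, spectral count; rows with a
      zero count are omitted (sparse convention).

    The layout is the whitespace-delimited one the reference spectral-count
    scoring tool consumes, so exported tables interoperate with it directly.
    """
    if len(table.frame) == 0:
        raise ValueError("cannot write interaction files from an empty detection table")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    baits = list(bait_lines) if bait_lines is not None else (
        design.experimental_lines + [design.positive_control_line]
    )
    controls = list(control_lines) if control_lines is not None else design.negative_control_lines
    reps = design.replicate_labels

    def ip_id(line: str, rep: int) -> str:
        return f"{line.replace(' ', '_')}_r{rep}"

    bait_rows = []
    for line in baits:
        for rep in reps:
            bait_rows.append((ip_id(line, rep), line.replace(" ", "_"), "T"))
    for line in controls:
        for rep in reps:
            bait_rows.append((ip_id(line, rep), line.replace(" ", "_"), "C"))

    genes = table.genes
    prey_rows = [(gene, "1", gene) for gene in genes]  # length unknown downstream of ID tables

    inter_rows = []
    for line in baits + controls:
        for rep in reps:
            for gene in genes:
                count = table.spectral_counts(gene, line, [rep])[0]
                if count > 0:
                    inter_rows.append((ip_id(line, rep), line.replace(" ", "_"), gene, str(count)))

    paths = {
        "bait": out / "bait.txt",
        "prey": out / "prey.txt",
        "interaction": out / "inter.txt",
    }
    paths["bait"].write_text("".join("\t".join(r) + "\n" for r in bait_rows))
    paths["prey"].write_text("".join("\t".join(r) + "\n" for r in prey_rows))
    paths["interaction"].write_text("".join("\t".join(r) + "\n" for r in inter_rows))
    return paths
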