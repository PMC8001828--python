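# segbioid

Candidate-identification toolkit for **segmented-bait BioID2** proximity-labeling
screens, with spectral-count interaction scoring and proximity ligation assay
(PLA) image quantification.

## The problem

BioID2 fuses a promiscuous biotin ligase to a bait protein; proteins within
~10 nm are biotinylated in vivo, captured on streptavidin, and identified by
LC-MS/MS. Fusing the ligase to *segments* of the bait — here the Ku70 von
Willebrand A (vWA) domain (residues 1–250) and the complementary ΔvWA segment
(residues 251–609) — maps each interactor to the part of the bait it contacts.
Because the two segments share no residues, **no true interactor can appear in
both lists**; shared hits are structural false positives. The hard part of any
BioID experiment is separating the few true interactors from hundreds of
nonspecific background proteins, and this package implements that filtering as
a tested, reusable pipeline:

1. **Negative-control subtraction.** A protein detected in ≥ 2 biological
   replicates *within* either negative-control line (parental cells or the
   nuclear-targeted ligase alone) is subtracted as background.
2. **Contaminant removal.** Keratins (gene prefix `KRT`) are dropped as
   sample-prep contaminants; endogenously biotinylated carboxylases
   (PC, ACACA, ACACB, PCCA, MCCC1) are checked per sample as an innate
   positive control for biotin capture.
3. **Venn comparison** of the filtered presence sets of the full-length bait
   and the two segments (7 disjoint regions, counts and % of the union).
4. **Three-criteria selection.** A segment-specific candidate must be
   (i) absent from *every* replicate of the mutually exclusive partner
   segment, (ii) present in ≥ 1 replicate of the full-length positive control,
   and (iii) present in all 3 replicates of its own segment's line.
5. **Spectral-count scoring.** A documented SAINT-style two-component Poisson
   posterior scores each bait–prey pair in [0, 1]
   (tiers ≥ 0.6 / ≥ 0.9 / ≥ 0.99), and the standard bait/prey/interaction
   files are written for the reference SAINTexpress tool.
6. **PLA quantification.** Nucleus segmentation, size-thresholded focus
   detection, per-nucleus focus counts with 95% t-intervals, Welch
   unequal-variance t-tests, and background-subtracted mean nuclear intensity.

A synthetic-data module generates detection tables and two-channel images with
planted ground truth (domain-specific interactors, heterodimer-mediated
interactors that survive the domain deletion, shared background, carboxylases,
keratins), so every stage is testable without the original mass-spectrometry
deposit.

## The score

For a prey with bait-replicate spectral counts \(x_1..x_n\) and pooled control
counts, let \(\lambda_0\) = control mean + 0.5 (pseudocount) and
\(\lambda_1 = \max(\bar x, \lambda_0)\). With prior \(\pi = 0.5\),

```
score = π Π Pois(xᵢ; λ₁) / [ π Π Pois(xᵢ; λ₁) + (1−π) Π Pois(xᵢ; λ₀) ]
```

The score is monotone in the counts, symmetric under replicate permutation,
and equals the prior exactly when the prey shows no enrichment over controls.
It is an explicitly simplified stand-in for SAINTexpress, whose internals are
not reproduced; the file writers keep full interoperability with the real tool.

## Worked example

```bash
segbioid simulate --seed 7 --out demo-fx
segbioid all --seed 7 --table demo-fx/detections.tsv \
    --nucleus demo-fx/nucleus.tif --signal demo-fx/pla.tif --out demo-run
```

prints

```
Ku70 vWA: 8 candidates -> VWAI003, VWAI004, VWAI005, VWAI006, VWAI007, VWAI008, VWAI010, VWAI011
Ku70 dvWA: 4 candidates -> CTRI001, CTRI003, CTRI004, HDMI003
reports in demo-run
```

The fixture plants 11 vWA-specific (`VWAI*`) and 7 ΔvWA-class interactors
(`CTRI*` non-vWA plus `HDMI*` heterodimer-mediated) detected with probability
0.85 per compatible replicate, 100 background proteins, 20 keratins and the 5
carboxylases. At that detection rate some planted interactors miss the
all-3-replicates criterion — exactly the behaviour real screens show — so 8 of
11 and 4 of 7 survive here; with detection probability 1 the recovery is exact
(this is asserted in the test suite). The two candidate lists are disjoint by
construction. `demo-run/` also contains the Venn summary (the three planted
`BKG*` proteins that slipped through filtering land in the central
all-three-lines region, flagging them as likely false positives), the score
tiers, a network edge list, SAINT-format input files, the carboxylase QC
table, a per-protein filter trace, and the PLA summary for the image pair
(10 nuclei, mean 4.5 foci/nucleus, 95% CI [2.77, 6.23]).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a seeded synthetic fixture, runs the complete pipeline (filtering,
candidate selection, scoring, image quantification) from scratch, prints the
per-segment candidate counts and QC status, and writes the JSON report.

## Layout

- `segbioid.core` — bait segments, experiment design, detection tables, TSV/YAML IO
- `segbioid.simulate` — planted interactomes, detection-table simulation, synthetic image pairs
- `segbioid.filtering` — background subtraction, contaminants, Venn partition, three-criteria selection, carboxylase QC
- `segbioid.scoring` — Poisson posterior score, tiers, SAINT-format and network export
- `segbioid.pla` — nucleus/foci segmentation, per-nucleus counts, Welch tests, nuclear intensity
- `segbioid.pipeline` / `segbioid.cli` — orchestration and the `segbioid` command

See `docs/methods.md` for the model assumptions, parameter defaults and known
limitations.
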