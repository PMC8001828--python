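# Methods

## Experimental design model

The design is five HEK293-derived cell lines, three biological replicates
each: an untransfected parental line and a nuclear-targeted ligase-only line
(NLS, Ku70 residues 539–556) as negative controls, full-length Ku70 (1–609) as
the positive control, and the mutually exclusive experimental pair Ku70 vWA
(1–250, with an appended NLS) and Ku70 ΔvWA (251–609). Residue coordinates are
1-based inclusive; coding length is 3 bp per residue, so the four constructs
span 54, 1827, 750 and 1077 bp. `ExperimentDesign` generalizes this layout
(any number of control lines, configurable replicate counts and thresholds)
but always requires exactly one positive-control segment.

Detection tables are sparse and gene-level: identification upstream (search
engine + FDR control) is out of scope, so a stored row simply asserts that a
gene was identified in one (cell line, replicate) with ≥ 1 unique peptide and
≥ 1 spectrum. Duplicate accessions per gene collapse to the best-evidence
record because all replicate set logic operates on gene names. Two presence
definitions coexist in practice (≥ 1 unique peptide for replicate comparisons;
stricter 2-peptide rules feeding external scoring tools), so every presence
query takes a `min_unique_peptides` parameter instead of hard-coding either.

## Filtering procedure

Background subtraction uses the **per-line rule**: a protein is background if
detected in ≥ `control_min_reps` (default 2) replicates *within* at least one
negative-control line. One hit in each of two control lines is therefore not
background, while 1 parental + 3 NLS replicates is — the pattern by which even
a genuine interactor can be dismissed when the ligase-only control tags it
consistently. A pooled-across-lines mode exists behind a flag (off by
default). Subtraction precedes the Venn comparison and the selection criteria;
the filter trace records both pre- and post-filter membership so unfiltered
comparisons remain reproducible.

Keratin contaminants are matched by case-insensitive gene prefix (`KRT`);
other families can be added to the policy. The carboxylase QC reports, per
sample, which of PC / ACACA / ACACB / PCCA / MCCC1 (alias MCCCA accepted) were
detected; a sample with none indicates failed biotin capture.

The three selection criteria are literal set predicates and their order is
immaterial: absence from the partner line is absolute (a single partner
replicate disqualifies, regardless of how many target replicates hit), the
positive-control requirement is ≥ 1 replicate, and the final-evidence
requirement is all `final_required_reps` (default 3) replicates of the target
line. Candidate lists are sorted by gene name then accession; no ties remain.
Mutual exclusivity of the two candidate lists is structural (criterion 1), and
the lists nest monotonically as `final_required_reps` varies.

## Interaction score

The score is a two-component Poisson posterior, deliberately simple and fully
specified rather than a reproduction of SAINTexpress (whose options and
internals are not part of this package's contract; exported bait/prey/
interaction files keep interoperability with the real tool, and numeric
agreement with it is expressly not a goal — the two approaches are expected to
disagree on real data). Background rate λ₀ = pooled control mean + 0.5
pseudocount (avoids a zero rate); foreground λ₁ = bait-replicate mean floored
at λ₀ (depletion is never evidence for interaction); prior 0.5. The posterior
is computed **jointly over replicates** (product of likelihoods). An earlier
formulation averaging per-replicate posteriors was rejected because it is not
monotone when bait counts rise unevenly: the shared λ₁ grows with the mean and
can collapse the likelihood ratio of a still-low replicate faster than the
high replicates gain, so adding spectra could lower the score. The joint
log-likelihood ratio is `−n(λ₁−λ₀) + T·log(λ₁/λ₀)` with `T` the count total,
which is nondecreasing in `T`; monotonicity and permutation symmetry are
therefore exact, and both are property-tested. Tier thresholds are 0.6 / 0.9 /
0.99 and tier lists nest by construction.

## Synthetic data: what it emulates, what it does not

`generate_interactome` plants six protein classes. Compatibility is
structural: vWA-specific preys can be labeled only by the full-length and vWA
constructs; non-vWA and heterodimer-mediated preys only by full-length and
ΔvWA (the deletion construct retains the heterodimerization surface); shared
background and keratins by every line including controls; carboxylases are
detected everywhere with probability 1. Defaults state the study-scale world:
11 vWA-class and 7 ΔvWA-class interactors (4 direct + 3 heterodimer-mediated),
100 background proteins, 20 keratins, 5 carboxylases; per-replicate detection
probability 0.85 for specific interactors (real screens lose candidates to
the all-replicates criterion, and so does the simulation), 0.7 for background
(so most background crosses the ≥ 2-replicate control threshold and is
subtracted), 0.2 for keratins (sporadic sample-prep contamination, which is
why the explicit keratin filter exists at all); spectral-count means 10 / 5 /
2 / 20 for specific / background / keratin / carboxylase preys. Counts are
zero-truncated Poisson given detection — adequate for testing scoring
monotonicity, but real spectral counts are overdispersed and
abundance-correlated, so a green scoring test establishes ordering behaviour,
not calibrated error rates. Scripted proteins with fixed per-line replicate
patterns support deterministic edge cases (e.g. the 1-parental + 3-NLS
background pattern).

Synthetic images render non-overlapping bright nuclear disks and small PLA
focus disks placed fully inside their parent nucleus (per-nucleus counts
Poisson, default mean 5), optional extranuclear foci and additive Gaussian
noise, 8-bit. Planted foci are kept separated so each remains one connected
component — real PLA foci can merge optically, and merged components count
once (documented behaviour of the detector), but the noiseless recovery tests
require unambiguous truth. The generator does not emulate uneven
illumination, out-of-focus light, nucleus clumping or 3-D structure; exact
recovery on these images validates the measurement code, not robustness to
real microscopy artefacts.

One global seed feeds independent child streams for tables and images;
identical seeds give bit-identical artefacts.

## Image quantification choices

Thresholds default to Otsu's method per channel (a flat image yields an empty
mask rather than an error); fixed thresholds are accepted for
reproducibility. Size gates are in pixels — published ImageJ workflows state
them in calibrated units whose conversion is instrument-specific — with
defaults (nucleus ≥ 100 px, focus ≥ 4 px) preserving the roughly
order-of-magnitude nucleus:focus area ratio; a pixels-per-unit conversion can
be applied by the caller. Focus-to-nucleus assignment uses centroid
containment (deterministic and boundary-stable; masks-merging conventions
differ between tools). Border-touching nuclei and foci are kept. Per-nucleus
summaries use the t-distribution interval (95% default); a zero-variance
sample gets a zero-width interval. Welch's test delegates to
`scipy.stats.ttest_ind(equal_var=False)` with the degenerate both-constant,
equal-means case returning p = 1 by convention; an independent textbook
Satterthwaite computation is kept in the test suite as the cross-check. Mean
nuclear intensity is the **mean of per-nucleus means** (not pixel-pooled, so
large nuclei do not dominate), minus a caller-supplied background estimated
from a negative-control line, floored at 0, on the 0–255 scale.

## Known limitations

- Gene-name set logic inherits upstream identifier hygiene; no accession-level
  disambiguation beyond best-evidence collapse.
- The score is uncalibrated as a probability of physical interaction; tiers
  are operating points, not FDR estimates.
- Image quantification is strictly 2-D single-channel-pair; no deconvolution,
  illumination correction or colocalization beyond focus counting.
- Headline candidate counts from any specific published screen depend on the
  raw-data reprocessing stack (search engine, database release) and are not
  desk-reproducible; the test suite therefore validates arithmetic identities,
  closed-form statistics and planted-truth recovery instead.
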