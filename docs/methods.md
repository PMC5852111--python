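# Methods

## The analysis model

The pipeline analyses an isobaric-reporter (iTRAQ 4-plex) time-course
design: within each biological replicate set, one labelled sample per
time point (channels 114, 115, 116 for 0, 3, 6 h of cold treatment) is
pooled and measured together, so reporter-ion intensities within a PSM
are directly comparable and the ratios 115/114 and 116/114 estimate
relative abundance change. Two genotypes are processed independently
and compared only at the level of their differential calls, which is
why the protein-ID space must be shared.

Assumptions inherited from this design:

- reporter intensities are multiplicative (log-normal) in peptide
  abundance, so ratios are analysed on the log2 scale;
- within a replicate set, channel effects other than the biological
  time-point effect cancel in the ratio (no isotope-impurity or
  ratio-compression correction is attempted);
- biological replicate sets are exchangeable, so replicate-to-replicate
  scatter of protein ratios estimates the null variation against which
  fold changes are judged.

## Stage-by-stage procedure and parameters

**Identification.** The FDR at a score threshold is estimated as
(decoy PSMs passing)/(target PSMs passing) — the direct estimator of
the false-target fraction; the doubled-count dialect 2D/(T+D) is not
used. Filtering is per (genotype, replicate set): among thresholds at
or above the score floor (`min_score`, default 20), the smallest
distinct observed score whose FDR estimate is ≤ `max_fdr` (default
0.02) is chosen, PSMs with score exactly equal to the cutoff are
retained, and decoys are then removed. Peptides matching more than one
protein are discarded entirely; a protein is confidently identified in
a set when it retains ≥ `min_unique_peptides` (default 2) distinct
peptides there.

**Quantitation.** Per PSM, ratios r115 = i115/i114 and r116 =
i116/i114 (a zero reference channel marks the PSM unquantifiable and
drops it). Protein ratios per replicate set are weighted averages in
linear ratio space with weight = summed reporter intensity of the PSM
(i114+i115+i116); unweighted averaging is available. Optional
median-centring of log2 ratios per set is off by default, matching a
workflow that reports raw channel ratios. Replicate concordance is the
OLS slope (free intercept) of log2 ratios between set pairs.

**Internal-error cutoff.** For proteins quantified in two sets i, j,
the internal error is |log2 r_i − log2 r_j|; each set pair is averaged
over proteins and `d_log2` is the mean over pairs (symmetric in sets,
invariant to a common additive shift). The fold cutoff is exactly
2^d_log2. The *applied* calling criterion defaults to a 1.4-fold
change (d_log2 = log2 1.4 ≈ 0.485): that is the published convention
this class of analysis uses, derived once from wet-lab replicate error
near 0.48 log2 units. On synthetic data the derived d_log2 is far
smaller (≈ 0.06 at the default noise level) because the generator
contains no sample-handling or search-engine variation; calling with
such a cutoff would let the fold filter degenerate and leave the raw
p ≤ 0.05 test as the only guard, so the derived value is reported in
the QC output while calling uses the fixed 1.4 unless
`use_derived_cutoff` is set.

**Differential test.** Two-sided, equal-variance two-sample t-test of
log2 channel sums across the n = 3 replicate sets, 0 h channel versus
the 3 h (or 6 h) channel. Degenerate zero-variance groups return p = 1
when the means agree and the p → 0 limit otherwise. The alternative
formulation (testing log2 ratios against a null of 1) exists for
sensitivity analyses; the intensity-versus-intensity form is default.
No multiple-testing correction is applied by default (the criterion is
a raw p ≤ 0.05 joint with the fold cutoff); Benjamini–Hochberg
adjustment is available.

**Transmembrane consensus.** Three predictors of distinct families:

- *hydropathy*: mean Kyte–Doolittle over a sliding window of 19
  (threshold 1.6, the stringent transmembrane setting); maximal runs of
  above-threshold window centres are extended by (window−1)/2 on each
  side, merged when separated by < 3 residues, and reported when ≥ 15
  residues;
- *dg_scale*: the same machinery on windowed sums of per-residue
  apparent insertion free energies (biological/translocon scale),
  seeding where ΔG ≤ 0 kcal/mol;
- *hmm*: a topology HMM with inside-loop, outside-loop, and a helix
  macro-state expanded into a chain of `min_helix_len` duplicated
  states so decoded helices have a minimum length. Emissions are
  hand-set (helix ∝ exp(0.5·hydropathy), loops uniform), transitions
  hand-set (loop→helix 0.015, helix exit 0.15); the model is not
  trained, which keeps it fully specified and lets tests verify the
  Viterbi decoder against exhaustive path enumeration.

A protein is a membrane protein when ≥ 2 of the 3 predictors report at
least one segment ("predicted by" is interpreted as ≥ 1 segment; the
predictors emit no separate membrane verdict). Coordinates are 1-based
inclusive.

**DAMP calling and accounting.** Only consensus membrane proteins
quantified in all replicate sets are eligible. Per time point the fold
is the arithmetic mean of the per-set weighted ratios; up if fold ≥
cutoff and p ≤ 0.05, down if fold ≤ 1/cutoff, thresholds inclusive.
Cross-genotype overlap tables count, per time point and direction,
totals, uniques (total − common), common calls (same protein **and**
same direction; ID-only matching is an option), and the common
percentage over the union, rounded to the nearest integer (ties away
from zero). Category tabulation is multi-label with an "unannotated"
bucket; enrichment is the one-sided hypergeometric upper tail.

**MRM design.** Trypsin cleaves C-terminal to K/R except before P;
with m allowed missed cleavages all concatenations of ≤ m+1 adjacent
fragments are emitted. Peptide and fragment m/z use standard
monoisotopic masses; b/y complementarity (b_i + y_{n−i} − 2·proton =
neutral mass) holds identically. Assay peptides are 7–25 residues,
Cys/Met-free, proteotypic within the supplied proteome, ranked by
closeness of length to 12 (ties lexicographic); per peptide the three
highest-m/z singly charged y ions above the doubly charged precursor
m/z are chosen (falling back to the highest-m/z y ions). Instrument-
driven empirical refinement of product ions cannot be reproduced
without spectra, so this deterministic rule stands in and the selector
reports shortfalls (< 3 eligible peptides) instead of failing.

**Auxiliary.** Peroxidase activity is reported as U per mg protein
with 1 U = 0.01 absorbance increase per minute; negative absorbance
slopes clamp to zero with a warning. (The unit definition is quoted at
a different wavelength than the guaiacol assay it accompanies in the
source protocol; the formula is implemented as written.)

## What the generator emulates — and what it does not

The generator plants: 17–25-residue transmembrane segments drawn from
a Leu/Ile/Val/Phe/Ala/Met-enriched composition inside polar loops;
soluble proteins guaranteed to contain no 9-residue run with mean
hydropathy above the predictors' threshold; per-protein log-normal
baselines (log2 mean 20, sd 2, a typical reporter dynamic range);
per-peptide ionisation offsets (sd 1 log2) so the weighted average is
non-trivial; 1–3 PSMs per peptide per set; independent log-normal
channel noise (sd `noise_sd_log2`, default 0.15); planted log2 effects
(default ±1, i.e. 2-fold, on 10% of membrane proteins, same effect at
3 h and 6 h); decoys from reversed sequences with Gaussian scores
(targets N(40, 10), decoys N(12, 5) — overlapping enough that the
adaptive FDR cutoff does real work); and optional protein dropout per
replicate set (default 0; 0.13 reproduces a ~66% triple-replicate
overlap via p³/(1−(1−p)³)).

It does **not** emulate: spectrum-level structure (peaks, isotope
envelopes, co-isolation and the resulting ratio compression),
retention time, peptide detectability, shared peptides between
homologues, search-engine score/abundance correlation, or
between-channel loading bias. Consequently, passing the planted-truth
recovery bounds (sensitivity ≥ 0.8, false-discovery proportion ≤ 0.1,
null positive fraction ≤ 0.05) demonstrates that the *inference
machinery* is correct and calibrated under the stated noise model — it
does not certify performance on real spectra, where ratio compression
and peptide-level missingness dominate.

## Numerical and design choices

- FDR dialect D/T, chosen for direct interpretability and monotonicity;
  the estimator is scale-free in the scores.
- Window-predictor seeds use strict `>` for hydropathy and inclusive
  `≤` for ΔG (each threshold's conventional direction); segment merging
  uses a gap of < 3 residues.
- Viterbi runs in log space; impossible transitions are −inf and ties
  resolve to the lowest state index via argmax.
- The fold cutoff is stored as d_log2 and exponentiated on demand, so
  fold = 2^d round-trips through log2 to machine precision.
- Percentage rounding in printed tables is nearest-integer, ties away
  from zero; fractional checkpoints (membrane fraction) are rounded to
  one decimal.
- Degenerate inputs are contracts, not silent NaNs: empty ratio lists,
  sub-minimum group sizes, zero reference channels, wrong consensus
  arity, and empty enrichment backgrounds all raise (or return the
  documented sentinel).

## Problem sizes

The test suite and the acceptance script run the full study at 1,000
proteins per genotype (~10⁵ PSM rows per genotype), the null
simulation at 400 proteins, the dropout scenario at 600, and unit
fixtures at 25–300 proteins; these sizes give stable stochastic checks
(planted-effect counts ≥ 30) while keeping a full run in the tens of
seconds on one CPU.

## Known limitations

- The three predictors are of the same *families* as the external
  programs commonly combined for membrane-proteome filtering, not
  re-implementations of them; absolute membrane-protein yields on real
  proteomes will differ. Signal peptides and topology orientation are
  out of scope.
- The derived internal-error cutoff reflects only simulated noise (see
  above); with real data it is the quantity of interest.
- "Common" DAMP accounting assumes a shared protein-ID space between
  genotypes; cross-species comparisons would need an orthology map.
- The t-test with n = 3 per group has limited power at small effects;
  the planted-truth bounds are evaluated at 2-fold effects.
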