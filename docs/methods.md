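# Methods

This note documents the models and procedures implemented in `scatyper`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a user auditing results
should know about.

## T-RFLP profile normalization

Capillary loading differs between runs, so raw peak heights (RFU) are not
comparable across samples. Normalization is a single pass: (1) total
fluorescence per sample trace; (2) the smallest total is the reference;
(3) each trace's heights are scaled by reference/own-total; (4) scaled
peaks below the detection cutoff (default 25 RFU, the theoretical limit of
detection of the instrument class) are removed; (5) relative peak heights
are computed against the post-removal totals. There is no iteration after
peak removal — re-scaling after the cutoff would change which peaks pass
it and make the procedure order-dependent. Peak *height* (not area) is the
abundance proxy throughout. Samples with zero total fluorescence are
excluded and reported, not errored.

Fragments are aligned across samples by fixed-width binning
([k·w, (k+1)·w), floor convention, default w = 1.0 bp — the size-call
resolution of capillary sequencers). Each enzyme is analyzed separately
(its two dye channels — forward- and reverse-labeled ends — enter one
matrix as dye-qualified bins); rows are renormalized to the simplex after
binning.

## Community statistics

* **Square-root transform** before dissimilarity, to damp dominant
  fragments; applied element-wise with no re-normalization.
* **Bray-Curtis** d(i,j) = Σₖ|xᵢₖ−xⱼₖ| / Σₖ(xᵢₖ+xⱼₖ) ∈ [0,1]. A pair of
  all-zero rows is defined as d = 0 with a warning (it is a degenerate
  input, not an error).
* **NMDS** minimizes Kruskal stress-1,
  √(Σ(d̂−d*)² / Σd̂²), where d̂ are configuration distances and d* their
  isotonic (pool-adjacent-violators) regression on the rank order of the
  observed dissimilarities. Each start alternates the isotonic fit with a
  Guttman-transform update; iteration stops when the stress improvement
  falls below 1e-6 (max 300 iterations), or immediately if stress would
  rise, so the recorded trajectory is non-increasing. Default 200 random
  starts, seeded; best start wins; coordinates are centered. Two
  dimensions by default. Stress near zero is expected only for
  configurations that embed exactly in the plane.
* **ANOSIM** ranks all n(n−1)/2 dissimilarities (average ranks on ties,
  Clarke's formulation) and computes R = (r̄_between − r̄_within)/(M/2),
  bounded by [−1, 1]; negative R means more variation within than between
  groups. The p-value enumerates all distinct relabelings exactly whenever
  their count is ≤ the requested permutation number (for 12 samples in two
  groups of six, C(12,6) = 924 ≤ 999, so the 12-sample weekly designs are
  always exact); otherwise it samples relabelings with the +1 correction
  p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm), which guarantees p ≥ 1/(n+1).
  Pairwise mode re-runs each level pair on the filtered matrix; pairwise
  p-values are reported raw (no multiple-testing correction), matching the
  conventional presentation of such tables.
* **SIMPER** decomposes the average between-group Bray-Curtis
  dissimilarity: for every between-group sample pair,
  cₖ(i,j) = |xᵢₖ−xⱼₖ| / Σₘ(xᵢₘ+xⱼₘ); per-feature means sum exactly to the
  average dissimilarity (checked to 1e-9), percents to 100. Two identical
  groups give a flagged degenerate result rather than NaN percents.

Permutation defaults follow the two marker surveys: 10,000 for 16S,
999 for scaC.

## Clone typing

Clones are trimmed to their longest open reading frame (start codon ATG by
default; GTG/TTG can be enabled) across the three forward frames, ending
at the codon before a stop or the in-frame sequence end; records without
an ORF of ≥ 60 nt are rejected with a reason, not an exception.

Pairwise identity comes from a global alignment (match +1, mismatch −1,
affine gaps: open −5, extend −2). Identity = matching columns / alignment
columns, excluding columns inside leading/trailing gap runs, because
trimmed clones have ragged ends that should not count against identity.
End-gap runs *extend* at −0.5 (opening still costs −5): with uniform
penalties the overhang alignment of a truncated clone against its
full-length founder is only co-optimal with alignments that scatter the
gaps, and an arbitrary co-optimal pick can collapse the measured identity.
The cheaper terminal extension makes the contiguous-overhang alignment the
unique optimum without affecting same-length comparisons. Identity is
computed on nucleotides by default; a protein mode (BLOSUM62) exists
because typing at an amino-acid threshold is a recognized variant.

Binning is greedy and order-dependent by design (the FastGroup dialect):
records are processed in input order, each compared against bin *founders*
in bin-creation order, joining the first bin whose founder identity meets
the threshold, else founding a new bin named by its own id. This is
deterministic for a fixed input order; a seeded shuffle can be applied
externally for order-sensitivity analysis. The sweep runs the same input
order at every threshold with a shared identity cache. A
best-match-instead-of-first-match dialect would change bin contents only
when a record clears the threshold for multiple founders; at the default
70% threshold on well-separated types the two dialects agree.

**Diversity.** Chao1 = S_obs + F1²/(2F2) (classic), falling back to the
bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when F2 = 0; both forms are
reported side by side in the sweep table since the choice is a known
source of small discrepancies between tools. Shannon–Wiener uses the
natural log (base 2 optional). Rarefaction is the analytic expectation
E[Sₙ] = Σᵢ[1 − C(N−nᵢ,n)/C(N,n)] via log-gamma, stable for large N.

**Universal types.** A type is universal iff observed in at least one
clone from every animal present in the metadata. The summary reports
per-type × per-animal counts (bin-creation order), the universal list,
each animal's share of clones in universal types, and count tables by
week/hour/fraction.

## Dockerin motif detection

Dockerin modules are ~70-residue modules containing a duplicated ~22-residue
repeat. Detection scans all pairs of 22-residue windows whose start-to-start
spacing lies in 22–48 residues (both repeats inside ≈70 residues; the
lower bound forbids overlap) and scores each pair by summed BLOSUM62
similarity. The default acceptance score of 30 corresponds roughly to a
22-mer pair with ~40% identical positions (≈9 diagonal hits at ~+5 minus
~13 off-diagonal at ~−1); shuffle-null testing shows <5% false positives
at this threshold. The best-scoring qualifying pair is reported with both
intervals; proteins too short for two spaced repeats return an explicit
too-short marker. Conservation profiling consumes an existing multiple
alignment (it never computes one): per column, the frequency of the modal
non-gap residue among non-gap rows; all-gap columns are undefined (NaN)
and excluded from region means.

## Synthetic-data generator

The generator defines the conditions under which the pipelines are tested.

* **Design**: the full crossing 3 animals (8, 64, 71) × 3 weeks (2, 5, 8)
  × 2 hours post-feed (1, 9) × 2 fractions (fiber-adherent, liquid) = 36
  samples.
* **Abundances**: a geometric series over K types (decay 0.7, giving the
  observed kind of dominance where one type holds ~30% of a community),
  perturbed multiplicatively and renormalized. Fraction enrichment:
  per-type log-fold factors ~ N(0, 2.5), applied as exp(±b/2) in
  fiber/liquid — calibrated so the fiber/liquid ANOSIM separation matches
  the strong fraction effects seen in real scaC fingerprint surveys
  (mean R ≈ 0.6–0.7). Week succession: per-type log-multipliers
  ~ N(0, 0.5) per week step. Animal individuality: per-animal gamma
  factors (shape = rate = 5). No hour effect is simulated, consistent with
  hour explaining essentially nothing in the motivating surveys.
* **Sequences**: one base amplicon flanked by the scaC primer pair
  (ScaFwd 5'-AGACARGRTATAATHAAAGGGGC, ScaRev 5'-GGGTTTKTATTCCTTTGTAAG;
  NED/6FAM labels), containing a single ORF: ATG + cohesin codons +
  22-codon dockerin repeat 1 (together the conserved span), then a
  10-codon linker + repeat 2 (initially an exact duplicate of repeat 1) +
  an 80-codon tail (together the variable span). Types are derived by
  per-site substitution at rate 0.5 in the variable span and rate/10
  elsewhere (primers never mutate). Substitution is codon-aware: the start
  and stop codons are preserved and internal stops are repaired, because
  diverged strains of a real gene remain coding — without this, ORF
  trimming fragments the library. Every other codon of repeat 2 is an
  anchor mutating at the low rate, mimicking the conserved dockerin
  consensus residues that keep the second repeat recognizable despite its
  divergence. These proportions put distinct types at ~50–64% pairwise
  nucleotide identity (well below a 70% typing threshold, reproducing the
  sigmoidal sweep with its 90–60% plateau) while the conserved region
  stays >95% identical.
* **Clones**: multinomial draws per sample at the requested depth;
  per-site substitution errors at 0.002 (≈1 error per clone), primer sites
  protected; clone ids encode the sample id.
* **Peaks**: per enzyme, each type contributes one peak per dye channel at
  its predicted TRF ± Gaussian jitter (sd 0.3 bp), height = abundance ×
  total fluorescence (default 50,000 RFU) × lognormal noise (sd 0.3),
  rounded to positive integers; spurious near-baseline peaks at a Poisson
  rate of 5 per trace.
* **Reference library**: random 16S-like records carrying the 8F/926R
  primer sites with Greengenes-style taxonomy strings, for exercising the
  assignment step.

Randomness: every operation is a pure function of its arguments including
the seed; named substreams per operation prevent cross-coupling.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no chimeras, no indels (substitutions only), no
chromatogram-level artifacts (pull-up, stutter, size-call bias), no PCR
primer bias or copy-number variation, no phylogenetic correlation between
types beyond the shared base sequence, and real dockerin divergence is
position-structured rather than i.i.d. Results on synthetic data
demonstrate correctness of the computations, not robustness to every
wet-lab artifact.

## Problem sizes used in tests and the acceptance script

The synthetic study uses K = 20 types, 17 clones × 36 samples (~600
clones) and the 4-enzyme scaC panel — large enough for stable permutation
statistics and sweep structure while keeping full runs in tens of seconds.
The ANOSIM null calibration uses 1000 replicate 12-sample datasets; the
power check 25–30 replicate communities; NMDS checks use 8–20 starts
(production default 200). The exact-recovery checks (pure bins, universal
set, per-sample proportions) run the noise-free generator, where the
pipeline must reproduce the sampled truth exactly.

## Known limitations

* The greedy binning dialect is one of several in circulation; counts at
  high thresholds (99%) are sensitive to input order and to the identity
  formula's gap treatment. The sweep table is the place to compare
  dialects, not single thresholds.
* NMDS is a local optimizer; with few points and many ties the reported
  stress depends on the start set. The exact-zero stress sometimes quoted
  for 12-point ordinations is not reproducible in general and is not a
  target.
* PAT-style assignment reports all taxa within tolerance (ambiguity is
  preserved); it does not attempt abundance-weighted deconvolution.
* Chao1 is a lower-bound-style estimator; with few doubletons its variance
  is large, and the classic and bias-corrected forms can differ
  noticeably (both are reported).
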