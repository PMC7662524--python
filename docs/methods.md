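# Methods

This note documents the models implemented in `tfdissect`, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Selection simulator

One round of restriction-protection selection is modelled per
molecule. A cassette `s` has a best site score `S(s)` — the maximum
log2-odds of the motif PWM over all offsets on both strands — and a
dissociation constant

    KD(s) = KD_ref · exp(ε · (S_max − S(s))),

where `S_max` is the consensus score, `KD_ref` the consensus KD
(default 2.214 nM, the measured consensus affinity) and `ε` the
energy scale in kT per log2 unit (default 1). Occupancy at protein
concentration `[P]` (default 50.6 nM, the selection condition) is
`[P]/([P]+KD)`, and survival of one cleavage challenge is

    p_survive = occupancy + (1 − occupancy) · (1 − efficiency),

with per-enzyme cleavage efficiency (defaults: enzyme A 0.95, the
replacement enzyme B 0.8 — the replacement is deliberately less
efficient). A configurable fraction of molecules (default 0) is
intrinsically resistant to enzyme A, emulating selection of
cleavage-resistant artifacts; switching the round schedule to enzyme
B purges them. Survivors are resampled to pool size with a uniform
multinomial (no PCR bias; a bias hook would slot into the resampling
weights). The "motif-bearing fraction" reported as ground truth
counts cassettes with `KD(s) ≤ 10 · KD_ref`; the factor 10 is a
reporting convention only.

Desk-scale caveat: a simulated pool holds 10³–10⁴ molecules, not the
~6×10¹⁰ of a real selection, so a 16-bp motif has no true sites in a
random pool at this scale. Selection-dynamics tests therefore use a
short (6-bp) motif, while motif-discovery tests plant 16-mer
instances directly at a stated frequency (`planted_read_pool`). A
green selection test demonstrates the dynamics (enrichment
monotonicity, contaminant sweep and purge), not 16-mer recovery from
selection alone.

## Read preparation

Reads are fixed-architecture amplicons, so cassette recovery is
Hamming-distance matching of both primer arms (no indels; default
max 1 mismatch per arm) with reverse-complement orientation rescue.
Deduplication defaults to exact string identity; `strand_collapsed`
identifies a cassette with its reverse complement (the cassette is
double-stranded and sequencing orientation arbitrary), keeping the
lexicographically smaller representative. Subsampling (default
practice: 1000 reads into discovery) is uniform without replacement.
Deduplication precedes subsampling. Optional mean-quality filtering
exists but is off by default.

## Motif discovery

ZOOPS likelihood: sequence `i` of length `L` contains, with prior γ,
one motif instance at a position uniform over `L−w+1` offsets and (in
both-strand mode) 2 strands, else is background. Background base
frequencies are estimated from the input (add-one smoothed). The
E-step computes exact posteriors over (no site) ∪ (strand, offset);
the M-step re-estimates column probabilities from posterior-weighted
counts with pseudocount 0.25 per base per column, and γ from the mean
site posterior. Under the palindromic constraint the weighted counts
are symmetrized with their reverse complement before normalization —
this is the exact constrained M-step, so the EM likelihood is
non-decreasing (asserted in tests to 1e−8). Convergence: likelihood
gain < 1e−6 nats or 200 iterations. Multi-start: `n_starts` seed
w-mers drawn from the data (softened to 0.7/0.1 probabilities); each
start is screened with 8 EM iterations and only the best is run to
convergence, the standard economy of EM motif finders.

Width selection. For each width the converged model's low-information
flanking columns (information content < 0.2 bits against the
background) are trimmed — symmetric for palindromic motifs since the
IC profile is symmetric — and the trimmed model briefly re-refined.
Candidates are then ranked by E-value. Without the trim, overwide
candidates that wrap the true motif in near-background columns win
marginal E-value improvements; with it, all overwide widths collapse
onto the true width and the comparison is meaningful.

E-value. Defined as (number of possible placements) × P(total site
log-likelihood ratio ≥ observed | background). The observed statistic
is the posterior-expected sum of site scores; the tail is bounded by
the large-deviation (Chernoff) rate `inf_λ [n·log M(λ) − λT]`, with
the moment generating function computed from the exact quantized
per-site score distribution (granularity 5e−3 log2 units here; the
DP is shared with the scanner). The bound is linear in site count at
fixed per-site score, which matches how selection-scale E-values
(10^−2000 and beyond) behave; only orderings and monotonicity are
asserted, never a printed E-value, since the reference tool's exact
E-value machinery is not reproduced.

Consensus notation. Columns render as: dominant base (≥ 0.75)
uppercase; strong two-base columns as `(X/y)` (pair sum ≥ 0.75,
second ≥ 0.20; a partner is uppercase iff its own probability ≥ 0.5);
top below 0.40 as `N`; otherwise the minimal IUPAC code over bases
≥ 0.20. The thresholds are package decisions calibrated once so that
a sharply learned PWM renders as the plain uppercase consensus; they
are configurable via `ConsensusSpec`.

## Genome scanning

Column log2-odds are quantized to 1/1000 log2 units (configurable);
the pmf of the total quantized score under the background is the
convolution of per-column 4-point pmfs, and the p-value of a score is
the right tail at its quantized value. Quantization error on any
score is ≤ w·g/2; the enumeration oracle in the tests bounds the
implementation exactly. Windows containing ambiguous bases are
skipped. Both strands are scanned; for a palindromic PWM the strands
duplicate each locus and the scanner keeps one record with the
forward-strand representation. q-values are BH over all tested
windows of all scanned strands. Coordinates are 1-based inclusive
throughout; the BED writer converts to 0-based half-open.

Annotation. For each hit, the nearest gene by |TSS-relative location|
on each strand within 1000 bp (beyond that a hit is an orphan) gets
one annotation — a site between divergent genes is annotated once per
flanking gene. The location `loc` is signed in the gene's reading
direction (negative upstream) and anchored at the hit edge nearest
the TSS; when a hit spans the TSS the upstream edge is used, so
spanning hits report `loc ≤ 0`. Which nucleotide of a site anchors a
printed location is not defined in the source material; this
proximal-edge convention is isolated in `tss_relative_location`.
Promoter classes are assigned from interval overlap against a gene's
−35/−10/+1 elements with precedence overlap > upstream-of-−35 >
downstream-of-−10; the elements are consumed as a data track (the
output of an external promoter predictor), never computed. A hit is
`proximal` in the −200..+20 window (boundary inclusive) and
`candidate_regulated` when additionally its gene is first-of-operon
("1/n") or a single transcriptional unit ("S").

## Kinetics

The 1:1 Langmuir model with shared kon, koff, Rmax across all
concentrations of a titration (default concentrations 17/50/150/450
nM). Fitting parametrizes (log kon, log koff, Rmax) and minimizes
summed squared residuals over all curves jointly (trust-region least
squares), started from a deterministic 5×5 log-spaced grid, kon ∈
10³..10⁷ M⁻¹s⁻¹, koff ∈ 10⁻⁵..10⁻¹ s⁻¹ — no randomness anywhere in
fitting. R² is pooled over every point of every curve (1 − SS_res /
SS_tot). The noise scale is estimated from first differences of the
traces (sd/√2); a probe whose largest response is below 3× that
scale is reported as non-binding with no rate estimates. `KD =
koff/kon` holds as an exact field identity on every converged fit.
Simulator phase durations default to 300 s association / 300 s
dissociation at 1 s sampling; the real step durations are not
published, and the defaults are configurable. Mass-transport
limitation, drift and reference-channel subtraction are out of scope.

## Expression comparison

logFC = mean(test) − mean(control) on the log2 scale; p-values from
the two-sided Welch (unequal-variance) t-test; BH adjustment shared
with the scanner. The reference analysis used a moderated
(empirical-Bayes) t; with n = 3 per group the unmoderated test is
slightly conservative and its p-values differ, so published per-gene
p-values are not comparison surfaces — only recovery of planted
effects on synthetic data is. Zero-variance, equal-mean genes get
p = 1 by convention. Input is assumed already log2-scale. Operon
summaries report member count, median logFC, direction (up iff
median > 0) and the fraction of members with adj p < 0.05; the
affected-gene report partitions by |logFC| ≥ 1 and adj p ≤ 0.05 by
default.

The expression generator plants fixed log2 effects on group means
with i.i.d. Gaussian noise (default sd 0.2, 3 vs 3). It does not
emulate probe-level effects, normalization artifacts, correlated
noise, or intensity-dependent variance of real microarrays, so a
green recovery test establishes estimator correctness, not platform
robustness.

## Pipeline

Stages hand off through plain files (FASTA / MEME-minimal / TSV /
CSV / JSON) in the output directory; the manifest records per-stage
parameters and SHA-256 output hashes, and identical config + seed
reproduce identical hashes. The demo configuration is scaled down
(hundreds of reads, narrowed width range) to run in seconds; the
full-scale discovery setting (1000 reads, widths 6–24, 10 starts) is
exercised by the acceptance checks.

## Known limitations

- Selection and discovery scales are desk-scale; nothing here models
  sequencing error, indels, or amplification bias.
- The E-value is a Chernoff-bound approximation: comparable within a
  run, not calibrated against any external tool's E-values.
- BH q-values for genome scans depend on the number of tested
  windows; values from scans of different genomes are not comparable.
- The annotation edge convention for `loc` is a declared choice; an
  alternative (site center or distal edge) would shift locations by
  up to the motif width.
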