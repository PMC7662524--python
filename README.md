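# tfdissect

Determination and dissection of a transcription factor's DNA-binding
specificity, built as a reusable, fully tested pipeline. The study
system is TTHB099, a CRP-family regulator from the thermophilic
bacterium *Thermus thermophilus* HB8 that binds a palindromic 16-bp
site (consensus `TGTATTCTAGAATACA`) as a homodimer, with nanomolar
affinity and no requirement for cAMP.

The pipeline covers five stages, each an importable module under
`src/tfdissect/` with a thin narrative driver under `analysis/`:

1. **Iterative selection** (`simulate`, `readprep`) — REPSA/SELEX-style
   rounds of bind → type IIS restriction cleavage → amplification over a
   randomized 24-bp cassette library, including the cleavage-resistant
   contaminant that sweeps the pool until the endonuclease is switched;
   cassette extraction and deduplication from raw selection reads.
2. **Motif discovery** (`discovery`, `pwm`) — ZOOPS
   expectation-maximization over both strands with an optional
   palindromic constraint: the PWM is projected onto the
   self-reverse-complementary subspace after each M-step, which is the
   constrained maximum-likelihood update, so the likelihood ascent
   guarantee survives. Candidate widths 6–24 are compared by an
   E-value after trimming uninformative flanking columns.
3. **Genome scanning** (`scan`) — exact PWM p-values by the
   quantized-score dynamic program used by FIMO-style scanners
   (column score pmfs convolved under the background model),
   Benjamini–Hochberg q-values over all tested windows, palindromic
   hit merging, and annotation of each hit against TSS, operon and
   core-promoter tracks: signed TSS-relative location, the
   activator-typical −200..+20 proximal window, and promoter-overlap
   classes (Class II-like core overlap, Class I-like upstream of −35,
   downstream of −10).
4. **Binding kinetics** (`kinetics`) — global 1:1 Langmuir fitting of
   biolayer-interferometry sensorgrams across analyte concentrations
   with shared kon, koff, Rmax (association
   `R(t) = Rmax·C/(C+K_D)·(1−e^{−(kon·C+koff)t})`, dissociation
   `R = R_end·e^{−koff·t}`, `K_D = koff/kon`), no-binding detection,
   and mutational-dissection fold-change tables.
5. **Expression comparison** (`expression`) — Welch-t differential
   expression for small-n two-group log2 designs with BH correction,
   operon-level aggregation and affected-gene partitioning.

Every stage's inputs can be generated synthetically with known ground
truth (`simulate`), so the whole pipeline is testable offline.

## Worked example

```
python analysis/01_simulate_selection.py --seed 0
python analysis/02_discover_motif.py --seed 0
```

The first script prints the selection trajectory (desk-scale pool,
short motif so true sites exist among thousands of random cassettes):

```
 round enzyme  motif_bearing_fraction  enzymeA_resistant_fraction
     0  input                 0.00500                     0.00100
     4      A                 0.80825                     0.18150
     7      B                 0.99650                     0.00325
```

Motif-bearing molecules rise from 0.5% to >99% over seven rounds; the
enzyme-A-resistant contaminant grows to 18% under enzyme A and is
purged after the switch to enzyme B. The second script recovers the
planted site from 1000 late-round reads:

```
 palindromic_filter  width        consensus  log10_e_value  expected_sites
               True     16 TGTATTCTAGAATACA        -5687.2           618.0
```

i.e. the best palindromic motif has width 16, its rendered consensus
is exactly the planted site, and the E-value is astronomically better
than background (618 of 1000 reads carry a site, matching the planted
fraction). Scripts 03–05 map the motif onto a synthetic genome and
reproduce the proximal-window site filter (16 of 25 catalogued
annotations retained), round-trip the published kinetic constants
(e.g. consensus K_D = 2.214 nM; the harshest point mutant m2 costs
15-fold in affinity; cAMP leaves binding unchanged), and recover a
planted +2.62 logFC induction in a 3-vs-3 expression design.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates, from scratch, ten independent synthetic late-round read
pools (1000 reads, 60% of cassettes carrying a consensus-model
instance), runs palindromic discovery over widths 6–24 on each, and
writes the modal best-motif width as JSON.

## Layout

```
src/tfdissect/     library: pwm, discovery, scan, kinetics,
                   expression, readprep, simulate, io, pipeline,
                   datasets (+ bundled reference tables in data/)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, assumptions, numerical choices
```
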