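# Methods

## Scope and model

`domforge` re-implements, as a tested library, the desk half of a soil
dissolved-organic-matter (DOM) chemodiversity study: ultrahigh-resolution
negative-ESI FT-ICR-MS peak lists are turned into CHNOS molecular
formulas, binned into van Krevelen biochemical classes, summarized per
sample, compared across conditions as degraded / remaining / produced
inventories, and correlated with soil chemistry and bacterial genus
abundances in a Spearman co-occurrence network.  The emulated design is
a continuous-cropping chronosequence: four conditions (CC1Y, CC3Y, CC5Y,
CC7Y — 1 to 7 years of continuous cropping) with three replicates each.

## Formula assignment

A peak (m/z, intensity, S/N) is retained if S/N >= 4 and m/z lies in the
instrument window 200-1000.  The neutral mass of a singly deprotonated
ion is M = m/z + 1.0072765 Da (electron mass folded into the proton
constant, so the round trip is exact).  Candidates are every composition
C_c H_h O_o N_(0-3) S_(0-1) within +/- `tol_ppm` (default 1.0 ppm — a
15 T instrument is routinely sub-ppm) that passes:

* H/C < 2.4 and O/C < 1.2 (strict);
* DBE = 1 + C − H/2 + N/2 a non-negative integer (even-electron
  neutral); note DBE >= 0 is algebraically the valence bound
  H <= 2C + N + 2, and integrality is the H ≡ N (mod 2) parity rule;
* element caps C <= 60, H <= 122, O <= 40 (sized to cover m/z 1000 with
  margin; configurable).

Enumeration pre-tabulates the (C, O, N, S) lattice sorted by partial
mass and solves H per query, which is exact and fast; the test suite
checks it against an independent exhaustive five-element lattice oracle.
The reported formula is the candidate with the smallest |mass error|;
exact ties break deterministically (fewer N+S, lower DBE, element
order).  Unassigned peaks are kept in the output so assignment rates are
reportable.

Known behaviour worth stating: CHNOS space contains quasi-degenerate
pairs (e.g. exchanging C21H12 for O13S shifts the exact mass by only
~0.13 mDa), so at 1 ppm tolerance a small fraction of heavy formulas is
assigned to a wrong but mass-closer candidate once measurement error
exceeds half the doublet spacing.  With 0.3 ppm (1 s.d.) Gaussian error
this affects ~1-3% of peaks, concentrated at high mass and low H/C; it
is a property of the method, not of this implementation.

## Van Krevelen classification

The seven conventional DOM class boxes in the (O/C, H/C) plane are:
lipids (0-0.3, 1.5-2.0), aliphatic/proteins (0.3-0.67, 1.5-2.2),
lignin/CRAM-like (0.1-0.67, 0.7-1.5), carbohydrates (0.67-1.2, 1.5-2.3),
unsaturated hydrocarbons (0-0.1, 0.5-1.5), condensed aromatics
(0-0.67, 0.1-0.7), tannins (0.67-1.2, 0.5-1.5).  The printed boxes
overlap, and published studies rarely state how the overlap was
resolved, so classification here is **first match wins** in the order
above, with **half-open intervals** [low, high) on both axes so shared
edges belong to the higher box.  Both the boxes and their precedence can
be replaced via a YAML table, letting users replicate other conventions
(e.g. aromaticity-index-based splits).  Formulas outside every box are
`unclassified`; O = 0 formulas are classifiable wherever a box starts at
O/C = 0.

## Chemodiversity accounting

All counting is over unique (C, H, O, N, S) tuples — the finest identity
exact mass resolves (isomers collapse).  Composition percentages are per
sample over unique assigned formulas.  Two-condition comparison is exact
set algebra after unioning replicate inventories within each condition
(a per-replicate mode exists): degraded = only-early, remaining = both,
produced = only-late, with overall percentages of the union and a
three-way split within each class and element group.  Percentages are
kept at full precision internally and rounded only when written
(half-away-from-zero; 2 d.p. for compositions, 1 d.p. for the overall
degraded/remaining/produced split).

## Co-occurrence network

Features are per-sample class percentages, element-group percentages,
chemistry variables, and genus relative abundances.  Every unordered
pair gets a Spearman rank correlation (average ranks on ties).  p-values
use the full permutation null when n <= 9 (enumerated exactly) and the
t-approximation t = rho sqrt((n−2)/(1−rho²)) otherwise; with the default
12 samples the approximation is standard.  Edges with p < 0.05 (raw, as
is conventional in this literature; a Benjamini-Hochberg flag is
provided) are kept with their sign.  Constant features are skipped with
a warning.  The default uses all samples rather than condition means —
the choice is exposed because the two give different networks.

## Synthetic-study generator

The generator is first-class, tested code; its defaults are the study
conditions being emulated, not tuning knobs.

* **Formula populations.**  Per-condition class mixtures interpolate the
  emulated trends linearly: tannins 18.13 -> 13.95%, aliphatic/proteins
  2.73 -> 8.85%, lignin/CRAM 56.83 -> 53.20%, condensed aromatics
  declining, lipids/carbohydrates/unsaturated hydrocarbons rising;
  element-group mixtures have CHON 52.24 -> 46.10%, CHOS 5.81 -> 11.10%,
  CHONS 5.51 -> 8.14%, CHO ~35-36%.  Formulas are rejection-sampled
  strictly inside their class box (margin 0.01 in both ratios, so edge
  conventions cannot flip a truth label), pass the assignment validity
  screen, and have their [M-H]- ion inside the m/z window.  Sampling is
  vectorized; C is drawn uniformly in 6-55, O and H uniformly in the
  box- and parity-feasible range, N in {1,2,3} with weights .5/.3/.2
  when the group requires nitrogen.
* **Shared pools.**  Each (class, group) stratum holds a study-wide pool
  of distinct formulas sized at twice its largest per-sample quota
  (`pool_factor = 2`); every replicate draws its multinomial quota from
  the pools without replacement.  Conditions therefore share inventory,
  producing non-trivial degraded/remaining/produced blocks, while
  mixture differences drive the turnover — the same logic by which real
  chronosequence inventories overlap.
* **Peaks.**  Observed m/z = exact [M-H]- m/z times (1 + e), with e ~
  Normal(0, 0.3 ppm).  Intensities are log-normal; 5% of signal peaks
  get S/N < 4 (testing the filter), the rest S/N in 4.5-60.  5% noise
  peaks are placed uniformly in the window after rejecting any m/z with
  a valid formula within 2 ppm, so "unassignable" has exact ground truth.
* **Chemistry.**  Condition means with Gaussian replicate noise: pH flat
  at 5.60 (sd 0.08); TC 12.5 -> 9.9 g/kg; TN 1.25 -> 0.82 g/kg; OM 21 ->
  14 g/kg; DOC 310 -> 235 -> 275 mg/kg (V-shaped).  C/N is derived per
  sample as TC/TN and rises late because TN falls faster.
* **Genera.**  A panel of named genera plus 16 log-normal fillers,
  column-normalized to relative abundance.  Planted couplings use a
  Gaussian copula: a genus tracks the normal scores of its target
  feature with Pearson parameter r = 2 sin(pi rho_s / 6), which makes
  the *population* Spearman correlation exactly rho_s (copula
  invariance).  Defaults: Methylobacter ~ aliphatic/proteins (+0.95),
  Thiobacillus ~ CHOS (+0.95), wb1-P19 ~ TN (+0.95), Aquabacterium ~
  C/N (+0.90).  Structural absences (e.g. wb1-P19 missing from the two
  late conditions, Aquabacterium from the first) give the presence /
  absence Venn stage real signal and truncate the coupling where a
  detection limit would.

What the generator does **not** emulate: isotopologue patterns, adducts
other than [M-H]-, intensity-dependent mass error, ionization bias,
compositional correlation structure between classes beyond the mixture
constraint, and real taxonomic covariance among genera.  Passing tests
therefore demonstrate correctness of the analysis pipeline under the
stated error model, not instrument-level realism.

## Numerical choices

* Monoisotopic masses: IUPAC/CODATA values, C = 12 exactly, H
  1.00782503207, O 15.99491461956, N 14.0030740048, S 31.97207100,
  proton 1.007276466812.
* Mass-tolerance comparisons are absolute (|Δm| <= M · tol · 1e-6); the
  enumerator and its test oracle use the same inequality.
* Rounding is half-away-from-zero via decimal quantization (so 0.125 ->
  0.13), applied at write time only.
* All randomness flows from one `numpy` Generator seeded by the scenario
  seed; equal config + seed reproduce every output byte-for-byte (the
  pipeline writes no timestamps into its artifact directory).
* Degenerate inputs: empty samples warn and return zero compositions;
  comparing two empty inventories, constant correlation vectors, < 4
  samples, empty Venn partitions, and malformed tables raise explicit
  errors.

## Problem sizes used by the test suite

The default scenario is 4 conditions x 3 replicates x 5000 formulas per
sample.  The acceptance suite runs 50 seeded studies for mixture
recovery, 500 random masses against the exhaustive enumeration oracle,
1000 classification round-trip draws per class, 200 planted-edge power
replicates and ~6000 null pairs at n = 12, and two complete byte-compared
pipeline runs; unit tests use smaller scenarios (120-300 formulas per
sample) chosen to keep each property cheap while leaving every code path
identical.

## Known limitations

* Only [M-H]- singly charged ions; no adducts, no positive mode, no
  isotopic fine structure, no recalibration.
* Class boxes are a convention; results near box edges depend on it.
  The half-open precedence scheme is documented and configurable but is
  still a choice the original vendor workflow may not share.
* Formula-count percentages only (no intensity weighting), matching how
  such inventories are usually reported; a weighted mode is a natural
  extension.
* The t-approximation for Spearman p at n = 12 is slightly liberal in
  the extreme tails; the exact path is available but combinatorially
  limited to n <= 9.
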