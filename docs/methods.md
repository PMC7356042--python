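# Methods

This note records the models, parameter choices and numerical conventions
behind `lipscout`, and what the synthetic benchmarks do and do not
demonstrate.

## Digestion model

Trypsin cleaves C-terminal to K or R except when the next residue is
proline; the trypsin/LysC mixture additionally cleaves after K even before
proline (LysC specificity). A peptide is *fully tryptic* when both termini
conform to the rule or coincide with the protein termini, *semi-tryptic*
when exactly one conforms, *non-tryptic* otherwise. `digest()` enumerates
fully tryptic peptides up to a missed-cleavage budget (default 2, the usual
database-search setting); the zero-missed peptides tile the sequence
exactly, and peptides with `m` missed cleavages are concatenations of
`m + 1` adjacent tiles. The test suite checks the engine against an
independent brute-force oracle that tests every substring of random
sequences for the fully-tryptic predicate.

Coordinates are 1-based inclusive throughout, matching the bracketed span
notation of limited-proteolysis reports (`G-[275-286]-K`); the flanking
letters in that notation are rendered as the peptide's own terminal
residues (the residue span, and hence every computed mass, is identical
under the alternative flanking-residue reading, so only label formatting
depends on this choice). Converters to 0-based half-open coordinates exist
at I/O boundaries only.

## Mass arithmetic

Monoisotopic residue masses, the water mass (18.010565 Da) and the proton
mass (1.007276 Da) are pinned in `lipscout.constants` so every m/z is
bit-reproducible; the suite cross-checks the table against an independent
mass library to 2·10⁻⁴ Da. Carbamidomethylation of cysteine (+57.02146 Da)
is the default fixed modification, reflecting iodoacetamide alkylation.
Oxidation (M) and phosphorylation (S/T) deltas are available for mass
computation but excluded from MRM planning, where unmodified peptides are
the quantification currency. Precursors default to charge 2 — the dominant
charge state for tryptic peptides of 7–25 residues, and the state
consistent with all eight published Q1 values of the CPS1 reference
peptides; charge 3 is an option.

## MRM transition planning

Fragment m/z follows standard b/y arithmetic with modification deltas
carried into the containing fragment; doubly charged products are only
generated for precursors of charge ≥ 3. Because observed fragment
intensities (the usual ranking criterion in spectral-library resources) are
not reproducible offline, the planner ranks transitions by a deterministic
surrogate score: +2 for y-series, +1 for fragment m/z above the precursor
m/z, +0.5 for mid-sequence ordinals (3 ≤ i ≤ n−2); ties break by series
(y first), higher ordinal, lower m/z. This encodes the standard manual
heuristics (y ions survive CID of tryptic peptides better; fragments above
the precursor are cleaner) while making the method export byte-identical
across runs. Default precursor filters: fully tryptic, zero missed
cleavages, length 7–25, m/z 300–1250, three transitions per precursor.
The number of precursors such a planner selects is database- and
detector-independent by construction and is not comparable to counts
obtained from empirical spectral libraries.

## DARTS protection score

`protection % = 100·(treated − control)/(undigested − control)` on
spectral-match counts, taken as given (the package does not recompute
identifications). The score is exactly 0 at the control level and 100 at
the undigested level, and is invariant under rescaling all three counts.
A denominator ≤ 0 yields no value and a `denominator_invalid` flag; values
outside [0, 100] are reported with an `out_of_range` flag and excluded
from ranking by default — sampling noise can push the ratio out of bounds,
and clamping would hide data problems. Ranking sorts by protection at the
highest concentration, flags dose-consistency (non-decreasing protection
with concentration), and breaks ties by protein id. Band nomination on
densitometric lane profiles requires monotone non-decreasing intensity
from control through increasing concentrations plus a total relative
increase of at least 20 % (configurable; no published numeric criterion
exists, and the default separates clearly rising bands from lane-to-lane
drift at typical densitometry noise).

## Peptide-level quantification

Fold change is the ratio of means (not the mean of ratios) of replicate
peak areas, treated over control, per concentration against the shared
vehicle control. The p-value is a two-sided two-sample Student t-test on
raw areas — the smallest-assumption reading for n = 3 replicates — with
Welch and log-area variants available. Degenerate inputs follow fixed
conventions: both groups constant and equal → p = 1; both constant and
unequal → p = 0. No multiple-testing correction is applied by default so
that protection calls remain comparable with raw p < 0.05 reporting;
Benjamini–Hochberg is available as an option. Replicates are treated as
unpaired (no pairing structure is assumed).

The protection call requires fold change > 1 **and** p < α at every tested
concentration. With two concentrations this dual requirement is the main
guard against type-I error at triplicate sample sizes: under the null the
single-test rejection rate is α, but the dual rate is roughly (α/2)² ≈
6·10⁻⁴ because the fold-change sign must also co-operate twice.

## Synthetic-data generator

The generator emulates the study design the pipeline consumes: 3 replicates
per condition; ligand concentrations 1 and 10 µM for quantification plus
100 µM for the gel stage; multiplicative protection of a planted peptide
subset; log-normal area noise; Poisson spectral counts bounded in
expectation by the undigested level.

* **Occupancy.** Protection scales with single-site binding occupancy
  `occ(c) = c/(c + K_D)`. The default K_D of 0.1 µM sits well below the
  assay concentrations, making the planted effect near-saturating where it
  is measured; `K_D = 0` models exact saturation and is used in the
  noise-free identity tests. This hyperbolic link is a modelling choice
  (the simplest mechanism producing graded, bounded protection), not an
  empirical claim.
* **Areas.** Control expected areas are log-uniform over [10⁴, 10⁷]
  (typical MRM peak-area dynamic range); planted peptides are scaled by
  `1 + (φ − 1)·occ(c)` with fold factor φ (default 2); observed areas
  multiply the expectation by `exp(ε)`, ε ~ N(0, σ_log) with σ_log = 0.15,
  approximating typical MRM area CVs of ~15 %.
* **Counts.** Undigested counts are Poisson(λ_u) with λ_u ∈ [50, 1000];
  control counts Poisson(r·λ_u) with survival ratio r ∈ (0, 1) (default
  0.3); treated counts Poisson(λ_c + π·occ(c)·(λ_u − λ_c)) for planted
  protection π ∈ [0, 1], so the treated expectation can never exceed the
  undigested one.
* **Sequences.** Random proteins draw residues from average proteome
  frequencies with K+R ≈ 11 %, giving realistic tryptic peptide lengths.
* **Determinism.** All randomness flows from one integer seed through
  PCG64 streams; identical parameters give byte-identical outputs.

What the generator does **not** emulate: chromatographic interference,
transition-level noise, missing values, run-order drift, between-run
normalisation problems, shared-peptide protein inference, or any
relationship between sequence and ionisation efficiency. Benchmarks passing
on this generator therefore demonstrate the *statistical* correctness of
the scoring and selection machinery under the stated noise model, not
robustness to every failure mode of real MRM data.

## Benchmark conditions and problem sizes

The statistical benchmarks (`lipscout.benchmarks`) run at the
peptide-statistics level, drawing replicate areas directly from the noise
model rather than materialising sequences, so large nulls run in seconds:

* Type-I control: 10,000 null peptides, σ_log = 0.15, n = 3, two
  concentrations; single-concentration rejection at α = 0.05 is required to
  fall in [0.035, 0.065] and the dual-concentration selection rate at or
  below 0.01.
* Recovery: 1,000 peptides with planted fold 2.0 at saturating occupancy
  (so the realised fold equals the planted fold at both concentrations);
  dual-call sensitivity required ≥ 0.90. DARTS recovery: 1,000 count
  simulations at π = 0.5, λ_u = 500, r = 0.3; the mean estimate must land
  within 50 ± 5 points.
* Digestion validation: 1,000 random sequences of length ≤ 300 against the
  brute-force substring oracle.

## Reference fixture

The CPS1 record in `lipscout.cps1` is an offline reconstruction of UniProt
P31327 (see that module's docstring for the verification inventory: all
eight protected-peptide m/z values to within 0.005 Th of published Q1s,
all 25 active-site residue letters, T'-loop boundaries, binding-pocket
residues, tryptic flanks, total length). The S1/S2/L1/L2/L3 domain
boundaries are an editable fixture consistent with the crystallographic
architecture (PDB 5DOU); the only containments treated as hard facts are
peptide 275–286 ⊂ S2, the 491–709 peptides ⊂ L1, the 1033–1115 peptides ⊂
L3, and T'-loop = 1269–1291. Region assignment uses a minimum overlap of a
single residue — published assignments are full containments, so no
threshold choice affects them. Spatial (3-D) proximity between peptides and
loops is out of scope; sequence-level containment is what the mapping
reports.

## Known limitations

* Gel image densitometry, chromatographic peak integration and search-engine
  identification are upstream of the package; it consumes their numeric
  outputs.
* The t-test default on raw areas is a deliberate smallest-assumption
  choice; heavy-tailed area noise would favour the log-area variant, which
  is available but not the default.
* The transition planner's surrogate intensity score is a reproducibility
  device, not a predictor of observed intensities.
* The protection call treats concentrations as independent experiments; a
  dose-response model (e.g. fitting K_D from graded fold changes) is not
  implemented.
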