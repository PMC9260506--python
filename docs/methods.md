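# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Repertoire processing

**Read model.** Each sequencing fragment is four well barcodes
(group, plate, row, column; 8 nt each, pairwise Hamming distance ≥ 3 within a
field) followed by a rearranged chain amplicon: the V segment (~60 nt), the
junction, the J segment, and a constant-region fragment (~48 nt) — about
180 nt in total, covered by a 120 nt read pair with a ~60 nt overlap.

**Merging.** Read 2 is reverse-complemented and all suffix/prefix overlaps of
length ≥ `min_overlap` (default 20) are scored exactly — per-offset match
counts come from four one-hot cross-correlations, so the search is global,
not seeded. An overlap qualifies when its mismatch fraction is ≤ 0.25; the
best overlap maximises matches − mismatches, two equally good candidates are
reported `ambiguous`, and disagreeing bases resolve to the higher-quality
read with ties to read 1.

**Demultiplexing.** Each barcode field needs a unique best match within
`max_mismatch` (default 1); equidistant candidates make the read
`ambiguous`. Reads shorter than the barcode layout are `too_short`. Assigned
+ unassigned always partitions the input.

**Error collapse.** Unique sequences per well and chain are tallied; a
sequence is absorbed into another with strictly greater multiplicity when
they differ by ≤ `max_mm` (default 1) mismatches and the larger outnumbers
the smaller ≥ `ratio_threshold`-fold. Absorption decisions use original
multiplicities (so the outcome is order-independent) and support follows the
largest qualifying absorber transitively. The default ratio is 5: at 1 %
substitution error over a ~140 nt amplicon only ~25 % of reads are
error-free, so the true sequence carries an expected count of ~12 of 50 and
must still absorb singleton error variants reliably; a much stricter ratio
leaves singletons unabsorbed and pushes wells into multiplet status.

**Annotation and CDR3.** V and J calls are best-scoring local alignments
(match +1, mismatch −1, gap −2) against the germline reference, ties broken
by score then name; segments below a minimum score (30 for V, 14 for J) make
the read unannotatable. The CDR3 spans the conserved V cysteine codon through
the J anchor codon inclusive, translated in the V frame; a frame break or
internal stop clears the `productive` flag. Coordinates are 0-based
half-open internally. D segments are not aligned (mouse TRBD is 6–14 nt and
not reliably assignable at amplicon scale); `d_call` stays empty.

**Pairing and clonotypes.** A well with one α and one β consensus is
`paired`; with several consensuses per chain, the dominant one is used when
its support is ≥ 10× the runner-up, otherwise the well is a `multiplet`.
Clonal lineages group paired cells on (CDR3α, Vα, Jα, CDR3β, Vβ, Jβ) at the
amino-acid level — matching how such panels are reported — with
nucleotide-level grouping available (`level="nt"`) since plate studies
sometimes define clones on identical nucleotide sequences. Contamination
screening is an exact nucleotide match against blacklists and sequences seen
in intentionally empty wells; near-matches are deliberately not flagged.

**Germline reference.** The packaged reference is synthetic with IMGT-like
names, avoiding redistribution of licensed germline data; user references
load from FASTA with per-segment cysteine/anchor offsets. The core segments'
junction-proximal residues are chosen so that the public p15E-reactive CDR3s
reconstruct exactly. J anchors are F or W except TRAJ7 — an ORF segment used
productively by these public clones — which anchors on leucine followed by
G-K-G; the validator therefore accepts {F, W, L}.

## Tetramer enrichment

Frequencies are per-fraction counts over fraction totals. A lineage is called
antigen-specific when it has ≥ 3 cells in the tetramer-positive fraction and
is ≥ 5-fold enriched, with an additive pseudocount of 1 applied to the
negative-fraction count and total so that lineages absent from the negative
fraction get a finite, conservative fold (the unadjusted fold, infinite in
that case, is reported alongside). The cell threshold applies to the
positive fraction, the sorted population under analysis. With pseudocount 1
at fraction sizes of ~2000 a lineage needs ≈ 5 positive cells to clear
5-fold when absent from the negative fraction; the planted scenario gives
specific clonotypes expanded frequencies (geometric decay, 30 % total mass),
so observed ≥ 3-cell specific lineages are nearly always well above that.

## Library design and selection analysis

An NNK codon (N = any base, K = G/T) spans 32 codons covering all 20 amino
acids with the single stop TAG. For the p15E library the TCR-contacting
positions 1, 4, 6, 7 of KSPWFTTL are diversified (`XSPXFXXL`), giving
32⁴ = 1,048,576 nucleotide variants and 20⁴ = 160,000 stop-free peptides;
fixed positions use mouse-frequent codons (configurable). Sequenced inserts
are accepted when stop-free and template-matching at fixed positions.
Clustering is an exact-identity tally with optional absorption of singletons
into a ≥ 10×-larger single-mismatch neighbour (a conservative stand-in for
sequence-identity clustering whose threshold is otherwise arbitrary).

Preference matrices weight the amino-acid prevalence at each position by read
count within one round; rounds are reported separately (a pooled variant is
provided) since per-round matrices are what convergence is judged on.
Trajectories use pseudocount-adjusted frequencies
(count + pc) / (depth + pc·U) over the union U of observed peptides, so
folds stay finite for peptides absent early; candidates rank by cumulative
fold enrichment, then final-round frequency, then sequence.

**Selection model.** The planted campaign treats the naive library as a full
census of the codon space — every nucleotide variant present once — which
matches a ≥ 10⁸-transformant library covering a ~10⁶-variant design at
~100× depth; the round-0 count of a peptide is its codon multiplicity.
Each subsequent round draws `depth_per_round` (default 10⁵) reads from a
multinomial with weights count(p)·exp(−stringency·E(p)). The planted additive
energy model gives wild-type-like residues 0, tolerated substitutions ~1 and
everything else 3 at each diversified position, with the unique minimum at
the mimotope-like KSPWFITL; with stringency 1 and 3 rounds this reproduces
the qualitative outcome of real selections — position 4 converges to
tryptophan (theoretical final weight ≈ 0.95) while positions 1, 6 and 7
retain some flexibility. The model has no avidity, display-level, growth or
PCR effects; enrichment depends only on the planted energies.

## Quantitative fits

- **One-site binding.** Nonlinear least squares on R(C) = R_max·C/(K_D + C)
  with positivity bounds; initial guesses R_max = max response and K_D = the
  concentration nearest half-max. Responses are normalised to the *fitted*
  R_max after fitting (fit-then-normalise; unweighted residuals). Steady
  state only — no kinetic rates.
- **Melt curves.** Default T_m is the temperature of the maximum of the
  smoothed derivative (centered moving average, window 5); a Boltzmann
  sigmoid fit is offered for low-noise traces. Flat or monotonically
  decreasing traces raise a no-transition error rather than returning a
  number.
- **ROUT outliers (univariate).** Robust center = median; robust scale = the
  68.27th percentile of absolute residuals (lower order statistic, which
  keeps gross outliers from inflating the scale at small n) with an
  n/(n−1) correction; two-tailed t p-values (df = n−1) enter a
  Benjamini–Hochberg step-up at rate Q (default 1 %). On clean normal data
  (n = 20) the per-point flag rate is ≈ 0.2 %, and a 10σ contaminant is
  essentially always flagged. Only the constant-model (replicate) case is
  implemented, which is how the rule is applied to cytokine-staining
  replicates.
- **Specific killing.** 100·(1 − r_exp/r_ctrl) for target/reference dye
  ratios, clipped to [0, 100] with an explicit flag when clipping occurred.

## Synthetic data: scope and defaults

Generators are pure functions of seed and parameters (byte-identical reruns)
and retain planted truth for scoring. Defaults: 96-well plates, 50 reads per
chain per well, 1 % i.i.d. substitution error (no indels — nested-PCR
amplicons are substitution-dominated and indels surface as filter rejects),
constant Q30 qualities, 12 planted clonotypes with 1/rank frequencies;
selections at 10⁵ reads/round for 3 rounds at stringency 1; tetramer sorts
of 2000 + 2000 cells at 90 % capture and 1 % leak. Sequencing depth per well
and per selection round are not reported for the real experiments; these
values are chosen as typical for MiSeq-scale amplicon runs. The generators do
not model PCR amplification bias, chimeras, index hopping, cell doublets, or
expression-level variation, so passing recovery tests demonstrates the
pipeline's correctness under its stated noise model, not robustness to every
artefact of real libraries.

## Limitations

- V/J assignment is tested against the packaged synthetic reference; scoring
  parameters of production annotators differ and allele-level genotyping is
  out of scope.
- The enrichment filter is deterministic thresholding, not a significance
  test; no multiplicity control is attempted or intended.
- The selection simulator's energies are a planted ground truth for
  validation, not a predictive binding model.
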