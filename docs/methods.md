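# Methods

This note documents the models implemented in `crossworm`, their
assumptions, the defaults that matter, and what the synthetic data do and
do not establish about real data.

## Meiosis under complete crossover interference

Every chromosome carries a genetic length of 50 cM by default: one
crossover per homolog pair per meiosis, so a transmitted chromatid carries
0 or 1 crossovers, each with probability 1/2.  Crossover positions are
drawn uniformly in genetic coordinates and mapped to physical coordinates
with a linear Marey map (placement does not affect any count statistic; a
non-uniform placement map can be supplied for visualisation purposes).  The
`poisson` mode draws the crossover count from Poisson(L/100), giving the
no-interference null with the same mean (0.5 at 50 cM) but variance 0.5
instead of 0.25.

Males are X0.  The X never recombines in males; a male transmits his X to
daughters and a nullosome to sons, each with probability 1/2.
Mitochondria are strictly maternal.

## The G4BC2 advanced-intercross design

The default `CrossDesign` is: founder cross A-female x B-male (A is the
recurrent, reference-strain founder), three generations of intercrossing
(G2–G4), then two backcrosses to founder A with the non-recurrent parent
male (A-female x recombinant-male).

**What is counted.** Each mapping line is sequenced as a pool of
final-backcross siblings that collectively carry one unique recombinant
chromosome set: the non-recurrent haplotype of the pool's shared backcross
parent.  Individual sibling gametes differ, but their ancestry averages
back to the parent's haplotype, so the pooled ancestry calls recover the
parental recombinant set.  The default counting mode
(`counted="pool_parent"`) therefore scores ancestry switch points on the
non-recurrent haplotype of the BC1 parent — the gamete produced by a G4
individual.

**Why this reproduces 1.25 and 0.75.** Junction (ancestry-switch)
accumulation under complete interference follows
`E[J_gamete] = mean(E[J] of the parent's two haplotypes) + 0.5 * P(het)`,
where `P(het)` is the probability the parent's haplotypes carry different
founder labels at a uniformly drawn point (1/2 throughout the intercross
for autosomes).  Autosomal expectation per intercross gamete is therefore
0.25(m+1) after m meioses: 0.5 (F1 gamete), 0.75, 1.0, and 1.25 for the G4
gamete — the expected autosomal crossover count per counted chromosome.
For the X, with the G4 transmitting parent male, the counted X is the G4
male's own X, i.e. the gamete of his G3 mother.  Her maternal X (through a
G2 female paired with an F1 male's pure-A X) carries founder B over an
expected 1/4 of its length, her paternal X (an F1 female's gamete passed
intact through a G2 male) over 1/2; both carry an expected 0.5 junctions.
Her gamete then has expectation 0.5 + 0.5 * (1/4 * 1/2 + 3/4 * 1/2) = 0.75.
Both expectations are exact, and the simulator reproduces them to
Monte-Carlo error.

Counting instead on the final BC2 individual's own non-recurrent haplotype
(`counted="final_individual"`) adds a backcross meiosis, and each such
meiosis halves the inherited junction count while adding 1/4
(`E_next = E/2 + 1/4`, giving 0.875 for the autosome); that mode exists for
designs where single final-generation individuals, not pools, are
sequenced.

**Infinite-pool lineages.** By default every simulated line draws its own
independent genealogy (equivalent to an infinite random-mating intercross
pool).  Expectations are identical to a large finite pool while lines stay
independent and the cost per line is a fixed ~20 meioses; a finite
random-mating pool (`pool_size=N`) is available when sib-sharing
covariance between lines is itself of interest.

**Monte-Carlo tests.** The crossover-count test simulates the null total
over N lines and reports the doubled smaller tail with the (k+1)/(n+1)
estimator, capped at 1.  The X:autosome ratio test is one-sided toward X
excess; a null replicate with zero autosomal crossovers counts as an
infinite ratio (upper tail).

**Reproducibility.** One root seed; line i consumes the stream
`SeedSequence(root, spawn_key=(i,))`, so results are independent of
execution order and identical across runs.

## Marey maps and domain regression

Genetic position is interpolated at 200 evenly spaced physical positions
per chromosome, 1 Mb is excluded from each end (tips recombine little and
are poorly resolved; they are reported but never fitted), and genetic
position is regressed on physical position under the constraint of three
joined linear segments.  The model `y = a + b x + c (x-LC)+ + d (x-CR)+`
is linear at fixed breakpoints, so the globally RSS-optimal breakpoint pair
is found by exhaustive search over ordered pairs of interpolation points
(normal equations assembled from suffix sums, O(1) per pair), then
polished between grid points by a deterministic Nelder–Mead refinement
accepted only when it strictly lowers the RSS.  Ties in RSS resolve to the
smallest LC, then the largest CR, making degenerate inputs reproducible.
Continuity is enforced by construction; discontinuous fits are out of
scope because genetic position is cumulative.

Each chromosome's genetic length is rescaled to 50 cM before rates are
reported (the complete-interference convention used for cross-species
comparison); raw-scale output is available (`normalize_to=None`).
Rescaling by default happens before fitting; because the fit is linear in
y, fitting first and rescaling after gives identical estimates.

A chromosome is flagged as *not* domain-structured ("No") when the fit is
degenerate, when the fitted centre rate is not below both arm rates, or
when the centre spans under 5% of the fitted range.  The flagging rule is
this package's own operational definition; published domain tables flag
such chromosomes without stating a criterion.

Breakpoint confidence intervals are not computed: simulation studies of
this estimator class put boundary uncertainty on the order of a megabase
even in favourable designs, and no downstream quantity here consumes a
boundary CI.  A bootstrap could be added over the interpolated grid if
needed.

## Medea penetrance

Two unlinked maternal-effect loci (chromosomes I and III; susceptible
homozygote = founder A) act in heterozygous mothers.  For a cross, the
probability an offspring is homozygous-susceptible at locus L is 0 unless
the mother is heterozygous, then 1/2, 1/4 or 0 as the father is
homozygous-susceptible, heterozygous, or homozygous for the other allele.

Two joint-action rules are implemented:

- **survival** (default for `expected_affected_fraction`):
  `P(affected) = 1 - (1 - bI hI)(1 - bIII hIII)`;
- **product**: doubly susceptible offspring are affected with probability
  `bI * bIII`, giving
  `P(affected) = bI hI (1-hIII) + bIII hIII (1-hI) + bI bIII hI hIII`.

The rules coincide at full penetrance.  The backcross-minus-F2 difference
`D` equals `bI/16 + bIII/16 + 3 bI bIII/16` under the product rule, and
that expectation is what the penetrance solvers invert
(`2b + 3b^2 = 16 D`; `1 + 4b = 16 D`), because it is the expectation the
published estimates derive from.  Under the survival rule the expectation
would instead be `bI/4 + bIII/4 - 3 bI bIII/16`.  Calibration checks of
the estimator (CI coverage) therefore simulate under the product rule so
that the generative model matches the estimator; with survival-rule data
the solver is conservative (biased downward) away from b = 1.  The
synthetic 16-cross preset uses the product rule for the same reason.

`D` carries a 95% Agresti–Caffo interval (one success and one failure
added per group, Wald on the adjusted proportions, z = 1.959964, clamped
to [-1, 1]); penetrance CIs map the interval endpoints through the
strictly monotone solvers, which reproduces the published +/-0.10 and
+/-0.16 without distributional assumptions.

Pooling defaults: affected = unhatched + deformed L1 + delayed L1–L3
larvae; denominator = affected + wild-type adults and L4s, with
unaccounted ("missing") embryos excluded.  Both choices are toggles
because published pooled counts are not decomposed by category.  Baseline
(Medea-independent) mortality in the forward simulator defaults to 0; a
nonzero rate shrinks `D` by the factor (1 - mortality) in expectation and
biases both solvers downward accordingly.  A mitochondrial/parent-of-origin
interaction is represented only implicitly (the reciprocal F1 classes are
distinct cross classes); no interaction parameter is estimated because
none is quantified upstream.

## Skew statistics

Preferred phase is fixed by the skew model — the insertion co-segregating
with the nullosome (insertion+ sons, insertion- daughters) — and both
phases' counts are printed so the convention cannot silently invert.  The
Fisher exact test is two-sided by the point-probability rule (sum over the
hypergeometric support of all tables whose point probability does not
exceed the observed one, ties included at 1e-9 relative tolerance); it is
implemented directly on the hypergeometric pmf so its tie behaviour is
pinned, and it is verified against exact rational enumeration for every
table with total at most 20.  The nullosome distance treats X-absence as a
locus: unpreferred-phase offspring are the recombinant class, distance =
100 x fraction cM, with a normal-approximation binomial CI (z = 1.959964)
clipped to [0, 100].

## Composition statistics

GC is G+C over unambiguous bases (N excluded from numerator and
denominator).  Windows tile from 0; trailing partial windows are dropped
rather than rescaled so that variance comparisons across scales use
equal-length windows.  Nested masking assigns exon bases first, then
repeat bases outside exons, then intronic bases inside gene spans, then
intergenic; the classes partition the unambiguous genome exactly and that
partition is asserted in tests.  Feature-windowed reporting applies a
minimum of 100 unambiguous bases per window before a window's class GC is
reported.  Telomere counting scores maximal tandem runs of TTAGGC at the
right end and its reverse complement at the left end.  RSCU uses the
standard nuclear code only (count x family size / family total; stops
excluded; codons containing N skipped).  Amino-acid deviations subtract
the unweighted cross-species mean, so they sum to zero across species by
construction.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* each estimator
assumes: piecewise-linear domain maps with marker jitter (iid Gaussian cM
noise, default sigma 0.25 cM, monotonised by running maximum — real map
noise is autocorrelated because neighbouring markers share crossovers);
multinomial progeny counts under exactly the two-locus model (real counts
include scoring error and brood-size variation between plates); binomially
skewed 2x2 tables; and toy genomes whose per-feature GC targets are
realised by iid base sampling (no isochore autocorrelation, no repeat
families, no Ns).  Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated models, not robustness to the
failure modes of real sequencing data (ancestry-call error, segregation
distortion coupling to the map, reference bias).

The map-like preset (`becei-map`) sets true domain parameters to the
published point estimates (five autosome arm rates averaging 8.1 cM/Mb
with maximum 10.9 on chromosome V, centre rates 0.1–0.6 cM/Mb, chromosome
V centre spanning 63% of its length, every chromosome 50 cM), so recovery
tests double as a substitute for re-analysing the original supplementary
marker table, which is not redistributed here.

## Problem sizes and numerical choices

Simulator calibration uses 200,000 independent lineages (Monte-Carlo
standard error ~0.002 on the means, against a +/-0.02 acceptance band).
Breakpoint-recovery experiments use 200-point grids and 50 noise
replicates; estimator-coverage experiments use 200 replicates of 16
crosses x 1000 embryos.  Segment-tiling invariants run over 10,000 random
pedigrees.  Floating-point ties in the segmented fit are compared with a
relative tolerance of 1e-10 on the RSS; haplotype bounds are exact floats
and segment normalisation merges empty and like-labelled segments.

## Known limitations

- The pedigree defaults are calibrated to the published expectation
  surface (1.25/0.75); pool sizes, backcross directions and the identity
  of sequenced individuals in the original experiment are configurable
  but not independently known here.
- No selection, viability differences, gene conversion or obligate-CO
  failure inside the meiosis simulator; segregation distortion lives only
  in the Medea module.
- Domain tips are reported, never fitted; X-specific interference
  differences are not modelled (the simulator treats the X's 50 cM the
  same way as autosomes in females).
- The linkage between skew strength and physical X length is not
  modelled; skew statistics are purely count-based.
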