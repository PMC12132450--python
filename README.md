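# crossworm

Genetics of experimental *Caenorhabditis* crosses: meiosis and
advanced-intercross simulation under complete crossover interference,
Marey-map recombination-domain estimation, two-locus maternal-effect
(*Medea*) penetrance estimation, autosome–X cosegregation ("skew")
statistics, and genome-composition statistics — with synthetic-data
generators so every analysis is testable offline.

The package is aimed at worm geneticists building genetic maps from
advanced-intercross panels (e.g. G4BC2 designs in gonochoristic
*Caenorhabditis* such as *C. becei*) and analysing the segregation
phenomena those crosses expose.

## The models in brief

**Meiosis / G4BC2 simulation.** Under complete crossover interference a
50 cM chromosome transmits 0 or 1 crossovers per meiosis (P = 1/2 each);
a Poisson mode gives the no-interference null. Males are X0: no X
recombination in males, nullosomic sperm, maternal mitochondria. The
G4BC2 design (founder cross, 3 intercross generations, 2 backcrosses to
the recurrent founder) yields an expected E[crossovers] = 1.25 per
transmitted autosome and 0.75 per X on each line's counted recombinant
haplotype; Monte-Carlo tests compare observed per-line counts and the
X:autosome ratio against the simulated null.

**Marey domains.** Genetic position y(x) is interpolated at 200 even
physical positions, 1 Mb trimmed per end, and fit with a continuous
three-segment regression y = a + b·x + c·(x−LC)₊ + d·(x−CR)₊ by
exhaustive breakpoint-pair search (plus deterministic refinement). LC and
CR are the arm/centre boundaries; segment slopes are the domain
recombination rates (cM/Mb), reported after rescaling each chromosome to
50 cM.

**Medea penetrance.** Two unlinked maternal-effect loci with penetrances
β_I, β_III damage offspring homozygous for the susceptible founder allele
when the mother is heterozygous. The backcross-minus-F2 affected
proportion difference D estimates β_I/16 + β_III/16 + 3β_Iβ_III/16
(Agresti–Caffo 95% CI); solving 2β + 3β² = 16D gives the equal-penetrance
solution and 1 + 4β = 16D the one-locus-fully-penetrant solution, with
CIs propagated through the monotone solvers.

**Skew.** From insertion± × sex offspring counts: the Transmission Bias
Ratio (preferred/unpreferred phase), a two-sided Fisher exact test
(point-probability rule), and the map distance of the insertion to the X
nullosome (unpreferred fraction × 100 cM, normal-approximation CI).

**Composition.** Windowed GC (N-excluded), nested exon→repeat→intron→
intergenic masking that exactly partitions the genome, GC variance by
scale, telomeric TTAGGC run counting, RSCU, and amino-acid usage
deviations.

## Worked example

```python
import crossworm as cw

# --- skew statistics from an insertion x sex offspring table
res = cw.SkewModel.from_counts(343, 278, 507, 591).fit()
print(res.summary())

# --- Medea penetrance from pooled affected/total counts
est = cw.MedeaPenetranceModel(517, 827, 644, 1544).fit()
print(est.summary())

# --- simulator calibration for the G4BC2 design
chroms = [cw.ChromosomeModel("auto", 17e6), cw.ChromosomeModel("X", 24e6, kind="X")]
s = cw.simulate_g4bc2(cw.CrossDesign(), chroms, n_lines=20_000, seed=1)
print(f"mean crossovers: autosome {s.mean('auto'):.3f}, X {s.mean('X'):.3f}")
```

prints

```
Autosome-X skew
  males   insertion+ 343   insertion- 278
  females insertion+ 507   insertion- 591
  n offspring            1719
  preferred/unpreferred  934/785
  TBR                    1.19
  Fisher exact p (2-sided) 0.00036
  distance to nullosome  45.7 +/- 2.4 cM
Medea penetrance estimation
  backcross affected     517/827 = 0.6252
  F2 affected            644/1544 = 0.4171
  difference D           0.2081  (95% AC CI 0.1665..0.2488, halfwidth 0.041)
  beta (equal loci)      0.772  (CI 0.666..0.866)
  beta (other locus | one fully penetrant)  0.582  (CI 0.416..0.745)
mean crossovers: autosome 1.255, X 0.752
```

The TBR of 1.19 says insertion-with-nullosome gametes outnumber the
opposite phase ~6:5; the 45.7 cM distance places the insertion in loose
linkage with X absence. The Medea fit says the two distorter loci each
kill well over half of susceptible homozygous offspring (β ≈ 0.77 if
equal). The simulated means match the design's analytic expectations of
1.25 and 0.75.

A command-line interface mirrors the library:
`crossworm simulate | mareyfit | medea | skew | gc | rscu | synth`
(see `crossworm --help`).

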