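"""Gamete and advanced-intercross (G4BC2) simulation under crossover interference.

The model
---------
Each chromosome is 50 cM by default: under *complete* crossover interference
a transmitted chromatid carries 0 or 1 crossovers, each with probability
1/2, with the crossover position uniform on the genetic map.  A ``poisson``
mode (count ~ Poisson(genetic length / 100), uniform positions) provides the
no-interference null with the same mean but double the variance.

Males are X0: a male transmits his single X intact to daughters and a
nullosome to sons, and the X never recombines in males.

The G4BC2 design
----------------
Two inbred founders (labelled A and B; A is the reference/recurrent strain)
are crossed (A female x B male), the F1s intercrossed for ``n_intercross``
generations (default 3, giving G4), and the result backcrossed
``n_backcross`` times (default 2) to the recurrent founder.  Each mapping
line is sequenced as a pool of final-backcross siblings; the pool carries
"one unique set of recombinant chromosomes" -- the non-recurrent haplotype
of the pool's shared backcross parent.  Counting ancestry switch points on
that haplotype (``counted="pool_parent"``, the default) gives expected
crossover counts of 1.25 per autosome and 0.75 per X under complete
interference with the default design; counting instead on the final
individual's own non-recurrent haplotype (``counted="final_individual"``)
adds one more backcross meiosis, which halves inherited junctions each
round.  See docs/methods.md for the junction-theory accounting.

Lineages are simulated genealogically: by default every line draws its own
independent ancestors (an effectively infinite intercross pool), which
leaves all expectations unchanged relative to a large finite pool while
keeping lines independent.  A finite random-mating pool is available via
``pool_size``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from ._util import ConfigError, rng_for

# ---------------------------------------------------------------------------
# chromosomes and haplotypes


@dataclass(frozen=True)
class ChromosomeModel:
    """A chromosome's physical and genetic dimensions."""

    name: str
    length_bp: float
    genetic_length_cM: float = 50.0
    kind: str = "autosome"  # "autosome" | "X"

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.genetic_length_cM <= 0:
            raise ConfigError("chromosome lengths must be positive")
        if self.kind not in ("autosome", "X"):
            raise ConfigError(f"unknown chromosome kind {self.kind!r}")


@dataclass(frozen=True)
class AncestryHaplotype:
    """Founder-labelled segments tiling [0, length).

    ``bounds`` has one more entry than ``labels``; segment i spans
    [bounds[i], bounds[i+1]) with founder ``labels[i]``.  After
    :meth:`normalized`, adjacent segments always carry different labels, so
    the crossover count of a haplotype is simply ``len(labels) - 1``.
    """

    chrom: str
    length: float
    bounds: tuple[float, ...]
    labels: tuple[str, ...]

    @classmethod
    def uniform(cls, chrom: str, length: float, label: str) -> "AncestryHaplotype":
        return cls(chrom, length, (0.0, float(length)), (label,))

    def normalized(self) -> "AncestryHaplotype":
        bounds = [self.bounds[0]]
        labels: list[str] = []
        for i, lab in enumerate(self.labels):
            if self.bounds[i + 1] <= self.bounds[i]:  # empty segment
                continue
            if labels and labels[-1] == lab:
                bounds[-1] = self.bounds[i + 1]
            else:
                labels.append(lab)
                bounds.append(self.bounds[i + 1])
        return AncestryHaplotype(self.chrom, self.length, tuple(bounds), tuple(labels))

    def label_at(self, pos: float) -> str:
        i = min(bisect_right(self.bounds, pos) - 1, len(self.labels) - 1)
        return self.labels[max(i, 0)]

    @property
    def n_crossovers(self) -> int:
        return len(self.normalized().labels) - 1

    def validate(self) -> None:
        b = self.bounds
        assert b[0] == 0.0 and abs(b[-1] - self.length) < 1e-9, "haplotype must span [0, length)"
        assert all(b[i] < b[i + 1] for i in range(len(b) - 1)), "bounds must increase"
        assert len(self.labels) == len(b) - 1


def count_crossovers(h: AncestryHaplotype) -> int:
    """Number of founder-label switch points along the haplotype."""
    return h.n_crossovers


# ---------------------------------------------------------------------------
# single meiosis


def _crossover_positions(chrom: ChromosomeModel, mode: str, rng: np.random.Generator) -> list[float]:
    """Draw crossover positions (bp) for one meiosis.

    Positions are uniform in genetic (cM) coordinates and mapped to bp with a
    linear Marey map; for a uniform map the two are equivalent.
    """
    p_map = chrom.genetic_length_cM / 100.0
    if mode == "complete":
        n = 1 if rng.random() < p_map else 0
    elif mode == "poisson":
        n = int(rng.poisson(p_map))
    else:
        raise ConfigError(f"unknown interference mode {mode!r}")
    if n == 0:
        return []
    return sorted(float(u) * chrom.length_bp for u in rng.random(n))


def _recombine(h1: AncestryHaplotype, h2: AncestryHaplotype,
               cuts: list[float], first: int) -> AncestryHaplotype:
    """Splice two haplotypes at ``cuts``, starting from haplotype ``first``."""
    if not cuts:
        return (h1, h2)[first]
    haps = (h1, h2)
    bounds = [0.0]
    labels: list[str] = []
    cur = first
    pos = 0.0
    for cut in list(cuts) + [h1.length]:
        if cut <= pos:
            cur = 1 - cur
            continue
        h = haps[cur]
        i = max(bisect_right(h.bounds, pos) - 1, 0)
        while pos < cut:
            seg_end = min(h.bounds[i + 1], cut)
            if labels and labels[-1] == h.labels[i]:
                bounds[-1] = seg_end
            else:
                labels.append(h.labels[i])
                bounds.append(seg_end)
            pos = seg_end
            i += 1
        cur = 1 - cur
    return AncestryHaplotype(h1.chrom, h1.length, tuple(bounds), tuple(labels))


def _gamete(pair: tuple[AncestryHaplotype, AncestryHaplotype],
            chrom: ChromosomeModel, mode: str, rng: np.random.Generator) -> AncestryHaplotype:
    cuts = _crossover_positions(chrom, mode, rng)
    first = int(rng.integers(2))
    return _recombine(pair[0], pair[1], cuts, first)


# ---------------------------------------------------------------------------
# individuals


@dataclass
class SimIndividual:
    """A simulated worm: autosome pairs, X haplotype(s), mitochondrial label.

    Females are XX (two X haplotypes), males X0 (one).  The mitochondrial
    label always equals the mother's.
    """

    sex: str  # "F" | "M"
    autosomes: dict[str, tuple[AncestryHaplotype, AncestryHaplotype]]
    x: tuple[AncestryHaplotype, ...]
    mito: str

    def __post_init__(self) -> None:
        if not self.x:  # X not tracked in this simulation
            return
        expect = 2 if self.sex == "F" else 1
        if len(self.x) != expect:
            raise ConfigError(f"sex {self.sex} must carry {expect} X haplotype(s)")


def simulate_meiosis(parent: SimIndividual, chrom: ChromosomeModel,
                     mode: str = "complete",
                     rng: np.random.Generator | None = None) -> AncestryHaplotype | None:
    """One transmitted chromatid from ``parent`` for ``chrom``.

    Autosomes recombine in both sexes.  The X recombines only in females;
    a male returns his intact X or ``None`` (a nullosome), each with
    probability 1/2.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if chrom.kind == "X":
        if parent.sex == "M":
            return parent.x[0] if rng.random() < 0.5 else None
        return _gamete((parent.x[0], parent.x[1]), chrom, mode, rng)
    if chrom.name not in parent.autosomes:
        raise ConfigError(f"parent does not carry chromosome {chrom.name!r}")
    return _gamete(parent.autosomes[chrom.name], chrom, mode, rng)


def mate(mother: SimIndividual, father: SimIndividual,
         chromosomes: list[ChromosomeModel], mode: str,
         rng: np.random.Generator) -> SimIndividual:
    """Produce one offspring; sex is decided by the paternal X/nullosome draw."""
    autos = {}
    x_chrom = None
    for c in chromosomes:
        if c.kind == "X":
            x_chrom = c
            continue
        autos[c.name] = (_gamete(mother.autosomes[c.name], c, mode, rng),
                         _gamete(father.autosomes[c.name], c, mode, rng))
    if x_chrom is None:
        # X not tracked: sex is still decided by the paternal X/nullosome draw
        sex = "M" if rng.random() < 0.5 else "F"
        return SimIndividual(sex, autos, (), mother.mito)
    maternal_x = _gamete((mother.x[0], mother.x[1]), x_chrom, mode, rng)
    paternal_x = simulate_meiosis(father, x_chrom, mode, rng)
    if paternal_x is None:
        return SimIndividual("M", autos, (maternal_x,), mother.mito)
    return SimIndividual("F", autos, (maternal_x, paternal_x), mother.mito)


# ---------------------------------------------------------------------------
# the cross design


@dataclass(frozen=True)
class CrossDesign:
    """Pedigree plan for the advanced intercross.

    ``counted`` selects the haplotype on which ancestry switch points are
    scored: ``"pool_parent"`` (default) scores the non-recurrent haplotype of
    the final pool's backcross parent -- the recombinant set a pooled-sequenced
    line represents; ``"final_individual"`` scores the non-recurrent haplotype
    of a final-generation individual, adding the remaining backcross meioses.

    ``bc_parent_sex`` is the sex of the non-recurrent parent in backcrosses
    ("male": A females x recombinant males, the configuration that reproduces
    the published 1.25/0.75 autosome/X expectations).
    ``pool_size`` of None simulates an effectively infinite intercross pool
    (independent ancestors per line).
    """

    founders: tuple[str, str] = ("A", "B")
    founder_cross: str = "AxB"  # "AxB": A mother, B father; "BxA" reversed
    n_intercross: int = 3
    n_backcross: int = 2
    recurrent: str = "A"
    interference: str = "complete"
    pool_size: int | None = None
    bc_parent_sex: str = "male"  # "male" | "female" | "random"
    counted: str = "pool_parent"  # "pool_parent" | "final_individual"
    count_both_haplotypes: bool = False

    def __post_init__(self) -> None:
        if len(self.founders) != 2 or len(set(self.founders)) != 2:
            raise ConfigError("design needs two distinct founders")
        if self.n_intercross < 0 or self.n_backcross < 0:
            raise ConfigError("generation counts must be >= 0")
        if self.recurrent not in self.founders:
            raise ConfigError("recurrent parent must be a founder")
        if self.pool_size is not None and self.pool_size < 1:
            raise ConfigError("pool size must be >= 1")
        if self.counted not in ("pool_parent", "final_individual"):
            raise ConfigError(f"unknown counted mode {self.counted!r}")
        if self.bc_parent_sex not in ("male", "female", "random"):
            raise ConfigError(f"unknown bc_parent_sex {self.bc_parent_sex!r}")


def _f1(design: CrossDesign, chromosomes: list[ChromosomeModel], sex: str) -> SimIndividual:
    a, b = design.founders
    mother_label, father_label = (a, b) if design.founder_cross == "AxB" else (b, a)
    autos = {}
    x_chrom = None
    for c in chromosomes:
        if c.kind == "X":
            x_chrom = c
            continue
        autos[c.name] = (AncestryHaplotype.uniform(c.name, c.length_bp, mother_label),
                         AncestryHaplotype.uniform(c.name, c.length_bp, father_label))
    if x_chrom is None:
        return SimIndividual(sex, autos, (), mother_label)
    x_m = AncestryHaplotype.uniform(x_chrom.name, x_chrom.length_bp, mother_label)
    if sex == "F":
        # daughter: X from mother plus the father's X
        x_p = AncestryHaplotype.uniform(x_chrom.name, x_chrom.length_bp, father_label)
        return SimIndividual("F", autos, (x_m, x_p), mother_label)
    # son: single X from the mother
    return SimIndividual("M", autos, (x_m,), mother_label)


def _intercross_individual(design: CrossDesign, chromosomes: list[ChromosomeModel],
                           gen: int, sex: str, rng: np.random.Generator) -> SimIndividual:
    """Generation-``gen`` pool individual (gen 1 = F1), independent genealogy."""
    if gen <= 1:
        return _f1(design, chromosomes, sex)
    mother = _intercross_individual(design, chromosomes, gen - 1, "F", rng)
    father = _intercross_individual(design, chromosomes, gen - 1, "M", rng)
    child = mate(mother, father, chromosomes, design.interference, rng)
    if child.sex != sex:  # pin the required sex by overriding the paternal X draw
        if not child.x:
            child = SimIndividual(sex, child.autosomes, (), child.mito)
        elif sex == "F":
            child = SimIndividual("F", child.autosomes, (child.x[0], father.x[0]), child.mito)
        else:
            child = SimIndividual("M", child.autosomes, (child.x[0],), child.mito)
    return child


def _pick_sex(policy: str, rng: np.random.Generator) -> str:
    if policy == "male":
        return "M"
    if policy == "female":
        return "F"
    return "M" if rng.random() < 0.5 else "F"


def simulate_line(design: CrossDesign, chromosomes: list[ChromosomeModel],
                  rng: np.random.Generator,
                  pool: list[SimIndividual] | None = None) -> dict[str, AncestryHaplotype]:
    """Counted recombinant haplotype (per chromosome) for one mapping line."""
    last_gen = design.n_intercross + 1
    sex = _pick_sex(design.bc_parent_sex, rng)
    if pool is not None:
        candidates = [ind for ind in pool if ind.sex == sex] or pool
        parent = candidates[int(rng.integers(len(candidates)))]
    elif design.n_backcross == 0 and design.n_intercross == 0:
        parent = _f1(design, chromosomes, sex)
    else:
        parent = _intercross_individual(design, chromosomes, last_gen, sex, rng)

    counted: dict[str, AncestryHaplotype] = {}
    x_chrom = None
    for c in chromosomes:
        if c.kind == "X":
            x_chrom = c
            continue
        counted[c.name] = _gamete(parent.autosomes[c.name], c, design.interference, rng)
    if x_chrom is not None:
        if parent.sex == "M":
            # transmitted intact to the backcross daughters
            counted[x_chrom.name] = parent.x[0]
        else:
            counted[x_chrom.name] = _gamete((parent.x[0], parent.x[1]), x_chrom,
                                            design.interference, rng)

    extra = design.n_backcross - 1 if design.counted == "pool_parent" else design.n_backcross
    extra = max(extra - 1, 0)  # the first backcross transmission is the gamete above
    for _ in range(extra):
        # subsequent backcrosses: the recombinant haplotype now sits on a
        # recurrent-parent background; model the transmitting parent as a
        # female het (recombinant/recurrent) so both autosomes and X recombine
        for c in chromosomes:
            rec = AncestryHaplotype.uniform(c.name, c.length_bp, design.recurrent)
            counted[c.name] = _gamete((counted[c.name], rec), c, design.interference, rng)
    return {k: v.normalized() for k, v in counted.items()}


def _build_pool(design: CrossDesign, chromosomes: list[ChromosomeModel],
                rng: np.random.Generator) -> list[SimIndividual]:
    """Random-mating finite pool through the intercross generations."""
    n = design.pool_size or 0
    pool = [_f1(design, chromosomes, "F" if i % 2 == 0 else "M") for i in range(2 * n)]
    for _ in range(design.n_intercross):
        females = [p for p in pool if p.sex == "F"]
        males = [p for p in pool if p.sex == "M"]
        nxt = []
        while len(nxt) < 2 * n:
            m = females[int(rng.integers(len(females)))]
            f = males[int(rng.integers(len(males)))]
            nxt.append(mate(m, f, chromosomes, design.interference, rng))
        pool = nxt
    return pool


@dataclass
class CrossoverCountSummary:
    """Per-chromosome crossover-count distributions over simulated lines."""

    design: CrossDesign
    n_lines: int
    seed: int | None
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, chrom: str) -> float:
        return float(np.mean(self.counts[chrom]))

    def distribution(self, chrom: str) -> np.ndarray:
        return np.bincount(self.counts[chrom])

    def to_frame(self):
        import pandas as pd

        rows = []
        for chrom, c in self.counts.items():
            q = np.quantile(c, [0.05, 0.5, 0.95])
            rows.append({"chrom": chrom, "mean": float(c.mean()),
                         "q05": q[0], "median": q[1], "q95": q[2],
                         "n_lines": self.n_lines, "seed": self.seed})
        return pd.DataFrame(rows)


def simulate_g4bc2(design: CrossDesign, chromosomes: list[ChromosomeModel],
                   n_lines: int, seed: int | None = None) -> CrossoverCountSummary:
    """Simulate ``n_lines`` mapping lines and count crossovers per chromosome.

    Reproducible: line ``i`` uses the stream ``SeedSequence(seed, spawn_key=(i,))``.
    """
    if n_lines < 1:
        raise ConfigError("n_lines must be >= 1")
    pool = None
    if design.pool_size is not None:
        pool = _build_pool(design, chromosomes, rng_for(seed, 999_999))
    out = {c.name: np.empty(n_lines, dtype=np.int64) for c in chromosomes}
    for i in range(n_lines):
        rng = rng_for(seed, i)
        haps = simulate_line(design, chromosomes, rng, pool=pool)
        for name, h in haps.items():
            out[name][i] = h.n_crossovers
    return CrossoverCountSummary(design, n_lines, seed, out)


# ---------------------------------------------------------------------------
# Monte-Carlo tests


def _mc_p_two_sided(null: np.ndarray, observed: float) -> float:
    """Two-sided Monte-Carlo p with the (k+1)/(n+1) estimator, doubled and capped."""
    n = len(null)
    lo = (np.sum(null <= observed) + 1) / (n + 1)
    hi = (np.sum(null >= observed) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class MonteCarloTest:
    statistic: float
    null_mean: float
    p_value: float
    n_sims: int


def crossover_count_test(observed: np.ndarray | list[int], design: CrossDesign,
                         chromosome: ChromosomeModel, n_sims: int = 1000,
                         seed: int | None = None) -> MonteCarloTest:
    """Two-sided Monte-Carlo test of an observed per-line crossover count vector.

    The statistic is the total count over the N observed lines; the null is
    the same total over N simulated lines, replicated ``n_sims`` times.
    """
    observed = np.asarray(observed)
    if observed.size == 0:
        raise ValueError("observed count vector is empty")
    n_lines = observed.size
    totals = np.empty(n_sims)
    for s in range(n_sims):
        rng = rng_for(seed, 1, s)
        totals[s] = sum(simulate_line(design, [chromosome], rng)[chromosome.name].n_crossovers
                        for _ in range(n_lines))
    obs_total = float(observed.sum())
    return MonteCarloTest(obs_total, float(totals.mean()), _mc_p_two_sided(totals, obs_total), n_sims)


def xa_ratio_test(observed_x: np.ndarray | list[int], observed_auto: np.ndarray | list[int],
                  design: CrossDesign, x_chrom: ChromosomeModel, auto_chrom: ChromosomeModel,
                  n_sims: int = 1000, seed: int | None = None) -> MonteCarloTest:
    """One-sided Monte-Carlo test for an excess X:autosome crossover ratio.

    Null replicates simulate len(observed_x) X lineages and
    len(observed_auto) autosomal lineages; a replicate with zero autosomal
    crossovers has ratio +inf (counted in the upper tail).
    """
    ox, oa = np.asarray(observed_x), np.asarray(observed_auto)
    if ox.size == 0 or oa.size == 0:
        raise ValueError("observed count vectors must be non-empty")
    obs_ratio = ox.mean() / oa.mean() if oa.mean() > 0 else np.inf
    ratios = np.empty(n_sims)
    for s in range(n_sims):
        rng = rng_for(seed, 2, s)
        xs = [simulate_line(design, [x_chrom], rng)[x_chrom.name].n_crossovers
              for _ in range(ox.size)]
        aus = [simulate_line(design, [auto_chrom], rng)[auto_chrom.name].n_crossovers
               for _ in range(oa.size)]
        mean_a = np.mean(aus)
        ratios[s] = np.mean(xs) / mean_a if mean_a > 0 else np.inf
    p = float((np.sum(ratios >= obs_ratio) + 1) / (n_sims + 1))
    return MonteCarloTest(float(obs_ratio), float(np.mean(ratios[np.isfinite(ratios)])), p, n_sims)


def becei_chromosomes() -> list[ChromosomeModel]:
    """A default six-chromosome set (50 cM each; X physically the largest)."""
    return [
        ChromosomeModel("I", 17.0e6),
        ChromosomeModel("II", 17.5e6),
        ChromosomeModel("III", 16.0e6),
        ChromosomeModel("IV", 16.5e6),
        ChromosomeModel("V", 17.0e6),
        ChromosomeModel("X", 24.0e6, kind="X"),
    ]
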