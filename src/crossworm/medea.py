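"""Two-locus maternal-effect (Medea) segregation-distortion model and estimator.

A *Medea* element acts in heterozygous mothers: offspring homozygous for
the non-Medea allele at the element's locus are killed or arrested with
penetrance beta.  (*Peel* is the paternal-effect mirror image.)  Here two
unlinked Medea loci (on chromosomes I and III, with the susceptible
homozygote being the reference founder, A = the recurrent mapping strain)
act together in the progeny of the sixteen pairwise crosses between the
two founders and the two reciprocal F1s.

Expected affected fractions
---------------------------
For a cross, let ``h_L`` be the probability that an offspring is homozygous
susceptible at locus L: 0 unless the mother is heterozygous at L, then 1/2
if the father is homozygous susceptible, 1/4 if the father is heterozygous,
0 if the father is homozygous for the other allele.  Two combination rules
are supported for how the loci jointly affect an offspring:

- ``"survival"`` (independent multiplicative survival):
  ``P(affected) = 1 - (1 - bI*hI) * (1 - bIII*hIII)``
- ``"product"``: each susceptible-homozygous locus affects independently,
  but a doubly homozygous offspring is affected with probability
  ``bI*bIII``; this is the rule under which the difference between
  backcross and F2 affected proportions equals
  ``bI/16 + bIII/16 + 3*bI*bIII/16``,
  the expectation the penetrance estimators below invert.

The two rules coincide at full penetrance.  See docs/methods.md for why
both exist and which is used where.

Estimation
----------
``D`` = (affected proportion in backcrosses of het mothers to susceptible
fathers) minus (affected proportion in F1 x F1 crosses), with a 95%
Agresti-Caffo interval (add one success and one failure per group, Wald on
the adjusted proportions).  Solving ``2b + 3b^2 = 16 D`` gives the
equal-penetrance solution; solving ``1 + 4b = 16 D`` gives the penetrance
of the second locus when the first is fully penetrant.  Confidence
intervals propagate through these strictly monotone solvers by mapping the
endpoints of the D interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ConfigError
from .io import PROGENY_COLUMNS, ProgenyCountTable

Z95 = 1.959964

# ---------------------------------------------------------------------------
# the sixteen cross classes


@dataclass(frozen=True)
class ParentGenotype:
    """Genotype labels of one parent at the loci the model tracks.

    ``chrom_i``/``chrom_iii`` are 'AA', 'BB' or 'AB'; ``x`` is 'AA'/'BB'/'AB'
    for females and a single 'A'/'B' for males; ``mito`` is 'A' or 'B'.
    """

    name: str
    chrom_i: str
    chrom_iii: str
    x: str
    mito: str


def _parent(name: str, sex: str) -> ParentGenotype:
    if name == "A":
        return ParentGenotype("A", "AA", "AA", "AA" if sex == "F" else "A", "A")
    if name == "B":
        return ParentGenotype("B", "BB", "BB", "BB" if sex == "F" else "B", "B")
    if name == "F1_AB":   # A mother x B father
        return ParentGenotype("F1_AB", "AB", "AB", "AB" if sex == "F" else "A", "A")
    if name == "F1_BA":   # B mother x A father
        return ParentGenotype("F1_BA", "AB", "AB", "AB" if sex == "F" else "B", "B")
    raise ConfigError(f"unknown parent genotype {name!r}")


PARENT_TYPES = ("A", "B", "F1_AB", "F1_BA")


@dataclass(frozen=True)
class CrossClass:
    """One of the sixteen mother x father genotype combinations (id 1-16)."""

    class_id: int
    mother: ParentGenotype
    father: ParentGenotype


def cross_classes() -> list[CrossClass]:
    """The canonical 16 classes, mother-major: id = 4*(mother index) + father index + 1."""
    out = []
    for mi, mname in enumerate(PARENT_TYPES):
        for fi, fname in enumerate(PARENT_TYPES):
            out.append(CrossClass(4 * mi + fi + 1, _parent(mname, "F"), _parent(fname, "M")))
    return out


def cross_class(class_id: int) -> CrossClass:
    if not 1 <= class_id <= 16:
        raise ValueError(f"cross class id {class_id} outside 1..16")
    return cross_classes()[class_id - 1]


# ---------------------------------------------------------------------------
# the penetrance model


@dataclass(frozen=True)
class MedeaModel:
    """Penetrances of the chromosome I and III loci plus the acting-parent mode."""

    beta_i: float
    beta_iii: float
    mode: str = "medea"          # "medea" (maternal) | "peel" (paternal)
    susceptible: str = "A"       # founder whose homozygotes are susceptible
    rule: str = "survival"       # "survival" | "product"

    def __post_init__(self) -> None:
        for b in (self.beta_i, self.beta_iii):
            if not 0.0 <= b <= 1.0:
                raise ConfigError("penetrances must lie in [0, 1]")
        if self.mode not in ("medea", "peel"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.rule not in ("survival", "product"):
            raise ConfigError(f"unknown combination rule {self.rule!r}")


def _h_susceptible(acting_gt: str, other_gt: str, susceptible: str) -> float:
    """P(offspring homozygous susceptible) given acting/other parent genotypes."""
    hom = susceptible * 2
    if acting_gt != "AB":
        return 0.0
    if other_gt == hom:
        return 0.5
    if other_gt == "AB":
        return 0.25
    return 0.0


def expected_affected_fraction(c: CrossClass, m: MedeaModel) -> float:
    """Expected fraction of affected offspring for one cross class.

    Zero whenever the acting parent (mother for medea, father for peel) is
    homozygous at both loci -- matching the observation that reciprocal
    crosses with homozygous mothers show no effect.
    """
    acting, other = (c.mother, c.father) if m.mode == "medea" else (c.father, c.mother)
    h_i = _h_susceptible(acting.chrom_i, other.chrom_i, m.susceptible)
    h_iii = _h_susceptible(acting.chrom_iii, other.chrom_iii, m.susceptible)
    if m.rule == "survival":
        return 1.0 - (1.0 - m.beta_i * h_i) * (1.0 - m.beta_iii * h_iii)
    # product rule: homozygosity events are independent across unlinked loci
    return (m.beta_i * h_i * (1 - h_iii)
            + m.beta_iii * h_iii * (1 - h_i)
            + m.beta_i * m.beta_iii * h_i * h_iii)


# ---------------------------------------------------------------------------
# forward simulation of count-table rows


@dataclass(frozen=True)
class PhenotypeSplit:
    """How affected and wild-type offspring distribute over scored classes."""

    affected: tuple[float, float, float] = (0.5, 0.3, 0.2)   # unhatched, deformed, delayed larvae
    wildtype: tuple[float, float, float, float] = (0.4, 0.4, 0.1, 0.1)  # adult F/M, L4 F/M


def simulate_progeny_counts(c: CrossClass, m: MedeaModel, n_embryos: int,
                            baseline_mortality: float = 0.0,
                            rng: np.random.Generator | None = None,
                            missing_rate: float = 0.0,
                            split: PhenotypeSplit = PhenotypeSplit(),
                            plate: str | int = 0) -> dict:
    """One progeny-table row: a multinomial draw over affected/wild-type/missing.

    Baseline mortality acts independently of the Medea effect and its victims
    are scored in the affected classes (they die the same deaths).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_embryos < 0:
        raise ValueError("n_embryos must be >= 0")
    p_med = expected_affected_fraction(c, m)
    p_aff = p_med + baseline_mortality - p_med * baseline_mortality
    p_missing = missing_rate * (1 - p_aff)
    p_wt = 1.0 - p_aff - p_missing
    if not (0 <= p_aff <= 1 and 0 <= p_wt <= 1):
        raise ConfigError("affected/wild-type probabilities left [0,1] after composition")
    pa, pw = split.affected, split.wildtype
    probs = [p_aff * pa[0], p_aff * pa[1], p_aff * pa[2],
             p_wt * pw[0], p_wt * pw[1], p_wt * pw[2], p_wt * pw[3],
             p_missing]
    draws = rng.multinomial(n_embryos, probs)
    unhatched, deformed, delayed, af, am, l4f, l4m, _missing = (int(v) for v in draws)
    return {"plate": plate, "embryos": int(n_embryos),
            "unhatched": unhatched, "deformed": deformed,
            "adult_females": af, "adult_males": am,
            "l4_females": l4f, "l4_males": l4m, "larvae": delayed,
            "mother": c.mother.name, "father": c.father.name,
            "cross_class": c.class_id}


# ---------------------------------------------------------------------------
# pooling and estimation


def classify_and_pool(t: ProgenyCountTable, include_delayed: bool = True,
                      denominator: str = "observed") -> pd.DataFrame:
    """Pool counts by cross class into (affected, total) plus phenotype proportions.

    affected = unhatched + deformed (+ delayed L1-L3 larvae when
    ``include_delayed``); wild-type = adults + L4s.  ``denominator`` is
    "observed" (affected + wild-type; missing excluded) or "embryos".
    """
    if denominator not in ("observed", "embryos"):
        raise ValueError(f"unknown denominator {denominator!r}")
    df = t.df
    g = df.groupby("cross_class").sum(numeric_only=True)
    affected = g["unhatched"] + g["deformed"] + (g["larvae"] if include_delayed else 0)
    wildtype = g["adult_females"] + g["adult_males"] + g["l4_females"] + g["l4_males"]
    total = affected + wildtype if denominator == "observed" else g["embryos"]
    out = pd.DataFrame({"affected": affected, "wildtype": wildtype,
                        "total": total, "embryos": g["embryos"],
                        "missing": g["missing"]})
    obs = out[["affected", "wildtype", "missing"]].sum(axis=1)
    for col in ("affected", "wildtype", "missing"):
        out[f"prop_{col}"] = out[col] / obs.where(obs > 0)
    out.index.name = "cross_class"
    return out


def pool_backcross_f2(pooled: pd.DataFrame, susceptible: str = "A") -> tuple[int, int, int, int]:
    """Extract (affected_bc, total_bc, affected_f2, total_f2) from class-pooled counts.

    Backcross classes: heterozygous mother x susceptible-homozygote father.
    F2 classes: heterozygous mother x heterozygous father.
    """
    classes = cross_classes()
    bc_ids = [c.class_id for c in classes
              if c.mother.chrom_i == "AB" and c.father.name == susceptible]
    f2_ids = [c.class_id for c in classes
              if c.mother.chrom_i == "AB" and c.father.chrom_i == "AB"]
    bc = pooled.loc[pooled.index.intersection(bc_ids)]
    f2 = pooled.loc[pooled.index.intersection(f2_ids)]
    return (int(bc["affected"].sum()), int(bc["total"].sum()),
            int(f2["affected"].sum()), int(f2["total"].sum()))


@dataclass
class PenetranceEstimate:
    """Difference estimator D with CI and the two penetrance solutions."""

    d: float
    d_ci: tuple[float, float]
    beta_equal: float | None = None
    beta_equal_ci: tuple[float, float] | None = None
    beta_single: float | None = None
    beta_single_ci: tuple[float, float] | None = None
    counts: tuple[int, int, int, int] | None = None  # affected_bc, total_bc, affected_f2, total_f2


def agresti_caffo_ci(a1: int, n1: int, a2: int, n2: int,
                     z: float = Z95) -> tuple[float, tuple[float, float]]:
    """Difference of proportions a1/n1 - a2/n2 with the add-one adjusted Wald CI."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if a1 > n1 or a2 > n2:
        raise ValueError("affected counts exceed totals")
    d = a1 / n1 - a2 / n2
    p1 = (a1 + 1) / (n1 + 2)
    p2 = (a2 + 1) / (n2 + 2)
    se = math.sqrt(p1 * (1 - p1) / (n1 + 2) + p2 * (1 - p2) / (n2 + 2))
    dd = p1 - p2
    return d, (max(dd - z * se, -1.0), min(dd + z * se, 1.0))


def difference_estimator(affected_bc: int, total_bc: int,
                         affected_f2: int, total_f2: int) -> PenetranceEstimate:
    """D = backcross minus F2 affected proportion, with 95% Agresti-Caffo CI."""
    d, ci = agresti_caffo_ci(affected_bc, total_bc, affected_f2, total_f2)
    return PenetranceEstimate(d=d, d_ci=ci,
                              counts=(affected_bc, total_bc, affected_f2, total_f2))


def expected_difference(beta_i: float, beta_iii: float) -> float:
    """The model expectation for D: bI/16 + bIII/16 + 3 bI bIII / 16."""
    return beta_i / 16 + beta_iii / 16 + 3 * beta_i * beta_iii / 16


def _solve_equal(d: float) -> float:
    # 3 b^2 + 2 b - 16 d = 0, positive root, clamped to [0, 1]
    if d < 0:
        warnings.warn("negative difference: equal-penetrance solution clamped to 0")
        return 0.0
    b = (-1.0 + math.sqrt(1.0 + 48.0 * d)) / 3.0
    return min(max(b, 0.0), 1.0)


def _solve_single(d: float) -> float:
    # 1 + 4 b = 16 d, clamped to [0, 1]
    if 16.0 * d < 1.0:
        warnings.warn("difference below 1/16: one-full-penetrance solution clamped to 0")
        return 0.0
    return min((16.0 * d - 1.0) / 4.0, 1.0)


def solve_equal_penetrance(d: float, d_ci: tuple[float, float] | None = None
                           ) -> tuple[float, tuple[float, float] | None]:
    """beta such that both loci share it and D matches; CI by endpoint mapping."""
    if not -1.0 <= d <= 1.0:
        raise ValueError("difference must lie in [-1, 1]")
    beta = _solve_equal(d)
    ci = None
    if d_ci is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = (_solve_equal(d_ci[0]), _solve_equal(d_ci[1]))
    return beta, ci


def solve_one_full_penetrance(d: float, d_ci: tuple[float, float] | None = None
                              ) -> tuple[float, tuple[float, float] | None]:
    """beta of the second locus assuming the first is fully penetrant."""
    if not -1.0 <= d <= 1.0:
        raise ValueError("difference must lie in [-1, 1]")
    beta = _solve_single(d)
    ci = None
    if d_ci is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = (_solve_single(d_ci[0]), _solve_single(d_ci[1]))
    return beta, ci


def estimate_penetrance(affected_bc: int, total_bc: int,
                        affected_f2: int, total_f2: int) -> PenetranceEstimate:
    """Full pipeline: D with CI, then both penetrance solutions with propagated CIs."""
    est = difference_estimator(affected_bc, total_bc, affected_f2, total_f2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.beta_equal, est.beta_equal_ci = solve_equal_penetrance(est.d, est.d_ci)
        est.beta_single, est.beta_single_ci = solve_one_full_penetrance(est.d, est.d_ci)
    return est


class MedeaPenetranceModel:
    """Penetrance estimation from pooled affected/total counts.

    Construct either from the four pooled counts or from a progeny table via
    :meth:`from_progeny_table` (which pools the heterozygous-mother backcross
    and F2 classes).
    """

    def __init__(self, affected_bc: int, total_bc: int, affected_f2: int, total_f2: int):
        self.counts = (affected_bc, total_bc, affected_f2, total_f2)

    @classmethod
    def from_progeny_table(cls, table: ProgenyCountTable, include_delayed: bool = True,
                           denominator: str = "observed", susceptible: str = "A"
                           ) -> "MedeaPenetranceModel":
        pooled = classify_and_pool(table, include_delayed=include_delayed,
                                   denominator=denominator)
        return cls(*pool_backcross_f2(pooled, susceptible=susceptible))

    def fit(self) -> "MedeaPenetranceResults":
        return MedeaPenetranceResults(self, estimate_penetrance(*self.counts))


class MedeaPenetranceResults:
    def __init__(self, model: MedeaPenetranceModel, estimate: PenetranceEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def params(self) -> pd.Series:
        e = self.estimate
        return pd.Series({"D": e.d, "beta_equal": e.beta_equal, "beta_single": e.beta_single})

    def summary(self) -> str:
        e = self.estimate
        a1, n1, a2, n2 = e.counts
        hw = (e.d_ci[1] - e.d_ci[0]) / 2
        lines = [
            "Medea penetrance estimation",
            f"  backcross affected     {a1}/{n1} = {a1 / n1:.4f}",
            f"  F2 affected            {a2}/{n2} = {a2 / n2:.4f}",
            f"  difference D           {e.d:.4f}  (95% AC CI {e.d_ci[0]:.4f}..{e.d_ci[1]:.4f}, halfwidth {hw:.3f})",
            f"  beta (equal loci)      {e.beta_equal:.3f}  (CI {e.beta_equal_ci[0]:.3f}..{e.beta_equal_ci[1]:.3f})",
            f"  beta (other locus | one fully penetrant)  {e.beta_single:.3f}"
            f"  (CI {e.beta_single_ci[0]:.3f}..{e.beta_single_ci[1]:.3f})",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# allele-frequency scan


def allele_frequency_scan(calls: pd.DataFrame, markers: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Per-marker founder-B allele frequency among mapping lines.

    ``calls``: markers x lines, entries in {"AA", "BB", "AB", None/NaN}.
    ``markers``: optional frame with chrom/bp aligned to the call rows.
    Frequency = (2*BB + AB) / (2 * non-missing lines); all-missing markers
    report NaN.
    """
    vals = calls.to_numpy(dtype=object)
    bb = (vals == "BB").sum(axis=1)
    het = (vals == "AB").sum(axis=1)
    aa = (vals == "AA").sum(axis=1)
    n = bb + het + aa
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, (2 * bb + het) / (2 * n), np.nan)
    out = pd.DataFrame({"freq_B": freq, "n_lines": n}, index=calls.index)
    if markers is not None:
        out = pd.concat([markers.reset_index(drop=True), out.reset_index(drop=True)], axis=1)
    return out


def make_progeny_table(rows: list[dict]) -> ProgenyCountTable:
    """Assemble simulated rows into a validated ProgenyCountTable."""
    return ProgenyCountTable(pd.DataFrame(rows, columns=[c for c in PROGENY_COLUMNS]))
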