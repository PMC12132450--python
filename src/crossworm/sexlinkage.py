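"""Autosome-X cosegregation ("skew") statistics from a 2x2 offspring table.

In X0 males, autosomal insertions tend to segregate away from the X and
into nullosomic (no-X) sperm, so an insertion carried by an F1 father turns
up in excess among sons and in deficit among daughters.  From the counts of
insertion+/- males and females this module computes:

- the Transmission Bias Ratio (TBR): preferred-phase over unpreferred-phase
  offspring, where preferred = insertion+ males + insertion- females;
- a two-sided Fisher exact test of insertion x sex (point-probability rule:
  sum the probabilities of all tables in the hypergeometric support whose
  point probability does not exceed the observed table's);
- the two-point map distance between the insertion and the nullosome:
  recombination fraction = unpreferred / n, in cM with the normal-
  approximation 95% binomial CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

Z95 = 1.959964
_TIE_REL = 1e-9  # relative tolerance for point-probability ties


@dataclass(frozen=True)
class SkewCounts:
    """Offspring counts: insertion+/- males, insertion+/- females."""

    ins_pos_males: int
    ins_neg_males: int
    ins_pos_females: int
    ins_neg_females: int

    def __post_init__(self) -> None:
        if min(self.ins_pos_males, self.ins_neg_males,
               self.ins_pos_females, self.ins_neg_females) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return (self.ins_pos_males + self.ins_neg_males
                + self.ins_pos_females + self.ins_neg_females)

    @property
    def preferred(self) -> int:
        # insertion co-segregating with the nullosome: insertion+ sons, insertion- daughters
        return self.ins_pos_males + self.ins_neg_females

    @property
    def unpreferred(self) -> int:
        return self.ins_neg_males + self.ins_pos_females

    def swapped_insertion(self) -> "SkewCounts":
        return SkewCounts(self.ins_neg_males, self.ins_pos_males,
                          self.ins_neg_females, self.ins_pos_females)


def tbr(c: SkewCounts) -> float:
    """Transmission Bias Ratio: preferred / unpreferred phase counts."""
    if c.unpreferred == 0:
        warnings.warn("no unpreferred-phase offspring: TBR is infinite")
        return float("inf")
    return c.preferred / c.unpreferred


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability rule over the hypergeometric support of the first
    cell given fixed margins; ties included up to a relative tolerance.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or min(r1, c1, n - r1, n - c1) == 0:
        raise ValueError("Fisher test needs all margins positive")
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL)].sum())
    return min(p, 1.0)


def skew_fisher(c: SkewCounts) -> float:
    """Two-sided Fisher exact test of insertion presence x offspring sex."""
    return fisher_exact_2x2(c.ins_pos_males, c.ins_pos_females,
                            c.ins_neg_males, c.ins_neg_females)


def nullosome_distance(c: SkewCounts) -> tuple[float, tuple[float, float]]:
    """Map distance (cM) of the insertion to the nullosome, with 95% CI.

    Unpreferred-phase offspring are the recombinants of the two-point cross;
    the distance is the recombination fraction in cM, CI by the normal
    approximation, clipped to [0, 100].
    """
    if c.n == 0:
        raise ValueError("empty table")
    frac = c.unpreferred / c.n
    cm = 100.0 * frac
    hw = Z95 * np.sqrt(frac * (1.0 - frac) / c.n) * 100.0
    return cm, (max(cm - hw, 0.0), min(cm + hw, 100.0))


class SkewModel:
    """Skew inference for one 2x2 insertion x sex offspring table."""

    def __init__(self, counts: SkewCounts):
        self.counts = counts

    @classmethod
    def from_counts(cls, ins_pos_males: int, ins_neg_males: int,
                    ins_pos_females: int, ins_neg_females: int) -> "SkewModel":
        return cls(SkewCounts(ins_pos_males, ins_neg_males, ins_pos_females, ins_neg_females))

    def fit(self) -> "SkewResults":
        c = self.counts
        cm, ci = nullosome_distance(c)
        return SkewResults(self, tbr(c), skew_fisher(c), cm, ci)


class SkewResults:
    def __init__(self, model: SkewModel, tbr_value: float, p_value: float,
                 distance_cm: float, distance_ci: tuple[float, float]):
        self.model = model
        self.tbr = tbr_value
        self.p_value = p_value
        self.distance_cm = distance_cm
        self.distance_ci = distance_ci

    @property
    def recombination_fraction(self) -> float:
        return self.distance_cm / 100.0

    def summary(self) -> str:
        c = self.model.counts
        hw = (self.distance_ci[1] - self.distance_ci[0]) / 2
        return "\n".join([
            "Autosome-X skew",
            f"  males   insertion+ {c.ins_pos_males}   insertion- {c.ins_neg_males}",
            f"  females insertion+ {c.ins_pos_females}   insertion- {c.ins_neg_females}",
            f"  n offspring            {c.n}",
            f"  preferred/unpreferred  {c.preferred}/{c.unpreferred}",
            f"  TBR                    {self.tbr:.2f}",
            f"  Fisher exact p (2-sided) {self.p_value:.2g}",
            f"  distance to nullosome  {self.distance_cm:.1f} +/- {hw:.1f} cM",
        ])
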