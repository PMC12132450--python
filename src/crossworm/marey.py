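"""Marey maps and recombination-domain estimation by segmented regression.

A Marey map plots genetic position (cM) against physical position (bp); its
local slope is the recombination rate.  *Caenorhabditis* chromosomes have a
characteristic domain structure -- low-recombination tips, high-rate arms, a
low-rate centre -- which is estimated here by regressing interpolated
genetic position on physical position under the constraint of three joined
linear segments.  The two breakpoints are the left-arm/centre (LC) and
centre/right-arm (CR) boundaries.

Procedure: genetic positions are linearly interpolated at ``n_points``
(default 200) evenly spaced physical positions per chromosome; 1 Mb is
excluded from each chromosome end (tip regions are poorly resolved and are
reported, not fitted); the breakpoint pair minimising the residual sum of
squares is found by exhaustive search over ordered pairs of interpolation
points, with closed-form least squares at fixed breakpoints.  The fit is
deterministic; ties in RSS resolve to the smallest LC, then largest CR.

Rates are reported per Mb after rescaling each chromosome's genetic length
to 50 cM (one obligate crossover per meiosis under complete interference),
matching how cross-species maps are normalised; raw rates are available by
passing ``normalize_to=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerTable

_MB = 1.0e6


@dataclass
class MareyMap:
    """Markers (bp, cM) along one chromosome, sorted by bp."""

    chrom: str
    length_bp: float
    bp: np.ndarray
    cM: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.bp, kind="stable")
        self.bp = np.asarray(self.bp, dtype=float)[order]
        self.cM = np.asarray(self.cM, dtype=float)[order]
        if self.cM[0] < 0:
            raise ValueError("genetic positions must start >= 0")

    @classmethod
    def from_marker_table(cls, table: MarkerTable, chrom: str,
                          length_bp: float | None = None) -> "MareyMap":
        sub = table.chromosome(chrom)
        if length_bp is None:
            length_bp = table.lengths.get(chrom, float(sub["bp"].max()))
        return cls(chrom, float(length_bp), sub["bp"].to_numpy(float), sub["cM"].to_numpy(float))

    @property
    def genetic_length(self) -> float:
        return float(self.cM[-1] - self.cM[0])

    def normalized(self, to: float = 50.0) -> "MareyMap":
        """Rescale the genetic axis so the map spans ``to`` cM."""
        gl = self.genetic_length
        if gl <= 0:
            return MareyMap(self.chrom, self.length_bp, self.bp.copy(), self.cM.copy())
        scale = to / gl
        return MareyMap(self.chrom, self.length_bp, self.bp.copy(), (self.cM - self.cM[0]) * scale)


def interpolate_map(m: MareyMap, n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Genetic positions at ``n_points`` evenly spaced bp spanning [0, length].

    Positions outside the marker span clamp to the terminal marker's cM.
    """
    if len(m.bp) < 2:
        raise ValueError("interpolation needs at least 2 markers")
    x = np.linspace(0.0, m.length_bp, n_points)
    y = np.interp(x, m.bp, m.cM)
    return x, y


@dataclass
class SegmentedFit:
    """Continuous three-segment least-squares fit of cM on bp."""

    lc: float                     # left arm / centre boundary (bp)
    cr: float                     # centre / right arm boundary (bp)
    slopes: tuple[float, float, float]  # cM per bp, left/centre/right
    intercept: float
    rss: float
    x_range: tuple[float, float]  # fitted (trimmed) physical range
    end_exclusion: float
    n_points: int
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        b1, b2, b3 = self.slopes
        y = self.intercept + b1 * x
        y = y + (b2 - b1) * np.clip(x - self.lc, 0.0, None)
        y = y + (b3 - b2) * np.clip(x - self.cr, 0.0, None)
        return y

    @property
    def slopes_cm_per_mb(self) -> tuple[float, float, float]:
        return tuple(s * _MB for s in self.slopes)


def _segment_rss_grid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """RSS and coefficients for every ordered breakpoint pair on the grid.

    The model y = a + b*x + c*(x-b1)_+ + d*(x-b2)_+ is linear at fixed
    breakpoints, so each candidate needs only the 4x4 normal equations,
    assembled from suffix sums in O(1) per pair.
    """
    n = len(x)
    i_idx, j_idx = np.triu_indices(n, k=1)
    keep = (i_idx >= 1) & (j_idx <= n - 2)
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    b1, b2 = x[i_idx], x[j_idx]

    def suffix(a):  # suffix[k] = sum over t >= k
        return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])

    sn = suffix(np.ones(n))
    sx = suffix(x)
    sxx = suffix(x * x)
    sy = suffix(y)
    sxy = suffix(x * y)

    tn, tx, txx, ty, txy = n, x.sum(), (x * x).sum(), y.sum(), (x * y).sum()
    yty = float(y @ y)

    m1 = sx[i_idx] - b1 * sn[i_idx]
    q11 = sxx[i_idx] - 2 * b1 * sx[i_idx] + b1 * b1 * sn[i_idx]
    q10 = sxx[i_idx] - b1 * sx[i_idx]
    r1 = sxy[i_idx] - b1 * sy[i_idx]

    m2 = sx[j_idx] - b2 * sn[j_idx]
    q22 = sxx[j_idx] - 2 * b2 * sx[j_idx] + b2 * b2 * sn[j_idx]
    q20 = sxx[j_idx] - b2 * sx[j_idx]
    r2 = sxy[j_idx] - b2 * sy[j_idx]

    q12 = sxx[j_idx] - (b1 + b2) * sx[j_idx] + b1 * b2 * sn[j_idx]

    p = len(i_idx)
    M = np.empty((p, 4, 4))
    M[:, 0, 0] = tn;  M[:, 0, 1] = tx;   M[:, 0, 2] = m1;  M[:, 0, 3] = m2
    M[:, 1, 0] = tx;  M[:, 1, 1] = txx;  M[:, 1, 2] = q10; M[:, 1, 3] = q20
    M[:, 2, 0] = m1;  M[:, 2, 1] = q10;  M[:, 2, 2] = q11; M[:, 2, 3] = q12
    M[:, 3, 0] = m2;  M[:, 3, 1] = q20;  M[:, 3, 2] = q12; M[:, 3, 3] = q22
    v = np.stack([np.full(p, ty), np.full(p, txy), r1, r2], axis=1)

    beta = np.linalg.solve(M + 1e-12 * np.eye(4), v[..., None])[..., 0]
    rss = yty - 2 * np.einsum("pi,pi->p", beta, v) + np.einsum("pi,pij,pj->p", beta, M, beta)
    rss = np.maximum(rss, 0.0)
    return b1, b2, beta, rss


def _rss_at(b1: float, b2: float, xs: np.ndarray, yt: np.ndarray
            ) -> tuple[float, np.ndarray]:
    """Exact least squares at fixed breakpoints (x already in Mb)."""
    A = np.column_stack([np.ones_like(xs), xs,
                         np.clip(xs - b1, 0.0, None), np.clip(xs - b2, 0.0, None)])
    beta, *_ = np.linalg.lstsq(A, yt, rcond=None)
    resid = yt - A @ beta
    return float(resid @ resid), beta


def fit_segmented(x: np.ndarray, y: np.ndarray, end_exclusion: float = 1.0e6,
                  min_points: int = 10, refine: bool = True) -> SegmentedFit:
    """Globally grid-optimal continuous three-segment fit of y (cM) on x (bp).

    ``end_exclusion`` trims that many bp from each end of the data range
    before fitting.  Breakpoint candidates are the retained interpolation
    points; equal-RSS ties resolve to the smallest LC then largest CR.
    With ``refine`` the breakpoint pair is then polished between grid points
    (deterministic Nelder-Mead), accepted only when it strictly lowers the
    RSS, so tie-break behaviour on flat surfaces is unchanged.
    All-constant y returns a flagged degenerate fit with zero slopes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo, hi = x.min() + end_exclusion, x.max() - end_exclusion
    keep = (x >= lo) & (x <= hi)
    xt, yt = x[keep], y[keep]
    if len(xt) < min_points:
        raise ValueError(f"only {len(xt)} points remain after end exclusion (need {min_points})")

    if np.allclose(yt, yt[0]):
        return SegmentedFit(float(xt[1]), float(xt[-2]), (0.0, 0.0, 0.0), float(yt[0]),
                            0.0, (float(xt[0]), float(xt[-1])), end_exclusion, len(xt),
                            degenerate=True)

    xs = xt / _MB  # condition the normal equations
    b1, b2, beta, rss = _segment_rss_grid(xs, yt)

    tol = max(1e-10 * float(yt @ yt), 1e-12)
    tied = np.flatnonzero(rss <= rss.min() + tol)
    # smallest LC, then largest CR
    order = np.lexsort((-b2[tied], b1[tied]))
    best = tied[order[0]]
    best_b1, best_b2 = float(b1[best]), float(b2[best])
    best_rss = float(rss[best])
    best_beta = beta[best]

    if refine and best_rss > tol:
        from scipy.optimize import minimize

        lo_b, hi_b = float(xs[1]), float(xs[-2])
        gap = float(np.min(np.diff(xs)))

        def objective(p):
            p1, p2 = p
            if not (lo_b <= p1 < p2 <= hi_b) or (p2 - p1) < gap:
                return best_rss * 10 + 1.0
            return _rss_at(p1, p2, xs, yt)[0]

        res = minimize(objective, [best_b1, best_b2], method="Nelder-Mead",
                       options={"xatol": gap * 1e-4, "fatol": best_rss * 1e-10 + 1e-15})
        if res.fun < best_rss - tol:
            best_b1, best_b2 = float(res.x[0]), float(res.x[1])
            best_rss, best_beta = _rss_at(best_b1, best_b2, xs, yt)

    a, b, c, d = best_beta
    slopes = (b / _MB, (b + c) / _MB, (b + c + d) / _MB)
    return SegmentedFit(float(best_b1 * _MB), float(best_b2 * _MB), slopes, float(a),
                        best_rss, (float(xt[0]), float(xt[-1])),
                        end_exclusion, len(xt))


@dataclass
class DomainSummary:
    """Domain extents (percent of chromosome) and per-domain rates (cM/Mb)."""

    chrom: str
    lc: float
    cr: float
    pct_left: float
    pct_center: float
    pct_right: float
    rate_left: float
    rate_center: float
    rate_right: float
    normalized_to: float | None
    domains: bool = True

    def as_row(self) -> dict:
        return {"chrom": self.chrom, "LC": self.lc, "CR": self.cr,
                "pct_left": self.pct_left, "pct_center": self.pct_center,
                "pct_right": self.pct_right, "rate_left": self.rate_left,
                "rate_center": self.rate_center, "rate_right": self.rate_right,
                "domains": "Yes" if self.domains else "No"}


def domain_summary(fit: SegmentedFit, m: MareyMap,
                   normalize_to: float | None = 50.0) -> DomainSummary:
    """Summarise a segmented fit as domain percents and rates.

    When ``normalize_to`` is set the genetic map is rescaled so the
    chromosome's total genetic length equals that many cM before rates are
    reported (the complete-interference convention); percents always refer to
    physical length including the excluded tips.
    """
    L = m.length_bp
    scale = 1.0
    if normalize_to is not None and m.genetic_length > 0:
        scale = normalize_to / m.genetic_length
    rates = tuple(s * scale for s in fit.slopes_cm_per_mb)
    flagged = _flag_domains(fit, rates)
    return DomainSummary(
        chrom=m.chrom, lc=fit.lc, cr=fit.cr,
        pct_left=100.0 * fit.lc / L,
        pct_center=100.0 * (fit.cr - fit.lc) / L,
        pct_right=100.0 * (L - fit.cr) / L,
        rate_left=rates[0], rate_center=rates[1], rate_right=rates[2],
        normalized_to=normalize_to, domains=flagged,
    )


def _flag_domains(fit: SegmentedFit, rates: tuple[float, float, float]) -> bool:
    """Arm/centre structure check: centre slower than both arms, non-trivial extent.

    Chromosomes whose fitted pattern does not match the expected
    high-arm/low-centre organisation are marked (the regression still runs,
    but its numbers are not meaningful as domain estimates).
    """
    if fit.degenerate:
        return False
    left, center, right = rates
    if not (center < left and center < right):
        return False
    span = fit.x_range[1] - fit.x_range[0]
    if (fit.cr - fit.lc) < 0.05 * span:
        return False
    return True


# ---------------------------------------------------------------------------
# model / results interface


class SegmentedMareyModel:
    """Three-segment recombination-domain model for one chromosome's Marey map.

    Pipeline: (optional) rescale the genetic axis to ``normalize_to`` cM,
    interpolate at ``n_points`` even physical positions, exclude
    ``end_exclusion`` bp per end, fit the continuous two-breakpoint model by
    exhaustive grid search.
    """

    def __init__(self, marey_map: MareyMap, n_points: int = 200,
                 end_exclusion: float = 1.0e6, normalize_to: float | None = 50.0,
                 rescale_before_fit: bool = True):
        self.map = marey_map
        self.n_points = n_points
        self.end_exclusion = end_exclusion
        self.normalize_to = normalize_to
        self.rescale_before_fit = rescale_before_fit

    @classmethod
    def from_marker_table(cls, table: MarkerTable, chrom: str, **kw) -> "SegmentedMareyModel":
        return cls(MareyMap.from_marker_table(table, chrom), **kw)

    def fit(self) -> "SegmentedMareyResults":
        m = self.map
        if self.normalize_to is not None and self.rescale_before_fit:
            m = m.normalized(self.normalize_to)
        x, y = interpolate_map(m, self.n_points)
        fit = fit_segmented(x, y, end_exclusion=self.end_exclusion)
        # rates from the fitted (possibly pre-rescaled) slopes
        post_norm = None if self.rescale_before_fit else self.normalize_to
        summary = domain_summary(fit, m, normalize_to=post_norm)
        return SegmentedMareyResults(self, fit, summary, (x, y))


class SegmentedMareyResults:
    """Fitted domain boundaries, rates and diagnostics for one chromosome."""

    def __init__(self, model: SegmentedMareyModel, fit: SegmentedFit,
                 domains: DomainSummary, grid: tuple[np.ndarray, np.ndarray]):
        self.model = model
        self.fit = fit
        self.domains = domains
        self.grid = grid

    @property
    def params(self) -> pd.Series:
        return pd.Series({"LC": self.fit.lc, "CR": self.fit.cr,
                          "rate_left": self.domains.rate_left,
                          "rate_center": self.domains.rate_center,
                          "rate_right": self.domains.rate_right,
                          "intercept": self.fit.intercept})

    @property
    def rss(self) -> float:
        return self.fit.rss

    def summary(self) -> str:
        d = self.domains
        lines = [
            f"Segmented Marey fit: chromosome {d.chrom}",
            f"  physical length     {self.model.map.length_bp / _MB:8.2f} Mb",
            f"  LC boundary         {self.fit.lc / _MB:8.2f} Mb",
            f"  CR boundary         {self.fit.cr / _MB:8.2f} Mb",
            f"  domain extents      {d.pct_left:.1f}% / {d.pct_center:.1f}% / {d.pct_right:.1f}% (L/C/R)",
            f"  rates (cM/Mb)       {d.rate_left:.2f} / {d.rate_center:.2f} / {d.rate_right:.2f}",
            f"  RSS                 {self.fit.rss:.4g}  (n={self.fit.n_points} grid points)",
            f"  domain structure    {'yes' if d.domains else 'NOT domain-like'}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Marey map with the fitted segments and boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model.map
        ax.plot(m.bp / _MB, m.cM, ".", ms=3, alpha=0.6, label="markers")
        xs = np.linspace(*self.fit.x_range, 200)
        ax.plot(xs / _MB, self.fit.predict(xs), "-", lw=2, label="3-segment fit")
        for b in (self.fit.lc, self.fit.cr):
            ax.axvline(b / _MB, color="gray", lw=1, ls="--")
        ax.set_xlabel("physical position (Mb)")
        ax.set_ylabel("genetic position (cM)")
        ax.set_title(m.chrom)
        ax.legend()
        return ax


def species_map_report(tables: dict[str, MarkerTable], n_points: int = 200,
                       end_exclusion: float = 1.0e6, normalize_to: float | None = 50.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every chromosome of every species; emit a domain table and
    normalized Marey coordinates (physical and genetic positions each scaled
    to [0, 1]) for plotting.

    Per-chromosome failures are reported as rows with ``domains="No"`` and
    NaN estimates rather than raised.
    """
    rows = []
    coords = []
    for species, table in tables.items():
        for chrom in table.chromosomes:
            m = MareyMap.from_marker_table(table, chrom)
            coords.append(pd.DataFrame({
                "species": species, "chrom": chrom,
                "rel_bp": m.bp / m.length_bp,
                "rel_cM": (m.cM - m.cM[0]) / m.genetic_length if m.genetic_length > 0 else 0.0,
            }))
            try:
                res = SegmentedMareyModel(m, n_points=n_points, end_exclusion=end_exclusion,
                                          normalize_to=normalize_to).fit()
                row = res.domains.as_row()
            except ValueError:
                row = {"chrom": chrom, "domains": "No"}
            row["species"] = species
            rows.append(row)
    report = pd.DataFrame(rows)
    cols = ["species"] + [c for c in report.columns if c != "species"]
    return report[cols], pd.concat(coords, ignore_index=True)
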