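"""Synthetic-data generation: every input the analyses consume, with the
statistical structure they assume, plus recorded ground truth.

Fixtures mirror the mapping experiment's data shapes:

- Marey marker tables sampled from piecewise-linear arm/centre/arm maps
  (tips with zero recombination), with per-marker cM jitter followed by a
  running-maximum monotonisation so the table validates;
- per-line ancestry mosaics and founder-call matrices from the G4BC2
  simulator, with the aggregated genetic map;
- 16-cross progeny count tables under the two-locus Medea model;
- 2x2 skew tables at a prescribed transmission bias;
- toy genomes (FASTA/GFF3/BED) with prescribed per-feature GC, codon-usage
  profile and optional telomeric ends.

Each generator is deterministic under a fixed seed, and writes a sidecar
``*.truth.yaml`` with its parameters when given an output directory.

Presets (``PRESETS``): "becei-map" (a six-chromosome map whose true domain
parameters match the published *C. becei* estimates: mean autosome arm rate
8.1 cM/Mb with range 6.5-10.9, centre rates 0.1-0.6 cM/Mb, chromosome V
centre spanning 63% of its length), "medea-16cross", "skew-1719" and
"gc-heterogeneity".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, rng_for
from .io import (FeatureSet, MarkerTable, ProgenyCountTable, SequenceSet,
                 write_bed, write_fasta, write_gff3, write_marker_table,
                 write_progeny_table)
from .medea import MedeaModel, cross_classes, make_progeny_table, simulate_progeny_counts
from .meiosis import ChromosomeModel, CrossDesign, simulate_line
from .sexlinkage import SkewCounts

# ---------------------------------------------------------------------------
# configuration


@dataclass
class MareyDomainSpec:
    """True domain geometry for one chromosome's synthetic Marey map.

    Tips (``tip_mb`` per end) have zero recombination; arms share
    ``arm_rate``; the centre spans ``center_fraction`` of the chromosome,
    centred on the midpoint, at ``center_rate``.  Rates in cM/Mb, length Mb.
    """

    name: str
    length_mb: float
    arm_rate: float
    center_rate: float
    center_fraction: float
    tip_mb: float = 1.0
    kind: str = "autosome"

    def breakpoints_mb(self) -> tuple[float, float]:
        half = self.center_fraction * self.length_mb / 2.0
        return self.length_mb / 2.0 - half, self.length_mb / 2.0 + half

    def true_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Node positions (Mb) and cumulative cM of the true piecewise map."""
        lc, cr = self.breakpoints_mb()
        xs = np.array([0.0, self.tip_mb, lc, cr, self.length_mb - self.tip_mb, self.length_mb])
        rates = np.array([0.0, self.arm_rate, self.center_rate, self.arm_rate, 0.0])
        if lc < self.tip_mb or cr > self.length_mb - self.tip_mb:
            raise ConfigError(f"{self.name}: centre overlaps tips")
        ys = np.concatenate([[0.0], np.cumsum(np.diff(xs) * rates)])
        return xs, ys

    @property
    def genetic_length(self) -> float:
        return float(self.true_map()[1][-1])


@dataclass
class ScenarioConfig:
    """All knobs for the synthetic study, serialisable to YAML."""

    seed: int = 0
    chromosomes: list[MareyDomainSpec] = dc_field(default_factory=list)
    n_markers: int = 200
    marey_noise_cm: float = 0.25
    # Medea
    beta_i: float = 0.77
    beta_iii: float = 0.77
    medea_rule: str = "product"
    baseline_mortality: float = 0.0
    embryos_per_cross: int = 1000
    replicates_per_cross: int = 1
    # skew
    transmission_bias: float = 0.457   # unpreferred-phase fraction
    n_offspring: int = 1719
    # composition
    exon_gc: float = 0.60
    intergenic_gc: float = 0.30
    repeat_gc: float = 0.45
    intron_gc: float = 0.35
    telomere_units: int = 10
    genome_seq_length: int = 100_000

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        d = yaml.safe_load(text)
        chroms = [MareyDomainSpec(**c) for c in d.pop("chromosomes", [])]
        return cls(chromosomes=chroms, **d)


def _becei_like_chromosomes() -> list[MareyDomainSpec]:
    # Domain truths chosen so each chromosome spans 50 cM (tips excluded),
    # the five autosome arm rates average 8.1 cM/Mb with range topping at
    # 10.9 on chromosome V (whose centre covers 63% of its length), and
    # centre rates sit in 0.1-0.6 cM/Mb.
    return [
        MareyDomainSpec("I", 17.0, 6.500, 0.40, 0.4581),
        MareyDomainSpec("II", 17.5, 7.300, 0.30, 0.5155),
        MareyDomainSpec("III", 16.0, 7.600, 0.60, 0.5036),
        MareyDomainSpec("IV", 16.5, 8.193, 0.25, 0.5249),
        MareyDomainSpec("V", 17.0, 10.907, 0.30, 0.6300),
        MareyDomainSpec("X", 24.0, 5.232, 0.30, 0.5500, kind="X"),
    ]


PRESETS: dict[str, ScenarioConfig] = {
    "becei-map": ScenarioConfig(seed=2082, chromosomes=_becei_like_chromosomes()),
    "medea-16cross": ScenarioConfig(seed=2083, beta_i=0.77, beta_iii=0.77,
                                    embryos_per_cross=1000),
    "skew-1719": ScenarioConfig(seed=4602, transmission_bias=0.457, n_offspring=1719),
    "gc-heterogeneity": ScenarioConfig(seed=55, exon_gc=0.60, intergenic_gc=0.30),
}


def _write_truth(out_dir: Path | None, stem: str, truth: dict) -> None:
    if out_dir is not None:
        (Path(out_dir) / f"{stem}.truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))


# ---------------------------------------------------------------------------
# Marey fixtures


def make_marey_fixture(cfg: ScenarioConfig, out_dir: str | Path | None = None
                       ) -> tuple[MarkerTable, dict]:
    """Marker table sampled from the configured true domain maps.

    Markers are evenly spaced; cM values get iid Gaussian jitter
    (``marey_noise_cm``) and are monotonised with a running maximum so the
    table validates.  Returns the table and the ground-truth record
    (per-chromosome LC/CR in bp and true rates).
    """
    if not cfg.chromosomes:
        raise ConfigError("scenario has no chromosomes")
    rng = rng_for(cfg.seed, 10)
    rows = []
    truth: dict = {"chromosomes": {}}
    lengths = {}
    for spec in cfg.chromosomes:
        xs, ys = spec.true_map()
        if np.any(np.diff(ys) < 0):
            raise ConfigError(f"{spec.name}: negative rate produced a non-monotone map")
        bp = np.linspace(0.0, spec.length_mb, cfg.n_markers)
        cm = np.interp(bp, xs, ys)
        cm = cm + rng.normal(0.0, cfg.marey_noise_cm, size=cm.size)
        cm = np.maximum.accumulate(np.clip(cm, 0.0, None))
        lc, cr = spec.breakpoints_mb()
        rows.append(pd.DataFrame({"chrom": spec.name,
                                  "bp": (bp * 1e6).astype(np.int64),
                                  "cM": cm}))
        lengths[spec.name] = int(spec.length_mb * 1e6)
        truth["chromosomes"][spec.name] = {
            "LC_bp": lc * 1e6, "CR_bp": cr * 1e6,
            "arm_rate": spec.arm_rate, "center_rate": spec.center_rate,
            "center_fraction": spec.center_fraction,
            "genetic_length": spec.genetic_length,
        }
    table = MarkerTable(pd.concat(rows, ignore_index=True), lengths=lengths)
    if out_dir is not None:
        write_marker_table(table, Path(out_dir) / "markers.tsv")
    _write_truth(Path(out_dir) if out_dir else None, "markers", truth)
    return table, truth


# ---------------------------------------------------------------------------
# G4BC2 line fixtures


def make_g4bc2_lines(cfg: ScenarioConfig, n_lines: int,
                     design: CrossDesign | None = None,
                     markers_per_chrom: int = 50,
                     out_dir: str | Path | None = None
                     ) -> tuple[dict[str, list], pd.DataFrame, MarkerTable]:
    """Simulated mapping lines: ancestry mosaics, founder calls, derived map.

    Returns (haplotypes per chromosome, call matrix, aggregated MarkerTable).
    Calls give the founder ancestry of each line's unique recombinant
    haplotype ("BB" where it carries founder B, "AA" elsewhere), the way the
    mapping data score each line's recombinant genome.  The aggregated map's
    cM column is the cumulative mean ancestry-switch count between marker
    positions, scaled to centiMorgans.
    """
    if n_lines < 2:
        raise ConfigError("need at least 2 lines")
    design = design or CrossDesign()
    chroms = [ChromosomeModel(s.name, s.length_mb * 1e6,
                              kind="X" if s.kind == "X" else "autosome")
              for s in cfg.chromosomes] or None
    if chroms is None:
        raise ConfigError("scenario has no chromosomes")
    haps: dict[str, list] = {c.name: [] for c in chroms}
    for i in range(n_lines):
        rng = rng_for(cfg.seed, 20, i)
        line = simulate_line(design, chroms, rng)
        for name, h in line.items():
            haps[name].append(h)

    call_rows = []
    map_rows = []
    for c in chroms:
        grid = np.linspace(0.0, c.length_bp, markers_per_chrom, endpoint=False) + \
            c.length_bp / markers_per_chrom / 2
        calls = np.empty((markers_per_chrom, n_lines), dtype=object)
        for j, h in enumerate(haps[c.name]):
            for k, pos in enumerate(grid):
                calls[k, j] = "BB" if h.label_at(pos) == "B" else "AA"
        # genetic map from mean switch counts per interval
        switch_mean = np.zeros(markers_per_chrom)
        for h in haps[c.name]:
            inner = np.asarray(h.bounds[1:-1])
            if inner.size:
                idx = np.searchsorted(grid, inner)
                idx = idx[idx < markers_per_chrom]
                np.add.at(switch_mean, idx, 1.0)
        switch_mean /= n_lines
        cm = 100.0 * np.concatenate([[0.0], np.cumsum(switch_mean[:-1])])
        for k, pos in enumerate(grid):
            map_rows.append({"chrom": c.name, "bp": int(pos), "cM": float(cm[k])})
        for k in range(markers_per_chrom):
            call_rows.append({"chrom": c.name, "bp": int(grid[k]),
                              **{f"line{j}": calls[k, j] for j in range(n_lines)}})
    call_df = pd.DataFrame(call_rows)
    table = MarkerTable(pd.DataFrame(map_rows),
                        lengths={c.name: int(c.length_bp) for c in chroms})
    if out_dir is not None:
        out = Path(out_dir)
        call_df.to_csv(out / "founder_calls.tsv", sep="\t", index=False)
        write_marker_table(table, out / "derived_map.tsv")
        _write_truth(out, "g4bc2", {"seed": cfg.seed, "n_lines": n_lines,
                                    "design": dataclasses.asdict(design)})
    return haps, call_df, table


# ---------------------------------------------------------------------------
# Medea count tables


def make_medea_table(cfg: ScenarioConfig, out_dir: str | Path | None = None
                     ) -> tuple[ProgenyCountTable, dict]:
    """16-class progeny count table under the configured Medea penetrances."""
    model = MedeaModel(cfg.beta_i, cfg.beta_iii, rule=cfg.medea_rule)
    rows = []
    plate = 1
    for rep in range(cfg.replicates_per_cross):
        for c in cross_classes():
            rng = rng_for(cfg.seed, 30, rep, c.class_id)
            rows.append(simulate_progeny_counts(
                c, model, cfg.embryos_per_cross,
                baseline_mortality=cfg.baseline_mortality, rng=rng, plate=plate))
            plate += 1
    table = make_progeny_table(rows)
    truth = {"beta_i": cfg.beta_i, "beta_iii": cfg.beta_iii, "rule": cfg.medea_rule,
             "baseline_mortality": cfg.baseline_mortality, "seed": cfg.seed}
    if out_dir is not None:
        write_progeny_table(table, Path(out_dir) / "medea_counts.tsv")
    _write_truth(Path(out_dir) if out_dir else None, "medea_counts", truth)
    return table, truth


# ---------------------------------------------------------------------------
# skew tables


def make_skew_counts(cfg: ScenarioConfig) -> tuple[SkewCounts, dict]:
    """2x2 insertion x sex counts at the configured unpreferred-phase fraction.

    Offspring sex is an independent fair draw from the paternal X/nullosome
    segregation; the insertion phase is unpreferred with probability
    ``transmission_bias`` (0.5 = no skew).
    """
    rng = rng_for(cfg.seed, 40)
    male = rng.random(cfg.n_offspring) < 0.5
    unpref = rng.random(cfg.n_offspring) < cfg.transmission_bias
    # preferred phase: insertion with the nullosome (males insertion+, females insertion-)
    ins = np.where(male, ~unpref, unpref)
    counts = SkewCounts(int((male & ins).sum()), int((male & ~ins).sum()),
                        int((~male & ins).sum()), int((~male & ~ins).sum()))
    return counts, {"transmission_bias": cfg.transmission_bias, "n": cfg.n_offspring,
                    "seed": cfg.seed}


# ---------------------------------------------------------------------------
# toy genomes


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=probs)])


def _codon_stream(rng: np.random.Generator, n_codons: int, gc: float,
                  profile: dict[str, float] | None) -> str:
    """Coding sequence as sampled codons (no stops), GC-weighted or from a profile."""
    from .composition import CODON_FAMILIES

    codons = [c for fam in CODON_FAMILIES.values() for c in fam]
    if profile:
        weights = np.array([profile.get(c, 0.0) for c in codons])
        if weights.sum() <= 0:
            raise ConfigError("codon profile has no mass on sense codons")
    else:
        gcf = np.array([sum(b in "GC" for b in c) / 3 for c in codons])
        weights = gc ** (3 * gcf) * (1 - gc) ** (3 * (1 - gcf))
    weights = weights / weights.sum()
    picks = rng.choice(len(codons), size=n_codons, p=weights)
    return "".join(codons[i] for i in picks)


def make_toy_genome(cfg: ScenarioConfig, n_genes: int = 20,
                    codon_profile: dict[str, float] | None = None,
                    out_dir: str | Path | None = None
                    ) -> tuple[SequenceSet, FeatureSet, dict]:
    """A single-sequence toy genome with prescribed per-feature GC.

    Layout per gene: intergenic spacer, then a gene whose exons (CDS) are
    codon streams at ``exon_gc`` separated by one intron at ``intron_gc``;
    a repeat at ``repeat_gc`` is dropped into every other spacer.  Optional
    telomeric repeat runs cap both ends.
    """
    for name, g in (("exon", cfg.exon_gc), ("intergenic", cfg.intergenic_gc),
                    ("repeat", cfg.repeat_gc), ("intron", cfg.intron_gc)):
        if not 0.0 <= g <= 1.0:
            raise ConfigError(f"impossible GC target for {name}: {g}")
    rng = rng_for(cfg.seed, 50)
    per_gene = max(cfg.genome_seq_length // max(n_genes, 1), 600)
    spacer_n = per_gene // 3
    repeat_n = max(per_gene // 10, 30)
    exon_codons = max(per_gene // 9, 30)
    intron_n = max(per_gene // 6, 60)

    parts: list[str] = []
    feats: list[dict] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start

    tel = "TTAGGC"
    if cfg.telomere_units:
        from Bio.Seq import Seq
        emit(str(Seq(tel).reverse_complement()) * cfg.telomere_units)
    for g in range(n_genes):
        start = emit(_random_seq(rng, spacer_n, cfg.intergenic_gc))
        if g % 2 == 0:
            rstart = emit(_random_seq(rng, repeat_n, cfg.repeat_gc))
            feats.append({"seqid": "toy1", "feature_class": "repeat",
                          "start": rstart, "end": rstart + repeat_n, "strand": "+"})
            emit(_random_seq(rng, spacer_n // 2, cfg.intergenic_gc))
        gene_start = pos
        e1 = emit(_codon_stream(rng, exon_codons, cfg.exon_gc, codon_profile))
        e1_len = pos - e1
        emit(_random_seq(rng, intron_n, cfg.intron_gc))
        e2 = emit(_codon_stream(rng, exon_codons, cfg.exon_gc, codon_profile))
        e2_len = pos - e2
        feats.append({"seqid": "toy1", "feature_class": "gene",
                      "start": gene_start, "end": pos, "strand": "+"})
        for es, el in ((e1, e1_len), (e2, e2_len)):
            feats.append({"seqid": "toy1", "feature_class": "exon",
                          "start": es, "end": es + el, "strand": "+"})
            feats.append({"seqid": "toy1", "feature_class": "CDS",
                          "start": es, "end": es + el, "strand": "+"})
    emit(_random_seq(rng, spacer_n, cfg.intergenic_gc))
    if cfg.telomere_units:
        emit(tel * cfg.telomere_units)

    seqs = SequenceSet({"toy1": "".join(parts)})
    fset = FeatureSet(pd.DataFrame(feats))
    truth = {"exon_gc": cfg.exon_gc, "intergenic_gc": cfg.intergenic_gc,
             "repeat_gc": cfg.repeat_gc, "intron_gc": cfg.intron_gc,
             "telomere_units": cfg.telomere_units, "seed": cfg.seed}
    if out_dir is not None:
        out = Path(out_dir)
        write_fasta(seqs, out / "toy.fa")
        write_gff3(fset, out / "toy.gff3")
        write_bed(fset, out / "toy_repeats.bed")
        _write_truth(out, "toy_genome", truth)
    return seqs, fset, truth
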