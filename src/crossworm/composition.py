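"""Genome composition statistics: windowed GC, nested per-feature GC,
GC variance by scale, telomeric repeat runs, RSCU and amino-acid usage.

GC content is G+C over unambiguous (non-N) bases; N is excluded from both
numerator and denominator.  Windows tile from position 0 and a trailing
partial window is dropped so windows at a given scale are equal length.

Per-feature GC uses nested masking: exon bases are assigned first, then
repeat bases outside exons, then intronic bases (within gene spans) not
already taken, and everything else is intergenic -- the four classes
partition the unambiguous genome exactly.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .io import FeatureSet, SequenceSet

_STANDARD_TABLE = unambiguous_dna_by_id[1]


def _codon_families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cods) for aa, cods in fams.items()}


CODON_FAMILIES = _codon_families()
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)


def _seq_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(is_gc, is_unambiguous) boolean arrays for a sequence."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (b == ord("G")) | (b == ord("C"))
    is_acgt = is_gc | (b == ord("A")) | (b == ord("T"))
    return is_gc, is_acgt


# ---------------------------------------------------------------------------
# windowed GC


def window_gc(seqs: SequenceSet, window: int) -> pd.DataFrame:
    """Non-overlapping window GC per sequence; trailing partial windows dropped.

    Columns: seqid, start, end, gc_percent (NaN for all-N windows), n_unambiguous.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for name, seq in seqs.items():
        n_win = len(seq) // window
        if n_win == 0:
            warnings.warn(f"sequence {name!r} shorter than one window; skipped")
            continue
        gc, ok = _seq_arrays(seq[:n_win * window])
        gc_w = gc.reshape(n_win, window).sum(axis=1)
        ok_w = ok.reshape(n_win, window).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(ok_w > 0, 100.0 * gc_w / ok_w, np.nan)
        for i in range(n_win):
            rows.append({"seqid": name, "start": i * window, "end": (i + 1) * window,
                         "gc_percent": float(pct[i]), "n_unambiguous": int(ok_w[i])})
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "gc_percent", "n_unambiguous"])


def gc_variance_profile(seqs: SequenceSet, scales: list[int]) -> pd.DataFrame:
    """Sample variance of window GC at each scale (pooled over sequences)."""
    rows = []
    for scale in scales:
        w = window_gc(seqs, scale)
        vals = w["gc_percent"].dropna().to_numpy()
        var = float(np.var(vals, ddof=1)) if len(vals) >= 2 else np.nan
        rows.append({"scale": scale, "variance": var, "n_windows": len(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nested feature masking

_CLASS_ORDER = ("exon", "repeat", "intron", "intergenic")


@dataclass
class FeatureClassGC:
    """Per-class GC percent and unambiguous base counts under nested masking."""

    table: pd.DataFrame  # index: exon/repeat/intron/intergenic/genome

    def gc(self, cls: str) -> float:
        return float(self.table.loc[cls, "gc_percent"])

    def bases(self, cls: str) -> int:
        return int(self.table.loc[cls, "n_unambiguous"])


def _paint(mask: np.ndarray, feats: pd.DataFrame, value: int, only_where: int) -> None:
    for _, r in feats.iterrows():
        seg = mask[int(r["start"]):int(r["end"])]
        seg[seg == only_where] = value


def nested_feature_gc(seqs: SequenceSet, feats: FeatureSet) -> FeatureClassGC:
    """GC by feature class with exon-first, then repeat, nested masking.

    A repeat inside an exon counts as exon; introns are gene-span bases that
    are neither exon nor repeat; the remainder is intergenic.  Class base
    counts partition the unambiguous genome length by construction.
    """
    gc_tot = Counter()
    n_tot = Counter()
    for name, seq in seqs.items():
        gc, ok = _seq_arrays(seq)
        # 0 intergenic, 1 exon, 2 repeat, 3 intron
        mask = np.zeros(len(seq), dtype=np.int8)
        sub = feats.df[feats.df["seqid"] == name]
        _paint(mask, sub[sub["feature_class"] == "exon"], 1, 0)
        _paint(mask, sub[sub["feature_class"] == "repeat"], 2, 0)
        _paint(mask, sub[sub["feature_class"] == "gene"], 3, 0)
        for value, cls in ((1, "exon"), (2, "repeat"), (3, "intron"), (0, "intergenic")):
            sel = mask == value
            gc_tot[cls] += int(gc[sel & ok].sum())
            n_tot[cls] += int((sel & ok).sum())
        gc_tot["genome"] += int(gc[ok].sum())
        n_tot["genome"] += int(ok.sum())
    rows = {}
    for cls in _CLASS_ORDER + ("genome",):
        n = n_tot[cls]
        rows[cls] = {"gc_percent": 100.0 * gc_tot[cls] / n if n else np.nan,
                     "n_unambiguous": n}
    return FeatureClassGC(pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# telomeric repeats


def _tandem_run(seq: str, unit: str, from_end: bool) -> int:
    n = 0
    if from_end:
        while seq.endswith(unit * (n + 1)):
            n += 1
    else:
        while seq.startswith(unit * (n + 1)):
            n += 1
    return n


def count_telomeric_repeats(seqs: SequenceSet, unit: str = "TTAGGC") -> pd.DataFrame:
    """Maximal tandem runs of the telomere unit at each sequence end.

    The right end is scanned for the unit in forward orientation, the left
    end for its reverse complement (telomeres point outward).
    """
    if not unit:
        raise ValueError("repeat unit must be non-empty")
    rc = str(Seq(unit).reverse_complement())
    rows = []
    for name, seq in seqs.items():
        rows.append({"seqid": name,
                     "left_units": _tandem_run(seq, rc, from_end=False),
                     "right_units": _tandem_run(seq, unit, from_end=True)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon and amino-acid usage


def codon_counts(cds: SequenceSet) -> Counter:
    """Codon counts over coding-strand CDS; trailing partial codons trimmed."""
    if len(cds) == 0:
        raise ValueError("empty CDS set")
    counts: Counter = Counter()
    for name, seq in cds.items():
        if len(seq) % 3:
            warnings.warn(f"CDS {name!r} length not divisible by 3; trailing remainder trimmed")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                continue
            counts[codon] += 1
    return counts


def rscu(cds: SequenceSet) -> pd.DataFrame:
    """Relative synonymous codon usage per codon, grouped by amino acid.

    RSCU = observed count x family size / family total; within an observed
    family the values average to 1.  Stop codons are excluded; single-codon
    families (Met, Trp) have RSCU 1 when observed.  Unobserved families
    report NaN.
    """
    counts = codon_counts(cds)
    rows = []
    for aa, fam in sorted(CODON_FAMILIES.items()):
        total = sum(counts[c] for c in fam)
        for codon in fam:
            val = counts[codon] * len(fam) / total if total > 0 else np.nan
            rows.append({"amino_acid": aa, "codon": codon,
                         "count": counts[codon], "rscu": val})
    return pd.DataFrame(rows)


def codon_gc_fraction(aa: str) -> float:
    """Mean fraction of G/C positions across the codons encoding ``aa``."""
    fam = CODON_FAMILIES[aa]
    return float(np.mean([sum(b in "GC" for b in c) / 3.0 for c in fam]))


def aa_usage(cds_sets: dict[str, SequenceSet]) -> pd.DataFrame:
    """Amino-acid usage percents per species with cross-species deviations.

    Deviation = species percent minus the unweighted cross-species mean for
    that amino acid (so deviations sum to zero over species).  The codon_gc
    column is the mean G+C fraction of each amino acid's codons in the
    standard code.  Species with zero residues are excluded with a warning.
    """
    if not cds_sets:
        raise ValueError("need at least one species")
    aas = sorted(CODON_FAMILIES)
    per_species = {}
    for species, cds in cds_sets.items():
        counts = codon_counts(cds)
        aa_counts = {aa: sum(counts[c] for c in fam) for aa, fam in CODON_FAMILIES.items()}
        total = sum(aa_counts.values())
        if total == 0:
            warnings.warn(f"species {species!r} has no residues; excluded")
            continue
        per_species[species] = {aa: 100.0 * aa_counts[aa] / total for aa in aas}
    pct = pd.DataFrame(per_species).T[aas]
    mean = pct.mean(axis=0)
    rows = []
    for species in pct.index:
        for aa in aas:
            rows.append({"species": species, "amino_acid": aa,
                         "percent": pct.loc[species, aa],
                         "deviation": pct.loc[species, aa] - mean[aa],
                         "codon_gc": codon_gc_fraction(aa)})
    return pd.DataFrame(rows)
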