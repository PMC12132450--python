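"""Readers and writers for the external formats the pipeline touches.

Tabular inputs are TSV/CSV with a header row; genomic inputs are FASTA,
GFF3 (1-based, end-inclusive) and BED (0-based, half-open).  All
coordinates are normalised to 0-based half-open internally, so a feature's
internal ``end - start`` always equals its BED ``end - start`` and its
GFF3 ``end - start + 1``.  Conversion happens only here, at the I/O
boundary.

Marker tables from different sources use heterogeneous column headers, so
:func:`read_marker_table` takes an explicit column map instead of sniffing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import FormatError, log

# ---------------------------------------------------------------------------
# marker tables

#: default column names for marker tables written by this package
MARKER_COLUMNS = {"chrom": "chrom", "bp": "bp", "cM": "cM"}


@dataclass
class MarkerTable:
    """Genetic-map markers: per row a chromosome, physical bp and genetic cM.

    ``lengths`` maps chromosome id to physical length (bp).  Rows are kept
    sorted by (chromosome, bp).  ``violations`` lists rows (by original file
    row number) where the genetic position decreased with physical position,
    i.e. where the map is not monotone.
    """

    df: pd.DataFrame
    lengths: dict[str, int] = field(default_factory=dict)
    violations: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "cM"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"marker table missing columns: {sorted(required - set(self.df.columns))}")
        self.df = self.df.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
        if (self.df["bp"] < 0).any() or (self.df["cM"] < 0).any():
            raise FormatError("marker positions must be non-negative")
        self._find_violations()
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self.lengths.setdefault(str(chrom), int(sub["bp"].max()))

    def _find_violations(self) -> None:
        self.violations = []
        for chrom, sub in self.df.groupby("chrom", sort=False):
            dec = np.flatnonzero(np.diff(sub["cM"].to_numpy()) < 0)
            for i in dec:
                self.violations.append((str(chrom), int(sub.index[i + 1])))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"].astype(str)))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_marker_table(path: str | Path, columns: Mapping[str, str] | None = None,
                      lengths: Mapping[str, int] | None = None, sep: str | None = None) -> MarkerTable:
    """Read a marker TSV/CSV into a validated :class:`MarkerTable`.

    ``columns`` maps the canonical names ``chrom``/``bp``/``cM`` to the file's
    header names; by default the canonical names themselves are expected.
    Non-monotone genetic positions are reported in ``MarkerTable.violations``
    per chromosome (row numbers refer to the sorted table), not raised.
    """
    path = Path(path)
    colmap = dict(MARKER_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})[["chrom", "bp", "cM"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("bp", "cM"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            raise FormatError(f"{path.name}: non-numeric value in column '{col}' at data row {bad[0] + 1}")
        df[col] = coerced
    df["bp"] = df["bp"].astype(np.int64)
    table = MarkerTable(df, lengths=dict(lengths) if lengths else {})
    if table.violations:
        log.warning("%s: %d marker(s) with decreasing cM", path.name, len(table.violations))
    return table


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# progeny count tables

PROGENY_COLUMNS = [
    "plate", "embryos", "unhatched", "deformed",
    "adult_females", "adult_males", "l4_females", "l4_males", "larvae",
    "mother", "father", "cross_class",
]
_COUNT_COLUMNS = ["embryos", "unhatched", "deformed", "adult_females",
                  "adult_males", "l4_females", "l4_males", "larvae"]


@dataclass
class ProgenyCountTable:
    """Per-plate progeny counts from the 16-cross segregation experiment.

    One row per mother: embryos laid, then the fates scored on the following
    days (unhatched embryos, deformed/arrested L1s, wild-type adults and L4s
    by sex, active L1-L3 larvae), the parental genotype labels and the cross
    class id (1-16).  ``missing`` is derived: embryos not accounted for by
    any scored class, floored at zero.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROGENY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"progeny table missing columns: {missing}")
        df = self.df.copy()
        for col in _COUNT_COLUMNS:
            df[col] = pd.to_numeric(df[col])
            if (df[col] < 0).any():
                raise ValueError(f"negative count in column '{col}'")
        if not df["cross_class"].isin(range(1, 17)).all():
            raise ValueError("cross_class must be in 1..16")
        accounted = df[_COUNT_COLUMNS[1:]].sum(axis=1)
        gap = df["embryos"] - accounted
        if (gap < 0).any():
            n = int((gap < 0).sum())
            warnings.warn(f"{n} row(s) with scored categories exceeding embryos laid; missing floored at 0")
        df["missing"] = gap.clip(lower=0).astype(int)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def read_progeny_table(path: str | Path, sep: str = "\t") -> ProgenyCountTable:
    return ProgenyCountTable(pd.read_csv(path, sep=sep))


def write_progeny_table(table: ProgenyCountTable, path: str | Path) -> None:
    table.df.drop(columns=["missing"], errors="ignore").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomes: FASTA + GFF3 + BED

@dataclass
class SequenceSet:
    """Named DNA sequences over {A,C,G,T,N} (uppercased on load)."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.seqs) == 0:
            raise FormatError("empty sequence set")
        for name, s in self.seqs.items():
            if len(s) == 0:
                raise FormatError(f"sequence {name!r} is empty")

    def __getitem__(self, name: str) -> str:
        return self.seqs[name]

    def __iter__(self):
        return iter(self.seqs)

    def __len__(self) -> int:
        return len(self.seqs)

    def items(self):
        return self.seqs.items()

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.seqs.items()}


FEATURE_CLASSES = ("gene", "exon", "CDS", "repeat")


@dataclass
class FeatureSet:
    """Features on sequences, internal 0-based half-open coordinates.

    Columns: seqid, feature_class (gene/exon/CDS/repeat), start, end, strand.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"seqid", "feature_class", "start", "end", "strand"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"feature set missing columns: {sorted(required - set(self.df.columns))}")
        if (self.df["end"] < self.df["start"]).any():
            raise FormatError("feature with end < start")
        self.df = self.df.reset_index(drop=True)

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.df[self.df["feature_class"] == cls]

    def __len__(self) -> int:
        return len(self.df)


_GFF_TYPE_MAP = {"gene": "gene", "exon": "exon", "cds": "CDS"}


def read_genome(fasta: str | Path, gff3: str | Path | None = None,
                repeat_bed: str | Path | None = None) -> tuple[SequenceSet, FeatureSet]:
    """Load a genome FASTA plus optional GFF3 annotation and repeat BED.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) are normalised to internal 0-based half-open.  Features on
    unknown sequences or extending past the sequence end are rejected.
    """
    seqs = SequenceSet({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")})
    lengths = seqs.lengths()
    rows: list[dict] = []
    if gff3 is not None:
        gff = pd.read_csv(gff3, sep="\t", comment="#", header=None,
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attributes"],
                          dtype={"seqid": str})
        for _, r in gff.iterrows():
            cls = _GFF_TYPE_MAP.get(str(r["type"]).lower())
            if cls is None:
                continue
            rows.append({"seqid": r["seqid"], "feature_class": cls,
                         "start": int(r["start"]) - 1, "end": int(r["end"]),
                         "strand": r["strand"] if r["strand"] in "+-" else "+"})
    if repeat_bed is not None:
        bed = pd.read_csv(repeat_bed, sep="\t", header=None, comment="#")
        for _, r in bed.iterrows():
            rows.append({"seqid": str(r[0]), "feature_class": "repeat",
                         "start": int(r[1]), "end": int(r[2]), "strand": "+"})
    df = pd.DataFrame(rows, columns=["seqid", "feature_class", "start", "end", "strand"])
    unknown = sorted(set(df["seqid"]) - set(lengths)) if len(df) else []
    if unknown:
        raise FormatError(f"features reference unknown sequence id(s): {unknown}")
    if len(df):
        over = df["end"] > df["seqid"].map(lengths)
        if over.any():
            bad = df.loc[over, ["seqid", "feature_class", "start", "end"]].head()
            raise FormatError(f"feature(s) extend past sequence end:\n{bad}")
    return seqs, FeatureSet(df)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(feats: FeatureSet, path: str | Path) -> None:
    """Write gene/exon/CDS features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in feats.df[feats.df["feature_class"] != "repeat"].iterrows():
            fh.write(f"{r['seqid']}\tcrossworm\t{r['feature_class']}\t{r['start'] + 1}\t{r['end']}\t.\t{r['strand']}\t.\tID=f{i}\n")


def write_bed(feats: FeatureSet, path: str | Path, feature_class: str = "repeat") -> None:
    sub = feats.of_class(feature_class)
    sub[["seqid", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def extract_cds(seqs: SequenceSet, feats: FeatureSet) -> SequenceSet:
    """Concatenate CDS parts per (seqid, strand-run), reverse-complementing minus strand.

    CDS features are grouped contiguously by their order in the table when an
    ``attributes``-free FeatureSet is used; for the synthetic genomes produced
    by this package each CDS feature is a complete coding sequence.
    """
    out: dict[str, str] = {}
    for i, r in feats.of_class("CDS").reset_index(drop=True).iterrows():
        s = seqs[r["seqid"]][int(r["start"]):int(r["end"])]
        if r["strand"] == "-":
            s = str(Seq(s).reverse_complement())
        out[f"{r['seqid']}_cds{i}"] = s
    return SequenceSet(out)
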