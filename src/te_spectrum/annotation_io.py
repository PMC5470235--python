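"""Annotation parsing, interval indexing and tabular I/O.

All coordinates are held internally as 0-based half-open intervals.
GTF (1-based inclusive) and RepeatMasker ``.out`` (1-based inclusive) are
converted at the parsing boundary; BED is passed through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA", "other")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """A gene with merged, ordered exons over the union of its transcripts.

    ``first_exon`` is the 5'-most exon in gene orientation (min-start exon on
    the + strand, max-end exon on the - strand).  ``acceptor_sites`` hold the
    genomic position of the first base (in gene orientation) of every
    non-first exon: the exon's genomic start on +, its genomic ``end - 1``
    on -.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    biotype: str = "coding"

    first_exon: Interval = field(init=False)
    acceptor_sites: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        self.exons = _merge_intervals(self.exons)
        if self.strand == "+":
            self.first_exon = self.exons[0]
            self.acceptor_sites = frozenset(e.start for e in self.exons[1:])
        else:
            self.first_exon = self.exons[-1]
            self.acceptor_sites = frozenset(e.end - 1 for e in self.exons[:-1])

    @property
    def tss(self) -> int:
        """Genomic position of the 5' base of the first exon in gene orientation."""
        return self.first_exon.start if self.strand == "+" else self.first_exon.end - 1

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)


@dataclass
class TEInstance:
    """One annotated repeat copy."""

    instance_id: str
    family: str
    te_class: str
    chrom: str
    interval: Interval
    strand: str

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            self.te_class = "other"


@dataclass
class RegionSet:
    """A named collection of labelled genomic regions (e.g. promoters, imprints)."""

    name: str
    regions: list[tuple[str, Interval, str]]

    def __post_init__(self) -> None:
        labels = [lab for _, _, lab in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError(f"region set {self.name}: duplicate labels")


class DesignTable:
    """Sample sheet mapping samples to condition / background / replicate."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "condition", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in design table")
        if "background" not in frame.columns:
            frame = frame.assign(background="NA")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Conditions in first-appearance order."""
        return list(dict.fromkeys(self.frame["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        sel = self.frame["condition"] == condition
        return list(self.frame.loc[sel, "sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in design table")
        return row["condition"].iloc[0]


def _merge_intervals(ivals: list[Interval]) -> list[Interval]:
    ivals = sorted(ivals, key=lambda i: (i.start, i.end))
    merged: list[Interval] = []
    for iv in ivals:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# parsers

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(field9))


def read_gtf(path: str) -> list[GeneModel]:
    """Parse exon features of a GTF into :class:`GeneModel` objects.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exons are pooled over all transcripts of a gene; genes contributing no
    exon features are skipped with a warning.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                # remember the gene so an exon-less record can be warned about
                gid = _gtf_attributes(attrs).get("gene_id")
                if gid and gid not in meta:
                    meta[gid] = (chrom, strand, "coding")
                    order.append(gid)
                continue
            try:
                iv = Interval(int(start) - 1, int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad exon coordinates: {exc}") from exc
            attr = _gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: exon without gene_id attribute")
            biotype = attr.get("gene_biotype", attr.get("gene_type", "coding"))
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand, biotype)
                order.append(gene_id)
            else:
                meta[gene_id] = (chrom, strand, biotype)
            exons.setdefault(gene_id, []).append(iv)
    genes = []
    for gid in order:
        chrom, strand, biotype = meta[gid]
        if not exons.get(gid):
            log.warning("gene %s has zero exons; excluded", gid)
            continue
        genes.append(GeneModel(gid, chrom, strand, exons[gid], biotype=biotype))
    return genes


def read_te_annotation(path: str, format: str = "bed6") -> list[TEInstance]:
    """Read TE instances from BED6 (name = ``family`` or ``family#class``)
    or a RepeatMasker ``.out`` table.  Unknown classes map to ``other``."""
    if format == "bed6":
        return _read_te_bed6(path)
    if format == "repeatmasker":
        return _read_te_repeatmasker(path)
    raise ValueError(f"unknown TE annotation format {format!r}")


def _resolve_class(raw: str) -> str:
    base = raw.split("/")[0]
    return base if base in TE_CLASSES else "other"


def _read_te_bed6(path: str) -> list[TEInstance]:
    out: list[TEInstance] = []
    counter: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line with <4 fields")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: record {name!r} has start >= end")
            family, _, klass = name.partition("#")
            te_class = _resolve_class(klass) if klass else "other"
            n = counter.get(family, 0)
            counter[family] = n + 1
            out.append(
                TEInstance(f"{family}.{n}", family, te_class, chrom, Interval(start, end), strand)
            )
    return out


def _read_te_repeatmasker(path: str) -> list[TEInstance]:
    out: list[TEInstance] = []
    counter: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] in ("SW", "score") or fields[0].startswith("="):
                continue  # header lines
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker record")
            chrom = fields[4]
            start, end = int(fields[5]) - 1, int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            family = fields[9]
            te_class = _resolve_class(fields[10])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: record {family!r} has start >= end")
            n = counter.get(family, 0)
            counter[family] = n + 1
            out.append(
                TEInstance(f"{family}.{n}", family, te_class, chrom, Interval(start, end), strand)
            )
    return out


def read_region_bed(path: str, name: str) -> RegionSet:
    """Read a labelled region set from BED (4+ columns; col 4 = label)."""
    regions: list[tuple[str, Interval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else f"{name}_{lineno}"
            regions.append((chrom, Interval(start, end), label))
    return RegionSet(name, regions)


def read_design(path: str) -> DesignTable:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"replicate": int})
    return DesignTable(frame)


# ---------------------------------------------------------------------------
# interval index


class GenomeIndex:
    """Per-chromosome interval index over features carrying chrom + interval.

    Overlap queries return exactly the features whose half-open interval
    intersects the half-open query, in insertion order.
    """

    def __init__(self, features=(), chrom_of=None, interval_of=None):
        self._chrom_of = chrom_of or (lambda f: f.chrom)
        self._interval_of = interval_of or (lambda f: f.interval)
        self._trees: dict[str, IntervalTree] = {}
        self._order: dict[int, int] = {}
        for f in features:
            self.add(f)

    def add(self, feature) -> None:
        iv = self._interval_of(feature)
        tree = self._trees.setdefault(self._chrom_of(feature), IntervalTree())
        self._order[id(feature)] = len(self._order)
        tree.addi(iv.start, iv.end, feature)

    def query(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda f: self._order[id(f)])
        return hits

    def query_point(self, chrom: str, pos: int) -> list:
        return self.query(chrom, pos, pos + 1)


def build_interval_index(features, chrom_of=None, interval_of=None) -> GenomeIndex:
    return GenomeIndex(features, chrom_of=chrom_of, interval_of=interval_of)


# ---------------------------------------------------------------------------
# writers — TSV with a commented header line


def write_tsv(frame: pd.DataFrame, path: str) -> None:
    """Write a DataFrame as TSV with a ``#``-commented header naming columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected commented header line")
        columns = header[1:].rstrip("\n").split("\t")
        frame = pd.read_csv(fh, sep="\t", header=None, names=columns)
    return frame


def write_design(design: DesignTable, path: str) -> None:
    write_tsv(design.frame, path)
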