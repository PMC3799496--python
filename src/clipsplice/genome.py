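"""Genomic coordinate system, gene/exon/intron models and region classification.

All coordinates are 0-based, half-open (BED convention). GTF input is converted
on read. Exons of a :class:`GeneModel` are stored in *transcript* order, so for
a minus-strand gene the first exon is the genomically rightmost one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CassetteExonContext:
    """An internal exon with its two flanking introns and their four splice sites.

    Splice-site positions are the first/last *intronic* bases, labelled in
    transcript orientation: ``up5ss``/``up3ss`` are donor/acceptor of the
    upstream intron, ``down5ss``/``down3ss`` of the downstream intron.
    """

    exon_id: str
    exon: GenomicInterval
    upstream_intron: GenomicInterval
    downstream_intron: GenomicInterval
    sites: dict = field(default_factory=dict)  # label -> genomic position

    SITE_LABELS = ("up5ss", "up3ss", "down5ss", "down3ss")

    def __post_init__(self) -> None:
        missing = set(self.SITE_LABELS) - set(self.sites)
        if missing:
            raise ValueError(f"missing splice-site labels: {sorted(missing)}")

    def intron_of(self, label: str) -> GenomicInterval:
        return self.upstream_intron if label.startswith("up") else self.downstream_intron


class GeneModel:
    """A transcript model: ordered exons with derived introns.

    Parameters
    ----------
    gene_id:
        Gene-level identifier (used for region classification).
    exons:
        Exon intervals in transcript order. They must share chromosome and
        strand, be non-overlapping and strictly ordered along the transcript.
    transcript_id:
        Optional transcript identifier; defaults to ``gene_id``.
    """

    __slots__ = ("gene_id", "transcript_id", "exons", "introns")

    def __init__(
        self,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        transcript_id: str | None = None,
    ):
        if not exons:
            raise ValueError("a gene model needs at least one exon")
        chrom, strand = exons[0].chrom, exons[0].strand
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError("exons must share chromosome and strand")
        sign = 1 if strand == "+" else -1
        for a, b in zip(exons, exons[1:]):
            if sign * (b.start - a.start) <= 0 or (
                a.overlaps(b)
            ):
                raise ValueError("exons must be non-overlapping and in transcript order")
        self.gene_id = gene_id
        self.transcript_id = transcript_id or gene_id
        self.exons = tuple(exons)
        introns = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if strand == "+" else (b.end, a.start)
            if hi - lo < 1:
                raise ValueError("adjacent exons leave no intron between them")
            introns.append(GenomicInterval(chrom, lo, hi, strand))
        self.introns = tuple(introns)

    # -- derived geometry ---------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def internal_exon_indices(self) -> range:
        return range(1, self.n_exons - 1)

    def exon_id(self, index: int) -> str:
        return f"{self.transcript_id}:E{index}"

    def intron_id(self, index: int) -> str:
        """Intron ``index`` lies between exons ``index`` and ``index+1`` (transcript order)."""
        return f"{self.transcript_id}:I{index}"

    def exon_kb(self) -> float:
        return sum(len(e) for e in self.exons) / 1000.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneModel({self.transcript_id!r}, {self.n_exons} exons, {self.strand})"


def flanking_splice_sites(exon_index: int, gene: GeneModel) -> CassetteExonContext:
    """Build the four-splice-site context of an internal exon.

    Site positions are first/last intronic bases; for a minus-strand gene the
    donor of an intron is its genomically rightmost base, so labels always
    follow transcript orientation.
    """
    if not (0 < exon_index < gene.n_exons - 1):
        raise IndexError(f"exon {exon_index} of {gene.transcript_id} is not an internal exon")
    up = gene.introns[exon_index - 1]
    down = gene.introns[exon_index]
    if gene.strand == "+":
        sites = {
            "up5ss": up.start, "up3ss": up.end - 1,
            "down5ss": down.start, "down3ss": down.end - 1,
        }
    else:
        sites = {
            "up5ss": up.end - 1, "up3ss": up.start,
            "down5ss": down.end - 1, "down3ss": down.start,
        }
    return CassetteExonContext(
        exon_id=gene.exon_id(exon_index),
        exon=gene.exons[exon_index],
        upstream_intron=up,
        downstream_intron=down,
        sites=sites,
    )


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str, lineno: int) -> GeneModel | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    try:
        chrom = fields[0]
        chrom_start = int(fields[1])
        name = fields[3]
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 record: {exc}") from None
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError(f"line {lineno}: blockCount disagrees with block lists")
    exons = []
    for size, rel in zip(sizes, starts):
        if size <= 0:
            warnings.warn(f"line {lineno}: zero-length exon in {name}; record rejected")
            return None
        s = chrom_start + rel
        exons.append(GenomicInterval(chrom, s, s + size, strand))
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(name, exons)


def _load_gtf(path: str | Path) -> list[GeneModel]:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    exon_df = df[df["Feature"] == "exon"]
    if exon_df.empty:
        raise ValueError(f"{path}: no exon features found")
    models = []
    for (tid,), grp in exon_df.groupby(["transcript_id"], sort=True):
        grp = grp.sort_values("Start")
        strand = grp["Strand"].iloc[0]
        gene_id = grp["gene_id"].iloc[0] if "gene_id" in grp else tid
        exons = []
        ok = True
        for row in grp.itertuples():
            if row.End <= row.Start:
                warnings.warn(f"zero-length exon in transcript {tid}; record rejected")
                ok = False
                break
            exons.append(GenomicInterval(row.Chromosome, row.Start, row.End, strand))
        if not ok:
            continue
        if strand == "-":
            exons = exons[::-1]
        models.append(GeneModel(gene_id, exons, transcript_id=tid))
    return models


def load_annotation(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a BED12 or GTF file.

    ``format`` is ``"bed12"`` or ``"gtf"``; when omitted it is inferred from
    the file suffix. Returns models deterministically ordered by
    (chrom, span start, transcript id).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "bed12", ".bed": "bed12", ".bed12": "bed12",
                  ".gtf": "gtf", ".gff": "gtf"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    format = format.lower()
    if format == "gtf":
        models = _load_gtf(path)
    elif format == "bed12":
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                model = _parse_bed12_line(line, lineno)
                if model is not None:
                    models.append(model)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    models.sort(key=lambda g: (g.chrom, g.span.start, g.transcript_id))
    return models


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (exons become blocks; score column is 0)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons)
            rels = ",".join(str(e.start - span.start) for e in exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(span.start), str(span.end), g.transcript_id,
                        "0", g.strand, str(span.start), str(span.end), "0",
                        str(len(exons)), sizes, rels,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Interval index over a gene-model collection for position classification.

    Overlapping transcripts of one gene are collapsed to the gene's longest
    transcript before indexing, so every position maps to at most one record
    per gene. Classification priority is exonic > intronic > intergenic; among
    genes, same-strand matches win, ties broken by smallest gene span.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        by_gene: dict[str, GeneModel] = {}
        for g in genes:
            cur = by_gene.get(g.gene_id)
            if cur is None or len(g.span) > len(cur.span):
                by_gene[g.gene_id] = g
        self.genes = {gid: g for gid, g in sorted(by_gene.items())}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            etree = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for e in g.exons:
                etree.addi(e.start, e.end, g)
            stree = self._span_trees.setdefault(g.chrom, IntervalTree())
            span = g.span
            stree.addi(span.start, span.end, g)

    @staticmethod
    def _best(hits: list[GeneModel], strand: str | None) -> GeneModel:
        def key(g: GeneModel):
            same = 0 if (strand is not None and g.strand == strand) else 1
            return (same, len(g.span), g.gene_id)

        return min(hits, key=key)

    def classify_position(
        self, chrom: str, pos: int, strand: str | None = None
    ) -> tuple[str, str | None]:
        """Label a single position as exonic / intronic / intergenic."""
        etree = self._exon_trees.get(chrom)
        if etree is not None:
            hits = [iv.data for iv in etree.at(pos)]
            if hits:
                return "exonic", self._best(hits, strand).gene_id
        stree = self._span_trees.get(chrom)
        if stree is not None:
            hits = [iv.data for iv in stree.at(pos)]
            if hits:
                return "intronic", self._best(hits, strand).gene_id
        return "intergenic", None


def classify_region(
    interval: GenomicInterval,
    index: GenomeIndex,
    representative: int | None = None,
) -> tuple[str, str | None]:
    """Classify an interval by a single representative position.

    Clusters are classified by their preferred crosslink site (pass it as
    ``representative``); any other interval by its midpoint. Each interval
    therefore receives exactly one label, so labels over a set of intervals
    partition it.
    """
    pos = interval.midpoint if representative is None else representative
    return index.classify_position(interval.chrom, pos, interval.strand)
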