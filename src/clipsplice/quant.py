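"""PSI / PIR / RPKM quantification from junction-aware read evidence.

Percent spliced in of an internal exon E is PSI = e_in / (e_in + e_out), where
e_in counts reads mappable only to E or to exon junctions containing E and
e_out counts reads mappable only to junctions skipping E (each junction side
must overlap its exon by at least 6 bp). Percent intron retention is
PIR = i_in / (i_in + i_out) from intron–exon junction reads versus skipping
exon–exon junction reads.

Because re-deriving mappability needs an aligner, exclusivity is carried on
the read record itself: each read states the single piece of junction
evidence it supports (exon body, exon–exon junction with side overlaps, or
intron–exon junction). One read receives exactly one evidence class, but a
class may legitimately feed several counters — an adjacent exon–exon junction
is inclusion evidence for both flanking exons and skipping evidence for the
intron between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import GeneModel

logger = logging.getLogger(__name__)

MIN_JUNCTION_OVERLAP = 6


# ---------------------------------------------------------------------------
# Elementary formulas
# ---------------------------------------------------------------------------

def psi(e_in: int, e_out: int) -> float | None:
    """Percent spliced in; ``None`` when no informative reads exist."""
    if e_in < 0 or e_out < 0:
        raise ValueError("junction counts must be non-negative")
    total = e_in + e_out
    if total == 0:
        return None
    return e_in / total


def pir(i_in: int, i_out: int) -> float | None:
    """Percent intron retention; ``None`` when no informative reads exist."""
    if i_in < 0 or i_out < 0:
        raise ValueError("junction counts must be non-negative")
    total = i_in + i_out
    if total == 0:
        return None
    return i_in / total


def rpkm(mapped_reads: int, exon_kb: float, total_mapped_millions: float) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    if exon_kb <= 0 or total_mapped_millions <= 0:
        raise ValueError("exon_kb and total_mapped_millions must be positive")
    return mapped_reads / (exon_kb * total_mapped_millions)


# ---------------------------------------------------------------------------
# Quant records
# ---------------------------------------------------------------------------

@dataclass
class ExonQuant:
    exon_id: str
    e_in: int = 0
    e_out: int = 0

    @property
    def psi(self) -> float | None:
        return psi(self.e_in, self.e_out)

    @property
    def coverage(self) -> int:
        return self.e_in + self.e_out


@dataclass
class IntronQuant:
    intron_id: str
    i_in: int = 0
    i_out: int = 0

    @property
    def pir(self) -> float | None:
        return pir(self.i_in, self.i_out)

    @property
    def coverage(self) -> int:
        return self.i_in + self.i_out


@dataclass
class GeneExpression:
    gene_id: str
    mapped_reads: int
    exon_kb: float

    def rpkm(self, total_mapped_millions: float) -> float:
        return rpkm(self.mapped_reads, self.exon_kb, total_mapped_millions)


# ---------------------------------------------------------------------------
# Junction-read counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpliceRead:
    """One read's exclusive junction evidence within a single transcript.

    kind:
      * ``exon`` — contiguous read inside exon ``left`` (overlaps unused);
      * ``junction`` — exon–exon junction between transcript-order exon
        indices ``left`` < ``right`` with per-side overlaps in bp;
      * ``intron_exon`` — junction between intron index ``left`` and one of
        its adjacent exons; ``overlap_left`` is the intronic overlap.
    """

    read_id: str
    transcript_id: str
    kind: str  # exon | junction | intron_exon
    left: int
    right: int = -1
    overlap_left: int = 0
    overlap_right: int = 0


def count_junction_reads(
    reads: Iterable[SpliceRead],
    genes: Sequence[GeneModel],
    min_overlap: int = MIN_JUNCTION_OVERLAP,
) -> tuple[dict[str, ExonQuant], dict[str, IntronQuant], dict[str, str]]:
    """Tally e_in/e_out and i_in/i_out from labelled junction evidence.

    Returns exon and intron count maps plus the evidence class assigned to
    each read (``inclusion`` / ``skipping`` / ``intron_junction`` /
    ``unassigned``); every read receives exactly one class. Reads whose
    junction overlap falls below ``min_overlap`` on any required side count
    nowhere. Reads naming an unknown transcript raise; inconsistent exon
    indices are dropped with a log entry.
    """
    by_tid = {g.transcript_id: g for g in genes}
    exon_counts: dict[str, ExonQuant] = {}
    intron_counts: dict[str, IntronQuant] = {}
    for g in genes:
        for i in range(g.n_exons):
            exon_counts[g.exon_id(i)] = ExonQuant(g.exon_id(i))
        for i in range(g.n_exons - 1):
            intron_counts[g.intron_id(i)] = IntronQuant(g.intron_id(i))

    assignment: dict[str, str] = {}
    for r in reads:
        gene = by_tid.get(r.transcript_id)
        if gene is None:
            raise KeyError(f"read {r.read_id}: unknown transcript {r.transcript_id!r}")
        cls = "unassigned"
        if r.kind == "exon":
            if 0 <= r.left < gene.n_exons:
                exon_counts[gene.exon_id(r.left)].e_in += 1
                cls = "inclusion"
            else:
                logger.warning("read %s: exon index out of range, dropped", r.read_id)
        elif r.kind == "junction":
            i, j = r.left, r.right
            if not (0 <= i < j < gene.n_exons):
                logger.warning("read %s: bad junction (%d,%d), dropped", r.read_id, i, j)
            elif r.overlap_left >= min_overlap and r.overlap_right >= min_overlap:
                if j == i + 1:  # adjacent junction: inclusion evidence
                    exon_counts[gene.exon_id(i)].e_in += 1
                    exon_counts[gene.exon_id(j)].e_in += 1
                    intron_counts[gene.intron_id(i)].i_out += 1
                    cls = "inclusion"
                else:  # skipping junction
                    for k in range(i + 1, j):
                        exon_counts[gene.exon_id(k)].e_out += 1
                    for m in range(i, j):
                        intron_counts[gene.intron_id(m)].i_out += 1
                    cls = "skipping"
        elif r.kind == "intron_exon":
            if not (0 <= r.left < gene.n_exons - 1):
                logger.warning("read %s: bad intron index, dropped", r.read_id)
            elif r.overlap_left >= min_overlap:
                intron_counts[gene.intron_id(r.left)].i_in += 1
                cls = "intron_junction"
        else:
            raise ValueError(f"read {r.read_id}: unknown evidence kind {r.kind!r}")
        assignment[r.read_id] = cls
    return exon_counts, intron_counts, assignment


# ---------------------------------------------------------------------------
# Cassette-exon universe
# ---------------------------------------------------------------------------

def define_cassette_exons(
    psi_tables: Sequence[Mapping[str, ExonQuant]] | Sequence[pd.DataFrame],
    lo: float = 0.02,
    hi: float = 0.98,
    internal_ids: set[str] | None = None,
) -> set[str]:
    """Internal exons with a defined PSI inside the closed interval [lo, hi]
    in at least one sample."""
    out: set[str] = set()
    for table in psi_tables:
        if isinstance(table, pd.DataFrame):
            items = (
                (row.feature_id, psi(int(row.e_in), int(row.e_out)))
                for row in table.itertuples()
            )
        else:
            items = ((eid, q.psi) for eid, q in table.items())
        for eid, value in items:
            if value is None:
                continue
            if lo <= value <= hi:
                if internal_ids is None or eid in internal_ids:
                    out.add(eid)
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def exon_counts_frame(counts: Mapping[str, ExonQuant]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": q.exon_id,
            "e_in": q.e_in,
            "e_out": q.e_out,
            "psi": q.psi if q.psi is not None else float("nan"),
            "coverage": q.coverage,
        }
        for q in counts.values()
    ]
    return pd.DataFrame(rows).sort_values("feature_id").reset_index(drop=True)


def intron_counts_frame(counts: Mapping[str, IntronQuant]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": q.intron_id,
            "i_in": q.i_in,
            "i_out": q.i_out,
            "pir": q.pir if q.pir is not None else float("nan"),
            "coverage": q.coverage,
        }
        for q in counts.values()
    ]
    return pd.DataFrame(rows).sort_values("feature_id").reset_index(drop=True)


def write_counts_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
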