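"""PAR-CLIP binding-cluster calling, consensus pairing and boundary profiles.

Uniquely mapped reads are merged by transitive same-strand overlap into
binding clusters; the cluster's preferred crosslink site is the position with
the most T-to-C conversions. A consensus cluster is a reciprocal pair across
two replicates: each replicate's preferred crosslink must fall inside the
other replicate's cluster interval. The consensus adopts replicate 1's
crosslink.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from math import log2
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import GeneModel, GenomicInterval


@dataclass(frozen=True)
class AlignedClipRead:
    interval: GenomicInterval
    conversion_positions: tuple[int, ...] = ()
    unique: bool = True

    def __post_init__(self) -> None:
        for p in self.conversion_positions:
            if not self.interval.contains(p):
                raise ValueError(
                    f"conversion at {p} outside read interval "
                    f"[{self.interval.start}, {self.interval.end})"
                )


@dataclass
class BindingCluster:
    interval: GenomicInterval
    n_reads: int
    n_converted_reads: int
    conversions_per_position: dict[int, int]
    preferred_crosslink: int | None

    @property
    def score(self) -> float:
        """Binding score: log2(1 + converted-read count), monotone in support."""
        return log2(1 + self.n_converted_reads)


@dataclass(frozen=True)
class ConsensusCluster:
    rep1: BindingCluster
    rep2: BindingCluster
    crosslink: int  # adopted from replicate 1

    @property
    def interval(self) -> GenomicInterval:
        return self.rep1.interval

    @property
    def score(self) -> float:
        return (self.rep1.score + self.rep2.score) / 2.0


def preferred_crosslink_site(conversions_per_position: dict[int, int]) -> int:
    """Position with the highest conversion count; ties go to the smallest coordinate."""
    if not conversions_per_position:
        raise ValueError("no conversions: preferred crosslink is undefined")
    return min(conversions_per_position.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def call_clusters(
    reads: Iterable[AlignedClipRead],
    min_reads: int = 2,
    require_conversion: bool = True,
    collapse_duplicates: bool = True,
) -> list[BindingCluster]:
    """Merge overlapping uniquely mapped reads into binding clusters.

    Reads are grouped by (chromosome, strand) and merged transitively under
    half-open overlap. Identical reads (same interval and conversions) are
    collapsed as PCR duplicates by default. Clusters with fewer than
    ``min_reads`` reads, or with no converted read when ``require_conversion``,
    are dropped.
    """
    kept = [r for r in reads if r.unique]
    if collapse_duplicates:
        seen = set()
        deduped = []
        for r in kept:
            key = (r.interval, r.conversion_positions)
            if key not in seen:
                seen.add(key)
                deduped.append(r)
        kept = deduped

    by_group: dict[tuple[str, str], list[AlignedClipRead]] = defaultdict(list)
    for r in kept:
        by_group[(r.interval.chrom, r.interval.strand)].append(r)

    clusters: list[BindingCluster] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda r: (r.interval.start, r.interval.end))
        block: list[AlignedClipRead] = []
        block_end = -1
        for r in group + [None]:  # sentinel flushes the last block
            if r is not None and block and r.interval.start < block_end:
                block.append(r)
                block_end = max(block_end, r.interval.end)
                continue
            if block:
                conv = Counter()
                n_converted = 0
                for m in block:
                    if m.conversion_positions:
                        n_converted += 1
                        conv.update(m.conversion_positions)
                if len(block) >= min_reads and (conv or not require_conversion):
                    clusters.append(
                        BindingCluster(
                            interval=GenomicInterval(
                                chrom, block[0].interval.start, block_end, strand
                            ),
                            n_reads=len(block),
                            n_converted_reads=n_converted,
                            conversions_per_position=dict(conv),
                            preferred_crosslink=(
                                preferred_crosslink_site(conv) if conv else None
                            ),
                        )
                    )
            if r is not None:
                block = [r]
                block_end = r.interval.end
    return clusters


def cluster_score(cluster: BindingCluster) -> float:
    return cluster.score


def consensus_clusters(
    rep1: Sequence[BindingCluster], rep2: Sequence[BindingCluster]
) -> list[ConsensusCluster]:
    """Pair clusters across replicates by reciprocal crosslink containment.

    A pair qualifies if replicate 1's preferred crosslink lies inside the
    replicate-2 cluster interval and vice versa (same chromosome and strand).
    Many-to-many candidates are resolved greedily by ascending crosslink
    distance, each cluster used at most once. The consensus crosslink is
    replicate 1's.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for j, c2 in enumerate(rep2):
        iv = c2.interval
        trees[(iv.chrom, iv.strand)].addi(iv.start, iv.end, j)

    candidates: list[tuple[int, int, int]] = []  # (|xl1-xl2|, i, j)
    for i, c1 in enumerate(rep1):
        if c1.preferred_crosslink is None:
            continue
        tree = trees.get((c1.interval.chrom, c1.interval.strand))
        if tree is None:
            continue
        for hit in tree.at(c1.preferred_crosslink):
            c2 = rep2[hit.data]
            if c2.preferred_crosslink is None:
                continue
            if c1.interval.contains(c2.preferred_crosslink):
                candidates.append(
                    (abs(c1.preferred_crosslink - c2.preferred_crosslink), i, hit.data)
                )

    candidates.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    out: list[ConsensusCluster] = []
    for _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        out.append(ConsensusCluster(rep1[i], rep2[j], crosslink=rep1[i].preferred_crosslink))
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.crosslink))
    return out


# ---------------------------------------------------------------------------
# Boundary density profiles
# ---------------------------------------------------------------------------

def _item_positions(item) -> tuple[str, str, list[int]]:
    """Representative positions: crosslink for clusters, full coverage for reads."""
    if isinstance(item, ConsensusCluster):
        iv = item.interval
        return iv.chrom, iv.strand, [item.crosslink]
    if isinstance(item, BindingCluster):
        iv = item.interval
        if item.preferred_crosslink is None:
            return iv.chrom, iv.strand, []
        return iv.chrom, iv.strand, [item.preferred_crosslink]
    if isinstance(item, AlignedClipRead):
        iv = item.interval
        return iv.chrom, iv.strand, list(range(iv.start, iv.end))
    raise TypeError(f"cannot profile item of type {type(item).__name__}")


def boundary_density_profile(
    items: Iterable,
    genes: Sequence[GeneModel],
    window: int = 300,
    which: Literal["exon-intron", "intron-exon"] = "intron-exon",
) -> np.ndarray:
    """Positional density of items around exon/intron boundaries.

    Offsets are transcript-oriented and anchored on the intronic boundary
    base: for an exon–intron boundary, offset 0 is the first intronic base
    (the donor), negative offsets are exonic; for an intron–exon boundary,
    offset 0 is the last intronic base (the acceptor), positive offsets are
    exonic. The returned array has length ``2*window + 1`` (offset -window ..
    +window) and is normalized per boundary, so its sum times the number of
    boundaries equals the number of item hits.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if which not in ("exon-intron", "intron-exon"):
        raise ValueError(f"unknown boundary kind {which!r}")

    # collect item representative positions per (chrom, strand), sorted
    pos_by_group: dict[tuple[str, str], list[int]] = defaultdict(list)
    for item in items:
        chrom, strand, positions = _item_positions(item)
        pos_by_group[(chrom, strand)].extend(positions)
    arrays = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in pos_by_group.items()}

    counts = np.zeros(2 * window + 1, dtype=float)
    n_boundaries = 0
    for g in genes:
        for intron in g.introns:
            if g.strand == "+":
                anchor = intron.start if which == "exon-intron" else intron.end - 1
                sign = 1
            else:
                anchor = intron.end - 1 if which == "exon-intron" else intron.start
                sign = -1
            n_boundaries += 1
            positions = arrays.get((g.chrom, g.strand))
            if positions is None or positions.size == 0:
                continue
            lo = np.searchsorted(positions, anchor - window, side="left")
            hi = np.searchsorted(positions, anchor + window, side="right")
            if hi > lo:
                offsets = sign * (positions[lo:hi] - anchor)
                np.add.at(counts, offsets + window, 1.0)
    if n_boundaries == 0:
        import warnings

        warnings.warn("annotation contains no boundaries of the requested kind")
        return counts
    return counts / n_boundaries


# ---------------------------------------------------------------------------
# Tabular I/O (simplified alignment TSV and BED6+ cluster tables)
# ---------------------------------------------------------------------------

READ_TSV_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "conversions"]


def write_clip_reads_tsv(reads: Iterable[AlignedClipRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READ_TSV_COLUMNS) + "\n")
        for i, r in enumerate(reads):
            conv = ",".join(str(p) for p in r.conversion_positions)
            iv = r.interval
            fh.write(f"read{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{conv}\n")


def read_clip_reads_tsv(path: str | Path) -> list[AlignedClipRead]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in READ_TSV_COLUMNS}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            conv = tuple(int(x) for x in f[idx["conversions"]].split(",") if x)
            reads.append(
                AlignedClipRead(
                    GenomicInterval(
                        f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]),
                        f[idx["strand"]],
                    ),
                    conversion_positions=conv,
                )
            )
    return reads


def read_clusters_bed(path: str | Path) -> list[BindingCluster]:
    """Read a BED6+ cluster table back into minimal cluster records.

    Per-position conversion detail is not serialized; the crosslink column is
    restored as the single conversion peak, which is sufficient for consensus
    pairing, classification and profiling.
    """
    clusters = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            n_conv = int(f[7])
            xl = None if f[8] in ("", "None") else int(f[8])
            clusters.append(
                BindingCluster(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    n_reads=int(f[6]),
                    n_converted_reads=n_conv,
                    conversions_per_position={xl: n_conv} if xl is not None else {},
                    preferred_crosslink=xl,
                )
            )
    return clusters


def write_clusters_bed(clusters: Sequence, path: str | Path) -> None:
    """Write clusters (binding or consensus) as BED6+ with support columns."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tn_reads\tn_converted\tcrosslink\n"
        )
        for i, c in enumerate(clusters):
            iv = c.interval
            if isinstance(c, ConsensusCluster):
                n_reads = c.rep1.n_reads + c.rep2.n_reads
                n_conv = c.rep1.n_converted_reads + c.rep2.n_converted_reads
                xl = c.crosslink
            else:
                n_reads, n_conv, xl = c.n_reads, c.n_converted_reads, c.preferred_crosslink
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster{i}\t{c.score:.4f}\t"
                f"{iv.strand}\t{n_reads}\t{n_conv}\t{xl}\n"
            )
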