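"""Integration of consensus binding with splicing changes.

Builds the RNA splicing map: positional densities of consensus crosslinks
around the four splice sites of cassette-exon contexts, stratified by splicing
response; classifies exons by which of the four sites carry proximal binding
(within 150 nt on the intronic side); compares group CDFs of Z values; relates
exon skipping to retention of the flanking introns; and scores splice-site
strength with a trained position weight matrix (log2 odds against genome-wide
base frequencies) to compare proximal and distal sites.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .clusters import ConsensusCluster
from .genome import CassetteExonContext, GeneModel, flanking_splice_sites

SITE_LABELS = CassetteExonContext.SITE_LABELS


# ---------------------------------------------------------------------------
# Crosslink index
# ---------------------------------------------------------------------------

class _CrosslinkIndex:
    def __init__(self, consensus: Iterable[ConsensusCluster]):
        grouped: dict[tuple[str, str], list[int]] = defaultdict(list)
        for c in consensus:
            iv = c.interval
            xl = getattr(c, "crosslink", None)
            if xl is None:  # plain binding clusters (e.g. read back from BED)
                xl = c.preferred_crosslink
            if xl is not None:
                grouped[(iv.chrom, iv.strand)].append(xl)
        self._sorted = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in grouped.items()}

    def in_range(self, chrom: str, strand: str, lo: int, hi: int) -> np.ndarray:
        """Crosslink positions in the half-open genomic range [lo, hi)."""
        arr = self._sorted.get((chrom, strand))
        if arr is None:
            return np.empty(0, dtype=np.int64)
        i = np.searchsorted(arr, lo, side="left")
        j = np.searchsorted(arr, hi, side="left")
        return arr[i:j]


# ---------------------------------------------------------------------------
# Binding proximity (four-site classification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProximityProfile:
    exon_id: str
    flags: dict  # site label -> bool

    @property
    def n_sites_bound(self) -> int:
        return sum(bool(v) for v in self.flags.values())


def binding_proximity(
    consensus: Iterable[ConsensusCluster] | _CrosslinkIndex,
    context: CassetteExonContext,
    max_dist: int = 150,
    include_exonic_side: bool = False,
) -> ProximityProfile:
    """Flag each of the four splice sites with proximal consensus binding.

    A flag is set iff at least one consensus crosslink lies within the flanking
    intron and within ``max_dist`` nt of that splice site. With
    ``include_exonic_side`` the exonic side of the site also qualifies.
    """
    index = consensus if isinstance(consensus, _CrosslinkIndex) else _CrosslinkIndex(consensus)
    exon = context.exon
    flags = {}
    for label in SITE_LABELS:
        site = context.sites[label]
        intron = context.intron_of(label)
        lo = max(site - max_dist, intron.start)
        hi = min(site + max_dist + 1, intron.end)
        hit = index.in_range(exon.chrom, exon.strand, lo, hi).size > 0
        if not hit and include_exonic_side:
            xlo = max(site - max_dist, exon.start)
            xhi = min(site + max_dist + 1, exon.end)
            if xhi > xlo:
                hit = index.in_range(exon.chrom, exon.strand, xlo, xhi).size > 0
        flags[label] = bool(hit)
    return ProximityProfile(context.exon_id, flags)


def proximity_table(
    consensus: Iterable[ConsensusCluster],
    contexts: Sequence[CassetteExonContext],
    max_dist: int = 150,
    include_exonic_side: bool = False,
) -> pd.DataFrame:
    index = _CrosslinkIndex(consensus)
    rows = []
    for ctx in contexts:
        prof = binding_proximity(index, ctx, max_dist, include_exonic_side)
        row = {"exon_id": prof.exon_id}
        row.update({k: int(v) for k, v in prof.flags.items()})
        row["n_sites_bound"] = prof.n_sites_bound
        rows.append(row)
    return pd.DataFrame(rows, columns=["exon_id", *SITE_LABELS, "n_sites_bound"])


# ---------------------------------------------------------------------------
# Splicing map
# ---------------------------------------------------------------------------

@dataclass
class SpliceMapProfile:
    label: str
    n_exons: int
    bin_edges: np.ndarray                      # offsets, shared across anchors
    densities: dict = field(default_factory=dict)  # anchor -> hits/exon per bin

    def integral(self, anchor: str) -> float:
        return float(self.densities[anchor].sum())


def splicing_map(
    consensus: Iterable[ConsensusCluster],
    exon_groups: Mapping[str, set],
    contexts: Mapping[str, CassetteExonContext],
    window: int = 300,
    bin_size: int = 5,
) -> list[SpliceMapProfile]:
    """Crosslink density around the four splice sites, per exon group.

    Offsets are transcript-oriented and anchored on the splice-site base
    (negative = upstream along the transcript), binned on a shared grid from
    -window to +window. Densities are hits per exon per bin, so the sum over
    bins times the group size recovers the group's crosslink hit count.
    """
    if window < 50:
        raise ValueError("window must be >= 50 nt")
    index = _CrosslinkIndex(consensus)
    edges = np.arange(-window, window + bin_size, bin_size)
    profiles = []
    for label, exon_ids in exon_groups.items():
        members = [contexts[eid] for eid in sorted(exon_ids) if eid in contexts]
        if not members:
            warnings.warn(f"exon group {label!r} is empty; returning zero profile")
            profiles.append(
                SpliceMapProfile(label, 0, edges,
                                 {a: np.zeros(len(edges) - 1) for a in SITE_LABELS})
            )
            continue
        densities = {}
        for anchor in SITE_LABELS:
            counts = np.zeros(len(edges) - 1)
            for ctx in members:
                site = ctx.sites[anchor]
                strand = ctx.exon.strand
                hits = index.in_range(ctx.exon.chrom, strand,
                                      site - window, site + window + 1)
                if hits.size:
                    sign = 1 if strand == "+" else -1
                    offs = sign * (hits - site)
                    counts += np.histogram(offs, bins=edges)[0]
            densities[anchor] = counts / len(members)
        profiles.append(SpliceMapProfile(label, len(members), edges, densities))
    return profiles


def splice_map_frame(profiles: Sequence[SpliceMapProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for anchor in SITE_LABELS:
            for off, dens in zip(p.bin_edges[:-1], p.densities[anchor]):
                rows.append(
                    {"group": p.label, "anchor": anchor,
                     "offset_bin": int(off), "density": float(dens)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group CDFs
# ---------------------------------------------------------------------------

@dataclass
class GroupCDFs:
    grid: np.ndarray
    cdfs: dict            # label -> CDF values on grid
    values: dict          # label -> sorted raw values
    comparisons: pd.DataFrame  # Mann-Whitney vs background


def group_effect_cdf(
    values: Mapping[str, float],
    groups: Mapping[str, set],
    background: str,
    min_group: int = 5,
) -> GroupCDFs:
    """Empirical CDFs of a per-feature value by group, compared with a
    background group by a two-sided Mann-Whitney U test."""
    if background not in groups:
        raise KeyError(f"background group {background!r} not among groups")
    raw = {
        label: np.sort([values[f] for f in members if f in values and np.isfinite(values[f])])
        for label, members in groups.items()
    }
    nonempty = [v for v in raw.values() if v.size]
    pooled = np.concatenate(nonempty) if nonempty else np.empty(0)
    grid = np.unique(pooled)
    cdfs = {
        label: (np.searchsorted(v, grid, side="right") / v.size if v.size else
                np.zeros_like(grid, dtype=float))
        for label, v in raw.items()
    }
    bg = raw[background]
    rows = []
    for label, v in raw.items():
        if label == background:
            continue
        if v.size < min_group or bg.size < min_group:
            warnings.warn(f"group {label!r} too small for comparison (n={v.size})")
            rows.append({"group": label, "n": int(v.size), "u": np.nan, "p": np.nan})
            continue
        u, p = mannwhitneyu(v, bg, alternative="two-sided")
        rows.append({"group": label, "n": int(v.size), "u": float(u), "p": float(p)})
    return GroupCDFs(grid, cdfs, raw,
                     pd.DataFrame(rows, columns=["group", "n", "u", "p"]))


def flanking_intron_ids(genes: Sequence[GeneModel]) -> dict[str, tuple[str, str]]:
    """Map each internal exon id to its (upstream, downstream) intron ids."""
    out = {}
    for g in genes:
        for i in g.internal_exon_indices():
            out[g.exon_id(i)] = (g.intron_id(i - 1), g.intron_id(i))
    return out


def intron_retention_association(
    z_pir: Mapping[str, float],
    exon_groups: Mapping[str, set],
    genes: Sequence[GeneModel],
    background: str,
) -> dict[str, GroupCDFs]:
    """Z_PIR CDFs of upstream / downstream flanking introns, stratified by
    exon response group. Introns without a PIR value are dropped and counted."""
    flank = flanking_intron_ids(genes)
    out = {}
    for side, pick in (("upstream", 0), ("downstream", 1)):
        side_values: dict[str, float] = {}
        groups_side: dict[str, set] = {}
        missing = 0
        for label, exon_ids in exon_groups.items():
            members = set()
            for eid in exon_ids:
                pair = flank.get(eid)
                if pair is None:
                    continue
                iid = pair[pick]
                z = z_pir.get(iid)
                if z is None or not np.isfinite(z):
                    missing += 1
                    continue
                side_values[iid] = float(z)
                members.add(iid)
            groups_side[label] = members
        if missing:
            warnings.warn(f"{missing} {side} introns lacked PIR coverage and were excluded")
        out[side] = group_effect_cdf(side_values, groups_side, background)
    return out


# ---------------------------------------------------------------------------
# Splice-site strength (PWM log-odds)
# ---------------------------------------------------------------------------

# window geometry in transcript orientation: (exonic nt, intronic nt)
DONOR_WINDOW = (3, 6)      # 9-mer across the 5'ss
ACCEPTOR_WINDOW = (20, 3)  # 23-mer across the 3'ss: 20 intronic + 3 exonic

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _site_window(seq: str, intron_start: int, intron_end: int, strand: str, kind: str) -> str | None:
    if kind == "5ss":
        ex, inn = DONOR_WINDOW
        if strand == "+":
            lo, hi = intron_start - ex, intron_start + inn
            win = seq[lo:hi] if lo >= 0 and hi <= len(seq) else None
        else:
            lo, hi = intron_end - inn, intron_end + ex
            win = _revcomp(seq[lo:hi]) if lo >= 0 and hi <= len(seq) else None
    elif kind == "3ss":
        inn, ex = ACCEPTOR_WINDOW
        if strand == "+":
            lo, hi = intron_end - inn, intron_end + ex
            win = seq[lo:hi] if lo >= 0 and hi <= len(seq) else None
        else:
            lo, hi = intron_start - ex, intron_start + inn
            win = _revcomp(seq[lo:hi]) if lo >= 0 and hi <= len(seq) else None
    else:
        raise ValueError(f"kind must be '5ss' or '3ss', got {kind!r}")
    if win is not None and (len(win) != ex + inn or "N" in win):
        return None
    return win


@dataclass
class SpliceSiteModel:
    """Trained donor/acceptor PWMs with genome background frequencies."""

    donor_pwm: object       # Bio.motifs position-specific probability matrix
    acceptor_pwm: object
    background: dict

    def pssm(self, kind: str):
        pwm = self.donor_pwm if kind == "5ss" else self.acceptor_pwm
        return pwm.log_odds(self.background)

    def probabilities(self, kind: str) -> np.ndarray:
        """(positions, 4) probability matrix, columns in ACGT order."""
        pwm = self.donor_pwm if kind == "5ss" else self.acceptor_pwm
        return np.array([[pwm[b][i] for b in "ACGT"] for i in range(pwm.length)])


@dataclass(frozen=True)
class SpliceSiteScore:
    position: int
    kind: str
    score: float


def _base_frequencies(sequences: Mapping[str, str]) -> dict:
    counts = {b: 1 for b in "ACGT"}  # pseudocount keeps all rates positive
    for seq in sequences.values():
        for b in "ACGT":
            counts[b] += seq.count(b)
    total = sum(counts.values())
    return {b: counts[b] / total for b in "ACGT"}


def train_splice_site_model(
    genes: Sequence[GeneModel],
    sequences: Mapping[str, str],
    min_sites: int = 50,
) -> SpliceSiteModel:
    """Train donor and acceptor PWMs from annotated introns.

    Position frequency matrices use a pseudocount of 1 per base and are scored
    as log2 odds against genome-wide base frequencies.
    """
    from Bio import motifs
    from Bio.Seq import Seq

    donors, acceptors = [], []
    for g in genes:
        seq = sequences.get(g.chrom)
        if seq is None:
            continue
        for intron in g.introns:
            w5 = _site_window(seq, intron.start, intron.end, g.strand, "5ss")
            w3 = _site_window(seq, intron.start, intron.end, g.strand, "3ss")
            if w5:
                donors.append(Seq(w5))
            if w3:
                acceptors.append(Seq(w3))
    if len(donors) < min_sites or len(acceptors) < min_sites:
        raise ValueError(
            f"only {len(donors)} donors / {len(acceptors)} acceptors; "
            f"need >= {min_sites} — supply a pre-trained model instead"
        )
    background = _base_frequencies(sequences)
    donor_pwm = motifs.create(donors).counts.normalize(pseudocounts=1.0)
    acceptor_pwm = motifs.create(acceptors).counts.normalize(pseudocounts=1.0)
    return SpliceSiteModel(donor_pwm, acceptor_pwm, background)


def splice_site_strength(
    sequences: Mapping[str, str],
    gene: GeneModel,
    intron_index: int,
    kind: str,
    model: SpliceSiteModel,
) -> SpliceSiteScore | None:
    """Log2-odds strength of one splice site of an intron; ``None`` when the
    scoring window falls off the contig."""
    from Bio.Seq import Seq

    seq = sequences.get(gene.chrom)
    if seq is None:
        return None
    intron = gene.introns[intron_index]
    win = _site_window(seq, intron.start, intron.end, gene.strand, kind)
    if win is None:
        return None
    score = float(model.pssm(kind).calculate(Seq(win)))
    if gene.strand == "+":
        pos = intron.start if kind == "5ss" else intron.end - 1
    else:
        pos = intron.end - 1 if kind == "5ss" else intron.start
    return SpliceSiteScore(pos, kind, score)


def score_window(window: str, kind: str, model: SpliceSiteModel) -> float:
    """Score an explicit transcript-orientation window with the trained PWM."""
    from Bio.Seq import Seq

    return float(model.pssm(kind).calculate(Seq(window)))
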