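"""Synthetic genomes, PAR-CLIP reads and splicing count tables with recorded truth.

The generator emulates the study design the pipeline is built for: multi-exon
gene models with cassette exons; crosslinking reads whose T-to-C conversions
mark binding sites placed preferentially on the intronic side of splice sites
(default mode 70 nt from the 3' splice site); and case/control junction count
tables (2 overexpression and 4 knockdown replicates with paired controls) with
beta-binomial sampling noise and planted ΔPSI effects coupled to binding.

Every random draw comes from generators seeded from ``SimulationConfig.seed``
(one independent stream per stage), so a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, flanking_splice_sites
from .clusters import AlignedClipRead

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int
    # genome geometry
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 250)
    intron_len: tuple[int, int] = (300, 1200)
    intergenic_gap: tuple[int, int] = (500, 2000)
    minus_strand_fraction: float = 0.5
    cassette_fraction: float = 0.5     # internal exons given intermediate control PSI
    # PAR-CLIP
    n_clip_replicates: int = 2
    clip_reads_per_site: float = 20.0
    clip_read_length: int = 30
    conversion_rate: float = 0.7       # at the crosslink-site uridine
    other_t_conversion_ratio: float = 0.03   # x conversion_rate, other covered Ts
    background_read_fraction: float = 0.1
    background_conversion_ratio: float = 0.01
    positional_offset_mean: float = 70.0     # nt into the intron from the splice site
    positional_offset_sd: float = 10.0
    site_weights: dict = field(
        default_factory=lambda: {
            "up5ss": 0.15, "up3ss": 0.35, "down5ss": 0.15, "down3ss": 0.35,
        }
    )
    background_binding_rate: float = 0.10    # per unplanted internal exon
    max_sites_per_exon: int = 4              # at most one per splice-site label
    extra_site_rate: float = 0.30            # P(each additional site), binomial
    additive_site_effect: float = 0.10       # extra |ΔPSI| per site beyond the first
    # RNA-seq
    conditions: dict = field(default_factory=lambda: {"KD": 4, "OE": 2})
    depth_per_exon: float = 100.0
    depth_per_intron: float = 100.0
    rnaseq_read_length: int = 100
    planted_fraction: float = 0.10
    true_delta_psi: float = 0.30
    oe_skipping_fraction: float = 0.85  # P(a planted exon is skipped upon OE)
    coupling: float = 0.80              # P(binding near >=1 splice site | planted)
    pir_base: tuple[float, float] = (0.02, 0.15)
    pir_effect: float = 0.10
    noise_overdispersion: float = 0.01  # beta-binomial rho
    mean_gene_reads: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "minus_strand_fraction", "cassette_fraction", "conversion_rate",
            "background_read_fraction", "planted_fraction", "oe_skipping_fraction",
            "coupling", "noise_overdispersion", "background_binding_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.intron_len[0] < 10:
            raise ValueError("introns shorter than 10 nt leave no room for splice sites")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons to have internal exons")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        tag = sum(ord(c) for c in stage)
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


@dataclass
class GroundTruth:
    """Planted truth tables completed stage by stage."""

    exons: pd.DataFrame
    introns: pd.DataFrame
    sites: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _write_splice_dinucleotides(seq: np.ndarray, intron: GenomicInterval) -> None:
    # transcript-strand GT..AG; on the plus strand of the genome a minus-strand
    # intron therefore reads CT..AC
    s, e = intron.start, intron.end
    if intron.strand == "+":
        seq[s], seq[s + 1], seq[e - 2], seq[e - 1] = (ord("G"), ord("T"), ord("A"), ord("G"))
    else:
        seq[s], seq[s + 1], seq[e - 2], seq[e - 1] = (ord("C"), ord("T"), ord("A"), ord("C"))


def simulate_genome(
    config: SimulationConfig, with_sequence: bool = True
) -> tuple[list[GeneModel], dict[str, str], GroundTruth]:
    """Generate gene models, (optionally) sequence, and the truth skeleton.

    The skeleton already fixes the splicing ground truth — control PSI per
    internal exon, planted signed ΔPSI per condition, control PIR and coupled
    ΔPIR per intron, and which exons are targeted for binding — so that the
    read and count generators draw around a single consistent truth.
    """
    rng = config.stage_rng("genome")
    genes: list[GeneModel] = []
    cursor = 0
    chrom = "chr1"
    for gi in range(config.n_genes):
        cursor += int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        exons = []
        pos = cursor
        for e in range(n_exons):
            length = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
        cursor = pos
        if strand == "-":
            exons = exons[::-1]
        genes.append(GeneModel(f"gene{gi:05d}", exons))

    sequences: dict[str, str] = {}
    if with_sequence:
        seq = rng.choice(_BASES, size=cursor + 100)
        for g in genes:
            for intron in g.introns:
                _write_splice_dinucleotides(seq, intron)
        sequences[chrom] = seq.tobytes().decode("ascii")

    truth = _truth_skeleton(genes, config, rng)
    return genes, sequences, truth


def _truth_skeleton(
    genes: list[GeneModel], config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    exon_rows = []
    for g in genes:
        for i in range(g.n_exons):
            e = g.exons[i]
            exon_rows.append(
                {
                    "exon_id": g.exon_id(i), "gene_id": g.gene_id,
                    "chrom": e.chrom, "start": e.start, "end": e.end,
                    "strand": e.strand, "exon_index": i,
                    "internal": 0 < i < g.n_exons - 1,
                }
            )
    exons = pd.DataFrame(exon_rows)

    internal = exons["internal"].to_numpy()
    n = len(exons)
    cassette = internal & (rng.random(n) < config.cassette_fraction)
    planted = cassette & (rng.random(n) < config.planted_fraction)

    psi_control = np.where(
        cassette, rng.uniform(0.10, 0.90, n), rng.uniform(0.985, 1.0, n)
    )
    # planted exons sit mid-range so the base effect survives clipping
    psi_control = np.where(planted, rng.uniform(0.35, 0.65, n), psi_control)
    sign_oe = np.where(rng.random(n) < config.oe_skipping_fraction, -1.0, 1.0)
    bound = (planted & (rng.random(n) < config.coupling)) | (
        internal & ~planted & (rng.random(n) < config.background_binding_rate)
    )
    n_sites = np.where(
        bound,
        1 + rng.binomial(max(config.max_sites_per_exon - 1, 0),
                         config.extra_site_rate, n),
        0,
    )
    exons["cassette"] = cassette
    exons["planted"] = planted
    exons["psi_control"] = np.where(internal, psi_control, np.nan)
    exons["bound_target"] = bound
    exons["n_sites_target"] = n_sites
    # effect grows additively with the number of bound splice sites
    magnitude = np.where(
        planted,
        config.true_delta_psi
        + config.additive_site_effect * np.maximum(n_sites - 1, 0) * bound,
        0.0,
    )
    for cond in config.conditions:
        # knockdown mirrors overexpression (inverse regulation)
        cond_sign = sign_oe if cond.upper().startswith("OE") else -sign_oe
        target = np.clip(psi_control + cond_sign * magnitude, 0.0, 1.0)
        # record the realized (clip-aware) change as the truth
        exons[f"delta_psi_{cond}"] = np.where(planted, target - psi_control, 0.0)

    intron_rows = []
    planted_ids = set(exons.loc[exons["planted"], "exon_id"])
    exon_delta = {
        cond: dict(zip(exons["exon_id"], exons[f"delta_psi_{cond}"]))
        for cond in config.conditions
    }
    for g in genes:
        for i in range(g.n_exons - 1):
            iv = g.introns[i]
            # introns flank exons i and i+1 in transcript order
            neighbours = [g.exon_id(i), g.exon_id(i + 1)]
            row = {
                "intron_id": g.intron_id(i), "gene_id": g.gene_id,
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "strand": iv.strand, "intron_index": i,
                "pir_control": float(rng.uniform(*config.pir_base)),
            }
            for cond in config.conditions:
                delta = 0.0
                for eid in neighbours:
                    if eid in planted_ids:
                        # skipping of the exon goes with retention of its flanks
                        delta = -np.sign(exon_delta[cond][eid]) * config.pir_effect
                row[f"delta_pir_{cond}"] = delta
            intron_rows.append(row)
    introns = pd.DataFrame(intron_rows)
    return GroundTruth(exons=exons, introns=introns)


# ---------------------------------------------------------------------------
# PAR-CLIP read simulation
# ---------------------------------------------------------------------------

_SITE_INTRON_STEP = {
    # genomic direction from the splice-site base into the intron interior
    ("+", "5ss"): 1, ("+", "3ss"): -1, ("-", "5ss"): -1, ("-", "3ss"): 1,
}


def _transcript_t_positions(seq: str, chrom: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return {
        "+": np.flatnonzero(arr == ord("T")),
        "-": np.flatnonzero(arr == ord("A")),
    }


def _snap_to_t(pos: int, lo: int, hi: int, t_positions: np.ndarray, max_shift: int = 10):
    """Nearest transcript-strand T within max_shift nt, constrained to [lo, hi)."""
    i = np.searchsorted(t_positions, pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < t_positions.size:
            cand = int(t_positions[j])
            if lo <= cand < hi and abs(cand - pos) <= max_shift:
                if best is None or abs(cand - pos) < abs(best - pos):
                    best = cand
    return best


def simulate_parclip_reads(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    sequences: dict[str, str],
) -> tuple[list[list[AlignedClipRead]], GroundTruth]:
    """Place binding sites at splice-site vicinities of targeted exons and draw
    replicate read sets around them.

    Each targeted exon receives one site: a splice-site anchor is chosen by
    ``site_weights``, the site sits a Normal(offset_mean, offset_sd) distance
    into the intron, snapped to the nearest transcript-strand T (re-drawn if
    none within 10 nt). Reads of fixed length cover the site with Poisson
    counts; the site T converts at ``conversion_rate``, other covered Ts at a
    small multiple of it. A background of non-specific, near-conversion-free
    reads is added. Replicates are drawn independently around the same sites.
    """
    rng = config.stage_rng("parclip")
    by_tid = {g.transcript_id: g for g in genes}
    t_pos = {chrom: _transcript_t_positions(seq, chrom) for chrom, seq in sequences.items()}
    labels = list(config.site_weights)
    weights = np.array([config.site_weights[l] for l in labels], dtype=float)
    weights = weights / weights.sum()

    site_rows = []
    targeted = truth.exons[truth.exons["bound_target"]]
    for row in targeted.itertuples():
        gene = by_tid[row.gene_id]
        ctx = flanking_splice_sites(row.exon_index, gene)
        n_sites = min(int(getattr(row, "n_sites_target", 1)), len(labels))
        chosen = rng.choice(len(labels), size=n_sites, replace=False, p=weights)
        for label in (labels[i] for i in chosen):
            placed = False
            for _ in range(20):  # re-draw on T-less windows
                intron = ctx.intron_of(label)
                site_pos = ctx.sites[label]
                step = _SITE_INTRON_STEP[(gene.strand, label[-3:])]
                d = max(3, int(round(rng.normal(config.positional_offset_mean,
                                                config.positional_offset_sd))))
                d = min(d, len(intron) - 3)
                pos = site_pos + step * d
                snapped = _snap_to_t(pos, intron.start, intron.end,
                                     t_pos[gene.chrom][gene.strand])
                if snapped is None:
                    continue
                tsign = 1 if gene.strand == "+" else -1
                site_rows.append(
                    {
                        "site_id": f"site{len(site_rows):05d}",
                        "exon_id": row.exon_id, "gene_id": row.gene_id,
                        "chrom": gene.chrom, "strand": gene.strand,
                        "label": label, "splice_site_pos": site_pos,
                        "position": snapped,
                        "offset": tsign * (snapped - site_pos),
                    }
                )
                placed = True
                break
            if not placed:
                logger.warning("no T near the %s of %s; site skipped", label, row.exon_id)

    sites = pd.DataFrame(
        site_rows,
        columns=["site_id", "exon_id", "gene_id", "chrom", "strand", "label",
                 "splice_site_pos", "position", "offset"],
    )
    truth.sites = sites

    other_rate = config.conversion_rate * config.other_t_conversion_ratio
    bg_rate = config.conversion_rate * config.background_conversion_ratio
    L = config.clip_read_length
    spans = [(g.chrom, g.strand, g.span.start, g.span.end) for g in genes]

    replicates: list[list[AlignedClipRead]] = []
    for _rep in range(config.n_clip_replicates):
        reads: list[AlignedClipRead] = []
        n_site_reads = 0
        for s in sites.itertuples():
            n = int(rng.poisson(config.clip_reads_per_site))
            n_site_reads += n
            ts = t_pos[s.chrom][s.strand]
            for _ in range(n):
                start = int(s.position) - int(rng.integers(0, L))
                start = max(start, 0)
                end = start + L
                lo = np.searchsorted(ts, start)
                hi = np.searchsorted(ts, end)
                conv = []
                for t in ts[lo:hi]:
                    rate = config.conversion_rate if t == s.position else other_rate
                    if rng.random() < rate:
                        conv.append(int(t))
                reads.append(
                    AlignedClipRead(
                        GenomicInterval(s.chrom, start, end, s.strand),
                        conversion_positions=tuple(conv),
                    )
                )
        n_bg = int(round(config.background_read_fraction * n_site_reads))
        for _ in range(n_bg):
            chrom, strand, lo_span, hi_span = spans[int(rng.integers(len(spans)))]
            start = int(rng.integers(lo_span, max(hi_span - L, lo_span + 1)))
            end = start + L
            ts = t_pos[chrom][strand]
            lo = np.searchsorted(ts, start)
            hi = np.searchsorted(ts, end)
            conv = [int(t) for t in ts[lo:hi] if rng.random() < bg_rate]
            reads.append(
                AlignedClipRead(
                    GenomicInterval(chrom, start, end, strand),
                    conversion_positions=tuple(conv),
                )
            )
        replicates.append(reads)
    return replicates, truth


# ---------------------------------------------------------------------------
# Splicing count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountTables:
    condition: str
    role: str            # case | control
    replicate: int       # 1-based
    exons: pd.DataFrame  # feature_id, e_in, e_out
    introns: pd.DataFrame
    genes: pd.DataFrame  # gene_id, mapped_reads, exon_kb


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, rho: float
) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(n, p)
    scale = (1.0 - rho) / rho
    a = np.maximum(p * scale, 1e-9)
    b = np.maximum((1.0 - p) * scale, 1e-9)
    draw = rng.beta(a, b)
    draw = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, draw))
    return rng.binomial(n, draw)


def simulate_splicing_counts(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[CountTables], GroundTruth]:
    """Draw per-sample junction count tables around the planted truth.

    For every internal exon, each sample draws a Poisson total of
    junction-informative reads and splits it e_in / e_out by a beta-binomial
    with the sample's true PSI and overdispersion rho; introns are sampled the
    same way from true PIR. Case samples use PSI + planted ΔPSI (clipped to
    [0, 1]); paired controls use control PSI. Gene-level exonic totals are
    Poisson around ``mean_gene_reads``.
    """
    rng = config.stage_rng("rnaseq")
    ex = truth.exons[truth.exons["internal"]].reset_index(drop=True)
    intr = truth.introns.reset_index(drop=True)
    rho = config.noise_overdispersion

    gene_rows = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "exon_kb": [g.exon_kb() for g in genes],
        }
    )

    tables: list[CountTables] = []
    for cond, n_reps in config.conditions.items():
        psi_case = np.clip(
            ex["psi_control"].to_numpy() + ex[f"delta_psi_{cond}"].to_numpy(), 0.0, 1.0
        )
        pir_case = np.clip(
            intr["pir_control"].to_numpy() + intr[f"delta_pir_{cond}"].to_numpy(), 0.0, 1.0
        )
        for rep in range(1, n_reps + 1):
            for role, psi_true, pir_true in (
                ("case", psi_case, None),
                ("control", ex["psi_control"].to_numpy(), None),
            ):
                totals = rng.poisson(config.depth_per_exon, size=len(ex))
                e_in = _beta_binomial(rng, totals, psi_true, rho)
                exon_df = pd.DataFrame(
                    {
                        "feature_id": ex["exon_id"],
                        "e_in": e_in,
                        "e_out": totals - e_in,
                    }
                )
                p = pir_case if role == "case" else intr["pir_control"].to_numpy()
                itotals = rng.poisson(config.depth_per_intron, size=len(intr))
                i_in = _beta_binomial(rng, itotals, p, rho)
                intron_df = pd.DataFrame(
                    {
                        "feature_id": intr["intron_id"],
                        "i_in": i_in,
                        "i_out": itotals - i_in,
                    }
                )
                gene_df = gene_rows.copy()
                gene_df["mapped_reads"] = rng.poisson(
                    config.mean_gene_reads, size=len(gene_rows)
                )
                tables.append(
                    CountTables(cond, role, rep, exon_df, intron_df, gene_df)
                )
    return tables, truth


def metric_matrices(
    tables: Sequence[CountTables], condition: str, feature: str = "exons"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack one condition's paired tables into (k, n) case / control ratio
    matrices plus per-replicate coverage (case + control totals)."""
    incol, outcol = ("e_in", "e_out") if feature == "exons" else ("i_in", "i_out")
    sel = [t for t in tables if t.condition == condition]
    reps = sorted({t.replicate for t in sel})
    case_rows, control_rows, cov_rows = [], [], []
    feature_ids: list[str] = []
    for rep in reps:
        case = next(t for t in sel if t.role == "case" and t.replicate == rep)
        ctrl = next(t for t in sel if t.role == "control" and t.replicate == rep)
        cdf = getattr(case, feature)
        kdf = getattr(ctrl, feature)
        if not feature_ids:
            feature_ids = list(cdf["feature_id"])
        for df, rows in ((cdf, case_rows), (kdf, control_rows)):
            tot = df[incol].to_numpy() + df[outcol].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                rows.append(np.where(tot > 0, df[incol].to_numpy() / tot, np.nan))
        cov_rows.append(
            (cdf[incol] + cdf[outcol] + kdf[incol] + kdf[outcol]).to_numpy(float)
        )
    return (
        np.vstack(case_rows),
        np.vstack(control_rows),
        np.vstack(cov_rows),
        feature_ids,
    )


# ---------------------------------------------------------------------------
# Labelled splice reads (for exercising the junction counter)
# ---------------------------------------------------------------------------

def simulate_splice_reads(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
):
    """Random labelled junction evidence records across the gene set.

    Overlap values span 1 .. read_length-1 so both sides of the 6 bp rule are
    exercised. Used to validate the counting rules against a per-read oracle;
    the count-table path remains authoritative for statistics.
    """
    from .quant import SpliceRead

    rng = rng or config.stage_rng("splice-reads")
    L = config.rnaseq_read_length
    reads = []
    eligible = [g for g in genes if g.n_exons >= 3]
    for i in range(n_reads):
        g = eligible[int(rng.integers(len(eligible)))]
        kind = ("exon", "junction", "junction", "intron_exon")[int(rng.integers(4))]
        if kind == "exon":
            reads.append(SpliceRead(f"r{i}", g.transcript_id, "exon",
                                    int(rng.integers(g.n_exons))))
        elif kind == "junction":
            a = int(rng.integers(g.n_exons - 1))
            b = int(rng.integers(a + 1, g.n_exons))
            ov1 = int(rng.integers(1, L))
            reads.append(
                SpliceRead(f"r{i}", g.transcript_id, "junction", a, b,
                           overlap_left=ov1, overlap_right=L - ov1)
            )
        else:
            intron = int(rng.integers(g.n_exons - 1))
            ov1 = int(rng.integers(1, L))
            reads.append(
                SpliceRead(f"r{i}", g.transcript_id, "intron_exon", intron,
                           overlap_left=ov1, overlap_right=L - ov1)
            )
    return reads


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def config_from_yaml(path: str | Path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "seed" not in data:
        raise ValueError("simulation config must set a seed")
    for key in ("exons_per_gene", "exon_len", "intron_len", "intergenic_gap", "pir_base"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    import yaml

    data = asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
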