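"""End-to-end orchestration: simulate -> clusters -> quant -> diff -> map -> evaluate.

A run is driven by one :class:`RunConfig`; a single global seed is fanned out
into per-stage derived seeds (hashed with the stage name) so disabling one
stage does not reshuffle another's randomness. Every output file is recorded
in a JSON manifest with a SHA-256 digest; rerunning the same config reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import GeneModel, flanking_splice_sites, load_annotation, write_bed12
from .clusters import (
    boundary_density_profile,
    call_clusters,
    consensus_clusters,
    read_clip_reads_tsv,
    write_clip_reads_tsv,
    write_clusters_bed,
)
from .diffstats import DifferentialConfig, differential_test
from .quant import define_cassette_exons, psi as psi_fn
from .simulate import (
    CountTables,
    GroundTruth,
    SimulationConfig,
    simulate_genome,
    simulate_parclip_reads,
    simulate_splicing_counts,
)
from .splicemap import (
    group_effect_cdf,
    proximity_table,
    splice_map_frame,
    splicing_map,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "clusters", "quant", "diff", "map", "evaluate")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    seed: int = 7
    outdir: str = "clipsplice_run"
    stages: tuple = ALL_STAGES
    simulation: SimulationConfig | None = None
    differential: DifferentialConfig | None = None
    min_reads: int = 2
    boundary_window: int = 300
    max_dist: int = 150
    map_window: int = 300
    map_bin: int = 5
    z_thresholds: tuple = (-1.0, -2.0)
    map_condition: str = "OE"

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=derive_seed(self.seed, "simulate"))
        if self.differential is None:
            self.differential = DifferentialConfig(seed=derive_seed(self.seed, "diff"))
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", None)
        diff = data.pop("differential", None)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "z_thresholds" in data:
            data["z_thresholds"] = tuple(data["z_thresholds"])
        cfg = cls(**data)
        if sim is not None:
            sim.setdefault("seed", derive_seed(cfg.seed, "simulate"))
            for key in ("exons_per_gene", "exon_len", "intron_len",
                        "intergenic_gap", "pir_base"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        if diff is not None:
            diff.setdefault("seed", derive_seed(cfg.seed, "diff"))
            cfg.differential = DifferentialConfig(**diff)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_fasta(sequences: Mapping[str, str], path: Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def counts_long_frame(tables: Sequence[CountTables], feature: str) -> pd.DataFrame:
    incol, outcol = ("e_in", "e_out") if feature == "exons" else ("i_in", "i_out")
    frames = []
    for t in tables:
        df = getattr(t, feature).copy()
        df.insert(1, "condition", t.condition)
        df.insert(2, "role", t.role)
        df.insert(3, "replicate", t.replicate)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["feature_id", "condition", "role", "replicate", incol, outcol]]


def long_counts_to_matrices(df: pd.DataFrame, condition: str, incol: str, outcol: str):
    """(k, n) case/control ratio and coverage matrices from a long count table."""
    sel = df[df["condition"] == condition]
    reps = sorted(sel["replicate"].unique())
    feature_ids = sorted(sel["feature_id"].unique())
    fidx = {f: i for i, f in enumerate(feature_ids)}
    k, n = len(reps), len(feature_ids)
    case = np.full((k, n), np.nan)
    control = np.full((k, n), np.nan)
    cov = np.zeros((k, n))
    for r, rep in enumerate(reps):
        for role, target in (("case", case), ("control", control)):
            part = sel[(sel["replicate"] == rep) & (sel["role"] == role)]
            idx = part["feature_id"].map(fidx).to_numpy()
            tot = part[incol].to_numpy() + part[outcol].to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                target[r, idx] = np.where(tot > 0, part[incol].to_numpy() / tot, np.nan)
            cov[r, idx] += tot
    return case, control, cov, feature_ids


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(diff_df: pd.DataFrame, truth_exons: pd.DataFrame, condition: str) -> dict:
    """Sensitivity, false-discovery proportion and ΔPSI accuracy against truth."""
    truth = truth_exons.set_index("exon_id")
    merged = diff_df.merge(
        truth[["planted", f"delta_psi_{condition}"]],
        left_on="feature_id", right_index=True, how="left",
    )
    merged = merged[merged["planted"].notna()]
    called = merged["call"] != "none"
    planted = merged["planted"].astype(bool)
    true_delta = merged[f"delta_psi_{condition}"]
    direction_ok = np.sign(merged["mean_delta"].fillna(0)) == np.sign(true_delta)
    tp = called & planted & direction_ok
    n_calls = int(called.sum())
    metrics = {
        "n_tested": int(merged["tested"].sum()),
        "n_planted": int(planted.sum()),
        "n_called": n_calls,
        "sensitivity": float(tp.sum() / planted.sum()) if planted.any() else float("nan"),
        "fdp": float((called & ~planted).sum() / n_calls) if n_calls else float("nan"),
    }
    if tp.any():
        err = merged.loc[tp, "mean_delta"] - true_delta[tp]
        metrics["delta_psi_bias"] = float(err.mean())
        metrics["delta_psi_rmse"] = float(np.sqrt((err**2).mean()))
    else:
        metrics["delta_psi_bias"] = float("nan")
        metrics["delta_psi_rmse"] = float("nan")
    return metrics


def evaluate_crosslinks(consensus, sites: pd.DataFrame, tol: int = 2) -> dict:
    """Fraction of true sites recovered within ``tol`` nt and their mean error."""
    from collections import defaultdict

    by_group = defaultdict(list)
    for c in consensus:
        iv = c.interval
        xl = getattr(c, "crosslink", None)
        if xl is None:
            xl = c.preferred_crosslink
        if xl is not None:
            by_group[(iv.chrom, iv.strand)].append(xl)
    arrays = {k: np.sort(np.asarray(v)) for k, v in by_group.items()}
    errors = []
    for s in sites.itertuples():
        arr = arrays.get((s.chrom, s.strand))
        if arr is None or arr.size == 0:
            errors.append(np.inf)
            continue
        i = np.searchsorted(arr, s.position)
        best = min(
            abs(int(arr[j]) - int(s.position))
            for j in (i - 1, i)
            if 0 <= j < arr.size
        )
        errors.append(best)
    errors = np.asarray(errors, dtype=float)
    recovered = errors <= tol
    return {
        "n_true_sites": int(len(sites)),
        "site_recovery": float(recovered.mean()) if len(sites) else float("nan"),
        "crosslink_mae": float(errors[recovered].mean()) if recovered.any() else float("nan"),
    }


def evaluate_proximity_enrichment(
    prox: pd.DataFrame, diff_df: pd.DataFrame, truth_exons: pd.DataFrame
) -> dict:
    """Ratio of binding-proximal fractions: called-changed exons vs the rest."""
    calls = diff_df.set_index("feature_id")["call"]
    bound = prox.set_index("exon_id")["n_sites_bound"] >= 1
    common = bound.index.intersection(calls.index)
    if len(common) == 0:
        return {"proximity_enrichment": float("nan")}
    called = calls.loc[common] != "none"
    frac_called = float(bound.loc[common][called].mean()) if called.any() else float("nan")
    frac_rest = float(bound.loc[common][~called].mean()) if (~called).any() else float("nan")
    ratio = frac_called / frac_rest if frac_rest and np.isfinite(frac_rest) else float("nan")
    return {
        "bound_fraction_called": frac_called,
        "bound_fraction_background": frac_rest,
        "proximity_enrichment": ratio,
    }


def evaluate_against_truth(outputs: dict, truth: GroundTruth) -> pd.DataFrame:
    """Deterministic metrics table from pipeline outputs and planted truth."""
    rows = []
    for cond, df in outputs.get("diff_exons", {}).items():
        for key, value in evaluate_calls(df, truth.exons, cond).items():
            rows.append({"metric": f"{key}_{cond}", "value": value})
    if "consensus" in outputs and truth.sites is not None:
        for key, value in evaluate_crosslinks(outputs["consensus"], truth.sites).items():
            rows.append({"metric": key, "value": value})
    if "proximity" in outputs and "diff_exons" in outputs:
        cond = outputs.get("map_condition", next(iter(outputs["diff_exons"])))
        for key, value in evaluate_proximity_enrichment(
            outputs["proximity"], outputs["diff_exons"][cond], truth.exons
        ).items():
            rows.append({"metric": key, "value": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Raises on stage failure after retaining partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "simulation": asdict(config.simulation),
            "differential": asdict(config.differential),
            "min_reads": config.min_reads,
            "max_dist": config.max_dist,
            "map_window": config.map_window,
            "map_bin": config.map_bin,
            "z_thresholds": list(config.z_thresholds),
            "map_condition": config.map_condition,
        },
        "stages": {},
        "files": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = _sha256(path)

    def save_tsv(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        record(name, path)
        return path

    state: dict = {}
    sim = config.simulation

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        logger.info("stage %s starting", stage)

        if stage == "simulate":
            genes, sequences, truth = simulate_genome(sim)
            replicates, truth = simulate_parclip_reads(genes, truth, sim, sequences)
            tables, truth = simulate_splicing_counts(genes, truth, sim)
            state.update(genes=genes, sequences=sequences, truth=truth,
                         clip_replicates=replicates, tables=tables)
            write_bed12(genes, outdir / "genome.bed12")
            record("genome.bed12", outdir / "genome.bed12")
            _write_fasta(sequences, outdir / "genome.fa")
            record("genome.fa", outdir / "genome.fa")
            for i, reads in enumerate(replicates, start=1):
                name = f"clip_reads_rep{i}.tsv"
                write_clip_reads_tsv(reads, outdir / name)
                record(name, outdir / name)
            save_tsv(truth.exons, "truth_exons.tsv")
            save_tsv(truth.introns, "truth_introns.tsv")
            save_tsv(truth.sites, "truth_sites.tsv")
            save_tsv(counts_long_frame(tables, "exons"), "exon_counts.tsv")
            save_tsv(counts_long_frame(tables, "introns"), "intron_counts.tsv")

        elif stage == "clusters":
            if "genes" not in state:
                state["genes"] = load_annotation(outdir / "genome.bed12")
            if "clip_replicates" not in state:
                state["clip_replicates"] = [
                    read_clip_reads_tsv(p)
                    for p in sorted(outdir.glob("clip_reads_rep*.tsv"))
                ]
            called = [
                call_clusters(reads, min_reads=config.min_reads)
                for reads in state["clip_replicates"]
            ]
            state["clusters"] = called
            for i, cl in enumerate(called, start=1):
                name = f"clusters_rep{i}.bed"
                write_clusters_bed(cl, outdir / name)
                record(name, outdir / name)
            consensus = consensus_clusters(called[0], called[1]) if len(called) >= 2 else []
            state["consensus"] = consensus
            write_clusters_bed(consensus, outdir / "consensus.bed")
            record("consensus.bed", outdir / "consensus.bed")
            for which in ("exon-intron", "intron-exon"):
                profile = boundary_density_profile(
                    consensus, state["genes"], window=config.boundary_window, which=which
                )
                offs = np.arange(-config.boundary_window, config.boundary_window + 1)
                save_tsv(
                    pd.DataFrame({"offset": offs, "density": profile}),
                    f"boundary_profile_{which}.tsv",
                )
            logger.info("clusters: %s per replicate, %d consensus",
                        [len(c) for c in called], len(consensus))

        elif stage == "quant":
            exon_long = state.get("exon_counts_long")
            if exon_long is None:
                exon_long = pd.read_csv(outdir / "exon_counts.tsv", sep="\t")
            with np.errstate(invalid="ignore", divide="ignore"):
                tot = exon_long["e_in"] + exon_long["e_out"]
                exon_long["psi"] = np.where(tot > 0, exon_long["e_in"] / tot, np.nan)
            state["exon_counts_long"] = exon_long
            save_tsv(exon_long, "exon_psi.tsv")
            per_sample = [
                g[["feature_id", "e_in", "e_out"]]
                for _, g in exon_long.groupby(["condition", "role", "replicate"])
            ]
            cassette = sorted(define_cassette_exons(per_sample))
            state["cassette"] = set(cassette)
            path = outdir / "cassette_exons.txt"
            path.write_text("\n".join(cassette) + "\n")
            record("cassette_exons.txt", path)

        elif stage == "diff":
            exon_long = state.get("exon_counts_long")
            if exon_long is None:
                exon_long = pd.read_csv(outdir / "exon_counts.tsv", sep="\t")
                state["exon_counts_long"] = exon_long
            intron_long = pd.read_csv(outdir / "intron_counts.tsv", sep="\t") \
                if "tables" not in state else counts_long_frame(state["tables"], "introns")
            state["diff_exons"] = {}
            state["diff_introns"] = {}
            conditions = sorted(exon_long["condition"].unique())
            for cond in conditions:
                case, control, cov, ids = long_counts_to_matrices(
                    exon_long, cond, "e_in", "e_out"
                )
                df = differential_test(case, control, cov, ids, "psi", config.differential)
                state["diff_exons"][cond] = df
                save_tsv(df, f"diff_exons_{cond}.tsv")
                case, control, cov, ids = long_counts_to_matrices(
                    intron_long, cond, "i_in", "i_out"
                )
                dfi = differential_test(case, control, cov, ids, "pir", config.differential)
                state["diff_introns"][cond] = dfi
                save_tsv(dfi, f"diff_introns_{cond}.tsv")

        elif stage == "map":
            if "genes" not in state:
                state["genes"] = load_annotation(outdir / "genome.bed12")
            if "consensus" not in state:
                from .clusters import read_clusters_bed  # stage modularity

                state["consensus"] = read_clusters_bed(outdir / "consensus.bed")
            diff_exons = state.get("diff_exons")
            if diff_exons is None:
                diff_exons = {
                    p.stem.replace("diff_exons_", ""): pd.read_csv(p, sep="\t")
                    for p in sorted(outdir.glob("diff_exons_*.tsv"))
                }
                state["diff_exons"] = diff_exons
            cond = config.map_condition if config.map_condition in diff_exons \
                else next(iter(diff_exons))
            dfe = diff_exons[cond]
            contexts = {}
            for g in state["genes"]:
                for i in g.internal_exon_indices():
                    ctx = flanking_splice_sites(i, g)
                    contexts[ctx.exon_id] = ctx
            cassette = state.get("cassette")
            if cassette is None:
                path = outdir / "cassette_exons.txt"
                cassette = set(path.read_text().split()) if path.exists() else set(contexts)
            zcols = [c for c in dfe.columns if c.startswith("z_rep")]
            dfe = dfe.assign(z_mean=dfe[zcols].mean(axis=1))
            tested = dfe[dfe["tested"] & dfe["feature_id"].isin(cassette)]
            groups = {"all_cassette": set(tested["feature_id"])}
            for thr in config.z_thresholds:
                groups[f"z_le_{thr:g}"] = set(
                    tested.loc[tested["z_mean"] <= thr, "feature_id"]
                )
            profiles = splicing_map(
                state["consensus"], groups, contexts,
                window=config.map_window, bin_size=config.map_bin,
            )
            save_tsv(splice_map_frame(profiles), "splice_map.tsv")
            prox = proximity_table(
                state["consensus"],
                [contexts[e] for e in sorted(set(tested["feature_id"]))],
                max_dist=config.max_dist,
            )
            state["proximity"] = prox
            save_tsv(prox, "proximity.tsv")
            nb = prox.set_index("exon_id")["n_sites_bound"]
            values = dict(zip(tested["feature_id"], tested["z_mean"]))
            nb_groups = {
                f"bound_{k}": set(nb.index[nb == k]) for k in range(5)
            }
            nb_groups = {k: v for k, v in nb_groups.items() if v}
            if "bound_0" in nb_groups and len(nb_groups) > 1:
                cdfs = group_effect_cdf(values, nb_groups, background="bound_0")
                save_tsv(cdfs.comparisons, "cdf_comparisons.tsv")

        elif stage == "evaluate":
            truth = state.get("truth")
            if truth is None:
                truth = GroundTruth(
                    exons=pd.read_csv(outdir / "truth_exons.tsv", sep="\t"),
                    introns=pd.read_csv(outdir / "truth_introns.tsv", sep="\t"),
                    sites=pd.read_csv(outdir / "truth_sites.tsv", sep="\t"),
                )
            outputs = {
                "diff_exons": state.get("diff_exons", {}),
                "map_condition": config.map_condition,
            }
            if "consensus" in state:
                outputs["consensus"] = state["consensus"]
            if "proximity" in state:
                outputs["proximity"] = state["proximity"]
            metrics = evaluate_against_truth(outputs, truth)
            state["metrics"] = metrics
            save_tsv(metrics, "metrics.tsv")

        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    state["manifest"] = manifest
    return manifest
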