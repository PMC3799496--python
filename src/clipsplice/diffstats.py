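"""Differential testing of splicing / expression changes.

The noise of a junction-based Δ metric (ΔPSI, ΔPIR, Δlog2 RPKM) depends
strongly on coverage: a 10-read exon yields far noisier PSI than a 1000-read
one. Rather than fit a parametric count model, changes are standardized by a
*local* standard deviation: features are sorted by the total number of
supporting reads, the SD of Δ is computed inside a sliding window covering 1%
of features (at least ``min_window``), the raw SDs are smoothed by loess
against coverage rank, and Z = Δ / local SD.

Replicates are then combined with the rank product: within each replicate,
features are ranked by Z (rank 1 = most extreme in the requested direction,
average ranks on ties) and the ranks are multiplied across replicates. A small
rank product means a feature was consistently extreme. Its significance is
calibrated by permuting each replicate's rank list independently: the FDR at a
feature's rank product RP is E[# null RP <= RP] divided by the observed number
of features with rank product <= RP, made monotone non-decreasing in RP and
capped at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-6


@dataclass
class DifferentialConfig:
    window_fraction: float = 0.01
    min_window: int = 25
    loess_span: float = 0.3
    n_permutations: int = 200
    fdr_cut: float = 0.05
    delta_cut: float = 0.10          # |ΔPSI| / |ΔPIR| floor; use log2(1.5) for expression
    pseudocount: float = 0.1         # for Δlog2 RPKM
    min_coverage: int = 10           # supporting-read floor before testing
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.window_fraction <= 1):
            raise ValueError("window_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def delta_metric(case_value, control_value, metric: str, pseudocount: float = 0.1):
    """Per-replicate change: case − control for PSI/PIR, pseudocounted log2
    ratio for expression. Returns ``None`` when either side is undefined."""
    if case_value is None or control_value is None:
        return None
    if isinstance(case_value, float) and np.isnan(case_value):
        return None
    if isinstance(control_value, float) and np.isnan(control_value):
        return None
    if metric in ("psi", "pir"):
        return float(case_value) - float(control_value)
    if metric == "expression":
        return float(np.log2((case_value + pseudocount) / (control_value + pseudocount)))
    raise ValueError(f"unknown metric {metric!r}")


def local_sd(
    deltas: np.ndarray,
    coverages: np.ndarray,
    config: DifferentialConfig | None = None,
    smooth: bool = True,
) -> np.ndarray:
    """Coverage-local standard deviation of Δ values.

    Features are sorted by coverage; each feature's raw SD is the sample SD of
    Δ inside a centered window of ``max(min_window, round(window_fraction*n))``
    features, the window shifted inward at the list edges so its size never
    shrinks. Raw SDs are loess-smoothed against coverage rank and floored at a
    small positive epsilon. Returned in the original feature order.
    """
    config = config or DifferentialConfig()
    deltas = np.asarray(deltas, dtype=float)
    coverages = np.asarray(coverages, dtype=float)
    if deltas.shape != coverages.shape or deltas.ndim != 1:
        raise ValueError("deltas and coverages must be aligned 1-d arrays")
    n = deltas.size
    if n < config.min_window:
        warnings.warn(
            f"only {n} features (< min_window={config.min_window}); using one global SD"
        )
        sd = float(np.std(deltas, ddof=1)) if n > 1 else 0.0
        return np.full(n, max(sd, SD_FLOOR))

    order = np.argsort(coverages, kind="stable")
    d = deltas[order]
    w = min(n, max(config.min_window, int(round(config.window_fraction * n))))
    starts = np.clip(np.arange(n) - w // 2, 0, n - w)

    css = np.concatenate([[0.0], np.cumsum(d)])
    css2 = np.concatenate([[0.0], np.cumsum(d * d)])
    s1 = css[starts + w] - css[starts]
    s2 = css2[starts + w] - css2[starts]
    var = (s2 - s1 * s1 / w) / (w - 1)
    raw_sd = np.sqrt(np.maximum(var, 0.0))

    if not smooth:  # pre-loess window SDs, mainly for validation
        out = np.empty(n)
        out[order] = raw_sd
        return out

    smoothed = lowess(
        raw_sd, np.arange(n, dtype=float), frac=config.loess_span,
        return_sorted=False,
    )
    smoothed = np.maximum(smoothed, SD_FLOOR)
    out = np.empty(n)
    out[order] = smoothed
    return out


def z_transform(delta, local_sd_value):
    """Z = Δ / local SD."""
    sd = np.asarray(local_sd_value, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("local SD must be positive")
    return np.asarray(delta, dtype=float) / sd


def rank_product(
    z_per_replicate: np.ndarray, direction: str = "up"
) -> tuple[np.ndarray, np.ndarray]:
    """Direction-specific ranks per replicate and their per-feature product.

    ``z_per_replicate`` is (k, n). Rank 1 is the largest Z for ``up`` and the
    smallest for ``down``; ties receive average ranks.
    """
    z = np.atleast_2d(np.asarray(z_per_replicate, dtype=float))
    if z.shape[0] < 1 or z.shape[1] < 1:
        raise ValueError("need at least one replicate and one feature")
    if direction == "up":
        ranks = rankdata(-z, method="average", axis=1)
    elif direction == "down":
        ranks = rankdata(z, method="average", axis=1)
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return ranks, ranks.prod(axis=0)


def rank_product_fdr(
    rank_products: np.ndarray,
    ranks: np.ndarray | None = None,
    *,
    n_features: int | None = None,
    n_replicates: int | None = None,
    n_permutations: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Permutation FDR for rank products.

    Each permutation shuffles every replicate's rank list independently and
    recomputes null rank products. The FDR at observed rank product RP is the
    expected number of null rank products <= RP divided by the observed number
    of features with rank product <= RP, monotonized (non-decreasing in RP by
    reverse cumulative minimum) and capped at 1.

    Pass the observed ``ranks`` matrix (k, n) so that tied (averaged) ranks
    are permuted as-is; alternatively give ``n_features``/``n_replicates`` to
    permute untied rank lists 1..n.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rp = np.asarray(rank_products, dtype=float)
    if ranks is not None:
        ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
        k, n = ranks.shape
    else:
        if n_features is None or n_replicates is None:
            raise ValueError("give ranks, or n_features and n_replicates")
        n, k = n_features, n_replicates
        ranks = np.tile(np.arange(1.0, n + 1.0), (k, 1))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    null = np.empty((n_permutations, n))
    for p in range(n_permutations):
        prod = np.ones(n)
        for r in range(k):
            prod *= rng.permutation(ranks[r])
        null[p] = prod
    null_sorted = np.sort(null.ravel())

    expected_false = np.searchsorted(null_sorted, rp, side="right") / n_permutations
    n_observed_le = np.searchsorted(np.sort(rp), rp, side="right")
    fdr = expected_false / np.maximum(n_observed_le, 1)

    order = np.argsort(rp, kind="stable")
    f = fdr[order]
    f = np.minimum.accumulate(f[::-1])[::-1]  # non-decreasing in RP
    out = np.empty(rp.size)
    out[order] = np.minimum(f, 1.0)
    return out


def call_differential(records: pd.DataFrame, config: DifferentialConfig) -> pd.Series:
    """Set the up/down/none call from direction-specific FDRs and mean Δ."""
    call = pd.Series("none", index=records.index, dtype=object)
    up = (records["fdr_up"] < config.fdr_cut) & (records["mean_delta"] >= config.delta_cut)
    down = (records["fdr_down"] < config.fdr_cut) & (
        records["mean_delta"] <= -config.delta_cut
    )
    call[up] = "up"
    call[down] = "down"
    return call


def differential_test(
    case: np.ndarray,
    control: np.ndarray,
    coverage: np.ndarray,
    feature_ids=None,
    metric: str = "psi",
    config: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Full differential analysis of one metric across paired replicates.

    ``case``, ``control`` and ``coverage`` are (k, n): k paired replicates by
    n features. Values may be NaN (undefined PSI/PIR); features undefined or
    under-covered in any replicate are excluded and returned with reason
    ``excluded``. Coverage is the per-replicate total of supporting reads in
    case plus control, the sorting key for the local SD.
    """
    config = config or DifferentialConfig()
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    coverage = np.atleast_2d(np.asarray(coverage, dtype=float))
    k, n = case.shape
    if control.shape != (k, n) or coverage.shape != (k, n):
        raise ValueError("case, control, coverage must share shape (k, n)")
    if feature_ids is None:
        feature_ids = [f"feature{i}" for i in range(n)]

    if metric == "expression":
        deltas = np.log2((case + config.pseudocount) / (control + config.pseudocount))
    elif metric in ("psi", "pir"):
        deltas = case - control
    else:
        raise ValueError(f"unknown metric {metric!r}")

    ok = (
        np.isfinite(deltas).all(axis=0)
        & (coverage >= config.min_coverage).all(axis=0)
    )
    n_ok = int(ok.sum())
    if n_ok < n:
        logger.info("%d/%d features excluded (undefined or coverage < %d)",
                    n - n_ok, n, config.min_coverage)

    out = pd.DataFrame({"feature_id": feature_ids})
    out["metric"] = metric
    out["tested"] = ok
    out["coverage"] = coverage.sum(axis=0)
    mean_delta = np.full(n, np.nan)
    if n_ok:
        mean_delta[ok] = deltas[:, ok].mean(axis=0)
    out["mean_delta"] = mean_delta
    for col in ("rank_product_up", "rank_product_down", "fdr_up", "fdr_down"):
        out[col] = np.nan
    out["call"] = "none"
    if n_ok == 0:
        return out

    d = deltas[:, ok]
    cov = coverage[:, ok]
    z = np.empty_like(d)
    for r in range(k):
        sd = local_sd(d[r], cov[r], config)
        z[r] = z_transform(d[r], sd)
    for r in range(k):
        out.loc[ok, f"delta_rep{r + 1}"] = d[r]
        out.loc[ok, f"z_rep{r + 1}"] = z[r]

    for direction in ("up", "down"):
        ranks, rp = rank_product(z, direction)
        # one seed for both directions keeps the analysis exactly symmetric
        # under a case/control swap
        fdr = rank_product_fdr(
            rp, ranks, n_permutations=config.n_permutations,
            rng=np.random.default_rng(config.seed),
        )
        out.loc[ok, f"rank_product_{direction}"] = rp
        out.loc[ok, f"fdr_{direction}"] = fdr

    tested = out.loc[ok]
    out.loc[ok, "call"] = call_differential(tested, config)
    return out
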