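"""Hit calling from summarized hairpin scores.

Hairpin-level hits are thresholded by departure from normality on a
quantile-quantile plot: after fitting the reference line through the robust
location/scale (median, 1.4826*MAD), the observed order statistics are
compared with their expected normal quantiles at Blom plotting positions.
Walking from each tail inward, the outermost run of points deviating from
the line by more than ``deviation_k`` score units is called; the threshold
is the observed value at the first conforming order statistic. This is a
concrete, reproducible instantiation of the visual QQ-plot method; a
fixed-|z| cutoff is available as a fallback.

Gene-level scores use a weighted average of the two most extreme hairpin
scores per gene (default weights 0.75/0.25, the conventional top-two
weighting), with significance from size-matched permutations of hairpin
sets drawn from the same pool and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, norm
from statsmodels.stats.multitest import multipletests

DEFAULT_DEVIATION_K = 0.5
DEFAULT_ALPHA = 0.75
DEFAULT_PERMUTATIONS = 1000


@dataclass
class QQThresholds:
    low: float
    high: float
    location: float
    scale: float


def qq_threshold(
    scores,
    deviation_k: float = DEFAULT_DEVIATION_K,
    min_scores: int = 100,
    min_run: int = 3,
) -> QQThresholds:
    """Estimate depletion/enrichment thresholds from QQ-plot departure.

    Walking from each tail inward, the i-th point is compared with the
    expected extreme of the sample that remains after trimming the i points
    already walked past (Blom position of the minimum/maximum of n - i
    values, on the robust reference line). Trimming matters: outliers occupy
    the outermost ranks and would otherwise displace the plotting positions
    of genuine null points, making the tail of the null itself look deviant.
    The outermost run of points deviating by more than ``deviation_k`` score
    units is called; runs shorter than ``min_run`` are regarded as
    extreme-value fluctuation of the sample minimum/maximum rather than a
    departure, and produce no threshold.

    Returns thresholds such that depleted hits are ``score < low`` and
    enriched hits are ``score > high``; (-inf, +inf) when no tail departs.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    n = scores.size
    if n < min_scores:
        raise ValueError(f"need >= {min_scores} scores for QQ thresholding, got {n}")
    if deviation_k <= 0:
        raise ValueError("deviation_k must be > 0")
    med = float(np.median(scores))
    mad = float(median_abs_deviation(scores, scale="normal"))
    if mad == 0:
        raise ValueError("degenerate scores: MAD is zero")
    obs = np.sort(scores)

    def _walk(sign: float) -> float:
        # sign=+1 walks the low tail on obs, sign=-1 the high tail on -obs
        vals = obs if sign > 0 else -obs[::-1]
        center = med if sign > 0 else -med
        i = 0
        while i < n:
            # expected minimum of the n - i values left after trimming
            pos = (1.0 - 0.375) / (n - i + 0.25)
            expected = center + mad * norm.ppf(pos)
            if abs(vals[i] - expected) <= deviation_k:
                break
            i += 1
        if i < min_run or i >= n:
            return -np.inf
        return float(vals[i])

    low = _walk(+1.0)
    high = -_walk(-1.0)
    return QQThresholds(low=low, high=high, location=med, scale=mad)


def fixed_z_threshold(scores, z: float = 3.0) -> QQThresholds:
    """Fallback: thresholds at median +/- z robust standard deviations."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    med = float(np.median(scores))
    mad = float(median_abs_deviation(scores, scale="normal"))
    if mad == 0:
        raise ValueError("degenerate scores: MAD is zero")
    return QQThresholds(low=med - z * mad, high=med + z * mad, location=med, scale=mad)


def call_hits(
    summary: pd.DataFrame,
    deviation_k: float = DEFAULT_DEVIATION_K,
    method: str = "qq",
    fixed_z: float = 3.0,
) -> pd.DataFrame:
    """Flag each kept hairpin as depleted, enriched, or none.

    ``summary`` is the pipeline output (construct_id, pool_id, score, kept);
    thresholds are estimated per pool on the kept hairpins only.
    """
    out = []
    for pool, grp in summary.groupby("pool_id"):
        kept = grp[grp["kept"]].copy()
        sc = kept["score"].to_numpy(dtype=float)
        if method == "qq":
            thr = qq_threshold(sc, deviation_k)
        elif method == "fixed_z":
            thr = fixed_z_threshold(sc, fixed_z)
        else:
            raise ValueError(f"unknown hit-calling method {method!r}")
        res = grp.copy()
        score = res["score"].to_numpy(dtype=float)
        flag = np.where(
            ~res["kept"].to_numpy(), "none",
            np.where(score < thr.low, "depleted",
                     np.where(score > thr.high, "enriched", "none")),
        )
        res["hit"] = flag
        res["threshold_low"] = thr.low
        res["threshold_high"] = thr.high
        out.append(res)
    return pd.concat(out, ignore_index=True)


def gene_weighted_score(
    scores: pd.Series,
    gene_map: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    direction: str = "depletion",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Weighted-average gene score with permutation p-values.

    For genes with >= 2 hairpins the score is
    ``alpha * (most extreme hairpin) + (1 - alpha) * (second most extreme)``
    in the tested direction; single-hairpin genes take that hairpin's score
    and are flagged. The empirical p-value compares each gene against
    ``n_permutations`` size-matched random hairpin sets from the same score
    pool: p = (1 + #{permuted at least as extreme}) / (1 + N).

    ``scores`` is indexed by construct_id (NaN scores, e.g. filtered
    hairpins, are dropped); every remaining construct must be in ``gene_map``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if direction not in ("depletion", "enrichment"):
        raise ValueError("direction must be 'depletion' or 'enrichment'")
    scores = scores.dropna()
    unknown = [cid for cid in scores.index if cid not in gene_map]
    if unknown:
        raise ValueError(f"constructs missing from gene map: {unknown[:5]}")
    rng = np.random.default_rng(rng)
    sign = 1.0 if direction == "depletion" else -1.0  # work on sign*score, minimize

    vals = sign * scores.to_numpy(dtype=float)
    genes = pd.Series([gene_map[c] for c in scores.index], index=scores.index)

    def weighted(v: np.ndarray) -> float:
        if v.size == 1:
            return float(v[0])
        part = np.partition(v, 1)[:2]  # two smallest of sign*score
        return float(alpha * part[0] + (1 - alpha) * part[1])

    rows = []
    by_size: dict[int, list[int]] = {}
    gene_groups = {g: vals[genes.to_numpy() == g] for g in genes.unique()}
    for g, v in gene_groups.items():
        by_size.setdefault(v.size, [])
    # one permutation null per distinct gene size
    null_by_size: dict[int, np.ndarray] = {}
    for size in by_size:
        draws = np.empty(n_permutations)
        for i in range(n_permutations):
            pick = rng.choice(vals, size=size, replace=False)
            draws[i] = weighted(pick)
        null_by_size[size] = draws

    for g, v in gene_groups.items():
        obs = weighted(v)
        null = null_by_size[v.size]
        p = (1 + int((null <= obs).sum())) / (1 + n_permutations)
        rows.append({
            "gene_symbol": g,
            "n_hairpins": int(v.size),
            "score": sign * obs,
            "p_value": p,
            "direction": direction,
            "single_hairpin": v.size == 1,
        })
    out = pd.DataFrame(rows).sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
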