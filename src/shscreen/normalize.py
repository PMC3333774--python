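"""Count normalization and per-hairpin scoring for paired screen arms.

The statistical core compares a reference arm (starting pool, vehicle, or
early time point) against a test arm (endpoint, drug) per replicate.
Pipeline order is fixed:

    abundance filter -> log2(count + pseudocount) -> log ratio M, mean
    abundance A -> loess normalization of M on A (per pool) -> MAD rescale
    to robust z-scores (per pool) -> optional quantile normalization across
    replicates -> replicate summarization (median or regularized t).

The loess step removes the systematic, abundance-dependent bias visible in
MA plots of screen arms: M (the log2 test/reference ratio) is regressed on
A (the mean log2 abundance) with locally weighted linear regression and the
fit subtracted. Scores are test - reference, so depletion is negative.

Low-abundance hairpins (mean reference count below ``min_ref_count``,
default 100) are flagged out: they are kept in the output but excluded from
MAD estimation and hit calling, because the log ratio of a small count is
dominated by sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SPAN = 0.5
DEFAULT_MIN_REF_COUNT = 100
ARMS = ("reference", "test")

SAMPLE_SHEET_COLUMNS = ["sample_id", "pool_id", "arm", "replicate_id"]


def validate_sample_sheet(sheet: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check the sample sheet contract: one reference and one test sample
    per (pool, replicate), arms named 'reference'/'test', sample ids
    matching the count-matrix columns."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    sheet = sheet.astype({c: str for c in SAMPLE_SHEET_COLUMNS})
    bad_arm = set(sheet["arm"]) - set(ARMS)
    if bad_arm:
        raise ValueError(f"unknown arm values {sorted(bad_arm)}; expected {ARMS}")
    for (pool, rep), grp in sheet.groupby(["pool_id", "replicate_id"]):
        arms = sorted(grp["arm"])
        if arms != ["reference", "test"]:
            raise ValueError(
                f"pool {pool!r} replicate {rep!r} must have exactly one "
                f"reference and one test sample, got arms {arms}"
            )
    if counts is not None:
        unknown = set(sheet["sample_id"]) - set(counts.columns)
        if unknown:
            raise ValueError(f"sample ids not in count matrix: {sorted(unknown)}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", comment="#", dtype=str))


def read_count_matrix(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", comment="#", index_col="construct_id")
    if counts.index.duplicated().any():
        raise ValueError("duplicate construct ids in count matrix")
    return counts


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def log2_counts(counts, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2(count + pseudocount); pseudocount > 0 keeps zero counts finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    out = np.log2(arr + pseudocount)
    if isinstance(counts, (pd.DataFrame, pd.Series)):
        return counts.__class__(out, index=counts.index,
                                **({"columns": counts.columns} if isinstance(counts, pd.DataFrame) else {}))
    return out


def log_ratio(test_col, ref_col):
    """Per-hairpin M = log2_test - log2_ref and A = their mean."""
    test_col = np.asarray(test_col, dtype=float)
    ref_col = np.asarray(ref_col, dtype=float)
    if test_col.shape != ref_col.shape:
        raise ValueError("columns must have the same length")
    m = test_col - ref_col
    a = (test_col + ref_col) / 2.0
    return m, a


def loess_normalize(
    m, a, span: float = DEFAULT_SPAN, degree: int = 1, iterations: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the abundance-dependent trend from log ratios.

    Locally weighted linear regression of M on A (tricube weights) with
    ``iterations`` bisquare robustness reweightings; returns
    ``(M - fit(A), fit(A))`` so the fitted trend can be plotted against A
    for before/after diagnostics.

    The robustness iterations (default 3, the classic lowess setting) matter
    scientifically: a screen's genuinely depleted or enriched hairpins are
    outliers with respect to the local null trend, and without downweighting
    them the fit absorbs part of their signal — especially at abundance
    extremes where hits concentrate — normalizing away the very effect being
    measured. Set ``iterations=0`` for a plain least-squares local fit.

    ``degree`` is part of the signature for forward compatibility but only
    local-linear (1) fits are provided.
    """
    if degree != 1:
        raise NotImplementedError("only degree-1 (local linear) loess is supported")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ValueError("M and A must have the same length")
    n = m.size
    if int(np.ceil(span * n)) < 4:
        raise ValueError(
            f"local window of {int(np.ceil(span * n))} points is too small for "
            f"a linear fit; increase span (n={n}, span={span})"
        )
    # delta collapses near-identical abundances into one local fit; this is
    # the standard linear-time approximation and is numerically negligible
    delta = 0.01 * float(np.ptp(a)) if n > 5000 else 0.0
    fit = lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=False)
    return m - fit, fit


def mad_rescale(scores) -> np.ndarray:
    """Robust z-scores: (score - median) / (1.4826 * MAD).

    After rescaling the pool median is 0 and the scaled MAD is 1, making
    score distributions comparable across pools.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.unique(scores).size < 2:
        raise ValueError("degenerate pool: need >= 2 distinct scores")
    med = np.median(scores)
    mad = median_abs_deviation(scores, scale="normal")
    if mad == 0:
        raise ValueError("degenerate pool: MAD is zero")
    return (scores - med) / mad


def quantile_normalize(scores: pd.DataFrame, method: str = "quantile") -> pd.DataFrame:
    """Force identical marginal distributions across replicate columns.

    ``quantile``: each column's sorted values are replaced by the
    across-column mean of order statistics; ties within a column receive the
    mean of the reference values their ranks span, so afterwards the sorted
    vectors of all columns are identical. ``rank`` replaces values by their
    average ranks instead (a coarser alternative).
    """
    if scores.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 replicate columns")
    if scores.isna().any().any():
        raise ValueError("scores must be complete (no NaN) for quantile normalization")
    arr = scores.to_numpy(dtype=float)
    if method == "rank":
        from scipy.stats import rankdata
        out = np.column_stack([rankdata(arr[:, j]) for j in range(arr.shape[1])])
        return pd.DataFrame(out, index=scores.index, columns=scores.columns)
    if method != "quantile":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(arr, axis=0, kind="mergesort")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = np.empty(arr.shape[0])
        col[order[:, j]] = reference
        # tie rule: every member of a run of equal input values gets the
        # mean of the reference values assigned across that run
        s = pd.Series(col)
        out[:, j] = s.groupby(arr[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)


def filter_low_abundance(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    min_ref_count: int = DEFAULT_MIN_REF_COUNT,
) -> pd.Series:
    """Keep flag per hairpin: mean reference-arm count >= min_ref_count."""
    if min_ref_count < 0:
        raise ValueError("min_ref_count must be >= 0")
    ref_cols = sheet.loc[sheet["arm"] == "reference", "sample_id"].tolist()
    keep = counts[ref_cols].mean(axis=1) >= min_ref_count
    keep.name = "kept"
    return keep


def summarize_replicates(
    scores: pd.DataFrame,
    method: str = "median",
    s0_quantile: float = 0.9,
) -> pd.Series:
    """Collapse per-replicate scores to one score per hairpin.

    ``median`` is the component-wise median. ``regularized_t`` is a
    SAM-style moderated statistic d = mean / (s0 + s/sqrt(n)) where s is the
    per-hairpin standard deviation across replicates and s0 the
    ``s0_quantile`` quantile of s over all hairpins — the additive fudge
    keeps low-variance hairpins from producing explosive statistics.
    """
    if method == "median":
        out = scores.median(axis=1)
    elif method == "regularized_t":
        n = scores.shape[1]
        if n < 2:
            raise ValueError("regularized_t needs >= 2 replicates")
        mean = scores.mean(axis=1)
        s = scores.std(axis=1, ddof=1)
        s0 = float(np.quantile(s.to_numpy(), s0_quantile))
        if s0 <= 0:
            raise ValueError("degenerate fudge factor s0 <= 0")
        out = mean / (s0 + s / np.sqrt(n))
    else:
        raise ValueError(f"unknown summarization method {method!r}")
    out.name = "score"
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ScreenScores:
    """Output of the normalization pipeline.

    ``replicate`` holds one row per (hairpin, pool, replicate) with every
    intermediate value; ``summary`` one row per (hairpin, pool) with the
    summarized score and the abundance-filter flag.
    """

    replicate: pd.DataFrame
    summary: pd.DataFrame


def normalize_screen(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    span: float = DEFAULT_SPAN,
    loess_iterations: int = 3,
    min_ref_count: int = DEFAULT_MIN_REF_COUNT,
    quantile: bool = False,
    summary_method: str = "median",
) -> ScreenScores:
    """Run the fixed pipeline for every pool in the sample sheet.

    Loess and MAD rescaling operate within each (pool, replicate) pair, on
    the hairpins passing the abundance filter; quantile normalization (when
    enabled) and summarization operate across a pool's replicates.
    """
    sheet = validate_sample_sheet(sheet, counts)
    rep_frames = []
    summaries = []
    for pool, pool_sheet in sheet.groupby("pool_id"):
        if len(counts) < 50:
            raise ValueError(
                f"pool {pool!r}: need >= 50 hairpins for loess normalization, "
                f"got {len(counts)}"
            )
        keep = filter_low_abundance(counts, pool_sheet, min_ref_count)
        z_cols: dict[str, pd.Series] = {}
        for rep, pair in pool_sheet.groupby("replicate_id"):
            ref_id = pair.loc[pair["arm"] == "reference", "sample_id"].iloc[0]
            test_id = pair.loc[pair["arm"] == "test", "sample_id"].iloc[0]
            l2_ref = log2_counts(counts[ref_id], pseudocount)
            l2_test = log2_counts(counts[test_id], pseudocount)
            m, a = log_ratio(l2_test, l2_ref)
            kept = keep.to_numpy()
            norm = np.full(len(counts), np.nan)
            fit = np.full(len(counts), np.nan)
            norm[kept], fit[kept] = loess_normalize(
                m[kept], a[kept], span=span, iterations=loess_iterations
            )
            z = np.full(len(counts), np.nan)
            z[kept] = mad_rescale(norm[kept])
            rep_frames.append(pd.DataFrame({
                "construct_id": counts.index,
                "pool_id": pool,
                "replicate_id": rep,
                "log2_ref": l2_ref.to_numpy(),
                "log2_test": l2_test.to_numpy(),
                "A": a,
                "M": m,
                "loess_fit": fit,
                "score_loess": norm,
                "score_z": z,
                "kept": kept,
            }))
            z_cols[rep] = pd.Series(z, index=counts.index)
        z_mat = pd.DataFrame(z_cols)
        if quantile and z_mat.shape[1] >= 2:
            kept_idx = keep[keep].index
            z_mat.loc[kept_idx] = quantile_normalize(z_mat.loc[kept_idx]).to_numpy()
        summary = summarize_replicates(z_mat.loc[keep[keep].index], summary_method)
        summaries.append(pd.DataFrame({
            "construct_id": counts.index,
            "pool_id": pool,
            "score": summary.reindex(counts.index).to_numpy(),
            "kept": keep.to_numpy(),
        }))
    return ScreenScores(
        replicate=pd.concat(rep_frames, ignore_index=True),
        summary=pd.concat(summaries, ignore_index=True),
    )
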