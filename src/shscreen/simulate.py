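"""Engineered-depletion screen simulator and detection-performance evaluator.

The generative model mirrors the structure of a pooled screen sequenced at
depth R per sample:

* starting relative abundances p_h proportional to exp(Normal(0, sigma_a))
  — a lognormal spread across hairpins (sigma_a = 0.5 natural-log units by
  default, roughly a 30-fold abundance range across a 10k pool);
* an engineered depletion design assigning a retention factor d_h in (0, 1]
  to chosen hairpin subsets (d_h = 1 means non-manipulated); expected test
  abundance is proportional to p_h * d_h, renormalized per sample;
* per-sample, per-hairpin multiplicative extra-Poisson noise 2^Normal(0,
  sigma_n) on the log2 scale (sigma_n = 0.08 by default, a calibration that
  reproduces observed null log-ratio spread; PCR amplification noise is
  subsumed here);
* sequencing sampling: count ~ Poisson(R * q_h * noise). Poisson rather
  than multinomial for cell-wise independence; at these depths the
  difference is negligible.

FASTQ emission adds per-base substitution errors (uniform over the three
alternative bases) and uncalled bases to 26-mers built as a 2-base 5' flank
+ the 19-nt sense sequence + a 5-base 3' flank (the flank defaults are
arbitrary stand-ins for the vector's constant regions).

Randomness: one master seed; each (purpose, arm, replicate) consumes its
own deterministic child stream, so adding replicates never perturbs counts
already generated for earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .library import HairpinLibrary

DEFAULT_ABUNDANCE_SIGMA = 0.5  # natural-log sd of starting abundance
DEFAULT_NOISE_SIGMA = 0.08     # log2 sd of per-sample multiplicative noise
DEFAULT_READS = 10_000_000
FLANK5 = "TA"
FLANK3 = "GGCAG"

_STREAM_ABUNDANCE = 0
_STREAM_DESIGN = 1
_STREAM_COUNTS = 2
_STREAM_FASTQ = 3
_ARM_INDEX = {"reference": 0, "test": 1}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass
class SimConfig:
    """Generative parameters of a synthetic engineered-depletion screen."""

    n_hairpins: int = 10_000
    abundance_sigma: float = DEFAULT_ABUNDANCE_SIGMA
    depletion_design: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    reads_per_sample: int = DEFAULT_READS
    n_replicates: int = 1
    read_error_rate: float = 0.005
    n_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("read_error_rate", self.read_error_rate),
                          ("n_rate", self.n_rate)):
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.abundance_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.reads_per_sample < self.n_hairpins:
            raise ValueError("reads_per_sample must be >= n_hairpins")
        for cid, d in self.depletion_design.items():
            if not 0 < d <= 1:
                raise ValueError(f"retention factor for {cid!r} must be in (0, 1]")

    @property
    def hairpin_ids(self) -> list[str]:
        width = len(str(self.n_hairpins))
        return [f"h{i:0{width}d}" for i in range(1, self.n_hairpins + 1)]


def make_depletion_design(
    n_hairpins: int,
    groups: list[tuple[int, float]],
    seed: int = 0,
) -> dict[str, float]:
    """Assign retention factors to disjoint random hairpin subsets.

    ``groups`` is a list of (group_size, retention) pairs, e.g.
    ``[(1000, 0.75), (1000, 0.5), (1000, 0.25)]`` for the three-level
    engineered-depletion design (25/50/75% depletion of ~1,000 hairpins
    each within the pool).
    """
    total = sum(n for n, _ in groups)
    if total > n_hairpins:
        raise ValueError("design assigns more hairpins than the pool contains")
    width = len(str(n_hairpins))
    ids = [f"h{i:0{width}d}" for i in range(1, n_hairpins + 1)]
    rng = _rng(seed, _STREAM_DESIGN)
    chosen = rng.choice(n_hairpins, size=total, replace=False)
    design: dict[str, float] = {}
    k = 0
    for n, d in groups:
        for idx in chosen[k : k + n]:
            design[ids[idx]] = float(d)
        k += n
    return design


@dataclass
class SimTruth:
    """Ground truth: per-hairpin starting abundance and retention factor."""

    table: pd.DataFrame  # index construct_id; columns: p (sums to 1), d

    @property
    def depleted_ids(self) -> pd.Index:
        return self.table.index[self.table["d"] < 1]

    def group_ids(self, d: float) -> pd.Index:
        return self.table.index[np.isclose(self.table["d"], d)]

    @property
    def retention_levels(self) -> list[float]:
        return sorted(set(self.table.loc[self.table["d"] < 1, "d"]))


def simulate_screen(cfg: SimConfig) -> tuple[SimTruth, pd.DataFrame, pd.DataFrame]:
    """Generate ground truth, a count matrix, and its sample sheet.

    Samples are named ``ref_<r>`` / ``test_<r>`` for replicates r = 1..n.
    Fully reproducible from ``cfg.seed``; each sample has its own stream.
    """
    ids = cfg.hairpin_ids
    unknown = set(cfg.depletion_design) - set(ids)
    if unknown:
        raise ValueError(f"depletion design references unknown hairpins: {sorted(unknown)[:5]}")
    rng_a = _rng(cfg.seed, _STREAM_ABUNDANCE)
    p = np.exp(rng_a.normal(0.0, cfg.abundance_sigma, size=cfg.n_hairpins))
    p /= p.sum()
    d = np.ones(cfg.n_hairpins)
    id_pos = {cid: i for i, cid in enumerate(ids)}
    for cid, ret in cfg.depletion_design.items():
        d[id_pos[cid]] = ret

    cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    for rep in range(1, cfg.n_replicates + 1):
        for arm in ("reference", "test"):
            q = p * (d if arm == "test" else 1.0)
            q = q / q.sum()
            rng_s = _rng(cfg.seed, _STREAM_COUNTS, _ARM_INDEX[arm], rep)
            noise = 2.0 ** rng_s.normal(0.0, cfg.noise_sigma, size=cfg.n_hairpins)
            lam = cfg.reads_per_sample * q * noise
            sample_id = f"{'ref' if arm == 'reference' else 'test'}_{rep}"
            cols[sample_id] = rng_s.poisson(lam)
            sheet_rows.append({
                "sample_id": sample_id, "pool_id": "pool1",
                "arm": arm, "replicate_id": str(rep),
            })
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="construct_id"))
    truth = SimTruth(pd.DataFrame({"p": p, "d": d},
                                  index=pd.Index(ids, name="construct_id")))
    return truth, counts, pd.DataFrame(sheet_rows)


def random_library(
    n_hairpins: int, seed: int = 0, name: str = "simulated"
) -> HairpinLibrary:
    """A synthetic library of distinct random 19-mers (uniform bases)."""
    from .library import HairpinRecord

    rng = _rng(seed, _STREAM_DESIGN, 1)
    width = len(str(n_hairpins))
    seen: set[str] = set()
    records = []
    i = 0
    while len(records) < n_hairpins:
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=19))
        if seq in seen:
            continue
        seen.add(seq)
        i += 1
        records.append(HairpinRecord(f"h{i:0{width}d}", f"GENE{(i - 1) // 3 + 1}", seq))
    return HairpinLibrary(records, name=name)


def emit_fastq(
    truth: SimTruth,
    lib: HairpinLibrary,
    cfg: SimConfig,
    sample: str,
    path: str | Path,
) -> np.ndarray:
    """Write simulated 26-base reads for one sample; returns true counts.

    ``sample`` is ``ref_<r>`` or ``test_<r>``. Per-hairpin read numbers
    follow the same Poisson model as :func:`simulate_screen` (independent
    draws from the FASTQ stream); each read is FLANK5 + sense + FLANK3 with
    substitutions at ``read_error_rate`` and uncalled bases at ``n_rate``.
    Qualities are a constant placeholder (binning ignores them).
    """
    arm = "reference" if sample.startswith("ref") else "test"
    rep = int(sample.rsplit("_", 1)[1])
    t = truth.table
    if list(t.index) != lib.construct_ids:
        raise ValueError("truth and library must list the same hairpins in order")
    q = t["p"].to_numpy() * (t["d"].to_numpy() if arm == "test" else 1.0)
    q = q / q.sum()
    rng = _rng(cfg.seed, _STREAM_FASTQ, _ARM_INDEX[arm], rep)
    noise = 2.0 ** rng.normal(0.0, cfg.noise_sigma, size=len(lib))
    n_reads = rng.poisson(cfg.reads_per_sample * q * noise)

    sense = lib.encoded()  # (n, 19) codes 0..3
    hairpin_of_read = np.repeat(np.arange(len(lib)), n_reads)
    total = hairpin_of_read.size
    flank5 = np.frombuffer(FLANK5.encode(), dtype=np.uint8)
    flank3 = np.frombuffer(FLANK3.encode(), dtype=np.uint8)
    decode = np.frombuffer(b"ACGTN", dtype=np.uint8)

    path = Path(path)
    qual_line = ("I" * (len(FLANK5) + 19 + len(FLANK3))).encode()
    with open(path, "wb") as fh:
        batch = 200_000
        written = 0
        for b0 in range(0, total, batch):
            idx = hairpin_of_read[b0 : b0 + batch]
            codes = sense[idx].copy()  # (m, 19)
            m = codes.shape[0]
            sub = rng.random((m, 19)) < cfg.read_error_rate
            if sub.any():
                shift = rng.integers(1, 4, size=int(sub.sum()))
                codes[sub] = (codes[sub] + shift) % 4
            if cfg.n_rate > 0:
                codes[rng.random((m, 19)) < cfg.n_rate] = 4
            seq = np.empty((m, len(qual_line)), dtype=np.uint8)
            seq[:, : len(FLANK5)] = flank5
            seq[:, len(FLANK5) : len(FLANK5) + 19] = decode[codes]
            seq[:, len(FLANK5) + 19 :] = flank3
            lines = []
            for r in range(m):
                written += 1
                lines.append(b"@read%d\n%s\n+\n%s\n"
                             % (written, seq[r].tobytes(), qual_line))
            fh.write(b"".join(lines))
    return n_reads


def subsample_counts(
    counts: pd.DataFrame, fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Binomial thinning of every cell — the exact model of sequencing a
    fraction of the original read depth.

    Thinning a Poisson(lambda) count at fraction f yields Poisson(f*lambda),
    and thinning composes: f1 then f2 equals f1*f2 in distribution.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return counts.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    arr = rng.binomial(counts.to_numpy(), fraction)
    return pd.DataFrame(arr, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Detection evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Detection performance of a scored screen against simulation truth.

    Rates are computed per depletion group by sweeping a score threshold
    (depletion direction: a hairpin is called when score < threshold):

    * ``fnr_at_zero_fpr``: fraction of the group missed at the most
      permissive threshold calling zero non-manipulated hairpins;
    * ``fpr_at_fnr5``: false-positive rate at the threshold where the
      group's FNR first reaches <= 5%;
    * ``mean_ratio``: group mean of raw per-hairpin test/reference count
      ratios (hairpins with reference count 0 excluded and tallied).
    """

    fnr_at_zero_fpr: dict[float, float]
    fpr_at_fnr5: dict[float, float]
    mean_ratio: dict[float, float]
    replicate_r2: float | None
    roc: pd.DataFrame  # columns: threshold, fpr, fnr (all depleted pooled)
    n_zero_ref: int = 0


def _zero_fpr_fnr(group_scores: np.ndarray, null_scores: np.ndarray) -> float:
    # most permissive zero-FPR threshold: call score < min(null)
    thr = null_scores.min()
    return float((group_scores >= thr).mean())


def _fpr_at_fnr(group_scores: np.ndarray, null_scores: np.ndarray,
                max_fnr: float = 0.05) -> float:
    srt = np.sort(group_scores)
    m = srt.size
    k = int(np.ceil((1 - max_fnr) * m))  # calls needed so FNR <= max_fnr
    thr = srt[k - 1]
    return float((null_scores <= thr).mean())


def evaluate_detection(
    scores: pd.Series,
    truth: SimTruth,
    counts: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    replicate_scores: pd.DataFrame | None = None,
) -> EvalResult:
    """Score detection of the engineered depletion against ground truth.

    ``scores`` is one summarized score per hairpin (NaN = filtered out,
    excluded from both groups and nulls). ``counts``/``sheet`` enable the
    raw mean test/reference ratios; ``replicate_scores`` (one column of
    normalized log ratios per replicate) enables the replicate r^2.
    """
    t = truth.table
    common = scores.dropna().index.intersection(t.index)
    if len(common) == 0:
        raise ValueError("scores and truth share no hairpins")
    sc = scores.loc[common]
    d = t.loc[common, "d"]
    levels = truth.retention_levels
    if not levels:
        raise ValueError("truth contains no depleted hairpins")
    null_scores = sc[d == 1].to_numpy(dtype=float)
    if null_scores.size == 0:
        raise ValueError("no non-manipulated hairpins among scored hairpins")

    fnr0: dict[float, float] = {}
    fpr5: dict[float, float] = {}
    for lev in levels:
        grp = sc[np.isclose(d, lev)].to_numpy(dtype=float)
        fnr0[lev] = _zero_fpr_fnr(grp, null_scores)
        fpr5[lev] = _fpr_at_fnr(grp, null_scores)

    mean_ratio: dict[float, float] = {}
    n_zero_ref = 0
    if counts is not None and sheet is not None:
        ref_cols = sheet.loc[sheet["arm"] == "reference", "sample_id"].tolist()
        test_cols = sheet.loc[sheet["arm"] == "test", "sample_id"].tolist()
        ref = counts[ref_cols].mean(axis=1)
        test = counts[test_cols].mean(axis=1)
        ok = ref > 0
        n_zero_ref = int((~ok).sum())
        ratio = test[ok] / ref[ok]
        d_all = t["d"].reindex(ratio.index)
        for lev in levels:
            mean_ratio[lev] = float(ratio[np.isclose(d_all, lev)].mean())

    replicate_r2 = None
    if replicate_scores is not None:
        if replicate_scores.shape[1] < 2:
            raise ValueError("replicate r^2 needs >= 2 replicate columns")
        a, b = (replicate_scores.iloc[:, j].to_numpy(dtype=float) for j in (0, 1))
        ok = ~(np.isnan(a) | np.isnan(b))
        replicate_r2 = float(pearsonr(a[ok], b[ok])[0] ** 2)

    # pooled ROC over all depleted hairpins, sweeping observed thresholds
    depl = sc[d < 1].to_numpy(dtype=float)
    thr_grid = np.unique(np.concatenate([depl, null_scores]))
    fpr = np.searchsorted(np.sort(null_scores), thr_grid, side="left") / null_scores.size
    fnr = 1.0 - np.searchsorted(np.sort(depl), thr_grid, side="left") / depl.size
    roc = pd.DataFrame({"threshold": thr_grid, "fpr": fpr, "fnr": fnr})

    return EvalResult(
        fnr_at_zero_fpr=fnr0,
        fpr_at_fnr5=fpr5,
        mean_ratio=mean_ratio,
        replicate_r2=replicate_r2,
        roc=roc,
        n_zero_ref=n_zero_ref,
    )
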