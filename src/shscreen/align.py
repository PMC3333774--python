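"""Hamming-distance alignment of barcode reads to a hairpin library.

The deconvolution problem is much simpler than genome alignment: each
26-base read carries the 19-nt sense sequence of exactly one library
hairpin at a fixed position (bases 3-21 by default), so a read is assigned
by finding the library sequence at minimal hamming distance, up to a
mismatch cap (default 2). Binning identical trimmed reads first means each
distinct 19-mer is aligned once and its multiplicity tallied, which is
semantically identical to per-read alignment.

Assignment uses best-stratum semantics: a read is ``unique`` only if a
single library sequence attains the minimal distance; ties at the minimum
are ``ambiguous`` (equivalent to bowtie ``--best --strata -v 2 -m 1 -a``).
A minimal distance above the cap is ``unmapped``. Reads failing the
uncalled-base filter (> max_n Ns in the 19-base window) or too short to
trim are ``filtered``. The four categories partition the input exactly:
``filtered + unique + ambiguous + unmapped == total``.

'N' (uncalled) counts as a mismatch against every base, including 'N':
an uncalled position carries no evidence of identity, and this composes
conservatively with the mismatch cap.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import BASE_CODES, HairpinLibrary, SENSE_LENGTH

DEFAULT_MAX_MISMATCH = 2
DEFAULT_MAX_N = 2


class FastqFormatError(ValueError):
    """Raised for truncated or malformed FASTQ records."""


@dataclass(frozen=True)
class TrimWindow:
    """1-based inclusive window of the sense sequence within the raw read.

    The default (3, 21) extracts the 19-nt sense sequence from a 26-base
    read with a 2-base 5' flank.
    """

    start: int = 3
    end: int = 21

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("trim window start must be >= 1")
        if self.length < 1:
            raise ValueError("trim window must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReadBin:
    """A distinct trimmed 19-mer and how many identical reads produced it."""

    trimmed_seq: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class Assignment:
    """Outcome of aligning one read bin against the library."""

    status: str  # unique | ambiguous | unmapped | filtered
    construct_id: str | None = None
    distance: int | None = None


@dataclass
class AlignmentTally:
    """Per-sample read counts per hairpin per edit distance, with bookkeeping.

    ``counts[construct_id][distance]`` is the number of reads assigned
    uniquely to that construct at that hamming distance. The totals satisfy
    exact conservation: filtered + unique + ambiguous + unmapped = total.
    """

    sample_id: str
    counts: dict[str, dict[int, int]] = field(default_factory=dict)
    total_reads: int = 0
    filtered_reads: int = 0
    unique_reads: int = 0
    ambiguous_reads: int = 0
    unmapped_reads: int = 0

    def add_unique(self, construct_id: str, distance: int, n: int) -> None:
        self.counts.setdefault(construct_id, {})
        self.counts[construct_id][distance] = (
            self.counts[construct_id].get(distance, 0) + n
        )
        self.unique_reads += n

    def check_conservation(self) -> None:
        parts = (
            self.filtered_reads
            + self.unique_reads
            + self.ambiguous_reads
            + self.unmapped_reads
        )
        if parts != self.total_reads:
            raise AssertionError(
                f"read conservation violated for {self.sample_id}: "
                f"{parts} != {self.total_reads}"
            )
        assigned = sum(sum(d.values()) for d in self.counts.values())
        if assigned != self.unique_reads:
            raise AssertionError(
                f"per-construct counts ({assigned}) != unique_reads "
                f"({self.unique_reads}) for {self.sample_id}"
            )

    def unique_by_distance(self, max_mismatch: int = DEFAULT_MAX_MISMATCH) -> dict[int, int]:
        out = {d: 0 for d in range(max_mismatch + 1)}
        for per_d in self.counts.values():
            for d, n in per_d.items():
                out[d] = out.get(d, 0) + n
        return out

    def total_counts(self, lib: HairpinLibrary) -> pd.Series:
        """Distance-collapsed counts in library row order."""
        vals = [sum(self.counts.get(cid, {}).values()) for cid in lib.construct_ids]
        return pd.Series(vals, index=pd.Index(lib.construct_ids, name="construct_id"),
                         name=self.sample_id, dtype=np.int64)


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path: str | Path, expect_length: int | None = None) -> Iterator[str]:
    """Stream read sequences from a FASTQ file (plain or gzip).

    Qualities are parsed for format validation and discarded; binning is
    quality-blind. A truncated or malformed record raises
    :class:`FastqFormatError` naming the 1-based record index. Reads whose
    length differs from ``expect_length`` are still yielded; the alignment
    pipeline routes too-short reads to the filtered tally.
    """
    n = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                _title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{Path(path).name}: malformed FASTQ at record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield seq.upper()


# ---------------------------------------------------------------------------
# Per-read primitives
# ---------------------------------------------------------------------------

def trim_read(raw_seq: str, window: TrimWindow) -> str | None:
    """Extract the sense window (1-based inclusive) from a raw read.

    Returns the uppercased trimmed sequence with '.' mapped to 'N', or
    None when the read is shorter than the window end (a filter signal).
    """
    if len(raw_seq) < window.end:
        return None
    return raw_seq[window.start - 1 : window.end].upper().replace(".", "N")


def filter_uncalled(seq19: str, max_n: int = DEFAULT_MAX_N) -> bool:
    """True (keep) iff the trimmed sequence has <= max_n uncalled bases."""
    return (seq19.count("N") + seq19.count(".")) <= max_n


def hamming(a: str, b: str, cap: int | None = None) -> int:
    """Hamming distance between equal-length sequences.

    'N' mismatches every base, including another 'N'. With ``cap`` set the
    scan stops early and any value > cap means "more than cap" (the exact
    count beyond the cap is not meaningful).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or x == ".":
            d += 1
            if cap is not None and d > cap:
                return d
    return d


def assign_bin(
    bin_: ReadBin | str,
    lib: HairpinLibrary,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Assignment:
    """Assign one trimmed 19-mer to the library by minimal hamming distance.

    Best-stratum semantics: unique iff exactly one library sequence attains
    the minimal distance d* <= max_mismatch; ties at d* are ambiguous even
    if the tied sequences would be separable at a larger distance.
    """
    if len(lib) == 0:
        raise ValueError("cannot assign against an empty library")
    seq = bin_.trimmed_seq if isinstance(bin_, ReadBin) else bin_
    best_d = max_mismatch + 1
    best_id: str | None = None
    n_best = 0
    for rec in lib.records:
        d = hamming(seq, rec.sense_seq, cap=max_mismatch)
        if d < best_d:
            best_d, best_id, n_best = d, rec.construct_id, 1
        elif d == best_d and d <= max_mismatch:
            n_best += 1
    if best_d > max_mismatch:
        return Assignment("unmapped")
    if n_best > 1:
        return Assignment("ambiguous")
    return Assignment("unique", construct_id=best_id, distance=best_d)


# ---------------------------------------------------------------------------
# Vectorized bin assignment
# ---------------------------------------------------------------------------

def _encode_bins(seqs: list[str]) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return BASE_CODES[flat].reshape(len(seqs), SENSE_LENGTH)


def _assign_bins_vectorized(
    seqs: list[str],
    lib_codes: np.ndarray,
    max_mismatch: int,
    batch_rows: int = 2048,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal distance, best-stratum tie count, and argmin for each 19-mer.

    Returns (min_distance, n_at_min, argmin_index) arrays. Library codes are
    0..3 only; bin codes may contain 4 (N), which never equals a library
    code, so the plain inequality already implements N-as-mismatch.
    """
    n = len(seqs)
    dmin = np.empty(n, dtype=np.int32)
    nbest = np.empty(n, dtype=np.int32)
    amin = np.empty(n, dtype=np.int64)
    codes = _encode_bins(seqs)
    for i0 in range(0, n, batch_rows):
        chunk = codes[i0 : i0 + batch_rows]
        # (m, n_lib) distance matrix
        d = (chunk[:, None, :] != lib_codes[None, :, :]).sum(axis=2, dtype=np.int32)
        dm = d.min(axis=1)
        sl = slice(i0, i0 + chunk.shape[0])
        dmin[sl] = dm
        nbest[sl] = (d == dm[:, None]).sum(axis=1)
        amin[sl] = d.argmin(axis=1)
    return dmin, nbest, amin


def align_reads(
    reads: Iterable[str],
    lib: HairpinLibrary,
    sample_id: str = "sample",
    window: TrimWindow | None = None,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_n: int = DEFAULT_MAX_N,
) -> AlignmentTally:
    """Align an iterable of raw read sequences; see :func:`align_sample`."""
    if len(lib) == 0:
        raise ValueError("cannot align against an empty library")
    window = window or TrimWindow()
    if window.length != SENSE_LENGTH:
        raise ValueError(
            f"trim window length {window.length} != sense length {SENSE_LENGTH}"
        )
    tally = AlignmentTally(sample_id=sample_id)

    bins: dict[str, int] = {}
    for raw in reads:
        tally.total_reads += 1
        trimmed = trim_read(raw, window)
        if trimmed is None or not filter_uncalled(trimmed, max_n):
            tally.filtered_reads += 1
            continue
        bins[trimmed] = bins.get(trimmed, 0) + 1

    # exact-match index short-circuits distance 0; duplicates in the library
    # make an exact match ambiguous at distance 0 (>= 2 sequences at d*=0)
    exact: dict[str, list[str]] = {}
    for rec in lib.records:
        exact.setdefault(rec.sense_seq, []).append(rec.construct_id)

    pending_seqs: list[str] = []
    pending_mult: list[int] = []
    for seq, mult in bins.items():
        hit = exact.get(seq)
        if hit is not None:
            if len(hit) == 1:
                tally.add_unique(hit[0], 0, mult)
            else:
                tally.ambiguous_reads += mult
        else:
            pending_seqs.append(seq)
            pending_mult.append(mult)

    if pending_seqs:
        lib_codes = lib.encoded()
        dmin, nbest, amin = _assign_bins_vectorized(
            pending_seqs, lib_codes, max_mismatch
        )
        ids = lib.construct_ids
        for i, mult in enumerate(pending_mult):
            if dmin[i] > max_mismatch:
                tally.unmapped_reads += mult
            elif nbest[i] > 1:
                tally.ambiguous_reads += mult
            else:
                tally.add_unique(ids[int(amin[i])], int(dmin[i]), mult)

    tally.check_conservation()
    return tally


def align_sample(
    fastq: str | Path,
    lib: HairpinLibrary,
    window: TrimWindow | None = None,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_n: int = DEFAULT_MAX_N,
    sample_id: str | None = None,
) -> AlignmentTally:
    """Full single-sample pipeline: stream FASTQ, filter, trim, bin, assign.

    Identical trimmed reads are binned and each distinct 19-mer aligned once
    (multiplicity-weighted), with an exact-match hash index short-circuiting
    distance-0 assignment; both accelerations are semantically equivalent to
    aligning every read by brute force.
    """
    sid = sample_id or Path(fastq).name.split(".")[0]
    return align_reads(
        read_fastq(fastq), lib, sample_id=sid,
        window=window, max_mismatch=max_mismatch, max_n=max_n,
    )


# ---------------------------------------------------------------------------
# Count-matrix output
# ---------------------------------------------------------------------------

def tallies_to_matrix(
    tallies: list[AlignmentTally], lib: HairpinLibrary
) -> pd.DataFrame:
    """Collapse per-distance counts and arrange hairpins x samples."""
    ids = [t.sample_id for t in tallies]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids: {ids}")
    cols = [t.total_counts(lib) for t in tallies]
    return pd.concat(cols, axis=1)


def sample_stats(
    tallies: list[AlignmentTally], max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> pd.DataFrame:
    rows = []
    for t in tallies:
        by_d = t.unique_by_distance(max_mismatch)
        row = {
            "sample_id": t.sample_id,
            "total": t.total_reads,
            "filtered": t.filtered_reads,
            "unique": t.unique_reads,
            "ambiguous": t.ambiguous_reads,
            "unmapped": t.unmapped_reads,
        }
        for d in range(max_mismatch + 1):
            row[f"unique_d{d}"] = by_d.get(d, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_count_matrix(
    tallies: list[AlignmentTally],
    lib: HairpinLibrary,
    path: str | Path,
    stats_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the hairpins x samples count matrix as TSV (+ per-sample stats)."""
    mat = tallies_to_matrix(tallies, lib)
    mat.to_csv(path, sep="\t")
    if stats_path is not None:
        sample_stats(tallies).to_csv(stats_path, sep="\t", index=False)
    return mat
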