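"""Reference shRNA hairpin library: parsing, validation, and QC.

A pooled shRNA screen is deconvoluted by counting sequencing reads against
the library's 19-nt sense sequences, so everything downstream depends on a
validated library. The file format is plain TSV with columns
``construct_id, gene_symbol, sense_seq[, gene_id]``.

Duplicate sense sequences are legal in real libraries (independent
constructs can share a sense strand) but they make distance-0 assignment
ambiguous, so the library exposes them for QC. The pairwise edit-distance
profile is the other QC tool: a library is only safely alignable with a
mismatch tolerance *k* if few pairs sit at distance <= k.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

SENSE_LENGTH = 19
_VALID_BASES = frozenset("ACGT")

# byte -> code lookup: A,C,G,T -> 0..3, N/'.' -> 4, everything else 255
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i
BASE_CODES[ord("N")] = 4
BASE_CODES[ord("n")] = 4
BASE_CODES[ord(".")] = 4


class LibraryFormatError(ValueError):
    """Raised for malformed library files or invalid hairpin records."""


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, N -> 4)."""
    codes = BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence {seq!r}")
    return codes


@dataclass(frozen=True)
class HairpinRecord:
    """One library construct: an id, the targeted gene, and the 19-nt sense sequence."""

    construct_id: str
    gene_symbol: str
    sense_seq: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.construct_id:
            raise LibraryFormatError("construct_id must be non-empty")
        seq = self.sense_seq.upper()
        if seq != self.sense_seq:
            object.__setattr__(self, "sense_seq", seq)
        if len(seq) != SENSE_LENGTH:
            raise LibraryFormatError(
                f"construct {self.construct_id!r}: sense sequence length "
                f"{len(seq)} != {SENSE_LENGTH}"
            )
        if not _VALID_BASES.issuperset(seq):
            bad = next(c for c in seq if c not in _VALID_BASES)
            raise LibraryFormatError(
                f"construct {self.construct_id!r}: invalid base {bad!r} "
                "(library sequences must be A/C/G/T only)"
            )


@dataclass
class HairpinLibrary:
    """Ordered collection of hairpin records with unique construct ids."""

    records: list[HairpinRecord]
    name: str = "library"
    _by_id: dict[str, HairpinRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, HairpinRecord] = {}
        for rec in self.records:
            if rec.construct_id in seen:
                raise LibraryFormatError(
                    f"duplicate construct_id {rec.construct_id!r}"
                )
            seen[rec.construct_id] = rec
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HairpinRecord]:
        return iter(self.records)

    def __getitem__(self, construct_id: str) -> HairpinRecord:
        return self._by_id[construct_id]

    @property
    def construct_ids(self) -> list[str]:
        return [r.construct_id for r in self.records]

    @property
    def sense_seqs(self) -> list[str]:
        return [r.sense_seq for r in self.records]

    def gene_map(self) -> dict[str, str]:
        """construct_id -> gene_symbol."""
        return {r.construct_id: r.gene_symbol for r in self.records}

    def duplicate_sense_report(self) -> dict[str, list[str]]:
        """Sense sequences shared by >1 construct, mapped to the construct ids.

        Such constructs are indistinguishable at distance 0 and force every
        exactly-matching read to be logged as ambiguous.
        """
        groups: dict[str, list[str]] = {}
        for rec in self.records:
            groups.setdefault(rec.sense_seq, []).append(rec.construct_id)
        return {seq: ids for seq, ids in groups.items() if len(ids) > 1}

    def encoded(self) -> np.ndarray:
        """(n_hairpins, 19) uint8 code matrix, row order = record order."""
        return np.vstack([encode_seq(r.sense_seq) for r in self.records])


def read_library(
    path: str | Path, has_header: bool | None = None, name: str | None = None
) -> HairpinLibrary:
    """Read a tab-delimited hairpin library.

    Columns: construct_id, gene_symbol, sense_seq and an optional 4th
    gene_id column. When ``has_header`` is None the header is auto-detected:
    a first row whose third field is not a valid 19-nt A/C/G/T sequence is
    treated as a header.

    Raises
    ------
    LibraryFormatError
        On a row with fewer than 3 columns (naming the line number), an
        invalid sequence (naming the construct), or a duplicate construct_id.
    """
    path = Path(path)
    records: list[HairpinRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LibraryFormatError(
                    f"{path.name} line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            if lineno == 1:
                # auto-detect: a third field with non-ACGT characters is a
                # header label; a pure-ACGT field is data even if malformed
                third = fields[2].strip().upper()
                looks_like_seq = bool(third) and _VALID_BASES.issuperset(third)
                if has_header is True or (has_header is None and not looks_like_seq):
                    continue
            cid, gene, seq = (f.strip() for f in fields[:3])
            gene_id = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
            records.append(HairpinRecord(cid, gene, seq, gene_id))
    return HairpinLibrary(records, name=name or path.stem)


def write_library(lib: HairpinLibrary, path: str | Path) -> None:
    """Write the library back as TSV (no header; round-trips read_library)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in lib.records:
            fields = [rec.construct_id, rec.gene_symbol, rec.sense_seq]
            if rec.gene_id is not None:
                fields.append(rec.gene_id)
            fh.write("\t".join(fields) + "\n")


@dataclass
class EditDistanceProfile:
    """Histogram of pairwise hamming distances between library sense sequences."""

    histogram: dict[int, int]   # distance -> pair count, for 0..max_report
    n_beyond: int               # pairs at distance > max_report
    n_within_cap: int           # pairs at distance <= mismatch_cap
    mismatch_cap: int
    n_pairs: int

    @property
    def fraction_within_cap(self) -> float:
        return self.n_within_cap / self.n_pairs if self.n_pairs else 0.0


def edit_distance_profile(
    lib: HairpinLibrary, max_report: int = 4, mismatch_cap: int = 2
) -> EditDistanceProfile:
    """All-pairs hamming distance histogram (QC for alignability).

    Pairs at distance <= ``mismatch_cap`` cannot be told apart by the aligner
    when both are hit with the worst-case errors; a well-designed library has
    nearly all pairs beyond the cap. Brute force O(n^2) pairs, vectorized over
    the 19 positions; intended for QC, not for hot paths.
    """
    if len(lib) == 0:
        raise ValueError("library is empty")
    enc = lib.encoded()
    n = enc.shape[0]
    hist: Counter[int] = Counter()
    n_beyond = 0
    n_within = 0
    # row-block the n^2 distance computation to bound memory
    block = max(1, 2_000_000 // max(n, 1))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        d = (enc[i0:i1, None, :] != enc[None, :, :]).sum(axis=2)
        for i in range(i0, i1):
            row = d[i - i0, i + 1 :]
            n_within += int((row <= mismatch_cap).sum())
            small = row[row <= max_report]
            n_beyond += row.size - small.size
            hist.update(small.tolist())
    histogram = {k: hist.get(k, 0) for k in range(max_report + 1)}
    return EditDistanceProfile(
        histogram=histogram,
        n_beyond=n_beyond,
        n_within_cap=n_within,
        mismatch_cap=mismatch_cap,
        n_pairs=n * (n - 1) // 2,
    )
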