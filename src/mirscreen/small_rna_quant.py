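"""From raw small-RNA reads to a miRNA count matrix.

The library chemistry ligates a single 3' adapter; reads are therefore
processed as::

    remove first base -> cut at the leftmost 3'-adapter occurrence -> drop
    reads shorter than 15 nt -> assign to mature miRNA sequences

Adapter matching follows 3'-adapter semantics: the adapter may occur in
full anywhere in the read, or as a prefix hanging off the read's 3' end,
with at most 10% mismatches of the aligned adapter length and a minimum
overlap of 3 nt.  ``N`` in the read never matches.  Indels are not modelled;
mature miRNAs are short enough that substitution-only matching is adequate.

Quantification replaces a seed-and-extend aligner with exact dictionary
lookup against the mature-miRNA reference, optionally tolerating a bounded
number of extra or missing terminal 3' bases (the dominant isomiR mode).
Reads matching several reference entries (identical paralogs) are split
fractionally; per-miRNA counts are rounded half-up at the end so the count
matrix stays integral.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from mirscreen.plate_io import CountMatrix, FormatError, ValidationError

__all__ = [
    "DEFAULT_ADAPTER",
    "MiRNAReference",
    "TrimResult",
    "TrimStats",
    "QuantResult",
    "trim_read",
    "trim_fastq",
    "quantify_well",
    "quantify_screen",
]

#: 3' adapter of the single-adapter small-RNA library protocol.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class MiRNAReference:
    """Mature miRNA reference: id -> sequence over {A,C,G,T}.

    Sequences are uppercased and U->T converted on load, so the FASTA may
    contain RNA or DNA.  ``ambiguous_sequences`` exposes mature sequences
    shared by several ids (identical paralogs such as family members), which
    quantification splits fractionally.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("miRNA reference is empty")
        for mid, seq in self.entries.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValidationError(
                    f"reference entry {mid!r}: sequence must be non-empty "
                    f"over A/C/G/T, got {seq!r}"
                )

    @classmethod
    def from_fasta(cls, path) -> "MiRNAReference":
        entries: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in entries:
                raise ValidationError(f"duplicate reference id {record.id!r}")
            entries[record.id] = str(record.seq).upper().replace("U", "T")
        return cls(entries)

    @property
    def sequence_to_ids(self) -> dict[str, list[str]]:
        lookup: dict[str, list[str]] = {}
        for mid, seq in self.entries.items():
            lookup.setdefault(seq, []).append(mid)
        return lookup

    @property
    def ambiguous_sequences(self) -> dict[str, list[str]]:
        return {s: ids for s, ids in self.sequence_to_ids.items() if len(ids) > 1}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read."""

    kept: bool
    trimmed_sequence: str
    discard_reason: str = "none"  # none | too_short
    adapter_start: int | None = None  # index into the post -u sequence

    def __post_init__(self) -> None:
        if self.kept != (self.discard_reason == "none"):
            raise ValueError("kept flag inconsistent with discard_reason")


@dataclass
class TrimStats:
    """Bookkeeping for a trimming run; kept + discarded == input."""

    n_input: int = 0
    n_kept: int = 0
    n_discarded_short: int = 0
    adapter: str = DEFAULT_ADAPTER
    min_length: int = 15
    max_error_rate: float = 0.1
    min_overlap: int = 3

    @property
    def n_discarded(self) -> int:
        return self.n_discarded_short


def _find_adapter(
    seq: str, adapter: str, max_error_rate: float, min_overlap: int
) -> int | None:
    """Leftmost start of a qualifying 3'-adapter alignment, or None.

    At start ``i`` the aligned region is ``min(len(adapter), len(seq)-i)``
    bases of the adapter prefix; it qualifies when overlap >= min_overlap
    and mismatches <= floor(max_error_rate * overlap).  'N' counts as a
    mismatch.
    """
    n, m = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = math.floor(max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return None


def trim_read(
    read_sequence: str,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = 15,
    *,
    trim_first: int = 1,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> TrimResult:
    """Trim one read: drop ``trim_first`` leading bases, cut at the 3' adapter.

    Returns kept=False with reason ``too_short`` when the insert falls below
    ``min_length``.  ``trim_first=0`` gives the pure adapter-removal stage,
    which is idempotent (adapter-free sequences pass unchanged).
    """
    if not read_sequence:
        raise ValueError("empty read")
    seq = read_sequence.upper()[trim_first:]
    start = _find_adapter(seq, adapter.upper(), max_error_rate, min_overlap)
    trimmed = seq[:start] if start is not None else seq
    if len(trimmed) < min_length:
        return TrimResult(False, trimmed, "too_short", start)
    return TrimResult(True, trimmed, "none", start)


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def trim_fastq(
    fastq_in,
    fastq_out=None,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = 15,
    *,
    trim_first: int = 1,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[list[tuple[str, str, str]], TrimStats]:
    """Trim a FASTQ file; qualities are truncated in lockstep with sequences.

    Returns the kept records as ``(title, sequence, quality)`` tuples plus a
    :class:`TrimStats`; when ``fastq_out`` is given the kept records are also
    written there.  Malformed records raise :class:`FormatError` naming the
    record index.
    """
    stats = TrimStats(
        adapter=adapter,
        min_length=min_length,
        max_error_rate=max_error_rate,
        min_overlap=min_overlap,
    )
    kept_records: list[tuple[str, str, str]] = []
    handle = _open_text(fastq_in) if isinstance(fastq_in, (str, Path)) else fastq_in
    try:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record {index}: {exc}") from exc
            stats.n_input += 1
            result = trim_read(
                seq,
                adapter,
                min_length,
                trim_first=trim_first,
                max_error_rate=max_error_rate,
                min_overlap=min_overlap,
            )
            if result.kept:
                stats.n_kept += 1
                n_cut_left = trim_first
                kept_len = len(result.trimmed_sequence)
                kept_records.append(
                    (title, result.trimmed_sequence,
                     qual[n_cut_left : n_cut_left + kept_len])
                )
            else:
                stats.n_discarded_short += 1
            index += 1
    finally:
        if isinstance(fastq_in, (str, Path)):
            handle.close()
    if fastq_out is not None:
        out = (
            _open_text(fastq_out, "wt")
            if isinstance(fastq_out, (str, Path))
            else fastq_out
        )
        try:
            for title, seq, qual in kept_records:
                out.write(f"@{title}\n{seq}\n+\n{qual}\n")
        finally:
            if isinstance(fastq_out, (str, Path)):
                out.close()
    return kept_records, stats


@dataclass
class QuantResult:
    """Per-well quantification: integer counts plus read-level accounting.

    ``n_assigned_reads + n_unassigned == n_reads`` always holds; the integer
    ``counts`` come from fractional multi-mapper splitting rounded half-up,
    so their sum can differ from ``n_assigned_reads`` by rounding.
    """

    counts: pd.Series
    n_reads: int
    n_assigned_reads: int
    n_unassigned: int
    fractional_counts: pd.Series = field(repr=False, default=None)


def _build_lookup(
    reference: MiRNAReference, tolerate_3p: int
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    exact: dict[str, set[str]] = {}
    truncated: dict[str, set[str]] = {}
    for mid, seq in reference.entries.items():
        exact.setdefault(seq, set()).add(mid)
        for d in range(1, tolerate_3p + 1):
            if len(seq) - d >= 1:
                truncated.setdefault(seq[:-d], set()).add(mid)
    return (
        {s: frozenset(v) for s, v in exact.items()},
        {s: frozenset(v) for s, v in truncated.items()},
    )


def quantify_well(
    reads: Iterable[str],
    reference: MiRNAReference,
    tolerate_3p: int = 2,
) -> QuantResult:
    """Assign trimmed reads to mature miRNAs by dictionary matching.

    A read counts toward a miRNA iff it equals the mature sequence exactly,
    or equals it with up to ``tolerate_3p`` terminal 3' bases added or
    removed (``tolerate_3p=0`` is the strict exact-match mode).  Reads
    matching several ids are split ``1/k`` each; the final per-miRNA counts
    are rounded half-up.
    """
    exact, truncated = _build_lookup(reference, tolerate_3p)
    fractional = {mid: 0.0 for mid in reference.entries}
    n_reads = n_assigned = 0
    for read in reads:
        n_reads += 1
        hits: set[str] = set()
        for d in range(0, tolerate_3p + 1):
            if len(read) - d >= 1:
                hits |= exact.get(read[: len(read) - d], frozenset())
        hits |= truncated.get(read, frozenset())
        if hits:
            n_assigned += 1
            share = 1.0 / len(hits)
            for mid in hits:
                fractional[mid] += share
    frac = pd.Series(fractional, name="count")
    counts = frac.add(0.5).apply(math.floor).astype(int)
    return QuantResult(
        counts=counts,
        n_reads=n_reads,
        n_assigned_reads=n_assigned,
        n_unassigned=n_reads - n_assigned,
        fractional_counts=frac,
    )


def read_fastq_manifest(path) -> dict[str, str]:
    """Read a CSV manifest mapping well_id -> fastq_path (header required)."""
    manifest: dict[str, str] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {
            "well_id",
            "fastq_path",
        } <= set(reader.fieldnames):
            raise FormatError(f"{path}: manifest needs well_id,fastq_path columns")
        for row in reader:
            manifest[row["well_id"]] = row["fastq_path"]
    return manifest


def quantify_screen(
    manifest: Mapping[str, str],
    reference: MiRNAReference,
    *,
    tolerate_3p: int = 2,
    adapter: str = DEFAULT_ADAPTER,
    min_length: int = 15,
    trim: bool = True,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Trim and quantify every well of a FASTQ manifest into a CountMatrix.

    Columns follow manifest order.  Returns the matrix plus a per-well
    summary table (reads in, kept, assigned, unassigned).
    """
    columns: dict[str, pd.Series] = {}
    summary_rows = []
    for well_id, fastq_path in manifest.items():
        if not Path(fastq_path).exists():
            raise FileNotFoundError(
                f"well {well_id}: FASTQ file {fastq_path} not found"
            )
        if trim:
            kept_records, stats = trim_fastq(
                fastq_path, adapter=adapter, min_length=min_length
            )
            reads = [seq for _, seq, _ in kept_records]
            n_input = stats.n_input
        else:
            with _open_text(fastq_path) as handle:
                reads = [seq for _, seq, _ in FastqGeneralIterator(handle)]
            n_input = len(reads)
        result = quantify_well(reads, reference, tolerate_3p)
        columns[well_id] = result.counts
        summary_rows.append(
            {
                "well_id": well_id,
                "reads_in": n_input,
                "reads_kept": len(reads),
                "reads_assigned": result.n_assigned_reads,
                "reads_unassigned": result.n_unassigned,
            }
        )
    matrix = CountMatrix(pd.DataFrame(columns))
    summary = pd.DataFrame(summary_rows).set_index("well_id")
    return matrix, summary
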