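"""Small-RNA read loading: collapse to unique sequences, length windowing.

The collapsed representation keeps the dataset's total input read count
(``total_reads``) separate from the per-sequence multiplicities: that total is
the library-size denominator of every RPM and frequency value downstream, and
it is deliberately left untouched by length filtering and host filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from exomir.errors import ParseError, ValidationError
from exomir.reference_io import normalize_sequence

#: Default length window (nt) for retained reads.  Mature miRNAs are mostly
#: 18-24 nt, but catalogs include matures up to 25-26 nt, so the default is
#: permissive rather than discarding catalog-matchable reads.
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 26


@dataclass
class ReadSet:
    """Unique read sequences with counts for one dataset.

    ``total_reads`` is the number of reads in the original input file — the
    T_k of the frequency formula — and never changes under filtering.
    """

    dataset_id: str
    total_reads: int
    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValidationError("total_reads must be non-negative")
        for seq, count in self.entries.items():
            if count <= 0:
                raise ValidationError(f"zero/negative count for {seq!r}")

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    @property
    def n_reads(self) -> int:
        """Reads represented by the current entries (<= total_reads)."""
        return sum(self.entries.values())


def _sniff_format(path) -> str:
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    if first == "":
        return "empty"
    raise ParseError(f"{path}: neither FASTQ ('@') nor FASTA ('>') input")


def collapse_reads(path, dataset_id: str) -> ReadSet:
    """Collapse a FASTQ or FASTA read file to unique sequences with counts.

    Quality values are ignored; the same multiset of sequences yields the
    same ReadSet regardless of input format or read order.  An empty file
    gives a ReadSet with ``total_reads`` 0.
    """
    fmt = _sniff_format(path)
    if fmt == "empty":
        return ReadSet(dataset_id=dataset_id, total_reads=0, entries={})
    entries: dict[str, int] = {}
    total = 0
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        try:
            seq = normalize_sequence(str(rec.seq), context=f"read #{i} ({rec.id})")
        except ParseError as exc:
            raise ParseError(f"{path}: {exc}") from None
        entries[seq] = entries.get(seq, 0) + 1
        total += 1
    return ReadSet(dataset_id=dataset_id, total_reads=total, entries=entries)


def filter_by_length(
    reads: ReadSet, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> ReadSet:
    """Keep entries with length in [min_len, max_len]; total_reads unchanged."""
    if min_len <= 0 or min_len > max_len:
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    kept = {s: c for s, c in reads.entries.items() if min_len <= len(s) <= max_len}
    return ReadSet(dataset_id=reads.dataset_id, total_reads=reads.total_reads, entries=kept)


# --- pre-collapsed TSV dialect ---------------------------------------------

def write_collapsed_tsv(reads: ReadSet, path) -> None:
    """Export a ReadSet as TSV (sequence, count, total_reads per row)."""
    df = pd.DataFrame(
        {
            "sequence": list(reads.entries),
            "count": list(reads.entries.values()),
            "total_reads": reads.total_reads,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_collapsed_tsv(path, dataset_id: str) -> ReadSet:
    """Load the pre-collapsed TSV dialect written by :func:`write_collapsed_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": int, "total_reads": int})
    required = {"sequence", "count", "total_reads"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return ReadSet(dataset_id=dataset_id, total_reads=0, entries={})
    totals = df["total_reads"].unique()
    if len(totals) != 1:
        raise ValidationError(f"{path}: inconsistent total_reads column")
    entries = {
        normalize_sequence(s, context=f"{path} row"): int(c)
        for s, c in zip(df["sequence"], df["count"])
    }
    if len(entries) != len(df):
        raise ValidationError(f"{path}: duplicate sequences in collapsed TSV")
    return ReadSet(dataset_id=dataset_id, total_reads=int(totals[0]), entries=entries)
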