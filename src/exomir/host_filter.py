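"""Host read filtering: mismatch-bounded full-length matching against references.

Implements the "map and remove" step without an external aligner: a read is
attributed to the host iff it aligns full-length, substitutions only (no
indels), to some window of some host reference — on either strand — with at
most ``max_mismatch`` mismatches (default 1).  ``N`` never matches anything.

The matcher is a k-mer seed index with a pigeonhole guarantee: a read of
length L split into ``max_mismatch + 1`` disjoint blocks must have at least
one block free of mismatches in any qualifying alignment, so the first k-mer
of each block is used as an exact seed.  When a query is too short for the
pigeonhole to hold at the requested bound (e.g. a 20 nt mature scanned at two
mismatches), the matcher falls back to an exhaustive vectorized scan of every
reference window, so results are exact at every bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from exomir.errors import ConfigurationError, ValidationError
from exomir.read_prep import ReadSet
from exomir.reference_io import SequenceRecord, revcomp

_N_BYTE = ord("N")

DEFAULT_SEED_LEN = 9
DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_READ_LEN = 18


class ScanHit(NamedTuple):
    """One full-length occurrence of a query in a reference.

    ``offset`` is 0-based on the forward strand of the reference; ``strand``
    is '+' when the query itself matches, '-' when its reverse complement does.
    """

    ref_id: str
    offset: int
    strand: str
    mismatches: int


@dataclass
class HostIndex:
    """Seed index over host reference sequences.

    ``seed_table`` maps every length-``k`` substring of every reference
    (forward strand) to its (reference index, offset) postings; queries are
    looked up in both orientations, which covers reverse-strand occurrences.
    """

    k: int
    max_mismatch: int
    min_read_len: int
    references: list[SequenceRecord]
    layers: list[str]
    seed_table: dict[str, list[tuple[int, int]]] = field(repr=False, default_factory=dict)
    _ref_arrays: list[np.ndarray] = field(repr=False, default_factory=list)


def build_index(
    references: Iterable[SequenceRecord],
    k: int = DEFAULT_SEED_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
    layers: Iterable[str] | None = None,
) -> HostIndex:
    """Index host references for mismatch-bounded matching.

    Raises :class:`ConfigurationError` if ``k`` is too large for the
    configured minimum read length and mismatch bound (the pigeonhole needs
    ``max_mismatch + 1`` disjoint seeds of length ``k`` inside every read).
    ``layers`` optionally labels each reference (genome/transcript/ncRNA...)
    for attribution reporting; it never affects which reads are removed.
    """
    refs = list(references)
    if not refs:
        raise ValidationError("cannot index an empty reference list")
    if k < 8:
        raise ConfigurationError(f"seed length k={k} too small (need k >= 8)")
    if min_read_len // (max_mismatch + 1) < k:
        raise ConfigurationError(
            f"k={k} too large: {max_mismatch + 1} disjoint seeds do not fit in "
            f"a {min_read_len} nt read; decrease k or the mismatch bound"
        )
    layer_list = list(layers) if layers is not None else ["reference"] * len(refs)
    if len(layer_list) != len(refs):
        raise ValidationError("layers must match references one-to-one")

    seed_table: dict[str, list[tuple[int, int]]] = {}
    arrays: list[np.ndarray] = []
    for ri, ref in enumerate(refs):
        seq = ref.sequence
        arrays.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
        for off in range(len(seq) - k + 1):
            seed_table.setdefault(seq[off : off + k], []).append((ri, off))
    return HostIndex(
        k=k,
        max_mismatch=max_mismatch,
        min_read_len=min_read_len,
        references=refs,
        layers=layer_list,
        seed_table=seed_table,
        _ref_arrays=arrays,
    )


def _hamming_at(ref_seq: str, start: int, query: str, bound: int) -> int | None:
    """Mismatch count of query vs ref_seq[start:start+len(query)], or None if > bound."""
    if start < 0 or start + len(query) > len(ref_seq):
        return None
    mism = 0
    for a, b in zip(query, ref_seq[start : start + len(query)]):
        if a != b or a == "N":
            mism += 1
            if mism > bound:
                return None
    return mism


def _seed_offsets(length: int, k: int, n_blocks: int) -> list[int]:
    # first k-mer of each of n_blocks disjoint, near-equal blocks
    return [round(i * length / n_blocks) for i in range(n_blocks)]


def _seed_candidates(index: HostIndex, query: str, max_mismatch: int):
    """Yield (ref_idx, start) alignment candidates from exact seed hits."""
    n_blocks = max_mismatch + 1
    seen: set[tuple[int, int]] = set()
    for q_off in _seed_offsets(len(query), index.k, n_blocks):
        postings = index.seed_table.get(query[q_off : q_off + index.k])
        if not postings:
            continue
        for ri, r_off in postings:
            cand = (ri, r_off - q_off)
            if cand not in seen:
                seen.add(cand)
                yield cand


def _scan_one_orientation(
    index: HostIndex, query: str, max_mismatch: int, strand: str, first_only: bool
) -> list[ScanHit]:
    """Exact hit list for one query orientation, choosing seed vs full scan."""
    hits: list[ScanHit] = []
    L = len(query)
    pigeonhole_ok = (max_mismatch + 1) * index.k <= L and max_mismatch <= index.max_mismatch
    if pigeonhole_ok:
        for ri, start in _seed_candidates(index, query, max_mismatch):
            mism = _hamming_at(index.references[ri].sequence, start, query, max_mismatch)
            if mism is not None:
                hits.append(ScanHit(index.references[ri].id, start, strand, mism))
                if first_only:
                    return hits
        return hits
    # exhaustive vectorized scan over every reference window
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    q_is_n = q == _N_BYTE
    for ri, arr in enumerate(index._ref_arrays):
        if arr.size < L:
            continue
        win = sliding_window_view(arr, L)
        neq = (win != q) | (win == _N_BYTE) | q_is_n
        mism = neq.sum(axis=1)
        for start in np.flatnonzero(mism <= max_mismatch):
            hits.append(ScanHit(index.references[ri].id, int(start), strand, int(mism[start])))
            if first_only:
                return hits
    return hits


def matches_host(read: str, index: HostIndex, max_mismatch: int | None = None) -> bool:
    """True iff the read aligns full-length to any reference window, either
    strand, with at most the configured number of substitutions."""
    mm = index.max_mismatch if max_mismatch is None else max_mismatch
    if len(read) < index.k:
        raise ValueError(
            f"read of length {len(read)} shorter than seed length k={index.k}"
        )
    for strand, query in (("+", read), ("-", revcomp(read))):
        if _scan_one_orientation(index, query, mm, strand, first_only=True):
            return True
    return False


def scan_occurrences(
    sequence: str,
    references: Iterable[SequenceRecord] | HostIndex,
    max_mismatch: int = 2,
) -> list[ScanHit]:
    """All full-length occurrences of *sequence* in the references within
    ``max_mismatch`` substitutions, both strands, exhaustively.

    Used by the provenance module to flag exogenous matures that are nearly
    identical to host genome regions (and would be absorbed by host filtering
    at a relaxed mapping bound).  Offsets are 0-based on the forward strand.
    """
    if isinstance(references, HostIndex):
        index = references
    else:
        refs = list(references)
        index = HostIndex(
            k=len(sequence) + 1,  # no seed fits: forces the exhaustive path
            max_mismatch=max_mismatch,
            min_read_len=len(sequence),
            references=refs,
            layers=["reference"] * len(refs),
            seed_table={},
            _ref_arrays=[
                np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8) for r in refs
            ],
        )
    hits: list[ScanHit] = []
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        hits.extend(
            _scan_one_orientation(index, query, max_mismatch, strand, first_only=False)
        )
    hits.sort(key=lambda h: (h.ref_id, h.offset, h.strand))
    return hits


def filter_host(reads: ReadSet, index: HostIndex) -> tuple[ReadSet, ReadSet]:
    """Partition a ReadSet into (host, residual) by mismatch-bounded matching.

    Every entry lands in exactly one partition with its count preserved, and
    both partitions carry the original ``total_reads`` denominator.
    """
    host: dict[str, int] = {}
    residual: dict[str, int] = {}
    for seq, count in reads.entries.items():
        (host if matches_host(seq, index) else residual)[seq] = count
    def _mk(entries: dict[str, int]) -> ReadSet:
        return ReadSet(
            dataset_id=reads.dataset_id, total_reads=reads.total_reads, entries=entries
        )

    return _mk(host), _mk(residual)


def host_layer_attribution(host_reads: ReadSet, index: HostIndex) -> dict[str, int]:
    """Read counts attributable to each reference layer (genome, transcript, ...).

    A read matching references in several layers is credited to each, so the
    column sums can exceed the host read count; removal itself (filter_host)
    is independent of layering.
    """
    counts: dict[str, int] = {layer: 0 for layer in dict.fromkeys(index.layers)}
    ref_layer = {ref.id: layer for ref, layer in zip(index.references, index.layers)}
    for seq, count in host_reads.entries.items():
        layers_hit = {
            ref_layer[h.ref_id]
            for h in scan_occurrences(seq, index, index.max_mismatch)
        }
        for layer in layers_hit:
            counts[layer] += count
    return counts
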