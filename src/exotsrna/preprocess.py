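"""Raw small-RNA-seq reads to collapsed sequence tags.

Quality filtering, 5'/3' adapter trimming, insert-length selection
(16-40 nt inclusive) and tag collapsing.  The 3' adapter is mandatory:
with 16-40 nt inserts on standard read lengths every genuine insert reads
through into the 3' adapter, so a read with no detectable 3' adapter is
discarded.  The 5' adapter is optional (read-through into it depends on
the library protocol) and reads lacking it pass unmodified.

The stage emits a conservation report so that
``reads_in == discarded_quality + discarded_no_adapter + discarded_length
+ retained`` always balances.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_TAG_LEN = 16
MAX_TAG_LEN = 40


@dataclass
class RawRead:
    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class SequenceTag:
    tag_sequence: str
    count: int


@dataclass
class TrimParams:
    adapter_3p: str
    adapter_5p: str | None = None
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_mean_q: float = 20.0
    min_base_q: int = 5


@dataclass
class PreprocessReport:
    """Per-sample read-conservation accounting."""

    reads_in: int = 0
    discarded_quality: int = 0
    discarded_no_adapter: int = 0
    discarded_length: int = 0
    retained: int = 0

    def balanced(self) -> bool:
        return self.reads_in == (
            self.discarded_quality
            + self.discarded_no_adapter
            + self.discarded_length
            + self.retained
        )


def _mismatches_within(a: str, b: str, budget: int) -> int | None:
    """Hamming distance if <= budget, else None. Early exit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def trim_adapter_3p(
    read: RawRead,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> RawRead | None:
    """Trim the 3' adapter; return None (discard) when it is absent.

    Scans insert lengths left to right and trims at the leftmost position
    where a prefix of the adapter matches the read suffix with overlap
    >= ``min_overlap`` and mismatch fraction <= ``max_mismatch_rate``.
    Leftmost-match keeps the shortest insert — the conservative
    anti-chimera choice.
    """
    if not adapter or min_overlap < 1:
        raise ValueError("adapter must be non-empty and min_overlap >= 1")
    seq = read.sequence
    n = len(seq)
    # Fast path: exact full-adapter occurrence.
    pos = seq.find(adapter)
    limit = n - min_overlap
    if 0 <= pos:
        limit = pos  # nothing left of an exact hit can be better than checking up to it
    for p in range(0, limit + 1):
        overlap = min(len(adapter), n - p)
        if overlap < min_overlap:
            break
        budget = int(max_mismatch_rate * overlap)
        if _mismatches_within(seq[p:p + overlap], adapter[:overlap], budget) is not None:
            return RawRead(read.read_id, seq[:p], read.qualities[:p])
    if 0 <= pos:
        return RawRead(read.read_id, seq[:pos], read.qualities[:pos])
    return None


def trim_adapter_5p(
    read: RawRead,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> RawRead:
    """Trim a 5' adapter occurrence at the read start; no-op when absent.

    The read may begin with the full adapter or with a partial adapter
    (either end of it, length >= ``min_overlap``); the longest qualifying
    match is removed.
    """
    if not adapter or min_overlap < 1:
        raise ValueError("adapter must be non-empty and min_overlap >= 1")
    seq = read.sequence
    max_e = min(len(seq), len(adapter))
    fallback = None  # longest mismatched qualifying overlap
    for e in range(max_e, min_overlap - 1, -1):
        budget = int(max_mismatch_rate * e)
        head = seq[:e]
        mms = [
            m
            for m in (
                _mismatches_within(head, adapter[:e], budget),
                _mismatches_within(head, adapter[-e:], budget),
            )
            if m is not None
        ]
        if not mms:
            continue
        if min(mms) == 0:  # exact overlap beats any longer mismatched one
            return RawRead(read.read_id, seq[e:], read.qualities[e:])
        if fallback is None:
            fallback = e
    if fallback is not None:
        return RawRead(read.read_id, seq[fallback:], read.qualities[fallback:])
    return read


def quality_filter(read: RawRead, min_mean_q: float = 20.0, min_base_q: int = 5) -> bool:
    """Keep iff mean Phred >= threshold, no base below floor, no N."""
    if "N" in read.sequence:
        return False
    q = read.qualities
    if len(q) == 0:
        return False
    return bool(q.min() >= min_base_q and q.mean() >= min_mean_q)


def length_filter(seq: str) -> bool:
    return MIN_TAG_LEN <= len(seq) <= MAX_TAG_LEN


def collapse_tags(sequences: Iterable[str]) -> list[SequenceTag]:
    """One tag per distinct sequence; counts conserve the input total."""
    counts = Counter(sequences)
    return [SequenceTag(s, c) for s, c in sorted(counts.items())]


def iter_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file (gzip-tolerant) as RawRead records."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: FASTQ record {lineno + 1} ({title.split()[0]}): "
                    "sequence/quality length mismatch"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            yield RawRead(title.split()[0], seq.upper(), quals)


def preprocess_reads(
    reads: Iterable[RawRead], params: TrimParams
) -> tuple[list[SequenceTag], PreprocessReport]:
    """quality filter -> 5' trim -> 3' trim (required) -> length filter -> collapse."""
    report = PreprocessReport()
    kept: list[str] = []
    for read in reads:
        report.reads_in += 1
        if not quality_filter(read, params.min_mean_q, params.min_base_q):
            report.discarded_quality += 1
            continue
        if params.adapter_5p:
            read = trim_adapter_5p(
                read, params.adapter_5p, params.min_overlap, params.max_mismatch_rate
            )
        trimmed = trim_adapter_3p(
            read, params.adapter_3p, params.min_overlap, params.max_mismatch_rate
        )
        if trimmed is None:
            report.discarded_no_adapter += 1
            continue
        if not length_filter(trimmed.sequence):
            report.discarded_length += 1
            continue
        report.retained += 1
        kept.append(trimmed.sequence)
    tags = collapse_tags(kept)
    assert report.balanced(), "read-conservation equation violated"
    return tags, report


def preprocess_fastq(
    path: str | Path, params: TrimParams
) -> tuple[list[SequenceTag], PreprocessReport]:
    return preprocess_reads(iter_fastq(path), params)


def write_tags_fasta(tags: list[SequenceTag], path: str | Path) -> None:
    """Collapsed tags as FASTA with count-encoded headers (tag_<i>_x<count>)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag_{i}_x{tag.count}\n{tag.tag_sequence}\n")


def write_tags_tsv(tags: list[SequenceTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_sequence\tcount\n")
        for tag in tags:
            fh.write(f"{tag.tag_sequence}\t{tag.count}\n")
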