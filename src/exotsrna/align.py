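"""Ungapped full-length tag alignment and hierarchical class annotation.

Tags (16-40 nt) are aligned against small per-class reference sets
(miRNA, tRNA, rRNA, snoRNA, snRNA, piRNA) instead of a whole genome.
Alignment is ungapped and full-length with a mismatch cap (default 1),
reported best-stratum: exact hits suppress mismatched ones.  Each tag is
assigned the highest-priority class with at least one alignment;
multi-mapping within the winning class is resolved by uniform fractional
weights.

Candidate positions come from an 8-mer seed index with pigeonhole seeding
(a hit with <= k mismatches matches at least one of k+1 tag chunks
exactly), verified by Hamming count; a brute-force scan backstops
parameter settings the seed length cannot cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

SEED_LEN = 8

DEFAULT_CLASS_PRIORITY = ("miRNA", "tRNA", "rRNA", "snoRNA", "snRNA", "piRNA")


@dataclass
class TagAlignment:
    tag_sequence: str
    reference_id: str
    ref_start: int
    ref_end: int
    mismatches: int
    weight: float = 1.0


@dataclass
class ClassAnnotation:
    tag_sequence: str
    rna_class: str  # one of DEFAULT_CLASS_PRIORITY or "other"
    alignments: list[TagAlignment] = field(default_factory=list)


class ReferenceIndex:
    """Seed-indexed set of reference sequences for one class."""

    def __init__(self, references: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = references.items() if isinstance(references, Mapping) else references
        self.names: list[str] = []
        self.seqs: list[str] = []
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for name, seq in items:
            idx = len(self.names)
            self.names.append(name)
            seq = seq.upper()
            self.seqs.append(seq)
            for p in range(len(seq) - SEED_LEN + 1):
                self._seeds.setdefault(seq[p:p + SEED_LEN], []).append((idx, p))

    def __len__(self) -> int:
        return len(self.names)

    def candidates(self, seed: str, offset: int) -> Iterable[tuple[int, int]]:
        """(ref index, tag start in ref) pairs for a seed at a tag offset."""
        for idx, p in self._seeds.get(seed, ()):
            start = p - offset
            if start >= 0:
                yield idx, start


def _hamming_leq(a: str, b: str, budget: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return None
    return mm


def align_tag(
    tag: str,
    index: ReferenceIndex,
    max_mismatches: int = 1,
) -> list[TagAlignment]:
    """All full-length ungapped placements of ``tag``, best-stratum.

    Exact hits are reported alone when any exist; otherwise all hits with
    1..max_mismatches substitutions (minimum mismatch stratum only is NOT
    enforced beyond the exact/inexact split, matching a single-pass
    aligner with an exact-first policy).
    """
    k = len(tag)
    n_chunks = max_mismatches + 1
    if k >= SEED_LEN and k // n_chunks >= SEED_LEN:
        return _align_seeded(tag, index, max_mismatches)
    return _align_scan(tag, index, max_mismatches)


def _align_seeded(
    tag: str, index: ReferenceIndex, max_mismatches: int
) -> list[TagAlignment]:
    k = len(tag)
    # Exact stratum: seed at offset 0.
    exact = []
    for idx, start in index.candidates(tag[:SEED_LEN], 0):
        ref = index.seqs[idx]
        if start + k <= len(ref) and ref[start:start + k] == tag:
            exact.append(TagAlignment(tag, index.names[idx], start, start + k, 0))
    if exact or max_mismatches == 0:
        return _dedup(exact)
    # Inexact stratum: pigeonhole over max_mismatches+1 chunks.
    n_chunks = max_mismatches + 1
    chunk = k // n_chunks
    seen: set[tuple[int, int]] = set()
    hits: list[TagAlignment] = []
    for c in range(n_chunks):
        off = c * chunk
        for idx, start in index.candidates(tag[off:off + SEED_LEN], off):
            if (idx, start) in seen:
                continue
            seen.add((idx, start))
            ref = index.seqs[idx]
            if start + k > len(ref):
                continue
            mm = _hamming_leq(ref[start:start + k], tag, max_mismatches)
            if mm:
                hits.append(TagAlignment(tag, index.names[idx], start, start + k, mm))
    return _dedup(hits)


def _align_scan(
    tag: str, index: ReferenceIndex, max_mismatches: int
) -> list[TagAlignment]:
    """Brute-force Hamming scan over every offset of every reference."""
    k = len(tag)
    exact: list[TagAlignment] = []
    inexact: list[TagAlignment] = []
    for idx, ref in enumerate(index.seqs):
        for start in range(len(ref) - k + 1):
            mm = _hamming_leq(ref[start:start + k], tag, max_mismatches)
            if mm is None:
                continue
            aln = TagAlignment(tag, index.names[idx], start, start + k, mm)
            (exact if mm == 0 else inexact).append(aln)
    return _dedup(exact if exact else inexact)


def _dedup(alignments: list[TagAlignment]) -> list[TagAlignment]:
    seen = set()
    out = []
    for a in alignments:
        key = (a.reference_id, a.ref_start)
        if key not in seen:
            seen.add(key)
            out.append(a)
    out.sort(key=lambda a: (a.reference_id, a.ref_start))
    return out


def assign_weights(alignments: Sequence[TagAlignment]) -> list[TagAlignment]:
    """Uniform 1/n multi-mapping weights over the retained alignments.

    Pure: returns re-weighted copies so that other views of the same
    alignments keep their own normalization.
    """
    n = len(alignments)
    return [replace(a, weight=1.0 / n) for a in alignments]


def annotate_hierarchical(
    tag: str,
    class_indexes: Sequence[tuple[str, ReferenceIndex]],
    max_mismatches: int = 1,
) -> ClassAnnotation:
    """Assign the highest-priority class with >= 1 alignment, else 'other'."""
    for rna_class, index in class_indexes:
        hits = align_tag(tag, index, max_mismatches)
        if hits:
            return ClassAnnotation(tag, rna_class, assign_weights(hits))
    return ClassAnnotation(tag, "other", [])


def resolve_trna_alignments(
    alignments: Sequence[TagAlignment],
    precursor_boundaries: Mapping[str, int],
) -> list[TagAlignment]:
    """Mature-vs-precursor precedence for tRNA-class hits.

    Mature hits win over precursor hits (the mature body is a substring of
    the precursor), EXCEPT that precursor alignments crossing the
    mature-3' boundary or lying wholly in the trailer are retained: they
    carry the only signal that distinguishes 3'U tRFs.  Weights are
    re-normalized over whatever is retained.
    """
    mature = [a for a in alignments if a.reference_id not in precursor_boundaries]
    pre_trailer = [
        a
        for a in alignments
        if a.reference_id in precursor_boundaries
        and a.ref_end > precursor_boundaries[a.reference_id]
    ]
    pre_body = [
        a
        for a in alignments
        if a.reference_id in precursor_boundaries
        and a.ref_end <= precursor_boundaries[a.reference_id]
    ]
    retained = mature + pre_trailer if (mature or pre_trailer) else pre_body
    return assign_weights(retained)


def write_sam(
    annotations: Iterable[ClassAnnotation],
    index_by_class: Mapping[str, ReferenceIndex],
    path: str,
) -> None:
    """Export tag alignments as ungapped SAM records (NM = mismatches)."""
    import pysam

    refs: list[tuple[str, int]] = []
    for index in index_by_class.values():
        refs.extend(zip(index.names, (len(s) for s in index.seqs)))
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in refs],
    }
    tid = {name: i for i, (name, _) in enumerate(refs)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, ann in enumerate(annotations):
            for aln in ann.alignments:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"tag_{i + 1}"
                rec.query_sequence = aln.tag_sequence
                rec.flag = 0
                rec.reference_id = tid[aln.reference_id]
                rec.reference_start = aln.ref_start
                rec.mapping_quality = 255
                rec.cigarstring = f"{len(aln.tag_sequence)}M"
                rec.set_tag("NM", aln.mismatches)
                out.write(rec)
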