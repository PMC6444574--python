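"""Mature and precursor tRNA reference construction.

Builds the reference model tsRNA reads are classified against: spliced
mature tRNA sequences with the non-templated 3' CCA appended, and
precursor sequences carrying genomic 5' leader and 3' trailer (the
trailer holds the transcribed poly-U tract that defines 3'U tRFs).
Multicopy genes producing identical mature sequences are collapsed to a
single representative so that read counts are not split across exact
duplicates.

Coordinates are 0-based half-open throughout.  Mature coordinates include
the appended CCA, so the mature 3' end equals ``len(sequence)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Fallback anticodon placement in mature coordinates (canonical positions
#: 34-36 of cloverleaf numbering) used when the annotation carries none.
CANONICAL_ANTICODON = (33, 36)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TRNAGene:
    """A tRNA gene annotation plus its sense-strand genomic sequence.

    ``intron_intervals`` and ``anticodon_interval`` are gene-local (0-based
    half-open, on the sense strand of the *unspliced* gene body).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str
    anticodon: str
    gene_sequence: str
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    anticodon_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if len(self.gene_sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: gene_sequence length "
                f"{len(self.gene_sequence)} != end - start {self.end - self.start}"
            )
        self._check_introns()
        if self.anticodon_interval is not None:
            a, b = self.anticodon_interval
            if b - a != 3:
                raise ValueError(f"{self.gene_id}: anticodon interval must span 3 nt")

    def _check_introns(self) -> None:
        length = len(self.gene_sequence)
        prev_end = 0
        for iv in self.intron_intervals:
            a, b = iv
            if not (0 < a < b < length):
                raise ValueError(
                    f"{self.gene_id}: intron {iv} outside (0, {length})"
                )
            if a < prev_end:
                raise ValueError(f"{self.gene_id}: introns overlap or unsorted at {iv}")
            prev_end = b

    @property
    def isoacceptor(self) -> str:
        return f"{self.amino_acid}{self.anticodon}"


@dataclass
class MatureTRNA:
    """Spliced gene body plus the non-templated CCA."""

    mature_id: str
    sequence: str
    anticodon_interval: tuple[int, int]
    source_gene_ids: list[str]
    amino_acid: str
    anticodon: str

    @property
    def isoacceptor(self) -> str:
        return f"{self.amino_acid}{self.anticodon}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrecursorTRNA:
    """Unspliced gene body with genomic 5' leader and 3' trailer.

    ``mature3_boundary`` is the offset of the first trailer base; a
    fragment whose alignment end exceeds it extends into the trailer.
    """

    precursor_id: str
    sequence: str
    leader_len: int
    trailer_len: int
    mature3_boundary: int
    amino_acid: str
    anticodon: str

    def __post_init__(self) -> None:
        body = len(self.sequence) - self.leader_len - self.trailer_len
        if body <= 0:
            raise ValueError(f"{self.precursor_id}: empty gene body")
        if self.mature3_boundary != self.leader_len + body:
            raise ValueError(
                f"{self.precursor_id}: mature3_boundary {self.mature3_boundary} "
                f"!= leader_len + body {self.leader_len + body}"
            )

    @property
    def isoacceptor(self) -> str:
        return f"{self.amino_acid}{self.anticodon}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """Collapsed mature references plus precursors and the gene id map."""

    matures: list[MatureTRNA]
    precursors: list[PrecursorTRNA]
    collapse_map: dict[str, str]

    @property
    def precursor_ids(self) -> frozenset[str]:
        if not hasattr(self, "_pre_ids"):
            self._pre_ids = frozenset(p.precursor_id for p in self.precursors)
        return self._pre_ids

    def mature_by_id(self, mature_id: str) -> MatureTRNA:
        return self._mature_index()[mature_id]

    def precursor_by_id(self, precursor_id: str) -> PrecursorTRNA:
        if not hasattr(self, "_prec_idx"):
            self._prec_idx = {p.precursor_id: p for p in self.precursors}
        return self._prec_idx[precursor_id]

    def _mature_index(self) -> dict[str, MatureTRNA]:
        if not hasattr(self, "_mat_idx"):
            self._mat_idx = {m.mature_id: m for m in self.matures}
        return self._mat_idx


def splice_introns(gene: TRNAGene) -> str:
    """Excise the annotated intron intervals from the gene body."""
    seq = gene.gene_sequence
    pieces = []
    cursor = 0
    for a, b in gene.intron_intervals:
        pieces.append(seq[cursor:a])
        cursor = b
    pieces.append(seq[cursor:])
    return "".join(pieces)


def _spliced_offset(gene: TRNAGene, pos: int) -> int:
    """Map a gene-local unspliced offset into spliced coordinates.

    Rejects positions falling inside an intron.
    """
    shift = 0
    for a, b in gene.intron_intervals:
        if a <= pos < b:
            raise ValueError(
                f"{gene.gene_id}: anticodon position {pos} falls inside intron ({a},{b})"
            )
        if b <= pos:
            shift += b - a
    return pos - shift


def build_mature(gene: TRNAGene) -> MatureTRNA:
    """Splice, append CCA, and locate the anticodon in mature coordinates."""
    spliced = splice_introns(gene)
    sequence = spliced + "CCA"
    if gene.anticodon_interval is not None:
        a, b = gene.anticodon_interval
        ac_iv = (_spliced_offset(gene, a), _spliced_offset(gene, b - 1) + 1)
    else:
        ac_iv = CANONICAL_ANTICODON
    sub = sequence[ac_iv[0]:ac_iv[1]]
    if sub != gene.anticodon:
        raise ValueError(
            f"{gene.gene_id}: annotated anticodon {gene.anticodon} not found at "
            f"mature interval {ac_iv} (found {sub!r})"
        )
    mature_id = f"tRNA-{gene.amino_acid}{gene.anticodon}"
    return MatureTRNA(
        mature_id=mature_id,
        sequence=sequence,
        anticodon_interval=ac_iv,
        source_gene_ids=[gene.gene_id],
        amino_acid=gene.amino_acid,
        anticodon=gene.anticodon,
    )


def build_precursor(
    gene: TRNAGene,
    genome: Mapping[str, str],
    leader_len: int = 50,
    trailer_len: int = 50,
) -> PrecursorTRNA:
    """Assemble 5' leader + unspliced body + 3' trailer, sense strand.

    ``genome`` maps contig name to plus-strand sequence (a plain dict or a
    pyfaidx-style mapping whose values stringify).  Flanks running off a
    contig edge are truncated and the recorded lengths reflect it.
    """
    contig = str(genome[gene.chrom])
    clen = len(contig)
    if gene.strand == "+":
        lead_start = max(0, gene.start - leader_len)
        trail_end = min(clen, gene.end + trailer_len)
        seq = contig[lead_start:trail_end]
        actual_leader = gene.start - lead_start
        actual_trailer = trail_end - gene.end
    else:
        # Sense leader is downstream on the plus strand for minus genes.
        lead_end = min(clen, gene.end + leader_len)
        trail_start = max(0, gene.start - trailer_len)
        seq = reverse_complement(contig[trail_start:lead_end])
        actual_leader = lead_end - gene.end
        actual_trailer = gene.start - trail_start
    body = gene.end - gene.start
    return PrecursorTRNA(
        precursor_id=f"pre-tRNA-{gene.amino_acid}{gene.anticodon}-{gene.gene_id}",
        sequence=seq,
        leader_len=actual_leader,
        trailer_len=actual_trailer,
        mature3_boundary=actual_leader + body,
        amino_acid=gene.amino_acid,
        anticodon=gene.anticodon,
    )


def collapse_identical(matures: Sequence[MatureTRNA]) -> ReferenceSet:
    """Collapse matures with identical sequence to one representative.

    Distinct sequences sharing an isoacceptor receive copy suffixes
    (``tRNA-GlyGCC-1``, ``tRNA-GlyGCC-2``, ...) in first-seen order of the
    lexicographically sorted input, which makes the result order-independent.
    """
    by_seq: dict[str, list[MatureTRNA]] = {}
    for m in sorted(matures, key=lambda m: (m.mature_id, m.sequence)):
        by_seq.setdefault(m.sequence, []).append(m)

    collapsed: list[MatureTRNA] = []
    collapse_map: dict[str, str] = {}
    copy_counter: dict[str, int] = {}
    for seq in sorted(by_seq, key=lambda s: (by_seq[s][0].mature_id, s)):
        group = by_seq[seq]
        rep = group[0]
        base = rep.mature_id
        copy_counter[base] = copy_counter.get(base, 0) + 1
        mature_id = f"{base}-{copy_counter[base]}"
        source_ids = sorted({g for m in group for g in m.source_gene_ids})
        collapsed.append(
            MatureTRNA(
                mature_id=mature_id,
                sequence=seq,
                anticodon_interval=rep.anticodon_interval,
                source_gene_ids=source_ids,
                amino_acid=rep.amino_acid,
                anticodon=rep.anticodon,
            )
        )
        for gid in source_ids:
            collapse_map[gid] = mature_id
    return ReferenceSet(matures=collapsed, precursors=[], collapse_map=collapse_map)


def build_reference_set(
    genes: Sequence[TRNAGene],
    genome: Mapping[str, str],
    leader_len: int = 50,
    trailer_len: int = 50,
) -> ReferenceSet:
    """Full reference build: mature collapse plus one precursor per gene."""
    refset = collapse_identical([build_mature(g) for g in genes])
    refset.precursors = [
        build_precursor(g, genome, leader_len, trailer_len) for g in genes
    ]
    return refset


# ---------------------------------------------------------------------------
# annotation I/O: BED-like TSV dialect
#   chrom  start  end  gene_id  aa-anticodon  strand  introns  anticodon_pos
# introns: comma-separated a-b pairs in gene-local coordinates, "." if none
# anticodon_pos: gene-local start of the anticodon, "." if unannotated
# ---------------------------------------------------------------------------

def write_annotation(genes: Iterable[TRNAGene], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            introns = (
                ",".join(f"{a}-{b}" for a, b in g.intron_intervals)
                if g.intron_intervals
                else "."
            )
            ac = str(g.anticodon_interval[0]) if g.anticodon_interval else "."
            w.writerow(
                [g.chrom, g.start, g.end, g.gene_id,
                 f"{g.amino_acid}-{g.anticodon}", g.strand, introns, ac]
            )


def read_annotation(path: str | Path, genome: Mapping[str, str]) -> list[TRNAGene]:
    genes = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            try:
                chrom, start, end, gene_id, label, strand, introns, ac = row[:8]
                start, end = int(start), int(end)
                aa, anticodon = label.split("-", 1)
                ivs = (
                    [tuple(map(int, p.split("-"))) for p in introns.split(",")]
                    if introns != "."
                    else []
                )
                ac_iv = (int(ac), int(ac) + 3) if ac != "." else None
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed annotation at line {lineno}: {exc}")
            plus = str(genome[chrom])[start:end]
            seq = plus if strand == "+" else reverse_complement(plus)
            genes.append(
                TRNAGene(
                    gene_id=gene_id, chrom=chrom, start=start, end=end,
                    strand=strand, amino_acid=aa, anticodon=anticodon,
                    gene_sequence=seq, intron_intervals=ivs,
                    anticodon_interval=ac_iv,
                )
            )
    return genes
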