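"""Positional classification of tRNA-annotated tags into tsRNA classes.

Classes follow the positional scheme for mature-tRNA fragments:

* ``tRNA-5``  — starts at (or within ``delta5`` of) the mature 5' end;
* ``tRNA-3``  — ends at (or within ``delta3`` of) the mature 3' end, the
  tolerance absorbing partial CCA;
* ``tRNA-i``  — internal fragments;
* ``3pU-tRF`` — precursor fragments extending past the mature-3' boundary
  into the trailer and ending in the transcribed poly-U (>= ``minU`` T's);
* ``unclassified`` — near-full-length tRNA carryover (both ends within
  tolerance: an intact tRNA is not a fragment), precursor body/leader
  fragments, and multi-mapping ties.

Within tRNA-5/tRNA-3 a fragment is a half (tRH) when it is long enough
(>= ``half_min_len``) AND its internal breakpoint falls in the anticodon
loop (anticodon interval padded by ``anticodon_window``) — the signature
of angiogenin cleavage; otherwise it is a tRF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import TagAlignment
from .reference import MatureTRNA, PrecursorTRNA, ReferenceSet

TS_CLASSES = ("tRNA-5", "tRNA-i", "tRNA-3", "3pU-tRF", "unclassified")

_CLASS_SUFFIX = {"tRNA-5": "5", "tRNA-i": "i", "tRNA-3": "3", "3pU-tRF": "3pU"}


@dataclass
class ClassifierParams:
    delta5: int = 1          # nt tolerance at the mature 5' end
    delta3: int = 2          # nt tolerance at the mature 3' end (CCA-aware)
    half_min_len: int = 28   # minimum length of a tRNA half
    anticodon_window: int = 2  # padding around the anticodon interval
    minU: int = 2            # terminal T count required of a 3'U tRF

    def __post_init__(self) -> None:
        for name in ("delta5", "delta3", "half_min_len", "anticodon_window", "minU"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TsRNARecord:
    """One classified tag: class, subtype, origin and weighted count."""

    tag_sequence: str
    ts_class: str
    subtype: str  # tRF | tRH | na
    source_id: str
    isoacceptor: str
    length: int
    weighted_count: float
    isoacceptor_weights: dict[str, float] = field(default_factory=dict)

    @property
    def species_key(self) -> str:
        """Species naming like tRNA-GlyTCC-5, disambiguated by sequence."""
        if self.ts_class == "unclassified":
            return f"unclassified|{self.tag_sequence}"
        suffix = _CLASS_SUFFIX[self.ts_class]
        return f"tRNA-{self.isoacceptor}-{suffix}|{self.tag_sequence}"


def classify_mature_alignment(
    aln: TagAlignment, mature: MatureTRNA, params: ClassifierParams
) -> str:
    """tRNA-5 / tRNA-i / tRNA-3 by position on the mature reference."""
    L = len(mature)
    if not (0 <= aln.ref_start < aln.ref_end <= L):
        raise ValueError(
            f"alignment ({aln.ref_start},{aln.ref_end}) outside {mature.mature_id} "
            f"bounds [0,{L})"
        )
    is5 = aln.ref_start <= params.delta5
    is3 = aln.ref_end >= L - params.delta3
    if is5 and is3:
        return "unclassified"  # near-full-length tRNA, not a fragment
    if is5:
        return "tRNA-5"
    if is3:
        return "tRNA-3"
    return "tRNA-i"


def subtype_half_or_fragment(
    aln: TagAlignment, mature: MatureTRNA, ts_class: str, params: ClassifierParams
) -> str:
    """tRH iff long enough and the breakpoint sits in the anticodon loop."""
    if ts_class not in ("tRNA-5", "tRNA-3"):
        raise ValueError(f"subtype undefined for class {ts_class}")
    length = aln.ref_end - aln.ref_start
    if length < params.half_min_len:
        return "tRF"
    breakpoint = aln.ref_end if ts_class == "tRNA-5" else aln.ref_start
    lo = mature.anticodon_interval[0] - params.anticodon_window
    hi = mature.anticodon_interval[1] + params.anticodon_window
    return "tRH" if lo <= breakpoint <= hi else "tRF"


def detect_3pU_trf(
    aln: TagAlignment, precursor: PrecursorTRNA, params: ClassifierParams
) -> bool:
    """Trailer-crossing fragment ending in >= minU templated U residues."""
    if aln.ref_end <= precursor.mature3_boundary:
        return False
    tail = aln.tag_sequence[-params.minU:] if params.minU else ""
    return tail == "T" * params.minU


def _classify_one_alignment(
    aln: TagAlignment, refset: ReferenceSet, params: ClassifierParams
) -> tuple[str, str, str, str]:
    """(ts_class, subtype, source_id, isoacceptor) for one alignment."""
    if aln.reference_id in refset.precursor_ids:
        pre = refset.precursor_by_id(aln.reference_id)
        if detect_3pU_trf(aln, pre, params):
            return "3pU-tRF", "na", pre.precursor_id, pre.isoacceptor
        return "unclassified", "na", pre.precursor_id, pre.isoacceptor
    mature = refset.mature_by_id(aln.reference_id)
    ts_class = classify_mature_alignment(aln, mature, params)
    if ts_class in ("tRNA-5", "tRNA-3"):
        subtype = subtype_half_or_fragment(aln, mature, ts_class, params)
    elif ts_class == "tRNA-i":
        subtype = "tRF"  # internal fragments are fragments by definition
    else:
        subtype = "na"
    return ts_class, subtype, mature.mature_id, mature.isoacceptor


def classify_tag(
    tag: str,
    alignments: list[TagAlignment],
    refset: ReferenceSet,
    params: ClassifierParams,
    count: float = 1.0,
) -> TsRNARecord:
    """Resolve a (possibly multi-mapping) tag to one TsRNARecord.

    Each weighted alignment is classified independently; the majority
    class by weight wins, a tie is ``unclassified``.  Isoacceptor weight
    is split fractionally across the winning alignments' references.
    """
    if not alignments:
        raise ValueError("classify_tag requires at least one alignment")
    per_aln = [
        (_classify_one_alignment(a, refset, params), a.weight) for a in alignments
    ]
    class_weight: dict[str, float] = {}
    for (ts_class, _, _, _), w in per_aln:
        class_weight[ts_class] = class_weight.get(ts_class, 0.0) + w
    best_w = max(class_weight.values())
    winners = sorted(c for c, w in class_weight.items() if w >= best_w - 1e-12)
    if len(winners) > 1:
        win_class, subtype = "unclassified", "na"
        iso_w: dict[str, float] = {}
        source_id = ""
        isoacceptor = ""
    else:
        win_class = winners[0]
        winning = [
            (info, w) for info, w in per_aln if info[0] == win_class
        ]
        total = sum(w for _, w in winning)
        iso_w = {}
        sub_w: dict[str, float] = {}
        src_w: dict[str, float] = {}
        for (_, subtype_i, src, iso), w in winning:
            iso_w[iso] = iso_w.get(iso, 0.0) + w / total
            sub_w[subtype_i] = sub_w.get(subtype_i, 0.0) + w
            src_w[src] = src_w.get(src, 0.0) + w
        subtype = max(sorted(sub_w), key=lambda s: sub_w[s])
        source_id = max(sorted(src_w), key=lambda s: src_w[s])
        isoacceptor = max(sorted(iso_w), key=lambda s: iso_w[s])
    return TsRNARecord(
        tag_sequence=tag,
        ts_class=win_class,
        subtype=subtype,
        source_id=source_id,
        isoacceptor=isoacceptor,
        length=len(tag),
        weighted_count=count,
        isoacceptor_weights=iso_w,
    )
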