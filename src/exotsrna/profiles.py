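"""Descriptive profiles of exosomal small-RNA and tsRNA content.

Composition fractions per small-RNA class, tsRNA type fractions over
{tRNA-5, tRNA-i, tRNA-3}, isoacceptor origins per type, integer length
histograms over the retained 16-40 nt range, CPM normalization,
replicate correlation on log2(CPM+1), and the ddCt arithmetic used for
RT-qPCR relative quantification.

All fractions are computed over weighted READ counts (the convention
behind "percentage of small RNAs" statements in small-RNA work), with
multi-mapping weights respected; a species-level alternative is exposed
via ``per_species=True`` where meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import TsRNARecord
from .preprocess import MAX_TAG_LEN, MIN_TAG_LEN

MATURE_TYPES = ("tRNA-5", "tRNA-i", "tRNA-3")


@dataclass
class Profile:
    """Class composition, tsRNA type mix, origins and length spectra."""

    class_fractions: dict[str, float]
    type_fractions: dict[str, float]                 # over MATURE_TYPES
    isoacceptor_fractions: dict[str, dict[str, float]]  # per type
    length_histograms: dict[str, pd.Series]          # per type, bins 16..40

    def __post_init__(self) -> None:
        for name, vec in (("class", self.class_fractions),
                          ("type", self.type_fractions)):
            total = sum(vec.values())
            if vec and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions sum to {total}, not 1")


class CountMatrix:
    """tsRNA species x samples weighted-count matrix with group labels."""

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: Mapping[str, str] | None = None,
        normalized: bool = False,
        library_sizes: Mapping[str, float] | None = None,
    ):
        if (counts.values < 0).any():
            raise ValueError("count matrix has negative entries")
        self.counts = counts
        self.groups = dict(groups) if groups else {}
        self.normalized = normalized
        self.library_sizes = dict(library_sizes) if library_sizes else None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> "CountMatrix":
        """Counts per million of the library (total annotated weighted count).

        When explicit library sizes are absent, column sums stand in.
        """
        if self.normalized:
            return self
        libs = pd.Series(
            self.library_sizes
            if self.library_sizes is not None
            else self.counts.sum(axis=0)
        ).reindex(self.counts.columns)
        if (libs <= 0).any():
            bad = list(libs.index[libs <= 0])
            raise ValueError(f"non-positive library size for sample(s) {bad}")
        return CountMatrix(
            self.counts * 1e6 / libs, groups=self.groups, normalized=True
        )


def _weighted_type_totals(records: Iterable[TsRNARecord]) -> dict[str, float]:
    totals: dict[str, float] = {}
    for r in records:
        totals[r.ts_class] = totals.get(r.ts_class, 0.0) + r.weighted_count
    return totals


def composition_profile(
    records: Sequence[TsRNARecord],
    class_counts: Mapping[str, float],
) -> Profile:
    """Weighted class and tsRNA-type fractions plus per-type breakdowns.

    ``class_counts`` holds weighted read totals per small-RNA class
    (including "other"); ``records`` are the classified tRNA tags.
    """
    if not records:
        raise ValueError("no tsRNA records: cannot profile an empty set")
    class_total = sum(class_counts.values())
    if class_total <= 0:
        raise ValueError("class counts are empty")
    class_fractions = {c: v / class_total for c, v in class_counts.items()}

    type_totals = _weighted_type_totals(records)
    mature_total = sum(type_totals.get(t, 0.0) for t in MATURE_TYPES)
    if mature_total <= 0:
        raise ValueError("no mature-tRNA-derived records to profile")
    type_fractions = {
        t: type_totals.get(t, 0.0) / mature_total for t in MATURE_TYPES
    }
    iso = {t: isoacceptor_breakdown(records, t) for t in MATURE_TYPES
           if type_totals.get(t, 0.0) > 0}
    hists = {t: length_distribution(records, t) for t in MATURE_TYPES
             if type_totals.get(t, 0.0) > 0}
    return Profile(class_fractions, type_fractions, iso, hists)


def isoacceptor_breakdown(
    records: Iterable[TsRNARecord], ts_type: str
) -> dict[str, float]:
    """Fractions per isoacceptor within one tsRNA type; sums to 1.

    A tag split across isoacceptors contributes its fractional
    multi-mapping weight to each.
    """
    totals: dict[str, float] = {}
    for r in records:
        if r.ts_class != ts_type:
            continue
        for iso, frac in r.isoacceptor_weights.items():
            totals[iso] = totals.get(iso, 0.0) + frac * r.weighted_count
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError(f"no records of type {ts_type}")
    return {iso: v / grand for iso, v in sorted(totals.items())}


def length_distribution(
    records: Iterable[TsRNARecord], ts_type: str
) -> pd.Series:
    """Weighted integer length histogram over the 16-40 nt bins."""
    bins = pd.Series(
        0.0, index=pd.RangeIndex(MIN_TAG_LEN, MAX_TAG_LEN + 1, name="length")
    )
    for r in records:
        if r.ts_class == ts_type:
            bins[r.length] += r.weighted_count
    return bins


def length_mode(hist: pd.Series) -> int:
    return int(hist.idxmax())


def records_to_matrix(
    per_sample: Mapping[str, Sequence[TsRNARecord]],
    groups: Mapping[str, str] | None = None,
    library_sizes: Mapping[str, float] | None = None,
) -> CountMatrix:
    """Assemble per-sample classified records into a species x sample matrix."""
    data: dict[str, dict[str, float]] = {}
    for sample, records in per_sample.items():
        col: dict[str, float] = {}
        for r in records:
            col[r.species_key] = col.get(r.species_key, 0.0) + r.weighted_count
        data[sample] = col
    df = pd.DataFrame(data).fillna(0.0).sort_index()
    df = df[list(per_sample.keys())]
    return CountMatrix(df, groups=groups, library_sizes=library_sizes)


def replicate_correlation(
    counts_a: Mapping[str, float],
    counts_b: Mapping[str, float],
) -> float:
    """Pearson r of log2(CPM+1) over the union of species in either sample.

    Species absent from one replicate enter as zero; using the union
    (rather than the intersection) avoids inflating r.
    """
    species = sorted(set(counts_a) | set(counts_b))
    if len(species) < 2:
        raise ValueError("need at least two species for a correlation")
    a = np.array([counts_a.get(s, 0.0) for s in species])
    b = np.array([counts_b.get(s, 0.0) for s in species])
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("empty replicate")
    la = np.log2(a * 1e6 / a.sum() + 1.0)
    lb = np.log2(b * 1e6 / b.sum() + 1.0)
    return float(np.corrcoef(la, lb)[0, 1])


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative fold change by the ddCt method: 2 ** -(dCt_case - dCt_ctrl)."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def profile_to_frames(profile: Profile) -> dict[str, pd.DataFrame]:
    """Flatten a Profile into tidy frames for TSV export."""
    out = {
        "class_fractions": pd.DataFrame(
            sorted(profile.class_fractions.items()),
            columns=["rna_class", "fraction"],
        ),
        "type_fractions": pd.DataFrame(
            [(t, profile.type_fractions[t]) for t in MATURE_TYPES],
            columns=["ts_class", "fraction"],
        ),
    }
    iso_rows = [
        (t, iso, f)
        for t, d in profile.isoacceptor_fractions.items()
        for iso, f in d.items()
    ]
    out["isoacceptor_fractions"] = pd.DataFrame(
        iso_rows, columns=["ts_class", "isoacceptor", "fraction"]
    )
    len_rows = [
        (t, int(length), w)
        for t, h in profile.length_histograms.items()
        for length, w in h.items()
    ]
    out["length_histograms"] = pd.DataFrame(
        len_rows, columns=["ts_class", "length", "weight"]
    )
    return out
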