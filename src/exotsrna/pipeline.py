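"""Pipeline orchestration and file-level I/O.

Ties the stages together: preprocess -> hierarchical class annotation ->
tsRNA classification -> profiling -> (optional) differential expression.
Each run writes plain TSV outputs plus a manifest recording inputs,
parameter values and per-stage read-conservation counts, so a run is
reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import (
    DEFAULT_CLASS_PRIORITY,
    ClassAnnotation,
    ReferenceIndex,
    annotate_hierarchical,
    resolve_trna_alignments,
)
from .classify import ClassifierParams, TsRNARecord, classify_tag
from .diffexpr import DEParams, de_test
from .preprocess import (
    PreprocessReport,
    SequenceTag,
    TrimParams,
    preprocess_fastq,
    preprocess_reads,
    write_tags_tsv,
)
from .profiles import (
    CountMatrix,
    Profile,
    composition_profile,
    profile_to_frames,
    records_to_matrix,
)
from .reference import ReferenceSet, read_annotation, build_reference_set


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths; defaults as declared."""

    sample_sheet: str
    out_dir: str
    genome_fasta: str | None = None
    trna_annotation: str | None = None
    class_fastas: dict[str, str] = field(default_factory=dict)
    adapter_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_5p: str | None = None
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_mean_q: float = 20.0
    max_mismatches: int = 1
    class_priority: tuple[str, ...] = DEFAULT_CLASS_PRIORITY
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    run_de: bool = False
    de: DEParams = field(default_factory=DEParams)
    leader_len: int = 50
    trailer_len: int = 50
    seed: int | None = None

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "classifier" in data and isinstance(data["classifier"], Mapping):
            data["classifier"] = ClassifierParams(**data["classifier"])
        if "de" in data and isinstance(data["de"], Mapping):
            data["de"] = DEParams(**data["de"])
        if "class_priority" in data:
            data["class_priority"] = tuple(data["class_priority"])
        return cls(**data)


@dataclass
class SampleResult:
    """Everything the pipeline derives from one library."""

    sample_id: str
    tags: list[SequenceTag]
    report: PreprocessReport
    annotations: list[ClassAnnotation]
    class_counts: dict[str, float]  # weighted read counts per small-RNA class
    records: list[TsRNARecord]
    library_size: float  # total annotated (non-"other") weighted count


def build_class_indexes(
    refset: ReferenceSet,
    class_fastas: Mapping[str, Sequence[tuple[str, str]]],
    priority: Sequence[str] = DEFAULT_CLASS_PRIORITY,
) -> tuple[list[tuple[str, ReferenceIndex]], dict[str, int]]:
    """Per-class reference indexes in priority order.

    The tRNA index holds collapsed matures plus precursors; the returned
    boundary map (precursor_id -> mature-3' boundary) drives the
    mature-vs-precursor precedence rule.
    """
    trna_refs = [(m.mature_id, m.sequence) for m in refset.matures] + [
        (p.precursor_id, p.sequence) for p in refset.precursors
    ]
    boundaries = {p.precursor_id: p.mature3_boundary for p in refset.precursors}
    indexes = []
    for cls in priority:
        if cls == "tRNA":
            indexes.append((cls, ReferenceIndex(trna_refs)))
        elif cls in class_fastas:
            indexes.append((cls, ReferenceIndex(list(class_fastas[cls]))))
    return indexes, boundaries


def process_tags(
    tags: Sequence[SequenceTag],
    class_indexes: Sequence[tuple[str, ReferenceIndex]],
    boundaries: Mapping[str, int],
    refset: ReferenceSet,
    cparams: ClassifierParams,
    max_mismatches: int = 1,
) -> tuple[list[ClassAnnotation], dict[str, float], list[TsRNARecord], float]:
    """Annotate tags by class and classify the tRNA-annotated ones."""
    annotations: list[ClassAnnotation] = []
    class_counts: dict[str, float] = {}
    records: list[TsRNARecord] = []
    for tag in tags:
        ann = annotate_hierarchical(tag.tag_sequence, class_indexes, max_mismatches)
        annotations.append(ann)
        class_counts[ann.rna_class] = class_counts.get(ann.rna_class, 0.0) + tag.count
        if ann.rna_class == "tRNA":
            retained = resolve_trna_alignments(ann.alignments, boundaries)
            records.append(
                classify_tag(
                    tag.tag_sequence, retained, refset, cparams, count=tag.count
                )
            )
    library_size = sum(v for c, v in class_counts.items() if c != "other")
    return annotations, class_counts, records, library_size


def process_sample(
    sample_id: str,
    fastq_path: str | Path,
    trim_params: TrimParams,
    class_indexes: Sequence[tuple[str, ReferenceIndex]],
    boundaries: Mapping[str, int],
    refset: ReferenceSet,
    cparams: ClassifierParams,
    max_mismatches: int = 1,
) -> SampleResult:
    tags, report = preprocess_fastq(fastq_path, trim_params)
    annotations, class_counts, records, library_size = process_tags(
        tags, class_indexes, boundaries, refset, cparams, max_mismatches
    )
    return SampleResult(
        sample_id, tags, report, annotations, class_counts, records, library_size
    )


def process_reads(
    sample_id: str,
    reads,
    trim_params: TrimParams,
    class_indexes,
    boundaries,
    refset: ReferenceSet,
    cparams: ClassifierParams,
    max_mismatches: int = 1,
) -> SampleResult:
    """In-memory variant of :func:`process_sample` (simulator-facing)."""
    from .preprocess import RawRead
    import numpy as np

    raw = (
        RawRead(rid, seq,
                np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33)
        for rid, seq, qual in reads
    )
    tags, report = preprocess_reads(raw, trim_params)
    annotations, class_counts, records, library_size = process_tags(
        tags, class_indexes, boundaries, refset, cparams, max_mismatches
    )
    return SampleResult(
        sample_id, tags, report, annotations, class_counts, records, library_size
    )


def reference_level_counts(result: SampleResult) -> dict[str, float]:
    """Weighted read counts aggregated per annotated reference.

    The replicate-concordance scatter is computed at this level (one
    point per miRNA / rRNA / ... reference or collapsed tRNA), the
    standard small-RNA QC aggregation: per-tag tsRNA species are too
    finely resolved to be well-sampled at modest depth, and sequencing
    errors are absorbed by the mismatch-tolerant alignment.
    """
    counts: dict[str, float] = {}
    for tag, ann in zip(result.tags, result.annotations):
        if ann.rna_class == "other":
            continue
        for aln in ann.alignments:
            key = f"{ann.rna_class}:{aln.reference_id}"
            counts[key] = counts.get(key, 0.0) + tag.count * aln.weight
    return counts


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "fastq_path", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks column(s) {sorted(missing)}")
    if sheet.sample_id.duplicated().any():
        raise ValueError(f"sample sheet {path} has duplicate sample ids")
    return sheet


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the output tree.

    Returns a manifest dict (also written as manifest.json) with input
    digests, parameters and per-stage conservation counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = read_sample_sheet(config.sample_sheet)
    for fq in sheet.fastq_path:
        if not Path(fq).exists():
            raise FileNotFoundError(f"FASTQ not found: {fq}")
    if config.genome_fasta is None or config.trna_annotation is None:
        raise ValueError("genome_fasta and trna_annotation are required")

    genome = dict(_read_fasta(config.genome_fasta))
    genes = read_annotation(config.trna_annotation, genome)
    refset = build_reference_set(
        genes, genome, config.leader_len, config.trailer_len
    )
    class_fastas = {
        cls: _read_fasta(path) for cls, path in config.class_fastas.items()
    }
    class_indexes, boundaries = build_class_indexes(
        refset, class_fastas, config.class_priority
    )
    trim = TrimParams(
        adapter_3p=config.adapter_3p,
        adapter_5p=config.adapter_5p,
        min_overlap=config.min_overlap,
        max_mismatch_rate=config.max_mismatch_rate,
        min_mean_q=config.min_mean_q,
    )

    results: dict[str, SampleResult] = {}
    for _, row in sheet.iterrows():
        res = process_sample(
            row.sample_id, row.fastq_path, trim, class_indexes, boundaries,
            refset, config.classifier, config.max_mismatches,
        )
        results[row.sample_id] = res
        write_tags_tsv(res.tags, out / f"{row.sample_id}.tags.tsv")
        _write_records_tsv(res.records, out / f"{row.sample_id}.tsrna.tsv")
        if res.records:
            profile = composition_profile(res.records, res.class_counts)
            for name, frame in profile_to_frames(profile).items():
                frame.to_csv(
                    out / f"{row.sample_id}.{name}.tsv", sep="\t", index=False
                )

    groups = dict(zip(sheet.sample_id, sheet.group))
    matrix = records_to_matrix(
        {sid: res.records for sid, res in results.items()},
        groups=groups,
        library_sizes={sid: res.library_size for sid, res in results.items()},
    )
    matrix.counts.to_csv(out / "count_matrix.tsv", sep="\t")

    de_summary = None
    if config.run_de:
        de_results = de_test(matrix, config.de)
        de_results.to_csv(out / "de_table.tsv", sep="\t")
        de_summary = {
            "tested": int(len(de_results)),
            "up": int((de_results.call == "up").sum()),
            "down": int((de_results.call == "down").sum()),
        }

    manifest = {
        "inputs": {
            "sample_sheet": str(config.sample_sheet),
            "digests": {
                str(fq): _file_digest(fq) for fq in sheet.fastq_path
            },
        },
        "parameters": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "conservation": {
            sid: asdict(res.report) for sid, res in results.items()
        },
        "library_sizes": {
            sid: res.library_size for sid, res in results.items()
        },
        "de_summary": de_summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_records_tsv(records: Sequence[TsRNARecord], path: Path) -> None:
    rows = [
        (r.tag_sequence, r.ts_class, r.subtype, r.isoacceptor, r.length,
         r.weighted_count, r.species_key)
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["tag_sequence", "ts_class", "subtype", "isoacceptor",
                 "length", "weighted_count", "species_key"],
    ).to_csv(path, sep="\t", index=False)
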