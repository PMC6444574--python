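"""Synthetic small-RNA-seq libraries with per-read ground truth.

The generator emulates the statistical structure of an exosomal
small-RNA library: 16-40 nt inserts flanked by a 3' sequencing adapter,
a small-RNA class mixture in which tRNA-derived reads are a few percent
of the library, tRNA-5 dominating the tsRNA pool (~90%) with 32-33 nt
fragments concentrated on Gly/Glu/Lys/Val isoacceptors, tRNA-3 peaking
at 16-18 nt, tRNA-i bimodal (16-17 and 28-32 nt), and an optional
precursor-derived 3'U-tRF channel whose reads cross the mature-3'
boundary and end in the transcribed poly-U trailer.

Every read is logged with its generating class, tsRNA type, source
reference and error-free insert, so each downstream stage can be scored
against truth.  Two-group designs spike selected (isoacceptor, type)
channels up or down by stated log2 effects; a count-matrix generator
with negative-binomial species abundances supports differential-
expression calibration at realistic species counts.

All randomness flows from a mandatory integer seed; per-sample streams
are spawned as ``default_rng([master_seed, sample_index])`` so that any
single sample can be regenerated alone.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    ReferenceSet,
    TRNAGene,
    build_reference_set,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))

DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"

#: Exosomal small-RNA class mixture (weighted read fractions): tRNA-derived
#: reads are 5% of the library; miRNA carries most of the remainder.
DEFAULT_CLASS_MIXTURE = {
    "miRNA": 0.70,
    "tRNA": 0.05,
    "rRNA": 0.15,
    "snoRNA": 0.04,
    "snRNA": 0.03,
    "piRNA": 0.03,
}

#: tsRNA type mixture: tRNA-5 / tRNA-i / tRNA-3 at 90 / 1 / 9 percent of
#: mature-derived reads; the precursor 3'U channel is off by default
#: (precursor-derived tsRNAs are a minor exosomal component) and enabled
#: explicitly where exercised.
DEFAULT_TYPE_PROBS = {
    "tRNA-5": 0.90,
    "tRNA-i": 0.01,
    "tRNA-3": 0.09,
    "3pU-tRF": 0.0,
}

#: Isoacceptor emission weights: 97% of tsRNA mass on Gly/Glu/Lys/Val.
DEFAULT_ISOACCEPTOR_WEIGHTS = {
    "GlyGCC": 0.28,
    "GlyTCC": 0.12,
    "GluCTC": 0.22,
    "GluTTC": 0.08,
    "ValTAC": 0.08,
    "ValAAC": 0.04,
    "ValCAC": 0.03,
    "LysCTT": 0.08,
    "LysTTT": 0.04,
    "AlaAGC": 0.01,
    "AspGTC": 0.01,
    "LeuAAG": 0.005,
    "HisGTG": 0.005,
}

#: tRNA-3 fragment lengths peak at 16-18 nt.
DEFAULT_TRNA3_LEN_PROBS = {16: 0.35, 17: 0.35, 18: 0.20, 19: 0.05, 20: 0.05}

_DECOY_SPECS = {  # class -> (n sequences, (min len, max len))
    "miRNA": (30, (20, 23)),
    "rRNA": (4, (120, 120)),
    "snoRNA": (5, (130, 130)),
    "snRNA": (5, (150, 150)),
    "piRNA": (20, (26, 31)),
}


@dataclass
class SimulationConfig:
    seed: int
    n_reads: int = 50_000
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    tsrna_type_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROBS)
    )
    isoacceptor_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOACCEPTOR_WEIGHTS)
    )
    trna5_end_mean: float = 32.5  # discretized-normal 5' fragment endpoint
    trna5_end_sd: float = 1.0
    trna3_len_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TRNA3_LEN_PROBS)
    )
    error_rate: float = 0.001
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str | None = None
    read_length: int = 50
    quality_char: str = "F"  # Phred 37

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name, mix in (
            ("class_mixture", self.class_mixture),
            ("tsrna_type_probs", self.tsrna_type_probs),
            ("isoacceptor_weights", self.isoacceptor_weights),
            ("trna3_len_probs", self.trna3_len_probs),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")


@dataclass
class SimReferences:
    """Toy references plus fixed per-species decoy abundance weights."""

    genes: list[TRNAGene]
    genome: dict[str, str]
    refset: ReferenceSet
    decoys: dict[str, list[tuple[str, str]]]
    decoy_weights: dict[str, np.ndarray]


@dataclass
class GroundTruth:
    """Per-read emission log plus run-level abundance and DE truth."""

    reads: pd.DataFrame  # read_id, rna_class, ts_class, source_id, isoacceptor, insert
    abundance: pd.DataFrame  # rna_class x count
    de_truth: pd.DataFrame | None = None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_toy_references(
    seed: int,
    isoacceptors: Sequence[str] | None = None,
    copies_per_isoacceptor: int = 2,
) -> SimReferences:
    """Deterministic synthetic tRNA gene set plus per-class decoy references.

    Gene bodies are 72-90 nt with the anticodon placed at the canonical
    spliced position (33,36); one isoacceptor gets an intron-bearing gene
    and one gets two identical copies (exercising collapse).  Each gene
    sits at offset 50 of its own contig whose trailer begins with a
    pol-III-style poly-T tract, so precursor fragments crossing the
    mature-3' boundary end in templated U residues.
    """
    rng = np.random.default_rng([seed, 7919])
    isoacceptors = list(isoacceptors or DEFAULT_ISOACCEPTOR_WEIGHTS)
    genes: list[TRNAGene] = []
    genome: dict[str, str] = {}
    dup_body: dict[str, str] = {}
    for iso_i, iso in enumerate(isoacceptors):
        aa, anticodon = iso[:3], iso[3:]
        for copy in range(copies_per_isoacceptor):
            gene_id = f"trna-{iso}-{copy + 1}"
            with_intron = iso_i == 1 and copy == 0
            spliced_len = int(rng.integers(72, 79))
            if with_intron:
                intron_len = int(rng.integers(10, 21))
                body_len = spliced_len + intron_len
                introns = [(38, 38 + intron_len)]
            else:
                body_len = spliced_len
                introns = []
            if iso_i == 0 and copy == 1:
                body = dup_body["body"]  # identical multicopy gene
                introns = []
                body_len = len(body)
            else:
                body = list(_random_dna(rng, body_len))
                body[33:36] = list(anticodon)
                body = "".join(body)
            if iso_i == 0 and copy == 0:
                dup_body["body"] = body
            strand = "-" if (iso_i + copy) % 3 == 2 else "+"
            leader = _random_dna(rng, 50)
            trailer = "TTTTT" + _random_dna(rng, 45)
            sense_window = leader + body + trailer
            contig = sense_window if strand == "+" else reverse_complement(sense_window)
            chrom = f"contig_{gene_id}"
            genome[chrom] = contig
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=50,
                    end=50 + body_len,
                    strand=strand,
                    amino_acid=aa,
                    anticodon=anticodon,
                    gene_sequence=body,
                    intron_intervals=introns,
                    anticodon_interval=(33, 36),
                )
            )
    refset = build_reference_set(genes, genome)

    decoys: dict[str, list[tuple[str, str]]] = {}
    decoy_weights: dict[str, np.ndarray] = {}
    for cls, (n, (lo, hi)) in _DECOY_SPECS.items():
        seqs = [
            (f"{cls}_{i + 1}", _random_dna(rng, int(rng.integers(lo, hi + 1))))
            for i in range(n)
        ]
        decoys[cls] = seqs
        w = rng.dirichlet(np.full(n, 1.5))
        decoy_weights[cls] = w / w.sum()
    return SimReferences(genes, genome, refset, decoys, decoy_weights)


def _matures_by_isoacceptor(refset: ReferenceSet) -> dict[str, list]:
    out: dict[str, list] = {}
    for m in refset.matures:
        out.setdefault(m.isoacceptor, []).append(m)
    return out


def _precursors_by_isoacceptor(refset: ReferenceSet) -> dict[str, list]:
    out: dict[str, list] = {}
    for p in refset.precursors:
        out.setdefault(p.isoacceptor, []).append(p)
    return out


def _draw_insert(
    rng: np.random.Generator,
    rna_class: str,
    config: SimulationConfig,
    refs: SimReferences,
    mat_by_iso: Mapping[str, list],
    pre_by_iso: Mapping[str, list],
    iso_names: list[str],
    iso_probs: np.ndarray,
) -> tuple[str, str, str, str]:
    """(insert, ts_class, source_id, isoacceptor) for one read."""
    if rna_class != "tRNA":
        seqs = refs.decoys[rna_class]
        idx = rng.choice(len(seqs), p=refs.decoy_weights[rna_class])
        name, seq = seqs[idx]
        if rna_class in ("miRNA", "piRNA"):
            return seq, "", name, ""
        length = int(rng.integers(18, 36))
        start = int(rng.integers(0, len(seq) - length + 1))
        return seq[start:start + length], "", name, ""

    types = list(config.tsrna_type_probs)
    ts_class = types[rng.choice(len(types), p=np.array(
        [config.tsrna_type_probs[t] for t in types]))]
    iso = iso_names[rng.choice(len(iso_names), p=iso_probs)]
    if ts_class == "3pU-tRF":
        pre = pre_by_iso[iso][rng.integers(len(pre_by_iso[iso]))]
        u = int(rng.integers(2, 6))  # 2-5 nt into the poly-T trailer
        length = int(rng.integers(20, 36))
        end = pre.mature3_boundary + u
        return pre.sequence[end - length:end], ts_class, pre.precursor_id, iso
    mature = mat_by_iso[iso][rng.integers(len(mat_by_iso[iso]))]
    L = len(mature)
    if ts_class == "tRNA-5":
        end = int(round(rng.normal(config.trna5_end_mean, config.trna5_end_sd)))
        end = int(np.clip(end, 28, min(38, L - 3)))
        return mature.sequence[:end], ts_class, mature.mature_id, iso
    if ts_class == "tRNA-3":
        lens = list(config.trna3_len_probs)
        length = lens[rng.choice(len(lens), p=np.array(
            [config.trna3_len_probs[x] for x in lens]))]
        return mature.sequence[L - length:], ts_class, mature.mature_id, iso
    # tRNA-i: bimodal 16-17 / 28-32 nt, strictly interior placement
    length = int(rng.integers(16, 18)) if rng.random() < 0.5 else int(
        rng.integers(28, 33))
    start = int(rng.integers(2, L - 3 - length + 1))
    return mature.sequence[start:start + length], ts_class, mature.mature_id, iso


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def simulate_library(
    config: SimulationConfig,
    refs: SimReferences,
    sample_id: str = "sample",
    sample_index: int = 0,
    class_mixture: Mapping[str, float] | None = None,
    iso_weights: Mapping[str, float] | None = None,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """One library: (read_id, read sequence, quality string) plus truth.

    Reads are insert + 3' adapter (optionally preceded by a 5' adapter),
    truncated to the configured read length; substitution errors are
    applied at ``error_rate`` per base of the final read.
    """
    rng = np.random.default_rng([config.seed, sample_index])
    mixture = dict(class_mixture or config.class_mixture)
    classes = list(mixture)
    class_p = np.array([mixture[c] for c in classes])
    class_p = class_p / class_p.sum()
    iso_w = dict(iso_weights or config.isoacceptor_weights)
    iso_names = list(iso_w)
    iso_probs = np.array([iso_w[i] for i in iso_names])
    iso_probs = iso_probs / iso_probs.sum()
    mat_by_iso = _matures_by_isoacceptor(refs.refset)
    pre_by_iso = _precursors_by_isoacceptor(refs.refset)

    class_draws = rng.choice(len(classes), size=config.n_reads, p=class_p)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(config.n_reads):
        rna_class = classes[class_draws[i]]
        insert, ts_class, source_id, iso = _draw_insert(
            rng, rna_class, config, refs, mat_by_iso, pre_by_iso,
            iso_names, iso_probs,
        )
        read_seq = insert + config.adapter_3p
        if config.adapter_5p:
            read_seq = config.adapter_5p + read_seq
        read_seq = read_seq[: config.read_length]
        read_seq = _apply_errors(rng, read_seq, config.error_rate)
        read_id = f"{sample_id}_read_{i + 1}"
        reads.append((read_id, read_seq, config.quality_char * len(read_seq)))
        truth_rows.append((read_id, rna_class, ts_class, source_id, iso, insert))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "rna_class", "ts_class", "source_id",
                 "isoacceptor", "insert"],
    )
    abundance = (
        truth.groupby("rna_class").size().rename("count").reset_index()
    )
    return reads, GroundTruth(reads=truth, abundance=abundance)


def spiked_iso_weights(
    base: Mapping[str, float], de_spec: Mapping[str, float]
) -> dict[str, float]:
    """Isoacceptor weights with log2 effects applied and renormalized."""
    w = {iso: v * (2.0 ** de_spec.get(iso, 0.0)) for iso, v in base.items()}
    total = sum(w.values())
    return {iso: v / total for iso, v in w.items()}


def simulate_two_group(
    config: SimulationConfig,
    refs: SimReferences,
    de_spec: Mapping[str, float],
    n_per_group: int = 5,
) -> tuple[dict[str, tuple[list, GroundTruth]], pd.DataFrame]:
    """Five-vs-five style design with spiked isoacceptor channels.

    ``de_spec`` maps isoacceptor -> log2 effect (case over control);
    control samples N1..Nn use the baseline weights, case samples T1..Tn
    the spiked ones.  Returns {sample_id: (reads, truth)} plus the DE
    truth table.
    """
    samples: dict[str, tuple[list, GroundTruth]] = {}
    case_w = spiked_iso_weights(config.isoacceptor_weights, de_spec)
    for i in range(n_per_group):
        sid = f"N{i + 1}"
        samples[sid] = simulate_library(config, refs, sid, sample_index=i)
    for i in range(n_per_group):
        sid = f"T{i + 1}"
        samples[sid] = simulate_library(
            config, refs, sid, sample_index=n_per_group + i, iso_weights=case_w
        )
    de_truth = pd.DataFrame(
        sorted(de_spec.items()), columns=["isoacceptor", "log2_effect"]
    )
    de_truth["direction"] = np.where(de_truth.log2_effect > 0, "up", "down")
    return samples, de_truth


def simulate_count_matrix(
    n_species: int,
    seed: int,
    n_case: int = 5,
    n_ctrl: int = 5,
    de_spec: Mapping[int, float] | None = None,
    dispersion: float = 0.05,
    mean_log2_range: tuple[float, float] = (6.0, 12.0),
):
    """Species x sample negative-binomial count matrix with spiked effects.

    Species baseline means are 2**U(mean_log2_range); counts are drawn
    NB(mean, dispersion) per sample, with case-group means multiplied by
    2**log2_effect for species listed in ``de_spec`` (index -> effect).
    Returns (CountMatrix, truth frame with true log2 effects).
    """
    from .profiles import CountMatrix

    de_spec = dict(de_spec or {})
    rng = np.random.default_rng([seed, 104729])
    means = 2.0 ** rng.uniform(*mean_log2_range, size=n_species)
    effects = np.zeros(n_species)
    for idx, lfc in de_spec.items():
        effects[idx] = lfc
    samples = [f"N{i + 1}" for i in range(n_ctrl)] + [
        f"T{i + 1}" for i in range(n_case)
    ]
    groups = {s: ("control" if s.startswith("N") else "case") for s in samples}
    n = 1.0 / dispersion
    cols = {}
    for j, s in enumerate(samples):
        srng = np.random.default_rng([seed, 104729, j])
        mu = means * np.where(
            np.array([groups[s] == "case"] * n_species), 2.0 ** effects, 1.0
        )
        cols[s] = srng.negative_binomial(n, n / (n + mu))
    species = [f"species_{i + 1}" for i in range(n_species)]
    counts = pd.DataFrame(cols, index=species).astype(float)
    truth = pd.DataFrame(
        {"species": species, "baseline_mean": means, "log2_effect": effects}
    ).set_index("species")
    return CountMatrix(counts, groups=groups), truth


# ---------------------------------------------------------------------------
# fixture corpus I/O
# ---------------------------------------------------------------------------

def write_fastq(
    reads: Sequence[tuple[str, str, str]], path: str | Path, compress: bool = False
) -> None:
    path = Path(path)
    opener = gzip.open if (compress or path.suffix == ".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def make_fixture_corpus(
    out_dir: str | Path,
    seed: int,
    n_reads: int = 5000,
    n_per_group: int = 2,
    de_spec: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write a complete small test corpus: references, FASTQs, sheet, truth."""
    from .reference import write_annotation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = make_toy_references(seed)
    config = SimulationConfig(seed=seed, n_reads=n_reads)
    paths: dict[str, Path] = {}

    write_fasta(
        [(c, s) for c, s in sorted(refs.genome.items())], out / "genome.fa"
    )
    write_annotation(refs.genes, out / "trna_annotation.tsv")
    write_fasta(
        [(m.mature_id, m.sequence) for m in refs.refset.matures],
        out / "mature_trna.fa",
    )
    write_fasta(
        [(p.precursor_id, p.sequence) for p in refs.refset.precursors],
        out / "precursor_trna.fa",
    )
    for cls, seqs in refs.decoys.items():
        write_fasta(seqs, out / f"{cls}.fa")
    with open(out / "collapse_map.tsv", "w") as fh:
        fh.write("gene_id\tmature_id\n")
        for gid, mid in sorted(refs.refset.collapse_map.items()):
            fh.write(f"{gid}\t{mid}\n")

    samples, de_truth = simulate_two_group(
        config, refs, de_spec or {}, n_per_group=n_per_group
    )
    sheet_rows = []
    for sid, (reads, truth) in samples.items():
        fq = out / f"{sid}.fastq"
        write_fastq(reads, fq)
        truth.reads.to_csv(out / f"{sid}.truth.tsv", sep="\t", index=False)
        group = "control" if sid.startswith("N") else "case"
        sheet_rows.append((sid, str(fq), group))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "fastq_path", "group"])
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    de_truth.to_csv(out / "de_truth.tsv", sep="\t", index=False)
    paths["sample_sheet"] = out / "samples.tsv"
    paths["out_dir"] = out
    return paths
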