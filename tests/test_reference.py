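"""Reference construction: splicing, CCA addition, precursors, collapse."""

import numpy as np
import pytest

import exotsrna as x
from exotsrna.reference import reverse_complement

from conftest import random_dna


def make_gene(body, gene_id="g1", aa="Gly", anticodon="GCC", introns=(),
              strand="+", chrom="c1", start=50, anticodon_interval=(33, 36)):
    body = list(body)
    # plant the anticodon at the annotated (unspliced) locus
    if anticodon_interval is not None:
        a, b = anticodon_interval
        body[a:b] = list(anticodon)
    body = "".join(body)
    return x.TRNAGene(
        gene_id=gene_id, chrom=chrom, start=start, end=start + len(body),
        strand=strand, amino_acid=aa, anticodon=anticodon, gene_sequence=body,
        intron_intervals=list(introns), anticodon_interval=anticodon_interval,
    )


class TestSpliceIntrons:
    def test_no_introns_is_identity(self):
        g = make_gene("AAACCCGGG", anticodon_interval=None)
        assert x.splice_introns(g) == g.gene_sequence

    def test_direct_excision(self):
        g = make_gene("AAACCCGGG", introns=[(3, 6)], anticodon_interval=None)
        assert x.splice_introns(g) == "AAAGGG"

    def test_random_sequence_slicing_oracle(self, rng):
        seq = random_dna(rng, 90)
        g = make_gene(seq, introns=[(37, 52)], anticodon_interval=None)
        out = x.splice_introns(g)
        assert len(out) == 75
        assert out == g.gene_sequence[:37] + g.gene_sequence[52:]

    def test_invalid_introns_rejected_with_gene_name(self):
        with pytest.raises(ValueError, match="gX"):
            make_gene("A" * 80, gene_id="gX", introns=[(5, 3)],
                      anticodon_interval=None)
        with pytest.raises(ValueError, match="overlap"):
            make_gene("A" * 80, introns=[(5, 20), (10, 30)],
                      anticodon_interval=None)


class TestBuildMature:
    def test_intronless_gene_gains_cca(self, rng):
        g = make_gene(random_dna(rng, 72))
        m = x.build_mature(g)
        assert len(m.sequence) == 75
        assert m.sequence.endswith("CCA")
        assert m.mature_id == "tRNA-GlyGCC"

    def test_intron_length_arithmetic(self, rng):
        g = make_gene(random_dna(rng, 82), introns=[(40, 50)])
        assert len(x.build_mature(g).sequence) == 82 - 10 + 3

    def test_anticodon_coordinates_preserved_without_introns(self, rng):
        g = make_gene(random_dna(rng, 72))
        m = x.build_mature(g)
        assert m.anticodon_interval == (33, 36)
        assert m.sequence[33:36] == "GCC"

    def test_anticodon_shifts_past_intron(self, rng):
        # intron upstream of the anticodon: mature interval shifts left
        g = make_gene(random_dna(rng, 85), introns=[(10, 20)],
                      anticodon_interval=(43, 46))
        m = x.build_mature(g)
        assert m.anticodon_interval == (33, 36)
        assert m.sequence[33:36] == g.anticodon

    def test_anticodon_mismatch_rejected(self, rng):
        body = random_dna(rng, 72)
        g = make_gene(body)
        g = x.TRNAGene(
            gene_id="g1", chrom="c1", start=50, end=122, strand="+",
            amino_acid="Gly", anticodon="TTT", gene_sequence=g.gene_sequence,
            anticodon_interval=(33, 36),
        )
        with pytest.raises(ValueError, match="anticodon"):
            x.build_mature(g)

    def test_mature_roundtrip_reproduces_gene(self, rng):
        """Removing CCA and re-inserting the intron recovers the gene body."""
        for _ in range(20):
            body_len = int(rng.integers(72, 95))
            has_intron = rng.random() < 0.5
            intron = []
            if has_intron:
                ilen = int(rng.integers(8, 20))
                intron = [(38, 38 + ilen)]
                body_len = max(body_len, 38 + ilen + 20)
            g = make_gene(random_dna(rng, body_len), introns=intron)
            m = x.build_mature(g)
            spliced = m.sequence[:-3]
            if intron:
                a, b = intron[0]
                rebuilt = spliced[:a] + g.gene_sequence[a:b] + spliced[a:]
            else:
                rebuilt = spliced
            assert rebuilt == g.gene_sequence


class TestBuildPrecursor:
    def test_flank_arithmetic(self, rng):
        body = random_dna(rng, 72)
        g = make_gene(body, start=50)
        genome = {"c1": random_dna(rng, 50) + body + random_dna(rng, 60)}
        p = x.build_precursor(g, genome, 50, 50)
        assert len(p.sequence) == 172
        assert p.mature3_boundary == 122
        assert p.sequence[50:122] == body

    def test_minus_strand_is_reverse_complement_of_window(self, rng):
        plus_window = random_dna(rng, 180)
        start, end = 60, 132
        body_sense = reverse_complement(plus_window[start:end])
        g = x.TRNAGene(
            gene_id="g1", chrom="c1", start=start, end=end, strand="-",
            amino_acid="Gly", anticodon=body_sense[33:36],
            gene_sequence=body_sense, anticodon_interval=(33, 36),
        )
        p = x.build_precursor(g, {"c1": plus_window}, 40, 40)
        expected = reverse_complement(plus_window[start - 40:end + 40])
        assert p.sequence == expected
        assert p.leader_len == 40 and p.trailer_len == 40

    def test_contig_edge_truncates_leader(self, rng):
        body = random_dna(rng, 72)
        g = make_gene(body, start=10)
        genome = {"c1": random_dna(rng, 10) + body + random_dna(rng, 60)}
        p = x.build_precursor(g, genome, 50, 50)
        assert p.leader_len == 10
        assert p.mature3_boundary == 10 + 72


class TestCollapseIdentical:
    def _matures(self, rng, n, distinct):
        seqs = [random_dna(rng, 73) + "CCA" for _ in range(distinct)]
        picks = [seqs[i % distinct] for i in range(n)]
        return [
            x.MatureTRNA(f"tRNA-GlyGCC", picks[i], (33, 36), [f"g{i}"],
                         "Gly", "GCC")
            for i in range(n)
        ]

    def test_two_identical_of_three(self, rng):
        ms = self._matures(rng, 3, 2)
        rs = x.collapse_identical(ms)
        assert len(rs.matures) == 2
        assert len(rs.collapse_map) == 3

    def test_all_distinct_is_identity(self, rng):
        ms = self._matures(rng, 5, 5)
        rs = x.collapse_identical(ms)
        assert len(rs.matures) == 5
        assert {m.sequence for m in rs.matures} == {m.sequence for m in ms}

    def test_hash_set_oracle_at_scale(self, rng):
        ms = self._matures(rng, 600, 420)
        rs = x.collapse_identical(ms)
        assert len(rs.matures) == len({m.sequence for m in ms}) == 420

    def test_idempotent_and_order_independent(self, rng):
        ms = self._matures(rng, 12, 7)
        rs1 = x.collapse_identical(ms)
        perm = [ms[i] for i in rng.permutation(len(ms))]
        rs2 = x.collapse_identical(perm)
        assert [m.sequence for m in rs1.matures] == [m.sequence for m in rs2.matures]
        assert rs1.collapse_map == rs2.collapse_map
        rs3 = x.collapse_identical(rs1.matures)
        assert {m.sequence for m in rs3.matures} == {m.sequence for m in rs1.matures}

    def test_copy_suffixes_disambiguate_same_isoacceptor(self, rng):
        ms = self._matures(rng, 4, 2)
        rs = x.collapse_identical(ms)
        assert sorted(m.mature_id for m in rs.matures) == [
            "tRNA-GlyGCC-1", "tRNA-GlyGCC-2"
        ]


def test_toy_reference_invariants(refs):
    """Generated matures are clean DNA ending in CCA; map is total."""
    for m in refs.refset.matures:
        assert set(m.sequence) <= set("ACGT")
        assert m.sequence.endswith("CCA")
        a, b = m.anticodon_interval
        assert m.sequence[a:b] == m.anticodon
    assert set(refs.refset.collapse_map) == {g.gene_id for g in refs.genes}
    seqs = [m.sequence for m in refs.refset.matures]
    assert len(seqs) == len(set(seqs))
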