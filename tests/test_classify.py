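"""tsRNA positional classification, tRF/tRH subtyping, 3'U-tRF detection."""

import numpy as np
import pytest

import exotsrna as x
from exotsrna.align import TagAlignment
from exotsrna.classify import _CLASS_SUFFIX

from conftest import random_dna


@pytest.fixture
def mature75(rng):
    seq = list(random_dna(rng, 72) + "CCA")
    seq[33:36] = list("GCC")
    return x.MatureTRNA("tRNA-GlyGCC-1", "".join(seq), (33, 36), ["g1"],
                        "Gly", "GCC")


def aln(mature, start, end):
    return TagAlignment(mature.sequence[start:end], mature.mature_id,
                        start, end, 0)


def oracle_class(start, end, L, p):
    """Literal transcription of the positional rules (independent of code path)."""
    five = start <= p.delta5
    three = end >= L - p.delta3
    if five and three:
        return "unclassified"
    if five:
        return "tRNA-5"
    if three:
        return "tRNA-3"
    return "tRNA-i"


def oracle_subtype(start, end, ts_class, ac, p):
    if end - start < p.half_min_len:
        return "tRF"
    bp = end if ts_class == "tRNA-5" else start
    return "tRH" if ac[0] - p.anticodon_window <= bp <= ac[1] + p.anticodon_window \
        else "tRF"


class TestClassifyMatureAlignment:
    @pytest.mark.parametrize(
        "interval,expected",
        [((0, 33), "tRNA-5"), ((57, 75), "tRNA-3"), ((20, 40), "tRNA-i"),
         ((1, 74), "unclassified")],
    )
    def test_positional_examples(self, mature75, cparams, interval, expected):
        assert x.classify_mature_alignment(
            aln(mature75, *interval), mature75, cparams) == expected

    def test_out_of_bounds_rejected(self, mature75, cparams):
        bad = TagAlignment("A" * 20, mature75.mature_id, 60, 80, 0)
        with pytest.raises(ValueError, match="bounds"):
            x.classify_mature_alignment(bad, mature75, cparams)

    def test_exhaustive_substring_oracle(self, mature75, cparams):
        """Every 16-40 nt substring of a 75-nt mature matches the rule oracle."""
        L = len(mature75)
        checked = 0
        for k in range(16, 41):
            for s in range(0, L - k + 1):
                got = x.classify_mature_alignment(
                    aln(mature75, s, s + k), mature75, cparams)
                assert got == oracle_class(s, s + k, L, cparams)
                checked += 1
        assert checked == sum(L - k + 1 for k in range(16, 41))

    def test_delta_monotonicity(self, mature75):
        """Enlarging tolerances never moves a tag OUT of tRNA-5/tRNA-3."""
        base = x.ClassifierParams()
        wide = x.ClassifierParams(delta5=3, delta3=5)
        for k in range(16, 41):
            for s in range(0, 75 - k + 1):
                a = aln(mature75, s, s + k)
                c0 = x.classify_mature_alignment(a, mature75, base)
                c1 = x.classify_mature_alignment(a, mature75, wide)
                if c0 == "tRNA-5":
                    assert c1 in ("tRNA-5", "unclassified")
                if c0 == "tRNA-3":
                    assert c1 in ("tRNA-3", "unclassified")


class TestSubtype:
    def test_long_fragment_ending_in_anticodon_is_half(self, mature75, cparams):
        a = aln(mature75, 0, 35)  # 35 nt, breakpoint 35 in padded (33,36)
        assert x.subtype_half_or_fragment(a, mature75, "tRNA-5", cparams) == "tRH"

    def test_short_fragment_is_trf(self, mature75, cparams):
        a = aln(mature75, 0, 18)
        assert x.subtype_half_or_fragment(a, mature75, "tRNA-5", cparams) == "tRF"

    def test_exhaustive_rule_transcription_agreement(self, mature75, cparams):
        for k in range(16, 41):
            for s in range(0, 75 - k + 1):
                a = aln(mature75, s, s + k)
                ts = x.classify_mature_alignment(a, mature75, cparams)
                if ts not in ("tRNA-5", "tRNA-3"):
                    continue
                got = x.subtype_half_or_fragment(a, mature75, ts, cparams)
                assert got == oracle_subtype(
                    s, s + k, ts, mature75.anticodon_interval, cparams)


class TestDetect3pU:
    @pytest.fixture
    def precursor(self, rng):
        body = random_dna(rng, 72)
        seq = random_dna(rng, 50) + body + "TTTTT" + random_dna(rng, 45)
        return x.PrecursorTRNA("pre-1", seq, 50, 50, 122, "Gly", "GCC")

    def test_trailer_crossing_poly_t_detected(self, precursor, cparams):
        a = TagAlignment(precursor.sequence[102:126], "pre-1", 102, 126, 0)
        assert a.tag_sequence.endswith("TTTT")
        assert x.detect_3pU_trf(a, precursor, cparams)

    def test_body_only_fragment_rejected(self, precursor, cparams):
        a = TagAlignment(precursor.sequence[60:90], "pre-1", 60, 90, 0)
        assert not x.detect_3pU_trf(a, precursor, cparams)

    def test_wrong_suffix_rejected(self, precursor, cparams):
        a = TagAlignment("A" * 18 + "TA", "pre-1", 104, 124, 0)
        assert not x.detect_3pU_trf(a, precursor, cparams)


class TestClassifyTag:
    def test_agreeing_multimaps_sum_weight(self, refs, cparams):
        # the toy set contains two identical collapsed copies -> one mature
        m = refs.refset.matures[0]
        tag = m.sequence[:30]
        alns = x.assign_weights([
            TagAlignment(tag, m.mature_id, 0, 30, 0),
            TagAlignment(tag, refs.refset.matures[1].mature_id, 0, 30, 0),
        ])
        rec = x.classify_tag(tag, alns, refs.refset, cparams, count=7.0)
        assert rec.ts_class == "tRNA-5"
        assert np.isclose(rec.weighted_count, 7.0)
        assert np.isclose(sum(rec.isoacceptor_weights.values()), 1.0)

    def test_class_tie_is_unclassified(self, refs, cparams):
        m1, m2 = refs.refset.matures[0], refs.refset.matures[1]
        tag = m1.sequence[:20]
        alns = x.assign_weights([
            TagAlignment(tag, m1.mature_id, 0, 20, 0),       # tRNA-5
            TagAlignment(tag, m2.mature_id, 25, 45, 0),      # tRNA-i
        ])
        rec = x.classify_tag(tag, alns, refs.refset, cparams)
        assert rec.ts_class == "unclassified" and rec.subtype == "na"

    def test_no_alignment_rejected(self, refs, cparams):
        with pytest.raises(ValueError):
            x.classify_tag("A" * 20, [], refs.refset, cparams)

    def test_species_key_uses_field_naming(self, refs, cparams):
        m = refs.refset.matures[0]
        tag = m.sequence[:30]
        rec = x.classify_tag(
            tag, x.assign_weights([TagAlignment(tag, m.mature_id, 0, 30, 0)]),
            refs.refset, cparams)
        assert rec.species_key == f"tRNA-{m.isoacceptor}-5|{tag}"

    def test_subtype_na_iff_noncanonical_class(self, refs, class_indexes,
                                               cparams):
        cfg = x.SimulationConfig(
            seed=13, n_reads=3000, error_rate=0.0,
            tsrna_type_probs={"tRNA-5": 0.4, "tRNA-i": 0.2, "tRNA-3": 0.2,
                              "3pU-tRF": 0.2},
        )
        reads, _ = x.simulate_library(cfg, refs, "S", 0)
        res = x.process_reads(
            "S", reads, x.TrimParams(adapter_3p=cfg.adapter_3p),
            class_indexes[0], class_indexes[1], refs.refset, cparams)
        assert res.records
        for r in res.records:
            assert (r.subtype == "na") == (
                r.ts_class in ("3pU-tRF", "unclassified"))


class TestGroundTruthRecovery:
    def test_error_free_class_recovery_above_99pct(self, refs, class_indexes,
                                                   cparams):
        """With error-free reads and default tolerances, nearly every tRNA
        read is assigned its generating tsRNA class."""
        cfg = x.SimulationConfig(
            seed=29, n_reads=20000, error_rate=0.0,
            class_mixture={"miRNA": 0.0, "tRNA": 1.0, "rRNA": 0.0,
                           "snoRNA": 0.0, "snRNA": 0.0, "piRNA": 0.0},
            tsrna_type_probs={"tRNA-5": 0.6, "tRNA-i": 0.1, "tRNA-3": 0.2,
                              "3pU-tRF": 0.1},
        )
        reads, truth = x.simulate_library(cfg, refs, "S", 0)
        res = x.process_reads(
            "S", reads, x.TrimParams(adapter_3p=cfg.adapter_3p),
            class_indexes[0], class_indexes[1], refs.refset, cparams)
        assigned = {r.tag_sequence: r.ts_class for r in res.records}
        hits = sum(
            assigned.get(ins) == tc
            for ins, tc in zip(truth.reads["insert"], truth.reads["ts_class"])
        )
        assert hits / len(truth.reads) >= 0.99
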