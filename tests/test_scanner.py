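"""Scanning: Phred conversion, PSSM scoring, tag extraction, strand
handling, quality gates and the probe prefilter."""

import numpy as np
import pytest

from ssutag import _seq
from ssutag.scanner import (ScanConfig, ScanStats, phred_error_prob,
                            pssm_score, scan_read, scan_reads)
from ssutag.evaluation import sensitivity

from conftest import RS23, TAG33, toy_profile


def q(n, score=40):
    return chr(33 + score) * n


class TestPhred:
    @pytest.mark.parametrize("qv,expected", [
        (30, 0.001),   # the Q30 filtering threshold: 0.1% error
        (0, 1.0),
        (10, 0.1),
        (20, 0.01),
    ])
    def test_closed_form(self, qv, expected):
        assert phred_error_prob(qv) == pytest.approx(expected, rel=1e-12)

    def test_q30_is_exactly_one_in_a_thousand(self):
        assert phred_error_prob(30) == 0.001

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phred_error_prob(-1)


class TestPssmScore:
    def test_zero_matrix(self):
        assert pssm_score(np.zeros((23, 4)), RS23) == 0.0

    def test_consensus_attains_maximum(self):
        prof = toy_profile(RS23)
        assert pssm_score(prof.pssm, RS23) == pytest.approx(23 * 2.0)

    def test_n_scores_column_minimum(self):
        prof = toy_profile(RS23)
        window = "N" + RS23[1:]
        assert pssm_score(prof.pssm, window) == pytest.approx(22 * 2.0 - 5.0)

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            pssm_score(np.zeros((23, 4)), "ACGT")

    def test_brute_force_oracle(self):
        """1000 random windows against an independently coded
        position-by-position summation."""
        rng = np.random.default_rng(42)
        pssm = rng.normal(size=(23, 4))
        for _ in range(1000):
            codes = rng.integers(0, 5, size=23)
            window = "".join("ACGTN"[c] for c in codes)
            expected = 0.0
            for i, ch in enumerate(window):
                if ch == "N":
                    expected += min(pssm[i])
                else:
                    expected += pssm[i]["ACGT".index(ch)]
            assert pssm_score(pssm, window) == pytest.approx(expected)


class TestScanRead:
    def setup_method(self):
        self.prof = toy_profile(RS23)

    def test_exact_rs_tag_read(self):
        read = ("r1", RS23 + TAG33, q(56))
        obs = scan_read(read, [self.prof])
        assert len(obs) == 1
        ob = obs[0]
        assert ob.tag == TAG33
        assert ob.strand == "+"
        assert ob.rs_offset == 0
        assert ob.min_tag_quality == 40
        assert ob.long_seq is None          # only 33 nt available

    def test_long_sequence_extracted_and_prefixed_by_tag(self):
        extra = "ACGGTTCAACGGTTCAACGGTTCAACG"      # 27 nt -> 60 total
        read = ("r1", RS23 + TAG33 + extra, q(83))
        ob = scan_read(read, [self.prof])[0]
        assert ob.long_seq == TAG33 + extra
        assert ob.long_seq.startswith(ob.tag)

    def test_insufficient_tag_length(self):
        read = ("r1", RS23 + TAG33[:20], q(43))
        assert scan_read(read, [self.prof]) == []

    def test_reverse_complement_read(self):
        fwd = RS23 + TAG33
        read = ("r1", _seq.revcomp(fwd), q(56))
        obs = scan_read(read, [self.prof])
        assert len(obs) == 1
        assert obs[0].strand == "-"
        assert obs[0].tag == TAG33          # reported in anchored sense

    def test_low_quality_tag_base_rejected(self):
        qual = q(23) + q(10) + chr(33 + 20) + q(22)   # one tag base at Q20
        read = ("r1", RS23 + TAG33, qual)
        assert scan_read(read, [self.prof]) == []

    def test_boundary_quality_accepted(self):
        read = ("r1", RS23 + TAG33, q(56, 30))        # exactly Q30
        assert len(scan_read(read, [self.prof])) == 1

    def test_n_in_tag_rejected(self):
        read = ("r1", RS23 + "N" + TAG33[1:], q(56))
        assert scan_read(read, [self.prof]) == []

    def test_fasta_input_no_quality_gate(self):
        ob = scan_read(("r1", RS23 + TAG33), [self.prof])[0]
        assert ob.min_tag_quality is None

    def test_downstream_profile_anchored_orientation(self):
        """For an RS downstream of the region, the anchored layout on
        the gene-sense strand is revcomp(tag)+revcomp(RS)... i.e. the
        read carries tag immediately 5' of the RS site."""
        prof = toy_profile(RS23, side="downstream")
        gene_sense = _seq.revcomp(RS23 + TAG33)
        ob = scan_read(("r1", gene_sense, q(56)), [prof])[0]
        assert ob.tag == TAG33              # anchored orientation
        assert ob.strand == "+"             # the read IS gene sense
        ob2 = scan_read(("r1", RS23 + TAG33, q(56)), [prof])[0]
        assert ob2.strand == "-"

    def test_best_hit_per_region(self):
        weak = toy_profile(RS23, pid="a_weak")
        weak.pssm = weak.pssm * 0.9
        strong = toy_profile(RS23, pid="b_strong")
        obs = scan_read(("r1", RS23 + TAG33, q(56)), [weak, strong])
        assert len(obs) == 1
        assert obs[0].profile_id == "b_strong"

    def test_malformed_quality_not_fatal(self):
        reads = [("bad", RS23 + TAG33, q(10)),
                 ("good", RS23 + TAG33, q(56))]
        obs, stats = scan_reads(reads, [self.prof])
        assert [o.read_id for o in obs] == ["good"]
        assert stats.bad_reads == 1

    def test_stats_accounting_identity(self):
        reads = [("a", RS23 + TAG33, q(56)),            # observation
                 ("b", RS23 + TAG33[:10], q(33)),       # length filtered
                 ("c", RS23 + TAG33, q(23) + q(33, 20)),  # quality filtered
                 ("d", "ACGT" * 20, q(80))]             # no hit
        obs, stats = scan_reads(reads, [self.prof])
        assert stats.reads_in == stats.reads_hit + stats.reads_no_hit
        assert stats.observations == (stats.hits - stats.length_filtered
                                      - stats.quality_filtered)
        assert stats.observations == len(obs) == 1
        assert stats.reads_hit == 3


class TestStrandSymmetry:
    def test_scan_of_revcomp_mirrors(self, small_ref, v4_profile):
        """Scanning a read and its reverse complement yields the same
        tags with flipped strand and identical anchored offsets."""
        for sid, seq, _ in small_ref.records[:6]:
            fwd = scan_read((sid, seq), [v4_profile])
            rev = scan_read((sid, _seq.revcomp(seq)), [v4_profile])
            key_f = sorted((o.tag, o.strand, o.rs_offset) for o in fwd)
            key_r = sorted((o.tag, "+-"[o.strand == "+"], o.rs_offset)
                           for o in rev)
            assert len(fwd) > 0
            assert key_f == key_r


class TestPrefilter:
    def test_soundness_without_mismatch_budget(self, small_ref, v4_profile):
        """With the prefilter disabled the scan must equal the exhaustive
        PSSM scan; with the default budget the loss on default synthetic
        data stays below 1%."""
        reads = [(sid, seq) for sid, seq, _ in small_ref.records]
        off = ScanConfig(probe_mismatches=None)
        s_off = sensitivity([v4_profile], reads, off)
        s_on = sensitivity([v4_profile], reads)
        assert s_off - s_on < 0.01
        obs_off, _ = scan_reads(reads, [v4_profile], off)
        obs_none, _ = scan_reads(reads, [v4_profile],
                                 ScanConfig(probe_mismatches=1000))
        assert ([(o.read_id, o.tag, o.rs_offset) for o in obs_off]
                == [(o.read_id, o.tag, o.rs_offset) for o in obs_none])
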