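"""Profile construction: entropy, PSSM arithmetic, window selection,
probe patterns, threshold calibration and serialization."""

import math

import numpy as np
import pytest

from ssutag import _seq
from ssutag.profiles import (AlignedReference, ProfileConfig,
                             ProfileConstructionError, build_profile,
                             build_pssm, build_taxon_profiles,
                             column_entropy, load_profiles, save_profiles)
from ssutag.scanner import pssm_score
from ssutag.synthetic import CommunitySpec, make_reference

from conftest import uniform_alignment


class TestColumnEntropy:
    @pytest.mark.parametrize("column,expected", [
        ("AAAA", 0.0),              # perfectly conserved
        ("ACGT", 2.0),              # uniform
        ("AACC", 1.0),              # two bases at 50/50
        ("----", 2.0),              # all-gap: no information
        ("AA--", 0.0),              # gaps excluded from denominator
    ])
    def test_closed_forms(self, column, expected):
        ref = uniform_alignment([c for c in column])
        assert column_entropy(ref, 0) == pytest.approx(expected)

    def test_direct_evaluation(self):
        # 50 A, 30 C, 20 G against -sum p log2 p computed by hand
        seqs = ["A"] * 50 + ["C"] * 30 + ["G"] * 20
        ref = uniform_alignment(seqs)
        expected = -(0.5 * math.log2(0.5) + 0.3 * math.log2(0.3)
                     + 0.2 * math.log2(0.2))
        assert column_entropy(ref, 0) == pytest.approx(expected)

    def test_out_of_range(self, small_ref):
        with pytest.raises(IndexError):
            column_entropy(small_ref, small_ref.alignment_length)


class TestBuildPssm:
    def test_conserved_position_log_odds(self):
        # 100 sequences all A: entry = log2((100.5/102)/0.25)
        ref = uniform_alignment(["A" * 23] * 100)
        m = build_pssm(ref, range(23), pseudocount=0.5)
        expected = math.log2((100.5 / 102.0) / 0.25)
        assert m[0, 0] == pytest.approx(expected)
        assert round(expected, 3) == 1.979
        # the other bases carry the pseudocount only
        assert m[0, 1] == pytest.approx(math.log2((0.5 / 102.0) / 0.25))

    def test_background_identity_is_zero(self):
        # counts proportional to the background give zero log-odds
        seqs = ["A" * 23, "C" * 23, "G" * 23, "T" * 23]
        ref = uniform_alignment(seqs)
        m = build_pssm(ref, range(23), pseudocount=0.5)
        assert np.allclose(m, 0.0)

    def test_all_gap_row_is_zero(self):
        seqs = ["-" + "A" * 22] * 5
        ref = uniform_alignment(seqs)
        m = build_pssm(ref, range(23))
        assert np.all(m[0] == 0.0)
        assert m[1, 0] > 0

    def test_window_geometry_enforced(self, small_ref):
        with pytest.raises(ValueError):
            build_pssm(small_ref, range(22))

    def test_round_trip_frequencies(self, small_ref):
        """Exponentiating the log-odds against the background and
        renormalizing recovers the smoothed training frequencies."""
        cols = range(100, 123)
        pc = 0.5
        m = build_pssm(small_ref, cols, pseudocount=pc)
        recovered = (2.0 ** m) * 0.25
        recovered /= recovered.sum(axis=1, keepdims=True)
        codes = small_ref.codes[:, list(cols)]
        n = len(small_ref.records)
        for i in range(23):
            counts = np.array([(codes[:, i] == b).sum() for b in range(4)])
            smoothed = (counts + pc) / (n + 4 * pc)
            assert np.allclose(recovered[i], smoothed / smoothed.sum())


class TestBuildProfile:
    def test_noiseless_recovery(self):
        """A perfectly conserved flank yields the consensus PSSM and
        100% training sensitivity."""
        rng = np.random.default_rng(5)
        flank = _seq.decode(rng.integers(0, 4, 23))
        n = 30
        variable = [_seq.decode(rng.integers(0, 4, 40)) for _ in range(n)]
        seqs = [flank + v + flank for v in variable]
        ref = uniform_alignment(seqs, region_map={"V1": (23, 63)})
        prof = build_profile(ref, "V1", domain=None)
        consensus = "".join("ACGT"[i] for i in np.argmax(prof.pssm, axis=1))
        assert consensus == flank
        assert prof.meta["training_sensitivity"] == 1.0
        assert prof.meta["shift"] == 0

    def test_training_sensitivity_under_noise(self):
        """2% per-base flank noise: the sweep still guarantees >= 95%
        training sensitivity."""
        spec = CommunitySpec(n_taxa=60, seed=11, conserved_mut_rate=0.02)
        ref = make_reference(spec, np.random.default_rng(11))
        prof = build_profile(ref, "V4")
        assert prof.meta["training_sensitivity"] >= 0.95

    def test_missing_region_raises(self, small_ref):
        with pytest.raises(KeyError):
            build_profile(small_ref, "V99")

    def test_unconserved_flank_fails(self):
        rng = np.random.default_rng(3)
        n = 20
        seqs = [_seq.decode(rng.integers(0, 4, 90)) for _ in range(n)]
        ref = uniform_alignment(seqs, region_map={"V1": (30, 60)})
        with pytest.raises(ProfileConstructionError):
            build_profile(ref, "V1", domain=None)

    def test_window_entropy_minimal_among_shifts(self, small_ref,
                                                 v4_profile):
        cfg = ProfileConfig()
        start, _ = small_ref.region_map["V4"]
        nominal = start - 23
        w0 = v4_profile.meta["window_start"]

        def mean_entropy(a):
            return np.mean([column_entropy(small_ref, c)
                            for c in range(a, a + 23)])

        chosen = mean_entropy(w0)
        for shift in range(-cfg.shift_range, cfg.shift_range + 1):
            assert chosen <= mean_entropy(nominal + shift) + 1e-12

    def test_structure(self, v4_profile):
        assert v4_profile.pssm.shape == (23, 4)
        assert v4_profile.tag_length == 33
        assert v4_profile.tag_length <= v4_profile.long_length
        assert len(v4_profile.probe_pattern) >= 8
        assert v4_profile.score_threshold <= v4_profile.max_score
        # consensus window attains the maximum score
        consensus = "".join("ACGT"[i]
                            for i in np.argmax(v4_profile.pssm, axis=1))
        assert pssm_score(v4_profile.pssm, consensus) == pytest.approx(
            v4_profile.max_score)


def _divergent_community(n_divergent_phyla: int, seed: int = 19):
    """A 96-taxon, 12-phylum community where each selected phylum
    carries its own (shared, clade-specific) V4 flank that the
    universal profile cannot recognize."""
    spec = CommunitySpec(n_taxa=96, lineage_tree=(1, 12, 2, 2, 2, 1),
                         seed=seed)
    rng = np.random.default_rng(seed)
    ref = make_reference(spec, rng)
    start, _ = ref.region_map["V4"]
    phyla = sorted({lin[1] for _, _, lin in ref.records})
    bad = phyla[:n_divergent_phyla]
    flank = {p: _seq.decode(rng.integers(0, 4, 28)) for p in bad}
    records = []
    for sid, seq, lin in ref.records:
        if lin[1] in flank:
            seq = seq[:start - 28] + flank[lin[1]] + seq[start:]
        records.append((sid, seq, lin))
    return AlignedReference(records=records, region_map=ref.region_map)


class TestTaxonProfiles:
    def test_no_supplements_when_universal_suffices(self):
        ref = _divergent_community(0)
        assert build_taxon_profiles(ref, "V4") == []

    @pytest.mark.parametrize("k", [1, 3])
    def test_one_supplement_per_divergent_phylum(self, k):
        ref = _divergent_community(k)
        sups = build_taxon_profiles(ref, "V4")
        assert len(sups) == k
        phyla = sorted({lin[1] for _, _, lin in ref.records})
        assert sorted(p.scope for p in sups) == phyla[:k]


class TestSerialization:
    def test_yaml_round_trip_is_bit_identical(self, small_ref, v4_profile,
                                              tmp_path):
        sups = build_taxon_profiles(small_ref, "V4", universal=v4_profile)
        path = tmp_path / "profiles.yaml"
        save_profiles([v4_profile] + sups, path)
        loaded = load_profiles(path)
        assert len(loaded) == 1 + len(sups)
        for a, b in zip([v4_profile] + sups, loaded):
            assert a.profile_id == b.profile_id
            assert np.array_equal(a.pssm, b.pssm)
            assert a.score_threshold == b.score_threshold
            assert a.probe_pattern == b.probe_pattern
            assert (a.tag_length, a.long_length) == (b.tag_length,
                                                     b.long_length)
        # writing again produces identical bytes
        path2 = tmp_path / "profiles2.yaml"
        save_profiles(loaded, path2)
        assert path.read_bytes() == path2.read_bytes()
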