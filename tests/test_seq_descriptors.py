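"""Sequence descriptor set: substitution indices, entropies, compositions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import savpred as sp
from savpred.residue_classes import AMINO_ACIDS, CLASS_SCHEMES, SCHEME_CLASS_PAIRS
from savpred.seq_descriptors import (
    SEQUENCE_FEATURE_NAMES,
    aac_features,
    entropy_profile,
    position_entropy,
    substitution_indices,
)

LOG2_20 = math.log2(20)


def flat_profile(seq):
    """Profile with all-zero log-odds and uniform percentages."""
    L = len(seq)
    return sp.PssmProfile(seq, np.zeros((L, 20)), np.full((L, 20), 5.0))


class TestSubstitutionIndices:
    def test_blosum_and_pam_entries(self):
        prof = flat_profile("AEA")
        v = substitution_indices("E", "K", prof, 2)
        assert v[0] == 1  # BLOSUM62(E,K)
        prof_w = flat_profile("AWA")
        v = substitution_indices("W", "W", prof_w, 2)
        assert v[1] == 17  # PAM250(W,W)

    def test_zero_logodds_gives_zero_pssm_index(self):
        v = substitution_indices("A", "V", flat_profile("CAC"), 2)
        assert v[2] == 0.0

    def test_difference_mode(self, toy_profile):
        seq, prof = toy_profile
        wt = seq[4]
        mut = "K" if wt != "K" else "R"
        v = substitution_indices(wt, mut, prof, 5, pssm_mode="difference")
        expected = prof.log_odds_at(5, mut) - prof.log_odds_at(5, wt)
        assert v[2] == pytest.approx(expected)

    def test_out_of_range_position(self):
        with pytest.raises(IndexError):
            substitution_indices("A", "V", flat_profile("AA"), 3)

    def test_wt_mismatch_warns_but_proceeds(self):
        with pytest.warns(UserWarning, match="does not match"):
            substitution_indices("W", "V", flat_profile("AAA"), 2)


class TestEntropy:
    def test_uniform_and_one_hot_bounds(self):
        assert position_entropy(sp.make_toy_pssm("AAA", 0.0, 0), 2) == pytest.approx(LOG2_20)
        assert position_entropy(sp.make_toy_pssm("AAA", 1.0, 0), 2) == 0.0

    def test_brute_force_oracle(self, toy_profile):
        _, prof = toy_profile
        for pos in range(1, len(prof) + 1):
            row = prof.obs_pct[pos - 1]
            p = row / row.sum()
            expected = -sum(pi * math.log2(pi) for pi in p if pi > 0)
            assert position_entropy(prof, pos) == pytest.approx(expected, abs=1e-12)

    def test_bounds_for_random_profiles(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            obs = rng.uniform(0, 10, size=(4, 20))
            prof = sp.PssmProfile("ACDE", np.zeros((4, 20)), obs)
            for pos in range(1, 5):
                h = position_entropy(prof, pos)
                assert 0.0 <= h <= LOG2_20 + 1e-12

    def test_vector_layout_and_terminal_sentinels(self, toy_profile):
        _, prof = toy_profile
        v = entropy_profile(prof, 1)  # N-terminal SAV: offsets -7..-1 off-sequence
        assert v.shape == (17,)
        assert np.all(v[:7] == 0.0)
        in_range = [position_entropy(prof, 1 + o) for o in range(0, 8)]
        assert v[15] == pytest.approx(np.mean(in_range))       # avg over 8 present
        assert v[16] == pytest.approx(np.mean(in_range[:3]))   # offsets 0..+2


class TestAac:
    def test_pure_alanine_window(self):
        v = aac_features("A" * 15, 8)
        named = dict(zip([f"aac_{s}_{c}" for s, c in SCHEME_CLASS_PAIRS], v))
        assert named["aac_H_neutral"] == 1.0
        assert named["aac_H_polar"] == 0.0
        assert named["aac_H_hydrophobic"] == 0.0

    def test_acidic_window(self):
        v = aac_features("DEDEDEDEDEDEDED", 8)
        named = dict(zip([f"aac_{s}_{c}" for s, c in SCHEME_CLASS_PAIRS], v))
        assert named["aac_F_acidic"] == 1.0
        assert named["aac_E_acidic"] == 1.0

    @pytest.mark.parametrize("pos", [1, 3, 5, 10])
    def test_truncated_window_partitions_sum_to_one(self, pos):
        seq = "ACDEFGHIKL"
        v = aac_features(seq, pos)
        named = dict(zip(SCHEME_CLASS_PAIRS, v))
        for scheme, classes in CLASS_SCHEMES.items():
            total = sum(named[(scheme, cls)] for cls in classes)
            assert total == pytest.approx(1.0)

    @given(st.permutations(list("ACDEFGHIKLMNPQR")))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, perm):
        base = aac_features("ACDEFGHIKLMNPQR", 8)
        assert np.allclose(aac_features("".join(perm), 8), base)


class TestAssembly:
    def test_length_and_names(self, toy_profile, toy_sav):
        seq, prof = toy_profile
        sav = sp.SAVRecord("TOY", "A", 15, 15, seq[14], "V" if seq[14] != "V" else "L")
        vec = sp.sequence_features(sav, seq, prof)
        assert len(vec) == 44
        assert list(vec.index) == SEQUENCE_FEATURE_NAMES

    def test_only_indices_depend_on_mutant(self, toy_profile):
        seq, prof = toy_profile
        wt = seq[14]
        muts = [m for m in "VLK" if m != wt][:2]
        v1 = sp.sequence_features(sp.SAVRecord("T", "A", 15, 15, wt, muts[0]), seq, prof)
        v2 = sp.sequence_features(sp.SAVRecord("T", "A", 15, 15, wt, muts[1]), seq, prof)
        diff = v1 != v2
        assert not diff[3:].any()

    def test_profile_changes_touch_entropy_not_aac(self, toy_profile):
        seq, prof = toy_profile
        flat = sp.PssmProfile(seq, prof.log_odds, np.full_like(prof.obs_pct, 5.0))
        sav = sp.SAVRecord("T", "A", 15, 15, seq[14], "V" if seq[14] != "V" else "L")
        v1 = sp.sequence_features(sav, seq, prof)
        v2 = sp.sequence_features(sav, seq, flat)
        assert not np.allclose(v1[3:20], v2[3:20])  # entropies moved
        assert np.allclose(v1[20:], v2[20:])        # AAC unchanged
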