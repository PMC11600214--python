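"""Dataset rules, transition categories and contact statistics."""

import numpy as np
import pytest

from transpath import curation as cu
from transpath import fixtures as fx
from transpath.structio import CaStructure, StatePair


def _dup_pair(struct, pid="dup"):
    return StatePair(protein_id=pid, state_a=struct, state_b=struct,
                     residue_map=tuple((i, i) for i in range(len(struct))))


@pytest.fixture(scope="module")
def toy60():
    return fx.make_toy_two_state(60, 150.0, seed=11)


class TestEvaluateMsPair:
    def test_identical_structures_not_ms(self, toy60):
        dec = cu.evaluate_ms_pair(_dup_pair(toy60.pair.state_a))
        assert not dec.is_ms
        assert dec.rmsd_nm == pytest.approx(0.0, abs=1e-9)
        assert dec.seq_identity == 1.0

    def test_hinge_fixture_qualifies(self, toy60):
        assert toy60.known_rmsd > 0.5
        dec = cu.evaluate_ms_pair(toy60.pair)
        assert dec.is_ms
        assert dec.longest_gap == 0

    def test_long_insertion_fails_gap_rule(self, toy60):
        # 25-residue unmapped insertion in state A
        a = toy60.pair.state_a
        ins = CaStructure(
            id="ins", sequence=a.sequence[:30] + "A" * 25 + a.sequence[30:],
            coords=np.vstack([a.coords[:30],
                              a.coords[29] + np.arange(1, 26)[:, None]
                              * [0.38, 0, 0],
                              a.coords[30:]]),
        )
        rmap = tuple((i, i) for i in range(30)) + tuple(
            (i + 25, i) for i in range(30, 60))
        pair = StatePair("gap", ins, toy60.pair.state_b, residue_map=rmap,
                         substitutions=tuple(
                             (ia, ib) for ia, ib in rmap
                             if ins.sequence[ia]
                             != toy60.pair.state_b.sequence[ib]))
        dec = cu.evaluate_ms_pair(pair)
        assert not dec.is_ms
        assert dec.longest_gap == 25
        assert any("gap" in r for r in dec.reasons if "fail" in r)

    def test_short_sequences_rejected(self, toy40):
        with pytest.raises(ValueError, match="length"):
            cu.evaluate_ms_pair(toy40.pair)


class TestEvaluateSsCluster:
    def test_six_rigid_copies_returns_shortest(self, toy60):
        base = toy60.pair.state_a
        short = CaStructure("short", base.sequence[:55], base.coords[:55])
        members = [base] * 5 + [short]
        rep = cu.evaluate_ss_cluster(members)
        assert rep is short

    def test_five_copies_is_not_enough(self, toy60):
        assert cu.evaluate_ss_cluster([toy60.pair.state_a] * 5) is None

    def test_perturbed_member_breaks_cluster(self, toy60):
        base = toy60.pair.state_a
        rng = np.random.default_rng(2)
        # random perturbation scaled to exceed the 0.2 nm RMSD rule
        noise = rng.normal(0, 1, base.coords.shape)
        noise -= noise.mean(axis=0)
        from transpath.structio import superpose_rmsd
        scale = 0.3 / superpose_rmsd(base.coords, base.coords + noise)
        bad = CaStructure("bad", base.sequence, base.coords + scale * noise)
        assert superpose_rmsd(base.coords, bad.coords) > 0.2
        assert cu.evaluate_ss_cluster([base] * 5 + [bad]) is None


class TestClassifyTransition:
    def _pair_with_ss(self, toy, ssa, ssb):
        from dataclasses import replace
        return StatePair(
            protein_id=toy.pair.protein_id,
            state_a=replace(toy.pair.state_a, ss=ssa),
            state_b=replace(toy.pair.state_b, ss=ssb),
            residue_map=toy.pair.residue_map,
        )

    def test_helix_sheet_swap_is_iv(self, toy64):
        n = 64
        ssa = "H" * n
        ssb = "H" * 20 + "E" * 6 + "H" * (n - 26)
        cat = cu.classify_transition(self._pair_with_ss(toy64, ssa, ssb))
        assert cat.category == "IV"
        assert cat.n_helix_sheet_swap == 6

    def test_melting_to_loop_is_iii(self, toy64):
        n = 64
        ssa = "H" * n
        ssb = "H" * 20 + "C" * 6 + "H" * (n - 26)
        cat = cu.classify_transition(self._pair_with_ss(toy64, ssa, ssb))
        assert cat.category == "III"
        assert cat.n_fold_to_loop == 6

    def test_rigid_hinge_is_category_i(self, toy64):
        # identical ss; two 32-residue arms move as rigid bodies
        cat = cu.classify_transition(toy64.pair)
        assert cat.category == "I"

    def test_small_rearrangement_is_ii(self, toy64):
        cat = cu.classify_transition(_dup_pair(toy64.pair.state_a))
        assert cat.category == "II"

    def test_missing_ss_raises(self, toy64):
        pair = self._pair_with_ss(toy64, None, None)
        with pytest.raises(ValueError, match="secondary-structure"):
            cu.classify_transition(pair)

    def test_pure_function(self, toy64):
        a = cu.classify_transition(toy64.pair)
        b = cu.classify_transition(toy64.pair)
        assert a == b


def _brute_force_frequencies(seq, coords):
    """Independent double-loop implementation of the frequency count."""
    counts = {}
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            if 0.3 < d < 1.0:
                key = tuple(sorted((seq[i], seq[j])))
                counts[key] = counts.get(key, 0) + 1
    out = {}
    for (p, q), npq in counts.items():
        out[(p, q)] = npq / (seq.count(p) * seq.count(q))
    return out


class TestContactFrequency:
    def test_two_ala_at_half_nm(self):
        s = CaStructure("aa", "AA", np.array([[0, 0, 0], [0.5, 0, 0]]))
        stats = cu.contact_frequency([s], kind="SS")
        assert stats.F[("A", "A")] == pytest.approx(0.25)
        assert sum(v != 0 for v in stats.F.values()) == 1

    def test_out_of_range_pair_is_zero(self):
        s = CaStructure("aa", "AA", np.array([[0, 0, 0], [2.0, 0, 0]]))
        stats = cu.contact_frequency([s], kind="SS")
        assert stats.F[("A", "A")] == 0.0

    def test_matches_brute_force_oracle(self, toy40):
        a = toy40.pair.state_a
        stats = cu.contact_frequency([a], kind="SS")
        oracle = _brute_force_frequencies(a.sequence, a.coords)
        for pq in cu.CONTACT_TYPES:
            assert stats.F[pq] == pytest.approx(oracle.get(pq, 0.0),
                                                rel=1e-12)

    def test_invariant_under_dataset_reordering(self, toy40, toy64):
        sa = [toy40.pair.state_a, toy64.pair.state_a]
        f1 = cu.contact_frequency(sa, kind="SS").F
        f2 = cu.contact_frequency(sa[::-1], kind="SS").F
        assert f1 == f2

    def test_210_types(self, toy40):
        stats = cu.contact_frequency([toy40.pair.state_a], kind="SS")
        assert len(stats.F) == 210


class TestFrequencyRatio:
    def test_equal_datasets_give_one(self, toy40):
        f = cu.contact_frequency([toy40.pair.state_a], kind="MS")
        ratio = cu.ms_frequency_ratio(f, f)
        present = [pq for pq in cu.CONTACT_TYPES if f.F[pq] > 0]
        assert present
        for pq in present:
            assert ratio[pq] == pytest.approx(1.0)

    def test_limits_and_missing(self):
        s1 = CaStructure("aa", "AA", np.array([[0, 0, 0], [0.5, 0, 0]]))
        s2 = CaStructure("gg", "GG", np.array([[0, 0, 0], [0.5, 0, 0]]))
        f_ms = cu.contact_frequency([s1], kind="MS")
        f_ss = cu.contact_frequency([s2], kind="SS")
        ratio = cu.ms_frequency_ratio(f_ms, f_ss)
        assert ratio[("A", "A")] == 2.0       # only in MS
        assert ratio[("G", "G")] == 0.0       # only in SS
        assert np.isnan(ratio[("C", "C")])    # in neither

    def test_hand_arithmetic(self):
        sa = CaStructure("m", "AAG",
                         np.array([[0, 0, 0], [0.5, 0, 0], [0.9, 0, 0]]))
        sb = CaStructure("s", "AAG",
                         np.array([[0, 0, 0], [0.5, 0, 0], [5.0, 0, 0]]))
        f_ms = cu.contact_frequency([sa], kind="MS")
        f_ss = cu.contact_frequency([sb], kind="SS")
        # MS: AA pair 0.5 (1/4... wait squared) -> N=1/(2*2); AG at 0.4 and 0.9
        assert f_ms.F[("A", "A")] == pytest.approx(0.25)
        assert f_ms.F[("A", "G")] == pytest.approx(2 / (2 * 1))
        assert f_ss.F[("A", "G")] == 0.0
        r = cu.ms_frequency_ratio(f_ms, f_ss)
        assert r[("A", "A")] == pytest.approx(
            2 * 0.25 / (0.25 + 0.25))
        assert r[("A", "G")] == 2.0


class TestChangedContactFrequency:
    def test_shrinking_pair_counts(self):
        a = CaStructure("a", "AAAAE",
                        np.array([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0],
                                  [1.14, 0, 0], [1.2, 0.4, 0]]))
        b = CaStructure("b", "AAAAE",
                        np.array([[0, 0, 0], [0.38, 0, 0], [0.76, 0, 0],
                                  [1.14, 0, 0], [0.55, 0.3, 0]]))
        pair = StatePair("p", a, b,
                         residue_map=tuple((i, i) for i in range(5)))
        stats = cu.changed_contact_frequency([pair])
        assert stats.F[("A", "E")] > 0

    def test_small_changes_all_zero(self, toy60):
        pair = _dup_pair(toy60.pair.state_a)
        stats = cu.changed_contact_frequency([pair])
        assert all(v == 0 for v in stats.F.values())

    def test_matches_brute_force(self, toy40, toy64):
        dataset = [toy40.pair, toy64.pair]
        stats = cu.changed_contact_frequency(dataset)
        acc = {pq: 0.0 for pq in cu.CONTACT_TYPES}
        for pair in dataset:
            seq = pair.state_a.sequence
            ca, cb = pair.mapped_coords()
            n = len(seq)
            counts = {}
            for i in range(n):
                for j in range(i + 1, n):
                    da = np.linalg.norm(ca[i] - ca[j])
                    db = np.linalg.norm(cb[i] - cb[j])
                    if abs(db - da) >= 0.5:
                        key = tuple(sorted((seq[i], seq[j])))
                        counts[key] = counts.get(key, 0) + 1
            for (p, q), npq in counts.items():
                acc[(p, q)] += npq / (seq.count(p) * seq.count(q))
        for pq in cu.CONTACT_TYPES:
            assert stats.F[pq] == pytest.approx(acc[pq] / 2, rel=1e-12)


class TestSequenceIdentity:
    def test_identical(self):
        assert cu.sequence_identity("ACDEFG", "ACDEFG") == 1.0

    def test_half(self):
        assert cu.sequence_identity("AAAA", "AAGG") == pytest.approx(0.5)

    def test_make_state_pair_maps_all_identical(self, toy60):
        pair = cu.make_state_pair(toy60.pair.state_a, toy60.pair.state_b)
        assert len(pair.residue_map) == 60
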