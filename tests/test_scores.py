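import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spanr import (
    Atom, ContactSet, PotentialContact, ProteinStructure, ScoringParams,
    contact_score, distance_score, max_long_range_pairs, product_map_export,
    read_product_map, shift_weight,
)


def brute_pair_count(n, min_sep=5):
    return sum(1 for i in range(1, n + 1) for j in range(i + 1, n + 1)
               if j - i >= min_sep)


@pytest.mark.parametrize("n,expected", [(10, 15), (5, 0), (6, 1), (1, 0)])
def test_max_long_range_pairs_examples(n, expected):
    assert max_long_range_pairs(n) == expected


def test_max_long_range_pairs_matches_enumeration():
    for n in range(1, 201):
        assert max_long_range_pairs(n) == brute_pair_count(n)
    for min_sep in (1, 2, 3, 7):
        for n in range(1, 60):
            assert max_long_range_pairs(n, min_sep) == brute_pair_count(n, min_sep)


def test_shift_weight_closed_form():
    assert shift_weight(0.0, 0.03) == 1.0
    assert shift_weight(0.03, 0.03) == 0.0
    assert shift_weight(0.015, 0.03) == pytest.approx(0.5)
    assert shift_weight(0.1, 0.03) == 0.0  # clamped past the ramp
    assert shift_weight(0.03, 0.03, mode="gaussian") == pytest.approx(np.exp(-1))
    with pytest.raises(ValueError):
        shift_weight(0.01, 0.0)


def _chain(positions):
    return ProteinStructure([Atom(i, "ALA", "CA", "C", p)
                             for i, p in positions.items()])


def _single_contact_set(i, j, delta_pc=0.0, n_resi=10):
    return ContactSet(by_peak={0: [PotentialContact(0, i, j, "HB", delta_pc)]},
                      n_resi=n_resi)


@pytest.fixture
def ten_residue_chain():
    # residues far apart except the (1, 7) pair at 8 A
    positions = {i: [100.0 * i, 0.0, 0.0] for i in range(1, 11)}
    positions[7] = [positions[1][0] + 8.0, 0.0, 0.0]
    return _chain(positions)


class TestContactScore:
    def test_no_long_range_contacts(self, ten_residue_chain):
        res = contact_score(_single_contact_set(1, 3), ten_residue_chain)
        assert res.cs == 0.0
        assert not res.product_map.any()

    def test_single_supported_contact(self, ten_residue_chain):
        res = contact_score(_single_contact_set(1, 7), ten_residue_chain)
        assert res.n_max_pairs == 15
        assert res.cs == pytest.approx(1 / 15)
        nz = np.argwhere(res.product_map > 0)
        assert {tuple(r) for r in nz} == {(0, 6), (6, 0)}

    def test_contact_beyond_threshold_ignored(self, ten_residue_chain):
        params = ScoringParams(eps_cs=7.0)
        res = contact_score(_single_contact_set(1, 7), ten_residue_chain, params)
        assert res.cs == 0.0

    def test_upper_bound_all_pairs_supported(self):
        # 6 residues in a tight cluster: every pair within eps_cs
        s = _chain({i: [0.1 * i, 0, 0] for i in range(1, 7)})
        contacts = ContactSet(by_peak={0: [
            PotentialContact(0, i, j, "HB", 0.0)
            for i in range(1, 7) for j in range(i + 1, 7) if j - i >= 5]},
            n_resi=6)
        res = contact_score(contacts, s)
        assert res.cs == pytest.approx(1.0)

    def test_per_pair_max_caps_at_one(self, ten_residue_chain):
        contacts = ContactSet(by_peak={
            0: [PotentialContact(0, 1, 7, "HB", 0.0)],
            1: [PotentialContact(1, 1, 7, "HB", 0.01)],
        }, n_resi=10)
        res = contact_score(contacts, ten_residue_chain)
        assert res.cs == pytest.approx(1 / 15)  # max weight, not the sum

    def test_missing_residue_is_error(self, ten_residue_chain):
        with pytest.raises(KeyError, match="11"):
            contact_score(_single_contact_set(1, 11, n_resi=12),
                          ten_residue_chain)

    def test_monotone_in_eps_cs(self, corpus300):
        entry = corpus300[0]
        high = contact_score(entry.contacts, entry.decoy, ScoringParams(eps_cs=14)).cs
        low = contact_score(entry.contacts, entry.decoy, ScoringParams(eps_cs=8)).cs
        assert low <= high


class TestDistanceScore:
    def test_all_explained(self, ten_residue_chain):
        res = distance_score(_single_contact_set(1, 7), ten_residue_chain)
        assert res.ds == 0.0 and res.n_considered == 1

    def test_fraction(self, ten_residue_chain):
        by_peak = {
            0: [PotentialContact(0, 1, 7, "HB", 0.0)],   # 8 A: explained
            1: [PotentialContact(1, 1, 8, "HB", 0.0)],   # far: unexplained
            2: [PotentialContact(2, 1, 7, "HB", 0.0)],
            3: [PotentialContact(3, 1, 7, "HB", 0.0)],
        }
        res = distance_score(ContactSet(by_peak=by_peak, n_resi=10),
                             ten_residue_chain)
        assert res.n_considered == 4
        assert res.ds == pytest.approx(0.25)
        assert res.unexplained_peak_ids == [1]

    def test_short_range_explainable_peak_excluded(self, ten_residue_chain):
        by_peak = {0: [PotentialContact(0, 1, 2, "HB", 0.0),
                       PotentialContact(0, 1, 8, "HB", 0.0)]}
        res = distance_score(ContactSet(by_peak=by_peak, n_resi=10),
                             ten_residue_chain)
        assert res.n_considered == 0 and res.ds is None

    def test_zero_considered_is_undefined_not_zero(self, ten_residue_chain):
        res = distance_score(_single_contact_set(1, 3), ten_residue_chain)
        assert res.ds is None

    def test_monotone_in_eps_d(self, corpus300):
        entry = corpus300[1]
        loose = distance_score(entry.contacts, entry.decoy, ScoringParams(eps_d=14)).ds
        tight = distance_score(entry.contacts, entry.decoy, ScoringParams(eps_d=6)).ds
        assert (loose or 0.0) <= (tight or 0.0)


def test_truth_explains_its_own_peaks(corpus300):
    # peaks were simulated from the truth with r_max = 6 A < eps_d = 10 A
    entry = corpus300[2]
    res = distance_score(entry.contacts, entry.truth)
    assert res.ds == 0.0


def test_scores_bounded_on_corpus(corpus300):
    for entry in corpus300[:40]:
        cs = contact_score(entry.contacts, entry.decoy).cs
        ds = distance_score(entry.contacts, entry.decoy).ds
        assert 0.0 <= cs <= 1.0
        assert ds is None or 0.0 <= ds <= 1.0


def test_product_map_round_trip(tmp_path, ten_residue_chain):
    res = contact_score(_single_contact_set(1, 7), ten_residue_chain)
    path = tmp_path / "map.tsv"
    product_map_export(res, path)
    back = read_product_map(path)
    assert np.allclose(back, res.product_map, atol=1e-6)
    assert np.allclose(back, back.T)


def test_params_validation():
    with pytest.raises(ValueError):
        ScoringParams(eps_cs=-1)
    with pytest.raises(ValueError):
        ScoringParams(contact_mode="nope")


def test_hh_mode_uses_hydrogen_distances(hairpin20, hairpin20_contacts):
    ca = contact_score(hairpin20_contacts, hairpin20,
                       ScoringParams(contact_mode="ca"))
    hh = contact_score(hairpin20_contacts, hairpin20,
                       ScoringParams(contact_mode="hh"))
    # both well-defined and bounded; generally different values
    assert 0 <= ca.cs <= 1 and 0 <= hh.cs <= 1
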