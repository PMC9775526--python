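"""Amplitude restoration: bank selection frequencies, SMOTE segment
geometry, ordering preservation, stage segregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepgan.restore import FactorBank, restore_random, restore_smote, smote_factors
from sleepgan.signal import Epoch, NormalizationFactors, NormalizedEpoch


def make_bank(triples, stage="N2"):
    bank = FactorBank(stage=stage)
    bank.entries = [NormalizationFactors(*t) for t in triples]
    return bank


def test_bank_from_epochs_records_factors(fixture_set):
    bank = FactorBank.from_epochs(fixture_set["N3"])
    assert bank.stage == "N3" and len(bank) == len(fixture_set["N3"])
    for f, e in zip(bank.entries, fixture_set["N3"]):
        assert f.mean == pytest.approx(e.samples.mean())
        assert f.max == pytest.approx(e.samples.max())


def test_single_entry_bank_is_forced_choice():
    bank = make_bank([(1.0, 3.0, 0.0)])
    norm = NormalizedEpoch([-0.5, -0.5, 1.0], "N2")
    for seed in range(5):
        np.testing.assert_allclose(restore_random(norm, bank, seed).samples, [0.0, 0.0, 3.0])


def test_zeros_epoch_restores_to_entry_mean():
    bank = make_bank([(5.0, 9.0, 2.0)])
    out = restore_random(NormalizedEpoch(np.zeros(8), "N2"), bank, 0)
    np.testing.assert_array_equal(out.samples, np.full(8, 5.0))


def test_random_restore_selection_is_uniform():
    bank = make_bank([(0, 1, -1), (10, 11, 9), (20, 21, 19), (30, 31, 29)])
    norm = NormalizedEpoch(np.zeros(4), "N2")
    means = [restore_random(norm, bank, s).samples[0] for s in range(10000)]
    freqs = np.array([np.mean(np.asarray(means) == m) for m in (0, 10, 20, 30)])
    assert np.abs(freqs - 0.25).max() < 0.02


def test_restore_rejects_empty_bank_and_stage_mismatch():
    with pytest.raises(ValueError, match="empty"):
        restore_random(NormalizedEpoch(np.zeros(4), "N2"), FactorBank("N2"), 0)
    bank = make_bank([(1.0, 3.0, 0.0)], stage="W")
    with pytest.raises(ValueError, match="mismatch"):
        restore_random(NormalizedEpoch(np.zeros(4), "N2"), bank, 0)


def test_bank_rejects_mixed_stages():
    with pytest.raises(ValueError, match="mixed"):
        FactorBank.from_epochs([Epoch([0.0, 1.0], "W"), Epoch([0.0, 1.0], "N1")])


# --------------------------------------------------------------------- SMOTE
def test_smote_identical_entries_reproduce_them():
    bank = make_bank([(1.0, 2.0, 0.0), (1.0, 2.0, 0.0)])
    for s in smote_factors(bank, k_neighbors=1, n_new=10, seed=0):
        assert (s.factors.mean, s.factors.max, s.factors.min) == (1.0, 2.0, 0.0)


def test_smote_midpoint_hand_example():
    a, b = (0.0, 1.0, -1.0), (2.0, 3.0, 1.0)
    f = NormalizationFactors(*a)
    g = NormalizationFactors(*b)
    mid = f.as_array() + 0.5 * (g.as_array() - f.as_array())
    np.testing.assert_array_equal(mid, [1.0, 2.0, 0.0])


def test_smote_outputs_lie_on_parent_segments():
    rng = np.random.default_rng(0)
    means = rng.uniform(-5, 5, 10)
    triples = [(m, m + rng.uniform(1, 3), m - rng.uniform(1, 3)) for m in means]
    bank = make_bank(triples)
    for s in smote_factors(bank, k_neighbors=3, n_new=1000, seed=1):
        expected = s.parent_a.as_array() + s.lam * (
            s.parent_b.as_array() - s.parent_a.as_array()
        )
        np.testing.assert_allclose(s.factors.as_array(), expected, atol=1e-12)
        assert s.factors.min <= s.factors.mean <= s.factors.max


def test_smote_rejects_small_bank():
    bank = make_bank([(0, 1, -1), (1, 2, 0)])
    with pytest.raises(ValueError, match="too small"):
        smote_factors(bank, k_neighbors=2, n_new=1)


def test_smote_neighbors_are_nearest_in_factor_space():
    """With k=1 each synthesized set interpolates towards the true nearest
    neighbour of its first parent."""
    bank = make_bank([(0, 1, -1), (0.1, 1.1, -0.9), (50, 51, 49)])
    for s in smote_factors(bank, k_neighbors=1, n_new=50, seed=2):
        a = s.parent_a.as_array()
        b = s.parent_b.as_array()
        others = [e.as_array() for e in bank.entries if not np.array_equal(e.as_array(), a)]
        dists = [np.linalg.norm(o - a) for o in others]
        assert np.linalg.norm(b - a) == pytest.approx(min(dists))


def test_restore_smote_determinism_and_segment_geometry():
    bank = make_bank([(0.0, 1.0, -1.0), (4.0, 6.0, 2.0)])
    norm = NormalizedEpoch(np.array([-1.0, 0.0, 1.0]), "N2")
    a = restore_smote(norm, bank, k_neighbors=1, seed=9)
    b = restore_smote(norm, bank, k_neighbors=1, seed=9)
    np.testing.assert_array_equal(a.samples, b.samples)
    # restored mean must lie between the two entry means
    assert 0.0 - 1e-12 <= a.samples.mean() <= 4.0 + 1e-12


def test_restored_extrema_match_applied_factors():
    """A zero-mean normalized epoch attaining both +-1 maps its extrema
    exactly onto mean +- scale of the applied factor set."""
    bank = make_bank([(2.0, 5.0, -1.0)])  # symmetric: scale = 3 both sides
    norm = NormalizedEpoch(np.array([-1.0, 0.0, 1.0]), "N2")
    out = restore_random(norm, bank, 0)
    assert out.samples.mean() == pytest.approx(2.0)
    assert out.samples.max() == pytest.approx(5.0)
    assert out.samples.min() == pytest.approx(-1.0)


@settings(max_examples=100, deadline=None)
@given(
    lam=st.floats(0, 1),
    a=st.tuples(st.floats(-50, 50), st.floats(0.1, 50), st.floats(0.1, 50)),
    b=st.tuples(st.floats(-50, 50), st.floats(0.1, 50), st.floats(0.1, 50)),
)
def test_interpolation_preserves_factor_ordering(lam, a, b):
    """min <= mean <= max survives convex combination of valid triples."""
    fa = NormalizationFactors(a[0], a[0] + a[1], a[0] - a[2])
    fb = NormalizationFactors(b[0], b[0] + b[1], b[0] - b[2])
    mixed = fa.as_array() + lam * (fb.as_array() - fa.as_array())
    m, mx, mn = mixed
    assert mn <= m <= mx
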