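import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nwatch.ring import (
    BaselineProfileParams,
    BeadSpec,
    RingField,
    apply_bead,
    apply_design,
    config_dump,
    config_load,
    make_baseline,
    ring_distance,
)


class TestRingDistance:
    @pytest.mark.parametrize(
        "i,j,n,expected",
        [(0, 0, 600, 0), (0, 300, 600, 300), (599, 0, 600, 1), (10, 590, 600, 20)],
    )
    def test_known_distances(self, i, j, n, expected):
        assert ring_distance(i, j, n) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            ring_distance(0, 600, 600)

    @given(
        st.integers(0, 599), st.integers(0, 599)
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, i, j):
        d = ring_distance(i, j, 600)
        assert d == ring_distance(j, i, 600)
        assert 0 <= d <= 300


class TestBaseline:
    def test_profile_extrema(self):
        p = BaselineProfileParams()
        field = make_baseline(p, 600)
        assert field.V[0] == pytest.approx(p.inducer_amplitude)
        assert field.B[0] == pytest.approx(p.inhibitor_min)
        assert field.B[300] == pytest.approx(p.inhibitor_max)
        assert np.argmax(field.V) == 0
        assert np.argmax(field.B) == 300

    def test_gaussian_value_one_sigma_out(self):
        field = make_baseline(
            BaselineProfileParams(inducer_sigma=40, inducer_amplitude=1.0), 600
        )
        assert field.V[40] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BaselineProfileParams(inducer_sigma=-1)
        with pytest.raises(ValueError):
            BaselineProfileParams(inhibitor_min=2.0, inhibitor_max=1.0)


class TestBeads:
    def test_zero_concentration_is_identity(self, baseline_field):
        bead = BeadSpec("inducer_source", center=300, concentration=0.0)
        out = apply_bead(baseline_field, bead)
        np.testing.assert_array_equal(out.V, baseline_field.V)
        np.testing.assert_array_equal(out.B, baseline_field.B)

    def test_neutral_bead_is_identity(self, baseline_field):
        bead = BeadSpec("neutral", center=300, concentration=5.0)
        out = apply_bead(baseline_field, bead)
        np.testing.assert_array_equal(out.V, baseline_field.V)

    def test_plateau_and_exponential_tail(self):
        field = RingField.zeros(600)
        bead = BeadSpec(
            "inducer_source", center=300, width=11, concentration=1.0, spread=5.0
        )
        out = apply_bead(field, bead)
        # constant core across the footprint
        np.testing.assert_allclose(out.V[295:306], 1.0)
        # 5 cells beyond the footprint edge: exp(-1)
        assert out.V[310] == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert out.V[290] == pytest.approx(np.exp(-1.0), rel=1e-12)
        # untouched inhibitor
        np.testing.assert_array_equal(out.B, field.B)

    def test_antagonist_subtracts_and_clamps(self, baseline_field):
        bead = BeadSpec(
            "inhibitor_antagonist", center=300, width=9, concentration=50.0, spread=3.0
        )
        out = apply_bead(baseline_field, bead)
        assert out.B[300] == 0.0
        assert np.all(out.B >= 0)
        # original untouched
        assert baseline_field.B[300] > 0

    def test_invalid_beads_rejected(self):
        with pytest.raises(ValueError):
            BeadSpec("mystery", center=0)
        with pytest.raises(ValueError):
            BeadSpec("neutral", center=0, width=4)
        with pytest.raises(ValueError):
            BeadSpec("neutral", center=0, spread=0)


class TestApplyDesign:
    def test_empty_design_is_identity(self, baseline_field):
        out = apply_design(baseline_field, [])
        np.testing.assert_array_equal(out.V, baseline_field.V)

    def test_two_identical_beads_double_the_delta(self):
        field = RingField.zeros(50)
        bead = BeadSpec("inducer_source", center=25, width=5, concentration=1.0, spread=2.0)
        one = apply_bead(field, bead)
        two = apply_design(field, [bead, bead])
        np.testing.assert_allclose(two.V, 2 * one.V)

    def test_additivity_matches_brute_force(self, rng):
        """Summed per-cell deltas equal sequential bead application (pre-clamp)."""
        n = 50
        field = RingField(n, rng.uniform(0, 1, n), rng.uniform(0, 1, n))
        beads = [
            BeadSpec(
                compound=str(rng.choice(["inducer_source", "inhibitor_source"])),
                center=int(rng.integers(0, n)),
                width=int(rng.choice([1, 3, 5])),
                concentration=float(rng.uniform(0, 2)),
                spread=float(rng.uniform(0.5, 5)),
            )
            for _ in range(4)
        ]
        expected_V = field.V.copy()
        expected_B = field.B.copy()
        for b in beads:
            delta = np.array(
                [
                    b.concentration
                    * np.exp(-max(ring_distance(i, b.center, n) - b.width // 2, 0) / b.spread)
                    for i in range(n)
                ]
            )
            if b.compound == "inducer_source":
                expected_V += delta
            else:
                expected_B += delta
        out = apply_design(field, beads)
        np.testing.assert_allclose(out.V, np.maximum(expected_V, 0), rtol=1e-12)
        np.testing.assert_allclose(out.B, np.maximum(expected_B, 0), rtol=1e-12)

    def test_rotation_equivariance(self):
        """Rotating all bead centers by k rotates the output field by k."""
        field = RingField.zeros(60)
        beads = [
            BeadSpec("inducer_source", center=10, width=3, concentration=1.0, spread=4.0),
            BeadSpec("inhibitor_source", center=30, width=5, concentration=0.5, spread=2.0),
        ]
        k = 17
        rotated = [
            BeadSpec(b.compound, (b.center + k) % 60, b.width, b.concentration, b.spread)
            for b in beads
        ]
        out = apply_design(field, beads)
        out_rot = apply_design(field, rotated)
        np.testing.assert_allclose(np.roll(out.V, k), out_rot.V)
        np.testing.assert_allclose(np.roll(out.B, k), out_rot.B)

    def test_mirror_symmetric_design_gives_symmetric_field(self, baseline_field):
        beads = [
            BeadSpec("inducer_source", center=280, width=9, concentration=1.0, spread=5.0),
            BeadSpec("inducer_source", center=320, width=9, concentration=1.0, spread=5.0),
        ]
        out = apply_design(baseline_field, beads)
        # mirror cell i -> (600 - i) % 600 fixes the posterior/anterior axis
        mirrored = out.V[(600 - np.arange(600)) % 600]
        np.testing.assert_allclose(out.V, mirrored, atol=1e-12)


def test_config_round_trip():
    baseline = BaselineProfileParams(inducer_sigma=33.5, inhibitor_min=0.25)
    beads = [
        BeadSpec("inducer_source", center=280, width=9, concentration=1.25, spread=5.5),
        BeadSpec("neutral", center=300, width=27, concentration=1.0, spread=5.0),
    ]
    text = config_dump(600, baseline, beads)
    n_cells, baseline2, beads2 = config_load(io.StringIO(text))
    assert n_cells == 600
    assert baseline2 == baseline
    assert beads2 == beads
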