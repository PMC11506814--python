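"""Geometric correctness of the Glass-pattern / mRDK generators."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vplearn._angles import axial_mean_sd, axial_resultant_length, wrap_axial
from vplearn.stimuli import (
    AnnulusGeometry,
    ENStimulusSpec,
    GPSpec,
    MRDKSpec,
    StimulusSpecError,
    generate_en_field,
    generate_gp_frame,
    generate_gp_sequence,
    generate_mrdk_sequence,
    n_signal_elements,
    render_frame,
    sequence_to_dataframe,
    spec_from_yaml,
    spec_to_yaml,
)


def radii(points):
    return np.hypot(points[..., 0], points[..., 1])


class TestGPFrame:
    def test_default_full_coherence(self, rng):
        frame = generate_gp_frame(GPSpec(coherence=1.0), rng)
        assert frame.n_elements == 250
        assert frame.is_signal.all()
        assert np.allclose(frame.element_orientations_or_directions, 0.0)

    def test_signal_count_rounding(self, rng):
        frame = generate_gp_frame(GPSpec(coherence=0.4), rng)
        assert frame.is_signal.sum() == 100

    @pytest.mark.parametrize("coherence", np.round(np.arange(0, 1.01, 0.07), 2).tolist())
    def test_signal_count_on_grid(self, coherence):
        assert n_signal_elements(coherence, 250) == int(np.floor(coherence * 250 + 0.5))

    def test_dipole_separation_and_annulus(self, rng):
        spec = GPSpec()
        frame = generate_gp_frame(spec, rng)
        gaps = np.linalg.norm(frame.dot_centers[:, 0] - frame.dot_centers[:, 1], axis=1)
        assert np.allclose(gaps, spec.dipole_separation, atol=1e-9)
        r = radii(frame.dot_centers.reshape(-1, 2))
        geometry = spec.geometry
        assert ((r >= geometry.inner_radius) & (r <= geometry.outer_radius)).all()

    def test_zero_coherence_orientations_uniform(self):
        frame = generate_gp_frame(
            GPSpec(n_dipoles=20_000, coherence=0.0), np.random.default_rng(0)
        )
        assert not frame.is_signal.any()
        # mean resultant length of doubled angles ~ 1/sqrt(n) under uniformity
        assert axial_resultant_length(
            frame.element_orientations_or_directions
        ) < 3.0 / np.sqrt(20_000)

    def test_seeded_generation_is_reproducible(self):
        a = generate_gp_frame(GPSpec(), np.random.default_rng(7))
        b = generate_gp_frame(GPSpec(), np.random.default_rng(7))
        np.testing.assert_array_equal(a.dot_centers, b.dot_centers)
        np.testing.assert_array_equal(
            a.element_orientations_or_directions, b.element_orientations_or_directions
        )

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_dipoles=0), dict(coherence=1.2), dict(coherence=-0.1),
         dict(dipole_separation=0.0), dict(frame_rate=10, frame_duration=0.2)],
    )
    def test_invalid_spec_raises(self, kwargs):
        with pytest.raises(StimulusSpecError):
            GPSpec(**kwargs)


class TestGPSequence:
    def test_duration_and_length(self, rng):
        seq = generate_gp_sequence(GPSpec(), 5, rng)
        assert len(seq) == 5
        assert seq.duration == pytest.approx(0.5)

    def test_frames_are_independent(self, rng):
        seq = generate_gp_sequence(GPSpec(), 2, rng)
        a = set(map(tuple, seq[0].element_centers.round(12)))
        b = set(map(tuple, seq[1].element_centers.round(12)))
        assert not a & b

    def test_signal_orientation_constant(self, rng):
        spec = GPSpec(coherence=0.5, signal_orientation=0.3)
        seq = generate_gp_sequence(spec, 4, rng)
        for frame in seq:
            assert np.allclose(
                frame.element_orientations_or_directions[frame.is_signal], 0.3
            )

    def test_rejects_empty_sequence(self, rng):
        with pytest.raises(StimulusSpecError):
            generate_gp_sequence(GPSpec(), 0, rng)


class TestMRDK:
    def test_default_dot_count_and_annulus(self, rng):
        spec = MRDKSpec()
        seq = generate_mrdk_sequence(spec, 4, rng)
        for frame in seq:
            assert frame.n_elements == 500
            r = radii(frame.element_centers)
            assert ((r >= spec.geometry.inner_radius) & (r <= spec.geometry.outer_radius)).all()

    def test_step_size_for_surviving_dots(self, rng):
        spec = MRDKSpec()
        seq = generate_mrdk_sequence(spec, 5, rng)
        for t in range(len(seq) - 1):
            moved = ~seq[t + 1].repositioned
            assert moved.any()
            d = np.linalg.norm(
                seq[t + 1].element_centers[moved] - seq[t].element_centers[moved], axis=1
            )
            assert np.allclose(d, spec.step_size, atol=1e-12)

    def test_signal_dots_move_along_axis(self, rng):
        spec = MRDKSpec(coherence=1.0, signal_axis=0.0)
        seq = generate_mrdk_sequence(spec, 4, rng)
        for t in range(len(seq) - 1):
            moved = ~seq[t + 1].repositioned
            dx = seq[t + 1].element_centers[moved, 0] - seq[t].element_centers[moved, 0]
            assert np.allclose(dx, 0.0, atol=1e-12)  # vertical axis: no x drift

    def test_zero_coherence_directions_uniform(self):
        seq = generate_mrdk_sequence(
            MRDKSpec(n_dots=20_000, coherence=0.0), 1, np.random.default_rng(1)
        )
        theta = seq[0].element_orientations_or_directions
        # no vertical-axis excess: axial resultant of directions ~ 0
        assert axial_resultant_length(theta) < 3.0 / np.sqrt(20_000)

    def test_lifetime_relocation(self, rng):
        seq = generate_mrdk_sequence(MRDKSpec(dot_lifetime=2), 6, rng)
        for frame in seq:
            assert frame.age.max() < 2
        # with lifetime 2 and staggered ages roughly half relocate per frame
        frac = np.mean([f.repositioned.mean() for f in seq[1:]])
        assert 0.3 < frac < 0.7


class TestENField:
    def test_zero_noise_pins_all_elements(self, rng):
        spec = ENStimulusSpec(base=GPSpec(), mean_offset=0.2, sigma_ext=0.0)
        frame = generate_en_field(spec, 1, rng)[0]
        assert frame.is_signal.all()
        assert np.allclose(frame.element_orientations_or_directions, 0.2)

    def test_axial_sample_moments(self):
        spec = ENStimulusSpec(base=GPSpec(n_dipoles=10_000), mean_offset=0.0,
                              sigma_ext=0.2)
        frame = generate_en_field(spec, 1, np.random.default_rng(2))[0]
        mean, sd = axial_mean_sd(frame.element_orientations_or_directions)
        assert abs(mean) < 3 * 0.2 / np.sqrt(10_000)
        assert sd == pytest.approx(0.2, rel=0.02)

    def test_tilted_mean_offset(self):
        spec = ENStimulusSpec(base=GPSpec(n_dipoles=10_000), mean_offset=np.pi / 4,
                              sigma_ext=0.1)
        frame = generate_en_field(spec, 1, np.random.default_rng(3))[0]
        mean, _ = axial_mean_sd(frame.element_orientations_or_directions)
        assert mean == pytest.approx(np.pi / 4, abs=3 * 0.1 / np.sqrt(10_000))

    def test_mrdk_base_supported(self, rng):
        spec = ENStimulusSpec(base=MRDKSpec(n_dots=200), sigma_ext=0.3)
        seq = generate_en_field(spec, 3, rng)
        assert all(f.is_signal.all() for f in seq)

    def test_rejects_partial_coherence_base(self):
        with pytest.raises(StimulusSpecError):
            ENStimulusSpec(base=GPSpec(coherence=0.5), sigma_ext=0.1)


class TestRender:
    def test_empty_frame_is_uniform_gray(self):
        from vplearn.stimuli import StimulusFrame

        frame = StimulusFrame(
            element_centers=np.empty((0, 2)),
            element_orientations_or_directions=np.empty(0),
            is_signal=np.empty(0, dtype=bool),
            kind="mrdk",
        )
        image = render_frame(frame, pixels_per_degree=20, image_size=64)
        assert (image == 128).all()

    def test_single_dot_locality_and_determinism(self):
        from vplearn.stimuli import StimulusFrame

        frame = StimulusFrame(
            element_centers=np.array([[0.0, 0.0]]),
            element_orientations_or_directions=np.zeros(1),
            is_signal=np.ones(1, dtype=bool),
            kind="mrdk",
        )
        image = render_frame(frame, pixels_per_degree=24, image_size=65)
        rows, cols = np.nonzero(image == 255)
        assert len(rows) > 0
        assert np.ptp(rows) <= 3 and np.ptp(cols) <= 3
        assert abs(rows.mean() - 32) < 2 and abs(cols.mean() - 32) < 2
        again = render_frame(frame, pixels_per_degree=24, image_size=65)
        np.testing.assert_array_equal(image, again)

    def test_frame_exceeding_image_raises(self, rng):
        frame = generate_gp_frame(GPSpec(), rng)
        with pytest.raises(ValueError):
            render_frame(frame, pixels_per_degree=100, image_size=64)


class TestSerialization:
    @pytest.mark.parametrize(
        "spec",
        [GPSpec(coherence=0.25), MRDKSpec(n_dots=42),
         ENStimulusSpec(base=GPSpec(), mean_offset=0.1, sigma_ext=0.2)],
    )
    def test_yaml_round_trip(self, spec):
        assert spec_from_yaml(spec_to_yaml(spec)) == spec

    def test_geometry_export_schema(self, rng):
        df = sequence_to_dataframe(generate_gp_sequence(GPSpec(n_dipoles=5), 2, rng))
        assert list(df.columns) == ["frame", "element_id", "x_deg", "y_deg",
                                    "theta_rad", "is_signal"]
        assert len(df) == 2 * 5 * 2  # two dots per dipole


@settings(max_examples=25, deadline=None, derandomize=True)
@given(theta=st.floats(-10, 10, allow_nan=False))
def test_wrap_axial_domain_and_equivalence(theta):
    w = wrap_axial(theta)
    assert -np.pi / 2 < w <= np.pi / 2
    # same axis: doubled angles agree
    assert np.exp(2j * w) == pytest.approx(np.exp(2j * theta), abs=1e-9)
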