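"""HOG descriptors: gradient conventions, vote interpolation, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beakid import hog
from beakid.errors import InvalidParameterError


def naive_hog(gray, cell=16, bins=9, block=2, stride=1):
    """Per-pixel double-loop reference implementation, kept deliberately
    independent of the vectorised code path."""
    gray = np.asarray(gray, dtype=float)
    h, w = gray.shape
    cy, cx = h // cell, w // cell
    hists = np.zeros((cy, cx, bins))
    bin_w = 180.0 / bins
    for y in range(cy * cell):
        for x in range(cx * cell):
            xm, xp = max(x - 1, 0), min(x + 1, w - 1)
            ym, yp = max(y - 1, 0), min(y + 1, h - 1)
            gx = gray[y, xp] - gray[y, xm]
            gy = gray[yp, x] - gray[ym, x]
            mag = np.hypot(gx, gy)
            theta = np.degrees(np.arctan2(gy, gx)) % 180.0 if mag > 0 else 0.0
            t = theta / bin_w
            lo = int(np.floor(t)) % bins
            frac = t - np.floor(t)
            hists[y // cell, x // cell, lo] += mag * (1 - frac)
            hists[y // cell, x // cell, (lo + 1) % bins] += mag * frac
    out = []
    for by in range(0, cy - block + 1, stride):
        for bx in range(0, cx - block + 1, stride):
            vec = hists[by : by + block, bx : bx + block].reshape(-1)
            n = np.linalg.norm(vec)
            out.append(vec / n if n > 0 else vec)
    return np.concatenate(out)


class TestGradients:
    def test_three_four_five_magnitude(self):
        # columns step by 1.5 -> Gx = 3; rows step by 2 -> Gy = 4
        y, x = np.mgrid[0:6, 0:6]
        field = hog.gradients(2.0 * y + 1.5 * x)
        assert field.magnitude[2, 2] == pytest.approx(5.0)

    def test_constant_image_zero_everywhere(self):
        field = hog.gradients(np.full((8, 8), 9.0))
        assert not field.magnitude.any()
        assert not field.orientation.any()

    def test_vertical_step_edge_is_zero_degrees(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 100.0
        field = hog.gradients(img)
        edge = field.magnitude > 0
        assert edge.any()
        assert np.allclose(field.orientation[edge], 0.0)

    def test_printed_orientation_toggle_transposes_ratio(self):
        img = np.add.outer(np.arange(8.0) * 3, np.arange(8.0))  # Gy=6, Gx=2
        std = hog.gradients(img).orientation[3, 3]
        printed = hog.gradients(img, as_printed=True).orientation[3, 3]
        assert std == pytest.approx(np.degrees(np.arctan2(6, 2)))
        assert printed == pytest.approx(np.degrees(np.arctan2(2, 6)))

    def test_degenerate_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            hog.gradients(np.zeros((2, 8)))


class TestCellHistograms:
    def test_study_resolution_cell_grid(self):
        assert hog.cell_grid_shape((299, 532), hog.HogParams()) == (2, 4)

    def test_bin_centre_votes_do_not_leak(self):
        """Gradients exactly at the 40-degree bin centre land wholly in bin 2."""
        theta = np.full((16, 16), 40.0)
        mag = np.ones((16, 16))
        field = hog.GradientField(gx=mag, gy=mag, magnitude=mag, orientation=theta)
        hists = hog.cell_histograms(field, hog.HogParams(cell_size=16))
        assert hists[0, 0, 2] == pytest.approx(256.0)
        assert hists[0, 0].sum() == pytest.approx(256.0)

    def test_linear_vote_split_between_adjacent_bins(self):
        theta = np.zeros((16, 16))
        mag = np.zeros((16, 16))
        theta[5, 5], mag[5, 5] = 30.0, 10.0
        field = hog.GradientField(gx=mag, gy=mag, magnitude=mag, orientation=theta)
        hists = hog.cell_histograms(field, hog.HogParams(cell_size=16))
        assert hists[0, 0, 1] == pytest.approx(5.0)
        assert hists[0, 0, 2] == pytest.approx(5.0)

    def test_vote_mass_conserved(self, rng):
        """Sum of all histogram entries equals total gradient magnitude over
        the retained (full-cell) pixels."""
        img = rng.uniform(0, 255, size=(70, 90))
        field = hog.gradients(img)
        params = hog.HogParams(cell_size=32)
        hists = hog.cell_histograms(field, params)
        assert hists.sum() == pytest.approx(field.magnitude[:64, :64].sum())

    def test_image_smaller_than_cell_rejected(self):
        field = hog.gradients(np.zeros((16, 16)))
        with pytest.raises(InvalidParameterError):
            hog.cell_histograms(field, hog.HogParams(cell_size=64))


class TestDescriptor:
    def test_study_geometry_has_108_features(self, rng):
        img = rng.uniform(0, 255, size=(299, 532))
        assert len(hog.hog_descriptor(img)) == 108

    def test_wider_image_has_144_features(self, rng):
        img = rng.uniform(0, 255, size=(256, 640))
        assert len(hog.hog_descriptor(img)) == 144

    def test_constant_image_gives_zero_descriptor(self):
        d = hog.hog_descriptor(np.full((299, 532), 7.0))
        assert not d.any()

    def test_blocks_have_unit_norm_or_zero(self, rng):
        d = hog.hog_descriptor(rng.uniform(0, 255, size=(299, 532)))
        norms = np.linalg.norm(d.reshape(-1, 36), axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))
        assert np.all(d >= 0)

    def test_matches_naive_oracle(self, rng):
        params = hog.HogParams(cell_size=16)
        for _ in range(3):
            img = rng.uniform(0, 255, size=rng.integers(33, 65, size=2))
            fast = hog.hog_descriptor(img, params)
            slow = naive_hog(img, cell=16)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(w=st.integers(32, 200), h=st.integers(32, 200))
    def test_length_formula(self, w, h):
        params = hog.HogParams(cell_size=16)
        expected = (w // 16 - 1) * (h // 16 - 1) * 36
        img = np.add.outer(np.arange(h, dtype=float), np.arange(w, dtype=float))
        assert len(hog.hog_descriptor(img, params)) == expected

    def test_unsigned_bins_invariant_to_180_degree_rotation(self):
        yy, xx = np.mgrid[:128, :128]
        disc = (((xx - 63.5) ** 2 + (yy - 63.5) ** 2) <= 40**2).astype(float) * 200
        params = hog.HogParams(cell_size=64)
        d = hog.hog_descriptor(disc, params)
        d_rot = hog.hog_descriptor(np.rot90(disc, 2), params)
        np.testing.assert_allclose(d, d_rot, atol=1e-9)


class TestColourHog:
    def test_equal_channels_match_grey_descriptor(self, rng):
        gray = rng.uniform(0, 255, size=(96, 96))
        img = np.stack([gray] * 3, axis=-1)
        params = hog.HogParams(cell_size=32)
        np.testing.assert_allclose(
            hog.colour_hog_descriptor(img, params), hog.hog_descriptor(gray, params), rtol=1e-12
        )

    def test_study_resolution_length_108(self, rng):
        img = rng.uniform(0, 255, size=(299, 532, 3))
        assert len(hog.colour_hog_descriptor(img)) == 108

    def test_constant_colour_image_gives_zeros(self):
        img = np.full((299, 532, 3), 120.0)
        assert not hog.colour_hog_descriptor(img).any()

    def test_dominant_channel_supplies_the_vote(self):
        """With a strong edge only in the green channel, the colour HOG
        equals the grey HOG of that channel alone."""
        img = np.full((64, 64, 3), 50.0)
        img[:, 32:, 1] = 250.0
        params = hog.HogParams(cell_size=32)
        np.testing.assert_allclose(
            hog.colour_hog_descriptor(img, params),
            hog.hog_descriptor(img[..., 1], params),
            rtol=1e-12,
        )
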