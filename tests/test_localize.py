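"""Localization: detection, Gaussian fitting, matching, fingerprint tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from nanobarcode.localize import (
    FEATURE_COLUMNS,
    Localization,
    LocalizeParams,
    build_feature_table,
    detect_spots,
    fit_gaussian,
    match_localizations,
    merge_channels,
)
from nanobarcode.optics import default_optical_model
from nanobarcode.scheme import CHANNEL_NAMES, barcode_from_id, enumerate_barcodes
from nanobarcode.simulate import (
    DEFAULT_PIXEL_SIZE_NM as PX,
    FOVImage,
    HeterogeneityParams,
    _pixel_integrated_gaussian,
    generate_dataset,
    render_fov,
    sample_particle,
)


def psf_image(shape, x_px, y_px, sigma_nm, total, bg=105.0, rng=None, read_sd=2.0):
    """Render a single pixel-integrated PSF with optional camera noise."""
    img = np.full(shape, float(bg))
    patch, sl = _pixel_integrated_gaussian(shape, x_px * PX, y_px * PX, sigma_nm, total, PX)
    img[sl] += patch
    if rng is not None:
        img = rng.poisson(img).astype(float) + rng.normal(0, read_sd, img.shape)
    return img


class TestMerge:
    def test_zero_and_single_plane(self):
        zero = FOVImage(np.zeros((6, 8, 8), dtype=np.uint16))
        assert np.all(merge_channels(zero) == 0)
        planes = np.zeros((6, 8, 8), dtype=np.uint16)
        planes[2, 3, 4] = 7
        one = FOVImage(planes)
        assert np.array_equal(merge_channels(one), planes[2].astype(float))

    def test_linearity_without_clipping(self):
        rng = np.random.default_rng(0)
        planes = rng.integers(0, 60000, size=(6, 16, 16)).astype(np.uint16)
        merged = merge_channels(FOVImage(planes))
        assert merged.sum() == planes.astype(np.int64).sum()
        assert merged.max() >= 65535  # exceeded 16-bit: wider accumulator


class TestDetect:
    def test_flat_image_no_candidates(self):
        assert len(detect_spots(np.full((64, 64), 100.0))) == 0

    def test_single_psf_at_snr20(self):
        rng = np.random.default_rng(5)
        img = psf_image((64, 64), 30.4, 28.7, 90.0, 2500.0, rng=rng)
        cands = detect_spots(img, sigma_px=90.0 / PX)
        assert len(cands) == 1
        assert math.hypot(cands[0][0] - 28.7, cands[0][1] - 30.4) < 1.0

    def test_two_psfs_ten_px_apart(self):
        rng = np.random.default_rng(6)
        img = psf_image((64, 64), 25.0, 25.0, 90.0, 2500.0, rng=rng)
        patch, sl = _pixel_integrated_gaussian((64, 64), 35.0 * PX, 25.0 * PX, 90.0, 2500.0, PX)
        img[sl] += patch
        assert len(detect_spots(img, sigma_px=90.0 / PX)) == 2

    def test_recall_and_false_positives_at_snr20(self):
        """>= 99 % recall and <= 1 false positive per FOV for bright
        single-dye particles with default detection settings."""
        codes = [barcode_from_id(6)]  # DiD high: SNR ~ 20 in channel alpha
        fovs, truth = generate_dataset(
            codes,
            particles_per_class=150,
            het=HeterogeneityParams(radius_cv=0.0, encapsulation_sd=0.0),
            seed=21,
        )
        params = LocalizeParams()
        sigma_px = params.nominal_sigma_px(638.0)
        hits = 0
        false_pos = 0
        for f, fov in enumerate(fovs):
            cands = detect_spots(
                fov.pixels[0].astype(float), sigma_px,
                params.threshold_k, params.min_separation_px,
            )
            tf = truth[truth["fov"] == f]
            tx = tf["x_nm"].to_numpy() / PX
            ty = tf["y_nm"].to_numpy() / PX
            matched = np.zeros(len(tf), dtype=bool)
            for r, c in cands:
                d = np.hypot(tx - c, ty - r)
                k = int(np.argmin(d))
                if d[k] < 2.0:
                    matched[k] = True
                else:
                    false_pos += 1
            hits += matched.sum()
        assert hits / len(truth) >= 0.99
        assert false_pos <= len(fovs)


class TestFit:
    def test_noiseless_recovery(self):
        """Noiseless PSF (N = 10000, sigma = 90 nm): intensity within 1 %,
        sigma within 2 %, position within 0.05 px."""
        img = np.rint(psf_image((41, 41), 20.3, 19.6, 90.0, 10000.0))
        loc = fit_gaussian(img, (20, 20), 7, PX, nominal_sigma_px=90.0 / PX)
        assert loc.fit_ok
        assert abs(loc.x_nm / PX - 20.3) < 0.05
        assert abs(loc.y_nm / PX - 19.6) < 0.05
        assert loc.integrated_intensity == pytest.approx(10000.0, rel=0.01)
        assert loc.sigma_nm == pytest.approx(90.0, rel=0.02)

    def test_centered_psf_symmetric(self):
        img = psf_image((41, 41), 20.5, 20.5, 90.0, 8000.0)
        loc = fit_gaussian(img, (20, 20), 7, PX, nominal_sigma_px=90.0 / PX)
        assert loc.x_nm / PX == pytest.approx(20.5, abs=1e-3)
        assert loc.y_nm / PX == pytest.approx(20.5, abs=1e-3)

    def test_flat_patch_rejected(self):
        loc = fit_gaussian(np.full((21, 21), 100.0), (10, 10), 7, PX, nominal_sigma_px=1.0)
        assert not loc.fit_ok

    def test_window_outside_image_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian(np.zeros((10, 10)), (1, 1), 7, PX, nominal_sigma_px=1.0)


def _loc(ch, x, y, i=100.0):
    return Localization(ch, x, y, i, 90.0, 0.0, True)


def _greedy_oracle(ref_xy, chan_xy, radius):
    """Brute-force all-pairs greedy assignment (reference order, nearest
    unused within radius, ties to the lower index)."""
    if len(chan_xy) == 0:
        return [-1] * len(ref_xy)
    d = np.hypot(
        ref_xy[:, 0][:, None] - chan_xy[:, 0][None, :],
        ref_xy[:, 1][:, None] - chan_xy[:, 1][None, :],
    )
    used = np.zeros(len(chan_xy), dtype=bool)
    out = []
    for i in range(len(ref_xy)):
        di = np.where(used, np.inf, d[i])
        j = int(np.argmin(di))  # argmin returns the first (lowest) index on ties
        if di[j] < radius:
            used[j] = True
            out.append(j)
        else:
            out.append(-1)
    return out


class TestMatching:
    def test_empty_channels_all_sentinels(self):
        refs = [_loc("merged", 1000.0, 1000.0)]
        recs = match_localizations(refs, {ch: [] for ch in CHANNEL_NAMES})
        assert len(recs) == 1
        for ch in CHANNEL_NAMES:
            assert recs[0][f"I_{ch}"] == 0.0 and recs[0][f"S_{ch}"] == 0.0

    def test_nearest_candidate_wins(self):
        refs = [_loc("merged", 1000.0, 1000.0)]
        per = {ch: [] for ch in CHANNEL_NAMES}
        per["alpha"] = [_loc("alpha", 1100.0, 1000.0, i=1.0), _loc("alpha", 1050.0, 1000.0, i=2.0)]
        recs = match_localizations(refs, per, radius_nm=120.0)
        assert recs[0]["I_alpha"] == 2.0  # the 50 nm candidate

    def test_matches_brute_force_oracle(self):
        """200 random instances agree with the all-pairs greedy oracle."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_ref = int(rng.integers(0, 31))
            n_ch = int(rng.integers(0, 31))
            ref_xy = rng.uniform(0, 2000, size=(n_ref, 2))
            ch_xy = rng.uniform(0, 2000, size=(n_ch, 2))
            refs = [_loc("merged", x, y) for x, y in ref_xy]
            per = {ch: [] for ch in CHANNEL_NAMES}
            per["beta"] = [_loc("beta", x, y, i=i + 1.0) for i, (x, y) in enumerate(ch_xy)]
            recs = match_localizations(refs, per, radius_nm=120.0)
            expected = _greedy_oracle(ref_xy, ch_xy, 120.0)
            got = [
                int(r["I_beta"] - 1) if r["I_beta"] > 0 else -1 for r in recs
            ]
            assert got == expected

    def test_radius_monotone(self):
        """Enlarging the radius never decreases the number of matched slots."""
        rng = np.random.default_rng(8)
        ref_xy = rng.uniform(0, 3000, size=(20, 2))
        ch_xy = rng.uniform(0, 3000, size=(20, 2))
        refs = [_loc("merged", x, y) for x, y in ref_xy]
        per = {"alpha": [_loc("alpha", x, y) for x, y in ch_xy]}
        counts = []
        for radius in (60.0, 120.0, 240.0, 480.0, 2000.0):
            recs = match_localizations(refs, per, radius_nm=radius)
            counts.append(sum(1 for r in recs if r["I_alpha"] > 0))
        assert counts == sorted(counts)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            match_localizations([], {}, radius_nm=0.0)


class TestFeatureTable:
    def test_round_trip_intensity_regression(self):
        """Noiseless simulation: fitted intensities regress on the expected
        channel signals with slope 1 +- 0.02 and R^2 > 0.999."""
        codes = [barcode_from_id(i) for i in (2, 4, 6)]
        fovs, truth = generate_dataset(
            codes,
            particles_per_class=25,
            het=HeterogeneityParams(radius_cv=0.0, encapsulation_sd=0.0),
            noise=False,
            seed=31,
        )
        table = build_feature_table(fovs, LocalizeParams(), truth)
        table = table[table["label"] > 0]
        fitted, expected = [], []
        for _, row in table.iterrows():
            d = np.hypot(truth["x_nm"] - row["x_nm"], truth["y_nm"] - row["y_nm"])
            t = truth.iloc[int(np.argmin(d))]
            for i, ch in enumerate(CHANNEL_NAMES):
                if row[f"I_{ch}"] > 0 and t[f"expected_{ch}"] > 100:
                    fitted.append(row[f"I_{ch}"])
                    expected.append(t[f"expected_{ch}"])
        fit = linregress(expected, fitted)
        assert fit.slope == pytest.approx(1.0, abs=0.02)
        assert fit.rvalue**2 > 0.999

    def test_labels_recovered(self):
        """50 well-separated bright particles give 50 records, >= 95 %
        correctly labeled from ground truth."""
        codes = [barcode_from_id(i) for i in (2, 6)]
        fovs, truth = generate_dataset(codes, particles_per_class=25, seed=33)
        table = build_feature_table(fovs, LocalizeParams(), truth)
        assert len(table) >= 48
        # label assigned by position must agree with the truth table class
        ok = 0
        for _, row in table.iterrows():
            d = np.hypot(truth["x_nm"] - row["x_nm"], truth["y_nm"] - row["y_nm"])
            if row["label"] == truth.iloc[int(np.argmin(d))]["barcode_id"]:
                ok += 1
        assert ok / len(table) >= 0.95

    def test_empty_input_gives_header_only(self):
        table = build_feature_table([], LocalizeParams())
        assert len(table) == 0
        assert list(table.columns) == ["particle_id", "fov", "x_nm", "y_nm"] + FEATURE_COLUMNS

    def test_schema_order(self, tmp_path):
        assert FEATURE_COLUMNS == [
            "I_alpha", "I_beta", "I_gamma", "I_delta", "I_epsilon", "I_zeta",
            "I_merged",
            "S_alpha", "S_beta", "S_gamma", "S_delta", "S_epsilon", "S_zeta",
            "S_merged",
        ]
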