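"""Single-particle localization and fingerprint assembly (the "reading" step).

Per channel and on a merged reference image: band-pass spot detection
(difference of Gaussians + robust threshold), least-squares fitting of a
pixel-integrated 2-D Gaussian per candidate, greedy nearest-neighbour
matching of channel localizations to the merged reference within a fixed
radius (120 nm), and assembly of the 14-feature fingerprint per particle
(integrated intensity and sigma for the six channels and the merged image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import least_squares
from scipy.special import erf

from .optics import psf_sigma_nm
from .scheme import CHANNEL_NAMES, default_channels
from .simulate import DEFAULT_PIXEL_SIZE_NM, FOVImage

__all__ = [
    "Localization",
    "LocalizeParams",
    "FEATURE_COLUMNS",
    "MAIN_CHANNEL_FEATURES",
    "merge_channels",
    "detect_spots",
    "fit_gaussian",
    "match_localizations",
    "build_feature_table",
]

#: Fingerprint schema, bit-exact column order of the dataset consumed by the
#: reader: intensities then sigmas, channels alpha..zeta then merged.
FEATURE_COLUMNS = (
    [f"I_{c}" for c in CHANNEL_NAMES]
    + ["I_merged"]
    + [f"S_{c}" for c in CHANNEL_NAMES]
    + ["S_merged"]
)

#: Feature subset from the three main channels only (ablation experiments).
MAIN_CHANNEL_FEATURES = [f"I_{c}" for c in ("alpha", "beta", "delta")] + [
    f"S_{c}" for c in ("alpha", "beta", "delta")
]


@dataclass
class Localization:
    """One fitted PSF in one channel (coordinates in nm)."""

    channel: str
    x_nm: float
    y_nm: float
    integrated_intensity: float
    sigma_nm: float
    background: float
    fit_ok: bool


@dataclass(frozen=True)
class LocalizeParams:
    """Detection / fitting / matching settings."""

    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    na: float = 1.4
    particle_diameter_nm: float = 100.0  # nominal, enters the expected PSF width
    threshold_k: float = 5.0  # robust-noise multiples for detection
    min_separation_px: float = 3.0
    fit_window_px: int = 7
    match_radius_nm: float = 120.0

    def nominal_sigma_nm(self, wavelength_nm: float) -> float:
        return psf_sigma_nm(wavelength_nm, self.na, self.particle_diameter_nm)

    def nominal_sigma_px(self, wavelength_nm: float) -> float:
        return self.nominal_sigma_nm(wavelength_nm) / self.pixel_size_nm


def merge_channels(fov: FOVImage) -> np.ndarray:
    """Per-pixel sum of the six planes in a wide accumulator (no clipping)."""
    pixels = fov.pixels
    if pixels.ndim != 3:
        raise ValueError("expected a multi-channel image stack")
    return pixels.sum(axis=0, dtype=np.float64)


def detect_spots(
    image: np.ndarray,
    sigma_px: float = 1.0,
    threshold_k: float = 5.0,
    min_separation_px: float = 3.0,
) -> np.ndarray:
    """Candidate spot positions (row, col) via a band-pass + robust threshold.

    Difference of Gaussians at scales ``sigma_px`` and ``2 * sigma_px``,
    3x3 local maxima, kept where the filtered response exceeds
    ``threshold_k`` times a robust noise estimate (1.4826 * MAD of the
    filtered image); maxima closer than ``min_separation_px`` collapse to
    the brighter one.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    dog = gaussian_filter(img, sigma_px) - gaussian_filter(img, 2.0 * sigma_px)
    noise = 1.4826 * np.median(np.abs(dog - np.median(dog)))
    is_max = (dog == maximum_filter(dog, size=3)) & (dog > threshold_k * max(noise, 1e-12))
    peaks = np.argwhere(is_max)
    if len(peaks) == 0:
        return peaks.reshape(0, 2)
    # suppress near-duplicates, brightest first
    order = np.argsort(dog[peaks[:, 0], peaks[:, 1]])[::-1]
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= min_separation_px for q in kept):
            kept.append(p)
    return np.asarray(kept)


def _integrated_gaussian_model(params, xs, ys):
    x0, y0, sigma, amplitude, bkg = params
    denom = math.sqrt(2.0) * sigma
    fx = 0.5 * (1.0 + erf((xs - x0) / denom))
    fy = 0.5 * (1.0 + erf((ys - y0) / denom))
    return amplitude * np.outer(np.diff(fy), np.diff(fx)) + bkg


def fit_gaussian(
    image: np.ndarray,
    candidate: tuple[int, int],
    window_px: int = 7,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    nominal_sigma_px: float = 1.0,
    channel: str = "merged",
) -> Localization:
    """Least-squares fit of a pixel-integrated symmetric 2-D Gaussian.

    Fits centre, width, integrated intensity (background-subtracted Gaussian
    volume) and a constant background over a ``window_px`` square around the
    candidate pixel.  ``fit_ok`` is false when the solver fails, the width
    leaves (0.3, 3) times the nominal PSF sigma, or the centre leaves the
    window.
    """
    img = np.asarray(image, dtype=float)
    half = window_px // 2
    r, c = int(candidate[0]), int(candidate[1])
    if r - half < 0 or c - half < 0 or r + half + 1 > img.shape[0] or c + half + 1 > img.shape[1]:
        raise ValueError("fit window extends outside the image")
    patch = img[r - half : r + half + 1, c - half : c + half + 1]
    xs = np.arange(c - half, c + half + 2, dtype=float)  # pixel edges
    ys = np.arange(r - half, r + half + 2, dtype=float)
    bkg0 = float(np.median(patch))
    amp0 = max(float(patch.sum() - bkg0 * patch.size), 1.0)
    p0 = np.array([c + 0.5, r + 0.5, nominal_sigma_px, amp0, bkg0])

    def residuals(params):
        return (_integrated_gaussian_model(params, xs, ys) - patch).ravel()

    try:
        sol = least_squares(
            residuals,
            p0,
            bounds=(
                [xs[0], ys[0], 0.05, 0.0, -np.inf],
                [xs[-1], ys[-1], 10.0 * nominal_sigma_px, np.inf, np.inf],
            ),
            method="trf",
            max_nfev=200,
        )
        ok = sol.success
        x0, y0, sigma, amplitude, bkg = sol.x
    except Exception:
        ok = False
        x0, y0, sigma, amplitude, bkg = p0
    if ok:
        in_window = xs[0] <= x0 <= xs[-1] and ys[0] <= y0 <= ys[-1]
        sane_sigma = 0.3 * nominal_sigma_px < sigma < 3.0 * nominal_sigma_px
        ok = in_window and sane_sigma and amplitude > 0
    return Localization(
        channel=channel,
        x_nm=float(x0 * pixel_size_nm),
        y_nm=float(y0 * pixel_size_nm),
        integrated_intensity=float(amplitude),
        sigma_nm=float(sigma * pixel_size_nm),
        background=float(bkg),
        fit_ok=bool(ok),
    )


def match_localizations(
    reference: list[Localization],
    per_channel: dict[str, list[Localization]],
    radius_nm: float = 120.0,
) -> list[dict]:
    """Greedy nearest-within-radius matching of channel localizations.

    Each reference (merged-image) localization becomes one record.  Per
    channel, references claim -- in reference order -- the nearest unused
    channel localization within ``radius_nm`` (ties broken by the lower
    localization index).  Unmatched channel slots carry the sentinel
    (intensity 0, sigma 0).  Merged intensity/sigma always come from the
    reference fit.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    records: list[dict] = []
    assigned = {ch: [False] * len(locs) for ch, locs in per_channel.items()}
    for ref in reference:
        rec: dict = {
            "x_nm": ref.x_nm,
            "y_nm": ref.y_nm,
            "I_merged": ref.integrated_intensity,
            "S_merged": ref.sigma_nm,
        }
        for ch in CHANNEL_NAMES:
            locs = per_channel.get(ch, [])
            used = assigned.setdefault(ch, [False] * len(locs))
            best_idx, best_d = -1, radius_nm
            for i, loc in enumerate(locs):
                if used[i]:
                    continue
                d = math.hypot(loc.x_nm - ref.x_nm, loc.y_nm - ref.y_nm)
                if d < best_d:  # strict: first (lowest) index wins on ties
                    best_idx, best_d = i, d
            if best_idx >= 0:
                used[best_idx] = True
                rec[f"I_{ch}"] = locs[best_idx].integrated_intensity
                rec[f"S_{ch}"] = locs[best_idx].sigma_nm
            else:
                rec[f"I_{ch}"] = 0.0
                rec[f"S_{ch}"] = 0.0
        records.append(rec)
    return records


def _localize_plane(
    image: np.ndarray, sigma_px: float, params: LocalizeParams, channel: str
) -> list[Localization]:
    candidates = detect_spots(
        image, sigma_px, params.threshold_k, params.min_separation_px
    )
    half = params.fit_window_px // 2
    locs = []
    for r, c in candidates:
        if (
            r - half < 0
            or c - half < 0
            or r + half + 1 > image.shape[0]
            or c + half + 1 > image.shape[1]
        ):
            continue
        loc = fit_gaussian(
            image,
            (r, c),
            params.fit_window_px,
            params.pixel_size_nm,
            nominal_sigma_px=sigma_px,
            channel=channel,
        )
        if loc.fit_ok:
            locs.append(loc)
    return locs


def build_feature_table(
    fovs: list[FOVImage],
    params: LocalizeParams = LocalizeParams(),
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run merge -> detect -> fit -> match over FOVs; assemble fingerprints.

    Returns one row per merged-channel localization with globally unique
    particle ids and the 14 fingerprint features.  When a ground-truth
    table is supplied (simulator output), a ``label`` column is attached by
    nearest-truth-particle within the matching radius.
    """
    channels = default_channels()
    rows: list[dict] = []
    next_id = 0
    for f, fov in enumerate(fovs):
        merged = merge_channels(fov)
        sigma_px = {
            ch.name: params.nominal_sigma_px(ch.laser) for ch in channels
        }
        merged_sigma = float(np.mean(list(sigma_px.values())))
        reference = _localize_plane(merged, merged_sigma, params, "merged")
        per_channel = {
            ch.name: _localize_plane(
                fov.pixels[i].astype(float), sigma_px[ch.name], params, ch.name
            )
            for i, ch in enumerate(channels)
        }
        records = match_localizations(reference, per_channel, params.match_radius_nm)
        truth_f = None
        if truth is not None:
            truth_f = truth[truth["fov"] == f] if "fov" in truth.columns else truth
        for rec in records:
            row = {
                "particle_id": next_id,
                "fov": f,
                "x_nm": rec["x_nm"],
                "y_nm": rec["y_nm"],
            }
            if truth_f is not None and len(truth_f):
                d = np.hypot(
                    truth_f["x_nm"].to_numpy() - rec["x_nm"],
                    truth_f["y_nm"].to_numpy() - rec["y_nm"],
                )
                k = int(np.argmin(d))
                row["label"] = (
                    int(truth_f["barcode_id"].iloc[k])
                    if d[k] <= params.match_radius_nm
                    else -1
                )
            for col in FEATURE_COLUMNS:
                row[col] = rec[col]
            rows.append(row)
            next_id += 1
    lead = ["particle_id", "fov", "x_nm", "y_nm"]
    if truth is not None:
        lead.append("label")
    table = pd.DataFrame(rows, columns=lead + FEATURE_COLUMNS)
    return table
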