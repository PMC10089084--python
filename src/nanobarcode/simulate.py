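"""Synthetic confocal imaging of barcoded nanoparticles (the "writing" step).

Generates ground-truth-annotated six-channel fields of view.  Each particle
draws a radius (lognormal), per-dye encapsulated loads scaling with the
particle volume (r^3) times a lognormal encapsulation factor, passes through
the quench/cross-talk/FRET optical model, and is rendered per channel as a
pixel-integrated 2-D Gaussian whose total integral equals the expected
channel signal.  Optional shot noise (Poisson), Gaussian read noise and a
constant detector offset emulate the camera.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .optics import OpticalModel, apply_quenching, expected_channel_signal, psf_sigma_nm
from .scheme import BarcodeCode, CHANNEL_NAMES, enumerate_barcodes

__all__ = [
    "HeterogeneityParams",
    "PsfParams",
    "ParticleGroundTruth",
    "FOVImage",
    "sample_particle",
    "render_fov",
    "generate_dataset",
    "save_fov",
    "load_fov",
]

logger = logging.getLogger(__name__)

#: Acquisition geometry used throughout (confocal scan settings).
DEFAULT_SHAPE = (504, 504)
DEFAULT_PIXEL_SIZE_NM = 92.45


@dataclass(frozen=True)
class HeterogeneityParams:
    """Particle-to-particle variability of the synthetic population.

    ``radius_mean``/``radius_cv`` parameterize a lognormal radius
    distribution (a PDI < 0.1 population has cv ~ 0.1); ``encapsulation_sd``
    is the sd of the per-dye lognormal encapsulation factor capturing the
    stochasticity of dye loading, aggregation and orientation inside the
    polymer core.  The default of 1.0 makes the single-particle intensity
    distributions of adjacent concentration levels of the same dye overlap
    substantially (the post-quenching level gap is ln(8.5) ~ 2.1 in log
    units, so a per-dye log-sd near half the gap is required for the marked
    overlap real single-particle data shows).
    """

    radius_mean_nm: float = 50.0
    radius_cv: float = 0.1
    encapsulation_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mean_nm <= 0:
            raise ValueError("radius_mean_nm must be positive")
        if self.radius_cv < 0 or self.encapsulation_sd < 0:
            raise ValueError("radius_cv and encapsulation_sd must be >= 0")


@dataclass(frozen=True)
class PsfParams:
    """Optics entering the PSF width: objective NA (oil immersion 100x)."""

    na: float = 1.4


@dataclass
class ParticleGroundTruth:
    """One simulated particle with full provenance."""

    particle_id: int
    barcode_id: int
    x_nm: float
    y_nm: float
    radius_nm: float
    loads: np.ndarray  # encapsulated load per dye (uM-equivalent units)
    emissive_loads: np.ndarray  # after quenching
    expected_signal: np.ndarray | None = None  # photons per channel


@dataclass
class FOVImage:
    """One six-channel field of view (16-bit counts, channel order alpha..zeta)."""

    pixels: np.ndarray  # (6, H, W) uint16
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channel_names):
            raise ValueError("pixels must be (n_channels, H, W)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def loads_for_radius(
    code: BarcodeCode,
    radius_nm: float,
    het: HeterogeneityParams,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Encapsulated loads ``a_d = C_d * (r / r_mean)**3 * exp(eta_d)``.

    Dye content scales with particle volume; zero-level dyes carry exactly
    zero load regardless of the multiplicative factors.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    conc = np.asarray(code.concentrations, dtype=float)
    scale = (radius_nm / het.radius_mean_nm) ** 3
    factor = np.ones(conc.size) if eta is None else np.exp(np.asarray(eta, dtype=float))
    loads = conc * scale * factor
    loads[conc == 0] = 0.0
    return loads


def sample_particle(
    code: BarcodeCode,
    het: HeterogeneityParams,
    rng: np.random.Generator,
    quench: np.ndarray | None = None,
) -> ParticleGroundTruth:
    """Draw one particle of the given barcode.

    Radius ~ lognormal(mean ``radius_mean_nm``, cv ``radius_cv``); the
    encapsulated load of dye ``d`` is
    ``a_d = C_d * (r / r_mean)**3 * exp(eta_d)`` with
    ``eta_d ~ N(0, encapsulation_sd^2)`` — dye content scales with particle
    volume.  Zero-level dyes carry exactly zero load.  Emissive loads are
    filled if the quench constants are supplied; position is assigned at
    placement time.
    """
    if het.radius_cv > 0:
        s = math.sqrt(math.log1p(het.radius_cv**2))
        mu = math.log(het.radius_mean_nm) - 0.5 * s * s
        radius = float(rng.lognormal(mu, s))
    else:
        radius = het.radius_mean_nm
    n_dyes = len(code.levels)
    eta = (
        rng.normal(0.0, het.encapsulation_sd, size=n_dyes)
        if het.encapsulation_sd > 0
        else np.zeros(n_dyes)
    )
    loads = loads_for_radius(code, radius, het, eta)
    emissive = apply_quenching(loads, quench) if quench is not None else loads.copy()
    return ParticleGroundTruth(
        particle_id=-1,
        barcode_id=code.id,
        x_nm=float("nan"),
        y_nm=float("nan"),
        radius_nm=radius,
        loads=loads,
        emissive_loads=emissive,
    )


def _pixel_integrated_gaussian(
    shape: tuple[int, int],
    x_nm: float,
    y_nm: float,
    sigma_nm: float,
    total: float,
    pixel_size_nm: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Photon expectation of a symmetric Gaussian integrated over pixels.

    Returns a patch and the slice placing it in the image.  Pixel (i, j)
    spans [j, j+1) x [i, i+1) pixel units; pixel centers sit at
    (j + 0.5) * pixel_size.
    """
    from scipy.special import erf

    sx = sigma_nm / pixel_size_nm
    cx = x_nm / pixel_size_nm  # in pixel units from the top-left edge
    cy = y_nm / pixel_size_nm
    half = max(4, int(math.ceil(6 * sx)))
    j0 = max(0, int(math.floor(cx)) - half)
    j1 = min(shape[1], int(math.floor(cx)) + half + 1)
    i0 = max(0, int(math.floor(cy)) - half)
    i1 = min(shape[0], int(math.floor(cy)) + half + 1)
    if j0 >= j1 or i0 >= i1:
        return np.zeros((0, 0)), (slice(0, 0), slice(0, 0))
    xs = np.arange(j0, j1 + 1) - cx
    ys = np.arange(i0, i1 + 1) - cy
    denom = math.sqrt(2.0) * sx
    fx = 0.5 * (1.0 + erf(xs / denom))
    fy = 0.5 * (1.0 + erf(ys / denom))
    patch = total * np.outer(np.diff(fy), np.diff(fx))
    return patch, (slice(i0, i1), slice(j0, j1))


def render_fov(
    particles: list[ParticleGroundTruth],
    model: OpticalModel,
    psf: PsfParams = PsfParams(),
    noise: bool = True,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> FOVImage:
    """Render one field of view; fills each particle's ``expected_signal``.

    Each particle appears per channel as a pixel-integrated 2-D Gaussian
    with integral equal to the expected channel signal and sigma from the
    channel's excitation wavelength and the particle diameter
    (FWHM = sqrt((0.51 * lambda / NA)^2 + d^2)).  The uniform background
    rate is always added; with ``noise`` on, per-pixel counts are Poisson
    draws plus Gaussian read noise plus the detector offset, clipped to
    16 bits.
    """
    if noise and rng is None:
        raise ValueError("rng is required when noise is on")
    planes = np.full((model.n_channels, *shape), model.background_rate, dtype=float)
    for p in particles:
        sig = expected_channel_signal(p.emissive_loads, model)
        p.expected_signal = sig
        for c, chan in enumerate(model.channels):
            if sig[c] <= 0:
                continue
            sigma = psf_sigma_nm(chan.laser, psf.na, 2.0 * p.radius_nm)
            patch, sl = _pixel_integrated_gaussian(
                shape, p.x_nm, p.y_nm, sigma, sig[c], pixel_size_nm
            )
            planes[c][sl] += patch
    if noise:
        counts = rng.poisson(planes).astype(float)
        counts += rng.normal(0.0, model.read_noise_sd, size=counts.shape)
        counts += model.offset
    else:
        counts = planes + model.offset
    counts = np.rint(counts)
    n_sat = int(np.count_nonzero(counts > 65535))
    if n_sat:
        logger.warning("%d pixels saturated the 16-bit range and were clipped", n_sat)
    counts = np.clip(counts, 0, 65535).astype(np.uint16)
    return FOVImage(counts, pixel_size_nm=pixel_size_nm)


def _place_particles(
    n: int,
    shape: tuple[int, int],
    pixel_size_nm: float,
    min_separation_nm: float,
    margin_nm: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (dart throwing)."""
    width = shape[1] * pixel_size_nm
    height = shape[0] * pixel_size_nm
    if width - 2 * margin_nm <= 0 or height - 2 * margin_nm <= 0:
        raise ValueError("margin leaves no room for particles")
    cell = min_separation_nm / math.sqrt(2.0)
    grid: dict[tuple[int, int], tuple[float, float]] = {}
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            x = rng.uniform(margin_nm, width - margin_nm)
            y = rng.uniform(margin_nm, height - margin_nm)
            gi, gj = int(y // cell), int(x // cell)
            ok = True
            for di in range(-2, 3):
                for dj in range(-2, 3):
                    other = grid.get((gi + di, gj + dj))
                    if other is not None and math.hypot(x - other[0], y - other[1]) < min_separation_nm:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                grid[(gi, gj)] = (x, y)
                placed.append((x, y))
                break
        else:
            raise RuntimeError(
                f"could not place {n} particles with {min_separation_nm:.0f} nm "
                f"separation in a {width:.0f} x {height:.0f} nm field"
            )
    return np.asarray(placed)


def generate_dataset(
    codes: list[BarcodeCode] | None = None,
    particles_per_class: int = 100,
    n_fovs: int | None = None,
    het: HeterogeneityParams = HeterogeneityParams(),
    model: OpticalModel | None = None,
    psf: PsfParams = PsfParams(),
    noise: bool = True,
    min_separation_nm: float = 1000.0,
    max_particles_per_fov: int = 250,
    seed: int = 0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> tuple[list[FOVImage], pd.DataFrame]:
    """Simulate a labeled imaging dataset.

    Particles of all requested barcodes are pooled, shuffled and distributed
    across fields of view; placement is uniform with a minimum pairwise
    separation (default 1 um).  Deterministic given ``seed``.  Returns the
    rendered FOVs and a ground-truth table with one row per particle.
    """
    if particles_per_class < 1:
        raise ValueError("particles_per_class must be >= 1")
    codes = enumerate_barcodes() if codes is None else codes
    model = OpticalModel() if model is None else model
    rng = np.random.default_rng(seed)
    particles: list[ParticleGroundTruth] = []
    for code in codes:
        for _ in range(particles_per_class):
            particles.append(sample_particle(code, het, rng, quench=model.quench))
    order = rng.permutation(len(particles))
    particles = [particles[i] for i in order]
    for pid, p in enumerate(particles):
        p.particle_id = pid
    total = len(particles)
    if n_fovs is None:
        n_fovs = max(1, math.ceil(total / max_particles_per_fov))
    per_fov = math.ceil(total / n_fovs)
    margin = 8 * pixel_size_nm
    fovs: list[FOVImage] = []
    rows = []
    for f in range(n_fovs):
        batch = particles[f * per_fov : (f + 1) * per_fov]
        if not batch:
            continue
        pos = _place_particles(
            len(batch), shape, pixel_size_nm, min_separation_nm, margin, rng
        )
        for p, (x, y) in zip(batch, pos):
            p.x_nm, p.y_nm = float(x), float(y)
        fovs.append(
            render_fov(batch, model, psf, noise=noise, rng=rng, shape=shape,
                       pixel_size_nm=pixel_size_nm)
        )
        for p in batch:
            row = {
                "particle_id": p.particle_id,
                "fov": f,
                "barcode_id": p.barcode_id,
                "x_nm": p.x_nm,
                "y_nm": p.y_nm,
                "radius_nm": p.radius_nm,
            }
            for d, name in enumerate(model.panel.names):
                row[f"load_{name}"] = p.loads[d]
                row[f"emissive_{name}"] = p.emissive_loads[d]
            for c, cname in enumerate(CHANNEL_NAMES):
                row[f"expected_{cname}"] = p.expected_signal[c]
            rows.append(row)
    truth = pd.DataFrame(rows).sort_values("particle_id").reset_index(drop=True)
    return fovs, truth


def save_fov(fov: FOVImage, path, metadata: dict | None = None) -> None:
    """Write a multi-page TIFF (one page per channel) plus a YAML sidecar."""
    tifffile.imwrite(str(path), fov.pixels, photometric="minisblack")
    sidecar = {
        "pixel_size_nm": float(fov.pixel_size_nm),
        "channels": list(fov.channel_names),
        "bit_depth": 16,
    }
    if metadata:
        sidecar.update(metadata)
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def load_fov(path) -> FOVImage:
    """Read a multi-page TIFF written by :func:`save_fov`."""
    pixels = tifffile.imread(str(path))
    pixel_size = DEFAULT_PIXEL_SIZE_NM
    try:
        with open(str(path) + ".yaml") as fh:
            sidecar = yaml.safe_load(fh)
        pixel_size = float(sidecar.get("pixel_size_nm", pixel_size))
    except FileNotFoundError:
        pass
    return FOVImage(pixels, pixel_size_nm=pixel_size)
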