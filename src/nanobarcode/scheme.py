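"""Barcode scheme: dye panel, intensity levels, code enumeration and channels.

A barcode is a combination of lipophilic carbocyanine dyes (by default DiO,
DiI, DiD) encapsulated at discrete intensity levels (zero / low / high,
corresponding to 0, 1 and 10 uM in the formulation).  With ``n`` levels and
``m`` dyes there are ``n**m - 1`` usable codes (the all-zero particle is not a
barcode).  Acquisition uses six confocal channels named with Greek letters:
three "main" channels pairing each dye's optimal laser line with its emission
window, and three "additional" channels pairing a laser with a longer-
wavelength window to capture cross-excitation, bleed-through and FRET.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DyePanel",
    "BarcodeCode",
    "ChannelSpec",
    "DEFAULT_PANEL",
    "enumerate_barcodes",
    "barcode_from_id",
    "default_channels",
    "valid_channel_pairs",
    "barcode_table",
    "channel_table",
    "level_concentration_um",
]

#: Channel names in acquisition order.
CHANNEL_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def level_concentration_um(level: int) -> float:
    """Concentration (uM) encoded by an intensity level.

    Level 0 is absent; level ``k >= 1`` maps to ``10**(k-1)`` uM, so the
    default three-level scheme uses 0, 1 and 10 uM.
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    return 0.0 if level == 0 else float(10 ** (level - 1))


@dataclass(frozen=True)
class DyePanel:
    """An ordered panel of spectrally separated dyes."""

    names: tuple[str, ...] = ("DiO", "DiI", "DiD")
    excitation_peak: tuple[float, ...] = (484.0, 549.0, 644.0)
    emission_peak: tuple[float, ...] = (501.0, 565.0, 665.0)

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("dye panel must contain at least one dye")
        if len(set(self.names)) != len(self.names):
            raise ValueError("dye names must be unique")
        if not (len(self.names) == len(self.excitation_peak) == len(self.emission_peak)):
            raise ValueError("panel fields must have equal length")

    @property
    def n_dyes(self) -> int:
        return len(self.names)


DEFAULT_PANEL = DyePanel()


@dataclass(frozen=True)
class BarcodeCode:
    """One barcode: a per-dye level tuple with a canonical integer id."""

    id: int
    levels: tuple[int, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if all(lv == 0 for lv in self.levels):
            raise ValueError("barcode must have at least one nonzero level")
        if len(self.levels) != len(self.concentrations):
            raise ValueError("levels and concentrations must align")

    @property
    def n_dyes_present(self) -> int:
        return sum(1 for lv in self.levels if lv > 0)


@dataclass(frozen=True)
class ChannelSpec:
    """One acquisition channel: excitation laser line + emission window (nm)."""

    name: str
    laser: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        low, high = self.window
        if not low < high:
            raise ValueError(f"emission window must be increasing, got {self.window}")
        if not low > self.laser:
            raise ValueError(
                f"emission window must sit above the laser line ({self.laser} nm)"
            )


def enumerate_barcodes(
    n_levels: int = 3, dyes: DyePanel = DEFAULT_PANEL
) -> list[BarcodeCode]:
    """Enumerate all ``n_levels**m - 1`` barcodes for an ``m``-dye panel.

    Canonical ordering: codes are grouped by which dyes are present --
    single-dye codes first (dye by panel order, levels ascending), then dye
    pairs in lexicographic pair order, then triples, and so on; within a
    group the nonzero levels run in lexicographic order.  For the default
    3-level / 3-dye panel this yields ids 1-6 for singles, 7-18 for duals
    and 19-26 for triples.
    """
    if n_levels < 2:
        raise ValueError(f"need at least 2 levels, got {n_levels}")
    m = dyes.n_dyes
    codes: list[BarcodeCode] = []
    next_id = 1
    for size in range(1, m + 1):
        for support in itertools.combinations(range(m), size):
            for nz in itertools.product(range(1, n_levels), repeat=size):
                levels = [0] * m
                for dye_idx, lv in zip(support, nz):
                    levels[dye_idx] = lv
                codes.append(
                    BarcodeCode(
                        id=next_id,
                        levels=tuple(levels),
                        concentrations=tuple(
                            level_concentration_um(lv) for lv in levels
                        ),
                    )
                )
                next_id += 1
    assert len(codes) == n_levels**m - 1
    return codes


def barcode_from_id(
    barcode_id: int, n_levels: int = 3, dyes: DyePanel = DEFAULT_PANEL
) -> BarcodeCode:
    """Decode a canonical id back to its :class:`BarcodeCode`."""
    codes = enumerate_barcodes(n_levels, dyes)
    if not 1 <= barcode_id <= len(codes):
        raise ValueError(f"barcode id {barcode_id} outside 1..{len(codes)}")
    return codes[barcode_id - 1]


# Acquisition channels: three main channels (alpha=DiD, beta=DiI, delta=DiO)
# and three additional channels (gamma, epsilon, zeta) capturing spectral
# overlap and dye-dye interactions.
_DEFAULT_CHANNELS = (
    ChannelSpec("alpha", 638.0, (648.0, 750.0)),
    ChannelSpec("beta", 552.0, (563.0, 620.0)),
    ChannelSpec("gamma", 552.0, (648.0, 750.0)),
    ChannelSpec("delta", 488.0, (498.0, 538.0)),
    ChannelSpec("epsilon", 488.0, (563.0, 620.0)),
    ChannelSpec("zeta", 488.0, (648.0, 750.0)),
)

#: Channels whose laser is the optimal line for one dye (alpha/beta/delta).
MAIN_CHANNELS = ("alpha", "beta", "delta")


def default_channels() -> list[ChannelSpec]:
    """The six standard acquisition channels, ordered alpha..zeta."""
    return list(_DEFAULT_CHANNELS)


def valid_channel_pairs(
    lasers: list[float], windows: list[tuple[float, float]]
) -> list[ChannelSpec]:
    """All laser/emission-window pairs with the window above the laser line.

    Pairs matching one of the six standard channels keep the Greek name;
    any other valid pair gets a descriptive synthetic name.
    """
    if not lasers or not windows:
        raise ValueError("lasers and windows must be nonempty")
    by_key = {(c.laser, c.window): c.name for c in _DEFAULT_CHANNELS}
    out: list[ChannelSpec] = []
    for laser in lasers:
        for window in windows:
            if window[0] > laser:
                name = by_key.get(
                    (laser, tuple(window)),
                    f"ex{laser:g}_em{window[0]:g}-{window[1]:g}",
                )
                out.append(ChannelSpec(name, laser, tuple(window)))
    return out


def barcode_table(codes: list[BarcodeCode], dyes: DyePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Explicit id <-> levels table (exported alongside every dataset)."""
    rows = []
    for code in codes:
        row: dict[str, float | int] = {"id": code.id}
        for name, lv in zip(dyes.names, code.levels):
            row[f"{name}_level"] = lv
        for name, conc in zip(dyes.names, code.concentrations):
            row[f"{name}_uM"] = conc
        rows.append(row)
    return pd.DataFrame(rows)


def channel_table(channels: list[ChannelSpec] | None = None) -> pd.DataFrame:
    channels = default_channels() if channels is None else channels
    return pd.DataFrame(
        {
            "name": [c.name for c in channels],
            "laser_nm": [c.laser for c in channels],
            "em_low_nm": [c.window[0] for c in channels],
            "em_high_nm": [c.window[1] for c in channels],
        }
    )
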