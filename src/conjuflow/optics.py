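"""Optical geometry of the conjunctival imaging system.

The imaging chain is a camera sensor (square pixels of pitch ``pixel_pitch_um``
microns) behind a zoom/tube lens train of total magnification ``magnification``.
Object-space sampling is then ``pixel_pitch_um / magnification`` microns per
pixel, and a red blood cell of nominal diameter ``rbc_diameter_um`` is sampled
by ``rbc_diameter_um * magnification / pixel_pitch_um`` pixels.  Reliable
velocimetry needs at least 4-5 pixels per RBC; the default system geometry
(3.45 um pitch, 3.798x) samples each 7.5 um RBC with ~8.26 pixels at
~0.908 um/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "OpticalConfig",
    "microns_per_pixel",
    "field_of_view_mm",
    "pixels_per_rbc",
    "load_optics",
]


class InvalidConfigError(ValueError):
    """Raised when an optical configuration is unphysical or incomplete."""


@dataclass(frozen=True)
class OpticalConfig:
    """Camera + lens geometry and acquisition timing.

    Parameters
    ----------
    pixel_pitch_um : float
        Physical size of one camera sensor pixel, microns.
    magnification : float
        Total optical magnification (dimensionless).
    fps : float
        Acquisition frame rate, frames per second.
    rbc_diameter_um : float
        Nominal red-blood-cell diameter, microns (default 7.5).
    frame_width_px, frame_height_px : int, optional
        Sensor region of interest in pixels; required only for
        field-of-view calculations.
    """

    pixel_pitch_um: float = 3.45
    magnification: float = 3.798
    fps: float = 25.0
    rbc_diameter_um: float = 7.5
    frame_width_px: Optional[int] = None
    frame_height_px: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("pixel_pitch_um", "magnification", "fps", "rbc_diameter_um"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidConfigError(f"{name} must be > 0, got {v!r}")
        for name in ("frame_width_px", "frame_height_px"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v <= 0):
                raise InvalidConfigError(f"{name} must be a positive integer, got {v!r}")

    @property
    def microns_per_pixel(self) -> float:
        return microns_per_pixel(self)

    @property
    def pixels_per_rbc(self) -> float:
        return pixels_per_rbc(self)


def microns_per_pixel(config: OpticalConfig) -> float:
    """Object-space sampling, microns per image pixel."""
    return config.pixel_pitch_um / config.magnification


def field_of_view_mm(config: OpticalConfig) -> tuple[float, float]:
    """Field of view (width_mm, height_mm) of the configured sensor region."""
    if config.frame_width_px is None or config.frame_height_px is None:
        raise InvalidConfigError("frame dimensions required for field of view")
    um_px = microns_per_pixel(config)
    return (
        config.frame_width_px * um_px / 1000.0,
        config.frame_height_px * um_px / 1000.0,
    )


def pixels_per_rbc(config: OpticalConfig) -> float:
    """Number of image pixels across one nominal red blood cell."""
    return config.rbc_diameter_um * config.magnification / config.pixel_pitch_um


def load_optics(path: str | Path) -> OpticalConfig:
    """Load an :class:`OpticalConfig` from a YAML file.

    The file carries an ``optics`` mapping (or the mapping at top level) with
    keys matching the dataclass fields.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict) and "optics" in data:
        data = data["optics"]
    if not isinstance(data, dict):
        raise InvalidConfigError(f"no optics mapping found in {path}")
    return OpticalConfig(**data)
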