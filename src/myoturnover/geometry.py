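"""Bipolar thick-filament geometry.

A skeletal-muscle thick filament is a bipolar assembly of ~300 myosin
molecules, ~1.6 µm long, centred on the M-line of a sarcomere.  Axial
positions are expressed in the normalized sarcomere coordinate used
throughout the package: the M-line sits at 0 and the Z-bands at ±1, so a
position x (dimensionless) corresponds to x * sarcomere_length / 2 in µm.
Under that convention the filament tips fall at ±filament_length /
sarcomere_length (±0.8 for the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigurationError


@dataclass(frozen=True)
class FilamentGeometry:
    """Geometry of one thick filament inside one sarcomere.

    Parameters
    ----------
    filament_length : float
        Thick-filament length in µm (default 1.6).
    sarcomere_length : float
        Z-band to Z-band distance in µm (default 2.0, chosen so the
        filament tips land at ±0.8 in normalized coordinates).
    n_myosins : int
        Number of myosin sites on the filament (default 300), split
        symmetrically about the M-line; must be even and >= 2.
    """

    filament_length: float = 1.6
    sarcomere_length: float = 2.0
    n_myosins: int = 300

    def __post_init__(self) -> None:
        if self.filament_length <= 0 or self.sarcomere_length <= 0:
            raise InvalidConfigurationError("lengths must be positive")
        if self.filament_length >= self.sarcomere_length:
            raise InvalidConfigurationError(
                "filament_length must be smaller than sarcomere_length"
            )
        if self.n_myosins < 2 or self.n_myosins % 2:
            raise InvalidConfigurationError(
                f"n_myosins must be even and >= 2, got {self.n_myosins}"
            )

    @property
    def half_sarcomere(self) -> float:
        """Half sarcomere length in µm (the unit of the normalized axis)."""
        return self.sarcomere_length / 2.0

    @property
    def tip_coordinate(self) -> float:
        """Normalized |x| of the filament tips: filament_length / sarcomere_length."""
        return self.filament_length / self.sarcomere_length

    def positions(self) -> np.ndarray:
        """Normalized axial positions of the myosin sites.

        Sites are evenly spaced per half-filament at the midpoints of
        n_myosins/2 equal bins over (0, tip_coordinate], mirrored about the
        M-line, and returned sorted ascending.  No site sits exactly at 0.
        """
        m = self.n_myosins // 2
        half = self.tip_coordinate * (np.arange(m) + 0.5) / m
        return np.concatenate([-half[::-1], half])

    def positions_um(self) -> np.ndarray:
        """Axial site positions in µm relative to the M-line."""
        return self.positions() * self.half_sarcomere
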