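"""Core data container for delay x wavenumber transient-absorption matrices.

Conventions used throughout the package: pump-probe delays in picoseconds,
probe axis in wavenumbers (cm^-1), difference absorbance in mOD.  A dataset
carries one polarization channel ("iso", "par", "per" or "raw").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TADataset"]


@dataclass
class TADataset:
    """A transient-absorption difference-absorbance matrix.

    Parameters
    ----------
    delays:
        Strictly increasing pump-probe delays in ps, shape ``(n_t,)``.
    wavenumbers:
        Strictly monotone probe axis in cm^-1, shape ``(n_w,)``.
    values:
        Difference absorbance in mOD, shape ``(n_t, n_w)``.
    channel:
        Polarization channel label: ``iso``, ``par``, ``per`` or ``raw``.
    meta:
        Free-form provenance (seeds, generator truth, processing history).
    """

    delays: np.ndarray
    wavenumbers: np.ndarray
    values: np.ndarray
    channel: str = "iso"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.delays.ndim != 1 or self.wavenumbers.ndim != 1:
            raise ValueError("delays and wavenumbers must be 1-D")
        if self.delays.size == 0 or self.wavenumbers.size == 0:
            raise ValueError("empty axis")
        if self.values.shape != (self.delays.size, self.wavenumbers.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.delays.size}, {self.wavenumbers.size})"
            )
        for name, ax in (("delays", self.delays), ("wavenumbers", self.wavenumbers)):
            d = np.diff(ax)
            if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} axis is not strictly monotone")
        if np.any(np.diff(self.delays) < 0):
            # normalise to increasing delay order
            self.delays = self.delays[::-1]
            self.values = self.values[::-1]

    # -- selection helpers -------------------------------------------------
    def wn_index(self, wavenumber: float) -> int:
        """Nearest-pixel index on the wavenumber axis."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def crop(self, t_range=None, wn_range=None) -> "TADataset":
        """Return a view-like copy restricted to the given axis windows."""
        tm = np.ones_like(self.delays, dtype=bool)
        wm = np.ones_like(self.wavenumbers, dtype=bool)
        if t_range is not None:
            tm = (self.delays >= min(t_range)) & (self.delays <= max(t_range))
        if wn_range is not None:
            wm = (self.wavenumbers >= min(wn_range)) & (self.wavenumbers <= max(wn_range))
        if not tm.any() or not wm.any():
            raise ValueError("crop window selects no points")
        return TADataset(
            self.delays[tm],
            self.wavenumbers[wm],
            self.values[np.ix_(tm, wm)],
            channel=self.channel,
            meta=dict(self.meta),
        )

    def same_grids(self, other: "TADataset") -> bool:
        return (
            self.delays.shape == other.delays.shape
            and self.wavenumbers.shape == other.wavenumbers.shape
            and np.array_equal(self.delays, other.delays)
            and np.array_equal(self.wavenumbers, other.wavenumbers)
        )

    def copy(self) -> "TADataset":
        return TADataset(
            self.delays.copy(),
            self.wavenumbers.copy(),
            self.values.copy(),
            channel=self.channel,
            meta=dict(self.meta),
        )
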