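"""The serial-section image volume and its geometry metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SliceStack"]


@dataclass
class SliceStack:
    """An ordered stack of registered serial-section images.

    Slice index 0 is the kidney surface (cortex end); index increases with
    depth toward the papilla.  Pixels are isotropic.

    Attributes
    ----------
    slices : ndarray, shape (n_slices, height, width)
        Grayscale images, uniform intensity range across the stack.
    pixel_size : float
        Micrometres per pixel (isotropic), > 0.
    slice_thickness : float
        Micrometres between consecutive sections, > 0.
    """

    slices: np.ndarray
    pixel_size: float = 1.0
    slice_thickness: float = 2.5

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError(
                f"slices must be a (n, H, W) array, got shape {self.slices.shape}"
            )
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel_size and slice_thickness must be > 0")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every slice."""
        return self.slices.shape[1], self.slices.shape[2]

    def __len__(self) -> int:
        return self.n_slices
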