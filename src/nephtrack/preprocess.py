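"""Slice preprocessing: from raw section images to binary lumen masks.

Each slice passes through grayscale conversion, background removal,
global + local adaptive histogram equalisation, thresholding,
morphological erode/dilate cleaning and component size filtering.
Tubule diameter drops sharply at the cortico-medullary transition zone,
so every numeric parameter may be depth-scheduled with a sigmoid whose
inflection sits at that transition.

Intensity convention: tubule lumens are *bright* against dark-stained
walls (toluidine-blue sections converted to grayscale); the slide
background is brighter still and is removed as the largest
above-threshold component.  The convention is configurable via
``lumen_bright``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology
from skimage.color import rgb2gray
from skimage.measure import label

from .stack import SliceStack

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidSchedule",
    "PreprocessParams",
    "to_grayscale",
    "background_mask",
    "remove_background",
    "equalize",
    "binarize",
    "morph_clean",
    "size_filter",
    "sigmoid_value",
    "detect_defective_slices",
    "replace_defective_slices",
    "preprocess_slice",
    "preprocess_stack",
]


@dataclass(frozen=True)
class SigmoidSchedule:
    """Depth-dependent parameter value following a logistic transition.

    The value equals ``cortex_value`` for slices far above the inflection
    (shallow, cortex end of the stack), ``medulla_value`` far below it, and
    crosses the midpoint exactly at ``inflection_slice``:

        v(n) = medulla + (cortex - medulla) * sigma(-steepness * (n - inflection))

    with ``sigma`` the standard logistic function.

    Parameters
    ----------
    cortex_value, medulla_value : float
        Asymptotic parameter values at the two ends of the stack.
    inflection_slice : float
        Slice index of the transition-zone midpoint.
    steepness : float
        Transition rate in 1/slices; larger is sharper.
    """

    cortex_value: float
    medulla_value: float
    inflection_slice: float
    steepness: float = 0.1

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")

    def value_at(self, slice_index: float) -> float:
        return sigmoid_value(self, slice_index)


def sigmoid_value(schedule: SigmoidSchedule, slice_index: float) -> float:
    """Evaluate a :class:`SigmoidSchedule` at a slice index."""
    t = -schedule.steepness * (slice_index - schedule.inflection_slice)
    sig = 1.0 / (1.0 + np.exp(-t))
    return schedule.medulla_value + (schedule.cortex_value - schedule.medulla_value) * sig


Scheduled = float | int | SigmoidSchedule


def _resolve(value: Scheduled, slice_index: float) -> float:
    if isinstance(value, SigmoidSchedule):
        return value.value_at(slice_index)
    return float(value)


@dataclass(frozen=True)
class PreprocessParams:
    """All tunable preprocessing parameters.

    Every numeric field accepts either a plain number or a
    :class:`SigmoidSchedule`; :meth:`at_slice` resolves a concrete
    parameter set for one slice.  Defaults are calibration values for the
    bright-lumen convention on intensity range [0, 1]; the area limits
    (components below 10 or above 100 000 pixels are discarded as
    non-lumen) are fixed points of the method.
    """

    background_threshold: Scheduled = 0.85
    bg_close_radius: Scheduled = 3
    global_eq_window: Scheduled = 64
    local_eq_window: Scheduled = 16
    binary_threshold: Scheduled = 0.7
    erode_dilate_radius: Scheduled = 1
    erode_dilate_cycles: Scheduled = 1
    min_area: Scheduled = 10
    max_area: Scheduled = 100_000
    clip_limit: Scheduled = 0.02
    lumen_bright: bool = True

    def at_slice(self, slice_index: float) -> "PreprocessParams":
        """Resolve every scheduled field to its value at ``slice_index``."""
        resolved = {
            f.name: _resolve(getattr(self, f.name), slice_index)
            for f in fields(self)
            if f.name != "lumen_bright"
        }
        p = PreprocessParams(lumen_bright=self.lumen_bright, **resolved)
        if not p.min_area < p.max_area:
            raise ValueError("min_area must be < max_area")
        return p


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 2D image to single-channel grayscale.

    Gray input is returned unchanged; RGB input is converted with the
    standard luminance weights.  Other channel counts are rejected.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return rgb2gray(image)
    raise ValueError(f"expected a 2D image with 1 or 3 channels, got shape {image.shape}")


def background_mask(
    image: np.ndarray,
    threshold: float = 0.85,
    close_radius: int = 3,
    lumen_bright: bool = True,
) -> np.ndarray | None:
    """Mask of the slide background, or None when no background is found.

    The mask is the largest connected component on the background side of
    ``threshold`` (above it under the bright-lumen convention, where the
    empty slide is brighter than any tissue), morphologically closed with
    a circular kernel.
    """
    image = np.asarray(image, dtype=float)
    candidates = image >= threshold if lumen_bright else image <= threshold
    if not candidates.any():
        logger.warning("remove_background: no background component found; image unchanged")
        return None
    labels, n = ndi.label(candidates)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    mask = labels == biggest
    if close_radius >= 1:
        mask = morphology.closing(mask, morphology.disk(int(round(close_radius))))
    return mask


def remove_background(
    image: np.ndarray,
    threshold: float = 0.85,
    close_radius: int = 3,
    lumen_bright: bool = True,
) -> np.ndarray:
    """Zero out the slide background, leaving tissue intensities untouched.

    The background mask from :func:`background_mask` is inverted and
    multiplied onto the image, so background pixels become exactly zero.
    """
    image = np.asarray(image, dtype=float)
    mask = background_mask(image, threshold, close_radius, lumen_bright)
    if mask is None:
        return image
    out = image.copy()
    out[mask] = 0.0
    return out


def equalize(image: np.ndarray, global_window: int, local_window: int) -> np.ndarray:
    """Two-pass adaptive histogram equalisation (large then small window).

    Windows larger than the image fall back to whole-image equalisation.
    Output is rescaled to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    out = image
    for window in (global_window, local_window):
        w = int(round(window))
        if w < 1:
            raise ValueError("equalisation window must be >= 1")
        w = min(w, *out.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = exposure.equalize_adapthist(np.clip(out, 0, 1), kernel_size=w)
    return out


def binarize(image: np.ndarray, threshold: float, lumen_bright: bool = True) -> np.ndarray:
    """Threshold to a binary lumen mask (true = lumen side of threshold)."""
    image = np.asarray(image)
    return image >= threshold if lumen_bright else image <= threshold


def morph_clean(binary: np.ndarray, radius: int = 1, cycles: int = 1) -> np.ndarray:
    """Erode/dilate cycles with a disk kernel; removes thin interstitial slivers.

    ``cycles = 0`` is the identity.  Each cycle is a morphological opening,
    so structures thinner than about two kernel radii vanish.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    out = np.asarray(binary, dtype=bool)
    footprint = morphology.disk(int(round(radius)))
    for _ in range(int(round(cycles))):
        out = morphology.erosion(out, footprint)
        out = morphology.dilation(out, footprint)
    return out


def size_filter(binary: np.ndarray, min_area: int = 10, max_area: int = 100_000) -> np.ndarray:
    """Remove 4-connected components smaller than ``min_area`` or larger
    than ``max_area`` pixels; everything else is kept bit-identical."""
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndi.label(binary, structure=ndi.generate_binary_structure(2, 1))
    if n == 0:
        return binary.copy()
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = (areas >= min_area) & (areas <= max_area)
    keep_labels = np.concatenate(([False], keep))
    return keep_labels[labels]


def detect_defective_slices(stack: SliceStack, z_cutoff: float = 3.0) -> list[int]:
    """Flag slices whose mean intensity is a robust outlier for the stack.

    A slice is defective when its mean intensity deviates from the stack
    median by more than ``z_cutoff`` robust standard deviations
    (1.4826 * MAD).
    """
    means = np.array([float(np.mean(s)) for s in stack.slices])
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = max(1e-12, np.std(means))
        if scale == 0:
            return []
    z = np.abs(means - med) / scale
    return [int(i) for i in np.nonzero(z > z_cutoff)[0]]


def replace_defective_slices(
    stack: SliceStack, defective: Sequence[int] | None = None
) -> SliceStack:
    """Replace defective slices by a copy of the nearest intact neighbour.

    ``defective`` may be given explicitly; when omitted it is detected with
    :func:`detect_defective_slices`.  Ties between the neighbour above and
    below are broken toward the slice above (lower index), so slice count
    and numbering never change.
    """
    if defective is None:
        defective = detect_defective_slices(stack)
    defective_set = {int(i) for i in defective}
    n = stack.n_slices
    for i in defective_set:
        if not 0 <= i < n:
            raise IndexError(f"defective slice index {i} out of range")
    good = [i for i in range(n) if i not in defective_set]
    if not good:
        raise ValueError("all slices are defective; nothing to replace from")
    good_arr = np.array(good)
    new_slices = np.array(stack.slices, copy=True)
    for i in sorted(defective_set):
        j = good_arr[np.argmin(np.abs(good_arr - i))]  # argmin ties -> lower index
        new_slices[i] = stack.slices[j]
    return replace(stack, slices=new_slices)


def preprocess_slice(
    image: np.ndarray, slice_index: int, params: PreprocessParams
) -> np.ndarray:
    """Run the full per-slice chain and return the binary lumen mask.

    Order: grayscale -> background removal -> global+local equalisation ->
    threshold -> erode/dilate cycles -> component size filter, with every
    parameter resolved from its (possibly sigmoid-scheduled) value at
    ``slice_index``.
    """
    p = params.at_slice(slice_index)
    gray = to_grayscale(image)
    bg = background_mask(
        gray, p.background_threshold, int(round(p.bg_close_radius)), p.lumen_bright
    )
    if bg is not None:
        gray = gray.copy()
        gray[bg] = 0.0
    eq = equalize(gray, int(round(p.global_eq_window)), int(round(p.local_eq_window)))
    if bg is not None:
        # equalisation has no notion of "empty slide"; keep background at zero
        eq = eq.copy()
        eq[bg] = 0.0
    binary = binarize(eq, p.binary_threshold, p.lumen_bright)
    binary = morph_clean(
        binary, int(round(p.erode_dilate_radius)), int(round(p.erode_dilate_cycles))
    )
    return size_filter(binary, int(round(p.min_area)), int(round(p.max_area)))


def preprocess_stack(
    stack: SliceStack,
    params: PreprocessParams | None = None,
    defective: Sequence[int] | None = (),
) -> np.ndarray:
    """Preprocess every slice; returns a boolean (n, H, W) binary stack.

    ``defective=()`` skips defect handling, ``None`` auto-detects, a list
    replaces those slices before filtering.
    """
    params = params or PreprocessParams()
    if defective is None or len(defective) > 0:
        stack = replace_defective_slices(stack, defective)
    return np.stack(
        [preprocess_slice(stack.slices[i], i, params) for i in range(stack.n_slices)]
    )
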