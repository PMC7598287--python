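"""Gray-level normalization and quantization of lesion ROIs.

Matrix-based texture families (co-occurrence, run-length, gradient) are
computed on quantized gray levels.  The default normalization limits the
intensity dynamics to the window [mu - 3*sigma, mu + 3*sigma], with mu and
sigma taken over the in-mask voxels of the whole 3D ROI, before linearly
mapping onto ``2**bits`` levels.  This removes per-lesion brightness and
contrast (any positive affine rescaling of the intensities yields the
same levels), which is the point: textures should reflect structure, not
scanner windowing.

First-order histogram features are deliberately *not* computed on these
levels but on raw intensities (see :mod:`cystex.texture_features`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegenerateROIError, ParameterError
from .imaging_io import ROI

NORM_STANDARD = "S"  # mu +/- 3 sigma windowing
NORM_NONE = "none"

#: width of the normalization window in standard deviations on each side
WINDOW_SIGMAS = 3.0


@dataclasses.dataclass
class QuantizedROI:
    """Per-slice quantized level grids plus the normalization record."""

    slices: list  # list of (levels 2D int array, mask 2D bool array)
    bits: int
    mu: float
    sigma: float
    norm_code: str

    @property
    def n_levels(self) -> int:
        return 2**self.bits

    def level_histogram(self) -> np.ndarray:
        """Counts per level over all in-mask voxels; sums to the ROI size."""
        counts = np.zeros(self.n_levels, dtype=np.int64)
        for levels, mask in self.slices:
            counts += np.bincount(levels[mask], minlength=self.n_levels)
        return counts


def normalize_quantize(roi: ROI, bits: int = 6, norm: str = NORM_STANDARD) -> QuantizedROI:
    """Quantize ROI intensities to ``2**bits`` gray levels.

    With ``norm="S"`` values are clipped to [mu - 3 sigma, mu + 3 sigma]
    (population sigma over the whole 3D ROI) and linearly mapped onto
    [0, 2**bits - 1], flooring, with the top window edge mapping to the
    top level.  With ``norm="none"`` raw values are used as levels and
    must already lie in range.
    """
    if not 1 <= int(bits) <= 12:
        raise ParameterError(f"bits per pixel must be in [1, 12], got {bits}")
    bits = int(bits)
    n_levels = 2**bits

    values = np.asarray(roi.values, dtype=np.float64)
    mu = float(values.mean())
    sigma = float(values.std())  # population (divide-by-N)

    out_slices = []
    if norm == NORM_STANDARD:
        if sigma == 0.0:
            raise DegenerateROIError(
                f"lesion {roi.lesion_id!r}: constant ROI, sigma = 0"
            )
        lo = mu - WINDOW_SIGMAS * sigma
        width = 2.0 * WINDOW_SIGMAS * sigma
        for view in roi.slices:
            t = (view.image.astype(np.float64) - lo) / width
            levels = np.floor(np.clip(t, 0.0, 1.0) * n_levels).astype(np.int64)
            np.minimum(levels, n_levels - 1, out=levels)  # top edge -> top level
            out_slices.append((levels, view.mask))
    elif norm == NORM_NONE:
        if values.min() < 0 or values.max() > n_levels - 1:
            raise ParameterError(
                "norm='none' requires raw values within "
                f"[0, {n_levels - 1}]; got [{values.min()}, {values.max()}]"
            )
        for view in roi.slices:
            levels = np.clip(
                np.floor(view.image.astype(np.float64)), 0, n_levels - 1
            ).astype(np.int64)
            out_slices.append((levels, view.mask))
    else:
        raise ParameterError(f"unknown normalization {norm!r}")

    return QuantizedROI(
        slices=out_slices, bits=bits, mu=mu, sigma=sigma, norm_code=norm
    )
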