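"""Texture feature families and the MaZda-style feature-name grammar.

Five families are computed over a lesion ROI:

* first-order histogram statistics on **raw** intensities (scanner
  units; normalization would defeat percentile features),
* gray-level co-occurrence matrix (GLCM / Haralick) features,
* gray-level run-length matrix (RLM) features,
* absolute-gradient statistics,
* Haar wavelet subband energies on raw slice crops.

Matrix families are computed per axial slice on normalized, quantized
levels and accumulated over every slice the lesion spans; directions are
coded H (horizontal, along columns), V (vertical, along rows), Z (45
degrees) and N (135 degrees).  Feature names follow the classic grammar
of MaZda-style texture software, e.g. ``CV2S6Entropy`` = grayscale
channel (C), vertical direction, inter-pixel distance 2, mu +/- 3 sigma
normalization (S), 6 bits per pixel, co-occurrence entropy;
``WavEnLL_s-2`` = wavelet energy, LL subband, scale 2.  All entropies use
the natural logarithm.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pywt

from .errors import EmptyMatrixError, EmptyROIError, FeatureNameError
from .imaging_io import ROI, LesionVolume, extract_roi
from .preprocess import NORM_STANDARD, QuantizedROI, normalize_quantize

logger = logging.getLogger(__name__)

HISTOGRAM_BASES = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Perc01",
    "Perc10",
    "Perc50",
    "Perc90",
    "Perc99",
)
GLCM_BASES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)
RLM_BASES = ("ShrtREmp", "LngREmph", "GLevNonU", "RLNonUni", "Fraction")
GRADIENT_BASES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
WAVELET_SUBBANDS = ("LL", "LH", "HL", "HH")

DIRECTIONS = ("H", "V", "Z", "N")
#: per-slice (delta_row, delta_col) unit offsets for each direction code
DIRECTION_OFFSETS = {"H": (0, 1), "V": (1, 0), "Z": (-1, 1), "N": (-1, -1)}


# ---------------------------------------------------------------------------
# feature-name grammar
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureName:
    family: str  # histogram | glcm | rlm | gradient | wavelet
    base: str
    channel: str = "C"
    direction: Optional[str] = None
    distance: Optional[int] = None
    norm: str = NORM_STANDARD
    bits: Optional[int] = None
    subband: Optional[str] = None
    scale: Optional[int] = None

    def render(self) -> str:
        if self.family == "histogram":
            return self.base
        if self.family == "wavelet":
            return f"WavEn{self.subband}_s-{self.scale}"
        if self.family == "glcm":
            return (
                f"{self.channel}{self.direction}{self.distance}"
                f"S{self.bits}{self.base}"
            )
        if self.family == "rlm":
            return f"{self.channel}{self.direction}S{self.bits}{self.base}"
        if self.family == "gradient":
            return f"{self.channel}S{self.bits}{self.base}"
        raise FeatureNameError(f"unknown family {self.family!r}")


_WAVELET_RE = re.compile(r"^WavEn(LL|LH|HL|HH)_s-(\d+)$")
_PREFIXED_RE = re.compile(r"^([CR])([HVZN])?([1-5])?S(\d{1,2})(.+)$")


def parse_feature_name(name: str) -> FeatureName:
    """Parse a rendered feature name back into its parts (lossless)."""
    m = _WAVELET_RE.match(name)
    if m:
        return FeatureName(
            family="wavelet", base="WavEn", subband=m.group(1),
            scale=int(m.group(2)),
        )
    if name in HISTOGRAM_BASES:
        return FeatureName(family="histogram", base=name)
    m = _PREFIXED_RE.match(name)
    if not m:
        raise FeatureNameError(f"unparseable feature name {name!r}")
    channel, direction, distance, bits, base = m.groups()
    distance = int(distance) if distance else None
    bits = int(bits)
    if base in GLCM_BASES:
        if direction is None or distance is None:
            raise FeatureNameError(
                f"{name!r}: co-occurrence base {base!r} needs a direction "
                "and a distance"
            )
        family = "glcm"
    elif base in RLM_BASES:
        if direction is None or distance is not None:
            raise FeatureNameError(
                f"{name!r}: run-length base {base!r} needs a direction and "
                "no distance"
            )
        family = "rlm"
    elif base in GRADIENT_BASES:
        if direction is not None or distance is not None:
            raise FeatureNameError(
                f"{name!r}: gradient base {base!r} carries no direction or "
                "distance"
            )
        family = "gradient"
    else:
        raise FeatureNameError(f"{name!r}: unknown base name segment {base!r}")
    return FeatureName(
        family=family, base=base, channel=channel, direction=direction,
        distance=distance, bits=bits,
    )


def render_feature_name(fn: FeatureName) -> str:
    return fn.render()


# ---------------------------------------------------------------------------
# first-order histogram features (raw intensities)
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of the raw in-mask intensity multiset.

    ``Variance`` is the population variance; ``Perc-n`` is the smallest
    intensity whose cumulative fraction reaches n%; ``Kurtosis`` is
    excess kurtosis.  Skewness/kurtosis of a constant ROI are reported
    as 0.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise EmptyROIError("histogram features need at least one voxel")
    mean = v.mean()
    var = v.var()
    sd = np.sqrt(var)
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    out = {
        "Mean": float(mean),
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
    }
    for q in (1, 10, 50, 90, 99):
        out[f"Perc{q:02d}"] = float(np.percentile(v, q, method="inverted_cdf"))
    return out


# ---------------------------------------------------------------------------
# co-occurrence matrix
# ---------------------------------------------------------------------------

def glcm(qroi: QuantizedROI, direction: str, distance: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix p(i, j).

    Pairs are counted per slice at offset ``distance`` times the
    direction's (delta_row, delta_col) unit vector, with *both* voxels of
    a pair in-mask, accumulated over every slice the lesion spans; the
    count matrix is symmetrized by adding its transpose and normalized to
    sum 1.
    """
    if direction not in DIRECTION_OFFSETS:
        raise FeatureNameError(f"unknown direction {direction!r}")
    dr, dc = (d * distance for d in DIRECTION_OFFSETS[direction])
    k = qroi.n_levels
    counts = np.zeros((k, k), dtype=np.int64)
    for levels, mask in qroi.slices:
        h, w = levels.shape
        nr, nc = h - abs(dr), w - abs(dc)
        if nr <= 0 or nc <= 0:
            continue
        r1, c1 = max(0, -dr), max(0, -dc)
        r2, c2 = max(0, dr), max(0, dc)
        rs1, cs1 = slice(r1, r1 + nr), slice(c1, c1 + nc)
        rs2, cs2 = slice(r2, r2 + nr), slice(c2, c2 + nc)
        valid = mask[rs1, cs1] & mask[rs2, cs2]
        if not valid.any():
            continue
        i = levels[rs1, cs1][valid]
        j = levels[rs2, cs2][valid]
        counts += np.bincount(i * k + j, minlength=k * k).reshape(k, k)
    total = counts.sum()
    if total == 0:
        raise EmptyMatrixError(
            f"no in-mask voxel pairs for direction {direction}, distance "
            f"{distance}"
        )
    sym = counts + counts.T
    return sym / sym.sum()


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Haralick statistics of a normalized symmetric co-occurrence matrix.

    Levels are indexed 1..K for the marginal sums (classic Haralick
    indexing, so the x+y marginal runs over k = 2..2K and SumAverg of a
    mid-gray image at K = 64 sits near 64).  Entropies use the natural
    log with 0*log(0) = 0.  Correlat is NaN when a marginal is constant.
    """
    k = p.shape[0]
    idx = np.arange(1, k + 1, dtype=np.float64)
    px = p.sum(axis=1)  # row marginal (== column marginal by symmetry)
    mu = float(idx @ px)
    var = float(((idx - mu) ** 2) @ px)

    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    # p_{x+y}(s), s = 2..2K  and  p_{x-y}(d), d = 0..K-1
    s_idx = (ii + jj).astype(np.int64)
    d_idx = np.abs(ii - jj).astype(np.int64)
    p_sum = np.bincount(s_idx.ravel(), weights=p.ravel(), minlength=2 * k + 1)
    p_dif = np.bincount(d_idx.ravel(), weights=p.ravel(), minlength=k)
    s_vals = np.arange(2 * k + 1, dtype=np.float64)
    d_vals = np.arange(k, dtype=np.float64)

    sum_averg = float(s_vals @ p_sum)
    sum_varnc = float(((s_vals - sum_averg) ** 2) @ p_sum)
    dif_mean = float(d_vals @ p_dif)
    dif_varnc = float(((d_vals - dif_mean) ** 2) @ p_dif)

    if var > 0:
        correlat = float(((ii - mu) * (jj - mu) * p).sum() / var)
    else:
        correlat = np.nan

    return {
        "AngScMom": float((p**2).sum()),
        "Contrast": float((d_vals**2) @ p_dif),
        "Correlat": correlat,
        "SumOfSqs": float((((ii - mu) ** 2) * p).sum()),
        "InvDfMom": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "SumAverg": sum_averg,
        "SumVarnc": sum_varnc,
        "SumEntrp": _entropy(p_sum),
        "Entropy": _entropy(p),
        "DifVarnc": dif_varnc,
        "DifEntrp": _entropy(p_dif),
    }


# ---------------------------------------------------------------------------
# run-length matrix
# ---------------------------------------------------------------------------

def _runs_along(levels: np.ndarray, mask: np.ndarray, direction: str):
    """All maximal in-mask constant-level runs along one direction.

    Returns (levels_of_runs, lengths_of_runs) as integer arrays.  Lines
    are rows (H), columns (V) or diagonals (Z: 45 degrees, N: 135
    degrees); out-of-mask voxels break runs and belong to none.
    """
    if direction == "H":
        lines = [(levels[r], mask[r]) for r in range(levels.shape[0])]
    elif direction == "V":
        lines = [(levels[:, c], mask[:, c]) for c in range(levels.shape[1])]
    elif direction in ("Z", "N"):
        # N runs along (+1,+1) == main diagonals; Z along (-1,+1) ==
        # diagonals of the up-down flipped image.
        lv = levels if direction == "N" else levels[::-1]
        mk = mask if direction == "N" else mask[::-1]
        h, w = lv.shape
        lines = [
            (lv.diagonal(o).copy(), mk.diagonal(o).copy())
            for o in range(-(h - 1), w)
        ]
    else:
        raise FeatureNameError(f"unknown direction {direction!r}")

    # Concatenate lines with sentinel separators, then run-length encode.
    parts = []
    for lv, mk in lines:
        coded = np.where(mk, lv, -1)
        parts.append(coded)
        parts.append(np.array([-1], dtype=np.int64))
    arr = np.concatenate(parts)
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [arr.size]))
    run_levels = arr[starts]
    run_lengths = ends - starts
    keep = run_levels >= 0
    return run_levels[keep], run_lengths[keep]


def rlm_features(qroi: QuantizedROI, direction: str) -> dict[str, float]:
    """Run-length statistics accumulated over all slices of the lesion.

    With r(i, j) runs of level i and length j and R their total:
    ShrtREmp = sum r/j^2 / R, LngREmph = sum r*j^2 / R, GLevNonU =
    sum_i (sum_j r)^2 / R, RLNonUni = sum_j (sum_i r)^2 / R and Fraction
    = R / (in-mask voxels traversed).
    """
    all_levels, all_lengths = [], []
    n_voxels = 0
    for levels, mask in qroi.slices:
        lv, ln = _runs_along(levels, mask, direction)
        all_levels.append(lv)
        all_lengths.append(ln)
        n_voxels += int(mask.sum())
    lv = np.concatenate(all_levels)
    ln = np.concatenate(all_lengths)
    r_total = lv.size
    if r_total == 0:
        raise EmptyROIError("no runs in ROI")
    per_level = np.bincount(lv, minlength=qroi.n_levels).astype(np.float64)
    per_length = np.bincount(ln).astype(np.float64)
    lnf = ln.astype(np.float64)
    return {
        "ShrtREmp": float((1.0 / lnf**2).sum() / r_total),
        "LngREmph": float((lnf**2).sum() / r_total),
        "GLevNonU": float((per_level**2).sum() / r_total),
        "RLNonUni": float((per_length**2).sum() / r_total),
        "Fraction": float(r_total / n_voxels),
    }


# ---------------------------------------------------------------------------
# absolute gradient
# ---------------------------------------------------------------------------

def gradient_features(qroi: QuantizedROI) -> dict[str, float]:
    """Moments of the in-plane gradient magnitude over interior voxels.

    The magnitude sqrt(dr^2 + dc^2) uses central differences (half the
    two-step difference) and is evaluated only at voxels whose full
    4-neighborhood is in-mask.  GrNonZeros is the fraction of those
    voxels with non-zero magnitude; GrKurtosis is excess kurtosis.
    Returns NaNs when no interior voxel exists.
    """
    mags = []
    for levels, mask in qroi.slices:
        h, w = levels.shape
        if h < 3 or w < 3:
            continue
        x = levels.astype(np.float64)
        dr = (x[2:, 1:-1] - x[:-2, 1:-1]) / 2.0
        dc = (x[1:-1, 2:] - x[1:-1, :-2]) / 2.0
        interior = (
            mask[1:-1, 1:-1]
            & mask[2:, 1:-1]
            & mask[:-2, 1:-1]
            & mask[1:-1, 2:]
            & mask[1:-1, :-2]
        )
        if interior.any():
            mags.append(np.sqrt(dr[interior] ** 2 + dc[interior] ** 2))
    if not mags:
        return {base: np.nan for base in GRADIENT_BASES}
    g = np.concatenate(mags)
    mean = g.mean()
    var = g.var()
    sd = np.sqrt(var)
    if sd > 0:
        z = (g - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    return {
        "GrMean": float(mean),
        "GrVariance": float(var),
        "GrSkewness": skew,
        "GrKurtosis": kurt,
        "GrNonZeros": float(np.mean(g > 0)),
    }


# ---------------------------------------------------------------------------
# Haar wavelet subband energies
# ---------------------------------------------------------------------------

def wavelet_energies(roi: ROI, max_scale: int = 3) -> dict[str, float]:
    """Mean squared orthonormal Haar coefficients per subband and scale.

    Each slice crop is mean-filled outside the mask, truncated to even
    dimensions at every scale, and decomposed one dyadic level at a time
    (the LL band feeds the next scale).  The lesion value for a subband
    at scale k is the average over the slices that are still at least
    2 x 2 at that scale; NaN if no slice reaches it.
    """
    acc: dict[str, list[float]] = {
        f"WavEn{sb}_s-{k}": []
        for k in range(1, max_scale + 1)
        for sb in WAVELET_SUBBANDS
    }
    for view in roi.slices:
        img = view.image.astype(np.float64)
        if view.mask.any():
            img = np.where(view.mask, img, img[view.mask].mean())
        cur = img
        for k in range(1, max_scale + 1):
            h, w = cur.shape
            h -= h % 2
            w -= w % 2
            if h < 2 or w < 2:
                break
            cur = cur[:h, :w]
            ll, (lh, hl, hh) = pywt.dwt2(cur, "haar", mode="periodization")
            for sb, band in zip(WAVELET_SUBBANDS, (ll, lh, hl, hh)):
                acc[f"WavEn{sb}_s-{k}"].append(float(np.mean(band**2)))
            cur = ll
    return {
        name: (float(np.mean(vals)) if vals else np.nan)
        for name, vals in acc.items()
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """What to extract: bit depths, directions, distances, wavelet scales."""

    bits: tuple[int, ...] = (4, 6)
    normalization: str = NORM_STANDARD
    directions: tuple[str, ...] = DIRECTIONS
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    wavelet_scales: int = 3

    def to_dict(self) -> dict:
        return {
            "bits": list(self.bits),
            "normalization": self.normalization,
            "directions": list(self.directions),
            "distances": list(self.distances),
            "wavelet_scales": self.wavelet_scales,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            bits=tuple(d["bits"]),
            normalization=d["normalization"],
            directions=tuple(d["directions"]),
            distances=tuple(d["distances"]),
            wavelet_scales=int(d["wavelet_scales"]),
        )


def extract_features(
    volume: LesionVolume, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """All configured features of one lesion; undefined features are NaN."""
    roi = extract_roi(volume)
    feats: dict[str, float] = {}
    feats.update(histogram_features(roi.values))
    feats.update(wavelet_energies(roi, config.wavelet_scales))
    for bits in config.bits:
        qroi = normalize_quantize(roi, bits=bits, norm=config.normalization)
        for direction in config.directions:
            for distance in config.distances:
                prefix = f"C{direction}{distance}S{bits}"
                try:
                    stats = glcm_features(glcm(qroi, direction, distance))
                except EmptyMatrixError:
                    stats = {base: np.nan for base in GLCM_BASES}
                for base, val in stats.items():
                    feats[f"{prefix}{base}"] = val
            rstats = rlm_features(qroi, direction)
            for base, val in rstats.items():
                feats[f"C{direction}S{bits}{base}"] = val
        for base, val in gradient_features(qroi).items():
            feats[f"CS{bits}{base}"] = val
    return feats


def extract_all(
    lesions: Sequence[LesionVolume], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Feature table of a cohort: one row per lesion, ``class_label`` first.

    A feature undefined for *any* lesion is dropped table-wide (with a
    logged warning) so downstream statistics stay rectangular.
    """
    rows = []
    index = []
    labels = []
    for les in lesions:
        rows.append(extract_features(les, config))
        index.append(les.lesion_id)
        labels.append(les.class_label)
    table = pd.DataFrame(rows, index=pd.Index(index, name="lesion_id"))
    bad = table.columns[table.isna().any()]
    if len(bad):
        logger.warning(
            "dropping %d feature(s) undefined for some lesion: %s",
            len(bad), ", ".join(bad[:10]) + ("..." if len(bad) > 10 else ""),
        )
        table = table.drop(columns=bad)
    table.insert(0, "class_label", labels)
    return table


def split_features(table: pd.DataFrame):
    """Split a feature table into (features-only frame, boolean labels)."""
    if "class_label" not in table.columns:
        raise KeyError("feature table has no class_label column")
    from .imaging_io import POSITIVE

    labels = table["class_label"] == POSITIVE
    return table.drop(columns=["class_label"]), labels
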