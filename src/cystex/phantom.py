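"""Synthetic two-class lesion phantoms.

The generator emulates the statistical contrast between the two ovarian
lesion classes the pipeline is built to separate:

* the *heterogeneous* class (endometrioma-like) — chocolate-fluid content
  with mixed cell populations and retracted clot: modelled as a
  short-correlation-length Gaussian random field, plus granular white
  noise, plus a few focal hypointense spherical inclusions ("dark
  spots");
* the *smooth* class (functional hemorrhagic cyst) — near-uniform fluid:
  a long-correlation-length, low-amplitude field with little noise.

Because the mu +/- 3 sigma gray-level normalization downstream removes
per-lesion brightness and contrast, the classes are separated by spatial
*structure* (correlation length, inclusions, noise fraction), not just by
amplitude.  Intensities are non-negative 16-bit integers, mirroring the
dynamic range of clinical DICOM exports.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .imaging_io import NEGATIVE, POSITIVE, LesionVolume

HETEROGENEOUS = "heterogeneous"
SMOOTH = "smooth"

#: a smooth-class field amplitude may be at most this fraction of the
#: heterogeneous reference amplitude
SMOOTH_CONTRAST_FRACTION = 0.25

BACKGROUND_INTENSITY = 100.0
DEFAULT_SPACING = (4.4, 0.75, 0.75)  # mm; 4 mm slices + gap, ~0.75 mm in-plane


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion.

    Intensity units are arbitrary scanner units; lengths are voxels.
    """

    class_label: str = HETEROGENEOUS
    grid_shape: tuple[int, int, int] = (12, 48, 48)
    lesion_radii: tuple[float, float, float] = (4.0, 16.0, 16.0)
    base_intensity: float = 16000.0
    contrast_sd: float = 3200.0
    correlation_length: float = 1.5
    n_dark_spots: int = 3
    spot_radius: float = 2.5
    spot_depth: float = 8000.0
    noise_sd: float = 1000.0
    seed: int = 0

    def validate(self, hetero_contrast_sd: float | None = None) -> None:
        """Check geometry and class constraints; raise on violation.

        ``hetero_contrast_sd`` is the heterogeneous-class reference
        amplitude the smooth-class ceiling is measured against; defaults
        to the class default.
        """
        if self.class_label not in (HETEROGENEOUS, SMOOTH):
            raise ParameterError(f"unknown phantom class {self.class_label!r}")
        if any(r <= 0 for r in self.lesion_radii):
            raise GeometryError("lesion radii must be strictly positive")
        for ax, (n, r) in enumerate(zip(self.grid_shape, self.lesion_radii)):
            if 2 * r >= n - 1:
                raise GeometryError(
                    f"lesion radius {r} does not fit grid axis {ax} (size {n})"
                )
        if self.class_label == SMOOTH:
            if self.n_dark_spots != 0:
                raise ParameterError("smooth lesions cannot carry dark spots")
            ref = (
                hetero_contrast_sd
                if hetero_contrast_sd is not None
                else PhantomSpec.__dataclass_fields__["contrast_sd"].default
            )
            if self.contrast_sd > SMOOTH_CONTRAST_FRACTION * ref:
                raise ParameterError(
                    "smooth-class contrast_sd exceeds "
                    f"{SMOOTH_CONTRAST_FRACTION} of the heterogeneous "
                    f"reference ({ref})"
                )
        if self.noise_sd < 0 or self.contrast_sd < 0:
            raise ParameterError("noise_sd and contrast_sd must be >= 0")


def smooth_spec_from(template: PhantomSpec) -> PhantomSpec:
    """Derive the smooth-class counterpart of a heterogeneous template.

    The smooth class keeps the template geometry and brightness but has a
    tenth of the field amplitude, a long correlation length (slow
    partial-volume-like variation instead of granular content), no dark
    spots and a twentieth of the granular noise.
    """
    return dataclasses.replace(
        template,
        class_label=SMOOTH,
        contrast_sd=0.1 * template.contrast_sd,
        correlation_length=max(4.0, 2.5 * template.correlation_length),
        n_dark_spots=0,
        spot_depth=0.0,
        noise_sd=0.05 * template.noise_sd,
    )


def _ellipsoid_mask(shape, radii) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _ball_footprint(radius: float) -> np.ndarray:
    r = max(1, int(np.ceil(radius)))
    z, y, x = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return z * z + y * y + x * x <= radius * radius


def generate_lesion(
    spec: PhantomSpec,
    lesion_id: str = "lesion",
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING,
    hetero_contrast_sd: float | None = None,
) -> LesionVolume:
    """Render one lesion volume from its spec, bit-reproducibly.

    The in-mask field is white noise smoothed with a Gaussian kernel of
    width ``correlation_length`` and rescaled so that its in-mask standard
    deviation equals ``contrast_sd`` exactly; dark spots are parabolic
    decrements of depth ``spot_depth`` wholly inside the mask; white
    noise of scale ``noise_sd`` is added everywhere.  Voxels outside the
    mask hold a low constant background.
    """
    spec.validate(hetero_contrast_sd)
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    mask = _ellipsoid_mask(shape, spec.lesion_radii)

    img = np.full(shape, BACKGROUND_INTENSITY, dtype=np.float64)
    img[mask] = spec.base_intensity

    if spec.contrast_sd > 0:
        field = ndimage.gaussian_filter(
            rng.standard_normal(shape), sigma=spec.correlation_length
        )
        sd = field[mask].std()
        if sd > 0:
            img[mask] += field[mask] * (spec.contrast_sd / sd)

    if spec.n_dark_spots > 0:
        eligible = ndimage.binary_erosion(
            mask, structure=_ball_footprint(spec.spot_radius)
        )
        flat = np.flatnonzero(eligible)
        if flat.size < spec.n_dark_spots:
            raise GeometryError(
                f"mask cannot host {spec.n_dark_spots} dark spots of radius "
                f"{spec.spot_radius}"
            )
        centers = np.unravel_index(
            rng.choice(flat, size=spec.n_dark_spots, replace=False), shape
        )
        zz, yy, xx = np.ogrid[tuple(slice(0, n) for n in shape)]
        for cz, cy, cx in zip(*centers):
            d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            profile = np.clip(1.0 - d2 / spec.spot_radius**2, 0.0, None)
            img -= spec.spot_depth * profile

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)

    grid = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    label = POSITIVE if spec.class_label == HETEROGENEOUS else NEGATIVE
    return LesionVolume(
        intensities=grid,
        mask=mask,
        voxel_spacing=voxel_spacing,
        lesion_id=lesion_id,
        class_label=label,
    )


def generate_cohort(
    n_per_class: tuple[int, int],
    template: PhantomSpec | None = None,
    seed: int = 0,
    smooth_template: PhantomSpec | None = None,
) -> list[LesionVolume]:
    """Generate a labelled cohort: heterogeneous lesions, then smooth.

    ``template`` parameterizes the heterogeneous class (default:
    :class:`PhantomSpec` defaults); the smooth class derives from it via
    :func:`smooth_spec_from` unless ``smooth_template`` overrides it.
    Per-lesion radii (+/-15%) and brightness (+/-8%) jitter and the field
    seeds come from deterministic per-lesion streams spawned from
    ``seed``, so the cohort is bit-reproducible.
    """
    n_pos, n_neg = n_per_class
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("need at least one lesion per class")
    template = template if template is not None else PhantomSpec()
    smooth = (
        smooth_template
        if smooth_template is not None
        else smooth_spec_from(template)
    )
    smooth.validate(hetero_contrast_sd=template.contrast_sd)

    children = np.random.SeedSequence(seed).spawn(n_pos + n_neg)
    lesions = []
    for i in range(n_pos + n_neg):
        base_spec = template if i < n_pos else smooth
        rng = np.random.default_rng(children[i])
        radii_scale = rng.uniform(0.85, 1.15)
        base_scale = rng.uniform(0.92, 1.08)
        lesion_seed = int(children[i].generate_state(1)[0] & 0x7FFFFFFF)
        spec = dataclasses.replace(
            base_spec,
            lesion_radii=tuple(r * radii_scale for r in base_spec.lesion_radii),
            base_intensity=base_spec.base_intensity * base_scale,
            contrast_sd=base_spec.contrast_sd * base_scale,
            spot_depth=base_spec.spot_depth * base_scale,
            seed=lesion_seed,
        )
        lesion_id = f"endo-{i:03d}" if i < n_pos else f"hc-{i - n_pos:03d}"
        lesions.append(
            generate_lesion(
                spec,
                lesion_id=lesion_id,
                hetero_contrast_sd=template.contrast_sd * base_scale,
            )
        )
    return lesions


def write_cohort(lesions, outdir) -> Path:
    """Write NIfTI image/mask pairs plus a manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for les in lesions:
        affine = np.diag(list(les.voxel_spacing) + [1.0])
        img_name = f"{les.lesion_id}_img.nii.gz"
        mask_name = f"{les.lesion_id}_mask.nii.gz"
        nib.save(
            nib.Nifti1Image(les.intensities.astype(np.uint16), affine),
            str(outdir / img_name),
        )
        nib.save(
            nib.Nifti1Image(les.mask.astype(np.uint8), affine),
            str(outdir / mask_name),
        )
        records.append(
            {
                "lesion_id": les.lesion_id,
                "image": img_name,
                "mask": mask_name,
                "class_label": les.class_label,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest
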