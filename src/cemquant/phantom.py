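"""Synthetic early/late recombined-view phantoms with known lesion contrast.

Each phantom is a pair of 16-bit grayscale images sharing one lesion.  The
lesion is a radially smoothed plateau: pixels inside a core radius sit exactly
at ``sb_level * (1 + peak)`` and a raised-cosine taper brings the profile back
to the background level, so in the noise-free case the lesion-ROI maximum
equals the programmed peak and CE recovery is exact.  The background ROI is
placed well away from the lesion (outside a dilation margin), emulating a
reader choosing non-enhancing fatty tissue.

Noise is additive zero-mean Gaussian with scale ``noise_scale * sb_level``,
clipped to the valid 16-bit range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["PhantomError", "PhantomCase", "generate_phantom", "write_case", "read_case"]

MAX_16BIT = 65535


class PhantomError(ValueError):
    """Raised for invalid phantom parameters or malformed case files."""


@dataclass
class PhantomCase:
    """Early/late image pair with lesion and background ROI masks.

    ``truth`` records the programmed parameters (background level, early and
    late peak amplitudes, noise scale, seed) so recovery can be scored.
    """

    early_image: np.ndarray
    late_image: np.ndarray
    lesion_mask: np.ndarray
    background_mask: np.ndarray
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        shapes = {
            self.early_image.shape,
            self.late_image.shape,
            self.lesion_mask.shape,
            self.background_mask.shape,
        }
        if len(shapes) != 1:
            raise PhantomError(f"images and masks disagree in shape: {shapes}")
        if (self.lesion_mask & self.background_mask).any():
            raise PhantomError("lesion and background masks overlap")
        if not self.lesion_mask.any() or not self.background_mask.any():
            raise PhantomError("both masks must be non-empty")
        for name, img in (("early", self.early_image), ("late", self.late_image)):
            if img.dtype != np.uint16:
                raise PhantomError(f"{name} image must be 16-bit, got {img.dtype}")


def _lesion_profile(shape: tuple[int, int], center: tuple[float, float],
                    core_radius: float, outer_radius: float) -> np.ndarray:
    """Unit-amplitude plateau profile: 1 inside the core, cosine taper to 0."""
    rr, cc = np.indices(shape)
    r = np.hypot(rr - center[0], cc - center[1])
    profile = np.zeros(shape, dtype=float)
    profile[r <= core_radius] = 1.0
    taper = (r > core_radius) & (r < outer_radius)
    t = (r[taper] - core_radius) / (outer_radius - core_radius)
    profile[taper] = 0.5 * (1.0 + np.cos(np.pi * t))
    return profile


def generate_phantom(
    shape: tuple[int, int] = (256, 256),
    sb_level: float = 1000.0,
    peak_early: float = 0.5,
    peak_late: float = 0.5,
    noise_scale: float = 0.0,
    lesion_shape_spec: dict | None = None,
    seed: int = 0,
) -> PhantomCase:
    """Build one phantom case with programmed lesion contrast.

    ``lesion_shape_spec`` accepts ``center`` (row, col), ``core_radius`` and
    ``outer_radius`` in pixels; defaults place a disk of core radius 12 at the
    image center.  The background mask is an annulus-free corner region whose
    pixels all lie beyond ``outer_radius`` plus a dilation margin.
    """
    if peak_early < 0 or peak_late < 0:
        raise PhantomError("peak amplitudes must be non-negative")
    if noise_scale < 0:
        raise PhantomError("noise scale must be non-negative")
    spec = dict(lesion_shape_spec or {})
    center = tuple(spec.get("center", (shape[0] / 2.0, shape[1] / 2.0)))
    core_radius = float(spec.get("core_radius", 12.0))
    outer_radius = float(spec.get("outer_radius", core_radius * 2.0))
    if outer_radius <= core_radius:
        raise PhantomError("outer_radius must exceed core_radius")
    if outer_radius >= min(shape) / 2.0:
        raise PhantomError("lesion larger than image")

    profile = _lesion_profile(shape, center, core_radius, outer_radius)
    rng = np.random.default_rng(seed)

    def render(peak: float) -> np.ndarray:
        img = sb_level * (1.0 + peak * profile)
        if noise_scale > 0:
            img = img + rng.normal(0.0, noise_scale * sb_level, size=shape)
        return np.clip(np.rint(img), 0, MAX_16BIT).astype(np.uint16)

    early = render(peak_early)
    late = render(peak_late)

    rr, cc = np.indices(shape)
    r = np.hypot(rr - center[0], cc - center[1])
    lesion_mask = r <= outer_radius
    # Background excludes a dilation margin around the lesion so the taper
    # and any mis-registration cannot contaminate the background mean.
    margin = 0.5 * (outer_radius - core_radius) + 4.0
    background_mask = r >= outer_radius + margin
    if not background_mask.any():
        raise PhantomError("no room for a background ROI outside the lesion margin")

    case = PhantomCase(
        early_image=early,
        late_image=late,
        lesion_mask=lesion_mask,
        background_mask=background_mask,
        truth={
            "sb_level": sb_level,
            "peak_early": peak_early,
            "peak_late": peak_late,
            "noise_scale": noise_scale,
            "seed": seed,
        },
    )
    case.validate()
    return case


_VIEW_FILES = {"early": "early.tif", "late": "late.tif"}
_MASK_FILES = {"lesion_mask": "lesion_mask.png", "background_mask": "background_mask.png"}


def write_case(case: PhantomCase, directory) -> None:
    """Write a case as 16-bit TIFF views, 8-bit 0/255 PNG masks, JSON truth."""
    case.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / _VIEW_FILES["early"], case.early_image)
    tifffile.imwrite(directory / _VIEW_FILES["late"], case.late_image)
    for attr, fname in _MASK_FILES.items():
        mask = getattr(case, attr)
        Image.fromarray((mask.astype(np.uint8)) * 255).save(directory / fname)
    (directory / "truth.json").write_text(json.dumps(case.truth, indent=2))


def read_case(directory) -> PhantomCase:
    """Read a case directory back; raises on missing views or invalid masks."""
    directory = Path(directory)
    images = {}
    for view, fname in _VIEW_FILES.items():
        path = directory / fname
        if not path.exists():
            raise PhantomError(f"missing {view} view image: {path}")
        img = tifffile.imread(path)
        if img.dtype != np.uint16:
            raise PhantomError(f"{view} view is not 16-bit (dtype {img.dtype})")
        images[view] = img
    masks = {}
    for attr, fname in _MASK_FILES.items():
        path = directory / fname
        if not path.exists():
            raise PhantomError(f"missing mask file: {path}")
        arr = np.asarray(Image.open(path))
        values = set(np.unique(arr).tolist())
        if not values <= {0, 255}:
            raise PhantomError(
                f"{attr} contains values other than 0/255: {sorted(values - {0, 255})}"
            )
        masks[attr] = arr == 255
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    case = PhantomCase(
        early_image=images["early"],
        late_image=images["late"],
        lesion_mask=masks["lesion_mask"],
        background_mask=masks["background_mask"],
        truth=truth,
    )
    case.validate()
    return case
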