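"""Fixed-threshold pixel-fraction quantification of axonal fluorescence.

8-bit images are normalized by 255 (16-bit by 65535) to the [0, 1] range;
a fixed per-channel threshold separates axon fluorescence from background
(0.5 for eYFP alone; 0.04 red / 0.06 green when scoring collaterals), and
density is the fraction of pixels strictly above the threshold. Regional
densities are reported relative to the mean fraction of a reference region
(typically the strongest projection target, the BLA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, ParameterError

__all__ = [
    "ImagePlane",
    "ProjectionQuantification",
    "fraction_above_threshold",
    "relative_density",
]

_MAX_CODE = {np.uint8: 255, np.uint16: 65535}


@dataclass
class ImagePlane:
    """A single 2-D fluorescence image normalized to [0, 1]."""

    data: np.ndarray
    bit_depth: int = 8
    region: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("ImagePlane expects a 2-D array")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise DataError("image must be normalized to [0, 1]; divide 8-bit "
                            "values by 255 (16-bit by 65535) first")

    @classmethod
    def from_array(cls, arr: np.ndarray, region: str = "", channel: str = ""):
        """Normalize a raw integer image (or z-stack) by its max code value.

        3-D input is max-intensity projected along the first axis before
        normalization.
        """
        arr = np.asarray(arr)
        if arr.ndim == 3:
            arr = arr.max(axis=0)
        if arr.dtype == np.uint8:
            return cls(arr / 255.0, 8, region, channel)
        if arr.dtype == np.uint16:
            return cls(arr / 65535.0, 16, region, channel)
        return cls(arr.astype(float), 0, region, channel)

    @classmethod
    def from_tiff(cls, path, region: str = "", channel: str = ""):
        return cls.from_array(tifffile.imread(path), region, channel)


@dataclass
class ProjectionQuantification:
    """Per-region pixel fractions and reference-normalized densities."""

    fractions: dict
    relative: dict
    reference_region: str
    reference_mean: float
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, frs in self.fractions.items():
            for f, r in zip(np.atleast_1d(frs), np.atleast_1d(self.relative[region])):
                rows.append({"region": region, "fraction": f,
                             "relative_density": r})
        return pd.DataFrame(rows)


def fraction_above_threshold(
    image: ImagePlane | np.ndarray, threshold: float, strict: bool = True
) -> float:
    """Fraction of pixels above a fixed threshold.

    ``strict=True`` (default) counts pixels strictly greater than the
    threshold; set False for >=.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    data = image.data if isinstance(image, ImagePlane) else np.asarray(image, float)
    if data.size and data.max() > 1:
        raise DataError("image is not normalized to [0, 1]; normalize first")
    if data.size == 0:
        raise DataError("empty image")
    above = data > threshold if strict else data >= threshold
    return float(above.mean())


def relative_density(
    fractions: dict, reference_region: str, threshold: float | None = None
) -> ProjectionQuantification:
    """Normalize per-region pixel fractions to a reference region's mean.

    ``fractions`` maps region label -> fraction or list of per-image
    fractions. Every value is divided by the mean fraction of
    ``reference_region``, whose own mean maps to exactly 1.
    """
    if reference_region not in fractions:
        raise ParameterError(f"reference region {reference_region!r} missing")
    ref = np.atleast_1d(np.asarray(fractions[reference_region], float))
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise DataError("reference region mean fraction is zero; cannot normalize")
    rel = {region: np.asarray(v, float) / ref_mean
           for region, v in fractions.items()}
    return ProjectionQuantification(
        fractions={k: np.asarray(v, float) for k, v in fractions.items()},
        relative=rel, reference_region=reference_region,
        reference_mean=ref_mean, threshold=threshold)
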