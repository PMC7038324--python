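"""Color-chart based image correction and the R_ave/G_ave ripeness feature.

A printed chart carrying 16 color chips of known reference color is imaged
next to the fruit.  Chip positions are known in the chart's own coordinate
frame; a homography (supplied by a marker-detection front end, or identity
for pre-registered images) maps them into the photograph.  A 3x4 affine
transformation in RGB space is fitted by least squares so that the observed
chip colors match the reference chip colors, and applying it to the whole
frame cancels the illumination of the shot.  The fruit is then segmented by
a bright-background rule (a pixel is background when R, G and B all exceed
90), and the ripeness feature is the ratio of the mean red to the mean green
channel over the fruit's foreground pixels — riper fruit are redder.

Images are numpy arrays of shape (H, W, 3); arithmetic is done in floating
point and values are clipped to [0, 255] and rounded only on export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.draw import polygon as _polygon

__all__ = [
    "ChipRegion",
    "ChartLayout",
    "ChipSample",
    "ColorTransform",
    "ChipLocalizationError",
    "DegenerateChartError",
    "NoForegroundError",
    "UndefinedFeatureError",
    "extract_chips",
    "fit_color_transform",
    "apply_color_transform",
    "remove_background",
    "average_rgb",
    "color_feature",
    "BACKGROUND_THRESHOLD",
    "N_CHIPS",
]

#: Channel value above which (all three channels) a pixel counts as background.
BACKGROUND_THRESHOLD = 90.0
#: Number of chips on the correction chart.
N_CHIPS = 16
#: Fraction of each chip cell (centred) actually sampled, tolerating edge bleed.
CHIP_SAMPLE_FRACTION = 0.6


class ChipLocalizationError(ValueError):
    """A chip region maps (partly) outside the image."""


class DegenerateChartError(ValueError):
    """Observed chip colors do not span a rank-4 design."""


class NoForegroundError(ValueError):
    """Background removal left no foreground pixels."""


class UndefinedFeatureError(ValueError):
    """The color feature is undefined (zero mean green)."""


@dataclass(frozen=True)
class ChipRegion:
    """One chip cell: axis-aligned square in chart coordinates.

    ``x, y`` is the top-left corner and ``size`` the side length, in the
    chart frame (pixels for pre-registered images, marker units otherwise).
    """

    chip_id: int
    x: float
    y: float
    size: float

    def sample_corners(self, fraction: float = CHIP_SAMPLE_FRACTION) -> np.ndarray:
        """Corners (4x2, x/y columns) of the centred sampling square."""
        pad = (1.0 - fraction) / 2.0 * self.size
        x0, y0 = self.x + pad, self.y + pad
        x1, y1 = self.x + self.size - pad, self.y + self.size - pad
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@dataclass(frozen=True)
class ChartLayout:
    """Geometry and reference colors of a 16-chip correction chart."""

    chips: tuple[ChipRegion, ...]
    reference_rgb: Mapping[int, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.chips) != N_CHIPS:
            raise ValueError(f"chart must have exactly {N_CHIPS} chips, got {len(self.chips)}")

    def reference_chips(self) -> list["ChipSample"]:
        """Reference colors as a chip sample list, in layout order."""
        if self.reference_rgb is None:
            raise ValueError("layout carries no reference chip colors")
        return [ChipSample(c.chip_id, tuple(self.reference_rgb[c.chip_id])) for c in self.chips]

    def to_json(self) -> str:
        payload = {
            "chips": [
                {"chip_id": c.chip_id, "x": c.x, "y": c.y, "size": c.size} for c in self.chips
            ],
            "reference_rgb": (
                None
                if self.reference_rgb is None
                else {str(k): list(map(float, v)) for k, v in self.reference_rgb.items()}
            ),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChartLayout":
        payload = json.loads(text)
        chips = tuple(
            ChipRegion(int(c["chip_id"]), float(c["x"]), float(c["y"]), float(c["size"]))
            for c in payload["chips"]
        )
        ref = payload.get("reference_rgb")
        if ref is not None:
            ref = {int(k): tuple(float(x) for x in v) for k, v in ref.items()}
        return cls(chips=chips, reference_rgb=ref)


@dataclass(frozen=True)
class ChipSample:
    """Mean RGB observed over one chip region."""

    chip_id: int
    mean_rgb: tuple[float, float, float]


@dataclass(frozen=True)
class ColorTransform:
    """Affine RGB correction: corrected = matrix @ (r, g, b, 1).

    ``matrix`` is 3x4 (twelve coefficients); ``residual_rms`` is the
    root-mean-square chip residual of the fit, in channel units.
    """

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise ValueError(f"transform matrix must be 3x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix has non-finite coefficients")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "ColorTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))


def _as_float_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"image must have shape (H, W, 3), got {arr.shape}")
    return arr


def extract_chips(
    image: np.ndarray,
    layout: ChartLayout,
    homography: np.ndarray | None = None,
    exclude_mask: np.ndarray | None = None,
) -> list[ChipSample]:
    """Mean RGB per chart chip, sampled through a homography.

    Parameters
    ----------
    image : (H, W, 3) array
    layout : ChartLayout
        Chip cells in chart coordinates.  The central 60% of each cell is
        sampled, to tolerate printing/edge bleed.
    homography : (3, 3) array, optional
        Maps chart (x, y, 1) to image (x, y, 1) homogeneous coordinates.
        Identity when omitted (layout already in pixel coordinates).
    exclude_mask : (H, W) bool array, optional
        Pixels to drop from chip means (True = excluded), e.g. occlusions.

    Raises
    ------
    ChipLocalizationError
        If a chip's sampling region falls (partly) outside the image or is
        fully excluded.
    """
    arr = _as_float_image(image)
    h, w = arr.shape[:2]
    hom = np.eye(3) if homography is None else np.asarray(homography, dtype=float)
    if hom.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {hom.shape}")
    out: list[ChipSample] = []
    for chip in layout.chips:
        corners = chip.sample_corners()
        pts = np.column_stack([corners, np.ones(len(corners))]) @ hom.T
        pts = pts[:, :2] / pts[:, 2:3]
        if (pts[:, 0] < -0.5).any() or (pts[:, 0] > w - 0.5).any() or (
            pts[:, 1] < -0.5
        ).any() or (pts[:, 1] > h - 0.5).any():
            raise ChipLocalizationError(f"chip {chip.chip_id} maps outside the image")
        rr, cc = _polygon(pts[:, 1], pts[:, 0], shape=(h, w))
        if exclude_mask is not None:
            keep = ~np.asarray(exclude_mask, dtype=bool)[rr, cc]
            rr, cc = rr[keep], cc[keep]
        if rr.size == 0:
            raise ChipLocalizationError(f"chip {chip.chip_id} has no sampleable pixels")
        out.append(ChipSample(chip.chip_id, tuple(arr[rr, cc].mean(axis=0))))
    return out


def fit_color_transform(
    reference: Sequence[ChipSample], observed: Sequence[ChipSample]
) -> ColorTransform:
    """Fit the 3x4 RGB correction matrix from 16 chip pairs by least squares.

    For each output channel the model ``channel' = a·(r, g, b, 1)`` is solved
    over the 16 observed chips so that corrected observed colors are closest,
    in the least-squares sense, to the reference colors.

    Raises
    ------
    ValueError
        Chip counts differ from 16 or chip ids mismatch.
    DegenerateChartError
        Observed chip colors span fewer than 4 design dimensions.
    """
    if len(reference) != N_CHIPS or len(observed) != N_CHIPS:
        raise ValueError(f"both chip sets must have exactly {N_CHIPS} chips")
    if [c.chip_id for c in reference] != [c.chip_id for c in observed]:
        raise ValueError("reference and observed chip ids must match in order")
    obs = np.array([c.mean_rgb for c in observed], dtype=float)
    ref = np.array([c.mean_rgb for c in reference], dtype=float)
    design = np.column_stack([obs, np.ones(N_CHIPS)])
    if np.linalg.matrix_rank(design) < 4:
        raise DegenerateChartError("observed chip colors are rank-deficient; cannot fit")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    residual = design @ coef - ref
    return ColorTransform(matrix=coef.T, residual_rms=float(np.sqrt(np.mean(residual**2))))


def apply_color_transform(image: np.ndarray, t: ColorTransform) -> np.ndarray:
    """Apply the RGB correction to every pixel; output clipped to [0, 255]."""
    arr = _as_float_image(image)
    corrected = arr @ t.matrix[:, :3].T + t.matrix[:, 3]
    return np.clip(corrected, 0.0, 255.0)


def remove_background(
    image: np.ndarray, threshold: float = BACKGROUND_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out bright background pixels; return (image, foreground mask).

    A pixel is background when R, G and B are *all* above ``threshold``;
    such pixels are set to (0, 0, 0).  Idempotent: black pixels never satisfy
    the condition.
    """
    arr = _as_float_image(image)
    background = np.all(arr > threshold, axis=-1)
    out = arr.copy()
    out[background] = 0.0
    return out, ~background


def average_rgb(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Per-channel mean over masked pixels: sum of values / number of pixels."""
    arr = _as_float_image(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape[:2]:
        raise ValueError("mask shape must match image height/width")
    if not m.any():
        raise NoForegroundError("mask selects no pixels")
    r, g, b = arr[m].mean(axis=0)
    return float(r), float(g), float(b)


def color_feature(
    image: np.ndarray,
    t: ColorTransform | None = None,
    threshold: float = BACKGROUND_THRESHOLD,
    foreground_only: bool = True,
) -> float:
    """R_ave/G_ave ripeness feature of a fruit photograph.

    Pipeline: apply the color correction, zero the bright background, average
    the channels, and return mean red over mean green.  With
    ``foreground_only=False`` the averages run over all pixels of the
    background-zeroed frame instead of the fruit mask only.

    Raises
    ------
    NoForegroundError
        No pixel survives background removal.
    UndefinedFeatureError
        Mean green is zero.
    """
    corrected = apply_color_transform(image, t) if t is not None else _as_float_image(image)
    cleaned, mask = remove_background(corrected, threshold)
    if foreground_only:
        r_ave, g_ave, _ = average_rgb(cleaned, mask)
    else:
        if not mask.any():
            raise NoForegroundError("image is entirely background")
        r_ave, g_ave, _ = average_rgb(cleaned, np.ones(mask.shape, dtype=bool))
    if g_ave == 0:
        raise UndefinedFeatureError("mean green channel is zero; R/G undefined")
    return r_ave / g_ave
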