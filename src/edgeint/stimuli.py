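"""Synthetic achromatic stimuli.

Every generator returns a :class:`LuminanceImage` paired with a
:class:`RegionMap`.  Luminance is in cd/m², angles in degrees, and the
generated ground truth always satisfies the photometric decomposition
``L = R × I`` (reflectance × illumination) exactly.

All generators are deterministic: the same parameters always produce
byte-identical arrays.  Region boundaries are pixel-aligned — each pixel
belongs to exactly one region, and a boundary is a 4-neighbour label
change — so downstream edge extraction is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

__all__ = [
    "LuminanceImage",
    "RegionMap",
    "StimulusSpec",
    "DEFAULT_SHAPE",
    "DEFAULT_PITCH",
    "make_disk_annulus",
    "make_simultaneous_contrast",
    "make_staircase_gelb",
    "make_coc_edge",
    "make_gradient_background_pair",
    "build_stimulus",
]

#: default canvas: 256×256 px at 0.1 deg/px → 25.6° square field, large
#: enough to place contextual edges 10° or more away from a central target.
DEFAULT_SHAPE = (256, 256)
DEFAULT_PITCH = 0.1


@dataclass
class LuminanceImage:
    """A positive-valued luminance field on a pixel grid.

    Parameters
    ----------
    values
        2D array of luminance in cd/m²; strictly positive everywhere so
        the log-luminance transform is defined at every pixel.
    pitch
        Angular size of one pixel, deg/px.
    reflectance, illumination
        Optional ground-truth decomposition with
        ``values == reflectance * illumination`` elementwise.
        Reflectance is unitless in (0, 1]; illumination is on the cd/m²
        scale of the incident light.
    """

    values: np.ndarray
    pitch: float
    reflectance: Optional[np.ndarray] = None
    illumination: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("luminance values must be a 2D grid")
        if not np.all(self.values > 0):
            raise ValueError("all luminances must be strictly positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive (deg/px)")
        if (self.reflectance is None) != (self.illumination is None):
            raise ValueError("ground truth needs both reflectance and illumination")
        if self.reflectance is not None:
            R = np.asarray(self.reflectance, dtype=float)
            I = np.asarray(self.illumination, dtype=float)
            if R.shape != self.values.shape or I.shape != self.values.shape:
                raise ValueError("ground-truth arrays must match the luminance grid")
            if not (np.all(R > 0) and np.all(R <= 1.0 + 1e-12)):
                raise ValueError("reflectance must lie in (0, 1]")
            if not np.allclose(self.values, R * I, rtol=1e-9, atol=0.0):
                raise ValueError("ground truth violates L = R × I")
            self.reflectance, self.illumination = R, I

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def has_ground_truth(self) -> bool:
        return self.reflectance is not None

    def log_values(self) -> np.ndarray:
        """Natural log of the luminance field."""
        return np.log(self.values)


@dataclass
class RegionMap:
    """Integer surface labels per pixel plus the designated background."""

    labels: np.ndarray
    background_label: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D grid")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if self.background_label not in np.unique(self.labels):
            raise ValueError("background_label does not occur in the map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class StimulusSpec:
    """Declarative description of a generated stimulus.

    ``kind`` selects the generator; ``params`` are its keyword arguments
    (geometry in deg, photometry in cd/m² or reflectance units).
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    KINDS = (
        "disk_annulus",
        "simultaneous_contrast",
        "staircase_gelb",
        "coc_edge",
        "gradient_background_pair",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")


def _grid(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in degrees, origin at the image centre."""
    h, w = shape
    y = (np.arange(h) - (h - 1) / 2.0) * pitch
    x = (np.arange(w) - (w - 1) / 2.0) * pitch
    return np.meshgrid(y, x, indexing="ij")


def _check_positive(**lums: float) -> None:
    for name, v in lums.items():
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")


def _with_ground_truth(values: np.ndarray, pitch: float) -> LuminanceImage:
    """Attach a trivially consistent R×I decomposition to a luminance field.

    The brightest pixel is assigned reflectance 0.9 under a spatially
    uniform illuminant; this is the generic fallback for stimuli whose
    parameters are given directly in luminance rather than reflectance.
    """
    illum_level = float(values.max()) / 0.9
    I = np.full_like(values, illum_level)
    R = values / I
    return LuminanceImage(values=values, pitch=pitch, reflectance=R, illumination=I)


def make_disk_annulus(
    disk_lum: float,
    annulus_lum: float,
    bg_lum: float,
    disk_radius: float = 1.0,
    annulus_outer_radius: float = 3.0,
    pitch: float = DEFAULT_PITCH,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[LuminanceImage, RegionMap]:
    """Concentric disk + annulus on a uniform background.

    Labels: background 0, annulus 1, disk 2.  A "double-increment"
    display (disk > annulus > background) has both annulus edges of the
    light-inside polarity; a decremental disk (disk < annulus) drives
    the darkness channel from its inner edge.
    """
    _check_positive(disk_lum=disk_lum, annulus_lum=annulus_lum, bg_lum=bg_lum)
    if not 0 < disk_radius < annulus_outer_radius:
        raise ValueError("need 0 < disk_radius < annulus_outer_radius")
    yy, xx = _grid(shape, pitch)
    cy, cx = center
    r = np.hypot(yy - cy, xx - cx)
    half_extent = min(shape) * pitch / 2.0
    if annulus_outer_radius + abs(cy) >= half_extent or annulus_outer_radius + abs(cx) >= half_extent:
        raise ValueError("annulus does not fit inside the image")
    labels = np.zeros(shape, dtype=int)
    labels[r <= annulus_outer_radius] = 1
    labels[r <= disk_radius] = 2
    values = np.full(shape, float(bg_lum))
    values[labels == 1] = annulus_lum
    values[labels == 2] = disk_lum
    return _with_ground_truth(values, pitch), RegionMap(labels, background_label=0)


def make_simultaneous_contrast(
    target_lum: float = 50.0,
    dark_bg_lum: float = 10.0,
    light_bg_lum: float = 250.0,
    target_size: float = 2.0,
    pitch: float = DEFAULT_PITCH,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> tuple[LuminanceImage, RegionMap]:
    """Classic simultaneous-contrast display: equal-luminance squares on a
    dark left half-field and a light right half-field.

    Labels: dark field 0 (background), light field 1, left target 2,
    right target 3.
    """
    _check_positive(target_lum=target_lum, dark_bg_lum=dark_bg_lum, light_bg_lum=light_bg_lum)
    yy, xx = _grid(shape, pitch)
    labels = np.zeros(shape, dtype=int)
    labels[xx > 0] = 1
    half = target_size / 2.0
    quarter = shape[1] * pitch / 4.0
    if half >= quarter:
        raise ValueError("target does not fit inside its half-field")
    left = (np.abs(yy) <= half) & (np.abs(xx + quarter) <= half)
    right = (np.abs(yy) <= half) & (np.abs(xx - quarter) <= half)
    labels[left] = 2
    labels[right] = 3
    values = np.where(labels == 1, float(light_bg_lum), float(dark_bg_lum))
    values[left | right] = target_lum
    return _with_ground_truth(values, pitch), RegionMap(labels, background_label=0)


def make_staircase_gelb(
    reflectances: "list[float] | np.ndarray",
    spotlight_illum: float = 1000.0,
    bg_lum: float = 1.0,
    paper_size: float = 3.0,
    gap: float = 0.0,
    frame: Optional[dict] = None,
    pitch: float = DEFAULT_PITCH,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> tuple[LuminanceImage, RegionMap]:
    """Row of achromatic papers in a common spotlight (staircase-Gelb).

    Paper *i* has luminance ``reflectances[i] * spotlight_illum``.  With
    ``gap=0`` the papers abut, so neighbouring papers share a border.
    ``frame={"reflectance": r, "thickness": t}`` inserts a constant-
    thickness insulating ring around the whole row so that papers touch
    only the frame, never the background.

    Labels: background 0, papers 1..n left to right, frame n+1.
    """
    refl = np.asarray(reflectances, dtype=float)
    if refl.ndim != 1 or refl.size < 2:
        raise ValueError("need at least 2 papers")
    if np.any(refl <= 0) or np.any(refl > 1.0):
        raise ValueError("reflectances must lie in (0, 1]")
    _check_positive(spotlight_illum=spotlight_illum, bg_lum=bg_lum)
    if gap < 0:
        raise ValueError("gap must be non-negative")
    n = refl.size
    h, w = shape
    paper_px = int(round(paper_size / pitch))
    gap_px = int(round(gap / pitch))
    if paper_px < 1:
        raise ValueError("paper thinner than one pixel")
    row_w = n * paper_px + (n - 1) * gap_px
    frame_px = 0
    frame_refl = None
    if frame is not None:
        frame_refl = float(frame["reflectance"])
        frame_px = int(round(float(frame["thickness"]) / pitch))
        if frame_px < 1:
            raise ValueError("frame thinner than one pixel")
        if not 0 < frame_refl <= 1.0:
            raise ValueError("frame reflectance must lie in (0, 1]")
    total_w = row_w + 2 * frame_px
    total_h = paper_px + 2 * frame_px
    if total_w >= w or total_h >= h:
        raise ValueError("paper row (plus frame) does not fit inside the image")

    labels = np.zeros(shape, dtype=int)
    r0 = (h - paper_px) // 2
    c_start = (w - row_w) // 2
    for i in range(n):
        c0 = c_start + i * (paper_px + gap_px)
        labels[r0 : r0 + paper_px, c0 : c0 + paper_px] = i + 1
    if frame_px:
        frame_label = n + 1
        fr0, fc0 = r0 - frame_px, c_start - frame_px
        ring = np.zeros(shape, dtype=bool)
        ring[fr0 : r0 + paper_px + frame_px, fc0 : c_start + row_w + frame_px] = True
        ring &= labels == 0
        if gap_px:
            # frame also fills the gaps so papers never touch background
            ring |= (labels == 0) & (np.arange(h)[:, None] >= r0) & (
                np.arange(h)[:, None] < r0 + paper_px
            ) & (np.arange(w)[None, :] >= c_start) & (np.arange(w)[None, :] < c_start + row_w)
        labels[ring] = frame_label

    I = np.full(shape, float(spotlight_illum))
    R = np.full(shape, bg_lum / spotlight_illum)
    if np.any(R > 1.0):
        raise ValueError("background luminance exceeds the spotlight illuminant")
    for i in range(n):
        R[labels == i + 1] = refl[i]
    if frame_px:
        R[labels == n + 1] = frame_refl
    values = R * I
    img = LuminanceImage(values=values, pitch=pitch, reflectance=R, illumination=I)
    return img, RegionMap(labels, background_label=0)


def make_coc_edge(
    plateau_lum: float = 100.0,
    cusp_amplitude: float = 25.0,
    cusp_width: float = 3.0,
    image_width: float = DEFAULT_SHAPE[1] * DEFAULT_PITCH,
    pitch: float = DEFAULT_PITCH,
    height_px: int = 64,
) -> tuple[LuminanceImage, RegionMap]:
    """Craik–O'Brien–Cornsweet edge.

    A horizontal luminance profile equal far left and far right, with a
    light exponential cusp to the left of centre and a dark cusp to the
    right, meeting at a central step of height ``2 * cusp_amplitude``.
    The cusps decay with space constant ``cusp_width / 3``.

    Labels: left half 0 (background), right half 1.
    """
    _check_positive(plateau_lum=plateau_lum)
    if cusp_amplitude < 0:
        raise ValueError("cusp amplitude must be non-negative")
    if cusp_amplitude >= plateau_lum:
        raise ValueError("cusp amplitude must be smaller than the plateau luminance")
    w = int(round(image_width / pitch))
    if w < 4:
        raise ValueError("image too narrow")
    x = (np.arange(w) - (w - 1) / 2.0) * pitch
    tau = cusp_width / 3.0
    profile = np.full(w, float(plateau_lum))
    left = x < 0
    # edge sits between the two pixels straddling x = 0; the cusp peaks
    # (plateau ± amplitude) at the two pixels abutting the edge, so the
    # central step height is exactly 2 × cusp_amplitude
    profile[left] += cusp_amplitude * np.exp((x[left] + pitch / 2) / tau)
    profile[~left] -= cusp_amplitude * np.exp(-(x[~left] - pitch / 2) / tau)
    values = np.tile(profile, (height_px, 1))
    labels = np.zeros((height_px, w), dtype=int)
    labels[:, ~left] = 1
    return _with_ground_truth(values, pitch), RegionMap(labels, background_label=0)


def make_gradient_background_pair(
    disk_lum: float = 40.0,
    annulus_lum: float = 55.0,
    bg_lum_left: float = 20.0,
    bg_lum_right: float = 150.0,
    disk_radius: float = 1.0,
    annulus_outer_radius: float = 2.5,
    pitch: float = DEFAULT_PITCH,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> tuple[LuminanceImage, RegionMap]:
    """Two identical disk–annulus patterns on a left-to-right luminance ramp.

    The background ramps linearly from ``bg_lum_left`` to
    ``bg_lum_right``; with the annulus luminance between the two local
    background levels, the annulus/background log ratio has opposite
    sign on the two sides while the disks and annuli themselves are
    photometrically identical.

    Labels: background 0, left annulus 1, left disk 2, right annulus 3,
    right disk 4.
    """
    _check_positive(
        disk_lum=disk_lum,
        annulus_lum=annulus_lum,
        bg_lum_left=bg_lum_left,
        bg_lum_right=bg_lum_right,
    )
    yy, xx = _grid(shape, pitch)
    width = shape[1] * pitch
    # linear ramp in x
    t = (xx - xx.min()) / (xx.max() - xx.min())
    values = bg_lum_left + (bg_lum_right - bg_lum_left) * t
    if np.any(values <= 0):
        raise ValueError("ramp drives background luminance non-positive")
    labels = np.zeros(shape, dtype=int)
    offset = width / 4.0
    if annulus_outer_radius >= offset:
        raise ValueError("patterns do not fit on their half-fields")
    for side, (cx, lab_ann, lab_disk) in enumerate(
        [(-offset, 1, 2), (offset, 3, 4)]
    ):
        r = np.hypot(yy, xx - cx)
        labels[r <= annulus_outer_radius] = lab_ann
        labels[r <= disk_radius] = lab_disk
    values = np.where(np.isin(labels, [1, 3]), float(annulus_lum), values)
    values = np.where(np.isin(labels, [2, 4]), float(disk_lum), values)
    return _with_ground_truth(values, pitch), RegionMap(labels, background_label=0)


_GENERATORS = {
    "disk_annulus": make_disk_annulus,
    "simultaneous_contrast": make_simultaneous_contrast,
    "staircase_gelb": make_staircase_gelb,
    "coc_edge": make_coc_edge,
    "gradient_background_pair": make_gradient_background_pair,
}


def build_stimulus(spec: StimulusSpec) -> tuple[LuminanceImage, RegionMap]:
    """Dispatch a :class:`StimulusSpec` to its generator."""
    return _GENERATORS[spec.kind](**spec.params)
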