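"""Post-V4 readout: achromatic color, anchoring, per-region estimates.

The signed achromatic-color signal AC(x) = L(x) − D(x) is a *relative*
quantity; anchoring maps it onto an absolute reflectance scale by
assigning a standard white reflectance (default 0.9) to an anchor
region — either the region of highest integrated lightness
(``highest_reflectance``, the default) or the region of highest
luminance (``highest_luminance``) — and scaling every other region by
``exp`` of its lightness difference from the anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .contrast import extract_edges
from .integration import ChannelMaps, ModelConfig, compute_channel_maps, path_lightness
from .selection import SpotlightSpec, apply_gain_field, build_region_graph, select_paths
from .stimuli import LuminanceImage, RegionMap

__all__ = [
    "AchromaticMap",
    "LightnessEstimate",
    "compute_ac",
    "anchor",
    "anchor_map",
    "estimate_region_lightness",
    "estimate_all_regions",
    "estimates_to_frame",
    "R_WHITE",
]

#: conventional reflectance of white paper used as the anchor value.
R_WHITE = 0.9


@dataclass
class AchromaticMap:
    """Signed achromatic color AC(x), optionally anchored to reflectance."""

    AC: np.ndarray
    anchored_reflectance: Optional[np.ndarray] = None
    anchor_rule: Optional[str] = None
    anchor_region: Optional[int] = None
    anchor_value: Optional[float] = None


@dataclass
class LightnessEstimate:
    """Scalar lightness of one region.

    ``lam`` is the integrated lightness Λ (log-luminance units);
    ``estimated_reflectance`` is set once anchored.
    """

    region: int
    lam: float
    luminance: float
    true_reflectance: Optional[float] = None
    estimated_reflectance: Optional[float] = None
    anchored: bool = False


def compute_ac(channels: ChannelMaps) -> AchromaticMap:
    """AC(x) = L(x) − D(x), pointwise."""
    return AchromaticMap(AC=channels.L - channels.D)


def _region_interior_means(
    values: np.ndarray, regions: RegionMap, band_px: float = 2.0
) -> dict[int, float]:
    """Mean of ``values`` over each region's interior (≥ band_px from its
    boundary), falling back to the whole region when it is too thin."""
    out = {}
    for lab in regions.region_labels():
        m = regions.labels == lab
        dist = ndimage.distance_transform_edt(m)
        interior = dist > band_px
        sel = interior if interior.any() else m
        out[int(lab)] = float(values[sel].mean())
    return out


def anchor_map(
    ac_map: AchromaticMap,
    regions: RegionMap,
    rule: str = "highest_reflectance",
    r_white: float = R_WHITE,
    image: Optional[LuminanceImage] = None,
) -> AchromaticMap:
    """Anchor an AC map to a reflectance scale.

    The anchor level is the maximum over regions of the region-interior
    mean (not the raw pixel max, which is dominated by boundary bands).
    """
    if rule not in ("highest_reflectance", "highest_luminance"):
        raise ValueError("rule must be highest_reflectance or highest_luminance")
    ac_means = _region_interior_means(ac_map.AC, regions)
    if rule == "highest_reflectance":
        anchor_region = max(ac_means, key=lambda k: ac_means[k])
    else:
        if image is None:
            raise ValueError("highest_luminance anchoring needs the stimulus image")
        lum_means = _region_interior_means(image.values, regions)
        anchor_region = max(lum_means, key=lambda k: lum_means[k])
    ac_anchor = ac_means[anchor_region]
    return AchromaticMap(
        AC=ac_map.AC,
        anchored_reflectance=r_white * np.exp(ac_map.AC - ac_anchor),
        anchor_rule=rule,
        anchor_region=anchor_region,
        anchor_value=ac_anchor,
    )


def anchor(
    estimates: Sequence[LightnessEstimate],
    rule: str = "highest_reflectance",
    r_white: float = R_WHITE,
) -> list[LightnessEstimate]:
    """Anchor a set of per-region estimates.

    ``highest_reflectance``: the region with maximal Λ becomes white
    (reflectance ``r_white``); every other region is scaled by
    exp(Λ_i − Λ_max), so ordering by Λ is preserved.
    ``highest_luminance``: the region of maximal luminance becomes the
    white anchor instead.  Anchoring an already-anchored set recomputes
    the same values (idempotent).
    """
    if not estimates:
        raise ValueError("no estimates to anchor")
    if rule == "highest_reflectance":
        ref = max(estimates, key=lambda e: e.lam)
    elif rule == "highest_luminance":
        ref = max(estimates, key=lambda e: e.luminance)
    else:
        raise ValueError("rule must be highest_reflectance or highest_luminance")
    out = []
    for e in estimates:
        out.append(
            replace(
                e,
                estimated_reflectance=r_white * math.exp(e.lam - ref.lam),
                anchored=True,
            )
        )
    return out


def _pipeline(
    image: LuminanceImage,
    regions: RegionMap,
    spotlight: SpotlightSpec,
    config: ModelConfig,
):
    edges = extract_edges(image, regions)
    edges = apply_gain_field(edges, spotlight)
    graph = build_region_graph(regions, edges)
    return edges, graph


def estimate_region_lightness(
    image: LuminanceImage,
    regions: RegionMap,
    target: int,
    spotlight: Optional[SpotlightSpec] = None,
    config: Optional[ModelConfig] = None,
) -> LightnessEstimate:
    """Full pipeline for one target region.

    extract edges → classify sharpness → apply top-down gains → select
    paths → integrate.  Deterministic; the returned estimate is
    unanchored (Λ only) — use :func:`anchor` on a set of estimates.
    """
    spotlight = spotlight or SpotlightSpec()
    config = config or ModelConfig()
    edges, graph = _pipeline(image, regions, spotlight, config)
    paths = select_paths(graph, target, spotlight)
    lam = path_lightness(paths, edges, config, regions)
    mask = regions.labels == target
    true_r = None
    if image.has_ground_truth:
        true_r = float(np.median(image.reflectance[mask]))
    return LightnessEstimate(
        region=target,
        lam=lam,
        luminance=float(image.values[mask].mean()),
        true_reflectance=true_r,
    )


def estimate_all_regions(
    image: LuminanceImage,
    regions: RegionMap,
    targets: Optional[Sequence[int]] = None,
    spotlight: Optional[SpotlightSpec] = None,
    config: Optional[ModelConfig] = None,
    anchor_rule: Optional[str] = "highest_reflectance",
    r_white: float = R_WHITE,
) -> list[LightnessEstimate]:
    """Estimate every (non-background) region, optionally anchored."""
    spotlight = spotlight or SpotlightSpec()
    config = config or ModelConfig()
    if targets is None:
        targets = [
            int(l) for l in regions.region_labels() if l != regions.background_label
        ]
    edges, graph = _pipeline(image, regions, spotlight, config)
    estimates = []
    for t in targets:
        paths = select_paths(graph, t, spotlight)
        lam = path_lightness(paths, edges, config, regions)
        mask = regions.labels == t
        true_r = None
        if image.has_ground_truth:
            true_r = float(np.median(image.reflectance[mask]))
        estimates.append(
            LightnessEstimate(
                region=t,
                lam=lam,
                luminance=float(image.values[mask].mean()),
                true_reflectance=true_r,
            )
        )
    if anchor_rule is not None:
        estimates = anchor(estimates, rule=anchor_rule, r_white=r_white)
    return estimates


def estimates_to_frame(estimates: Sequence[LightnessEstimate], anchor_rule: str = "") -> pd.DataFrame:
    """Per-region estimates as a table for CSV export."""
    return pd.DataFrame(
        [
            {
                "region": e.region,
                "luminance": e.luminance,
                "true_reflectance": e.true_reflectance,
                "lightness": e.lam,
                "estimated_reflectance": e.estimated_reflectance,
                "anchor_rule": anchor_rule if e.anchored else "",
            }
            for e in estimates
        ]
    )
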