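"""Foreground pixel areas per channel, overlap subtraction, co-culture arithmetic.

All cell-fate measures are pixel ratios, so this module reduces binary masks
to integer pixel counts: per-channel areas summed over all z-slices, and
pairwise intersection counts computed slice-wise in 2D (never on a
z-projection, which would merge distinct cells).  Cells labeled by both
death markers (EtHd and Apopxin) are counted once via inclusion-exclusion,
and in co-culture the H2B-eGFP lineage's pixels are removed from the nuclear
and dead counts by subtracting intersections, which cannot go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .image_io import ChannelRole

__all__ = [
    "ChannelAreas", "CocultureAreas", "measure_areas", "dead_area",
    "coculture_areas", "coloc_fraction",
]

RolePair = frozenset


@dataclass
class ChannelAreas:
    """Per-(well, position) foreground pixel counts and pairwise intersections."""

    well: str
    position: int
    area: dict[ChannelRole, int] = field(default_factory=dict)
    intersections: dict[frozenset, int] = field(default_factory=dict)

    def intersection(self, a: ChannelRole, b: ChannelRole) -> int:
        return self.intersections.get(frozenset((a, b)), 0)


@dataclass
class CocultureAreas:
    """Channel arithmetic for a GFP-lineage co-culture position.

    ``*_target`` counts exclude the GFP lineage (e.g. melanoma-only pixels);
    ``ethd_fibroblast`` is the dead area attributable to the GFP lineage.
    """

    hoechst_total: int
    gfp: int
    ethd_total: int
    hoechst_target: int
    ethd_target: int
    ethd_fibroblast: int


def measure_areas(
    masks: Mapping[ChannelRole, Sequence[np.ndarray] | np.ndarray],
    well: str = "",
    position: int = 0,
) -> ChannelAreas:
    """Count foreground pixels per channel and per role-pair intersection.

    ``masks[role]`` is the per-slice binary mask stack for that channel; all
    stacks must share slice count and shape.  Counts are sums over slices of
    per-slice counts, so the result is invariant to slice order.
    """
    stacks = {ChannelRole(r): np.asarray(m, dtype=bool) for r, m in masks.items()}
    shapes = {m.shape for m in stacks.values()}
    if len(shapes) > 1:
        raise ValueError(f"mask stacks differ in shape: {sorted(shapes)}")
    areas = ChannelAreas(well=well, position=position)
    roles = sorted(stacks, key=lambda r: r.value)
    for r in roles:
        areas.area[r] = int(stacks[r].sum())
    for i, a in enumerate(roles):
        for b in roles[i + 1:]:
            areas.intersections[frozenset((a, b))] = int((stacks[a] & stacks[b]).sum())
    return areas


def dead_area(areas: ChannelAreas) -> int:
    """Total dead-cell pixels with the dual-marker overlap counted once.

    ``|EtHd| + |Apopxin| - |EtHd ∩ Apopxin|``; if only one death channel was
    configured (e.g. co-culture runs drop Apopxin) its area is returned
    as-is.
    """
    e = areas.area.get(ChannelRole.DEAD_MEMBRANE)
    a = areas.area.get(ChannelRole.DEAD_APOPTOTIC)
    if e is None and a is None:
        raise ValueError("no death channel measured")
    if a is None:
        return e
    if e is None:
        return a
    return e + a - areas.intersection(ChannelRole.DEAD_MEMBRANE, ChannelRole.DEAD_APOPTOTIC)


def coculture_areas(areas: ChannelAreas, subtract_mode: str = "intersection") -> CocultureAreas:
    """Split nuclear and dead areas into GFP-lineage and target-cell parts.

    Default mode subtracts the *intersection* of each channel with GFP, which
    is non-negative by construction even when GFP bleeds outside Hoechst;
    ``subtract_mode="raw"`` subtracts the raw GFP area (clamped at zero) for
    parity studies with literal-subtraction processing.
    """
    if ChannelRole.LINEAGE_GFP not in areas.area:
        raise ValueError("lineage_gfp channel not measured")
    hoechst = areas.area[ChannelRole.NUCLEAR]
    gfp = areas.area[ChannelRole.LINEAGE_GFP]
    ethd = areas.area.get(ChannelRole.DEAD_MEMBRANE, 0)
    gfp_in_hoechst = areas.intersection(ChannelRole.NUCLEAR, ChannelRole.LINEAGE_GFP)
    gfp_in_ethd = areas.intersection(ChannelRole.DEAD_MEMBRANE, ChannelRole.LINEAGE_GFP)
    if subtract_mode == "intersection":
        hoechst_target = hoechst - gfp_in_hoechst
        ethd_target = ethd - gfp_in_ethd
    elif subtract_mode == "raw":
        hoechst_target = max(hoechst - gfp, 0)
        ethd_target = max(ethd - gfp, 0)
    else:
        raise ValueError(f"unknown subtract_mode {subtract_mode!r}")
    return CocultureAreas(
        hoechst_total=hoechst, gfp=gfp, ethd_total=ethd,
        hoechst_target=hoechst_target, ethd_target=ethd_target,
        ethd_fibroblast=gfp_in_ethd,
    )


def coloc_fraction(areas: ChannelAreas, a: ChannelRole, b: ChannelRole) -> float | None:
    """Fraction of channel ``b``'s area that also lies in channel ``a``.

    Used as the co-culture QC check (GFP-in-Hoechst fraction should exceed
    0.8 for a pure GFP lineage).  Returns None when ``area[b]`` is zero
    (undefined, reported as missing).
    """
    a, b = ChannelRole(a), ChannelRole(b)
    denom = areas.area.get(b, 0)
    if denom == 0:
        return None
    return areas.intersection(a, b) / denom
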