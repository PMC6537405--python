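"""Seeded generator of ground-truthed multi-channel z-stacks.

The generator emulates the imaging physics the pipeline must cope with so
that every stage is testable without microscope data: nuclei with
fate-dependent marker expression (Hoechst in every cell, EtHd in
membrane-compromised cells, an Apopxin membrane ring in apoptotic cells, EdU
in S-phase cells, H2B-eGFP in a tagged lineage), out-of-focus halos that
grow dimmer and blurrier with z-distance from a cell's in-focus slice,
center-bright vignetting, a constant background level, and Gaussian detector
read noise.  Everything is deterministic under a fixed seed, down to file
bytes when a plate is written to disk.

A cell is a solid ball: slices cutting it render full-intensity Gaussian
cross-section disks (``blob_sharpness`` generalizes the profile to a
super-Gaussian), and slices beyond it render halos that dim exponentially
with physical defocus distance — pinned to ``halo_scale`` of the in-focus
peak at one nucleus radius — while broadening.  Gaussian blob skirts give
the intensity histogram the smooth heavy tail characteristic of fluorescence
images, which is what lets Yen's criterion sit well above the background.
The per-channel ground truth is the set of voxels whose noiseless,
vignetting-free rendering is strictly brighter than the brightest
out-of-focus structure (``halo_scale * nucleus_mean``): the planted
"in-focus" foreground a correct threshold should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .image_io import ChannelRole, ImageStack, PlateLayout, StackKey, write_stack

__all__ = [
    "FateFractions", "IntensityParams", "SceneParams", "CellTruth",
    "SyntheticScene", "DoseResponse", "PlateSimulation",
    "simulate_scene", "render_channel", "render_ideal_channel", "simulate_plate",
    "DEFAULT_CHANNEL_TOKENS",
]

#: filename tokens used when synthetic plates are written to disk
DEFAULT_CHANNEL_TOKENS = {
    ChannelRole.NUCLEAR: "hoechst",
    ChannelRole.DEAD_MEMBRANE: "ethd",
    ChannelRole.DEAD_APOPTOTIC: "apopxin",
    ChannelRole.PROLIFERATION: "edu",
    ChannelRole.LINEAGE_GFP: "gfp",
}

_ROLE_INDEX = {r: i for i, r in enumerate(ChannelRole)}


@dataclass
class FateFractions:
    """Cell-fate probabilities.

    ``dead_ethd``/``dead_apopxin``/``dead_both`` are mutually exclusive death
    categories (a both-marked cell is counted once in death totals); the
    defaults model the appreciable baseline death of vehicle-treated 3D
    collagen cultures.  ``s_phase`` applies to every cell independently of
    death (EdU incorporated during S phase persists in cells that later
    die); ``gfp_lineage`` is the fraction of cells belonging to the tagged
    (drug-insensitive) lineage, whose own EtHd-death probability is
    ``gfp_dead_ethd`` regardless of treatment.
    """

    dead_ethd: float = 0.10
    dead_apopxin: float = 0.06
    dead_both: float = 0.04
    s_phase: float = 0.4
    gfp_lineage: float = 0.0
    gfp_dead_ethd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("dead_ethd", "dead_apopxin", "dead_both", "s_phase",
                     "gfp_lineage", "gfp_dead_ethd"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dead_total > 1:
            raise ValueError("death fractions sum above 1")

    @property
    def dead_total(self) -> float:
        return self.dead_ethd + self.dead_apopxin + self.dead_both


@dataclass
class IntensityParams:
    """Photometric settings (arbitrary detector units, 16-bit range)."""

    nucleus_mean: float = 2000.0
    halo_scale: float = 0.3    # halo peak relative to in-focus at one radius of defocus
    noise_sd: float = 15.0
    background: float = 80.0   # stray light / matrix autofluorescence level


@dataclass
class SceneParams:
    """Everything needed to generate one position's multi-channel stack."""

    n_cells: int = 150
    volume_shape: tuple[int, int, int] = (16, 256, 256)  # (z, y, x)
    nucleus_radius_px: float = 4.0
    fractions: FateFractions = field(default_factory=FateFractions)
    intensity: IntensityParams = field(default_factory=IntensityParams)
    vignetting_strength: float = 0.5
    z_psf_sigma: float = 0.3   # fractional blur growth per slice of defocus
    z_step_px: float = 3.0     # z-slice spacing expressed in xy pixels (anisotropy)
    blob_sharpness: float = 2.0
    z_range: tuple[float, float] | None = None  # in-focus z placement range (slices)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be > 0")
        if not 0 <= self.vignetting_strength < 1:
            raise ValueError("vignetting_strength must be in [0, 1)")
        nz, ny, nx = self.volume_shape
        ball_slices = max(2 * self.nucleus_radius_px / self.z_step_px, 1.0)
        density = self.n_cells * math.pi * self.nucleus_radius_px ** 2 \
            * ball_slices / (nz * ny * nx)
        if density > 0.2:
            raise ValueError(
                f"infeasible density: expected nucleus volume fraction "
                f"{density:.2f} > 0.2; enlarge the volume or drop cells"
            )


@dataclass
class CellTruth:
    """Ground-truth record for one simulated cell."""

    center: tuple[float, float, float]  # (z, y, x)
    alive: bool
    ethd: bool
    apopxin: bool
    s_phase: bool
    gfp: bool


@dataclass
class SyntheticScene:
    """Cell list plus per-channel ground-truth voxel masks and counts."""

    params: SceneParams
    cells: list[CellTruth]
    ground_truth: dict[ChannelRole, np.ndarray] = field(default_factory=dict)

    def truth_count(self, role: ChannelRole) -> int:
        return int(self.ground_truth[role].sum()) if role in self.ground_truth else 0

    def fate_counts(self) -> dict[str, int]:
        c = {"alive": 0, "ethd_only": 0, "apopxin_only": 0, "both": 0,
             "s_phase": 0, "gfp": 0}
        for cell in self.cells:
            if cell.gfp:
                c["gfp"] += 1
            if cell.ethd and cell.apopxin:
                c["both"] += 1
            elif cell.ethd:
                c["ethd_only"] += 1
            elif cell.apopxin:
                c["apopxin_only"] += 1
            else:
                c["alive"] += 1
            if cell.s_phase:
                c["s_phase"] += 1
        return c


def simulate_scene(params: SceneParams) -> SyntheticScene:
    """Place cells uniformly at random and draw fate flags (seeded).

    Placement is hard-sphere: nuclei are mutually exclusive volumes, so
    candidate centers closer than 1.6 radii (z scaled by ``z_step_px``) to
    an accepted cell are rejected and redrawn.  RNG call order (fixed
    contract for reproducibility): cell centers (one (z, y, x) triple per
    candidate), GFP lineage permutation, death-category multinomial over
    non-GFP cells, GFP death multinomial, S-phase uniforms over all cells.
    Ground-truth masks are the noiseless renders cut strictly above the halo
    peak level.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.volume_shape
    r = params.nucleus_radius_px
    n = params.n_cells

    zlo, zhi = params.z_range if params.z_range is not None else (0.0, nz - 1.0)
    min_sep2 = (1.6 * r) ** 2
    step = params.z_step_px
    zs = np.empty(n)
    ys = np.empty(n)
    xs = np.empty(n)
    placed = 0
    attempts = 0
    while placed < n:
        if attempts > 200 * max(n, 1):
            raise ValueError(
                f"infeasible density: placed only {placed}/{n} cells with "
                f"minimum separation {1.6 * r:.1f} px"
            )
        attempts += 1
        z = rng.uniform(zlo, zhi)
        y = rng.uniform(r, ny - 1 - r)
        x = rng.uniform(r, nx - 1 - r)
        if placed:
            d2 = ((zs[:placed] - z) * step) ** 2 + (ys[:placed] - y) ** 2 \
                + (xs[:placed] - x) ** 2
            if d2.min() < min_sep2:
                continue
        zs[placed], ys[placed], xs[placed] = z, y, x
        placed += 1

    f = params.fractions
    n_gfp = int(round(f.gfp_lineage * n))
    gfp = np.zeros(n, dtype=bool)
    gfp[rng.permutation(n)[:n_gfp]] = True

    ethd = np.zeros(n, dtype=bool)
    apop = np.zeros(n, dtype=bool)
    target_idx = np.flatnonzero(~gfp)
    probs = [1.0 - f.dead_total, f.dead_ethd, f.dead_apopxin, f.dead_both]
    counts = rng.multinomial(len(target_idx), probs)
    j = counts[0]
    ethd[target_idx[j:j + counts[1]]] = True
    j += counts[1]
    apop[target_idx[j:j + counts[2]]] = True
    j += counts[2]
    ethd[target_idx[j:]] = True
    apop[target_idx[j:]] = True

    gfp_idx = np.flatnonzero(gfp)
    g_counts = rng.multinomial(len(gfp_idx), [1.0 - f.gfp_dead_ethd, f.gfp_dead_ethd])
    ethd[gfp_idx[g_counts[0]:]] = True

    alive = ~(ethd | apop)
    s_phase = rng.random(n) < f.s_phase

    cells = [
        CellTruth(center=(float(zs[i]), float(ys[i]), float(xs[i])),
                  alive=bool(alive[i]), ethd=bool(ethd[i]), apopxin=bool(apop[i]),
                  s_phase=bool(s_phase[i]), gfp=bool(gfp[i]))
        for i in range(n)
    ]
    scene = SyntheticScene(params=params, cells=cells)
    # planted foreground: voxels strictly brighter than the brightest
    # out-of-focus structure (the halo peak) in the noiseless render
    cutoff = params.intensity.halo_scale * params.intensity.nucleus_mean
    for role in ChannelRole:
        ideal = render_ideal_channel(scene, role)
        scene.ground_truth[role] = ideal > cutoff
    return scene


def _positive_cells(scene: SyntheticScene, role: ChannelRole) -> list[CellTruth]:
    if role is ChannelRole.NUCLEAR:
        return list(scene.cells)
    if role is ChannelRole.DEAD_MEMBRANE:
        return [c for c in scene.cells if c.ethd]
    if role is ChannelRole.DEAD_APOPTOTIC:
        return [c for c in scene.cells if c.apopxin]
    if role is ChannelRole.PROLIFERATION:
        return [c for c in scene.cells if c.s_phase]
    if role is ChannelRole.LINEAGE_GFP:
        return [c for c in scene.cells if c.gfp]
    raise ValueError(role)


def _blob_sigma0(params: SceneParams) -> float:
    # half-max radius of the super-Gaussian equals nucleus_radius_px
    s = params.blob_sharpness
    return params.nucleus_radius_px / (2 * math.log(2)) ** (1.0 / s)


def _add_blob(plane: np.ndarray, cy: float, cx: float, peak: float,
              sigma: float, sharpness: float, ring_mid: float = 0.0) -> None:
    """Accumulate one blob (or annulus when ring_mid > 0) into a plane."""
    ny, nx = plane.shape
    ext = int(math.ceil(ring_mid + 4 * sigma))
    y0, y1 = max(0, int(cy) - ext), min(ny, int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(nx, int(cx) + ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float64)[:, None] - cy
    xx = np.arange(x0, x1, dtype=np.float64)[None, :] - cx
    rho = np.sqrt(yy * yy + xx * xx)
    if ring_mid > 0:
        u = ((rho - ring_mid) ** 2) / (2 * sigma * sigma)
    else:
        u = (rho * rho) / (2 * sigma * sigma)
    plane[y0:y1, x0:x1] += peak * np.exp(-(u ** (sharpness / 2.0)))


def render_ideal_channel(scene: SyntheticScene, role: ChannelRole) -> np.ndarray:
    """Noiseless, vignetting-free, background-free rendering of one channel.

    A positive cell is a solid ball of radius ``nucleus_radius_px``: every
    slice cutting the ball renders a full-intensity super-Gaussian disk with
    half-max radius equal to the ball's cross-section there.  Slices beyond
    the ball get an out-of-focus halo: peak
    ``nucleus_mean * halo_scale**(d / nucleus_radius_px)`` at defocus
    distance d (so exactly ``halo_scale`` of the in-focus peak at one radius)
    with width growing by ``z_psf_sigma`` per slice.  Apopxin is an annulus
    at 1.1 cross-section radii with width 0.5 radii (a membrane stain).
    """
    p = scene.params
    nz, ny, nx = p.volume_shape
    A = p.intensity.nucleus_mean
    r = p.nucleus_radius_px
    sigma0 = _blob_sigma0(p)
    halo = p.intensity.halo_scale
    step = p.z_step_px
    # halos rendered out to where their peak falls below 5% of in-focus
    halo_reach_px = r * math.log(0.05) / math.log(halo) if 0 < halo < 1 else r
    z_extent = halo_reach_px / step
    is_ring = role is ChannelRole.DEAD_APOPTOTIC

    stack = np.zeros((nz, ny, nx), dtype=np.float64)
    for cell in _positive_cells(scene, role):
        cz, cy, cx = cell.center
        for z in range(max(0, int(math.floor(cz - z_extent))),
                       min(nz, int(math.ceil(cz + z_extent)) + 1)):
            d_px = abs(z - cz) * step  # physical defocus distance in pixels
            if d_px < r:
                # the plane cuts through the nucleus: full-intensity
                # cross-section of radius sqrt(r^2 - d^2)
                cross = math.sqrt(r * r - d_px * d_px) / r
                if cross < 0.05:
                    continue
                peak = A
                sigma_d = sigma0 * cross
                ring_mid = 1.1 * r * cross if is_ring else 0.0
                ring_w = 0.5 * r if is_ring else sigma_d
            else:
                # out of focus: halo dimming exponentially with defocus,
                # pinned to halo_scale of the in-focus peak at one radius,
                # and broadening with distance
                if not 0 < halo < 1:
                    continue
                peak = A * halo ** (d_px / r)
                if peak < 0.05 * A:
                    continue
                grow = 1.0 + p.z_psf_sigma * (d_px - r) / step
                sigma_d = sigma0 * grow
                ring_mid = 1.1 * r * grow if is_ring else 0.0
                ring_w = 0.5 * r * grow if is_ring else sigma_d
            _add_blob(stack[z], cy, cx, peak,
                      ring_w if is_ring else sigma_d,
                      p.blob_sharpness, ring_mid=ring_mid)
    return stack


def vignetting_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Centered Gaussian illumination field: exactly 1 at center, 1-strength at corners."""
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy = (np.arange(ny)[:, None] - cy) ** 2
    xx = (np.arange(nx)[None, :] - cx) ** 2
    sigma = 0.35 * min(ny, nx)
    g = np.exp(-0.5 * (yy + xx) / sigma ** 2)
    g_corner = math.exp(-0.5 * (cy ** 2 + cx ** 2) / sigma ** 2)
    return (1.0 - strength) + strength * (g - g_corner) / (1.0 - g_corner)


def render_channel(
    scene: SyntheticScene, role: ChannelRole, params: SceneParams | None = None
) -> ImageStack:
    """Render one channel with vignetting, background, and read noise (uint16).

    Deterministic: the noise RNG is derived from the scene seed and the
    channel role, so re-rendering the same scene gives bit-identical stacks.
    """
    p = params if params is not None else scene.params
    ideal = render_ideal_channel(scene, role)
    nz, ny, nx = ideal.shape
    field2d = vignetting_field((ny, nx), p.vignetting_strength)
    out = ideal + p.intensity.background * field2d[None, :, :]
    if p.intensity.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, _ROLE_INDEX[role], 7]))
        out = out + rng.normal(0.0, p.intensity.noise_sd, out.shape)
    out = np.clip(np.rint(out), 0, 65535).astype(np.uint16)
    key = StackKey(well="sim", position=0, channel=role)
    return ImageStack(key=key, planes=out, z_spacing_um=2.0)


@dataclass
class DoseResponse:
    """Four-parameter logistic dose responses for the planted plate.

    The drug-added kill fraction rises logistically from 0 to ``kill_max``
    and compounds with the baseline death of vehicle-treated cultures
    (total = 1 - (1 - baseline)(1 - added)); the S-phase fraction falls
    logistically from its baseline to ``s_phase_min``.  Doses are in the
    same (arbitrary concentration) units as the EC50s.
    """

    viability_ec50: float = 100.0
    viability_hill: float = 1.5
    prolif_ec50: float = 50.0
    prolif_hill: float = 1.5
    kill_max: float = 0.9
    s_phase_min: float = 0.05

    def added_kill(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        x = dose ** self.viability_hill
        return self.kill_max * x / (self.viability_ec50 ** self.viability_hill + x)

    def kill_fraction(self, dose: float, baseline: float) -> float:
        return 1.0 - (1.0 - baseline) * (1.0 - self.added_kill(dose))

    def s_phase_fraction(self, dose: float, baseline: float) -> float:
        if dose <= 0:
            return baseline
        x = dose ** self.prolif_hill
        return self.s_phase_min + (baseline - self.s_phase_min) * \
            self.prolif_ec50 ** self.prolif_hill / (self.prolif_ec50 ** self.prolif_hill + x)


@dataclass
class PlateSimulation:
    """In-memory plate plus (optionally) its on-disk representation."""

    stacks: dict[StackKey, ImageStack]
    layout: PlateLayout
    truth: pd.DataFrame
    root: Path | None = None


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2 ** 31))


def simulate_plate(
    doses: Sequence[float],
    response: DoseResponse,
    base: SceneParams,
    n_positions: int = 2,
    channels: Sequence[ChannelRole] = (
        ChannelRole.NUCLEAR, ChannelRole.DEAD_MEMBRANE,
        ChannelRole.DEAD_APOPTOTIC, ChannelRole.PROLIFERATION,
    ),
    out_dir: str | Path | None = None,
    control_label: str = "DMSO",
    kill_fractions: Sequence[float] | None = None,
    s_phase_fractions: Sequence[float] | None = None,
) -> PlateSimulation:
    """Simulate a dose-series plate: one well per dose, several positions each.

    Dose 0 must be present; it becomes the vehicle control.  Drug-added kill
    and S-phase fractions follow ``response``'s logistics of dose, or can be
    planted explicitly per dose via ``kill_fractions`` (added kill,
    compounded with the baseline death) and ``s_phase_fractions``; the
    planted per-well fractions are recorded in the truth table.  With
    ``out_dir`` set, single-plane TIFFs (one per slice per channel),
    ``layout.yaml`` and ``truth.csv`` are written in the package's default
    filename grammar.
    """
    doses = list(doses)
    if 0 not in doses and 0.0 not in doses:
        raise ValueError("doses must include 0 (the vehicle control)")
    if kill_fractions is not None and len(kill_fractions) != len(doses):
        raise ValueError("kill_fractions must align with doses")
    if s_phase_fractions is not None and len(s_phase_fractions) != len(doses):
        raise ValueError("s_phase_fractions must align with doses")
    f0 = base.fractions
    base_kill = f0.dead_total
    death_split = (
        np.array([f0.dead_ethd, f0.dead_apopxin, f0.dead_both]) / base_kill
        if base_kill > 0 else np.array([0.5, 0.3, 0.2])
    )
    # drop death channels that are not being imaged (e.g. co-culture runs
    # have no Apopxin): their planted probability mass goes to EtHd
    if ChannelRole.DEAD_APOPTOTIC not in channels:
        death_split = np.array([death_split[0] + death_split[1] + death_split[2], 0.0, 0.0])

    stacks: dict[StackKey, ImageStack] = {}
    assignments: dict[str, str] = {}
    truth_rows = []
    for wi, dose in enumerate(doses):
        well = f"d{wi}"
        treatment = control_label if dose == 0 else f"dose_{dose:g}"
        assignments[well] = treatment
        if kill_fractions is not None:
            kill = 1.0 - (1.0 - base_kill) * (1.0 - kill_fractions[wi])
        else:
            kill = response.kill_fraction(dose, base_kill)
        if s_phase_fractions is not None:
            s_phase = s_phase_fractions[wi]
        else:
            s_phase = response.s_phase_fraction(dose, f0.s_phase)
        fr = replace(
            f0,
            dead_ethd=kill * death_split[0],
            dead_apopxin=kill * death_split[1],
            dead_both=kill * death_split[2],
            s_phase=s_phase,
        )
        truth_rows.append({
            "well": well, "treatment": treatment, "dose": dose,
            "kill_fraction": kill, "s_phase_fraction": s_phase,
        })
        for pos in range(n_positions):
            params = replace(base, fractions=fr, seed=_child_seed(base.seed, wi, pos))
            scene = simulate_scene(params)
            for role in channels:
                stack = render_channel(scene, role)
                key = StackKey(well=well, position=pos, channel=role)
                stacks[key] = ImageStack(key=key, planes=stack.planes,
                                         z_spacing_um=stack.z_spacing_um)

    layout = PlateLayout(assignments=assignments, control_label=control_label)
    truth = pd.DataFrame(truth_rows)
    root = None
    if out_dir is not None:
        root = Path(out_dir)
        img_dir = root / "images"
        for key, stack in stacks.items():
            write_stack(stack, img_dir, DEFAULT_CHANNEL_TOKENS[key.channel])
        with open(root / "layout.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "channels": {str(r): DEFAULT_CHANNEL_TOKENS[r] for r in channels},
                    "wells": assignments,
                    "control": control_label,
                },
                fh, sort_keys=True,
            )
        truth.to_csv(root / "truth.csv", index=False)
    return PlateSimulation(stacks=stacks, layout=layout, truth=truth, root=root)
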