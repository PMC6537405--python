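"""The scene generator: determinism, fate draws, rendering geometry."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from cellfate3d.image_io import ChannelRole as CR, discover_dataset
from cellfate3d.synthetic import (
    DoseResponse, FateFractions, SceneParams, _blob_sigma0,
    render_channel, render_ideal_channel, simulate_plate, simulate_scene,
)

SMALL = dict(volume_shape=(8, 96, 96), n_cells=20)


class TestSimulateScene:
    def test_empty_scene_has_empty_truth(self):
        scene = simulate_scene(SceneParams(n_cells=0, volume_shape=(4, 32, 32), seed=0))
        assert scene.cells == []
        assert all(not m.any() for m in scene.ground_truth.values())

    def test_all_ethd_fraction_marks_every_cell(self):
        scene = simulate_scene(SceneParams(
            seed=1, fractions=FateFractions(dead_ethd=1.0, dead_apopxin=0, dead_both=0),
            **SMALL))
        assert all(c.ethd for c in scene.cells)

    def test_fate_counts_match_seeded_multinomial_redraw(self):
        params = SceneParams(seed=123, n_cells=200, volume_shape=(10, 256, 256),
                             fractions=FateFractions(dead_ethd=0.1, dead_apopxin=0.1,
                                                     dead_both=0.05))
        scene = simulate_scene(params)
        # independent re-draw following the documented RNG call order
        rng = np.random.default_rng(123)
        n, r = params.n_cells, params.nucleus_radius_px
        nz, ny, nx = params.volume_shape
        placed = 0
        min_sep2 = (1.6 * r) ** 2
        pts = np.empty((n, 3))
        while placed < n:
            z = rng.uniform(0.0, nz - 1.0)
            y = rng.uniform(r, ny - 1 - r)
            x = rng.uniform(r, nx - 1 - r)
            if placed:
                d2 = ((pts[:placed, 0] - z) * params.z_step_px) ** 2 \
                    + (pts[:placed, 1] - y) ** 2 + (pts[:placed, 2] - x) ** 2
                if d2.min() < min_sep2:
                    continue
            pts[placed] = (z, y, x)
            placed += 1
        rng.permutation(n)  # GFP assignment (empty lineage here)
        expected = rng.multinomial(n, [0.75, 0.1, 0.1, 0.05])
        counts = scene.fate_counts()
        assert counts["alive"] == expected[0]
        assert counts["ethd_only"] == expected[1]
        assert counts["apopxin_only"] == expected[2]
        assert counts["both"] == expected[3]

    def test_fate_counts_conserve_n_cells(self):
        scene = simulate_scene(SceneParams(seed=7, **SMALL))
        c = scene.fate_counts()
        assert c["alive"] + c["ethd_only"] + c["apopxin_only"] + c["both"] == 20

    def test_hard_sphere_minimum_separation(self):
        params = SceneParams(seed=3, **SMALL)
        scene = simulate_scene(params)
        pts = np.array([c.center for c in scene.cells])
        step = params.z_step_px
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                dz = (pts[i, 0] - pts[j, 0]) * step
                d = math.sqrt(dz ** 2 + (pts[i, 1] - pts[j, 1]) ** 2
                              + (pts[i, 2] - pts[j, 2]) ** 2)
                assert d >= 1.6 * params.nucleus_radius_px

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="density"):
            SceneParams(n_cells=5000, volume_shape=(4, 64, 64))


class TestRenderChannel:
    def test_same_seed_renders_bit_identical_stacks(self):
        a = render_channel(simulate_scene(SceneParams(seed=9, **SMALL)), CR.NUCLEAR)
        b = render_channel(simulate_scene(SceneParams(seed=9, **SMALL)), CR.NUCLEAR)
        np.testing.assert_array_equal(a.planes, b.planes)

    def test_channels_get_independent_noise(self):
        scene = simulate_scene(SceneParams(seed=9, n_cells=0, volume_shape=(4, 64, 64)))
        a = render_channel(scene, CR.NUCLEAR)
        b = render_channel(scene, CR.DEAD_MEMBRANE)
        assert (a.planes != b.planes).any()

    def test_dead_free_scene_gives_pure_noise_death_channels(self):
        scene = simulate_scene(SceneParams(
            seed=2, fractions=FateFractions(dead_ethd=0, dead_apopxin=0, dead_both=0),
            **SMALL))
        for role in (CR.DEAD_MEMBRANE, CR.DEAD_APOPTOTIC):
            assert not scene.ground_truth[role].any()
            ideal = render_ideal_channel(scene, role)
            assert ideal.max() == 0.0

    def test_single_cell_truth_matches_analytic_ball_cross_sections(self):
        """Noiseless, bias-free single nucleus: the planted foreground in
        each slice is the lattice disk where the Gaussian cross-section
        exceeds the halo-peak cutoff, an analytically computable radius."""
        params = SceneParams(
            n_cells=1, volume_shape=(9, 64, 64), seed=4,
            vignetting_strength=0.0, z_range=(4.0, 4.0),
        )
        params = replace(params, intensity=replace(params.intensity, noise_sd=0.0))
        scene = simulate_scene(params)
        (cell,) = scene.cells
        cz, cy, cx = cell.center
        r = params.nucleus_radius_px
        sigma0 = _blob_sigma0(params)
        cutoff = params.intensity.halo_scale  # fraction of peak
        truth = scene.ground_truth[CR.NUCLEAR]
        yy, xx = np.mgrid[0:64, 0:64]
        for z in range(9):
            d_px = abs(z - cz) * params.z_step_px
            if d_px < r:
                cross = math.sqrt(r * r - d_px * d_px) / r
                sigma_d = sigma0 * cross
                rho_max = sigma_d * math.sqrt(2 * math.log(1 / cutoff))
                expected = int((((yy - cy) ** 2 + (xx - cx) ** 2)
                                < rho_max ** 2).sum())
            else:
                expected = 0  # halo peak never exceeds the cutoff
            assert truth[z].sum() == pytest.approx(expected, abs=6)

    def test_halo_peak_is_pinned_to_halo_scale_at_one_radius(self):
        params = SceneParams(
            n_cells=1, volume_shape=(9, 64, 64), seed=4,
            vignetting_strength=0.0, z_range=(4.0, 4.0), z_step_px=4.0,
        )
        params = replace(params, intensity=replace(params.intensity, noise_sd=0.0))
        scene = simulate_scene(params)
        ideal = render_ideal_channel(scene, CR.NUCLEAR)
        # one slice away = one nucleus radius of defocus here (z_step = r)
        assert ideal[5].max() == pytest.approx(
            params.intensity.halo_scale * params.intensity.nucleus_mean, rel=0.01)

    def test_uint16_output_within_range(self):
        stack = render_channel(simulate_scene(SceneParams(seed=5, **SMALL)), CR.NUCLEAR)
        assert stack.planes.dtype == np.uint16


class TestSimulatePlate:
    def test_dose_zero_plants_baseline_fractions(self):
        base = SceneParams(seed=0, **SMALL)
        sim = simulate_plate([0, 50], DoseResponse(), base, n_positions=1)
        row = sim.truth.set_index("dose").loc[0]
        assert row["kill_fraction"] == pytest.approx(base.fractions.dead_total)
        assert row["s_phase_fraction"] == pytest.approx(base.fractions.s_phase)
        assert row["treatment"] == "DMSO"

    def test_ec50_dose_plants_half_maximal_added_kill(self):
        base = SceneParams(seed=0, **SMALL)
        resp = DoseResponse(viability_ec50=100, kill_max=0.8)
        sim = simulate_plate([0, 100], resp, base, n_positions=1)
        total = sim.truth.set_index("dose").loc[100, "kill_fraction"]
        baseline = base.fractions.dead_total
        added = 1 - (1 - total) / (1 - baseline)
        assert added == pytest.approx(0.4, rel=1e-6)

    def test_written_plate_is_rediscoverable(self, tmp_path):
        base = SceneParams(seed=1, n_cells=4, volume_shape=(4, 48, 48))
        sim = simulate_plate([0, 10], DoseResponse(), base, n_positions=2,
                             out_dir=tmp_path)
        manifest = discover_dataset(
            tmp_path, {"nuclear": "hoechst", "dead_membrane": "ethd",
                       "dead_apoptotic": "apopxin", "proliferation": "edu"})
        assert len(manifest.stacks) == len(sim.stacks)
        assert (tmp_path / "layout.yaml").exists()
        assert (tmp_path / "truth.csv").exists()

    def test_doses_must_include_control(self):
        with pytest.raises(ValueError, match="control"):
            simulate_plate([10, 100], DoseResponse(), SceneParams(seed=0, **SMALL))
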