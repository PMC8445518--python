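"""Tests for Siddon tracing, TOF weighting, sensitivity, and LM-MLEM."""

import math

import numpy as np
import pytest

import tofmix as tm
from tofmix._tracing import C_MM_PER_PS
from tofmix.geometry import crystal_centers
from tofmix.listmode import EVENT_DTYPE, ListModeData
from tofmix.recon import (
    ReconConfig,
    ReconModel,
    TOFBinning,
    calibrate,
    lm_mlem,
    sensitivity_image,
    siddon_path,
    tof_weight,
    voxel_tof_projection,
)
from tofmix.simulate import AcquisitionConfig, TimingModel, simulate_acquisition


def dense_sampling_lengths(grid, p1, p2, n_samples=200_000):
    """Brute-force chord lengths: distribute many points along the segment
    and credit each with an equal share of the total length."""
    t = (np.arange(n_samples) + 0.5) / n_samples
    pts = p1[None, :] + t[:, None] * (p2 - p1)[None, :]
    rel = (pts - grid.origin_mm) / np.asarray(grid.voxel_size_mm)
    inside = np.all((rel >= 0) & (rel < grid.shape), axis=1)
    idx = np.floor(rel[inside]).astype(int)
    flat = (idx[:, 0] * grid.ny + idx[:, 1]) * grid.nz + idx[:, 2]
    total = np.linalg.norm(p2 - p1)
    lengths = np.bincount(flat, minlength=grid.nx * grid.ny * grid.nz) * (
        total / n_samples
    )
    return lengths


class TestSiddon:
    def test_axis_aligned_ray(self):
        g = tm.VoxelGrid(nx=3, ny=3, nz=1, voxel_size_mm=(1.0, 1.0, 1.0))
        idx, ln = siddon_path(g, np.array([-5.0, 0.0, 0.0]), np.array([5.0, 0.0, 0.0]))
        assert idx.tolist() == [[0, 1, 0], [1, 1, 0], [2, 1, 0]]
        assert np.allclose(ln, 1.0)

    def test_single_voxel_diagonal(self):
        g = tm.VoxelGrid(nx=1, ny=1, nz=1, voxel_size_mm=(1.0, 1.0, 1.0))
        idx, ln = siddon_path(
            g, np.array([-0.5, -0.5, -0.5]), np.array([0.5, 0.5, 0.5])
        )
        assert len(ln) == 1
        assert ln[0] == pytest.approx(math.sqrt(3.0), abs=1e-12)

    def test_degenerate_ray_rejected(self):
        g = tm.VoxelGrid(nx=2, ny=2, nz=1, voxel_size_mm=(1, 1, 1))
        p = np.array([0.1, 0.1, 0.0])
        with pytest.raises(ValueError):
            siddon_path(g, p, p.copy())

    def test_lengths_sum_to_chord(self):
        g = tm.VoxelGrid(nx=16, ny=16, nz=16, voxel_size_mm=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(0)
        for _ in range(50):
            p1 = rng.uniform(-20, 20, 3)
            p2 = rng.uniform(-20, 20, 3)
            idx, ln = siddon_path(g, p1, p2)
            # chord length from slab clipping
            d = p2 - p1
            tmin, tmax = 0.0, 1.0
            for ax in range(3):
                if d[ax] != 0:
                    lo = (g.origin_mm[ax] - p1[ax]) / d[ax]
                    hi = (g.origin_mm[ax] + g.extent_mm[ax] - p1[ax]) / d[ax]
                    lo, hi = min(lo, hi), max(lo, hi)
                    tmin, tmax = max(tmin, lo), min(tmax, hi)
                elif not (g.origin_mm[ax] <= p1[ax] <= g.origin_mm[ax] + g.extent_mm[ax]):
                    tmin, tmax = 1.0, 0.0
            chord = max(tmax - tmin, 0.0) * np.linalg.norm(d)
            assert ln.sum() == pytest.approx(chord, abs=1e-9)

    def test_matches_dense_sampling_oracle(self):
        g = tm.VoxelGrid(nx=16, ny=16, nz=16, voxel_size_mm=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(42)
        for _ in range(20):
            p1 = rng.uniform(-15, 15, 3)
            p2 = rng.uniform(-15, 15, 3)
            if np.allclose(p1, p2):
                continue
            idx, ln = siddon_path(g, p1, p2)
            oracle = dense_sampling_lengths(g, p1, p2)
            if len(ln) == 0:
                assert oracle.sum() < 1e-6
                continue
            mine = np.zeros_like(oracle)
            flat = (idx[:, 0] * g.ny + idx[:, 1]) * g.nz + idx[:, 2]
            mine[flat] = ln
            assert np.abs(mine - oracle).max() < 0.01 * max(ln.max(), 1e-12)


class TestVoxelProjection:
    def test_midpoint_voxel_is_zero(self):
        g = tm.VoxelGrid(nx=5, ny=5, nz=1, voxel_size_mm=(2.0, 2.0, 2.0))
        p1 = np.array([-100.0, 0.0, 0.0])
        p2 = np.array([100.0, 0.0, 0.0])
        assert voxel_tof_projection(g, (2, 2, 0), p1, p2) == pytest.approx(0.0)

    def test_closed_form_offset(self):
        g = tm.VoxelGrid(nx=61, ny=61, nz=1, voxel_size_mm=(1.0, 1.0, 1.0))
        p1 = np.array([-100.0, 0.0, 0.0])
        p2 = np.array([100.0, 0.0, 0.0])
        # voxel (60, 30): center x = +30 mm, toward p2
        v = voxel_tof_projection(g, (60, 30, 0), p1, p2)
        assert v == pytest.approx(2 * 30.0 / C_MM_PER_PS, abs=1e-9)

    def test_reflection_antisymmetry(self):
        g = tm.VoxelGrid(nx=61, ny=61, nz=1, voxel_size_mm=(1.0, 1.0, 1.0))
        p1 = np.array([-90.0, -40.0, 0.0])
        p2 = np.array([80.0, 55.0, 0.0])
        a = voxel_tof_projection(g, (40, 40, 0), p1, p2)
        b = voxel_tof_projection(g, (40, 40, 0), p2, p1)
        assert a == pytest.approx(-b)


def one_event(crystal_a=0, crystal_b=180, dt=0.0, kernel_id=0, comp=0):
    ev = np.zeros(1, dtype=EVENT_DTYPE)
    ev["crystal_a"], ev["crystal_b"] = crystal_a, crystal_b
    ev["delta_t_ps"] = dt
    ev["kernel_id"], ev["component_flag"] = kernel_id, comp
    return ev


class TestTofWeight:
    def test_degenerate_mixture_equals_single_gaussian(self, bank):
        k = bank.get(1)
        mix = ReconModel(mode="single_mixture", bank=bank, kernel_id=1)
        gauss = ReconModel(mode="single_gaussian", fwhm_ps=k.fast.fwhm_ps)
        binning = TOFBinning(1.0)
        ev_mix = one_event(dt=35.0, kernel_id=1)[0]
        ev_g = one_event(dt=35.0)[0]
        # alpha -> 1 collapses the mixture weight to the fast Gaussian's
        from tofmix.kernels import GaussianComponent, KernelBank, MixtureTimingKernel

        k_alpha1 = MixtureTimingKernel(
            kernel_id=1, fast=k.fast, slow=k.slow, alpha_fast=1.0
        )
        bank1 = KernelBank(kernels=(k_alpha1,))
        mix1 = ReconModel(mode="single_mixture", bank=bank1, kernel_id=1)
        for v in (-80.0, 0.0, 42.0):
            assert tof_weight(mix1, ev_mix, v, binning) == pytest.approx(
                tof_weight(gauss, ev_g, v, binning), abs=1e-15
            )

    @pytest.mark.parametrize("mode", ["single_mixture", "single_gaussian", "decomposed"])
    def test_weights_sum_to_one_over_all_bins(self, bank, mode):
        binning = TOFBinning(25.0)
        if mode == "single_gaussian":
            model = ReconModel(mode=mode, fwhm_ps=213.0)
            ev = one_event(dt=12.0)[0]
        elif mode == "decomposed":
            model = ReconModel(mode=mode, bank=bank)
            ev = one_event(dt=12.0, kernel_id=13, comp=1)[0]
        else:
            model = ReconModel(mode=mode, bank=bank, kernel_id=13)
            ev = one_event(dt=12.0, kernel_id=13)[0]
        edges = np.concatenate([[-np.inf], np.arange(-5000, 5001, 25.0), [np.inf]])
        v = 140.0
        total = sum(
            tof_weight(model, ev, v, binning, bin_edges=(edges[i], edges[i + 1]))
            for i in range(len(edges) - 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_fine_bin_weight_approximates_pdf(self, bank):
        from tofmix.kernels import mixture_pdf

        k = bank.get(1)
        model = ReconModel(mode="single_mixture", bank=bank, kernel_id=1)
        binning = TOFBinning(1.0)
        ev = one_event(dt=0.2, kernel_id=1)[0]
        w = tof_weight(model, ev, 0.2, binning)
        assert w == pytest.approx(mixture_pdf(k, 0.0) * 1.0, rel=1e-3)

    def test_non_tof_weight_is_one(self):
        model = ReconModel(mode="non_tof")
        assert tof_weight(model, one_event()[0], 123.0, TOFBinning(1.0)) == 1.0

    def test_decomposed_requires_flags(self, bank):
        model = ReconModel(mode="decomposed", bank=bank)
        ev = one_event(dt=0.0, kernel_id=13, comp=0)
        with pytest.raises(ValueError, match="component"):
            model.event_kernel_params(ev)


class TestSensitivity:
    def test_matches_exhaustive_pair_loop(self):
        scanner = tm.RingScanner(n_crystals_per_ring=32, n_rings=1, ring_radius_mm=60.0)
        grid = tm.VoxelGrid(nx=8, ny=8, nz=1, voxel_size_mm=(4.0, 4.0, 4.0))
        min_sector = 4
        s = sensitivity_image(scanner, grid, min_sector_difference=min_sector)
        brute = np.zeros(grid.shape)
        centers = crystal_centers(scanner)
        for a in range(32):
            for b in range(a + 1, 32):
                diff = min(abs(a - b), 32 - abs(a - b))
                if diff < min_sector:
                    continue
                idx, ln = siddon_path(grid, centers[a], centers[b])
                for (i, j, k), l in zip(idx, ln):
                    brute[i, j, k] += l
        assert np.allclose(s, brute, atol=1e-9)

    def test_symmetric_and_positive_in_fov(self, desk_sensitivity):
        s = desk_sensitivity[:, :, 0]
        # mirror symmetry is exact away from the two center rows, where
        # LORs running exactly along voxel boundaries break ties one-sidedly
        interior = np.ones_like(s, dtype=bool)
        interior[63:65, :] = False
        interior[:, 63:65] = False
        flipped = s[::-1, :]
        assert np.allclose(s[interior], flipped[interior], rtol=1e-9)
        transposed = s.T
        assert np.allclose(s[interior], transposed[interior], rtol=1e-9)
        assert s[64, 64] > 0
        assert s[64, 64] > 0.7 * s.max()

    def test_voxel_outside_all_lors_masked(self):
        scanner = tm.RingScanner(n_crystals_per_ring=32, n_rings=1, ring_radius_mm=60.0)
        # grid larger than the detector ring: corners see no LORs
        grid = tm.VoxelGrid(nx=40, ny=40, nz=1, voxel_size_mm=(4.0, 4.0, 4.0))
        s = sensitivity_image(scanner, grid, min_sector_difference=4)
        assert s[0, 0, 0] == 0.0
        ev = one_event(crystal_a=0, crystal_b=16)
        data = ListModeData(
            events=np.concatenate([ev] * 3),
            header=ListModeData.scanner_header(scanner),
        )
        res = lm_mlem(
            data,
            ReconConfig(grid=grid, model=ReconModel(mode="non_tof"), n_iterations=2,
                        sensitivity=s),
        )
        assert res.image[0, 0, 0] == 0.0


class TestMlem:
    def test_two_voxel_closed_form_update(self):
        """Hand-computed first MLEM update for one event on two voxels with
        unit sensitivity: lambda1 = w / sum(w)."""
        scanner = tm.RingScanner(n_crystals_per_ring=16, n_rings=1, ring_radius_mm=30.0)
        grid = tm.VoxelGrid(nx=2, ny=1, nz=1, voxel_size_mm=(10.0, 10.0, 10.0))
        data = ListModeData(
            events=one_event(crystal_a=0, crystal_b=8),
            header=ListModeData.scanner_header(scanner),
        )
        sens = np.ones(grid.shape)
        res = lm_mlem(
            data,
            ReconConfig(grid=grid, model=ReconModel(mode="non_tof"), n_iterations=1,
                        sensitivity=sens),
        )
        # symmetric chord: both voxels get length 10, so lambda = 10/20 each
        assert res.image[:, 0, 0] == pytest.approx([0.5, 0.5])

    def test_count_conservation_every_iteration(self, nema_sim, desk_grid, desk_sensitivity, bank):
        res = lm_mlem(
            nema_sim,
            ReconConfig(
                grid=desk_grid,
                model=ReconModel(mode="mixture_bank", bank=bank),
                n_iterations=5,
                sensitivity=desk_sensitivity,
            ),
        )
        assert np.all(res.conservation_residual < 1e-6)

    def test_log_likelihood_nondecreasing(self, nema_sim, desk_grid, desk_sensitivity, bank):
        for model in (
            ReconModel(mode="mixture_bank", bank=bank),
            ReconModel(mode="non_tof"),
        ):
            res = lm_mlem(
                nema_sim,
                ReconConfig(grid=desk_grid, model=model, n_iterations=6,
                            sensitivity=desk_sensitivity),
            )
            ll = res.log_likelihood
            assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))

    def test_alpha_one_mixture_equals_single_gaussian_recon(self, desk_scanner, desk_grid,
                                                            desk_sensitivity):
        from tofmix.kernels import GaussianComponent, KernelBank, MixtureTimingKernel

        # equal components so the weight truncation window matches too
        k = MixtureTimingKernel(
            kernel_id=1,
            fast=GaussianComponent(213.0),
            slow=GaussianComponent(213.0),
            alpha_fast=1.0,
        )
        bank1 = KernelBank(kernels=(k,))
        cfg = AcquisitionConfig(
            phantom=tm.nema_iq_phantom(), scanner=desk_scanner, grid=desk_grid,
            duration_s=1.0, timing_model=TimingModel.single_gaussian(213.0), rng_seed=5,
        )
        data = simulate_acquisition(cfg)
        imgs = {}
        for name, model in (
            ("mix", ReconModel(mode="single_mixture", bank=bank1, kernel_id=1)),
            ("gauss", ReconModel(mode="single_gaussian", fwhm_ps=213.0)),
        ):
            imgs[name] = lm_mlem(
                data,
                ReconConfig(grid=desk_grid, model=model, n_iterations=4,
                            sensitivity=desk_sensitivity),
            ).image
        scale = imgs["gauss"].max()
        assert np.abs(imgs["mix"] - imgs["gauss"]).max() < 1e-9 * scale

    def test_very_wide_gaussian_approaches_non_tof(self, desk_scanner, desk_grid,
                                                   desk_sensitivity):
        cfg = AcquisitionConfig(
            phantom=tm.nema_iq_phantom(), scanner=desk_scanner, grid=desk_grid,
            duration_s=0.5, timing_model=TimingModel.none(), rng_seed=9,
        )
        data = simulate_acquisition(cfg)
        wide = lm_mlem(
            data,
            ReconConfig(grid=desk_grid,
                        model=ReconModel(mode="single_gaussian", fwhm_ps=1e7),
                        n_iterations=3, sensitivity=desk_sensitivity),
        ).image
        notof = lm_mlem(
            data,
            ReconConfig(grid=desk_grid, model=ReconModel(mode="non_tof"),
                        n_iterations=3, sensitivity=desk_sensitivity),
        ).image
        assert np.abs(wide - notof).max() < 0.01 * notof.max()

    def test_point_source_localized_and_sharper_with_narrow_kernel(self, desk_scanner):
        from tofmix.geometry import PhantomSpec, Region, Sphere

        grid = tm.VoxelGrid(nx=63, ny=63, nz=1, voxel_size_mm=(2.0, 2.0, 4.0))
        # off-center point source
        src = (24.0, -16.0, 0.0)
        phantom = PhantomSpec(regions=(Region(Sphere(src, 1.5), 4000.0),))
        cfg = AcquisitionConfig(
            phantom=phantom, scanner=desk_scanner, grid=grid, duration_s=60.0,
            timing_model=TimingModel.single_gaussian(213.0), rng_seed=17,
        )
        data = simulate_acquisition(cfg)
        assert len(data) > 5000
        sens = sensitivity_image(desk_scanner, grid)
        spreads = {}
        for fwhm in (213.0, 800.0):
            res = lm_mlem(
                data,
                ReconConfig(grid=grid,
                            model=ReconModel(mode="single_gaussian", fwhm_ps=fwhm),
                            n_iterations=10, save_iterations=(3,), sensitivity=sens),
            )
            img = res.image[:, :, 0]
            peak = np.unravel_index(img.argmax(), img.shape)
            center = grid.voxel_center(peak[0], peak[1], 0)
            assert abs(center[0] - src[0]) <= 2.0 and abs(center[1] - src[1]) <= 2.0
            x = grid.axis_centers(0)[:, None]
            y = grid.axis_centers(1)[None, :]
            r2 = (x - src[0]) ** 2 + (y - src[1]) ** 2
            # peak width at an early iteration, where the TOF kernel still
            # dominates over MLEM's own sharpening; second moment within a
            # 20-mm window (the far field is reconstruction noise)
            early = res.snapshots[3][:, :, 0]
            win = r2 <= 20.0**2
            w = early * win
            w = w / w.sum()
            spreads[fwhm] = float((w * r2)[win].sum())
        assert spreads[213.0] <= spreads[800.0]

    def test_empty_events_rejected(self, desk_grid, desk_scanner):
        data = ListModeData(events=np.zeros(0, dtype=EVENT_DTYPE),
                            header=ListModeData.scanner_header(desk_scanner))
        with pytest.raises(ValueError):
            lm_mlem(data, ReconConfig(grid=desk_grid, model=ReconModel(mode="non_tof")))


class TestCalibration:
    def test_identity_and_linearity(self):
        img = np.full((4, 4, 1), 7.0)
        mask = np.ones_like(img, dtype=bool)
        out, scale = calibrate(img, mask, 7.0)
        assert scale == pytest.approx(1.0)
        out, scale = calibrate(img, mask, 3.5)
        assert scale == pytest.approx(0.5)
        assert np.allclose(out, 3.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            calibrate(np.ones((2, 2, 1)), np.zeros((2, 2, 1), bool), 1.0)
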