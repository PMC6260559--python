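"""Simulation pipeline: material weighting, projection, FBP, triplets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marcnet.artifact_sim import (
    E_REF_KEV,
    MU_REF,
    DatasetConfig,
    SimConfig,
    Sinogram,
    build_dataset,
    default_angles,
    forward_project,
    monoenergetic_spectrum,
    mu_table_at,
    polychromatic_project,
    reconstruct_fbp,
    segment_materials,
    simulate_artifact_insert,
)
from marcnet.evaluation import psnr
from marcnet.phantom import ImageGrid, MetalMask


def antialiased_disk(n: int, radius: float, sub: int = 4) -> np.ndarray:
    """Pixel-coverage-weighted disk centered on the grid center."""
    nn = n * sub
    yy, xx = np.mgrid[0:nn, 0:nn].astype(np.float64)
    c = (nn - 1) / 2.0
    hard = ((yy - c) ** 2 + (xx - c) ** 2 <= (radius * sub) ** 2).astype(np.float64)
    return hard.reshape(n, sub, n, sub).mean(axis=(1, 3))


class TestSegmentMaterials:
    def test_soft_threshold_ramp(self, mask64):
        vals = np.full((64, 64), -1000.0)
        vals[10, 10] = 100.0  # below t_water
        vals[20, 20] = 500.0  # ramp midpoint for (300, 700)
        vals[30, 30] = 900.0  # above t_bone
        img = ImageGrid(vals)
        mm = segment_materials(img, None, t_water=300.0, t_bone=700.0)
        assert tuple(mm.weights[10, 10]) == (1.0, 0.0, 0.0)
        assert mm.weights[20, 20] == pytest.approx([0.5, 0.5, 0.0])
        assert tuple(mm.weights[30, 30]) == (0.0, 1.0, 0.0)

    def test_metal_mask_overrides(self, phantom64, mask64):
        mm = segment_materials(phantom64, mask64)
        inside = mask64.mask
        assert np.all(mm.weights[inside, 2] == 1.0)
        assert np.all(mm.weights[inside, :2] == 0.0)

    def test_weights_sum_to_one_everywhere(self, phantom64, mask64):
        mm = segment_materials(phantom64, mask64)
        assert np.allclose(mm.weights.sum(axis=2), 1.0, atol=1e-12)

    def test_threshold_order_enforced(self, phantom64):
        with pytest.raises(ValueError):
            segment_materials(phantom64, None, t_water=700.0, t_bone=300.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        hu=st.floats(-1000.0, 3000.0),
        t_water=st.floats(-500.0, 1000.0),
        width=st.floats(10.0, 2000.0),
    )
    def test_weights_partition_unity_for_any_thresholds(self, hu, t_water, width):
        vals = np.full((32, 32), hu)
        mm = segment_materials(ImageGrid(vals), None, t_water, t_water + width)
        w = mm.weights[0, 0]
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)
        # bone weight is monotone in the pixel value
        mm2 = segment_materials(
            ImageGrid(np.full((32, 32), min(hu + 100.0, 3000.0))), None, t_water, t_water + width
        )
        assert mm2.weights[0, 0, 1] >= w[1]


class TestForwardProject:
    def test_zero_image_gives_zero_sinogram(self):
        s = forward_project(np.zeros((64, 64)), default_angles(8))
        assert np.all(s.values == 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.random((48, 48))
        b = rng.random((48, 48))
        ang = default_angles(12)
        sa = forward_project(a, ang).values
        sb = forward_project(b, ang).values
        sab = forward_project(a + b, ang).values
        assert np.abs(sab - (sa + sb)).max() <= 1e-9 * max(1.0, np.abs(sab).max())

    def test_uniform_disk_matches_chord_length(self):
        r = 20.0
        disk = antialiased_disk(101, r)
        s = forward_project(disk, np.array([0.0, 37.0, 90.0]))
        off = np.arange(s.n_detectors) - s.n_detectors // 2
        chord = 2.0 * np.sqrt(np.clip(r**2 - off.astype(float) ** 2, 0.0, None))
        inside = np.abs(off) <= 0.9 * r
        for a in range(s.n_angles):
            rel = np.abs(s.values[a][inside] - chord[inside]) / chord[inside]
            assert rel.max() < 0.02

    def test_radial_image_projections_angle_invariant(self):
        n = 101
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        c = (n - 1) / 2.0
        rr = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        blob = np.exp(-((rr / 12.0) ** 2))
        s = forward_project(blob, np.array([0.0, 30.0, 45.0, 77.0, 90.0]))
        assert np.abs(s.values - s.values[0]).max() <= 1e-6 * s.values.max()

    def test_empty_angle_list_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.zeros((64, 64)), np.array([]))

    def test_sinogram_validates_angles(self):
        with pytest.raises(ValueError):
            Sinogram(np.zeros((2, 8)), np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            Sinogram(np.zeros((2, 8)), np.array([0.0, 181.0]))


class TestPolychromaticProject:
    def test_single_bin_collapses_to_monoenergetic(self, phantom64, mask64):
        mm = segment_materials(phantom64, mask64)
        ang = default_angles(16)
        p_poly = polychromatic_project(mm, monoenergetic_spectrum(80.0), ang)
        mu80 = mu_table_at(np.array([80.0]))[:, 0]
        mu_ref = np.array([MU_REF["water"], MU_REF["bone"], MU_REF["metal"]])
        composite = (mm.weights * mm.mu_ref_image[..., None] * (mu80 / mu_ref)).sum(axis=2)
        p_mono = forward_project(composite * 0.1, ang)  # 1 mm pixels -> 0.1 cm
        assert np.abs(p_poly.values - p_mono.values).max() <= 1e-9 * p_mono.values.max()

    def test_beam_hardening_lowers_effective_attenuation(self, phantom64, empty_mask64):
        # water-only object: polychromatic p <= monoenergetic p at the mean mu
        soft = ImageGrid(np.clip(phantom64.values, -1000.0, 80.0))
        mm = segment_materials(soft, empty_mask64)
        ang = default_angles(8)
        from marcnet.artifact_sim import default_spectrum

        spec = default_spectrum(0.5)
        p_poly = polychromatic_project(mm, spec, ang)
        mu_bins = mu_table_at(spec.energies_kev)[0]
        mu_mean = float((spec.weights * mu_bins).sum())
        p_mono = forward_project(mm.mu_ref_image * (mu_mean / MU_REF["water"]) * 0.1, ang)
        assert np.all(p_poly.values <= p_mono.values + 1e-9)

    def test_longer_paths_attenuate_more(self, phantom64, mask64):
        mm = segment_materials(phantom64, mask64)
        ang = default_angles(8)
        from marcnet.artifact_sim import default_spectrum

        p1 = polychromatic_project(mm, default_spectrum(), ang)
        mm2 = segment_materials(phantom64, mask64)
        mm2.mu_ref_image = mm.mu_ref_image * 2.0  # doubles every path length
        p2 = polychromatic_project(mm2, default_spectrum(), ang)
        support = p1.values > 1e-6
        assert np.all(p2.values[support] > p1.values[support])


class TestReconstructFBP:
    def test_zero_sinogram_gives_zero_image(self):
        s = Sinogram(np.zeros((16, 91)), default_angles(16))
        rec = reconstruct_fbp(s, (64, 64))
        assert np.allclose(rec, 0.0)

    def test_linearity_in_sinogram_scale(self, phantom64):
        s = forward_project(phantom64.values, default_angles(32))
        r1 = reconstruct_fbp(s, (64, 64))
        s3 = Sinogram(3.0 * s.values, s.angles_deg)
        r3 = reconstruct_fbp(s3, (64, 64))
        assert np.abs(r3 - 3.0 * r1).max() <= 1e-9 * max(1.0, np.abs(r3).max())

    def test_round_trip_accuracy_and_angle_monotonicity(self, phantom128, inscribed_circle128):
        circ = inscribed_circle128
        ref = np.sqrt(np.mean(phantom128.values[circ] ** 2))
        errs = []
        for n_ang in (45, 90, 180):
            s = forward_project(phantom128.values, default_angles(n_ang))
            rec = reconstruct_fbp(s, (128, 128))
            errs.append(np.sqrt(np.mean((rec - phantom128.values)[circ] ** 2)) / ref)
        assert errs[-1] < 0.05
        assert errs[0] > errs[1] > errs[2]

    def test_detector_count_must_cover_diagonal(self):
        s = Sinogram(np.zeros((16, 51)), default_angles(16))
        with pytest.raises(ValueError):
            reconstruct_fbp(s, (64, 64))


class TestSimulateArtifactInsert:
    def test_no_metal_single_bin_recovers_input(self, phantom128, inscribed_circle128):
        empty = MetalMask(np.zeros((128, 128), dtype=bool))
        trip = simulate_artifact_insert(phantom128, empty, SimConfig(n_bins=1))
        circ = inscribed_circle128
        err = trip.artifact_insert.values - phantom128.values
        rel = np.sqrt(np.mean(err[circ] ** 2)) / np.sqrt(np.mean(phantom128.values[circ] ** 2))
        assert rel < 0.05
        assert np.abs(trip.artifact_residual.values[circ]).mean() < 50.0  # ~FBP error only, HU

    def test_metal_strictly_degrades_fidelity(self, phantom128):
        mask = MetalMask(np.zeros((128, 128), dtype=bool))
        from marcnet.phantom import generate_metal_mask

        metal = generate_metal_mask(1, (128, 128), "ovoid-pair")
        clean_trip = simulate_artifact_insert(phantom128, mask, SimConfig(n_bins=1))
        metal_trip = simulate_artifact_insert(phantom128, metal)
        psnr_round = psnr(clean_trip.artifact_insert, phantom128)
        psnr_metal = psnr(metal_trip.artifact_insert, phantom128)
        assert psnr_metal < psnr_round

    def test_residual_is_exact_difference(self, phantom64, mask64):
        trip = simulate_artifact_insert(phantom64, mask64, SimConfig(n_angles=60))
        diff = trip.artifact_insert.values - trip.artifact_free.values
        assert np.array_equal(trip.artifact_residual.values, diff)

    def test_streaks_extend_outside_mask(self, phantom64, mask64):
        trip = simulate_artifact_insert(phantom64, mask64, SimConfig(n_angles=60))
        outside = ~mask64.mask
        assert np.abs(trip.artifact_residual.values[outside]).max() > 100.0


class TestBuildDataset:
    def test_subject_disjoint_splits_and_proportions(self):
        ds = build_dataset(12, 1, seed=0, config=DatasetConfig(size=(64, 64)))
        subs = ds.manifest["subject_splits"]
        assert len(subs["train"]) == 9 and len(subs["val"]) == 2 and len(subs["test"]) == 1
        all_subs = subs["train"] + subs["val"] + subs["test"]
        assert sorted(all_subs) == list(range(12))
        for name, idxs in ds.splits.items():
            for i in idxs:
                assert ds.subject_of[i] in subs[name]

    def test_manifest_reproducible(self):
        a = build_dataset(4, 1, seed=3, config=DatasetConfig(size=(64, 64)))
        b = build_dataset(4, 1, seed=3, config=DatasetConfig(size=(64, 64)))
        assert a.manifest["manifest_hash"] == b.manifest["manifest_hash"]
        for ta, tb in zip(a.triplets, b.triplets):
            assert np.array_equal(ta.artifact_insert.values, tb.artifact_insert.values)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(2, 1, seed=0)
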