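import numpy as np
import pytest

from dwibench.core import AcquisitionScheme, AtlasError
from dwibench.geometry import rotation_zyx
from dwibench.modelfit import fit_wlls, scalar_metrics
from dwibench.simulate import (
    ArtifactSpec,
    PopulationSpec,
    add_rician_noise,
    apply_gibbs,
    apply_motion_eddy,
    axisymmetric_eigenvalues,
    build_atlas,
    forward_signal,
    sample_subject,
    simulate_cohort,
    tract_baselines,
)


class TestBuildAtlas:
    def test_deterministic(self):
        a = build_atlas((16, 16, 16), 6, seed=7)
        b = build_atlas((16, 16, 16), 6, seed=7)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.tract_names == b.tract_names

    def test_pair_and_midline_counts(self):
        a = build_atlas((24, 24, 24), 6, seed=7)
        assert len(a.pairs) == 4  # 2 mirrored pairs
        assert sum(1 for n in a.tract_names if n not in a.pairs) == 2

    def test_mirror_symmetry_of_pairs(self, small_atlas):
        left = small_atlas.probability("bundle_01_left")
        right = small_atlas.probability("bundle_01_right")
        assert np.allclose(left, np.flip(right, axis=0), atol=1e-10)

    def test_probabilities_soft_and_bounded(self, small_atlas):
        p = small_atlas.probabilities
        assert p.min() >= 0 and p.max() <= 1
        assert ((p > 0.05) & (p < 0.95)).any()  # soft edges exist

    def test_single_tract_occupies_under_half_the_grid(self):
        a = build_atlas((16, 16, 16), 1, seed=0)
        assert (a.probabilities >= 0.5).mean() < 0.5

    def test_overpacked_grid_rejected(self):
        with pytest.raises((AtlasError, ValueError)):
            build_atlas((16, 16, 16), 40, seed=0)

    def test_grid_minimum_enforced(self):
        with pytest.raises(ValueError, match="16"):
            build_atlas((8, 8, 8), 2, seed=0)


class TestSampleSubject:
    def test_null_effect_gives_identical_group_distributions(self, tiny_atlas):
        pop = PopulationSpec(n_hc=2, n_sle=2, designed_d=0.0,
                             affected_tracts=(tiny_atlas.tract_names[0],))
        hc = sample_subject(pop, tiny_atlas, "HC", seed=5, with_kurtosis=False)
        sle = sample_subject(pop, tiny_atlas, "SLE", seed=5, with_kurtosis=False)
        assert np.array_equal(hc.tensor, sle.tensor)

    def test_designed_shift_is_d_times_sd(self, tiny_atlas):
        tract = tiny_atlas.tract_names[0]
        pop = PopulationSpec(n_hc=2, n_sle=2, designed_d=0.8,
                             affected_tracts=(tract,),
                             between_subject_sd={"FA": 0.02, "MD": 0.03e-3, "MK": 0.06,
                                                 "AK": 0.05, "RK": 0.08})
        hc = sample_subject(pop, tiny_atlas, "HC", seed=5)
        sle = sample_subject(pop, tiny_atlas, "SLE", seed=5)
        fa_hc = hc.tract_params.set_index("tract").loc[tract, "FA"]
        fa_sle = sle.tract_params.set_index("tract").loc[tract, "FA"]
        assert fa_hc - fa_sle == pytest.approx(0.8 * 0.02, abs=1e-12)

    def test_fa_inversion_hand_value(self):
        ad, rd = axisymmetric_eigenvalues(0.799, 0.7667e-3)
        assert ad == pytest.approx(1.70e-3, rel=2e-3)
        assert rd == pytest.approx(0.30e-3, rel=6e-3)

    def test_fa_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            axisymmetric_eigenvalues(1.0, 1e-3)

    def test_unknown_affected_tract_rejected(self, tiny_atlas):
        pop = PopulationSpec(n_hc=2, n_sle=2, affected_tracts=("nope",))
        with pytest.raises(ValueError, match="nope"):
            sample_subject(pop, tiny_atlas, "HC", seed=0)

    def test_baselines_shared_across_subjects_and_sides(self, tiny_atlas):
        pop = PopulationSpec(n_hc=2, n_sle=2)
        base = tract_baselines(tiny_atlas, pop)
        for a, b in tiny_atlas.pairs.items():
            assert base.loc[a, "FA"] == base.loc[b, "FA"]

    def test_tensor_psd(self, tissue_dki):
        assert np.linalg.eigvalsh(tissue_dki.tensor).min() >= -1e-15

    def test_kurtosis_targets_realized_in_tract_core(self, schemes, small_atlas, tissue_dki):
        """Forward + DKI fit at a pure tract voxel reproduces AK/RK within the
        partial-volume blend tolerance."""
        ds = forward_signal(tissue_dki, schemes["3T-DKI"])
        p0 = small_atlas.probability(small_atlas.tract_names[0])
        vox = np.unravel_index(np.argmax(p0), p0.shape)
        mask = np.zeros(p0.shape, bool)
        mask[vox] = True
        maps = scalar_metrics(fit_wlls(ds, "dki", mask=mask))
        row = tissue_dki.tract_params.set_index("tract").loc[small_atlas.tract_names[0]]
        w = p0[vox]
        from dwibench.simulate import BACKGROUND
        # blended target: tract value with weight w, background otherwise
        assert maps.ak[vox] == pytest.approx(w * row["AK"] + (1 - w) * BACKGROUND["AK"], abs=0.12)
        assert maps.rk[vox] == pytest.approx(w * row["RK"] + (1 - w) * BACKGROUND["RK"], abs=0.2)


class TestForwardSignal:
    def test_b0_equals_s0_exactly(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        for v in np.flatnonzero(schemes["7T-DTI"].b0_mask):
            assert np.array_equal(ds.signal[..., v], tissue_dti.s0)

    def test_monoexponential_limit(self):
        """Isotropic D = 1e-3 mm^2/s, W = 0, b = 1000 -> S/S0 = exp(-1)."""
        from dwibench.simulate import TissueModel

        tis = TissueModel(s0=np.ones((2, 2, 2)),
                          tensor=np.tile(np.eye(3) * 1e-3, (2, 2, 2, 1, 1)),
                          kurtosis=None)
        s = AcquisitionScheme("x", [0] + [1000] * 6,
                              np.vstack([np.zeros(3), fibo(6)]))
        ds = forward_signal(tis, s)
        assert np.allclose(ds.signal[..., 1:] / ds.signal[..., :1], np.exp(-1), rtol=1e-12)

    def test_kurtosis_log_signal_hand_value(self):
        """D_app = 1e-3, MD = 1e-3 (mm^2/s), W_app = 1, b = 2750:
        ln(S/S0) = -2.75 + 2750^2 * 1e-6 / 6 = -1.48958."""
        from dwibench.simulate import TissueModel

        w15 = np.zeros((1, 1, 1, 15))
        # isotropic W with W_app(n) = 1 for all n: W_iiii = 1, W_iijj = 1/3
        w15[..., :3] = 1.0
        w15[..., 9:12] = 1.0 / 3.0
        tis = TissueModel(s0=np.ones((1, 1, 1)),
                          tensor=np.eye(3).reshape(1, 1, 1, 3, 3) * 1e-3,
                          kurtosis=w15)
        s = AcquisitionScheme("x", [0, 250, 2750],
                              np.array([[0, 0, 0], [1, 0, 0], [1.0, 0, 0]]))
        ds = forward_signal(tis, s)
        assert np.log(ds.signal[0, 0, 0, 2]) == pytest.approx(-2.75 + 2750**2 * 1e-6 / 6,
                                                              abs=1e-9)


def fibo(n):
    from dwibench.core import fibonacci_sphere
    return fibonacci_sphere(n)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        out = add_rician_noise(ds, ArtifactSpec(snr_b0=np.inf), seed=1)
        assert np.array_equal(out.signal, ds.signal)

    def test_rectified_floor_mean_is_sigma_sqrt_pi_over_2(self):
        """Zero signal through the Rician channel has mean sigma*sqrt(pi/2)."""
        rng = np.random.default_rng(42)
        n = 10**6
        e1, e2 = rng.normal(0, 1.0, (2, n))
        mean = np.mean(np.sqrt(e1**2 + e2**2))
        assert mean == pytest.approx(np.sqrt(np.pi / 2), rel=0.01)

    def test_seeded_noise_reproducible(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        spec = ArtifactSpec(snr_b0=30)
        a = add_rician_noise(ds, spec, seed=9)
        b = add_rician_noise(ds, spec, seed=9)
        assert np.array_equal(a.signal, b.signal)

    def test_sigma_scales_with_b0_mean(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        noisy = add_rician_noise(ds, ArtifactSpec(snr_b0=50), seed=3)
        resid = noisy.signal - ds.signal
        b0 = ds.signal[..., schemes["7T-DTI"].b0_mask].mean()
        assert np.std(resid) == pytest.approx(b0 / 50, rel=0.1)


class TestGibbs:
    def test_full_kspace_is_identity_within_roundoff(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        out = apply_gibbs(ds, ArtifactSpec(gibbs_truncation=1.0))
        assert np.allclose(out.signal, ds.signal, atol=1e-9 * ds.signal.max())

    def test_truncation_raises_edge_total_variation(self, schemes):
        sig = np.zeros((32, 32, 4, 33))
        sig[8:24, 8:24, :, :] = 1.0
        from dwibench.core import DWIDataset
        ds = DWIDataset(signal=sig, scheme=schemes["7T-DTI"])
        out = apply_gibbs(ds, ArtifactSpec(gibbs_truncation=0.6))
        tv_in = np.abs(np.diff(sig[:, 16, 1, 0])).sum()
        tv_out = np.abs(np.diff(out.signal[:, 16, 1, 0])).sum()
        assert tv_out > tv_in

    def test_bandlimited_input_nearly_invariant(self, schemes):
        x, y = np.mgrid[0:32, 0:32]
        blob = np.exp(-((x - 16) ** 2 + (y - 16) ** 2) / (2 * 6.0**2))
        sig = np.tile(blob[:, :, None, None], (1, 1, 4, 33)) + 0.1
        from dwibench.core import DWIDataset
        ds = DWIDataset(signal=sig, scheme=schemes["7T-DTI"])
        out = apply_gibbs(ds, ArtifactSpec(gibbs_truncation=0.6))
        rel = np.abs(out.signal - sig).max() / sig.max()
        assert rel < 0.01

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(gibbs_truncation=0.0)


class TestMotionEddy:
    def test_zero_ranges_are_identity(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        out, recs = apply_motion_eddy(ds, ArtifactSpec(), seed=4)
        assert np.array_equal(out.signal, ds.signal)
        assert all(np.allclose(r["matrix"], np.eye(3)) for r in recs)

    def test_translation_recovered_by_phase_correlation(self, schemes, tissue_dti):
        """A pure shift moves the FFT cross-correlation peak accordingly."""
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        from dwibench.geometry import apply_affine

        shifted = apply_affine(ds.signal[..., 0], np.eye(3), (2.0, 0, 0), order=1)
        f1 = np.fft.fftn(ds.signal[..., 0])
        f2 = np.fft.fftn(shifted)
        cp = f1 * np.conj(f2)
        cp /= np.maximum(np.abs(cp), 1e-12)
        cc = np.abs(np.fft.ifftn(cp))
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        # output(x) = input(x - 2), so the correlation peak sits at -2 mod n
        assert peak[0] == cc.shape[0] - 2 and peak[1] == 0 and peak[2] == 0

    def test_b0_volumes_get_no_eddy_component(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        spec = ArtifactSpec(eddy_scale=0.1, eddy_shear=0.1)
        _, recs = apply_motion_eddy(ds, spec, seed=2)
        for v in np.flatnonzero(schemes["7T-DTI"].b0_mask):
            assert recs[v]["eddy_scale"] == 0 and np.all(recs[v]["eddy_shears"] == 0)
        weighted = [r for r in recs if r["eddy_scale"] != 0]
        assert weighted  # eddy actually applied to diffusion-weighted volumes

    def test_first_b0_is_anchor(self, schemes, tissue_dti):
        ds = forward_signal(tissue_dti, schemes["7T-DTI"])
        spec = ArtifactSpec(motion_rot_deg=3, motion_trans_vox=2)
        _, recs = apply_motion_eddy(ds, spec, seed=2)
        assert np.allclose(recs[0]["matrix"], np.eye(3))
        assert np.all(recs[0]["translation_vox"] == 0)


def test_cohort_determinism(schemes, tiny_atlas):
    pop = PopulationSpec(n_hc=2, n_sle=3, affected_tracts=(tiny_atlas.tract_names[0],))
    art = ArtifactSpec(snr_b0=50)
    sch = schemes["7T-DTI"].subsample_directions(6, seed=0)
    a, da, _ = simulate_cohort(sch, tiny_atlas, pop, art, seed=12)
    b, db, _ = simulate_cohort(sch, tiny_atlas, pop, art, seed=12)
    assert all(np.array_equal(x.signal, y.signal) for x, y in zip(a, b))
    assert da.equals(db)


def test_null_design_group_means_statistically_indistinguishable(tiny_atlas):
    """With designed_d = 0 the per-tract mean distributions of the two groups
    coincide (same generator); a two-sample t-test across subjects is null."""
    from scipy import stats

    pop = PopulationSpec(n_hc=12, n_sle=12, designed_d=0.0)
    fa = {g: [] for g in ("HC", "SLE")}
    for i in range(12):
        for g in ("HC", "SLE"):
            t = sample_subject(pop, tiny_atlas, g, seed=100 + 2 * i + (g == "SLE"),
                               with_kurtosis=False)
            fa[g].append(t.tract_params["FA"].mean())
    p = stats.ttest_ind(fa["HC"], fa["SLE"]).pvalue
    assert p > 0.01
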