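"""Sign alignment, temporal PCA, channel projection and reconstruction."""

from dataclasses import replace

import numpy as np
import pytest

from dcetensor import (
    BinaryMask,
    FCMParams,
    TemporalBasisStack,
    TemporalPCA,
    align_signs,
    build_temporal_stack,
    compute_enhancement_series,
    fit_temporal_pca,
    generate_phantom,
    hosvd_decompose,
    hybrid_segment,
    mode_multiply,
    project_channel_basis,
    reconstruct,
    reconstruct_channel,
)
from dcetensor.errors import DegenerateInputError, DimensionError, ParameterError
from dcetensor.pipeline import reconstruct_study
from dcetensor.preprocess import MaskPipelineParams, build_and_apply_mask


def frame_factors(rng, n=4, shape=(6, 5, 4)):
    return [hosvd_decompose(rng.normal(size=shape), frame_index=t + 1) for t in range(n)]


class TestAlignSigns:
    def test_negated_bases_flip_back_to_reference(self, rng):
        f = hosvd_decompose(rng.normal(size=(5, 4, 3)))
        flipped = replace_bases(f, [-b for b in f.mode_bases], core=-f.core)
        # core sign chosen so the reconstruction matches; alignment must
        # restore the reference bases exactly
        aligned = align_signs([f, flipped])
        for mode in range(3):
            np.testing.assert_allclose(
                aligned[1].mode_bases[mode], f.mode_bases[mode], atol=1e-12
            )

    def test_per_frame_reconstruction_unchanged(self, rng):
        factors = frame_factors(rng)
        aligned = align_signs(factors)
        for before, after in zip(factors, aligned):
            np.testing.assert_allclose(reconstruct(before), reconstruct(after), atol=1e-12)

    def test_idempotence(self, rng):
        factors = align_signs(frame_factors(rng))
        twice = align_signs(factors)
        for a, b in zip(factors, twice):
            np.testing.assert_array_equal(a.core, b.core)
            for m1, m2 in zip(a.mode_bases, b.mode_bases):
                np.testing.assert_array_equal(m1, m2)


def replace_bases(f, bases, core=None):
    from dcetensor.tensor import HOSVDFactors

    return HOSVDFactors(tuple(bases), f.core if core is None else core, f.frame_index)


class TestTemporalPCA:
    def test_eigenvalue_sum_equals_covariance_trace(self, rng):
        U = rng.normal(size=(200, 6))
        pca = TemporalPCA().fit(U)
        assert pca.eigenvalues_.sum() == pytest.approx(np.trace(pca.covariance_), abs=1e-8)

    def test_time_constant_stack_closed_form(self):
        """A time-constant stack is a rank-1 stack along the flat temporal
        direction: the ensemble covariance is var(v) * ones, the single
        non-zero eigenvalue is n * var(v) and the first eigenvector is the
        normalized flat vector."""
        v = np.arange(12.0).reshape(4, 3)
        n = 5
        stack = TemporalBasisStack(mode=0, matrices=[v] * n, sign_aligned=True)
        model = fit_temporal_pca(stack)
        var = np.var(v)
        np.testing.assert_allclose(model.covariance, var * np.ones((n, n)), atol=1e-12)
        np.testing.assert_allclose(model.eigenvalues[0], n * var, atol=1e-10)
        np.testing.assert_allclose(model.eigenvalues[1:], 0.0, atol=1e-10)
        np.testing.assert_allclose(model.eigenvectors[:, 0], np.full(n, n**-0.5), atol=1e-10)

    def test_pixel_constant_stack_has_zero_covariance(self):
        """Only a stack with no across-pixel variation has zero covariance."""
        mats = [np.full((4, 3), 2.5)] * 5
        stack = TemporalBasisStack(mode=0, matrices=mats, sign_aligned=True)
        model = fit_temporal_pca(stack)
        np.testing.assert_allclose(model.covariance, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_rank1_stack_recovers_generating_direction(self, rng):
        w = rng.normal(size=6)
        w /= np.linalg.norm(w)
        c = rng.normal(size=500)
        U = c[:, None] * w[None, :] + rng.normal(0, 1e-3, size=(500, 6))
        pca = TemporalPCA().fit(U)
        cosine = abs(np.dot(pca.components_[0], w))
        assert cosine > 0.99

    def test_channel_image_recovers_coefficients_up_to_sign(self, rng):
        w = rng.normal(size=6)
        w /= np.linalg.norm(w)
        c = rng.normal(size=(20, 10))
        U = c.reshape(-1, 1) * w[None, :] + rng.normal(0, 1e-3, size=(200, 6))
        mats = [U[:, t].reshape(20, 10) for t in range(6)]
        stack = TemporalBasisStack(mode=0, matrices=mats, sign_aligned=True)
        model = fit_temporal_pca(stack)
        img = project_channel_basis(stack, model, channel=1)
        # scale-match then compare up to a global sign
        flip = np.sign(np.vdot(img, c)) or 1.0
        scaled = flip * img * (np.linalg.norm(c) / np.linalg.norm(img))
        assert np.max(np.abs(scaled - c)) < 1e-2

    def test_covariance_uses_pixel_count_divisor(self, rng):
        U = rng.normal(size=(50, 4))
        pca = TemporalPCA().fit(U)
        dev = U - U.mean(axis=0)
        np.testing.assert_allclose(pca.covariance_, dev.T @ dev / 50, atol=1e-12)

    def test_eigenvectors_orthonormal_and_sorted(self, rng):
        pca = TemporalPCA().fit(rng.normal(size=(100, 5)))
        E = pca.components_
        np.testing.assert_allclose(E @ E.T, np.eye(5), atol=1e-10)
        assert np.all(np.diff(pca.eigenvalues_) <= 1e-12)

    def test_single_state_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            TemporalPCA().fit(np.ones((1, 6)))

    def test_unaligned_stack_rejected(self, rng):
        stack = TemporalBasisStack(mode=0, matrices=[rng.normal(size=(4, 3))] * 3)
        with pytest.raises(ParameterError):
            fit_temporal_pca(stack)


class TestProjectChannelBasis:
    def test_output_shape_matches_basis_shape(self, rng):
        factors = align_signs(frame_factors(rng))
        stack = build_temporal_stack(factors, 1)
        model = fit_temporal_pca(stack)
        assert project_channel_basis(stack, model, 1).shape == stack.basis_shape

    def test_channel_out_of_range_raises(self, rng):
        factors = align_signs(frame_factors(rng))
        stack = build_temporal_stack(factors, 0)
        model = fit_temporal_pca(stack)
        with pytest.raises(ParameterError):
            project_channel_basis(stack, model, stack.n + 1)


class TestReconstructChannel:
    def test_all_zero_series_reconstructs_to_zero(self):
        factors = align_signs([hosvd_decompose(np.zeros((5, 4, 3))) for _ in range(4)])
        recon = reconstruct_channel(factors)
        np.testing.assert_allclose(recon.volume, 0.0, atol=1e-12)

    def test_volume_shape_equals_roi_box_shape(self, rng):
        factors = align_signs(frame_factors(rng, shape=(6, 5, 4)))
        assert reconstruct_channel(factors).volume.shape == (6, 5, 4)

    def test_matches_brute_force_summation_oracle(self, rng):
        factors = align_signs(frame_factors(rng, shape=(6, 5, 4)))
        recon = reconstruct_channel(factors, core_frames=(1, 2, 3))
        core = np.mean([factors[t].core for t in range(3)], axis=0)
        A1, A2, A3 = recon.channel_bases
        oracle = np.zeros((6, 5, 4))
        R1, R2, R3 = core.shape
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    total = 0.0
                    for a in range(R1):
                        for b in range(R2):
                            for c in range(R3):
                                total += core[a, b, c] * A1[i, a] * A2[j, b] * A3[k, c]
                    oracle[i, j, k] = total
        np.testing.assert_allclose(recon.volume, oracle, atol=1e-10)

    def test_core_frame_average_honours_selection(self, rng):
        factors = align_signs(frame_factors(rng, n=6))
        early = reconstruct_channel(factors, core_frames=(1, 2, 3))
        all_frames = reconstruct_channel(factors, core_frames=tuple(range(1, 7)))
        np.testing.assert_allclose(
            early.averaged_core, np.mean([factors[t].core for t in range(3)], axis=0), atol=1e-12
        )
        assert not np.allclose(early.averaged_core, all_frames.averaged_core)

    def test_empty_core_frames_raises(self, rng):
        with pytest.raises(ParameterError):
            reconstruct_channel(align_signs(frame_factors(rng)), core_frames=())

    def test_scale_equivariance(self, rng):
        """Scaling every ES frame by a > 0 scales Gamma by the same factor
        (bases are scale-invariant, cores and projections scale linearly).
        Checked on full-rank frames, where the SVD factors are unique."""
        frames = [rng.normal(size=(6, 5, 4)) for _ in range(5)]
        ref = frames[2]
        f1 = align_signs([hosvd_decompose(x) for x in frames])
        f3 = align_signs([hosvd_decompose(3.0 * x) for x in frames])
        g1 = reconstruct_channel(f1, orient_to=ref).volume
        g3 = reconstruct_channel(f3, orient_to=ref).volume
        np.testing.assert_allclose(g3, 3.0 * g1, rtol=1e-8, atol=1e-10)

    def test_dominant_first_channel_on_low_noise_phantom(self, small_spec):
        """A washout tumour produces a strictly dominant temporal channel."""
        spec = replace(small_spec, noise_sigma=1.0)
        study, _ = generate_phantom(spec)
        es = compute_enhancement_series(study)
        masked, mask = build_and_apply_mask(es, MaskPipelineParams(), study=study)
        recon, _, _ = reconstruct_study(masked, mask)
        for model in recon.models:
            lam = model.eigenvalues
            assert lam[0] == lam.max()
            assert lam[0] >= 2.0 * lam[1]


def replace_series_values(es, factor):
    from dcetensor.core import EnhancementSeries, VolumeImage

    return EnhancementSeries(
        [VolumeImage(factor * f.values, spacing=f.spacing, affine=f.affine) for f in es.frames],
        source=es.source,
    )


class TestHybridSegment:
    def test_output_contained_in_roi(self, rng):
        roi = np.zeros((8, 8, 4), dtype=bool)
        roi[2:6, 2:6, 1:3] = True
        vol = rng.normal(size=(8, 8, 4))
        vol[3:5, 3:5, 1:3] += 50.0
        seg = hybrid_segment(vol, BinaryMask(roi))
        assert np.all(roi[seg.values])

    def test_high_intensity_block_segmented(self, rng):
        roi = np.ones((8, 8, 4), dtype=bool)
        vol = rng.normal(0, 0.5, size=(8, 8, 4))
        target = np.zeros_like(roi)
        target[2:5, 2:5, 1:3] = True
        vol[target] += 30.0
        seg = hybrid_segment(vol, BinaryMask(roi))
        np.testing.assert_array_equal(seg.values, target)

    def test_five_class_top_cluster_setting(self, rng):
        roi = np.ones((10, 10, 4), dtype=bool)
        vol = rng.normal(0, 0.2, size=(10, 10, 4))
        target = np.zeros_like(roi)
        target[2:5, 2:5, 1:3] = True
        vol[target] += 40.0
        vol[6:8, 6:8, 1:3] += 8.0  # mid-intensity confounder
        seg = hybrid_segment(vol, BinaryMask(roi), FCMParams(n_clusters=5), k_top=1)
        np.testing.assert_array_equal(seg.values, target)

    def test_constant_reconstruction_raises(self):
        roi = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(DegenerateInputError):
            hybrid_segment(np.full((4, 4, 4), 2.0), BinaryMask(roi))

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            hybrid_segment(np.zeros((4, 4, 4)), BinaryMask(np.ones((3, 3, 3), bool)))
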