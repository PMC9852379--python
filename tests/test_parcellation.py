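import numpy as np
import pytest
from scipy import ndimage

from hydroparc.parcellation import (
    DeformationField,
    RigidTransform,
    brain_mask,
    compose,
    dice_per_label,
    propagate_brain_mask,
    register_nonrigid,
    register_rigid,
    warp,
)
from hydroparc.synthetic_data import PhantomSpec, make_symmetric_phantom


@pytest.fixture(scope="module")
def brain_image():
    img, lab = make_symmetric_phantom(
        PhantomSpec(image_size=48, n_regions=12, seed=3)
    )
    return img.astype(np.float64), lab


class TestDeformationField:
    def test_identity_and_invariants(self):
        f = DeformationField.identity((10, 12))
        assert f.shape == (10, 12)
        assert f.mean_magnitude() == 0.0
        with pytest.raises(ValueError):
            DeformationField(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            DeformationField(np.full((2, 4, 4), np.nan))


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([2.0, 1.0, 1.0]))
        # reflections (det -1) are not rigid motions
        M = np.eye(3)
        M[0, 0] = -1.0
        with pytest.raises(ValueError):
            RigidTransform(M)

    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform.from_params(0.3, 2.0, -1.5, center=(10, 10))
        ident = t @ t.inverse()
        assert np.allclose(ident.matrix, np.eye(3), atol=1e-12)


class TestWarp:
    def test_identity_field_is_noop(self, brain_image):
        img, lab = brain_image
        f = DeformationField.identity(img.shape)
        assert np.allclose(warp(img, f), img)
        assert np.array_equal(warp(lab, f, "nearest"), lab)

    def test_label_map_requires_nearest(self, brain_image):
        _, lab = brain_image
        f = DeformationField.identity(lab.shape)
        with pytest.raises(ValueError, match="nearest"):
            warp(lab, f, "linear")

    def test_nearest_never_invents_labels(self, brain_image):
        _, lab = brain_image
        rng = np.random.default_rng(0)
        disp = ndimage.gaussian_filter(
            rng.normal(0, 3, (2,) + lab.shape), sigma=(0, 4, 4)
        )
        warped = warp(lab, DeformationField(disp), "nearest")
        assert set(np.unique(warped)) <= set(np.unique(lab))

    def test_translation_moves_delta_peak(self):
        img = np.zeros((32, 32))
        img[10, 10] = 1.0
        # displacement +3 rows: output samples moving at x + u
        f = DeformationField(
            np.stack([np.full((32, 32), 3.0), np.zeros((32, 32))])
        )
        w = warp(img, f)
        assert np.unravel_index(np.argmax(w), w.shape) == (7, 10)

    def test_out_of_bounds_fills_background(self):
        img = np.ones((8, 8))
        f = DeformationField(
            np.stack([np.full((8, 8), 100.0), np.zeros((8, 8))])
        )
        assert warp(img, f).sum() == 0.0


class TestCompose:
    def test_identity_composition(self):
        i = DeformationField.identity((16, 16))
        assert compose(i, i).mean_magnitude() == 0.0

    def test_translations_add(self):
        a = DeformationField(np.full((2, 16, 16), 2.0))
        b = DeformationField(np.full((2, 16, 16), 1.25))
        c = compose(a, b)
        interior = c.disp[:, 2:-4, 2:-4]
        assert np.allclose(interior, 3.25)

    def test_matches_sequential_warping(self, brain_image):
        img, _ = brain_image
        smooth = ndimage.gaussian_filter(img, 2.0)
        rng = np.random.default_rng(1)
        mk = lambda s: DeformationField(
            ndimage.gaussian_filter(rng.normal(0, 2, (2,) + img.shape),
                                    sigma=(0, 5, 5))
        )
        f1, f2 = mk(1), mk(2)
        two_step = warp(warp(smooth, f1), f2)
        one_step = warp(smooth, compose(f1, f2))
        interior = (slice(6, -6), slice(6, -6))
        assert np.abs(two_step[interior] - one_step[interior]).mean() < 0.01

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose(
                DeformationField.identity((8, 8)),
                DeformationField.identity((10, 10)),
            )


class TestRegisterNonrigid:
    def test_self_registration_near_identity(self, brain_image):
        img, _ = brain_image
        f = register_nonrigid(img, img)
        assert f.mean_magnitude() < 0.1

    def test_known_translation_recovered(self, brain_image):
        img, _ = brain_image
        # fixed(x) = moving(x + 5 rows) -> displacement (+5, 0)
        fixed = ndimage.shift(img, (-5, 0), order=1)
        f = register_nonrigid(img, fixed)
        fg = fixed > 0.05
        assert abs(f.disp[0][fg].mean() - 5.0) < 0.5
        assert abs(f.disp[1][fg].mean()) < 0.5

    def test_similarity_never_degrades(self, brain_image):
        img, _ = brain_image
        rng = np.random.default_rng(2)
        fixed = np.clip(
            img + rng.normal(0, 0.02, img.shape), 0, 1
        )
        f = register_nonrigid(img, fixed)
        before = np.mean((img - fixed) ** 2)
        after = np.mean((warp(img, f) - fixed) ** 2)
        assert after <= before


class TestRegisterRigid:
    def test_self_registration_identity(self, brain_image):
        img, _ = brain_image
        t = register_rigid(img, img)
        assert abs(np.rad2deg(t.angle)) < 0.5
        assert np.abs(t.translation).max() < 0.5

    def test_known_rotation_recovered(self, brain_image):
        img, _ = brain_image
        c = (np.asarray(img.shape) - 1) / 2.0
        truth = RigidTransform.from_params(np.deg2rad(10), 0, 0, center=c)
        fixed = warp(img, truth)
        rec = register_rigid(img, fixed)
        assert abs(np.rad2deg(rec.angle) - 10.0) < 1.0
        # recovered o truth^-1 ~ identity
        resid = rec @ truth.inverse()
        assert abs(np.rad2deg(resid.angle)) < 1.0


class TestBrainMaskPropagation:
    def test_identity_case(self, brain_image):
        img, _ = brain_image
        m = brain_mask(img)
        M_T, stripped = propagate_brain_mask(img, img, m)
        assert np.array_equal(M_T, m)
        assert np.all(stripped[M_T == 0] == 0)

    def test_translated_head_dice(self, brain_image):
        img, _ = brain_image
        m = brain_mask(img)
        fixed = ndimage.shift(img, (-3, 2), order=1)
        true_mask = ndimage.shift(m, (-3, 2), order=0)
        M_T, _ = propagate_brain_mask(img, fixed, m)
        inter = np.logical_and(M_T, true_mask).sum()
        dice = 2 * inter / (M_T.sum() + true_mask.sum())
        assert dice > 0.95

    def test_grid_mismatch_rejected(self, brain_image):
        img, _ = brain_image
        with pytest.raises(ValueError):
            propagate_brain_mask(img, img, np.ones((8, 8)))


class TestParcellate:
    def test_lesion_free_same_family_high_dice(self):
        from hydroparc.parcellation import parcellate
        from hydroparc.synthetic_data import make_atlas

        atlas = make_atlas(image_size=48, n_regions=12, seed=99)
        # subject = the atlas itself under a tiny smooth warp, no lesion
        rng = np.random.default_rng(0)
        u = ndimage.gaussian_filter(
            rng.normal(0, 1, (2, 48, 48)), sigma=(0, 8, 8)
        )
        u *= 1.2 / (np.abs(u).max() + 1e-9)
        rr, cc = np.mgrid[0:48, 0:48].astype(np.float64)
        img = ndimage.map_coordinates(
            atlas.image.astype(np.float64),
            np.stack([rr + u[0], cc + u[1]]), order=1, mode="nearest",
        )
        lab = ndimage.map_coordinates(
            atlas.labels, np.stack([rr + u[0], cc + u[1]]),
            order=0, mode="nearest",
        )
        res = parcellate(
            img, np.zeros_like(img, dtype=np.uint8), None, atlas,
            no_inpaint=True,
        )
        dices = dice_per_label(res.L_T, lab)
        assert np.mean(list(dices.values())) > 0.9

    def test_label_set_never_exceeds_atlas(self, tiny_trained_model):
        from hydroparc.experiments import _make_subject
        from hydroparc.parcellation import parcellate
        from hydroparc.synthetic_data import make_atlas

        model, _ = tiny_trained_model
        atlas = make_atlas(image_size=32, n_regions=6, seed=99)
        rng = np.random.default_rng(1)
        img, lab, lesion = _make_subject(atlas, rng, 32)
        fmri_mean = ndimage.zoom(img, 1.0, order=1)
        res = parcellate(img, lesion, model, atlas, fmri_mean=fmri_mean)
        assert set(np.unique(res.L_T)) <= set(np.unique(atlas.labels))
        assert res.L_F is not None
        assert set(np.unique(res.L_F)) <= set(np.unique(atlas.labels))

    def test_stage_failure_names_stage(self):
        from hydroparc.parcellation import parcellate
        from hydroparc.synthetic_data import make_atlas

        atlas = make_atlas(image_size=32, n_regions=6, seed=0)
        black = np.zeros((32, 32))
        with pytest.raises(RuntimeError, match="stage"):
            parcellate(black, np.zeros((32, 32), dtype=np.uint8), None,
                       atlas, no_inpaint=True)


def test_dice_per_label_exact_overlap():
    lab = np.zeros((10, 10), dtype=np.int32)
    lab[:5, :5] = 1
    lab[5:, 5:] = 2
    d = dice_per_label(lab, lab)
    assert d == {1: 1.0, 2: 1.0}
    shifted = np.roll(lab, 1, axis=0)
    d2 = dice_per_label(shifted, lab)
    assert 0 < d2[1] < 1.0
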