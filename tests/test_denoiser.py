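"""Trunk and equivariant head: identity at init, equivariance, templates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plcdiff import (DenoiserConfig, LigandAtom, LigandBond, NoisePredictor,
                     NoiseSchedule, build_system, denoise_to_x,
                     load_checkpoint, save_checkpoint)
from plcdiff.geometry import sample_subspace_gaussian
from plcdiff.nn import Tensor, perturb_parameters

SMALL = DenoiserConfig(n_blocks=1, c_s=16, c_p=8, n_heads=2, c_outer=4,
                       c_tri=4, n_rbf=16, time_dim=8)


def _ligand(n=3):
    atoms = [LigandAtom(atomic_number=6 + k, degree=1) for k in range(n)]
    bonds = [LigandBond(k, k + 1) for k in range(n - 1)]
    return atoms, bonds


def test_zero_initialized_trunk_is_identity(toy):
    """Residual branches have zero-initialized outputs: block 1 = identity."""
    system, frame = toy
    model = NoisePredictor(SMALL, seed=5)
    z = frame.coords * model.config.coord_scale
    reps = model.build_representations(system, z, 0.5)
    out = model.trunk_update(reps)
    np.testing.assert_array_equal(out.single.data, reps.single.data)
    np.testing.assert_array_equal(out.pair.data, reps.pair.data)


def test_output_shapes(small_model, toy, rng):
    system, _ = toy
    n = system.n_tokens
    z = sample_subspace_gaussian(n, rng)
    out = small_model.predict_noise(system, z, 0.3)
    assert out.eps_hat.shape == (n, 3)
    assert out.weight_matrix.shape == (n, n)
    zb = sample_subspace_gaussian(n, rng, size=4)
    outb = small_model.predict_noise(system, zb, 0.3)
    assert outb.eps_hat.shape == (4, n, 3)


def test_ligand_permutation_equivariance(rng):
    """Swapping two ligand tokens permutes the output identically."""
    model = NoisePredictor(SMALL, seed=1)
    perturb_parameters(model, np.random.default_rng(1), 0.05)
    atoms, bonds = _ligand(3)
    system = build_system("MKVL", (atoms, bonds))
    perm_atoms = [atoms[1], atoms[0], atoms[2]]
    perm_bonds = [LigandBond(1, 0), LigandBond(0, 2)]
    system_p = build_system("MKVL", (perm_atoms, perm_bonds))
    perm = np.array([0, 1, 2, 3, 5, 4, 6])  # swap ligand tokens 0 and 1
    z = sample_subspace_gaussian(system.n_tokens, rng)
    out = model.predict_noise(system, z, 0.4).eps_hat.data
    out_p = model.predict_noise(system_p, z[perm], 0.4).eps_hat.data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_forced_weight_matrix_hand_value():
    """Two atoms with W12 = W21 = w give eps_hat = [(-w,0,0), (w,0,0)]."""
    model = NoisePredictor(SMALL, seed=0)
    w = 0.7
    z = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    weights = Tensor(np.array([[[0.0, w], [w, 0.0]]]))
    eps_hat = model.weights_to_noise(weights, z[None]).data[0]
    np.testing.assert_allclose(eps_hat, [[-w, 0, 0], [w, 0, 0]], atol=1e-12)


def test_se3_equivariance(small_model, toy, rng):
    system, _ = toy
    z = sample_subspace_gaussian(system.n_tokens, rng)
    base = small_model.predict_noise(system, z, 0.6).eps_hat.data
    r = Rotation.random(random_state=2).as_matrix()
    tau = np.array([3.0, -1.0, 2.0])
    moved = small_model.predict_noise(system, z @ r.T + tau, 0.6).eps_hat.data
    rel = np.linalg.norm(moved - base @ r.T) / np.linalg.norm(base)
    assert rel < 1e-10


def test_translation_invariance_and_zero_centroid(small_model, toy, rng):
    system, _ = toy
    z = sample_subspace_gaussian(system.n_tokens, rng)
    out = small_model.predict_noise(system, z, 0.2).eps_hat.data
    shifted = small_model.predict_noise(system, z + 5.0, 0.2).eps_hat.data
    np.testing.assert_allclose(shifted, out, atol=1e-10)
    np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


def test_coincident_atoms_are_finite(small_model, toy):
    system, _ = toy
    z = np.zeros((system.n_tokens, 3))
    out = small_model.predict_noise(system, z, 0.9).eps_hat.data
    assert np.all(np.isfinite(out))


def test_weight_matrix_depends_on_distances_only(small_model, toy, rng):
    system, _ = toy
    z = sample_subspace_gaussian(system.n_tokens, rng)
    r = Rotation.random(random_state=6).as_matrix()
    w1 = small_model.predict_noise(system, z, 0.5).weight_matrix.data
    w2 = small_model.predict_noise(system, z @ r.T, 0.5).weight_matrix.data
    np.testing.assert_allclose(w1, w2, atol=1e-10)


class TestDenoiseToX:
    def test_exact_inversion(self, schedule, rng):
        x = sample_subspace_gaussian(6, rng)
        eps = sample_subspace_gaussian(6, rng)
        t = 0.55
        alpha, sigma = schedule.alpha_sigma(t)
        z = alpha * x + sigma * eps
        np.testing.assert_allclose(denoise_to_x(z, eps, t, schedule), x, atol=1e-10)

    def test_zero_noise_prediction(self, schedule, rng):
        z = sample_subspace_gaussian(6, rng)
        alpha, _ = schedule.alpha_sigma(0.3)
        np.testing.assert_allclose(denoise_to_x(z, np.zeros_like(z), 0.3, schedule),
                                   z / alpha, atol=1e-12)

    def test_affine_superposition(self, schedule, rng):
        z1, z2 = (sample_subspace_gaussian(5, rng) for _ in range(2))
        e1, e2 = (sample_subspace_gaussian(5, rng) for _ in range(2))
        t = 0.7
        lhs = denoise_to_x(0.3 * z1 + 0.7 * z2, 0.3 * e1 + 0.7 * e2, t, schedule)
        rhs = 0.3 * denoise_to_x(z1, e1, t, schedule) + 0.7 * denoise_to_x(z2, e2, t, schedule)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestTemplateConditioning:
    def _model(self, conditioning):
        cfg = DenoiserConfig(n_blocks=1, c_s=16, c_p=8, n_heads=2, c_outer=4,
                             c_tri=4, n_rbf=16, time_dim=8,
                             template_conditioning=conditioning)
        model = NoisePredictor(cfg, seed=9)
        perturb_parameters(model, np.random.default_rng(9), 0.05)
        return model

    def test_off_leaves_representations_unchanged(self, toy, rng):
        system, frame = toy
        model = self._model("off")
        z = frame.coords * model.config.coord_scale
        template = rng.standard_normal((system.n_res, 3)) * 4
        a = model.build_representations(system, z, 0.5)
        b = model.build_representations(system, z, 0.5, template_ca=template)
        np.testing.assert_array_equal(a.pair.data, b.pair.data)

    def test_rigidly_moved_template_conditions_identically(self, toy, rng):
        system, frame = toy
        model = self._model("backbone")
        z = frame.coords * model.config.coord_scale
        template = rng.standard_normal((system.n_res, 3)) * 4
        r = Rotation.random(random_state=3).as_matrix()
        a = model.build_representations(system, z, 0.5, template_ca=template)
        b = model.build_representations(system, z, 0.5,
                                        template_ca=template @ r.T + 2.0)
        np.testing.assert_allclose(a.pair.data, b.pair.data, atol=1e-10)

    def test_equal_distance_matrices_condition_identically(self, toy, rng):
        system, frame = toy
        model = self._model("backbone")
        z = frame.coords * model.config.coord_scale
        template = rng.standard_normal((system.n_res, 3)) * 4
        mirrored = -template  # reflection: identical distance matrix
        a = model.build_representations(system, z, 0.5, template_ca=template)
        b = model.build_representations(system, z, 0.5, template_ca=mirrored)
        np.testing.assert_allclose(a.pair.data, b.pair.data, atol=1e-10)

    def test_template_row_count_checked(self, toy, rng):
        system, frame = toy
        model = self._model("backbone")
        z = frame.coords * model.config.coord_scale
        with pytest.raises(ValueError, match="template"):
            model.build_representations(system, z, 0.5,
                                        template_ca=rng.standard_normal((3, 3)))


def test_nonfinite_activation_names_block(small_model, toy, rng):
    system, _ = toy
    z = sample_subspace_gaussian(system.n_tokens, rng)
    model = NoisePredictor(SMALL, seed=2)
    model.blocks[0].strans1.w.data[0, 0] = np.nan
    with pytest.raises(FloatingPointError, match="block 0"):
        model.predict_noise(system, z, 0.5)


def test_checkpoint_round_trip(tmp_path, small_model):
    path = tmp_path / "model.npz"
    named = dict(small_model.named_parameters())
    ema = {"ema": [p.data * 0.5 for p in named.values()],
           "ema_best": [p.data * 0.25 for p in named.values()]}
    save_checkpoint(path, small_model, ema=ema, meta={"note": 1})
    loaded, info = load_checkpoint(path)
    assert loaded.config == small_model.config
    for (name, p), (_, q) in zip(named.items(), loaded.named_parameters()):
        np.testing.assert_array_equal(p.data, q.data)
    np.testing.assert_array_equal(info["ema"]["ema_best"][0],
                                  list(named.values())[0].data * 0.25)
    assert info["meta"]["note"] == 1
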