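"""Ancestral sampling of complex structures from a trained noise predictor.

Generation discretizes time uniformly into T steps, initializes z_1 from
the standard zero-centroid subspace Gaussian, and iterates the reverse
transition

    z_s = z_t / alpha_{t|s}
        - (sigma_{t|s}^2 / (alpha_{t|s} sigma_t)) eps_hat(z_t; t)
        + sigma_{t->s} noise,

which is the posterior q(z_s | z_t, x) with x replaced by the denoised
estimate. The returned structure is the mean z_0 / alpha_0 of the final
reconstruction distribution (its stddev is negligible by the endpoint
contract), so a frame is deterministic given its seed. Frames of an
ensemble use independent child seeds spawned from the ensemble seed, and
the per-frame seeds are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .denoiser import NoisePredictor
from .featurize import MolecularSystem
from .geometry import CoordinateFrame, project_zero_centroid, sample_subspace_gaussian
from .schedule import NoiseSchedule

__all__ = ["SamplerConfig", "StructureEnsemble", "ancestral_step",
           "sample_structure", "generate_ensemble"]


@dataclass(frozen=True)
class SamplerConfig:
    n_steps: int = 250
    n_samples: int = 64
    seed: int = 0
    use_ema: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_samples < 1:
            raise ValueError("n_steps and n_samples must be >= 1")


@dataclass
class StructureEnsemble:
    """Generated frames for one system with their per-frame seeds."""

    system: MolecularSystem
    frames: list[CoordinateFrame]
    frame_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for frame in self.frames:
            if np.any(np.abs(frame.coords.mean(axis=0)) > 1e-6):
                raise ValueError("ensemble frames must be zero-centroid")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


def ancestral_step(z_t: np.ndarray, s: float, t: float, eps_hat: np.ndarray,
                   schedule: NoiseSchedule, noise: np.ndarray) -> np.ndarray:
    """One reverse transition z_t -> z_s (latent units).

    ``noise`` must be a zero-centroid subspace draw (pass zeros for the
    deterministic mean). Supports a leading batch axis on ``z_t``,
    ``eps_hat`` and ``noise``.
    """
    if not s < t:
        raise ValueError("ancestral step requires s < t")
    z_t = np.asarray(z_t, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    _, sigma_t = schedule.alpha_sigma(t)
    _, sigma_s = schedule.alpha_sigma(s)
    alpha_ts, sigma2_ts = schedule.transition_params(s, t)
    sigma_post = np.sqrt(sigma2_ts) * sigma_s / sigma_t
    z_s = z_t / alpha_ts - (sigma2_ts / (alpha_ts * sigma_t)) * eps_hat \
        + sigma_post * np.asarray(noise, dtype=np.float64)
    if not np.all(np.isfinite(z_s)):
        raise FloatingPointError(f"non-finite latent after step to s={s:.6g}")
    return z_s


def _run_reverse_chain(model: NoisePredictor, schedule: NoiseSchedule,
                       system: MolecularSystem, rngs: list[np.random.Generator],
                       T: int, plm_embedding=None, template_ca=None,
                       predictor=None) -> np.ndarray:
    """Batched reverse diffusion; one independent rng per frame.

    Returns coordinates in Angstrom, zero-centroid. ``predictor`` may
    override the model's noise prediction (e.g. an analytic oracle) with
    signature (z_batch, t) -> eps_hat_batch.
    """
    n = system.n_tokens
    b = len(rngs)
    z = np.stack([sample_subspace_gaussian(n, rng) for rng in rngs])
    with nn.no_grad():
        for i in range(T, 0, -1):
            t, s = i / T, (i - 1) / T
            if predictor is not None:
                eps_hat = predictor(z, t)
            else:
                eps_hat = model.predict_noise(
                    system, z, t, plm_embedding, template_ca
                ).eps_hat.data
            noise = np.stack([sample_subspace_gaussian(n, rng) for rng in rngs])
            try:
                z = ancestral_step(z, s, t, eps_hat, schedule, noise)
            except FloatingPointError as err:
                raise FloatingPointError(f"step {T - i + 1}/{T}: {err}") from None
    alpha0, _ = schedule.alpha_sigma(0.0)
    x_latent = z / alpha0
    return project_zero_centroid(x_latent) / model.config.coord_scale


def _frame_seeds(config: SamplerConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(config.seed).spawn(config.n_samples)


def _with_params(model: NoisePredictor, config: SamplerConfig,
                 ema_params: list[np.ndarray] | None):
    if config.use_ema and ema_params is not None:
        return nn.swap_params(model.parameters(), ema_params)
    import contextlib
    return contextlib.nullcontext()


def sample_structure(model: NoisePredictor, schedule: NoiseSchedule,
                     system: MolecularSystem, config: SamplerConfig,
                     sample_index: int = 0,
                     ema_params: list[np.ndarray] | None = None,
                     plm_embedding=None, template_ca=None) -> CoordinateFrame:
    """Generate one structure; deterministic given (config.seed, sample_index)."""
    if not 0 <= sample_index < config.n_samples:
        raise ValueError("sample_index out of range")
    seed_seq = _frame_seeds(config)[sample_index]
    with _with_params(model, config, ema_params):
        coords = _run_reverse_chain(model, schedule, system,
                                    [np.random.default_rng(seed_seq)],
                                    config.n_steps, plm_embedding, template_ca)[0]
    return CoordinateFrame(coords=coords, atom_roles=system.atom_roles, centered=True)


def generate_ensemble(model: NoisePredictor, schedule: NoiseSchedule,
                      system: MolecularSystem, config: SamplerConfig,
                      ema_params: list[np.ndarray] | None = None,
                      plm_embedding=None, template_ca=None,
                      predictor=None) -> StructureEnsemble:
    """Generate ``config.n_samples`` i.i.d. frames (batched over frames)."""
    seed_seqs = _frame_seeds(config)
    rngs = [np.random.default_rng(ss) for ss in seed_seqs]
    with _with_params(model, config, ema_params):
        coords = _run_reverse_chain(model, schedule, system, rngs,
                                    config.n_steps, plm_embedding, template_ca,
                                    predictor=predictor)
    frames = [
        CoordinateFrame(coords=c, atom_roles=system.atom_roles, centered=True)
        for c in coords
    ]
    seeds = [int(ss.entropy) if ss.spawn_key == () else ss.spawn_key[-1]
             for ss in seed_seqs]
    return StructureEnsemble(system=system, frames=frames, frame_seeds=seeds)
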