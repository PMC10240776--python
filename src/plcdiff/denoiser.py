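"""Noise-prediction network: residual single/pair trunk + equivariant head.

The trunk is a single-sequence pair-representation stack: each block applies
pair-biased self-attention over tokens, a transition MLP on the single
representation, an outer-product update of the pair representation from the
single one, an optional triangular multiplicative update on the pair
representation, and a pair transition -- all residual, with every branch's
output projection zero-initialized so a freshly built block is the identity.

The head symmetrizes the final pair representation, maps it through an MLP
to a scalar weight matrix W, and predicts noise as the weighted sum of unit
relative-difference vectors

    eps_hat_i = sum_{j != i} W_ij / max(||z_i - z_j||, eps_dist) (z_i - z_j)

followed by centroid removal. W sees coordinates only through radial-basis
distance features, so the whole model is SE(3)-equivariant: rotating and
translating z rotates eps_hat and leaves W unchanged.

An optional template-conditioning switch (the structure-conditioned model
variant) adds radial-basis embeddings of a provided backbone-Calpha distance
matrix to the protein-protein pair block; conditioning is on distances only,
never raw coordinates, so it is itself rigid-motion invariant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .featurize import InputEmbedder, MolecularSystem, Representations
from .nn import LayerNorm, Linear, Module, Tensor
from .schedule import NoiseSchedule

__all__ = ["DenoiserConfig", "DenoiserOutput", "NoisePredictor",
           "denoise_to_x", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters (desk-scale defaults)."""

    n_blocks: int = 2
    c_s: int = 64
    c_p: int = 32
    n_heads: int = 4
    c_outer: int = 16
    c_tri: int = 16
    use_triangular_update: bool = True
    epsilon_dist: float = 1e-2       # Angstrom floor for the head denominator
    template_conditioning: str = "off"  # "off" | "backbone"
    coord_scale: float = 0.1         # Angstrom -> latent unit conversion
    n_rbf: int = 64
    d_max: float = 30.0              # Angstrom span of the distance RBFs
    time_dim: int = 32
    plm_dim: int = 0                 # 0 disables the PLM input channel

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.epsilon_dist <= 0:
            raise ValueError("epsilon_dist must be positive")
        if self.c_s % self.n_heads:
            raise ValueError("c_s must be divisible by n_heads")
        if self.template_conditioning not in ("off", "backbone"):
            raise ValueError("template_conditioning must be 'off' or 'backbone'")


@dataclass
class DenoiserOutput:
    """Predicted noise (B, N, 3) and the pair-derived weights (B, N, N)."""

    eps_hat: Tensor
    weight_matrix: Tensor


class FoldingBlock(Module):
    """One residual update of the (single, pair) representations."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        c_s, c_p, h = cfg.c_s, cfg.c_p, cfg.n_heads
        self.n_heads = h
        self.d_head = c_s // h
        self.attn_ln_s = LayerNorm(c_s)
        self.attn_ln_p = LayerNorm(c_p)
        self.q = Linear(c_s, c_s, rng, bias=False)
        self.k = Linear(c_s, c_s, rng, bias=False)
        self.v = Linear(c_s, c_s, rng, bias=False)
        self.pair_bias = Linear(c_p, h, rng, bias=False)
        self.attn_out = Linear(c_s, c_s, rng, zero_init=True)
        self.strans_ln = LayerNorm(c_s)
        self.strans1 = Linear(c_s, 4 * c_s, rng)
        self.strans2 = Linear(4 * c_s, c_s, rng, zero_init=True)
        self.opm_ln = LayerNorm(c_s)
        self.opm_a = Linear(c_s, cfg.c_outer, rng)
        self.opm_b = Linear(c_s, cfg.c_outer, rng)
        self.opm_out = Linear(cfg.c_outer, c_p, rng, zero_init=True)
        self.use_tri = cfg.use_triangular_update
        if self.use_tri:
            self.tri_ln = LayerNorm(c_p)
            self.tri_a = Linear(c_p, cfg.c_tri, rng)
            self.tri_a_gate = Linear(c_p, cfg.c_tri, rng)
            self.tri_b = Linear(c_p, cfg.c_tri, rng)
            self.tri_b_gate = Linear(c_p, cfg.c_tri, rng)
            self.tri_o_ln = LayerNorm(cfg.c_tri)
            self.tri_gate = Linear(c_p, c_p, rng)
            self.tri_out = Linear(cfg.c_tri, c_p, rng, zero_init=True)
        self.ptrans_ln = LayerNorm(c_p)
        self.ptrans1 = Linear(c_p, 4 * c_p, rng)
        self.ptrans2 = Linear(4 * c_p, c_p, rng, zero_init=True)

    def __call__(self, single: Tensor, pair: Tensor) -> tuple[Tensor, Tensor]:
        b, n, c_s = single.shape
        h, d = self.n_heads, self.d_head
        # pair-biased self-attention over tokens
        s_ln = self.attn_ln_s(single)
        bias = self.pair_bias(self.attn_ln_p(pair)).transpose((0, 3, 1, 2))
        q = self.q(s_ln).reshape((b, n, h, d))
        k = self.k(s_ln).reshape((b, n, h, d))
        v = self.v(s_ln).reshape((b, n, h, d))
        logits = nn.einsum2("bihd,bjhd->bhij", q, k) * (1.0 / np.sqrt(d)) + bias
        attn = nn.softmax_op(logits, axis=-1)
        ctx = nn.einsum2("bhij,bjhd->bihd", attn, v).reshape((b, n, c_s))
        single = single + self.attn_out(ctx)
        # single transition
        single = single + self.strans2(nn.relu(self.strans1(self.strans_ln(single))))
        # outer-product update of pair from single
        s2 = self.opm_ln(single)
        outer = nn.einsum2("bic,bjc->bijc", self.opm_a(s2), self.opm_b(s2))
        pair = pair + self.opm_out(outer)
        # triangular multiplicative update (outgoing edges)
        if self.use_tri:
            p_ln = self.tri_ln(pair)
            a = nn.sigmoid(self.tri_a_gate(p_ln)) * self.tri_a(p_ln)
            bb = nn.sigmoid(self.tri_b_gate(p_ln)) * self.tri_b(p_ln)
            tri = nn.einsum2("bikc,bjkc->bijc", a, bb)
            update = nn.sigmoid(self.tri_gate(p_ln)) * self.tri_out(self.tri_o_ln(tri))
            pair = pair + update
        # pair transition
        pair = pair + self.ptrans2(nn.relu(self.ptrans1(self.ptrans_ln(pair))))
        self._check_finite(single, pair)
        return single, pair

    @staticmethod
    def _check_finite(single: Tensor, pair: Tensor) -> None:
        if not np.all(np.isfinite(single.data)):
            raise FloatingPointError("non-finite activations in single representation")
        if not np.all(np.isfinite(pair.data)):
            raise FloatingPointError("non-finite activations in pair representation")


class NoisePredictor(Module):
    """Full noise-prediction model eps_hat_theta(z_t; t)."""

    def __init__(self, config: DenoiserConfig = DenoiserConfig(),
                 seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.config = config
        # the embedder sees latent-unit coordinates: convert the RBF span
        self.embedder = InputEmbedder(
            config.c_s, config.c_p, rng, n_rbf=config.n_rbf,
            d_max=config.d_max * config.coord_scale,
            time_dim=config.time_dim, plm_dim=config.plm_dim,
        )
        self.blocks = [FoldingBlock(config, rng) for _ in range(config.n_blocks)]
        self.head_ln = LayerNorm(config.c_p)
        self.head_hidden = Linear(config.c_p, config.c_p, rng)
        self.head_out = Linear(config.c_p, 1, rng, zero_init=True)
        if config.template_conditioning == "backbone":
            self.template_proj = Linear(config.n_rbf, config.c_p, rng)

    # -- representation building -------------------------------------------

    def build_representations(self, system: MolecularSystem, z_latent: np.ndarray,
                              t, plm_embedding: np.ndarray | None = None,
                              template_ca: np.ndarray | None = None) -> Representations:
        """Initial single/pair representations for latent coords at time t.

        ``z_latent`` is (N, 3) or (B, N, 3) in latent units; ``t`` a scalar
        or per-frame vector. Distance and time terms are recomputed here on
        every call.
        """
        z = np.asarray(z_latent, dtype=np.float64)
        if z.ndim == 2:
            z = z[None]
        t_vec = np.broadcast_to(np.asarray(t, dtype=np.float64), (z.shape[0],))
        single_dyn, pair_dyn = self.embedder.dynamic_terms(z, t_vec)
        single = self.embedder.single_base(system, plm_embedding) + single_dyn
        pair = self.embedder.pair_base(system) + pair_dyn
        pair = self.apply_template(pair, system, template_ca)
        return Representations(single=single, pair=pair)

    def apply_template(self, pair: Tensor, system: MolecularSystem,
                       template_ca: np.ndarray | None) -> Tensor:
        """Add template Calpha distance features to the protein-protein block.

        A no-op unless template conditioning is enabled and a template is
        supplied; conditioning uses distances only, so rigidly moving the
        template changes nothing.
        """
        if self.config.template_conditioning != "backbone" or template_ca is None:
            return pair
        term = self.embedder.template_term(system, template_ca,
                                           self.template_proj,
                                           d_max=self.config.d_max)
        return pair + term

    def trunk_update(self, reps: Representations) -> Representations:
        single, pair = reps.single, reps.pair
        for i, block in enumerate(self.blocks):
            try:
                single, pair = block(single, pair)
            except FloatingPointError as err:
                raise FloatingPointError(f"block {i}: {err}") from None
        return Representations(single=single, pair=pair)

    # -- equivariant head --------------------------------------------------

    def pair_to_weights(self, pair: Tensor) -> Tensor:
        """Symmetrize the pair tensor and map it to the (B, N, N) weights."""
        sym = (pair + pair.transpose((0, 2, 1, 3))) * 0.5
        w = self.head_out(nn.relu(self.head_hidden(self.head_ln(sym))))
        b, n = w.shape[0], w.shape[1]
        w = w.reshape((b, n, n))
        off_diag = 1.0 - np.eye(n)
        return w * Tensor(off_diag)

    def weights_to_noise(self, weights: Tensor, z_latent: np.ndarray) -> Tensor:
        """Weighted sum of relative differences, centroid-projected."""
        z = np.asarray(z_latent, dtype=np.float64)
        if z.ndim == 2:
            z = z[None]
        diff = z[:, :, None, :] - z[:, None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        eps_floor = self.config.epsilon_dist * self.config.coord_scale
        directions = diff / np.maximum(dist, eps_floor)[..., None]
        eps_hat = nn.einsum2("bij,bijc->bic", weights, directions)
        return eps_hat - eps_hat.mean(axis=1, keepdims=True)

    def predict_noise(self, system: MolecularSystem, z_latent: np.ndarray, t,
                      plm_embedding: np.ndarray | None = None,
                      template_ca: np.ndarray | None = None) -> DenoiserOutput:
        """eps_hat for latent coordinates (N, 3) or (B, N, 3) at time t."""
        z = np.asarray(z_latent, dtype=np.float64)
        squeeze = z.ndim == 2
        if squeeze:
            z = z[None]
        reps = self.build_representations(system, z, t, plm_embedding, template_ca)
        reps = self.trunk_update(reps)
        weights = self.pair_to_weights(reps.pair)
        eps_hat = self.weights_to_noise(weights, z)
        if squeeze:
            eps_hat = eps_hat.reshape(eps_hat.shape[1:])
            weights = weights.reshape(weights.shape[1:])
        return DenoiserOutput(eps_hat=eps_hat, weight_matrix=weights)


def denoise_to_x(z_t: np.ndarray, eps_hat: np.ndarray, t: float,
                 schedule: NoiseSchedule) -> np.ndarray:
    """Invert the noise parameterization: x_hat = (z_t - sigma_t eps_hat)/alpha_t."""
    alpha, sigma = schedule.alpha_sigma(t)
    return (np.asarray(z_t, dtype=np.float64)
            - sigma * np.asarray(eps_hat, dtype=np.float64)) / alpha


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(path, model: NoisePredictor,
                    ema: dict[str, list[np.ndarray]] | None = None,
                    meta: dict | None = None) -> None:
    """Single-file checkpoint: config + parameters (+ EMA shadows).

    Format (versioned): an .npz archive with keys ``param/<name>`` for raw
    parameters, ``<group>/<name>`` for each EMA group passed in ``ema``
    (e.g. ``ema``, ``ema_best``), and a JSON header under ``__meta__``.
    """
    named = dict(model.named_parameters())
    arrays = {f"param/{k}": v.data for k, v in named.items()}
    if ema:
        for group, shadows in ema.items():
            for (k, _), s in zip(named.items(), shadows):
                arrays[f"{group}/{k}"] = s
    header = {
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(model.config),
        "meta": meta or {},
        "ema_groups": sorted(ema) if ema else [],
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[NoisePredictor, dict]:
    """Rebuild a model from a checkpoint; returns (model, info).

    ``info`` carries the header plus any EMA groups as name->array dicts.
    """
    with np.load(path) as archive:
        header = json.loads(archive["__meta__"].tobytes().decode())
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        model = NoisePredictor(DenoiserConfig(**header["config"]))
        named = dict(model.named_parameters())
        for name, tensor in named.items():
            tensor.data = np.array(archive[f"param/{name}"])
        info = {"meta": header["meta"], "ema": {}}
        for group in header["ema_groups"]:
            info["ema"][group] = [np.array(archive[f"{group}/{name}"]) for name in named]
    return model, info
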