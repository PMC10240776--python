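"""System assembly and input featurization.

A ``MolecularSystem`` joins a protein sequence (one token per residue,
modeled at the Calpha position) and a ligand molecular graph (one token per
heavy atom), protein-first. The ``InputEmbedder`` turns the system into the
initial single (per-token) and pair (per-token-pair) representations:

* protein single rows: learned amino-acid embeddings, optionally augmented
  by a normalized + linearly mapped per-residue matrix from an external
  protein language model (supplied as a file-based input, never computed
  in-process);
* ligand single rows: summed embeddings of nine per-atom chemical features;
* pair entries: relative-position encoding for protein-protein pairs
  (sequence offset clipped at +/-32), bond-feature embeddings for bonded
  ligand-ligand pairs, and learned block-type embeddings that distinguish
  protein-ligand and unbonded ligand-ligand pairs;
* radial-basis embeddings of current inter-atom distances and a sinusoidal
  embedding of diffusion time are added on every denoising call, so the
  coordinate-dependent part of the features is recomputed per step.

All coordinate-dependent features are functions of pairwise distances only,
which is what makes the downstream noise predictor SE(3)-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Embedding, Linear, LayerNorm, Module, Tensor

__all__ = [
    "LigandAtom",
    "LigandBond",
    "MolecularSystem",
    "Representations",
    "build_system",
    "graph_automorphisms",
    "rbf_embedding",
    "time_embedding",
    "InputEmbedder",
]

MAX_TOKENS_DEFAULT = 384
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
AA_TO_INDEX["X"] = len(AMINO_ACIDS)  # unknown residue bucket
N_AA = len(AMINO_ACIDS) + 1

RELPOS_CLIP = 32
N_RELPOS = 2 * RELPOS_CLIP + 2  # signed offsets plus a "not applicable" bucket
RELPOS_NA = 2 * RELPOS_CLIP + 1

# pair block types
PAIR_PROT_PROT, PAIR_PROT_LIG, PAIR_LIG_UNBONDED, PAIR_LIG_BONDED = range(4)

# -- categorical vocabularies (an explicit "other" bucket closes each) ------

_ATOMIC_NUMBERS = [5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53]
_CHIRALITY = ["unspecified", "tet_cw", "tet_ccw"]
_DEGREES = list(range(7))
_FORMAL_CHARGES = [-2, -1, 0, 1, 2]
_N_HYDROGENS = list(range(5))
_N_RADICAL = list(range(3))
_HYBRIDIZATIONS = ["s", "sp", "sp2", "sp3", "sp3d", "sp3d2"]
_BOND_TYPES = ["single", "double", "triple", "aromatic"]
_BOND_STEREO = ["none", "any", "z", "e", "cis", "trans"]


def _code(vocab: list, value) -> int:
    try:
        return vocab.index(value)
    except ValueError:
        return len(vocab)  # "other"


ATOM_VOCAB_SIZES = [
    len(_ATOMIC_NUMBERS) + 1, len(_CHIRALITY) + 1, len(_DEGREES) + 1,
    len(_FORMAL_CHARGES) + 1, len(_N_HYDROGENS) + 1, len(_N_RADICAL) + 1,
    len(_HYBRIDIZATIONS) + 1, 2, 2,
]
BOND_VOCAB_SIZES = [len(_BOND_TYPES) + 1, len(_BOND_STEREO) + 1, 2]


@dataclass(frozen=True)
class LigandAtom:
    """Heavy atom of the ligand graph with its nine chemical features."""

    atomic_number: int
    chirality: str = "unspecified"
    degree: int = 0
    formal_charge: int = 0
    n_hydrogens: int = 0
    n_radical_electrons: int = 0
    hybridization: str = "sp3"
    is_aromatic: bool = False
    is_in_ring: bool = False

    def __post_init__(self) -> None:
        if self.atomic_number < 1 or self.atomic_number == 1:
            raise ValueError("ligand atoms must be heavy (atomic number > 1)")
        if self.degree < 0:
            raise ValueError("degree must be non-negative")

    def feature_codes(self) -> np.ndarray:
        return np.array([
            _code(_ATOMIC_NUMBERS, self.atomic_number),
            _code(_CHIRALITY, self.chirality),
            _code(_DEGREES, self.degree),
            _code(_FORMAL_CHARGES, self.formal_charge),
            _code(_N_HYDROGENS, self.n_hydrogens),
            _code(_N_RADICAL, self.n_radical_electrons),
            _code(_HYBRIDIZATIONS, self.hybridization),
            int(self.is_aromatic),
            int(self.is_in_ring),
        ])


@dataclass(frozen=True)
class LigandBond:
    """Bond of the ligand graph with its three features."""

    atom_i: int
    atom_j: int
    bond_type: str = "single"
    stereo: str = "none"
    is_conjugated: bool = False

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("a bond must join two distinct atoms")

    def feature_codes(self) -> np.ndarray:
        return np.array([
            _code(_BOND_TYPES, self.bond_type),
            _code(_BOND_STEREO, self.stereo),
            int(self.is_conjugated),
        ])


@dataclass
class MolecularSystem:
    """Joined protein + ligand entity, tokens ordered protein-first."""

    sequence: str
    lig_atoms: list[LigandAtom]
    lig_bonds: list[LigandBond]
    residue_index: np.ndarray = field(default=None)  # 1-based, contiguous
    max_tokens: int = MAX_TOKENS_DEFAULT

    def __post_init__(self) -> None:
        if self.residue_index is None:
            self.residue_index = np.arange(1, len(self.sequence) + 1)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        for bond in self.lig_bonds:
            n = len(self.lig_atoms)
            if not (0 <= bond.atom_i < n and 0 <= bond.atom_j < n):
                raise ValueError("bond references an invalid atom index")
        if self.n_tokens > self.max_tokens:
            raise ValueError(
                f"system has {self.n_tokens} tokens, exceeding the "
                f"max_tokens cutoff of {self.max_tokens}"
            )

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    @property
    def n_lig(self) -> int:
        return len(self.lig_atoms)

    @property
    def n_tokens(self) -> int:
        return self.n_res + self.n_lig

    @property
    def atom_roles(self) -> np.ndarray:
        from .geometry import LIGAND_HEAVY, PROTEIN_CA
        return np.array([PROTEIN_CA] * self.n_res + [LIGAND_HEAVY] * self.n_lig)

    # -- integer feature codes used by the embedder ------------------------

    def aa_codes(self) -> np.ndarray:
        return np.array([AA_TO_INDEX[aa] for aa in self.sequence])

    def lig_atom_codes(self) -> np.ndarray:
        if not self.lig_atoms:
            return np.zeros((0, 9), dtype=np.int64)
        return np.stack([a.feature_codes() for a in self.lig_atoms])

    def relpos_codes(self) -> np.ndarray:
        """(n_tokens, n_tokens) clipped-offset buckets; ligand pairs -> NA."""
        n = self.n_tokens
        codes = np.full((n, n), RELPOS_NA, dtype=np.int64)
        ri = self.residue_index
        off = np.clip(ri[None, :] - ri[:, None], -RELPOS_CLIP, RELPOS_CLIP)
        codes[: self.n_res, : self.n_res] = off + RELPOS_CLIP
        return codes

    def pair_type_codes(self) -> np.ndarray:
        n, p = self.n_tokens, self.n_res
        codes = np.full((n, n), PAIR_PROT_PROT, dtype=np.int64)
        codes[:p, p:] = PAIR_PROT_LIG
        codes[p:, :p] = PAIR_PROT_LIG
        codes[p:, p:] = PAIR_LIG_UNBONDED
        for b in self.lig_bonds:
            codes[p + b.atom_i, p + b.atom_j] = PAIR_LIG_BONDED
            codes[p + b.atom_j, p + b.atom_i] = PAIR_LIG_BONDED
        return codes


def build_system(sequence: str,
                 ligand: tuple[list[LigandAtom], list[LigandBond]],
                 max_tokens: int = MAX_TOKENS_DEFAULT) -> MolecularSystem:
    """Assemble a MolecularSystem from a sequence and a ligand graph spec."""
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = sorted({aa for aa in sequence if aa not in AA_TO_INDEX})
    if bad:
        raise ValueError(f"unknown residue letters: {''.join(bad)}")
    atoms, bonds = ligand
    if len(atoms) < 1:
        raise ValueError("ligand must contain at least one heavy atom")
    return MolecularSystem(sequence=sequence, lig_atoms=list(atoms),
                           lig_bonds=list(bonds), max_tokens=max_tokens)


@dataclass
class Representations:
    """Single (tokens x c_s) and pair (tokens x tokens x c_p) features.

    Batched tensors carry a leading frame axis: single (B, N, c_s) and
    pair (B, N, N, c_p).
    """

    single: Tensor
    pair: Tensor


def graph_automorphisms(lig_atoms: list[LigandAtom], lig_bonds: list[LigandBond],
                        max_count: int = 1000) -> list[np.ndarray]:
    """Symmetry permutations of the ligand graph (feature-preserving).

    Enumerates graph automorphisms that preserve every atom feature tuple
    and every bond feature tuple, for the symmetry-aware RMSD variant.
    Returns index arrays (the identity first); enumeration stops at
    ``max_count`` mappings.
    """
    import networkx as nx

    g = nx.Graph()
    for i, atom in enumerate(lig_atoms):
        g.add_node(i, feat=tuple(atom.feature_codes()))
    for bond in lig_bonds:
        g.add_edge(bond.atom_i, bond.atom_j, feat=tuple(bond.feature_codes()))
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["feat"] == b["feat"],
        edge_match=lambda a, b: a["feat"] == b["feat"],
    )
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perms.append(np.array([mapping[i] for i in range(len(lig_atoms))]))
        if len(perms) >= max_count:
            break
    identity = np.arange(len(lig_atoms))
    perms.sort(key=lambda p: not np.array_equal(p, identity))
    return perms


# -- coordinate-free feature transforms ------------------------------------


def rbf_embedding(coords: np.ndarray, n_centers: int = 64, d_max: float = 30.0) -> np.ndarray:
    """Gaussian radial-basis features of pairwise distances.

    Centers span [0, d_max] with width equal to their spacing; output shape
    (..., N, N, n_centers), symmetric in the two token axes and invariant
    to rigid motion of ``coords``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    diff = coords[..., :, None, :] - coords[..., None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    centers = np.linspace(0.0, d_max, n_centers)
    width = d_max / (n_centers - 1)
    return np.exp(-((dist[..., None] - centers) ** 2) / (2.0 * width**2))


def time_embedding(t, dim: int = 32, max_freq: float = 1000.0) -> np.ndarray:
    """Sinusoidal embedding of diffusion time at geometric frequencies.

    Returns (..., dim) with [sin(w_k t), cos(w_k t)] pairs, w_k spanning
    [1, max_freq] geometrically. At t=0 all sines are 0 and cosines 1; the
    leading frequency (w=1) makes the map injective on [0, 1].
    """
    if dim % 2 != 0:
        raise ValueError("time embedding dimension must be even")
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("diffusion time must lie in [0, 1]")
    k = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(max_freq), k))
    phase = t[..., None] * freqs
    return np.concatenate([np.sin(phase), np.cos(phase)], axis=-1)


# -- learned embedder -------------------------------------------------------


class InputEmbedder(Module):
    """Learned tables and projections producing the initial representations."""

    def __init__(self, c_s: int, c_p: int, rng: np.random.Generator,
                 n_rbf: int = 64, d_max: float = 30.0, time_dim: int = 32,
                 plm_dim: int = 0):
        self.c_s, self.c_p = c_s, c_p
        self.n_rbf, self.d_max, self.time_dim = n_rbf, d_max, time_dim
        self.plm_dim = plm_dim
        self.aa_embed = Embedding(N_AA, c_s, rng)
        self.atom_embeds = [Embedding(n, c_s, rng) for n in ATOM_VOCAB_SIZES]
        self.relpos_embed = Embedding(N_RELPOS, c_p, rng)
        self.pair_type_embed = Embedding(4, c_p, rng)
        self.bond_embeds = [Embedding(n, c_p, rng) for n in BOND_VOCAB_SIZES]
        self.rbf_proj = Linear(n_rbf, c_p, rng)
        self.time_to_single = Linear(time_dim, c_s, rng)
        self.time_to_pair = Linear(time_dim, c_p, rng)
        if plm_dim:
            self.plm_norm = LayerNorm(plm_dim)
            self.plm_proj = Linear(plm_dim, c_s, rng)

    # coordinate-independent parts (computable once per system) ------------

    def single_base(self, system: MolecularSystem,
                    plm_embedding: np.ndarray | None = None) -> Tensor:
        """Initial single representation (n_tokens, c_s), no time term."""
        parts = [self.aa_embed(system.aa_codes())]
        if plm_embedding is not None:
            if not self.plm_dim:
                raise ValueError("model was built without a PLM input channel")
            plm = np.asarray(plm_embedding, dtype=np.float64)
            if plm.shape != (system.n_res, self.plm_dim):
                raise ValueError(
                    f"PLM embedding must be ({system.n_res}, {self.plm_dim}), "
                    f"got {plm.shape}"
                )
            parts.append(self.plm_proj(self.plm_norm(Tensor(plm))))
        protein = parts[0]
        for extra in parts[1:]:
            protein = protein + extra
        if system.n_lig == 0:
            return protein
        codes = system.lig_atom_codes()
        ligand = self.atom_embeds[0](codes[:, 0])
        for f in range(1, 9):
            ligand = ligand + self.atom_embeds[f](codes[:, f])
        return _concat_rows(protein, ligand)

    def pair_base(self, system: MolecularSystem) -> Tensor:
        """Initial pair representation (n, n, c_p), no distance/time terms."""
        pair = self.relpos_embed(system.relpos_codes())
        pair = pair + self.pair_type_embed(system.pair_type_codes())
        if system.lig_bonds:
            n, p = system.n_tokens, system.n_res
            codes = np.zeros((n, n, 3), dtype=np.int64)
            mask = np.zeros((n, n, 1))
            for b in system.lig_bonds:
                fc = b.feature_codes()
                for i, j in ((p + b.atom_i, p + b.atom_j), (p + b.atom_j, p + b.atom_i)):
                    codes[i, j] = fc
                    mask[i, j] = 1.0
            bond = self.bond_embeds[0](codes[..., 0])
            for f in range(1, 3):
                bond = bond + self.bond_embeds[f](codes[..., f])
            pair = pair + bond * mask
        return pair

    # coordinate/time-dependent parts (recomputed every denoising call) ----

    def dynamic_terms(self, coords: np.ndarray, t) -> tuple[Tensor, Tensor]:
        """(single_term, pair_term) from time and current distances.

        ``coords`` may be (N, 3) or batched (B, N, 3); ``t`` a scalar or a
        (B,) vector of per-frame diffusion times. Distances are taken in the
        coordinate units passed in (the model converts its Angstrom-valued
        RBF span to latent units before calling this).
        """
        te = time_embedding(np.atleast_1d(np.asarray(t, dtype=np.float64)),
                            self.time_dim)  # (B, time_dim)
        single_term = self.time_to_single(Tensor(te[:, None, :]))  # (B,1,c_s)
        pair_time = self.time_to_pair(Tensor(te[:, None, None, :]))  # (B,1,1,c_p)
        rbf = rbf_embedding(coords, self.n_rbf, self.d_max)
        if rbf.ndim == 3:
            rbf = rbf[None]
        pair_term = self.rbf_proj(Tensor(rbf)) + pair_time
        return single_term, pair_term

    def template_term(self, system: MolecularSystem,
                      backbone_coords: np.ndarray, proj: Linear,
                      d_max: float | None = None) -> Tensor:
        """RBF embedding of template Calpha distances on the protein block.

        ``d_max`` overrides the embedder span (templates arrive in Angstrom
        whereas the dynamic terms see latent-unit coordinates).
        """
        backbone = np.asarray(backbone_coords, dtype=np.float64)
        if backbone.shape != (system.n_res, 3):
            raise ValueError(
                f"template must provide ({system.n_res}, 3) coordinates, "
                f"got {backbone.shape}"
            )
        rbf = rbf_embedding(backbone, self.n_rbf,
                            self.d_max if d_max is None else d_max)
        term = proj(Tensor(rbf))  # (n_res, n_res, c_p)
        n = system.n_tokens
        mask = np.zeros((n, n, 1))
        mask[: system.n_res, : system.n_res] = 1.0
        padded = np.zeros((n, n, term.shape[-1]))
        full = Tensor(padded) + _pad_pair(term, n)
        return full * Tensor(mask)


def _concat_rows(a: Tensor, b: Tensor) -> Tensor:
    """Row-concatenate two 2-D tensors with gradient routing."""
    na = a.shape[0]
    data = np.concatenate([a.data, b.data], axis=0)
    out = nn._make(data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(out.grad[:na])
            if b.requires_grad:
                b._accumulate(out.grad[na:])
        out._backward = _bw
    return out


def _pad_pair(term: Tensor, n: int) -> Tensor:
    """Zero-pad an (m, m, c) pair block into the top-left of (n, n, c)."""
    m = term.shape[0]
    data = np.zeros((n, n, term.shape[-1]))
    data[:m, :m] = term.data
    out = nn._make(data, (term,))
    if out.requires_grad:
        def _bw():
            term._accumulate(out.grad[:m, :m])
        out._backward = _bw
    return out
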