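"""Zero-centroid subspace operations and structural comparison metrics.

The diffusion process lives on the linear subspace of point clouds whose
centroid is at the origin; this module provides the projection onto that
subspace, Gaussian sampling restricted to it, least-squares rigid
superposition (Kabsch), the TM-score with the standard iterative
fragment-seeded refinement, and the ligand RMSD after protein alignment
(L-rms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoordinateFrame",
    "project_zero_centroid",
    "sample_subspace_gaussian",
    "kabsch_superpose",
    "tm_score",
    "ligand_rms",
]

PROTEIN_CA = "protein-ca"
LIGAND_HEAVY = "ligand-heavy"


@dataclass
class CoordinateFrame:
    """An (N, 3) coordinate set in Angstrom with per-row role tags."""

    coords: np.ndarray
    atom_roles: np.ndarray  # array of PROTEIN_CA / LIGAND_HEAVY strings
    centered: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_roles = np.asarray(self.atom_roles)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.atom_roles) != len(self.coords):
            raise ValueError("one role per coordinate row required")
        if self.centered and np.any(np.abs(self.coords.mean(axis=0)) > 1e-6):
            raise ValueError("frame marked centered but centroid exceeds 1e-6 A")

    @property
    def protein_mask(self) -> np.ndarray:
        return self.atom_roles == PROTEIN_CA

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.atom_roles == LIGAND_HEAVY

    def protein_coords(self) -> np.ndarray:
        return self.coords[self.protein_mask]

    def ligand_coords(self) -> np.ndarray:
        return self.coords[self.ligand_mask]


def project_zero_centroid(coords: np.ndarray) -> np.ndarray:
    """Remove the centroid; idempotent."""
    coords = np.asarray(coords, dtype=np.float64)
    return coords - coords.mean(axis=-2, keepdims=True)


def sample_subspace_gaussian(n_atoms: int, rng: np.random.Generator | int,
                             size: int | None = None) -> np.ndarray:
    """Draw from the standard Gaussian on the zero-centroid subspace.

    Draws i.i.d. standard normals per coordinate and projects out the
    centroid. Returns (n_atoms, 3), or (size, n_atoms, 3) when ``size`` is
    given. For a single atom the subspace is {0}.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    shape = (n_atoms, 3) if size is None else (size, n_atoms, 3)
    return project_zero_centroid(rng.standard_normal(shape))


# -- rigid superposition ---------------------------------------------------


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target`` (optionally
    weighted). Only proper rotations are returned: if the optimal orthogonal
    transform is a reflection, the smallest singular direction is flipped.
    Degenerate inputs (collinear or identical points) still yield a valid
    transform. RMSD reported is always unweighted.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (N, 3)")
    if len(mobile) < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(len(mobile), 1.0 / len(mobile))
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    mu_m = w @ mobile
    mu_t = w @ target
    h = (mobile - mu_m).T @ (w[:, None] * (target - mu_t))
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = mu_t - rotation @ mu_m
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return rotation, translation, rmsd


def _apply(rotation: np.ndarray, translation: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


# -- TM-score --------------------------------------------------------------


def tm_d0(length: int) -> float:
    """Length-dependent distance scale, clamped to 0.5 A for short chains."""
    if length > 15:
        d0 = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_from_transform(pred, ref, rotation, translation, d0):
    d2 = ((_apply(rotation, translation, pred) - ref) ** 2).sum(axis=1)
    return float(np.mean(1.0 / (1.0 + d2 / d0**2)))


def _refine(pred, ref, rotation, translation, d0, max_iter=60):
    """Monotone TM-score ascent by iteratively re-weighted superposition.

    The TM kernel f(d^2) = 1 / (1 + d^2/d0^2) is convex in d^2, so the
    linearization at the current fit is a global lower bound; maximizing it
    is a weighted least-squares superposition with weights f(d^2)^2. Each
    iteration therefore cannot decrease the score; iteration stops at a
    fixed point.
    """
    best = _tm_from_transform(pred, ref, rotation, translation, d0)
    for _ in range(max_iter):
        d2 = ((_apply(rotation, translation, pred) - ref) ** 2).sum(axis=1)
        w = 1.0 / (1.0 + d2 / d0**2) ** 2
        rotation, translation, _ = kabsch_superpose(pred, ref, weights=w)
        score = _tm_from_transform(pred, ref, rotation, translation, d0)
        if score <= best + 1e-12:
            best = max(best, score)
            break
        best = score
    return best, rotation, translation


def _fragment_seeds(length: int, all_seeds: bool) -> list[tuple[int, int]]:
    if all_seeds:
        lengths = range(4, length + 1)
    else:
        lengths = sorted({length, max(length // 2, 4), max(length // 4, 4),
                          min(4, length)}, reverse=True)
    seeds = []
    for fl in lengths:
        if fl < 3 or fl > length:
            continue
        for start in range(0, length - fl + 1):
            seeds.append((start, fl))
    return seeds


def tm_score(pred_ca: np.ndarray, ref_ca: np.ndarray, all_seeds: bool = False) -> float:
    """TM-score of two same-length Calpha traces (correspondence by index).

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i/d0)^2) with
    d0 = 1.24 (L-15)^(1/3) - 1.8 clamped to >= 0.5 A. The maximization
    seeds a superposition from contiguous fragments and refines each seed
    by iteratively re-weighted superposition; ``all_seeds=True`` enumerates
    every contiguous fragment of length >= 4 (exhaustive, for small L).
    """
    pred_ca = np.asarray(pred_ca, dtype=np.float64)
    ref_ca = np.asarray(ref_ca, dtype=np.float64)
    if pred_ca.shape != ref_ca.shape:
        raise ValueError("TM-score requires equal-length residue sets")
    length = len(pred_ca)
    if length < 3:
        raise ValueError("TM-score requires at least 3 residues")
    d0 = tm_d0(length)
    best = 0.0
    for start, fl in _fragment_seeds(length, all_seeds):
        sl = slice(start, start + fl)
        rotation, translation, _ = kabsch_superpose(pred_ca[sl], ref_ca[sl])
        score, _, _ = _refine(pred_ca, ref_ca, rotation, translation, d0)
        best = max(best, score)
    return best


# -- ligand RMSD after protein alignment -----------------------------------


def ligand_rms(pred: CoordinateFrame, ref: CoordinateFrame,
               permutations=None) -> float:
    """Heavy-atom ligand RMSD after superposing the proteins (L-rms).

    The predicted frame is rigidly fitted to the reference using protein
    Calpha atoms only; the resulting transform is applied to the predicted
    ligand and the plain coordinate RMSD over ligand heavy atoms returned.
    Atom correspondence is by index. Optionally, ``permutations`` (an
    iterable of ligand index permutations, e.g. the graph automorphisms
    from :func:`plcdiff.featurize.graph_automorphisms`) enables the
    stricter symmetry-aware variant: the minimum RMSD over the given
    renumberings is returned.
    """
    p_prot, r_prot = pred.protein_coords(), ref.protein_coords()
    p_lig, r_lig = pred.ligand_coords(), ref.ligand_coords()
    if p_prot.shape != r_prot.shape or len(p_prot) < 3:
        raise ValueError("matching protein Calpha sets (>= 3 atoms) required")
    if p_lig.shape != r_lig.shape or len(p_lig) == 0:
        raise ValueError("matching non-empty ligand heavy-atom sets required")
    rotation, translation, _ = kabsch_superpose(p_prot, r_prot)
    moved = _apply(rotation, translation, p_lig)
    if permutations is None:
        permutations = [np.arange(len(p_lig))]
    best = np.inf
    for perm in permutations:
        rms = np.sqrt(((moved[np.asarray(perm)] - r_lig) ** 2).sum(axis=1).mean())
        best = min(best, float(rms))
    return best
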