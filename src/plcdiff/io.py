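"""File formats, run configuration and format conversions.

Scope is the single-chain, single-ligand setting: a complex PDB carries one
protein chain as Calpha ATOM records and one ligand as non-water HETATM
records; multiple ligands are an explicit error, waters and hydrogens are
dropped. Residue numbering is 1-based on file (PDB convention) and token
indices are 0-based in memory; this module is the only place that boundary
appears.

Ligands are read from SDF/MOL (through RDKit, hydrogens folded into the
per-atom hydrogen counts) or from a minimal JSON graph dialect used by the
fixtures:

    {"atoms": [{"atomic_number": 6, "degree": 2, ...}, ...],
     "bonds": [[i, j, "single", "none", false], ...]}

Per-residue protein-language-model embeddings arrive as a whitespace table
(one row per residue) or an .npy matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.sequence.io.fasta as fasta_io
from biotite.sequence import ProteinSequence

from .denoiser import DenoiserConfig
from .featurize import LigandAtom, LigandBond, MolecularSystem, build_system
from .geometry import CoordinateFrame, project_zero_centroid
from .sampling import SamplerConfig, StructureEnsemble
from .schedule import NoiseSchedule
from .training import TrainConfig

__all__ = [
    "RunConfig", "load_run_config",
    "read_fasta", "write_fasta",
    "read_ligand", "write_ligand_json",
    "read_plm_embedding",
    "read_complex_pdb", "write_ensemble_pdb", "write_complex_pdb",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
LIGAND_RES_NAME = "LIG"
LIGAND_CHAIN = "L"
PROTEIN_CHAIN = "A"


# -- configuration ---------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated YAML run configuration (each section checks its own invariants)."""

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int = 0


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        schedule=NoiseSchedule(**raw.get("schedule", {})),
        denoiser=DenoiserConfig(**raw.get("denoiser", {})),
        train=TrainConfig(**raw.get("train", {})),
        sampler=SamplerConfig(**raw.get("sampler", {})),
        seed=int(raw.get("seed", 0)),
    )


# -- sequences -------------------------------------------------------------


def read_fasta(path) -> str:
    """First record of a FASTA file, uppercased."""
    records = fasta_io.FastaFile.read(str(path))
    for _, seq in records.items():
        return str(seq).strip().upper()
    raise ValueError(f"no sequences in {path}")


def write_fasta(path, sequence: str, name: str = "protein") -> None:
    records = fasta_io.FastaFile()
    records[name] = sequence
    records.write(str(path))


# -- ligand graphs ---------------------------------------------------------

_RDKIT_CHIRALITY = {"CHI_UNSPECIFIED": "unspecified",
                    "CHI_TETRAHEDRAL_CW": "tet_cw",
                    "CHI_TETRAHEDRAL_CCW": "tet_ccw"}
_RDKIT_BOND_TYPES = {"SINGLE": "single", "DOUBLE": "double",
                     "TRIPLE": "triple", "AROMATIC": "aromatic"}
_RDKIT_STEREO = {"STEREONONE": "none", "STEREOANY": "any", "STEREOZ": "z",
                 "STEREOE": "e", "STEREOCIS": "cis", "STEREOTRANS": "trans"}


def _ligand_from_rdkit(mol) -> tuple[list[LigandAtom], list[LigandBond]]:
    from rdkit import Chem

    mol = Chem.RemoveHs(mol)  # fold explicit hydrogens into H counts
    atoms = []
    for atom in mol.GetAtoms():
        atoms.append(LigandAtom(
            atomic_number=atom.GetAtomicNum(),
            chirality=_RDKIT_CHIRALITY.get(str(atom.GetChiralTag()), "other"),
            degree=atom.GetDegree(),
            formal_charge=atom.GetFormalCharge(),
            n_hydrogens=atom.GetTotalNumHs(),
            n_radical_electrons=atom.GetNumRadicalElectrons(),
            hybridization=str(atom.GetHybridization()).lower(),
            is_aromatic=atom.GetIsAromatic(),
            is_in_ring=atom.IsInRing(),
        ))
    bonds = [
        LigandBond(
            atom_i=b.GetBeginAtomIdx(), atom_j=b.GetEndAtomIdx(),
            bond_type=_RDKIT_BOND_TYPES.get(str(b.GetBondType()), "other"),
            stereo=_RDKIT_STEREO.get(str(b.GetStereo()), "other"),
            is_conjugated=b.GetIsConjugated(),
        )
        for b in mol.GetBonds()
    ]
    if not atoms:
        raise ValueError("ligand has no heavy atoms")
    return atoms, bonds


def read_ligand(path) -> tuple[list[LigandAtom], list[LigandBond]]:
    """Ligand graph spec from an SDF/MOL file or the JSON dialect."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        atoms = [LigandAtom(**a) for a in raw["atoms"]]
        bonds = [
            LigandBond(atom_i=i, atom_j=j, bond_type=bt, stereo=st,
                       is_conjugated=bool(conj))
            for i, j, bt, st, conj in raw.get("bonds", [])
        ]
        if not atoms:
            raise ValueError("ligand has no heavy atoms")
        return atoms, bonds
    from rdkit import Chem

    mol = Chem.MolFromMolFile(path, removeHs=False)
    if mol is None:
        raise ValueError(f"could not parse molecule from {path}")
    return _ligand_from_rdkit(mol)


def write_ligand_json(path, atoms: list[LigandAtom], bonds: list[LigandBond]) -> None:
    payload = {
        "atoms": [
            {"atomic_number": a.atomic_number, "chirality": a.chirality,
             "degree": a.degree, "formal_charge": a.formal_charge,
             "n_hydrogens": a.n_hydrogens,
             "n_radical_electrons": a.n_radical_electrons,
             "hybridization": a.hybridization,
             "is_aromatic": a.is_aromatic, "is_in_ring": a.is_in_ring}
            for a in atoms
        ],
        "bonds": [[b.atom_i, b.atom_j, b.bond_type, b.stereo, b.is_conjugated]
                  for b in bonds],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_plm_embedding(path) -> np.ndarray:
    """Per-residue embedding matrix: whitespace table or .npy."""
    path = str(path)
    if path.endswith(".npy"):
        return np.asarray(np.load(path), dtype=np.float64)
    return np.atleast_2d(np.loadtxt(path, dtype=np.float64))


# -- complex PDB -----------------------------------------------------------


def read_complex_pdb(path, max_tokens: int = 384
                     ) -> tuple[MolecularSystem, list[CoordinateFrame]]:
    """Parse a (possibly multi-model) complex PDB.

    Returns a MolecularSystem skeleton (sequence from residue names, ligand
    atoms carrying element identity only, no bonds) and one CoordinateFrame
    per MODEL. Waters and hydrogens are dropped; more than one ligand
    residue is an error.
    """
    stack = PDBFile.read(str(path)).get_structure(altloc="occupancy")
    arr = stack[0]
    protein = arr[~arr.hetero]
    ca_mask = protein.atom_name == "CA"
    ca = protein[ca_mask]
    if len(np.unique(protein.chain_id)) > 1:
        raise ValueError("multi-chain proteins are out of scope (single chain only)")
    n_residues_with_atoms = len(np.unique(protein.res_id))
    if len(ca) < n_residues_with_atoms:
        warnings.warn(
            f"{n_residues_with_atoms - len(ca)} residue(s) without a CA atom "
            "were skipped", stacklevel=2)
    if len(ca) == 0:
        raise ValueError("no protein CA atoms found")
    sequence = "".join(
        _three_to_one(rn) for rn in ca.res_name
    )
    het = arr[arr.hetero]
    het = het[~np.isin(het.res_name, list(_WATER_NAMES))]
    het = het[~np.isin(het.element, ["H", "D"])]
    if len(het) == 0:
        raise ValueError("no ligand heavy atoms found (waters excluded)")
    lig_ids = {(c, r, n) for c, r, n in zip(het.chain_id, het.res_id, het.res_name)}
    if len(lig_ids) > 1:
        raise ValueError(f"multiple ligands found: {sorted(lig_ids)}")
    lig_atoms = [
        LigandAtom(atomic_number=_atomic_number(el), degree=0, n_hydrogens=0)
        for el in het.element
    ]
    system = MolecularSystem(sequence=sequence, lig_atoms=lig_atoms,
                             lig_bonds=[], residue_index=np.asarray(ca.res_id),
                             max_tokens=max_tokens)
    ca_sel = (~arr.hetero) & (arr.atom_name == "CA")
    het_sel = arr.hetero & ~np.isin(arr.res_name, list(_WATER_NAMES)) \
        & ~np.isin(arr.element, ["H", "D"])
    frames = []
    for m in range(stack.stack_depth()):
        coords = np.concatenate([stack.coord[m][ca_sel], stack.coord[m][het_sel]])
        frames.append(CoordinateFrame(coords=np.asarray(coords, dtype=np.float64),
                                      atom_roles=system.atom_roles))
    return system, frames


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"


def _atomic_number(element: str) -> int:
    from rdkit import Chem

    z = Chem.GetPeriodicTable().GetAtomicNumber(element.capitalize())
    if z <= 1:
        raise ValueError(f"not a heavy-atom element: {element!r}")
    return z


def _element_symbol(z: int) -> str:
    from rdkit import Chem

    return Chem.GetPeriodicTable().GetElementSymbol(int(z))


def _template_atom_array(system: MolecularSystem) -> struc.AtomArray:
    n = system.n_tokens
    arr = struc.AtomArray(n)
    p = system.n_res
    chain = np.array([PROTEIN_CHAIN] * p + [LIGAND_CHAIN] * system.n_lig)
    res_id = np.concatenate([system.residue_index,
                             np.ones(system.n_lig, dtype=np.int64)])
    res_name = np.array(
        [ProteinSequence.convert_letter_1to3(aa) if aa != "X" else "UNK"
         for aa in system.sequence]
        + [LIGAND_RES_NAME] * system.n_lig
    )
    elements = [_element_symbol(a.atomic_number) for a in system.lig_atoms]
    atom_name = np.array(
        ["CA"] * p + [f"{el.upper()}{k + 1}"[:4] for k, el in enumerate(elements)]
    )
    arr.chain_id = chain
    arr.res_id = res_id
    arr.res_name = res_name
    arr.atom_name = atom_name
    arr.element = np.array(["C"] * p + [el.upper() for el in elements])
    arr.hetero = np.array([False] * p + [True] * system.n_lig)
    return arr


def write_complex_pdb(path, system: MolecularSystem,
                      frames: list[CoordinateFrame] | CoordinateFrame) -> None:
    """Write one or more conformers of a system as a (multi-MODEL) PDB."""
    if isinstance(frames, CoordinateFrame):
        frames = [frames]
    template = _template_atom_array(system)
    arrays = []
    for frame in frames:
        arr = template.copy()
        arr.coord = np.asarray(frame.coords, dtype=np.float32)
        arrays.append(arr)
    pdb_file = PDBFile()
    pdb_file.set_structure(struc.stack(arrays))
    pdb_file.write(str(path))


def write_ensemble_pdb(path, ensemble: StructureEnsemble) -> None:
    """Multi-MODEL PDB of a generated ensemble (MODEL numbered 1..n)."""
    write_complex_pdb(path, ensemble.system, ensemble.frames)
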