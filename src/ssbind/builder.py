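"""Coarse-grained model construction.

Proteins are reduced to two beads per residue (Cα and Cβ; Gly keeps only
Cα) with a Go-type native topology: harmonic bonds and angles, the
1−cos(Δφ)−cos(3Δφ) dihedral, and a 12-10 native-contact well per contact
pair.  Charged residues carry ±1 e on the Cβ bead.

Single-stranded nucleic acids are beads-on-a-string polymers with three
beads per nucleotide — phosphate (P, charge −1), sugar (S) and base (B),
each at the geometric center of its moiety.  Reference bond lengths,
angles and dihedrals come from an idealized helical template (the
conformation a strand adopts inside the duplex); strand flexibility is
controlled by two dihedral families whose stiffness differs between DNA
and RNA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .params import (
    AROMATIC_RESIDUES,
    NEGATIVE_RESIDUES,
    POSITIVE_RESIDUES,
    ForceFieldParams,
    load_params,
)

log = logging.getLogger(__name__)

__all__ = [
    "AtomicStructure",
    "BeadTable",
    "CGProteinModel",
    "CGNucleicModel",
    "build_protein_model",
    "build_na_model",
    "map_complex",
    "helix_template_coords",
]

# Bead role codes shared across the package
ROLE_CA, ROLE_CB, ROLE_P, ROLE_S, ROLE_B = 0, 1, 2, 3, 4
ROLE_NAMES = {ROLE_CA: "CA", ROLE_CB: "CB", ROLE_P: "P", ROLE_S: "S", ROLE_B: "B"}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}

DNA_ALPHABET = set("ACGT")
RNA_ALPHABET = set("ACGU")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
NA_RESNAMES = {
    "DA": ("A", "DNA"), "DC": ("C", "DNA"), "DG": ("G", "DNA"), "DT": ("T", "DNA"),
    "A": ("A", "RNA"), "C": ("C", "RNA"), "G": ("G", "RNA"), "U": ("U", "RNA"),
}
# atom-name partition of a nucleotide into its three moieties
_P_ATOMS = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'"}
_S_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'", "O2'"}


# ---------------------------------------------------------------------------
# Atomic structures
# ---------------------------------------------------------------------------

@dataclass
class AtomicResidue:
    name: str                # PDB residue name (3-letter for amino acids)
    resid: int
    atoms: dict              # atom name -> (3,) coordinates, Å
    bfactors: dict           # atom name -> B-factor, Å²

    def mean_bfactor(self) -> float:
        vals = list(self.bfactors.values())
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class AtomicChain:
    chain_id: str
    residues: list

    @property
    def is_nucleic(self) -> bool:
        return any(r.name.strip() in NA_RESNAMES for r in self.residues)


@dataclass
class AtomicStructure:
    """Minimal atomic-coordinate container parsed from a PDB file (model 1)."""

    chains: list

    @classmethod
    def from_pdb(cls, path) -> "AtomicStructure":
        from Bio.PDB import PDBParser

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure("s", str(path))
        model = next(structure.get_models())
        chains = []
        for chain in model:
            residues = []
            for res in chain:
                if res.id[0].strip():  # skip waters / heteroatoms
                    continue
                atoms, bf = {}, {}
                for atom in res:
                    if atom.element == "H":
                        continue
                    atoms[atom.get_name()] = np.asarray(atom.coord, dtype=float)
                    bf[atom.get_name()] = float(atom.get_bfactor())
                residues.append(AtomicResidue(res.get_resname().strip(), res.id[1], atoms, bf))
            if residues:
                chains.append(AtomicChain(chain.id, residues))
        out = cls(chains)
        out.validate()
        return out

    def validate(self) -> None:
        for chain in self.chains:
            ids = [r.resid for r in chain.residues]
            if any(b <= a for a, b in zip(ids, ids[1:])):
                raise ValueError(f"residue numbering not strictly ordered in chain {chain.chain_id}")
            for res in chain.residues:
                for name, xyz in res.atoms.items():
                    if not np.all(np.isfinite(xyz)):
                        raise ValueError(f"non-finite coordinates at {chain.chain_id}/{res.resid}/{name}")

    def protein_chains(self) -> list:
        return [c for c in self.chains if not c.is_nucleic and any(r.name in THREE_TO_ONE for r in c.residues)]

    def nucleic_chains(self) -> list:
        return [c for c in self.chains if c.is_nucleic]


# ---------------------------------------------------------------------------
# Bead-level models
# ---------------------------------------------------------------------------

@dataclass
class BeadTable:
    """Per-bead data: role code, residue/base letter, residue index, charge, native xyz."""

    roles: np.ndarray       # (n,) int8 role codes
    names: np.ndarray       # (n,) unicode, one-letter residue or base type
    resids: np.ndarray      # (n,) int32 residue/nucleotide index (0-based)
    charges: np.ndarray     # (n,) float
    xyz: np.ndarray         # (n, 3) float native/reference coordinates

    def __len__(self) -> int:
        return len(self.roles)


@dataclass
class CGProteinModel:
    """Two-bead-per-residue Go model of a (set of) protein chain(s)."""

    sequence: str
    beads: BeadTable
    bonds: np.ndarray            # (nb, 2) int
    bond_b0: np.ndarray
    angles: np.ndarray           # (na, 3) int
    angle_t0: np.ndarray
    dihedrals: np.ndarray        # (nd, 4) int
    dihedral_phi0: np.ndarray
    dihedral_kmult: np.ndarray   # stiffness multiplier (flexibility weighting)
    contacts: np.ndarray         # (nc, 2) int, i < j, duplicate-free
    contact_A: np.ndarray
    flexible_residues: np.ndarray  # bool per residue
    angle_kmult: np.ndarray = None

    def __post_init__(self):
        if self.angle_kmult is None:
            self.angle_kmult = np.ones(len(self.angles))

    @property
    def n_residues(self) -> int:
        return int(self.beads.resids.max()) + 1 if len(self.beads) else 0

    def ca_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beads.roles == ROLE_CA)

    def cb_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beads.roles == ROLE_CB)

    def aromatic_cb_indices(self) -> np.ndarray:
        mask = (self.beads.roles == ROLE_CB) & np.isin(self.beads.names, AROMATIC_RESIDUES)
        return np.flatnonzero(mask)

    def positive_cb_indices(self) -> np.ndarray:
        return np.flatnonzero((self.beads.roles == ROLE_CB) & (self.beads.charges > 0))


@dataclass
class CGNucleicModel:
    """Three-bead-per-nucleotide model of a single strand."""

    sequence: str
    kind: str                    # "DNA" or "RNA"
    beads: BeadTable
    bonds: np.ndarray
    bond_b0: np.ndarray
    angles: np.ndarray
    angle_t0: np.ndarray
    dihedrals: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray       # absolute stiffness per dihedral, kcal/mol
    stacks: np.ndarray           # (ns, 2) consecutive base-bead pairs
    stack_eps: np.ndarray

    @property
    def n_nucleotides(self) -> int:
        return len(self.sequence)

    def p_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beads.roles == ROLE_P)

    def base_indices(self) -> np.ndarray:
        return np.flatnonzero(self.beads.roles == ROLE_B)


# ---------------------------------------------------------------------------
# Protein building
# ---------------------------------------------------------------------------

def _reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place a Cβ from backbone N/CA/C using ideal tetrahedral geometry."""
    b1 = ca - n
    b2 = c - ca
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bisector = b1 - b2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    # 1.53 Å bond, tilted out of the N-CA-C plane
    direction = bisector * np.sin(np.deg2rad(54.75)) + perp * np.cos(np.deg2rad(54.75))
    return ca + 1.53 * direction


def build_protein_model(
    structure: AtomicStructure,
    charge_his: bool = False,
    contact_rule: str = "heavy_atom_cutoff",
    contact_cutoff: float = 4.5,
    min_seq_sep: int = 3,
    charged_his_resids: tuple = (),
    cb_policy: str = "reconstruct",
    flexibility_multiplier: float = 0.5,
    flexible_resids: tuple = (),
) -> CGProteinModel:
    """Map an atomic protein structure onto the two-bead Go model.

    Native bond/angle/dihedral references and contact distances A_ij are
    measured from the structure itself.  Residues with a B-factor above
    the chain mean (or listed in ``flexible_resids``) get their local
    angle/dihedral stiffness scaled by ``flexibility_multiplier``.
    """
    if contact_rule not in ("heavy_atom_cutoff",):
        raise ValueError(f"unknown contact rule: {contact_rule}")
    chains = structure.protein_chains()
    if not chains:
        raise ValueError("structure contains no protein chain")

    roles, names, resids, charges, xyz = [], [], [], [], []
    seq = []
    heavy = []            # per residue: (natoms, 3) heavy-atom coordinates
    rep_bead = []         # per residue: representative bead index (CB else CA)
    ca_of, cb_of = [], []
    chain_of_res = []
    bfac = []
    gidx = 0
    res_counter = 0
    for ci, chain in enumerate(chains):
        for res in chain.residues:
            one = THREE_TO_ONE.get(res.name)
            if one is None:
                log.warning("skipping non-standard residue %s", res.name)
                continue
            if "CA" not in res.atoms:
                raise ValueError(f"missing CA atom for residue {res.name}{res.resid} (chain {chain.chain_id})")
            seq.append(one)
            chain_of_res.append(ci)
            bfac.append(res.mean_bfactor())
            heavy.append(np.array(list(res.atoms.values())))

            roles.append(ROLE_CA); names.append(one); resids.append(res_counter)
            charges.append(0.0); xyz.append(res.atoms["CA"])
            ca_of.append(gidx); gidx += 1

            if one == "G":
                cb_of.append(-1)
                rep_bead.append(ca_of[-1])
            else:
                if "CB" in res.atoms:
                    cb_xyz = res.atoms["CB"]
                else:
                    if cb_policy != "reconstruct":
                        raise ValueError(f"missing CB for residue {res.name}{res.resid}")
                    if not {"N", "C"} <= set(res.atoms):
                        raise ValueError(f"cannot reconstruct CB for {res.name}{res.resid}: incomplete backbone")
                    cb_xyz = _reconstruct_cb(res.atoms["N"], res.atoms["CA"], res.atoms["C"])
                    log.info("reconstructed CB for %s%s", res.name, res.resid)
                q = 0.0
                if one in POSITIVE_RESIDUES:
                    q = 1.0
                elif one in NEGATIVE_RESIDUES:
                    q = -1.0
                elif one == "H" and (charge_his or res.resid in charged_his_resids):
                    q = 1.0
                roles.append(ROLE_CB); names.append(one); resids.append(res_counter)
                charges.append(q); xyz.append(cb_xyz)
                cb_of.append(gidx)
                rep_bead.append(gidx)
                gidx += 1
            res_counter += 1

    n_res = res_counter
    beads = BeadTable(
        roles=np.array(roles, dtype=np.int8),
        names=np.array(names),
        resids=np.array(resids, dtype=np.int32),
        charges=np.array(charges, dtype=float),
        xyz=np.array(xyz, dtype=float),
    )

    # flexibility flags: B-factor above the chain mean, or explicit override
    bfac = np.asarray(bfac)
    chain_of_res = np.asarray(chain_of_res)
    flexible = np.zeros(n_res, dtype=bool)
    for ci in np.unique(chain_of_res):
        m = chain_of_res == ci
        if bfac[m].any():
            flexible[m] = bfac[m] > bfac[m].mean()
    for r in flexible_resids:
        flexible[r] = True

    same_chain = lambda a, b: chain_of_res[a] == chain_of_res[b]

    bonds, angles, dihedrals = [], [], []
    for r in range(n_res):
        if cb_of[r] >= 0:
            bonds.append((ca_of[r], cb_of[r]))
        if r + 1 < n_res and same_chain(r, r + 1):
            bonds.append((ca_of[r], ca_of[r + 1]))
            if cb_of[r] >= 0:
                angles.append((cb_of[r], ca_of[r], ca_of[r + 1]))
        if r >= 1 and same_chain(r - 1, r):
            if r + 1 < n_res and same_chain(r, r + 1):
                angles.append((ca_of[r - 1], ca_of[r], ca_of[r + 1]))
            if cb_of[r] >= 0:
                angles.append((ca_of[r - 1], ca_of[r], cb_of[r]))
        if r + 3 < n_res and same_chain(r, r + 3):
            dihedrals.append((ca_of[r], ca_of[r + 1], ca_of[r + 2], ca_of[r + 3]))

    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    # stiffness multipliers from flexibility flags (any participating residue)
    def _mult(idx_array):
        if len(idx_array) == 0:
            return np.ones(0)
        res_of_bead = beads.resids
        flagged = flexible[res_of_bead[idx_array]].any(axis=1)
        return np.where(flagged, flexibility_multiplier, 1.0)

    angle_kmult = _mult(angles)
    dihedral_kmult = _mult(dihedrals)

    # native contacts: heavy-atom pairs within cutoff, sequence separation >= min_seq_sep
    contacts = set()
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if same_chain(i, j) and j - i < min_seq_sep:
                continue
            di = heavy[i][:, None, :] - heavy[j][None, :, :]
            if np.any(np.einsum("ijk,ijk->ij", di, di) < contact_cutoff ** 2):
                contacts.add((rep_bead[i], rep_bead[j]))
    contacts = np.array(sorted(contacts), dtype=np.int64).reshape(-1, 2)
    contact_A = geometry.bond_lengths(beads.xyz, contacts) if len(contacts) else np.zeros(0)

    return CGProteinModel(
        sequence="".join(seq),
        beads=beads,
        bonds=bonds,
        bond_b0=geometry.bond_lengths(beads.xyz, bonds) if len(bonds) else np.zeros(0),
        angles=angles,
        angle_t0=geometry.bend_angles(beads.xyz, angles) if len(angles) else np.zeros(0),
        dihedrals=dihedrals,
        dihedral_phi0=geometry.dihedral_angles(beads.xyz, dihedrals) if len(dihedrals) else np.zeros(0),
        dihedral_kmult=dihedral_kmult,
        contacts=contacts,
        contact_A=np.asarray(contact_A),
        flexible_residues=flexible,
        angle_kmult=angle_kmult,
    )


# ---------------------------------------------------------------------------
# Nucleic-acid building
# ---------------------------------------------------------------------------

def helix_template_coords(n: int, kind: str, params: ForceFieldParams) -> np.ndarray:
    """Bead coordinates of an n-nucleotide strand on the idealized helix.

    Beads are ordered P, S, B per nucleotide, 5'→3', helix axis along z.
    """
    spec = params.templates[kind.upper()]
    twist = np.deg2rad(spec["twist_deg"])
    rise = float(spec["rise"])
    out = np.empty((3 * n, 3))
    for i in range(n):
        for k, role in enumerate(("P", "S", "B")):
            b = spec["beads"][role]
            ang = i * twist + np.deg2rad(b["phase_deg"])
            out[3 * i + k] = (
                b["radius"] * np.cos(ang),
                b["radius"] * np.sin(ang),
                i * rise + b["dz"],
            )
    return out


def na_term_indices(n: int) -> dict:
    """Bonded-term index arrays for an n-nucleotide P/S/B strand."""
    P = lambda i: 3 * i
    S = lambda i: 3 * i + 1
    B = lambda i: 3 * i + 2
    bonds, angles, dih_bs, dih_bb = [], [], [], []
    for i in range(n):
        bonds.append((P(i), S(i)))
        bonds.append((S(i), B(i)))
        angles.append((P(i), S(i), B(i)))
        if i + 1 < n:
            bonds.append((S(i), P(i + 1)))
            angles.append((B(i), S(i), P(i + 1)))
            angles.append((P(i), S(i), P(i + 1)))
            angles.append((S(i), P(i + 1), S(i + 1)))
            dih_bs.append((B(i), S(i), S(i + 1), B(i + 1)))
        if i + 3 < n:
            dih_bb.append((P(i), P(i + 1), P(i + 2), P(i + 3)))
    return {
        "bonds": np.array(bonds, dtype=np.int64).reshape(-1, 2),
        "angles": np.array(angles, dtype=np.int64).reshape(-1, 3),
        "dih_base_sugar": np.array(dih_bs, dtype=np.int64).reshape(-1, 4),
        "dih_backbone": np.array(dih_bb, dtype=np.int64).reshape(-1, 4),
    }


def build_na_model(
    sequence: str,
    kind: str,
    params: ForceFieldParams = None,
    coords: np.ndarray = None,
    reference_from_coords: bool = False,
) -> CGNucleicModel:
    """Build the three-bead strand model for a sequence.

    Reference bonded geometry comes from the helical template; ``coords``
    (e.g. experimental bead positions) only replaces the stored
    conformation.  ``reference_from_coords=True`` instead derives the
    bonded references from the supplied coordinates — used by synthetic
    test systems that need a strain-free designed pose, never for
    modelling real strands.
    """
    params = params or load_params()
    kind = kind.upper()
    if kind not in ("DNA", "RNA"):
        raise ValueError(f"kind must be DNA or RNA, got {kind}")
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    alphabet = DNA_ALPHABET if kind == "DNA" else RNA_ALPHABET
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} for {kind}")

    n = len(sequence)
    template = helix_template_coords(n, kind, params)
    if reference_from_coords:
        if coords is None:
            raise ValueError("reference_from_coords requires coords")
        template = np.asarray(coords, dtype=float)
    idx = na_term_indices(n)

    k_bs, k_bb = params.na_dihedral_constants(kind)
    dihedrals = np.concatenate([idx["dih_base_sugar"], idx["dih_backbone"]])
    dihedral_k = np.concatenate([
        np.full(len(idx["dih_base_sugar"]), k_bs),
        np.full(len(idx["dih_backbone"]), k_bb),
    ])

    stacks = np.array(
        [(3 * i + 2, 3 * (i + 1) + 2) for i in range(n - 1)], dtype=np.int64
    ).reshape(-1, 2)
    stack_eps = np.array(
        [params.eps_base_base(sequence[i], sequence[i + 1]) for i in range(n - 1)]
    )

    roles = np.tile(np.array([ROLE_P, ROLE_S, ROLE_B], dtype=np.int8), n)
    names = np.repeat(list(sequence), 3)
    resids = np.repeat(np.arange(n, dtype=np.int32), 3)
    charges = np.where(roles == ROLE_P, -1.0, 0.0)

    beads = BeadTable(roles=roles, names=np.asarray(names), resids=resids,
                      charges=charges, xyz=template if coords is None else np.asarray(coords, dtype=float))

    return CGNucleicModel(
        sequence=sequence,
        kind=kind,
        beads=beads,
        bonds=idx["bonds"],
        bond_b0=geometry.bond_lengths(template, idx["bonds"]),
        angles=idx["angles"],
        angle_t0=geometry.bend_angles(template, idx["angles"]),
        dihedrals=dihedrals,
        dihedral_phi0=geometry.dihedral_angles(template, dihedrals) if len(dihedrals) else np.zeros(0),
        dihedral_k=dihedral_k,
        stacks=stacks,
        stack_eps=stack_eps,
    )


def set_na_dihedral_constants(model: CGNucleicModel, base_sugar: float, backbone: float) -> CGNucleicModel:
    """Return a copy of the strand model with new dihedral stiffnesses."""
    n = model.n_nucleotides
    n_bs = max(n - 1, 0)
    k = np.concatenate([np.full(n_bs, base_sugar), np.full(len(model.dihedrals) - n_bs, backbone)])
    return replace(model, dihedral_k=k)


# ---------------------------------------------------------------------------
# Complex mapping
# ---------------------------------------------------------------------------

def _nucleotide_beads(res: AtomicResidue) -> np.ndarray:
    """P/S/B bead positions as geometric centers of the moiety atoms."""
    p_atoms = [xyz for name, xyz in res.atoms.items() if name in _P_ATOMS]
    s_atoms = [xyz for name, xyz in res.atoms.items() if name in _S_ATOMS]
    b_atoms = [xyz for name, xyz in res.atoms.items()
               if name not in _P_ATOMS and name not in _S_ATOMS]
    centers = []
    for group, label in ((p_atoms, "phosphate"), (s_atoms, "sugar"), (b_atoms, "base")):
        if group:
            centers.append(np.mean(group, axis=0))
        else:
            log.warning("nucleotide %s%s missing %s atoms; using residue centroid",
                        res.name, res.resid, label)
            centers.append(np.mean(list(res.atoms.values()), axis=0))
    return np.array(centers)


def map_complex(structure: AtomicStructure, params: ForceFieldParams = None,
                **protein_kwargs):
    """Map a protein / single-strand complex to CG models plus reference coordinates.

    Returns ``(protein_model, na_model, reference)`` where ``reference`` is the
    concatenated experimental bead coordinates (protein first) used as the
    native pose by the interface-similarity metrics.
    """
    params = params or load_params()
    na_chains = structure.nucleic_chains()
    if len(na_chains) != 1:
        raise ValueError(
            "expected exactly one nucleic-acid chain, found "
            f"{[c.chain_id for c in na_chains]}"
        )
    if not structure.protein_chains():
        raise ValueError("no protein chain in structure")

    protein = build_protein_model(structure, **protein_kwargs)

    na_chain = na_chains[0]
    seq, kinds, bead_xyz = [], [], []
    for res in na_chain.residues:
        entry = NA_RESNAMES.get(res.name.strip())
        if entry is None:
            raise ValueError(f"unknown nucleotide {res.name}")
        seq.append(entry[0])
        kinds.append(entry[1])
        bead_xyz.append(_nucleotide_beads(res))
    kind = "RNA" if "RNA" in kinds and "T" not in seq else kinds[0]
    na = build_na_model("".join(seq), kind, params, coords=np.vstack(bead_xyz))

    reference = np.vstack([protein.beads.xyz, na.beads.xyz])
    return protein, na, reference
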