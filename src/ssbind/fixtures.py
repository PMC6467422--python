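"""Synthetic inputs: homopolymers, shuffled sequences and a toy receptor.

Everything here is generated programmatically so the full pipeline can
be built and tested without downloading any experimental structure.
The toy receptor is a rigid bead-level plate carrying a designed patch
of aromatic and positively charged side-chain beads over which a strand
is laid in an open, bases-up pose — a desk-scale stand-in for the
OB-fold/KH-domain receptors the model targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .builder import (
    ROLE_CA,
    ROLE_CB,
    BeadTable,
    CGNucleicModel,
    CGProteinModel,
    build_na_model,
)
from . import geometry
from .params import ForceFieldParams, load_params

log = logging.getLogger(__name__)

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "make_homopolymer",
    "shuffle_sequence",
    "make_toy_complex",
    "flexibility_swap",
]


def make_homopolymer(base: str, n: int, kind: str,
                     params: ForceFieldParams = None) -> CGNucleicModel:
    """An n-mer homopolymer strand model in its extended conformation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return build_na_model(base * n, kind, params)


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of a sequence with the base composition fixed.

    Never returns the input itself unless the composition admits only a
    single permutation (e.g. a homopolymer), in which case a note is
    logged.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    letters = list(seq)
    if len(set(letters)) == 1:
        log.info("sequence %s has a single permutation; returning unchanged", seq)
        return seq
    for _ in range(1000):
        perm = list(rng.permutation(letters))
        if "".join(perm) != seq:
            return "".join(perm)
    return "".join(perm)  # pragma: no cover — composition forces identity


def flexibility_swap(model: CGNucleicModel,
                     params: ForceFieldParams = None) -> CGNucleicModel:
    """Swap the strand's dihedral stiffnesses with the other chemistry's.

    A DNA strand receives the RNA constants and vice versa; stacking
    strengths and all other parameters are untouched, so a double swap
    is the identity.
    """
    params = params or load_params()
    own = params.na_dihedral_constants(model.kind)
    other_kind = "RNA" if model.kind == "DNA" else "DNA"
    n_bs_cur = max(model.n_nucleotides - 1, 0)
    currently_swapped = (
        n_bs_cur > 0 and len(model.dihedral_k)
        and not np.isclose(model.dihedral_k[0], own[0])
    )
    k_bs, k_bb = own if currently_swapped else params.na_dihedral_constants(other_kind)
    n_bs = max(model.n_nucleotides - 1, 0)
    k = np.concatenate([
        np.full(n_bs, k_bs),
        np.full(len(model.dihedrals) - n_bs, k_bb),
    ])
    return replace(model, dihedral_k=k)


# ---------------------------------------------------------------------------
# Toy receptor / complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Deterministic recipe for the synthetic bound complex."""

    sequence: str = "TTTTTT"
    kind: str = "DNA"
    aromatic_type: str = "W"
    positive_type: str = "R"
    aromatic_sites: tuple = (0, 2, 4)    # nucleotide indices carrying an aromatic CB
    positive_sites: tuple = (1, 4)       # nucleotide indices carrying a positive CB
    n_scaffold: int = 19                 # neutral residues forming the rigid plate
    scaffold_type: str = "L"
    nt_spacing: float = 6.0              # Å between successive phosphates
    stack_gap: float = 3.6               # aromatic CB height above each base bead
    contact_cutoff: float = 9.0          # bead-pair contact densification cutoff

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {
                "aromatic_sites": list(self.aromatic_sites),
                "positive_sites": list(self.positive_sites)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ToyComplexSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["aromatic_sites"] = tuple(d["aromatic_sites"])
        d["positive_sites"] = tuple(d["positive_sites"])
        return cls(**d)


@dataclass
class ToyComplex:
    protein: CGProteinModel
    na: CGNucleicModel
    reference: np.ndarray        # stacked native bead coordinates (protein first)
    spec: ToyComplexSpec
    aromatic_beads: np.ndarray   # protein bead indices of the patch aromatics
    positive_beads: np.ndarray


def _strand_open_pose(n: int, spacing: float) -> np.ndarray:
    """Bases-up open strand pose: P on a line, sugars above, bases on top."""
    pose = np.empty((3 * n, 3))
    for i in range(n):
        x = spacing * i
        pose[3 * i + 0] = (x, 0.0, 0.0)            # P
        pose[3 * i + 1] = (x + 2.0, 0.0, 2.8)      # S
        pose[3 * i + 2] = (x + 2.0, 0.0, 7.3)      # B
    return pose


def _toy_protein(spec: ToyComplexSpec, strand_pose: np.ndarray) -> CGProteinModel:
    n_nt = len(spec.sequence)
    for s in spec.aromatic_sites + spec.positive_sites:
        if not 0 <= s < n_nt:
            raise ValueError(f"patch site {s} outside strand of length {n_nt}")

    # patch residues: CB near its strand partner, CA stacked 3.8 Å above
    entries = []  # (sort_x, res_type, ca_xyz, cb_xyz)
    for i in spec.aromatic_sites:
        b = strand_pose[3 * i + 2]
        cb = b + (0.0, 0.0, spec.stack_gap)
        entries.append((cb[0], spec.aromatic_type, cb + (0.0, 0.0, 3.8), cb))
    for i in spec.positive_sites:
        p = strand_pose[3 * i]
        cb = p + (0.0, 4.5, 6.0)
        entries.append((cb[0], spec.positive_type, cb + (0.0, 0.0, 3.8), cb))
    entries.sort(key=lambda e: e[0])

    # scaffold: serpentine rows above/behind the patch, far from the strand
    z_plate = 14.0
    xs = np.linspace(-3.0, (n_nt - 1) * spec.nt_spacing + 5.0,
                     max(spec.n_scaffold // 2 + 1, 2))
    scaffold = []
    i = 0
    for row, y in enumerate((6.0, 11.0)):
        order = xs if row % 2 else xs[::-1]
        for x in order:
            if i >= spec.n_scaffold:
                break
            ca = np.array([x, y, z_plate])
            scaffold.append((spec.scaffold_type, ca, ca + (0.0, 1.0, 3.7)))
            i += 1

    roles, names, resids, charges, xyz = [], [], [], [], []
    res = 0

    def _add(rtype, ca, cb):
        nonlocal res
        roles.append(ROLE_CA); names.append(rtype); resids.append(res)
        charges.append(0.0); xyz.append(ca)
        q = 1.0 if rtype in ("K", "R") else (-1.0 if rtype in ("D", "E") else 0.0)
        roles.append(ROLE_CB); names.append(rtype); resids.append(res)
        charges.append(q); xyz.append(cb)
        res += 1

    for _, rtype, ca, cb in entries:
        _add(rtype, np.asarray(ca), np.asarray(cb))
    for rtype, ca, cb in scaffold:
        _add(rtype, ca, cb)

    beads = BeadTable(
        roles=np.array(roles, dtype=np.int8),
        names=np.array(names),
        resids=np.array(resids, dtype=np.int32),
        charges=np.array(charges, dtype=float),
        xyz=np.array(xyz, dtype=float),
    )
    n_res = res
    ca_of = [2 * r for r in range(n_res)]
    cb_of = [2 * r + 1 for r in range(n_res)]

    bonds, angles, dihedrals = [], [], []
    for r in range(n_res):
        bonds.append((ca_of[r], cb_of[r]))
        if r + 1 < n_res:
            bonds.append((ca_of[r], ca_of[r + 1]))
            angles.append((cb_of[r], ca_of[r], ca_of[r + 1]))
        if 1 <= r < n_res - 1:
            angles.append((ca_of[r - 1], ca_of[r], ca_of[r + 1]))
            angles.append((ca_of[r - 1], ca_of[r], cb_of[r]))
        if r + 3 < n_res:
            dihedrals.append((ca_of[r], ca_of[r + 1], ca_of[r + 2], ca_of[r + 3]))
    bonds = np.array(bonds, dtype=np.int64)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    # densified contact map: every CA-CA and CB-CB pair within the cutoff,
    # sequence separation >= 3 — holds the plate rigid
    contacts = []
    coords = beads.xyz
    for idx_list in (ca_of, cb_of):
        for a in range(n_res):
            for b in range(a + 3, n_res):
                i, j = idx_list[a], idx_list[b]
                if np.linalg.norm(coords[i] - coords[j]) <= spec.contact_cutoff:
                    contacts.append((i, j))
    contacts = np.array(sorted(set(contacts)), dtype=np.int64).reshape(-1, 2)

    return CGProteinModel(
        sequence="".join(names[::2]),
        beads=beads,
        bonds=bonds,
        bond_b0=geometry.bond_lengths(coords, bonds),
        angles=angles,
        angle_t0=geometry.bend_angles(coords, angles),
        dihedrals=dihedrals,
        dihedral_phi0=geometry.dihedral_angles(coords, dihedrals)
        if len(dihedrals) else np.zeros(0),
        dihedral_kmult=np.ones(len(dihedrals)),
        contacts=contacts,
        contact_A=geometry.bond_lengths(coords, contacts),
        flexible_residues=np.zeros(n_res, dtype=bool),
        angle_kmult=np.ones(len(angles)),
    )


def make_toy_complex(spec: ToyComplexSpec = None,
                     params: ForceFieldParams = None,
                     rng: np.random.Generator = None) -> ToyComplex:
    """Build the synthetic bound receptor–strand reference system.

    The strand lies in an open bases-up pose with each patch aromatic CB
    at the stacking distance above a base and positive CBs within the
    interface cutoff of phosphates, so the constructed pose is a valid
    "experimental" reference for the similarity metrics, kinetics and
    specificity machinery.  The strand's bonded reference geometry is
    taken from the pose itself (synthetic system — see builder docs).
    """
    spec = spec or ToyComplexSpec()
    params = params or load_params()
    pose = _strand_open_pose(len(spec.sequence), spec.nt_spacing)
    protein = _toy_protein(spec, pose)
    na = build_na_model(spec.sequence, spec.kind, params, coords=pose,
                        reference_from_coords=True)
    reference = np.vstack([protein.beads.xyz, na.beads.xyz])
    names = protein.beads.names
    roles = protein.beads.roles
    aromatic = np.flatnonzero((roles == ROLE_CB) & (names == spec.aromatic_type))
    positive = np.flatnonzero((roles == ROLE_CB) & (protein.beads.charges > 0))
    return ToyComplex(protein=protein, na=na, reference=reference, spec=spec,
                      aromatic_beads=aromatic, positive_beads=positive)
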