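"""Shared fixtures: parameters, synthetic PDB files, the toy complex."""

from __future__ import annotations

import numpy as np
import pytest

from ssbind import build_na_model, build_system, load_params
from ssbind.fixtures import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex()


@pytest.fixture(scope="session")
def toy_system(toy, params):
    return build_system(toy.protein, toy.na, params)


@pytest.fixture(scope="session")
def t6_system(params):
    na = build_na_model("TTTTTT", "DNA", params)
    return build_system(na=na, params=params)


# ---------------------------------------------------------------------------
# Synthetic PDB files
# ---------------------------------------------------------------------------

def _pdb_atom(serial, name, resname, chain, resid, xyz, element, bfactor=10.0):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00{bfactor:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(path, residues):
    """residues: list of (resname, chain, resid, {atom: xyz}, bfactor)."""
    serial = 1
    with open(path, "w") as fh:
        last_chain = None
        for resname, chain, resid, atoms, bfactor in residues:
            if last_chain is not None and chain != last_chain:
                fh.write("TER\n")
            last_chain = chain
            for name, xyz in atoms.items():
                element = name[0] if name[0].isalpha() else name[1]
                fh.write(_pdb_atom(serial, name, resname, chain, resid, xyz,
                                   element, bfactor))
                serial += 1
        fh.write("TER\nEND\n")


def synthetic_peptide(sequence, bfactors=None, start=(0.0, 0.0, 0.0)):
    """Residue records for an idealized α-helical peptide with N/CA/C/O/CB atoms."""
    from ssbind.builder import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    residues = []
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    for i, one in enumerate(sequence):
        ang = i * twist
        ca = np.array(start) + (radius * np.cos(ang), radius * np.sin(ang), rise * i)
        outward = np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms = {
            "N": ca + (-0.8, 0.6, -0.9),
            "CA": ca,
            "C": ca + (0.9, -0.4, 0.8),
            "O": ca + (1.4, -1.2, 1.1),
        }
        if one != "G":
            atoms["CB"] = ca + 1.53 * outward
        bf = 10.0 if bfactors is None else bfactors[i]
        residues.append((one_to_three[one], "A", i + 1, atoms, bf))
    return residues


@pytest.fixture()
def helix_pdb(tmp_path):
    """Ideal-geometry 10-residue helix used for contact-map oracle checks."""
    path = tmp_path / "helix.pdb"
    write_pdb(path, synthetic_peptide("AKWDELYRGT"))
    return path


def nucleotide_records(seq, kind="DNA", start_resid=1, chain="B"):
    """Minimal nucleotide records with one atom per moiety plus extras."""
    recs = []
    resnames = {"DNA": {b: "D" + b for b in "ACGT"}, "RNA": {b: b for b in "ACGU"}}
    for i, b in enumerate(seq):
        x = 7.0 * i
        atoms = {
            "P": np.array([x, 0.0, 0.0]),
            "OP1": np.array([x + 0.5, 0.8, 0.0]),
            "C4'": np.array([x + 2.0, 2.0, 1.0]),
            "O4'": np.array([x + 2.6, 2.8, 1.2]),
            "N1": np.array([x + 2.0, 5.0, 2.0]),
            "C2": np.array([x + 2.8, 5.6, 2.4]),
        }
        recs.append((resnames[kind][b], chain, start_resid + i, atoms, 12.0))
    return recs
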