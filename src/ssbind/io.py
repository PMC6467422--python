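"""File formats: CG topology tables, trajectory stores, configs, manifests.

Topologies are written as a documented plain-text table (one bead per
line plus term sections); trajectory stores are NumPy ``.npz`` containers
holding frames and the per-frame energy table.  Every simulation run
emits a JSON manifest with the config snapshot, input hashes and the
per-replica seeds, sufficient to reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .builder import ROLE_CODES, ROLE_NAMES, BeadTable, CGNucleicModel, CGProteinModel
from .simulate import SimulationConfig, Trajectory

__all__ = [
    "write_topology",
    "read_topology",
    "write_fasta",
    "read_sequence",
    "save_trajectories",
    "load_trajectories",
    "load_config",
    "write_manifest",
    "topology_hash",
    "export_frames_pdb",
]

_TOPOLOGY_HEADER = (
    "# ssbind coarse-grained topology\n"
    "# sections: [meta] key=value; [beads] index role resname resid charge x y z;\n"
    "# [bonds] i j b0; [angles] i j k theta0; [dihedrals] i j k l phi0 k;\n"
    "# [contacts|stacks] i j A_or_eps\n"
)


def _fmt_block(name, rows):
    out = [f"[{name}]"]
    out += [" ".join(str(x) for x in row) for row in rows]
    return out


def write_topology(model, path) -> None:
    """Serialize a protein or strand model to the tabular text format."""
    is_na = isinstance(model, CGNucleicModel)
    lines = [_TOPOLOGY_HEADER, "[meta]"]
    lines.append(f"moltype={'nucleic' if is_na else 'protein'}")
    lines.append(f"sequence={model.sequence}")
    if is_na:
        lines.append(f"kind={model.kind}")
    b = model.beads
    rows = [
        (i, ROLE_NAMES[int(b.roles[i])], b.names[i], int(b.resids[i]),
         f"{b.charges[i]:+.0f}", f"{b.xyz[i,0]:.6f}", f"{b.xyz[i,1]:.6f}", f"{b.xyz[i,2]:.6f}")
        for i in range(len(b))
    ]
    lines += _fmt_block("beads", rows)
    lines += _fmt_block("bonds", [(i, j, f"{v:.10f}") for (i, j), v in zip(model.bonds, model.bond_b0)])
    lines += _fmt_block("angles", [(i, j, k, f"{v:.10f}") for (i, j, k), v in zip(model.angles, model.angle_t0)])
    dk = model.dihedral_k if is_na else model.dihedral_kmult
    lines += _fmt_block("dihedrals", [
        (i, j, k, l, f"{v:.10f}", f"{kk:.10f}")
        for (i, j, k, l), v, kk in zip(model.dihedrals, model.dihedral_phi0, dk)
    ])
    if is_na:
        lines += _fmt_block("stacks", [(i, j, f"{v:.10f}") for (i, j), v in zip(model.stacks, model.stack_eps)])
    else:
        lines += _fmt_block("contacts", [(i, j, f"{v:.10f}") for (i, j), v in zip(model.contacts, model.contact_A)])
        lines += _fmt_block("flexible", [(int(i),) for i in np.flatnonzero(model.flexible_residues)])
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path):
    """Read a model written by :func:`write_topology` (bit-faithful round trip)."""
    sections: dict = {}
    meta: dict = {}
    current = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            current = line.strip("[]")
            sections[current] = []
            continue
        if current == "meta":
            k, v = line.split("=", 1)
            meta[k] = v
        else:
            sections[current].append(line.split())

    beads_rows = sections["beads"]
    n = len(beads_rows)
    b = BeadTable(
        roles=np.array([ROLE_CODES[r[1]] for r in beads_rows], dtype=np.int8),
        names=np.array([r[2] for r in beads_rows]),
        resids=np.array([int(r[3]) for r in beads_rows], dtype=np.int32),
        charges=np.array([float(r[4]) for r in beads_rows]),
        xyz=np.array([[float(r[5]), float(r[6]), float(r[7])] for r in beads_rows]),
    )

    def _arr(name, ncols, dtype=float):
        rows = sections.get(name, [])
        idx = np.array([[int(x) for x in r[:ncols]] for r in rows], dtype=np.int64).reshape(-1, ncols)
        vals = [np.array([dtype(r[ncols + c]) for r in rows]) for c in range(len(rows[0]) - ncols)] if rows else []
        return idx, vals

    bonds, (bond_b0,) = _arr("bonds", 2)
    angles, (angle_t0,) = _arr("angles", 3)
    dih, dvals = _arr("dihedrals", 4)
    phi0, dk = (dvals if dvals else (np.zeros(0), np.zeros(0)))

    if meta["moltype"] == "nucleic":
        stacks, (eps,) = _arr("stacks", 2)
        return CGNucleicModel(
            sequence=meta["sequence"], kind=meta["kind"], beads=b,
            bonds=bonds, bond_b0=bond_b0, angles=angles, angle_t0=angle_t0,
            dihedrals=dih, dihedral_phi0=phi0, dihedral_k=dk,
            stacks=stacks, stack_eps=eps,
        )
    contacts, cvals = _arr("contacts", 2)
    contact_A = cvals[0] if cvals else np.zeros(0)
    flexible = np.zeros(int(b.resids.max()) + 1, dtype=bool)
    for row in sections.get("flexible", []):
        flexible[int(row[0])] = True
    return CGProteinModel(
        sequence=meta["sequence"], beads=b,
        bonds=bonds, bond_b0=bond_b0, angles=angles, angle_t0=angle_t0,
        dihedrals=dih, dihedral_phi0=phi0, dihedral_kmult=dk,
        contacts=contacts, contact_A=contact_A, flexible_residues=flexible,
    )


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def read_sequence(source: str) -> str:
    """A sequence from a literal string or a FASTA file path."""
    p = Path(source)
    if p.exists():
        seq = []
        for line in p.read_text().splitlines():
            if line.startswith(">") or not line.strip():
                continue
            seq.append(line.strip())
        return "".join(seq).upper()
    return source.upper()


# ---------------------------------------------------------------------------
# Trajectory store
# ---------------------------------------------------------------------------

def save_trajectories(trajectories, path) -> None:
    """Write a list of trajectories to one ``.npz`` container."""
    payload = {}
    meta = []
    for n, t in enumerate(trajectories):
        payload[f"frames_{n}"] = np.asarray(t.frames, dtype=np.float32)
        payload[f"energies_{n}"] = np.asarray(t.energies)
        meta.append({
            "seed": int(t.seed), "placement": int(t.placement),
            "start_state": t.start_state, "stable": bool(t.stable),
            "config": dataclasses.asdict(t.config) | {
                "placement_distance": list(t.config.placement_distance)},
        })
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_trajectories(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        out = []
        for n, m in enumerate(meta):
            cfg = m["config"]
            cfg["placement_distance"] = tuple(cfg["placement_distance"])
            out.append(Trajectory(
                frames=data[f"frames_{n}"].astype(float),
                energies=data[f"energies_{n}"],
                config=SimulationConfig(**cfg),
                seed=m["seed"], placement=m["placement"],
                start_state=m["start_state"], stable=m["stable"],
            ))
    return out


def export_frames_pdb(frames, system, path, stride: int = 1) -> None:
    """Multi-model PDB export of trajectory frames for visualization."""
    role_atom = {0: "CA", 1: "CB", 2: "P", 3: "S", 4: "B"}
    with open(path, "w") as fh:
        for m, frame in enumerate(np.asarray(frames)[::stride], start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, xyz in enumerate(frame):
                role = role_atom[int(system.roles[i])]
                chain = "A" if i < system.n_protein_beads else "B"
                fh.write(
                    f"ATOM  {i+1:5d} {role:<4s} BEA {chain}{i%9999+1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
                )
            fh.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# Config and manifest
# ---------------------------------------------------------------------------

def load_config(path) -> SimulationConfig:
    """Simulation config from a YAML file; missing keys take protocol defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "placement_distance" in data:
        data["placement_distance"] = tuple(data["placement_distance"])
    return SimulationConfig(**data)


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def topology_hash(model) -> str:
    h = hashlib.sha256()
    b = model.beads
    for arr in (b.roles, b.resids, np.round(b.xyz, 6)):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update("".join(b.names).encode())
    return h.hexdigest()


def write_manifest(path, config: SimulationConfig, inputs: dict, seeds,
                   outputs: dict) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config) | {
            "placement_distance": list(config.placement_distance)},
        "input_hashes": inputs,
        "replica_seeds": [int(s) for s in seeds],
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
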