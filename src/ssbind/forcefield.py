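"""Energy terms and analytic forces of the coarse-grained model.

The total potential is E_prot + E_strand + E_interface with

* harmonic bonds  K_b (b − b⁰)²  and angles  K_a (θ − θ⁰)²,
* dihedrals  K_d [1 − cos(Δφ) − cos(3Δφ)]  (a conventional
  (1 − cosΔφ) + ½(1 − cos3Δφ) form is available as a switch),
* 12-10 native-contact wells  K [5(A/r)¹² − 6(A/r)¹⁰]  (depth −K at r = A),
* base–base and base–aromatic stacking wells of the same 12-10 shape with
  depth −ε at r⁰ = 3.6 Å,
* Debye–Hückel electrostatics  pref · q_i q_j e^{−κr}/r  between charged
  beads (never between two phosphates of the same strand),
* and (C_ij/r)¹² excluded-volume repulsion for all remaining pairs.

Pair lists are enumerated once at system-build time; a single numba
kernel evaluates energies and exact analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .builder import ROLE_B, ROLE_CB, ROLE_P, CGNucleicModel, CGProteinModel
from .params import ForceFieldParams, load_params

__all__ = [
    "EnergyBreakdown",
    "System",
    "build_system",
    "total_energy_and_forces",
    "bonded_energy",
    "interface_energy",
    "stacking_energy",
    "lj_12_10",
    "debye_huckel",
]

# pair kinds
PAIR_CONTACT, PAIR_STACK_BB, PAIR_STACK_BAA, PAIR_DH, PAIR_REP = 0, 1, 2, 3, 4
# energy component slots
(C_BOND, C_ANGLE, C_DIHEDRAL, C_CONTACT, C_ELEC, C_REP, C_STACK_BB, C_STACK_BAA) = range(8)
# zones
ZONE_PROTEIN, ZONE_NA, ZONE_INTERFACE = 0, 1, 2

PAIR_COMPONENT = np.array([C_CONTACT, C_STACK_BB, C_STACK_BAA, C_ELEC, C_REP], dtype=np.int8)


@dataclass
class EnergyBreakdown:
    """Per-term potential energy, kcal/mol."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    native_contact: float = 0.0
    electrostatic: float = 0.0
    repulsion: float = 0.0
    base_stacking: float = 0.0
    aromatic_stacking: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.native_contact
                + self.electrostatic + self.repulsion + self.base_stacking
                + self.aromatic_stacking)

    @classmethod
    def from_array(cls, comps: np.ndarray) -> "EnergyBreakdown":
        return cls(
            bond=float(comps[C_BOND]), angle=float(comps[C_ANGLE]),
            dihedral=float(comps[C_DIHEDRAL]), native_contact=float(comps[C_CONTACT]),
            electrostatic=float(comps[C_ELEC]), repulsion=float(comps[C_REP]),
            base_stacking=float(comps[C_STACK_BB]), aromatic_stacking=float(comps[C_STACK_BAA]),
        )

    def as_array(self) -> np.ndarray:
        return np.array([
            self.bond, self.angle, self.dihedral, self.native_contact,
            self.electrostatic, self.repulsion, self.base_stacking,
            self.aromatic_stacking,
        ])


@dataclass
class System:
    """Flattened term arrays for one protein, one strand, or a bound pair."""

    n_beads: int
    n_protein_beads: int            # 0 for a free strand
    roles: np.ndarray
    charges: np.ndarray
    coords0: np.ndarray             # native/initial reference coordinates
    bonds: np.ndarray
    bond_b0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray
    angle_t0: np.ndarray
    angle_k: np.ndarray
    dihedrals: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray
    pairs: np.ndarray               # (m, 2) int64
    pair_kind: np.ndarray           # (m,) int8
    pair_a: np.ndarray              # A | r0 | q_i q_j | C_ij
    pair_k: np.ndarray              # K | eps | 1 | K_rep
    pair_zone: np.ndarray           # (m,) int8
    dh_prefactor: float
    dh_kappa: float
    dh_cutoff: float
    lj_cutoff_factor: float
    rep_cutoff_factor: float
    dihedral_form: int = 0          # 0 printed, 1 conventional
    energy_unit: float = 1.0        # kcal/mol per reduced energy (thermostat scale)
    protein: CGProteinModel = None
    na: CGNucleicModel = None

    @property
    def na_slice(self) -> slice:
        return slice(self.n_protein_beads, self.n_beads)

    def kernel_args(self, coords: np.ndarray):
        return (
            coords, self.bonds, self.bond_b0, self.bond_k,
            self.angles, self.angle_t0, self.angle_k,
            self.dihedrals, self.dihedral_phi0, self.dihedral_k, self.dihedral_form,
            self.pairs, self.pair_kind, self.pair_a, self.pair_k, self.pair_zone,
            self.dh_prefactor, self.dh_kappa, self.dh_cutoff,
            self.lj_cutoff_factor, self.rep_cutoff_factor,
        )


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

def _protein_terms(protein: CGProteinModel, params: ForceFieldParams):
    nb = len(protein.bonds)
    na_ = len(protein.angles)
    nd = len(protein.dihedrals)
    return dict(
        bonds=protein.bonds, bond_b0=protein.bond_b0,
        bond_k=np.full(nb, params.k_bonds),
        angles=protein.angles, angle_t0=protein.angle_t0,
        angle_k=params.k_angles * protein.angle_kmult if na_ else np.zeros(0),
        dihedrals=protein.dihedrals, dihedral_phi0=protein.dihedral_phi0,
        dihedral_k=params.k_dihedrals_protein * protein.dihedral_kmult if nd else np.zeros(0),
    )


def _na_terms(na: CGNucleicModel, params: ForceFieldParams):
    return dict(
        bonds=na.bonds, bond_b0=na.bond_b0,
        bond_k=np.full(len(na.bonds), params.k_bonds),
        angles=na.angles, angle_t0=na.angle_t0,
        angle_k=np.full(len(na.angles), params.k_angles),
        dihedrals=na.dihedrals, dihedral_phi0=na.dihedral_phi0,
        dihedral_k=na.dihedral_k,
    )


def build_system(
    protein: CGProteinModel = None,
    na: CGNucleicModel = None,
    params: ForceFieldParams = None,
    dihedral_form: str = None,
) -> System:
    """Enumerate every interaction of a protein, a strand, or their complex.

    Exclusion rules for the excluded-volume term: bonded pairs, native
    contacts, beads of the same or adjacent nucleotides, and declared
    stacking (base–base or base–aromatic) pairs.  Debye–Hückel pairs are
    never created between two phosphate beads.
    """
    if protein is None and na is None:
        raise ValueError("need at least one molecule")
    params = params or load_params()

    blocks = []
    offset = 0
    n_prot_beads = 0
    tables = []
    if protein is not None:
        blocks.append((_protein_terms(protein, params), 0))
        n_prot_beads = len(protein.beads)
        tables.append(protein.beads)
        offset = n_prot_beads
    if na is not None:
        blocks.append((_na_terms(na, params), offset))
        tables.append(na.beads)

    roles = np.concatenate([t.roles for t in tables])
    charges = np.concatenate([t.charges for t in tables])
    coords0 = np.vstack([t.xyz for t in tables])
    resids = np.concatenate([t.resids for t in tables])
    names = np.concatenate([t.names for t in tables])
    n_beads = len(roles)

    bonds, bond_b0, bond_k = [], [], []
    angles, angle_t0, angle_k = [], [], []
    dihedrals, dihedral_phi0, dihedral_k = [], [], []
    for blk, off in blocks:
        bonds.append(blk["bonds"] + off); bond_b0.append(blk["bond_b0"]); bond_k.append(blk["bond_k"])
        angles.append(blk["angles"] + off); angle_t0.append(blk["angle_t0"]); angle_k.append(blk["angle_k"])
        dihedrals.append(blk["dihedrals"] + off); dihedral_phi0.append(blk["dihedral_phi0"]); dihedral_k.append(blk["dihedral_k"])
    bonds = np.vstack(bonds) if bonds else np.zeros((0, 2), dtype=np.int64)
    angles = np.vstack(angles) if angles else np.zeros((0, 3), dtype=np.int64)
    dihedrals = np.vstack(dihedrals) if dihedrals else np.zeros((0, 4), dtype=np.int64)

    radius = np.array([params.radii[{0: "CA", 1: "CB", 2: "P", 3: "S", 4: "B"}[r]]
                       for r in roles])

    pair_rows = []  # (i, j, kind, a, k, zone)
    bonded_set = {(min(i, j), max(i, j)) for i, j in bonds}

    # --- intra-protein non-bonded -------------------------------------
    if protein is not None:
        contact_set = set()
        for (i, j), a in zip(protein.contacts, protein.contact_A):
            contact_set.add((min(i, j), max(i, j)))
            pair_rows.append((i, j, PAIR_CONTACT, a, params.k_contacts, ZONE_PROTEIN))
        charged = np.flatnonzero(charges[:n_prot_beads] != 0)
        for ii, i in enumerate(charged):
            for j in charged[ii + 1:]:
                if (min(i, j), max(i, j)) not in bonded_set:
                    pair_rows.append((i, j, PAIR_DH, charges[i] * charges[j], 1.0, ZONE_PROTEIN))
        for i in range(n_prot_beads):
            for j in range(i + 1, n_prot_beads):
                key = (i, j)
                if key in bonded_set or key in contact_set:
                    continue
                pair_rows.append((i, j, PAIR_REP, radius[i] + radius[j],
                                  params.k_repulsion, ZONE_PROTEIN))

    # --- intra-strand non-bonded --------------------------------------
    if na is not None:
        for (i, j), eps in zip(na.stacks + offset, na.stack_eps):
            pair_rows.append((i, j, PAIR_STACK_BB, params.stack_r0, eps, ZONE_NA))
        nt = resids[offset:]
        for a in range(n_beads - offset):
            for b in range(a + 1, n_beads - offset):
                if abs(int(nt[a]) - int(nt[b])) < 2:
                    continue
                i, j = a + offset, b + offset
                pair_rows.append((i, j, PAIR_REP, radius[i] + radius[j],
                                  params.k_repulsion, ZONE_NA))

    # --- interface ----------------------------------------------------
    if protein is not None and na is not None:
        aromatic = set(protein.aromatic_cb_indices())
        for i in range(n_prot_beads):
            is_arom = i in aromatic
            qi = charges[i]
            for j in range(offset, n_beads):
                role_j = roles[j]
                if is_arom and role_j == ROLE_B:
                    eps = params.eps_base_aromatic(str(names[i]), str(names[j]))
                    pair_rows.append((i, j, PAIR_STACK_BAA, params.stack_r0, eps, ZONE_INTERFACE))
                    continue  # stacking pairs are excluded from repulsion
                pair_rows.append((i, j, PAIR_REP, radius[i] + radius[j],
                                  params.k_repulsion, ZONE_INTERFACE))
                if qi != 0.0 and role_j == ROLE_P:
                    pair_rows.append((i, j, PAIR_DH, qi * charges[j], 1.0, ZONE_INTERFACE))

    if pair_rows:
        arr = np.array(pair_rows, dtype=float)
        pairs = arr[:, :2].astype(np.int64)
        pair_kind = arr[:, 2].astype(np.int8)
        pair_a = arr[:, 3]
        pair_k = arr[:, 4]
        pair_zone = arr[:, 5].astype(np.int8)
    else:
        pairs = np.zeros((0, 2), dtype=np.int64)
        pair_kind = np.zeros(0, dtype=np.int8)
        pair_a = np.zeros(0)
        pair_k = np.zeros(0)
        pair_zone = np.zeros(0, dtype=np.int8)

    lam_d = params.debye_length
    form = dihedral_form or getattr(params, "dihedral_form", "printed")
    return System(
        n_beads=n_beads,
        n_protein_beads=n_prot_beads,
        roles=roles,
        charges=charges,
        coords0=coords0,
        bonds=bonds, bond_b0=np.concatenate(bond_b0) if len(bond_b0) else np.zeros(0),
        bond_k=np.concatenate(bond_k) if len(bond_k) else np.zeros(0),
        angles=angles, angle_t0=np.concatenate(angle_t0) if len(angle_t0) else np.zeros(0),
        angle_k=np.concatenate(angle_k) if len(angle_k) else np.zeros(0),
        dihedrals=dihedrals,
        dihedral_phi0=np.concatenate(dihedral_phi0) if len(dihedral_phi0) else np.zeros(0),
        dihedral_k=np.concatenate(dihedral_k) if len(dihedral_k) else np.zeros(0),
        pairs=pairs, pair_kind=pair_kind, pair_a=pair_a, pair_k=pair_k,
        pair_zone=pair_zone,
        dh_prefactor=params.dh_prefactor,
        dh_kappa=1.0 / lam_d,
        dh_cutoff=params.dh_cutoff_debye_lengths * lam_d,
        lj_cutoff_factor=params.lj_cutoff_factor,
        rep_cutoff_factor=params.rep_cutoff_factor,
        dihedral_form={"printed": 0, "conventional": 1}[form],
        energy_unit=params.energy_unit,
        protein=protein,
        na=na,
    )


def interaction_list(system: System):
    """Typed pairwise interaction records (kind, i, j, parameters)."""
    kinds = {PAIR_CONTACT: "contact", PAIR_STACK_BB: "base_stack",
             PAIR_STACK_BAA: "aromatic_stack", PAIR_DH: "DH", PAIR_REP: "repulsion"}
    out = []
    for (i, j), k, a, kk in zip(system.pairs, system.pair_kind, system.pair_a, system.pair_k):
        out.append({"kind": kinds[int(k)], "i": int(i), "j": int(j),
                    "a": float(a), "k": float(kk)})
    return out


# ---------------------------------------------------------------------------
# Elementary potentials (python-level, used directly and as documentation)
# ---------------------------------------------------------------------------

def lj_12_10(r, A, K=1.0):
    """12-10 well K[5(A/r)¹² − 6(A/r)¹⁰]; minimum −K at r = A."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    u = A / r
    return K * (5.0 * u ** 12 - 6.0 * u ** 10)


def debye_huckel(qi, qj, r, salt_mM=None, eps_r=None, params: ForceFieldParams = None):
    """Screened Coulomb energy pref·B(κ)·q_i q_j e^{−κr}/(ε_r r), kcal/mol."""
    params = params or load_params()
    if salt_mM is not None:
        params = params.with_salt(salt_mM)
    if eps_r is not None:
        from dataclasses import replace
        if eps_r <= 0:
            raise ValueError("dielectric must be positive")
        params = replace(params, dielectric=float(eps_r))
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    return params.dh_prefactor * qi * qj * np.exp(-r / params.debye_length) / r


def stacking_energy(coords, pairs, eps, r0=3.6):
    """Sum of 12-10 stacking wells (depth −ε at r⁰) over the given bead pairs."""
    eps = np.atleast_1d(np.asarray(eps, dtype=float))
    if np.any(eps < 0):
        raise ValueError("stacking well depths must be >= 0")
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(np.sum(lj_12_10(d, r0, eps)))


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _eval_kernel(coords, bonds, bond_b0, bond_k, angles, angle_t0, angle_k,
                 dihedrals, dihedral_phi0, dihedral_k, dihedral_form,
                 pairs, pair_kind, pair_a, pair_k, pair_zone,
                 dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut,
                 zone_filter, forces, comps):
    """Fill ``forces`` (negative gradient) and per-component energies ``comps``.

    ``zone_filter`` < 0 evaluates everything; otherwise only pair terms of
    that zone (bonded terms are skipped, used for interface-only energies).
    """
    forces[:] = 0.0
    comps[:] = 0.0
    do_bonded = zone_filter < 0

    if do_bonded:
        for n in range(bonds.shape[0]):
            i, j = bonds[n, 0], bonds[n, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            db = r - bond_b0[n]
            comps[0] += bond_k[n] * db * db
            fmag = -2.0 * bond_k[n] * db / r
            forces[i, 0] += fmag * dx; forces[i, 1] += fmag * dy; forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx; forces[j, 1] -= fmag * dy; forces[j, 2] -= fmag * dz

        for n in range(angles.shape[0]):
            i, j, k = angles[n, 0], angles[n, 1], angles[n, 2]
            ax = coords[i, 0] - coords[j, 0]; ay = coords[i, 1] - coords[j, 1]; az = coords[i, 2] - coords[j, 2]
            bx = coords[k, 0] - coords[j, 0]; by = coords[k, 1] - coords[j, 1]; bz = coords[k, 2] - coords[j, 2]
            ra = np.sqrt(ax * ax + ay * ay + az * az)
            rb = np.sqrt(bx * bx + by * by + bz * bz)
            cosang = (ax * bx + ay * by + az * bz) / (ra * rb)
            if cosang > 1.0:
                cosang = 1.0
            elif cosang < -1.0:
                cosang = -1.0
            theta = np.arccos(cosang)
            dt = theta - angle_t0[n]
            comps[1] += angle_k[n] * dt * dt
            sin_t = np.sqrt(1.0 - cosang * cosang)
            if sin_t < 1e-8:
                sin_t = 1e-8
            coef = 2.0 * angle_k[n] * dt / sin_t
            # dtheta/dxi and dtheta/dxk
            fix = coef * (bx / (ra * rb) - cosang * ax / (ra * ra))
            fiy = coef * (by / (ra * rb) - cosang * ay / (ra * ra))
            fiz = coef * (bz / (ra * rb) - cosang * az / (ra * ra))
            fkx = coef * (ax / (ra * rb) - cosang * bx / (rb * rb))
            fky = coef * (ay / (ra * rb) - cosang * by / (rb * rb))
            fkz = coef * (az / (ra * rb) - cosang * bz / (rb * rb))
            forces[i, 0] += fix; forces[i, 1] += fiy; forces[i, 2] += fiz
            forces[k, 0] += fkx; forces[k, 1] += fky; forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx; forces[j, 1] -= fiy + fky; forces[j, 2] -= fiz + fkz

        for n in range(dihedrals.shape[0]):
            i, j, k, l = dihedrals[n, 0], dihedrals[n, 1], dihedrals[n, 2], dihedrals[n, 3]
            b1x = coords[j, 0] - coords[i, 0]; b1y = coords[j, 1] - coords[i, 1]; b1z = coords[j, 2] - coords[i, 2]
            b2x = coords[k, 0] - coords[j, 0]; b2y = coords[k, 1] - coords[j, 1]; b2z = coords[k, 2] - coords[j, 2]
            b3x = coords[l, 0] - coords[k, 0]; b3y = coords[l, 1] - coords[k, 1]; b3z = coords[l, 2] - coords[k, 2]
            n1x = b1y * b2z - b1z * b2y; n1y = b1z * b2x - b1x * b2z; n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y; n2y = b2z * b3x - b2x * b3z; n2z = b2x * b3y - b2y * b3x
            rb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            # phi via atan2
            mx = n1y * b2z - n1z * b2y; my = n1z * b2x - n1x * b2z; mz = n1x * b2y - n1y * b2x
            y = (mx * n2x + my * n2y + mz * n2z) / rb2
            x = n1x * n2x + n1y * n2y + n1z * n2z
            phi = np.arctan2(y, x)
            dphi = phi - dihedral_phi0[n]
            kd = dihedral_k[n]
            if dihedral_form == 0:
                comps[2] += kd * (1.0 - np.cos(dphi) - np.cos(3.0 * dphi))
                dedphi = kd * (np.sin(dphi) + 3.0 * np.sin(3.0 * dphi))
            else:
                comps[2] += kd * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
                dedphi = kd * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            if n1sq < 1e-12 or n2sq < 1e-12:
                continue
            cfi = -dedphi * rb2 / n1sq
            cfl = dedphi * rb2 / n2sq
            fix = cfi * n1x; fiy = cfi * n1y; fiz = cfi * n1z
            flx = cfl * n2x; fly = cfl * n2y; flz = cfl * n2z
            t = (b1x * b2x + b1y * b2y + b1z * b2z) / (rb2 * rb2)
            s = (b3x * b2x + b3y * b2y + b3z * b2z) / (rb2 * rb2)
            fjx = -fix - t * fix + s * flx
            fjy = -fiy - t * fiy + s * fly
            fjz = -fiz - t * fiz + s * flz
            fkx = -flx + t * fix - s * flx
            fky = -fly + t * fiy - s * fly
            fkz = -flz + t * fiz - s * flz
            forces[i, 0] += fix; forces[i, 1] += fiy; forces[i, 2] += fiz
            forces[j, 0] += fjx; forces[j, 1] += fjy; forces[j, 2] += fjz
            forces[k, 0] += fkx; forces[k, 1] += fky; forces[k, 2] += fkz
            forces[l, 0] += flx; forces[l, 1] += fly; forces[l, 2] += flz

    for n in range(pairs.shape[0]):
        if zone_filter >= 0 and pair_zone[n] != zone_filter:
            continue
        i, j = pairs[n, 0], pairs[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        kind = pair_kind[n]
        a = pair_a[n]
        kk = pair_k[n]
        if kind == 3:  # Debye-Hückel; a = q_i q_j
            if r2 > dh_cutoff * dh_cutoff:
                continue
            r = np.sqrt(r2)
            e = dh_pref * a * np.exp(-dh_kappa * r) / r
            comps[4] += e
            dedr = -e * (dh_kappa + 1.0 / r)
            fmag = -dedr / r
        elif kind == 4:  # repulsion; a = C_ij
            rc = rep_cut * a
            if r2 > rc * rc:
                continue
            r = np.sqrt(r2)
            u6 = (a * a / r2) ** 3
            e = kk * u6 * u6
            comps[5] += e
            dedr = -12.0 * e / r
            fmag = -dedr / r
        else:  # 12-10 well; a = A or r0
            rc = lj_cut * a
            if r2 > rc * rc:
                continue
            r = np.sqrt(r2)
            u2 = a * a / r2
            u10 = u2 * u2 * u2 * u2 * u2
            u12 = u10 * u2
            e = kk * (5.0 * u12 - 6.0 * u10)
            if kind == 0:
                comps[3] += e
            elif kind == 1:
                comps[6] += e
            else:
                comps[7] += e
            dedr = -60.0 * kk * (u12 - u10) / r
            fmag = -dedr / r
        forces[i, 0] += fmag * dx; forces[i, 1] += fmag * dy; forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx; forces[j, 1] -= fmag * dy; forces[j, 2] -= fmag * dz


@njit(cache=True, fastmath=True)
def _pair_subset(coords, pairs, pair_kind, pair_a, pair_k, idx, n_idx,
                 dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut,
                 forces, comps):
    """Accumulate energies/forces for the pair terms listed in ``idx[:n_idx]``.

    Same mathematics as the pair loop of :func:`_eval_kernel`; used by the
    integrator's neighbor-list path.  Does not zero its outputs.
    """
    for q in range(n_idx):
        n = idx[q]
        i, j = pairs[n, 0], pairs[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        kind = pair_kind[n]
        a = pair_a[n]
        kk = pair_k[n]
        if kind == 3:
            if r2 > dh_cutoff * dh_cutoff:
                continue
            r = np.sqrt(r2)
            e = dh_pref * a * np.exp(-dh_kappa * r) / r
            comps[4] += e
            fmag = e * (dh_kappa + 1.0 / r) / r
        elif kind == 4:
            rc = rep_cut * a
            if r2 > rc * rc:
                continue
            r = np.sqrt(r2)
            u6 = (a * a / r2) ** 3
            e = kk * u6 * u6
            comps[5] += e
            fmag = 12.0 * e / r2
        else:
            rc = lj_cut * a
            if r2 > rc * rc:
                continue
            r = np.sqrt(r2)
            u2 = a * a / r2
            u10 = u2 * u2 * u2 * u2 * u2
            u12 = u10 * u2
            e = kk * (5.0 * u12 - 6.0 * u10)
            if kind == 0:
                comps[3] += e
            elif kind == 1:
                comps[6] += e
            else:
                comps[7] += e
            fmag = 60.0 * kk * (u12 - u10) / r2
        forces[i, 0] += fmag * dx; forces[i, 1] += fmag * dy; forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx; forces[j, 1] -= fmag * dy; forces[j, 2] -= fmag * dz


# ---------------------------------------------------------------------------
# Public evaluation API
# ---------------------------------------------------------------------------

def _evaluate(coords, system: System, zone_filter: int = -1):
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError(f"coords shape {coords.shape} != ({system.n_beads}, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    forces = np.zeros_like(coords)
    comps = np.zeros(8)
    _eval_kernel(*system.kernel_args(coords), zone_filter, forces, comps)
    return EnergyBreakdown.from_array(comps), forces


def total_energy_and_forces(coords, system: System):
    """Total potential energy breakdown and analytic forces (kcal/mol/Å)."""
    return _evaluate(coords, system, zone_filter=-1)


def bonded_energy(coords, system: System) -> EnergyBreakdown:
    """Bond + angle + dihedral energies only.

    Raises on degenerate (collinear) angle triples, where the bending
    force is undefined.
    """
    from . import geometry

    if len(system.angles):
        th = geometry.bend_angles(np.asarray(coords, dtype=float), system.angles)
        if np.any(np.abs(np.sin(th)) < 1e-10):
            raise ValueError("degenerate geometry: collinear angle triple")
    breakdown, _ = _evaluate(coords, system)
    return EnergyBreakdown(bond=breakdown.bond, angle=breakdown.angle,
                           dihedral=breakdown.dihedral)


def interface_energy(coords, system: System):
    """Protein–strand interaction energy and the λ = E_elec/E_arom ratio.

    Returns ``(EnergyBreakdown, lam)`` where only the electrostatic,
    aromatic-stacking and repulsion components are populated; ``lam`` is
    NaN when both components vanish.
    """
    if system.n_protein_beads == 0 or system.na is None:
        raise ValueError("system does not contain both molecules")
    breakdown, _ = _evaluate(coords, system, zone_filter=ZONE_INTERFACE)
    elec, arom = breakdown.electrostatic, breakdown.aromatic_stacking
    lam = np.nan if arom == 0.0 else elec / arom
    if elec == 0.0 and arom != 0.0:
        lam = 0.0
    return breakdown, lam
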