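"""Force-field parameters.

All numeric constants of the model live in versioned YAML files under
:mod:`ssbind.data`; this module loads them into a frozen
:class:`ForceFieldParams` and derives the Debye–Hückel screening
quantities from the salt concentration and dielectric.

Units: energies kcal/mol, lengths Å, charges e, angles rad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

__all__ = ["ForceFieldParams", "load_params", "debye_length"]

AROMATIC_RESIDUES = ("W", "F", "Y", "H")
POSITIVE_RESIDUES = ("K", "R")
NEGATIVE_RESIDUES = ("D", "E")

# kB in kcal mol^-1 K^-1
_KB = 1.987204259e-3
# e^2 * NA / (4 pi eps0) in kcal Å mol^-1
_E2_NA_OVER_4PIEPS0 = 332.0637


def debye_length(salt_mM: float, eps_r: float, temperature_K: float = 298.0) -> float:
    """Debye screening length in Å for a 1:1 salt.

    kappa^2 = 8 pi l_B * NA * I with the Bjerrum length l_B evaluated at
    the given dielectric and temperature; I is the ionic strength in
    mol/L (equal to the concentration for a 1:1 salt).
    """
    if salt_mM <= 0:
        raise ValueError("salt concentration must be positive")
    if eps_r <= 0:
        raise ValueError("dielectric constant must be positive")
    l_bjerrum = _E2_NA_OVER_4PIEPS0 / (eps_r * _KB * temperature_K)  # Å
    ions_per_A3 = 2.0 * (salt_mM * 1e-3) * 6.02214076e23 * 1e-27
    kappa2 = 4.0 * math.pi * l_bjerrum * ions_per_A3
    return 1.0 / math.sqrt(kappa2)


def _read_yaml(name: str) -> dict:
    with resources.files("ssbind.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ForceFieldParams:
    """Container for every constant of the coarse-grained force field."""

    k_bonds: float
    k_angles: float
    k_dihedrals_protein: float
    na_dihedrals: dict  # kind -> {"base_sugar": K, "backbone": K}
    k_contacts: float
    k_repulsion: float
    stack_r0: float
    radii: dict  # bead role -> Å
    eps_bb: dict  # frozenset-like 2-char key "XY" -> kcal/mol
    eps_baa: dict  # (aromatic residue, base) -> kcal/mol
    coulomb_constant: float
    dielectric: float
    salt_mM: float
    temperature_K: float
    dh_ion_size: float
    dh_cutoff_debye_lengths: float
    lj_cutoff_factor: float
    rep_cutoff_factor: float
    energy_unit: float = 1.0  # kcal/mol per reduced energy unit
    dihedral_form: str = "printed"  # "printed" or "conventional"
    templates: dict = field(default_factory=dict, repr=False)

    # ---- derived electrostatics -------------------------------------
    @property
    def debye_length(self) -> float:
        return debye_length(self.salt_mM, self.dielectric, self.temperature_K)

    @property
    def b_kappa(self) -> float:
        """Salt-activity prefactor B(kappa) = exp(kappa a)/(1 + kappa a)."""
        ka = self.dh_ion_size / self.debye_length
        return math.exp(ka) / (1.0 + ka)

    @property
    def dh_prefactor(self) -> float:
        """Energy prefactor so that E = pref * q_i q_j exp(-r/lD) / r."""
        return self.coulomb_constant * self.b_kappa / self.dielectric

    # ---- lookups ----------------------------------------------------
    def eps_base_base(self, x: str, y: str) -> float:
        key = x.upper() + y.upper()
        if key in self.eps_bb:
            return self.eps_bb[key]
        key = y.upper() + x.upper()
        if key in self.eps_bb:
            return self.eps_bb[key]
        raise KeyError(f"no base-base stacking entry for pair {x}{y}")

    def eps_base_aromatic(self, residue: str, base: str) -> float:
        try:
            return self.eps_baa[(residue.upper(), base.upper())]
        except KeyError:
            raise KeyError(
                f"no base-aromatic stacking entry for {residue}-{base}"
            ) from None

    def na_dihedral_constants(self, kind: str) -> tuple[float, float]:
        """(base_sugar, backbone) dihedral stiffness for DNA or RNA."""
        entry = self.na_dihedrals[kind.upper()]
        return entry["base_sugar"], entry["backbone"]

    def with_salt(self, salt_mM: float) -> "ForceFieldParams":
        return replace(self, salt_mM=salt_mM)


def load_params(**overrides) -> ForceFieldParams:
    """Load the packaged parameter files into a :class:`ForceFieldParams`.

    Keyword overrides replace any scalar field, e.g.
    ``load_params(salt_mM=100.0)``.
    """
    ff = _read_yaml("forcefield.yaml")
    bb = _read_yaml("stacking_base_base.yaml")
    baa = _read_yaml("stacking_base_aromatic.yaml")
    templates = _read_yaml("helix_templates.yaml")

    eps_bb = {k.upper(): float(v) for k, v in bb["pairs"].items()}
    for key, val in eps_bb.items():
        if val < 0:
            raise ValueError(f"stacking well depth must be >= 0: {key}")
    eps_baa = {}
    for res, row in baa["pairs"].items():
        for base, val in row.items():
            if val < 0:
                raise ValueError(f"eps_B-AA must be >= 0: {res}-{base}")
            eps_baa[(res.upper(), base.upper())] = float(val)

    fields = dict(
        k_bonds=ff["k_bonds"],
        k_angles=ff["k_angles"],
        k_dihedrals_protein=ff["k_dihedrals_protein"],
        na_dihedrals={k.upper(): dict(v) for k, v in ff["na_dihedrals"].items()},
        k_contacts=ff["k_contacts"],
        k_repulsion=ff["k_repulsion"],
        stack_r0=ff["stack_r0"],
        radii=dict(ff["radii"]),
        eps_bb=eps_bb,
        eps_baa=eps_baa,
        coulomb_constant=ff["coulomb_constant"],
        dielectric=ff["dielectric"],
        salt_mM=ff["salt_mM"],
        temperature_K=ff["temperature_K"],
        dh_ion_size=ff["dh_ion_size"],
        dh_cutoff_debye_lengths=ff["dh_cutoff_debye_lengths"],
        lj_cutoff_factor=ff["lj_cutoff_factor"],
        rep_cutoff_factor=ff["rep_cutoff_factor"],
        energy_unit=ff.get("energy_unit", 1.0),
        templates={k: v for k, v in templates.items() if k in ("DNA", "RNA")},
    )
    fields.update(overrides)
    return ForceFieldParams(**fields)
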