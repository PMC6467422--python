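"""Trajectory statistics: interface similarity, landscapes, kinetics, specificity.

The native interface is the set of positively charged Cβ beads within a
cutoff (9 Å) of any phosphate bead plus aromatic Cβ beads within the
same cutoff of any base bead, measured in the reference (experimental)
pose.  Two similarity distances quantify how close a simulated frame is
to that pose:

* ``D_Site`` compares each interfacial residue's summed distances to all
  phosphate (charged residues) or base (aromatic residues) beads and is
  blind to strand directionality;
* ``D_Conf`` compares the specific native pairings (each base with its
  nearest aromatic residue, each phosphate with its nearest positive
  residue) and therefore distinguishes a 5'→3' flipped strand.

Both are mean absolute deviations in Å and are zero exactly at the
reference.  The interface is split into two moieties (by whether a
residue's nearest strand bead lies in the 5' or 3' half), giving the
moiety-resolved variants D¹/D² used for landscapes and filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .builder import ROLE_B, ROLE_CB, ROLE_P
from .forcefield import System, interface_energy

log = logging.getLogger(__name__)

__all__ = [
    "InterfaceDefinition",
    "SimilarityScores",
    "SpecificityMetrics",
    "KineticsEstimate",
    "identify_native_interface",
    "compute_dsite",
    "compute_dconf",
    "similarity_scores",
    "persistence_length",
    "free_energy_surface",
    "binding_energy_summary",
    "estimate_kinetics",
    "compute_isr",
    "lambda_ratio",
]


# ---------------------------------------------------------------------------
# Interface definition
# ---------------------------------------------------------------------------

@dataclass
class InterfaceDefinition:
    """Native interfacial beads, moiety split, and the D_Conf pair list."""

    cutoff: float
    # interfacial protein CB beads (global indices) and their kind
    residue_beads: np.ndarray      # (n,) int
    residue_kind: np.ndarray       # (n,) unicode: "positive" | "aromatic"
    moiety: np.ndarray             # (n,) int, 1 or 2
    # D_Site reference sums: for bead i, sum_j r0_ij over its NA partner set
    site_ref_sums: np.ndarray      # (n,)
    # D_Conf native pairs
    pair_na_bead: np.ndarray       # (m,) int global NA bead index
    pair_prot_bead: np.ndarray     # (m,) int global protein bead index
    pair_r0: np.ndarray            # (m,) native distances
    pair_moiety: np.ndarray        # (m,) moiety of the protein bead
    n_nucleotides: int

    def moiety_counts(self) -> tuple:
        return int(np.sum(self.moiety == 1)), int(np.sum(self.moiety == 2))


@dataclass
class SimilarityScores:
    d_site: float = np.nan
    d_site_1: float = np.nan
    d_site_2: float = np.nan
    d_conf: float = np.nan
    d_conf_1: float = np.nan
    d_conf_2: float = np.nan


def _partner_beads(system: System, kind: str) -> np.ndarray:
    role = ROLE_P if kind == "positive" else ROLE_B
    na = np.arange(system.n_protein_beads, system.n_beads)
    return na[system.roles[system.na_slice] == role]


def identify_native_interface(system: System, reference: np.ndarray = None,
                              cutoff: float = 9.0) -> InterfaceDefinition:
    """Find the native interfacial residues and the D_Conf pairing in a
    reference complex.

    Raises if no bead qualifies (molecules unbound or cutoff too small).
    """
    if system.n_protein_beads == 0 or system.na is None:
        raise ValueError("system must contain both molecules")
    ref = system.coords0 if reference is None else np.asarray(reference, dtype=float)
    prot = system.protein
    n_nt = system.na.n_nucleotides

    pos = prot.positive_cb_indices()
    arom = prot.aromatic_cb_indices()
    p_beads = _partner_beads(system, "positive")
    b_beads = _partner_beads(system, "aromatic")

    beads, kinds = [], []
    for cand, partners, kind in ((pos, p_beads, "positive"), (arom, b_beads, "aromatic")):
        for i in cand:
            d = np.linalg.norm(ref[partners] - ref[i], axis=1)
            if len(d) and d.min() <= cutoff:
                beads.append(int(i))
                kinds.append(kind)
    if not beads:
        raise ValueError("empty interface: molecules unbound or cutoff too small")
    beads = np.array(beads)
    kinds = np.array(kinds)

    # moiety by the 5'/3' half of the nearest strand bead
    na_all = np.arange(system.n_protein_beads, system.n_beads)
    nt_index = system.na.beads.resids
    moiety = np.empty(len(beads), dtype=int)
    for n, i in enumerate(beads):
        d = np.linalg.norm(ref[na_all] - ref[i], axis=1)
        nearest_nt = nt_index[int(np.argmin(d))]
        moiety[n] = 1 if nearest_nt < n_nt / 2 else 2

    site_ref_sums = np.array([
        np.sum(np.linalg.norm(ref[_partner_beads(system, k)] - ref[i], axis=1))
        for i, k in zip(beads, kinds)
    ])

    # native D_Conf pairing: base -> nearest aromatic, phosphate -> nearest positive
    pair_na, pair_prot, pair_r0, pair_moiety = [], [], [], []
    for na_set, kind in ((b_beads, "aromatic"), (p_beads, "positive")):
        sel = beads[kinds == kind]
        sel_moiety = moiety[kinds == kind]
        if len(sel) == 0:
            continue
        for j in na_set:
            d = np.linalg.norm(ref[sel] - ref[j], axis=1)
            a = int(np.argmin(d))
            pair_na.append(int(j))
            pair_prot.append(int(sel[a]))
            pair_r0.append(float(d[a]))
            pair_moiety.append(int(sel_moiety[a]))

    return InterfaceDefinition(
        cutoff=cutoff,
        residue_beads=beads,
        residue_kind=kinds,
        moiety=moiety,
        site_ref_sums=site_ref_sums,
        pair_na_bead=np.array(pair_na),
        pair_prot_bead=np.array(pair_prot),
        pair_r0=np.array(pair_r0),
        pair_moiety=np.array(pair_moiety),
        n_nucleotides=n_nt,
    )


def compute_dsite(frame: np.ndarray, system: System,
                  interface: InterfaceDefinition) -> SimilarityScores:
    """Direction-blind interface similarity (Å); 0 at the reference pose."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_beads, 3):
        raise ValueError("frame does not match system topology")
    dev = np.empty(len(interface.residue_beads))
    for n, (i, kind) in enumerate(zip(interface.residue_beads, interface.residue_kind)):
        partners = _partner_beads(system, str(kind))
        s = np.sum(np.linalg.norm(frame[partners] - frame[i], axis=1))
        dev[n] = abs(s - interface.site_ref_sums[n])
    n_nt = interface.n_nucleotides
    out = SimilarityScores()
    out.d_site = float(dev.sum() / (len(dev) * n_nt))
    for m, attr in ((1, "d_site_1"), (2, "d_site_2")):
        sel = interface.moiety == m
        if sel.any():
            setattr(out, attr, float(dev[sel].sum() / (sel.sum() * n_nt)))
    return out


def compute_dconf(frame: np.ndarray, system: System,
                  interface: InterfaceDefinition) -> SimilarityScores:
    """Direction-aware similarity over the native pair list (Å)."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (system.n_beads, 3):
        raise ValueError("frame does not match system topology")
    r = np.linalg.norm(frame[interface.pair_na_bead] - frame[interface.pair_prot_bead], axis=1)
    dev = np.abs(r - interface.pair_r0)
    out = SimilarityScores()
    out.d_conf = float(dev.mean())
    for m, attr in ((1, "d_conf_1"), (2, "d_conf_2")):
        sel = interface.pair_moiety == m
        if sel.any():
            setattr(out, attr, float(dev[sel].mean()))
    return out


def similarity_scores(frame, system, interface) -> SimilarityScores:
    """Both D_Site and D_Conf (plus moiety-resolved variants) for one frame."""
    s = compute_dsite(frame, system, interface)
    c = compute_dconf(frame, system, interface)
    s.d_conf, s.d_conf_1, s.d_conf_2 = c.d_conf, c.d_conf_1, c.d_conf_2
    return s


# ---------------------------------------------------------------------------
# Persistence length
# ---------------------------------------------------------------------------

def persistence_length(frames: np.ndarray, p_indices: np.ndarray) -> float:
    """Flexible-polymer persistence length <L·l0>/<|l0|> in Å.

    ``l0`` is the bond vector between the two 5'-end phosphate beads and
    ``L`` the end-to-end phosphate vector, averaged over frames.
    """
    p_indices = np.asarray(p_indices, dtype=int)
    if len(p_indices) < 2:
        raise ValueError("need at least two phosphate beads")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) < 100:
        warnings.warn("fewer than 100 frames: persistence length estimate has high variance")
    l0 = frames[:, p_indices[1]] - frames[:, p_indices[0]]
    L = frames[:, p_indices[-1]] - frames[:, p_indices[0]]
    return float(np.mean(np.einsum("ij,ij->i", L, l0)) / np.mean(np.linalg.norm(l0, axis=1)))


# ---------------------------------------------------------------------------
# Landscapes and binding energies
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray   # -T ln p, minimum shifted to 0; NaN where empty


def free_energy_surface(x, y, bins=40, temperature: float = 0.3,
                        range_=None) -> FreeEnergySurface:
    """2-D free-energy surface −T·ln p over two score coordinates."""
    counts, xe, ye = np.histogram2d(np.asarray(x), np.asarray(y), bins=bins, range=range_)
    if (counts > 0).sum() <= 1:
        warnings.warn("degenerate surface: all frames fall into a single bin")
    with np.errstate(divide="ignore"):
        f = -temperature * np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return FreeEnergySurface(x_edges=xe, y_edges=ye, counts=counts, free_energy=f)


@dataclass
class BindingEnergySummary:
    mean: float
    sd: float
    count: int
    components_mean: np.ndarray = None  # (elec, aromatic, repulsion)

    @property
    def empty(self) -> bool:
        return self.count == 0


def binding_energy_summary(trajectories, system: System,
                           interface: InterfaceDefinition,
                           near_native_cut: float = 5.0) -> BindingEnergySummary:
    """Mean ± sd of E_bind over near-native analysis frames.

    A frame qualifies when both moiety-resolved D_Conf values are ≤ the
    cutoff; only each trajectory's equilibrated analysis window is used.
    An empty result (count 0) is returned explicitly rather than NaN.
    """
    energies, comps = [], []
    for traj in trajectories:
        if not traj.stable:
            continue
        for frame in traj.frames[traj.analysis_mask()]:
            sc = compute_dconf(frame, system, interface)
            if sc.d_conf_1 <= near_native_cut and sc.d_conf_2 <= near_native_cut:
                br, _ = interface_energy(frame, system)
                energies.append(br.electrostatic + br.aromatic_stacking + br.repulsion)
                comps.append((br.electrostatic, br.aromatic_stacking, br.repulsion))
    if not energies:
        return BindingEnergySummary(mean=np.nan, sd=np.nan, count=0)
    energies = np.asarray(energies)
    return BindingEnergySummary(mean=float(energies.mean()),
                                sd=float(energies.std(ddof=0)),
                                count=len(energies),
                                components_mean=np.mean(comps, axis=0))


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticsEstimate:
    k_on: float = np.nan          # 1 / reduced time
    k_off: float = np.nan
    n_binding_events: int = 0
    n_dissociation_events: int = 0
    censored_on: bool = False
    censored_off: bool = False
    threshold: float = 5.0


def _first_passage(series: np.ndarray, threshold: float, direction: str):
    hit = series < threshold if direction == "down" else series > threshold
    idx = np.flatnonzero(hit)
    return int(idx[0]) if len(idx) else None


def estimate_kinetics(trajectories, system: System = None,
                      interface: InterfaceDefinition = None,
                      threshold: float = 5.0,
                      dconf_series: list = None,
                      frame_time: float = None) -> KineticsEstimate:
    """First-passage rate estimates from binding/unbinding trajectories.

    Binding is D_Conf dropping below the threshold starting unbound;
    dissociation is D_Conf rising above it starting bound.  Rates are
    inverse mean first-passage times; with zero events the rate is
    reported as a censored bound 1/(total simulated time).

    ``dconf_series`` may supply precomputed per-trajectory D_Conf arrays
    (paired with ``trajectories`` for start-state labels and timing).
    """
    on_times, off_times = [], []
    on_total = off_total = 0.0
    for n, traj in enumerate(trajectories):
        if not traj.stable:
            continue
        dt_frame = (frame_time if frame_time is not None
                    else traj.config.dt * traj.config.save_interval)
        if dconf_series is not None:
            series = np.asarray(dconf_series[n])
        else:
            series = np.array([
                compute_dconf(f, system, interface).d_conf for f in traj.frames
            ])
        total = len(series) * dt_frame
        if traj.start_state == "unbound":
            on_total += total
            i = _first_passage(series, threshold, "down")
            if i is not None:
                on_times.append((i + 1) * dt_frame)
        else:
            off_total += total
            i = _first_passage(series, threshold, "up")
            if i is not None:
                off_times.append((i + 1) * dt_frame)

    out = KineticsEstimate(threshold=threshold,
                           n_binding_events=len(on_times),
                           n_dissociation_events=len(off_times))
    if on_times:
        out.k_on = 1.0 / float(np.mean(on_times))
    elif on_total > 0:
        out.k_on = 1.0 / on_total
        out.censored_on = True
    if off_times:
        out.k_off = 1.0 / float(np.mean(off_times))
    elif off_total > 0:
        out.k_off = 1.0 / off_total
        out.censored_off = True
    return out


# ---------------------------------------------------------------------------
# Intrinsic specificity ratio
# ---------------------------------------------------------------------------

@dataclass
class SpecificityMetrics:
    delta_e: float        # energy gap |native - non-native mean|, kcal/mol
    sigma_e: float        # non-native energy spread, kcal/mol
    entropy: float        # -sum p ln p over binned non-native energies
    isr: float            # delta_e / (sigma_e * sqrt(2 * entropy))


def compute_isr(energies, dconf1, dconf2, native_cut: float = 3.0,
                bin_width: float = 0.5) -> SpecificityMetrics:
    """Intrinsic specificity ratio ISR = δE / (ΔE √(2S)).

    Native frames satisfy both moiety D_Conf ≤ ``native_cut``;
    non-native frames have negative binding energy and both D_Conf
    above the cutoff.  S is the Shannon entropy of the binned
    non-native energy distribution.
    """
    energies = np.asarray(energies, dtype=float)
    d1 = np.asarray(dconf1, dtype=float)
    d2 = np.asarray(dconf2, dtype=float)
    native = (d1 <= native_cut) & (d2 <= native_cut)
    nonnative = (d1 > native_cut) & (d2 > native_cut) & (energies < 0)
    if not native.any():
        raise ValueError("no native frames (both D_Conf <= cutoff)")
    if not nonnative.any():
        raise ValueError("no non-native frames with negative binding energy")
    e_nn = energies[nonnative]
    delta_e = abs(float(energies[native].mean()) - float(e_nn.mean()))
    sigma_e = float(e_nn.std(ddof=0))
    if sigma_e == 0:
        raise ValueError("undefined ISR: zero non-native energy variance")
    nbins = max(int(np.ceil((e_nn.max() - e_nn.min()) / bin_width)), 1)
    counts, _ = np.histogram(e_nn, bins=nbins)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    if entropy == 0:
        raise ValueError("undefined ISR: zero configurational entropy")
    return SpecificityMetrics(delta_e=delta_e, sigma_e=sigma_e, entropy=entropy,
                              isr=delta_e / (sigma_e * np.sqrt(2.0 * entropy)))


# ---------------------------------------------------------------------------
# Electrostatic / aromatic balance
# ---------------------------------------------------------------------------

@dataclass
class LambdaRatio:
    value: float            # mean E_elec / mean E_arom over near-native frames
    label: str              # "", "very low", "very high", "undefined"
    mean_elec: float
    mean_arom: float
    count: int


def lambda_ratio(trajectories, system: System, interface: InterfaceDefinition,
                 near_native_cut: float = 5.0,
                 component_floor: float = 0.5) -> LambdaRatio:
    """λ = E_elec/E_arom averaged over near-native frames.

    When a component's mean magnitude is below ``component_floor``
    (kcal/mol) the ratio is reported with a sentinel label: negligible
    aromatic energy → "very high", negligible electrostatics →
    "very low"; both negligible → "undefined".
    """
    elec, arom = [], []
    for traj in trajectories:
        if not traj.stable:
            continue
        for frame in traj.frames[traj.analysis_mask()]:
            sc = compute_dconf(frame, system, interface)
            if sc.d_conf_1 <= near_native_cut and sc.d_conf_2 <= near_native_cut:
                br, _ = interface_energy(frame, system)
                elec.append(br.electrostatic)
                arom.append(br.aromatic_stacking)
    if not elec:
        raise ValueError("no qualifying near-native frames")
    me, ma = float(np.mean(elec)), float(np.mean(arom))
    if abs(me) < component_floor and abs(ma) < component_floor:
        return LambdaRatio(np.nan, "undefined", me, ma, len(elec))
    if abs(ma) < component_floor:
        return LambdaRatio(np.inf, "very high", me, ma, len(elec))
    value = me / ma
    label = "very low" if abs(me) < component_floor else ""
    return LambdaRatio(value, label, me, ma, len(elec))
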