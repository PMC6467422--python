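"""Interface metrics, landscapes, kinetics and specificity statistics."""

import numpy as np
import pytest

from ssbind import SimulationConfig, build_system
from ssbind.analysis import (
    compute_dconf,
    compute_dsite,
    compute_isr,
    estimate_kinetics,
    free_energy_surface,
    identify_native_interface,
    lambda_ratio,
    persistence_length,
    binding_energy_summary,
    similarity_scores,
)
from ssbind.builder import ROLE_B, ROLE_P
from ssbind.fixtures import ToyComplexSpec, make_toy_complex
from ssbind.geometry import rotation_matrix
from ssbind.simulate import Trajectory


@pytest.fixture(scope="module")
def iface(toy_system):
    return identify_native_interface(toy_system)


def _synthetic_trajectory(frames, config=None, start="unbound", stable=True):
    frames = np.asarray(frames, dtype=float)
    cfg = config or SimulationConfig(n_steps=len(frames) * 1000, save_interval=1000)
    return Trajectory(frames=frames, energies=np.zeros((len(frames), 8)),
                      config=cfg, seed=0, start_state=start, stable=stable)


# ---------------------------------------------------------------------------
# Interface identification
# ---------------------------------------------------------------------------

def test_interface_threshold_behavior(params):
    """An Arg CB at 8 Å from a P is interfacial; one at 12 Å is not; a Trp at
    8 Å from a base enters via the aromatic rule."""
    spec = ToyComplexSpec(sequence="TTTT", aromatic_sites=(1,), positive_sites=(0, 3),
                          n_scaffold=6)
    tc = make_toy_complex(spec, params)
    sys = build_system(tc.protein, tc.na, params)
    ref = tc.reference.copy()
    near, far = tc.positive_beads
    # push one positive CB to 12 Å from every phosphate
    p_xyz = ref[sys.n_protein_beads:][tc.na.beads.roles == ROLE_P]
    ref[far] = p_xyz.mean(axis=0) + np.array([0.0, 0.0, 60.0])
    # move the aromatic to ~8 Å from its base
    ref[tc.aromatic_beads[0]] += np.array([0.0, 0.0, 8.0 - 3.6])
    iface = identify_native_interface(sys, ref)
    assert near in iface.residue_beads
    assert far not in iface.residue_beads
    assert tc.aromatic_beads[0] in iface.residue_beads


def test_empty_interface_raises(toy_system):
    ref = toy_system.coords0.copy()
    ref[toy_system.n_protein_beads:] += 500.0
    with pytest.raises(ValueError, match="interface"):
        identify_native_interface(toy_system, ref)


def test_pair_list_matches_brute_force_nearest_neighbor(toy_system, iface):
    ref = toy_system.coords0
    sel_arom = iface.residue_beads[iface.residue_kind == "aromatic"]
    sel_pos = iface.residue_beads[iface.residue_kind == "positive"]
    na0 = toy_system.n_protein_beads
    roles = toy_system.roles
    for j, prot, r0 in zip(iface.pair_na_bead, iface.pair_prot_bead, iface.pair_r0):
        sel = sel_arom if roles[j] == ROLE_B else sel_pos
        d = [np.linalg.norm(ref[i] - ref[j]) for i in sel]
        assert prot == sel[int(np.argmin(d))]
        assert r0 == pytest.approx(min(d))


# ---------------------------------------------------------------------------
# D_Site / D_Conf
# ---------------------------------------------------------------------------

def test_metrics_zero_at_reference(toy_system, iface):
    s = similarity_scores(toy_system.coords0, toy_system, iface)
    assert s.d_site == 0.0 and s.d_conf == 0.0
    assert s.d_site_1 == 0.0 and s.d_site_2 == 0.0
    assert s.d_conf_1 == 0.0 and s.d_conf_2 == 0.0


def test_metrics_invariant_under_rigid_motion_of_complex(toy_system, iface):
    rng = np.random.default_rng(2)
    x = toy_system.coords0 + 0.4 * rng.standard_normal(toy_system.coords0.shape)
    s0 = similarity_scores(x, toy_system, iface)
    rot = rotation_matrix(rng.standard_normal(3), 1.1)
    moved = x @ rot.T + np.array([5.0, -3.0, 8.0])
    s1 = similarity_scores(moved, toy_system, iface)
    assert s1.d_site == pytest.approx(s0.d_site, abs=1e-9)
    assert s1.d_conf == pytest.approx(s0.d_conf, abs=1e-9)


def test_flipped_strand_small_dsite_large_dconf(params):
    """Reversing a symmetric homopolymer in place fools D_Site but not D_Conf."""
    spec = ToyComplexSpec(sequence="TTTTTT", aromatic_sites=(1, 4),
                          positive_sites=(0, 5), n_scaffold=8)
    tc = make_toy_complex(spec, params)
    sys = build_system(tc.protein, tc.na, params)
    iface = identify_native_interface(sys)
    flipped = tc.reference.copy()
    n0 = sys.n_protein_beads
    n_nt = tc.na.n_nucleotides
    for i in range(n_nt):
        for k in range(3):
            flipped[n0 + 3 * i + k] = tc.reference[n0 + 3 * (n_nt - 1 - i) + k]
    s = similarity_scores(flipped, sys, iface)
    # symmetric patch: per-residue distance sums barely change...
    assert s.d_site < 1.0
    # ...but the native 5'->3' pairings are broken
    assert s.d_conf > 2.0 * max(s.d_site, 0.1)


def test_dsite_dconf_match_double_loop_oracle(toy_system, iface):
    rng = np.random.default_rng(4)
    na0 = toy_system.n_protein_beads
    roles = toy_system.roles
    ref = toy_system.coords0
    for _ in range(3):
        x = ref + 1.5 * rng.standard_normal(ref.shape)

        # oracle D_Site
        total, per_moiety = [], {1: [], 2: []}
        for bead, kind, m in zip(iface.residue_beads, iface.residue_kind, iface.moiety):
            role = ROLE_P if kind == "positive" else ROLE_B
            partners = [j for j in range(na0, toy_system.n_beads) if roles[j] == role]
            s = sum(np.linalg.norm(x[j] - x[bead]) for j in partners)
            s0 = sum(np.linalg.norm(ref[j] - ref[bead]) for j in partners)
            total.append(abs(s - s0))
            per_moiety[m].append(abs(s - s0))
        n_nt = iface.n_nucleotides
        d_site = sum(total) / (len(total) * n_nt)

        # oracle D_Conf
        devs = [abs(np.linalg.norm(x[j] - x[i]) - r0)
                for j, i, r0 in zip(iface.pair_na_bead, iface.pair_prot_bead, iface.pair_r0)]
        d_conf = float(np.mean(devs))

        s = similarity_scores(x, toy_system, iface)
        assert s.d_site == pytest.approx(d_site, abs=1e-10)
        assert s.d_conf == pytest.approx(d_conf, abs=1e-10)
        m1 = per_moiety[1]
        assert s.d_site_1 == pytest.approx(sum(m1) / (len(m1) * n_nt), abs=1e-10)


def test_topology_mismatch_rejected(toy_system, iface):
    with pytest.raises(ValueError):
        compute_dsite(np.zeros((3, 3)), toy_system, iface)


# ---------------------------------------------------------------------------
# Persistence length
# ---------------------------------------------------------------------------

def test_persistence_length_straight_chain():
    """Frozen straight chain of N bonds of length b: L_ps = N*b."""
    n, b = 10, 6.5
    frame = np.zeros((n + 1, 3))
    frame[:, 0] = np.arange(n + 1) * b
    frames = np.repeat(frame[None], 120, axis=0)
    lp = persistence_length(frames, np.arange(n + 1))
    assert lp == pytest.approx(n * b, rel=1e-12)


def test_persistence_length_perpendicular_is_zero():
    frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0], [1.0, 2.0, 0]])
    frame[3] = [1.0, 3.0, 0.0]
    # make end-to-end exactly perpendicular to the first bond
    frame[3][0] = 0.0
    frames = np.repeat(frame[None], 150, axis=0)
    lp = persistence_length(frames, [0, 1, 2, 3])
    assert lp == pytest.approx(0.0, abs=1e-12)


def test_persistence_length_freely_jointed_chain_limit():
    """FJC: <L·l0> = b², so the estimator converges to the bond length b."""
    rng = np.random.default_rng(12)
    n_bonds, b, n_frames = 30, 6.0, 4000
    steps = rng.standard_normal((n_frames, n_bonds, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    pos = np.concatenate([np.zeros((n_frames, 1, 3)), np.cumsum(b * steps, axis=1)], axis=1)
    lp = persistence_length(pos, np.arange(n_bonds + 1))
    se = b / np.sqrt(n_frames)  # rough scale of the sampling error
    assert abs(lp - b) < 4 * se + 0.3


def test_persistence_length_warns_on_few_frames():
    frames = np.zeros((10, 3, 3))
    frames[:, 1, 0] = 5.0
    frames[:, 2, 0] = 10.0
    with pytest.warns(UserWarning, match="frames"):
        persistence_length(frames, [0, 1, 2])


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------

def test_fes_uniform_scores_flat_surface():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, 20000)
    y = rng.uniform(0, 1, 20000)
    fes = free_energy_surface(x, y, bins=4, temperature=0.3)
    spread = np.nanmax(fes.free_energy) - np.nanmin(fes.free_energy)
    assert spread < 0.05  # ~flat at this sampling


def test_fes_two_cluster_depth_difference():
    """Two point clusters: depth difference equals T ln(p1/p2) exactly."""
    x = np.array([0.1] * 300 + [0.9] * 100)
    y = np.array([0.1] * 300 + [0.9] * 100)
    fes = free_energy_surface(x, y, bins=2, temperature=0.3)
    depths = fes.free_energy[np.isfinite(fes.free_energy)]
    diff = depths.max() - depths.min()
    assert diff == pytest.approx(0.3 * np.log(3.0), rel=1e-10)


def test_fes_counts_match_histogram_oracle():
    rng = np.random.default_rng(8)
    x, y = rng.uniform(0, 10, 500), rng.uniform(0, 10, 500)
    fes = free_energy_surface(x, y, bins=5)
    counts, _, _ = np.histogram2d(x, y, bins=5)
    assert np.array_equal(fes.counts, counts)
    assert fes.counts.sum() == 500


def test_fes_degenerate_warning():
    with pytest.warns(UserWarning, match="single bin"):
        free_energy_surface(np.ones(50), np.ones(50), bins=3)


# ---------------------------------------------------------------------------
# Binding-energy summary
# ---------------------------------------------------------------------------

def test_binding_energy_filter_and_threshold_edge(toy_system, iface):
    """Frames exactly at D_Conf = 5.0 are included; just above are excluded."""
    ref = toy_system.coords0
    na0 = toy_system.n_protein_beads

    def frame_with_dconf(delta):
        # uniformly inflate every native pair distance by delta (strand shifted
        # perpendicular to the plate gives approx uniform deviation)
        x = ref.copy()
        x[na0:] += np.array([0.0, 0.0, -delta])
        return x

    # calibrate shifts that land exactly at / above the threshold
    from ssbind.analysis import compute_dconf as dc

    lo = frame_with_dconf(0.0)
    exact, above = None, None
    for delta in np.linspace(0.1, 12.0, 400):
        s = dc(frame_with_dconf(delta), toy_system, iface)
        m = max(s.d_conf_1, s.d_conf_2)
        if exact is None and m <= 5.0:
            pass
        if m <= 5.0:
            exact = delta
        elif above is None:
            above = delta
    frames = [lo, frame_with_dconf(exact), frame_with_dconf(above)]
    cfg = SimulationConfig(n_steps=3000, save_interval=1000, analysis_fraction=1.0)
    traj = _synthetic_trajectory(frames, cfg)
    out = binding_energy_summary([traj], toy_system, iface)
    assert out.count == 2  # the > 5 Å frame is excluded

    far = _synthetic_trajectory([frame_with_dconf(50.0)] * 3, cfg)
    empty = binding_energy_summary([far], toy_system, iface)
    assert empty.empty and empty.count == 0


def test_binding_energy_constant_frames(toy_system, iface):
    cfg = SimulationConfig(n_steps=5000, save_interval=1000, analysis_fraction=1.0)
    traj = _synthetic_trajectory([toy_system.coords0] * 5, cfg)
    out = binding_energy_summary([traj], toy_system, iface)
    assert out.count == 5
    assert out.sd == pytest.approx(0.0, abs=1e-12)
    from ssbind import interface_energy

    br, _ = interface_energy(toy_system.coords0, toy_system)
    assert out.mean == pytest.approx(
        br.electrostatic + br.aromatic_stacking + br.repulsion)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def test_telegraph_process_rates_recovered():
    """Two-state telegraph signal with known switching rates as the oracle."""
    rng = np.random.default_rng(42)
    k_on_true, k_off_true = 0.01, 0.002  # per frame
    n_traj, n_frames = 120, 2000
    cfg = SimulationConfig(n_steps=n_frames * 1000, save_interval=1000, dt=1.0)
    # frame_time = dt * save_interval = 1000; rates in reduced time = k/1000
    on_trajs, off_trajs, on_series, off_series = [], [], [], []
    for _ in range(n_traj):
        t_bind = rng.geometric(k_on_true)
        series = np.full(n_frames, 10.0)
        if t_bind < n_frames:
            series[t_bind:] = 1.0
        on_trajs.append(_synthetic_trajectory(np.zeros((n_frames, 1, 3)), cfg, "unbound"))
        on_series.append(series)
        t_diss = rng.geometric(k_off_true)
        series = np.full(n_frames, 1.0)
        if t_diss < n_frames:
            series[t_diss:] = 10.0
        off_trajs.append(_synthetic_trajectory(np.zeros((n_frames, 1, 3)), cfg, "bound"))
        off_series.append(series)
    est = estimate_kinetics(on_trajs + off_trajs,
                            dconf_series=on_series + off_series, threshold=5.0)
    assert est.n_binding_events >= 100
    frame_time = 1.0 * 1000
    assert est.k_on * frame_time == pytest.approx(k_on_true, rel=0.2)
    assert est.k_off * frame_time == pytest.approx(k_off_true, rel=0.2)


def test_censored_when_no_events():
    cfg = SimulationConfig(n_steps=100_000, save_interval=1000)
    traj = _synthetic_trajectory(np.zeros((100, 1, 3)), cfg, "unbound")
    est = estimate_kinetics([traj], dconf_series=[np.full(100, 20.0)])
    assert est.censored_on
    assert est.n_binding_events == 0
    assert est.k_on == pytest.approx(1.0 / (100 * cfg.dt * cfg.save_interval))


def test_rate_ratio_of_identical_ensembles_is_one():
    cfg = SimulationConfig(n_steps=50_000, save_interval=1000)
    series = [np.concatenate([np.full(10 + 3 * i, 10.0), np.full(40, 1.0)])[:50]
              for i in range(10)]
    trajs = [_synthetic_trajectory(np.zeros((50, 1, 3)), cfg, "unbound")
             for _ in range(10)]
    a = estimate_kinetics(trajs, dconf_series=series)
    b = estimate_kinetics(trajs, dconf_series=series)
    assert a.k_on / b.k_on == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ISR
# ---------------------------------------------------------------------------

def test_isr_constructed_gaussian_landscape():
    rng = np.random.default_rng(5)
    n = 4000
    e_native = np.full(400, -20.0)
    e_nonnative = rng.normal(-10.0, 2.0, n)
    e_nonnative = e_nonnative[e_nonnative < 0]
    energies = np.concatenate([e_native, e_nonnative])
    d1 = np.concatenate([np.full(400, 1.0), np.full(len(e_nonnative), 8.0)])
    d2 = d1.copy()
    m = compute_isr(energies, d1, d2, native_cut=3.0)
    assert m.delta_e == pytest.approx(10.0, rel=0.05)
    assert m.sigma_e == pytest.approx(2.0, rel=0.05)
    # independent spreadsheet-style recomputation of the full ISR
    nn = energies[(d1 > 3) & (energies < 0)]
    counts, _ = np.histogram(nn, bins=max(int(np.ceil((nn.max() - nn.min()) / 0.5)), 1))
    p = counts[counts > 0] / counts.sum()
    s = -(p * np.log(p)).sum()
    isr_oracle = abs(e_native.mean() - nn.mean()) / (nn.std() * np.sqrt(2 * s))
    assert m.isr == pytest.approx(isr_oracle, rel=1e-10)


def test_isr_scales_inversely_with_sigma():
    rng = np.random.default_rng(6)
    half = np.clip(rng.normal(0.0, 1.0, 2500), -3.9, 3.9)
    base = -10.0 + np.concatenate([half, -half])  # exactly symmetric about -10
    e1 = np.concatenate([np.full(100, -20.0), base])
    e2 = np.concatenate([np.full(100, -20.0), (base + 10) * 2 - 10])
    d1 = np.concatenate([np.full(100, 1.0), np.full(5000, 8.0)])
    m1 = compute_isr(e1, d1, d1)
    m2 = compute_isr(e2, d1, d1)
    # doubling sigma at fixed delta_e halves the gap-to-spread ratio
    assert (m1.delta_e / m1.sigma_e) / (m2.delta_e / m2.sigma_e) == pytest.approx(2.0, rel=1e-9)


def test_isr_error_conditions():
    d_nat = np.array([1.0, 1.0, 8.0, 8.0])
    with pytest.raises(ValueError, match="variance"):
        compute_isr(np.array([-20, -20, -5.0, -5.0]), d_nat, d_nat)
    with pytest.raises(ValueError, match="native"):
        compute_isr(np.array([-1.0, -2.0]), np.array([8.0, 8.0]), np.array([8.0, 8.0]))


# ---------------------------------------------------------------------------
# Lambda ratio
# ---------------------------------------------------------------------------

def test_lambda_ratio_synthetic_frames(toy_system, iface, monkeypatch):
    cfg = SimulationConfig(n_steps=4000, save_interval=1000, analysis_fraction=1.0)
    traj = _synthetic_trajectory([toy_system.coords0] * 4, cfg)
    import ssbind.analysis as ana

    monkeypatch.setattr(ana, "interface_energy",
                        lambda f, s: (type("B", (), {"electrostatic": -2.0,
                                                     "aromatic_stacking": -8.0,
                                                     "repulsion": 0.0})(), 0.25))
    lam = ana.lambda_ratio([traj], toy_system, iface)
    assert lam.value == pytest.approx(0.25)
    assert lam.label == ""


def test_lambda_very_high_without_aromatics(params):
    """A patch with no aromatic residues yields the 'very high' sentinel."""
    spec = ToyComplexSpec(sequence="TTTT", aromatic_sites=(), positive_sites=(0, 2),
                          n_scaffold=8)
    tc = make_toy_complex(spec, params)
    sys = build_system(tc.protein, tc.na, params)
    iface = identify_native_interface(sys)
    cfg = SimulationConfig(n_steps=2000, save_interval=1000, analysis_fraction=1.0)
    traj = _synthetic_trajectory([tc.reference] * 2, cfg)
    lam = lambda_ratio([traj], sys, iface)
    assert lam.label == "very high"
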