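# Methods

`ssbind` implements a transferable coarse-grained model for the binding
of single-stranded DNA or RNA to proteins, a Langevin sampler for the
binding process, and the statistics used to characterise the resulting
binding landscapes. This note records the model, its parameters, the
numerical choices, and what the synthetic test systems do and do not
establish.

## The model

### Protein

Each residue is reduced to a Cα bead plus a Cβ bead (glycine keeps only
Cα). The protein is held near its experimental structure by a Go-type
native topology:

* harmonic bonds `K_b (b − b⁰)²` with `K_b = 100 kcal mol⁻¹ Å⁻²` over
  consecutive Cα–Cα and intra-residue Cα–Cβ pairs;
* harmonic angles `K_a (θ − θ⁰)²`, `K_a = 20 kcal mol⁻¹ rad⁻²`;
* dihedrals over consecutive Cα quadruplets,
  `K_d [1 − cos(Δφ) − cos(3Δφ)]` with `K_d = 1 kcal/mol`;
* a 12-10 well `K[5(A/r)¹² − 6(A/r)¹⁰]` (depth −K at the native
  distance A) for every native contact, `K = 1 kcal/mol`;
* `(C_ij/r)¹²` excluded volume between all remaining bead pairs
  (radii: backbone 1.9 Å, side chain 1.5 Å);
* Debye–Hückel electrostatics between charged side-chain beads.

Lys/Arg carry +1 e and Asp/Glu −1 e on the Cβ bead. Histidine is
neutral by default; a flag or per-residue override list can protonate
it (this replaces pKa-server estimates with an explicit user decision).
Native contacts are heavy-atom pairs within 4.5 Å between residues at
least 3 apart in sequence, mapped to the representative bead (Cβ when
present, else Cα) — the standard cutoff recipe for structure-based
models; the rule and cutoff are config-exposed.

Reference values b⁰, θ⁰, φ⁰ and A are measured from the input
structure, so a freshly built model has exactly zero bond/angle strain
at its native coordinates, and each native dihedral contributes −K_d
(the printed dihedral form has its minimum at −K, not 0; a switch to
the conventional `(1 − cosΔφ) + ½(1 − cos3Δφ)` form is provided).

Residues whose B-factor exceeds the chain mean, or with missing
coordinates, get their local angle/dihedral stiffness multiplied by 0.5
(configurable): segments that are mobile in the crystal stay mobile in
the model. NMR structures use the same mechanism via the override
list.

### Single strand

Each nucleotide is three beads — phosphate (P, charge −1), sugar (S),
base (B) — at the geometric centers of the moieties. Connectivity:
bonds (Pᵢ–Sᵢ), (Sᵢ–Bᵢ), (Sᵢ–Pᵢ₊₁); angles (Pᵢ–Sᵢ–Bᵢ), (Bᵢ–Sᵢ–Pᵢ₊₁),
(Pᵢ–Sᵢ–Pᵢ₊₁), (Sᵢ–Pᵢ₊₁–Sᵢ₊₁); same force constants as the protein.
There are no native contacts and no intra-strand electrostatics — in
particular no P–P Debye–Hückel repulsion. Strand flexibility is
instead controlled by two dihedral families:

| family | beads | DNA | RNA |
|---|---|---|---|
| base–sugar | Bᵢ–Sᵢ–Sᵢ₊₁–Bᵢ₊₁ | 0.5 | 1.5 kcal/mol |
| backbone | Pᵢ–Pᵢ₊₁–Pᵢ₊₂–Pᵢ₊₃ | 0.3 | 0.9 kcal/mol |

Consecutive bases attract through a 12-10 stacking well of depth
−ε_B−B at r⁰ = 3.6 Å, with the sequence-dependent well depths
(kcal/mol): AA 1.4, TT 1.0, GG 1.8, CC 1.4, UU 0.9, AT 1.4, AG 1.8,
AC 1.5, TG 1.7, TC 1.4, GC 1.5, AU 1.3, GU 1.5, CU 1.3 — purines
strongest, pyrimidines weakest. Excluded volume applies between all
beads of non-adjacent nucleotides (radii: P 3.7, S 3.7, B 1.5 Å).
Intra-strand base-pairing is deliberately absent: the strands studied
are short, and several are homopolymeric.

The strand has no secondary-structure machinery; reference bond
lengths, angles and dihedrals come from an idealized single-strand
helical template (the conformation a strand adopts inside a duplex;
B-like for DNA, A-like for RNA) shipped as cylindrical bead
coordinates in `data/helix_templates.yaml`. Simulations start from
this (overall linear) conformation.

### Interface

The protein–strand interaction has exactly three terms:

* Debye–Hückel electrostatics between every charged Cβ bead and every
  phosphate bead;
* an aromatic stacking well (same 12-10 shape, r⁰ = 3.6 Å) between
  every aromatic side-chain bead (W, F, Y, H) and every base bead,
  with the pair-specific depth ε_B−AA;
* excluded volume between all remaining cross pairs (stacking pairs
  are excluded from repulsion).

Sequence specificity enters only through ε_B−AA (and ε_B−B). The
ε_B−AA table ships in `data/stacking_base_aromatic.yaml`: it is
constructed from solution-phase quantum-chemical stacked-dimer
magnitudes rescaled by 0.15 into the model's energy scale, ordered
F < H ≈ Y < W across residues and purine > pyrimidine across bases,
with uracil 9% below thymine. The per-pair numbers are synthetic
reconstructions consistent with those constraints (the file header
documents this); they are data, not code, and can be replaced wholesale.

### Electrostatics

Screened Coulomb: `E = k_C · B(κ) · q_i q_j · e^(−κr) / (ε_r r)` with
the Coulomb constant k_C = 332.0637 kcal Å mol⁻¹ e⁻², dielectric
ε_r = 70, and the Debye length computed from the salt concentration
(default 10 mM, 1:1 salt, 298 K → λ_D ≈ 28.7 Å).
`B(κ) = e^(κa)/(1 + κa)` with ion size a = 4 Å is the standard
Debye–Hückel salt-activity correction (≈1.01 at 10 mM). All constants
live in `data/forcefield.yaml`.

## Sampling

Langevin dynamics with a BAOAB splitting, unit bead masses, reduced
friction γ = 1, time step 0.005, and a reduced working temperature of
0.3. The reduced temperature is converted to kcal/mol through the
force field's energy unit ε₀ (`energy_unit` in the parameter file):
k_BT = T·ε₀ = 0.3 × 0.5 = 0.15 kcal/mol. At this temperature a built
protein fluctuates about its native fold without unfolding while a
strand explores its surface. The binding protocol places the strand, in its extended
conformation and with a random orientation, at one of six
axis-symmetric positions (± the protein's principal axes) with the
minimum inter-molecular bead distance in 35–40 Å, and runs many
replicas per placement, each with a unique seed (default protocol:
6 placements × 100 replicas × 10⁷ steps, frames saved every 10³ steps,
the final 20% of frames analysed). Identical (system, config, seed)
inputs reproduce trajectories bitwise. A bead moving more than 2 Å in
a single step marks the replica unstable; it is kept in the store but
flagged and excluded from analyses.

Integrator, friction and masses are the package's own choices (the
sampling protocol constrains only temperature, step count and time
step); equilibrium averages do not depend on friction or masses.
Binding campaigns default to γ = 1. The free-strand calibration runs
use γ = 0.2: block analysis of the 40-mer end-to-end statistics shows
several-fold faster relaxation at the lower friction (even so, the
ssDNA strand needs ~1.5×10⁶ steps to forget its extended start), and a
lower friction only rescales the dynamics, not the sampled ensemble.

## Strand-flexibility calibration

The persistence length is computed with the flexible-polymer estimator
`L_ps = <L·l₀>/<|l₀|>`, where l₀ is the 5′-end P–P bond vector and L
the end-to-end P–P vector. The dihedral stiffnesses per chemistry are
fixed at the values above and the templates keep canonical fiber-model
twists (36° B-like, 32.7° A-like); the one remaining free scale, the
reduced-unit energy ε₀, was calibrated to 0.5 kcal/mol so that a free
T₄₀ strand gives L_ps ≈ 30–33 Å and a free U₄₀ strand ≈ 42–44 Å (ssRNA
stiffer than ssDNA, as the SAXS comparisons require). The dihedral
constants are meaningful only relative to the thermal energy: at this
scale the ssDNA backbone dihedral (0.3) sits near its order–disorder
crossover — which is also why its persistence length responds strongly
to that constant — while the ssRNA constants (0.9/1.5) are deep in the
ordered regime, making U₄₀ both stiffer and far less variable. `scripts/acceptance.py` recomputes both
numbers from scratch. Single-strand end-to-end statistics are
intrinsically noisy (the end-to-end projection decorrelates over
several 10⁵ steps, and the crossover-regime ssDNA fluctuates between
locally ordered and disordered stretches), so the estimator pools
independently seeded chains and discards each chain's initial
relaxation window (10⁶ steps for ssDNA, 5×10⁵ for the ordered ssRNA).
Because a ssDNA chain can take a stochastic multi-10⁶-step excursion to
forget its starting basin, half of the ssDNA chains begin from the
extended template and half from a pivot-randomized coil
(`randomize_strand`), so the two one-sided initialization biases
largely cancel; ordered strands always start extended, which is
already their equilibrium. The default protocol is 10 × 2×10⁶ steps
for ssDNA and 3 × 3×10⁶ for ssRNA. Even so, desk-scale runs carry a
sampling error of roughly ±3 Å for ssDNA and ±2 Å for ssRNA;
individual runs scatter around the calibrated values at that level.

## Analysis statistics

* **Interface definition**: positive Cβ beads within 9 Å of any
  phosphate and aromatic Cβ beads within 9 Å of any base in the
  reference pose. Interfacial residues are split into two moieties by
  whether their nearest strand bead lies in the 5′ or 3′ half — the
  split rule is a package choice; any rule that partitions the
  interface into its two structural ends would do.
* **D_Site**: for each interfacial residue, the summed distances to all
  partner beads (phosphates for charged, bases for aromatic residues)
  are compared with the reference sums; D_Site is the mean absolute
  deviation normalised by the nucleotide count. It ignores strand
  direction.
* **D_Conf**: each base is paired with its nearest native aromatic
  residue and each phosphate with its nearest native positive residue;
  D_Conf is the mean absolute deviation of those pair distances, and
  is therefore sensitive to a 3′↔5′ flip. Both metrics are implemented
  with the absolute value inside the average so that 0 means identity
  and values behave as distances; both are invariant under rigid
  motion of the whole complex.
* **Free-energy surfaces**: 2-D histograms over (D¹, D²) converted to
  −k_BT ln p, minimum shifted to zero, empty bins flagged NaN.
* **E_bind**: mean ± sd of the interface energy (electrostatic +
  aromatic + repulsion) over analysis frames with both moiety D_Conf
  values ≤ 5 Å; an empty qualifying set is reported as an explicit
  empty result.
* **λ**: mean electrostatic over mean aromatic interface energy on the
  same near-native frames; when a component's mean magnitude is below
  0.5 kcal/mol the ratio is labelled "very low"/"very high" instead of
  quoted numerically.
* **Kinetics**: k_on is the inverse mean first-passage time of D_Conf
  dropping below 5 Å from an unbound start; k_off the inverse MFPT of
  crossing above 5 Å from a bound start. With zero events the rate is
  reported as a censored bound (1/total simulated time), never NaN.
* **ISR**: intrinsic specificity ratio δE/(ΔE√(2S)) with δE the gap
  between the mean native (both D_Conf ≤ 3 Å) and mean non-native
  binding energies, ΔE the non-native standard deviation over frames
  with negative binding energy, and S = −Σp ln p the entropy of the
  non-native energy histogram (0.5 kcal/mol bins, configurable).
  Entropy is computed with the conventional non-negative sign.

## Synthetic test systems

The fixtures module generates every input the tests need: homopolymer
strands, composition-preserving sequence shuffles, and a toy receptor —
a rigid plate of scaffold residues (densified contact map) carrying a
designed patch of aromatic and positively charged side-chain beads,
with a strand laid across it in an open bases-up pose at the stacking
and electrostatic contact distances. The toy strand takes its bonded
reference geometry from the designed pose (not the duplex template) so
the constructed complex is strain-free by construction; this is
flagged in the builder API and used only by synthetic systems.

What the toy systems establish: that the metrics, landscape, kinetics
and specificity code are correct against closed forms and brute-force
oracles, and that the simulator preserves a designed native pose.
What they do not establish: that the force field reproduces any real
protein's binding mode or affinity — that requires experimental
structures and the full 600 × 10⁷-step campaigns, which this package
supports but which are outside desk scale.

## Numerical choices and limitations

* Pair terms are truncated: Debye–Hückel at 3 Debye lengths, 12-10
  wells at 3 × (A or r⁰), repulsion at 1.8 × C_ij; the largest
  truncation error is below 10⁻³ of a well depth.
* The printed stacking expression with a leading minus sign would make
  stacking repulsive at its own reference distance; the wells are
  implemented attractive (depth −ε at r⁰), consistent with every
  binding-energy sign in the analyses.
* Degenerate geometry (collinear angle triples) raises rather than
  returning garbage forces; the kernel guards the singularity.
* Problem sizes in the test-suite and acceptance script (10⁵–10⁶-step
  strand runs, toy receptors of ~15–25 residues) were chosen as the
  smallest ensembles at which the statistics of interest stabilise;
  production studies of real systems should use the full protocol
  defaults.
* Modified nucleotides, RNA secondary structure, explicit ions,
  base-pairing and multi-domain induced-fit binders are out of scope.
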