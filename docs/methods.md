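# Methods

## Scope and model class

`pbsquench` implements incoherent hopping (Förster) kinetics of a single
excitation on a network of chromophores: phycocyanobilins (PCB) of the
phycobilisome rods and core, and the canthaxanthin (CAN) S₁ dark state of
PBS-bound orange carotenoid protein acting as the quencher. Coherent
effects, generalized Förster/modified Redfield corrections, multi-exciton
dynamics and annihilation are outside the model class. Quantum-chemical
quantities — site energies, transition-dipole moments (TDMs), transition
charges, coupling distributions — are *inputs*: the package consumes them,
it does not compute them.

## Couplings

Two coupling operators, selected per pigment-class pair:

* **Point-dipole approximation (PDA)**, used for every bilin–bilin pair:
  V = s·C·κ·μ₁μ₂/R³ with the orientation factor
  κ = û₁·û₂ − 3(û₁·R̂)(û₂·R̂) ∈ [−2, 2]. The constant
  C = D²/(4πε₀Å³hc) ≈ 5034.1 cm⁻¹·Å³·D⁻² is derived from CODATA values at
  import time (unit-tested against independent arithmetic), not hard-coded.
  The screening factor s defaults to 1 (vacuum); any effective-dielectric
  screening is the user's responsibility via configuration, since no single
  screening model is canonical for protein-embedded bilins.
* **Transition-charge Coulomb sum (TrEsp)**, used for the short CAN–ApcA
  contacts (center separations ~10–15 Å, comparable to the conjugated
  systems themselves, where the PDA is not justified):
  V = K·ΣᵢΣⱼ qᵢqⱼ/rᵢⱼ, K = e²/(4πε₀Å hc) ≈ 1.1614×10⁵ cm⁻¹·Å·e⁻².
  Transition-charge sets are validated on load: charges must sum to ~0
  (default tolerance 10⁻³ e) and may be checked against a declared TDM.

Only whitelisted CAN–bilin pairs (each carotenoid's two nearest ApcA
partners) carry nonzero coupling; every other CAN coupling is exactly zero,
reflecting the negligible contribution of the more distant contacts.
Instead of TrEsp evaluation, whitelisted couplings can be injected as
sampled values drawn from an ensemble distribution (the default pipeline
mode; see *Carotenoid parameter sampling*).

In the long-range limit the TrEsp sum converges to the PDA value; the test
suite checks < 1% relative deviation at 25× the charge-set extent, and the
two operators are never collapsed onto one another — the PDA serves as the
independent cross-check of the Coulomb sum.

## Lineshapes and spectral overlap

Lineshapes are sums of Gaussian vibronic components (offset from the 0-0
energy, weight, width σ) on a 1 cm⁻¹ wavenumber grid, normalized to unit
trapezoidal area; emission is the mirror image of absorption about the 0-0
energy. The overlap J = ∫f_D(ν)a_A(ν)dν then carries units of cm. The
trapezoidal integrator reproduces the analytic Gaussian-product overlap to
better than 0.1% for grid steps ≤ σ/10.

Default templates (editable in configuration):

* `pcb` — bilin band: 0-0 plus one vibronic satellite at 1300 cm⁻¹,
  weights 1.0/0.4, σ = 450 cm⁻¹.
* `can` — carotenoid S₁ band: 0-0 plus satellites at 1400 and 2800 cm⁻¹,
  weights 1.0/0.7/0.3, σ = 600 cm⁻¹.

Both are **surrogates**: the true CAN S₀→S₁ band shape is not measurable
directly (the transition is nominally dark), and practice in the field is
to borrow a keto-carotenoid emission profile and mirror it. The surrogate
parameters are plausible for such a progression but cannot be validated
against measured band shapes; conclusions that depend on the detailed
J values (rather than on their order of magnitude and energy-gap trends)
should be checked against user-supplied lineshapes.

## Rates and detailed balance

k = 1.18·V²·J (V in cm⁻¹, J in cm, k in ps⁻¹), the standard Förster
prefactor for these units. For each coupled pair the *downhill* direction
(higher → lower 0-0 site energy) is computed from the donor's mirror-image
emission and the acceptor's absorption; the uphill rate is
k↑ = k↓·exp(−Δε/k_BT) with Δε the 0-0 gap and k_B = 0.6950348 cm⁻¹/K.
Applying detailed balance on 0-0 gaps (not spectral maxima) gives each
pigment a single unambiguous energy and makes the stationary state of any
closed network exactly Boltzmann — verified against an eigen-solver oracle.
Computing the uphill overlap independently would break that exactness;
the package deliberately derives uphill rates from balance alone.

Temperature defaults to 300 K.

## Site-energy scheme (defaults, configurable)

| class | E₀₀ (cm⁻¹) | origin |
|---|---|---|
| ROD_PCB | 16130 | rod phycocyanin, ~620 nm |
| APCA_PCB, APCB_PCB | 15152 | 660 nm core emitters |
| APCD_PCB, APCE_PCB | 14706 | 680 nm terminal emitters |
| CAN | 16131 − 1400 (sampled) | see below |

Bilin intrinsic decay is 1/1600 ps⁻¹ (≈1.6 ns excited-state lifetime);
bilin TDMs are 7 D. The CAN S₁ intrinsic decay defaults to 0.25 ps⁻¹
(a ~4 ps carotenoid S₁ lifetime); a perfect-sink limit can be emulated by
raising this rate in configuration. Back-transfer CAN→bilin is allowed and
detailed-balanced.

**CAN 0-0 energy.** The carotenoid S₁ energies quoted from quantum-chemical
ensembles (mean 2.00 eV) are vertical excitation energies — they locate the
absorption-band maximum, not the 0-0 origin. Detailed balance, however,
operates on 0-0 energies. The sampler therefore converts each drawn
vertical energy to a 0-0 site energy by subtracting `e00_shift_cm1`
(default 1400 cm⁻¹, one vibronic quantum — the scale of the S₁
intramolecular relaxation). Without this distinction the carotenoid would
sit ~980 cm⁻¹ *above* the ApcA bilins and uphill suppression
(e^(−Δε/k_BT) ≈ 10⁻²) would contradict the efficient quenching the model
is meant to describe. The shift is exposed in configuration and its choice
is the single most influential surrogate parameter in the model.

## Carotenoid parameter sampling

Each ensemble run draws, independently for each of the four carotenoids:
S₁ vertical energy (truncated normal, mean 2.00 eV, sd 0.07 eV) and the two
CAN–ApcA couplings (truncated normals, means 54 and 27 cm⁻¹, sd 40% of the
mean). Ensemble means are anchored to the quantum-chemical averages; the
*spreads* are not published as numbers and are configuration, not claims —
the defaults give coefficient-of-variation comparable to the broad
distributions those ensembles display. Truncation at zero keeps draws
physical. An `empirical_samples` mode resamples a user-supplied table
instead. Sampling is verified by law-of-large-numbers mean checks and a
Kolmogorov–Smirnov test against the configured truncated normal.

## Stochastic dynamics and oracle

`gillespie_run` is an exact continuous-time Markov jump simulation: from
pigment i with total exit rate Λᵢ (intrinsic decay + all hops out), the
waiting time is Exponential(Λᵢ) and the channel is chosen with probability
proportional to its rate; a trajectory terminates at its decay event. Each
run's seed derives from the master seed through a counter-based
`SeedSequence` scheme, so runs are independent and individually replayable,
and a `DecayEnsemble` is a pure function of (network, sampler spec, n_runs,
master seed).

The master equation dp/dt = K·p (off-diagonal K_ji = transfer i→j,
diagonal = −total exit) is solved by matrix exponential for ≤200 pigments
and by an implicit stiff solver (Radau, rtol 10⁻¹⁰) above. It supplies the
independent oracle for the stochastic engine: survival curves agree within
binomial error, terminal-channel frequencies match the time-integrated flux
decomposition decayᵢ·[(−K)⁻¹p₀]ᵢ, and the ensemble mean lifetime matches
Σᵢ[(−K)⁻¹p₀]ᵢ.

**Lifetime estimator.** The reported lifetime is the arithmetic mean decay
time, which equals the area under the empirical survival curve and, for
fully observed decay times, the maximum-likelihood single-exponential time
constant; both numbers are reported so that censored or multi-exponential
variants can be distinguished later.

Only the carotenoid rows of the rate matrix depend on the per-run sampled
parameters, so the bilin–bilin block is built once per ensemble and reused;
spectral overlaps are memoized per (emission, absorption) lineshape pair.

## Synthetic antenna

The generator emulates the features of PBS architecture that matter for
quenching kinetics, not the architecture itself:

* a tri-cylindrical core (three cylinders of stacked 6-rings, 12 bilins
  each by default) holding ApcA/ApcB-class bilins plus one ApcD and one
  ApcE terminal emitter;
* six rods of six ROD_PCB bilins at 25 Å nearest-neighbour spacing, each
  anchored one spacing outside the outermost, dipole-aligned core pigment
  along its direction (so every rod has a genuine ~25 Å, κ-allowed contact
  with the core); rod dipoles are head-to-tail (κ ≈ −2), the efficient 1D
  transport arrangement — with in-plane core dipoles and a fixed docking
  radius, accidental κ ≈ 0 interfaces make transport, not quenching, rate
  limiting, which is a lattice artifact rather than antenna physics;
* core dipoles tangential to their ring with a 0.8·x̂ out-of-plane tilt,
  plus small seeded orientation jitter (8°) on all dipoles;
* four CAN quenchers placed 12 Å outside consecutive core ApcA pigments,
  each whitelisted to two ApcA partners (configurable attachment; attaching
  a CAN to a rod bilin is rejected — the OCP binds the core).

Geometry is deterministic given the configuration; the seed affects only
dipole jitter. What the toy does **not** reproduce: true per-disc pigment
counts and disc symmetry, linker-protein effects, the real distance and
orientation disorder, and the published PBS parametrization. Consequently,
passing tests on the toy demonstrate that the kinetics stack is correct and
that carotenoid attachment at published mean couplings shortens the antenna
lifetime many-fold (the default antenna gives a quenched mean lifetime of
roughly 100 ps versus the 1.6 ns unquenched baseline); they do not
demonstrate quantitative agreement with measurements on the real complex,
which requires the deposited coordinates and the full published
parametrization as inputs.

## Structure input

`read_structure` (gemmi-backed, PDB and mmCIF) extracts one pigment per
matched cofactor: position = centroid of the configured conjugated atoms,
dipole axis = principal axis of their second-moment tensor (sign fixed so
the largest-magnitude component is positive). The principal geometric axis
is a stand-in for the quantum-chemical TDM direction chosen for robustness
across cofactor-naming dialects; bilin ligand codes vary between entries,
so the extraction configuration must name them per file. Pigment classes
come from ligand code and chain identity (deterministic and auditable),
never from geometric inference. Ordering is by chain then residue number.

## Numerical choices and degenerate inputs

* Lineshape grids are auto-sized to cover every component to ±6σ in both
  absorption and emission orientation; a user grid narrower than ±5σ is an
  error. Disjoint overlap grids are an error, distinct from J ≈ 0.
* Coincident atoms (TrEsp) and coincident pigments (PDA) are errors naming
  the offending pair; degenerate geometry (< 3 points or zero extent)
  rejects the axis fit.
* A reachable pigment with zero total exit rate makes a trajectory
  non-terminating and is rejected up front by a reachability check.
* Gillespie channel selection uses per-pigment cumulative rate tables with
  binary search; waiting times use the inverse-transform exponential of
  numpy's PCG64 generator.
* Probability conservation of the master-equation solution (population +
  cumulative decayed mass = 1) is tested to 10⁻⁴ on a fine grid.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the default 76-pigment
synthetic antenna with ensembles of 10²–10³ trajectories, the
oracle-equivalence checks with 10⁴ trajectories on ≤6-pigment networks,
and 10⁴–10⁵ draws for sampler statistics. These sizes give Monte Carlo
errors well below the tested tolerances while keeping a full run of the
suite in tens of seconds.

## Known limitations

* All quantum-chemical inputs are surrogate parameters unless the user
  supplies ensemble data; the CAN lineshape and the vertical→0-0 shift are
  the dominant unvalidated choices.
* Vacuum couplings (s = 1) likely overestimate screened couplings in the
  protein by a factor ~1/ε_eff.
* The point-dipole bilin network ignores extended-dipole corrections at
  the shortest bilin–bilin contacts.
* Single-exciton kinetics only; no annihilation, no light-driven source
  terms, no time-dependent OCP binding/unbinding.
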