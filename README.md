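# pbsquench

Förster energy-transfer modelling of carotenoid quenching in the
cyanobacterial phycobilisome (PBS).

Under high light, cyanobacteria protect their photosynthetic machinery by
docking the activated orange carotenoid protein (OCP) onto the PBS core,
where the dark S₁ state of its bound keto-carotenoid (canthaxanthin, CAN)
drains excitation energy from the allophycocyanin bilins and dissipates it
as heat. `pbsquench` is a library and command-line tool for quantifying that
quenching: it turns pigment geometry and transition properties into
electronic couplings, Förster hopping rates and ensemble stochastic
simulations of excited-state decay, for structural photosynthesis
researchers who want a transparent, fully reproducible kinetic model of
OCP-mediated non-photochemical quenching.

## The model

* **Couplings.** Bilin–bilin couplings use the point-dipole approximation,
  V = s·C·κ·μ₁μ₂/R³ (μ in debye, R in Å, κ = û₁·û₂ − 3(û₁·R̂)(û₂·R̂),
  C ≈ 5034 cm⁻¹·Å³·D⁻² from vacuum constants). The short CAN–ApcA contacts,
  where a point dipole is not justified, use the transition-charge (TrEsp)
  Coulomb sum V = K·ΣᵢΣⱼ qᵢqⱼ/rᵢⱼ (q in e, r in Å, K ≈ 1.1614×10⁵ cm⁻¹·Å·e⁻²)
  or externally sampled coupling values; all other carotenoid couplings are
  exactly zero.
* **Rates.** Pairwise Förster rates k = 1.18·V²·J (V in cm⁻¹; J in cm, the
  overlap integral of unit-area donor-emission and acceptor-absorption
  lineshapes; k in ps⁻¹). Emission is the mirror image of absorption about
  the 0-0 energy. The downhill direction is computed from the overlap; the
  uphill partner follows detailed balance, k↑ = k↓·exp(−Δε/k_BT), so every
  closed network relaxes exactly to Boltzmann populations.
* **Dynamics.** A single exciton performs a continuous-time Markov jump
  process on the rate network (Gillespie algorithm). Each ensemble run
  starts from a random rod bilin and independently resamples each
  carotenoid's S₁ energy (mean 2.00 eV) and its two ApcA couplings
  (means 54 and 27 cm⁻¹) from truncated normal distributions. A
  matrix-exponential master-equation solver provides an independent
  deterministic oracle.
* **Synthetic antenna.** A built-in generator emulates the PBS topology —
  a tri-cylindrical allophycocyanin core, six radiating phycocyanin rods
  and four core-attached carotenoids — so the full pipeline runs and is
  tested without any downloaded structure. Real structures are read from
  PDB/mmCIF via gemmi.

## Worked example

```sh
pbsquench simulate -c example.yaml
```

with

```yaml
# example.yaml
toy:
  n_rods: 6
  pigments_per_rod: 6
  n_can: 4
simulation:
  n_runs: 500
  master_seed: 42
output: run42
```

prints

```
mean lifetime: 104.6 ± 5.0 ps over 500 runs
single-exponential fit: 104.6 ps
quench fraction (terminating on CAN): 0.934
outputs in run42
```

The mean excited-state lifetime of the quenched antenna (~100 ps here)
is the area under the ensemble survival curve; the quench fraction is the
share of excitons whose terminal decay happened on a carotenoid rather than
as bilin fluorescence/internal conversion. Setting `n_can: 0` in the same
configuration yields the unquenched antenna, whose lifetime is the intrinsic
bilin excited-state lifetime (~1.6 ns). The output directory contains the
pigment table, coupling matrix, mean-parameter rate matrix, per-run decay
times, the survival curve with confidence band, and a manifest recording the
configuration hash, seeds and all sampled carotenoid parameters, so any run
is exactly reproducible.

Other subcommands: `pbsquench couplings` (coupling matrix only),
`pbsquench extract` (pigment table from a PDB/mmCIF structure),
`pbsquench toy` (synthetic network export) and `pbsquench validate`
(internal consistency checks against analytic and master-equation oracles).

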