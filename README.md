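# oxytraj

Trajectory statistics and spin-crossing kinetics for gas migration in
enzymes.

Cofactor-independent oxygenases must deliver a ground-state triplet O₂
molecule through the protein matrix to a small reactive pocket and then
react with a singlet substrate — a spin-forbidden step. Understanding how
such an enzyme handles O₂ therefore requires answering, from molecular
dynamics trajectories and from electronic-structure inputs, four different
kinds of question:

* **Where does the gas go?** — 3-D occupancy densities of the sampled gas
  positions, connected high-density clusters (pockets) with volumes and
  probability masses, free energies by Boltzmann inversion
  `G = −k_BT ln(p/p_max)`, metadynamics-style reweighting
  (`w ∝ exp(+V_bias/k_BT)`), and entry barriers as the bottleneck
  (minimax) free energy along the best voxel path between two pockets.
* **How long does it stay?** — residence events at a spherical region
  detected with a hysteresis (inner/outer radius) rule, right-censored at
  the observation cutoff; escape rates by the censored-exponential MLE
  `k_off⁻¹ = Σtᵢ / n_escapes` and by least-squares fitting of
  `1 − exp(−t/τ)` to the cumulative escape fraction; and the closed-form
  truncated mean `E[T | T < c] = m − c·e^(−c/m)/(1 − e^(−c/m))` linking
  the fitted `k_off⁻¹` to the mean one observes over escaped events.
* **In which conformation?** — side-chain χ1 (N–CA–CB–OG) rotamer series
  classified into *plus* (+60°), *trans* (180°) and *minus* (−60°),
  replica-averaged histograms, rotamer fractions conditioned on gas
  occupancy, and per-atom RMSF after iterative mean-structure
  superposition.
* **Is the spin flip rate limiting?** — the nonadiabatic correction
  `ΔG‡ += −k_BT ln(p)` for a triplet→singlet hopping probability `p`,
  compared against the competing adiabatic barrier, plus a documented
  double-passage Landau–Zener utility.

Because microsecond MD is not reproducible at desk scale, the package
includes a first-class synthetic-trajectory generator (`oxytraj.synthgen`)
with the statistical structure the analyses assume — a continuous-time
Markov chain hopping between pockets, exponential escape with censoring, a
hidden two-state rotamer chain with von Mises χ1 emission — so that every
stage is validated against analytic truths. See `docs/methods.md`.

Intended users: computational structural biologists analysing small-ligand
(O₂, CO, NO, Xe, water) migration in protein simulations.

## Worked example

Regenerate the full synthetic study from one seed:

```sh
oxytraj demo --seed 1 --out demo_out
```

The report (`demo_out/report.json`) from this exact command contains,
among others:

```
occupancy   sites I/II/III with volumes 31.2 / 18.6 / 12.1 Å³ and
            probability masses 0.352 / 0.173 / 0.090; site I → II
            bottleneck barrier 1.37 kcal/mol
residence   30 runs, 29 escapes (96.7%), uncensored mean 17.2 ± 2.5 ns,
            k_off⁻¹ = 18.9 ± 3.5 ns (censored MLE), 19.4 ns (cumulative
            fit), predicted uncensored mean 15.1 ns
rotamer     trans fraction 0.922 with the gas at the reactive pocket vs
            0.612 without — the occupancy-coupled shift from a bimodal to
            a trans-dominated distribution
spincross   correction 3.14 kcal/mol at p = 0.005, effective barrier
            10.2 + 3.14 = 13.34 > 10.8 kcal/mol → verdict "ISC-limiting"
```

The generator's true escape kinetics here are `k_off⁻¹ = 15 ns` with a
50 ns cutoff, so the run above illustrates both the estimators and their
finite-`n` scatter (30 runs). The same quantities are available from the
library:

```python
from oxytraj.spincross import SpinCrossingParams, effective_barrier
r = effective_barrier(SpinCrossingParams(hop_probability=0.005,
                                         e_mecp=10.2, e_competing=10.8))
print(r.correction_kcal_mol)   # 3.139166571140289
print(r.verdict)               # ISC-limiting
```

Individual stages are also exposed as subcommands (`oxytraj generate`,
`occupancy`, `residence`, `rotamer`, `rmsf`, `spincross`, `report`); run
any with `--help`.

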