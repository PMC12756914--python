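# avidmc

Monte Carlo simulation of multivalent nanoparticle–membrane adhesion, with
free-energy decomposition and superselectivity analysis.

## The scientific problem

Ligand-coated nanoparticles (NPs) bind cell membranes through many
individually reversible ligand–receptor bonds.  How strongly — and how
*selectively* with respect to receptor density — a particle binds depends
on an interplay of particle mechanics (rigid sphere vs. tether-coated vs.
soft core–shell), membrane mechanics (excess area / tension), monovalent
bond strength, and receptor expression.  `avidmc` is aimed at researchers
in nanomedicine and membrane biophysics who want to explore that design
space with an equilibrium statistical-mechanics model rather than all-atom
simulation.

The model couples:

* a **triangulated fluid membrane** with the Helfrich Hamiltonian
  E = (κ/2)∫(2H)² dA plus an area term, periodic in-plane, with excess
  area A_ex = (A − A_p)/A imposed in the 6–20 % range (κ = 20 k_BT);
* **mobile flexural-rod receptors** (length 19 nm, rigidity 7000 pN·nm²)
  diffusing on the surface;
* **four NP mechanical classes** — rigid (RG), semirigid with ligand
  tethers (SRG), and deformable bead–spring core–shell particles without
  (LSt) and with (HSt) internal crosslinking — each carrying up to
  N_l = 162 ligands;
* a **Bell bond potential** ΔG₀ + ½k_b(d − d₀)² for each ligand–receptor
  pair, with strong/intermediate/weak binder systems
  (ΔG₀ = −19.1/−11.45/−1.76 k_BT).

Sampling is Metropolis Monte Carlo with configurational-bias
(Rosenbluth-weighted) bond moves; see `docs/methods.md` for the model and
sampler in full.  Observables are the multivalency distribution P(m) and
its mean ⟨m⟩, the ligand coverage θ = ⟨m⟩/N_l, the selectivity index
α = d lnθ/d lnN_r (α ≥ 1 ⇒ superselective), and the decomposition
ΔF = ΔH − TΔS with particle/membrane/receptor entropy components.

## Worked example

Sample the small deformable particle with abundant receptors — the
ligand-limited regime — and summarize its multivalency:

```python
import copy
from avidmc import mc_engine as eng
from avidmc.system_builder import desk_fixture
from avidmc.thermo_analysis import multivalency_distribution, coverage_theta

system = desk_fixture("mini_LSt_strong_highNr")   # 10 ligands, 40 receptors
sched = copy.deepcopy(system.schedule)
sched.equilibration_steps, sched.production_steps = 120_000, 200_000
traj = eng.run_mc(system, sched, seed=11)

support, p, mean_m, modes = multivalency_distribution(
    traj.m_series, m_max=system.nano.n_ligands)
print(f"<m> = {mean_m:.2f}, modes at {modes}, "
      f"theta = {coverage_theta(mean_m, system.nano.n_ligands):.2f}")
```

Output:

```
<m> = 9.89, modes at [10], theta = 0.99
```

The distribution is sharply peaked at m = 10 — every ligand engaged: the
soft particle flattens against the membrane and saturates its own ligand
capacity.  Running the `mini_LSt_strong_lowNr` fixture (4 receptors)
instead peaks at m = 4 (receptor-limited saturation), while the rigid
particle fixture under the same strong binder averages ⟨m⟩ ≈ 5 of its 162
ligands (~3 % of capacity) and under the intermediate binder stays near
⟨m⟩ ≈ 0.

The numbered drivers under `analysis/` run the full desk-scale study:
system building and validation (`01`, `02`), the multivalency sweep over
particle classes and binders (`03`), the ΔF = ΔH − TΔS decomposition
(`04`), and the (A_ex, N_r) phase diagram with Welch/Benjamini–Hochberg
row contrasts (`05`); each writes tables under `results/`.  A thin CLI
(`avidmc build|run|analyze|phase-diagram|fixtures`) wraps the same
library calls for config-file-driven runs.

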