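"""Desk-scale mechanics-affinity phase diagram for the deformable particle.

Sweeps the (A_ex, N_r) grid for the small low-stiffness particle under
strong binding, computes per-tile dF (replica mean +- SD), coverage theta,
the selectivity index alpha along each excess-area row, and the
Welch/Benjamini-Hochberg row contrasts, then renders the tile figure and a
machine-readable table.  Writes results/phase_diagram/.
"""

import copy
import pathlib
import time

import numpy as np

from avidmc import io_cli, mc_engine as eng
from avidmc.system_builder import _mini_system, _small_coreshell
from avidmc.thermo_analysis import (PhaseTile, analyze_ensembles,
                                    build_phase_diagram, coverage_theta,
                                    selectivity_index, welch_bh_contrast)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "phase_diagram"
OUT.mkdir(parents=True, exist_ok=True)

A_EX_ROWS = (0.06, 0.20)
N_R_COLS = (2, 6, 20, 40)          # desk-scale receptor counts per patch
SEEDS = [11, 22, 33]
EQUIL, PROD = 60_000, 100_000

t0 = time.time()
theta_grid = {}
dF_samples = {}
for a_ex in A_EX_ROWS:
    for n_r in N_R_COLS:
        system = _mini_system("strong", n_r, 120.0, _small_coreshell(0.0),
                              a_ex=a_ex)
        sched = copy.deepcopy(system.schedule)
        sched.equilibration_steps, sched.production_steps = EQUIL, PROD
        sched.sample_interval, sched.record_interval = 200, 500
        bound = eng.run_replicas(system, sched, SEEDS)
        unbound = eng.EnsembleResult(
            [eng.run_unbound_reference(system, sched, s + 5) for s in SEEDS],
            [s + 5 for s in SEEDS])
        res = analyze_ensembles(bound, unbound, system)
        n_l = system.nano.n_ligands
        theta_grid[(a_ex, n_r)] = coverage_theta(res.mean_m, n_l)
        dF_samples[(a_ex, n_r)] = (
            bound.replica_means("total") - unbound.replica_means("total"))
        print(f"A_ex={a_ex:.0%} N_r={n_r:3d}: theta="
              f"{theta_grid[(a_ex, n_r)]:.2f} dF={res.dF:.1f} k_BT", flush=True)

# row contrasts with BH control across the whole diagram
pv, qv, reject, favors = welch_bh_contrast(
    [dF_samples[(0.20, n)] for n in N_R_COLS],
    [dF_samples[(0.06, n)] for n in N_R_COLS])

tiles = []
for a_ex in A_EX_ROWS:
    thetas = np.array([theta_grid[(a_ex, n)] for n in N_R_COLS])
    alpha, valid = selectivity_index(np.array(N_R_COLS, float), thetas)
    for j, n_r in enumerate(N_R_COLS):
        tiles.append(PhaseTile(
            a_ex=a_ex, n_r=n_r,
            dF=float(np.mean(dF_samples[(a_ex, n_r)])),
            dF_sd=float(np.std(dF_samples[(a_ex, n_r)], ddof=1)),
            theta=thetas[j], alpha=float(alpha[j]) if valid[j] else None,
            alpha_valid=bool(valid[j]), q_value=float(qv[j])))

df, fig = build_phase_diagram(
    tiles, expected_grid=[(a, n) for a in A_EX_ROWS for n in N_R_COLS])
fig.savefig(OUT / "phase_diagram.png", dpi=150)
manifest = io_cli.RunManifest(config={"a_ex": A_EX_ROWS, "n_r": N_R_COLS},
                              seeds=SEEDS)
io_cli.write_outputs({"tiles": df}, manifest, OUT, overwrite=True)
print()
print(df.to_string(index=False))
print(f"\ntotal {time.time() - t0:.0f}s; figure and tile table in {OUT}")
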