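"""Metropolis Monte Carlo orchestration.

One "MC step" is one attempted elementary move, drawn from a configured
move mix:

``vertex``
    out-of-plane displacement of one membrane vertex;
``hop``
    lateral diffusion hop of one receptor anchor;
``np_rigid``
    rigid-body translation+rotation trial of the nanoparticle;
``np_bead``
    single-bead (or ligand-tip) displacement for deformable particles;
``bond``
    configurational-bias bond formation/breakage.

Move amplitudes are auto-tuned toward a 30-50% acceptance band during
equilibration and frozen for production.  Energy components are tracked
incrementally (each move computes its exact local energy change) and
re-synchronized against a full recomputation at a configurable interval.
Identical (system, schedule, seed) yield bit-identical trajectories.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import binding as bd
from . import membrane as mb

__all__ = [
    "McSchedule",
    "Trajectory",
    "EnsembleResult",
    "metropolis_accept",
    "total_energy",
    "run_mc",
    "run_replicas",
    "run_unbound_reference",
    "DESK_SCHEDULE",
    "FULL_SCHEDULE",
]

MOVE_TYPES = ("vertex", "hop", "np_rigid", "np_bead", "bond")


@dataclass
class McSchedule:
    """Move mix, step counts and sampling grid for one MC run."""

    move_mix: Dict[str, float] = field(default_factory=lambda: {
        "vertex": 0.35, "hop": 0.25, "np_rigid": 0.10,
        "np_bead": 0.15, "bond": 0.15})
    equilibration_steps: int = 40_000
    production_steps: int = 120_000
    sample_interval: int = 100
    record_interval: int = 1_000          # fluctuation-record stride
    n_replicas: int = 4
    amplitudes: Dict[str, float] = field(default_factory=lambda: {
        "vertex": 1.2, "hop": 8.0, "np_trans": 1.5,
        "np_rot": 0.08, "bead": 2.0, "pivot": 0.5})
    auto_tune: bool = True
    resync_interval: int = 20_000

    def __post_init__(self) -> None:
        bad = [k for k in self.move_mix if k not in MOVE_TYPES]
        if bad:
            raise ValueError(f"unknown move types {bad}")
        tot = sum(self.move_mix.values())
        if tot <= 0 or any(v < 0 for v in self.move_mix.values()):
            raise ValueError("move frequencies must be positive")
        self.move_mix = {k: v / tot for k, v in self.move_mix.items()}
        if self.production_steps and self.sample_interval > self.production_steps:
            raise ValueError("production_steps must be >= sample_interval")

    def scaled(self, factor: float) -> "McSchedule":
        """Proportionally scaled step counts (desk-scale derivation)."""
        return replace(
            self,
            equilibration_steps=int(self.equilibration_steps * factor),
            production_steps=int(self.production_steps * factor),
        )


#: desk-scale default (minutes on one CPU)
DESK_SCHEDULE = McSchedule()
#: nominal full-scale protocol (relaxation then sampling; the separate
#: membrane/NP pre-equilibration is performed by the system builder)
FULL_SCHEDULE = McSchedule(
    equilibration_steps=500_000_000, production_steps=1_000_000_000,
    sample_interval=100_000, record_interval=1_000_000)


@dataclass
class Trajectory:
    """Sampled observables of one MC run (shared sampling grid)."""

    m_series: np.ndarray                      # bond counts
    energy_series: Dict[str, np.ndarray]      # per-component, k_BT
    nano_frames: np.ndarray                   # (F, n_internal, 3) bead+tip coords
    mesh_z_frames: np.ndarray                 # (F, N_v) vertex heights
    receptor_xy_frames: np.ndarray            # (F, N_r, 2)
    acceptance: Dict[str, float]
    attempted: Dict[str, int]
    seed: int
    n_ligands: int
    n_receptors: int
    final_amplitudes: Dict[str, float] = field(default_factory=dict)

    @property
    def mean_m(self) -> float:
        return float(self.m_series.mean()) if self.m_series.size else 0.0

    def mean_energy(self, component: str = "total") -> float:
        e = self.energy_series[component]
        return float(e.mean()) if e.size else 0.0


@dataclass
class EnsembleResult:
    """Replica trajectories plus per-quantity replica SDs."""

    trajectories: List[Trajectory]
    seeds: List[int]

    @property
    def n_replicas(self) -> int:
        return len(self.trajectories)

    def replica_means(self, component: Optional[str] = None) -> np.ndarray:
        if component is None:
            return np.array([t.mean_m for t in self.trajectories])
        return np.array([t.mean_energy(component) for t in self.trajectories])

    def mean_and_sd(self, component: Optional[str] = None):
        v = self.replica_means(component)
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    def pooled_m(self) -> np.ndarray:
        return np.concatenate([t.m_series for t in self.trajectories])


def metropolis_accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/k_BT))."""
    if not math.isfinite(delta_e):
        if math.isnan(delta_e):
            raise ValueError("non-finite energy change")
        return delta_e < 0
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e)


# ---------------------------------------------------------------------------
# global energy
# ---------------------------------------------------------------------------

def total_energy(system) -> Dict[str, float]:
    """Full recomputation of every energy component (k_BT)."""
    comps = {
        "bending": mb.bending_energy(system.mesh),
        "area": mb.area_energy(system.mesh, mb.total_area(system.mesh)),
        "np_internal": 0.0,
        "overlap": 0.0,
        "bond": 0.0,
        "restraint": 0.0,
    }
    if system.nano is not None:
        from .nanoparticle import np_internal_energy
        comps["np_internal"] = np_internal_energy(system.nano)
        comps["overlap"] = (system.mesh_np_overlap_energy()
                            + system.tip_penalty_energy())
        comps["restraint"] = system.restraint_energy()
        comps["bond"] = float(np.sum(system.bound_bond_energies()))
    comps["total"] = sum(comps.values())
    return comps


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Runner:
    """Mutable sampling state for one trajectory."""

    def __init__(self, system, schedule: McSchedule, seed: int):
        self.sys = system
        self.sched = schedule
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.amp = dict(schedule.amplitudes)
        self.energy = total_energy(system)
        self.area = mb.total_area(system.mesh)
        self.attempted = {k: 0 for k in MOVE_TYPES}
        self.accepted = {k: 0 for k in MOVE_TYPES}
        self.win_att = {k: 0 for k in MOVE_TYPES}
        self.win_acc = {k: 0 for k in MOVE_TYPES}
        keys = list(self.sys.schedule_move_keys(schedule.move_mix))
        probs = np.array([schedule.move_mix[k] for k in keys])
        self.move_keys = keys
        self.move_cum = np.cumsum(probs / probs.sum())

    # -- elementary moves -------------------------------------------------
    def _move_vertex(self) -> bool:
        s = self.sys
        mesh = s.mesh
        v = int(self.rng.integers(mesh.n_vertices))
        disp = np.array([0.0, 0.0, self.rng.uniform(-self.amp["vertex"],
                                                    self.amp["vertex"])])
        res = mb.vertex_move(mesh, v, disp, current_area=self.area)
        if not res.ok:
            return False
        d_e = res.delta_energy
        d_bend_area = d_e
        # membrane-NP overlap change for this vertex
        d_ov = 0.0
        if s.nano is not None:
            new_vpos = mesh.vertices[v] + disp
            d_ov = (s.vertex_overlap_energy(new_vpos)
                    - s.vertex_overlap_energy(mesh.vertices[v]))
        # receptors / tips whose containing triangle touches v
        rec_aff = np.nonzero(np.any(s.rec_nodes == v, axis=1))[0]
        tip_aff = (np.nonzero(np.any(s.tip_nodes == v, axis=1))[0]
                   if s.nano is not None else np.zeros(0, dtype=int))
        d_bond = 0.0
        d_tip = 0.0
        if rec_aff.size or tip_aff.size:
            zv = mesh.vertices[:, 2].copy()
            zv[v] += disp[2]
            if rec_aff.size:
                bound_aff = rec_aff[s.receptors.bound_partner[rec_aff] >= 0]
                if bound_aff.size:
                    e_old = s.bound_bond_energies(bound_aff).sum()
                    e_new = s.bound_bond_energies(bound_aff, z_override=zv).sum()
                    d_bond = float(e_new - e_old)
            if tip_aff.size:
                z_new = np.einsum("qk,qk->q", s.tip_weights[tip_aff],
                                  zv[s.tip_nodes[tip_aff]])
                d_tip = float(
                    s.tip_penalty_energy(tip_idx=tip_aff, surf_z=z_new)
                    - s.tip_penalty_energy(tip_idx=tip_aff))
        d_total = d_bend_area + d_ov + d_bond + d_tip
        if not metropolis_accept(d_total, self.rng):
            return False
        mesh.vertices[v, 2] += disp[2]
        self.area += res.delta_area
        if rec_aff.size:
            s.refresh_receptor_heights(rec_aff)
        if tip_aff.size:
            s.refresh_tip_heights(tip_aff)
        e = self.energy
        e["bending"] += d_e - (mb.area_energy(mesh, self.area)
                               - mb.area_energy(mesh, self.area - res.delta_area))
        e["area"] = mb.area_energy(mesh, self.area)
        e["overlap"] += d_ov + d_tip
        e["bond"] += d_bond
        e["total"] += d_total
        return True

    def _move_hop(self) -> bool:
        s = self.sys
        n = s.receptors.n_receptors
        if n == 0:
            return False
        idx = int(self.rng.integers(n))
        prop = bd.receptor_hop_move(s, idx, self.amp["hop"], self.rng)
        if not metropolis_accept(prop.delta_energy, self.rng):
            return False
        s.receptors.anchors_xy[idx] = prop.new_xy
        s.install_receptor_sample(idx, prop.sample)
        self.energy["bond"] += prop.delta_energy
        self.energy["total"] += prop.delta_energy
        return True

    def _move_np_rigid(self) -> bool:
        s = self.sys
        nano = s.nano
        t = self.rng.uniform(-self.amp["np_trans"], self.amp["np_trans"], 3)
        axis = self.rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        ang = self.rng.uniform(-self.amp["np_rot"], self.amp["np_rot"])
        from .nanoparticle import np_rigid_body_move
        trial = np_rigid_body_move(nano, t, Rotation.from_rotvec(ang * axis))
        bound_tips = np.where(s.ligand_bound >= 0)[0]
        hold_tips = nano.tips_mobile and bound_tips.size > 0
        if hold_tips:
            # stiff bonds pin tip<->receptor; the body couples to them
            # through the soft ligand linkers, which stretch instead
            trial.tips[bound_tips] = nano.tips[bound_tips]
        d_e, parts = s.np_interaction_delta(trial, internal_changed=hold_tips)
        if not math.isfinite(d_e) or not metropolis_accept(d_e, self.rng):
            return False
        s.nano = trial
        s.refresh_tip_cache()
        self.energy["overlap"] += parts["overlap"]
        self.energy["bond"] += parts["bond"]
        self.energy["restraint"] += parts["restraint"]
        self.energy["np_internal"] += parts.get("np_internal", 0.0)
        self.energy["total"] += d_e
        return True

    def _move_np_bead(self) -> bool:
        s = self.sys
        nano = s.nano
        n_b, n_t = nano.n_beads, (nano.n_ligands if nano.tips_mobile else 0)
        if n_b + n_t == 0:
            return False
        if n_b and nano.arm_of_bead.size and self.rng.random() < 0.25:
            # whole-arm pivot about the core: the large-scale conformational
            # move (flattening against the membrane)
            arm = int(self.rng.integers(nano.arm_of_bead.max() + 1))
            axis = self.rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            ang = self.rng.uniform(-self.amp["pivot"], self.amp["pivot"])
            d_e, parts, apply = s.arm_pivot_delta(
                arm, Rotation.from_rotvec(ang * axis))
        else:
            k = int(self.rng.integers(n_b + n_t))
            disp = self.rng.uniform(-self.amp["bead"], self.amp["bead"], 3)
            if k < n_b:
                d_e, parts, apply = s.bead_move_delta(k, disp)
            else:
                d_e, parts, apply = s.tip_move_delta(k - n_b, disp)
        if not math.isfinite(d_e) or not metropolis_accept(d_e, self.rng):
            return False
        apply()
        for key, val in parts.items():
            self.energy[key] += val
        self.energy["total"] += d_e
        return True

    def _move_bond(self) -> bool:
        s = self.sys
        if not s.bonds_enabled:
            return False
        res = bd.cbmc_bond_move(s, self.rng)
        if not res.accepted:
            return False
        if res.parts is not None:
            for key, val in res.parts.items():
                self.energy[key] += val
        else:
            self.energy["bond"] += res.delta_energy
        self.energy["total"] += res.delta_energy
        return True

    _DISPATCH = {"vertex": _move_vertex, "hop": _move_hop,
                 "np_rigid": _move_np_rigid, "np_bead": _move_np_bead,
                 "bond": _move_bond}

    # -- driver -----------------------------------------------------------
    def step(self) -> None:
        kind = self.move_keys[
            min(int(np.searchsorted(self.move_cum, self.rng.random())),
                len(self.move_keys) - 1)]
        self.attempted[kind] += 1
        self.win_att[kind] += 1
        ok = self._DISPATCH[kind](self)
        if ok:
            self.accepted[kind] += 1
            self.win_acc[kind] += 1

    _AMP_OF = {"vertex": "vertex", "hop": "hop", "np_rigid": "np_trans",
               "np_bead": "bead"}

    def tune(self) -> None:
        for kind, amp_key in self._AMP_OF.items():
            att = self.win_att[kind]
            if att < 50:
                continue
            rate = self.win_acc[kind] / att
            if rate < 0.30:
                self.amp[amp_key] *= 0.85
                if kind == "np_rigid":
                    self.amp["np_rot"] *= 0.85
            elif rate > 0.50:
                self.amp[amp_key] *= 1.15
                if kind == "np_rigid":
                    self.amp["np_rot"] *= 1.15
            self.win_att[kind] = 0
            self.win_acc[kind] = 0
        # keep amplitudes physically sensible
        if self.sys.mesh.box is not None:
            self.amp["hop"] = min(self.amp["hop"], self.sys.mesh.box / 4.0)
        self.amp["np_rot"] = min(self.amp["np_rot"], math.pi)

    def resync(self) -> None:
        self.energy = total_energy(self.sys)
        self.area = mb.total_area(self.sys.mesh)


def run_mc(system, schedule: McSchedule, seed: int,
           inplace: bool = False) -> Trajectory:
    """Equilibrate then sample one trajectory.  Deterministic per seed.

    The input system is left untouched unless ``inplace=True``.
    """
    sys_ = system if inplace else copy.deepcopy(system)
    # nucleation scaffold: a soft z-restraint keeps the particle near its
    # initial (near-membrane) height while the first bonds form; it is
    # removed before production, so sampled statistics are unbiased
    scaffold = (sys_.nano is not None and sys_.np_restraint is None
                and getattr(sys_, "equil_scaffold", True)
                and schedule.equilibration_steps > 0)
    if scaffold:
        sys_.np_restraint = (float(sys_.nano.core_center[2]), 0.02)
    runner = _Runner(sys_, schedule, seed)
    tune_interval = 2_000

    for i in range(schedule.equilibration_steps):
        runner.step()
        if schedule.auto_tune and (i + 1) % tune_interval == 0:
            runner.tune()
        if (i + 1) % schedule.resync_interval == 0:
            runner.resync()
    if scaffold:
        sys_.np_restraint = None
    runner.resync()

    n_samp = schedule.production_steps // schedule.sample_interval
    n_rec = (schedule.production_steps // schedule.record_interval
             if schedule.record_interval else 0)
    comp_keys = list(runner.energy.keys())
    m_series = np.zeros(n_samp, dtype=np.int64)
    e_series = {k: np.zeros(n_samp) for k in comp_keys}
    n_internal = (sys_.nano.internal_coordinates().shape[0]
                  if sys_.nano is not None else 0)
    nano_frames = np.zeros((n_rec, n_internal, 3))
    mesh_z = np.zeros((n_rec, sys_.mesh.n_vertices))
    rec_xy = np.zeros((n_rec, sys_.receptors.n_receptors, 2))

    si, ri = 0, 0
    for i in range(schedule.production_steps):
        runner.step()
        j = i + 1
        if j % schedule.resync_interval == 0:
            runner.resync()
        if j % schedule.sample_interval == 0 and si < n_samp:
            m_series[si] = sys_.receptors.n_bound
            for k in comp_keys:
                e_series[k][si] = runner.energy[k]
            si += 1
        if schedule.record_interval and j % schedule.record_interval == 0 \
                and ri < n_rec:
            if n_internal:
                nano_frames[ri] = sys_.nano.internal_coordinates()
            mesh_z[ri] = sys_.mesh.vertices[:, 2]
            rec_xy[ri] = sys_.receptors.anchors_xy
            ri += 1

    acc = {k: (runner.accepted[k] / runner.attempted[k]
               if runner.attempted[k] else 0.0) for k in MOVE_TYPES}
    return Trajectory(
        m_series=m_series[:si], energy_series={k: v[:si] for k, v in e_series.items()},
        nano_frames=nano_frames[:ri], mesh_z_frames=mesh_z[:ri],
        receptor_xy_frames=rec_xy[:ri], acceptance=acc,
        attempted=dict(runner.attempted), seed=seed,
        n_ligands=(sys_.nano.n_ligands if sys_.nano is not None else 0),
        n_receptors=sys_.receptors.n_receptors,
        final_amplitudes=dict(runner.amp))


def run_replicas(system, schedule: McSchedule, seeds) -> EnsembleResult:
    """Independent replica trajectories (distinct seeds enforced)."""
    seeds = [int(s) for s in seeds]
    if len(seeds) < 2:
        raise ValueError("need at least 2 replicas")
    if len(set(seeds)) != len(seeds):
        raise ValueError("replica seeds must be distinct")
    trajs = [run_mc(system, schedule, s) for s in seeds]
    return EnsembleResult(trajectories=trajs, seeds=seeds)


def run_unbound_reference(system, schedule: McSchedule, seed: int,
                          standoff: Optional[float] = None) -> Trajectory:
    """Reference ensemble with the particle displaced out of interaction
    range, bonds disabled, under an identical move schedule.

    A soft positional restraint on the particle center replaces the (absent)
    adhesion in holding the particle near its reference position, so its
    internal and rotational fluctuations are sampled under comparable
    conditions.
    """
    sys_ = copy.deepcopy(system)
    # break any existing bonds
    sys_.receptors.bound_partner[:] = -1
    sys_.ligand_bound[:] = -1
    sys_.bonds_enabled = False
    if sys_.nano is not None:
        from .nanoparticle import np_rigid_body_move
        if standoff is None:
            reach = (sys_.nano.ligand_length + sys_.receptors.rod_length
                     + 4.0 * sys_.nano.bead_radius)
            zmax = float(sys_.mesh.vertices[:, 2].max())
            low = float(np.min(sys_.nano.internal_coordinates()[:, 2])
                        if sys_.nano.internal_coordinates().size
                        else sys_.nano.core_center[2])
            standoff = max(0.0, zmax + 3.0 * reach - low)
        sys_.nano = np_rigid_body_move(sys_.nano, [0.0, 0.0, standoff])
        sys_.np_restraint = (float(sys_.nano.core_center[2]), 0.01)
        sys_.refresh_tip_cache()
    return run_mc(sys_, schedule, seed, inplace=True)
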