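"""System assembly: membrane + nanoparticle + receptors + bond model.

This module is the synthetic-system generator.  Full-scale presets mirror
the studied conditions (500 x 500 nm^2 periodic patch, kappa = 20 k_BT,
excess area 6-20 %, 162 ligands per particle, receptor counts
{50, 125, 250, 500, 1000} per 0.25 um^2); desk-scale presets keep the same
statistical structure at sizes that sample in minutes on one CPU.

The :class:`System` also owns the mutable simulation state and the cached
surface interpolations the Monte Carlo engine needs (receptor anchor
heights/normals, ligand-tip clearances), plus the interaction-energy pieces
that couple the blocks: membrane-particle soft-core overlap, a soft
penalty keeping ligand tips above the surface, and the bond energies.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import binding as bd
from . import membrane as mb
from . import nanoparticle as npm
from .mc_engine import DESK_SCHEDULE, FULL_SCHEDULE, McSchedule

__all__ = [
    "SystemConfig",
    "System",
    "build_membrane_fixture",
    "build_system",
    "desk_fixture",
    "fixture_registry",
    "RECEPTOR_SET",
]

#: studied receptor counts per 0.25 um^2 reference patch
RECEPTOR_SET = (50, 125, 250, 500, 1000)
FULL_PATCH_LENGTH = 500.0
FULL_PATCH_AREA = FULL_PATCH_LENGTH ** 2


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class SystemConfig(BaseModel):
    """Validated configuration for one simulated state point."""

    model_config = ConfigDict(extra="forbid")

    patch_length: float = FULL_PATCH_LENGTH     # nm
    nx: Optional[int] = None                    # lattice columns (derived)
    ny: Optional[int] = None
    a_ex: float = 0.20                          # target excess area
    kappa: float = 20.0                         # k_BT
    sigma: float = 0.0                          # k_BT/nm^2 (tension mode)
    area_mode: Literal["clamp", "tension"] = "clamp"
    np_class: Literal["RG", "SRG", "LSt", "HSt"] = "RG"
    np_scale: Literal["full", "desk"] = "full"
    binder_class: Literal["strong", "intermediate", "weak"] = "strong"
    n_receptors: int = 250                      # per 0.25 um^2 reference
    schedule: Literal["full", "desk"] = "desk"
    seed: int = 0
    study_mode: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SystemConfig":
        if self.patch_length <= 0 or self.kappa <= 0:
            raise ValueError("patch_length and kappa must be positive")
        if not 0.0 <= self.a_ex < 1.0:
            raise ValueError("a_ex must lie in [0, 1)")
        if self.study_mode:
            if not 0.06 <= self.a_ex <= 0.20:
                raise ValueError(
                    "study-mode a_ex must lie in the studied range 6-20%")
            if self.n_receptors not in RECEPTOR_SET:
                raise ValueError(
                    f"study-mode n_receptors must be one of {RECEPTOR_SET}")
        return self

    def receptors_in_patch(self) -> int:
        """Scale the reference receptor count to this patch at fixed areal
        density (quarter-scaling convention of the reference membrane)."""
        frac = self.patch_length ** 2 / FULL_PATCH_AREA
        return max(1, int(round(self.n_receptors * frac)))


# ---------------------------------------------------------------------------
# system state
# ---------------------------------------------------------------------------

@dataclass
class System:
    """Assembled simulation state (mesh + particle + receptors + binder)."""

    mesh: mb.MembraneMesh
    nano: Optional[npm.Nanoparticle]
    receptors: bd.ReceptorField
    bond_model: bd.BondModel
    schedule: McSchedule
    ligand_bound: np.ndarray = field(default=None)   # (N_l,) receptor id or -1
    bonds_enabled: bool = True
    relocation_bond_moves: bool = True
    equil_scaffold: bool = True
    box_height: Optional[float] = None               # nm; hard wall for the NP core
    np_restraint: Optional[Tuple[np.ndarray, float]] = None
    vertex_contact_radius: float = 5.0               # nm, membrane half-thickness proxy
    overlap_stiffness: float = 2.0                   # k_BT/nm^2 soft-core
    tip_penalty_stiffness: float = 10.0              # k_BT/nm^2, tips below surface
    config: Optional[dict] = None
    expectation: Optional[dict] = None

    def __post_init__(self) -> None:
        n_l = self.nano.n_ligands if self.nano is not None else 0
        if self.ligand_bound is None:
            self.ligand_bound = np.full(n_l, -1, dtype=np.int64)
        self.refresh_receptor_cache()
        self.refresh_tip_cache()

    # -- bookkeeping ------------------------------------------------------
    @property
    def m(self) -> int:
        return self.receptors.n_bound

    @property
    def m_max(self) -> int:
        n_l = self.nano.n_ligands if self.nano is not None else 0
        return min(n_l, self.receptors.n_receptors)

    def copy(self) -> "System":
        return copy.deepcopy(self)

    def schedule_move_keys(self, move_mix: Dict[str, float]):
        keys = []
        for k, v in move_mix.items():
            if v <= 0:
                continue
            if k in ("np_rigid", "np_bead", "bond") and self.nano is None:
                continue
            if k == "np_bead" and self.nano is not None and \
                    self.nano.n_beads == 0 and not self.nano.tips_mobile:
                continue
            if k == "hop" and self.receptors.n_receptors == 0:
                continue
            keys.append(k)
        if not keys:
            raise ValueError("no applicable moves in move mix")
        return keys

    # -- surface caches ---------------------------------------------------
    def refresh_receptor_cache(self, idx: Optional[np.ndarray] = None) -> None:
        rec = self.receptors
        if rec.n_receptors == 0:
            self._rec_sample = None
            self.rec_nodes = np.zeros((0, 3), dtype=np.int64)
            return
        if idx is None or self._rec_sample_missing():
            self._rec_sample = mb.surface_sample(self.mesh, rec.anchors_xy)
        else:
            sub = mb.surface_sample(self.mesh, rec.anchors_xy[idx])
            s = self._rec_sample
            s.nodes[idx] = sub.nodes
            s.weights[idx] = sub.weights
            s.z[idx] = sub.z
            s.normals[idx] = sub.normals
            s.e1xy[idx] = sub.e1xy
            s.e2xy[idx] = sub.e2xy
        self.rec_nodes = self._rec_sample.nodes

    def _rec_sample_missing(self) -> bool:
        return getattr(self, "_rec_sample", None) is None

    def refresh_tip_cache(self, idx: Optional[np.ndarray] = None) -> None:
        if self.nano is None or self.nano.n_ligands == 0:
            self._tip_sample = None
            self.tip_nodes = np.zeros((0, 3), dtype=np.int64)
            return
        tips_xy = self.nano.tips[:, :2]
        if idx is None or getattr(self, "_tip_sample", None) is None:
            self._tip_sample = mb.surface_sample(self.mesh, tips_xy)
        else:
            sub = mb.surface_sample(self.mesh, tips_xy[idx])
            s = self._tip_sample
            s.nodes[idx] = sub.nodes
            s.weights[idx] = sub.weights
            s.z[idx] = sub.z
            s.normals[idx] = sub.normals
            s.e1xy[idx] = sub.e1xy
            s.e2xy[idx] = sub.e2xy
        self.tip_nodes = self._tip_sample.nodes

    def refresh_receptor_heights(self, idx: np.ndarray) -> None:
        """Update cached anchor heights/normals after vertex-height changes
        (containing triangles unchanged, so no relocation needed)."""
        s = self._rec_sample
        sub = mb.SurfaceSample(nodes=s.nodes[idx], weights=s.weights[idx],
                               z=None, normals=None,
                               e1xy=s.e1xy[idx], e2xy=s.e2xy[idx])
        s.z[idx], s.normals[idx] = sub.reevaluate(self.mesh.vertices[:, 2])

    def refresh_tip_heights(self, idx: np.ndarray) -> None:
        s = self._tip_sample
        sub = mb.SurfaceSample(nodes=s.nodes[idx], weights=s.weights[idx],
                               z=None, normals=None,
                               e1xy=s.e1xy[idx], e2xy=s.e2xy[idx])
        s.z[idx], s.normals[idx] = sub.reevaluate(self.mesh.vertices[:, 2])

    def install_receptor_sample(self, idx: int, sample: mb.SurfaceSample) -> None:
        self._install(self._rec_sample, idx, sample)

    def install_tip_sample(self, idx: int, sample: mb.SurfaceSample) -> None:
        self._install(self._tip_sample, idx, sample)

    @staticmethod
    def _install(s: mb.SurfaceSample, idx: int, sample: mb.SurfaceSample) -> None:
        s.nodes[idx] = sample.nodes[0]
        s.weights[idx] = sample.weights[0]
        s.z[idx] = sample.z[0]
        s.normals[idx] = sample.normals[0]
        s.e1xy[idx] = sample.e1xy[0]
        s.e2xy[idx] = sample.e2xy[0]

    @property
    def rec_z(self) -> np.ndarray:
        return self._rec_sample.z

    @property
    def rec_normals(self) -> np.ndarray:
        return self._rec_sample.normals

    @property
    def rec_weights(self) -> np.ndarray:
        return self._rec_sample.weights

    @property
    def tip_weights(self) -> np.ndarray:
        return self._tip_sample.weights

    def rec_anchor_pos(self, idx: Optional[np.ndarray] = None) -> np.ndarray:
        rec = self.receptors
        if idx is None:
            return np.column_stack([rec.anchors_xy, self._rec_sample.z])
        return np.column_stack([rec.anchors_xy[idx], self._rec_sample.z[idx]])

    # -- bond energies ----------------------------------------------------
    def bound_bond_energies(self, rec_idx: Optional[np.ndarray] = None,
                            z_override: Optional[np.ndarray] = None,
                            tips_override: Optional[np.ndarray] = None) -> np.ndarray:
        rec = self.receptors
        if rec_idx is None:
            rec_idx = np.where(rec.bound_partner >= 0)[0]
        rec_idx = np.atleast_1d(rec_idx)
        if rec_idx.size == 0:
            return np.zeros(0)
        lig = rec.bound_partner[rec_idx]
        if np.any(lig < 0):
            raise ValueError("bound_bond_energies called on unbound receptor")
        tips = self.nano.tips if tips_override is None else tips_override
        if z_override is None:
            z = self._rec_sample.z[rec_idx]
            normals = self._rec_sample.normals[rec_idx]
        else:
            sub = mb.SurfaceSample(
                nodes=self._rec_sample.nodes[rec_idx],
                weights=self._rec_sample.weights[rec_idx],
                z=None, normals=None,
                e1xy=self._rec_sample.e1xy[rec_idx],
                e2xy=self._rec_sample.e2xy[rec_idx])
            z, normals = sub.reevaluate(z_override)
        anchors = np.column_stack([rec.anchors_xy[rec_idx], z])
        return bd.pair_bond_energies(tips[lig], anchors, normals,
                                     self.bond_model, rec.flexural_k,
                                     box=self.mesh.box,
                                     rod_length=rec.rod_length)

    def bond_energy_of(self, r: int) -> float:
        return float(self.bound_bond_energies(np.array([r]))[0])

    def trial_bond_energy(self, l: int, r: int) -> float:
        """Bond-state energy a (ligand, receptor) pair would have right now."""
        rec = self.receptors
        anchor = np.array([[rec.anchors_xy[r, 0], rec.anchors_xy[r, 1],
                            self._rec_sample.z[r]]])
        return float(bd.pair_bond_energies(
            self.nano.tips[l][None, :], anchor,
            self._rec_sample.normals[r][None, :], self.bond_model,
            rec.flexural_k, box=self.mesh.box,
            rod_length=rec.rod_length)[0])

    def bond_energy_at(self, r: int, new_xy: np.ndarray) -> float:
        sub = mb.surface_sample_one(self.mesh, new_xy[0], new_xy[1])
        l = int(self.receptors.bound_partner[r])
        anchor = np.array([[new_xy[0], new_xy[1], sub.z[0]]])
        e = bd.pair_bond_energies(self.nano.tips[l][None, :], anchor,
                                  sub.normals, self.bond_model,
                                  self.receptors.flexural_k, box=self.mesh.box,
                                  rod_length=self.receptors.rod_length)
        return float(e[0])

    # -- particle/membrane interaction ------------------------------------
    def _np_bodies(self, nano: Optional[npm.Nanoparticle] = None):
        nano = nano or self.nano
        centers = [nano.core_center[None, :]]
        radii = [nano.core_radius]
        if nano.n_beads:
            centers.append(nano.beads)
            radii.extend([nano.bead_radius] * nano.n_beads)
        return np.vstack(centers), np.asarray(radii)

    def mesh_np_overlap_energy(self, nano: Optional[npm.Nanoparticle] = None) -> float:
        """Soft-core repulsion between membrane vertices and particle bodies."""
        if self.nano is None:
            return 0.0
        nano = nano or self.nano
        centers, radii = self._np_bodies(nano)
        v = self.mesh.vertices
        box = self.mesh.box
        # coarse in-plane prefilter around the particle
        r_out = float(radii.max() + np.max(np.linalg.norm(
            centers - nano.core_center, axis=1))) if centers.shape[0] > 1 \
            else nano.core_radius
        dxy = v[:, :2] - nano.core_center[:2]
        if box is not None:
            dxy = dxy - box * np.round(dxy / box)
        near = np.einsum("ij,ij->i", dxy, dxy) <= (
            r_out + self.vertex_contact_radius + 2.0) ** 2
        if not np.any(near):
            return 0.0
        d = v[near][:, None, :] - centers[None, :, :]
        if box is not None:
            d[..., :2] -= box * np.round(d[..., :2] / box)
        dist = np.linalg.norm(d, axis=2)
        ov = np.maximum(0.0, (radii[None, :] + self.vertex_contact_radius) - dist)
        return float(0.5 * self.overlap_stiffness * np.sum(ov ** 2))

    def vertex_overlap_energy(self, vpos: np.ndarray) -> float:
        """Overlap energy of a single (possibly trial) vertex position."""
        if self.nano is None:
            return 0.0
        centers, radii = self._np_bodies()
        d = vpos[None, :] - centers
        if self.mesh.box is not None:
            d[:, :2] -= self.mesh.box * np.round(d[:, :2] / self.mesh.box)
        dist = np.linalg.norm(d, axis=1)
        ov = np.maximum(0.0, (radii + self.vertex_contact_radius) - dist)
        return float(0.5 * self.overlap_stiffness * np.sum(ov ** 2))

    def tip_penalty_energy(self, tip_idx: Optional[np.ndarray] = None,
                           surf_z: Optional[np.ndarray] = None,
                           tips_override: Optional[np.ndarray] = None) -> float:
        """Soft penalty for ligand tips dipping below the membrane surface."""
        if self.nano is None or self.nano.n_ligands == 0:
            return 0.0
        tips = self.nano.tips if tips_override is None else tips_override
        if tip_idx is None:
            tip_idx = np.arange(self.nano.n_ligands)
        if surf_z is None:
            surf_z = self._tip_sample.z[tip_idx]
        depth = np.maximum(0.0, surf_z - tips[tip_idx, 2])
        return float(0.5 * self.tip_penalty_stiffness * np.sum(depth ** 2))

    def restraint_energy(self, nano: Optional[npm.Nanoparticle] = None) -> float:
        """Soft z-restraint on the particle center (nucleation scaffold
        during equilibration; holds the unbound reference at its standoff)."""
        if self.np_restraint is None or self.nano is None:
            return 0.0
        nano = nano or self.nano
        z_ref, k = self.np_restraint
        return float(0.5 * k * (nano.core_center[2] - z_ref) ** 2)

    # -- trial-move deltas used by the engine -----------------------------
    def np_interaction_delta(self, trial: npm.Nanoparticle,
                             internal_changed: bool = False):
        """Energy change of replacing the particle pose (rigid move).

        With ``internal_changed`` the trial is allowed to differ internally
        (e.g. bound tips held in place while the body moves), and the
        internal-energy difference is included."""
        parts = {}
        if self.box_height is not None and not (
                0.0 <= trial.core_center[2] <= self.box_height):
            return float("inf"), {"overlap": 0.0, "bond": 0.0,
                                  "restraint": 0.0, "np_internal": 0.0}
        parts["np_internal"] = (
            npm.np_internal_energy(trial) - npm.np_internal_energy(self.nano)
            if internal_changed else 0.0)
        sub = mb.surface_sample(self.mesh, trial.tips[:, :2])
        parts["overlap"] = (
            self.mesh_np_overlap_energy(trial)
            + self.tip_penalty_energy(surf_z=sub.z, tips_override=trial.tips)
            - self.mesh_np_overlap_energy()
            - self.tip_penalty_energy())
        bound = np.where(self.receptors.bound_partner >= 0)[0]
        if bound.size:
            e_new = self.bound_bond_energies(bound, tips_override=trial.tips)
            e_old = self.bound_bond_energies(bound)
            parts["bond"] = float(np.sum(e_new) - np.sum(e_old))
        else:
            parts["bond"] = 0.0
        parts["restraint"] = (self.restraint_energy(trial)
                              - self.restraint_energy())
        return sum(parts.values()), parts

    def bead_move_delta(self, k: int, disp: np.ndarray):
        nano = self.nano
        new_beads = nano.beads.copy()
        new_beads[k] += disp
        d_int = (npm.np_internal_energy_positions(nano, beads=new_beads)
                 - npm.np_internal_energy(nano))
        d_ov = (self._body_overlap(new_beads[k], nano.bead_radius)
                - self._body_overlap(nano.beads[k], nano.bead_radius))
        parts = {"np_internal": float(d_int), "overlap": float(d_ov)}

        def apply():
            nano.beads[k] = new_beads[k]

        return sum(parts.values()), parts, apply

    def tip_move_delta(self, t: int, disp: np.ndarray):
        nano = self.nano
        new_tip = nano.tips[t] + disp
        # tether
        if nano.class_tag == "SRG":
            ref = nano.anchors[t]
        else:
            ref = nano.beads[nano.tip_parent[t]]
        k_t, r0 = nano.tether_k, nano.tether_rest
        d_teth = (0.5 * k_t * (np.linalg.norm(new_tip - ref) - r0) ** 2
                  - 0.5 * k_t * (np.linalg.norm(nano.tips[t] - ref) - r0) ** 2)
        # surface clearance
        sub = mb.surface_sample_one(self.mesh, new_tip[0], new_tip[1])
        depth_new = max(0.0, sub.z[0] - new_tip[2])
        depth_old = max(0.0, self._tip_sample.z[t] - nano.tips[t, 2])
        d_pen = 0.5 * self.tip_penalty_stiffness * (depth_new ** 2 - depth_old ** 2)
        # bond, if this ligand is engaged
        d_bond = 0.0
        r = int(self.ligand_bound[t])
        if r >= 0:
            tips_new = nano.tips.copy()
            tips_new[t] = new_tip
            d_bond = (self.bound_bond_energies(np.array([r]), tips_override=tips_new)[0]
                      - self.bound_bond_energies(np.array([r]))[0])
        parts = {"np_internal": float(d_teth),
                 "overlap": float(d_pen),
                 "bond": float(d_bond)}

        def apply():
            nano.tips[t] = new_tip
            self.install_tip_sample(t, sub)

        return sum(parts.values()), parts, apply

    def arm_pivot_delta(self, arm: int, rotation):
        """Energy change of rigidly rotating one arm (beads + its tips)
        about the core center.  Cheap for uncrosslinked particles, hence the
        workhorse for large-scale shape change (flattening/wrapping)."""
        nano = self.nano
        sel_b = np.where(nano.arm_of_bead == arm)[0]
        # bound tips stay pinned to their receptors; only free tips pivot
        sel_t = np.where(np.isin(nano.tip_parent, sel_b)
                         & (self.ligand_bound < 0))[0]
        R = rotation.as_matrix()
        c = nano.core_center
        new_beads = nano.beads.copy()
        new_beads[sel_b] = (nano.beads[sel_b] - c) @ R.T + c
        new_tips = nano.tips.copy()
        new_tips[sel_t] = (nano.tips[sel_t] - c) @ R.T + c
        d_int = (npm.np_internal_energy_positions(nano, beads=new_beads,
                                                  tips=new_tips)
                 - npm.np_internal_energy(nano))
        d_ov = 0.0
        for k in sel_b:
            d_ov += (self._body_overlap(new_beads[k], nano.bead_radius)
                     - self._body_overlap(nano.beads[k], nano.bead_radius))
        sub = mb.surface_sample(self.mesh, new_tips[sel_t][:, :2])
        d_pen = (self.tip_penalty_energy(tip_idx=sel_t, surf_z=sub.z,
                                         tips_override=new_tips)
                 - self.tip_penalty_energy(tip_idx=sel_t))
        d_bond = 0.0
        bound_r = np.array([self.ligand_bound[t] for t in sel_t
                            if self.ligand_bound[t] >= 0], dtype=np.int64)
        if bound_r.size:
            d_bond = float(
                self.bound_bond_energies(bound_r, tips_override=new_tips).sum()
                - self.bound_bond_energies(bound_r).sum())
        parts = {"np_internal": float(d_int),
                 "overlap": float(d_ov + d_pen),
                 "bond": d_bond}

        def apply():
            nano.beads[sel_b] = new_beads[sel_b]
            nano.tips[sel_t] = new_tips[sel_t]
            self.refresh_tip_cache(sel_t)

        return sum(parts.values()), parts, apply

    def _body_overlap(self, pos: np.ndarray, radius: float) -> float:
        """Overlap of one particle body (bead) with the membrane vertices."""
        v = self.mesh.vertices
        d = v - pos[None, :]
        if self.mesh.box is not None:
            d[:, :2] -= self.mesh.box * np.round(d[:, :2] / self.mesh.box)
        dist2 = np.einsum("ij,ij->i", d, d)
        r_c = radius + self.vertex_contact_radius
        close = dist2 < r_c * r_c
        if not np.any(close):
            return 0.0
        ov = r_c - np.sqrt(dist2[close])
        return float(0.5 * self.overlap_stiffness * np.sum(ov ** 2))

    # -- invariants -------------------------------------------------------
    def check_invariants(self) -> bool:
        rec = self.receptors
        n_l = self.nano.n_ligands if self.nano is not None else 0
        ok = rec.check_matching(n_l)
        bound_r = np.where(rec.bound_partner >= 0)[0]
        for r in bound_r:
            l = rec.bound_partner[r]
            if self.ligand_bound[l] != r:
                return False
        ok &= self.m <= self.m_max
        return bool(ok)


# ---------------------------------------------------------------------------
# membrane fixture
# ---------------------------------------------------------------------------

def _spectrum_heights(nx: int, ny: int, L: float, kappa: float,
                      seed: int) -> np.ndarray:
    """Random surface with Helfrich-like undulation spectrum ~1/(kappa q^4)."""
    rng = np.random.default_rng(seed)
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=L / nx)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=L / ny)
    q2 = qx[None, :] ** 2 + qy[:, None] ** 2
    q2[0, 0] = np.inf  # no mean-height mode
    mu = kappa * (2.0 * np.pi / L) ** 4  # IR regularizer ~ box mode
    spec = 1.0 / (kappa * q2 ** 2 + mu)
    white = rng.standard_normal((ny, nx))
    h = np.real(np.fft.ifft2(np.fft.fft2(white) * np.sqrt(spec)))
    return h / max(1e-30, h.std())


def build_membrane_fixture(L: float, n_vertices: int, a_ex: float, seed: int,
                           kappa: float = 20.0, sigma: float = 0.0,
                           area_mode: str = "clamp",
                           tolerance: float = 0.005,
                           **mesh_kwargs) -> mb.MembraneMesh:
    """Periodic patch pre-shaped to the target excess area.

    The undulation field follows a bending-dominated spectrum and its
    amplitude is bisected until A_ex matches the target within ``tolerance``
    (default +-0.5 percentage points).  Deterministic per seed.
    """
    nx = max(4, int(round(np.sqrt(n_vertices))))
    ny = nx + (nx % 2)
    nx = ny
    mesh = mb.triangular_lattice_patch(L, nx, ny, kappa=kappa, sigma=sigma,
                                       area_mode=area_mode, **mesh_kwargs)
    ap = mesh.projected_area
    if area_mode == "clamp":
        mesh.target_area = ap / (1.0 - a_ex) if a_ex > 0 else ap
    if a_ex <= 0:
        return mesh
    base = _spectrum_heights(nx, ny, L, kappa, seed).ravel()

    def aex_of(c: float) -> float:
        z = c * base
        pos = mesh.vertices.copy()
        pos[:, 2] = z
        return mb.excess_area(mesh, pos)

    lo, hi = 0.0, 1.0
    while aex_of(hi) < a_ex:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(f"cannot reach A_ex={a_ex}: amplitude diverges")
    c = None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = aex_of(mid)
        if abs(val - a_ex) <= 0.1 * tolerance:
            c = mid
            break
        if val < a_ex:
            lo = mid
        else:
            hi = mid
    if c is None:
        c = 0.5 * (lo + hi)
    mesh.vertices[:, 2] = c * base
    got = mb.excess_area(mesh)
    if abs(got - a_ex) > tolerance:
        raise RuntimeError(
            f"builder failed to reach A_ex={a_ex:.3f} (got {got:.3f})")
    return mesh


# ---------------------------------------------------------------------------
# full system assembly
# ---------------------------------------------------------------------------

_NP_FULL = dict(n_ligands=162, radius=50.0, f=25, n_beads_per_arm=4,
                core_radius=16.0)
_NP_DESK = dict(n_ligands=24, radius=20.0, f=8, n_beads_per_arm=2,
                core_radius=10.0)


def _build_np(np_class: str, scale: str, seed: int) -> npm.Nanoparticle:
    p = _NP_FULL if scale == "full" else _NP_DESK
    if np_class == "RG":
        return npm.build_rigid_np(n_ligands=p["n_ligands"], radius=p["radius"],
                                  seed=seed)
    if np_class == "SRG":
        return npm.build_semirigid_np(n_ligands=p["n_ligands"],
                                      radius=p["radius"], seed=seed)
    frac = 0.0 if np_class == "LSt" else 1.0
    return npm.build_coreshell_np(
        f=p["f"], n_beads_per_arm=p["n_beads_per_arm"],
        crosslink_fraction=frac, seed=seed, core_radius=p["core_radius"],
        n_ligands=p["n_ligands"], class_tag=np_class)


def build_system(config: SystemConfig) -> System:
    """Assemble an overlap-free initial state from a validated config.

    The particle is positioned near the membrane (lowest ligand tip one rod
    length above the local surface, i.e. within capture range); receptors are
    placed uniformly at random over the patch.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    n_v_target = 2704 if config.patch_length >= 400 else \
        max(16, int(round(2704 * (config.patch_length / FULL_PATCH_LENGTH) ** 2)))
    if config.nx is not None:
        n_v_target = config.nx * (config.ny or config.nx)
    mesh = build_membrane_fixture(
        config.patch_length, n_v_target, config.a_ex, config.seed,
        kappa=config.kappa, sigma=config.sigma, area_mode=config.area_mode)

    nano = _build_np(config.np_class, config.np_scale, config.seed)
    # place particle core over the patch center, lowest tip within capture
    L = config.patch_length
    center_xy = np.array([L / 2.0, L / 2.0])
    nano = npm.np_rigid_body_move(
        nano, np.concatenate([center_xy - nano.core_center[:2], [0.0]]))
    tips_xy = np.mod(nano.tips[:, :2], L)
    surf = mb.surface_sample(mesh, tips_xy)
    rod = 19.0
    lowest = np.argmin(nano.tips[:, 2])
    dz = (surf.z[lowest] + rod) - nano.tips[lowest, 2]
    nano = npm.np_rigid_body_move(nano, [0.0, 0.0, dz])

    n_rec = config.receptors_in_patch()
    anchors = rng.uniform(0.0, L, size=(n_rec, 2))
    receptors = bd.ReceptorField(anchors_xy=anchors)
    schedule = FULL_SCHEDULE if config.schedule == "full" else DESK_SCHEDULE
    system = System(mesh=mesh, nano=nano, receptors=receptors,
                    bond_model=bd.BINDERS[config.binder_class],
                    schedule=schedule, config=config.model_dump(),
                    box_height=1.24 * L)  # 620 nm at the full 500 nm patch
    seed_initial_bond(system)
    if not system.check_invariants():
        raise RuntimeError("assembled system violates invariants")
    return system


# ---------------------------------------------------------------------------
# desk fixtures
# ---------------------------------------------------------------------------

def _toy_mesh(L: float = 60.0, n: int = 6) -> mb.MembraneMesh:
    return mb.triangular_lattice_patch(L, n, n, kappa=20.0, sigma=0.0,
                                       area_mode="tension")


def _frozen_pair_toy(target_energies) -> System:
    """One rigid ligand above ``len(target_energies)`` frozen receptors.

    Receptor anchors are placed so each bond's total state energy lands near
    the requested value; the attached expectation record holds the *exact*
    energies of the placed geometry (recomputed through the bond energy
    model), so the bond-state system is exactly enumerable."""
    from scipy.optimize import brentq

    mesh = _toy_mesh()
    bm = bd.BondModel("toy", dG0=-10.0, k_b_si=0.01)
    nano = npm.build_rigid_np(n_ligands=1, radius=5.0, seed=0,
                              center=(30.0, 30.0, 0.0))
    # single tip pointing straight down at height d0 above the surface
    nano.tips = np.array([[30.0, 30.0, bm.rest_length]])
    nano.core_center = np.array([30.0, 30.0, bm.rest_length + 20.0])
    flex_k = bd.ReceptorField(np.zeros((1, 2))).flexural_k
    anchors = []
    for e in target_energies:
        def cost(rho, target=e):
            d = np.hypot(rho, bm.rest_length)
            th = np.arctan2(rho, bm.rest_length)
            return (bm.dG0 + 0.5 * bm.k_b * (d - bm.rest_length) ** 2
                    + 0.5 * flex_k * th ** 2
                    + bd.rod_orientation_penalty(d, bm, bm.rest_length)
                    ) - target
        rho = brentq(cost, 0.0, 60.0)
        anchors.append([30.0 + rho, 30.0])
    receptors = bd.ReceptorField(anchors_xy=np.array(anchors))
    schedule = McSchedule(move_mix={"bond": 1.0}, equilibration_steps=2_000,
                          production_steps=200_000, sample_interval=10,
                          record_interval=0, auto_tune=False)
    sys_ = System(mesh=mesh, nano=nano, receptors=receptors, bond_model=bm,
                  schedule=schedule, relocation_bond_moves=False)
    # exact per-bond state energies of the placed geometry
    e_exact = [float(sys_.trial_bond_energy(0, r))
               for r in range(receptors.n_receptors)]
    sys_.expectation = {"energies": e_exact}
    return sys_


def _mini_system(binder: str, n_rec: int, patch: float,
                 make_np, seed: int = 0, a_ex: float = 0.12) -> System:
    """Desk-scale system with an explicit particle builder."""
    n_v = max(100, int(round(2704 * (patch / FULL_PATCH_LENGTH) ** 2)))
    mesh = build_membrane_fixture(patch, n_v, a_ex, seed, kappa=20.0)
    nano = make_np(seed)
    nano = npm.np_rigid_body_move(
        nano, np.concatenate([[patch / 2, patch / 2] - nano.core_center[:2],
                              [0.0]]))
    surf = mb.surface_sample(mesh, np.mod(nano.tips[:, :2], patch))
    low = int(np.argmin(nano.tips[:, 2]))
    nano = npm.np_rigid_body_move(
        nano, [0.0, 0.0, surf.z[low] + 19.0 - nano.tips[low, 2]])
    rng = np.random.default_rng(seed + 1)
    receptors = bd.ReceptorField(
        anchors_xy=rng.uniform(0.0, patch, size=(n_rec, 2)))
    sys_ = System(mesh=mesh, nano=nano, receptors=receptors,
                  bond_model=bd.BINDERS[binder], schedule=DESK_SCHEDULE,
                  box_height=1.24 * patch)
    seed_initial_bond(sys_)
    return sys_


def seed_initial_bond(system: System) -> None:
    """Pre-form one favorable bond between a low ligand tip and a receptor
    relocated beneath it (the near-membrane initialization made concrete).

    The anchor is aligned with the local surface normal to minimize the
    flexural cost; the lowest-energy candidate among the lowest tips is
    used.  Unfavorable bonds dissolve during equilibration, so this only
    skips the first-contact waiting time of strongly bound states."""
    nano = system.nano
    if nano is None or system.receptors.n_receptors == 0:
        return
    d0 = system.bond_model.rest_length
    box = system.mesh.box
    if nano.tips_mobile:
        _seed_bond_mobile_tip(system)
        return
    order = np.argsort(nano.tips[:, 2])[:8]
    best = None
    for low in order:
        tip = nano.tips[low]
        for phi in np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False):
            u = np.array([math.cos(phi), math.sin(phi)])
            # scan the radial ray for the point at exactly bond distance
            hit = None
            for rho in np.arange(0.4, 8.0, 0.1):
                a_xy = np.mod(tip[:2] + rho * u, box)
                sub = mb.surface_sample_one(system.mesh, a_xy[0], a_xy[1])
                d = math.sqrt(rho * rho + (tip[2] - sub.z[0]) ** 2)
                if (hit is None or abs(d - d0) < hit[0]):
                    hit = (abs(d - d0), a_xy.copy())
            if hit[0] > 0.9 * system.bond_model.capture_halfwidth:
                continue
            system.receptors.anchors_xy[0] = hit[1]
            system.refresh_receptor_cache(np.array([0]))
            e = system.trial_bond_energy(int(low), 0)
            if best is None or e < best[0]:
                best = (e, int(low), hit[1])
    if best is None:
        return
    e, low, a_xy = best
    system.receptors.anchors_xy[0] = a_xy
    system.refresh_receptor_cache(np.array([0]))
    if np.isfinite(e) and e < 0:
        system.ligand_bound[low] = 0
        system.receptors.bound_partner[0] = low


def _seed_bond_mobile_tip(system: System) -> None:
    """Seeding variant for particles with mobile ligand tips: the tip is
    regrown onto the perfect bond geometry (one rod length along the local
    normal) above the best anchor spot reachable by its tether."""
    nano = system.nano
    d0 = system.bond_model.rest_length
    box = system.mesh.box
    order = np.argsort(nano.tips[:, 2])[:4]
    best = None
    for low in order:
        ref, r0, k_t = bd._tether_reference(nano, int(low))
        span = np.arange(-r0 - 6.0, r0 + 6.5, 1.0)
        gx, gy = np.meshgrid(span, span)
        a_xy = np.mod(np.column_stack([gx.ravel() + ref[0],
                                       gy.ravel() + ref[1]]), box)
        sub = mb.surface_sample(system.mesh, a_xy)
        a3 = np.column_stack([a_xy, sub.z])
        tip_c = a3 + d0 * sub.normals
        d_ref = tip_c - ref
        d_ref[:, :2] -= box * np.round(d_ref[:, :2] / box)
        teth = 0.5 * k_t * (np.linalg.norm(d_ref, axis=1) - r0) ** 2
        k = int(np.argmin(teth))
        score = float(teth[k])
        if best is None or score < best[0]:
            best = (score, int(low), a_xy[k].copy(), tip_c[k].copy())
    score, low, a_xy, tip = best
    old_tip = nano.tips[low].copy()
    nano.tips[low] = tip
    system.refresh_tip_cache(np.array([low]))
    system.receptors.anchors_xy[0] = a_xy
    system.refresh_receptor_cache(np.array([0]))
    e = system.trial_bond_energy(low, 0) + score
    if np.isfinite(e) and e < 0:
        system.ligand_bound[low] = 0
        system.receptors.bound_partner[0] = low
    else:
        nano.tips[low] = old_tip
        system.refresh_tip_cache(np.array([low]))


def _small_coreshell(crosslink: float):
    def make(seed: int) -> npm.Nanoparticle:
        return npm.build_coreshell_np(
            f=5, n_beads_per_arm=2, crosslink_fraction=crosslink, seed=seed,
            core_radius=10.0, n_ligands=10,
            class_tag="LSt" if crosslink < 0.5 else "HSt")
    return make


def _desk_rigid(seed: int) -> npm.Nanoparticle:
    return npm.build_rigid_np(n_ligands=24, radius=20.0, seed=seed)


def _full_rigid(seed: int) -> npm.Nanoparticle:
    return npm.build_rigid_np(seed=seed)          # 162 ligands, R = 50 nm


def _desk_semirigid(seed: int) -> npm.Nanoparticle:
    return npm.build_semirigid_np(n_ligands=24, radius=20.0, seed=seed)


def _fixture_two_state() -> System:
    s = _frozen_pair_toy([-2.0])
    e = s.expectation["energies"][0]
    w = math.exp(-e)
    s.expectation.update({"kind": "two_state", "p_bound": w / (1.0 + w)})
    return s


def _fixture_three_state() -> System:
    s = _frozen_pair_toy([-2.0, -1.0])
    w = np.exp([0.0] + [-e for e in s.expectation["energies"]])
    s.expectation.update({"kind": "three_state",
                          "p_states": (w / w.sum()).tolist()})
    return s


def _fixture_mini(binder: str, n_rec: int, patch: float, make_np,
                  expectation: dict, a_ex: float = 0.12):
    def make() -> System:
        s = _mini_system(binder, n_rec, patch, make_np, a_ex=a_ex)
        s.expectation = dict(expectation)
        return s
    return make


_REGISTRY: Dict[str, Callable[[], System]] = {
    "two_state_toy": _fixture_two_state,
    "three_state_toy": _fixture_three_state,
    # rigid fixtures run at the high studied excess area (20 %)
    "mini_RG_strong": _fixture_mini(
        "strong", 30, 180.0, _full_rigid,
        {"kind": "rigid_low_engagement", "max_fraction": 0.10}, a_ex=0.20),
    "mini_RG_intermediate": _fixture_mini(
        "intermediate", 20, 140.0, _desk_rigid,
        {"kind": "no_binding", "mean_m_below": 0.5}, a_ex=0.20),
    "mini_SRG_strong": _fixture_mini(
        "strong", 20, 140.0, _desk_semirigid,
        {"kind": "high_multivalency"}),
    "mini_LSt_strong_lowNr": _fixture_mini(
        "strong", 4, 120.0, _small_coreshell(0.0),
        {"kind": "receptor_limited", "mode_at": 4}),
    "mini_LSt_strong_highNr": _fixture_mini(
        "strong", 40, 120.0, _small_coreshell(0.0),
        {"kind": "ligand_limited", "mode_at": 10}),
    "mini_HSt_strong": _fixture_mini(
        "strong", 40, 120.0, _small_coreshell(1.0),
        {"kind": "high_multivalency"}),
    # weak binder: negative control, no class nucleates adhesion
    "mini_LSt_weak": _fixture_mini(
        "weak", 40, 120.0, _small_coreshell(0.0),
        {"kind": "no_binding", "mean_m_below": 0.5}),
}


def fixture_registry():
    return sorted(_REGISTRY)


def desk_fixture(name: str) -> System:
    """Small registry systems with attached expectation records."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_registry())}")
    return _REGISTRY[name]()
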