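"""Nanoparticle mechanical classes and their internal energetics.

Four classes are modeled, spanning the rigidity spectrum of ligand-coated
nanocarriers:

``RG``
    Rigid sphere (radius 50 nm) with ligands grafted radially; no internal
    degrees of freedom, internal energy identically zero.
``SRG``
    Semirigid: rigid spherical core (50 nm) with flexible polymeric tethers
    bearing the ligands; each tether is a harmonic spring from a surface
    anchor to the mobile ligand tip.
``LSt`` / ``HSt``
    Deformable core-shell particles (lysozyme-core/dextran-shell style),
    represented bead-spring: ``f`` arms of ``n_beads_per_arm`` beads grafted
    to a small core, ligand tips tethered to the outer-shell beads.  The
    low-stiffness variant has no crosslinks; the high-stiffness variant adds
    a dense network of crosslink springs between neighboring beads, which is
    what limits its deformability.

All coordinates are world-space nm; energies k_BT.  Rigid-body moves
transform every block (beads, tips, anchors) consistently, so internal
energy is exactly invariant under them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import stiffness_kbt

__all__ = [
    "Nanoparticle",
    "build_rigid_np",
    "build_semirigid_np",
    "build_coreshell_np",
    "np_internal_energy",
    "np_internal_energy_positions",
    "np_rigid_body_move",
    "estimate_elastic_modulus",
    "fibonacci_sphere",
]

#: default soft-sphere overlap stiffness (k_BT/nm^2); form not given by the
#: source model, documented in docs/methods.md
DEFAULT_EV_STIFFNESS = 2.0

# Table-derived defaults (SI stiffnesses in N/m = J/m^2)
K_SPRING_CORESHELL = 1.74e-4
K_TETHER_SRG = 3.3e-4
BEAD_RADIUS = 6.8
BEAD_MASS = 1.44e-19 * 1e-3  # g -> kg
LIGAND_LENGTH = 15.0
RECEPTOR_COUNT_FULL = 162
#: Kuhn segment length of the shell polymer (nm)
KUHN_LENGTH = 0.44


def ligand_tether_stiffness(ligand_length: float = LIGAND_LENGTH,
                            kuhn_length: float = KUHN_LENGTH) -> float:
    """Entropic-spring stiffness (k_BT/nm^2) of the ligand linker, treated
    as a Gaussian chain of its contour length in Kuhn segments:
    k = 3 k_BT / (N_k b_k^2)."""
    n_k = max(1.0, ligand_length / kuhn_length)
    return 3.0 / (n_k * kuhn_length ** 2)


def fibonacci_sphere(n: int, seed: int = 0) -> np.ndarray:
    """Quasi-uniform unit directions; deterministically rotated by seed."""
    k = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    rot = Rotation.random(random_state=np.random.default_rng(seed))
    return pts @ rot.as_matrix().T


@dataclass
class Nanoparticle:
    class_tag: str                      # RG | SRG | LSt | HSt
    core_center: np.ndarray             # (3,)
    core_radius: float
    beads: np.ndarray                   # (n_beads, 3); empty for RG/SRG
    tips: np.ndarray                    # (N_l, 3) ligand tip positions
    anchors: np.ndarray                 # (N_l, 3) SRG tether anchors; empty otherwise
    bead_radius: float = BEAD_RADIUS
    bead_mass: float = BEAD_MASS
    tip_mass: float = 5.0e-24
    ligand_length: float = LIGAND_LENGTH
    # harmonic network (k in k_BT/nm^2, rest lengths nm)
    springs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    spring_rest: np.ndarray = field(default_factory=lambda: np.zeros(0))
    spring_k: float = 0.0
    core_spring_beads: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    core_spring_rest: np.ndarray = field(default_factory=lambda: np.zeros(0))
    crosslinks: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    crosslink_rest: np.ndarray = field(default_factory=lambda: np.zeros(0))
    crosslink_k: float = 0.0
    tip_parent: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    tether_rest: float = 0.0
    tether_k: float = 0.0
    ev_stiffness: float = DEFAULT_EV_STIFFNESS
    arm_of_bead: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    rest_reach: float = 0.0          # max tip distance from core at build
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("core_center", "beads", "tips", "anchors"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.rest_reach == 0.0 and self.tips.size:
            self.rest_reach = float(np.max(np.linalg.norm(
                self.tips - self.core_center, axis=1)))

    # -- derived ----------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return int(self.beads.shape[0])

    @property
    def n_ligands(self) -> int:
        return int(self.tips.shape[0])

    @property
    def is_rigid(self) -> bool:
        return self.class_tag == "RG"

    @property
    def tips_mobile(self) -> bool:
        return self.class_tag != "RG"

    def copy(self) -> "Nanoparticle":
        return replace(
            self,
            core_center=self.core_center.copy(),
            beads=self.beads.copy(),
            tips=self.tips.copy(),
            anchors=self.anchors.copy(),
        )

    def internal_coordinates(self) -> np.ndarray:
        """Stacked fluctuating coordinates (beads then tips), (n, 3)."""
        return np.vstack([self.beads, self.tips])

    def internal_masses(self) -> np.ndarray:
        return np.concatenate([
            np.full(self.n_beads, self.bead_mass),
            np.full(self.n_ligands, self.tip_mass),
        ])


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_rigid_np(n_ligands: int = RECEPTOR_COUNT_FULL, radius: float = 50.0,
                   ligand_length: float = LIGAND_LENGTH, seed: int = 0,
                   center=(0.0, 0.0, 0.0)) -> Nanoparticle:
    """Rigid sphere with radially grafted ligands (tips at R + L_l)."""
    u = fibonacci_sphere(n_ligands, seed)
    center = np.asarray(center, dtype=np.float64)
    return Nanoparticle(
        class_tag="RG", core_center=center, core_radius=radius,
        beads=np.zeros((0, 3)), tips=center + (radius + ligand_length) * u,
        anchors=np.zeros((0, 3)), ligand_length=ligand_length, seed=seed)


def build_semirigid_np(n_ligands: int = RECEPTOR_COUNT_FULL, radius: float = 50.0,
                       ligand_length: float = LIGAND_LENGTH,
                       k_tether_si: float = K_TETHER_SRG, seed: int = 0,
                       center=(0.0, 0.0, 0.0)) -> Nanoparticle:
    """Rigid core with flexible ligand-bearing tethers (anchor->tip springs)."""
    u = fibonacci_sphere(n_ligands, seed)
    center = np.asarray(center, dtype=np.float64)
    return Nanoparticle(
        class_tag="SRG", core_center=center, core_radius=radius,
        beads=np.zeros((0, 3)),
        tips=center + (radius + ligand_length) * u,
        anchors=center + radius * u,
        ligand_length=ligand_length,
        tether_rest=ligand_length, tether_k=stiffness_kbt(k_tether_si),
        seed=seed)


def build_coreshell_np(f: int = 25, n_beads_per_arm: int = 4,
                       k_s_si: float = K_SPRING_CORESHELL,
                       crosslink_fraction: float = 0.0, seed: int = 0,
                       a_bead: float = BEAD_RADIUS, core_radius: float = 16.0,
                       n_ligands: int = RECEPTOR_COUNT_FULL,
                       ligand_length: float = LIGAND_LENGTH,
                       k_crosslink_si: Optional[float] = None,
                       class_tag: Optional[str] = None,
                       center=(0.0, 0.0, 0.0)) -> Nanoparticle:
    """Deformable core-shell NP: ``f`` bead-spring arms on a small core.

    ``crosslink_fraction`` is the realized fraction of candidate crosslink
    pairs (same-shell nearest neighbors from different arms).  Zero yields the
    uncrosslinked low-stiffness (LSt) topology; a dense fraction the
    high-stiffness (HSt) one.  Deterministic for fixed seed.
    """
    if f < 1 or n_beads_per_arm < 1:
        raise ValueError("f and n_beads_per_arm must be >= 1")
    if not 0.0 <= crosslink_fraction <= 1.0:
        raise ValueError("crosslink_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=np.float64)
    dirs = fibonacci_sphere(f, seed)

    radii = core_radius + a_bead * (2.0 * np.arange(n_beads_per_arm) + 1.0)
    beads = (dirs[:, None, :] * radii[None, :, None]).reshape(-1, 3) + center
    arm_of_bead = np.repeat(np.arange(f), n_beads_per_arm)
    level_of_bead = np.tile(np.arange(n_beads_per_arm), f)

    # consecutive-bead springs along each arm
    idx = np.arange(f * n_beads_per_arm).reshape(f, n_beads_per_arm)
    springs = np.vstack([np.stack([idx[:, i], idx[:, i + 1]], axis=1)
                         for i in range(n_beads_per_arm - 1)]) \
        if n_beads_per_arm > 1 else np.zeros((0, 2), dtype=np.int64)
    springs = springs.astype(np.int64)
    spring_rest = np.full(springs.shape[0], 2.0 * a_bead)
    core_spring_beads = idx[:, 0].astype(np.int64)
    core_spring_rest = np.full(f, core_radius + a_bead)

    # crosslink candidates: per shell level, 3 nearest neighbors across arms
    candidates = set()
    for level in range(n_beads_per_arm):
        members = np.where(level_of_bead == level)[0]
        p = beads[members]
        d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        for a_i, row in enumerate(d):
            for b_i in np.argsort(row)[:3]:
                pair = tuple(sorted((int(members[a_i]), int(members[b_i]))))
                candidates.add(pair)
    candidates = sorted(candidates)
    n_pick = int(round(crosslink_fraction * len(candidates)))
    pick = rng.permutation(len(candidates))[:n_pick] if n_pick else []
    crosslinks = (np.asarray([candidates[i] for i in sorted(pick)], dtype=np.int64)
                  if n_pick else np.zeros((0, 2), dtype=np.int64))
    crosslink_rest = (np.linalg.norm(beads[crosslinks[:, 0]] - beads[crosslinks[:, 1]], axis=1)
                      if n_pick else np.zeros(0))

    # ligand tips on the outer shell, round-robin over arms, small cone jitter
    outer = idx[:, -1]
    tip_parent = outer[np.arange(n_ligands) % f].astype(np.int64)
    tether_rest = a_bead + ligand_length
    jitter_angle = 0.35  # rad, spreads several tips per outer bead
    tips = np.empty((n_ligands, 3))
    for li in range(n_ligands):
        d0 = dirs[tip_parent[li] // n_beads_per_arm]
        # deterministic tangent frame
        t1 = np.cross(d0, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-8:
            t1 = np.cross(d0, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(d0, t1)
        k = li // f
        ang = 2.399963 * li  # golden-angle fan
        tilt = jitter_angle if k > 0 else 0.0
        dvec = (np.cos(tilt) * d0 +
                np.sin(tilt) * (np.cos(ang) * t1 + np.sin(ang) * t2))
        tips[li] = beads[tip_parent[li]] + tether_rest * dvec

    tag = class_tag
    if tag is None:
        tag = "LSt" if crosslink_fraction < 0.5 else "HSt"
    k_x = k_s_si if k_crosslink_si is None else k_crosslink_si
    return Nanoparticle(
        class_tag=tag, core_center=center, core_radius=core_radius,
        beads=beads, tips=tips, anchors=np.zeros((0, 3)),
        bead_radius=a_bead, ligand_length=ligand_length,
        springs=springs, spring_rest=spring_rest,
        spring_k=stiffness_kbt(k_s_si),
        core_spring_beads=core_spring_beads, core_spring_rest=core_spring_rest,
        crosslinks=crosslinks, crosslink_rest=crosslink_rest,
        crosslink_k=stiffness_kbt(k_x),
        tip_parent=tip_parent, tether_rest=tether_rest,
        tether_k=ligand_tether_stiffness(ligand_length),
        arm_of_bead=arm_of_bead, seed=seed)


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------

def _pair_overlap_energy(p: np.ndarray, radii_sum: float, k_ev: float) -> float:
    """Soft-sphere repulsion (k_ev/2)*(overlap)^2 over all pairs of ``p``."""
    n = p.shape[0]
    if n < 2:
        return 0.0
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    overlap = np.maximum(0.0, radii_sum - d[iu])
    return float(0.5 * k_ev * np.sum(overlap ** 2))


def np_internal_energy(nano: Nanoparticle) -> float:
    """Internal elastic energy (springs + crosslinks + tethers + overlap), k_BT.

    Zero at the build (rest) geometry; exactly invariant under rigid-body
    motion.  Rigid particles return 0 identically.
    """
    return np_internal_energy_positions(nano)


def np_internal_energy_positions(nano: Nanoparticle,
                                 beads: Optional[np.ndarray] = None,
                                 tips: Optional[np.ndarray] = None) -> float:
    """Internal energy with optional trial bead/tip position overrides."""
    if nano.is_rigid:
        return 0.0
    e = 0.0
    b = nano.beads if beads is None else beads
    tp = nano.tips if tips is None else tips
    if nano.springs.shape[0]:
        d = np.linalg.norm(b[nano.springs[:, 0]] - b[nano.springs[:, 1]], axis=1)
        e += 0.5 * nano.spring_k * np.sum((d - nano.spring_rest) ** 2)
    if nano.core_spring_beads.shape[0]:
        d = np.linalg.norm(b[nano.core_spring_beads] - nano.core_center, axis=1)
        e += 0.5 * nano.spring_k * np.sum((d - nano.core_spring_rest) ** 2)
    if nano.crosslinks.shape[0]:
        d = np.linalg.norm(b[nano.crosslinks[:, 0]] - b[nano.crosslinks[:, 1]], axis=1)
        e += 0.5 * nano.crosslink_k * np.sum((d - nano.crosslink_rest) ** 2)
    if nano.class_tag == "SRG":
        d = np.linalg.norm(tp - nano.anchors, axis=1)
        e += 0.5 * nano.tether_k * np.sum((d - nano.tether_rest) ** 2)
    elif nano.n_beads:
        d = np.linalg.norm(tp - b[nano.tip_parent], axis=1)
        e += 0.5 * nano.tether_k * np.sum((d - nano.tether_rest) ** 2)
        e += _pair_overlap_energy(b, 2.0 * nano.bead_radius, nano.ev_stiffness)
        # bead-core overlap
        dc = np.linalg.norm(b - nano.core_center, axis=1)
        ov = np.maximum(0.0, nano.core_radius + nano.bead_radius - dc)
        e += float(0.5 * nano.ev_stiffness * np.sum(ov ** 2))
    return float(e)


def np_rigid_body_move(nano: Nanoparticle, translation: np.ndarray,
                       rotation: Optional[Rotation] = None) -> Nanoparticle:
    """Rigid transform (rotation about the core center, then translation).

    Returns a new particle; all blocks move consistently, so pairwise
    distances and internal energy are preserved.
    """
    t = np.asarray(translation, dtype=np.float64)
    out = nano.copy()
    c = nano.core_center
    if rotation is not None:
        R = rotation.as_matrix()
        for name in ("beads", "tips", "anchors"):
            arr = getattr(out, name)
            if arr.size:
                setattr(out, name, (arr - c) @ R.T + c)
    out.core_center = c + t
    for name in ("beads", "tips", "anchors"):
        arr = getattr(out, name)
        if arr.size:
            setattr(out, name, arr + t)
    return out


def estimate_elastic_modulus(nano: Nanoparticle, strain: float = 0.05) -> float:
    """Apparent elastic modulus (Pa) from an affine uniaxial compression probe.

    The particle is affinely compressed along z about its center by ``strain``
    and the stored elastic energy U maps to a modulus via U = (1/2) E eps^2 V
    with V the circumscribing sphere volume.  This is the in-repo calibration
    probe for the crosslink-density -> stiffness mapping; it orders LSt below
    HSt as the physical particles are ordered.
    """
    if nano.is_rigid:
        return float("inf")
    squeezed = nano.copy()
    c = nano.core_center
    for name in ("beads", "tips", "anchors"):
        arr = getattr(squeezed, name)
        if arr.size:
            arr = arr.copy()
            arr[:, 2] = c[2] + (1.0 - strain) * (arr[:, 2] - c[2])
            setattr(squeezed, name, arr)
    u_kbt = np_internal_energy(squeezed) - np_internal_energy(nano)
    coords = nano.internal_coordinates()
    r_out = float(np.max(np.linalg.norm(coords - c, axis=1))) if coords.size else nano.core_radius
    vol_nm3 = 4.0 / 3.0 * np.pi * r_out ** 3
    kbt_per_nm3_to_pa = 4.11433402e-21 / 1e-27
    return float(2.0 * u_kbt / (strain ** 2 * vol_nm3) * kbt_per_nm3_to_pa)
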