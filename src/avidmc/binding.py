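"""Ligand-receptor energetics and bond Monte Carlo moves.

Bond model
----------
A formed ligand-receptor bond carries a Bell-type energy

    E_bond(d) = dG0 + (1/2) k_b (d - d0)^2        [k_BT]

where ``d`` is the ligand-tip to receptor-anchor separation and the rest
length ``d0`` equals the receptor rod length L_ant: the rod pivots about its
membrane anchor and its bound orientation is slaved to the bond direction,
so the tip-tip contact condition becomes |tip - anchor| = L_ant.  The well
depth dG0 < 0 is the monovalent binding free energy.  Bound receptors also
pay a flexural energy (1/2)(k_f/L_ant) theta^2 for tilting away from the
local membrane normal; unbound rods are free (their orientation is
integrated out).

Bond formation/breakage is sampled with a configurational-bias move:
formation proposes a partner among all capture-range candidates with
Rosenbluth (Boltzmann) weights, breakage picks a bond uniformly, and the
acceptance rules below satisfy detailed balance with respect to the total
energy (verified against exact partition-function enumeration in the tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .constants import PNNM_TO_KBT, stiffness_kbt

__all__ = [
    "BondModel",
    "BINDERS",
    "ReceptorField",
    "bell_bond_energy",
    "receptor_flexural_energy",
    "bond_geometry",
    "rod_orientation_penalty",
    "pair_bond_energies",
    "enumerate_bond_candidates",
    "cbmc_bond_move",
    "effective_stiffness",
    "receptor_hop_move",
]

#: capture window: harmonic term at the window edge (k_BT); spec'd default
CAPTURE_ENERGY = 5.0


@dataclass(frozen=True)
class BondModel:
    """One binder system: well depth, stiffness and geometry of the bond."""

    binder_class: str          # strong | intermediate | weak
    dG0: float                 # k_BT (< 0)
    k_b_si: float              # N/m
    rest_length: float = 19.0  # nm (= receptor rod length by convention)
    capture_energy: float = CAPTURE_ENERGY

    def __post_init__(self) -> None:
        if self.dG0 >= 0:
            raise ValueError("binder well depth dG0 must be negative")
        if self.k_b_si <= 0:
            raise ValueError("bond stiffness must be positive")

    @property
    def k_b(self) -> float:
        """Bond stiffness in k_BT/nm^2."""
        return stiffness_kbt(self.k_b_si)

    @property
    def capture_halfwidth(self) -> float:
        """Half-width delta of the capture window, (1/2) k_b delta^2 = E_cap."""
        return math.sqrt(2.0 * self.capture_energy / self.k_b)

    @property
    def capture_cutoff(self) -> float:
        return self.rest_length + self.capture_halfwidth


#: the three binder systems studied (monovalent well depth, bond stiffness)
BINDERS = {
    "strong": BondModel("strong", dG0=-19.1, k_b_si=1.0),
    "intermediate": BondModel("intermediate", dG0=-11.45, k_b_si=0.38),
    "weak": BondModel("weak", dG0=-1.76, k_b_si=0.56),
}


@dataclass
class ReceptorField:
    """Mobile flexural-rod receptors anchored to the membrane.

    ``bound_partner[j]`` is the ligand index bound to receptor ``j`` or -1;
    the matching is one-to-one.  Anchor positions are stored as in-plane
    coordinates; their height and local normal are interpolated from the
    membrane surface and cached by the engine.
    """

    anchors_xy: np.ndarray                  # (N_r, 2) nm
    rod_length: float = 19.0                # L_ant, nm
    flexural_rigidity: float = 7000.0       # k_f, pN nm^2
    mass: float = 1.5e-22                   # kg; enters ln(Lambda) only
    bound_partner: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.anchors_xy = np.asarray(self.anchors_xy, dtype=np.float64)
        if self.bound_partner is None:
            self.bound_partner = np.full(self.n_receptors, -1, dtype=np.int64)

    @property
    def n_receptors(self) -> int:
        return int(self.anchors_xy.shape[0])

    @property
    def n_bound(self) -> int:
        return int(np.count_nonzero(self.bound_partner >= 0))

    @property
    def flexural_k(self) -> float:
        """Angular spring constant k_f / L_ant, in k_BT/rad^2."""
        return self.flexural_rigidity / self.rod_length * PNNM_TO_KBT

    def check_matching(self, n_ligands: int) -> bool:
        b = self.bound_partner[self.bound_partner >= 0]
        return (b.size == np.unique(b).size) and np.all(b < n_ligands)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def bell_bond_energy(d, bm: BondModel):
    """Bell bond energy (k_BT) at separation ``d`` (nm).

    Minimum dG0 at d = d0; no bond exists beyond the capture cutoff (+inf
    there, so trial moves cannot stretch a bond past capture range).
    """
    d = np.asarray(d, dtype=np.float64)
    e = bm.dG0 + 0.5 * bm.k_b * (d - bm.rest_length) ** 2
    out = np.where(d <= bm.capture_cutoff, e, np.inf)
    return out if out.ndim else float(out)


def receptor_flexural_energy(theta, flexural_k: float, bound=True):
    """Harmonic rod-bending energy (k_BT); active only for bound receptors."""
    theta = np.asarray(theta, dtype=np.float64)
    e = np.where(bound, 0.5 * flexural_k * theta ** 2, 0.0)
    return e if e.ndim else float(e)


def bond_geometry(tips: np.ndarray, anchors: np.ndarray, normals: np.ndarray,
                  box: Optional[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Separations d and tilt angles theta for tip/anchor pairs (row-wise)."""
    dvec = np.atleast_2d(tips) - np.atleast_2d(anchors)
    if box is not None:
        dvec = dvec.copy()
        dvec[:, :2] -= box * np.round(dvec[:, :2] / box)
    d = np.linalg.norm(dvec, axis=1)
    u = dvec / np.maximum(d[:, None], 1e-12)
    ct = np.clip(np.einsum("ij,ij->i", u, np.atleast_2d(normals)), -1.0, 1.0)
    return d, np.arccos(ct)


#: 1 M standard-state volume (nm^3) used to map solution binding free
#: energies onto the tethered geometry
V_STANDARD = 1.0 / 0.6022


def rod_orientation_penalty(d, bm: BondModel, rod_length: float):
    """Standard-state anchoring cost (k_BT) of a rod-tethered bond.

    The monovalent well depth dG0 is a solution binding free energy, so the
    statistical weight of a formed bond is K_A * rho_tip, with
    K_A = v0 exp(-dG0) (v0 the 1 M standard-state volume) and rho_tip the
    spatial density of the free rod's tip at the ligand position: the rod
    pivots on its anchor, spreading its tip over a shell of area 2 pi L d
    and radial width sigma_d = k_b^{-1/2} (the bond compliance).  Written as
    an energy this contributes

        + ln( 2 pi L d sigma_d sqrt(2 pi) / v0 )

    per bond (~5-6 k_BT for the studied binders).  Omitting it would
    overstate binding of stiff bonds; integrating the rod orientation as an
    additional free degree of freedom would double-count phase space already
    contained in the measured dG0.
    """
    d = np.maximum(np.asarray(d, dtype=np.float64), 0.1 * rod_length)
    sigma_d = 1.0 / math.sqrt(bm.k_b)
    out = np.log(2.0 * np.pi * rod_length * d * sigma_d
                 * math.sqrt(2.0 * math.pi) / V_STANDARD)
    return out if out.ndim else float(out)


def pair_bond_energies(tips, anchors, normals, bm: BondModel,
                       flexural_k: float, box=None, rod_length: float = 19.0):
    """Total bond-state free energies for tip/anchor pairs.

    Bell well + harmonic stretch + flexural tilt + rod-orientation pinning.
    """
    d, theta = bond_geometry(tips, anchors, normals, box)
    return (bell_bond_energy(d, bm) + 0.5 * flexural_k * theta ** 2
            + rod_orientation_penalty(d, bm, rod_length))


def effective_stiffness(k_b: float, k_m: float) -> float:
    """Series combination k_eff = k_b k_m / (k_b + k_m) of bond and membrane
    stiffness (mean-field membrane surrogate)."""
    if k_b <= 0 or k_m <= 0:
        raise ValueError("stiffnesses must be positive")
    return k_b * k_m / (k_b + k_m)


# ---------------------------------------------------------------------------
# candidates and configurational-bias bond moves
# ---------------------------------------------------------------------------

def enumerate_bond_candidates(tips: np.ndarray, ligand_free: np.ndarray,
                              anchors: np.ndarray, anchor_normals: np.ndarray,
                              receptor_free: np.ndarray, bm: BondModel,
                              flexural_k: float, box: Optional[float],
                              rod_length: float = 19.0):
    """All unbound ligand/receptor pairs within capture range.

    Returns ``(lig_idx, rec_idx, energies)`` for pairs with
    |d - d0| <= capture halfwidth, under the in-plane minimum-image
    convention.  Complexity O(N_l N_r), fully vectorized.
    """
    li = np.where(ligand_free)[0]
    rj = np.where(receptor_free)[0]
    if li.size == 0 or rj.size == 0:
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(0))
    dvec = tips[li][:, None, :] - anchors[rj][None, :, :]
    if box is not None:
        dvec[..., :2] -= box * np.round(dvec[..., :2] / box)
    d = np.linalg.norm(dvec, axis=2)
    delta = bm.capture_halfwidth
    mask = np.abs(d - bm.rest_length) <= delta
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                np.zeros(0))
    dv = dvec[ii, jj]
    dd = d[ii, jj]
    u = dv / dd[:, None]
    ct = np.clip(np.einsum("ij,ij->i", u, anchor_normals[rj[jj]]), -1.0, 1.0)
    theta = np.arccos(ct)
    e = (bm.dG0 + 0.5 * bm.k_b * (dd - bm.rest_length) ** 2
         + 0.5 * flexural_k * theta ** 2
         + rod_orientation_penalty(dd, bm, rod_length))
    return li[ii], rj[jj], e


@dataclass
class BondMoveResult:
    kind: str          # "form" | "break" | "gibbs"
    accepted: bool
    delta_energy: float = 0.0
    ligand: int = -1
    receptor: int = -1
    parts: Optional[dict] = None   # per-component energy deltas (default: bond)


def _candidate_weights(system) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    rec = system.receptors
    ligand_free = system.ligand_bound < 0
    receptor_free = rec.bound_partner < 0
    return enumerate_bond_candidates(
        system.nano.tips, ligand_free, system.rec_anchor_pos(),
        system.rec_normals, receptor_free, system.bond_model,
        rec.flexural_k, system.mesh.box, rec.rod_length)


def _inplace_form(system, rng, n_bonds) -> BondMoveResult:
    """Rosenbluth-weighted formation among current capture-range candidates."""
    rec = system.receptors
    li, rj, e = _candidate_weights(system)
    if li.size == 0:
        return BondMoveResult("form", False)
    w = np.exp(-e)
    W = float(w.sum())
    pick = rng.choice(li.size, p=w / W)
    if rng.random() < min(1.0, W / (n_bonds + 1.0)):
        l, r = int(li[pick]), int(rj[pick])
        system.ligand_bound[l] = r
        rec.bound_partner[r] = l
        return BondMoveResult("form", True, float(e[pick]), l, r)
    return BondMoveResult("form", False)


def _inplace_break(system, rng, n_bonds) -> BondMoveResult:
    """Uniform bond removal balanced against the Rosenbluth formation."""
    rec = system.receptors
    if n_bonds == 0:
        return BondMoveResult("break", False)
    bound_rec = np.where(rec.bound_partner >= 0)[0]
    r = int(bound_rec[rng.integers(bound_rec.size)])
    l = int(rec.bound_partner[r])
    e_cur = float(system.bond_energy_of(r))
    rec.bound_partner[r] = -1          # Rosenbluth sum of post-removal state
    system.ligand_bound[l] = -1
    _, _, e_after = _candidate_weights(system)
    W_after = float(np.exp(-e_after).sum())
    if W_after > 0 and rng.random() < min(1.0, n_bonds / W_after):
        return BondMoveResult("break", True, -e_cur, l, r)
    rec.bound_partner[r] = l           # revert
    system.ligand_bound[l] = r
    return BondMoveResult("break", False)


#: radial width (nm) of the capture-ring proposal; efficiency only, the
#: bias is cancelled exactly in the acceptance
_RING_WIDTH = 1.0


def _ring_radius(system, l: int) -> float:
    """Radius of the in-plane circle where an anchor sits one rod length
    from ligand tip ``l`` (the sweet spot of bond formation)."""
    d0 = system.bond_model.rest_length
    h = float(system.nano.tips[l, 2] - system._tip_sample.z[l])
    h = min(max(h, 0.0), d0 - 0.5)
    return math.sqrt(d0 * d0 - h * h)


def _form_proposal_density(system, l: int, rho: float) -> float:
    """Mixture density (per nm^2) of the anchor proposal around tip ``l``:
    half uniform over the capture disk, half a Gaussian ring at the
    capture radius."""
    r_g = system.bond_model.capture_cutoff
    s = _RING_WIDTH
    rho_star = _ring_radius(system, l)
    z_norm = 0.5 * (1.0 + math.erf(rho_star / (s * math.sqrt(2.0))))
    f_rho = (math.exp(-0.5 * ((rho - rho_star) / s) ** 2)
             / (s * math.sqrt(2.0 * math.pi) * z_norm))
    g_ring = f_rho / (2.0 * math.pi * max(rho, 0.2))
    g_disk = 1.0 / (math.pi * r_g * r_g) if rho <= r_g else 0.0
    return 0.5 * g_disk + 0.5 * g_ring


def _reloc_form(system, rng, n_bonds) -> BondMoveResult:
    """Biased formation: regrow a free receptor's anchor next to a free
    ligand tip (mixture of capture-disk and capture-ring proposals) and
    bind it there.

    Acceptance min(1, e^{-E} N_fL N_fR / ((B+1) A g)) balances exactly
    against :func:`_reloc_break`, which relocates the freed anchor
    uniformly over the patch.
    """
    from . import membrane as mb

    rec = system.receptors
    free_l = np.where(system.ligand_bound < 0)[0]
    free_r = np.where(rec.bound_partner < 0)[0]
    if free_l.size == 0 or free_r.size == 0:
        return BondMoveResult("form", False)
    l = int(free_l[rng.integers(free_l.size)])
    r = int(free_r[rng.integers(free_r.size)])
    bm = system.bond_model
    box = system.mesh.box
    r_g = bm.capture_cutoff
    if rng.random() < 0.5:          # uniform over the capture disk
        rho = r_g * math.sqrt(rng.random())
    else:                           # Gaussian ring at the capture radius
        rho_star = _ring_radius(system, l)
        for _ in range(10):
            rho = rho_star + _RING_WIDTH * rng.standard_normal()
            if rho > 0:
                break
        else:
            return BondMoveResult("form", False)
    phi = 2.0 * np.pi * rng.random()
    new_xy = np.mod(system.nano.tips[l, :2]
                    + [rho * math.cos(phi), rho * math.sin(phi)], box)
    g = _form_proposal_density(system, l, rho)
    sample = mb.surface_sample_one(system.mesh, new_xy[0], new_xy[1])
    anchor = np.array([[new_xy[0], new_xy[1], sample.z[0]]])
    e = float(pair_bond_energies(system.nano.tips[l][None, :], anchor,
                                 sample.normals, bm, rec.flexural_k,
                                 box=box, rod_length=rec.rod_length)[0])
    if not np.isfinite(e):
        return BondMoveResult("form", False)
    area = box * box
    ratio = (math.exp(-e) * free_l.size * free_r.size
             / ((n_bonds + 1.0) * area * g))
    if rng.random() < min(1.0, ratio):
        rec.anchors_xy[r] = new_xy
        system.install_receptor_sample(r, sample)
        system.ligand_bound[l] = r
        rec.bound_partner[r] = l
        return BondMoveResult("form", True, e, l, r)
    return BondMoveResult("form", False)


def _reloc_break(system, rng, n_bonds) -> BondMoveResult:
    """Reverse of :func:`_reloc_form`: break a bond and scatter the anchor
    uniformly over the patch."""
    from . import membrane as mb

    rec = system.receptors
    if n_bonds == 0:
        return BondMoveResult("break", False)
    bound_rec = np.where(rec.bound_partner >= 0)[0]
    r = int(bound_rec[rng.integers(bound_rec.size)])
    l = int(rec.bound_partner[r])
    e_cur = float(system.bond_energy_of(r))
    box = system.mesh.box
    area = box * box
    dxy = rec.anchors_xy[r] - system.nano.tips[l, :2]
    dxy = dxy - box * np.round(dxy / box)
    g = _form_proposal_density(system, l, float(np.hypot(*dxy)))
    n_fl = int(np.count_nonzero(system.ligand_bound < 0)) + 1
    n_fr = int(np.count_nonzero(rec.bound_partner < 0)) + 1
    ratio = math.exp(e_cur) * n_bonds * area * g / (n_fl * n_fr)
    if rng.random() < min(1.0, ratio):
        new_xy = rng.uniform(0.0, box, 2)
        sample = mb.surface_sample_one(system.mesh, new_xy[0], new_xy[1])
        rec.bound_partner[r] = -1
        system.ligand_bound[l] = -1
        rec.anchors_xy[r] = new_xy
        system.install_receptor_sample(r, sample)
        return BondMoveResult("break", True, -e_cur, l, r)
    return BondMoveResult("break", False)


def _tether_reference(nano, l: int) -> Tuple[np.ndarray, float, float]:
    """Tether anchor point, rest length and stiffness for ligand ``l``."""
    if nano.class_tag == "SRG":
        ref = nano.anchors[l]
    else:
        ref = nano.beads[nano.tip_parent[l]]
    return ref, nano.tether_rest, nano.tether_k


def _q_tether(tip: np.ndarray, ref: np.ndarray, r0: float, k_t: float) -> float:
    """Density (nm^-3) of the tether-cloud tip proposal: uniform direction,
    radius ~ Normal(r0, k_t^{-1/2}) truncated to r > 0."""
    sig = 1.0 / math.sqrt(k_t)
    r = float(np.linalg.norm(tip - ref))
    if r < 1e-9:
        return 0.0
    z_t = 0.5 * (1.0 + math.erf(r0 / (sig * math.sqrt(2.0))))
    f_r = (math.exp(-0.5 * ((r - r0) / sig) ** 2)
           / (sig * math.sqrt(2.0 * math.pi) * z_t))
    return f_r / (4.0 * math.pi * r * r)


def _sample_tether(ref: np.ndarray, r0: float, k_t: float, rng) -> np.ndarray:
    sig = 1.0 / math.sqrt(k_t)
    for _ in range(20):
        r = r0 + sig * rng.standard_normal()
        if r > 0:
            break
    else:
        r = r0
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    return ref + r * u


def _q_bond(tip: np.ndarray, anchor: np.ndarray, normal: np.ndarray,
            bm: BondModel, flex_k: float, box) -> float:
    """Density (nm^-3) of the bond-shaped tip proposal around a receptor:
    direction truncated-Rayleigh in the tilt angle (matching the flexural
    Boltzmann factor), separation ~ Normal(d0, k_b^{-1/2})."""
    dvec = tip - anchor
    if box is not None:
        dvec = dvec.copy()
        dvec[:2] -= box * np.round(dvec[:2] / box)
    d = float(np.linalg.norm(dvec))
    if d < 1e-9:
        return 0.0
    ct = float(np.clip(np.dot(dvec / d, normal), -1.0, 1.0))
    theta = math.acos(ct)
    if theta >= 0.5 * math.pi:
        return 0.0
    sig_d = 1.0 / math.sqrt(bm.k_b)
    f_d = (math.exp(-0.5 * ((d - bm.rest_length) / sig_d) ** 2)
           / (sig_d * math.sqrt(2.0 * math.pi)))
    z_ang = 1.0 - math.exp(-0.5 * flex_k * (0.5 * math.pi) ** 2)
    p_theta = (flex_k * theta * math.exp(-0.5 * flex_k * theta * theta)
               / z_ang)
    sin_t = max(math.sin(theta), 1e-9)
    return f_d * p_theta / (2.0 * math.pi * sin_t) / (d * d)


def _sample_bond_tip(anchor: np.ndarray, normal: np.ndarray, bm: BondModel,
                     flex_k: float, rng) -> np.ndarray:
    z_ang = 1.0 - math.exp(-0.5 * flex_k * (0.5 * math.pi) ** 2)
    theta = math.sqrt(-2.0 / flex_k * math.log(1.0 - z_ang * rng.random()))
    phi = 2.0 * math.pi * rng.random()
    d = bm.rest_length + rng.standard_normal() / math.sqrt(bm.k_b)
    t1 = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(normal, [1.0, 0.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    u = (math.cos(theta) * normal
         + math.sin(theta) * (math.cos(phi) * t1 + math.sin(phi) * t2))
    return anchor + d * u


def _near_receptors(system, free_r: np.ndarray) -> np.ndarray:
    """Free receptors within binding reach of the particle (in-plane).

    The radius (rest reach + capture range + 40 nm of tether slack) is a
    state-independent bound on any anchor a bond could involve, which keeps
    the regrowth move pair reversible."""
    nano = system.nano
    box = system.mesh.box
    r_near = (nano.rest_reach + system.bond_model.capture_cutoff + 40.0)
    axy = system.receptors.anchors_xy[free_r] - nano.core_center[:2]
    if box is not None:
        axy = axy - box * np.round(axy / box)
    return free_r[np.hypot(axy[:, 0], axy[:, 1]) <= r_near]


def _tip_regrow_form(system, rng, n_bonds) -> BondMoveResult:
    """Configurational-bias formation by ligand regrowth: pick a free
    receptor and a free ligand, regrow the ligand tip directly into a
    bond-shaped configuration around the receptor (Rosenbluth-style biased
    growth), and bind.  Balanced against :func:`_tip_regrow_break`, which
    regrows the freed tip back into its tether cloud.

    This decouples bond formation from the instantaneous tip presentation
    height, which is what equilibrates multivalent (saturated) states of
    deformable particles within reachable run lengths.
    """
    from . import membrane as mb

    rec = system.receptors
    nano = system.nano
    free_l = np.where(system.ligand_bound < 0)[0]
    free_r = np.where(rec.bound_partner < 0)[0]
    if free_l.size == 0 or free_r.size == 0:
        return BondMoveResult("form", False)
    near_r = _near_receptors(system, free_r)
    if near_r.size == 0:
        return BondMoveResult("form", False)
    l = int(free_l[rng.integers(free_l.size)])
    r = int(near_r[rng.integers(near_r.size)])
    anchor = system.rec_anchor_pos(np.array([r]))[0]
    normal = system.rec_normals[r]
    bm = system.bond_model
    flex_k = rec.flexural_k
    new_tip = _sample_bond_tip(anchor, normal, bm, flex_k, rng)
    q_fwd = _q_bond(new_tip, anchor, normal, bm, flex_k, system.mesh.box)
    if q_fwd <= 0:
        return BondMoveResult("form", False)
    ref, r0, k_t = _tether_reference(nano, l)
    q_rev = _q_tether(nano.tips[l], ref, r0, k_t)
    e_bond = float(pair_bond_energies(
        new_tip[None, :], anchor[None, :], normal[None, :], bm, flex_k,
        box=system.mesh.box, rod_length=rec.rod_length)[0])
    d_teth = (0.5 * k_t * (np.linalg.norm(new_tip - ref) - r0) ** 2
              - 0.5 * k_t * (np.linalg.norm(nano.tips[l] - ref) - r0) ** 2)
    sub = mb.surface_sample_one(system.mesh, new_tip[0], new_tip[1])
    pen_new = 0.5 * system.tip_penalty_stiffness * \
        max(0.0, sub.z[0] - new_tip[2]) ** 2
    pen_old = 0.5 * system.tip_penalty_stiffness * \
        max(0.0, system._tip_sample.z[l] - nano.tips[l, 2]) ** 2
    d_e = e_bond + float(d_teth) + pen_new - pen_old
    if not math.isfinite(d_e):
        return BondMoveResult("form", False)
    ratio = (math.exp(-d_e) * free_l.size * near_r.size * q_rev
             / ((n_bonds + 1.0) * q_fwd))
    if rng.random() < min(1.0, ratio):
        nano.tips[l] = new_tip
        system.install_tip_sample(l, sub)
        system.ligand_bound[l] = r
        rec.bound_partner[r] = l
        res = BondMoveResult("form", True, d_e, l, r)
        res.parts = {"bond": e_bond, "np_internal": float(d_teth),
                     "overlap": pen_new - pen_old}
        return res
    return BondMoveResult("form", False)


def _tip_regrow_break(system, rng, n_bonds) -> BondMoveResult:
    """Reverse of :func:`_tip_regrow_form`: break a bond and regrow the
    freed tip into its tether cloud."""
    from . import membrane as mb

    rec = system.receptors
    nano = system.nano
    if n_bonds == 0:
        return BondMoveResult("break", False)
    bound_rec = np.where(rec.bound_partner >= 0)[0]
    r = int(bound_rec[rng.integers(bound_rec.size)])
    l = int(rec.bound_partner[r])
    anchor = system.rec_anchor_pos(np.array([r]))[0]
    normal = system.rec_normals[r]
    bm = system.bond_model
    flex_k = rec.flexural_k
    e_bond = float(system.bond_energy_of(r))
    ref, r0, k_t = _tether_reference(nano, l)
    new_tip = _sample_tether(ref, r0, k_t, rng)
    q_fwd = _q_tether(new_tip, ref, r0, k_t)
    q_rev = _q_bond(nano.tips[l], anchor, normal, bm, flex_k, system.mesh.box)
    if q_fwd <= 0 or q_rev <= 0:
        return BondMoveResult("break", False)
    d_teth = (0.5 * k_t * (np.linalg.norm(new_tip - ref) - r0) ** 2
              - 0.5 * k_t * (np.linalg.norm(nano.tips[l] - ref) - r0) ** 2)
    sub = mb.surface_sample_one(system.mesh, new_tip[0], new_tip[1])
    pen_new = 0.5 * system.tip_penalty_stiffness * \
        max(0.0, sub.z[0] - new_tip[2]) ** 2
    pen_old = 0.5 * system.tip_penalty_stiffness * \
        max(0.0, system._tip_sample.z[l] - nano.tips[l, 2]) ** 2
    d_e = -e_bond + float(d_teth) + pen_new - pen_old
    n_fl = int(np.count_nonzero(system.ligand_bound < 0)) + 1
    # reverse formation selects among near free receptors incl. this one
    n_near = _near_receptors(system,
                             np.where(rec.bound_partner < 0)[0]).size + 1
    ratio = (math.exp(-d_e) * n_bonds * q_rev / (n_fl * n_near * q_fwd))
    if rng.random() < min(1.0, ratio):
        rec.bound_partner[r] = -1
        system.ligand_bound[l] = -1
        nano.tips[l] = new_tip
        system.install_tip_sample(l, sub)
        res = BondMoveResult("break", True, d_e, l, r)
        res.parts = {"bond": -e_bond, "np_internal": float(d_teth),
                     "overlap": pen_new - pen_old}
        return res
    return BondMoveResult("break", False)


def _gibbs_partner(system, rng) -> BondMoveResult:
    """Heat-bath resampling of one receptor's bond state.

    Conditional on everything else, a receptor is either unbound (weight 1)
    or bound to one of the ligands within capture range (weight exp(-E)).
    Sampling that conditional exactly is rejection-free and lets
    quasi-irreversible strong bonds exchange partners instead of having to
    fully dissociate, which is what equilibrates saturated states.
    """
    rec = system.receptors
    n = rec.n_receptors
    if n == 0:
        return BondMoveResult("gibbs", False)
    r = int(rng.integers(n))
    l_old = int(rec.bound_partner[r])
    e_old = system.bond_energy_of(r) if l_old >= 0 else 0.0
    # ligands available to r: free ones plus its current partner
    avail = np.where(system.ligand_bound < 0)[0]
    if l_old >= 0:
        avail = np.concatenate([avail, [l_old]])
    if avail.size == 0:
        return BondMoveResult("gibbs", False)
    anchor = system.rec_anchor_pos(np.array([r]))
    nrm = system.rec_normals[r][None, :]
    bm = system.bond_model
    dvec = system.nano.tips[avail] - anchor
    if system.mesh.box is not None:
        dvec[:, :2] -= system.mesh.box * np.round(dvec[:, :2] / system.mesh.box)
    d = np.linalg.norm(dvec, axis=1)
    in_range = np.abs(d - bm.rest_length) <= bm.capture_halfwidth
    cand = avail[in_range]
    if cand.size == 0 and l_old < 0:
        return BondMoveResult("gibbs", False)
    energies = np.array([
        pair_bond_energies(system.nano.tips[c][None, :], anchor, nrm, bm,
                           rec.flexural_k, box=system.mesh.box,
                           rod_length=rec.rod_length)[0]
        for c in cand])
    w = np.concatenate([[1.0], np.exp(-energies)])   # slot 0 = unbound
    pick = int(rng.choice(w.size, p=w / w.sum()))
    if l_old >= 0:
        rec.bound_partner[r] = -1
        system.ligand_bound[l_old] = -1
    if pick == 0:
        changed = l_old >= 0
        return BondMoveResult("gibbs", changed, -e_old if changed else 0.0,
                              l_old, r)
    l_new = int(cand[pick - 1])
    rec.bound_partner[r] = l_new
    system.ligand_bound[l_new] = r
    e_new = float(energies[pick - 1])
    changed = l_new != l_old
    return BondMoveResult("gibbs", True, e_new - e_old, l_new, r)


def cbmc_bond_move(system, rng: np.random.Generator) -> BondMoveResult:
    """One configurational-bias bond move (formation or breakage).

    Three balanced flavors, each exact on its own:

    * in-place: formation draws a partner among capture-range candidates
      with Rosenbluth weights w_i = exp(-E_i), accepted with
      min(1, W/(B+1)); breakage removes a uniform bond with min(1, B/W').
    * regrowth (skipped when ``system.relocation_bond_moves`` is false,
      e.g. frozen-receptor toys): formation relocates a free receptor anchor
      into the capture disk of a free ligand tip; breakage scatters the
      freed anchor uniformly.  The proposal bias is cancelled in the
      acceptance, which is what makes stiff (sub-nm capture window) bonds
      sampleable at all.
    * heat-bath partner resampling (:func:`_gibbs_partner`), which exchanges
      partners of strong bonds without full dissociation.

    * ligand regrowth (:func:`_tip_regrow_form` / ``_break``; mobile tips
      only): the tip itself is regrown into a bond-shaped configuration
      around a receptor, with the tether cloud as the reverse proposal.

    Exactness is verified against partition-function enumeration on toys.
    """
    n_bonds = system.receptors.n_bound
    reloc_ok = getattr(system, "relocation_bond_moves", True)
    regrow_ok = reloc_ok and system.nano is not None and system.nano.tips_mobile
    u = rng.random()
    form = rng.random() < 0.5
    if u < 0.25:
        return _gibbs_partner(system, rng)
    if u < 0.5:
        if regrow_ok:
            return (_tip_regrow_form if form else _tip_regrow_break)(
                system, rng, n_bonds)
        return (_inplace_form if form else _inplace_break)(
            system, rng, n_bonds)
    if u < 0.75 and reloc_ok:
        return (_reloc_form if form else _reloc_break)(system, rng, n_bonds)
    return (_inplace_form if form else _inplace_break)(system, rng, n_bonds)


# ---------------------------------------------------------------------------
# receptor diffusion
# ---------------------------------------------------------------------------

@dataclass
class HopProposal:
    new_xy: np.ndarray
    delta_energy: float
    sample: object = None   # SurfaceSample at the trial anchor


def receptor_hop_move(system, index: int, amplitude: float,
                      rng: np.random.Generator) -> HopProposal:
    """Trial lateral anchor displacement (bounded hop, periodic wrap).

    Unbound receptors diffuse freely (dE = 0); bound receptors drag the bond
    and flexural energy change into dE.
    """
    from . import membrane as mb

    rec = system.receptors
    old_xy = rec.anchors_xy[index]
    new_xy = np.mod(old_xy + rng.uniform(-amplitude, amplitude, 2),
                    system.mesh.box)
    sample = mb.surface_sample_one(system.mesh, new_xy[0], new_xy[1])
    l = int(rec.bound_partner[index])
    if l < 0:
        return HopProposal(new_xy, 0.0, sample)
    e_old = system.bond_energy_of(index)
    anchor = np.array([[new_xy[0], new_xy[1], sample.z[0]]])
    e_new = pair_bond_energies(system.nano.tips[l][None, :], anchor,
                               sample.normals, system.bond_model,
                               rec.flexural_k, box=system.mesh.box,
                               rod_length=rec.rod_length)[0]
    return HopProposal(new_xy, float(e_new - e_old), sample)
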