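"""Thermodynamic decomposition, multivalency statistics and phase diagrams.

The binding free energy is decomposed as dF = dH - T dS, with the entropy
change split into three configurational terms, each evaluated as a
bound-minus-unbound difference under identical sampling protocols:

* particle entropy from a classical quasiharmonic analysis of bead/tip
  fluctuations (eigenvalues of the mass-weighted positional covariance);
* membrane entropy from the same covariance-spectrum construction applied
  to the out-of-plane vertex displacements;
* receptor translational entropy from the two-dimensional Sackur-Tetrode
  equation, with bound receptors removed from the mobile count and the
  accessible area reduced by the adhesion footprint.

Multivalency is summarized by the bond-number distribution P(m), its mean
<m>, the ligand-normalized coverage theta = <m>/N_l, and the selectivity
index alpha = d ln(theta)/d ln(N_r); alpha >= 1 flags a superselective
response.  Free-energy contrasts between membrane excess-area rows use
Welch's two-sample test with Benjamini-Hochberg control of the false
discovery rate across all contrasts of a diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats
from scipy.spatial import ConvexHull, QhullError
from statsmodels.stats.multitest import multipletests

from .constants import HBAR_J, KB_J, T_REF, thermal_wavelength_nm

__all__ = [
    "ThermoResult",
    "PhaseTile",
    "binding_enthalpy",
    "quasiharmonic_entropy",
    "membrane_entropy_delta",
    "receptor_translational_entropy",
    "receptor_entropy_delta",
    "binding_free_energy",
    "multivalency_distribution",
    "coverage_theta",
    "selectivity_index",
    "welch_bh_contrast",
    "welch_test",
    "build_phase_diagram",
    "align_frames",
    "analyze_ensembles",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ThermoResult:
    """Free-energy decomposition (all energies in k_BT, entropies as T*dS)."""

    dH: float
    TdS_np: float
    TdS_mem: float
    TdS_rec: float
    temperature: float = T_REF
    dH_sd: float = 0.0
    TdS_sd: float = 0.0
    mean_m: float = 0.0

    @property
    def TdS_total(self) -> float:
        return self.TdS_np + self.TdS_mem + self.TdS_rec

    @property
    def dF(self) -> float:
        return self.dH - self.TdS_total

    @property
    def dF_sd(self) -> float:
        return math.hypot(self.dH_sd, self.TdS_sd)

    def per_bond(self) -> Optional[Dict[str, float]]:
        """Per-bond quantities; undefined when no bonds form."""
        if self.mean_m <= 0:
            return None
        m = self.mean_m
        return {"dF": self.dF / m, "dH": self.dH / m,
                "TdS": self.TdS_total / m}

    def as_dict(self) -> Dict[str, float]:
        d = {"dH": self.dH, "TdS_np": self.TdS_np, "TdS_mem": self.TdS_mem,
             "TdS_rec": self.TdS_rec, "TdS_total": self.TdS_total,
             "dF": self.dF, "dH_sd": self.dH_sd, "TdS_sd": self.TdS_sd,
             "dF_sd": self.dF_sd, "mean_m": self.mean_m,
             "temperature": self.temperature}
        return d


@dataclass
class PhaseTile:
    """One (A_ex, N_r) tile of a mechanics-affinity phase diagram."""

    a_ex: float
    n_r: int
    dF: float
    dF_sd: float
    theta: float
    alpha: Optional[float] = None
    alpha_valid: bool = False
    q_value: Optional[float] = None
    contrast_favors: Optional[float] = None   # more favorable A_ex row

    THETA_STAR = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0 + 1e-9:
            raise ValueError("theta must lie in [0, 1]")

    @property
    def coverage_marker(self) -> bool:
        return self.theta >= self.THETA_STAR

    @property
    def superselective(self) -> bool:
        return bool(self.alpha_valid and self.alpha is not None
                    and self.alpha >= 1.0)

    @property
    def significant(self) -> bool:
        return self.q_value is not None and self.q_value < 0.05


# ---------------------------------------------------------------------------
# enthalpy
# ---------------------------------------------------------------------------

def binding_enthalpy(bound, unbound, component: str = "total"):
    """dH = <H>_bound - <H>_unbound with replica SD.

    Accepts :class:`~avidmc.mc_engine.EnsembleResult` pairs (replica SD over
    matched replicas) or single trajectories (SD = 0).  Protocol mismatch
    (different replica counts) raises.
    """
    def means(x):
        if hasattr(x, "trajectories"):
            return np.array([t.mean_energy(component) for t in x.trajectories])
        return np.array([x.mean_energy(component)])

    mb_, mu_ = means(bound), means(unbound)
    if mb_.size != mu_.size:
        raise ValueError("bound and unbound ensembles use different protocols "
                         f"({mb_.size} vs {mu_.size} replicas)")
    diff = mb_ - mu_
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def align_frames(frames: np.ndarray, reference: Optional[np.ndarray] = None
                 ) -> np.ndarray:
    """Remove rigid-body motion (Kabsch superposition onto a reference)."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, n_particles, 3)")
    ref = (frames[0] if reference is None else reference).copy()
    ref -= ref.mean(axis=0)
    out = np.empty_like(frames)
    for k, fr in enumerate(frames):
        x = fr - fr.mean(axis=0)
        h = x.T @ ref
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out[k] = x @ rot
    return out


def quasiharmonic_entropy(samples: np.ndarray, masses_kg: np.ndarray,
                          temperature: float = T_REF,
                          min_samples: int = 50,
                          mode_filter: float = 1e-10,
                          align: bool = False) -> float:
    """Classical quasiharmonic entropy (units of k_B) from coordinate samples.

    ``samples`` is (n_frames, n_particles, 3) in nm (or (n_frames, K) with
    per-coordinate masses).  Each eigenvalue ``mu`` of the mass-weighted
    covariance maps to an oscillator of frequency ``omega = sqrt(kT/mu)``
    contributing ``S_i/k_B = 1 + (1/2) ln(kT mu / hbar^2)`` in the classical
    (high-temperature) limit.  Near-zero modes below ``mode_filter`` times
    the largest eigenvalue are discarded as rigid-body/constraint modes.
    """
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim == 3:
        if align:
            s = align_frames(s)
        n, p, _ = s.shape
        coord_masses = np.repeat(np.asarray(masses_kg, dtype=np.float64), 3)
        s = s.reshape(n, 3 * p)
    else:
        n = s.shape[0]
        coord_masses = np.asarray(masses_kg, dtype=np.float64)
        if coord_masses.size == 1:
            coord_masses = np.full(s.shape[1], float(coord_masses))
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} decorrelated samples, got {n}")
    q = s * np.sqrt(coord_masses)[None, :] * 1e-9       # sqrt(kg) * m
    q = q - q.mean(axis=0)
    cov = q.T @ q / (n - 1)
    evals = np.linalg.eigvalsh(cov)
    # absolute floor (kg m^2) far below any physical mode: discards pure
    # numerical-noise directions left by alignment or frozen coordinates
    evals = evals[evals > 1e-60]
    if evals.size == 0:
        raise ValueError("covariance is rank-deficient beyond filter "
                         "tolerance (no fluctuating modes)")
    top = evals[-1]
    keep = evals[evals > mode_filter * top]
    if keep.size == 0:
        raise ValueError("covariance is rank-deficient beyond filter tolerance")
    kt = KB_J * temperature
    s_per_mode = 1.0 + 0.5 * np.log(kt * keep / HBAR_J ** 2)
    return float(np.sum(s_per_mode))


def membrane_entropy_delta(z_bound: np.ndarray, z_unbound: np.ndarray,
                           vertex_mass: float,
                           temperature: float = T_REF, **kw) -> float:
    """dS_MEM (k_B): vertex-fluctuation entropy, bound minus unbound."""
    def entropy(z):
        z = np.asarray(z, dtype=np.float64)
        return quasiharmonic_entropy(z, np.full(z.shape[1], vertex_mass),
                                     temperature, **kw)
    return entropy(z_bound) - entropy(z_unbound)


def receptor_translational_entropy(n_r: float, area_nm2: float,
                                   receptor_mass: float = 1.5e-22,
                                   temperature: float = T_REF) -> float:
    """2-D Sackur-Tetrode entropy (k_B): S = N [ln(A/(N Lambda^2)) + 2]."""
    if n_r < 1 or area_nm2 <= 0 or receptor_mass <= 0:
        raise ValueError("need n_r >= 1, positive area and mass")
    lam = thermal_wavelength_nm(receptor_mass, temperature)
    return float(n_r * (math.log(area_nm2 / (n_r * lam ** 2)) + 2.0))


def _footprint_area(bound_xy: np.ndarray) -> float:
    """Adhesion footprint estimated from the convex hull of bound anchors."""
    if bound_xy.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(bound_xy).volume)   # 2-D hull: volume == area
    except QhullError:
        return 0.0


def receptor_entropy_delta(n_r: int, area_nm2: float, mean_bound: float,
                           bound_anchors_xy: Optional[np.ndarray] = None,
                           receptor_mass: float = 1.5e-22,
                           temperature: float = T_REF,
                           bond_well_area: float = 10.0) -> float:
    """dS_REC (k_B), bound minus unbound.

    Convention: the mobile remainder explores the patch area minus the
    adhesion footprint (convex hull of the bound anchors); each bound
    receptor keeps the translational entropy of its own bond well of
    in-plane area ``bond_well_area`` (the annulus 2 pi d0 sigma_d for the
    binder at hand) instead of being deleted from the count — deleting it
    would charge the full absolute Sackur-Tetrode entropy per bond and
    double-count confinement already carried by the bond free energy.
    Returns 0 when nothing binds.
    """
    if mean_bound <= 0:
        return 0.0
    lam = thermal_wavelength_nm(receptor_mass, temperature)
    fp = _footprint_area(bound_anchors_xy) if bound_anchors_xy is not None else 0.0
    a_eff = max(area_nm2 - fp, 0.01 * area_nm2)
    n_free = n_r - mean_bound
    s_bound = mean_bound * (math.log(bond_well_area / lam ** 2) + 2.0)
    if n_free >= 1:
        s_bound += receptor_translational_entropy(n_free, a_eff,
                                                  receptor_mass, temperature)
    s_unbound = receptor_translational_entropy(n_r, area_nm2, receptor_mass,
                                               temperature)
    return s_bound - s_unbound


def binding_free_energy(dH: float, TdS_np: float, TdS_mem: float,
                        TdS_rec: float, mean_m: float = 0.0,
                        dH_sd: float = 0.0, TdS_sd: float = 0.0,
                        temperature: float = T_REF) -> ThermoResult:
    """Assemble dF = dH - T dS with replica SDs propagated in quadrature."""
    return ThermoResult(dH=dH, TdS_np=TdS_np, TdS_mem=TdS_mem,
                        TdS_rec=TdS_rec, temperature=temperature,
                        dH_sd=dH_sd, TdS_sd=TdS_sd, mean_m=mean_m)


# ---------------------------------------------------------------------------
# multivalency statistics
# ---------------------------------------------------------------------------

def multivalency_distribution(m_series: np.ndarray, m_max: Optional[int] = None,
                              smooth_sigma: float = 1.5,
                              min_prominence: float = 0.02):
    """Normalized P(m), its mean, and mode locations.

    Modes are local maxima of a Gaussian-smoothed histogram with a minimum
    prominence (peak *locations* are the robust observable; heights of
    coexisting adhesion modes converge slowly and are not reported).
    """
    m = np.asarray(m_series)
    if m.size == 0:
        raise ValueError("empty multivalency series")
    if m_max is None:
        m_max = int(m.max())
    support = np.arange(m_max + 1)
    p = np.bincount(m, minlength=m_max + 1)[:m_max + 1] / m.size
    if smooth_sigma > 0 and p.size > 3:
        from scipy.ndimage import gaussian_filter1d
        ps = gaussian_filter1d(p, smooth_sigma, mode="nearest")
    else:
        ps = p
    peaks, _ = signal.find_peaks(ps, prominence=min_prominence)
    # include support endpoints (saturation peaks have no right flank)
    if ps.size > 1:
        if ps[0] > ps[1] + min_prominence:
            peaks = np.concatenate([[0], peaks])
        if ps[-1] > ps[-2] + min_prominence * 0.1 or p[-1] == p.max():
            if (p.size - 1) not in peaks:
                peaks = np.concatenate([peaks, [p.size - 1]])
    modes = sorted(int(x) for x in peaks)
    if not modes:
        modes = [int(np.argmax(p))]
    return support, p, float(m.mean()), modes


def coverage_theta(mean_m: float, n_ligands_total: int) -> float:
    """Ligand-normalized fractional coverage theta = <m>/N_l."""
    if n_ligands_total <= 0:
        raise ValueError("n_ligands_total must be positive")
    return float(np.clip(mean_m / n_ligands_total, 0.0, 1.0))


def selectivity_index(n_r_grid: Sequence[float], theta: Sequence[float],
                      window: Tuple[float, float] = (0.1, 0.9)):
    """alpha = d ln(theta)/d ln(N_r) by log-log finite differences.

    Central differences at interior points, one-sided at the edges; alpha is
    reported (``valid``) only where theta lies inside ``window`` (neither
    near zero nor saturated).  Points with theta = 0 are excluded.
    """
    n_r = np.asarray(n_r_grid, dtype=np.float64)
    th = np.asarray(theta, dtype=np.float64)
    if n_r.size != th.size or n_r.size < 2:
        raise ValueError("need matching grids with >= 2 points")
    alpha = np.full(n_r.size, np.nan)
    ok = th > 0
    if ok.sum() >= 2:
        ln_n, ln_t = np.log(n_r[ok]), np.log(th[ok])
        alpha[ok] = np.gradient(ln_t, ln_n)
    valid = ok & (th >= window[0]) & (th <= window[1]) & np.isfinite(alpha)
    return alpha, valid


# ---------------------------------------------------------------------------
# statistical contrasts
# ---------------------------------------------------------------------------

def welch_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite dof and two-sided p."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicate values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    dof = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return float(t), float(dof), float(p)


def welch_bh_contrast(groups_a: Iterable[Sequence[float]],
                      groups_b: Iterable[Sequence[float]],
                      alpha: float = 0.05):
    """Row contrasts (Welch) with Benjamini-Hochberg FDR across the family.

    ``groups_a``/``groups_b`` are matched lists of replicate dF values (one
    pair per N_r column).  Returns per-contrast p-values, BH q-values, star
    flags (q < alpha) and the sign of the favored group (-1: a more
    favorable, i.e. more negative; +1: b).
    """
    pvals, favors = [], []
    for a, b in zip(groups_a, groups_b, strict=True):
        _, _, p = welch_test(a, b)
        pvals.append(p)
        favors.append(-1.0 if np.mean(a) < np.mean(b) else 1.0)
    pvals = np.asarray(pvals)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pvals, qvals, reject, np.asarray(favors)


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

def build_phase_diagram(tiles: List[PhaseTile], expected_grid=None):
    """Tile table plus rendered figure for one binder/NP-class diagram.

    Returns ``(DataFrame, figure)``.  Missing tiles of ``expected_grid``
    (pairs of (a_ex, n_r)) raise instead of being silently dropped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    have = {(t.a_ex, t.n_r) for t in tiles}
    if expected_grid is not None:
        missing = [g for g in expected_grid if tuple(g) not in have]
        if missing:
            raise ValueError(f"missing phase-diagram tiles: {missing}")
    rows = [{
        "a_ex": t.a_ex, "n_r": t.n_r, "dF": t.dF, "dF_sd": t.dF_sd,
        "theta": t.theta, "coverage_marker": t.coverage_marker,
        "alpha": t.alpha if t.alpha_valid else np.nan,
        "superselective": t.superselective,
        "q_value": np.nan if t.q_value is None else t.q_value,
        "significant": t.significant,
    } for t in sorted(tiles, key=lambda t: (t.a_ex, t.n_r))]
    df = pd.DataFrame(rows)

    a_levels = sorted(df.a_ex.unique())
    n_levels = sorted(df.n_r.unique())
    fig, ax = plt.subplots(figsize=(1.6 * len(n_levels) + 2,
                                    1.4 * len(a_levels) + 1.5))
    vmin, vmax = df.dF.min(), max(df.dF.max(), df.dF.min() + 1e-9)
    cmap = plt.get_cmap("viridis_r")
    for t in tiles:
        i = a_levels.index(t.a_ex)
        j = n_levels.index(t.n_r)
        col = cmap((t.dF - vmin) / (vmax - vmin))
        ax.add_patch(plt.Rectangle((j, i), 1, 1, color=col))
        ax.add_patch(plt.Rectangle((j + 0.05, i + 0.8), 0.9 * t.theta, 0.12,
                                   color="0.25"))
        if t.coverage_marker:
            ax.plot(j + 0.5, i + 0.5, "o", color="white", ms=8)
        if t.alpha_valid and t.alpha is not None:
            h = 0.9 * min(abs(t.alpha), 2.0) / 2.0
            ax.add_patch(plt.Rectangle((j + 0.88, i + 0.05), 0.07, h,
                                       color="orange"))
            if t.superselective:
                ax.plot(j + 0.915, i + h + 0.1, "^", color="white", ms=6)
        if t.significant:
            ax.plot(j + 0.15, i + 0.15, "*", color="white", ms=9)
    ax.set_xlim(0, len(n_levels))
    ax.set_ylim(0, len(a_levels))
    ax.set_xticks([j + 0.5 for j in range(len(n_levels))],
                  [str(n) for n in n_levels])
    ax.set_yticks([i + 0.5 for i in range(len(a_levels))],
                  [f"{a:.0%}" for a in a_levels])
    ax.set_xlabel(r"receptor density $N_r$ per 0.25 $\mu$m$^2$")
    ax.set_ylabel(r"excess area $A_{ex}$")
    fig.tight_layout()
    return df, fig


# ---------------------------------------------------------------------------
# high-level pipeline
# ---------------------------------------------------------------------------

def analyze_ensembles(bound, unbound, system,
                      temperature: float = T_REF) -> ThermoResult:
    """Full dF = dH - T dS decomposition for a bound/unbound ensemble pair.

    Entropy components are computed from fluctuation records pooled per
    replica and averaged; replica SDs propagate into the dF error estimate.
    """
    dH, dH_sd = binding_enthalpy(bound, unbound)
    nano = system.nano
    masses = nano.internal_masses() if nano is not None else None
    area = system.mesh.projected_area
    rec = system.receptors
    tds_np, tds_mem, tds_rec = [], [], []
    for tb, tu in zip(bound.trajectories, unbound.trajectories, strict=True):
        if nano is not None and tb.nano_frames.shape[1] > 0 and not nano.is_rigid:
            s_b = quasiharmonic_entropy(tb.nano_frames, masses,
                                        temperature, align=True)
            s_u = quasiharmonic_entropy(tu.nano_frames, masses,
                                        temperature, align=True)
            tds_np.append(s_b - s_u)
        else:
            tds_np.append(0.0)
        tds_mem.append(membrane_entropy_delta(
            tb.mesh_z_frames, tu.mesh_z_frames, system.mesh.vertex_mass,
            temperature))
        mean_b = tb.mean_m
        if mean_b > 0 and tb.receptor_xy_frames.shape[0]:
            bound_idx = np.where(rec.bound_partner >= 0)[0]
            anchors = (tb.receptor_xy_frames[-1][bound_idx]
                       if bound_idx.size else None)
        else:
            anchors = None
        bm = system.bond_model
        well = 2.0 * math.pi * bm.rest_length / math.sqrt(bm.k_b)
        tds_rec.append(receptor_entropy_delta(
            rec.n_receptors, area, mean_b, anchors, rec.mass, temperature,
            bond_well_area=well))
    tds_np, tds_mem, tds_rec = map(np.asarray, (tds_np, tds_mem, tds_rec))
    tds_tot = tds_np + tds_mem + tds_rec
    tds_sd = float(tds_tot.std(ddof=1)) if tds_tot.size > 1 else 0.0
    mean_m = float(np.mean([t.mean_m for t in bound.trajectories]))
    return binding_free_energy(
        dH, float(tds_np.mean()), float(tds_mem.mean()),
        float(tds_rec.mean()), mean_m=mean_m, dH_sd=dH_sd, TdS_sd=tds_sd,
        temperature=temperature)
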