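"""Single-trajectory MM/GBSA binding free-energy scoring.

The binding free energy of the two-partner complex is estimated from the
complex trajectory alone (partner coordinates are extracted from the
complex frames), as the ensemble average of

    dG = G(complex) - G(partner A) - G(partner B)

with G = E_coulomb + E_vdw + G_GB + G_SA per species.  Bonded/internal
terms are identical between the complex and the extracted partners and
cancel in the difference, so they are omitted.  The polar solvation term
uses the generalized-Born pairwise formula with Hawkins-Cramer-Truhlar
(HCT) effective radii; the nonpolar term is gamma * SASA + b with SASA
from a deterministic Shrake-Rupley evaluation.  No entropy term is
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ppikit.structure_io import Structure, TrajectoryEnsemble

__all__ = [
    "GBSAConfig", "EnergyDecomposition", "BindingFreeEnergy",
    "mm_energy", "hct_born_radii", "gb_energy", "sasa",
    "group_energy", "binding_free_energy",
]

COULOMB_K = 332.0636  # kcal A / (mol e^2)
MIN_PAIR_DISTANCE = 0.1  # A; closer atoms indicate a broken geometry


class DescreeningError(ValueError):
    """HCT descreening produced a nonpositive effective Born radius."""


@dataclass(frozen=True)
class GBSAConfig:
    """Dielectrics, nonpolar coefficients and SASA resolution.

    surface_tension is in kcal/(mol A^2), probe_radius in A.  sphere_points
    controls the Shrake-Rupley resolution (>= 92 for sub-percent areas).
    """

    epsilon_solvent: float = 78.5
    epsilon_solute: float = 1.0
    surface_tension: float = 0.00542
    surface_offset: float = 0.0
    probe_radius: float = 1.4
    sphere_points: int = 960
    coulomb_constant: float = COULOMB_K

    def __post_init__(self) -> None:
        if not self.epsilon_solvent > self.epsilon_solute >= 1.0:
            raise ValueError("need epsilon_solvent > epsilon_solute >= 1")
        if self.sphere_points < 92:
            raise ValueError("sphere_points must be >= 92")


@dataclass(frozen=True)
class EnergyDecomposition:
    """Energy components (kcal/mol) of one species in one frame."""

    e_coulomb: float
    e_vdw: float
    g_gb: float
    g_sa: float
    frame: int
    species: str

    @property
    def g_total(self) -> float:
        return self.e_coulomb + self.e_vdw + self.g_gb + self.g_sa


def _require_parameters(topology: Structure, fields: tuple[str, ...]) -> None:
    missing = [a.name for a in topology.atoms
               if any(getattr(a, f) is None for f in fields)]
    if missing:
        raise ValueError(f"atoms lack force-field parameters: {missing[:5]}")


def _exclusions_12_13(topology: Structure) -> set[tuple[int, int]]:
    """Bonded 1-2 pairs plus 1-3 pairs through one intervening atom."""
    neigh: dict[int, set[int]] = {}
    excl: set[tuple[int, int]] = set()
    for i, j in topology.bonds:
        excl.add((min(i, j), max(i, j)))
        neigh.setdefault(i, set()).add(j)
        neigh.setdefault(j, set()).add(i)
    for centre, around in neigh.items():
        for i in around:
            for j in around:
                if i < j:
                    excl.add((i, j))
    return excl


def mm_energy(frame: np.ndarray, topology: Structure,
              group: np.ndarray | None = None,
              cfg: GBSAConfig = GBSAConfig(),
              ) -> tuple[float, float]:
    """Molecular-mechanics nonbonded energy of a group of atoms.

    Coulomb uses k_e q_i q_j / (eps_solute r); Lennard-Jones uses the
    eps/rmin form with geometric-mean epsilon and summed rmin halves.
    Bonded 1-2 and 1-3 pairs are excluded; no distance cutoff is applied.
    """
    _require_parameters(topology, ("charge", "lj_epsilon", "lj_rmin_half"))
    frame = np.asarray(frame, dtype=float)
    idx = np.arange(len(topology)) if group is None \
        else np.asarray(group, dtype=int)
    if idx.size < 2:
        return 0.0, 0.0
    q = np.array([topology.atoms[i].charge for i in idx])
    eps = np.array([topology.atoms[i].lj_epsilon for i in idx])
    rmh = np.array([topology.atoms[i].lj_rmin_half for i in idx])
    xyz = frame[idx]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    iu, ju = np.triu_indices(idx.size, k=1)
    r = d[iu, ju]
    if np.any(r < MIN_PAIR_DISTANCE):
        k = int(np.argmin(r))
        raise ValueError(
            f"overlapping atoms (r = {r[k]:.3f} A) between atoms "
            f"{idx[iu[k]]} and {idx[ju[k]]}")
    excl = _exclusions_12_13(topology)
    keep = np.array([(min(a, b), max(a, b)) not in excl
                     for a, b in zip(idx[iu], idx[ju])])
    r = r[keep]
    qq = (q[iu] * q[ju])[keep]
    eij = np.sqrt(eps[iu] * eps[ju])[keep]
    rmin = (rmh[iu] + rmh[ju])[keep]
    e_coulomb = float(cfg.coulomb_constant / cfg.epsilon_solute
                      * np.sum(qq / r))
    sr6 = (rmin / r) ** 6
    e_vdw = float(np.sum(eij * (sr6 ** 2 - 2.0 * sr6)))
    return e_coulomb, e_vdw


def hct_born_radii(frame: np.ndarray, topology: Structure,
                   group: np.ndarray) -> np.ndarray:
    """Effective Born radii by HCT pairwise descreening (no scaling).

    The inverse effective radius of atom i is its inverse intrinsic GB
    radius minus the summed analytic descreening integrals over every
    other atom of the group.  An isolated atom keeps its intrinsic radius
    exactly, which pins the Born-ion limit.
    """
    _require_parameters(topology, ("gb_radius",))
    idx = np.asarray(group, dtype=int)
    rho = np.array([topology.atoms[i].gb_radius for i in idx])
    xyz = np.asarray(frame, dtype=float)[idx]
    n = idx.size
    inv_r = 1.0 / rho
    for i in range(n):
        r = np.linalg.norm(xyz - xyz[i], axis=1)
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= r + rho > rho[i]  # j fully engulfed by i contributes 0
        rj = r[mask]
        sj = rho[mask]
        lower = np.maximum(rho[i], np.abs(rj - sj))
        upper = rj + sj
        term = 0.5 * ((1.0 / lower - 1.0 / upper)
                      + (rj / 4.0) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
                      + (1.0 / (2.0 * rj)) * np.log(lower / upper)
                      + (sj ** 2 / (4.0 * rj))
                      * (1.0 / lower ** 2 - 1.0 / upper ** 2))
        inv_r[i] -= term.sum()
        if inv_r[i] <= 0:
            a = topology.atoms[idx[i]]
            raise DescreeningError(
                f"nonpositive effective Born radius for atom "
                f"{a.resname}{a.resid}:{a.name}")
    return 1.0 / inv_r


def gb_energy(frame: np.ndarray, topology: Structure,
              group: np.ndarray | None = None,
              cfg: GBSAConfig = GBSAConfig()) -> float:
    """Generalized-Born polar solvation energy of a group (kcal/mol).

    dG_GB = -(k_e/2)(1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the i = j term
    reduces to the Born self energy with f_GB = R_i.
    """
    frame = np.asarray(frame, dtype=float)
    idx = np.arange(len(topology)) if group is None \
        else np.asarray(group, dtype=int)
    if idx.size == 0:
        return 0.0
    _require_parameters(topology, ("charge", "gb_radius"))
    q = np.array([topology.atoms[i].charge for i in idx])
    if not np.any(q):
        return 0.0
    radii = hct_born_radii(frame, topology, idx)
    xyz = frame[idx]
    r2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
    rirj = radii[:, None] * radii[None, :]
    f_gb = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    pref = -0.5 * cfg.coulomb_constant * (1.0 / cfg.epsilon_solute
                                          - 1.0 / cfg.epsilon_solvent)
    return float(pref * np.sum(np.outer(q, q) / f_gb))


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(frame: np.ndarray, topology: Structure,
         group: np.ndarray | None = None,
         cfg: GBSAConfig = GBSAConfig(),
         ) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    GB radii double as van der Waals radii.  Each atom is covered with a
    deterministic golden-spiral point set on its probe-expanded sphere; a
    point counts as exposed when outside every neighbour's expanded
    sphere.  Returns (per-atom areas, total).
    """
    _require_parameters(topology, ("gb_radius",))
    frame = np.asarray(frame, dtype=float)
    idx = np.arange(len(topology)) if group is None \
        else np.asarray(group, dtype=int)
    radii = np.array([topology.atoms[i].gb_radius for i in idx]) \
        + cfg.probe_radius
    xyz = frame[idx]
    sphere = _unit_sphere_points(cfg.sphere_points)
    tree = cKDTree(xyz)
    areas = np.zeros(idx.size)
    rmax = radii.max()
    for k in range(idx.size):
        pts = xyz[k] + radii[k] * sphere
        neigh = [j for j in tree.query_ball_point(xyz[k], radii[k] + rmax)
                 if j != k
                 and np.linalg.norm(xyz[j] - xyz[k]) < radii[k] + radii[j]]
        exposed = np.ones(cfg.sphere_points, dtype=bool)
        for j in neigh:
            exposed &= (np.linalg.norm(pts - xyz[j], axis=1) >= radii[j])
            if not exposed.any():
                break
        areas[k] = exposed.mean() * 4.0 * np.pi * radii[k] ** 2
    return areas, float(areas.sum())


def group_energy(frame: np.ndarray, topology: Structure,
                 group: np.ndarray | None, species: str, frame_index: int,
                 cfg: GBSAConfig = GBSAConfig()) -> EnergyDecomposition:
    """Full nonbonded + solvation decomposition of one species."""
    e_c, e_v = mm_energy(frame, topology, group, cfg)
    g_gb = gb_energy(frame, topology, group, cfg)
    _, total_sasa = sasa(frame, topology, group, cfg)
    g_sa = cfg.surface_tension * total_sasa + cfg.surface_offset
    return EnergyDecomposition(e_c, e_v, g_gb, g_sa, frame_index, species)


@dataclass
class BindingFreeEnergy:
    """Per-replica means and the grand mean +/- s.d. of dG_bind."""

    replica_means: list[float]
    mean: float
    sd: float
    per_frame: list[tuple[int, int, float]]  # (replica, frame, dG)
    decompositions: list[EnergyDecomposition]
    frame_stride: int


def binding_free_energy(ens: TrajectoryEnsemble,
                        cfg: GBSAConfig = GBSAConfig(),
                        frame_stride: int = 10) -> BindingFreeEnergy:
    """Single-trajectory MM/GBSA dG_bind over a replica ensemble.

    Partner coordinates are taken from the complex frames; per analysed
    frame dG = G(complex) - G(A) - G(B).  The headline number is the mean
    of per-replica means, +/- the standard deviation across replicas
    (ddof=1 when more than one replica).
    """
    top = ens.topology
    ia, ib = top.partner_indices("A"), top.partner_indices("B")
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both partners must be non-empty")
    all_idx = np.arange(len(top))
    per_frame = []
    decomps = []
    replica_means = []
    for r, frames in enumerate(ens.replicas):
        dgs = []
        for f_i in range(0, frames.shape[0], frame_stride):
            frame = frames[f_i]
            e_complex = group_energy(frame, top, all_idx, "complex", f_i, cfg)
            e_a = group_energy(frame, top, ia, "partnerA", f_i, cfg)
            e_b = group_energy(frame, top, ib, "partnerB", f_i, cfg)
            dg = e_complex.g_total - e_a.g_total - e_b.g_total
            dgs.append(dg)
            per_frame.append((r, f_i, dg))
            decomps.extend([e_complex, e_a, e_b])
        replica_means.append(float(np.mean(dgs)))
    mean = float(np.mean(replica_means))
    sd = float(np.std(replica_means, ddof=1)) if len(replica_means) > 1 else 0.0
    return BindingFreeEnergy(replica_means, mean, sd, per_frame, decomps,
                             frame_stride)
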