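"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by the most direct route available
(closed form, exhaustive enumeration, ODE integration), sharing no code
with the package paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """Minimum RMSD via Horn's quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    n = mobile.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else \
        np.asarray(weights, float) / np.sum(weights)
    x = mobile - (w[:, None] * mobile).sum(0)
    y = reference - (w[:, None] * reference).sum(0)
    sxx = x.T @ (w[:, None] * y)
    a = np.zeros((4, 4))
    a[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    a[0, 1] = a[1, 0] = sxx[1, 2] - sxx[2, 1]
    a[0, 2] = a[2, 0] = sxx[2, 0] - sxx[0, 2]
    a[0, 3] = a[3, 0] = sxx[0, 1] - sxx[1, 0]
    a[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    a[1, 2] = a[2, 1] = sxx[0, 1] + sxx[1, 0]
    a[1, 3] = a[3, 1] = sxx[0, 2] + sxx[2, 0]
    a[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    a[2, 3] = a[3, 2] = sxx[1, 2] + sxx[2, 1]
    a[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam_max = np.linalg.eigvalsh(a)[-1]
    gx = float((w * np.einsum("ij,ij->i", x, x)).sum())
    gy = float((w * np.einsum("ij,ij->i", y, y)).sum())
    msd = max(gx + gy - 2.0 * lam_max, 0.0)
    return float(np.sqrt(msd))


def brute_contacts(frame, topology, cutoff):
    """All-pairs heavy-atom contact residue pairs with min distances."""
    atoms = topology.atoms
    part = topology.partner_assignment or topology.default_partner_assignment()
    best = {}
    for i, ai in enumerate(atoms):
        if ai.element == "H" or part[ai.chain] != "A":
            continue
        for j, aj in enumerate(atoms):
            if aj.element == "H" or part[aj.chain] != "B":
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if d <= cutoff:
                key = (ai.residue_key, aj.residue_key)
                if key not in best or d < best[key]:
                    best[key] = d
    return best


def brute_hbonds(frame, topology, roles, dist_cutoff, angle_cutoff):
    """All donor x acceptor pairs passing distance + angle, keyed like the
    package's hbond records (resA/resB with atom names)."""
    atoms = topology.atoms
    part = topology.partner_assignment or topology.default_partner_assignment()
    found = set()
    for d_heavy, h in roles.donor_pairs:
        for acc in roles.acceptors:
            if part[atoms[acc].chain] == part[atoms[d_heavy].chain]:
                continue
            v_da = frame[acc] - frame[d_heavy]
            dist = float(np.linalg.norm(v_da))
            if dist > dist_cutoff or dist < 1e-9:
                continue
            v_dh = frame[h] - frame[d_heavy]
            cosang = float(v_dh @ v_da /
                           (np.linalg.norm(v_dh) * np.linalg.norm(v_da)))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang > angle_cutoff:
                continue
            if part[atoms[d_heavy].chain] == "A":
                found.add(("hbond", atoms[d_heavy].residue_key,
                           atoms[acc].residue_key,
                           (atoms[d_heavy].name, atoms[h].name),
                           (atoms[acc].name,)))
            else:
                found.add(("hbond", atoms[acc].residue_key,
                           atoms[d_heavy].residue_key,
                           (atoms[acc].name,),
                           (atoms[d_heavy].name, atoms[h].name)))
    return found


def brute_saltbridges(frame, topology, roles, cutoff):
    """All anionic-O x cationic-N cross-interface residue pairs."""
    atoms = topology.atoms
    part = topology.partner_assignment or topology.default_partner_assignment()
    pairs = set()
    for i in roles.anionic_atoms:
        for j in roles.cationic_atoms:
            if part[atoms[i].chain] == part[atoms[j].chain]:
                continue
            if np.linalg.norm(frame[i] - frame[j]) <= cutoff:
                if part[atoms[i].chain] == "A":
                    pairs.add(("saltbridge", atoms[i].residue_key,
                               atoms[j].residue_key))
                else:
                    pairs.add(("saltbridge", atoms[j].residue_key,
                               atoms[i].residue_key))
    return pairs


def brute_single_linkage(items, linked) -> list[list]:
    """Exhaustive single-linkage clustering by repeated merging."""
    clusters = [[x] for x in items]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(linked(a, b) for a in clusters[i]
                       for b in clusters[j]):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return sorted([sorted(c) for c in clusters], key=lambda c: c[0])


def mm_pair_oracle(coords, charges, epsilons, rmin_halves, excluded,
                   k_e=332.0636, eps_solute=1.0):
    """Direct double-loop Coulomb + LJ sums with explicit exclusions."""
    n = len(charges)
    e_c = e_v = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded or (j, i) in excluded:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            e_c += k_e * charges[i] * charges[j] / (eps_solute * r)
            eij = np.sqrt(epsilons[i] * epsilons[j])
            rmin = rmin_halves[i] + rmin_halves[j]
            e_v += eij * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    return e_c, e_v


def ode_sensorgram(times, ka, kd, rmax, conc, association_end):
    """Numerically integrated 1:1 Langmuir response dR/dt = kaC(Rmax-R)-kdR."""
    times = np.asarray(times, float)

    def rhs(t, r, c):
        return [ka * c * (rmax - r[0]) - kd * r[0]]

    assoc_t = times[times <= association_end]
    sol_a = solve_ivp(rhs, (times[0], association_end), [0.0], args=(conc,),
                      t_eval=assoc_t, rtol=1e-12, atol=1e-12, method="LSODA")
    r_end = sol_a.y[0, -1]
    dissoc_t = times[times > association_end]
    out = list(sol_a.y[0])
    if dissoc_t.size:
        sol_d = solve_ivp(rhs, (association_end, times[-1]), [r_end],
                          args=(0.0,), t_eval=dissoc_t, rtol=1e-12,
                          atol=1e-12, method="LSODA")
        out.extend(sol_d.y[0])
    return np.asarray(out)
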