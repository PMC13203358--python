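"""Frame-wise interfacial contact / hydrogen-bond / salt-bridge detection.

All three detectors use purely geometric criteria applied across the
partner interface:

* contact: any heavy-atom pair across the interface within the contact
  cutoff (default 3.5 A); one record per residue pair carrying the minimum
  distance.
* hydrogen bond: donor-heavy to acceptor distance within cutoff (default
  3.5 A) AND the deviation angle between the D->H and D->A vectors within
  the angle cutoff (default 30 deg), donor and acceptor on different
  partners.
* salt bridge: anionic side-chain oxygen to cationic side-chain nitrogen
  within cutoff (default 3.5 A).

Candidate pairs come from a scipy KD-tree; correctness is defined by (and
tested against) the all-pairs brute-force evaluation of the same criteria.
Occupancy is the fraction of analysed frames in which an interaction
satisfies its criteria, bookkept per replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ppikit.structure_io import ChemRoles, Structure, TrajectoryEnsemble

__all__ = [
    "GeometryCriteria", "InteractionRecord", "OccupancyTable",
    "detect_contacts_frame", "detect_hbonds_frame",
    "detect_saltbridges_frame", "detect_frame", "occupancy_over_ensemble",
]

ResKey = tuple[str, int, str]


@dataclass(frozen=True)
class GeometryCriteria:
    """Distance/angle cutoffs for the three interaction detectors."""

    contact_cutoff: float = 3.5       # A, heavy-atom
    hbond_dist_cutoff: float = 3.5    # A, donor-heavy to acceptor
    hbond_angle_cutoff: float = 30.0  # deg, deviation from linear D-H...A
    saltbridge_cutoff: float = 3.5    # A, anionic O to cationic N
    sidechain_only_contacts: bool = False

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hbond_dist_cutoff", "saltbridge_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hbond_angle_cutoff <= 90:
            raise ValueError("hbond_angle_cutoff must be in (0, 90] degrees")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction in one frame.

    resA is always the partner-A residue and resB the partner-B residue;
    atomsA/atomsB name the participating atoms (donor heavy + hydrogen on
    the donor side for hydrogen bonds).  geometry_distance is in A;
    geometry_angle (deg) is set for hydrogen bonds only.
    """

    kind: str
    resA: ResKey
    resB: ResKey
    atomsA: tuple[str, ...]
    atomsB: tuple[str, ...]
    frame: int
    geometry_distance: float
    geometry_angle: float | None = None

    @property
    def pair_key(self) -> tuple:
        """Bookkeeping key: residue pair for contacts/salt bridges, plus
        donor/acceptor atom names for hydrogen bonds."""
        if self.kind == "hbond":
            return (self.kind, self.resA, self.resB, self.atomsA, self.atomsB)
        return (self.kind, self.resA, self.resB)


_BACKBONE = {"N", "CA", "C", "O", "OXT", "HN", "H", "HA", "HA1", "HA2"}


def _partner_split(topology: Structure) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = topology.partner_indices("A"), topology.partner_indices("B")
    if ia.size == 0 or ib.size == 0:
        raise ValueError("partner assignment must cover both partners")
    if ia.size + ib.size != len(topology):
        raise ValueError("partner assignment must cover all atoms")
    return ia, ib


def _cross_pairs_within(frame: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                        cutoff: float) -> Iterable[tuple[int, int, float]]:
    """(i, j, distance) with i from ia, j from ib, distance <= cutoff."""
    if ia.size == 0 or ib.size == 0:
        return
    tree_b = cKDTree(frame[ib])
    tree_a = cKDTree(frame[ia])
    for a_loc, b_locs in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        i = int(ia[a_loc])
        for b_loc in b_locs:
            j = int(ib[b_loc])
            d = float(np.linalg.norm(frame[i] - frame[j]))
            yield i, j, d


def detect_contacts_frame(frame: np.ndarray, topology: Structure,
                          criteria: GeometryCriteria = GeometryCriteria(),
                          frame_index: int = 0) -> list[InteractionRecord]:
    """Residue pairs with any cross-interface heavy-atom pair in contact.

    One record per residue pair, carrying the minimum heavy-atom distance
    and the atom names realising it.
    """
    frame = np.asarray(frame, dtype=float)
    ia, ib = _partner_split(topology)
    atoms = topology.atoms

    def eligible(i: int) -> bool:
        if atoms[i].element == "H":
            return False
        if criteria.sidechain_only_contacts and atoms[i].name in _BACKBONE:
            return False
        return True

    ia = np.array([i for i in ia if eligible(i)], dtype=int)
    ib = np.array([i for i in ib if eligible(i)], dtype=int)
    best: dict[tuple[ResKey, ResKey], tuple[float, str, str]] = {}
    for i, j, d in _cross_pairs_within(frame, ia, ib, criteria.contact_cutoff):
        key = (atoms[i].residue_key, atoms[j].residue_key)
        if key not in best or d < best[key][0]:
            best[key] = (d, atoms[i].name, atoms[j].name)
    return [InteractionRecord("contact", ra, rb, (na,), (nb,),
                              frame_index, d)
            for (ra, rb), (d, na, nb) in sorted(best.items())]


def detect_hbonds_frame(frame: np.ndarray, topology: Structure,
                        roles: ChemRoles,
                        criteria: GeometryCriteria = GeometryCriteria(),
                        frame_index: int = 0) -> list[InteractionRecord]:
    """Cross-interface hydrogen bonds by the distance + angle criterion.

    A donor/acceptor pair is reported when the donor-heavy to acceptor
    distance is within the cutoff and the angle between the D->H and D->A
    vectors is within the angle cutoff.  Without any donor hydrogens the
    result is empty (structure_io already warned at role inference).
    """
    frame = np.asarray(frame, dtype=float)
    ia, ib = _partner_split(topology)
    part = np.empty(len(topology), dtype="U1")
    part[ia], part[ib] = "A", "B"
    atoms = topology.atoms
    acceptors = np.asarray(roles.acceptors, dtype=int)
    if acceptors.size == 0 or not roles.donor_pairs:
        return []
    acc_tree = cKDTree(frame[acceptors])
    cos_cut = np.cos(np.deg2rad(criteria.hbond_angle_cutoff))
    records = []
    for d_heavy, h in roles.donor_pairs:
        near = acc_tree.query_ball_point(frame[d_heavy],
                                         criteria.hbond_dist_cutoff)
        for loc in near:
            acc = int(acceptors[loc])
            if part[acc] == part[d_heavy]:
                continue
            v_dh = frame[h] - frame[d_heavy]
            v_da = frame[acc] - frame[d_heavy]
            dist = float(np.linalg.norm(v_da))
            if dist < 1e-9:
                continue
            cosang = float(v_dh @ v_da
                           / (np.linalg.norm(v_dh) * dist))
            if cosang < cos_cut:
                continue
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if part[d_heavy] == "A":
                rec = InteractionRecord(
                    "hbond", atoms[d_heavy].residue_key,
                    atoms[acc].residue_key,
                    (atoms[d_heavy].name, atoms[h].name),
                    (atoms[acc].name,), frame_index, dist, angle)
            else:
                rec = InteractionRecord(
                    "hbond", atoms[acc].residue_key,
                    atoms[d_heavy].residue_key,
                    (atoms[acc].name,),
                    (atoms[d_heavy].name, atoms[h].name),
                    frame_index, dist, angle)
            records.append(rec)
    return sorted(records, key=lambda r: (r.resA, r.resB, r.atomsA, r.atomsB))


def detect_saltbridges_frame(frame: np.ndarray, topology: Structure,
                             roles: ChemRoles,
                             criteria: GeometryCriteria = GeometryCriteria(),
                             frame_index: int = 0) -> list[InteractionRecord]:
    """Cross-interface anionic-O / cationic-N pairs within the cutoff.

    One record per residue pair with the minimum N-O distance.
    """
    frame = np.asarray(frame, dtype=float)
    ia, ib = _partner_split(topology)
    part = np.empty(len(topology), dtype="U1")
    part[ia], part[ib] = "A", "B"
    atoms = topology.atoms
    anion = np.asarray(roles.anionic_atoms, dtype=int)
    cation = np.asarray(roles.cationic_atoms, dtype=int)
    best: dict[tuple[ResKey, ResKey], tuple[float, str, str]] = {}
    for i in anion:
        for j in cation:
            if part[i] == part[j]:
                continue
            d = float(np.linalg.norm(frame[i] - frame[j]))
            if d > criteria.saltbridge_cutoff:
                continue
            if part[i] == "A":
                key = (atoms[i].residue_key, atoms[j].residue_key)
                names = (d, atoms[i].name, atoms[j].name)
            else:
                key = (atoms[j].residue_key, atoms[i].residue_key)
                names = (d, atoms[j].name, atoms[i].name)
            if key not in best or d < best[key][0]:
                best[key] = names
    return [InteractionRecord("saltbridge", ra, rb, (na,), (nb,),
                              frame_index, d)
            for (ra, rb), (d, na, nb) in sorted(best.items())]


def detect_frame(frame: np.ndarray, topology: Structure, roles: ChemRoles,
                 criteria: GeometryCriteria = GeometryCriteria(),
                 frame_index: int = 0) -> list[InteractionRecord]:
    """All three detectors on one frame."""
    return (detect_contacts_frame(frame, topology, criteria, frame_index)
            + detect_hbonds_frame(frame, topology, roles, criteria, frame_index)
            + detect_saltbridges_frame(frame, topology, roles, criteria,
                                       frame_index))


@dataclass
class OccupancyTable:
    """Per-replica occupancy of every interaction key seen in an ensemble.

    occupancy[key][r] is the fraction of analysed frames of replica r in
    which the interaction was present; frames_analyzed[r] the denominator.
    """

    occupancy: dict[tuple, np.ndarray]
    frames_analyzed: list[int]
    n_replicas: int

    def __post_init__(self) -> None:
        for key, occ in self.occupancy.items():
            if len(occ) != self.n_replicas:
                raise ValueError(f"{key}: occupancy length != n_replicas")
            if np.any(occ < 0) or np.any(occ > 1):
                raise ValueError(f"{key}: occupancies must lie in [0, 1]")

    def keys_of_kind(self, kind: str) -> list[tuple]:
        return [k for k in self.occupancy if k[0] == kind]


def occupancy_over_ensemble(ens: TrajectoryEnsemble, roles: ChemRoles,
                            criteria: GeometryCriteria = GeometryCriteria(),
                            analysis_window: slice | None = None,
                            ) -> OccupancyTable:
    """Run the detectors over every analysed frame of every replica.

    analysis_window restricts which frames enter the occupancy
    denominator (default: all frames).  Deterministic given its inputs.
    """
    window = analysis_window if analysis_window is not None else slice(None)
    counts: dict[tuple, np.ndarray] = {}
    frames_analyzed: list[int] = []
    for r, frames in enumerate(ens.replicas):
        sub = frames[window]
        if sub.shape[0] == 0:
            raise ValueError(f"replica {r}: empty analysis window")
        frames_analyzed.append(sub.shape[0])
        for f_i, frame in enumerate(sub):
            seen = {rec.pair_key
                    for rec in detect_frame(frame, ens.topology, roles,
                                            criteria, f_i)}
            for key in seen:
                if key not in counts:
                    counts[key] = np.zeros(ens.n_replicas)
                counts[key][r] += 1
    occ = {key: c / np.asarray(frames_analyzed, dtype=float)
           for key, c in counts.items()}
    return OccupancyTable(occ, frames_analyzed, ens.n_replicas)
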