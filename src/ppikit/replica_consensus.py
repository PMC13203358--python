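"""k-of-n replica consensus, interface clustering and blocker peptides.

An interaction nominated from replica MD is only trusted when it recurs in
independent runs: a pair counts as present in a replica when its occupancy
there reaches presence_occupancy_min, and is kept when it is present in at
least min_replicas_present of the replicas (default 3 of 4).  Kept
partner-B residues are clustered into candidate pockets, and short
blocking peptides are cut from the partner-B sequence so that each peptide
covers its anchor residues plus flanking context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ppikit.interface_geometry import OccupancyTable, ResKey
from ppikit.structure_io import Structure

__all__ = [
    "ConsensusConfig", "ConsensusRow", "ConsensusTable", "PeptideDesign",
    "consensus_pairs", "pool_alternative_partners", "interface_clusters",
    "design_peptides",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "HSE": "H", "HSP": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class ConsensusConfig:
    """k-of-n consensus thresholds.

    presence_occupancy_min is the occupancy fraction above which an
    interaction counts as "present in a run"; min_replicas_present is the
    k of the k-of-n rule.
    """

    n_replicas: int = 4
    min_replicas_present: int = 3
    presence_occupancy_min: float = 0.10

    def __post_init__(self) -> None:
        if not 1 <= self.min_replicas_present <= self.n_replicas:
            raise ValueError("need 1 <= min_replicas_present <= n_replicas")
        if not 0 < self.presence_occupancy_min <= 1:
            raise ValueError("presence_occupancy_min must be in (0, 1]")


@dataclass(frozen=True)
class ConsensusRow:
    key: tuple
    kind: str
    resA: ResKey
    resB: ResKey
    present: tuple[bool, ...]
    n_present: int
    kept: bool


@dataclass
class ConsensusTable:
    rows: list[ConsensusRow]
    config: ConsensusConfig

    @property
    def kept(self) -> list[ConsensusRow]:
        return [r for r in self.rows if r.kept]

    def kept_pairs(self, kind: str | None = None) -> set[tuple[ResKey, ResKey]]:
        return {(r.resA, r.resB) for r in self.kept
                if kind is None or r.kind == kind}

    def kept_partner_b_resids(self) -> set[int]:
        return {r.resB[1] for r in self.kept}


@dataclass(frozen=True)
class PeptideDesign:
    """A contiguous partner-B segment covering its anchor residues."""

    chain: str
    start_resid: int
    end_resid: int
    sequence: str
    anchors: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.start_resid <= self.end_resid:
            raise ValueError("start_resid must not exceed end_resid")
        if not all(self.start_resid <= a <= self.end_resid
                   for a in self.anchors):
            raise ValueError("anchors must lie inside [start, end]")
        if len(self.sequence) != self.end_resid - self.start_resid + 1:
            raise ValueError("sequence length must equal residue span")


def consensus_pairs(occ: OccupancyTable, cfg: ConsensusConfig,
                    ) -> ConsensusTable:
    """Apply the k-of-n presence rule to every interaction key.

    Present-in-replica flags are (occupancy >= presence_occupancy_min);
    a row is kept iff the flags sum to at least min_replicas_present.
    Deterministic and independent of table ordering.
    """
    if occ.n_replicas < cfg.n_replicas:
        raise ValueError(
            f"occupancy table has {occ.n_replicas} replicas, config "
            f"expects {cfg.n_replicas}")
    rows = []
    for key in sorted(occ.occupancy):
        o = occ.occupancy[key]
        present = tuple(bool(x >= cfg.presence_occupancy_min) for x in o)
        n_present = sum(present)
        rows.append(ConsensusRow(
            key=key, kind=key[0], resA=key[1], resB=key[2],
            present=present, n_present=n_present,
            kept=n_present >= cfg.min_replicas_present))
    return ConsensusTable(rows, cfg)


def pool_alternative_partners(occ: OccupancyTable, topology: Structure,
                              frame: np.ndarray | None = None,
                              kind: str = "saltbridge",
                              centroid_cutoff: float = 8.0) -> OccupancyTable:
    """Pool records sharing resA whose partner-B residues sit close in space.

    Optional pre-consensus merge for the "alternative partner" situation:
    the same partner-A residue bridges to either of two adjacent
    partner-B residues in different runs.  Records of the given kind with
    identical resA whose partner-B side-chain centroids lie within
    centroid_cutoff (A, measured in the supplied reference frame, default
    the topology coordinates) are combined into a single record whose
    per-replica occupancy is the max over the pooled members.  Off by
    default in the pipeline.
    """
    coords = np.asarray(frame, dtype=float) if frame is not None \
        else topology.coords
    centroids: dict[ResKey, np.ndarray] = {}
    for res_key, idx in topology.residues():
        side = [i for i in idx
                if topology.atoms[i].name not in ("N", "CA", "C", "O", "OXT")
                and topology.atoms[i].element != "H"]
        centroids[res_key] = coords[side or idx].mean(axis=0)

    keys = occ.keys_of_kind(kind)
    by_resA: dict[ResKey, list[tuple]] = {}
    for key in keys:
        by_resA.setdefault(key[1], []).append(key)

    new_occ = {k: v.copy() for k, v in occ.occupancy.items()}
    for resA, group in by_resA.items():
        if len(group) < 2:
            continue
        group = sorted(group)
        # single-linkage pooling over partner-B centroid distances
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if np.linalg.norm(centroids[group[i][2]]
                                  - centroids[group[j][2]]) <= centroid_cutoff:
                    parent[find(j)] = find(i)
        pools_by_root: dict[int, list[tuple]] = {}
        for i, key in enumerate(group):
            pools_by_root.setdefault(find(i), []).append(key)
        for pool in [p for p in pools_by_root.values() if len(p) > 1]:
            pooled = np.max([occ.occupancy[k] for k in pool], axis=0)
            resBs = sorted({k[2] for k in pool})
            merged_resB = (resBs[0][0],
                           resBs[0][1],
                           "|".join(r[2] + str(r[1]) for r in resBs))
            for k in pool:
                new_occ.pop(k, None)
            new_occ[(kind, resA, merged_resB)] = pooled
    return OccupancyTable(new_occ, occ.frames_analyzed, occ.n_replicas)


def interface_clusters(tbl: ConsensusTable, topology: Structure,
                       linkage_gap: int = 4,
                       spatial_cutoff: float = 8.0,
                       frame: np.ndarray | None = None,
                       ) -> list[list[int]]:
    """Single-linkage clusters of kept partner-B residues.

    Two residues join a cluster when they are within linkage_gap in
    sequence OR their side-chain centroids are within spatial_cutoff (A)
    in the reference frame.  Every kept residue is assigned to exactly one
    cluster; clusters are returned sorted by their lowest resid.
    """
    resids = sorted(tbl.kept_partner_b_resids())
    if not resids:
        return []
    coords = np.asarray(frame, dtype=float) if frame is not None \
        else topology.coords
    centroids: dict[int, np.ndarray] = {}
    for (chain, resid, resname), idx in topology.residues():
        if resid in resids and resid not in centroids:
            side = [i for i in idx
                    if topology.atoms[i].name not in ("N", "CA", "C", "O", "OXT")
                    and topology.atoms[i].element != "H"]
            centroids[resid] = coords[side or idx].mean(axis=0)

    def linked(a: int, b: int) -> bool:
        if abs(a - b) <= linkage_gap:
            return True
        if a in centroids and b in centroids:
            return bool(np.linalg.norm(centroids[a] - centroids[b])
                        <= spatial_cutoff)
        return False

    # union-find single linkage
    parent = {r: r for r in resids}

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for i, a in enumerate(resids):
        for b in resids[i + 1:]:
            if linked(a, b):
                parent[find(b)] = find(a)
    groups: dict[int, list[int]] = {}
    for r in resids:
        groups.setdefault(find(r), []).append(r)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def design_peptides(anchors: list[int], topology: Structure, chain: str,
                    flank: int = 4, max_len: int = 20,
                    label_prefix: str = "PEP") -> list[PeptideDesign]:
    """Cut blocking peptides from the partner chain around anchor residues.

    Anchors are greedily partitioned left-to-right so that each group's
    residue span plus both flanks fits within max_len; one peptide per
    group, extended by flank residues on each side and clipped to the
    chain termini.  Far-apart anchors therefore yield separate short
    peptides rather than one long one.
    """
    if max_len < 2 * flank + 1:
        raise ValueError("max_len must be at least 2*flank + 1")
    chain_residues = {resid: resname
                      for (c, resid, resname), _ in topology.residues()
                      if c == chain}
    if not chain_residues:
        raise ValueError(f"chain {chain!r} not found")
    missing = [a for a in anchors if a not in chain_residues]
    if missing:
        raise ValueError(f"anchor resids absent from chain {chain}: {missing}")

    lo, hi = min(chain_residues), max(chain_residues)
    groups: list[list[int]] = []
    for a in sorted(set(anchors)):
        if groups and (a - groups[-1][0]) + 2 * flank + 1 <= max_len:
            groups[-1].append(a)
        else:
            groups.append([a])

    designs = []
    for g_i, group in enumerate(groups, start=1):
        start = max(lo, group[0] - flank)
        end = min(hi, group[-1] + flank)
        seq = "".join(THREE_TO_ONE.get(chain_residues.get(r, ""), "X")
                      for r in range(start, end + 1))
        designs.append(PeptideDesign(
            chain=chain, start_resid=start, end_resid=end, sequence=seq,
            anchors=tuple(group), label=f"{label_prefix}-{g_i}"))
    return designs
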