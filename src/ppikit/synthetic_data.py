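"""Synthetic fixtures with known ground truth for every pipeline stage.

Real replica-MD output for a two-partner complex is large and not
redistributable, so every input the pipeline consumes can be generated
here instead: toy two-chain complexes built from simplified amino-acid
templates, replica trajectory ensembles with planted interfacial
interactions that persist in a configurable subset of replicas, a matching
per-atom parameter table, and 1:1-kinetics sensorgram sets with additive
noise and a competitive-inhibitor series.  All generators are pure
functions of their recipe plus seed.

Geometry is deliberately schematic: chains are extended zig-zag backbones
along x, side chains point along +/-z toward the partner chain, and a
planted interaction is realised by translating the partner-B side chain so
that its interacting tip atom meets the partner-A tip at the exact target
distance (and, for hydrogen bonds, on the donor's D-H axis so the planted
angle is zero).  "Breaking" an interaction displaces that side chain well
beyond the detection cutoff; frame counts stay balanced across replicas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ppikit.interface_geometry import GeometryCriteria
from ppikit.spr_kinetics import Sensorgram, sensorgram_model, simulate_sensorgram
from ppikit.structure_io import (AtomRecord, ATOMIC_MASSES, Structure,
                                 TrajectoryEnsemble, element_from_name,
                                 write_pdb_models)

__all__ = [
    "PlantedInteraction", "EnsembleRecipe", "ConstructionError",
    "build_toy_complex", "generate_ensemble", "write_ensemble",
    "default_recipe", "toy_parameter_table", "write_parameter_table",
    "expected_consensus_pairs", "generate_sensorgram_set",
    "default_sensorgram_conditions", "generate_inhibition_set",
]


class ConstructionError(ValueError):
    """The requested plant set cannot be realised geometrically."""


# ----------------------------------------------------------------------
# Residue templates (side-chain offsets from CA; z flips for partner B)
# ----------------------------------------------------------------------

_SIDE_CHAINS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", (0.0, 0.0, 1.53))],
    "ASP": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.05)),
            ("OD1", (1.06, 0.0, 3.69)), ("OD2", (-1.06, 0.0, 3.69))],
    "GLU": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.05)),
            ("CD", (0.0, 0.0, 4.57)),
            ("OE1", (1.06, 0.0, 5.21)), ("OE2", (-1.06, 0.0, 5.21))],
    "LYS": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.05)),
            ("CD", (0.0, 0.0, 4.57)), ("CE", (0.0, 0.0, 6.09)),
            ("NZ", (0.0, 0.0, 7.58)),
            ("HZ1", (0.94, 0.0, 7.92)), ("HZ2", (-0.47, 0.81, 7.92)),
            ("HZ3", (-0.47, -0.81, 7.92))],
    "ARG": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.05)),
            ("CD", (0.0, 0.0, 4.57)), ("NE", (0.0, 0.0, 6.04)),
            ("HE", (0.95, 0.0, 6.35)), ("CZ", (0.0, 0.0, 7.37)),
            ("NH1", (1.13, 0.0, 8.07)), ("HH11", (1.95, 0.0, 8.64)),
            ("NH2", (-1.13, 0.0, 8.07)), ("HH21", (-1.95, 0.0, 8.64))],
    "SER": [("CB", (0.0, 0.0, 1.53)), ("OG", (0.0, 0.0, 2.95)),
            ("HG", (0.31, 0.0, 3.90))],
    "HSD": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.02)),
            ("ND1", (1.108, 0.0, 3.825)), ("HD1", (2.059, 0.0, 3.516)),
            ("CE1", (0.685, 0.0, 5.128)), ("NE2", (-0.685, 0.0, 5.128)),
            ("CD2", (-1.108, 0.0, 3.825))],
    "HSE": [("CB", (0.0, 0.0, 1.53)), ("CG", (0.0, 0.0, 3.02)),
            ("ND1", (1.108, 0.0, 3.825)),
            ("CE1", (0.685, 0.0, 5.128)), ("NE2", (-0.685, 0.0, 5.128)),
            ("HE2", (-1.636, 0.0, 4.819)), ("CD2", (-1.108, 0.0, 3.825))],
}

# Interacting "tip" atoms per role; HH11/NH1 is the Arg donor pair used
# for planted hydrogen bonds, OG/HG the Ser one.
_TIPS = {
    ("ASP", "anion"): ("OD1", "OD2"),
    ("GLU", "anion"): ("OE1", "OE2"),
    ("LYS", "cation"): ("NZ",),
    ("ARG", "cation"): ("NH1",),
    ("ARG", "donor"): ("NH1", "HH11"),
    ("SER", "donor"): ("OG", "HG"),
    ("GLU", "acceptor"): ("OE1", "OE2"),
    ("ASP", "acceptor"): ("OD1", "OD2"),
    ("ALA", "contact"): ("CB",),
}


def _template_x(resname: str, atom: str) -> float:
    for name, off in _SIDE_CHAINS[resname]:
        if name == atom:
            return off[0]
    raise KeyError((resname, atom))

# Toy per-atom parameters: charge (e), LJ epsilon (kcal/mol), LJ
# rmin/2 (A), GB radius (A).  Charges sum to each residue's formal charge
# exactly; LJ/GB values are element-typical.
_ELEMENT_PARAMS = {"C": (0.07, 2.00, 1.70), "N": (0.20, 1.85, 1.55),
                   "O": (0.12, 1.70, 1.50), "H": (0.046, 0.225, 1.20)}

_BACKBONE_CHARGES = {"N": -0.40, "HN": 0.30, "CA": 0.10, "C": 0.50,
                     "O": -0.50}

_SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "GLY": {},
    "ALA": {"CB": 0.0},
    "ASP": {"CB": -0.28, "CG": 0.62, "OD1": -0.67, "OD2": -0.67},
    "GLU": {"CB": 0.0, "CG": -0.28, "CD": 0.62, "OE1": -0.67, "OE2": -0.67},
    "LYS": {"CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.13, "NZ": -0.12,
            "HZ1": 0.33, "HZ2": 0.33, "HZ3": 0.33},
    "ARG": {"CB": 0.0, "CG": 0.0, "CD": 0.30, "NE": -0.70, "HE": 0.44,
            "CZ": 0.64, "NH1": -0.30, "HH11": 0.46, "NH2": -0.30,
            "HH21": 0.46},
    "SER": {"CB": 0.23, "OG": -0.66, "HG": 0.43},
    "HSD": {"CB": 0.0, "CG": 0.0, "ND1": -0.36, "HD1": 0.32, "CE1": 0.25,
            "NE2": -0.70, "CD2": 0.49},
    "HSE": {"CB": 0.0, "CG": 0.0, "ND1": -0.70, "CE1": 0.25, "NE2": -0.36,
            "HE2": 0.32, "CD2": 0.49},
}

FORMAL_CHARGES = {"GLY": 0.0, "ALA": 0.0, "ASP": -1.0, "GLU": -1.0,
                  "LYS": 1.0, "ARG": 1.0, "SER": 0.0, "HSD": 0.0,
                  "HSE": 0.0}


def toy_parameter_table() -> tuple[dict[tuple[str, str], tuple[float, float, float, float]],
                                   dict[str, float]]:
    """Parameter table covering every template residue."""
    table: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for resname, side in _SIDE_CHAINS.items():
        charges = dict(_BACKBONE_CHARGES)
        charges.update(_SIDECHAIN_CHARGES[resname])
        names = list(_BACKBONE_CHARGES) + [n for n, _ in side]
        for name in names:
            elem = element_from_name(name)
            eps, rmin_half, gb_r = _ELEMENT_PARAMS[elem]
            table[(resname, name)] = (charges[name], eps, rmin_half, gb_r)
    return table, dict(FORMAL_CHARGES)


def write_parameter_table(path: str | Path) -> None:
    """Write the toy table in the text format structure_io reads."""
    table, formal = toy_parameter_table()
    lines = ["resname\tatom\tcharge\tepsilon\trmin_half\tgb_radius"]
    for resname, q in sorted(formal.items()):
        lines.append(f"#formal {resname} {q:g}")
    for (resname, atom), (q, eps, rmh, gbr) in sorted(table.items()):
        lines.append(f"{resname}\t{atom}\t{q:.4f}\t{eps:.4f}\t{rmh:.4f}"
                     f"\t{gbr:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Recipes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One designed cross-interface interaction with its ground truth.

    resid_a / resid_b address the partner-A / partner-B residues; the
    target distance must clear the detection cutoff by at least 0.2 A
    (planted hydrogen bonds are built collinear, 30 deg under the angle
    cutoff).  persistence is the fraction of frames, in replicas listed in
    replicas_present, during which the interaction holds.
    """

    kind: str                      # contact | hbond | saltbridge
    resid_a: int
    resid_b: int
    resname_a: str = ""
    resname_b: str = ""
    target_distance: float = 3.0
    persistence: float = 1.0
    replicas_present: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        crit = GeometryCriteria()
        cutoff = {"contact": crit.contact_cutoff,
                  "hbond": crit.hbond_dist_cutoff,
                  "saltbridge": crit.saltbridge_cutoff}[self.kind]
        if self.target_distance > cutoff - 0.2:
            raise ValueError("target distance must clear the cutoff by 0.2 A")
        if not 0 < self.persistence <= 1:
            raise ValueError("persistence must be in (0, 1]")

    def with_defaults(self) -> "PlantedInteraction":
        defaults = {"saltbridge": ("ASP", "LYS"), "hbond": ("ARG", "GLU"),
                    "contact": ("ALA", "ALA")}
        ra, rb = defaults[self.kind]
        if self.resname_a and self.resname_b:
            return self
        object.__setattr__(self, "resname_a", self.resname_a or ra)
        object.__setattr__(self, "resname_b", self.resname_b or rb)
        return self


@dataclass(frozen=True)
class EnsembleRecipe:
    """Shape of a synthetic replica ensemble.

    Defaults mirror the study design this package emulates: four
    independent replicas of one two-partner complex, with an Arg->Glu
    hydrogen bond + salt bridge supported by all four runs and an Asp
    residue bridging to either of two nearby lysines in different run
    subsets.  jitter_sigma is the per-coordinate thermal noise (A).
    """

    n_replicas: int = 4
    n_frames: int = 50
    jitter_sigma: float = 0.1
    chain_a_start: int = 110
    chain_a_len: int = 31
    chain_b_start: int = 876
    chain_b_len: int = 73
    chain_gap: float = 30.0
    frame_dt_ns: float = 1.0
    planted: tuple[PlantedInteraction, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain_a_len < 3 or self.chain_b_len < 3:
            raise ValueError("chains need at least 3 residues")
        if self.n_replicas < 1 or self.n_frames < 2:
            raise ValueError("need >= 1 replica and >= 2 frames")
        for p in self.planted:
            if max(p.replicas_present, default=-1) >= self.n_replicas:
                raise ValueError(f"plant {p.kind} {p.resid_a}-{p.resid_b}: "
                                 "replicas_present out of range")


def default_recipe(seed: int = 0, jitter_sigma: float = 0.1,
                   n_frames: int = 50) -> EnsembleRecipe:
    """The packaged study-shaped recipe (4 replicas, 3 planted motifs)."""
    plants = (
        PlantedInteraction("hbond", 137, 883, "ARG", "GLU",
                           persistence=0.9, replicas_present=(0, 1, 2, 3)),
        PlantedInteraction("saltbridge", 137, 883, "ARG", "GLU",
                           persistence=0.9, replicas_present=(0, 1, 2, 3)),
        PlantedInteraction("saltbridge", 115, 940, "ASP", "LYS",
                           persistence=0.8, replicas_present=(0, 1, 2)),
        PlantedInteraction("saltbridge", 115, 943, "ASP", "LYS",
                           persistence=0.8, replicas_present=(2, 3)),
    )
    return EnsembleRecipe(planted=plants, seed=seed,
                          jitter_sigma=jitter_sigma, n_frames=n_frames)


# ----------------------------------------------------------------------
# Structure construction
# ----------------------------------------------------------------------

_COS30, _SIN30 = np.cos(np.pi / 6), 0.5


def _backbone(resid: int, index: int, origin: np.ndarray, zdir: float,
              ) -> dict[str, np.ndarray]:
    """Zig-zag backbone atoms of residue number `index` along x."""
    p = 1.0 if index % 2 == 0 else -1.0
    period = (1.46 + 1.52 + 1.33) * _COS30
    n = origin + np.array([index * period, 0.0, 0.0])
    ca = n + 1.46 * np.array([_COS30, p * _SIN30, 0.0])
    c = ca + 1.52 * np.array([_COS30, -p * _SIN30, 0.0])
    o = c + np.array([0.0, -1.23 * p, 0.0])
    hn = n + np.array([-0.35, 0.94 * p, 0.0])
    return {"N": n, "HN": hn, "CA": ca, "C": c, "O": o}


def _build_chain(chain_id: str, start_resid: int, length: int,
                 sequence: dict[int, str], origin: np.ndarray,
                 zdir: float, serial0: int) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    serial = serial0
    for i in range(length):
        resid = start_resid + i
        resname = sequence.get(resid, "GLY")
        bb = _backbone(resid, i, origin, zdir)
        positions = list(bb.items())
        for name, off in _SIDE_CHAINS[resname]:
            off = np.asarray(off)
            positions.append((name, bb["CA"]
                              + np.array([off[0], off[1], zdir * off[2]])))
        for name, xyz in positions:
            elem = element_from_name(name)
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem, resname=resname,
                resid=resid, chain=chain_id, xyz=xyz,
                mass=ATOMIC_MASSES[elem]))
            serial += 1
    return atoms


def _plant_roles(kind: str, resname_a: str, resname_b: str,
                 ) -> tuple[str, str]:
    """Interaction roles of the partner-A / partner-B residues.

    Salt bridges work in either orientation (anionic residue on A against
    cationic on B, or vice versa); hydrogen bonds are planted with the
    donor on partner A.
    """
    if kind == "hbond":
        roles = ("donor", "acceptor")
    elif kind == "contact":
        roles = ("contact", "contact")
    else:
        roles = ("anion", "cation") if (resname_a, "anion") in _TIPS \
            else ("cation", "anion")
    if (resname_a, roles[0]) not in _TIPS or (resname_b, roles[1]) not in _TIPS:
        raise ConstructionError(
            f"{kind} plant needs a {roles[0]} residue on A and a "
            f"{roles[1]} residue on B; got {resname_a}/{resname_b}")
    return roles


def build_toy_complex(recipe: EnsembleRecipe,
                      ) -> tuple[Structure, dict]:
    """Build the base-frame structure realising every planted interaction.

    Returns (structure, plant_geometry) where plant_geometry records, per
    plant, the realised tip atoms and the side-chain displacement vector
    used to break the interaction.  Raises ConstructionError when the
    plant set is inconsistent (conflicting residue types, a partner-B
    residue claimed by two partner-A residues, or unmet target geometry).
    """
    plants = [p.with_defaults() for p in recipe.planted]
    seq_a: dict[int, str] = {}
    seq_b: dict[int, str] = {}
    for p in plants:
        for seq, resid, resname, chain_len, start in (
                (seq_a, p.resid_a, p.resname_a, recipe.chain_a_len,
                 recipe.chain_a_start),
                (seq_b, p.resid_b, p.resname_b, recipe.chain_b_len,
                 recipe.chain_b_start)):
            if not start <= resid < start + chain_len:
                raise ConstructionError(
                    f"plant resid {resid} outside chain ({start}..."
                    f"{start + chain_len - 1})")
            if seq.get(resid, resname) != resname:
                raise ConstructionError(
                    f"resid {resid} claimed as both {seq[resid]} and "
                    f"{resname}")
            seq[resid] = resname

    # one partner-A owner per partner-B residue (its side chain can only
    # be in one place)
    owners: dict[int, int] = {}
    for p in plants:
        if owners.setdefault(p.resid_b, p.resid_a) != p.resid_a:
            raise ConstructionError(
                f"partner-B residue {p.resid_b} planted against two "
                f"different partner-A residues")
    groups: dict[tuple[int, int], list[PlantedInteraction]] = {}
    for p in plants:
        groups.setdefault((p.resid_a, p.resid_b), []).append(p)
    for group in groups.values():
        if len({(g.replicas_present, g.persistence) for g in group}) > 1:
            raise ConstructionError(
                "plants sharing a residue pair must share replicas_present "
                "and persistence (one side chain, one position)")

    atoms = _build_chain("A", recipe.chain_a_start, recipe.chain_a_len,
                         seq_a, np.zeros(3), +1.0, 1)
    atoms += _build_chain("B", recipe.chain_b_start, recipe.chain_b_len,
                          seq_b, np.array([0.0, 0.0, recipe.chain_gap]),
                          -1.0, len(atoms) + 1)
    structure = Structure(atoms, {"A": "A", "B": "B"})
    index = {(a.chain, a.resid, a.name): i for i, a in enumerate(atoms)}
    coords = structure.coords

    # planted pairs sharing a partner-A residue fan out along +/-x
    by_resA: dict[int, list[int]] = {}
    for (ra, rb) in sorted(groups):
        by_resA.setdefault(ra, []).append(rb)

    plant_geometry: dict = {}
    for (ra, rb), group in sorted(groups.items()):
        lead = group[0]
        role_a, role_b = _plant_roles(lead.kind, lead.resname_a,
                                      lead.resname_b)
        siblings = by_resA[ra]
        k = siblings.index(rb)
        tips_a = _TIPS[(lead.resname_a, role_a)]
        if role_a == "donor":
            # acceptor goes on the D-H axis: planted angle is exactly 0
            if len(siblings) > 1:
                raise ConstructionError(
                    f"residue {ra}: only one hydrogen-bond direction "
                    f"available, cannot serve {len(siblings)} partners")
            d_name, h_name = tips_a
            d = coords[index[("A", ra, d_name)]]
            h = coords[index[("A", ra, h_name)]]
            direction = (h - d) / np.linalg.norm(h - d)
            anchor = d
            tip_a_name = d_name
        else:
            # alternative partners fan out: the k-th sibling docks onto the
            # k-th tip atom (ordered +x first) and tilts toward that side,
            # keeping sibling side chains clear of each other
            if len(siblings) > len(tips_a):
                raise ConstructionError(
                    f"residue {ra} ({lead.resname_a}) has {len(tips_a)} "
                    f"interaction tips but {len(siblings)} planted partners")
            ordered = sorted(tips_a,
                             key=lambda n: -_template_x(lead.resname_a, n))
            tip_a_name = ordered[k]
            tilt = 0.0 if len(siblings) == 1 else (0.35 if k == 0 else -0.35)
            anchor = coords[index[("A", ra, tip_a_name)]]
            direction = np.array([tilt, 0.0, 1.0])
            direction /= np.linalg.norm(direction)
        # partner-B tip: for symmetric pairs pick the member whose sibling
        # atom ends up on the far side of the anchor
        tips_b = _TIPS[(lead.resname_b, role_b)]
        if len(tips_b) == 1 or abs(direction[0]) < 0.01:
            tip_b_name = tips_b[0]
        elif direction[0] > 0:
            tip_b_name = min(tips_b,
                             key=lambda n: _template_x(lead.resname_b, n))
        else:
            tip_b_name = max(tips_b,
                             key=lambda n: _template_x(lead.resname_b, n))
        target_pos = anchor + lead.target_distance * direction
        side_idx = [index[("B", rb, n)]
                    for n, _ in _SIDE_CHAINS[lead.resname_b]]
        shift = target_pos - coords[index[("B", rb, tip_b_name)]]
        coords[side_idx] += shift
        break_vector = (GeometryCriteria().contact_cutoff + 1.0 + 0.5) \
            * np.array([0.0, 0.0, 1.0])
        plant_geometry[(ra, rb)] = {
            "tip_a": tip_a_name, "tip_b": tip_b_name,
            "side_chain_indices": side_idx,
            "break_vector": break_vector,
            "plants": group,
        }

    for i, a in enumerate(structure.atoms):
        a.xyz = coords[i]

    # verify every plant's geometry in the base frame
    for (ra, rb), geom in plant_geometry.items():
        for p in geom["plants"]:
            role_a, _ = _plant_roles(p.kind, p.resname_a, p.resname_b)
            tips = _TIPS[(p.resname_a, role_a)]
            a_name = tips[0] if role_a == "donor" else geom["tip_a"]
            d = np.linalg.norm(coords[index[("A", ra, a_name)]]
                               - coords[index[("B", rb, geom["tip_b"])]])
            if abs(d - p.target_distance) > 0.05:
                raise ConstructionError(
                    f"plant {p.kind} {ra}-{rb}: achieved {d:.2f} A, "
                    f"target {p.target_distance:.2f} A")
    return structure, plant_geometry


def generate_ensemble(recipe: EnsembleRecipe,
                      ) -> tuple[TrajectoryEnsemble, dict]:
    """Replica ensemble with thermal jitter and planted persistence.

    Present frames of a plant are the first round(persistence * n_frames)
    frames of each replica in replicas_present; everywhere else the
    involved partner-B side chain is displaced beyond cutoff + 1 A.
    Returns (ensemble, manifest); the manifest carries the full ground
    truth needed to score detection and consensus without re-deriving any
    geometry.
    """
    structure, plant_geometry = build_toy_complex(recipe)
    base = structure.coords
    rng = np.random.default_rng(recipe.seed)
    replicas = []
    for r in range(recipe.n_replicas):
        frames = np.repeat(base[None, :, :], recipe.n_frames, axis=0)
        for geom in plant_geometry.values():
            lead = geom["plants"][0]
            n_present = int(round(lead.persistence * recipe.n_frames))
            for f in range(recipe.n_frames):
                present = (r in lead.replicas_present) and (f < n_present)
                if not present:
                    frames[f, geom["side_chain_indices"]] \
                        += geom["break_vector"]
        frames += rng.normal(0.0, recipe.jitter_sigma, size=frames.shape)
        replicas.append(frames)
    times = [np.arange(recipe.n_frames) * recipe.frame_dt_ns
             for _ in range(recipe.n_replicas)]
    ens = TrajectoryEnsemble(structure, replicas, times)

    manifest = {
        "recipe": {
            "n_replicas": recipe.n_replicas, "n_frames": recipe.n_frames,
            "jitter_sigma": recipe.jitter_sigma, "seed": recipe.seed,
            "chain_gap": recipe.chain_gap,
        },
        "plants": [
            {
                "kind": p.kind,
                "resA": ["A", p.resid_a, p.resname_a],
                "resB": ["B", p.resid_b, p.resname_b],
                "target_distance": p.target_distance,
                "persistence": p.persistence,
                "replicas_present": list(p.replicas_present),
            }
            for p in (q.with_defaults() for q in recipe.planted)
        ],
    }
    return ens, manifest


def expected_consensus_pairs(manifest: dict, min_replicas_present: int = 3,
                             ) -> dict[str, set]:
    """Ground-truth kept pairs per kind implied by a manifest.

    A planted interaction should survive k-of-n consensus iff it is
    present in at least k replicas.  Planted hydrogen bonds and salt
    bridges imply a contact between the same residue pair.
    """
    expected: dict[str, set] = {"contact": set(), "hbond": set(),
                                "saltbridge": set()}
    contact_support: dict[tuple, set[int]] = {}
    for p in manifest["plants"]:
        key = (tuple(p["resA"]), tuple(p["resB"]))
        support = set(p["replicas_present"])
        if len(support) >= min_replicas_present:
            expected[p["kind"]].add(key)
        contact_support.setdefault(key, set()).update(support)
    for key, support in contact_support.items():
        if len(support) >= min_replicas_present:
            expected["contact"].add(key)
    return expected


def write_ensemble(recipe: EnsembleRecipe, outdir: str | Path,
                   ) -> tuple[TrajectoryEnsemble, dict]:
    """Generate and write replica PDBs, parameter table and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ens, manifest = generate_ensemble(recipe)
    paths = []
    for r, frames in enumerate(ens.replicas):
        p = outdir / f"replica_{r + 1}.pdb"
        write_pdb_models(p, ens.topology, frames)
        paths.append(p.name)
    write_parameter_table(outdir / "parameters.tsv")
    manifest = dict(manifest)
    manifest["files"] = {"replicas": paths, "parameters": "parameters.tsv"}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ens, manifest


# ----------------------------------------------------------------------
# Sensorgram sets
# ----------------------------------------------------------------------

def default_sensorgram_conditions() -> dict:
    """Emulated assay conditions: low-nanomolar 1:1 binding.

    ka/kd give KD = 2.78 nM with a slow dissociation rate, matching the
    affinity regime the assay design targets; concentrations span
    0.1-10 x KD; injections are run in duplicate; noise is ~1% of Rmax.
    """
    ka, kd = 3.6e5, 1.0e-3
    kD = kd / ka
    return {
        "ka": ka, "kd": kd, "Rmax": 100.0,
        "concentrations": [f * kD for f in (0.1, 0.3, 1.0, 3.0, 10.0)],
        "association_start": 0.0, "association_end": 120.0,
        "dissociation_end": 300.0, "sampling_rate": 1.0,
        "noise_sigma": 1.0, "n_replicates": 2,
    }


def generate_sensorgram_set(ka: float, kd: float, Rmax: float,
                            concentrations: list[float],
                            noise_sigma: float = 1.0,
                            n_replicates: int = 2,
                            association_start: float = 0.0,
                            association_end: float = 120.0,
                            dissociation_end: float = 300.0,
                            sampling_rate: float = 1.0,
                            seed: int = 0,
                            ) -> tuple[list[Sensorgram], dict]:
    """Duplicate injections of each analyte concentration, plus manifest."""
    rng = np.random.default_rng(seed)
    curves = []
    for c_i, conc in enumerate(concentrations):
        for rep in range(n_replicates):
            curves.append(simulate_sensorgram(
                ka, kd, Rmax, conc, association_start, association_end,
                dissociation_end, sampling_rate, noise_sigma,
                seed=int(rng.integers(2 ** 31)),
                label=f"C{c_i + 1}_rep{rep + 1}", role="active"))
    manifest = {"ka": ka, "kd": kd, "KD": kd / ka, "Rmax": Rmax,
                "concentrations": list(concentrations),
                "noise_sigma": noise_sigma, "n_replicates": n_replicates,
                "seed": seed}
    return curves, manifest


def generate_inhibition_set(ka: float = 3.6e5, kd: float = 1.0e-3,
                            Rmax: float = 100.0,
                            analyte_concentration: float = 100e-9,
                            peptide_concentrations: tuple[float, ...] = (
                                25e-6, 50e-6, 100e-6, 200e-6, 400e-6),
                            Ki: float = 4e-6,
                            peptide_bulk_ru_per_m: float = 2.0e4,
                            noise_sigma: float = 0.5,
                            n_replicates: int = 2,
                            seed: int = 0,
                            label: str = "PEP-1",
                            ) -> tuple[Sensorgram, list[Sensorgram],
                                       list[Sensorgram], dict]:
    """Competitive-inhibition sensorgram series with ground truth.

    The peptide sequesters a fraction of the analyte in solution, scaling
    the active analyte concentration by 1 / (1 + [pep]/Ki).  Peptide-only
    curves contribute a square bulk-response pulse during association that
    the mixture curves inherit, so the peptide-only subtraction step has
    real work to do.  Returns (control, mixtures, peptide_only, manifest).
    """
    rng = np.random.default_rng(seed)
    t0, t1, t2, rate = 0.0, 120.0, 300.0, 1.0

    def noisy(curve: Sensorgram) -> Sensorgram:
        curve.response = curve.response + rng.normal(
            0.0, noise_sigma, size=curve.times.shape)
        return curve

    control = noisy(simulate_sensorgram(
        ka, kd, Rmax, analyte_concentration, t0, t1, t2, rate,
        0.0, label="control", role="active"))
    mixtures: list[Sensorgram] = []
    peptide_only: list[Sensorgram] = []
    for pep in peptide_concentrations:
        c_eff = analyte_concentration / (1.0 + pep / Ki)
        for rep in range(n_replicates):
            bulk = np.zeros_like(control.times)
            bulk[(control.times >= t0) & (control.times <= t1)] = \
                peptide_bulk_ru_per_m * pep
            mix = simulate_sensorgram(
                ka, kd, Rmax, c_eff, t0, t1, t2, rate, 0.0,
                label=f"TDP1+{label}", role="mixture")
            mix.response = mix.response + bulk
            mix.peptide_concentration = pep
            mixtures.append(noisy(mix))
            pep_curve = Sensorgram(
                control.times.copy(), bulk.copy(), 0.0, t0, t1, t2,
                label=label, role="peptide_only",
                peptide_concentration=pep)
            peptide_only.append(noisy(pep_curve))
    manifest = {"ka": ka, "kd": kd, "Rmax": Rmax,
                "analyte_concentration": analyte_concentration,
                "peptide_concentrations": list(peptide_concentrations),
                "Ki": Ki, "expected_percent": [
                    100.0 * sensorgram_model(
                        np.array([t1]), ka, kd, Rmax,
                        analyte_concentration / (1.0 + pep / Ki), t0, t1)[0]
                    / sensorgram_model(
                        np.array([t1]), ka, kd, Rmax,
                        analyte_concentration, t0, t1)[0]
                    for pep in peptide_concentrations],
                "seed": seed}
    return control, mixtures, peptide_only, manifest
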