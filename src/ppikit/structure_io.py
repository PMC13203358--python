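"""Multi-model PDB I/O, per-atom force-field parameters and chemical roles.

The trajectory carrier is the multi-model PDB file: one file per replica,
one MODEL per frame, all MODELs sharing a single topology.  Reading goes
through Biopython's :class:`Bio.PDB.PDBParser`; a light pre-scan supplies
line-numbered errors for malformed ATOM/HETATM records that the permissive
parser would silently repair.

Coordinates are in Angstrom throughout, atom indices are 0-based, residue
ids are 1-based as in the PDB format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord", "Structure", "TrajectoryEnsemble", "ChemRoles",
    "PDBParseError", "TopologyMismatchError", "MissingParameterError",
    "read_pdb_models", "write_pdb_models", "read_parameter_table",
    "assign_parameters", "infer_chem_roles",
]

# Standard atomic masses (amu) for the elements that occur in proteins.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}

MAX_HYDROGEN_BOND = 1.2   # A, H to its heavy donor
MAX_HEAVY_BOND = 2.0      # A, heavy-heavy covalent bond


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""


class TopologyMismatchError(ValueError):
    """MODELs of one file (or replicas of one ensemble) disagree on topology."""


class MissingParameterError(KeyError):
    """Atoms without an entry in the force-field parameter table."""

    def __init__(self, offenders: Sequence[tuple[str, str]]):
        self.offenders = list(offenders)
        names = ", ".join(f"{r} {a}" for r, a in self.offenders)
        super().__init__(f"no parameter-table entry for: {names}")


@dataclass
class AtomRecord:
    """One atom of the topology with optional force-field parameters.

    charge is in elementary charge units, lj_epsilon in kcal/mol,
    lj_rmin_half and gb_radius in Angstrom.
    """

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray
    mass: float
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    gb_radius: float | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.resname)


def element_from_name(name: str) -> str:
    """Element symbol from a PDB atom name (protein atoms only)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {name!r}")
    two = stripped[:2].upper()
    if two in ("SE", "FE", "ZN", "MG", "NA", "CL"):
        return two
    return stripped[0].upper()


@dataclass
class Structure:
    """An ordered atom list plus inferred bonds and partner assignment.

    partner_assignment maps each chain id to one of the two binding
    partners "A" / "B".  (chain, resid, name) triples are unique.
    """

    atoms: list[AtomRecord]
    partner_assignment: dict[str, str] = field(default_factory=dict)
    _bonds: list[tuple[int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain, a.resid, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
        for part in self.partner_assignment.values():
            if part not in ("A", "B"):
                raise ValueError("partners must be labelled 'A' or 'B'")

    # ---- basic views -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def default_partner_assignment(self) -> dict[str, str]:
        """First chain is partner A, all remaining chains partner B."""
        chains = self.chains
        if len(chains) < 2:
            raise ValueError("need at least two chains to assign partners")
        return {c: ("A" if i == 0 else "B") for i, c in enumerate(chains)}

    def partner_indices(self, partner: str) -> np.ndarray:
        assignment = self.partner_assignment or self.default_partner_assignment()
        idx = [i for i, a in enumerate(self.atoms)
               if assignment.get(a.chain) == partner]
        return np.asarray(idx, dtype=int)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Residues in atom order as ((chain, resid, resname), atom indices)."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = a.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        return [(key, groups[key]) for key in order]

    # ---- bonds -------------------------------------------------------
    @property
    def bonds(self) -> list[tuple[int, int]]:
        """Covalent bonds inferred from distances.

        Each hydrogen bonds to its nearest heavy atom when that atom is
        within 1.2 A; heavy-heavy pairs bond when within 2.0 A.
        """
        if self._bonds is None:
            self._bonds = self._infer_bonds()
        return self._bonds

    def _infer_bonds(self) -> list[tuple[int, int]]:
        xyz = self.coords
        is_h = np.array([a.element == "H" for a in self.atoms])
        heavy = np.flatnonzero(~is_h)
        bonds: set[tuple[int, int]] = set()
        if heavy.size >= 2:
            tree = cKDTree(xyz[heavy])
            for i, j in tree.query_pairs(MAX_HEAVY_BOND):
                bonds.add(tuple(sorted((int(heavy[i]), int(heavy[j])))))
        if heavy.size and is_h.any():
            tree = cKDTree(xyz[heavy])
            for h in np.flatnonzero(is_h):
                dist, j = tree.query(xyz[h])
                if dist <= MAX_HYDROGEN_BOND:
                    bonds.add(tuple(sorted((int(h), int(heavy[j])))))
        return sorted(bonds)

    def select(self, selection: str) -> np.ndarray:
        """Atom indices matching a tiny selection mini-language.

        Clauses joined by ``and``: ``chain A[,B]``, ``name CA[,CB]``,
        ``resid 10-20[,25]``, ``heavy``, ``all``.
        """
        mask = np.ones(len(self.atoms), dtype=bool)
        for clause in selection.split(" and "):
            clause = clause.strip()
            if not clause or clause == "all":
                continue
            if clause == "heavy":
                mask &= np.array([a.element != "H" for a in self.atoms])
                continue
            try:
                keyword, arg = clause.split(None, 1)
            except ValueError:
                raise ValueError(f"cannot parse selection clause {clause!r}")
            values = [v.strip() for v in arg.split(",")]
            if keyword == "chain":
                mask &= np.array([a.chain in values for a in self.atoms])
            elif keyword == "name":
                mask &= np.array([a.name in values for a in self.atoms])
            elif keyword == "resid":
                allowed: set[int] = set()
                for v in values:
                    if "-" in v[1:]:
                        lo, hi = v.split("-", 1) if not v.startswith("-") else v[1:].split("-", 1)
                        allowed.update(range(int(lo), int(hi) + 1))
                    else:
                        allowed.add(int(v))
                mask &= np.array([a.resid in allowed for a in self.atoms])
            else:
                raise ValueError(f"unknown selection keyword {keyword!r}")
        return np.flatnonzero(mask)


@dataclass
class TrajectoryEnsemble:
    """Replica frame stacks over a shared topology.

    replicas[r] has shape (n_frames, n_atoms, 3) in Angstrom; frame_times[r]
    is the matching time axis in nanoseconds.
    """

    topology: Structure
    replicas: list[np.ndarray]
    frame_times: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("ensemble needs at least one replica")
        n_atoms = len(self.topology)
        cleaned = []
        for r, frames in enumerate(self.replicas):
            frames = np.asarray(frames, dtype=float)
            if frames.ndim != 3 or frames.shape[1:] != (n_atoms, 3):
                raise TopologyMismatchError(
                    f"replica {r}: frames shape {frames.shape} does not match "
                    f"topology with {n_atoms} atoms")
            cleaned.append(frames)
        self.replicas = cleaned
        if self.frame_times is None:
            self.frame_times = [np.arange(f.shape[0], dtype=float)
                                for f in self.replicas]

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames(self) -> list[int]:
        return [f.shape[0] for f in self.replicas]


@dataclass(frozen=True)
class ChemRoles:
    """Hydrogen-bond and salt-bridge roles of the topology atoms.

    donor_pairs are (heavy donor index, hydrogen index); acceptors are
    oxygen atoms plus unprotonated histidine side-chain nitrogens;
    anionic/cationic sets hold the charged side-chain termini used for
    salt-bridge detection.  Histidine protonation follows CHARMM residue
    naming (HSD/HSE/HSP); plain HIS is treated as neutral NE2-protonated.
    """

    donor_pairs: tuple[tuple[int, int], ...]
    acceptors: tuple[int, ...]
    anionic_atoms: tuple[int, ...]
    cationic_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.anionic_atoms) & set(self.cationic_atoms):
            raise ValueError("anionic and cationic sets must be disjoint")


# ----------------------------------------------------------------------
# PDB reading / writing
# ----------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Raise PDBParseError with a line number for malformed coordinate rows."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}, line {lineno}: truncated {rec} record")
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}, line {lineno}: malformed {rec} record "
                    f"({exc})") from exc


def read_pdb_models(path: str | Path,
                    partner_assignment: Mapping[str, str] | None = None,
                    ) -> TrajectoryEnsemble:
    """Read a multi-model PDB file as a single-replica ensemble.

    Each MODEL becomes one frame; a file without MODEL records yields one
    frame.  All MODELs must agree on atom count and (chain, resid, name)
    ordering, otherwise :class:`TopologyMismatchError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure(path.stem, str(path))
    models = list(bio.get_models())
    if not models:
        raise PDBParseError(f"{path}: no coordinate records found")

    def model_atoms(model):
        out = []
        for chain in model:
            for res in chain:
                for atom in res:
                    out.append((chain.id, res.id[1], res.resname.strip(),
                                atom.get_name(), atom))
        return out

    first = model_atoms(models[0])
    signature = [(c, r, n) for c, r, _, n, _ in first]
    frames = []
    for m_i, model in enumerate(models):
        entries = model_atoms(model)
        sig = [(c, r, n) for c, r, _, n, _ in entries]
        if sig != signature:
            raise TopologyMismatchError(
                f"{path}: MODEL {model.id} has {len(sig)} atoms / ordering "
                f"inconsistent with MODEL {models[0].id} ({len(signature)})")
        frames.append(np.array([a.get_coord() for *_, a in entries],
                               dtype=float))

    atoms = []
    for serial, (chain_id, resid, resname, name, atom) in enumerate(first, 1):
        elem = (atom.element or "").strip().upper() or element_from_name(name)
        atoms.append(AtomRecord(
            serial=serial, name=name, element=elem, resname=resname,
            resid=resid, chain=chain_id, xyz=frames[0][serial - 1],
            mass=ATOMIC_MASSES.get(elem, 12.011)))
    topology = Structure(atoms, dict(partner_assignment or {}))
    return TrajectoryEnsemble(topology, [np.stack(frames)])


def write_pdb_models(path: str | Path, topology: Structure,
                     frames: np.ndarray | Sequence[np.ndarray]) -> None:
    """Write frames over a topology as a fixed-column multi-model PDB file."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != (len(topology), 3):
        raise TopologyMismatchError(
            f"frame shape {frames.shape} does not match topology")
    lines: list[str] = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        prev_chain = None
        for a, xyz in zip(topology.atoms, frame):
            if prev_chain is not None and a.chain != prev_chain:
                lines.append("TER")
            prev_chain = a.chain
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial % 100000:5d} {name}{'':1s}{a.resname:<4s}"
                f"{a.chain:1s}{a.resid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Parameter tables
# ----------------------------------------------------------------------

def read_parameter_table(path: str | Path,
                         ) -> tuple[dict[tuple[str, str], tuple[float, float, float, float]],
                                    dict[str, float]]:
    """Read a tab/space separated per-atom parameter table.

    Header: ``resname atom charge epsilon rmin_half gb_radius``.  Lines of
    the form ``#formal RESNAME q`` declare the formal charge of a residue
    type; other ``#`` lines are comments.  Returns (parameters, formal
    charges).
    """
    params: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    formal: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "formal":
                    formal[parts[1]] = float(parts[2])
                continue
            parts = line.split()
            if parts[0] == "resname":  # header
                continue
            resname, atom = parts[0], parts[1]
            params[(resname, atom)] = tuple(float(x) for x in parts[2:6])
    return params, formal


def assign_parameters(s: Structure,
                      table: Mapping[tuple[str, str], tuple[float, float, float, float]],
                      formal_charges: Mapping[str, float] | None = None,
                      ) -> Structure:
    """Return a copy of the structure with charges/LJ/GB radii attached.

    Every atom must have a (resname, atom name) entry; when formal charges
    are declared, each residue's net charge must match within 1e-6 e.
    """
    missing = [(a.resname, a.name) for a in s.atoms
               if (a.resname, a.name) not in table]
    if missing:
        raise MissingParameterError(sorted(set(missing)))
    new_atoms = []
    for a in s.atoms:
        q, eps, rmin_half, gb_r = table[(a.resname, a.name)]
        new_atoms.append(replace(a, charge=q, lj_epsilon=eps,
                                 lj_rmin_half=rmin_half, gb_radius=gb_r))
    out = Structure(new_atoms, dict(s.partner_assignment))
    if formal_charges:
        for (chain, resid, resname), idx in out.residues():
            if resname not in formal_charges:
                continue
            net = sum(out.atoms[i].charge for i in idx)
            if abs(net - formal_charges[resname]) > 1e-6:
                raise ValueError(
                    f"residue {resname}{resid} chain {chain}: net charge "
                    f"{net:.6f} != declared formal charge "
                    f"{formal_charges[resname]:.6f}")
    return out


# ----------------------------------------------------------------------
# Chemical roles
# ----------------------------------------------------------------------

_ANIONIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CATIONIC = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
             "HSP": ("ND1", "NE2")}
# His side-chain N that is NOT protonated accepts hydrogen bonds.
_HIS_ACCEPTOR = {"HSD": "NE2", "HSE": "ND1", "HIS": "ND1"}


def infer_chem_roles(s: Structure) -> ChemRoles:
    """Classify atoms as H-bond donors/acceptors and salt-bridge partners.

    Donor pairs are (N or O heavy atom, hydrogen) with the hydrogen bonded
    within 1.2 A.  Acceptors are all oxygens plus the unprotonated
    histidine side-chain nitrogen.  Anionic atoms are the carboxylate
    oxygens of Asp/Glu and C-terminal O/OXT; cationic atoms are Lys NZ,
    Arg NE/NH1/NH2 and both ring nitrogens of doubly protonated His (HSP).
    A structure with no hydrogens only triggers a warning (hydrogen-bond
    detection is then unavailable).
    """
    atoms = s.atoms
    if not any(a.element == "H" for a in atoms):
        warnings.warn("structure has no hydrogens: hydrogen-bond detection "
                      "is disabled", stacklevel=2)
    donor_pairs: list[tuple[int, int]] = []
    for i, j in s.bonds:
        if atoms[i].element == "H":
            i, j = j, i
        if atoms[j].element == "H" and atoms[i].element in ("N", "O"):
            donor_pairs.append((i, j))

    acceptors: list[int] = []
    anionic: list[int] = []
    cationic: list[int] = []
    residues = s.residues()
    for (chain, resid, resname), idx in residues:
        names = {atoms[i].name: i for i in idx}
        has_oxt = "OXT" in names
        for i in idx:
            a = atoms[i]
            if a.element == "O":
                acceptors.append(i)
            if a.name in _ANIONIC.get(resname, ()):
                anionic.append(i)
            if has_oxt and a.name in ("O", "OXT"):
                anionic.append(i)
            if a.name in _CATIONIC.get(resname, ()):
                cationic.append(i)
        his_acc = _HIS_ACCEPTOR.get(resname)
        if his_acc and his_acc in names:
            acceptors.append(names[his_acc])
    return ChemRoles(
        donor_pairs=tuple(sorted(donor_pairs)),
        acceptors=tuple(sorted(set(acceptors))),
        anionic_atoms=tuple(sorted(set(anionic))),
        cationic_atoms=tuple(sorted(set(cationic))),
    )
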