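"""Molecular constitution and holonomic distance bounds.

The distance-geometry engine never sees angles or torsions: everything it
knows about covalent structure is encoded as lower/upper bounds on
interatomic distances.  This module builds those *holonomic* bounds from a
guess geometry: bonded (1-2) and geminal (1-3) pairs, plus pairs inside
declared planar fragments, are pinned to the guess distance within a small
slack (default +/-1%); every other pair is left wide open between a scaled
van der Waals contact and a generous molecular-diameter cap, so that the
bounds carry no information about the configuration of stereocenters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "BoundsMatrix",
    "load_molecule",
    "build_bounds",
    "read_groups",
    "vdw_radius",
]


def _load_vdw_table() -> dict[str, float]:
    text = resources.files("fcdg.data").joinpath("vdw_radii.json").read_text()
    table = json.loads(text)
    return {k: float(v) for k, v in table.items() if not k.startswith("_")}


_VDW = _load_vdw_table()


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Angstrom for an element symbol."""
    try:
        return _VDW[element]
    except KeyError:
        raise ValueError(f"unknown element {element!r}: no vdW radius tabulated") from None


@dataclass(frozen=True)
class Atom:
    """One atom: 1-based index, element symbol, vdW radius, optional proton-group label."""

    index: int
    element: str
    vdw_radius: float
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str = "single"  # single / double / triple / aromatic

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")


@dataclass
class Molecule:
    """Constitution plus an optional guess geometry.

    Atom identifiers are 1-based everywhere, following chemical-table
    conventions; coordinates are orthonormal Angstrom.
    """

    atoms: Sequence[Atom]
    bonds: Sequence[Bond]
    guess_coords: np.ndarray | None = None
    proton_groups: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [a.index for a in self.atoms]
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise ValueError("atom indices must be unique and contiguous from 1")
        valid = set(idx)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.i not in valid or b.j not in valid:
                raise ValueError(f"bond ({b.i},{b.j}) references unknown atom")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if not self.bonds and len(self.atoms) > 1:
            raise ValueError("molecule has atoms but zero bonds")
        g = self.graph()
        if len(self.atoms) > 0 and not nx.is_connected(g):
            raise ValueError("molecule is not a single connected fragment")
        if self.guess_coords is not None:
            c = np.asarray(self.guess_coords, dtype=float)
            if c.shape != (len(self.atoms), 3):
                raise ValueError("guess_coords must be n x 3")
            self.guess_coords = c
        for gid, members in self.proton_groups.items():
            for m in members:
                if m not in valid:
                    raise ValueError(f"proton group {gid!r} references unknown atom {m}")

    # -- derived views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def hydrogens(self) -> list[int]:
        return [a.index for a in self.atoms if a.element == "H"]

    def group_members(self, gid: str) -> tuple[int, ...]:
        return tuple(self.proton_groups[gid])


@dataclass
class BoundsMatrix:
    """Symmetric lower/upper interatomic distance bounds in Angstrom."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = self.lower.shape[0]
        if self.lower.shape != (n, n) or self.upper.shape != (n, n):
            raise ValueError("bounds must be square matrices of equal shape")
        self.validate()

    def validate(self) -> None:
        if not np.allclose(self.lower, self.lower.T) or not np.allclose(self.upper, self.upper.T):
            raise ValueError("bounds matrices must be symmetric")
        if np.any(np.abs(np.diag(self.lower)) > 1e-12) or np.any(np.abs(np.diag(self.upper)) > 1e-12):
            raise ValueError("diagonal of bounds must be zero")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    def copy(self) -> "BoundsMatrix":
        return BoundsMatrix(self.lower.copy(), self.upper.copy())


# ---------------------------------------------------------------------------
# readers


_RDKIT_ORDER = {"SINGLE": "single", "DOUBLE": "double", "TRIPLE": "triple", "AROMATIC": "aromatic"}


def _molecule_from_rdkit(rdmol, proton_groups: Mapping[str, tuple[int, ...]] | None = None) -> Molecule:
    from rdkit import Chem  # noqa: F401

    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        sym = a.GetSymbol()
        atoms.append(Atom(index=i + 1, element=sym, vdw_radius=vdw_radius(sym)))
    bonds = []
    for b in rdmol.GetBonds():
        order = _RDKIT_ORDER.get(str(b.GetBondType()), "single")
        bonds.append(Bond(b.GetBeginAtomIdx() + 1, b.GetEndAtomIdx() + 1, order))
    coords = None
    if rdmol.GetNumConformers() > 0:
        conf = rdmol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z] for i in range(rdmol.GetNumAtoms())])
    groups: Mapping[str, tuple[int, ...]] = proton_groups or {}
    if not groups and rdmol.HasProp("PROTON_GROUPS"):
        groups = _parse_group_lines(rdmol.GetProp("PROTON_GROUPS").splitlines())
    return Molecule(atoms=atoms, bonds=bonds, guess_coords=coords, proton_groups=groups)


def _parse_group_lines(lines: Iterable[str]) -> dict[str, tuple[int, ...]]:
    groups: dict[str, tuple[int, ...]] = {}
    for ln in lines:
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.replace("\t", " ").split()
        if parts[0].lower() == "group_id":  # header
            continue
        groups[parts[0]] = tuple(int(p) for p in parts[1:])
    return groups


def read_groups(path_or_text: str | Path) -> dict[str, tuple[int, ...]]:
    """Read an isochronous proton-group table (TSV: group_id, atom indices)."""
    text = _as_text(path_or_text)
    return _parse_group_lines(text.splitlines())


def _as_text(path_or_text: str | Path) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    s = str(path_or_text)
    if "\n" not in s and len(s) < 4096:
        p = Path(s)
        try:
            if p.is_file():
                return p.read_text()
        except OSError:
            pass
    return s


def load_molecule(
    path_or_text: str | Path,
    fmt: str | None = None,
    bonds: str | Path | None = None,
    groups: Mapping[str, tuple[int, ...]] | str | Path | None = None,
) -> Molecule:
    """Load a molecule from an SDF/MOL V2000 document or an XYZ file plus bond table.

    Hydrogens must be explicit.  For XYZ input a two-column bond TSV is
    required (``bonds=``); SDF carries its own bond block.  Proton groups may
    come from the SDF property ``PROTON_GROUPS``, or via ``groups=`` as a
    mapping or a TSV path.
    """
    text = _as_text(path_or_text)
    if fmt is None:
        name = str(path_or_text).lower()
        if name.endswith(".xyz"):
            fmt = "xyz"
        elif "V2000" in text:
            fmt = "sdf"
        elif name.endswith((".sdf", ".mol")):
            fmt = "sdf"
        else:
            raise ValueError("cannot infer format; pass fmt='sdf' or 'xyz'")
    if isinstance(groups, (str, Path)):
        groups = read_groups(groups)
    if fmt == "sdf":
        from rdkit import Chem

        rdmol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if rdmol is None:
            raise ValueError("unparsable SDF/MOL document")
        if rdmol.GetNumBonds() == 0 and rdmol.GetNumAtoms() > 1:
            raise ValueError("molecule has zero bonds")
        # re-attach properties lost by MolFromMolBlock only when reading files
        if groups is None and "PROTON_GROUPS" in text:
            groups = _parse_group_lines(_sdf_property(text, "PROTON_GROUPS"))
        return _molecule_from_rdkit(rdmol, groups)
    if fmt == "xyz":
        if bonds is None:
            raise ValueError("bonds required: XYZ carries no connectivity; pass a bond table")
        lines = text.strip().splitlines()
        try:
            n = int(lines[0].split()[0])
        except (ValueError, IndexError):
            raise ValueError("unparsable XYZ document") from None
        body = lines[2 : 2 + n]
        if len(body) != n:
            raise ValueError("XYZ atom count does not match body")
        atoms, coords = [], []
        for k, ln in enumerate(body):
            parts = ln.split()
            sym = parts[0]
            atoms.append(Atom(index=k + 1, element=sym, vdw_radius=vdw_radius(sym)))
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        bond_list = []
        for ln in _as_text(bonds).splitlines():
            ln = ln.split("#", 1)[0].strip()
            if not ln or ln.lower().startswith("i"):
                continue
            i, j, *rest = ln.split()
            bond_list.append(Bond(int(i), int(j), rest[0] if rest else "single"))
        return Molecule(atoms=atoms, bonds=bond_list, guess_coords=np.array(coords), proton_groups=dict(groups or {}))
    raise ValueError(f"unknown format {fmt!r}")


def _sdf_property(text: str, key: str) -> list[str]:
    lines = text.splitlines()
    out: list[str] = []
    grab = False
    for ln in lines:
        if ln.startswith(">") and f"<{key}>" in ln:
            grab = True
            continue
        if grab:
            if not ln.strip() or ln.startswith((">", "$$$$")):
                break
            out.append(ln)
    return out


# ---------------------------------------------------------------------------
# planar fragments and holonomic bounds


def planar_groups(mol: Molecule) -> list[tuple[int, ...]]:
    """Planar fragments implied by the constitution.

    Each aromatic ring contributes its ring atoms plus their direct
    substituents; each double bond contributes the two sp2 atoms plus their
    neighbours.  Intra-group distances are then holonomically pinned.
    """
    g = mol.graph()
    groups: list[tuple[int, ...]] = []
    arom = nx.Graph((b.i, b.j) for b in mol.bonds if b.order == "aromatic")
    for ring in nx.cycle_basis(arom) if arom.number_of_nodes() else []:
        members = set(ring)
        for a in ring:
            members.update(g.neighbors(a))
        groups.append(tuple(sorted(members)))
    for b in mol.bonds:
        if b.order == "double":
            members = {b.i, b.j} | set(g.neighbors(b.i)) | set(g.neighbors(b.j))
            groups.append(tuple(sorted(members)))
    return groups


def build_bounds(
    mol: Molecule,
    slack: float = 0.01,
    vdw_factor: float = 0.7,
    cap: float | None = None,
) -> BoundsMatrix:
    """Holonomic distance bounds from the guess geometry.

    1-2 (bonded) and 1-3 (geminal) pairs, and all pairs within a planar
    fragment, get windows guess_distance * (1 -/+ slack).  Every other pair
    is bounded below by ``vdw_factor`` times the sum of vdW radii (0.7, so
    genuinely congested contacts of real geometries stay admissible) and above
    by ``cap`` (default ``n * 2.0`` A).  1-4 and longer-range pairs are
    deliberately NOT derived from the guess: their windows must admit every
    configuration.
    """
    if mol.guess_coords is None:
        raise ValueError("build_bounds requires guess coordinates")
    n = mol.n_atoms
    coords = mol.guess_coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    radii = mol.vdw_radii()
    lower = vdw_factor * (radii[:, None] + radii[None, :])
    upper = np.full((n, n), cap if cap is not None else n * 2.0, dtype=float)

    g = mol.graph()
    pin = np.zeros((n, n), dtype=bool)
    for b in mol.bonds:
        pin[b.i - 1, b.j - 1] = pin[b.j - 1, b.i - 1] = True
    for center in g.nodes:
        nbrs = sorted(g.neighbors(center))
        for a in range(len(nbrs)):
            for bb in range(a + 1, len(nbrs)):
                pin[nbrs[a] - 1, nbrs[bb] - 1] = pin[nbrs[bb] - 1, nbrs[a] - 1] = True
    for grp in planar_groups(mol):
        idx = np.array(grp, dtype=int) - 1
        pin[np.ix_(idx, idx)] = True

    np.fill_diagonal(pin, False)
    lower[pin] = d[pin] * (1.0 - slack)
    upper[pin] = d[pin] * (1.0 + slack)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    return BoundsMatrix(lower, upper)
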