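"""Chiral volumes, stereocenter bookkeeping and configuration fingerprints.

The configuration of an sp3 center is encoded by the sign of the chiral
volume, the pseudo scalar triple product

    V = (r1 - r4) . ((r2 - r4) x (r3 - r4))

over an ordered quadruple of substituent positions.  V = 0 encodes
planarity (sp2 frames).  Because NMR determines relative configuration
only, fingerprints of chiral-volume signs are normalized so that a chosen
reference center always reads '+': a structure and its mirror image get the
same fingerprint, and n stereocenters give 2^(n-1) distinct fingerprints
(diastereomers).

Substituent ordering convention: ascending atom index.  Any self-consistent
convention yields the same *relative* configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .moltop import Molecule

__all__ = [
    "StereoCenter",
    "ChiralRestraint",
    "ConfigFingerprint",
    "chiral_volume",
    "chiral_volume_gradient",
    "detect_stereocenters",
    "standard_chiral_restraints",
    "fingerprint",
    "enumerate_relative_configs",
    "ideal_tetrahedral_volume",
    "DEGENERACY_FLOOR",
]

#: |V| below this (A^3) marks a center geometrically indeterminate.
DEGENERACY_FLOOR = 0.01


@dataclass(frozen=True)
class StereoCenter:
    """A stereogenic center: the central atom and its ordered substituents.

    ``substituents`` holds four atom indices, or three plus the center
    itself as the fourth point for trisubstituted centers.
    """

    center: int
    substituents: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.substituents)) != 4:
            raise ValueError("substituent quadruple must contain four distinct atoms")


@dataclass(frozen=True)
class ChiralRestraint:
    """Signed chiral-volume target over an ordered atom quadruple.

    mode 'fixed-sign' pins a tetrahedral center to a signed volume, 'planar'
    pins an sp2 frame to V=0, 'unrestrained' marks a floating center that
    contributes no pseudo-energy.
    """

    atoms: tuple[int, int, int, int]
    target_volume: float
    weight: float = 1.0
    mode: str = "fixed-sign"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-sign", "planar", "unrestrained"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "planar" and self.target_volume != 0.0:
            raise ValueError("planar restraints require target_volume = 0")
        if len(set(self.atoms)) != 4:
            raise ValueError("atom quadruple must be distinct")


@dataclass(frozen=True)
class ConfigFingerprint:
    """Signs of chiral volumes over stereocenters, reference normalized to '+'."""

    signs: tuple[int, ...]  # +1 / -1 per center, 0 = indeterminate
    centers: tuple[int, ...] = ()

    @property
    def text(self) -> str:
        return "".join({1: "+", -1: "-", 0: "?"}[s] for s in self.signs)

    @property
    def indeterminate(self) -> bool:
        return any(s == 0 for s in self.signs)

    def __str__(self) -> str:  # pragma: no cover
        return self.text


def chiral_volume(coords: np.ndarray, atoms: Sequence[int]) -> float:
    """Signed chiral volume (A^3) of an ordered atom quadruple (1-based ids).

    Only the first three coordinate columns enter, so 4D structures are
    evaluated on their 3D projection.
    """
    a = tuple(atoms)
    if len(set(a)) != 4:
        raise ValueError("chiral volume needs four distinct atoms")
    c = np.asarray(coords, dtype=float)[[i - 1 for i in a], :3]
    v1, v2, v3 = c[0] - c[3], c[1] - c[3], c[2] - c[3]
    return float(np.dot(v1, np.cross(v2, v3)))


def chiral_volume_gradient(coords: np.ndarray, atoms: Sequence[int]) -> np.ndarray:
    """dV/dr for the four atoms of a quadruple; shape (4, 3)."""
    c = np.asarray(coords, dtype=float)[[i - 1 for i in atoms], :3]
    v1, v2, v3 = c[0] - c[3], c[1] - c[3], c[2] - c[3]
    g1 = np.cross(v2, v3)
    g2 = np.cross(v3, v1)
    g3 = np.cross(v1, v2)
    return np.stack([g1, g2, g3, -(g1 + g2 + g3)])


# ---------------------------------------------------------------------------
# stereocenter detection


def _branch_signature(g: nx.Graph, start: int, center: int, max_depth: int = 8) -> str:
    """Canonical signature of the branch entered from ``center`` via ``start``.

    Depth-bounded DFS with per-path visited sets, so fused rings terminate;
    two branches compare equal iff their depth-bounded trees are isomorphic
    with element labels.
    """

    def walk(node: int, prev: int, depth: int, path: frozenset[int]) -> str:
        label = g.nodes[node]["element"]
        if depth == 0:
            return label
        subs = sorted(
            walk(nb, node, depth - 1, path | {nb})
            for nb in g.neighbors(node)
            if nb != prev and nb not in path
        )
        return label + "(" + ",".join(subs) + ")"

    return walk(start, center, max_depth, frozenset({center, start}))


def detect_stereocenters(
    mol: Molecule,
    declared: Sequence[StereoCenter] | None = None,
) -> list[StereoCenter]:
    """sp3 carbons whose four substituent branches are pairwise distinct.

    A user-supplied ``declared`` list overrides detection verbatim (NMR work
    often knows the stereogenic centers from the constitution even when the
    bounded graph walk cannot distinguish symmetric ring branches).
    """
    if declared is not None:
        return list(declared)
    g = mol.graph()
    out = []
    for atom in mol.atoms:
        if atom.element != "C":
            continue
        nbrs = sorted(g.neighbors(atom.index))
        if len(nbrs) != 4:
            continue
        sigs = [_branch_signature(g, nb, atom.index) for nb in nbrs]
        if len(set(sigs)) == 4:
            out.append(StereoCenter(center=atom.index, substituents=tuple(nbrs)))
    return out


def ideal_tetrahedral_volume(bond_lengths: Sequence[float]) -> float:
    """|V| of an ideal tetrahedral center (109.47 deg) with the given four bond lengths.

    Substituent k sits at distance L_k along the k-th vertex direction of a
    regular tetrahedron; the triple product is evaluated over substituents
    1-3 relative to substituent 4.
    """
    dirs = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    pts = dirs * np.asarray(bond_lengths, dtype=float)[:, None]
    v1, v2, v3 = pts[0] - pts[3], pts[1] - pts[3], pts[2] - pts[3]
    return abs(float(np.dot(v1, np.cross(v2, v3))))


def _quad_for_center(g: nx.Graph, center: int) -> tuple[int, int, int, int]:
    nbrs = sorted(g.neighbors(center))
    if len(nbrs) >= 4:
        return tuple(nbrs[:4])  # ascending-index convention
    if len(nbrs) == 3:
        return (nbrs[0], nbrs[1], nbrs[2], center)
    raise ValueError(f"atom {center} has fewer than three substituents")


def standard_chiral_restraints(
    mol: Molecule,
    fixed_center: int,
    centers: Sequence[StereoCenter] | None = None,
    k_planar: float = 1.0,
    k_fixed: float = 1.0,
) -> list[ChiralRestraint]:
    """The default floating-chirality restraint set.

    Planarity restraints (target 0) for every aromatic-ring atom and
    double-bond frame; fixed-sign tetrahedral restraints on methyl carbons
    (geometry upkeep only -- methyl H's are interchangeable); exactly one
    fixed-sign restraint on ``fixed_center`` to suppress the enantiomeric
    duplicate.  All other stereocenters float free.

    Signs of fixed targets are taken from the guess geometry (arbitrary but
    concrete); magnitudes from ideal tetrahedral geometry with the observed
    bond lengths.
    """
    g = mol.graph()
    stereo = centers if centers is not None else detect_stereocenters(mol)
    stereo_ids = {c.center for c in stereo}
    if fixed_center not in stereo_ids:
        raise ValueError(f"atom {fixed_center} is not a stereogenic center")
    if mol.guess_coords is None:
        raise ValueError("standard restraints need guess coordinates for target volumes")
    coords = mol.guess_coords
    out: list[ChiralRestraint] = []

    # planarity: sp2 frames
    for atom in mol.atoms:
        orders = [g.edges[atom.index, nb]["order"] for nb in g.neighbors(atom.index)]
        if "aromatic" in orders or "double" in orders:
            nbrs = sorted(g.neighbors(atom.index))
            if len(nbrs) == 3:
                out.append(
                    ChiralRestraint(
                        atoms=(nbrs[0], nbrs[1], nbrs[2], atom.index),
                        target_volume=0.0,
                        weight=k_planar,
                        mode="planar",
                    )
                )

    # methyl tetrahedrality
    for atom in mol.atoms:
        if atom.element != "C":
            continue
        nbrs = sorted(g.neighbors(atom.index))
        if len(nbrs) != 4:
            continue
        h = [n for n in nbrs if g.nodes[n]["element"] == "H"]
        if len(h) == 3:
            quad = _quad_for_center(g, atom.index)
            lengths = [np.linalg.norm(coords[q - 1] - coords[atom.index - 1]) if q != atom.index else 0.0 for q in quad]
            if atom.index in quad:
                mag = ideal_tetrahedral_volume([l for l in lengths if l > 0] + [0.0])
            else:
                mag = ideal_tetrahedral_volume(lengths)
            sign = np.sign(chiral_volume(coords, quad)) or 1.0
            out.append(ChiralRestraint(atoms=quad, target_volume=float(sign * mag), mode="fixed-sign"))

    # the single fixed stereocenter
    for c in stereo:
        quad = c.substituents
        if c.center == fixed_center:
            lengths = [
                np.linalg.norm(coords[q - 1] - coords[c.center - 1]) if q != c.center else 0.0
                for q in quad
            ]
            nonzero = [l for l in lengths if l > 0]
            mag = ideal_tetrahedral_volume(nonzero + [0.0] * (4 - len(nonzero)))
            sign = np.sign(chiral_volume(coords, quad)) or 1.0
            out.append(
                ChiralRestraint(atoms=quad, target_volume=float(sign * mag), weight=k_fixed, mode="fixed-sign")
            )
        else:
            out.append(ChiralRestraint(atoms=quad, target_volume=0.0, weight=0.0, mode="unrestrained"))
    return out


def fingerprint(
    coords: np.ndarray,
    centers: Sequence[StereoCenter],
    reference: StereoCenter,
    floor: float = DEGENERACY_FLOOR,
) -> ConfigFingerprint:
    """Relative-configuration fingerprint of a structure.

    Signs of chiral volumes over ``centers`` (sorted by center atom), flipped
    globally so the reference center reads '+'.  Centers with |V| below the
    degeneracy floor are flagged indeterminate ('?').
    """
    ordered = sorted(centers, key=lambda c: c.center)
    if reference.center not in {c.center for c in ordered}:
        ordered = sorted(list(ordered) + [reference], key=lambda c: c.center)
    signs = []
    ref_sign = 0
    for c in ordered:
        v = chiral_volume(coords, c.substituents)
        s = 0 if abs(v) < floor else (1 if v > 0 else -1)
        signs.append(s)
        if c.center == reference.center:
            ref_sign = s
    if ref_sign == -1:
        signs = [-s for s in signs]
    return ConfigFingerprint(signs=tuple(signs), centers=tuple(c.center for c in ordered))


def enumerate_relative_configs(n_centers: int, explicit: bool = False):
    """Number (or list) of relative configurations of n stereocenters: 2^(n-1).

    The first position is fixed '+' (mirror images are the same
    diastereomer), so 7 centers give 64 and 8 give 128.
    """
    if n_centers < 1:
        raise ValueError("need at least one stereocenter")
    count = 2 ** (n_centers - 1)
    if not explicit:
        return count
    vectors = [(1,) + tail for tail in product((1, -1), repeat=n_centers - 1)]
    assert len(vectors) == count
    return vectors
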