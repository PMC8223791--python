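"""Residual dipolar couplings: back-calculation, tensor fitting, pseudo-energy.

A weakly aligned molecule shows residual dipolar couplings

    D_ij = D_max(pair) * u^T S u,        u = r_ij / |r_ij|

with S the symmetric traceless 3x3 alignment (Saupe) order matrix (five
independent components) and D_max the gyromagnetic/r^3 prefactor of the
spin pair.  The tensor is obtained from observed couplings by linear least
squares (SVD); unassigned diastereotopic methylene protons enter only as
the *sum* of their two C-H couplings, i.e. as summed rows of the linear
system.  The RDC pseudo-energy refits the tensor to the current coordinates
at every evaluation and penalizes the squared residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentTensor",
    "RDCRestraint",
    "dmax",
    "backcalc_rdc",
    "fit_tensor",
    "random_tensor",
    "rdc_energy",
    "read_rdc_table",
    "write_rdc_table",
]


def _load_constants() -> dict[str, float]:
    text = resources.files("fcdg.data").joinpath("rdc_constants.json").read_text()
    return {k: float(v) for k, v in json.loads(text).items() if not k.startswith("_")}


_K = _load_constants()


def dmax(elem_i: str, elem_j: str, r: float) -> float:
    """Dipolar prefactor D_max = K(pair)/r^3 in Hz for a pair at distance r (A)."""
    key = "".join(sorted((elem_i, elem_j)))
    if key not in _K:
        key = "".join(sorted((elem_j, elem_i)))
    if key not in _K:
        raise ValueError(f"no dipolar constant for pair {elem_i}-{elem_j}")
    return _K[key] / r**3


@dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless order matrix; stored as the full 3x3."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("alignment tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("alignment tensor must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, np.abs(m).max()):
            raise ValueError("alignment tensor must be traceless")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_components(cls, sxx: float, syy: float, sxy: float, sxz: float, syz: float) -> "AlignmentTensor":
        szz = -(sxx + syy)
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @property
    def components(self) -> np.ndarray:
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)


@dataclass(frozen=True)
class RDCRestraint:
    """One observed coupling: a single atom pair or a set of pairs summed.

    ``pairs`` holds 1-based (i, j) tuples; more than one pair means the
    observed value is the sum of the individual couplings (unassigned
    methylene convention).
    """

    pairs: tuple[tuple[int, int], ...]
    observed: float  # Hz
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("RDC restraint needs at least one atom pair")
        for i, j in self.pairs:
            if i == j:
                raise ValueError("RDC pair atoms must be distinct")


def _row(coords: np.ndarray, elements: Sequence[str], pair: tuple[int, int]) -> np.ndarray:
    """Design-matrix row of one pair: D = row . (Sxx, Syy, Sxy, Sxz, Syz)."""
    i, j = pair
    r = coords[i - 1, :3] - coords[j - 1, :3]
    dist = np.linalg.norm(r)
    if dist < 1e-9:
        raise ValueError(f"coincident atoms in RDC pair {pair}")
    u = r / dist
    k = dmax(elements[i - 1], elements[j - 1], dist)
    x, y, z = u
    # u^T S u with trace-free parametrization: Szz = -(Sxx+Syy)
    return k * np.array([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def backcalc_rdc(
    coords: np.ndarray,
    tensor: AlignmentTensor,
    pair: tuple[int, int] | Sequence[tuple[int, int]],
    elements: Sequence[str],
) -> float:
    """Back-calculated coupling (Hz) for one pair, or the sum over a pair set."""
    pairs = [pair] if isinstance(pair[0], (int, np.integer)) else list(pair)
    total = 0.0
    for p in pairs:
        i, j = p
        r = coords[i - 1, :3] - coords[j - 1, :3]
        dist = np.linalg.norm(r)
        if dist < 1e-9:
            raise ValueError(f"coincident atoms in RDC pair {p}")
        u = r / dist
        total += dmax(elements[i - 1], elements[j - 1], dist) * float(u @ tensor.matrix @ u)
    return total


def _design_matrix(coords: np.ndarray, elements: Sequence[str], rdcs: Sequence[RDCRestraint]) -> np.ndarray:
    rows = []
    for r in rdcs:
        rows.append(sum((_row(coords, elements, p) for p in r.pairs), np.zeros(5)))
    return np.array(rows)


def fit_tensor(
    coords: np.ndarray,
    rdcs: Sequence[RDCRestraint],
    elements: Sequence[str],
) -> tuple[AlignmentTensor, dict]:
    """Least-squares alignment tensor from observed couplings (SVD solution).

    Returns the tensor and a residual report (per-restraint residuals, RMS
    and the Q factor).  Requires at least five linearly independent
    orientation rows; summed methylene pairs contribute summed rows.
    """
    a = _design_matrix(coords, elements, rdcs)
    obs = np.array([r.observed for r in rdcs], dtype=float)
    w = np.sqrt(np.array([r.weight for r in rdcs], dtype=float))
    rank = np.linalg.matrix_rank(a, tol=1e-10 * max(1.0, np.abs(a).max()))
    if rank < 5:
        raise ValueError(f"RDC system is rank deficient (rank {rank} < 5); add independent orientations")
    sol, *_ = np.linalg.lstsq(a * w[:, None], obs * w, rcond=None)
    tensor = AlignmentTensor.from_components(*sol)
    calc = a @ sol
    resid = obs - calc
    q = float(np.sqrt(np.sum(resid**2) / np.sum(obs**2))) if np.any(obs) else 0.0
    report = {
        "residuals": resid,
        "calc": calc,
        "rms": float(np.sqrt(np.mean(resid**2))),
        "q_factor": q,
    }
    return tensor, report


def random_tensor(rng: np.random.Generator, magnitude: float = 1e-3) -> AlignmentTensor:
    """Random alignment tensor with eigenvalue scale set by ``magnitude``.

    ``magnitude`` is the scale of the largest (dimensionless) order-matrix
    eigenvalue; ~1e-3 gives one-bond C-H couplings of a few tens of Hz.  The
    largest eigenvalue magnitude is drawn uniformly in [magnitude/2,
    magnitude] and the frame is a random rotation.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    lam1 = rng.uniform(0.5, 1.0) * magnitude * rng.choice([-1.0, 1.0])
    lam2 = -lam1 * rng.uniform(0.3, 0.7)
    lam3 = -lam1 - lam2
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    m = q @ np.diag([lam1, lam2, lam3]) @ q.T
    m = 0.5 * (m + m.T)
    m -= np.eye(3) * np.trace(m) / 3.0
    return AlignmentTensor(m)


def rdc_energy(
    coords: np.ndarray,
    rdcs: Sequence[RDCRestraint],
    elements: Sequence[str],
    k_rdc: float = 1.0,
    tensor: AlignmentTensor | None = None,
) -> tuple[float, np.ndarray]:
    """RDC pseudo-energy and its gradient on 3D coordinates.

    The tensor is refit to the current coordinates (unless given), then

        e_rdc = k_rdc * sum_w (D_obs - D_calc)^2

    The gradient treats the fitted tensor as locally constant (Gauss-Newton
    convention): only the geometric dependence of D_calc on the internuclear
    unit vectors is differentiated.  If the refit is rank deficient, the
    term reports as inactive (zero energy/gradient) with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] != 3:
        raise ValueError("RDC term is defined on 3D coordinates only")
    if tensor is None:
        try:
            tensor, _ = fit_tensor(coords, rdcs, elements)
        except ValueError:
            import warnings

            warnings.warn("RDC tensor refit rank deficient; RDC term inactive for this evaluation")
            return 0.0, np.zeros_like(coords)
    s = tensor.matrix
    grad = np.zeros_like(coords)
    energy = 0.0
    for r in rdcs:
        calc = 0.0
        pair_grads = []
        for i, j in r.pairs:
            rij = coords[i - 1] - coords[j - 1]
            dist = np.linalg.norm(rij)
            u = rij / dist
            k = dmax(elements[i - 1], elements[j - 1], dist)
            usu = float(u @ s @ u)
            calc += k * usu
            # d(k * u^T S u)/d r_i ; k depends on r via 1/r^3
            dudr = (2.0 / dist) * (s @ u - usu * u)
            dk = -3.0 * k / dist * usu * u
            pair_grads.append((i, j, k * dudr + dk))
        diff = calc - r.observed
        energy += r.weight * diff * diff
        for i, j, gvec in pair_grads:
            grad[i - 1] += 2.0 * r.weight * diff * gvec
            grad[j - 1] -= 2.0 * r.weight * diff * gvec
    return k_rdc * energy, k_rdc * grad


# ---------------------------------------------------------------------------
# TSV dialect: atom_i atom_j (or "i1,j1+i2,j2") D_Hz weight


def read_rdc_table(path_or_text: str | Path) -> list[RDCRestraint]:
    from .moltop import _as_text

    out = []
    for ln in _as_text(path_or_text).splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln or ln.lower().startswith(("atom_i", "pair")):
            continue
        parts = ln.split()
        if len(parts) >= 4 and "+" not in parts[0]:
            pairs = ((int(parts[0]), int(parts[1])),)
            d, w = float(parts[2]), float(parts[3])
        else:
            spec = parts[0]
            pairs = tuple(tuple(int(x) for x in chunk.split(",")) for chunk in spec.split("+"))
            d = float(parts[1])
            w = float(parts[2]) if len(parts) > 2 else 1.0
        out.append(RDCRestraint(pairs=pairs, observed=d, weight=w))
    return out


def write_rdc_table(rdcs: Sequence[RDCRestraint], path: str | Path) -> None:
    lines = ["# pair\tD_Hz\tweight"]
    for r in rdcs:
        spec = "+".join(f"{i},{j}" for i, j in r.pairs)
        lines.append(f"{spec}\t{r.observed:.4f}\t{r.weight:g}")
    Path(path).write_text("\n".join(lines) + "\n")
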