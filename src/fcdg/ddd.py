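"""Distance-bounds-driven dynamics: pseudo-energy, forces, annealing, ensembles.

No physical force field enters anywhere.  The only "energy" is the
dimensionless sum of weighted squared restraint violations,

    E = k_dist * sum max(0, d-u)^2 + max(0, l-d)^2        (bounds + NOE windows)
      + k_chir * sum (V - V_target)^2                     (chiral volumes)
      + k_rdc  * sum w (D_obs - D_calc)^2                 (optional RDCs, 3D only)

whose analytic gradient acts as the force in a velocity-rescaled leapfrog
annealing run: hot at T_high in 4D, cooled linearly to 0 K, projected to
3D, annealed again, then quenched by gradient descent.  Structures are
ranked ascending by the final pseudo-energy; low energy means the
configuration+conformation explains the data.

The engine is batch-vectorized: an ensemble anneals as one (B, n, dim)
array, with per-structure RNG streams derived from (seed, structure index)
so results are independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calib import DistanceRestraint
from .embed import SmoothedBounds, embed_metric, metrize, smooth_bounds
from .moltop import BoundsMatrix, Molecule
from .rdc import RDCRestraint
from .stereo import ChiralRestraint, ConfigFingerprint, StereoCenter, detect_stereocenters, fingerprint

__all__ = [
    "DDDParams",
    "EnergyBreakdown",
    "RestraintSystem",
    "StructureResult",
    "RankedEnsemble",
    "pseudo_energy",
    "energy_gradient",
    "anneal_stage",
    "reduce_dimension",
    "generate_ensemble",
    "write_ensemble_pdb",
]

try:  # fused pair-loop kernel; the numpy path below is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _bounds_kernel(coords, lower, upper, k):  # pragma: no cover - exercised via energy_grad
        b_sz, n, dim = coords.shape
        e = np.zeros(b_sz)
        grad = np.zeros_like(coords)
        for b in range(b_sz):
            for i in range(n):
                for j in range(i + 1, n):
                    d2 = 0.0
                    for c in range(dim):
                        t = coords[b, i, c] - coords[b, j, c]
                        d2 += t * t
                    d = np.sqrt(d2)
                    if d < 1e-6:
                        d = 1e-6
                    viol = 0.0
                    if d > upper[i, j]:
                        viol = d - upper[i, j]
                    elif d < lower[i, j]:
                        viol = d - lower[i, j]
                    if viol != 0.0:
                        e[b] += k * viol * viol
                        cf = 2.0 * k * viol / d
                        for c in range(dim):
                            g = cf * (coords[b, i, c] - coords[b, j, c])
                            grad[b, i, c] += g
                            grad[b, j, c] -= g
        return e, grad

    @njit(cache=True)
    def _restraint_kernel(  # pragma: no cover - exercised via energy_grad
        coords, gstart, gmembers, ga, gb, lw, up, wt, k_dist, quads, targets, cweights, k_chir
    ):
        b_sz, n, dim = coords.shape
        n_groups = gstart.shape[0] - 1
        e_dist = np.zeros(b_sz)
        e_chir = np.zeros(b_sz)
        grad = np.zeros_like(coords)
        cent = np.zeros((n_groups, dim))
        for b in range(b_sz):
            for g in range(n_groups):
                m0, m1 = gstart[g], gstart[g + 1]
                for c in range(dim):
                    acc = 0.0
                    for m in range(m0, m1):
                        acc += coords[b, gmembers[m], c]
                    cent[g, c] = acc / (m1 - m0)
            for r in range(ga.shape[0]):
                d2 = 0.0
                for c in range(dim):
                    t = cent[ga[r], c] - cent[gb[r], c]
                    d2 += t * t
                d = np.sqrt(d2)
                if d < 1e-6:
                    d = 1e-6
                viol = 0.0
                if d > up[r]:
                    viol = d - up[r]
                elif d < lw[r]:
                    viol = d - lw[r]
                if viol != 0.0:
                    e_dist[b] += k_dist * wt[r] * viol * viol
                    cf = 2.0 * k_dist * wt[r] * viol / d
                    for gi, sgn in ((ga[r], 1.0), (gb[r], -1.0)):
                        m0, m1 = gstart[gi], gstart[gi + 1]
                        share = 1.0 / (m1 - m0)
                        for m in range(m0, m1):
                            for c in range(dim):
                                grad[b, gmembers[m], c] += (
                                    sgn * share * cf * (cent[ga[r], c] - cent[gb[r], c])
                                )
            for q in range(quads.shape[0]):
                a0, a1, a2, a3 = quads[q, 0], quads[q, 1], quads[q, 2], quads[q, 3]
                v1x = coords[b, a0, 0] - coords[b, a3, 0]
                v1y = coords[b, a0, 1] - coords[b, a3, 1]
                v1z = coords[b, a0, 2] - coords[b, a3, 2]
                v2x = coords[b, a1, 0] - coords[b, a3, 0]
                v2y = coords[b, a1, 1] - coords[b, a3, 1]
                v2z = coords[b, a1, 2] - coords[b, a3, 2]
                v3x = coords[b, a2, 0] - coords[b, a3, 0]
                v3y = coords[b, a2, 1] - coords[b, a3, 1]
                v3z = coords[b, a2, 2] - coords[b, a3, 2]
                g1x = v2y * v3z - v2z * v3y
                g1y = v2z * v3x - v2x * v3z
                g1z = v2x * v3y - v2y * v3x
                vol = v1x * g1x + v1y * g1y + v1z * g1z
                dv = vol - targets[q]
                e_chir[b] += k_chir * cweights[q] * dv * dv
                f = 2.0 * k_chir * cweights[q] * dv
                g2x = v3y * v1z - v3z * v1y
                g2y = v3z * v1x - v3x * v1z
                g2z = v3x * v1y - v3y * v1x
                g3x = v1y * v2z - v1z * v2y
                g3y = v1z * v2x - v1x * v2z
                g3z = v1x * v2y - v1y * v2x
                grad[b, a0, 0] += f * g1x
                grad[b, a0, 1] += f * g1y
                grad[b, a0, 2] += f * g1z
                grad[b, a1, 0] += f * g2x
                grad[b, a1, 1] += f * g2y
                grad[b, a1, 2] += f * g2z
                grad[b, a2, 0] += f * g3x
                grad[b, a2, 1] += f * g3y
                grad[b, a2, 2] += f * g3z
                grad[b, a3, 0] -= f * (g1x + g2x + g3x)
                grad[b, a3, 1] -= f * (g1y + g2y + g3y)
                grad[b, a3, 2] -= f * (g1z + g2z + g3z)
        return e_dist, e_chir, grad

except ImportError:  # pragma: no cover
    _bounds_kernel = None
    _restraint_kernel = None


#: Thermostat scale: pseudo-energy units per Kelvin per degree of freedom.
#: Purely a search-dynamics knob (the pseudo-energy is dimensionless); the
#: default puts the thermal violation amplitude at 300 K near the width of a
#: +/-10% restraint window.
BOLTZMANN_PSEUDO = 2.0e-3


@dataclass(frozen=True)
class DDDParams:
    """Schedule and weights of one fc-rDG/DDD run.

    Times are in fs on a nominal unit-mass time scale; temperatures in K of
    the dimensionless thermostat.  Defaults follow the reference protocol:
    300 K, 5 ps hot + 5 ps linear cooling at 10 fs steps, in 4D then 3D.
    """

    t_high: float = 300.0
    hot_steps: int = 5000
    cool_steps: int = 5000
    dt: float = 10.0  # fs
    k_dist: float = 1.0
    k_chir: float = 10.0
    k_rdc: float = 0.02
    seed: int = 0
    kb: float = BOLTZMANN_PSEUDO
    quench_tol: float = 1.0e-8
    quench_max_iter: int = 1500
    compress_w: bool = False  # experimental: ramp a 4th-axis penalty during 4D cooling

    def __post_init__(self) -> None:
        if self.hot_steps <= 0 or self.cool_steps <= 0 or self.dt <= 0:
            raise ValueError("steps and dt must be positive")
        if min(self.k_dist, self.k_chir, self.k_rdc) < 0:
            raise ValueError("force constants must be non-negative")

    @property
    def dt_internal(self) -> float:
        return self.dt * 1.0e-3  # fs -> internal time unit

    def schedule(self) -> np.ndarray:
        """Target temperature per step: hot plateau then linear ramp to 0 K."""
        hot = np.full(self.hot_steps, self.t_high)
        cool = np.linspace(self.t_high, 0.0, self.cool_steps, endpoint=True)
        return np.concatenate([hot, cool])


@dataclass(frozen=True)
class EnergyBreakdown:
    e_dist: float
    e_chir: float
    e_rdc: float

    @property
    def e_total(self) -> float:
        return self.e_dist + self.e_chir + self.e_rdc


@dataclass(frozen=True)
class StructureResult:
    coords: np.ndarray  # n x 3
    energy: EnergyBreakdown
    fingerprint: ConfigFingerprint
    index: int  # generation index (RNG stream id)


@dataclass
class RankedEnsemble:
    """Structures sorted ascending by total pseudo-energy, with provenance."""

    structures: list[StructureResult]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        es = self.e_totals
        if np.any(np.diff(es) < -1e-9):
            raise ValueError("ensemble must be sorted ascending by e_total")
        lens = {len(s.fingerprint.signs) for s in self.structures}
        if len(lens) > 1:
            raise ValueError("fingerprints differ in length")

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def e_totals(self) -> np.ndarray:
        return np.array([s.energy.e_total for s in self.structures])

    @property
    def fingerprints(self) -> list[ConfigFingerprint]:
        return [s.fingerprint for s in self.structures]


# ---------------------------------------------------------------------------
# compiled restraint system


class RestraintSystem:
    """Bounds + restraints compiled to arrays; evaluates energies/gradients
    for a batch of structures at once (coords shape (B, n, dim))."""

    def __init__(
        self,
        mol: Molecule,
        bounds: SmoothedBounds | BoundsMatrix,
        dist_restraints: Sequence[DistanceRestraint] = (),
        chiral_restraints: Sequence[ChiralRestraint] = (),
        rdcs: Sequence[RDCRestraint] | None = None,
        k_dist: float = 1.0,
        k_chir: float = 10.0,
        k_rdc: float = 0.02,
    ):
        self.mol = mol
        self.n = mol.n_atoms
        self.lower = np.asarray(bounds.lower, dtype=float)
        self.upper = np.asarray(bounds.upper, dtype=float)
        self.k_dist, self.k_chir, self.k_rdc = float(k_dist), float(k_chir), float(k_rdc)
        self.elements = mol.elements()

        # experimental restraints between proton-group centroids
        groups = dict(mol.proton_groups)
        g_ids: list[str] = []
        g_index: dict[str, int] = {}

        def resolve(gid: str) -> int:
            if gid not in g_index:
                if gid in groups:
                    members = groups[gid]
                else:
                    try:
                        members = (int(gid),)
                    except ValueError:
                        raise ValueError(f"unknown group identifier {gid!r}") from None
                g_index[gid] = len(g_ids)
                g_ids.append(gid)
                self._members.append(members)
            return g_index[gid]

        self._members: list[tuple[int, ...]] = []
        ga, gb, lw, up, wt = [], [], [], [], []
        for r in dist_restraints:
            ga.append(resolve(r.group_i))
            gb.append(resolve(r.group_j))
            lw.append(r.lower)
            up.append(r.upper)
            wt.append(r.weight)
        self.r_ga = np.array(ga, dtype=int)
        self.r_gb = np.array(gb, dtype=int)
        self.r_lw = np.array(lw, dtype=float)
        self.r_up = np.array(up, dtype=float)
        self.r_wt = np.array(wt, dtype=float)
        m = np.zeros((len(g_ids), self.n))
        for k, members in enumerate(self._members):
            for a in members:
                m[k, a - 1] = 1.0 / len(members)
        self.cent_m = m
        self._gstart = np.cumsum([0] + [len(mm) for mm in self._members]).astype(np.int64)
        self._gmembers = np.array(
            [a - 1 for mm in self._members for a in mm], dtype=np.int64
        )

        # chiral restraints (active = fixed-sign or planar)
        quads, targets, cw = [], [], []
        for c in chiral_restraints:
            if c.mode == "unrestrained" or c.weight == 0.0:
                continue
            quads.append([a - 1 for a in c.atoms])
            targets.append(c.target_volume)
            cw.append(c.weight)
        self.c_quads = np.array(quads, dtype=int).reshape(-1, 4)
        self.c_targets = np.array(targets, dtype=float)
        self.c_weights = np.array(cw, dtype=float)

        # RDCs
        self.rdcs = list(rdcs) if rdcs else []
        if self.rdcs:
            pi, pj, seg, kconst = [], [], [], []
            for ridx, r in enumerate(self.rdcs):
                for (i, j) in r.pairs:
                    pi.append(i - 1)
                    pj.append(j - 1)
                    seg.append(ridx)
                    from .rdc import _K

                    key = "".join(sorted((self.elements[i - 1], self.elements[j - 1])))
                    if key not in _K:
                        raise ValueError(f"no dipolar constant for pair {key}")
                    kconst.append(_K[key])
            self.p_i = np.array(pi, dtype=int)
            self.p_j = np.array(pj, dtype=int)
            self.p_seg = np.array(seg, dtype=int)
            self.p_k = np.array(kconst, dtype=float)
            self.r_obs = np.array([r.observed for r in self.rdcs])
            self.r_w = np.array([r.weight for r in self.rdcs])

    # -- energy/gradient ------------------------------------------------

    def energy_grad(
        self,
        coords: np.ndarray,
        include_rdc: bool = True,
        w_penalty: float = 0.0,
        rdc_scale: float = 1.0,
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Pseudo-energy terms and gradient for a batch (B, n, dim)."""
        coords = np.asarray(coords, dtype=float)
        batched = coords.ndim == 3
        if not batched:
            coords = coords[None]
        b, n, dim = coords.shape
        grad = np.zeros_like(coords)

        cc = np.ascontiguousarray(coords)

        # --- bounds term over all pairs
        if _bounds_kernel is not None:
            e_dist, gb = _bounds_kernel(cc, self.lower, self.upper, self.k_dist)
            grad += gb
        else:
            # reference numpy path: Gram-matrix distances + BLAS scatter
            # grad_i = (sum_j c_ij) r_i - (C r)_i avoids any (B,n,n,dim) temporary
            sq = np.sum(coords * coords, axis=-1)
            dots = coords @ coords.transpose(0, 2, 1)
            d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * dots
            d = np.sqrt(np.clip(d2, 1e-12, None))
            np.einsum("bii->bi", d)[:] = 1.0  # avoid 0/0 on the diagonal
            vu = np.clip(d - self.upper, 0.0, None)
            vl = np.clip(self.lower - d, 0.0, None)
            np.einsum("bii->bi", vu)[:] = 0.0
            np.einsum("bii->bi", vl)[:] = 0.0
            e_dist = 0.5 * self.k_dist * np.sum(vu * vu + vl * vl, axis=(1, 2))
            coef = (vu - vl)
            coef *= 2.0 * self.k_dist
            coef /= d
            grad += coef.sum(axis=2)[..., None] * coords - coef @ coords

        # --- experimental restraints + chiral volumes (fused kernel when available)
        e_chir = np.zeros(b)
        if _restraint_kernel is not None:
            ed_exp, e_chir, gr = _restraint_kernel(
                cc,
                self._gstart,
                self._gmembers,
                self.r_ga.astype(np.int64),
                self.r_gb.astype(np.int64),
                self.r_lw,
                self.r_up,
                self.r_wt,
                self.k_dist,
                self.c_quads.astype(np.int64),
                self.c_targets,
                self.c_weights,
                self.k_chir,
            )
            e_dist = e_dist + ed_exp
            grad += gr
        elif self.r_ga.size:
            cent = np.einsum("gn,bnd->bgd", self.cent_m, coords)
            dv = cent[:, self.r_ga] - cent[:, self.r_gb]
            dr = np.linalg.norm(dv, axis=-1)
            ru = np.clip(dr - self.r_up, 0.0, None)
            rl = np.clip(self.r_lw - dr, 0.0, None)
            e_dist = e_dist + self.k_dist * np.sum(self.r_wt * (ru * ru + rl * rl), axis=1)
            rcoef = 2.0 * self.k_dist * self.r_wt * (ru - rl) / np.maximum(dr, 1e-12)
            gvec = rcoef[..., None] * dv  # dE/d cent_ga
            gcent = np.zeros((b, self.cent_m.shape[0], dim))
            np.add.at(gcent, (slice(None), self.r_ga), gvec)
            np.add.at(gcent, (slice(None), self.r_gb), -gvec)
            grad += np.einsum("gn,bgd->bnd", self.cent_m, gcent)

        # --- chiral volumes (first three coordinates only; numpy fallback)
        if _restraint_kernel is not None:
            chiral_iter = ()
        else:
            chiral_iter = zip(self.c_quads, self.c_targets, self.c_weights)
        for q, t, w in chiral_iter:
            c = coords[:, q, :3]
            v1, v2, v3 = c[:, 0] - c[:, 3], c[:, 1] - c[:, 3], c[:, 2] - c[:, 3]
            vol = np.einsum("bd,bd->b", v1, np.cross(v2, v3))
            dvol = vol - t
            e_chir += self.k_chir * w * dvol * dvol
            g1 = np.cross(v2, v3)
            g2 = np.cross(v3, v1)
            g3 = np.cross(v1, v2)
            factor = (2.0 * self.k_chir * w * dvol)[:, None]
            grad[:, q[0], :3] += factor * g1
            grad[:, q[1], :3] += factor * g2
            grad[:, q[2], :3] += factor * g3
            grad[:, q[3], :3] -= factor * (g1 + g2 + g3)

        # --- RDCs (3D stages only)
        e_rdc = np.zeros(b)
        if include_rdc and self.rdcs and dim == 3 and rdc_scale > 0.0:
            e_rdc, grdc = self._rdc_batch(coords)
            e_rdc = rdc_scale * e_rdc
            grad += rdc_scale * grdc

        # --- optional 4th-axis compression penalty
        e_w = np.zeros(b)
        if w_penalty > 0.0 and dim == 4:
            w4 = coords[..., 3]
            e_w = w_penalty * np.sum(w4 * w4, axis=1)
            grad[..., 3] += 2.0 * w_penalty * w4

        terms = {
            "e_dist": e_dist if batched else e_dist[0],
            "e_chir": e_chir if batched else e_chir[0],
            "e_rdc": e_rdc if batched else e_rdc[0],
        }
        e_total = e_dist + e_chir + e_rdc + e_w
        terms["e_total"] = e_total if batched else e_total[0]
        return terms, (grad if batched else grad[0])

    def _rdc_batch(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, n, _ = coords.shape
        rvec = coords[:, self.p_i] - coords[:, self.p_j]  # (B,P,3)
        dist = np.linalg.norm(rvec, axis=-1)
        u = rvec / dist[..., None]
        k = self.p_k / dist**3
        x, y, z = u[..., 0], u[..., 1], u[..., 2]
        rows = k[..., None] * np.stack(
            [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=-1
        )  # (B,P,5)
        nr = len(self.rdcs)
        a = np.zeros((b, nr, 5))
        np.add.at(a, (slice(None), self.p_seg), rows)
        atwa = np.einsum("brf,r,brg->bfg", a, self.r_w, a)
        atwb = np.einsum("brf,r,r->bf", a, self.r_w, self.r_obs)
        ridge = 1e-10 * np.trace(atwa, axis1=1, axis2=2)[:, None, None] * np.eye(5) + 1e-30 * np.eye(5)
        sol = np.linalg.solve(atwa + ridge, atwb[..., None])[..., 0]  # (B,5)
        calc = np.einsum("brf,bf->br", a, sol)
        diffr = calc - self.r_obs
        e = self.k_rdc * np.sum(self.r_w * diffr * diffr, axis=1)
        # gradient at frozen tensor
        s = np.zeros((b, 3, 3))
        s[:, 0, 0] = sol[:, 0]
        s[:, 1, 1] = sol[:, 1]
        s[:, 2, 2] = -(sol[:, 0] + sol[:, 1])
        s[:, 0, 1] = s[:, 1, 0] = sol[:, 2]
        s[:, 0, 2] = s[:, 2, 0] = sol[:, 3]
        s[:, 1, 2] = s[:, 2, 1] = sol[:, 4]
        su = np.einsum("bij,bpj->bpi", s, u)
        usu = np.einsum("bpi,bpi->bp", u, su)
        gpair = k[..., None] * (2.0 / dist)[..., None] * (su - usu[..., None] * u) + (
            -3.0 * k / dist * usu
        )[..., None] * u
        coefp = 2.0 * self.k_rdc * (self.r_w[self.p_seg] * diffr[:, self.p_seg])
        contrib = coefp[..., None] * gpair  # (B,P,3)
        gt = np.zeros((n, b, 3))
        np.add.at(gt, self.p_i, contrib.transpose(1, 0, 2))
        np.add.at(gt, self.p_j, -contrib.transpose(1, 0, 2))
        return e, gt.transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# public single-structure API


def _make_system(
    mol: Molecule,
    bounds,
    restraints: Sequence,
    rdcs: Sequence[RDCRestraint] | None = None,
    k_dist: float = 1.0,
    k_chir: float = 10.0,
    k_rdc: float = 0.02,
) -> RestraintSystem:
    dist = [r for r in restraints if isinstance(r, DistanceRestraint)]
    chir = [r for r in restraints if isinstance(r, ChiralRestraint)]
    return RestraintSystem(mol, bounds, dist, chir, rdcs, k_dist, k_chir, k_rdc)


def pseudo_energy(
    coords: np.ndarray,
    mol: Molecule,
    bounds,
    restraints: Sequence = (),
    rdcs: Sequence[RDCRestraint] | None = None,
    k_dist: float = 1.0,
    k_chir: float = 10.0,
    k_rdc: float = 0.02,
) -> EnergyBreakdown:
    """Total pseudo-energy of one structure (dim 3 or 4).

    ``restraints`` may mix DistanceRestraint and ChiralRestraint; chiral
    volumes are evaluated on the first three coordinates, the RDC term only
    on 3D coordinates.
    """
    sys_ = _make_system(mol, bounds, restraints, rdcs, k_dist, k_chir, k_rdc)
    terms, _ = sys_.energy_grad(np.asarray(coords, dtype=float))
    return EnergyBreakdown(float(terms["e_dist"]), float(terms["e_chir"]), float(terms["e_rdc"]))


def energy_gradient(
    coords: np.ndarray,
    mol: Molecule,
    bounds,
    restraints: Sequence = (),
    rdcs: Sequence[RDCRestraint] | None = None,
    k_dist: float = 1.0,
    k_chir: float = 10.0,
    k_rdc: float = 0.02,
) -> np.ndarray:
    """Analytic gradient dE/dr of the pseudo-energy (forces are its negative)."""
    sys_ = _make_system(mol, bounds, restraints, rdcs, k_dist, k_chir, k_rdc)
    _, grad = sys_.energy_grad(np.asarray(coords, dtype=float))
    return grad


# ---------------------------------------------------------------------------
# dynamics


def _anneal_batch(
    coords: np.ndarray,
    system: RestraintSystem,
    params: DDDParams,
    velocities: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-rescaled leapfrog on a batch; returns coords and e_total trace (steps, B)."""
    coords = coords.copy()
    v = velocities.copy()
    b, n, dim = coords.shape
    dof = n * dim
    dt = params.dt_internal
    temps = params.schedule()
    nsteps = len(temps)
    trace = np.empty((nsteps, b))
    _, grad = system.energy_grad(coords)
    force = -grad
    for step, t_target in enumerate(temps):
        w_pen = 0.0
        if params.compress_w and dim == 4 and step >= params.hot_steps:
            w_pen = params.k_dist * (step - params.hot_steps + 1) / params.cool_steps
        # anisotropic restraints ramp in during cooling: early 3D geometry is too
        # distorted for a meaningful alignment-tensor fit
        rdc_scale = 0.0 if step < params.hot_steps else (step - params.hot_steps + 1) / params.cool_steps
        v += 0.5 * dt * force
        coords += dt * v
        terms, grad = system.energy_grad(coords, w_penalty=w_pen, rdc_scale=rdc_scale)
        force = -grad
        v += 0.5 * dt * force
        ke = 0.5 * np.sum(v * v, axis=(1, 2))
        if not np.all(np.isfinite(terms["e_total"])):
            bad = int(np.argmax(~np.isfinite(terms["e_total"])))
            raise FloatingPointError(f"energy overflow at step {step} (structure {bad})")
        t_inst = 2.0 * ke / (params.kb * dof)
        if t_target <= 0.0:
            v[:] = 0.0
        else:
            dead = t_inst < 1e-12
            scale = np.sqrt(t_target / np.maximum(t_inst, 1e-12))
            scale[dead] = 0.0
            v *= scale[:, None, None]
        trace[step] = terms["e_total"]
    return coords, trace


def _quench_batch(
    coords: np.ndarray,
    system: RestraintSystem,
    params: DDDParams,
) -> np.ndarray:
    """Zero-Kelvin quench by batched FIRE descent to gradient-norm tolerance.

    FIRE (fast inertial relaxation engine): inertial descent with adaptive
    time step, velocity projected onto the force direction, and a restart
    whenever a structure moves uphill.  Far more effective than plain
    steepest descent on the rugged sum-of-penalties landscape.
    """
    coords = coords.copy()
    b, n, dim = coords.shape
    dt0 = 0.05
    dt = np.full(b, dt0)
    alpha = np.full(b, 0.1)
    since_neg = np.zeros(b, dtype=int)
    v = np.zeros_like(coords)
    _, grad = system.energy_grad(coords)
    f = -grad
    for _ in range(params.quench_max_iter):
        gn = np.sqrt(np.sum(f * f, axis=(1, 2)))
        active = gn > params.quench_tol
        if not np.any(active):
            break
        power = np.sum(f * v, axis=(1, 2))
        vnorm = np.sqrt(np.sum(v * v, axis=(1, 2)))
        fn = np.maximum(gn, 1e-300)
        # mix velocity toward the force direction
        v = (1.0 - alpha[:, None, None]) * v + (alpha * vnorm / fn)[:, None, None] * f
        uphill = power < 0.0
        v[uphill] = 0.0
        dt[uphill] *= 0.5
        alpha[uphill] = 0.1
        since_neg[uphill] = 0
        ok = ~uphill
        since_neg[ok] += 1
        grow = ok & (since_neg > 5)
        dt[grow] = np.minimum(dt[grow] * 1.1, 10.0 * dt0)
        alpha[grow] *= 0.99
        v += dt[:, None, None] * f
        coords += dt[:, None, None] * v
        _, grad = system.energy_grad(coords)
        f = -grad
    return coords


def anneal_stage(
    start,
    system: RestraintSystem,
    params: DDDParams,
    dim: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One simulated-annealing stage on a single structure.

    ``start`` is an EmbeddedStructure or an (n, dim) array.  Initial
    velocities are Maxwell-distributed at t_high (zero if t_high == 0).
    Returns (final coordinates, per-step e_total trace).
    """
    coords = np.asarray(getattr(start, "coords4d", start), dtype=float)
    if coords.shape[1] != dim:
        raise ValueError(f"start coordinates have dim {coords.shape[1]}, expected {dim}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("start coordinates must be finite")
    rng = rng or np.random.default_rng(params.seed)
    scale = np.sqrt(params.kb * params.t_high)
    v = rng.normal(size=coords.shape) * scale
    out, trace = _anneal_batch(coords[None], system, params, v[None])
    return out[0], trace[:, 0]


def reduce_dimension(coords4d: np.ndarray) -> np.ndarray:
    """Drop the 4th coordinate (4D -> 3D projection)."""
    coords4d = np.asarray(coords4d, dtype=float)
    if coords4d.ndim != 2 or coords4d.shape[1] != 4:
        raise ValueError("expected n x 4 coordinates")
    return coords4d[:, :3].copy()


def _principal_project(coords: np.ndarray) -> np.ndarray:
    """Rotate a (B, n, 4) batch so the 4th axis carries the least variance.

    A proper 4D rotation costs no pseudo-energy, so projecting out the
    least-populated axis minimizes the damage of the 4D -> 3D truncation.
    """
    out = np.empty_like(coords)
    for k in range(coords.shape[0]):
        c = coords[k] - coords[k].mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        out[k] = c @ vt.T  # columns ordered by decreasing singular value
    return out


# ---------------------------------------------------------------------------
# ensemble generation


def generate_ensemble(
    mol: Molecule,
    bounds: BoundsMatrix,
    restraints: Sequence,
    n_structures: int = 1000,
    params: DDDParams | None = None,
    rdcs: Sequence[RDCRestraint] | None = None,
    centers: Sequence[StereoCenter] | None = None,
    reference: StereoCenter | None = None,
    max_retries: int = 5,
) -> RankedEnsemble:
    """Full fc-rDG/DDD pipeline: metrize -> embed 4D -> anneal 4D -> project ->
    anneal 3D -> quench -> rank.

    ``restraints`` mixes DistanceRestraint (NOE windows between proton
    groups) and ChiralRestraint (planarity, methyls, the one fixed center).
    Experimental windows are folded into the bounds matrix before smoothing
    so that metrization already samples near the data.  Fingerprints are
    evaluated over ``centers`` (auto-detected when omitted) relative to
    ``reference`` (defaults to the center carrying a fixed-sign restraint).
    """
    params = params or DDDParams()
    dist_rs = [r for r in restraints if isinstance(r, DistanceRestraint)]
    chir_rs = [r for r in restraints if isinstance(r, ChiralRestraint)]

    stereo_centers = list(centers) if centers is not None else detect_stereocenters(mol)
    if not stereo_centers:
        raise ValueError("no stereocenters: nothing to fingerprint")
    if reference is None:
        fixed_quads = {c.atoms for c in chir_rs if c.mode == "fixed-sign"}
        ref = next((c for c in stereo_centers if c.substituents in fixed_quads), stereo_centers[0])
    else:
        ref = reference

    # fold experimental windows into the bounds before smoothing
    work = bounds.copy()
    groups = dict(mol.proton_groups)

    def members_of(gid: str) -> tuple[int, ...]:
        if gid in groups:
            return groups[gid]
        return (int(gid),)

    for r in dist_rs:
        mi, mj = members_of(r.group_i), members_of(r.group_j)
        single = len(mi) == 1 and len(mj) == 1
        for a in mi:
            for c in mj:
                i, j = a - 1, c - 1
                work.upper[i, j] = work.upper[j, i] = min(work.upper[i, j], r.upper)
                if single:
                    work.lower[i, j] = work.lower[j, i] = max(work.lower[i, j], r.lower)
    smoothed = smooth_bounds(work)
    if not smoothed.consistent:
        raise ValueError(f"restraints inconsistent with holonomic bounds at pair {smoothed.violation}")

    system = RestraintSystem(
        mol, smoothed, dist_rs, chir_rs, rdcs, params.k_dist, params.k_chir, params.k_rdc
    )

    # the fixed-sign stereocenter restraint drives the post-projection mirror fix
    fixed_restraint = next(
        (c for c in chir_rs if c.mode == "fixed-sign" and set(c.atoms) == set(ref.substituents)),
        None,
    )

    n = mol.n_atoms
    coords4 = np.empty((n_structures, n, 4))
    vel4 = np.empty_like(coords4)
    vscale = np.sqrt(params.kb * params.t_high)
    for i in range(n_structures):
        for attempt in range(max_retries):
            rng = np.random.default_rng([params.seed % (2**31), i, attempt])
            try:
                dmat = metrize(smoothed, rng)
                emb = embed_metric(dmat, dim=4)
                coords4[i] = emb.coords4d
                vel4[i] = rng.normal(size=(n, 4)) * vscale
                break
            except (RuntimeError, ValueError):
                if attempt == max_retries - 1:
                    raise
    coords4, _ = _anneal_batch(coords4, system, params, vel4)
    coords4 = _quench_batch(coords4, system, params)  # optimize in 4D before projecting

    coords4 = _principal_project(coords4)
    coords3 = coords4[:, :, :3].copy()

    # mirror fix: in 3D the global enantiomer can no longer invert, so reflect
    # structures whose fixed reference center came out with the wrong sign
    if fixed_restraint is not None:
        q = [a - 1 for a in fixed_restraint.atoms]
        c = coords3[:, q]
        vols = np.einsum(
            "bd,bd->b", c[:, 0] - c[:, 3], np.cross(c[:, 1] - c[:, 3], c[:, 2] - c[:, 3])
        )
        wrong = np.sign(vols) != np.sign(fixed_restraint.target_volume)
        coords3[wrong, :, 2] *= -1.0

    vel3 = np.empty_like(coords3)
    for i in range(n_structures):
        rng = np.random.default_rng([params.seed % (2**31), i, 1000])
        vel3[i] = rng.normal(size=(n, 3)) * vscale
    coords3, _ = _anneal_batch(coords3, system, params, vel3)
    coords3 = _quench_batch(coords3, system, params)

    terms, _ = system.energy_grad(coords3)
    results = []
    for i in range(n_structures):
        fp = fingerprint(coords3[i], stereo_centers, ref)
        results.append(
            StructureResult(
                coords=coords3[i],
                energy=EnergyBreakdown(
                    float(terms["e_dist"][i]), float(terms["e_chir"][i]), float(terms["e_rdc"][i])
                ),
                fingerprint=fp,
                index=i,
            )
        )
    results.sort(key=lambda s: (s.energy.e_total, s.index))  # deterministic tie-break
    prov = {
        "seed": params.seed,
        "n_structures": n_structures,
        "params": params,
        "k_dist": params.k_dist,
        "k_chir": params.k_chir,
        "k_rdc": params.k_rdc,
    }
    return RankedEnsemble(structures=results, provenance=prov)


def write_ensemble_pdb(ensemble: RankedEnsemble, mol: Molecule, path) -> None:
    """Multi-model PDB, MODEL records in rank order, e_total in REMARK."""
    lines = [
        "REMARK   fc-rDG/DDD ensemble, ranked ascending by pseudo-energy",
        f"REMARK   force constants k_dist={ensemble.provenance.get('k_dist', 1.0)} "
        f"k_chir={ensemble.provenance.get('k_chir', 10.0)} k_rdc={ensemble.provenance.get('k_rdc', 1.0)}",
    ]
    elements = mol.elements()
    for rank, s in enumerate(ensemble.structures, start=1):
        lines.append(f"MODEL     {rank:4d}")
        lines.append(f"REMARK   e_total {s.energy.e_total:.6f} fingerprint {s.fingerprint.text}")
        for a, (x, y, z) in enumerate(s.coords, start=1):
            el = elements[a - 1]
            name = f"{el}{a}"[:4]
            lines.append(
                f"HETATM{a:5d} {name:<4s} LIG A   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
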