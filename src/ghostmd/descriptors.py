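"""Atom-centered symmetry functions (radial G2, angular G4) with Jacobians.

The descriptor of atom i is invariant under rotations, translations and
permutations of like atoms:

    G2(i; e, η, R_s) = Σ_{j∈e} exp(−η (r_ij − R_s)²) f_c(r_ij)
    G4(i; ee', ζ, λ, η) = 2^(1−ζ) Σ_{j<k ∈ ee'} (1 + λ cos θ_ijk)^ζ
                          · exp(−η (r_ij² + r_ik² + r_jk²))
                          · f_c(r_ij) f_c(r_ik) f_c(r_jk)

with the cosine cutoff f_c(r) = ½(cos(π r/R_c)+1) for r < R_c, else 0.
One parameter list is shared across element pairs/triples, so every atom of a
given composition sees the same descriptor length.  Jacobians are returned in
a sparse per-neighbor layout (slot 0 = the center atom itself) which the
potential's force evaluation and trainer contract without densifying.

The hot loops are numba-compiled; the pure-path reference used in tests is a
separate brute-force implementation kept deliberately independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .system import Configuration, GhostMDError, minimum_image

__all__ = ["SymmetryFunctionSet", "cutoff_fn", "symmetry_vectors",
           "SparseJacobian"]


@dataclass
class SymmetryFunctionSet:
    """Frozen descriptor parameterization shared by all shipped models."""

    elements: tuple[str, ...] = ("H", "O")
    r_cut: float = 4.0            # radial cutoff R_c, Å
    r_cut_angular: float = 3.2    # angular cutoff (≤ r_cut), Å
    radial: tuple[tuple[float, float], ...] = (      # (η Å⁻², R_s Å)
        (8.0, 0.95), (8.0, 1.30), (4.0, 1.70),
        (4.0, 2.20), (4.0, 2.70), (3.0, 3.30),
    )
    angular: tuple[tuple[float, float, float], ...] = (   # (ζ, λ, η)
        (1.0, 1.0, 0.2), (1.0, -1.0, 0.2),
        (4.0, 1.0, 0.2), (4.0, -1.0, 0.2),
    )

    def __post_init__(self) -> None:
        if self.r_cut <= 0 or self.r_cut_angular <= 0:
            raise GhostMDError("cutoffs must be positive")
        if self.r_cut_angular > self.r_cut:
            raise GhostMDError("angular cutoff must not exceed radial cutoff")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_pairs(self) -> int:
        n = self.n_elements
        return n * (n + 1) // 2

    @property
    def n_descriptors(self) -> int:
        return self.n_elements * len(self.radial) + self.n_pairs * len(self.angular)

    def element_index(self, elems: np.ndarray) -> np.ndarray:
        lut = {e: i for i, e in enumerate(self.elements)}
        try:
            return np.array([lut[e] for e in elems], dtype=np.int64)
        except KeyError as exc:
            raise GhostMDError(f"element {exc} not covered by symmetry set")

    def to_dict(self) -> dict:
        return dict(elements=list(self.elements), r_cut=self.r_cut,
                    r_cut_angular=self.r_cut_angular,
                    radial=[list(p) for p in self.radial],
                    angular=[list(p) for p in self.angular])

    @classmethod
    def from_dict(cls, d: dict) -> "SymmetryFunctionSet":
        return cls(elements=tuple(d["elements"]), r_cut=d["r_cut"],
                   r_cut_angular=d["r_cut_angular"],
                   radial=tuple(tuple(p) for p in d["radial"]),
                   angular=tuple(tuple(p) for p in d["angular"]))


def cutoff_fn(r, r_cut: float):
    """Cosine cutoff ½(cos(π r/R_c)+1) for r < R_c, else 0 (scalar or array)."""
    if r_cut <= 0:
        raise GhostMDError("r_cut must be positive")
    r = np.asarray(r, dtype=float)
    out = np.where(r < r_cut, 0.5 * (np.cos(np.pi * r / r_cut) + 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SparseJacobian:
    """∂G_i,d/∂R_a in per-neighbor layout.

    values[i, s, d, :] is the derivative of descriptor d of atom i with
    respect to the position of ``atoms[i, s]``; slot 0 is atom i itself,
    slots 1..counts[i] are its neighbors.
    """

    atoms: np.ndarray     # (N, S) int
    values: np.ndarray    # (N, S, ndesc, 3)
    counts: np.ndarray    # (N,) valid slots per atom (including self)

    def to_dense(self) -> np.ndarray:
        """Return the full (N, ndesc, N, 3) array (test/debug use)."""
        N, S, nd, _ = self.values.shape
        dense = np.zeros((N, nd, N, 3))
        for i in range(N):
            for s in range(self.counts[i]):
                dense[i, :, self.atoms[i, s], :] += self.values[i, s]
        return dense


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_neighbors(pos, cell, rc):
    """O(N²) minimum-image neighbor list: idx, disp (pos[j]-pos[i]), dist, count."""
    N = pos.shape[0]
    nb_idx = np.full((N, N - 1), -1, dtype=np.int64)
    nb_disp = np.zeros((N, N - 1, 3))
    nb_dist = np.zeros((N, N - 1))
    nb_cnt = np.zeros(N, dtype=np.int64)
    for i in range(N):
        for j in range(N):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= cell[0] * round(dx / cell[0])
            dy -= cell[1] * round(dy / cell[1])
            dz -= cell[2] * round(dz / cell[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rc:
                s = nb_cnt[i]
                nb_idx[i, s] = j
                nb_disp[i, s, 0] = dx
                nb_disp[i, s, 1] = dy
                nb_disp[i, s, 2] = dz
                nb_dist[i, s] = r
                nb_cnt[i] = s + 1
    return nb_idx, nb_disp, nb_dist, nb_cnt


@njit(cache=True, inline="always")
def _fc(r, rc):
    if r < rc:
        return 0.5 * (np.cos(np.pi * r / rc) + 1.0)
    return 0.0


@njit(cache=True, inline="always")
def _fc_d(r, rc):
    if r < rc:
        return -0.5 * np.pi / rc * np.sin(np.pi * r / rc)
    return 0.0


@njit(cache=True)
def _symfunc_kernel(nb_idx, nb_disp, nb_dist, nb_cnt, elem_idx, n_elem,
                    rad_eta, rad_rs, ang_zeta, ang_lam, ang_eta,
                    rc, rc_ang, want_jac):
    """Descriptors and (optionally) sparse Jacobians for all atoms."""
    N = nb_idx.shape[0]
    n_rad = rad_eta.shape[0]
    n_ang = ang_zeta.shape[0]
    n_pair = n_elem * (n_elem + 1) // 2
    ndesc = n_elem * n_rad + n_pair * n_ang
    maxnb = 0
    for i in range(N):
        if nb_cnt[i] > maxnb:
            maxnb = nb_cnt[i]
    G = np.zeros((N, ndesc))
    if want_jac:
        J = np.zeros((N, maxnb + 1, ndesc, 3))
    else:
        J = np.zeros((1, 1, 1, 3))

    for i in range(N):
        cnt = nb_cnt[i]
        # radial
        for s in range(cnt):
            j = nb_idx[i, s]
            r = nb_dist[i, s]
            fc = _fc(r, rc)
            fcd = _fc_d(r, rc)
            base = elem_idx[j] * n_rad
            for p in range(n_rad):
                g = np.exp(-rad_eta[p] * (r - rad_rs[p]) ** 2)
                G[i, base + p] += g * fc
                if want_jac:
                    dgdr = (-2.0 * rad_eta[p] * (r - rad_rs[p]) * g * fc
                            + g * fcd)
                    for c in range(3):
                        u = nb_disp[i, s, c] / r       # d r/dR_j
                        J[i, s + 1, base + p, c] += dgdr * u
                        J[i, 0, base + p, c] -= dgdr * u
        # angular
        off0 = n_elem * n_rad
        for sj in range(cnt):
            rij = nb_dist[i, sj]
            if rij >= rc_ang:
                continue
            fij = _fc(rij, rc_ang)
            fij_d = _fc_d(rij, rc_ang)
            for sk in range(sj + 1, cnt):
                rik = nb_dist[i, sk]
                if rik >= rc_ang:
                    continue
                vx = nb_disp[i, sk, 0] - nb_disp[i, sj, 0]   # d_ik - d_ij
                vy = nb_disp[i, sk, 1] - nb_disp[i, sj, 1]
                vz = nb_disp[i, sk, 2] - nb_disp[i, sj, 2]
                rjk = np.sqrt(vx * vx + vy * vy + vz * vz)
                if rjk >= rc_ang or rjk < 1e-10:
                    continue
                fik = _fc(rik, rc_ang)
                fjk = _fc(rjk, rc_ang)
                fik_d = _fc_d(rik, rc_ang)
                fjk_d = _fc_d(rjk, rc_ang)
                dot = (nb_disp[i, sj, 0] * nb_disp[i, sk, 0] +
                       nb_disp[i, sj, 1] * nb_disp[i, sk, 1] +
                       nb_disp[i, sj, 2] * nb_disp[i, sk, 2])
                cth = dot / (rij * rik)
                r2sum = rij * rij + rik * rik + rjk * rjk
                ej = elem_idx[nb_idx[i, sj]]
                ek = elem_idx[nb_idx[i, sk]]
                lo = min(ej, ek)
                hi = max(ej, ek)
                q = (lo * (2 * n_elem - lo - 1)) // 2 + hi
                base = off0 + q * n_ang
                for a in range(n_ang):
                    zeta = ang_zeta[a]
                    lam = ang_lam[a]
                    eta = ang_eta[a]
                    one_l = 1.0 + lam * cth
                    if one_l <= 0.0:
                        continue
                    pref = 2.0 ** (1.0 - zeta)
                    Apow = one_l ** zeta
                    P = np.exp(-eta * r2sum)
                    Fc = fij * fik * fjk
                    t = pref * Apow * P * Fc
                    G[i, base + a] += t
                    if want_jac:
                        # common scalar pieces
                        dA = pref * zeta * lam * one_l ** (zeta - 1.0) * P * Fc
                        for c in range(3):
                            dij_c = nb_disp[i, sj, c]
                            dik_c = nb_disp[i, sk, c]
                            v_c = (vx, vy, vz)[c]
                            # dcosθ/dd_ij and /dd_ik
                            dc_dij = dik_c / (rij * rik) - cth * dij_c / (rij * rij)
                            dc_dik = dij_c / (rij * rik) - cth * dik_c / (rik * rik)
                            # dΣr²/dd_ij = 2 d_ij − 2 v ; /dd_ik = 2 d_ik + 2 v
                            ds_dij = 2.0 * dij_c - 2.0 * v_c
                            ds_dik = 2.0 * dik_c + 2.0 * v_c
                            # dFc/dd_ij and /dd_ik
                            dF_dij = (fij_d * dij_c / rij * fik * fjk
                                      - fij * fik * fjk_d * v_c / rjk)
                            dF_dik = (fik_d * dik_c / rik * fij * fjk
                                      + fij * fik * fjk_d * v_c / rjk)
                            g_j = (dA * dc_dij
                                   + pref * Apow * P * (-eta) * ds_dij * Fc
                                   + pref * Apow * P * dF_dij)
                            g_k = (dA * dc_dik
                                   + pref * Apow * P * (-eta) * ds_dik * Fc
                                   + pref * Apow * P * dF_dik)
                            J[i, sj + 1, base + a, c] += g_j
                            J[i, sk + 1, base + a, c] += g_k
                            J[i, 0, base + a, c] -= g_j + g_k
    return G, J


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def symmetry_vectors(config: Configuration, sfset: SymmetryFunctionSet,
                     want_jacobian: bool = False):
    """Per-atom descriptor matrix (N, ndesc) and optional sparse Jacobian."""
    if np.min(config.cell) < 2.0 * sfset.r_cut:
        raise GhostMDError("cell too small for descriptor cutoff (minimum image)")
    return _symmetry_raw(config.positions, config.cell,
                         sfset.element_index(config.elements), sfset,
                         want_jacobian)


def _symmetry_raw(positions, cell, elem_idx, sfset, want_jacobian):
    rad = np.array(sfset.radial, dtype=float)
    ang = np.array(sfset.angular, dtype=float)
    nb_idx, nb_disp, nb_dist, nb_cnt = _build_neighbors(
        np.ascontiguousarray(positions, dtype=np.float64),
        np.asarray(cell, float), sfset.r_cut)
    G, J = _symfunc_kernel(nb_idx, nb_disp, nb_dist, nb_cnt, elem_idx,
                           sfset.n_elements,
                           np.ascontiguousarray(rad[:, 0]),
                           np.ascontiguousarray(rad[:, 1]),
                           np.ascontiguousarray(ang[:, 0]),
                           np.ascontiguousarray(ang[:, 1]),
                           np.ascontiguousarray(ang[:, 2]),
                           sfset.r_cut, sfset.r_cut_angular, want_jacobian)
    if not want_jacobian:
        return G, None
    maxnb = J.shape[1] - 1
    atoms = np.empty((len(G), maxnb + 1), dtype=np.int64)
    atoms[:, 0] = np.arange(len(G))
    atoms[:, 1:] = nb_idx[:, :maxnb]
    counts = nb_cnt + 1
    return G, SparseJacobian(atoms=atoms, values=J, counts=counts)
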