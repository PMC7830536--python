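"""Diluted elastic lattice (Kantor-Webman) model and critical-exponent fits.

The network Hamiltonian combines bond stretching and bond bending,

    H = (alpha/2) sum_<ij> e_ij [(u_i - u_j) . r_ij]^2
      + (beta/2)  sum_<ijk> e_ij e_ik (dtheta_ijk)^2,

where e_ij are i.i.d. Bernoulli(p) bond occupations, u_i are infinitesimal
node displacements, r_ij unit bond vectors, and dtheta_ijk the linearized
change of the angle between bonds j-i and i-k (sum over all bond pairs
centred at i). The effective modulus of a diluted lattice under an affine
boundary strain vanishes when no occupied-bond cluster spans the strained
boundaries and grows as |p - p_c|^f above threshold, with an exponent f
that depends on the stretch/bend stiffness ratio (weak universality).

The default geometry is a 2D triangular lattice oriented so that boundary
columns are vertical (constant x): a component touching only one boundary
can then relax to a rigid translation, making the zero-modulus/no-spanning
equivalence exact. 3D (cubic with face diagonals) is supported at small
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import linregress

from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "LatticeNetwork",
    "ExponentEstimate",
    "build_lattice",
    "network_energy",
    "effective_modulus",
    "estimate_critical_exponent",
]

_SQ3_2 = np.sqrt(3.0) / 2.0


@dataclass
class LatticeNetwork:
    """Bond-diluted lattice with stretching (alpha) and bending (beta) stiffness."""

    dimension: int
    side_length: int
    node_positions: np.ndarray  # (N, dim)
    bonds: np.ndarray  # (M, 2) int node indices
    occupancy: np.ndarray  # (M,) bool, e_ij
    alpha: float
    beta: float
    p: float
    seed: int | None = None
    _forms: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise DomainError("dimension must be 2 or 3")
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise DomainError("alpha, beta must be >= 0 and not both zero")

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    def column_of(self, node: np.ndarray | int):
        """Column index along the strain axis (x) for a node id."""
        per_col = self.side_length ** (self.dimension - 1)
        return np.asarray(node) // per_col


def _triangular_geometry(side: int):
    """Triangular lattice with vertical columns: x = i*sqrt(3)/2, y = j + (i%2)/2."""
    cols = rows = side
    idx = lambda i, j: i * rows + j
    pos = np.empty((cols * rows, 2))
    for i in range(cols):
        for j in range(rows):
            pos[idx(i, j)] = (i * _SQ3_2, j + 0.5 * (i % 2))
    bonds = []
    for i in range(cols):
        for j in range(rows):
            if j + 1 < rows:  # vertical
                bonds.append((idx(i, j), idx(i, j + 1)))
            if i + 1 < cols:
                if i % 2 == 0:  # partners at y -/+ 0.5
                    bonds.append((idx(i, j), idx(i + 1, j)))
                    if j - 1 >= 0:
                        bonds.append((idx(i, j), idx(i + 1, j - 1)))
                else:
                    bonds.append((idx(i, j), idx(i + 1, j)))
                    if j + 1 < rows:
                        bonds.append((idx(i, j), idx(i + 1, j + 1)))
    return pos, np.asarray(bonds, dtype=np.int64)


def _cubic_fcc_geometry(side: int):
    """Simple cubic lattice with axis bonds plus face diagonals."""
    n = side
    idx = lambda i, j, k: (i * n + j) * n + k
    grid = np.indices((n, n, n)).reshape(3, -1).T.astype(float)
    offsets = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    ]
    bonds = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for di, dj, dk in offsets:
                    a, b, c = i + di, j + dj, k + dk
                    if 0 <= a < n and 0 <= b < n and 0 <= c < n:
                        bonds.append((idx(i, j, k), idx(a, b, c)))
    return grid, np.asarray(bonds, dtype=np.int64)


def build_lattice(
    dimension: int = 2,
    side_length: int = 12,
    p: float = 0.6,
    alpha: float = 1.0,
    beta: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> LatticeNetwork:
    """Build a bond-diluted lattice; each bond is present independently w.p. p."""
    if side_length < 3:
        raise DomainError("side length must be at least 3")
    if not 0.0 <= p <= 1.0:
        raise DomainError("p must lie in [0, 1]")
    if dimension == 2:
        pos, bonds = _triangular_geometry(side_length)
    elif dimension == 3:
        if side_length > 8:
            raise DomainError("3D lattices are limited to side length 8")
        pos, bonds = _cubic_fcc_geometry(side_length)
    else:
        raise DomainError("dimension must be 2 or 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupancy = rng.random(bonds.shape[0]) < p
    return LatticeNetwork(
        dimension=dimension,
        side_length=side_length,
        node_positions=pos,
        bonds=bonds,
        occupancy=occupancy,
        alpha=alpha,
        beta=beta,
        p=p,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def _linear_forms(net: LatticeNetwork):
    """Energy as H(u) = 1/2 sum_r w_r (g_r . u)^2; returns sparse G and weights w.

    Rows cover occupied stretch bonds (weight alpha) and occupied bond pairs
    at each centre node (weight beta). Bending rows are the linearized angle
    change: in 2D the difference of the scalar bond rotations; in 3D the
    exact first-order change of the inter-bond angle (with the collinear
    case handled by the transverse-difference norm, one row per component).
    """
    if net._forms is not None:
        return net._forms
    dim = net.dimension
    pos = net.node_positions
    rows_i, cols_j, vals, weights = [], [], [], []
    row = 0

    occ = net.bonds[net.occupancy]
    vecs = pos[occ[:, 1]] - pos[occ[:, 0]]
    lengths = np.linalg.norm(vecs, axis=1)
    units = vecs / lengths[:, None]

    if net.alpha > 0:
        for (a, b), r in zip(occ, units):
            for d in range(dim):
                rows_i += [row, row]
                cols_j += [b * dim + d, a * dim + d]
                vals += [r[d], -r[d]]
            weights.append(net.alpha)
            row += 1

    if net.beta > 0:
        # incident occupied bonds per node
        incident: dict[int, list[tuple[int, np.ndarray, float]]] = {}
        for (a, b), r, L in zip(occ, units, lengths):
            incident.setdefault(a, []).append((b, r, L))
            incident.setdefault(b, []).append((a, -r, L))

        def bond_rotation_coeffs(center, nbr, r, L):
            """Linear form(s) for the transverse rotation of bond center->nbr."""
            if dim == 2:
                # scalar rotation: cross(r, u_nbr - u_center)/L
                return [((nbr, 0, -r[1] / L), (nbr, 1, r[0] / L),
                         (center, 0, r[1] / L), (center, 1, -r[0] / L))]
            # 3D: vector rotation P_perp (u_nbr - u_center)/L, one form per axis
            P = (np.eye(3) - np.outer(r, r)) / L
            forms = []
            for d in range(3):
                forms.append(tuple(
                    (node, e, sgn * P[d, e])
                    for node, sgn in ((nbr, 1.0), (center, -1.0))
                    for e in range(3)
                ))
            return forms

        for center, nbrs in incident.items():
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    j, rj, Lj = nbrs[a]
                    k, rk, Lk = nbrs[b]
                    if dim == 2:
                        (fj,) = bond_rotation_coeffs(center, j, rj, Lj)
                        (fk,) = bond_rotation_coeffs(center, k, rk, Lk)
                        for node, d, v in fj:
                            rows_i.append(row); cols_j.append(node * dim + d); vals.append(v)
                        for node, d, v in fk:
                            rows_i.append(row); cols_j.append(node * dim + d); vals.append(-v)
                        weights.append(net.beta)
                        row += 1
                        continue
                    cos_t = float(np.dot(rj, rk))
                    fj_forms = bond_rotation_coeffs(center, j, rj, Lj)
                    fk_forms = bond_rotation_coeffs(center, k, rk, Lk)
                    if cos_t < -1.0 + 1e-9:
                        # collinear: |dtheta|^2 = |drhat_j + drhat_k|^2
                        for fj, fk in zip(fj_forms, fk_forms):
                            for node, d, v in fj:
                                rows_i.append(row); cols_j.append(node * dim + d); vals.append(v)
                            for node, d, v in fk:
                                rows_i.append(row); cols_j.append(node * dim + d); vals.append(v)
                            weights.append(net.beta)
                            row += 1
                    else:
                        # dtheta = -(rk . drhat_j + rj . drhat_k)/sin(theta)
                        sin_t = np.sqrt(max(1.0 - cos_t**2, 1e-18))
                        coeffs: dict[int, float] = {}
                        for d in range(3):
                            for node, e, v in fj_forms[d]:
                                coeffs[node * dim + e] = coeffs.get(node * dim + e, 0.0) - rk[d] * v / sin_t
                            for node, e, v in fk_forms[d]:
                                coeffs[node * dim + e] = coeffs.get(node * dim + e, 0.0) - rj[d] * v / sin_t
                        for col, v in coeffs.items():
                            rows_i.append(row); cols_j.append(col); vals.append(v)
                        weights.append(net.beta)
                        row += 1

    G = sparse.csr_matrix(
        (vals, (rows_i, cols_j)), shape=(row, net.n_nodes * dim)
    )
    w = np.asarray(weights)
    net._forms = (G, w)
    return net._forms


def network_energy(net: LatticeNetwork, displacements: np.ndarray) -> float:
    """Elastic energy of a displacement field; zero for rigid translations."""
    u = np.asarray(displacements, dtype=float)
    if u.shape != (net.n_nodes, net.dimension):
        raise DomainError(
            f"displacements must have shape {(net.n_nodes, net.dimension)}, got {u.shape}"
        )
    G, w = _linear_forms(net)
    y = G @ u.ravel()
    return float(0.5 * np.sum(w * y**2))


def _spans(net: LatticeNetwork) -> bool:
    """True if an occupied-bond cluster connects the two strained boundaries."""
    occ = net.bonds[net.occupancy]
    n = net.n_nodes
    if occ.size == 0:
        return False
    adj = sparse.coo_matrix(
        (np.ones(occ.shape[0]), (occ[:, 0], occ[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    cols = net.column_of(np.arange(n))
    left = set(labels[cols == 0])
    right = set(labels[cols == net.side_length - 1])
    return bool(left & right)


def effective_modulus(net: LatticeNetwork, applied_strain: float = 1e-3) -> float:
    """Effective elastic modulus under an affine x-strain of the boundary columns.

    Boundary nodes (first and last column along x) are pinned to the affine
    displacement u = (strain * x, 0, ...); interior displacements minimize
    the quadratic network energy. Returns 2 E_min / (strain^2 * volume) in
    lattice units; exactly 0 when no occupied cluster spans the boundaries.
    """
    if not 0 < applied_strain < 0.1:
        raise DomainError("applied strain must be small and positive")
    if not _spans(net):
        return 0.0
    dim = net.dimension
    n = net.n_nodes
    cols = net.column_of(np.arange(n))
    boundary = (cols == 0) | (cols == net.side_length - 1)

    x = net.node_positions[:, 0]
    u = np.zeros((n, dim))
    u[boundary, 0] = applied_strain * (x[boundary] - x.min())

    G, w = _linear_forms(net)
    K = (G.T.multiply(w) @ G).tocsr()
    dof_pinned = np.repeat(boundary, dim)
    free = ~dof_pinned
    u_flat = u.ravel()
    rhs = -K[free][:, dof_pinned] @ u_flat[dof_pinned]
    K_ff = K[free][:, free]
    if free.sum() > 0:
        if free.sum() <= 2500:
            sol, *_ = np.linalg.lstsq(K_ff.toarray(), rhs, rcond=None)
        else:
            sol = sparse.linalg.lsmr(K_ff, rhs, atol=1e-12, btol=1e-12)[0]
        if not np.all(np.isfinite(sol)):
            raise FitFailureError("energy minimization returned non-finite displacements")
        u_flat[free] = sol
    energy = network_energy(net, u_flat.reshape(n, dim))

    width = x.max() - x.min()
    cross = net.side_length ** (dim - 1)  # unit node spacing per transverse axis
    volume = width * cross
    return float(2.0 * energy / (applied_strain**2 * volume))


@dataclass(frozen=True)
class ExponentEstimate:
    """OLS estimate of the elasticity critical exponent f and its standard error."""

    exponent: float
    stderr: float
    log_amplitude: float
    n: int

    def confidence_interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.exponent - z * self.stderr, self.exponent + z * self.stderr)


def estimate_critical_exponent(samples, p_c: float) -> ExponentEstimate:
    """Fit E = A (p - p_c)^f by OLS of log E on log(p - p_c).

    ``samples`` is an iterable of (p, modulus) pairs with p > p_c and
    modulus > 0. Returns the slope (exponent) with its standard error.
    """
    pts = [(float(p), float(e)) for p, e in samples]
    if len(pts) < 3:
        raise InsufficientDataError("need at least 3 (p, modulus) points")
    p_arr = np.array([p for p, _ in pts])
    e_arr = np.array([e for _, e in pts])
    if np.any(p_arr <= p_c):
        raise DomainError("all p must exceed p_c for the log-log fit")
    if np.any(e_arr <= 0):
        raise DomainError("all moduli must be strictly positive")
    log_x = np.log(p_arr - p_c)
    log_y = np.log(e_arr)
    if np.allclose(log_y, log_y[0]):
        return ExponentEstimate(exponent=0.0, stderr=0.0, log_amplitude=float(log_y[0]), n=len(pts))
    res = linregress(log_x, log_y)
    return ExponentEstimate(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        log_amplitude=float(res.intercept),
        n=len(pts),
    )
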