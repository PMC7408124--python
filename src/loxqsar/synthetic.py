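"""Synthetic descriptor matrices, responses and toy geometries.

The generator emulates the shape of a small-molecule QSAR problem — a few
dozen compounds, tens to hundreds of inter-correlated descriptor columns,
and an activity driven by a sparse linear combination of a few of them plus
Gaussian noise — so that subset selection and every validation statistic can
be exercised with known ground truth and no chemistry. Descriptor marginals
are Gaussian (optionally Poisson for count-valued columns mimicking fragment
counts); real descriptor distributions are skewed and discrete, which the
generator does not attempt to reproduce.

Toy molecules cover the descriptor edge cases: diatomics at fixed
separation, linear chains, a planar hexagon (rank-2 geometry), a regular
tetrahedron, and flat aromatic rings with typed substituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compounds import Molecule3D

__all__ = [
    "SyntheticSpec",
    "gen_descriptors",
    "gen_response",
    "gen_toy_molecules",
    "diatomic",
    "planar_hexagon",
    "tetrahedral",
    "linear_chain",
    "flat_benzene",
    "flat_phenol",
]


@dataclass
class SyntheticSpec:
    """Ground-truth specification of one synthetic QSAR problem.

    ``correlation`` may be a scalar (equicorrelation across all columns), a
    full p x p correlation matrix, or None (independent columns).
    """

    n_compounds: int = 28
    n_descriptors: int = 53
    correlation: float | np.ndarray | None = 0.5
    true_subset: tuple[int, ...] = (5, 12, 21)
    true_coef: tuple[float, ...] = (3.0, -2.0, 1.0)
    intercept: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0
    count_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.true_subset) != len(self.true_coef):
            raise ValueError("true_subset and true_coef must have equal length")
        if any(not 0 <= j < self.n_descriptors for j in self.true_subset):
            raise ValueError("true_subset indices out of range")

    def correlation_matrix(self) -> np.ndarray:
        p = self.n_descriptors
        if self.correlation is None:
            return np.eye(p)
        if np.isscalar(self.correlation):
            C = np.full((p, p), float(self.correlation))
            np.fill_diagonal(C, 1.0)
        else:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (p, p):
                raise ValueError(f"correlation matrix must be {p}x{p}")
        lam = np.linalg.eigvalsh(C)
        if lam.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return C


def gen_descriptors(spec: SyntheticSpec) -> np.ndarray:
    """Multivariate-normal descriptor matrix with the requested correlation.

    Columns listed in ``spec.count_columns`` are replaced by Poisson counts
    (rate 1.5) that mimic integer fragment-count descriptors while keeping
    the seeded reproducibility.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.correlation_matrix()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(spec.n_descriptors))
    Z = rng.standard_normal((spec.n_compounds, spec.n_descriptors))
    X = Z @ L.T
    for j in spec.count_columns:
        X[:, j] = rng.poisson(1.5, size=spec.n_compounds).astype(float)
    return X


def gen_response(
    X: np.ndarray,
    spec: SyntheticSpec,
    rescale_to: tuple[float, float] | None = None,
) -> np.ndarray:
    """Sparse linear response with Gaussian noise.

    With ``rescale_to=(lo, hi)`` the response is affinely mapped onto that
    range (e.g. the 0.85-1.98 log-activity window of the coumarin set).
    """
    rng = np.random.default_rng(spec.seed + 1)
    y = spec.intercept + X[:, list(spec.true_subset)] @ np.asarray(spec.true_coef)
    y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    if rescale_to is not None:
        lo, hi = rescale_to
        span = y.max() - y.min()
        if span > 0:
            y = lo + (y - y.min()) * (hi - lo) / span
    return y


def _chain_bonds(n: int) -> list[tuple[int, int, float]]:
    return [(i, i + 1, 1.0) for i in range(n - 1)]


def diatomic(distance: float = 3.5, elements=("C", "C")) -> Molecule3D:
    """Two atoms at an exact separation (single-pair RDF/HATS cases)."""
    coords = [[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]
    return Molecule3D.from_graph(list(elements), coords, [(0, 1, 1.0)])


def linear_chain(n: int = 10, spacing: float = 1.54) -> Molecule3D:
    """n collinear carbons (rank-1 geometry, long topological diameter)."""
    coords = [[i * spacing, 0.0, 0.0] for i in range(n)]
    return Molecule3D.from_graph(["C"] * n, coords, _chain_bonds(n))


def planar_hexagon(side: float = 1.39) -> Molecule3D:
    """Six carbons on a flat hexagon: a rank-2 geometry."""
    ang = np.arange(6) * np.pi / 3
    r = side
    coords = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)])
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    return Molecule3D.from_graph(["C"] * 6, coords, bonds)


def tetrahedral(edge: float = 1.8) -> Molecule3D:
    """Four atoms at regular-tetrahedron vertices (equal leverages)."""
    a = edge / np.sqrt(2.0)
    coords = np.array(
        [[a, a, a], [a, -a, -a], [-a, a, -a], [-a, -a, a]]
    ) / 2.0
    bonds = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]
    return Molecule3D.from_graph(["C"] * 4, coords, bonds)


def _flat_ring(substituents: dict[int, str]) -> Molecule3D:
    """Planar benzene with optional single-atom substituents.

    Ring atoms 0-5 are aromatic carbons on a hexagon of side 1.39 A; each
    substituent atom sits 1.4 A radially outward from its ring carbon;
    remaining ring positions carry radial hydrogens at 1.09 A.
    """
    side = 1.39
    ring_r = side  # circumradius equals side for a regular hexagon
    ang = np.arange(6) * np.pi / 3
    elements = ["C"] * 6
    coords = [
        [ring_r * np.cos(a), ring_r * np.sin(a), 0.0] for a in ang
    ]
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    aromatic = [True] * 6
    for i, a in enumerate(ang):
        sym = substituents.get(i, "H")
        dist = 1.09 if sym == "H" else 1.40
        coords.append(
            [(ring_r + dist) * np.cos(a), (ring_r + dist) * np.sin(a), 0.0]
        )
        elements.append(sym)
        bonds.append((i, 6 + i, 1.0))
        aromatic.append(False)
    return Molecule3D.from_graph(elements, coords, bonds, aromatic)


def flat_benzene() -> Molecule3D:
    return _flat_ring({})


def flat_phenol() -> Molecule3D:
    """Benzene with one hydroxyl oxygen: exactly one R--CX--R carbon."""
    return _flat_ring({0: "O"})


def gen_toy_molecules() -> dict[str, Molecule3D]:
    """Deterministic fixture set covering the descriptor edge cases."""
    return {
        "diatomic_3p5": diatomic(3.5),
        "diatomic_1p0": diatomic(1.0),
        "chain10": linear_chain(10),
        "hexagon": planar_hexagon(),
        "tetrahedron": tetrahedral(),
        "benzene": flat_benzene(),
        "phenol": flat_phenol(),
        "chlorobenzene": _flat_ring({0: "Cl"}),
        "catechol": _flat_ring({0: "O", 1: "O"}),
        "toluene_like": _flat_ring({0: "C"}),
    }
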