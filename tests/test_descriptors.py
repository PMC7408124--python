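"""Fragment counts, RDF, influence matrix and HATS."""

import numpy as np
import pytest

from loxqsar.compounds import Molecule3D
from loxqsar.descriptors import (
    atom_centered_fragments,
    atomic_weights,
    count_C026,
    descriptor_matrix,
    hats,
    influence_matrix,
    rdf,
    rdf_grid_radii,
)
from loxqsar.synthetic import diatomic, linear_chain, planar_hexagon, tetrahedral


class TestWeights:
    def test_carbon_scaling_is_exact(self, toys):
        mol = toys["benzene"]
        for scheme in ("mass", "vdw_volume", "electronegativity", "polarizability"):
            w = atomic_weights(mol, scheme)
            assert np.allclose(w[:6], 1.0)  # ring carbons
            assert np.all(w > 0)

    def test_unit_scheme(self, toys):
        assert np.all(atomic_weights(toys["phenol"], "unit") == 1.0)

    def test_unknown_scheme(self, toys):
        with pytest.raises(ValueError, match="scheme"):
            atomic_weights(toys["benzene"], "charge")


class TestC026:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("benzene", 0),
            ("phenol", 1),
            ("chlorobenzene", 1),
            ("catechol", 2),
            ("toluene_like", 0),
        ],
    )
    def test_hand_typed_toys(self, toys, name, expected):
        assert count_C026(toys[name]) == expected

    def test_published_worked_examples(self, embedded):
        assert count_C026(embedded[7]) == 2
        assert count_C026(embedded[5]) == 1

    def test_fragment_totals_cover_all_carbons(self, embedded):
        mol = embedded[7]
        counts = atom_centered_fragments(mol)
        assert sum(counts.values()) == sum(el == "C" for el in mol.elements)
        assert counts["C-026"] == 2


def rotate(mol: Molecule3D, rng) -> Molecule3D:
    # random proper rotation + translation via QR of a Gaussian matrix
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    moved = Molecule3D(
        elements=list(mol.elements),
        coords=mol.coords @ Q.T + rng.uniform(-5, 5, 3),
        bonds=list(mol.bonds),
        aromatic_flags=mol.aromatic_flags.copy(),
        topo_dist=mol.topo_dist.copy(),
    )
    return moved


class TestRDF:
    def test_single_pair_at_exact_radius(self):
        mol = diatomic(3.5)
        assert rdf(mol, 3.5, weight="unit") == pytest.approx(1.0, abs=1e-12)

    def test_single_atom_is_zero(self):
        mol = Molecule3D.from_graph(["C"], [[0.0, 0.0, 0.0]], [])
        assert rdf(mol, 3.5) == 0.0

    def test_nonnegative_on_grid(self, embedded):
        for r in rdf_grid_radii():
            assert rdf(embedded[2], float(r)) >= 0.0

    def test_rigid_motion_invariance(self, embedded, rng):
        mol = embedded[15]
        ref = rdf(mol, 3.5)
        for _ in range(5):
            assert rdf(rotate(mol, rng), 3.5) == pytest.approx(ref, abs=1e-9)

    def test_gaussian_mass_conservation(self):
        # integrating unit-weight RDF over the grid approximates the number
        # of atom pairs when every distance lies inside the grid
        mol = linear_chain(5, spacing=1.5)  # distances 1.5 .. 6.0
        grid = np.arange(0.25, 12.0, 0.05)
        total = sum(rdf(mol, float(r), weight="unit") for r in grid) * 0.05
        n_pairs = 5 * 4 / 2
        expected = n_pairs * np.sqrt(np.pi / 100.0)  # Gaussian mass per pair
        assert total == pytest.approx(expected, rel=0.10)


class TestInfluenceMatrix:
    def test_three_dimensional_trace(self, embedded):
        assert influence_matrix(embedded[5]).sum() == pytest.approx(3.0, abs=1e-9)

    def test_planar_trace(self):
        assert influence_matrix(planar_hexagon()).sum() == pytest.approx(2.0, abs=1e-9)

    def test_linear_trace(self):
        assert influence_matrix(linear_chain(6)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_tetrahedron_symmetry(self):
        h = influence_matrix(tetrahedral())
        assert np.allclose(h, h[0])
        # direct matrix arithmetic cross-check
        mol = tetrahedral()
        M = mol.coords - mol.coords.mean(axis=0)
        H = M @ np.linalg.pinv(M.T @ M) @ M.T
        np.testing.assert_allclose(h, np.diag(H), atol=1e-12)

    def test_leverages_bounded(self, embedded):
        h = influence_matrix(embedded[7])
        assert np.all(h >= -1e-12) and np.all(h <= 1.0 + 1e-12)

    def test_coincident_atoms_error(self):
        mol = Molecule3D.from_graph(
            ["C", "C"], [[0, 0, 0], [0, 0, 0]], [(0, 1, 1.0)]
        )
        with pytest.raises(ValueError, match="degenerate"):
            influence_matrix(mol)


def hats_bruteforce(mol, lag, weight="polarizability"):
    h = influence_matrix(mol)
    w = atomic_weights(mol, weight)
    if lag == 0:
        return sum((h[i] * w[i]) ** 2 for i in range(mol.n_atoms))
    total = 0.0
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if mol.topo_dist[i, j] == lag:
                total += (h[i] * w[i]) * (h[j] * w[j])
    return total


class TestHATS:
    def test_matches_bruteforce_pair_sum(self, embedded):
        for no in (5, 15):
            for lag in range(9):
                assert hats(embedded[no], lag) == pytest.approx(
                    hats_bruteforce(embedded[no], lag), abs=1e-12
                )

    def test_lag_beyond_diameter_is_zero(self):
        mol = linear_chain(4)  # diameter 3
        assert hats(mol, 8, weight="unit") == 0.0

    def test_diatomic_closed_form(self):
        mol = diatomic(1.5)
        h = influence_matrix(mol)
        assert hats(mol, 1, weight="unit") == pytest.approx(h[0] * h[1], abs=1e-12)

    def test_lag_domain(self, toys):
        with pytest.raises(ValueError, match="lag"):
            hats(toys["benzene"], 9)
        with pytest.raises(ValueError, match="lag"):
            hats(toys["benzene"], -1)

    def test_rigid_motion_invariance(self, embedded, rng):
        mol = embedded[15]
        ref = hats(mol, 8)
        for _ in range(5):
            assert hats(rotate(mol, rng), 8) == pytest.approx(ref, abs=1e-9)


class TestDescriptorMatrix:
    def test_contract_on_subset(self, records):
        subset = [r for r in records if r.no in (2, 5, 7)]
        mat = descriptor_matrix(subset, seed=1)
        assert mat.shape[0] == 3
        assert not mat.isna().any().any()
        assert list(mat.index) == [2, 5, 7]
        assert "RDF035p" in mat.columns and "HATS8p" in mat.columns
        assert mat.columns.is_unique
        assert mat.loc[5, "C-026"] == 1 and mat.loc[7, "C-026"] == 2
        # matrix values agree with the single-descriptor entry points
        from loxqsar.compounds import embed_3d

        mol = embed_3d(subset[1].smiles, seed=1)
        assert mat.loc[5, "RDF035p"] == pytest.approx(rdf(mol, 3.5), abs=1e-12)
        assert mat.loc[5, "HATS8p"] == pytest.approx(hats(mol, 8), abs=1e-12)
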