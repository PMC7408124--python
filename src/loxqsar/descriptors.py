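"""3D and fragment molecular descriptors.

Three families, matching those selected in the published lipoxygenase model:

* **Atom-centred fragments** — Ghose–Crippen-style carbon typing; the key
  type is C-026 ("R--CX--R"): an aromatic carbon flanked by two aromatic
  carbons and bearing a heteroatom substituent.
* **Radial distribution function (RDF)** — ``RDF(r) = sum_{i<j} w_i w_j
  exp(-beta (r - r_ij)^2)``, the Gaussian-smoothed distribution of atom
  pairs over interatomic distance, evaluated on a grid of radii and for
  several atomic weighting schemes. ``RDF035p`` is the value at r = 3.5 A
  with polarizability weights.
* **GETAWAY HATS** — leverage autocorrelations built from the molecular
  influence matrix ``H = M (M^T M)^+ M^T`` of the centred coordinates;
  ``HATS_k(w) = sum over unordered pairs at topological distance k of
  (h_ii w_i)(h_jj w_j)``, with ``HATS_0(w) = sum_i (h_ii w_i)^2``.
  ``HATS8p`` is lag 8, polarizability-weighted.

Atomic weights follow the descriptor-software convention of scaling each
elemental property to carbon, so w(C) = 1 under every scheme. Hydrogens are
included throughout (configurable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compounds import CompoundRecord, Molecule3D, embed_3d

__all__ = [
    "ATOMIC_PROPERTIES",
    "WEIGHT_SCHEMES",
    "atomic_weights",
    "count_C026",
    "atom_centered_fragments",
    "rdf",
    "rdf_grid_radii",
    "influence_matrix",
    "hats",
    "descriptor_matrix",
]

# Elemental property tables (descriptor-software conventions):
# atomic mass (u), van der Waals volume (A^3), Sanderson electronegativity,
# atomic polarizability (A^3). Carbon is the scaling reference for each.
ATOMIC_PROPERTIES: dict[str, dict[str, float]] = {
    "mass": {
        "H": 1.01, "C": 12.01, "N": 14.01, "O": 16.00, "F": 19.00,
        "S": 32.07, "Cl": 35.45, "Br": 79.90, "I": 126.90,
    },
    "vdw_volume": {
        "H": 6.709, "C": 22.449, "N": 15.599, "O": 11.494, "F": 9.203,
        "S": 24.429, "Cl": 23.228, "Br": 31.954, "I": 44.839,
    },
    "electronegativity": {
        "H": 2.592, "C": 2.746, "N": 3.194, "O": 3.654, "F": 4.000,
        "S": 2.957, "Cl": 3.475, "Br": 3.219, "I": 2.778,
    },
    "polarizability": {
        "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
        "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
    },
}

#: Scheme name -> Dragon-style one-letter suffix used in column names.
WEIGHT_SCHEMES: dict[str, str] = {
    "unit": "u",
    "mass": "m",
    "vdw_volume": "v",
    "electronegativity": "e",
    "polarizability": "p",
}

HETEROATOMS = frozenset({"N", "O", "S", "F", "Cl", "Br", "I"})

#: Default Gaussian smoothing constant of the RDF, in A^-2.
DEFAULT_BETA = 100.0


def atomic_weights(
    mol: Molecule3D, scheme: str = "polarizability", carbon_scaled: bool = True
) -> np.ndarray:
    """Per-atom weights for one scheme, scaled to carbon unless disabled."""
    if scheme == "unit":
        return np.ones(mol.n_atoms)
    try:
        table = ATOMIC_PROPERTIES[scheme]
    except KeyError:
        raise ValueError(f"unknown weighting scheme: {scheme!r}") from None
    try:
        raw = np.array([table[el] for el in mol.elements])
    except KeyError as err:
        raise ValueError(f"no {scheme} value for element {err}") from None
    return raw / table["C"] if carbon_scaled else raw


def _aromatic_carbon_environment(mol: Molecule3D, i: int):
    """(n aromatic-C neighbours, substituent symbols) for aromatic carbon i."""
    flags = mol.aromatic_flags
    ring_c = 0
    subs = []
    for j in mol.neighbors(i):
        if flags[j] and mol.elements[j] == "C":
            ring_c += 1
        else:
            subs.append(mol.elements[j])
    return ring_c, subs


def count_C026(mol: Molecule3D) -> int:
    """Number of R--CX--R carbons.

    An aromatic carbon whose two ring neighbours are aromatic carbons and
    whose remaining substituent is a heteroatom. Ring-fusion carbons (three
    aromatic neighbours) never qualify.
    """
    count = 0
    for i, el in enumerate(mol.elements):
        if el != "C" or not mol.aromatic_flags[i]:
            continue
        ring_c, subs = _aromatic_carbon_environment(mol, i)
        if ring_c != 2:
            continue
        if any(s in HETEROATOMS for s in subs):
            count += 1
    return count


def atom_centered_fragments(mol: Molecule3D) -> dict[str, int]:
    """Carbon-centred fragment counts distinguishable on this chemistry.

    Aromatic carbons are typed by their substituent: H -> C-024 (R--CH--R),
    carbon or ring fusion -> C-025 (R--CR--R), heteroatom -> C-026
    (R--CX--R). Non-aromatic carbons fall into coarse classes: nitrile,
    carbonyl, sp3 by hydrogen count and heteroatom attachment, and a vinylic
    remainder (the scaffold C3=C4 carbons).
    """
    counts = {
        "C-024": 0, "C-025": 0, "C-026": 0,
        "C-sp3-CH3": 0, "C-sp3-CH2": 0, "C-sp3-CHn-X": 0,
        "C-carbonyl": 0, "C-nitrile": 0, "C-vinylic": 0,
    }
    for i, el in enumerate(mol.elements):
        if el != "C":
            continue
        nbrs = mol.neighbors(i)
        symbols = [mol.elements[j] for j in nbrs]
        if mol.aromatic_flags[i]:
            ring_c, subs = _aromatic_carbon_environment(mol, i)
            if ring_c >= 3:
                counts["C-025"] += 1
            elif any(s in HETEROATOMS for s in subs):
                counts["C-026"] += 1
            elif subs == ["H"]:
                counts["C-024"] += 1
            else:
                counts["C-025"] += 1
            continue
        orders = [o for a, b, o in mol.bonds if i in (a, b)]
        n_h = symbols.count("H")
        if any(o == 3.0 for o in orders) and "N" in symbols:
            counts["C-nitrile"] += 1
        elif any(
            o == 2.0 and mol.elements[b if a == i else a] == "O"
            for a, b, o in mol.bonds
            if i in (a, b)
        ):
            counts["C-carbonyl"] += 1
        elif all(o == 1.0 for o in orders):
            if n_h >= 3:
                counts["C-sp3-CH3"] += 1
            elif n_h == 2 and not any(s in HETEROATOMS for s in symbols):
                counts["C-sp3-CH2"] += 1
            else:
                counts["C-sp3-CHn-X"] += 1
        else:
            counts["C-vinylic"] += 1
    return counts


def rdf_grid_radii() -> np.ndarray:
    """The standard radius grid: 1.0, 1.5, ..., 15.5 A (30 points)."""
    return np.arange(1.0, 15.51, 0.5)


def rdf(
    mol: Molecule3D,
    radius: float,
    weight: str = "polarizability",
    beta: float = DEFAULT_BETA,
    carbon_scaled: bool = True,
) -> float:
    """Gaussian-smoothed radial distribution function at one radius."""
    if mol.n_atoms < 2:
        return 0.0
    w = atomic_weights(mol, weight, carbon_scaled)
    d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    iu = np.triu_indices(mol.n_atoms, 1)
    return float(np.sum(w[iu[0]] * w[iu[1]] * np.exp(-beta * (radius - d[iu]) ** 2)))


def influence_matrix(mol: Molecule3D) -> np.ndarray:
    """Diagonal of the molecular influence matrix (atomic leverages).

    ``H = M (M^T M)^+ M^T`` with M the row-centred coordinate matrix; the
    pseudo-inverse handles planar and linear geometries, for which the
    leverages sum to 2 and 1 instead of 3.
    """
    if mol.n_atoms < 2:
        raise ValueError("influence matrix needs at least 2 atoms")
    M = mol.coords - mol.coords.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.max() <= 0:
        raise ValueError("degenerate geometry: all atoms coincident")
    keep = s > 1e-9 * s.max()
    return np.sum(U[:, keep] ** 2, axis=1)


def hats(
    mol: Molecule3D,
    lag: int,
    weight: str = "polarizability",
    carbon_scaled: bool = True,
) -> float:
    """Leverage autocorrelation at one topological lag."""
    if not 0 <= lag <= 8:
        raise ValueError(f"HATS lag must be in 0..8, got {lag}")
    hw = influence_matrix(mol) * atomic_weights(mol, weight, carbon_scaled)
    if lag == 0:
        return float(np.sum(hw**2))
    iu = np.triu_indices(mol.n_atoms, 1)
    mask = mol.topo_dist[iu] == lag
    return float(np.sum(hw[iu[0]][mask] * hw[iu[1]][mask]))


def descriptor_matrix(
    compounds: list[CompoundRecord],
    seed: int = 17,
    beta: float = DEFAULT_BETA,
    carbon_scaled: bool = True,
) -> pd.DataFrame:
    """Full descriptor grid for a compound list.

    Columns: atom-centred fragment counts, the 30-radius RDF grid for all
    five weighting schemes (named RDF010u .. RDF155p), and HATS lags 0-8 for
    all five schemes (HATS0u .. HATS8p). Rows are indexed by compound number
    and ordered as given. Compounds without a structure are skipped.
    """
    radii = rdf_grid_radii()
    rows = []
    index = []
    for rec in compounds:
        if rec.smiles is None:
            continue
        try:
            mol = embed_3d(rec.smiles, seed=seed)
        except Exception as err:
            raise RuntimeError(
                f"descriptor computation failed for compound {rec.no} ({rec.mol_id})"
            ) from err
        row: dict[str, float] = {}
        row.update(atom_centered_fragments(mol))
        d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
        iu = np.triu_indices(mol.n_atoms, 1)
        dij = d[iu]
        for scheme, letter in WEIGHT_SCHEMES.items():
            w = atomic_weights(mol, scheme, carbon_scaled)
            ww = w[iu[0]] * w[iu[1]]
            for r in radii:
                row[f"RDF{int(round(r * 10)):03d}{letter}"] = float(
                    np.sum(ww * np.exp(-beta * (r - dij) ** 2))
                )
        hvals = influence_matrix(mol)
        for scheme, letter in WEIGHT_SCHEMES.items():
            hw = hvals * atomic_weights(mol, scheme, carbon_scaled)
            row[f"HATS0{letter}"] = float(np.sum(hw**2))
            for lag in range(1, 9):
                mask = mol.topo_dist[iu] == lag
                row[f"HATS{lag}{letter}"] = float(
                    np.sum(hw[iu[0]][mask] * hw[iu[1]][mask])
                )
        rows.append(row)
        index.append(rec.no)
    frame = pd.DataFrame(rows, index=pd.Index(index, name="no"))
    frame.attrs["weighting"] = {
        "carbon_scaled": carbon_scaled,
        "beta": beta,
        "seed": seed,
        "hydrogens": "included",
    }
    return frame
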