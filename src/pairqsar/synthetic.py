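"""Synthetic data: planted linear signals and a typed toy-molecule suite.

Two generators make the whole pipeline testable without downloads:

* :func:`make_planted` draws a Gaussian descriptor matrix with a known
  k-column linear signal and noise solved so the population R² hits a
  target — emulating the statistical regime of a small QSAR study
  (n ≈ 67–84 training compounds, k = 5 descriptors, R² ≈ 0.81–0.83).
* :func:`toy_molecule_suite` returns small drug-like molecules covering
  every atom type of the descriptor grammar, with golden descriptor
  values recomputed on demand by an independent brute-force oracle
  (networkx breadth-first search and explicit double loops — no shared
  code with the descriptor engine's distance matrix or counters).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .descriptors import TOKEN_FLAGS, parse_descriptor
from .molecule import MolecularGraph, compute_partial_charges, parse_molecule
from .validation import fit_ols


@dataclass
class PlantedDataset:
    X: np.ndarray
    y: np.ndarray
    planted: list  # column indices of the signal
    beta: np.ndarray
    intercept: float
    sigma: float
    seed: int
    achieved_r2: float  # OLS R² of y on the planted columns
    names: list = None


def make_planted(
    n: int = 67,
    p: int = 200,
    k: int = 5,
    target_r2: float = 0.83,
    seed: int = 0,
    intercept: float = 7.0,
    decoy_correlation: float | None = None,
    n_decoys: int = 0,
    beta_range: tuple | None = None,
) -> PlantedDataset:
    """Gaussian X with a planted k-column signal at a target population R².

    y = intercept + X[:, planted] @ beta + eps, with unit-magnitude
    coefficients of random sign (the standard planted-signal benchmark;
    pass ``beta_range=(lo, hi)`` for varied magnitudes ±U(lo, hi)) and
    sigma solved from Var(signal) = Σβ² (iid standard normal columns)
    so that Var(signal)/(Var(signal)+σ²) = target_r2.  The planted
    columns are redrawn until their pairwise |r| < 0.5, so the signal
    survives correlation pruning by construction.  With
    ``decoy_correlation`` set, ``n_decoys`` non-signal columns are made
    collinear (at that correlation) with planted ones to stress the GA.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    if n <= k + 2 or p < k:
        raise ValueError("need n > k + 2 and p >= k")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    planted = sorted(rng.choice(p, size=k, replace=False).tolist())

    # enforce mutual near-orthogonality of the signal columns
    for _ in range(100):
        sub = X[:, planted]
        r = np.corrcoef(sub, rowvar=False)
        if k == 1 or np.abs(r[np.triu_indices(k, 1)]).max() < 0.5:
            break
        X[:, planted] = rng.standard_normal((n, k))

    if decoy_correlation is not None and n_decoys > 0:
        rho = float(decoy_correlation)
        free = [j for j in range(p) if j not in planted]
        decoys = rng.choice(free, size=min(n_decoys, len(free)), replace=False)
        for d in decoys:
            src = planted[int(rng.integers(k))]
            X[:, d] = rho * X[:, src] + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    if beta_range is None:
        beta = rng.choice([-1.0, 1.0], size=k)
    else:
        beta = rng.uniform(*beta_range, size=k) * rng.choice([-1.0, 1.0], size=k)
    signal_var = float((beta**2).sum())
    sigma = float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))
    y = intercept + X[:, planted] @ beta + sigma * rng.standard_normal(n)

    achieved = fit_ols(X[:, planted], y).r2
    return PlantedDataset(
        X=X,
        y=y,
        planted=planted,
        beta=beta,
        intercept=intercept,
        sigma=sigma,
        seed=seed,
        achieved_r2=achieved,
        names=[f"d{j:04d}" for j in range(p)],
    )


# ---------------------------------------------------------------------------
# brute-force descriptor oracle (independent of the engine)


def _nx_graph(g: MolecularGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from(g.bonds)
    return G


def _atom_has(g: MolecularGraph, idx: int, token: str) -> bool:
    flag = TOKEN_FLAGS.get(token, token)
    info = g.atoms[idx]
    if flag in info.flags:
        return True
    return info.element == flag


def oracle_pair_count(g: MolecularGraph, center: str, target: str, n: int) -> int:
    """Ordered (center, target) pairs at exactly n bonds, by BFS."""
    G = _nx_graph(g)
    count = 0
    for a in range(g.n_atoms):
        if not _atom_has(g, a, center):
            continue
        lengths = nx.single_source_shortest_path_length(G, a)
        for b, d in lengths.items():
            if b != a and d == n and _atom_has(g, b, target):
                count += 1
    return count


def oracle_charge_sum(g: MolecularGraph, center: str, target: str, n: int) -> float:
    """Summed charge of target atoms within 1..n bonds of any center."""
    G = _nx_graph(g)
    contributing = set()
    for a in range(g.n_atoms):
        if not _atom_has(g, a, center):
            continue
        lengths = nx.single_source_shortest_path_length(G, a, cutoff=n)
        for b, d in lengths.items():
            if 1 <= d <= n and _atom_has(g, b, target):
                contributing.add(b)
    return float(sum(g.atoms[b].partial_charge for b in contributing))


def oracle_avg_molweight(g: MolecularGraph) -> float:
    masses = [a.GetMass() for a in g.rdmol.GetAtoms()]
    return float(sum(masses)) / len(masses)


def oracle_value(g: MolecularGraph, name: str) -> float:
    spec = parse_descriptor(name)
    if spec.family == "exact_pair_count":
        return oracle_pair_count(
            g, spec.center_type, spec.target_type, int(spec.distance)
        )
    if spec.family == "charge_sum_within":
        return oracle_charge_sum(
            g, spec.center_type, spec.target_type, int(spec.distance)
        )
    if spec.family == "global_property":
        return oracle_avg_molweight(g)
    raise ValueError(f"oracle does not cover {name!r}")


# ---------------------------------------------------------------------------
# toy molecules

#: SMILES covering every atom type the grammar uses: ring S (thiophene,
#: tetrahydrothiophene), amide N (acetamide, DMF, N-methylbenzamide),
#: donors (ethanol, morpholine, aniline), sp2 O (formaldehyde, esters),
#: non-ring O (ethers), halogens, and plain hydrocarbons.
TOY_SMILES = (
    "C",  # methane
    "OCC",  # ethanol
    "CC(N)=O",  # acetamide
    "c1ccsc1",  # thiophene
    "c1ccncc1",  # pyridine
    "c1ccccc1",  # benzene
    "NCCCCCC1CCCCC1",  # 6-cyclohexylhexan-1-amine backbone
    "C=O",  # formaldehyde
    "Cc1ccccc1",  # toluene
    "COC(C)=O",  # methyl acetate
    "C1CCSC1",  # tetrahydrothiophene
    "C1COCCN1",  # morpholine
    "Clc1ccccc1",  # chlorobenzene
    "CN(C)C=O",  # dimethylformamide
    "Nc1ccccc1",  # aniline
    "O=C(NC)c1ccccc1",  # N-methylbenzamide
)

#: descriptor names evaluated over the suite (the topological members
#: of the two published model equations)
TOY_DESCRIPTORS = (
    "fNringC6B",
    "fringCH3B",
    "fdonsp3C2B",
    "fsp3CamdN4B",
    "famdNnotringO9B",
    "lipo_ringS_8Bc",
    "avg_molweight",
)


def toy_molecule_suite(descriptors=TOY_DESCRIPTORS):
    """Parsed toy molecules with oracle-computed golden descriptor values.

    Returns a list of (smiles, MolecularGraph, {name: value}).  Golden
    values are always regenerated by the brute-force oracle, never
    hand-edited, so the suite doubles as the engine's reference data.
    """
    needs_charges = any(
        parse_descriptor(d).family == "charge_sum_within" for d in descriptors
    )
    out = []
    for smi in TOY_SMILES:
        g = parse_molecule(smi)
        if needs_charges:
            compute_partial_charges(g)
        golden = {name: oracle_value(g, name) for name in descriptors}
        out.append((smi, g, golden))
    return out


def toy_activity_table(seed: int = 0):
    """Toy activity records over the suite, log-uniform EC50 in 0.3–90000 nM."""
    from .dataset import ActivityRecord

    rng = np.random.default_rng(seed)
    ec50 = 10.0 ** rng.uniform(np.log10(0.3), np.log10(9e4), size=len(TOY_SMILES))
    return [
        ActivityRecord(compound_id=f"toy{i + 1:02d}", smiles=smi, ec50=float(e))
        for i, (smi, e) in enumerate(zip(TOY_SMILES, ec50))
    ]
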