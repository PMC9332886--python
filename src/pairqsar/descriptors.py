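"""Distance-constrained pharmacophore-pair descriptors.

The descriptor grammar covers four families:

``f<center><target><n>B``
    frequency of ordered (center, target) atom pairs exactly ``n`` bonds
    apart, e.g. ``fNringC6B`` = ring carbons exactly 6 bonds from a
    nitrogen, ``fringCH3B`` = hydrogens exactly 3 bonds from a ring
    carbon.
``<class>_<center>_<n>Bc``
    sum of partial charges of a class of atoms lying within 1..n bonds
    of any center atom, e.g. ``lipo_ringS_8Bc`` = summed charges of
    lipophilic atoms within 8 bonds of a ring sulfur.
``com_<target>_<n>A``
    number of target atoms within ``n`` Å (Euclidean) of the molecular
    center of mass, e.g. ``com_sp2O_4A``.
``avg_molweight``
    molecular weight divided by the total (explicit-hydrogen) atom
    count.

Counting is over ordered (center, target) pairs so that a target seen
from several centers contributes once per center — the "frequency of
occurrence" convention.  "within n bonds" means shortest-path distance
in 1..n, excluding the center atom itself.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDescriptorError, NoGeometryError
from .molecule import (
    MolecularGraph,
    atomic_masses,
    compute_partial_charges,
    embed_3d,
)

ENGINE_VERSION = "1.0"

#: grammar token -> flag understood by MolecularGraph.flag_mask
TOKEN_FLAGS = {
    "ringC": "ring_C",
    "ringS": "ring_S",
    "notringO": "nonring_O",
    "don": "donor",
    "amdN": "amide_N",
    "sp3C": "sp3_C",
    "sp2O": "sp2_O",
    "lipo": "lipophilic",
    "H": "H",
    "C": "C",
    "N": "N",
    "O": "O",
    "S": "S",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
}

# longest tokens first so greedy center/target splitting is unambiguous
_TOKENS_BY_LENGTH = sorted(TOKEN_FLAGS, key=len, reverse=True)


@dataclass(frozen=True)
class DescriptorSpec:
    """A parsed descriptor definition.

    ``family`` is one of ``exact_pair_count``, ``charge_sum_within``,
    ``geometric_count``, ``global_property``.  ``distance`` is in bonds
    for the topological families and in Å for the geometric one.
    """

    name: str
    family: str
    center_type: str | None = None
    target_type: str | None = None
    distance: float | None = None
    mode: str = "exact"  # "exact" | "within"


def _split_pair_tokens(body: str) -> tuple[str, str]:
    for tok in _TOKENS_BY_LENGTH:
        if body.startswith(tok) and body[len(tok):] in TOKEN_FLAGS:
            return tok, body[len(tok):]
    raise InvalidDescriptorError(f"cannot split pair tokens in {body!r}")


def parse_descriptor(name: str) -> DescriptorSpec:
    """Parse a descriptor name; unknown names fail loudly."""
    if name == "avg_molweight":
        return DescriptorSpec(name=name, family="global_property")

    m = re.fullmatch(r"([A-Za-z0-9]+)_([A-Za-z0-9]+)_(\d+)Bc", name)
    if m:
        target, center, n = m.group(1), m.group(2), int(m.group(3))
        if target not in TOKEN_FLAGS or center not in TOKEN_FLAGS:
            raise InvalidDescriptorError(f"unknown atom token in {name!r}")
        if n < 1:
            raise InvalidDescriptorError(f"distance must be >= 1 in {name!r}")
        return DescriptorSpec(
            name=name,
            family="charge_sum_within",
            center_type=center,
            target_type=target,
            distance=n,
            mode="within",
        )

    m = re.fullmatch(r"com_([A-Za-z0-9]+)_(\d+)A", name)
    if m:
        target, r = m.group(1), int(m.group(2))
        if target not in TOKEN_FLAGS:
            raise InvalidDescriptorError(f"unknown atom token in {name!r}")
        return DescriptorSpec(
            name=name,
            family="geometric_count",
            target_type=target,
            distance=r,
            mode="within",
        )

    m = re.fullmatch(r"f([A-Za-z0-9]+?)(\d+)B", name)
    if m:
        body, n = m.group(1), int(m.group(2))
        if n < 1:
            raise InvalidDescriptorError(f"distance must be >= 1 in {name!r}")
        center, target = _split_pair_tokens(body)
        return DescriptorSpec(
            name=name,
            family="exact_pair_count",
            center_type=center,
            target_type=target,
            distance=n,
            mode="exact",
        )

    raise InvalidDescriptorError(f"unknown descriptor name {name!r}")


def make_name(spec: DescriptorSpec) -> str:
    """Canonical name for a spec (inverse of :func:`parse_descriptor`)."""
    if spec.family == "global_property":
        return "avg_molweight"
    if spec.family == "exact_pair_count":
        return f"f{spec.center_type}{spec.target_type}{int(spec.distance)}B"
    if spec.family == "charge_sum_within":
        return f"{spec.target_type}_{spec.center_type}_{int(spec.distance)}Bc"
    if spec.family == "geometric_count":
        return f"com_{spec.target_type}_{int(spec.distance)}A"
    raise InvalidDescriptorError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# evaluators


def count_exact_pairs(
    g: MolecularGraph, center: str, target: str, n: int
) -> int:
    """|{(a, b): a is center-typed, b is target-typed, dist(a,b) = n}|."""
    if n <= 0:
        raise InvalidDescriptorError("pair distance must be a positive bond count")
    cmask = g.flag_mask(TOKEN_FLAGS.get(center, center))
    tmask = g.flag_mask(TOKEN_FLAGS.get(target, target))
    if not cmask.any() or not tmask.any():
        return 0
    sub = g.dist[np.ix_(cmask, tmask)]
    return int((sub == n).sum())


def sum_charges_within(
    g: MolecularGraph, center: str, target_class: str, n: int
) -> float:
    """Summed partial charge of target-class atoms within 1..n bonds of
    any center atom; each contributing atom is counted once."""
    if n <= 0:
        raise InvalidDescriptorError("bond radius must be positive")
    cmask = g.flag_mask(TOKEN_FLAGS.get(center, center))
    if not cmask.any():
        return 0.0
    tmask = g.flag_mask(TOKEN_FLAGS.get(target_class, target_class))
    d = g.dist[cmask]
    within = ((d >= 1) & (d <= n)).any(axis=0)
    return float(g.charges[tmask & within].sum())


def geometric_count(g: MolecularGraph, target: str, r: float) -> int:
    """Number of target atoms within r Å of the molecular center of mass."""
    if g.coords3d is None:
        raise NoGeometryError(
            f"no 3D coordinates on {g.smiles!r}; embed or load an SDF first"
        )
    masses = atomic_masses(g)
    com = (masses[:, None] * g.coords3d).sum(axis=0) / masses.sum()
    tmask = g.flag_mask(TOKEN_FLAGS.get(target, target))
    dists = np.linalg.norm(g.coords3d[tmask] - com, axis=1)
    return int((dists <= r).sum())


def avg_molweight(g: MolecularGraph) -> float:
    """Molecular weight per atom over the explicit-hydrogen graph."""
    return g.molweight / g.n_atoms


def evaluate(g: MolecularGraph, spec: DescriptorSpec) -> float:
    if spec.family == "exact_pair_count":
        return count_exact_pairs(
            g, spec.center_type, spec.target_type, int(spec.distance)
        )
    if spec.family == "charge_sum_within":
        return sum_charges_within(
            g, spec.center_type, spec.target_type, int(spec.distance)
        )
    if spec.family == "geometric_count":
        return geometric_count(g, spec.target_type, spec.distance)
    if spec.family == "global_property":
        return avg_molweight(g)
    raise InvalidDescriptorError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# the matrix


@dataclass
class DescriptorMatrix:
    compound_ids: list
    descriptor_names: list
    values: np.ndarray  # (n_compounds, n_descriptors)
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )


def _provenance() -> str:
    table_hash = hashlib.sha1(
        repr(sorted(TOKEN_FLAGS.items())).encode()
    ).hexdigest()[:12]
    return f"pairqsar-descriptors/{ENGINE_VERSION}+{table_hash}"


def compute_matrix(
    mols: list,
    specs: list,
    compound_ids: list | None = None,
    charge_iters: int = 8,
    embed_seed: int = 42,
) -> DescriptorMatrix:
    """Evaluate every spec on every molecule.

    Charges and 3D coordinates are computed lazily, only if some spec
    needs them.  Any per-molecule failure aborts with the molecule id
    and the offending descriptor name in the error message.
    """
    specs = [parse_descriptor(s) if isinstance(s, str) else s for s in specs]
    if compound_ids is None:
        compound_ids = [g.smiles or str(i) for i, g in enumerate(mols)]
    needs_charges = any(s.family == "charge_sum_within" for s in specs)
    needs_geometry = any(s.family == "geometric_count" for s in specs)

    values = np.zeros((len(mols), len(specs)), dtype=float)
    for i, g in enumerate(mols):
        try:
            if needs_charges:
                compute_partial_charges(g, n_iter=charge_iters)
            if needs_geometry:
                embed_3d(g, seed=embed_seed)
        except Exception as exc:
            raise type(exc)(
                f"compound {compound_ids[i]!r}: {exc}"
            ) from exc
        for j, spec in enumerate(specs):
            try:
                values[i, j] = evaluate(g, spec)
            except Exception as exc:
                raise type(exc)(
                    f"compound {compound_ids[i]!r}, descriptor {spec.name!r}: {exc}"
                ) from exc
    return DescriptorMatrix(
        compound_ids=list(compound_ids),
        descriptor_names=[s.name for s in specs],
        values=values,
        provenance=_provenance(),
    )


def default_pool(
    max_bonds: int = 9,
    charge_radii: tuple = (2, 4, 6, 8),
    geometric_radii: tuple = (4,),
    include_geometric: bool = True,
) -> list:
    """Combinatorial descriptor pool over the typed-atom grammar.

    Pair counts run over ordered (center, target) token pairs and
    distances 1..max_bonds; charge sums take the lipophilic class around
    every center token; geometric counts use the center-of-mass ball.
    Individual halogen tokens are parseable but folded into the
    lipophilic class for the grid, which keeps the pool at the
    ~1500-descriptor scale typical of a contracted topological pool.
    """
    tokens = [t for t in TOKEN_FLAGS if t not in ("F", "Cl", "Br", "I")]
    specs = [parse_descriptor("avg_molweight")]
    for c, t in itertools.product(tokens, tokens):
        for n in range(1, max_bonds + 1):
            specs.append(
                DescriptorSpec(
                    name=f"f{c}{t}{n}B",
                    family="exact_pair_count",
                    center_type=c,
                    target_type=t,
                    distance=n,
                )
            )
    for c in tokens:
        for n in charge_radii:
            specs.append(
                DescriptorSpec(
                    name=f"lipo_{c}_{n}Bc",
                    family="charge_sum_within",
                    center_type=c,
                    target_type="lipo",
                    distance=n,
                    mode="within",
                )
            )
    if include_geometric:
        for t in tokens:
            for r in geometric_radii:
                specs.append(
                    DescriptorSpec(
                        name=f"com_{t}_{r}A",
                        family="geometric_count",
                        target_type=t,
                        distance=r,
                        mode="within",
                    )
                )
    return specs


# ---------------------------------------------------------------------------
# IO


def write_matrix(matrix: DescriptorMatrix, path) -> None:
    """TSV with header of descriptor names; first column compound_id."""
    df = matrix.to_frame()
    df.index.name = "compound_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path) -> DescriptorMatrix:
    df = pd.read_csv(path, sep="\t", index_col="compound_id")
    return DescriptorMatrix(
        compound_ids=list(df.index),
        descriptor_names=list(df.columns),
        values=df.to_numpy(dtype=float),
        provenance=_provenance(),
    )


def read_spec_list(path) -> list:
    """Plain-text descriptor list, one name per line."""
    with open(path) as fh:
        return [
            parse_descriptor(line.strip())
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
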