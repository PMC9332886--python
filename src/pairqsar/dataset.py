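"""Activity-table curation, pEC50 transform, and train/test splitting.

The modelling table is a list of :class:`ActivityRecord`.  Curation
flags structural duplicates (same canonical structure as an earlier
kept record), multi-component inputs (salts/mixtures) and imprecise
activities (qualifier other than '='); everything else is kept.  EC50
values are converted to molar and transformed to pEC50 = −log10 EC50(M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import CurationError

_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6, "µM": 1e-6, "M": 1.0}


@dataclass
class ActivityRecord:
    compound_id: str
    smiles: str
    ec50: float | None = None  # in the stated unit (nM by default)
    pec50: float | None = None
    qualifier: str = "="  # one of =, >, <, ~, none
    curation_flags: set = field(default_factory=set)
    subset: str = "unassigned"  # train | test | unassigned

    @property
    def kept(self) -> bool:
        return "kept" in self.curation_flags


def to_pec50(ec50: float, unit: str = "nM") -> float:
    """pEC50 = −log10 of the molar EC50.

    Values in nM (or µM) are converted to molar first, so 1 M gives 0.0
    and more potent (smaller) EC50s give larger pEC50s.
    """
    if unit not in _UNIT_TO_MOLAR:
        raise CurationError(f"unknown activity unit {unit!r}")
    if not np.isfinite(ec50) or ec50 <= 0:
        raise CurationError(f"EC50 must be positive and finite, got {ec50!r}")
    return -math.log10(ec50 * _UNIT_TO_MOLAR[unit])


def from_pec50(pec50: float, unit: str = "nM") -> float:
    """Inverse transform: EC50 in the requested unit."""
    return 10.0 ** (-pec50) / _UNIT_TO_MOLAR[unit]


def structure_key(smiles: str) -> str | None:
    """Canonical structure key for duplicate detection (stereo ignored)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def curate(records: list, unit: str = "nM") -> list:
    """Assign curation flags in place and fill missing pEC50s.

    Rules, applied in input order:

    * unparsable SMILES -> flagged ``unparsable`` (never fatal);
    * disconnected SMILES (salts/mixtures) -> ``multi_component``;
    * qualifier other than '=' -> ``imprecise``;
    * same canonical structure as an earlier *kept* record ->
      ``duplicate`` (the first occurrence is kept);
    * everything else -> ``kept``, with pEC50 computed from EC50 when
      absent.  Stored pEC50s are kept as given, never reconciled.
    """
    seen: dict = {}
    for rec in records:
        flags = set()
        key = structure_key(rec.smiles)
        if key is None:
            flags.add("unparsable")
        elif "." in rec.smiles or len(Chem.GetMolFrags(Chem.MolFromSmiles(rec.smiles))) > 1:
            flags.add("multi_component")
        if rec.qualifier not in ("=",):
            flags.add("imprecise")
        if rec.ec50 is None and rec.pec50 is None:
            flags.add("no_activity")
        if not flags and key in seen:
            flags.add("duplicate")
        if not flags:
            flags.add("kept")
            seen[key] = rec.compound_id
            if rec.pec50 is None:
                rec.pec50 = to_pec50(rec.ec50, unit)
        rec.curation_flags = flags
    return records


def curation_report(records: list) -> dict:
    """Counts per curation flag plus totals."""
    counts: dict = {}
    for rec in records:
        for f in rec.curation_flags:
            counts[f] = counts.get(f, 0) + 1
    counts["total"] = len(records)
    return counts


def split_dataset(n_kept: int, fraction: float = 0.8, seed: int = 0):
    """Random train/test index split: train size = floor(fraction × n).

    Returns (train_idx, test_idx) as sorted integer arrays, disjoint and
    exhaustive; identical for identical seeds.
    """
    if not 0 < fraction < 1:
        raise CurationError("split fraction must be in (0, 1)")
    if n_kept < 5:
        raise CurationError(
            f"need at least 5 records to split (got {n_kept}); "
            "cross-validation is undefined below that"
        )
    n_train = int(math.floor(fraction * n_kept))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_kept)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return train, test


def assign_split(records: list, fraction: float = 0.8, seed: int = 0) -> list:
    """Assign kept records to train/test subsets using :func:`split_dataset`."""
    kept = [r for r in records if r.kept]
    train, test = split_dataset(len(kept), fraction, seed)
    test_set = set(test.tolist())
    for i, rec in enumerate(kept):
        rec.subset = "test" if i in test_set else "train"
    return records


# ---------------------------------------------------------------------------
# IO


def read_activity_csv(path, unit: str = "nM") -> list:
    """CSV with columns compound_id, smiles, ec50_nM and/or pec50,
    optional qualifier."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise CurationError("activity CSV needs a 'smiles' column")
    ec_col = next(
        (cols[c] for c in ("ec50_nm", "ec50", "ic50_nm") if c in cols), None
    )
    records = []
    for i, row in df.iterrows():
        cid = str(row[cols["compound_id"]]) if "compound_id" in cols else str(i)
        ec50 = float(row[ec_col]) if ec_col and pd.notna(row[ec_col]) else None
        pec50 = (
            float(row[cols["pec50"]])
            if "pec50" in cols and pd.notna(row[cols["pec50"]])
            else None
        )
        qual = (
            str(row[cols["qualifier"]])
            if "qualifier" in cols and pd.notna(row[cols["qualifier"]])
            else "="
        )
        records.append(
            ActivityRecord(
                compound_id=cid,
                smiles=str(row[cols["smiles"]]),
                ec50=ec50,
                pec50=pec50,
                qualifier=qual,
            )
        )
    return records


def write_curated_csv(records: list, path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "ec50_nM": r.ec50,
            "pec50": r.pec50,
            "qualifier": r.qualifier,
            "flags": ";".join(sorted(r.curation_flags)),
            "subset": r.subset,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
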