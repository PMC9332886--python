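"""End-to-end run: curate → descriptors → OFS → split → GA-MLR → validate.

Every run is driven by a :class:`RunConfig`, fully serialized into the
output directory together with every seed, threshold and removal
decision, so a run can be replayed byte-for-byte.  Stage outputs are
pure functions of (inputs, config, seed); partial outputs are retained
when a later stage fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import descriptors as de
from . import selection as fs
from . import validation as mv
from .errors import StageError
from .molecule import parse_molecule


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; replayable by construction."""

    input_csv: str = ""
    activity_unit: str = "nM"
    split_fraction: float = 0.8
    split_seed: int = 0
    near_constant_fraction: float = 0.95
    corr_threshold: float = 0.90
    max_bonds: int = 9
    include_geometric: bool = True
    k_max: int = 8
    breaking_epsilon: float = 0.02
    ga_population: int = 50
    ga_generations: int = 150
    ga_crossover: float = 0.9
    ga_mutation: float = 0.2
    ga_elitism: int = 2
    ga_seed: int = 0
    lmo_fraction: float = 0.3
    lmo_iters: int = 1000
    yrand_iters: int = 2000
    quik_delta: float = 0.05
    resid_cutoff: float = 3.0
    output_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: dict) -> dict:
    """Flatten a validation report into JSON-serializable structure."""
    model = report["model"]
    out = {
        "equation": model.equation(),
        "coefficients": dict(
            zip(model.descriptor_names, model.coefficients.tolist())
        ),
        "standard_errors": dict(
            zip(model.descriptor_names, model.coefficient_se.tolist())
        ),
        "intercept": model.intercept,
        "intercept_se": model.intercept_se,
        "fit": {
            "r2": model.r2,
            "r2_adj": model.r2_adj,
            "f": model.f_stat,
            "rmse_tr": model.rmse_tr,
            "mae_tr": model.mae_tr,
            "rss_tr": model.rss_tr,
            "ccc_tr": model.ccc_tr,
            "s": model.s,
            "n_train": model.n_train,
        },
        "internal": _jsonable(report["internal"]),
        "quik": _jsonable(report["quik"]),
    }
    rand = dict(report["randomization"])
    rand.pop("r2", None)
    rand.pop("q2", None)
    out["randomization"] = _jsonable(rand)
    if "external" in report:
        out["external"] = _jsonable(report["external"])
    return out


def run_pipeline(cfg: RunConfig, records=None, matrix=None, y=None) -> Path:
    """Run the full workflow and write all artifacts to the output dir.

    ``records`` may carry pre-built ActivityRecords (bypassing the input
    CSV); ``matrix`` may inject a pre-computed DescriptorMatrix at the
    OFS stage (used to run the statistical stages on synthetic pools),
    in which case a ``y`` response vector stands in for curated pEC50s
    when no records are given.  Returns the output directory path.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_resolved.yaml")

    # -- curation ----------------------------------------------------------
    try:
        if records is None and matrix is not None and y is not None:
            # synthetic injection: the matrix rows are the compounds
            records = [
                ds.ActivityRecord(
                    compound_id=str(cid),
                    smiles="",
                    pec50=float(val),
                    curation_flags={"kept"},
                )
                for cid, val in zip(matrix.compound_ids, y)
            ]
            kept = records
        else:
            if records is None:
                records = ds.read_activity_csv(
                    cfg.input_csv, unit=cfg.activity_unit
                )
            records = ds.curate(records, unit=cfg.activity_unit)
            kept = [r for r in records if r.kept]
        with open(out / "curation_report.json", "w") as fh:
            json.dump(ds.curation_report(records), fh, indent=2)
    except Exception as exc:
        raise StageError("curate", exc) from exc

    # -- descriptors -------------------------------------------------------
    try:
        if matrix is None:
            mols = [parse_molecule(r.smiles) for r in kept]
            pool = de.default_pool(
                max_bonds=cfg.max_bonds,
                include_geometric=cfg.include_geometric,
            )
            matrix = de.compute_matrix(
                mols, pool, compound_ids=[r.compound_id for r in kept]
            )
        de.write_matrix(matrix, out / "descriptor_matrix.tsv")
    except Exception as exc:
        raise StageError("descriptors", exc) from exc

    y_all = np.array([r.pec50 for r in kept], dtype=float)

    # -- OFS ---------------------------------------------------------------
    try:
        X_red, names_red, ofs = fs.objective_feature_selection(
            matrix.values,
            matrix.descriptor_names,
            near_constant_fraction=cfg.near_constant_fraction,
            corr_threshold=cfg.corr_threshold,
        )
        pd.DataFrame(ofs.removal_log).to_csv(out / "ofs_removals.csv", index=False)
    except Exception as exc:
        raise StageError("ofs", exc) from exc

    # -- split -------------------------------------------------------------
    try:
        train_idx, test_idx = ds.split_dataset(
            len(kept), cfg.split_fraction, cfg.split_seed
        )
        for pos in train_idx:
            kept[pos].subset = "train"
        for pos in test_idx:
            kept[pos].subset = "test"
        ds.write_curated_csv(records, out / "curated_dataset.csv")
    except Exception as exc:
        raise StageError("split", exc) from exc

    Xtr, ytr = X_red[train_idx], y_all[train_idx]
    Xte, yte = X_red[test_idx], y_all[test_idx]

    # -- GA-MLR ------------------------------------------------------------
    try:
        base = fs.GAConfig(
            population_size=cfg.ga_population,
            n_generations=cfg.ga_generations,
            crossover_rate=cfg.ga_crossover,
            mutation_rate=cfg.ga_mutation,
            elitism=cfg.ga_elitism,
            seed=cfg.ga_seed,
        )
        chosen_k, warning, per_k, curve = fs.select_model_size(
            Xtr, ytr, k_max=cfg.k_max, epsilon=cfg.breaking_epsilon, cfg=base
        )
        pd.DataFrame(curve).to_csv(out / "breaking_point_curve.csv", index=False)
        ga_log = [
            {"k": k, "generation": g, "best": b, "mean": m}
            for k, res in per_k.items()
            for g, (b, m) in enumerate(res.history)
        ]
        pd.DataFrame(ga_log).to_csv(out / "ga_log.csv", index=False)
        best = per_k[chosen_k]
        subset_names = [names_red[j] for j in best.subset]
        with open(out / "selection.json", "w") as fh:
            json.dump(
                {
                    "chosen_k": chosen_k,
                    "plateau_warning": warning,
                    "subset": subset_names,
                    "fitness_q2_loo": best.fitness,
                    "ga_config": dataclasses.asdict(best.config),
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        raise StageError("ga_select", exc) from exc

    # -- validation --------------------------------------------------------
    try:
        report = mv.validate_model(
            Xtr[:, best.subset],
            ytr,
            Xte[:, best.subset] if len(test_idx) else None,
            yte if len(test_idx) else None,
            descriptor_names=subset_names,
            lmo_fraction=cfg.lmo_fraction,
            lmo_iters=cfg.lmo_iters,
            yrand_iters=cfg.yrand_iters,
            quik_delta=cfg.quik_delta,
            resid_cutoff=cfg.resid_cutoff,
            seed=cfg.ga_seed,
        )
        with open(out / "model_equation.txt", "w") as fh:
            fh.write(report["model"].equation() + "\n")
        with open(out / "validation_report.json", "w") as fh:
            json.dump(report_to_json(report), fh, indent=2)
        report["domain"].to_csv(out / "williams_plot.csv", index=False)
        # experimental-vs-predicted plot data
        fitplot = pd.DataFrame(
            {
                "compound_id": [kept[i].compound_id for i in train_idx]
                + [kept[i].compound_id for i in test_idx],
                "subset": ["train"] * len(train_idx) + ["test"] * len(test_idx),
                "observed": np.concatenate([ytr, yte]),
                "predicted": np.concatenate(
                    [
                        report["model"].predict(Xtr[:, best.subset]),
                        report["model"].predict(Xte[:, best.subset])
                        if len(test_idx)
                        else [],
                    ]
                ),
            }
        )
        fitplot.to_csv(out / "fit_plot.csv", index=False)
    except Exception as exc:
        raise StageError("validate", exc) from exc

    return out


def parse_equation(text: str) -> dict:
    """Parse a model-equation line back to {term: coefficient}.

    Inverse of :meth:`MLRModel.equation`; the intercept is stored under
    the key ``"intercept"``.
    """
    import re

    rhs = text.split("=", 1)[1].strip()
    pattern = re.compile(
        r"([+-]?)\s*(\d+\.?\d*)\s*\(±\s*\d+\.?\d*\)\s*([A-Za-z_][\w]*)?"
    )
    out = {}
    for sign, coef, name in pattern.findall(rhs):
        value = float(coef) * (-1.0 if sign == "-" else 1.0)
        out[name if name else "intercept"] = value
    return out
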