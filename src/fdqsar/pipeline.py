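"""Study orchestration: synthetic data or an input table → descriptors →
DCW → regression models (1a: QPpolrz+TD, 2a: DCW) → CPANN models
(1b: QPpolrz+TD, 2b: DCW) → response-correlation matrix → applicability-
domain reports → weight-map / top-map / heat-map exports, under one config
with a reproducibility manifest.

Model naming: the "a" models are ordinary least squares, the "b" models are
counter-propagation networks; "1" uses the two size/polarizability
descriptors, "2" uses the Monte Carlo optimal descriptor DCW.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cpann, dcw
from . import descriptors as desc
from .applicability_domain import williams_data
from .dataset_io import (
    RESPONSE_COLUMNS,
    SPLIT_LABELS,
    read_compounds,
    records_to_frame,
)
from .regression_stats import fit_ols, pearson_matrix
from .smiles_graph import parse
from .synthetic_data import SyntheticConfig, generate_dataset

log = logging.getLogger("fdqsar")


@dataclass
class RunConfig:
    """One study run: data source, model hyper-parameters, responses."""

    input_path: str | None = None  # CSV; None -> synthetic generator
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    responses: tuple[str, ...] = RESPONSE_COLUMNS
    dcw_T: int = 1
    dcw_N: int = 20
    dcw_delta: float = 0.1
    dcw_seed: int = 7
    grid: tuple[int, int] = (14, 14)
    epochs_1b: int = 400
    epochs_2b: int = 500
    eta_max: float = 0.5
    eta_min: float = 0.01
    cpann_seed: int = 7
    loo: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SyntheticConfig(**raw.pop("synth", {}))
        cfg = cls(synth=synth, **raw)
        cfg.grid = tuple(cfg.grid)  # type: ignore[assignment]
        cfg.responses = tuple(cfg.responses)
        return cfg

    def canonical(self) -> str:
        payload = asdict(self)
        payload["synth"]["fragments"] = {
            k: list(v) for k, v in payload["synth"]["fragments"].items()
        }
        return json.dumps(payload, sort_keys=True, default=list)


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.input_path:
        frame = records_to_frame(read_compounds(config.input_path))
    else:
        frame = generate_dataset(config.synth).set_index("id")
    if "split" not in frame.columns:
        raise ValueError("input table must carry a 'split' column")
    bad = set(frame["split"]) - set(SPLIT_LABELS)
    if bad:
        raise ValueError(f"unknown split labels {sorted(bad)}")
    return frame


def _group_lists(frame: pd.DataFrame):
    groups = {g: list(frame.index[frame["split"] == g]) for g in SPLIT_LABELS}
    train = groups["active"] + groups["passive"] + groups["calibration"]
    return groups, train, groups["validation"]


def _fit_dcw_models(frame, groups, config: RunConfig):
    """Per-endpoint DCW optimization; returns models and the DCW columns."""
    models: dict[str, dcw.DCWModel] = {}
    dcw_cols = pd.DataFrame(index=frame.index)
    smiles_by_group = {g: list(frame.loc[ids, "smiles"]) for g, ids in groups.items()}
    for endpoint in config.responses:
        endpoint_by_group = {
            g: frame.loc[ids, endpoint].to_numpy(dtype=float)
            for g, ids in groups.items()
        }
        model = dcw.optimize_weights(
            smiles_by_group,
            endpoint_by_group,
            T=config.dcw_T,
            N=config.dcw_N,
            delta=config.dcw_delta,
            seed=config.dcw_seed,
        )
        models[endpoint] = model
        dcw_cols[f"DCW_{endpoint}"] = [model.dcw(s) for s in frame["smiles"]]
    return models, dcw_cols


def rank_compounds(predictions: pd.DataFrame, response: str) -> list[str]:
    """Compound ids ordered by descending predicted score, ties by id."""
    if response not in predictions.columns:
        raise KeyError(f"unknown response {response!r}")
    frame = predictions.reset_index()
    id_col = frame.columns[0]
    frame = frame.sort_values([response, id_col], ascending=[False, True])
    return list(frame[id_col])


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, **kw)


def run_study(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full study replica and write the report bundle.

    The bundle is deterministic: identical configs give byte-identical
    files.  On any stage error the partially written bundle is removed.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t_start = time.time()
    try:
        stage = "load"
        log.info("stage=%s", stage)
        frame = _load_table(config)
        groups, train_ids, test_ids = _group_lists(frame)
        responses = list(config.responses)

        stage = "descriptors"
        log.info("stage=%s", stage)
        computed = pd.DataFrame(
            [desc.descriptor_vector(parse(s)) for s in frame["smiles"]],
            index=frame.index,
        )
        for col in computed.columns:
            if col not in frame.columns:
                frame[col] = computed[col]

        stage = "correlation"
        log.info("stage=%s", stage)
        corr = pearson_matrix(frame[responses])
        _write_csv(corr, out / "correlation_matrix.csv")

        stage = "dcw"
        log.info("stage=%s", stage)
        dcw_models, dcw_cols = _fit_dcw_models(frame, groups, config)
        frame = frame.join(dcw_cols)
        for endpoint, model in dcw_models.items():
            rows = [
                {"kind": k, "text": t, "weight": w}
                for (k, t), w in sorted(model.weights.weights.items())
            ]
            _write_csv(
                pd.DataFrame(rows),
                out / "dcw" / f"weights_{endpoint}.csv",
                index=False,
            )

        stage = "regression"
        log.info("stage=%s", stage)
        reg_models: dict[str, dict[str, object]] = {"1a": {}, "2a": {}}
        for label, predictors in (
            ("1a", lambda r: ["QPpolrz", "TD"]),
            ("2a", lambda r: [f"DCW_{r}"]),
        ):
            stats_rows = []
            for response in responses:
                preds = predictors(response)
                model = fit_ols(
                    frame[preds],
                    frame[response],
                    fit_ids=train_ids,
                    response_name=response,
                )
                reg_models[label][response] = model
                row = {"response": response}
                for grp, st in model.stats.items():
                    row[f"r2_{grp}"] = st["r2"]
                    row[f"rmse_{grp}"] = st["rmse"]
                for name, c in zip(["intercept"] + preds, model.coefficients):
                    row[f"coef_{name}"] = c
                stats_rows.append(row)
            _write_csv(
                pd.DataFrame(stats_rows),
                out / "models" / f"model_{label}_stats.csv",
                index=False,
            )

        stage = "applicability_domain"
        log.info("stage=%s", stage)
        williams_count = 0
        for label in ("1a", "2a"):
            for response in responses:
                model = reg_models[label][response]
                preds = model.predictors
                report = williams_data(model, frame[preds], frame[response])
                _write_csv(
                    report.table.assign(h_star=report.h_star),
                    out / "williams" / f"model_{label}_{response}.csv",
                )
                williams_count += 1

        stage = "cpann"
        log.info("stage=%s", stage)
        cp_results = {}
        for label, inputs, epochs in (
            ("1b", ["QPpolrz", "TD"], config.epochs_1b),
            ("2b", ["DCW_AvgBScore"], config.epochs_2b),
        ):
            schedule = cpann.TrainingSchedule(
                epochs=epochs, eta_max=config.eta_max, eta_min=config.eta_min
            )
            model, stats = cpann.fit_cpann(
                frame,
                inputs,
                responses,
                train_ids,
                test_ids,
                config.grid,
                schedule,
                seed=config.cpann_seed,
                loo=config.loo,
            )
            cp_results[label] = (model, stats)
            _write_csv(stats, out / "models" / f"model_{label}_stats.csv")
            for plane in inputs + responses:
                grid = cpann.weight_map(model, plane)
                _write_csv(
                    pd.DataFrame(grid),
                    out / "maps" / f"model_{label}_{plane}.csv",
                    header=False,
                    index=False,
                )
            Xn = model.norm_in.apply(frame)
            cells = cpann.top_map(model, Xn.to_numpy(), list(frame.index))
            rows = [
                {"row": i, "col": j, "ids": ";".join(ids)}
                for (i, j), ids in sorted(cells.items())
            ]
            _write_csv(
                pd.DataFrame(rows),
                out / "maps" / f"model_{label}_top_map.csv",
                index=False,
            )

        stage = "ranking"
        log.info("stage=%s", stage)
        model_1b = cp_results["1b"][0]
        Xn = model_1b.norm_in.apply(frame)
        pred = cpann.predict_batch(model_1b, Xn.to_numpy())
        pred_frame = pd.DataFrame(pred, index=frame.index, columns=responses)
        _write_csv(pred_frame, out / "predictions_model_1b.csv")
        ranking = rank_compounds(pred_frame, "AvgBScore")
        _write_csv(
            pd.DataFrame({"rank": range(1, len(ranking) + 1), "id": ranking}),
            out / "ranking_AvgBScore.csv",
            index=False,
        )

        stage = "heatmap"
        _write_csv(frame[responses], out / "binding_heatmap.csv")

        stage = "manifest"
        files = sorted(
            str(p.relative_to(out)) for p in out.rglob("*.csv") if p.is_file()
        )
        hashes = {
            f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files
        }
        manifest = {
            "fdqsar_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config_hash": hashlib.sha256(config.canonical().encode()).hexdigest(),
            "config": json.loads(config.canonical()),
            "seeds": {"dcw": config.dcw_seed, "cpann": config.cpann_seed,
                      "synthetic": config.synth.seed},
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "files": hashes,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("bundle complete in %.1fs (%d files)", time.time() - t_start,
                 len(files) + 1)
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for child in out.iterdir():
                if child.is_dir():
                    shutil.rmtree(child, ignore_errors=True)
                else:
                    child.unlink(missing_ok=True)
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc
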