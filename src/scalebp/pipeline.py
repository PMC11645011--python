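"""End-to-end pipeline: filter -> segment -> extract -> train -> export.

:func:`run_pipeline` wires the stages with one configuration object and
writes four artifacts to an output directory:

* ``features.csv`` — the labeled per-segment feature table,
* ``model_sbp.json`` / ``model_dbp.json`` — the trained tree ensembles,
* ``model_sbp.c`` / ``model_dbp.c`` — the exported embedded source,
* ``evaluation.csv`` — PCC/ME/MAE for both targets on the held-out split.

Every artifact is stamped with a hash of the configuration and the seed, so
re-running with identical inputs reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import metrics
from .errors import ConfigError, QualityError
from .experiments import extract_session_records
from .fiducials import ExtractionParams
from .filters import filter_session
from .model import (
    FEATURE_COLUMNS,
    GBTHyperparams,
    build_feature_table,
    max_trees_under_budget,
    stratified_split,
    train,
)
from .export import export_embedded_source
from .session import read_session


@dataclass
class PipelineConfig:
    filter_source: str = "designed"         # "printed" | "designed"
    precision: str = "double"               # "double" | "single"
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    hyperparams: GBTHyperparams = field(default_factory=GBTHyperparams)
    budget_bytes: int = 1_000_000           # the board's 1 MB flash
    tree_candidates: tuple[int, ...] = (50, 60, 70, 80, 90, 100)
    select_under_budget: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget_bytes <= 0:
            raise ConfigError("budget_bytes must be positive")
        if self.filter_source not in ("printed", "designed"):
            raise ConfigError(f"unknown filter source {self.filter_source!r}")
        if self.precision not in ("double", "single"):
            raise ConfigError(f"unknown precision {self.precision!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        extraction = ExtractionParams(**raw.pop("extraction", {}))
        hyperparams = GBTHyperparams(**raw.pop("hyperparams", {}))
        try:
            return cls(extraction=extraction, hyperparams=hyperparams, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig, session_paths: list[str | Path],
                 out_dir: str | Path) -> dict[str, Path]:
    """Run the full chain over recorded/simulated sessions; return artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"

    records = []
    for p in session_paths:
        session = read_session(p)
        filtered = filter_session(session, config.filter_source, config.precision)
        records.extend(extract_session_records(filtered, config.extraction))
    if not records:
        raise QualityError("no usable segments in any input session")
    table = build_feature_table(records)

    artifacts: dict[str, Path] = {}
    feat_path = out_dir / "features.csv"
    with open(feat_path, "w") as fh:
        fh.write(f"# {stamp}\n")
        table.to_csv(fh, index=False)
    artifacts["features"] = feat_path

    train_df, test_df = stratified_split(table, seed=config.seed)
    if config.select_under_budget:
        selection = max_trees_under_budget(
            train_df, config.hyperparams, config.budget_bytes,
            config.tree_candidates, seed=config.seed)
        models = {"sbp": selection.sbp_model, "dbp": selection.dbp_model}
    else:
        models = {
            t: train(train_df, train_df[c].to_numpy(), config.hyperparams,
                     seed=config.seed, target=t)
            for t, c in (("sbp", "ref_sbp"), ("dbp", "ref_dbp"))
        }

    eval_rows = []
    for target, col in (("sbp", "ref_sbp"), ("dbp", "ref_dbp")):
        m = models[target]
        mp = out_dir / f"model_{target}.json"
        mp.write_text(json.dumps(
            {"provenance": stamp, **json.loads(m.to_json())}))
        artifacts[f"model_{target}"] = mp
        exported = export_embedded_source(m, config.precision)
        cp = out_dir / f"model_{target}.c"
        cp.write_text(f"/* {stamp} */\n" + exported.source_text)
        artifacts[f"source_{target}"] = cp
        if len(test_df) >= 2:
            pred = m.predict(test_df[FEATURE_COLUMNS].to_numpy())
            rep = metrics.evaluate(test_df[col].to_numpy(), pred)
            eval_rows.append({"target": target, **rep.as_dict()})

    eval_path = out_dir / "evaluation.csv"
    with open(eval_path, "w") as fh:
        fh.write(f"# {stamp}\n")
        pd.DataFrame(eval_rows).to_csv(fh, index=False)
    artifacts["evaluation"] = eval_path
    return artifacts
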