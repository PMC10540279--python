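"""End-to-end run orchestration: simulate/load -> select -> LOO -> validate.

A run is described by a single config mapping (YAML or JSON on disk).  Every
stage logs what it consumed and produced, outputs land in a run directory,
and a manifest records the config hash and seeds so a re-run with the same
config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureTable, correlation_rank, select_manual
from .nn import NNConfig, loo_cross_validate, train_table
from .synth import PlantedSystem, simulate_feature_table
from .validation import metric_bakeoff, xy_randomization_test, y_shuffle_test

logger = logging.getLogger("stereonn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"preset": "paper-regime"},
    "select": {"method": "manual", "k": 15, "metric": "s_select"},
    "nn": {
        "hidden_layers": [15, 15],
        "activation": "relu",
        "learning_rate": 1e-3,
        "max_epochs": 5000,
        "target_metric": "s_select",
    },
    "validate": {"y_shuffle_replicates": 5, "xy_replicates": 5},
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration."""

    raw: dict
    out_dir: Path
    dry_run: bool = False

    @classmethod
    def load(cls, path: str | Path | None, out_dir: str | Path,
             overrides: dict | None = None, dry_run: bool = False) -> "RunConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
        if path is not None:
            text = Path(path).read_text()
            loaded = yaml.safe_load(text) or {}
            _deep_update(cfg, loaded)
        if overrides:
            _deep_update(cfg, overrides)
        return cls(cfg, Path(out_dir), dry_run)

    def nn_config(self, n_features: int) -> NNConfig:
        nn = self.raw["nn"]
        return NNConfig(
            input_dim=n_features,
            hidden_layers=tuple(nn.get("hidden_layers", (15, 15))),
            activation=nn.get("activation", "relu"),
            learning_rate=float(nn.get("learning_rate", 1e-3)),
            max_epochs=int(nn.get("max_epochs", 5000)),
            seed=int(self.raw.get("seed", 0)),
            target_metric=nn.get("target_metric", "s_select"),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


STAGES = ("simulate", "select", "loocv", "randomize", "bakeoff", "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write tables, model, reports + manifest.

    Returns the manifest dict.  With ``dry_run`` set, only the stage plan is
    returned and nothing is written.
    """
    if cfg.dry_run:
        return {"plan": list(STAGES), "config_hash": cfg.config_hash()}

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.raw.get("seed", 0))
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": seed,
                      "stages": [], "config": cfg.raw}

    def _stage(name, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") from exc
        manifest["stages"].append(name)
        logger.info("stage %s: done", name)
        return result

    # -- simulate -----------------------------------------------------------
    sim = cfg.raw.get("simulate", {})
    if "train_csv" in sim:
        def _load():
            train = FeatureTable.from_csv(Path(sim["train_csv"]).read_text())
            val = (FeatureTable.from_csv(Path(sim["val_csv"]).read_text())
                   if "val_csv" in sim else None)
            return train, val
        train, val1 = _stage("simulate", _load)
    else:
        system = PlantedSystem(seed=seed, **{
            k: v for k, v in sim.items() if k != "preset"
        })
        train, val1, _val2, _truth = _stage(
            "simulate", lambda: simulate_feature_table(system)
        )
        (out / "train.csv").write_text(train.to_csv())
        (out / "val1.csv").write_text(val1.to_csv())

    # -- select -------------------------------------------------------------
    sel = cfg.raw["select"]
    if sel.get("method", "manual") == "manual":
        k = min(int(sel.get("k", 15)), len(train.feature_names))
        def _select():
            ranking = correlation_rank(train, sel.get("metric", "s_select"))
            reduced = select_manual(train, k, ranking)
            reduced_val = val1.restrict(reduced.feature_names) if val1 else None
            return reduced, reduced_val
        train_red, val_red = _stage("select", _select)
    else:
        train_red, val_red = train, val1
    (out / "reduced.csv").write_text(train_red.to_csv())

    nn_cfg = cfg.nn_config(len(train_red.feature_names))

    # -- loocv --------------------------------------------------------------
    loo = _stage("loocv", lambda: loo_cross_validate(train_red, nn_cfg))
    (out / "loocv.json").write_text(json.dumps(loo.to_dict(), indent=1))
    model = train_table(train_red, nn_cfg)
    (out / "model.json").write_text(model.to_json())

    # -- randomize ----------------------------------------------------------
    vcfg = cfg.raw.get("validate", {})
    shuffle = _stage("randomize", lambda: y_shuffle_test(
        train_red, nn_cfg,
        replicates=int(vcfg.get("y_shuffle_replicates", 5)), seed=seed,
    ))
    xy = xy_randomization_test(
        train_red.n_ligands, len(train_red.feature_names), (0.0, 100.0),
        nn_cfg, replicates=int(vcfg.get("xy_replicates", 5)), seed=seed,
    )
    (out / "randomization.json").write_text(json.dumps(
        {"y_shuffle": shuffle.to_dict(), "xy_random": xy.to_dict()}, indent=1
    ))

    # -- bakeoff ------------------------------------------------------------
    if val_red is not None and val_red.labels is not None:
        bake = _stage("bakeoff", lambda: metric_bakeoff(
            train_red, val_red, nn_cfg, run_train_loo=False
        ))
        (out / "bakeoff.json").write_text(json.dumps(bake.to_dict(), indent=1))

    # -- report -------------------------------------------------------------
    def _report():
        manifest["loo_rmse"] = loo.rmse
        manifest["loo_r_squared"] = loo.r_squared
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    return _stage("report", _report)
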