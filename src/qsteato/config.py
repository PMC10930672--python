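"""YAML run configuration: blocks data / model / train / federated / eval.

Every command writes a resolved copy of its effective configuration beside
its outputs so runs can be re-executed bit-identically.
"""

from __future__ import annotations

import copy
import pathlib

import yaml

DEFAULTS: dict = {
    "data": {
        "n_per_grade": 25,
        "side_px": 64,
        "crop_px": None,
        "n_confounders": 2,
        "seed": 0,
        "render": False,
    },
    "model": {
        "kind": "hybrid",  # or "classical"
        "backbone": "tiny-test-cnn",
        "backbone_dim": 32,
        "fc_pre": [64],
        "hidden": [64, 100],
        "qdi": {
            "n_qubits": 5,
            "n_reupload_blocks": 20,
            "entangler": "chain",
            "readout_observable": "Y",
        },
    },
    "train": {
        "epochs": 30,
        "lr": 1.0e-3,
        "batch_size": 32,
        "folds": 5,
        "split_ratio": 0.8,
        "lambda_fn": 1.0,
        "seed": 0,
    },
    "federated": {
        "clients": 4,
        "samples_per_client": None,
        "rounds": 15,
        "local_epochs": 1,
        "seed": 0,
    },
    "eval": {
        "test_size": 400,
        "lambda_grid": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        "sizes": [100, 200, 400],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def write_resolved(cfg: dict, out_dir) -> pathlib.Path:
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
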