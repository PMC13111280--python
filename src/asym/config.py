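"""Layered run configuration.

Resolution precedence: package defaults <- named profile <- config file
<- command-line overrides (dotted keys).  Unknown keys fail hard with the
list of valid keys.  A resolved config serialises to YAML and round-trips
to an identical object.
"""

from __future__ import annotations

import copy
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .data_io import AugmentSpec, SplitSpec, SyntheticSpec
from .model import ModelConfig
from .train import TrainConfig

DEFAULTS: dict = {
    "profile": "synth",
    "seed": 0,
    "out_dir": "runs/latest",
    "model": {
        "model_width": 256, "state_dim": 16, "conv_kernel": 4,
        "expansion": 0.5, "n_blocks": 2, "static_ssm": False,
        "n_heads": 2, "d_k": 16, "merge": "residual",
        "level_width": 64, "fpn_kernel": 3, "fpn_dilation": 1,
        "dropout": 0.1, "upsample": "nearest",
        "gate_granularity": "channel",
        "head_width": 128, "head_state_dim": 16,
        "n_res_blocks": 1, "res_kernel": 3, "pool": "mean",
        "audio_only": False, "video_only": False, "no_cma": False,
        "uni_mamba": False, "no_fpn": False, "no_gd": False,
        "no_enhance": False,
    },
    "train": {
        "epochs": 16, "lr": 8e-5, "weight_decay": 1e-3,
        "batch_size": 16, "patience": None,
    },
    "split": {"ratios": [0.7, 0.1, 0.2], "stratified": True},
    "augment": {
        "enabled": False, "max_segments": 5, "min_length": 500,
        "length_mode": "min",
    },
    "synthetic": {
        "n_per_class": 50, "t_range": [600, 600],
        "f_audio": 12, "f_video": 20, "lag": 8,
        "transient_rate": [0.01, 0.05], "modulation_decay": [0.0, 3.0],
        "drift_slope": [0.0, -1.0], "cue_presence": 0.8,
        "ar_coeff": 0.6, "modulation_depth": 0.8,
        "modulation_cycles": 4.0, "noise_scale": 0.4,
    },
}

PROFILES: dict[str, dict] = {
    "dvlog": {
        "model": {"state_dim": 16},
        "train": {"epochs": 16, "lr": 8e-5, "weight_decay": 1e-3},
        "split": {"ratios": [0.7, 0.1, 0.2]},
        "augment": {"enabled": True},
    },
    "lmvd": {
        "model": {"state_dim": 12},
        "train": {"epochs": 12, "lr": 8e-5, "weight_decay": 1e-3},
        "split": {"ratios": [0.8, 0.1, 0.1]},
        "augment": {"enabled": True},
    },
    "synth": {
        "model": {
            "model_width": 32, "state_dim": 4, "expansion": 1.0,
            "n_heads": 2, "d_k": 8, "level_width": 8,
            "head_width": 32, "head_state_dim": 4, "dropout": 0.1,
        },
        "train": {"epochs": 20, "lr": 2e-3, "weight_decay": 1e-4,
                  "batch_size": 16},
    },
}


class UnknownConfigKey(ValueError):
    pass


def _merge(base: dict, extra: dict, path: str = ""):
    for key, val in extra.items():
        here = f"{path}{key}"
        if key not in base:
            valid = ", ".join(sorted(f"{path}{k}" for k in base))
            raise UnknownConfigKey(
                f"unknown config key {here!r}; valid keys here: {valid}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            _merge(base[key], val, path=f"{here}.")
        else:
            base[key] = val


def _set_dotted(cfg: dict, dotted: str, value):
    parts = dotted.split(".")
    node, path = cfg, ""
    for p in parts[:-1]:
        path += p + "."
        if p not in node or not isinstance(node[p], dict):
            valid = ", ".join(sorted(node))
            raise UnknownConfigKey(
                f"unknown config key {dotted!r}; valid keys at "
                f"{path.rstrip('.') or 'top level'}: {valid}")
        node = node[p]
    _merge(node, {parts[-1]: value},
           path=".".join(parts[:-1]) + "." if len(parts) > 1 else "")


@dataclass
class RunConfig:
    data: dict

    # -- typed views -----------------------------------------------------
    def model_config(self, **extra) -> ModelConfig:
        return ModelConfig(**{**self.data["model"], **extra})

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.data["train"])

    def split_spec(self) -> SplitSpec:
        d = self.data["split"]
        return SplitSpec(ratios=tuple(d["ratios"]),
                         stratified=d["stratified"], seed=self.seed)

    def augment_spec(self) -> AugmentSpec:
        d = self.data["augment"]
        return AugmentSpec(max_segments=d["max_segments"],
                           min_length=d["min_length"],
                           length_mode=d["length_mode"], seed=self.seed)

    def synthetic_spec(self) -> SyntheticSpec:
        d = dict(self.data["synthetic"])
        for k in ("t_range", "transient_rate", "modulation_decay",
                  "drift_slope"):
            d[k] = tuple(d[k])
        return SyntheticSpec(seed=self.seed, **d)

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def profile(self) -> str:
        return self.data["profile"]

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    def write_run_stamp(self, out_dir) -> None:
        """Resolved config + seed + library versions into the run directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.save(out / "config.yaml")
        import scipy
        import pandas
        stamp = {
            "seed": self.seed,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        }
        (out / "versions.json").write_text(json.dumps(stamp, indent=2))


def load_config(path=None, overrides: dict | list | None = None,
                profile: str | None = None) -> RunConfig:
    """Resolve defaults <- profile <- file <- overrides.

    ``overrides`` maps dotted keys to values (or is a list of
    ``key=value`` strings whose values are YAML-parsed).
    """
    file_data = {}
    if path is not None:
        file_data = yaml.safe_load(Path(path).read_text()) or {}
    if profile is None:
        profile = file_data.get("profile", DEFAULTS["profile"])
    if profile not in PROFILES:
        raise UnknownConfigKey(
            f"unknown profile {profile!r}; valid: {sorted(PROFILES)}")
    cfg = copy.deepcopy(DEFAULTS)
    cfg["profile"] = profile
    _merge(cfg, copy.deepcopy(PROFILES[profile]))
    _merge(cfg, file_data)
    cfg["profile"] = profile
    if overrides:
        if isinstance(overrides, list):
            parsed = {}
            for item in overrides:
                if "=" not in item:
                    raise ValueError(f"override {item!r} is not key=value")
                k, v = item.split("=", 1)
                val = yaml.safe_load(v)
                if isinstance(val, str):
                    try:  # YAML leaves '1e-3' a string; numbers win
                        val = float(val)
                    except ValueError:
                        pass
                parsed[k.strip()] = val
            overrides = parsed
        for k, v in overrides.items():
            _set_dotted(cfg, k, v)
    return RunConfig(cfg)
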