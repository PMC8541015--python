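"""Layered run configuration.

All method constants live here as named keys (never literals in code):
loss t = 1.02 with clamp [1, 50], 300 epochs, learning rate 1e-4,
alpha = 0.33, large-tumor ratio threshold 0.10, HU window (-200, 250),
Gaussian sigma 1.0.  A YAML file and dotted CLI overrides are merged onto
the defaults; unknown keys are rejected.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "preprocess": {
        "window": {"low": -200.0, "high": 250.0},
        "gaussian": {"sigma": 1.0},
        "drop_empty": True,
    },
    "model": {
        "coarse": {"in_channels": 1, "base_width": 64, "depth": 4, "n_classes": 3},
        "fine": {
            "in_channels": 1,
            "width": 32,
            "growth_rate": 32,
            "dilation_rates": [1, 3, 6, 12],
            "attention": {"K": 3, "branch_kernels": [1, 3, 5]},
            "resolutions": [1, 2, 4],
            "n_classes": 3,
            "use_attention": True,
        },
    },
    "loss": {"t": 1.02, "clamp": [1.0, 50.0]},
    "train": {
        "epochs": 300,
        "fine_epochs": None,
        "learning_rate": 0.0001,
        "alpha": 0.33,
        "batch_size": 8,
        "val_fraction": 0.2,
        "joint_epochs": 0,
    },
    "eval": {"large_tumor_ratio": 0.10, "patterns": True},
    "phantom": {
        "image_side": 512,
        "liver_hu_mean": 60.0, "liver_hu_sd": 10.0,
        "tumor_hu_mean": 30.0, "tumor_hu_sd": 8.0,
        "background_hu_mean": -100.0, "noise_sd": 15.0,
        "slope": 1.0, "intercept": -1024.0,
        "pattern_mix": {"large": 0.25, "small": 0.25,
                        "multiple": 0.25, "none": 0.25},
    },
}

#: reduced widths/epochs for CPU-scale runs (``--profile cpu-test``)
CPU_TEST_OVERRIDES: dict = {
    "model": {
        "coarse": {"base_width": 8, "depth": 3},
        "fine": {"width": 8, "growth_rate": 8},
    },
    "train": {"epochs": 16, "fine_epochs": 24, "learning_rate": 0.003},
    "phantom": {"image_side": 64},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        full = f"{path}.{key}" if path else key
        if key not in out:
            raise ConfigError(f"unknown config key: {full}")
        if isinstance(out[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{full} must be a mapping")
            out[key] = _merge(out[key], val, full)
        else:
            out[key] = val
    return out


def _set_dotted(tree: dict, dotted: str, value) -> dict:
    node: dict = {}
    cur = node
    parts = dotted.split(".")
    for p in parts[:-1]:
        cur[p] = {}
        cur = cur[p]
    cur[parts[-1]] = yaml.safe_load(value) if isinstance(value, str) else value
    return _merge(tree, node)


def load_config(path: str | Path | None = None,
                overrides: list[str] | None = None,
                profile: str | None = None) -> dict:
    """Defaults <- optional profile <- optional YAML file <- CLI overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if profile == "cpu-test":
        cfg = _merge(cfg, CPU_TEST_OVERRIDES)
    elif profile is not None:
        raise ConfigError(f"unknown profile {profile!r}")
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, loaded)
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override must look like key.path=value: {ov!r}")
        key, _, value = ov.partition("=")
        cfg = _set_dotted(cfg, key.strip(), value.strip())
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def to_dataclasses(cfg: dict):
    """Materialise the config tree into the typed configs the library uses."""
    from .cascade_train import TrainConfig
    from .coarse_net import UNetConfig
    from .fine_net import ADenseConfig
    from .io_preprocess import PreprocessConfig

    pre = cfg["preprocess"]
    preprocess = PreprocessConfig(
        window=(pre["window"]["low"], pre["window"]["high"]),
        sigma=pre["gaussian"]["sigma"], drop_empty=pre["drop_empty"])
    coarse = UNetConfig(**cfg["model"]["coarse"])
    f = cfg["model"]["fine"]
    fine = ADenseConfig(
        in_channels=f["in_channels"], width=f["width"],
        growth_rate=f["growth_rate"],
        dilation_rates=tuple(f["dilation_rates"]),
        attention_kernel=f["attention"]["K"],
        branch_kernels=tuple(f["attention"]["branch_kernels"]),
        resolutions=tuple(f["resolutions"]), n_classes=f["n_classes"],
        use_attention=f["use_attention"])
    t = cfg["train"]
    train = TrainConfig(epochs=t["epochs"], learning_rate=t["learning_rate"],
                        alpha=t["alpha"], batch_size=t["batch_size"],
                        seed=cfg["seed"], val_fraction=t["val_fraction"],
                        joint_epochs=t["joint_epochs"],
                        fine_epochs=t["fine_epochs"])
    return preprocess, coarse, fine, train
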