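"""CSV / YAML round-tripping for panels, subject tables and configs.

All tables are UTF-8 CSV with a header row and empty fields for missing
values; configs are YAML mappings mirroring the dataclass fields.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig

__all__ = [
    "write_panel",
    "read_panel",
    "write_meta",
    "read_meta",
    "write_sim_config",
    "read_sim_config",
]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
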