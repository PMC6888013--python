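"""CSV and configuration I/O.

On-disk conventions: comma-separated UTF-8 CSV with a header row, "." as
the decimal mark and the string "NA" as the missing marker.  Every output
written by the CLI carries a leading comment line stamping the package
version, the seed and a digest of the run configuration, so results can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .likelihoods import ObservedData

__all__ = [
    "read_dataset_csv",
    "write_dataset_csv",
    "config_digest",
    "write_stamped_csv",
    "read_stamped_csv",
    "load_config",
]

_NA = "NA"


def read_dataset_csv(path) -> ObservedData:
    """Read (region_id, z, o, E, covariates...) with "NA" missing markers.

    Requires columns ``o`` and ``E``; ``z`` is optional, all other columns
    except ``region_id`` are treated as count-side covariates.
    """
    df = pd.read_csv(path, na_values=[_NA], comment="#")
    for col in ("o", "E"):
        if col not in df.columns:
            raise ValueError(f"dataset CSV is missing required column {col!r}")
    labels = (
        tuple(str(v) for v in df["region_id"]) if "region_id" in df.columns else None
    )
    cov_cols = [c for c in df.columns if c not in ("region_id", "o", "z", "E")]
    x = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return ObservedData(
        o=df["o"].to_numpy(dtype=float),
        E=df["E"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float) if "z" in df.columns else None,
        x=x,
        region_labels=labels,
    )


def write_dataset_csv(data: ObservedData, path) -> None:
    df = pd.DataFrame(
        {
            "region_id": data.region_labels
            if data.region_labels is not None
            else np.arange(data.n) + 1,
            "o": data.o,
            "E": data.E,
        }
    )
    if data.z is not None:
        df.insert(1, "z", data.z)
    if data.x is not None:
        for j in range(data.x.shape[1]):
            df[f"x{j + 1}"] = data.x[:, j]
    df.to_csv(path, index=False, na_rep=_NA)


def config_digest(config: dict) -> str:
    """Short stable digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_stamped_csv(df: pd.DataFrame, path, seed, config: dict, index=True) -> None:
    """Write a CSV with a reproducibility stamp comment line."""
    from . import __version__

    stamp = (
        f"# spatzip v{__version__} seed={seed} config={config_digest(config)}\n"
    )
    with open(path, "w") as fh:
        fh.write(stamp)
        df.to_csv(fh, na_rep=_NA, index=index)


def read_stamped_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", na_values=[_NA], **kwargs)


def load_config(path) -> dict:
    """Load a JSON or YAML run-configuration file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
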