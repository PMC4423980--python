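"""Persist trial batches and experiment summaries (HDF5 container + flat CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig
from .engine import ReleaseBatch


def save_release_batch(
    batch: ReleaseBatch, cfg: SimConfig, path: str | Path, name: str = "batch"
) -> None:
    """Store a trial batch in an HDF5 container, config echoed for provenance."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.attrs["config_json"] = cfg.model_dump_json()
        g.attrs["n_trials"] = batch.n_trials
        g.create_dataset("fusion_counts", data=batch.fusion_counts)
        g.create_dataset("released_per_trial", data=batch.released_per_trial)
        g.create_dataset("injected_per_trial", data=batch.injected_per_trial)
        g.create_dataset("stop_times_ms", data=batch.stop_times_ms)
        ft = g.create_group("fusion_times")
        for v, times in enumerate(batch.fusion_times):
            ft.create_dataset(str(v), data=times)


def load_release_batch(path: str | Path, name: str = "batch") -> tuple[ReleaseBatch, SimConfig]:
    with h5py.File(path, "r") as f:
        g = f[name]
        cfg = SimConfig.model_validate(json.loads(g.attrs["config_json"]))
        nv = len(g["fusion_counts"])
        batch = ReleaseBatch(
            n_trials=int(g.attrs["n_trials"]),
            n_vesicles=nv,
            fusion_counts=g["fusion_counts"][...],
            fusion_times=[g["fusion_times"][str(v)][...] for v in range(nv)],
            released_per_trial=g["released_per_trial"][...],
            injected_per_trial=g["injected_per_trial"][...],
            stop_times_ms=g["stop_times_ms"][...],
        )
    return batch, cfg


def cooperativity_to_frame(result) -> pd.DataFrame:
    """Flatten a CooperativityResult into a tidy per-(seed, width) table."""
    rows = []
    n_seeds, n_w = result.q_ca_fC.shape
    for s in range(n_seeds):
        for w in range(n_w):
            rows.append(
                {
                    "spatial_seed": s,
                    "width_scale": result.width_scales[w],
                    "q_ca_fC": result.q_ca_fC[s, w],
                    "mean_p_ves": result.mean_p_ves[s, w],
                    "included_in_fit": bool(result.fits[s].included[w]),
                    "slope": result.slopes[s],
                }
            )
    return pd.DataFrame(rows)
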