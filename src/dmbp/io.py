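"""HDF5 serialization of movies and filter traces."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .inference import FilterTrace
from .params import ModelParams, StimulusParams
from .stimulus import Movie


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as an HDF5 dataset ``frames`` with parameter attrs."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("frames", data=movie.frames,
                               compression="gzip")
        ds.attrs["delta_t"] = movie.delta_t
        ds.attrs["seed"] = movie.seed
        ds.attrs["params"] = json.dumps(
            dataclasses.asdict(movie.params), default=str)


def load_movie(path: str | Path) -> Movie:
    with h5py.File(path, "r") as fh:
        ds = fh["frames"]
        raw = json.loads(ds.attrs["params"])
        raw["flash_frames"] = tuple(raw["flash_frames"])
        params = StimulusParams(**raw)
        return Movie(ds[...], float(ds.attrs["delta_t"]), params,
                     int(ds.attrs["seed"]))


def save_trace(trace: FilterTrace, path: str | Path) -> None:
    """Write per-frame particle arrays and weights, layer-tagged."""
    with h5py.File(path, "w") as fh:
        for name in ("source_states", "source_weights", "target_states",
                     "target_weights"):
            fh.create_dataset(name, data=getattr(trace, name),
                              compression="gzip")
        if trace.smoothed_states is not None:
            fh.create_dataset("smoothed_states", data=trace.smoothed_states,
                              compression="gzip")
            fh.create_dataset("smoothed_weights",
                              data=trace.smoothed_weights,
                              compression="gzip")
        fh.attrs["seed"] = trace.seed
        fh.attrs["smoothing_lag"] = trace.smoothing_lag
        fh.attrs["n_smoothed"] = trace.n_smoothed
        fh.attrs["model"] = json.dumps(dataclasses.asdict(trace.model),
                                       default=str)
        fh.attrs["stimulus"] = json.dumps(dataclasses.asdict(trace.stimulus),
                                          default=str)


def load_trace(path: str | Path) -> FilterTrace:
    with h5py.File(path, "r") as fh:
        model_raw = json.loads(fh.attrs["model"])
        if model_raw.get("D_V") in ("inf", "Infinity"):
            model_raw["D_V"] = np.inf
        model = ModelParams(**{k: (np.inf if v == "inf" else v)
                               for k, v in model_raw.items()})
        stim_raw = json.loads(fh.attrs["stimulus"])
        stim_raw["flash_frames"] = tuple(stim_raw["flash_frames"])
        stim = StimulusParams(**stim_raw)
        kwargs = {}
        if "smoothed_states" in fh:
            kwargs["smoothed_states"] = fh["smoothed_states"][...]
            kwargs["smoothed_weights"] = fh["smoothed_weights"][...]
        return FilterTrace(
            fh["source_states"][...], fh["source_weights"][...],
            fh["target_states"][...], fh["target_weights"][...],
            model, stim, int(fh.attrs["seed"]),
            smoothing_lag=float(fh.attrs["smoothing_lag"]),
            n_smoothed=int(fh.attrs["n_smoothed"]), **kwargs)


def trace_summary_csv(trace: FilterTrace, path: str | Path) -> None:
    """Per-frame MAP and SD of the dot-attributed target posterior."""
    import pandas as pd

    from .readout import circular_sd, object_map

    rows = []
    for k in range(trace.n_frames):
        try:
            x_map = object_map(trace, k, "dot")
            ens = trace.ensemble(k, "target")
            sd = circular_sd(ens.states[:, 0], ens.weights)
        except ValueError:
            x_map, sd = np.nan, np.nan
        rows.append({"frame": k, "dot_map_x": x_map, "target_sd_x": sd})
    pd.DataFrame(rows).to_csv(path, index=False)
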