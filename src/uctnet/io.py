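"""HDF5 dataset container and model checkpoints.

Dataset layout (schema ``uctnet-dataset/1``)::

    /meta                      group; attrs: schema_version, spacing_mm,
                               f_char, wavelet_f0, wavelet_duration, dt,
                               n_steps, clot_velocity
    /meta/sensor_positions     (N, ndim) mm
    /meta/labels               static (clot-free) region-label grid
    /samples/<i>/velocity      velocity map, m/s (float32)
    /samples/<i>/feature       normalized N x N feature matrix; attr divisor
    /samples/<i>/traces        optional (source, receiver, time) shot cube
    /samples/<i>               attrs: clot_center, clot_radius, clot_velocity

Traces are optional and dropped by default: the features are what training
consumes, and full shot cubes dominate the file size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional

import h5py
import numpy as np

from .config import PipelineConfig
from .features import FeatureMatrix, feature_matrix, normalize_matrix
from .forward import default_sim_config, ricker_wavelet, simulate_survey
from .network import Model, NetworkSpec
from .phantom import ClotSpec, embed_clot, make_head_phantom, place_sensors, sample_clot

__all__ = [
    "SCHEMA_VERSION",
    "Dataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "uctnet-dataset/1"


@dataclass
class Dataset:
    """In-memory dataset: aligned features, velocity labels and clot specs."""

    features: List[FeatureMatrix]
    velocities: List[np.ndarray]
    clots: List[ClotSpec]
    labels: np.ndarray  # static clot-free region labels
    sensor_positions: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)
    traces: Optional[List[np.ndarray]] = None

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_sensors(self) -> int:
        return int(self.sensor_positions.shape[0])


def generate_dataset(
    cfg: PipelineConfig,
    n_samples: Optional[int] = None,
    out_path=None,
    progress: Optional[Callable[[int, int], None]] = None,
    keep_traces: bool = False,
) -> Dataset:
    """Simulate the whole training database for a pipeline config.

    For each sample: draw a clot (per-sample seed spawned deterministically
    from the dataset seed), embed it, run the full every-sensor-fires survey,
    extract the characteristic-frequency matrix and normalize it.
    Deterministic under ``cfg.dataset_seed``.
    """
    n = cfg.n_samples if n_samples is None else n_samples
    base = make_head_phantom(cfg.phantom)
    sensors = place_sensors(
        base,
        cfg.sensor_count,
        layout=cfg.sensor_layout,
        gap_mm=cfg.sensor_gap_mm,
        layers=cfg.sensor_layers,
        layer_spacing_mm=cfg.sensor_layer_spacing_mm,
    )
    sim = default_sim_config(
        base,
        record_time=cfg.record_time,
        cfl_safety=cfg.cfl_safety,
        sponge_width=cfg.sponge_width,
        sponge_strength=cfg.sponge_strength,
        spatial_order=cfg.spatial_order,
        constant_density=cfg.constant_density,
    )
    wavelet = ricker_wavelet(cfg.wavelet_f0, sim.dt, cfg.wavelet_duration)
    f_char = cfg.characteristic_frequency

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(cfg.dataset_seed).spawn(n)]

    ds = Dataset(
        features=[],
        velocities=[],
        clots=[],
        labels=base.labels.copy(),
        sensor_positions=sensors.positions.copy(),
        spacing=base.spacing,
        meta={
            "f_char": f_char,
            "wavelet_f0": cfg.wavelet_f0,
            "wavelet_duration": cfg.wavelet_duration,
            "dt": sim.dt,
            "n_steps": sim.n_steps,
            "clot_velocity": cfg.clot_velocity,
        },
        traces=[] if keep_traces else None,
    )
    for i in range(n):
        clot = sample_clot(base, cfg.clot_radius_range, cfg.clot_velocity, seed=seeds[i])
        sample = embed_clot(base, clot)
        survey = simulate_survey(sample, sensors, wavelet, sim)
        feat = normalize_matrix(feature_matrix(survey, f_char))
        ds.features.append(feat)
        ds.velocities.append(sample.velocity.astype(np.float32))
        ds.clots.append(clot)
        if keep_traces:
            ds.traces.append(
                np.stack([s.traces for s in survey.shots]).astype(np.float32)
            )
        if progress is not None:
            progress(i + 1, n)
    if out_path is not None:
        write_dataset(ds, out_path)
    return ds


def write_dataset(ds: Dataset, path) -> None:
    """Write the dataset; an incomplete sample is removed on failure."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["spacing_mm"] = ds.spacing
        for k, v in ds.meta.items():
            meta.attrs[k] = v
        meta.create_dataset("sensor_positions", data=ds.sensor_positions)
        meta.create_dataset("labels", data=ds.labels)
        samples = f.create_group("samples")
        for i in range(ds.n_samples):
            g = None
            try:
                g = samples.create_group(str(i))
                g.attrs["clot_center"] = np.asarray(ds.clots[i].center)
                g.attrs["clot_radius"] = ds.clots[i].radius
                g.attrs["clot_velocity"] = ds.clots[i].velocity
                g.create_dataset("velocity", data=ds.velocities[i])
                feat = ds.features[i]
                d = g.create_dataset("feature", data=feat.values)
                d.attrs["f_char"] = np.atleast_1d(
                    np.asarray(feat.characteristic_frequency, dtype=np.float64)
                )
                d.attrs["divisor"] = feat.normalization_divisor or np.nan
                if ds.traces is not None:
                    g.create_dataset("traces", data=ds.traces[i])
            except Exception:
                if g is not None:
                    del samples[str(i)]
                raise


def read_dataset(path) -> Dataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise ValueError(f"{path}: missing /meta group — not a dataset file")
        meta = f["meta"]
        version = meta.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"{path}: schema version {version!r} != {SCHEMA_VERSION!r}")
        spacing = float(meta.attrs["spacing_mm"])
        mdict = {k: meta.attrs[k] for k in meta.attrs if k not in ("schema_version", "spacing_mm")}
        ds = Dataset(
            features=[],
            velocities=[],
            clots=[],
            labels=meta["labels"][...],
            sensor_positions=meta["sensor_positions"][...],
            spacing=spacing,
            meta=mdict,
        )
        keys = sorted(f["samples"].keys(), key=int)
        any_traces = False
        traces = []
        for k in keys:
            g = f["samples"][k]
            ds.velocities.append(g["velocity"][...])
            div = float(g["feature"].attrs["divisor"])
            fc = np.atleast_1d(np.asarray(g["feature"].attrs["f_char"], dtype=float))
            ds.features.append(
                FeatureMatrix(
                    values=g["feature"][...],
                    characteristic_frequency=(
                        float(fc[0]) if fc.size == 1 else tuple(float(x) for x in fc)
                    ),
                    normalization_divisor=None if np.isnan(div) else div,
                )
            )
            ds.clots.append(
                ClotSpec(
                    center=tuple(np.asarray(g.attrs["clot_center"], dtype=float)),
                    radius=float(g.attrs["clot_radius"]),
                    velocity=float(g.attrs["clot_velocity"]),
                )
            )
            if "traces" in g:
                any_traces = True
                traces.append(g["traces"][...])
            else:
                traces.append(None)
        if any_traces:
            ds.traces = traces
    return ds


def save_model(model: Model, path) -> None:
    """Checkpoint: weights + architecture + velocity bounds + history (npz)."""
    spec_json = json.dumps(
        {
            "input_size": model.spec.input_size,
            "input_channels": model.spec.input_channels,
            "hidden": [list(h) for h in model.spec.hidden],
            "pool_window": model.spec.pool_window,
            "pool_stride": model.spec.pool_stride,
            "pool_after": model.spec.pool_after,
            "leaky_slope": model.spec.leaky_slope,
            "output_grid": list(model.spec.output_grid),
            "output_kernel_size": model.spec.output_kernel_size,
            "resize_after": model.spec.resize_after,
        }
    )
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters)}
    np.savez_compressed(
        path,
        spec_json=np.bytes_(spec_json.encode()),
        dtype=np.bytes_(str(model.dtype).encode()),
        velocity_bounds=np.asarray(model.velocity_bounds or (np.nan, np.nan)),
        best_epoch=np.asarray(-1 if model.best_epoch is None else model.best_epoch),
        train_mse=np.asarray(model.history.get("train_mse", [])),
        val_mse=np.asarray(model.history.get("val_mse", [])),
        **arrays,
    )


def load_model(path) -> Model:
    with np.load(path) as z:
        spec_d = json.loads(bytes(z["spec_json"]).decode())
        spec_d["hidden"] = tuple(tuple(h) for h in spec_d["hidden"])
        spec_d["output_grid"] = tuple(spec_d["output_grid"])
        spec = NetworkSpec(**spec_d)
        model = Model(spec, seed=0, weight_init="uniform01", dtype=bytes(z["dtype"]).decode())
        weights = [z[f"param_{i}"] for i in range(len(model.parameters))]
        model.set_weights(weights)
        vb = z["velocity_bounds"]
        model.velocity_bounds = None if np.isnan(vb[0]) else (float(vb[0]), float(vb[1]))
        be = int(z["best_epoch"])
        model.best_epoch = None if be < 0 else be
        model.history = {"train_mse": list(z["train_mse"]), "val_mse": list(z["val_mse"])}
    return model
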