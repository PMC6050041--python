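"""Serialization: Recording <-> HDF5, generator configs <-> YAML, ground
truth -> CSV.

HDF5 schema (attribute ``schema_version`` = "1"): groups ``/traces``,
``/events``, ``/protocol``, ``/cell_meta`` and, for synthetic recordings,
``/ground_truth``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .population import DELTA_THETAS, FEATURE_TAGS, CellGroundTruth, GeneratorConfig
from .protocols import FlashGridProtocol, StimulusCondition, StimulusProtocol
from .recording import Recording

SCHEMA_VERSION = "1"


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def ground_truth_frame(cells: list[CellGroundTruth]) -> pd.DataFrame:
    """Flatten ground-truth parameters into one row per cell (for CSV export)."""
    rows = []
    for i, c in enumerate(cells):
        row = {
            "cell_id": i,
            "cell_class": c.cell_class,
            "depth_um": c.depth_um,
            "preferred_direction": c.preferred_direction,
            "tuning_concentration": c.tuning_concentration,
            "peak_response": c.peak_response,
            "center_silent": c.center_silent,
            "surround_alone_responsive": c.surround_alone_responsive,
            "rf_x": c.rf_centroid[0],
            "rf_y": c.rf_centroid[1],
            "rf_sigma_deg": c.rf_sigma_deg,
            "baseline_F": c.baseline_F,
            "noise_sd": c.noise_sd,
            "indicator": c.indicator,
            "surround_gain": c.surround_gain,
            "static_gain": c.static_gain,
            "rf_gain": c.rf_gain,
            "has_mappable_rf": c.has_mappable_rf,
            "fov_id": c.fov_id,
        }
        for d in DELTA_THETAS:
            row[f"a_{d}"] = c.modulation_law[d][0]
            row[f"b_{d}"] = c.modulation_law[d][1]
        for tag in FEATURE_TAGS:
            row[f"factor_{tag}"] = c.feature_contrast_factors.get(tag, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _cells_from_frame(df: pd.DataFrame) -> list[CellGroundTruth]:
    cells = []
    for _, r in df.iterrows():
        cells.append(
            CellGroundTruth(
                cell_class=str(r["cell_class"]),
                depth_um=float(r["depth_um"]),
                preferred_direction=float(r["preferred_direction"]),
                tuning_concentration=float(r["tuning_concentration"]),
                peak_response=float(r["peak_response"]),
                center_silent=bool(r["center_silent"]),
                surround_alone_responsive=bool(r["surround_alone_responsive"]),
                modulation_law={d: (float(r[f"a_{d}"]), float(r[f"b_{d}"])) for d in DELTA_THETAS},
                feature_contrast_factors={t: float(r[f"factor_{t}"]) for t in FEATURE_TAGS},
                rf_centroid=(float(r["rf_x"]), float(r["rf_y"])),
                rf_sigma_deg=float(r["rf_sigma_deg"]),
                baseline_F=float(r["baseline_F"]),
                noise_sd=float(r["noise_sd"]),
                indicator=str(r["indicator"]),
                surround_gain=float(r["surround_gain"]),
                static_gain=float(r["static_gain"]),
                rf_gain=float(r["rf_gain"]),
                has_mappable_rf=bool(r["has_mappable_rf"]),
                fov_id=int(r["fov_id"]),
            )
        )
    return cells


def _write_frame(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object or data.dtype.kind in "US":
            data = np.array([str(v) for v in data], dtype=h5py.string_dtype())
        group.create_dataset(col, data=data)
    group.attrs["columns"] = list(df.columns)


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    out = {}
    for col in cols:
        data = group[col][()]
        if data.dtype.kind in ("O", "S"):
            data = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in data])
        out[col] = data
    return pd.DataFrame(out)


def save_recording(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_rate_hz"] = recording.frame_rate_hz
        f.attrs["indicator"] = recording.indicator
        if recording.seed is not None:
            f.attrs["seed"] = recording.seed
        f.create_dataset("traces", data=recording.traces, compression="gzip", compression_opts=4)
        _write_frame(f.create_group("events"), recording.events)
        _write_frame(f.create_group("cell_meta"), recording.cell_meta)

        p = f.create_group("protocol")
        proto = recording.protocol
        p.attrs["protocol_kind"] = proto.protocol_kind
        p.attrs["n_repeats"] = proto.n_repeats
        if proto.seed is not None:
            p.attrs["seed"] = proto.seed
        p.create_dataset("presentation_order", data=proto.presentation_order)
        if isinstance(proto, FlashGridProtocol):
            p.attrs["grid_shape"] = proto.grid_shape
            p.attrs["square_size_deg"] = proto.square_size_deg
            p.attrs["extent_deg"] = proto.extent_deg
            p.attrs["on_s"] = proto.on_s
            p.attrs["off_s"] = proto.off_s
        else:
            _write_frame(p.create_group("conditions"), proto.condition_table().reset_index())

        if recording.ground_truth is not None:
            _write_frame(f.create_group("ground_truth"), ground_truth_frame(recording.ground_truth))


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        if str(f.attrs.get("schema_version")) != SCHEMA_VERSION:
            raise InvalidParameterError(f"unsupported schema version {f.attrs.get('schema_version')!r}")
        p = f["protocol"]
        kind = p.attrs["protocol_kind"]
        order = p["presentation_order"][()]
        n_repeats = int(p.attrs["n_repeats"])
        seed = int(p.attrs["seed"]) if "seed" in p.attrs else None
        if kind == "rf_mapping":
            protocol: StimulusProtocol | FlashGridProtocol = FlashGridProtocol(
                grid_shape=tuple(int(v) for v in p.attrs["grid_shape"]),
                square_size_deg=float(p.attrs["square_size_deg"]),
                extent_deg=tuple(float(v) for v in p.attrs["extent_deg"]),
                on_s=float(p.attrs["on_s"]),
                off_s=float(p.attrs["off_s"]),
                n_repeats=n_repeats,
                presentation_order=order,
                seed=seed,
            )
        else:
            cond_df = _read_frame(p["conditions"]).sort_values("condition")
            conditions = [
                StimulusCondition(
                    center_direction=None if np.isnan(r["center_direction"]) else float(r["center_direction"]),
                    surround_direction=None if np.isnan(r["surround_direction"]) else float(r["surround_direction"]),
                    surround_kind=str(r["surround_kind"]),
                    surround_param=None if np.isnan(r["surround_param"]) else float(r["surround_param"]),
                    duration_s=float(r["duration_s"]),
                    iti_s=float(r["iti_s"]),
                )
                for _, r in cond_df.iterrows()
            ]
            protocol = StimulusProtocol(conditions, n_repeats, order, str(kind), seed=seed)

        ground_truth = None
        if "ground_truth" in f:
            ground_truth = _cells_from_frame(_read_frame(f["ground_truth"]))
        events = _read_frame(f["events"])
        events["condition"] = events["condition"].astype(int)
        events["repeat"] = events["repeat"].astype(int)
        cell_meta = _read_frame(f["cell_meta"])
        cell_meta["cell_id"] = cell_meta["cell_id"].astype(int)
        return Recording(
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            traces=f["traces"][()],
            events=events,
            protocol=protocol,
            cell_meta=cell_meta,
            indicator=str(f.attrs["indicator"]),
            ground_truth=ground_truth,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
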