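"""TIFF stack IO, run configuration, manifests, and pipeline orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .stack import TimeLapseStack

log = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "RunConfig",
    "RunManifest",
    "run_pipeline",
]

_AXES = "TZCYX"


def write_stack(path: str | Path, stack: TimeLapseStack) -> None:
    """Write a stack as TIFF with acquisition metadata in the description."""
    meta = {
        "axes": _AXES,
        "timestamps_h": stack.timestamps_h.tolist(),
        "channel_names": stack.channel_names,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "inducer_time_h": stack.inducer_time_h,
    }
    tifffile.imwrite(
        str(path), stack.pixels, description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    axes: str | None = None,
    timestamps_h=None,
    channel_names: list[str] | None = None,
    inducer_time_h: float | None = None,
) -> TimeLapseStack:
    """Read a TIFF into the canonical (T, Z, C, Y, X) order.

    Metadata written by :func:`write_stack` is honoured; otherwise the axis
    order must be supplied via ``axes`` (a permutation of "TZCYX", or fewer
    letters for lower-dimensional files — missing axes are promoted to
    length 1).  A plain 2-D image becomes T=Z=C=1.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc)
        if not isinstance(meta, dict):
            meta = {}
    except (json.JSONDecodeError, TypeError):
        meta = {}

    file_axes = axes or meta.get("axes")
    if file_axes is None:
        if data.ndim == 2:
            file_axes = "YX"
        elif data.ndim == 5:
            file_axes = _AXES
        else:
            raise ValueError(
                f"{data.ndim}-D TIFF without axis metadata; pass axes="
            )
    file_axes = file_axes.upper()
    if data.ndim != len(file_axes):
        raise ValueError(
            f"axes {file_axes!r} do not match {data.ndim}-D data"
        )
    # promote missing axes, then permute into canonical order
    for ax in _AXES:
        if ax not in file_axes:
            data = data[None]
            file_axes = ax + file_axes
    perm = [file_axes.index(ax) for ax in _AXES]
    data = np.transpose(data, perm)

    ts = timestamps_h if timestamps_h is not None else meta.get(
        "timestamps_h", list(range(data.shape[0]))
    )
    names = channel_names or meta.get(
        "channel_names", [f"ch{i}" for i in range(data.shape[2])]
    )
    return TimeLapseStack(
        pixels=data,
        timestamps_h=np.asarray(ts, dtype=float),
        channel_names=list(names),
        pixel_size_um=float(meta.get("pixel_size_um", 0.1)),
        z_step_um=float(meta.get("z_step_um", 0.8)),
        inducer_time_h=(
            inducer_time_h if inducer_time_h is not None
            else meta.get("inducer_time_h")
        ),
    )


# --------------------------------------------------------------------------
# configuration and manifest
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str = ""
    output_dir: str = "results"
    target_channel: str = "target"
    reporter_channel: str | None = None
    inducer_time_h: float = 0.0
    detection: dict = field(default_factory=lambda: {
        "sigma_range": [1.0, 2.5],
        "min_separation_px": 4,
        "intensity_threshold": None,
    })
    tracking: dict = field(
        default_factory=lambda: {"search_radius_px": 4.0, "max_gap": None}
    )
    fit: dict = field(default_factory=lambda: {
        "tau_min": 0.1, "tau_max": 1000.0,
        "steps_per_decade": 40, "f_step": 0.01,
    })
    background_mode: str = "median"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Accounting record emitted for every pipeline run."""

    software_version: str = __version__
    config_hash: str = ""
    seed: int = 0
    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: RunConfig) -> dict:
    """Detect, track, measure, normalize, and fit one culture movie.

    Writes long-format trace CSV, a track-classification CSV, a per-time-
    point counts CSV, a fit-summary JSON, and a run manifest into the
    configured output directory.  Returns the result bundle in memory.
    """
    from .culture import (detect_puncta, extract_traces, max_project,
                          segment_and_count, track_puncta)
    from .kinetics import (GridSpec, fit_biexponential, normalize_table,
                           population_average)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.digest(), seed=config.seed)

    stack = read_stack(
        config.input_path, inducer_time_h=config.inducer_time_h
    )
    if config.target_channel not in stack.channel_names:
        raise ValueError(
            f"channel {config.target_channel!r} not present in "
            f"{stack.channel_names}"
        )
    chan = stack.channel_index(config.target_channel)

    det_kwargs = dict(config.detection)
    det_kwargs["sigma_range"] = tuple(det_kwargs.get("sigma_range", (1.0, 2.5)))
    detections = [
        detect_puncta(max_project(stack, ti, chan), **det_kwargs)[0]
        for ti in range(stack.n_timepoints)
    ]
    tracks = track_puncta(detections, **config.tracking)
    by_label: dict[str, int] = {}
    for tr in tracks:
        by_label[tr.label] = by_label.get(tr.label, 0) + 1
    manifest.stage_counts["tracks"] = by_label
    for tr in tracks:
        if not tr.persistent:
            manifest.warnings.append(
                f"punctum {tr.punctum_id} excluded ({tr.label})"
            )

    traces = extract_traces(
        stack, tracks, channels=[chan],
        background_mode=config.background_mode,
    )
    manifest.stage_counts["trace_rows"] = len(traces)
    normed = normalize_table(traces, config.inducer_time_h)
    manifest.stage_counts["normalized_traces"] = int(
        normed["punctum_id"].nunique()
    ) if len(normed) else 0

    pop = population_average(
        normed.assign(neuron_id=0), value_col="normalized"
    )
    fit = fit_biexponential(
        pop["time_h"].to_numpy(), pop["mean"].to_numpy(),
        config.inducer_time_h, grid=GridSpec(**config.fit),
    )
    counts = segment_and_count(stack, channel=chan, **det_kwargs)

    traces.to_csv(out / "traces.csv", index=False)
    normed.to_csv(out / "traces_normalized.csv", index=False)
    counts.to_csv(out / "counts.csv", index=False)
    pd.DataFrame(
        [
            {"punctum_id": tr.punctum_id, "label": tr.label,
             "persistent": tr.persistent}
            for tr in tracks
        ]
    ).to_csv(out / "tracks.csv", index=False)
    fit_summary = {
        "f_major": fit.f_major,
        "tau_major_h": fit.tau_major,
        "tau_minor_h": fit.tau_minor,
        "amplitude_mode": "fixed_to_reference",
        "ssr": fit.ssr,
        "boundary_hit": fit.boundary_hit,
        "non_decaying": fit.non_decaying,
        "n_points": fit.n_points,
    }
    with open(out / "fit.json", "w") as fh:
        json.dump(fit_summary, fh, indent=2)
    manifest.save(out / "manifest.json")
    return {
        "traces": traces,
        "normalized": normed,
        "population": pop,
        "fit": fit,
        "counts": counts,
        "tracks": tracks,
        "manifest": manifest,
    }
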