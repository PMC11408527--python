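"""Plain-text readers and writers for the pipeline's file formats.

Everything is diff-able text: timecourses as TSV (time column + one column
per ROI), spikes as CSV (unit_id, region, time_s), session events and
blocks as JSON, images as 16-bit TIFF, results as TSV/JSON.  Every table
written here carries a comment header with the package version, the seed,
and a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .session import Block, RoiTimecourseSet, SessionEvents, SpikeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "config_hash",
    "write_timecourses",
    "read_timecourses",
    "write_spikes",
    "read_spikes",
    "write_od_image",
    "read_od_image",
    "write_table",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a config dataclass or dict."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed=None, config=None) -> str:
    parts = [f"clawfc {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    return "# " + "; ".join(parts)


def write_table(path, df: pd.DataFrame, seed=None, config=None,
                sep: str = "\t") -> None:
    """Write a DataFrame as TSV/CSV with the provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, config) + "\n")
        df.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# pfUS timecourses
# ---------------------------------------------------------------------------

def write_timecourses(tsv_path, events_path, subject: RoiTimecourseSet,
                      seed=None, config=None) -> None:
    df = pd.DataFrame(subject.traces, columns=subject.roi_labels)
    df.insert(0, "time_s", subject.time_s)
    write_table(tsv_path, df, seed=seed, config=config)
    meta = {
        "subject_id": subject.subject_id,
        "vehicle_time_s": subject.events.vehicle_time_s,
        "drug_time_s": subject.events.drug_time_s,
        "duration_s": subject.events.duration_s,
    }
    Path(events_path).write_text(json.dumps(meta, indent=2))


def read_timecourses(tsv_path, events_path) -> RoiTimecourseSet:
    """Read a timecourse TSV plus its events JSON into a validated set.

    The sampling rate is inferred from the time column, which must be
    uniform within 1e-6 relative tolerance.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    if "time_s" not in df.columns or df.shape[1] < 3:
        raise ValueError("expected a time_s column plus >= 2 ROI columns")
    if df.isna().any().any():
        raise ValueError("NaNs in timecourse table")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or dt.min() <= 0:
        raise ValueError("time column must be strictly increasing")
    if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean():
        raise ValueError("non-uniform sampling in time column")
    meta = json.loads(Path(events_path).read_text())
    events = SessionEvents(meta["vehicle_time_s"], meta["drug_time_s"],
                           meta["duration_s"])
    rois = [c for c in df.columns if c != "time_s"]
    return RoiTimecourseSet(
        subject_id=str(meta.get("subject_id", "unknown")),
        fs=1.0 / dt.mean(),
        traces=df[rois].to_numpy(dtype=float),
        roi_labels=rois,
        events=events,
    )


# ---------------------------------------------------------------------------
# spike datasets
# ---------------------------------------------------------------------------

def write_spikes(csv_path, events_path, dataset: SpikeDataset,
                 seed=None, config=None) -> None:
    rows = []
    for uid, region in dataset.units:
        for t in dataset.spikes[uid]:
            rows.append((uid, region, t))
    df = pd.DataFrame(rows, columns=["unit_id", "region", "time_s"])
    write_table(csv_path, df, seed=seed, config=config, sep=",")
    meta = {
        "group_label": dataset.group_label,
        "blocks": [dataclasses.asdict(b) for b in dataset.blocks],
    }
    Path(events_path).write_text(json.dumps(meta, indent=2))


def read_spikes(csv_path, events_path,
                allowed_regions: tuple[str, ...] | None = ("MOs", "SSp"),
                ) -> SpikeDataset:
    """Read a spike CSV plus its blocks JSON into a validated dataset.

    Unsorted times are sorted with a warning; exact duplicate
    (unit, time) rows are dropped with the count logged; a region outside
    ``allowed_regions`` raises (pass ``None`` to accept any label).
    """
    df = pd.read_csv(csv_path, sep="\t", comment="#")
    if df.shape[1] == 1:  # fall back to comma separation
        df = pd.read_csv(csv_path, comment="#")
    meta = json.loads(Path(events_path).read_text())
    blocks = [Block(**b) for b in meta["blocks"]]
    units: list[tuple[str, str]] = []
    spikes: dict[str, np.ndarray] = {}
    if len(df):
        for col in ("unit_id", "region", "time_s"):
            if col not in df.columns:
                raise ValueError(f"spike table missing column {col!r}")
        n_dup = int(df.duplicated(["unit_id", "time_s"]).sum())
        if n_dup:
            logger.warning("dropping %d duplicate (unit, time) rows", n_dup)
            df = df.drop_duplicates(["unit_id", "time_s"])
        for uid, sub in df.groupby("unit_id", sort=False):
            regions = sub["region"].unique()
            if len(regions) != 1:
                raise ValueError(f"unit {uid!r} has multiple region labels")
            region = str(regions[0])
            if allowed_regions is not None and region not in allowed_regions:
                raise ValueError(f"unknown region {region!r} for unit {uid!r}")
            t = sub["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                logger.warning("unit %s: spike times unsorted, sorting", uid)
                t = np.sort(t)
            units.append((str(uid), region))
            spikes[str(uid)] = t
    return SpikeDataset(units=units, spikes=spikes, blocks=blocks,
                        group_label=str(meta.get("group_label", "")))


# ---------------------------------------------------------------------------
# OD images
# ---------------------------------------------------------------------------

def write_od_image(tiff_path, image: np.ndarray) -> None:
    """Write a grayscale image as 16-bit TIFF (values clipped to uint16)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535)
    tifffile.imwrite(tiff_path, arr.astype(np.uint16))


def read_od_image(tiff_path) -> np.ndarray:
    return tifffile.imread(tiff_path).astype(float)
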