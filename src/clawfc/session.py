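"""Core data containers shared across the analysis chains.

All time coordinates are seconds from acquisition start; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SessionEvents", "RoiTimecourseSet", "Block", "SpikeDataset"]


@dataclass(frozen=True)
class SessionEvents:
    """Injection schedule of a pfUS session."""

    vehicle_time_s: float
    drug_time_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.vehicle_time_s < self.drug_time_s < self.duration_s:
            raise ValueError("events must satisfy vehicle < drug < duration")


def parse_roi_label(label: str) -> tuple[str, str]:
    """Split an ROI label like ``"ACA-L"`` into (region, hemisphere)."""
    parts = label.split("-")
    if len(parts) != 2 or parts[1] not in ("L", "R"):
        raise ValueError(f"cannot parse ROI label {label!r} as region-hemisphere")
    return parts[0], parts[1]


@dataclass
class RoiTimecourseSet:
    """Per-subject regional power-Doppler timecourses.

    ``traces`` is (n_samples, n_rois), positive power-Doppler intensity in
    arbitrary units.  The standard atlas set is the 8 bilateral cortical
    ROIs {ACA, MOs, MOp, SSp} x {L, R}; arbitrary label sets are accepted
    in library use.
    """

    subject_id: str
    fs: float
    traces: np.ndarray
    roi_labels: list[str]
    events: SessionEvents

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (samples x ROIs)")
        if self.traces.shape[1] != len(self.roi_labels):
            raise ValueError("one label per trace column required")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class Block:
    """One experimental block with its injection time."""

    name: str
    start_s: float
    end_s: float
    injection_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("block must have positive length")


@dataclass
class SpikeDataset:
    """Curated spike times for sorted units with region labels.

    ``units`` preserves recording order as (unit_id, region) pairs;
    ``spikes`` maps unit_id to a sorted array of spike times in seconds.
    The canonical session has three 20-min blocks (baseline, vehicle,
    drug) with injections at block starts.
    """

    units: list[tuple[str, str]]
    spikes: dict[str, np.ndarray]
    blocks: list[Block]
    group_label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for uid, _region in self.units:
            if uid in seen:
                raise ValueError(f"duplicate unit id {uid!r}")
            seen.add(uid)
            if uid not in self.spikes:
                raise ValueError(f"unit {uid!r} has no spike array")
        starts = sorted((b.start_s, b.end_s) for b in self.blocks)
        for (s0, e0), (s1, _e1) in zip(starts, starts[1:]):
            if s1 < e0:
                raise ValueError("blocks must not overlap")

    def unit_ids(self, region: str | None = None) -> list[str]:
        return [uid for uid, reg in self.units if region is None or reg == region]

    @property
    def regions(self) -> list[str]:
        out: list[str] = []
        for _uid, reg in self.units:
            if reg not in out:
                out.append(reg)
        return out
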