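"""Dual-probe unit-level functional-connectivity chain.

Spike trains from sorted units in two cortical regions (MOs on one probe,
SSp on the other) are binned at 50 ms, smoothed with a Gaussian kernel
(sigma = 2 bins = 100 ms), and z-scored over the analysed span.  Pearson
correlations between every cross-region unit pair are computed in 60 s
windows slid by 30 s over the 15 min after each injection and Fisher
z-transformed.  Static fc matrices are the per-pair time-averages of the
windowed values; the difference matrix subtracts the vehicle block's
static fc from the drug block's; the per-unit effect summary is the mean
of each MOs unit's difference-matrix row across all SSp units, tested
against zero per group and compared across groups nonparametrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as spnd

from .session import Block, SpikeDataset
from .stats import TestResult, fisher_z, inverse_fisher_z, kruskal_dunn, wilcoxon_one_sample

logger = logging.getLogger(__name__)

__all__ = [
    "NpxConfig",
    "UnitFcResult",
    "GroupComparison",
    "bin_spikes",
    "smooth_zscore",
    "windowed_unit_fc",
    "static_and_diff_fc",
    "group_compare",
    "analyze_spike_dataset",
]


def _nanmean_or_nan(a: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that returns NaN (without warning) for all-NaN slices."""
    valid = ~np.isnan(a)
    count = valid.sum(axis=axis)
    total = np.where(valid, a, 0.0).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / count
    return np.where(count == 0, np.nan, out)


@dataclass
class NpxConfig:
    """Parameters of the unit-fc chain.

    Defaults follow the recording protocol: 50 ms bins, Gaussian smoothing
    with sigma = 2 bins truncated at 4 sigma, 60 s windows slid by 30 s
    over the 15 min after each injection.  ``average_domain`` selects
    whether static matrices average the Fisher-z values (default) or raw
    correlations.
    """

    bin_dt_s: float = 0.05
    smooth_sigma_bins: float = 2.0
    kernel_truncation_sigmas: float = 4.0
    fc_window_s: float = 60.0
    fc_step_s: float = 30.0
    analysis_span_s: float = 900.0
    injection_lag_s: float = 0.0
    clip_eps: float = 1e-7
    average_domain: str = "z"

    def __post_init__(self) -> None:
        wbins = self.fc_window_s / self.bin_dt_s
        if abs(wbins - round(wbins)) > 1e-9:
            raise ValueError("fc window must be a multiple of the bin width")
        if self.average_domain not in ("z", "r"):
            raise ValueError("average_domain must be 'z' or 'r'")


@dataclass
class UnitFcResult:
    """Windowed, static, and difference connectivity for one dataset."""

    mos_ids: list[str]
    ssp_ids: list[str]
    window_fc: dict[str, np.ndarray]        # block name -> (W, M, S) z
    static_fc: dict[str, np.ndarray]        # block name -> (M, S)
    diff_fc: np.ndarray                     # (M, S): drug - vehicle
    per_unit_delta: np.ndarray              # (M,): mean diff row per MOs unit
    excluded_units: list[tuple[str, str]] = field(default_factory=list)
    group_label: str = ""


@dataclass
class GroupComparison:
    """Per-group one-sample tests plus the across-group omnibus."""

    group_names: list[str]
    per_group: dict[str, TestResult]
    omnibus: TestResult
    pairwise: list[TestResult]


def bin_spikes(
    dataset: SpikeDataset,
    block: Block | tuple[float, float],
    bin_dt_s: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Spike counts per unit in half-open ``[t, t + dt)`` bins.

    The binning grid starts at the block start; a trailing partial bin is
    dropped.  Rows follow the dataset's unit order.  Returns (counts with
    shape units x bins, unit ids).
    """
    if bin_dt_s <= 0:
        raise ValueError("bin_dt_s must be positive")
    start, stop = (block.start_s, block.end_s) if isinstance(block, Block) else block
    n_bins = int(np.floor((stop - start) / bin_dt_s))
    if n_bins < 1:
        raise ValueError("empty block: no complete bin fits")
    end = start + n_bins * bin_dt_s
    ids = [uid for uid, _ in dataset.units]
    counts = np.zeros((len(ids), n_bins), dtype=np.int64)
    for i, uid in enumerate(ids):
        t = dataset.spikes[uid]
        t = t[(t >= start) & (t < end)]
        if t.size:
            counts[i] = np.bincount(
                ((t - start) / bin_dt_s).astype(np.int64), minlength=n_bins
            )[:n_bins]
    return counts, ids


def smooth_zscore(
    counts: np.ndarray,
    sigma_bins: float = 2.0,
    truncation: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smooth and z-score binned counts per unit.

    Each row is convolved with a discrete Gaussian (unit sum, truncated at
    ``truncation`` sigmas, reflected boundaries) and then z-scored over the
    full span.  Zero-variance rows cannot be z-scored; they are returned
    as NaN with ``retained=False`` so downstream stages exclude them.

    Returns (rates with shape units x bins, retained mask).
    """
    x = np.asarray(counts, dtype=float)
    if sigma_bins < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_bins > 0:
        sm = spnd.gaussian_filter1d(
            x, sigma_bins, axis=-1, mode="reflect", truncate=truncation
        )
    else:
        sm = x.copy()
    mean = sm.mean(axis=-1, keepdims=True)
    sd = sm.std(axis=-1, keepdims=True)
    retained = sd[..., 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (sm - mean) / sd
    z[~retained] = np.nan
    if not retained.all():
        logger.info("smooth_zscore: %d zero-variance units flagged",
                    int((~retained).sum()))
    return z, retained


def windowed_unit_fc(
    rates_mos: np.ndarray,
    rates_ssp: np.ndarray,
    bin_dt_s: float = 0.05,
    fc_window_s: float = 60.0,
    fc_step_s: float = 30.0,
    clip_eps: float = 1e-7,
    exclude_diagonal: bool = False,
) -> np.ndarray:
    """Per-window Fisher-z Pearson correlations between two unit sets.

    Both rate matrices must share the same bin grid.  Returns an array of
    shape (n_windows, n_mos, n_ssp); pairs with zero in-window variance
    are NaN.  ``exclude_diagonal`` masks the diagonal for the same-region
    case where both inputs are the same units.
    """
    a = np.atleast_2d(np.asarray(rates_mos, dtype=float))
    b = np.atleast_2d(np.asarray(rates_ssp, dtype=float))
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("rate matrices must share the bin grid")
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("need at least one unit per region")
    wbins = int(round(fc_window_s / bin_dt_s))
    sbins = int(round(fc_step_s / bin_dt_s))
    n = a.shape[-1]
    if wbins > n:
        raise ValueError("no complete window fits the analysed span")
    starts = np.arange(0, n - wbins + 1, sbins)
    out = np.full((starts.size, a.shape[0], b.shape[0]), np.nan)
    for w, s in enumerate(starts):
        sa = a[:, s: s + wbins]
        sb = b[:, s: s + wbins]
        ca = sa - np.nanmean(sa, axis=1, keepdims=True)
        cb = sb - np.nanmean(sb, axis=1, keepdims=True)
        da = np.sqrt(np.nansum(ca * ca, axis=1))
        db = np.sqrt(np.nansum(cb * cb, axis=1))
        ok_a, ok_b = da > 0, db > 0
        ca = np.where(np.isnan(ca), 0.0, ca)
        cb = np.where(np.isnan(cb), 0.0, cb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ca @ cb.T) / np.outer(da, db)
        r[~ok_a, :] = np.nan
        r[:, ~ok_b] = np.nan
        valid = ~np.isnan(r)
        r[valid] = np.clip(r[valid], -1.0, 1.0)
        z = np.where(valid, fisher_z(np.where(valid, r, 0.0), clip_eps), np.nan)
        out[w] = z
    if exclude_diagonal:
        if a.shape[0] != b.shape[0]:
            raise ValueError("diagonal exclusion requires square matrices")
        di = np.arange(a.shape[0])
        out[:, di, di] = np.nan
    return out


def static_and_diff_fc(
    window_fc_vehicle: np.ndarray,
    window_fc_doi: np.ndarray,
    mos_ids: list[str] | None = None,
    ssp_ids: list[str] | None = None,
    average_domain: str = "z",
    group_label: str = "",
) -> UnitFcResult:
    """Static fc per block, their difference, and per-MOs-unit deltas.

    Static fc averages each pair's windowed values across time (missing
    windows excluded per pair); the difference matrix is drug minus
    vehicle.  ``per_unit_delta[i]`` is the mean of difference row i over
    all SSp units.  Units whose every pair is missing in either block are
    excluded and reported with a reason.
    """
    wv = np.asarray(window_fc_vehicle, dtype=float)
    wd = np.asarray(window_fc_doi, dtype=float)
    if wv.shape[1:] != wd.shape[1:]:
        raise ValueError("vehicle and drug blocks must share the unit sets")
    m, s = wv.shape[1], wv.shape[2]
    mos_ids = list(mos_ids) if mos_ids is not None else [f"MOs-{i}" for i in range(m)]
    ssp_ids = list(ssp_ids) if ssp_ids is not None else [f"SSp-{j}" for j in range(s)]

    def static(w: np.ndarray) -> np.ndarray:
        if average_domain == "r":
            w = inverse_fisher_z(w)
        out = _nanmean_or_nan(w, axis=0)
        if average_domain == "r":
            out = fisher_z(out)
        return out

    st_v, st_d = static(wv), static(wd)
    diff = st_d - st_v

    excluded: list[tuple[str, str]] = []
    for i, uid in enumerate(mos_ids):
        if np.all(np.isnan(st_v[i])) or np.all(np.isnan(st_d[i])):
            excluded.append((uid, "all pairs missing in a block"))
    for j, uid in enumerate(ssp_ids):
        if np.all(np.isnan(st_v[:, j])) or np.all(np.isnan(st_d[:, j])):
            excluded.append((uid, "all pairs missing in a block"))
    per_unit = _nanmean_or_nan(diff, axis=1)
    return UnitFcResult(
        mos_ids=mos_ids, ssp_ids=ssp_ids,
        window_fc={"vehicle": wv, "doi": wd},
        static_fc={"vehicle": st_v, "doi": st_d},
        diff_fc=diff, per_unit_delta=per_unit,
        excluded_units=excluded, group_label=group_label,
    )


def group_compare(
    per_unit_deltas: dict[str, np.ndarray],
    q: float = 0.05,
) -> GroupComparison:
    """Per-group Wilcoxon vs 0 and across-group Kruskal–Wallis + Dunn.

    Each group's per-unit delta-z values (units pooled across animals) are
    tested against zero with the two-sided one-sample Wilcoxon signed-rank
    test; groups are then compared with Kruskal–Wallis and Dunn's post-hoc
    pairs (BH-adjusted).  A group whose deltas are all exactly zero cannot
    be ranked; it is reported non-significant with a flag.
    """
    names = list(per_unit_deltas)
    cleaned = {
        g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for g, v in per_unit_deltas.items()
    }
    per_group: dict[str, TestResult] = {}
    for g, v in cleaned.items():
        try:
            per_group[g] = wilcoxon_one_sample(v, mu=0.0)
        except ValueError:
            per_group[g] = TestResult(
                0.0, 1.0, int(v.size), method="wilcoxon_signed_rank",
                extra={"degenerate": True, "reason": "no non-zero differences"},
            )
    if len(names) >= 2:
        omnibus, pairwise = kruskal_dunn([cleaned[g] for g in names], q=q)
    else:
        omnibus = TestResult(0.0, 1.0, int(cleaned[names[0]].size),
                             method="kruskal_wallis", extra={"df": 0})
        pairwise = []
    for t in pairwise:
        i, j = t.extra["pair"]
        t.extra["groups"] = (names[i], names[j])
    return GroupComparison(names, per_group, omnibus, pairwise)


def analyze_spike_dataset(
    dataset: SpikeDataset,
    config: NpxConfig | None = None,
    regions: tuple[str, str] = ("MOs", "SSp"),
    vehicle_block: str = "vehicle",
    drug_block: str = "doi",
) -> UnitFcResult:
    """Full unit-fc chain for one session.

    For each of the vehicle and drug blocks, the analysed span starts at
    the block's injection time (plus ``injection_lag_s``) and covers
    ``analysis_span_s``; binning, smoothing and z-scoring are per span so
    the two blocks are normalised symmetrically.  ``regions`` selects the
    row/column unit sets; passing the same region twice gives the
    within-region (same-probe) analogue with the diagonal masked.
    """
    cfg = config or NpxConfig()
    by_name = {b.name: b for b in dataset.blocks}
    for name in (vehicle_block, drug_block):
        if name not in by_name:
            raise ValueError(f"dataset has no block named {name!r}")
    same_region = regions[0] == regions[1]
    row_ids = dataset.unit_ids(regions[0])
    col_ids = dataset.unit_ids(regions[1])
    if not row_ids or not col_ids:
        raise ValueError(f"no units found for regions {regions}")
    all_ids = [uid for uid, _ in dataset.units]

    window_fc: dict[str, np.ndarray] = {}
    retained_rows = np.ones(len(row_ids), dtype=bool)
    retained_cols = np.ones(len(col_ids), dtype=bool)
    for name in (vehicle_block, drug_block):
        blk = by_name[name]
        t0 = blk.injection_s + cfg.injection_lag_s
        span = (t0, min(t0 + cfg.analysis_span_s, blk.end_s))
        counts, _ = bin_spikes(dataset, span, cfg.bin_dt_s)
        rates, retained = smooth_zscore(
            counts, cfg.smooth_sigma_bins, cfg.kernel_truncation_sigmas
        )
        ridx = [all_ids.index(u) for u in row_ids]
        cidx = [all_ids.index(u) for u in col_ids]
        retained_rows &= retained[ridx]
        retained_cols &= retained[cidx]
        window_fc[name] = windowed_unit_fc(
            rates[ridx], rates[cidx], cfg.bin_dt_s, cfg.fc_window_s,
            cfg.fc_step_s, cfg.clip_eps, exclude_diagonal=same_region,
        )
    result = static_and_diff_fc(
        window_fc[vehicle_block], window_fc[drug_block],
        mos_ids=row_ids, ssp_ids=col_ids,
        average_domain=cfg.average_domain, group_label=dataset.group_label,
    )
    flagged = [
        (uid, "zero variance") for uid, keep in
        zip(row_ids + col_ids, np.concatenate([retained_rows, retained_cols]))
        if not keep
    ]
    result.excluded_units = list(dict.fromkeys(result.excluded_units + flagged))
    return result
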