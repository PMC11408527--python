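"""Pharmacological functional-ultrasound (pfUS) analysis chain.

The chain reproduces the standard drug-challenge workflow on regional
power-Doppler timecourses:

1. despike motion artifacts (rolling-median/MAD detection, interpolation);
2. quantify regional ΔCBV/CBV against the final 5 min before the drug,
   on the despiked but *unfiltered* traces;
3. band-pass 0.01–0.2 Hz (zero-phase Butterworth);
4. sliding-window Pearson correlations between all ROI pairs,
   Fisher z-transformed;
5. regional connectivity strengths and the PFC–SM delta-connectivity
   curve referenced to the final pre-drug window, with per-window paired
   t-tests vs baseline under Benjamini–Hochberg FDR control, and the
   post-drug area under the Δz curve per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as spnd
from scipy import signal as spsig

from .session import RoiTimecourseSet, SessionEvents, parse_roi_label
from .stats import FdrDecision, TestResult, bh_fdr, fisher_z, t_test

logger = logging.getLogger(__name__)

__all__ = [
    "PfusConfig",
    "FcWindowSeries",
    "DeltaSummary",
    "CbvResult",
    "PfusCohortResult",
    "despike",
    "bandpass",
    "delta_cbv",
    "windowed_regional_fc",
    "regional_strength",
    "group_delta_fc",
    "cbv_cohort_tests",
    "analyze_pfus_cohort",
]

PFC_DEFAULT = ("ACA", "MOs")
SM_DEFAULT = ("MOp", "SSp")


@dataclass
class PfusConfig:
    """Analysis parameters of the pfUS chain.

    The band edges and the 5-min baseline span are the protocol's values;
    window/step of the sliding correlation (300 s / 60 s) and the 60 s CBV
    binning are exposed because the protocol fixes only the baseline
    window length.
    """

    band_low_hz: float = 0.01
    band_high_hz: float = 0.2
    baseline_span_s: float = 300.0
    fc_window_s: float = 300.0
    fc_step_s: float = 60.0
    despike_k: float = 5.0
    despike_window: int = 11
    consensus_fraction: float = 0.5
    cbv_bin_s: float = 60.0
    q: float = 0.05
    clip_eps: float = 1e-7

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < fs / 2:
            raise ValueError("need band_low < band_high < fs/2")
        if self.fc_window_s * fs < 2:
            raise ValueError("fc window shorter than 2 samples")


@dataclass
class FcWindowSeries:
    """Time-indexed Fisher-z correlation matrices from a sliding window.

    ``z`` has shape (n_windows, R, R); the diagonal is NaN and excluded
    from every average, as are pairs with zero in-window variance.
    """

    window_start_s: np.ndarray
    z: np.ndarray
    n_samples_per_window: int
    roi_labels: list[str]
    window_s: float = 0.0

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]


@dataclass
class DeltaSummary:
    """Baseline-referenced delta curve with its AUC and attached tests.

    ``delta`` is (n_subjects, n_times); ``auc`` is the per-subject
    trapezoidal integral of the post-drug delta series (units x seconds).
    """

    times: np.ndarray
    delta: np.ndarray
    baseline_value: np.ndarray
    baseline_time_s: float
    auc: np.ndarray
    units: str
    tests: list[TestResult] = field(default_factory=list)
    fdr: FdrDecision | None = None

    @property
    def mean_delta(self) -> np.ndarray:
        return np.nanmean(self.delta, axis=0)


@dataclass
class CbvResult:
    """Binned ΔCBV/CBV percentage curves for a cohort.

    ``percent`` is (n_subjects, n_bins, n_rois); tests cover post-drug
    region x bin cells under one BH family.
    """

    bin_start_s: np.ndarray
    percent: np.ndarray
    roi_labels: list[str]
    drug_time_s: float
    tests: list[TestResult] = field(default_factory=list)
    fdr: FdrDecision | None = None

    def trough(self, rois: list[str] | None = None) -> float:
        """Most negative post-drug value of the cohort-mean curve, in %.

        ``rois`` restricts (and averages over) a subset of ROI columns
        before taking the minimum over post-drug bins.
        """
        idx = (
            [self.roi_labels.index(r) for r in rois]
            if rois is not None
            else list(range(len(self.roi_labels)))
        )
        mean_curve = np.nanmean(self.percent[:, :, idx], axis=(0, 2))
        post = self.bin_start_s >= self.drug_time_s
        return float(np.min(mean_curve[post]))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def despike(
    trace: np.ndarray, k: float = 5.0, window: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Flag and interpolate transient outliers in a single trace.

    A sample is flagged when its deviation from the rolling median
    (``window`` samples) exceeds ``k`` times the rolling MAD (floored at a
    tiny epsilon so constant stretches flag nothing).  Flagged samples are
    replaced by linear interpolation between the nearest clean neighbours;
    flagged edges take the nearest clean value.  Detection is iterated on
    the progressively cleaned trace until no new samples are flagged:
    clustered bursts corrupt the first-pass rolling statistics (the MAD
    inflates and masks part of the burst, the median shift falsely flags
    clean neighbours), and re-estimating after removal repairs both.

    Returns (clean trace, boolean artifact mask).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike expects a 1-D trace")
    if x.size < window:
        raise ValueError(f"trace shorter than the rolling window ({window})")
    if k <= 0:
        raise ValueError("k must be positive")
    tiny = 1e-12 * max(1.0, float(np.max(np.abs(x))))
    work = x.copy()
    mask = np.zeros(x.size, dtype=bool)
    floor = tiny
    # a second, coarser scale catches outlier runs long enough to capture
    # the short rolling median itself (e.g. overlapping bursts)
    scales = (window, 2 * window + 1)
    for it in range(10):
        new = np.zeros(x.size, dtype=bool)
        for w_size in scales:
            med = spnd.median_filter(work, size=w_size, mode="reflect")
            resid = work - med
            mad = spnd.median_filter(np.abs(resid), size=w_size, mode="reflect")
            if it == 0 and w_size == window:
                # global robust scale: keeps the threshold from collapsing
                # in stretches later passes replace by smooth interpolation
                floor = max(float(np.median(np.abs(resid))), tiny)
            new |= (np.abs(resid) > k * np.maximum(mad, floor)) & ~mask
        if not new.any():
            break
        mask |= new
        if mask.all():
            raise ValueError("all samples flagged as artifacts")
        good = np.flatnonzero(~mask)
        bad = np.flatnonzero(mask)
        work[bad] = np.interp(bad, good, x[good])
    frac = mask.mean()
    if frac > 0.20:
        logger.warning("despike flagged %.1f%% of samples", 100 * frac)
    return work, mask


def bandpass(trace: np.ndarray, fs: float, low: float = 0.01,
             high: float = 0.2) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass; removes DC, keeps length.

    Forward-backward filtering (sosfiltfilt) so the pass band is applied
    without phase shift — window timing downstream is unaffected.
    """
    x = np.asarray(trace, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    min_len = int(np.ceil(3 * fs / low))
    if x.shape[0] < min_len:
        raise ValueError(
            f"trace too short for band: need >= {min_len} samples at "
            f"low={low} Hz")
    sos = spsig.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return spsig.sosfiltfilt(sos, x, axis=0)


# ---------------------------------------------------------------------------
# ΔCBV/CBV
# ---------------------------------------------------------------------------

def delta_cbv(
    traces: np.ndarray,
    fs: float,
    events: SessionEvents,
    cbv_bin_s: float = 60.0,
    baseline_span_s: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔCBV/CBV percentage from despiked, unfiltered traces.

    The baseline B is the mean over the final ``baseline_span_s`` before
    the drug; the percent change 100*(x - B)/B is then averaged in
    ``cbv_bin_s`` bins.  Returns (bin start times, binned percent) with
    binned percent of shape (n_bins, n_rois); raises on non-positive B.
    """
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    if x.shape[0] == 1 and x.size > x.shape[1]:
        x = x.T
    n = x.shape[0]
    b_lo = int(round((events.drug_time_s - baseline_span_s) * fs))
    b_hi = int(round(events.drug_time_s * fs))
    if b_lo < 0 or b_hi > n:
        raise ValueError("baseline span outside recording")
    base = x[b_lo:b_hi].mean(axis=0)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline")
    pct = 100.0 * (x - base) / base
    bin_len = int(round(cbv_bin_s * fs))
    n_bins = n // bin_len
    binned = pct[: n_bins * bin_len].reshape(n_bins, bin_len, -1).mean(axis=1)
    bin_starts = np.arange(n_bins) * bin_len / fs
    return bin_starts, binned


def cbv_cohort_tests(
    raw_traces: list[np.ndarray],
    fs: float,
    events: SessionEvents,
    roi_labels: list[str],
    cbv_bin_s: float = 60.0,
    baseline_span_s: float = 300.0,
    q: float = 0.05,
) -> CbvResult:
    """Cohort ΔCBV/CBV with per region x post-drug bin tests vs baseline.

    For each ROI and each post-drug bin, the binned raw CBV values are
    compared to the subjects' own baseline means with a paired t-test; the
    whole region x bin family is BH-corrected at ``q``.
    """
    pct_all, base_all = [], []
    bin_starts = None
    for tr in raw_traces:
        x = np.asarray(tr, dtype=float)
        bin_starts, binned = delta_cbv(x, fs, events, cbv_bin_s, baseline_span_s)
        pct_all.append(binned)
        b_lo = int(round((events.drug_time_s - baseline_span_s) * fs))
        b_hi = int(round(events.drug_time_s * fs))
        base_all.append(x[b_lo:b_hi].mean(axis=0))
    percent = np.stack(pct_all)          # (S, n_bins, R)
    result = CbvResult(bin_starts, percent, list(roi_labels), events.drug_time_s)

    n_subj = percent.shape[0]
    if n_subj >= 2:
        post = np.flatnonzero(bin_starts >= events.drug_time_s)
        tests, ps = [], []
        for j in range(percent.shape[2]):
            for b in post:
                deltas = percent[:, b, j]  # percent change is already paired to baseline
                try:
                    res = t_test(deltas, mode="one_sample", mu=0.0)
                except ValueError:
                    res = TestResult(0.0, 1.0, n_subj, method="one_sample_t",
                                     extra={"degenerate": True})
                res.extra.update(roi=roi_labels[j], bin_start_s=float(bin_starts[b]))
                tests.append(res)
                ps.append(res.p_value)
        fdr = bh_fdr(ps, q)
        for res, adj, rej in zip(tests, fdr.adjusted_p, fdr.rejected):
            res.extra.update(adjusted_p=float(adj), significant=bool(rej))
        result.tests, result.fdr = tests, fdr
    return result


# ---------------------------------------------------------------------------
# sliding-window connectivity
# ---------------------------------------------------------------------------

def _window_starts(n: int, wlen: int, step: int) -> np.ndarray:
    if wlen > n:
        raise ValueError("no complete window fits the trace")
    return np.arange(0, n - wlen + 1, step)


def windowed_regional_fc(
    traces: np.ndarray,
    fs: float,
    fc_window_s: float = 300.0,
    fc_step_s: float = 60.0,
    roi_labels: list[str] | None = None,
    clip_eps: float = 1e-7,
) -> FcWindowSeries:
    """Sliding-window pairwise Fisher-z correlation matrices over ROIs.

    For every window of ``fc_window_s`` advanced by ``fc_step_s``, the
    Pearson correlation of each ROI pair over the in-window samples is
    Fisher z-transformed.  ROIs with zero in-window variance yield NaN
    (missing) entries for their pairs, excluded from downstream averages.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D array with >= 2 ROI columns")
    wlen = int(round(fc_window_s * fs))
    step = int(round(fc_step_s * fs))
    if wlen < 4:
        raise ValueError("window must span >= 4 samples")
    starts = _window_starts(x.shape[0], wlen, step)
    n_roi = x.shape[1]
    labels = list(roi_labels) if roi_labels is not None else [
        f"roi{j}" for j in range(n_roi)
    ]
    z = np.full((starts.size, n_roi, n_roi), np.nan)
    for w, s in enumerate(starts):
        seg = x[s: s + wlen]
        centred = seg - seg.mean(axis=0)
        sd = centred.std(axis=0)
        ok = sd > 0
        if ok.sum() >= 2:
            u = centred[:, ok] / sd[ok]
            r = (u.T @ u) / wlen
            r = np.clip(r, -1.0, 1.0)
            zz = fisher_z(r, clip_eps)
            np.fill_diagonal(zz, np.nan)
            zi = np.flatnonzero(ok)
            z[np.ix_([w], zi, zi)] = zz[None]
        if not ok.all():
            logger.debug("window %d: %d zero-variance ROIs", w, (~ok).sum())
    return FcWindowSeries(starts / fs, z, wlen, labels, window_s=wlen / fs)


def regional_strength(fcs: FcWindowSeries, roi: str) -> np.ndarray:
    """Per-window mean z of all edges incident to ``roi`` (7 in the 8-ROI set)."""
    if roi not in fcs.roi_labels:
        raise ValueError(f"unknown ROI {roi!r}")
    j = fcs.roi_labels.index(roi)
    row = fcs.z[:, j, :]
    valid = ~np.isnan(row)
    count = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, row, 0.0).sum(axis=1) / count
    return np.where(count == 0, np.nan, out)


def _baseline_window_index(starts: np.ndarray, window_s: float,
                           drug_time_s: float) -> int:
    """Final window fully inside the pre-drug period."""
    pre = np.flatnonzero(starts + window_s <= drug_time_s + 1e-9)
    if pre.size == 0:
        raise ValueError("baseline window not computable: no pre-drug window")
    return int(pre[-1])


def group_delta_fc(
    fc_per_subject: list[FcWindowSeries],
    events: SessionEvents,
    pfc_regions: tuple[str, ...] = PFC_DEFAULT,
    sm_regions: tuple[str, ...] = SM_DEFAULT,
    q: float = 0.05,
) -> DeltaSummary:
    """PFC–SM delta connectivity: per-window mean z over cross-group edges.

    Per subject and window, z is averaged over all PFC x SM ROI pairs (16
    edges in the standard set); the delta curve references the final full
    pre-drug window.  Per post-drug window, the subjects' deltas are tested
    against zero (paired-to-baseline t-test) under BH-FDR; the AUC is the
    per-subject trapezoidal integral of the post-drug delta series.
    """
    if not fc_per_subject:
        raise ValueError("need at least one subject")
    ref = fc_per_subject[0]
    starts = ref.window_start_s
    labels = ref.roi_labels

    def group_idx(regions: tuple[str, ...]) -> list[int]:
        out = []
        for i, lbl in enumerate(labels):
            try:
                region, _ = parse_roi_label(lbl)
            except ValueError:
                region = lbl
            if region in regions:
                out.append(i)
        return out

    pfc = group_idx(pfc_regions)
    sm = group_idx(sm_regions)
    if not pfc or not sm:
        raise ValueError("PFC or SM group matched no ROI labels")

    values = np.stack([
        np.nanmean(f.z[np.ix_(range(f.n_windows), pfc, sm)], axis=(1, 2))
        for f in fc_per_subject
    ])  # (S, W)

    window_s = ref.window_s if ref.window_s > 0 else float(ref.n_samples_per_window)
    b_idx = _baseline_window_index(starts, window_s, events.drug_time_s)
    baseline = values[:, b_idx]
    delta = values - baseline[:, None]
    post = np.flatnonzero(starts >= events.drug_time_s)
    auc = np.array([
        np.trapezoid(delta[s_i, post], starts[post]) for s_i in range(delta.shape[0])
    ]) if post.size >= 2 else np.zeros(delta.shape[0])

    summary = DeltaSummary(
        times=starts, delta=delta, baseline_value=baseline,
        baseline_time_s=float(starts[b_idx]), auc=auc, units="z",
    )
    if delta.shape[0] >= 2 and post.size:
        tests, ps = [], []
        for w in post:
            try:
                res = t_test(delta[:, w], mode="one_sample", mu=0.0)
            except ValueError:
                res = TestResult(0.0, 1.0, delta.shape[0], method="one_sample_t",
                                 extra={"degenerate": True})
            res.extra.update(window_start_s=float(starts[w]))
            tests.append(res)
            ps.append(res.p_value)
        fdr = bh_fdr(ps, q)
        for res, adj, rej in zip(tests, fdr.adjusted_p, fdr.rejected):
            res.extra.update(adjusted_p=float(adj), significant=bool(rej))
        summary.tests, summary.fdr = tests, fdr
    return summary


def compare_auc(auc_a: np.ndarray, auc_b: np.ndarray) -> TestResult:
    """Between-group comparison of per-subject AUCs (two-sided unpaired t)."""
    return t_test(auc_a, auc_b, mode="unpaired")


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class PfusCohortResult:
    """Everything the pfUS chain produces for one cohort."""

    delta_fc: DeltaSummary
    cbv: CbvResult
    fc_series: list[FcWindowSeries]
    artifact_masks: list[np.ndarray]
    strengths: dict[str, np.ndarray]


def analyze_pfus_cohort(
    subjects: list[RoiTimecourseSet],
    config: PfusConfig | None = None,
) -> PfusCohortResult:
    """Run the full pfUS chain on a cohort of timecourse sets."""
    cfg = config or PfusConfig()
    if not subjects:
        raise ValueError("empty cohort")
    fs = subjects[0].fs
    cfg.validate(fs)
    events = subjects[0].events
    labels = subjects[0].roi_labels

    despiked, masks, filtered = [], [], []
    for sub in subjects:
        cols, mcols = [], []
        for j in range(sub.traces.shape[1]):
            clean, mask = despike(sub.traces[:, j], cfg.despike_k, cfg.despike_window)
            cols.append(clean)
            mcols.append(mask)
        d = np.column_stack(cols)
        m = np.column_stack(mcols)
        # motion hits all ROIs in the same frames: censor any sample the
        # per-trace detector flags in a consensus of ROIs, in every ROI,
        # so residual frame-global transients cannot masquerade as
        # coherent signal
        shared = m.mean(axis=1) >= cfg.consensus_fraction
        if shared.any() and not shared.all():
            good = np.flatnonzero(~shared)
            bad = np.flatnonzero(shared)
            for j in range(d.shape[1]):
                d[bad, j] = np.interp(bad, good, d[good, j])
            m[bad, :] = True
        despiked.append(d)
        masks.append(m)
        filtered.append(np.column_stack([
            bandpass(d[:, j], fs, cfg.band_low_hz, cfg.band_high_hz)
            for j in range(d.shape[1])
        ]))

    cbv = cbv_cohort_tests(
        despiked, fs, events, labels, cfg.cbv_bin_s, cfg.baseline_span_s, cfg.q
    )
    fc_series = [
        windowed_regional_fc(f, fs, cfg.fc_window_s, cfg.fc_step_s, labels,
                             cfg.clip_eps)
        for f in filtered
    ]
    delta_fc = group_delta_fc(fc_series, events, q=cfg.q)
    strengths = {
        lbl: np.nanmean(
            np.stack([regional_strength(f, lbl) for f in fc_series]), axis=0
        )
        for lbl in labels
    }
    return PfusCohortResult(delta_fc, cbv, fc_series, masks, strengths)
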