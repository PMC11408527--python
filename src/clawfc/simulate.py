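"""Seeded synthetic recordings with recorded ground truth.

Three generators emulate the data the analysis chains consume:

``gen_pfus``
    Per-subject power-Doppler ROI timecourses for 8 bilateral cortical ROIs
    (ACA, MOs, MOp, SSp x L/R).  ROI fluctuations share latent
    Ornstein–Uhlenbeck factors realising a target inter-ROI correlation;
    after the drug event the prefrontal (ACA+MOs) and sensorimotor
    (MOp+SSp) group factors merge into one shared factor, raising the
    cross-group correlation by a configurable delta, while prefrontal ROIs
    receive a gamma-shaped fractional CBV drop.  Short multiplicative
    motion-like bursts are superimposed at recorded sample indices.

``gen_spikes``
    Dual-probe spike datasets: doubly stochastic Poisson spike trains whose
    log-intensity loads on a per-region latent factor and a shared
    cross-region factor; the shared loading is scheduled per 20-min block
    so that cross-region unit correlations can drop in the final (drug)
    block, or stay flat, depending on the simulated genotype regime.

``gen_od_image``
    Grayscale images with a Gaussian-profile intensity band on a uniform
    background, for the optical-density line-profile quantifier.

All generators are pure functions of (config, seed): the same seed gives
bit-identical output.  Each returns a :class:`GroundTruth` recording every
injected effect so downstream recovery tests never re-read the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .session import Block, RoiTimecourseSet, SessionEvents, SpikeDataset

__all__ = [
    "PfusSimConfig",
    "SpikeSimConfig",
    "GroundTruth",
    "gen_pfus",
    "gen_spikes",
    "gen_od_image",
    "DEFAULT_ROI_LABELS",
    "ctrl_spike_config",
    "cko_spike_config",
]

DEFAULT_ROI_LABELS = (
    "ACA-L", "ACA-R", "MOs-L", "MOs-R", "MOp-L", "MOp-R", "SSp-L", "SSp-R",
)
PFC_REGIONS = ("ACA", "MOs")
SM_REGIONS = ("MOp", "SSp")


@dataclass
class GroundTruth:
    """Record of every effect a generator injected.

    Fields are populated by whichever generator produced the dataset and
    left ``None`` otherwise, so recovery tests can score pipeline output
    without re-deriving anything from the config.
    """

    artifact_sample_indices: list[np.ndarray] | None = None
    injected_cbv_curve: np.ndarray | None = None  # (n_samples, n_rois)
    coupling: dict | None = None
    band_amplitude: float | None = None
    band_center: float | None = None
    extra: dict = field(default_factory=dict)


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float,
        size: int = 1) -> np.ndarray:
    """Stationary unit-variance Ornstein–Uhlenbeck paths, shape (size, n)."""
    phi = np.exp(-dt / tau)
    innov_sd = np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal((size, n)) * innov_sd
    eps[:, 0] = rng.standard_normal(size)  # stationary start
    out = spsig.lfilter([1.0], [1.0, -phi], eps, axis=1)
    return out


# ---------------------------------------------------------------------------
# pfUS sessions
# ---------------------------------------------------------------------------

@dataclass
class PfusSimConfig:
    """Conditions for a simulated pfUS cohort.

    Session timing follows the drug-challenge protocol: a 40-min scan with
    vehicle at 5 min and the drug at 20 min.  The synthetic sampling rate
    defaults to 1 Hz — the analysis band (0.01–0.2 Hz) only requires
    fs > 0.4 Hz, so traces stay small; ``fs`` is configurable.

    ``baseline_coupling`` is the pre-drug correlation between ROIs of
    different functional groups (PFC vs SM); within-group pairs sit at
    ``baseline_coupling + drug_coupling_delta``, so after the drug merges
    the two group factors the cross-group correlation rises by exactly
    ``drug_coupling_delta`` and the implied correlation matrix stays
    positive definite whenever ``baseline_coupling + drug_coupling_delta``
    is below 1.
    """

    n_subjects: int = 10
    fs: float = 1.0
    duration_s: float = 2400.0
    vehicle_time_s: float = 300.0
    drug_time_s: float = 1200.0
    roi_labels: tuple[str, ...] = DEFAULT_ROI_LABELS
    baseline_coupling: float = 0.3
    drug_coupling_delta: float = 0.3
    coupling_onset_tau_s: float = 120.0
    drug_cbv_drop: float = -0.15
    cbv_kernel_shape: float = 3.0
    cbv_kernel_scale_s: float = 120.0
    latent_timescale_s: float = 20.0
    fluct_sd: float = 0.05          # relative amplitude of coupled fluctuations
    noise_sd: float = 0.01          # relative white measurement noise
    artifact_rate_per_min: float = 1.0
    artifact_gain: float = 0.8      # multiplicative burst amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration_s must be integral")
        if not self.vehicle_time_s < self.drug_time_s < self.duration_s:
            raise ValueError("events must satisfy vehicle < drug < duration")
        if self.drug_coupling_delta < 0:
            raise ValueError(
                "infeasible coupling: drug_coupling_delta must be >= 0 "
                "(post-drug block)")
        rho_hi = self.baseline_coupling + self.drug_coupling_delta
        if not 0.0 <= self.baseline_coupling < 1.0 or not rho_hi < 1.0:
            raise ValueError(
                "infeasible coupling: need 0 <= baseline_coupling and "
                "baseline_coupling + drug_coupling_delta < 1 (post-drug block)")


def _roi_group(label: str) -> str:
    region = label.split("-")[0]
    if region in PFC_REGIONS:
        return "PFC"
    if region in SM_REGIONS:
        return "SM"
    return "other"


def gen_pfus(config: PfusSimConfig) -> tuple[list[RoiTimecourseSet], list[GroundTruth]]:
    """Simulate a pfUS cohort; returns per-subject timecourse sets and truths."""
    cfg = config
    n = int(round(cfg.fs * cfg.duration_s))
    dt = 1.0 / cfg.fs
    t = np.arange(n) * dt
    rois = list(cfg.roi_labels)
    n_roi = len(rois)
    groups = [_roi_group(lbl) for lbl in rois]

    c = np.sqrt(cfg.baseline_coupling)
    p = np.sqrt(cfg.drug_coupling_delta)
    e = np.sqrt(1.0 - cfg.baseline_coupling - cfg.drug_coupling_delta)

    # post-drug mixing of the two group factors into one shared factor
    m = np.zeros(n)
    post = t >= cfg.drug_time_s
    m[post] = 1.0 - np.exp(-(t[post] - cfg.drug_time_s) / cfg.coupling_onset_tau_s)

    # gamma-shaped CBV response, normalised to unit peak
    kern = np.zeros(n)
    tk = t[post] - cfg.drug_time_s
    pdf = sps.gamma.pdf(tk, a=cfg.cbv_kernel_shape, scale=cfg.cbv_kernel_scale_s)
    peak = sps.gamma.pdf((cfg.cbv_kernel_shape - 1) * cfg.cbv_kernel_scale_s,
                         a=cfg.cbv_kernel_shape, scale=cfg.cbv_kernel_scale_s)
    kern[post] = pdf / peak

    cbv_curves = np.zeros((n, n_roi))
    for j, g in enumerate(groups):
        if g == "PFC":
            cbv_curves[:, j] = cfg.drug_cbv_drop * kern

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    subjects: list[RoiTimecourseSet] = []
    truths: list[GroundTruth] = []
    events = SessionEvents(cfg.vehicle_time_s, cfg.drug_time_s, cfg.duration_s)
    n_art_mean = cfg.artifact_rate_per_min * cfg.duration_s / 60.0

    for s_idx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        f0 = _ou(rng, n, dt, cfg.latent_timescale_s)[0]
        f_pfc = _ou(rng, n, dt, cfg.latent_timescale_s)[0]
        f_sm = _ou(rng, n, dt, cfg.latent_timescale_s)[0]
        f_x = _ou(rng, n, dt, cfg.latent_timescale_s)[0]
        # idiosyncratic per-ROI fluctuations: white, only the shared
        # factors carry the slow (latent) structure
        eta = rng.standard_normal((n_roi, n))

        mix_a, mix_b = np.sqrt(1.0 - m), np.sqrt(m)
        f_group = {
            "PFC": mix_a * f_pfc + mix_b * f_x,
            "SM": mix_a * f_sm + mix_b * f_x,
            "other": np.zeros(n),
        }
        levels = 100.0 * np.exp(0.1 * rng.standard_normal(n_roi))
        traces = np.empty((n, n_roi))
        for j, g in enumerate(groups):
            s = c * f0 + p * f_group[g] + e * eta[j]
            traces[:, j] = levels[j] * (
                1.0 + cfg.fluct_sd * s + cbv_curves[:, j]
            ) + levels[j] * cfg.noise_sd * rng.standard_normal(n)

        # motion-like bursts hit all ROIs at the same frames
        n_art = rng.poisson(n_art_mean)
        art_idx: list[int] = []
        for _ in range(n_art):
            start = int(rng.integers(0, n))
            length = int(rng.integers(1, 4))
            art_idx.extend(range(start, min(start + length, n)))
        art_idx = np.unique(np.asarray(art_idx, dtype=int))
        if art_idx.size:
            gain = 1.0 + cfg.artifact_gain * rng.uniform(0.75, 1.25, art_idx.size)
            traces[art_idx, :] *= gain[:, None]

        subjects.append(RoiTimecourseSet(
            subject_id=f"sim{s_idx:02d}", fs=cfg.fs, traces=traces,
            roi_labels=rois, events=events,
        ))
        truths.append(GroundTruth(
            artifact_sample_indices=[art_idx],
            injected_cbv_curve=cbv_curves.copy(),
            coupling={
                "baseline_cross": cfg.baseline_coupling,
                "baseline_within": cfg.baseline_coupling + cfg.drug_coupling_delta,
                "post_cross": cfg.baseline_coupling + cfg.drug_coupling_delta,
                "delta": cfg.drug_coupling_delta,
            },
            extra={"levels": levels, "cbv_drop": cfg.drug_cbv_drop},
        ))
    return subjects, truths


# ---------------------------------------------------------------------------
# dual-probe spike sessions
# ---------------------------------------------------------------------------

_RATE_CAP_HZ = 500.0


@dataclass
class SpikeSimConfig:
    """Conditions for a simulated dual-probe session (MOs + SSp units).

    The session is three contiguous 20-min blocks (baseline, vehicle,
    drug), injections at block starts.  Per-unit intensity is

        lambda_u(t) = exp(mu_u + a * f_region(t) + b_k * f_shared(t))

    with unit-variance OU latent factors; ``b_k`` is the entry of
    ``cross_region_coupling_by_block`` for block k.  ``mu_u`` is normalised
    per block so expected rates do not change with the coupling schedule —
    the drug effect is purely correlational.  The default schedule is the
    control regime (shared coupling collapses in the drug block); see
    :func:`cko_spike_config` for the knockout regime (no shared factor, so
    nothing changes across blocks).
    """

    n_mos_units: int = 250
    n_ssp_units: int = 60
    block_length_s: float = 1200.0
    n_blocks: int = 3
    base_rate_hz: float = 5.0
    rate_log_sd: float = 0.5
    within_region_coupling: float = 0.15
    cross_region_coupling_by_block: tuple[float, ...] = (0.3, 0.3, 0.05)
    latent_timescale_s: float = 2.0
    bin_dt_for_latent_s: float = 0.05
    group_label: str = "Ctrl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks != len(self.cross_region_coupling_by_block):
            raise ValueError("need one cross coupling per block")
        if self.base_rate_hz <= 0:
            raise ValueError("rates must be positive")
        load = max(abs(self.within_region_coupling),
                   max(abs(b) for b in self.cross_region_coupling_by_block))
        if load >= 3.0:
            raise ValueError("couplings too large: log-rates would diverge")


def ctrl_spike_config(**kw) -> SpikeSimConfig:
    """Control regime: shared cross-region coupling drops in the drug block."""
    kw.setdefault("group_label", "Ctrl")
    kw.setdefault("cross_region_coupling_by_block", (0.3, 0.3, 0.05))
    return SpikeSimConfig(**kw)


def cko_spike_config(**kw) -> SpikeSimConfig:
    """Knockout regime: no shared-factor modulation in any block (null)."""
    kw.setdefault("group_label", "cKO")
    kw.setdefault("cross_region_coupling_by_block", (0.0, 0.0, 0.0))
    return SpikeSimConfig(**kw)


def gen_spikes(config: SpikeSimConfig) -> tuple[SpikeDataset, GroundTruth]:
    """Simulate a dual-probe spike dataset with a per-block coupling schedule."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_units = cfg.n_mos_units + cfg.n_ssp_units
    regions = ["MOs"] * cfg.n_mos_units + ["SSp"] * cfg.n_ssp_units
    unit_ids = [f"{reg}-{i:04d}" for i, reg in enumerate(regions)]
    dt = cfg.bin_dt_for_latent_s
    nb = int(round(cfg.block_length_s / dt))
    a = cfg.within_region_coupling

    rates = cfg.base_rate_hz * np.exp(
        cfg.rate_log_sd * rng.standard_normal(n_units)
        - 0.5 * cfg.rate_log_sd**2
    )
    if np.any(rates > _RATE_CAP_HZ):
        raise ValueError("rate too high: expected rate exceeds safety cap")

    # sign-balanced within-region loadings: units couple to their region's
    # population factor with either sign, so region-factor realisations do
    # not shift the whole cohort's cross-region correlations one way
    a_sign = rng.choice([-1.0, 1.0], size=n_units)
    a_u = a * a_sign

    is_mos = np.array([r == "MOs" for r in regions])
    spike_lists: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    blocks = []
    block_names = ["baseline", "vehicle", "doi"][: cfg.n_blocks] + [
        f"block{k}" for k in range(3, cfg.n_blocks)
    ]
    for k in range(cfg.n_blocks):
        b = cfg.cross_region_coupling_by_block[k]
        t0 = k * cfg.block_length_s
        blocks.append(Block(block_names[k], t0, t0 + cfg.block_length_s, t0))
        f_mos = _ou(rng, nb, dt, cfg.latent_timescale_s)[0]
        f_ssp = _ou(rng, nb, dt, cfg.latent_timescale_s)[0]
        f_sh = _ou(rng, nb, dt, cfg.latent_timescale_s)[0]
        f_reg = np.where(is_mos[:, None], f_mos[None, :], f_ssp[None, :])
        # normalise so E[lambda] = rates regardless of loadings
        log_lam = (
            np.log(rates)[:, None] - 0.5 * (a * a + b * b)
            + a_u[:, None] * f_reg + b * f_sh[None, :]
        )
        lam = np.exp(log_lam)
        counts = rng.poisson(lam * dt)
        bin_starts = t0 + np.arange(nb) * dt
        for u in range(n_units):
            c_u = counts[u]
            total = int(c_u.sum())
            if total == 0:
                continue
            times = np.repeat(bin_starts, c_u) + rng.random(total) * dt
            spike_lists[u].append(np.sort(times))

    spikes = {
        uid: (np.concatenate(lst) if lst else np.array([], dtype=float))
        for uid, lst in zip(unit_ids, spike_lists)
    }
    dataset = SpikeDataset(
        units=list(zip(unit_ids, regions)), spikes=spikes,
        blocks=blocks, group_label=cfg.group_label,
    )
    truth = GroundTruth(
        coupling={
            "within_region": a,
            "cross_by_block": tuple(cfg.cross_region_coupling_by_block),
        },
        extra={"unit_rates_hz": rates, "regions": regions,
               "within_loadings": a_u},
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# optical-density images
# ---------------------------------------------------------------------------

def gen_od_image(
    width: int,
    height: int,
    band_center: float,
    band_width: float,
    band_amplitude: float,
    background_level: float = 50.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Grayscale image with a vertical Gaussian-profile band.

    The band runs along image columns: ``image[y, x] = background +
    amplitude * exp(-(x - center)^2 / (2 width^2)) + noise``, emulating the
    dense mRNA signal stripe an autoradiograph shows where the labelled
    region crosses the section.
    """
    if band_amplitude < 0:
        raise ValueError("band amplitude must be >= 0")
    if not 0 <= band_center < width:
        raise ValueError("band outside image")
    rng = np.random.default_rng(seed)
    x = np.arange(width, dtype=float)
    profile = band_amplitude * np.exp(-((x - band_center) ** 2) / (2.0 * band_width**2))
    image = (
        background_level
        + np.broadcast_to(profile, (height, width)).copy()
        + noise_sd * rng.standard_normal((height, width))
    )
    truth = GroundTruth(band_amplitude=band_amplitude, band_center=band_center,
                        extra={"band_width": band_width,
                               "background_level": background_level})
    return image, truth
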