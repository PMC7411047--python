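"""Synthetic-data generators for the flash-grab adaptation analyses.

Every generator is a stand-in for an unavailable empirical dataset: it
produces data with exactly the statistical structure the downstream
analyses assume (logistic 2AFC observers, Gaussian-tuned retinotopic
voxels, latency-structured lateralized EEG components), not a mechanistic
model of the underlying physiology.  All generators are bit-reproducible
given their configuration and seed; one global seed is expanded into
per-subject substreams so enlarging a study never changes earlier
subjects' data.

Conventions: angles in degrees, times in milliseconds relative to flash
onset, EEG amplitudes in microvolts.  Polar angle is 0 at the upper
vertical meridian, positive clockwise, wrapped to ``[-180, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import DEFAULT_CHANNELS, EEGStudy, SubjectEpochs

__all__ = [
    "ObserverParams",
    "AdjustmentConfig",
    "VoxelSimConfig",
    "EEGSimConfig",
    "simulate_2afc_trials",
    "simulate_adjustments",
    "simulate_voxel_table",
    "simulate_eeg_study",
]


# --------------------------------------------------------------------------
# psychophysics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    """Parameters of a four-parameter logistic 2AFC observer.

    ``p(x) = gamma + (1 - lambda - gamma) / (1 + exp(-beta * (x - alpha)))``

    Parameters
    ----------
    alpha : float
        Inflection point of the logistic — the point of subjective
        equality (PSE), degrees.
    beta : float
        Slope, 1/deg; must be positive.
    gamma : float
        Lower asymptote (guess rate toward the other response).
    lapse : float
        Lapse rate (shortfall of the upper asymptote).
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0 or self.lapse < 0:
            raise ValueError("gamma and lapse must be non-negative")
        if self.gamma + self.lapse >= 1:
            raise ValueError("gamma + lapse must be < 1")

    def prob_upward(self, x) -> np.ndarray:
        """Probability of an 'upward' response at test angle(s) ``x``."""
        x = np.asarray(x, dtype=float)
        z = np.clip(-self.beta * (x - self.alpha), -700, 700)
        return self.gamma + (1.0 - self.lapse - self.gamma) / (1.0 + np.exp(z))


def simulate_2afc_trials(
    obs: ObserverParams,
    angles: Sequence[float],
    n_per_angle: int,
    seed,
    condition: str = "main",
    subject: str = "s00",
) -> pd.DataFrame:
    """Simulate Bernoulli 2AFC trials from a logistic observer.

    Parameters
    ----------
    obs : ObserverParams
        Generating psychometric parameters.
    angles : sequence of float
        Test angles in degrees (the x axis of the psychometric function).
    n_per_angle : int
        Trials per test angle (>= 1).
    seed : int or numpy Generator/SeedSequence
        Randomness source.

    Returns
    -------
    pandas.DataFrame
        Columns ``test_angle``, ``response_upward`` (0/1), ``condition``,
        ``subject``.
    """
    angles = np.asarray(list(angles), dtype=float)
    if angles.size == 0:
        raise ValueError("angles must be non-empty")
    if n_per_angle < 1:
        raise ValueError("n_per_angle must be >= 1")
    rng = np.random.default_rng(seed)
    p = obs.prob_upward(angles)
    resp = rng.random((angles.size, n_per_angle)) < p[:, None]
    return pd.DataFrame(
        {
            "test_angle": np.repeat(angles, n_per_angle),
            "response_upward": resp.ravel().astype(int),
            "condition": condition,
            "subject": subject,
        }
    )


@dataclass(frozen=True)
class AdjustmentConfig:
    """Configuration of the pointer-adjustment illusion-size experiment.

    Each subject's true perceived tilt is drawn from
    ``Normal(true_tilt_mean, between_subject_sd)``; individual settings add
    ``Normal(0, within_subject_sd)`` noise and are signed by the rotation
    direction (clockwise positive).
    """

    true_tilt_mean: float = 15.55
    between_subject_sd: float = 7.54
    within_subject_sd: float = 2.0
    n_subjects: int = 8
    n_reps_per_direction: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_subjects < 1 or self.n_reps_per_direction < 1:
            raise ValueError("counts must be >= 1")


def simulate_adjustments(cfg: AdjustmentConfig) -> pd.DataFrame:
    """Simulate a table of pointer-adjustment settings.

    Returns
    -------
    pandas.DataFrame
        Columns ``subject``, ``direction`` ('cw'/'ccw'), ``setting_deg``
        (signed setting: positive = clockwise of vertical) and
        ``true_tilt_deg`` (generator provenance, not used by analyses).
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tilt = cfg.true_tilt_mean + rng.normal(0.0, cfg.between_subject_sd) \
            if cfg.between_subject_sd > 0 else cfg.true_tilt_mean
        for direction, sign in (("cw", 1.0), ("ccw", -1.0)):
            noise = (
                rng.normal(0.0, cfg.within_subject_sd, cfg.n_reps_per_direction)
                if cfg.within_subject_sd > 0
                else np.zeros(cfg.n_reps_per_direction)
            )
            for k in range(cfg.n_reps_per_direction):
                rows.append(
                    {
                        "subject": f"s{i:02d}",
                        "direction": direction,
                        "setting_deg": sign * tilt + noise[k],
                        "true_tilt_deg": tilt,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fMRI voxel tables
# --------------------------------------------------------------------------

_DEFAULT_SHIFTS: Mapping[str, Mapping[str, float]] = {
    # Stand-in laminar illusion shifts (degrees of polar angle): feedback-
    # dominated superficial layers carry most of the illusory displacement,
    # the input-dominated middle layer little; extrastriate areas more than
    # V1.  These are generator conditions, not estimates of real data.
    "V1": {"S": 8.0, "M": 1.0, "D": 4.0},
    "V2": {"S": 15.0, "M": 12.0, "D": 13.0},
    "V3": {"S": 16.0, "M": 14.0, "D": 15.0},
}


@dataclass(frozen=True)
class VoxelSimConfig:
    """Configuration of the retinotopic voxel-table generator.

    Per condition (clockwise / counter-clockwise illusion), each voxel's
    response amplitude is a Gaussian tuning bump in polar angle centred at
    ``meridian_deg`` displaced by the layer- and area-specific illusory
    shift (positive shift = clockwise), plus optional white noise.
    """

    areas: tuple[str, ...] = ("V1", "V2", "V3")
    n_voxels_per_area: int = 1800
    illusion_shift: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {a: dict(m) for a, m in _DEFAULT_SHIFTS.items()}
    )
    tuning_width: float = 25.0
    tuning_profile: str = "cosine"
    noise_sd: float = 0.05
    meridian_deg: float = 0.0
    n_subjects: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.areas:
            raise ValueError("areas must be non-empty")
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_voxels_per_area < 1:
            raise ValueError("n_voxels_per_area must be >= 1")
        if self.tuning_profile not in ("cosine", "gaussian"):
            raise ValueError("tuning_profile must be 'cosine' or 'gaussian'")
        for a in self.areas:
            if a not in self.illusion_shift:
                raise ValueError(f"no illusion_shift entry for area {a!r}")
            for layer in ("S", "M", "D"):
                v = self.illusion_shift[a][layer]
                if not np.isfinite(v):
                    raise ValueError("illusion shifts must be finite")


def wrap_angle(a):
    """Wrap angles (degrees) into ``[-180, 180)``."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


#: depth ranges of the three layer bins (superficial/middle/deep)
_LAYER_RANGES = {"S": (0.0, 0.4), "M": (0.4, 0.8), "D": (0.8, 1.0)}


def _tuning(d: np.ndarray, width: float, profile: str) -> np.ndarray:
    """Unit-peak polar-angle tuning as a function of angular distance d.

    ``cosine`` (default) is a raised cosine with compact support ``|d| <=
    2 * width`` — a bump of similar scale to a Gaussian of SD ``width``
    but with exactly zero tails, so hemifield-window truncation cannot
    bias the equal-area estimate.  ``gaussian`` is the classic unbounded
    profile.
    """
    if profile == "gaussian":
        return np.exp(-0.5 * (d / width) ** 2)
    half = 2.0 * width
    out = np.zeros_like(d)
    inside = np.abs(d) < half
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / half))
    return out


def simulate_voxel_table(cfg: VoxelSimConfig) -> pd.DataFrame:
    """Simulate a voxel table with layer-dependent illusory angular shifts.

    Voxels are allocated to the three depth layers in proportion to layer
    thickness; within each layer, polar-angle preferences tile ``[-180,
    180)`` on a uniform grid (so noiseless binned curves are exactly
    symmetric about the configured bump centres and the equal-area
    estimator recovers the shifts without bias) while depth fractions are
    drawn uniformly inside the layer's depth range — uniform in ``[0, 1]``
    marginally.

    Returns
    -------
    pandas.DataFrame
        Columns ``subject``, ``area``, ``polar_pref``, ``depth_fraction``,
        ``amp_cw``, ``amp_ccw``.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(max(cfg.n_subjects, 1))
    frames = []
    n = cfg.n_voxels_per_area
    for si, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        for area in cfg.areas:
            prefs_l, depth_l, shift_l = [], [], []
            for layer, (d0, d1) in _LAYER_RANGES.items():
                n_l = max(int(round(n * (d1 - d0))), 1)
                prefs_l.append(
                    wrap_angle(-180.0 + 360.0 * (np.arange(n_l) + 0.5) / n_l)
                )
                depth = rng.uniform(d0, d1, n_l)
                depth_l.append(np.minimum(depth, 1.0))
                shift_l.append(np.full(n_l, cfg.illusion_shift[area][layer]))
            prefs = np.concatenate(prefs_l)
            depth = np.concatenate(depth_l)
            shift = np.concatenate(shift_l)
            amps = {}
            for cond, sgn in (("cw", 1.0), ("ccw", -1.0)):
                centre = cfg.meridian_deg + sgn * shift
                d = wrap_angle(prefs - centre)
                amp = _tuning(d, cfg.tuning_width, cfg.tuning_profile)
                if cfg.noise_sd > 0:
                    amp = amp + rng.normal(0.0, cfg.noise_sd, amp.size)
                amps[cond] = amp
            frames.append(
                pd.DataFrame(
                    {
                        "subject": f"s{si:02d}",
                        "area": area,
                        "polar_pref": prefs,
                        "depth_fraction": depth,
                        "amp_cw": amps["cw"],
                        "amp_ccw": amps["ccw"],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# EEG studies
# --------------------------------------------------------------------------

#: left/right posterior channel groups carrying the lateralized components
_LEFT_GROUP = ("P3", "P5", "PO5", "PO7", "O1")
_RIGHT_GROUP = ("P4", "P6", "PO6", "PO8", "O2")


@dataclass(frozen=True)
class EEGSimConfig:
    """Configuration of the multi-subject EEG epoch generator.

    Three conditions x two sides are generated per subject:

    * ``retinal`` — a physically lateralized bar: early lateralized
      component inside the C1 latency band.
    * ``background`` — rotating inducer alone: a mid-latency lateralized
      component.
    * ``illusory`` — flash-grab bar on the inducer: the background
      component plus a late lateralized component whose amplitude is
      ``late_gain_uv_per_deg`` x the subject's illusion size.

    Component time courses are raised-cosine bumps supported exactly on
    their ``(onset, offset)`` windows.  Lateralization is realized as
    opposite-polarity loadings on two disjoint posterior channel groups,
    scaled so the contralateral-minus-ipsilateral difference wave equals
    the nominal component amplitude.  Noise is white Gaussian plus 1/f
    ("pink") noise, independent across channels and trials.
    """

    n_subjects: int = 12
    n_trials_per_cell: int = 200
    srate: float = 1000.0
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 500.0
    decimate: int = 1
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    conditions: tuple[str, ...] = ("retinal", "background", "illusory")
    retinal_window_ms: tuple[float, float] = (46.0, 98.0)
    retinal_amp_uv: float = 2.0
    background_window_ms: tuple[float, float] = (118.0, 161.0)
    background_amp_uv: float = 1.5
    late_window_ms: tuple[float, float] = (178.0, 400.0)
    late_gain_uv_per_deg: float = 0.15
    illusion_size_mean: float = 6.25
    illusion_size_sd: float = 2.35
    noise_white_sd_uv: float = 5.0
    noise_pink_sd_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.epoch_end_ms <= self.epoch_start_ms:
            raise ValueError("epoch must have positive duration")
        if self.decimate < 1:
            raise ValueError("decimate must be >= 1")
        if self.n_subjects < 1 or self.n_trials_per_cell < 1:
            raise ValueError("counts must be >= 1")
        for name in ("retinal_window_ms", "background_window_ms", "late_window_ms"):
            t0, t1 = getattr(self, name)
            if t1 <= t0:
                raise ValueError(f"{name} must satisfy onset < offset")
            if t0 < self.epoch_start_ms or t1 > self.epoch_end_ms:
                raise ValueError(f"{name} lies outside the epoch")
        unknown = set(self.conditions) - {"retinal", "background", "illusory"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        for a in (self.retinal_amp_uv, self.background_amp_uv,
                  self.late_gain_uv_per_deg):
            if not np.isfinite(a):
                raise ValueError("component amplitudes must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.srate
        n = int(round((self.epoch_end_ms - self.epoch_start_ms) / dt))
        t = self.epoch_start_ms + dt * np.arange(n)
        return t[:: self.decimate]


def _raised_cosine(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Unit-peak raised-cosine bump supported on ``[t0, t1]``."""
    prof = np.zeros_like(times)
    inside = (times >= t0) & (times <= t1)
    prof[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[inside] - t0) / (t1 - t0)))
    return prof


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                axis_len: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude-shaped noise along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(axis_len)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    pink = np.fft.irfft(spec, n=axis_len, axis=-1)
    sd = pink.std()
    if sd > 0:
        pink /= sd
    return pink


def simulate_eeg_study(cfg: EEGSimConfig) -> EEGStudy:
    """Simulate a multi-subject EEG study with lateralized components.

    Returns
    -------
    EEGStudy
        One :class:`~flashgrab.containers.SubjectEpochs` per subject and
        an ``illusion_sizes`` vector (degrees).  Trial order within each
        subject interleaves conditions and sides deterministically.
    """
    times = cfg.times_ms
    n_t = times.size
    names = list(cfg.channel_names)
    n_ch = len(names)
    idx_left = [names.index(c) for c in _LEFT_GROUP if c in names]
    idx_right = [names.index(c) for c in _RIGHT_GROUP if c in names]
    if not idx_left or len(idx_left) != len(idx_right):
        raise ValueError("channel_names must include the posterior pairs")

    prof_retinal = _raised_cosine(times, *cfg.retinal_window_ms)
    prof_background = _raised_cosine(times, *cfg.background_window_ms)
    prof_late = _raised_cosine(times, *cfg.late_window_ms)

    cells = [(c, s) for c in cfg.conditions for s in ("left", "right")]
    n_trials = cfg.n_trials_per_cell * len(cells)

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    subjects = []
    sizes = np.empty(cfg.n_subjects)
    for si, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        size = cfg.illusion_size_mean + (
            rng.normal(0.0, cfg.illusion_size_sd) if cfg.illusion_size_sd > 0 else 0.0
        )
        sizes[si] = size

        data = np.zeros((n_ch, n_t, n_trials), dtype=np.float32)
        cond_labels = np.empty(n_trials, dtype=object)
        side_labels = np.empty(n_trials, dtype=object)

        tr = 0
        for cond, side in cells:
            sl = slice(tr, tr + cfg.n_trials_per_cell)
            cond_labels[sl] = cond
            side_labels[sl] = side
            wave = np.zeros(n_t)
            if cond == "retinal":
                wave += cfg.retinal_amp_uv * prof_retinal
            elif cond == "background":
                wave += cfg.background_amp_uv * prof_background
            else:  # illusory = background + size-scaled late component
                wave += cfg.background_amp_uv * prof_background
                wave += cfg.late_gain_uv_per_deg * size * prof_late
            # contralateral hemisphere gets +wave/2, ipsilateral -wave/2 so
            # that (contra - ipsi) recovers the nominal amplitude exactly
            contra = idx_right if side == "left" else idx_left
            ipsi = idx_left if side == "left" else idx_right
            data[contra, :, sl.start:sl.stop] += (wave / 2.0)[None, :, None]
            data[ipsi, :, sl.start:sl.stop] -= (wave / 2.0)[None, :, None]
            tr += cfg.n_trials_per_cell

        if cfg.noise_white_sd_uv > 0:
            data += cfg.noise_white_sd_uv * rng.standard_normal(
                (n_ch, n_t, n_trials)
            ).astype(np.float32)
        if cfg.noise_pink_sd_uv > 0:
            pink = _pink_noise(rng, (n_ch, n_trials, n_t), n_t)
            data += cfg.noise_pink_sd_uv * np.transpose(pink, (0, 2, 1)).astype(
                np.float32
            )

        subjects.append(
            SubjectEpochs(
                data=data,
                times=times,
                srate=cfg.srate / cfg.decimate,
                channel_names=names,
                condition=cond_labels,
                side=side_labels,
                subject=f"s{si:02d}",
            )
        )
    from dataclasses import asdict

    return EEGStudy(subjects=subjects, illusion_sizes=sizes, config=asdict(cfg))
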