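"""ERP preprocessing, lateralized difference waves and time-resolved decoding.

The lateralized analyses exploit the fact that a bar flashed (or perceived)
left vs. right of fixation drives opposite hemispheres: subtracting the
ipsilateral from the contralateral member of homologous posterior electrode
pairs isolates side-specific processing and cancels everything bilateral.

Decoding follows the mini-ERP scheme: averaging k same-class trials into
one classifier sample suppresses trial noise by sqrt(k) (a 3-fold SNR gain
at k = 9) before a linear max-margin classifier is trained per time point
under stratified cross-validation.  Feature standardization is fit on
training samples only and applied to test samples, so no information leaks
across the fold boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .containers import DEFAULT_PAIRS, EEGStudy, SubjectEpochs, posterior_channels

__all__ = [
    "DiffWave",
    "DecodingTimecourse",
    "CrossDecodingMatrix",
    "preprocess_epochs",
    "select_c1_electrodes",
    "lateralized_difference",
    "lateralized_differences",
    "subtract_background",
    "make_mini_erps",
    "decode_timecourse",
    "cross_decode",
    "window_mean_amplitude",
    "intersubject_correlation",
]


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess_epochs(
    study: EEGStudy,
    *,
    l_freq: float = 1.0,
    h_freq: float = 35.0,
    reject_uv: float = 75.0,
    reject_window_ms: tuple[float, float] = (-100.0, 300.0),
    reject_channel: str = "VEO",
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    order: int = 4,
) -> tuple[EEGStudy, dict[str, int]]:
    """Band-pass filter, baseline-correct and artifact-reject all epochs.

    Per trial: zero-phase Butterworth band-pass (``l_freq``-``h_freq`` Hz,
    forward-backward so latencies are preserved), baseline correction over
    ``baseline_ms``, then rejection of trials whose absolute excursion at
    the ocular channel within ``reject_window_ms`` exceeds ``reject_uv``.

    Returns the cleaned study and a per-subject rejection count.
    """
    srate = study.subjects[0].srate
    nyq = srate / 2.0
    if not (0 < l_freq < h_freq < nyq):
        raise ValueError(
            f"band ({l_freq}-{h_freq} Hz) invalid for srate {srate} Hz"
        )
    sos = signal.butter(order, [l_freq, h_freq], btype="bandpass", fs=srate,
                        output="sos")
    log: dict[str, int] = {}
    cleaned = []
    for subj in study.subjects:
        if reject_channel not in subj.channel_names:
            raise ValueError(f"missing artifact channel {reject_channel!r}")
        times = subj.times
        t0, t1 = reject_window_ms
        if times[0] > t0 or times[-1] < t1:
            raise ValueError("epoch does not cover the rejection window")
        filt = signal.sosfiltfilt(sos, subj.data.astype(float), axis=1)
        b0, b1 = baseline_ms
        bmask = (times >= b0) & (times <= b1)
        if bmask.any():
            filt -= filt[:, bmask, :].mean(axis=1, keepdims=True)
        veo = filt[subj.channel_index(reject_channel)]
        wmask = (times >= t0) & (times <= t1)
        keep = np.abs(veo[wmask, :]).max(axis=0) <= reject_uv
        log[subj.subject] = int((~keep).sum())
        if not keep.any():
            raise ValueError(f"all trials rejected for subject {subj.subject}")
        cleaned.append(
            SubjectEpochs(
                data=filt[:, :, keep],
                times=times,
                srate=srate,
                channel_names=list(subj.channel_names),
                condition=subj.condition[keep],
                side=subj.side[keep],
                subject=subj.subject,
            )
        )
    out = EEGStudy(subjects=cleaned, illusion_sizes=study.illusion_sizes.copy(),
                   config=dict(study.config))
    return out, log


def select_c1_electrodes(
    grand_erps: np.ndarray,
    times: np.ndarray,
    channel_names: Sequence[str],
    n: int = 5,
    *,
    window_ms: tuple[float, float] = (60.0, 100.0),
    posterior: Sequence[str] | None = None,
) -> list[str]:
    """Pick the n electrodes with the largest C1 amplitude.

    Ranks posterior electrodes by absolute mean grand-ERP amplitude inside
    the C1 search window; ties break by channel-name order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grand_erps = np.asarray(grand_erps, dtype=float)
    names = list(channel_names)
    cand = list(posterior) if posterior is not None else posterior_channels(names)
    missing = [c for c in cand if c not in names]
    if missing:
        raise ValueError(f"posterior electrodes not in montage: {missing}")
    if n > len(cand):
        raise ValueError(f"requested {n} electrodes, only {len(cand)} posterior")
    mask = (np.asarray(times) >= window_ms[0]) & (np.asarray(times) <= window_ms[1])
    if not mask.any():
        raise ValueError("C1 window outside the epoch")
    scores = {
        c: abs(float(grand_erps[names.index(c), mask].mean())) for c in cand
    }
    ranked = sorted(cand, key=lambda c: (-scores[c], c))
    return ranked[:n]


# --------------------------------------------------------------------------
# lateralized difference waves
# --------------------------------------------------------------------------

@dataclass
class DiffWave:
    """Contralateral-minus-ipsilateral ERP difference wave (one subject)."""

    amplitude: np.ndarray
    times: np.ndarray
    electrodes_used: tuple[str, ...]
    correction: str = "raw"
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.amplitude.shape != self.times.shape:
            raise ValueError("amplitude and times must be aligned")


def _resolve_pairs(
    electrodes: Sequence[str], pairs: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Map selected electrodes onto homologous (left, right) pairs."""
    by_member: dict[str, tuple[str, str]] = {}
    for left, right in pairs:
        by_member[left] = (left, right)
        by_member[right] = (left, right)
    resolved = []
    for e in electrodes:
        if e not in by_member:
            raise ValueError(f"no homologous pairing defined for electrode {e!r}")
        p = by_member[e]
        if p not in resolved:
            resolved.append(p)
    return resolved


def lateralized_difference(
    subj: SubjectEpochs,
    condition: str,
    electrodes: Sequence[str] = ("P3", "P5", "PO5", "PO7", "O1"),
    *,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> DiffWave:
    """Condition-averaged contra-minus-ipsi wave over homologous pairs.

    The contralateral hemisphere is determined per trial from the trial's
    side label (left-side stimulus -> right hemisphere contralateral).
    """
    mask = subj.condition == condition
    if not mask.any():
        raise ValueError(f"no trials with condition {condition!r}")
    pair_list = _resolve_pairs(electrodes, pairs)
    li = [subj.channel_index(l) for l, _ in pair_list]
    ri = [subj.channel_index(r) for _, r in pair_list]
    data = subj.data[:, :, mask]
    sides = subj.side[mask]
    left_vals = data[li, :, :].mean(axis=0)   # (time, trials) over pairs
    right_vals = data[ri, :, :].mean(axis=0)
    is_left = sides == "left"
    # contra - ipsi per trial, then average over trials
    per_trial = np.where(is_left[None, :], right_vals - left_vals,
                         left_vals - right_vals)
    return DiffWave(
        amplitude=per_trial.mean(axis=1),
        times=subj.times,
        electrodes_used=tuple(e for p in pair_list for e in p),
        correction="raw",
        subject=subj.subject,
        condition=condition,
    )


def lateralized_differences(
    study: EEGStudy, condition: str, electrodes=("P3", "P5", "PO5", "PO7", "O1"),
    **kw,
) -> np.ndarray:
    """Stack per-subject difference waves into a (subjects x time) array."""
    return np.stack(
        [lateralized_difference(s, condition, electrodes, **kw).amplitude
         for s in study.subjects]
    )


def subtract_background(illusory: DiffWave, background: DiffWave) -> DiffWave:
    """Point-wise difference of two waves on the same time base."""
    if illusory.times.shape != background.times.shape or not np.allclose(
        illusory.times, background.times
    ):
        raise ValueError("time bases differ")
    return replace(
        illusory,
        amplitude=illusory.amplitude - background.amplitude,
        correction="background_subtracted",
    )


def window_mean_amplitude(wave: DiffWave, t0: float, t1: float) -> float:
    """Mean amplitude of a wave over the closed time window [t0, t1] ms."""
    mask = (wave.times >= t0) & (wave.times <= t1)
    if not mask.any():
        raise ValueError(f"no samples inside [{t0}, {t1}] ms")
    return float(wave.amplitude[mask].mean())


def intersubject_correlation(amplitudes, illusion_sizes) -> np.ndarray:
    """Pearson r across subjects between amplitude and illusion size, per time.

    ``amplitudes`` is subjects x time.  If illusion sizes have zero
    variance the correlation is undefined; NaNs are returned with a
    warning.
    """
    amp = np.asarray(amplitudes, dtype=float)
    sizes = np.asarray(illusion_sizes, dtype=float)
    if amp.ndim != 2 or amp.shape[0] != sizes.size:
        raise ValueError("amplitudes must be subjects x time, one size each")
    if amp.shape[0] < 3:
        raise ValueError("need >= 3 subjects for a correlation")
    s = sizes - sizes.mean()
    denom_s = np.sqrt((s**2).sum())
    if denom_s == 0:
        warnings.warn("illusion sizes have zero variance; r undefined",
                      stacklevel=2)
        return np.full(amp.shape[1], np.nan)
    a = amp - amp.mean(axis=0, keepdims=True)
    denom_a = np.sqrt((a**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * s[:, None]).sum(axis=0) / (denom_a * denom_s)
    return r


# --------------------------------------------------------------------------
# mini-ERP construction and decoding
# --------------------------------------------------------------------------

def make_mini_erps(
    trials: np.ndarray,
    labels: np.ndarray,
    k: int,
    n_samples: int,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Average k random same-class trials into mini-ERP samples.

    Parameters
    ----------
    trials : ndarray, trial axis last (e.g. channels x time x trials).
    labels : per-trial class labels.
    k : trials averaged per sample (drawn without replacement within a
        sample, independently across samples).
    n_samples : samples generated per class.  As a deterministic special
        case, ``k = 1`` with ``n_samples`` equal to the class trial count
        returns the raw trials of each class exactly once (in order).
    seed : int or numpy Generator/SeedSequence.

    Returns
    -------
    (samples, labels) with the sample axis last; class blocks are
    contiguous and balanced.
    """
    trials = np.asarray(trials)
    labels = np.asarray(labels)
    if labels.shape != (trials.shape[-1],):
        raise ValueError("labels must align with the trial axis")
    if k < 1 or n_samples < 1:
        raise ValueError("k and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    flat = trials.reshape(-1, trials.shape[-1])
    blocks, out_labels = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        m = idx.size
        if m < k:
            raise ValueError(f"class {cls!r} has {m} trials, fewer than k={k}")
        if k == 1 and n_samples == m:
            block = flat[:, idx]
        else:
            # each column of `weights` averages k distinct trials
            picks = np.argsort(rng.random((n_samples, m)), axis=1)[:, :k]
            weights = np.zeros((m, n_samples))
            weights[picks.ravel(), np.repeat(np.arange(n_samples), k)] = 1.0 / k
            block = flat[:, idx] @ weights
        blocks.append(block)
        out_labels.append(np.repeat(cls, n_samples if not (k == 1 and n_samples == m) else m))
    samples = np.concatenate(blocks, axis=1)
    samples = samples.reshape(trials.shape[:-1] + (samples.shape[-1],))
    return samples, np.concatenate(out_labels)


@dataclass
class DecodingTimecourse:
    """Cross-validated decoding accuracy per time point."""

    accuracy: np.ndarray          # mean over subjects, per time point
    per_subject: np.ndarray       # subjects x time
    times: np.ndarray
    n_folds: int
    k: int
    n_samples: int


def _fit_predict_time(
    train_x: np.ndarray, train_y: np.ndarray,
    test_x: np.ndarray, test_y: np.ndarray, C: float,
) -> float:
    scaler = StandardScaler().fit(train_x)
    clf = LinearSVC(C=C, dual=False)
    clf.fit(scaler.transform(train_x), train_y)
    return float(clf.score(scaler.transform(test_x), test_y))


def decode_timecourse(
    study: EEGStudy,
    condition: str,
    k: int = 9,
    n_samples: int = 1000,
    folds: int = 10,
    C: float = 1.0,
    seed=0,
    *,
    exclude_channels: Sequence[str] = ("VEO", "HEO"),
) -> DecodingTimecourse:
    """Per-time-point left/right decoding with mini-ERP samples.

    For each subject the condition's raw trials are split with stratified
    k-fold CV; mini-ERPs are built independently inside the training and
    test portions of every fold; features (electrodes) are standardized
    with training-set statistics; a linear max-margin classifier (C as
    given) is fitted at every time point and scored on the held-out
    mini-ERPs.  Accuracies are averaged over folds, then over subjects.
    """
    from sklearn.model_selection import StratifiedKFold

    streams = np.random.SeedSequence(seed).spawn(study.n_subjects)
    times = study.times
    n_t = times.size
    acc = np.zeros((study.n_subjects, n_t))
    for si, (subj, ss) in enumerate(zip(study.subjects, streams)):
        rng = np.random.default_rng(ss)
        mask = subj.condition == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        ch_keep = [i for i, c in enumerate(subj.channel_names)
                   if c not in exclude_channels]
        data = subj.data[ch_keep, :, :][:, :, mask].astype(float)
        y = subj.side[mask].astype(str)
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        fold_acc = np.zeros((folds, n_t))
        for fi, (tr, te) in enumerate(skf.split(y, y)):
            tr_x, tr_y = make_mini_erps(data[:, :, tr], y[tr], k, n_samples,
                                        rng.spawn(1)[0])
            te_x, te_y = make_mini_erps(data[:, :, te], y[te], k,
                                        n_samples, rng.spawn(1)[0])
            for ti in range(n_t):
                fold_acc[fi, ti] = _fit_predict_time(
                    tr_x[:, ti, :].T, tr_y, te_x[:, ti, :].T, te_y, C
                )
        acc[si] = fold_acc.mean(axis=0)
    return DecodingTimecourse(
        accuracy=acc.mean(axis=0), per_subject=acc, times=times,
        n_folds=folds, k=k, n_samples=n_samples,
    )


@dataclass
class CrossDecodingMatrix:
    """Train-time x test-time accuracy matrix across conditions."""

    accuracy: np.ndarray          # train_time x test_time, mean over subjects
    per_subject: np.ndarray       # subjects x train_time x test_time
    time_grid: np.ndarray
    train_condition: str
    test_condition: str


def cross_decode(
    study: EEGStudy,
    cond_train: str,
    cond_test: str,
    *,
    decimate: int = 10,
    folds: int = 10,
    C: float = 1.0,
    seed=0,
    exclude_channels: Sequence[str] = ("VEO", "HEO"),
) -> CrossDecodingMatrix:
    """Temporal generalization: train at one time, test at another.

    Raw single trials are used (k = 1) on a time grid decimated by
    ``decimate``.  Across distinct conditions the classifier trains on all
    trials of ``cond_train`` and tests on all trials of ``cond_test``;
    within one condition, stratified folds keep every matrix entry free of
    train/test leakage.
    """
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    grid_idx = np.arange(0, study.times.size, decimate)
    if grid_idx.size == 0:
        raise ValueError("empty time grid")
    grid = study.times[grid_idx]
    n_g = grid.size
    streams = np.random.SeedSequence(seed).spawn(study.n_subjects)
    per_subj = np.zeros((study.n_subjects, n_g, n_g))
    for si, (subj, ss) in enumerate(zip(study.subjects, streams)):
        rng = np.random.default_rng(ss)
        ch_keep = [i for i, c in enumerate(subj.channel_names)
                   if c not in exclude_channels]
        data = subj.data[ch_keep][:, grid_idx, :].astype(float)

        def cond_xy(cond):
            m = subj.condition == cond
            if not m.any():
                raise ValueError(f"no trials with condition {cond!r}")
            return data[:, :, m], subj.side[m].astype(str)

        if cond_train != cond_test:
            xa, ya = cond_xy(cond_train)
            xb, yb = cond_xy(cond_test)
            per_subj[si] = _generalize(xa, ya, xb, yb, C)
        else:
            from sklearn.model_selection import StratifiedKFold

            x, y = cond_xy(cond_train)
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            mats = [
                _generalize(x[:, :, tr], y[tr], x[:, :, te], y[te], C)
                for tr, te in skf.split(y, y)
            ]
            per_subj[si] = np.mean(mats, axis=0)
    return CrossDecodingMatrix(
        accuracy=per_subj.mean(axis=0), per_subject=per_subj,
        time_grid=grid, train_condition=cond_train, test_condition=cond_test,
    )


def _generalize(train_x, train_y, test_x, test_y, C) -> np.ndarray:
    """Accuracy matrix over (train time, test time) for fixed trial sets."""
    n_g = train_x.shape[1]
    out = np.zeros((n_g, n_g))
    for ta in range(n_g):
        scaler = StandardScaler().fit(train_x[:, ta, :].T)
        clf = LinearSVC(C=C, dual=False)
        clf.fit(scaler.transform(train_x[:, ta, :].T), train_y)
        for tb in range(n_g):
            out[ta, tb] = clf.score(scaler.transform(test_x[:, tb, :].T), test_y)
    return out
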