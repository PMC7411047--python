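"""Psychometric-function fitting, tilt-aftereffect estimation and group stats.

The observer model is a four-parameter logistic,

    p(x) = gamma + (1 - lambda - gamma) / (1 + exp(-beta (x - alpha))),

fitted by least squares to per-angle response proportions (the quantity the
experiments plot), not by trial-level likelihood.  The point of subjective
equality (PSE) is defined as ``alpha``, the logistic's inflection; note this
differs from the x where p = 0.5 whenever gamma != lambda.  The tilt
aftereffect (TAE) is half the distance between the PSEs measured after
adaptation in the two opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import ObserverParams

__all__ = [
    "DegenerateDataError",
    "PsychometricModel",
    "PsychometricFit",
    "TAEResult",
    "AdjustmentSummary",
    "fit_psychometric",
    "pse",
    "tae_magnitude",
    "summarize_adjustments",
    "paired_t_and_d",
    "holm_adjust",
]


class DegenerateDataError(ValueError):
    """Raised when the response data cannot constrain the psychometric fit."""


def logistic4(x, alpha: float, beta: float, gamma: float, lapse: float):
    """Four-parameter logistic psychometric function."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-beta * (x - alpha), -700, 700)
    return gamma + (1.0 - lapse - gamma) / (1.0 + np.exp(z))


@dataclass
class PsychometricFit:
    """Fitted psychometric parameters with diagnostics.

    ``alpha`` (deg) is the PSE, ``beta`` (1/deg) the slope, ``gamma`` and
    ``lapse`` the asymptote parameters.  ``residual_ss`` is the sum of
    squared deviations between observed and fitted per-angle proportions.
    """

    alpha: float
    beta: float
    gamma: float
    lapse: float
    residual_ss: float
    converged: bool
    n_angles: int = 0
    n_trials: int = 0
    subject: str = ""
    condition: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.lapse])

    def predict(self, x):
        """Fitted probability of an upward response at test angle(s) x."""
        return logistic4(x, self.alpha, self.beta, self.gamma, self.lapse)

    def summary(self) -> str:
        rows = [
            ("PSE alpha (deg)", self.alpha),
            ("slope beta (1/deg)", self.beta),
            ("lower asymptote gamma", self.gamma),
            ("lapse lambda", self.lapse),
            ("residual SS", self.residual_ss),
        ]
        head = "Psychometric fit"
        if self.subject or self.condition:
            head += f"  [{self.subject} {self.condition}]".rstrip()
        lines = [head, "-" * 34]
        lines += [f"{name:<24s}{val: .4f}" for name, val in rows]
        lines.append(f"{'angles / trials':<24s} {self.n_angles} / {self.n_trials}")
        lines.append(f"{'converged':<24s} {self.converged}")
        return "\n".join(lines)


class PsychometricModel:
    """Least-squares psychometric model over per-angle response proportions.

    Parameters
    ----------
    angles : array-like
        Distinct test angles, degrees.
    prop_upward : array-like
        Observed proportion of upward responses at each angle.
    n_trials : array-like, optional
        Trials per angle (diagnostics only; the fit is unweighted, matching
        a balanced design).
    """

    #: parameter bounds: alpha free within the extended test range, beta in
    #: (0, 100].  The guess/lapse parameters are restricted to [0, 0.06]
    #: (standard practice for psychometric fitting): with only a handful of
    #: test angles, wide asymptote bounds let gamma/lambda absorb response
    #: structure and destroy the identifiability of the PSE.
    BETA_MAX = 100.0
    ASYMPTOTE_MAX = 0.06

    def __init__(self, angles, prop_upward, n_trials=None, *,
                 subject: str = "", condition: str = ""):
        self.angles = np.asarray(angles, dtype=float)
        self.prop = np.asarray(prop_upward, dtype=float)
        if self.angles.ndim != 1 or self.angles.shape != self.prop.shape:
            raise ValueError("angles and prop_upward must be 1-D and aligned")
        if np.unique(self.angles).size < 4:
            raise ValueError("need >= 4 distinct test angles")
        if np.any((self.prop < 0) | (self.prop > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if np.all(self.prop == self.prop[0]):
            raise DegenerateDataError(
                "all response proportions identical "
                f"({self.prop[0]:.3f}); psychometric slope is unidentified"
            )
        self.n_trials = (
            np.asarray(n_trials, dtype=int)
            if n_trials is not None
            else np.zeros_like(self.angles, dtype=int)
        )
        self.subject = subject
        self.condition = condition

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, *, angle_col: str = "test_angle",
                    response_col: str = "response_upward") -> "PsychometricModel":
        """Build the model from a per-trial table (one 0/1 row per trial)."""
        for col in (angle_col, response_col):
            if col not in trials.columns:
                raise ValueError(f"trial table lacks column {col!r}")
        grouped = trials.groupby(angle_col)[response_col].agg(["mean", "count"])
        subject = str(trials["subject"].iloc[0]) if "subject" in trials else ""
        condition = str(trials["condition"].iloc[0]) if "condition" in trials else ""
        return cls(
            grouped.index.to_numpy(),
            grouped["mean"].to_numpy(),
            grouped["count"].to_numpy(),
            subject=subject,
            condition=condition,
        )

    # -- fitting ------------------------------------------------------------

    def _starts(self) -> list[np.ndarray]:
        qs = np.quantile(self.angles, [0.25, 0.5, 0.75])
        starts = []
        for a0 in qs:
            for b0 in (0.5, 2.0, 8.0):
                starts.append(np.array([a0, b0, 0.02, 0.02]))
        return starts

    def fit(self, *, ss_tol: float = 1e-8) -> PsychometricFit:
        """Multi-start bounded least squares over (alpha, beta, gamma, lambda).

        The best run is kept (ties broken by lowest residual SS, then by
        smallest ``|alpha|``); ``converged`` reports the optimizer status of
        that run.
        """
        span = self.angles.max() - self.angles.min()
        lo = np.array([self.angles.min() - 2 * span, 1e-3, 0.0, 0.0])
        hi = np.array([self.angles.max() + 2 * span, self.BETA_MAX,
                       self.ASYMPTOTE_MAX, self.ASYMPTOTE_MAX])

        x = self.angles

        def resid(p):
            return logistic4(x, *p) - self.prop

        def jac(p):
            alpha, beta, gamma, lapse = p
            z = np.clip(-beta * (x - alpha), -700, 700)
            s = 1.0 / (1.0 + np.exp(z))
            core = (1.0 - lapse - gamma) * s * (1.0 - s)
            return np.column_stack(
                [-beta * core, (x - alpha) * core, 1.0 - s, -s]
            )

        best = None
        for x0 in self._starts():
            sol = optimize.least_squares(
                resid, x0, jac=jac, bounds=(lo, hi),
                ftol=ss_tol, xtol=1e-9, gtol=1e-9, max_nfev=200,
            )
            ss = float(2.0 * sol.cost)
            cand = (ss, abs(sol.x[0]), sol)
            if best is None or cand[:2] < best[:2]:
                best = cand
        ss, _, sol = best
        alpha, beta, gamma, lapse = sol.x
        # an essentially interpolating solution is converged even if the
        # optimizer ran out of iterations wandering its flat manifold
        converged = bool(sol.success) or ss <= 1e-10
        return PsychometricFit(
            alpha=float(alpha),
            beta=float(beta),
            gamma=float(gamma),
            lapse=float(lapse),
            residual_ss=ss,
            converged=converged,
            n_angles=int(self.angles.size),
            n_trials=int(self.n_trials.sum()),
            subject=self.subject,
            condition=self.condition,
        )


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Fit the logistic psychometric function to a per-trial 2AFC table."""
    return PsychometricModel.from_trials(trials).fit()


def pse(fit: PsychometricFit) -> float:
    """Point of subjective equality: the fitted inflection ``alpha``.

    Refuses non-converged fits — their location parameter is not trustworthy.
    """
    if not fit.converged:
        raise ValueError(
            "fit did not converge (residual_ss="
            f"{fit.residual_ss:.3g}); PSE unavailable"
        )
    return fit.alpha


@dataclass(frozen=True)
class TAEResult:
    """Tilt-aftereffect magnitude for one subject/condition."""

    tae: float
    pse_positive: float
    pse_negative: float
    subject: str = ""
    condition: str = ""


def tae_magnitude(fit_pos: PsychometricFit, fit_neg: PsychometricFit) -> TAEResult:
    """TAE = half the PSE distance between opposite adaptation directions."""
    p_pos, p_neg = pse(fit_pos), pse(fit_neg)
    return TAEResult(
        tae=abs(p_pos - p_neg) / 2.0,
        pse_positive=p_pos,
        pse_negative=p_neg,
        subject=fit_pos.subject,
        condition=fit_pos.condition,
    )


@dataclass(frozen=True)
class AdjustmentSummary:
    """Group summary of the pointer-adjustment illusion-size task."""

    mean_tilt: float
    sd: float
    n_subjects: int
    subject_means: tuple[float, ...] = ()


def summarize_adjustments(table: pd.DataFrame) -> AdjustmentSummary:
    """Group mean/SD of perceived tilt from signed adjustment settings.

    Settings are sign-aligned by rotation direction (counter-clockwise
    settings are negated) and averaged within subject; the summary is the
    mean and SD across subject means.  Subjects missing either rotation
    direction are excluded with a warning.
    """
    import warnings

    required = {"subject", "direction", "setting_deg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"adjustment table lacks columns {sorted(missing)}")
    sign = table["direction"].map({"cw": 1.0, "ccw": -1.0})
    if sign.isna().any():
        bad = sorted(table.loc[sign.isna(), "direction"].unique())
        raise ValueError(f"unknown rotation directions: {bad}")
    aligned = table.assign(aligned=sign * table["setting_deg"])

    means = []
    for subj, grp in aligned.groupby("subject"):
        dirs = set(grp["direction"])
        if len(dirs) < 2:
            warnings.warn(
                f"subject {subj} has settings for only {sorted(dirs)}; excluded",
                stacklevel=2,
            )
            continue
        means.append(float(grp["aligned"].mean()))
    if not means:
        raise ValueError("no subject with settings in both rotation directions")
    arr = np.asarray(means)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AdjustmentSummary(
        mean_tilt=float(arr.mean()),
        sd=sd,
        n_subjects=arr.size,
        subject_means=tuple(arr),
    )


def paired_t_and_d(x, y):
    """Two-sided paired t test with Cohen's d on the differences.

    Returns ``(t, df, p, d)`` where ``d = mean(x - y) / sd(x - y)``.
    Zero-variance differences yield an infinite t (flagged by the inf
    value itself) and an undefined-d of ±inf, with p = 0 unless the mean
    difference is also zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 2")
    diff = x - y
    df = diff.size - 1
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, df, 1.0, 0.0
        t = np.inf * np.sign(diff.mean())
        return float(t), df, 0.0, float(t)
    res = stats.ttest_rel(x, y)
    d = float(diff.mean() / sd)
    return float(res.statistic), df, float(res.pvalue), d


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="holm")[1]
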