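"""Peak functions and the five-parameter generalized-Gaussian fit.

Probe-trial responses are grouped into uniform time bins (1 s by default)
and averaged over trials into a "peak function" — mean response rate as a
function of time since cue onset.  Each peak function is fit with

    y(t) = B + S · exp(−½ · (|t − PT| / SP)^K)

where B is the baseline rate, S the scale, PT the mode (taken as the peak
time), SP the spread, and K a kurtosis exponent (K = 2 recovers the
ordinary Gaussian).  The coefficient of variation CV = SP / PT; its
constancy across trained intervals is the scalar property.

Fitting is deterministic: a fixed initialization plus a small multi-start
schedule over K, no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import AnalysisConfig, Dataset, TrialRecord


class EmptySelectionError(ValueError):
    """No qualifying probe trials for the requested subject/cue/phase."""


class UnfittableError(ValueError):
    """Peak function has no signal to fit (all-zero rates)."""


@dataclass
class PeakFunction:
    """Mean response rate in uniform bins over probe trials for one cell."""

    subject_id: str
    cue_id: str
    phase: str
    context: str
    bin_edges: np.ndarray      # length n_bins + 1, uniform
    rate: np.ndarray           # responses/s per bin
    n_trials: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GGaussFit:
    """Fitted generalized-Gaussian parameters with derived peak time and CV."""

    B: float
    S: float
    PT: float
    SP: float
    K: float
    sse: float
    converged: bool
    n_trials: int = 0

    @property
    def peak_time(self) -> float:
        # The model is symmetric in |t − PT|, so its mode is PT exactly.
        return self.PT

    @property
    def cv(self) -> float:
        return self.SP / self.PT


def gg_model(t, B: float, S: float, PT: float, SP: float, K: float):
    """Evaluate B + S·exp(−½·(|t − PT|/SP)^K)."""
    if SP <= 0:
        raise ValueError("SP must be > 0")
    if K <= 0:
        raise ValueError("K must be > 0")
    t = np.asarray(t, dtype=float)
    return B + S * np.exp(-0.5 * (np.abs(t - PT) / SP) ** K)


def _passes_cutoff(trial: TrialRecord, cutoff: Optional[float]) -> bool:
    if cutoff is None:
        return True
    fr = trial.first_response
    return fr is not None and fr < cutoff


def select_probe_trials(
    dataset: Dataset,
    subject_id: str,
    cue_id: str,
    phase: str,
    config: AnalysisConfig,
    context: Optional[str] = None,
) -> list[TrialRecord]:
    """Probe trials for one analysis cell, with session matching and cutoff.

    When ``phase == "train"`` only the final ``sessions_per_phase`` training
    sessions contribute, matching the number of test sessions (inferred from
    the data when the config leaves it unset).
    """
    trials = dataset.select(
        subject_id=subject_id, cue_id=cue_id, phase=phase,
        context=context, trial_type="probe",
    )
    if phase == "train":
        k = config.sessions_per_phase
        if k is None:
            n_test = len(dataset.sessions("test"))
            k = max(n_test, 1)
        sessions = sorted({t.session for t in trials})[-k:]
        trials = [t for t in trials if t.session in sessions]
    return [t for t in trials if _passes_cutoff(t, config.early_response_cutoff)]


def bin_probe_responses(
    dataset: Dataset,
    subject_id: str,
    cue_id: str,
    phase: str,
    config: Optional[AnalysisConfig] = None,
    context: Optional[str] = None,
) -> PeakFunction:
    """Average probe-trial responding into a :class:`PeakFunction`.

    Bins are half-open [b, b + width) from cue onset; the number of bins is
    floor(min contributing probe length / width), so every contributing
    trial covers every bin.  Bin rate = total responses in the bin across
    trials / (n_trials × width); trials with zero responses still count in
    the denominator.
    """
    config = config or AnalysisConfig()
    trials = select_probe_trials(dataset, subject_id, cue_id, phase, config, context)
    if not trials:
        raise EmptySelectionError(
            f"no qualifying probe trials for ({subject_id}, {cue_id}, {phase})"
        )
    bw = config.bin_width
    n_bins = int(np.floor(min(t.probe_duration for t in trials) / bw))
    if n_bins < 1:
        raise EmptySelectionError("probe trials shorter than one bin")
    edges = np.arange(n_bins + 1, dtype=float) * bw
    counts = np.zeros(n_bins)
    for t in trials:
        r = t.responses
        idx = np.floor(r / bw).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1.0)
    rate = counts / (len(trials) * bw)
    ctx = context if context is not None else trials[0].context
    return PeakFunction(subject_id, cue_id, phase, ctx, edges, rate, len(trials))


class GeneralizedGaussianRegressor(BaseEstimator, RegressorMixin):
    """Least-squares fit of the five-parameter generalized Gaussian.

    scikit-learn-style estimator: ``fit(X, y)`` takes times (n, 1) or (n,)
    and rates; fitted attributes are ``baseline_``, ``scale_``,
    ``peak_time_``, ``spread_``, ``exponent_``, ``cv_``, ``sse_`` and
    ``converged_``.

    Parameters
    ----------
    exponent_starts : sequence of float
        Multi-start values for K.  The best (lowest SSE) solution wins;
        the schedule is fixed, so fitting is deterministic.
    exponent_bounds, max_nfev : optimizer bounds for K and iteration cap.
    """

    def __init__(
        self,
        exponent_starts: Sequence[float] = (1.0, 2.0, 4.0),
        exponent_bounds: tuple[float, float] = (0.5, 10.0),
        max_nfev: int = 2000,
    ):
        self.exponent_starts = exponent_starts
        self.exponent_bounds = exponent_bounds
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = check_array(X, ensure_2d=False, dtype=float)
        t = X.ravel() if X.ndim > 1 else X
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        if t.size < 10:
            raise ValueError("need at least 10 points to fit five parameters")
        if not np.any(y > 0):
            raise UnfittableError("all-zero rates cannot be fit")

        t_end = float(t.max())
        ymax, ymin = float(y.max()), float(y.min())
        pt0 = float(t[int(np.argmax(y))])
        b0 = ymin
        s0 = max(ymax - ymin, 1e-6)
        sp0 = _half_width_at_half_height(t, y, pt0) or t_end / 8.0

        lo = np.array([0.0, 1e-9, 0.0, 1e-6, self.exponent_bounds[0]])
        hi = np.array([ymax, 2.0 * ymax, t_end, t_end, self.exponent_bounds[1]])

        best = None
        for k0 in self.exponent_starts:
            x0 = np.clip(np.array([b0, s0, pt0, sp0, k0]), lo, hi)
            res = least_squares(
                lambda p: gg_model(t, *p) - y,
                x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=self.max_nfev,
            )
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[0]:
                best = (sse, res)
        sse, res = best

        self.baseline_, self.scale_, self.peak_time_, self.spread_, self.exponent_ = (
            float(v) for v in res.x
        )
        self.cv_ = self.spread_ / self.peak_time_ if self.peak_time_ > 0 else np.nan
        self.sse_ = sse
        self.converged_ = bool(res.success)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "peak_time_")
        X = check_array(X, ensure_2d=False, dtype=float)
        t = X.ravel() if X.ndim > 1 else X
        return gg_model(t, self.baseline_, self.scale_, self.peak_time_,
                        self.spread_, self.exponent_)


def _half_width_at_half_height(t: np.ndarray, y: np.ndarray, pt0: float) -> Optional[float]:
    half = 0.5 * (y.max() + y.min())
    above = np.where(y >= half)[0]
    if above.size < 2:
        return None
    width = t[above[-1]] - t[above[0]]
    return max(width / 2.0, 1e-3)


def fit_peak(pf: PeakFunction, options: Optional[dict] = None) -> GGaussFit:
    """Fit a :class:`PeakFunction`, returning a :class:`GGaussFit`.

    Thin wrapper over :class:`GeneralizedGaussianRegressor` fit to
    bin-center/rate pairs.
    """
    reg = GeneralizedGaussianRegressor(**(options or {}))
    reg.fit(pf.bin_centers, pf.rate)
    return GGaussFit(
        B=reg.baseline_, S=reg.scale_, PT=reg.peak_time_, SP=reg.spread_,
        K=reg.exponent_, sse=reg.sse_, converged=reg.converged_,
        n_trials=pf.n_trials,
    )


def normalize_for_display(pf: PeakFunction, window: int = 6) -> PeakFunction:
    """Display-only transform: divide by the maximum, then smooth.

    Smoothing is an edge-corrected moving average over ``window`` bins
    (kernel coverage renormalized at the edges, so a constant input stays
    constant).  For the even default window the kernel for bin i spans bins
    [i − window//2 + 1, i + window//2] (numpy 'same' alignment).  Never feed
    the output to :func:`fit_peak` or to any statistic.
    """
    m = float(pf.rate.max())
    if m <= 0:
        raise UnfittableError("all-zero peak function cannot be normalized")
    norm = pf.rate / m
    kernel = np.ones(window)
    smooth = np.convolve(norm, kernel, mode="same") / np.convolve(
        np.ones_like(norm), kernel, mode="same"
    )
    return PeakFunction(
        pf.subject_id, pf.cue_id, pf.phase, pf.context,
        pf.bin_edges.copy(), smooth, pf.n_trials,
    )
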