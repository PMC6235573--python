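"""Grid-based Bayes factors for the no-shift null hypothesis.

Following the Gallistel-style recipe: per-subject percent changes are given
normal likelihoods with a common SD (pooled within-group across the data
and reference groups); the product over subjects, normalized on a uniform
θ-grid, is the group marginal likelihood L(θ|D).  The null prior is the
same construction after subtracting the sample mean (mean-zero by design).
Two alternative priors are supported:

* *incremental* — a uniform density spanning ± the largest absolute shift
  in the reference group, convolved with the null prior (a shift of any
  sign and plausible size occurred);
* *reference* — the reference group's own marginal likelihood (the data
  shifted exactly like the group that was expected to shift).

The Bayes factor is the ratio of the null and alternative marginals
Σ L(θ)π(θ)·step; values > 1 favor "no shift", with heuristic evidence
bands > 3 substantial, > 10 strong, > 100 decisive.  Everything here is
deterministic: no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

DEFAULT_STEP = 0.05          # grid resolution in percent-change units
TAIL_TOLERANCE = 1e-9        # max truncated probability mass before widening
_MARGIN_SDS = 8.0


class GridError(ValueError):
    """The θ-grid truncates probability mass; widen and retry."""


@dataclass
class ThetaGrid:
    """Uniform grid over percent-change values θ."""

    theta: np.ndarray
    step: float

    def __post_init__(self) -> None:
        d = np.diff(self.theta)
        if self.theta.size < 2 or np.any(d <= 0):
            raise ValueError("theta must be strictly increasing")
        if not np.allclose(d, self.step, rtol=0, atol=1e-9):
            raise ValueError("theta must be uniformly spaced at `step`")

    @classmethod
    def span(cls, lo: float, hi: float, step: float = DEFAULT_STEP) -> "ThetaGrid":
        n = int(np.ceil((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n), step)

    def same_as(self, other: "ThetaGrid") -> bool:
        return (
            self.theta.size == other.theta.size
            and abs(self.step - other.step) < 1e-12
            and np.allclose(self.theta, other.theta, rtol=0, atol=1e-9)
        )


@dataclass
class LikelihoodGrid:
    grid: ThetaGrid
    values: np.ndarray          # density: sum(values)·step == 1
    source: str = "data_group"


@dataclass
class Prior:
    grid: ThetaGrid
    values: np.ndarray
    kind: str                   # null | incremental | reference


@dataclass
class BFResult:
    """Bayes factor with its two marginals and provenance."""

    marginal_null: float
    marginal_alt: float
    bf: float
    grid_lo: float
    grid_hi: float
    grid_step: float
    provenance: dict = field(default_factory=dict)

    @property
    def band(self) -> str:
        if self.bf > 100:
            return "decisive"
        if self.bf > 10:
            return "strong"
        if self.bf > 3:
            return "substantial"
        if self.bf > 1:
            return "anecdotal"
        return "favors-alternative"


def pooled_sd(
    values_a: Sequence[float], values_b: Sequence[float], method: str = "pooled_within"
) -> float:
    """Common SD across two groups of per-subject percent changes.

    ``pooled_within`` (default) is the df-weighted within-group SD
    sqrt(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)), which does not inflate
    with the between-group mean difference; ``concatenated`` is the plain
    SD of the merged values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    if method == "pooled_within":
        df = a.size + b.size - 2
        s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        sd = float(np.sqrt(s2))
    elif method == "concatenated":
        sd = float(np.concatenate([a, b]).std(ddof=1))
    else:
        raise ValueError(f"unknown sd method {method!r}")
    if sd == 0.0:
        raise ValueError("degenerate zero pooled SD")
    return sd


def make_grid(
    construction_values: Sequence[float],
    sd: float,
    n: int,
    halfwidth: float = 0.0,
    step: float = DEFAULT_STEP,
) -> ThetaGrid:
    """Grid covering every construction input with wide normal margins.

    The margin 8·sd·max(1, √n) dwarfs the width sd/√n of any group marginal
    likelihood built from n subjects; the incremental halfwidth is added on
    both sides so the convolution support fits.
    """
    v = np.asarray(construction_values, dtype=float)
    margin = _MARGIN_SDS * sd * max(1.0, np.sqrt(n)) + halfwidth
    return ThetaGrid.span(float(v.min()) - margin, float(v.max()) + margin, step)


def marginal_likelihood(
    values: Sequence[float],
    sd: float,
    grid: ThetaGrid,
    source: str = "data_group",
) -> LikelihoodGrid:
    """Normalized product of per-subject normal likelihoods on the grid.

    Computed in log space (sum of log-likelihoods over subjects per θ),
    exponentiated against the maximum, and normalized so the values
    integrate (sum × step) to 1.  Raises :class:`GridError` when more than
    ``TAIL_TOLERANCE`` of the mass would fall outside the grid — the
    product of normals is itself normal, so the truncated mass has a closed
    form.
    """
    v = np.asarray(values, dtype=float)
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if v.size == 0:
        raise ValueError("need at least one value")

    # Analytic tail check: the product is ∝ Normal(mean(v), sd/√n).
    mu, se = float(v.mean()), sd / np.sqrt(v.size)
    tail = stats.norm.cdf(grid.theta[0], mu, se) + stats.norm.sf(grid.theta[-1], mu, se)
    if tail > TAIL_TOLERANCE:
        raise GridError(
            f"grid truncates {tail:.2e} of likelihood mass (limit {TAIL_TOLERANCE})"
        )

    log_l = -0.5 * np.sum(
        ((v[:, None] - grid.theta[None, :]) / sd) ** 2, axis=0
    )
    w = np.exp(log_l - log_l.max())
    dens = w / (w.sum() * grid.step)
    return LikelihoodGrid(grid=grid, values=dens, source=source)


def null_prior(values: Sequence[float], sd: float, grid: ThetaGrid) -> Prior:
    """Marginal likelihood of the mean-centered data (mean-zero null prior)."""
    v = np.asarray(values, dtype=float)
    ml = marginal_likelihood(v - v.mean(), sd, grid)
    return Prior(grid=grid, values=ml.values, kind="null")


def incremental_prior(null: Prior, halfwidth: float) -> Prior:
    """Uniform(−halfwidth, +halfwidth) convolved with the null prior.

    ``halfwidth`` is the largest absolute per-subject percent change in the
    reference group (computed by the caller); 0 reduces to the null prior.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    step = null.grid.step
    n_half = int(round(halfwidth / step))
    if n_half == 0:
        return Prior(grid=null.grid, values=null.values.copy(), kind="incremental")
    # trapezoid end-weights: the discrete kernel integrates the continuous
    # uniform on [-halfwidth, +halfwidth] to O(step^2)
    kernel = np.ones(2 * n_half + 1)
    kernel[0] = kernel[-1] = 0.5
    kernel /= kernel.sum()
    full = np.convolve(null.values, kernel, mode="full")
    # center-crop back onto the original grid; discarded tails must be tiny
    vals = full[n_half:-n_half]
    lost = (full.sum() - vals.sum()) * step
    if lost > TAIL_TOLERANCE:
        raise GridError(
            f"incremental prior support overflows grid by mass {lost:.2e}"
        )
    vals = vals / (vals.sum() * step)
    return Prior(grid=null.grid, values=vals, kind="incremental")


def reference_prior(
    reference_values: Sequence[float], sd: float, grid: ThetaGrid
) -> Prior:
    """Marginal likelihood of the reference (expected-to-shift) group."""
    ml = marginal_likelihood(reference_values, sd, grid, source="reference_group")
    return Prior(grid=grid, values=ml.values, kind="reference")


def bayes_factor(likelihood: LikelihoodGrid, null: Prior, alt: Prior) -> BFResult:
    """Ratio of areas: BF = Σ L·π_null·step / Σ L·π_alt·step.

    BF > 1 favors the no-shift null; identical prior arrays give BF = 1
    exactly.
    """
    if not (likelihood.grid.same_as(null.grid) and likelihood.grid.same_as(alt.grid)):
        raise ValueError("likelihood and priors must share one grid")
    step = likelihood.grid.step
    m_null = float(np.sum(likelihood.values * null.values) * step)
    m_alt = float(np.sum(likelihood.values * alt.values) * step)
    if m_alt == 0.0:
        raise ZeroDivisionError("alternative marginal underflowed to exact zero")
    bf = 1.0 if np.array_equal(null.values, alt.values) else m_null / m_alt
    return BFResult(
        marginal_null=m_null,
        marginal_alt=m_alt,
        bf=bf,
        grid_lo=float(likelihood.grid.theta[0]),
        grid_hi=float(likelihood.grid.theta[-1]),
        grid_step=step,
        provenance={"null_kind": null.kind, "alt_kind": alt.kind},
    )


def no_shift_evidence(
    data_values: Sequence[float],
    reference_values: Sequence[float],
    prior: str = "incremental",
    sd_method: str = "pooled_within",
    step: float = DEFAULT_STEP,
    max_widen: int = 4,
) -> BFResult:
    """Full no-shift analysis for one group against a reference group.

    Builds the pooled SD, a grid covering all construction inputs (data,
    centered data, reference values), the group likelihood, the mean-zero
    null prior and the requested alternative prior, then returns the
    Bayes factor.  On a tail-mass violation the grid is widened and the
    computation retried.
    """
    data = np.asarray(data_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    sd = pooled_sd(data, ref, method=sd_method)
    halfwidth = float(np.max(np.abs(ref))) if prior == "incremental" else 0.0
    inputs = np.concatenate([data, data - data.mean(), ref])
    n = max(data.size, ref.size)

    widen = 1.0
    for _ in range(max_widen + 1):
        try:
            grid = make_grid(inputs, sd * widen, n, halfwidth=halfwidth, step=step)
            like = marginal_likelihood(data, sd, grid)
            null = null_prior(data, sd, grid)
            if prior == "incremental":
                alt = incremental_prior(null, halfwidth)
            elif prior == "reference":
                alt = reference_prior(ref, sd, grid)
            else:
                raise ValueError(f"unknown prior kind {prior!r}")
            result = bayes_factor(like, null, alt)
            result.provenance.update(
                {
                    "sd": sd,
                    "sd_method": sd_method,
                    "prior": prior,
                    "halfwidth": halfwidth,
                    "n_data": int(data.size),
                    "n_reference": int(ref.size),
                }
            )
            return result
        except GridError:
            widen *= 2.0
    raise GridError("grid still truncates mass after widening retries")
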