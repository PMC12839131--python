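"""Four-parameter logistic dose-response fitting and censored IC50 reporting.

The model is ``response(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``
fitted by least squares on the per-concentration mean responses, with the
midpoint parameterised as log10(ic50) for numerical stability and a small
multi-start over jittered initial guesses.  An IC50 is reported as

* ``definite`` — converged, inside the tested range, and the response
  actually crossed half-maximum;
* ``greater_than`` the top tested dose — curve right-shifted or too shallow
  to cross half-maximum in range;
* ``not_determinable`` — too few points, fit failure, or upstream QC
  invalidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class DoseSeries:
    """Mean response per positive concentration (nM), dose-ordered."""

    concentrations: np.ndarray
    responses: np.ndarray
    sds: np.ndarray | None = None
    readout: str = "metric"  # proliferative | area | metric
    qc_invalid: bool = False
    qc_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if (self.concentrations <= 0).any():
            raise ValueError("fit concentrations must be > 0 (control is the anchor, not a point)")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.responses = self.responses[order]
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)[order]


@dataclass
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ic50: float
    converged: bool
    rmse: float = math.nan
    covariance: np.ndarray | None = None
    message: str = ""


@dataclass(frozen=True)
class CensoredIC50:
    kind: str  # definite | greater_than | not_determinable
    value: float | None = None  # nM (the bound for greater_than)
    reason: str = ""

    @property
    def is_definite(self) -> bool:
        return self.kind == "definite"

    def __str__(self) -> str:
        if self.kind == "definite":
            return f"{self.value:g}"
        if self.kind == "greater_than":
            return f">{self.value:g}"
        return "n/a"


MIN_POINTS = 4


def _model(logc, top, bottom, hill, log_ic50):
    return bottom + (top - bottom) / (1 + 10 ** (hill * (logc - log_ic50)))


def fit_4pl(s: DoseSeries, n_restarts: int = 5, weighted: bool = False) -> FourPLFit:
    """Least-squares 4PL fit of a dose series.

    Initialisation: top/bottom from the extreme-dose responses, ic50 at the
    dose nearest the half-maximal response, hill = 1; plus ``n_restarts``
    jittered restarts (deterministic).  ``converged`` is False when the
    optimiser fails or the midpoint lands on a search bound.
    """
    c = s.concentrations
    y = s.responses
    if np.unique(c).size < MIN_POINTS:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, False,
                         message="fewer than 4 distinct concentrations")
    if not np.isfinite(y).all():
        raise ValueError("non-finite responses")
    logc = np.log10(c)
    top0, bot0 = float(y[0]), float(y[-1])
    if math.isclose(top0, bot0):
        top0, bot0 = float(y.max()), float(y.min())
    half = (top0 + bot0) / 2
    lg50_0 = float(logc[np.argmin(np.abs(y - half))])
    lo, hi = logc.min() - 3.0, logc.max() + 3.0
    bounds = ([-np.inf, -np.inf, 0.05, lo], [np.inf, np.inf, 10.0, hi])
    sigma = s.sds if (weighted and s.sds is not None and np.all(s.sds > 0)) else None

    rng = np.random.default_rng(0)
    starts = [(top0, bot0, 1.0, lg50_0)]
    for _ in range(n_restarts):
        starts.append(
            (
                top0 * (1 + 0.1 * rng.standard_normal()),
                bot0 * (1 + 0.1 * rng.standard_normal()) if bot0 != 0 else 0.05 * rng.random(),
                float(np.exp(rng.normal(0, 0.5))),
                float(np.clip(lg50_0 + rng.normal(0, 0.7), lo, hi)),
            )
        )
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _model, logc, y, p0=np.clip(p0, bounds[0], bounds[1]),
                bounds=bounds, sigma=sigma, maxfev=1000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _model(logc, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
        if sse < 1e-12 * max(1.0, float(y @ y)):
            break  # essentially exact; restarts cannot improve
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, False,
                         message="optimizer failed for all starts")
    sse, popt, pcov = best
    top, bottom, hill, lg50 = popt
    hit_bound = lg50 <= lo + 1e-6 or lg50 >= hi - 1e-6 or hill >= 10.0 - 1e-6
    rmse = math.sqrt(sse / y.size)
    return FourPLFit(
        top=float(top), bottom=float(bottom), hill=float(hill), ic50=float(10**lg50),
        converged=not hit_bound, rmse=rmse, covariance=pcov,
        message="midpoint/hill at search bound" if hit_bound else "",
    )


def classify_ic50(fit: FourPLFit, s: DoseSeries, min_span_fraction: float = 0.5) -> CensoredIC50:
    """Censoring verdict for a fitted series.

    ``definite`` requires convergence, an IC50 inside the tested range and
    a response that actually crossed half-maximum: the observed swing must
    reach ``min_span_fraction`` of the fitted top-bottom span, and the
    span itself must be at least a third of the low-dose asymptote level.
    The second, absolute requirement encodes the same convention as
    printed ">max-dose" entries — a readout that cannot move by an
    appreciable fraction of its control level within the tested range does
    not support a definite midpoint — and stops a 4PL that merely absorbed
    noise on a flat series from reporting one.
    A converged but right-shifted or shallow curve is reported as
    ``greater_than`` the maximum tested dose; QC invalidation or fit
    failure give ``not_determinable``.
    """
    if s.qc_invalid:
        return CensoredIC50("not_determinable", reason="; ".join(s.qc_reasons) or "QC invalid")
    if not np.isfinite(fit.ic50):
        return CensoredIC50("not_determinable", reason=fit.message or "fit failed")
    c = s.concentrations
    y = s.responses
    span = abs(fit.top - fit.bottom)
    # fit.top is the low-dose asymptote under the hill > 0 parameterisation.
    observed_swing = float(np.max(np.abs(y - fit.top))) if span > 0 else 0.0
    crossed = (
        span > 0
        and observed_swing >= min_span_fraction * span
        and span >= abs(fit.top) / 3.0
    )
    if fit.converged and c.min() <= fit.ic50 <= c.max() and crossed:
        return CensoredIC50("definite", value=fit.ic50)
    if fit.ic50 > c.max() or not crossed:
        return CensoredIC50(
            "greater_than", value=float(c.max()),
            reason="response did not cross half-maximum in the tested range",
        )
    return CensoredIC50("not_determinable", reason=fit.message or "unstable fit")


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def ic50_ratio(a: CensoredIC50, b: CensoredIC50) -> str:
    """Ratio a/b with censoring-aware arithmetic.

    Both definite -> the ratio to 2 decimals.  A lower bound on ``a`` with a
    definite ``b`` gives a lower bound ('>x'); a definite ``a`` over a lower
    bound on ``b`` gives an upper bound ('<x'), both to 2 significant
    digits.  Anything else is 'n/a'.
    """
    if a.is_definite and b.is_definite:
        return f"{round(a.value / b.value, 2):.2f}"
    if a.kind == "greater_than" and b.is_definite:
        return f">{_round_sig(a.value / b.value):g}"
    if a.is_definite and b.kind == "greater_than":
        return f"<{_round_sig(a.value / b.value):g}"
    return "n/a"
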