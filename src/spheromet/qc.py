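"""Assay-specific triplicate quality control.

Two independent policies, never combined on the same data:

* fluorescence (viability) readouts — coefficient-of-variation screening
  with plate-validity rules (20% CV gate, single-removal rescue, plateau-only
  exclusion, invalidation when trouble sits at the curve midpoint);
* morphometric features — Dixon's Q test at n = 3, restricted to replacing
  at most one suspect value per triplicate with the mean of the remaining
  two, and only when the cleaned concentration series still follows the
  expected monotone dose-response trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Dixon r10 critical value at n = 3, two-sided, 95% confidence.
Q_CRIT_N3_95 = 0.970

#: CV gate for fluorescence triplicates, percent.
CV_LIMIT_PCT = 20.0


@dataclass(frozen=True)
class Triplicate:
    """Exactly three positive replicate measurements of one condition."""

    values: tuple[float, float, float]
    key: tuple = ()

    def __post_init__(self) -> None:
        if len(self.values) != 3:
            raise ValueError("a triplicate holds exactly 3 values")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("triplicate values must be finite")


@dataclass
class QDecision:
    """Outcome of the Dixon test on one triplicate."""

    q_stat: float
    q_crit: float = Q_CRIT_N3_95
    suspect_index: int | None = None
    action: str = "none"  # none | replaced | refused(guard)
    replacement: float | None = None
    key: tuple = ()


@dataclass
class PlateValidity:
    status: str = "valid"  # valid | invalid
    reasons: list[str] = field(default_factory=list)
    excluded_points: list[float] = field(default_factory=list)

    def invalidate(self, reason: str) -> None:
        self.status = "invalid"
        self.reasons.append(reason)


def cv_percent(values) -> float:
    """Coefficient of variation of a triplicate, percent.

    Sample (n - 1) standard deviation over the mean, times 100.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean * 100.0)


def dixon_q(t: Triplicate) -> QDecision:
    """Dixon's Q statistic for a triplicate.

    Q = |suspect - nearest| / |highest - lowest|, the suspect being the
    value most distant from the other two.  All-equal triplicates give
    Q = 0 and no action.
    """
    v = np.asarray(t.values, dtype=float)
    rng = v.max() - v.min()
    if rng == 0:
        return QDecision(q_stat=0.0, suspect_index=None, action="none", key=t.key)
    order = np.argsort(v, kind="stable")
    s = v[order]
    gap_low = s[1] - s[0]
    gap_high = s[2] - s[1]
    if gap_low >= gap_high:
        suspect = int(order[0])
        q = gap_low / rng
    else:
        suspect = int(order[2])
        q = gap_high / rng
    return QDecision(q_stat=float(q), suspect_index=suspect, action="none", key=t.key)


def _monotone_violation(means: np.ndarray, direction: int, rel_tol: float) -> float:
    """Total wrong-direction excess beyond a relative tolerance band.

    ``direction`` +1 for an expected increase with dose, -1 for a decrease.
    A step from m[i] to m[i+1] violates when it moves against the expected
    direction by more than ``rel_tol`` of m[i]; the excesses are summed.
    """
    total = 0.0
    for a, b in zip(means[:-1], means[1:]):
        band = rel_tol * abs(a)
        if direction <= 0:
            excess = b - (a + band)
        else:
            excess = (a - band) - b
        if excess > 0:
            total += excess
    return total


def dixon_replace(
    triplicates: dict[float, "Triplicate | tuple | list"],
    rel_tol: float = 0.05,
    q_crit: float = Q_CRIT_N3_95,
) -> tuple[dict[float, np.ndarray], list[QDecision]]:
    """Dixon single-replacement over a dose-ordered series of triplicates.

    For each triplicate with Q above ``q_crit`` the suspect value is
    replaced by the mean of the remaining two — but only if the resulting
    concentration-ordered triplicate means keep the expected monotone
    dose-response trend at least as well as before (monotonicity guard:
    the total wrong-direction excess beyond a ``rel_tol`` band, with the
    direction set by the first and last dose means, must not increase).
    Refusals are recorded as ``action="refused(guard)"``; they are data,
    not errors.  A second pass over cleaned data changes nothing.
    """
    concs = sorted(triplicates)
    cleaned: dict[float, np.ndarray] = {}
    for c in concs:
        t = triplicates[c]
        vals = np.asarray(t.values if isinstance(t, Triplicate) else t, dtype=float)
        if vals.shape != (3,):
            raise ValueError("each dose needs exactly 3 replicate values")
        cleaned[c] = vals.copy()

    def series_means(override_c=None, override_vals=None) -> np.ndarray:
        out = []
        for c in concs:
            v = override_vals if c == override_c else cleaned[c]
            out.append(float(np.mean(v)))
        return np.asarray(out)

    # Direction probe uses triplicate medians: a single gross outlier at an
    # extreme dose would flip a mean-based sign.
    med_first = float(np.median(cleaned[concs[0]]))
    med_last = float(np.median(cleaned[concs[-1]]))
    direction = 1 if med_last > med_first else -1

    decisions: list[QDecision] = []
    for c in concs:
        t = Triplicate(tuple(cleaned[c]), key=(c,))
        dec = dixon_q(t)
        dec.q_crit = q_crit
        if dec.q_stat > q_crit and dec.suspect_index is not None:
            others = np.delete(cleaned[c], dec.suspect_index)
            candidate = cleaned[c].copy()
            candidate[dec.suspect_index] = others.mean()
            before = _monotone_violation(series_means(), direction, rel_tol)
            after = _monotone_violation(series_means(c, candidate), direction, rel_tol)
            if after <= before:
                cleaned[c] = candidate
                dec.action = "replaced"
                dec.replacement = float(others.mean())
            else:
                dec.action = "refused(guard)"
        decisions.append(dec)
    return cleaned, decisions


def _best_single_removal(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Lowest pair CV (percent) achievable by dropping one value, and the pair."""
    best_cv = np.inf
    best_pair = values[:2]
    for i in range(3):
        pair = np.delete(values, i)
        cv = cv_percent(pair)
        if cv < best_cv:
            best_cv = cv
            best_pair = pair
    return best_cv, best_pair


def apply_fluorescence_rules(
    triplicates: dict[float, "Triplicate | tuple | list"],
    cv_limit: float = CV_LIMIT_PCT,
) -> tuple[dict[float, float], PlateValidity]:
    """CV-based QC for one fluorescence dose series (control at dose 0).

    In order: (1) a triplicate with CV above the gate first attempts a
    single-value removal; (2) if no removal brings the remaining pair under
    the gate, the point is excluded; (3) the curve is invalidated if an
    excluded or outlying point lies in the IC50/inflection region (the two
    doses bracketing the provisional half-maximal response); (4) at most one
    exclusion is permitted, and only in the plateau region; (5) the plate is
    invalid if the control triplicate exceeds the gate and cannot be fixed
    by removing one value.

    Returns the per-dose cleaned means (excluded points absent) and the
    :class:`PlateValidity` verdict.
    """
    if 0.0 not in triplicates:
        raise ValueError("missing zero-dose (negative control) triplicate")
    validity = PlateValidity()
    values = {}
    for c, t in triplicates.items():
        v = np.asarray(t.values if isinstance(t, Triplicate) else t, dtype=float)
        if v.shape != (3,):
            raise ValueError("each dose needs exactly 3 replicate values")
        values[c] = v

    # Rule (5): control first.
    ctrl = values[0.0]
    cleaned: dict[float, float] = {}
    flagged: list[float] = []  # doses where QC intervened (removal or exclusion)
    if cv_percent(ctrl) > cv_limit:
        best_cv, pair = _best_single_removal(ctrl)
        if best_cv > cv_limit:
            validity.invalidate("control CV above gate and not fixable by single removal")
            return cleaned, validity
        cleaned[0.0] = float(pair.mean())
    else:
        cleaned[0.0] = float(ctrl.mean())

    excluded: list[float] = []
    for c in sorted(values):
        if c == 0.0:
            continue
        v = values[c]
        if cv_percent(v) <= cv_limit:
            cleaned[c] = float(v.mean())
            continue
        best_cv, pair = _best_single_removal(v)
        if best_cv <= cv_limit:
            cleaned[c] = float(pair.mean())
            flagged.append(c)
        else:
            excluded.append(c)
            flagged.append(c)
    validity.excluded_points = list(excluded)

    # Provisional inflection: dose whose cleaned response is closest to the
    # half-way point between the extreme responses; region = bracketing doses.
    doses = sorted(c for c in cleaned if c > 0)
    if doses:
        resp = np.array([cleaned[c] for c in doses])
        half = (resp.max() + resp.min()) / 2
        mid_ix = int(np.argmin(np.abs(resp - half)))
        lo = doses[max(mid_ix - 1, 0)]
        hi = doses[min(mid_ix + 1, len(doses) - 1)]
        region = {c for c in doses if lo <= c <= hi}
    else:
        region = set()

    # Rule (3): trouble at the midpoint invalidates the curve.
    for c in flagged:
        if c in region:
            validity.invalidate(f"outlier/excluded point at {c} nM lies in the IC50 region")
    # Rule (4): at most one exclusion, plateau only.
    if len(excluded) > 1:
        validity.invalidate(f"{len(excluded)} points excluded; only one permitted")
    for c in excluded:
        if c in region:
            validity.invalidate(f"exclusion at {c} nM is not in the plateau region")
    return cleaned, validity
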