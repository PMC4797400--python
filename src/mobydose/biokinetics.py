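"""Time-activity curve fitting and cumulated activity.

A source region's kinetics are modelled as a bi-exponential in
decay-corrected activity,

    A(t) = A1 exp(-lambda1 t) + A2 exp(-lambda2 t),

fitted by least squares to %IA (or %IA/g) measurements.  The cumulated
activity is the closed-form integral of the model multiplied by the
physical decay factor exp(-lambda_phys t):

    Atilde = A1/(lambda1 + lambda_phys) + A2/(lambda2 + lambda_phys).

One amplitude may be negative so the model can describe an uptake phase
(rise then fall), as antibody curves in tumors do; non-negativity is
enforced on the model value A(t) over the fitted span, not on amplitudes.
Red-marrow kinetics are derived from blood by a fixed concentration
ratio.

Units: time in hours; activity as percent of injected activity, either
per organ (%IA) or per gram (%IA/g), tracked explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize

__all__ = [
    "TimeActivityCurve",
    "BiexponentialFit",
    "fit_biexponential",
    "cumulated_activity",
    "marrow_curve_from_blood",
    "decays_per_mbq_administered",
    "read_tacs",
    "write_tacs",
    "MARROW_TO_BLOOD_RATIO",
    "DISINTEGRATIONS_PER_MBQ_HOUR",
    "InsufficientDataError",
    "DegenerateFitError",
    "DivergentIntegralError",
    "UnitMismatchError",
]

#: Red-marrow %IA/g is assumed proportional to blood %IA/g at this ratio.
MARROW_TO_BLOOD_RATIO = 0.36

#: 1 MBq.h = 1e6 decays/s x 3600 s.
DISINTEGRATIONS_PER_MBQ_HOUR = 3.6e9

_TAC_COLUMNS = ["region", "time_h", "value", "value_kind", "n"]


class InsufficientDataError(ValueError):
    """Fewer time points than the model can identify."""


class DegenerateFitError(ValueError):
    """Curve carries no information (e.g. all zeros)."""


class DivergentIntegralError(ValueError):
    """Cumulated-activity integral does not converge."""


class UnitMismatchError(ValueError):
    """Operation received per-organ data where per-gram was required (or v.v.)."""


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected activity samples for one source region."""

    region: str
    times: np.ndarray  # hours post-injection, strictly increasing
    values: np.ndarray  # %IA (per_organ) or %IA/g (per_gram)
    value_kind: str = "per_gram"
    n_animals_per_point: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if np.any(v < 0):
            raise ValueError("activity values must be non-negative")
        if self.value_kind not in ("per_organ", "per_gram"):
            raise ValueError("value_kind must be 'per_organ' or 'per_gram'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BiexponentialFit:
    """Fitted bi-exponential parameters for one region.

    Amplitudes are in the units of the fitted curve (%IA or %IA/g); rates
    and the physical decay constant are in h^-1.  ``lambda1`` is the faster
    rate by convention.
    """

    region: str
    a1: float
    lambda1: float
    a2: float
    lambda2: float
    lambda_phys: float
    residual_norm: float
    value_kind: str = "per_gram"

    def __post_init__(self) -> None:
        if self.lambda1 + self.lambda_phys <= 0 or self.lambda2 + self.lambda_phys <= 0:
            raise DivergentIntegralError(
                f"{self.region}: lambda_i + lambda_phys must be > 0 for an "
                "integrable cumulated-activity integral"
            )
        if self.a1 + self.a2 < -1e-9 * max(abs(self.a1), abs(self.a2), 1.0):
            raise ValueError("initial activity A1 + A2 must be non-negative")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, float)
        return self.a1 * np.exp(-self.lambda1 * t) + self.a2 * np.exp(-self.lambda2 * t)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "a1": self.a1,
            "lambda1_per_h": self.lambda1,
            "a2": self.a2,
            "lambda2_per_h": self.lambda2,
            "lambda_phys_per_h": self.lambda_phys,
            "residual_norm": self.residual_norm,
            "value_kind": self.value_kind,
        }


# ---------------------------------------------------------------------------
# fitting


def _amplitudes_for_rates(t, y, l1, l2):
    """Given rates, solve the linear least-squares problem for amplitudes."""
    if abs(l1 - l2) < 1e-12:  # degenerate: single exponential
        col = np.exp(-l1 * t)
        a = float(col @ y / (col @ col))
        return np.array([a, 0.0]), float(np.sum((a * col - y) ** 2))
    X = np.column_stack([np.exp(-l1 * t), np.exp(-l2 * t)])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = float(np.sum((X @ coef - y) ** 2))
    return coef, r


def _canonical(a1, l1, a2, l2):
    """Order components: faster rate first; a negligible (spurious) component
    is zeroed and demoted to slot 2 so single-exponential data reports its
    one real component as (A1, lambda1)."""
    if l2 > l1:
        a1, l1, a2, l2 = a2, l2, a1, l1
    if abs(l1 - l2) < 1e-12 and a2 != 0.0:  # identical rates: merge the split
        a1, a2 = a1 + a2, 0.0
    big = max(abs(a1), abs(a2), 1e-300)
    if abs(a1) <= 1e-7 * big:
        a1, l1, a2, l2 = a2, l2, 0.0, l1
    elif abs(a2) <= 1e-7 * big:
        a2 = 0.0
    return a1, l1, a2, l2


def _model_nonnegative(a1, l1, a2, l2, t_max):
    tt = np.linspace(0.0, 2.0 * t_max, 257)
    vals = a1 * np.exp(-l1 * tt) + a2 * np.exp(-l2 * tt)
    scale = max(abs(a1), abs(a2), 1e-300)
    return vals.min() >= -1e-7 * scale


def fit_biexponential(
    tac: TimeActivityCurve,
    lambda_phys: float,
    rate_grid: np.ndarray | None = None,
) -> BiexponentialFit:
    """Least-squares bi-exponential fit to a decay-corrected curve.

    Deterministic multi-start: rates are initialized on a fixed log-spaced
    grid (1e-4 to 1 h^-1, plus 0), amplitudes solved linearly for each rate
    pair (variable projection), and the best starts refined with a
    trust-region least-squares optimizer.  Candidates whose model value goes
    negative on [0, 2 x last time] are rejected.  Ties are broken by lowest
    residual, then lowest lambda1.
    """
    t, y = tac.times, tac.values
    if t.size < 4:
        raise InsufficientDataError(
            f"{tac.region}: need >= 4 time points to fit a bi-exponential, got {t.size}"
        )
    if np.all(y == 0):
        raise DegenerateFitError(f"{tac.region}: all activity values are zero")

    if rate_grid is None:
        rate_grid = np.concatenate([[0.0], np.logspace(-4, 0, 9)])
    t_max = float(t[-1])

    # grid stage: score every ordered rate pair
    cands = []
    for i, l2 in enumerate(rate_grid):
        for l1 in rate_grid[i:]:
            (a1, a2), r = _amplitudes_for_rates(t, y, l1, l2)
            cands.append((r, l1, a1, l2, a2))
    cands.sort(key=lambda c: (c[0], c[1]))

    def residuals(p):
        a1, l1, a2, l2 = p
        return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) - y

    refined = []
    for r0, l1, a1, l2, a2 in cands[:5]:
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[a1, l1, a2, l2],
                bounds=([-np.inf, 0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=400,
            )
        except Exception:
            continue
        a1f, l1f, a2f, l2f = _canonical(*sol.x)
        if a1f + a2f < -1e-7 * max(abs(a1f), abs(a2f), 1.0):
            continue
        if not _model_nonnegative(a1f, l1f, a2f, l2f, t_max):
            continue
        r = float(np.sum(residuals([a1f, l1f, a2f, l2f]) ** 2))
        refined.append((r, l1f, a1f, a2f, l2f))

    if not refined:
        # every unconstrained optimum dips negative somewhere (noisy uptake
        # curves can do this near t=0): retry with a hinge penalty that
        # pushes the model back to A(t) >= 0 over [0, 2 t_max]
        tt = np.linspace(0.0, 2.0 * t_max, 129)
        scale = float(np.max(np.abs(y)))

        def penalized(p):
            a1, l1, a2, l2 = p
            model = a1 * np.exp(-l1 * tt) + a2 * np.exp(-l2 * tt)
            hinge = np.minimum(model, 0.0) * (50.0 / scale) * scale
            return np.concatenate([residuals(p), hinge])

        for r0, l1, a1, l2, a2 in cands[:4]:
            try:
                sol = optimize.least_squares(
                    penalized,
                    x0=[a1, l1, a2, l2],
                    bounds=([-np.inf, 0.0, -np.inf, 0.0], [np.inf] * 4),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    max_nfev=300,
                )
            except Exception:
                continue
            a1f, l1f, a2f, l2f = _canonical(*sol.x)
            model = a1f * np.exp(-l1f * tt) + a2f * np.exp(-l2f * tt)
            if model.min() < -1e-3 * scale or a1f + a2f < -1e-3 * scale:
                continue
            if a1f + a2f < 0:  # clip residual numerical negativity at t=0
                a1f = -a2f
            r = float(np.sum(residuals([a1f, l1f, a2f, l2f]) ** 2))
            refined.append((r, l1f, a1f, a2f, l2f))

    if not refined:
        raise DegenerateFitError(f"{tac.region}: no admissible bi-exponential fit found")
    # ties (residuals equal to within 1e-9 relative) broken by lowest lambda1
    r_min = min(c[0] for c in refined)
    tol = 1e-9 * max(r_min, 1e-30)
    tied = [c for c in refined if c[0] <= r_min + tol]
    r, l1f, a1f, a2f, l2f = min(tied, key=lambda c: c[1])
    return BiexponentialFit(
        region=tac.region,
        a1=float(a1f),
        lambda1=float(l1f),
        a2=float(a2f),
        lambda2=float(l2f),
        lambda_phys=float(lambda_phys),
        residual_norm=float(np.sqrt(r)),
        value_kind=tac.value_kind,
    )


# ---------------------------------------------------------------------------
# cumulated activity


def cumulated_activity(fit: BiexponentialFit) -> float:
    """Closed-form cumulated activity in %IA.h (or %IA/g.h for per-gram fits).

    Atilde = A1/(lambda1+lambda_phys) + A2/(lambda2+lambda_phys), the exact
    integral over [0, inf) of the fitted curve times exp(-lambda_phys t).
    """
    d1 = fit.lambda1 + fit.lambda_phys
    d2 = fit.lambda2 + fit.lambda_phys
    if d1 <= 0 or d2 <= 0:
        raise DivergentIntegralError(
            f"{fit.region}: lambda_i + lambda_phys <= 0, integral diverges"
        )
    return fit.a1 / d1 + fit.a2 / d2


def cumulated_activity_quadrature(fit: BiexponentialFit) -> float:
    """Adaptive-quadrature evaluation of the same integral (cross-check)."""

    def integrand(t):
        return (
            fit.a1 * np.exp(-fit.lambda1 * t) + fit.a2 * np.exp(-fit.lambda2 * t)
        ) * np.exp(-fit.lambda_phys * t)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
    return float(val)


def marrow_curve_from_blood(blood_tac: TimeActivityCurve) -> TimeActivityCurve:
    """Red-marrow TAC from blood via the fixed concentration ratio 0.36."""
    if blood_tac.value_kind != "per_gram":
        raise UnitMismatchError(
            "marrow-from-blood rule applies to per-gram (%IA/g) blood curves"
        )
    return TimeActivityCurve(
        region="marrow",
        times=blood_tac.times.copy(),
        values=MARROW_TO_BLOOD_RATIO * blood_tac.values,
        value_kind="per_gram",
        n_animals_per_point=blood_tac.n_animals_per_point,
    )


def decays_per_mbq_administered(
    fit: BiexponentialFit,
    region_mass_g: float | None = None,
    value_kind: str | None = None,
) -> float:
    """Total disintegrations in the region per MBq administered.

    Converts the cumulated activity from %IA.h to MBq.h per MBq administered
    (divide by 100; per-gram curves are first multiplied by the region mass),
    then to disintegrations via 3.6e9 per MBq.h.
    """
    kind = value_kind or fit.value_kind
    atilde = cumulated_activity(fit)  # %IA.h or %IA/g.h
    if kind == "per_gram":
        if region_mass_g is None or region_mass_g <= 0:
            raise UnitMismatchError(
                f"{fit.region}: per-gram cumulated activity needs a positive region mass"
            )
        atilde = atilde * region_mass_g
    mbq_h_per_mbq = atilde / 100.0
    return mbq_h_per_mbq * DISINTEGRATIONS_PER_MBQ_HOUR


# ---------------------------------------------------------------------------
# I/O


def read_tacs(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Read TACs from CSV with columns region,time_h,value,value_kind,n."""
    df = pd.read_csv(path)
    if list(df.columns) != _TAC_COLUMNS:
        raise ValueError(
            f"TAC file {path}: expected columns {_TAC_COLUMNS}, got {list(df.columns)}"
        )
    out = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("time_h")
        kinds = grp["value_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"TAC region {region}: mixed value_kind entries")
        out[str(region)] = TimeActivityCurve(
            region=str(region),
            times=grp["time_h"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            value_kind=str(kinds[0]),
            n_animals_per_point=int(grp["n"].iloc[0]),
        )
    return out


def write_tacs(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    rows = []
    for tac in tacs.values():
        for t, v in zip(tac.times, tac.values):
            rows.append(
                {
                    "region": tac.region,
                    "time_h": t,
                    "value": v,
                    "value_kind": tac.value_kind,
                    "n": tac.n_animals_per_point,
                }
            )
    pd.DataFrame(rows, columns=_TAC_COLUMNS).to_csv(path, index=False)


def write_fits(fits: dict[str, BiexponentialFit], path: str | Path) -> None:
    """Export fitted parameters as JSON."""
    Path(path).write_text(
        json.dumps({r: f.to_dict() for r, f in fits.items()}, indent=2)
    )
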