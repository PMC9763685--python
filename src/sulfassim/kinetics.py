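"""Michaelis-Menten kinetics: rate law, fitting, progress curves, standards.

The central object is :class:`MichaelisMentenModel`, built from (substrate,
rate) observations; ``fit()`` returns an :class:`MMResults` carrying the
Vmax/Km estimates, their standard errors from the Jacobian, the residual SSE
and a ``summary()`` table. Rate units are treated as opaque assay units/min
and never converted.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit


@dataclasses.dataclass(frozen=True)
class KineticParams:
    """Vmax (assay units/min) and Km (mM) for one enzyme."""

    enzyme: str
    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax < 0:
            raise ValueError("Vmax must be >= 0")
        if not (self.km > 0) and not math.isnan(self.km):
            raise ValueError("Km must be > 0")


@dataclasses.dataclass(frozen=True)
class DilutionSeries:
    start: float
    ratio: float
    n: int
    concentrations: tuple[float, ...]
    blank: float = 0.0


def mm_rate(S, params: KineticParams):
    """v = Vmax * S / (Km + S); monotone increasing and concave in S."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    return params.vmax * S / (params.km + S)


class MMResults:
    """Fit results: estimates, SEs, covariance, SSE, diagnostics."""

    def __init__(self, params, se, cov, sse, n_obs, unidentifiable=False, warnings_=()):
        self.params = params
        self.se = se  # dict vmax/km
        self.cov = cov
        self.sse = sse
        self.n_obs = n_obs
        self.unidentifiable = unidentifiable
        self.warnings = list(warnings_)

    @property
    def vmax(self) -> float:
        return self.params.vmax

    @property
    def km(self) -> float:
        return self.params.km

    def predict(self, S):
        return mm_rate(S, self.params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.vmax, self.km],
                "se": [self.se.get("vmax", np.nan), self.se.get("km", np.nan)],
            },
            index=["Vmax", "Km"],
        )

    def __repr__(self):
        flag = " (Km unidentifiable)" if self.unidentifiable else ""
        return (
            f"<MMResults {self.params.enzyme}: Vmax={self.vmax:.4g}, "
            f"Km={self.km:.4g}, SSE={self.sse:.3g}{flag}>"
        )


class MichaelisMentenModel:
    """Nonlinear least-squares Michaelis-Menten model for rate observations.

    Initialisation is by the Hanes-Woolf linearisation (S/v regressed on S),
    with positivity bounds on both parameters; the fit is deterministic given
    the data.
    """

    def __init__(self, S: Sequence[float], v: Sequence[float], enzyme: str = "enzyme"):
        self.S = np.asarray(S, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.enzyme = enzyme
        if self.S.shape != self.v.shape or self.S.ndim != 1:
            raise ValueError("S and v must be 1-D arrays of equal length")
        if np.any(self.S < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("non-finite rates")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme: str = "enzyme"):
        return cls(df["S_mM"].to_numpy(), df["rate"].to_numpy(), enzyme=enzyme)

    def _hanes_woolf_start(self):
        mask = (self.S > 0) & (self.v > 0)
        if mask.sum() >= 2:
            s, v = self.S[mask], self.v[mask]
            slope, intercept = np.polyfit(s, s / v, 1)
            if slope > 0 and intercept > 0:
                return 1.0 / slope, intercept / slope
        vmax0 = max(self.v.max(), 1e-12)
        km0 = max(np.median(self.S[self.S > 0]) if np.any(self.S > 0) else 1.0, 1e-6)
        return vmax0, km0

    def fit(self) -> MMResults:
        warns = []
        if np.allclose(self.v, 0.0):
            # catalytically dead: Vmax 0, Km has no information
            params = KineticParams(self.enzyme, 0.0, float("nan"))
            return MMResults(params, {"vmax": 0.0, "km": np.nan}, None, 0.0,
                             len(self.S), unidentifiable=True)
        if len(np.unique(self.S)) < 3:
            raise ValueError("need >= 3 distinct substrate concentrations")
        p0 = self._hanes_woolf_start()
        popt, pcov = curve_fit(
            lambda s, vmax, km: vmax * s / (km + s),
            self.S, self.v, p0=p0, bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
        vmax, km = float(popt[0]), float(popt[1])
        if not (self.S.min() < km < self.S.max()):
            warns.append("fitted Km outside the observed substrate range")
            warnings.warn(warns[-1])
        resid = self.v - vmax * self.S / (km + self.S)
        sse = float(resid @ resid)
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
        params = KineticParams(self.enzyme, vmax, km)
        return MMResults(params, {"vmax": float(se[0]), "km": float(se[1])},
                         pcov, sse, len(self.S), warnings_=warns)


def fit_mm(observations, enzyme: str = "enzyme") -> MMResults:
    """Fit Vmax/Km to (S, v) observations (array pair or S_mM/rate frame)."""
    if isinstance(observations, pd.DataFrame):
        return MichaelisMentenModel.from_dataframe(observations, enzyme).fit()
    S, v = observations
    return MichaelisMentenModel(S, v, enzyme).fit()


def simulate_progress_curve(
    params: KineticParams,
    S0: float,
    timepoints: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate dP/dt = Vmax (S0 - P) / (Km + S0 - P) from P(0) = 0.

    Product is non-decreasing and never exceeds the initial substrate; mass
    balance S(t) + P(t) = S0 holds by construction of the state variable.
    """
    if S0 <= 0:
        raise ValueError("S0 must be > 0")
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")

    def rhs(_, y):
        s = max(S0 - y[0], 0.0)
        return [params.vmax * s / (params.km + s) if s > 0 else 0.0]

    t_eval = np.sort(np.unique(np.concatenate([[0.0], t])))
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1]) if t_eval[-1] > 0 else 1e-12),
                    [0.0], t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:  # fixed-step RK4 fallback for reproducibility
        P = _rk4_progress(params, S0, t_eval)
    else:
        P = sol.y[0]
    lookup = dict(zip(t_eval, np.minimum(np.maximum(P, 0.0), S0)))
    return np.array([lookup[x] for x in t])


def _rk4_progress(params, S0, t_eval, n_sub=200):
    def f(p):
        s = max(S0 - p, 0.0)
        return params.vmax * s / (params.km + s) if s > 0 else 0.0

    P = [0.0]
    for a, b in zip(t_eval[:-1], t_eval[1:]):
        p = P[-1]
        h = (b - a) / n_sub
        for _ in range(n_sub):
            k1 = f(p)
            k2 = f(p + 0.5 * h * k1)
            k3 = f(p + 0.5 * h * k2)
            k4 = f(p + h * k3)
            p += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        P.append(min(p, S0))
    return np.array(P)


def make_dilution_series(start: float = 15.0, ratio: float = 0.2, n: int = 7) -> DilutionSeries:
    """Geometric dilution series plus a separate 0 mM blank.

    The defaults give the seven-member 1:5 series from 15 mM down to
    0.00096 mM used for homocysteine standard curves.
    """
    if start <= 0:
        raise ValueError("start must be > 0")
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    concs = tuple(start * ratio**i for i in range(n))
    return DilutionSeries(start, ratio, n, concs, blank=0.0)


def calibrate_and_quantify(
    standards: Sequence[tuple[float, float]],
    unknowns: Sequence[float],
    loglog: bool = False,
):
    """Fit a line signal = a*conc + b to standards; invert unknowns through it.

    With ``loglog=True`` the line is fitted in log-log space (useful across a
    wide dynamic range; requires positive values). Returns (concentrations,
    extrapolated flags); unknowns outside the standards' signal range are
    flagged rather than rejected.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    sig = np.array([s for _, s in standards], dtype=float)
    if len(conc) < 2:
        raise ValueError("need >= 2 standards")
    if np.allclose(conc, conc[0]):
        raise ValueError("singular design: all standards at one concentration")
    unknowns = np.asarray(unknowns, dtype=float)
    if loglog:
        a, b = np.polyfit(np.log(conc), np.log(sig), 1)
        est = np.exp((np.log(unknowns) - b) / a)
    else:
        a, b = np.polyfit(conc, sig, 1)
        if a == 0:
            raise ValueError("flat standard curve")
        est = (unknowns - b) / a
    lo, hi = sig.min(), sig.max()
    flags = (unknowns < lo) | (unknowns > hi)
    return est, flags
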