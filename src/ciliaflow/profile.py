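"""Parabolic velocity-profile fit and the shear-stress efficiency index.

The effective bead velocity above a ciliated edge follows, to a very good
approximation, a parabola vanishing with zero slope at the top of the
driven layer:

    V(y) = Uw* · (1 − y/h)²,   0 ≤ y ≤ h,

where Uw* is the velocity extrapolated at the cilia wall and h the
x-intercept — the altitude above which the fluid is stagnant.  This
functional form satisfies V(0) = Uw*, V(h) = 0, dV/dy(h) = 0 and yields a
wall shear μ|dV/dy|(0) = 2μUw*/h, so the efficiency index

    τw = 2 μ Uw* / h      (reported in mPa)

is exactly the steady tangential stress the ciliated wall exerts on the
fluid.  For comparison, a plane Couette flow of gap e and plate velocity V
carries μV/e — half of τw when (V, e) = (Uw*, h), the factor 2 reflecting
the parabolic (rather than linear) profile.

The fit is exposed as a small model/results pair in the spirit of
statsmodels: build :class:`ParabolicProfile` from samples, call ``fit()``,
read estimates, standard errors and diagnostics off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

WATER_VISCOSITY = 1.0e-3   # Pa·s


@dataclass
class VelocityProfile:
    """Samples (y0, V_eff) of a bead velocity profile, in μm and μm/s."""

    y: np.ndarray
    v: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.y.shape != self.v.shape:
            raise ValueError("y and v must have the same shape")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    def __len__(self):
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y0_um": self.y, "veff_um_s": self.v})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VelocityProfile":
        return cls(y=df["y0_um"].to_numpy(), v=df["veff_um_s"].to_numpy())

    def fit(self, **kwargs) -> "ParabolicProfileResults":
        return ParabolicProfile(self.y, self.v, self.weights).fit(**kwargs)


class ParabolicProfile:
    """Model V(y) = Uw·(1 − y/h)² for a sampled velocity profile.

    Parameters
    ----------
    y, v : array_like
        Sample altitudes (μm) and velocities (μm/s); at least 3 distinct
        altitudes are required.
    weights : array_like, optional
        Relative weights applied to the squared residuals.
    """

    param_names = ("uw", "h")

    def __init__(self, y, v, weights=None):
        self.y = np.asarray(y, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if self.y.shape != self.v.shape:
            raise ValueError("y and v must have the same shape")
        if len(np.unique(self.y)) < 3:
            raise ValueError("need at least 3 samples with distinct y0")
        self.weights = (np.ones_like(self.y) if weights is None
                        else np.asarray(weights, dtype=float))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y_col: str = "y0_um",
                       v_col: str = "veff_um_s") -> "ParabolicProfile":
        return cls(df[y_col].to_numpy(), df[v_col].to_numpy())

    @staticmethod
    def predict_at(params, y):
        uw, h = params
        return uw * (1.0 - np.asarray(y, dtype=float) / h) ** 2

    def _initial_guess(self):
        uw0 = float(self.v.max())
        pos = self.v > 0
        h0 = 1.5 * float(self.y.max())
        if pos.sum() >= 2:
            # sqrt(V) is linear in y below the intercept
            coef = np.polyfit(self.y[pos], np.sqrt(self.v[pos]), 1)
            if coef[0] < 0:
                h0 = float(-coef[1] / coef[0])
        return np.array([max(uw0, 1e-6), max(h0, 1e-3)])

    def fit(self, xtol: float = 1e-12, ftol: float = 1e-12
            ) -> "ParabolicProfileResults":
        sw = np.sqrt(self.weights)
        if np.all(self.v == 0.0):
            # no flow at any altitude: wall velocity is zero and the
            # intercept carries no information
            return ParabolicProfileResults(
                model=self, params=np.array([0.0, np.nan]),
                bse=np.array([0.0, np.nan]), degenerate=True)

        def resid(p):
            return sw * (self.v - self.predict_at(p, self.y))

        def jac(p):
            uw, h = p
            one = 1.0 - self.y / h
            d_uw = -(one ** 2)
            d_h = -uw * 2.0 * one * self.y / h ** 2
            return sw[:, None] * np.column_stack([d_uw, d_h])

        sol = least_squares(resid, self._initial_guess(), jac=jac,
                            bounds=([0.0, 1e-9], [np.inf, np.inf]),
                            xtol=xtol, ftol=ftol, gtol=None)
        if not sol.success:
            raise RuntimeError(
                "parabolic fit did not converge from initial guess "
                f"{self._initial_guess()}: {sol.message}")
        n, p = len(self.y), 2
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * s2
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(2, np.nan)
        return ParabolicProfileResults(model=self, params=sol.x, bse=bse)


@dataclass
class ParabolicProfileResults:
    """Estimates, uncertainties and diagnostics of a profile fit."""

    model: ParabolicProfile
    params: np.ndarray
    bse: np.ndarray
    degenerate: bool = False

    @property
    def uw(self) -> float:
        """Extrapolated wall velocity Uw* (μm/s)."""
        return float(self.params[0])

    @property
    def h(self) -> float:
        """x-intercept of the parabola: stagnant-fluid altitude (μm)."""
        return float(self.params[1])

    @property
    def fittedvalues(self) -> np.ndarray:
        if self.degenerate:
            return np.zeros_like(self.model.v)
        return ParabolicProfile.predict_at(self.params, self.model.y)

    @property
    def resid(self) -> np.ndarray:
        return self.model.v - self.fittedvalues

    @property
    def resid_sd(self) -> float:
        dof = max(len(self.model.y) - 2, 1)
        return float(np.sqrt((self.resid ** 2).sum() / dof))

    @property
    def rsquared(self) -> float:
        sst = ((self.model.v - self.model.v.mean()) ** 2).sum()
        if sst == 0:
            return 1.0
        return float(1.0 - (self.resid ** 2).sum() / sst)

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    def predict(self, y) -> np.ndarray:
        return ParabolicProfile.predict_at(self.params, y)

    def shear_stress_mpa(self, mu: float = WATER_VISCOSITY) -> float:
        """The efficiency index τw = 2μUw*/h in mPa."""
        if self.degenerate:
            return 0.0
        return shear_stress(self.uw, self.h, mu)

    def summary(self) -> str:
        lines = [
            "Parabolic velocity profile  V(y) = Uw*(1 - y/h)^2",
            "=" * 52,
            f"{'n observations':<24}{self.nobs:>12d}",
            f"{'R-squared':<24}{self.rsquared:>12.4f}",
            f"{'residual SD (um/s)':<24}{self.resid_sd:>12.4f}",
            "-" * 52,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
            f"{'Uw* (um/s)':<12}{self.uw:>12.4f}{self.bse[0]:>14.4f}",
            f"{'h (um)':<12}{self.h:>12.4f}{self.bse[1]:>14.4f}",
            "-" * 52,
            f"{'tau_w (mPa, water)':<24}"
            f"{self.shear_stress_mpa():>12.4f}",
        ]
        if self.degenerate:
            lines.append("WARNING: all velocities zero; h indeterminate")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Samples, fitted parabola and the x-intercept h."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.y, self.model.v, "o", label="samples")
        if not self.degenerate:
            yy = np.linspace(0.0, self.h, 200)
            ax.plot(yy, self.predict(yy), "-", label="fit")
            ax.axvline(self.h, ls="--", color="grey", label="h")
        ax.set_xlabel("distance to edge y0 (μm)")
        ax.set_ylabel("V_eff (μm/s)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Stress indices and per-patient aggregation
# ---------------------------------------------------------------------------

def shear_stress(uw: float, h: float, mu: float = WATER_VISCOSITY) -> float:
    """Efficiency index τw = 2μUw*/h, returned in mPa.

    ``uw`` in μm/s and ``h`` in μm: the ratio is 1/s, so
    τw[Pa] = 2·μ·uw/h and 1 Pa = 1000 mPa.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    return 2.0e3 * mu * uw / h


def couette_stress(v: float, e: float, mu: float = WATER_VISCOSITY) -> float:
    """Plane-Couette shear μV/e in mPa (linear profile benchmark).

    Equals τw/2 when (V, e) = (Uw*, h).
    """
    if e <= 0:
        raise ValueError("plate gap e must be positive")
    return 1.0e3 * mu * v / e


def patient_summary(taus):
    """Mean and sample (n−1) standard deviation of per-edge τw values.

    A single edge yields ``(tau, None)``; an empty list is an error.
    """
    taus = np.asarray(list(taus), dtype=float)
    if taus.size == 0:
        raise ValueError("need at least one edge")
    mean = float(taus.mean())
    sd = float(taus.std(ddof=1)) if taus.size > 1 else None
    return mean, sd
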