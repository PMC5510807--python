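"""Statistical comparisons for bead-velocity datasets.

Three analyses accompany the tracking experiment: an ordinary
least-squares regression of effective bead velocity on the five
exploratory variables (CBF, cilia density, CBA, distance to the edge, and
metachronal wavelength), a Mann–Whitney comparison of bead speeds split at
the median distance to the edge, and a Bland–Altman agreement analysis of
measured versus simulated velocities.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

PREDICTORS = ("cbf", "rho_c", "cba", "y0", "wavelength")


# ---------------------------------------------------------------------------
# Multiple linear regression of V_eff
# ---------------------------------------------------------------------------

@dataclass
class VeffRegression:
    """Thin wrapper over the fitted OLS: coefficients, R², p-values."""

    results: object   # statsmodels RegressionResults

    @property
    def params(self) -> pd.Series:
        return self.results.params

    @property
    def rsquared(self) -> float:
        return float(self.results.rsquared)

    @property
    def pvalues(self) -> pd.Series:
        return self.results.pvalues

    @property
    def f_pvalue(self) -> float:
        return float(self.results.f_pvalue)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(df[list(PREDICTORS)], has_constant="add")
        return np.asarray(self.results.predict(x))

    def summary(self):
        return self.results.summary()


def fit_veff_regression(data: pd.DataFrame,
                        response: str = "veff") -> VeffRegression:
    """OLS of V_eff on (CBF, ρc, CBA, y0, λ) with intercept.

    ``data`` must carry columns ``veff, cbf, rho_c, cba, y0, wavelength``
    (ρc as a fraction).  Requires at least 10 rows and a full-rank design.
    """
    missing = {response, *PREDICTORS} - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(data) < 10:
        raise ValueError("need at least 10 beads")
    x = sm.add_constant(data[list(PREDICTORS)].astype(float),
                        has_constant="add")
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("rank-deficient design: collinear predictors")
    fit = sm.OLS(data[response].astype(float), x).fit()
    return VeffRegression(results=fit)


# ---------------------------------------------------------------------------
# Median-split Mann–Whitney comparison
# ---------------------------------------------------------------------------

MedianSplit = namedtuple(
    "MedianSplit",
    ["median_y0", "mean_near", "mean_far", "sem_near", "sem_far",
     "n_near", "n_far", "u_statistic", "p_value"])


def median_split_test(v_b, y0) -> MedianSplit:
    """Two-sided Mann–Whitney U of bead speeds split at the median distance.

    Beads below the median distance form the *near* group, the rest the
    *far* group.  The exact null distribution is used for combined n ≤ 20
    without ties; otherwise the normal approximation with tie correction
    (no continuity correction, so identical groups give p = 1).
    """
    v_b = np.asarray(v_b, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if v_b.shape != y0.shape or v_b.size < 4:
        raise ValueError("need matched arrays of at least 4 beads")
    med = float(np.median(y0))
    near = v_b[y0 < med]
    far = v_b[y0 >= med]
    if near.size == 0 or far.size == 0:
        raise ValueError("median split left one group empty")
    pooled = np.concatenate([near, far])
    exact_ok = (pooled.size <= 20
                and len(np.unique(pooled)) == pooled.size)
    res = mannwhitneyu(near, far, alternative="two-sided",
                       method="exact" if exact_ok else "asymptotic",
                       use_continuity=False)
    return MedianSplit(
        median_y0=med,
        mean_near=float(near.mean()), mean_far=float(far.mean()),
        sem_near=float(near.std(ddof=1) / np.sqrt(near.size))
        if near.size > 1 else float("nan"),
        sem_far=float(far.std(ddof=1) / np.sqrt(far.size))
        if far.size > 1 else float("nan"),
        n_near=int(near.size), n_far=int(far.size),
        u_statistic=float(res.statistic), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# Bland–Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class BlandAltman:
    """Pairwise agreement: bias and 1.96-SD limits of agreement."""

    means: np.ndarray
    diffs: np.ndarray
    bias: float
    sd: float

    @property
    def limits(self):
        return (self.bias - 1.96 * self.sd, self.bias + 1.96 * self.sd)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.means, self.diffs, "o")
        ax.axhline(self.bias, ls="--", color="C0", label="bias")
        for lim in self.limits:
            ax.axhline(lim, ls="--", color="C3")
        ax.set_xlabel("pair mean (μm/s)")
        ax.set_ylabel("pair difference (μm/s)")
        ax.legend()
        return ax


def bland_altman(v_measured, v_simulated) -> BlandAltman:
    """Agreement between two velocity estimates per bead.

    Plots (conceptually) the per-pair difference against the per-pair mean;
    reports the overall bias and the mean ± 1.96·SD limits of agreement.
    """
    a = np.asarray(v_measured, dtype=float)
    b = np.asarray(v_simulated, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least 2 matched pairs")
    diffs = a - b
    sd = float(diffs.std(ddof=1))
    return BlandAltman(means=(a + b) / 2.0, diffs=diffs,
                       bias=float(diffs.mean()), sd=sd)


# ---------------------------------------------------------------------------
# Per-cilium force
# ---------------------------------------------------------------------------

PerCiliumForce = namedtuple("PerCiliumForce", ["force_pn", "caveat"])

_FORCE_CAVEAT = (
    "steady wall stress divided by areal cilia count; not directly "
    "comparable to oscillatory single-cilium force measurements, and the "
    "published per-cilium figures obtained from comparable stress values "
    "are not recovered by this plain division")


def per_cilium_force(tau_mpa: float,
                     areal_density_per_um2: float) -> PerCiliumForce:
    """Average steady force per cilium from the wall shear stress.

    τw in mPa over an areal density in cilia/μm² gives, per cilium,
    τw·10⁻³ Pa / (ρ·10¹² m⁻²) newtons, i.e. ``tau_mpa / density × 10⁻³``
    piconewtons.  Returned with an explicit caveat about comparability.
    """
    if areal_density_per_um2 <= 0:
        raise ValueError("areal density must be positive")
    force_pn = 1.0e-3 * tau_mpa / areal_density_per_um2
    return PerCiliumForce(force_pn=force_pn, caveat=_FORCE_CAVEAT)
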