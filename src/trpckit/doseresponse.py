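"""Hill dose-response analysis and chelator equilibria.

Normalized open probabilities of a ligand-gated channel are fitted to
the Hill equation

    Po(x) = A * x^n / (Kd^n + x^n)

with x the ligand (e.g. diC8-PIP2 or G-alpha) concentration, Kd the
apparent dissociation constant, n the Hill coefficient and A the
amplitude as a fraction of the within-patch maximum.  A two-ligand
surface is analysed as an independent Hill fit per co-ligand
concentration, giving the Kd shift and an amplification-ratio curve
(high-co-ligand curve divided by the low-co-ligand curve).

The module also contains a mass-action equilibrium solver for chelator
recipes (EGTA buffers), used to compute free divalent-cation
concentrations of recording solutions from total concentrations and
apparent stability constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HillFit",
    "PoSurface",
    "BufferRecipe",
    "DEFAULT_K_APP",
    "hill",
    "normalize_po",
    "fit_hill",
    "fit_surface",
    "amplification_curve",
    "free_ion_solver",
]


def hill(x, kd: float, n: float, amplitude: float = 1.0):
    """Hill equation A * x^n / (Kd^n + x^n)."""
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n)
    return amplitude * xn / (np.power(kd, n) + xn)


@dataclass
class HillFit:
    """Result of a Hill-equation fit.

    ``stderr`` holds asymptotic standard errors from the Jacobian at the
    optimum; ``flags`` lists quality problems (non-convergence, Kd far
    outside the dosed range, non-identifiable data).
    """

    kd: float
    n: float
    amplitude: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: list = field(default_factory=list)
    n_fixed: bool = False

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags

    def predict(self, x):
        return hill(x, self.kd, self.n, self.amplitude)

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd, "n": self.n, "amplitude": self.amplitude,
            "stderr": self.stderr, "converged": self.converged,
            "flags": list(self.flags), "n_fixed": self.n_fixed,
        }


def normalize_po(po_values, max_condition_po: float):
    """Normalize open probabilities to the same-patch maximum condition.

    Values exceeding 1 after normalization are reported with a warning
    but not clipped (they carry information about patch run-up).
    """
    if max_condition_po <= 0:
        raise ValueError("maximum-condition Po must be positive")
    out = np.asarray(po_values, dtype=float) / max_condition_po
    n_over = int(np.sum(out > 1.0))
    if n_over:
        warnings.warn(f"{n_over} normalized values exceed 1")
    return out


def fit_hill(concs, responses, fix_n: float | None = None,
             weights=None) -> HillFit:
    """Weighted nonlinear least-squares fit of the Hill equation.

    Bounded trust-region-reflective least squares initialised at
    Kd = geometric mean of the doses, n = 1 and A = max response.
    Needs >= 3 distinct concentrations (>= 2 when n is fixed).
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concs and responses must have the same shape")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    n_min = 2 if fix_n is not None else 3
    if np.unique(x).size < n_min:
        raise ValueError(f"need >= {n_min} distinct concentrations")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    flags: list[str] = []
    if np.ptp(y) < 1e-12:
        return HillFit(kd=np.nan, n=np.nan, amplitude=float(np.mean(y)),
                       converged=False, flags=["non-identifiable: constant responses"])

    kd0 = float(np.exp(np.mean(np.log(x))))
    a0 = float(max(y.max(), 1e-6))

    if fix_n is not None:
        theta0 = np.log([kd0, a0])
        def resid(theta):
            kd, a = np.exp(theta)
            return w * (hill(x, kd, fix_n, a) - y)
    else:
        theta0 = np.log([kd0, 1.0, a0])
        def resid(theta):
            kd, n, a = np.exp(theta)
            return w * (hill(x, kd, n, a) - y)

    # log-parameterization keeps Kd, n, A positive without hard bounds
    sol = optimize.least_squares(resid, theta0, method="trf",
                                 bounds=(-30.0, 30.0), xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14)
    params = np.exp(sol.x)
    if fix_n is not None:
        kd, a = params
        n = float(fix_n)
    else:
        kd, n, a = params

    # standard errors via the Jacobian in natural parameters
    stderr: dict[str, float] = {}
    dof = y.size - sol.x.size
    if sol.success and dof > 0:
        J = sol.jac * params  # chain rule: d/dlog(p) = p * d/dp
        s2 = 2.0 * sol.cost / dof
        try:
            cov_log = np.linalg.inv(J.T @ J) * s2 / params[:, None] / params[None, :]
            se = np.sqrt(np.diag(cov_log)) * params
            if fix_n is not None:
                stderr = {"kd": float(se[0]), "amplitude": float(se[1])}
            else:
                stderr = {"kd": float(se[0]), "n": float(se[1]),
                          "amplitude": float(se[2])}
        except np.linalg.LinAlgError:
            flags.append("singular covariance")

    span = (x.min(), x.max())
    if kd < span[0] / 100.0 or kd > span[1] * 100.0:
        flags.append("Kd outside dosed range by >100x")
    if not sol.success:
        flags.append("optimizer did not converge")
    return HillFit(kd=float(kd), n=float(n), amplitude=float(a),
                   stderr=stderr, converged=bool(sol.success), flags=flags,
                   n_fixed=fix_n is not None)


@dataclass
class PoSurface:
    """Normalized-Po measurements over a [PIP2] x [G-alpha] grid.

    ``data`` is long format with columns (pip2_uM, gai3_uM, replicate,
    po_norm).  ``truth`` optionally carries the generating parameters of
    synthetic surfaces.
    """

    data: pd.DataFrame
    truth: dict | None = None

    REQUIRED = ("pip2_uM", "gai3_uM", "replicate", "po_norm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"surface data missing columns: {missing}")
        if self.data.empty:
            raise ValueError("empty surface")

    @property
    def pip2_concs(self) -> np.ndarray:
        return np.sort(self.data["pip2_uM"].unique())

    @property
    def gai3_concs(self) -> np.ndarray:
        return np.sort(self.data["gai3_uM"].unique())

    @classmethod
    def from_csv(cls, path) -> "PoSurface":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SurfaceFit:
    fits: dict            # gai3_uM -> HillFit
    kd_trend: pd.DataFrame
    monotone_decreasing: bool
    flagged_columns: list


def fit_surface(surface: PoSurface, fix_n: float | None = None) -> SurfaceFit:
    """Independent Hill fit of Po vs [PIP2] for each co-ligand column.

    Returns the per-column fits, the apparent-Kd trend across the
    co-ligand concentrations and whether that trend is monotonically
    decreasing (increasing co-ligand sensitizing the channel to PIP2).
    Columns whose fit fails are flagged and excluded from the trend.
    """
    fits: dict[float, HillFit] = {}
    flagged: list[float] = []
    rows = []
    for g, sub in surface.data.groupby("gai3_uM"):
        x = sub["pip2_uM"].to_numpy(float)
        y = sub["po_norm"].to_numpy(float)
        if np.unique(x).size < 3:
            flagged.append(g)
            continue
        try:
            fit = fit_hill(x, y, fix_n=fix_n)
        except ValueError:
            flagged.append(g)
            continue
        fits[float(g)] = fit
        if fit.converged:
            rows.append({"gai3_uM": float(g), "kd_pip2_uM": fit.kd,
                         "n": fit.n, "amplitude": fit.amplitude})
        else:
            flagged.append(g)
    trend = pd.DataFrame(rows).sort_values("gai3_uM").reset_index(drop=True)
    mono = bool(len(trend) >= 2 and
                np.all(np.diff(trend["kd_pip2_uM"].to_numpy()) <= 0))
    return SurfaceFit(fits=fits, kd_trend=trend, monotone_decreasing=mono,
                      flagged_columns=flagged)


def amplification_curve(fit_lo: HillFit, fit_hi: HillFit, eval_points,
                        floor_fraction: float = 0.01) -> pd.DataFrame:
    """Fold-amplification of the response by the co-ligand.

    The fitted high-co-ligand Hill curve divided by the low-co-ligand
    curve, evaluated at the given doses.  Points where the denominator
    falls below ``floor_fraction`` of the global curve maximum are
    masked (NaN) to avoid the numerical singularity at vanishing doses.
    """
    x = np.asarray(eval_points, dtype=float)
    if np.any(x <= 0):
        raise ValueError("evaluation doses must be positive")
    lo = fit_lo.predict(x)
    hi = fit_hi.predict(x)
    floor = floor_fraction * max(fit_lo.amplitude, fit_hi.amplitude)
    ratio = np.where(lo >= floor, hi / np.where(lo > 0, lo, np.nan), np.nan)
    if np.all(np.isnan(ratio)):
        raise ValueError("denominator below floor at every evaluation point")
    return pd.DataFrame({"dose_uM": x, "po_lo": lo, "po_hi": hi,
                         "amplification": ratio,
                         "masked": ~np.isfinite(ratio)})


# Apparent (proton-corrected) 1:1 association constants, M^-1, for EGTA
# at pH 7.2, ~22 C, ionic strength ~0.15 M.  User-overridable; apparent
# constants of this kind are tabulation-dependent at the tens-of-percent
# level.
DEFAULT_K_APP: dict[tuple[str, str], float] = {
    ("Ca", "EGTA"): 10 ** 6.8,
    ("Mg", "EGTA"): 10 ** 1.6,
}


@dataclass
class BufferRecipe:
    """Total metal and chelator concentrations of a recording solution.

    Concentrations in mM; ``k_app`` maps (metal, chelator) to the
    apparent association constant in M^-1 at the recipe's pH,
    temperature and ionic strength.  Metal-chelator binding is treated
    as 1:1.
    """

    metals_mM: dict
    chelators_mM: dict
    pH: float = 7.2
    temperature_C: float = 22.0
    k_app: dict = field(default_factory=lambda: dict(DEFAULT_K_APP))

    def __post_init__(self) -> None:
        for name, tot in {**self.metals_mM, **self.chelators_mM}.items():
            if tot < 0:
                raise ValueError(f"negative total for {name}")
        for pair, k in self.k_app.items():
            if k <= 0:
                raise ValueError(f"non-positive stability constant for {pair}")


def free_ion_solver(recipe: BufferRecipe, tol: float = 1e-12,
                    max_iter: int = 500) -> dict:
    """Free metal-ion concentrations of a chelator buffer, in mM.

    Solves the coupled 1:1 mass-action equilibria

        [ML_j] = K_ij [M_i] [L_j]
        [M_i] + sum_j [ML_j] = M_i,tot      (each metal)
        [L_j] + sum_i [ML_j] = L_j,tot      (each chelator)

    by root-finding on the free chelator concentrations (bracketed
    Brent iteration for a single chelator, a damped Newton-type vector
    root otherwise) to a relative tolerance of ``tol``, then audits mass
    conservation.
    """
    metals = list(recipe.metals_mM)
    chels = list(recipe.chelators_mM)
    M_tot = np.array([recipe.metals_mM[m] for m in metals]) * 1e-3   # M
    L_tot = np.array([recipe.chelators_mM[c] for c in chels]) * 1e-3
    K = np.array([[recipe.k_app.get((m, c), 0.0) for c in chels]
                  for m in metals])  # M^-1

    if not chels or np.all(L_tot == 0) or K.size == 0 or np.all(K == 0):
        return {m: recipe.metals_mM[m] for m in metals}

    def chel_residual(L: np.ndarray) -> np.ndarray:
        M_free = M_tot / (1.0 + K @ L)
        return L * (1.0 + (K * M_free[:, None]).sum(axis=0)) - L_tot

    if len(chels) == 1:
        # 1-D residual is monotone increasing in L: bracket and solve
        f = lambda l: chel_residual(np.array([l]))[0]
        lo = 0.0
        hi = float(L_tot[0])
        L0 = optimize.brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16,
                             maxiter=max_iter)
        L = np.array([L0])
    else:
        sol = optimize.root(lambda z: chel_residual(np.exp(z)),
                            np.log(np.maximum(L_tot, 1e-30)),
                            method="hybr", tol=tol)
        if not sol.success:
            raise RuntimeError(
                f"free-ion solver did not converge: {sol.message}; "
                f"residuals {chel_residual(np.exp(sol.x))}")
        L = np.exp(sol.x)

    M_free = M_tot / (1.0 + K @ L)
    # mass-conservation audit
    ML = K * M_free[:, None] * L[None, :]
    metal_resid = np.abs(M_free + ML.sum(axis=1) - M_tot)
    chel_resid = np.abs(L + ML.sum(axis=0) - L_tot)
    if np.any(metal_resid > 1e-9 * np.maximum(M_tot, 1e-300)) or \
       np.any(chel_resid > 1e-9 * np.maximum(L_tot, 1e-300)):
        raise RuntimeError("mass conservation violated in free-ion solution")
    out = {m: float(M_free[i] * 1e3) for i, m in enumerate(metals)}
    out.update({f"{c}_free": float(L[j] * 1e3) for j, c in enumerate(chels)})
    return out
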