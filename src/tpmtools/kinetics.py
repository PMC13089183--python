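"""Michaelis–Menten kinetics for methyltransferase initial-rate data.

Implements single-substrate Michaelis–Menten fitting and a piecewise
dual-substrate model for reactions where the added substrate (e.g. Na2S in
the presence of GSH) is converted in situ into a second, more efficiently
methylated species (GSS-) up to a breakpoint concentration C1.  Below C1 all
substrate reacts through the persulfide branch; above C1 the persulfide
branch saturates at C1 and the excess behaves as free H2S:

    v0_app(S) = v0_GSS(S) + v0_H2S(S)
    v0_GSS(S) = MM(S; Km_GSS, Vmax_GSS)        if S <  C1
              = MM(C1; Km_GSS, Vmax_GSS)       if S >= C1
    v0_H2S(S) = 0                              if S <  C1
              = MM(S - C1; Km_H2S, Vmax_H2S)   if S >= C1

Units: concentrations in uM, rates in nmol/min/mg.  The catalytic
efficiency Vmax/Km is then numerically in L/min/g because
(nmol min^-1 mg^-1) / (umol L^-1) = (L min^-1 g^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MMParams",
    "KineticDataset",
    "MMFit",
    "DualMMModel",
    "DualMMFit",
    "predict_mm",
    "fit_mm",
    "catalytic_efficiency",
    "predict_dual_mm",
    "fit_c1",
]

KINETIC_COLUMNS = ("substrate_uM", "rate_nmol_min_mg", "replicate", "condition")


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten parameters: Km in uM, Vmax in nmol/min/mg."""

    km: float
    vmax: float

    def __post_init__(self) -> None:
        if not (self.km > 0):
            raise ValueError(f"km must be > 0, got {self.km}")
        if not (self.vmax >= 0):
            raise ValueError(f"vmax must be >= 0, got {self.vmax}")


@dataclass
class KineticDataset:
    """Replicated initial-rate observations versus substrate concentration.

    ``table`` has columns substrate_uM (>= 0), rate_nmol_min_mg, replicate,
    condition.  Zero-concentration rows are retained: the model passes
    through the origin, so blanks anchor the fit rather than being discarded.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KINETIC_COLUMNS[:2] if c not in self.table.columns]
        if missing:
            raise ValueError(f"kinetic table missing columns: {missing}")
        if "replicate" not in self.table.columns:
            self.table = self.table.assign(replicate=0)
        if "condition" not in self.table.columns:
            self.table = self.table.assign(condition="")
        s = self.table["substrate_uM"].to_numpy(dtype=float)
        if np.any(s < 0):
            raise ValueError("negative substrate concentrations are not allowed")
        if not np.all(np.isfinite(self.table["rate_nmol_min_mg"].to_numpy(dtype=float))):
            raise ValueError("rates must be finite")

    @property
    def s(self) -> np.ndarray:
        return self.table["substrate_uM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.table["rate_nmol_min_mg"].to_numpy(dtype=float)

    def n_distinct_positive(self) -> int:
        return int(np.unique(self.s[self.s > 0]).size)

    @classmethod
    def from_arrays(
        cls,
        substrate_uM: Sequence[float],
        rate: Sequence[float],
        replicate: Sequence[int] | None = None,
        condition: str = "",
    ) -> "KineticDataset":
        n = len(substrate_uM)
        rep = replicate if replicate is not None else np.zeros(n, dtype=int)
        return cls(
            pd.DataFrame(
                {
                    "substrate_uM": np.asarray(substrate_uM, dtype=float),
                    "rate_nmol_min_mg": np.asarray(rate, dtype=float),
                    "replicate": np.asarray(rep),
                    "condition": condition,
                }
            )
        )


@dataclass
class MMFit:
    """Result of a single-substrate Michaelis–Menten fit."""

    km: float
    vmax: float
    efficiency: float
    residual_ss: float
    converged: bool
    n_obs: int
    standard_errors: dict[str, float] | None = None
    identifiable: bool = True
    message: str = ""


@dataclass(frozen=True)
class DualMMModel:
    """Two Michaelis–Menten branches joined at breakpoint ``c1`` (uM)."""

    gss: MMParams
    h2s: MMParams
    c1: float

    def __post_init__(self) -> None:
        if not (self.c1 >= 0):
            raise ValueError(f"c1 must be >= 0, got {self.c1}")


@dataclass
class DualMMFit:
    model: DualMMModel
    residual_ss: float
    converged: bool
    c1_se: float | None = None


def predict_mm(params: MMParams, s) -> np.ndarray | float:
    """Initial rate v0 = Vmax * S / (Km + S) at concentration(s) ``s`` (uM)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = params.vmax * s_arr / (params.km + s_arr)
    return float(out) if np.isscalar(s) or out.ndim == 0 else out


def catalytic_efficiency(vmax: float, km: float) -> float:
    """Vmax/Km in L/min/g (for vmax in nmol/min/mg and km in uM)."""
    if not (km > 0):
        raise ValueError(f"km must be > 0, got {km}")
    return vmax / km


def predict_dual_mm(model: DualMMModel, s) -> np.ndarray | float:
    """Apparent rate of the piecewise dual-substrate model.

    Continuous at S = c1 because the H2S branch starts from MM(0) = 0 while
    the GSS branch freezes at its value at c1.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    below = s_arr < model.c1
    v_gss = np.where(
        below,
        model.gss.vmax * s_arr / (model.gss.km + s_arr),
        model.gss.vmax * model.c1 / (model.gss.km + model.c1),
    )
    excess = np.clip(s_arr - model.c1, 0.0, None)
    v_h2s = np.where(below, 0.0, model.h2s.vmax * excess / (model.h2s.km + excess))
    out = v_gss + v_h2s
    return float(out[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else out


def _mm_residuals(theta: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    km, vmax = theta
    return vmax * s / (km + s) - v


def fit_mm(data: KineticDataset, init: MMParams | None = None) -> MMFit:
    """Bounded non-linear least-squares fit of (Km, Vmax).

    Default initialization sets Vmax0 to the largest observed rate and Km0
    to the design concentration whose mean rate is nearest Vmax0/2.  Three
    starts (Km0, Km0/10, Km0*10) guard against the shallow-Km pathology when
    the design barely saturates the enzyme.
    """
    s, v = data.s, data.v
    n = s.size
    if data.n_distinct_positive() < 2:
        raise ValueError(
            "at least 2 distinct positive substrate concentrations are required "
            "to identify (Km, Vmax)"
        )
    if np.allclose(v, 0.0):
        return MMFit(
            km=float("nan"),
            vmax=0.0,
            efficiency=float("nan"),
            residual_ss=0.0,
            converged=True,
            n_obs=n,
            identifiable=False,
            message="all rates zero: vmax = 0, km unidentifiable",
        )

    if init is not None:
        starts = [(init.km, init.vmax)]
    else:
        vmax0 = float(np.max(v))
        pos = s > 0
        means = pd.Series(v[pos]).groupby(pd.Series(s[pos])).mean()
        km0 = float(means.index[np.argmin(np.abs(means.to_numpy() - vmax0 / 2))])
        starts = [(km0, vmax0), (km0 / 10, vmax0), (km0 * 10, vmax0)]

    best = None
    for km0, vmax0 in starts:
        res = optimize.least_squares(
            _mm_residuals,
            x0=[max(km0, 1e-6), max(vmax0, 0.0)],
            bounds=([1e-9, 0.0], [np.inf, np.inf]),
            args=(s, v),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res

    km_hat, vmax_hat = best.x
    ss = float(2 * best.cost)
    ses = None
    dof = n - 2
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * ss / dof
            ses = {"km": float(np.sqrt(cov[0, 0])), "vmax": float(np.sqrt(cov[1, 1]))}
        except np.linalg.LinAlgError:
            ses = None
    return MMFit(
        km=float(km_hat),
        vmax=float(vmax_hat),
        efficiency=catalytic_efficiency(float(vmax_hat), float(km_hat)),
        residual_ss=ss,
        converged=bool(best.success),
        n_obs=n,
        standard_errors=ses,
        message=best.message,
    )


def fit_c1(
    data: KineticDataset,
    gss: MMParams,
    h2s: MMParams,
    n_grid: int = 2001,
    refine_xatol: float = 1e-6,
    refit_branches: bool = False,
) -> DualMMFit:
    """Least-squares estimate of the breakpoint C1 with branch parameters fixed.

    The branch (Km, Vmax) pairs are determined beforehand from the
    single-substrate reactions and held constant; only C1 is free, on
    [0, max(S)].  Because the objective has kinks where C1 crosses a design
    concentration, a dense grid locates the basin and bounded scalar
    minimization refines within the bracketing grid cells.

    With ``refit_branches=True`` all five parameters are re-optimized from
    the C1 solution (off by default; the breakpoint-only fit mirrors the
    intended two-stage procedure).
    """
    s, v = data.s, data.v
    if s.size == 0:
        raise ValueError("empty dataset")
    smax = float(np.max(s))

    def sse(c1: float) -> float:
        model = DualMMModel(gss=gss, h2s=h2s, c1=float(c1))
        r = predict_dual_mm(model, s) - v
        return float(np.dot(r, r))

    grid = np.linspace(0.0, smax, n_grid)
    sses = np.array([sse(c) for c in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    converged = True
    if hi > lo:
        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": refine_xatol}
        )
        c1_hat = float(res.x) if res.fun <= sses[i] else float(grid[i])
        converged = bool(res.success)
    else:
        c1_hat = float(grid[i])

    if refit_branches:
        def resid(theta: np.ndarray) -> np.ndarray:
            model = DualMMModel(
                gss=MMParams(theta[0], theta[1]),
                h2s=MMParams(theta[2], theta[3]),
                c1=theta[4],
            )
            return predict_dual_mm(model, s) - v

        res = optimize.least_squares(
            resid,
            x0=[gss.km, gss.vmax, h2s.km, h2s.vmax, c1_hat],
            bounds=([1e-9, 0, 1e-9, 0, 0], [np.inf] * 4 + [smax]),
        )
        model = DualMMModel(
            gss=MMParams(*res.x[:2]), h2s=MMParams(*res.x[2:4]), c1=float(res.x[4])
        )
        return DualMMFit(model=model, residual_ss=float(2 * res.cost), converged=bool(res.success))

    model = DualMMModel(gss=gss, h2s=h2s, c1=c1_hat)
    return DualMMFit(model=model, residual_ss=sse(c1_hat), converged=converged)
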