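"""Non-compartmental analysis, fold-error validation and sensitivity scans.

NCA endpoints are estimated directly from observed concentration-time
points: Cmax/Tmax by inspection, AUC by the trapezoidal rule, the terminal
slope lambda_z by log-linear regression over the suffix of terminal points
(length >= 3, Tmax excluded) with the best adjusted R^2, and the usual
derived quantities AUC0-inf = AUC0-t + C_last/lambda_z, t1/2 = ln2/lambda_z,
MRT = AUMC/AUC, CL = dose/AUC0-inf and Vd = CL/lambda_z. For non-iv routes
CL and Vd are apparent (CL/F, Vd/F).

Prediction accuracy is scored by the fold error, max(obs/sim, sim/obs),
with <= 2 the customary accuracy bound; the sensitivity factor of an output
scanned over a parameter range is (max - min)/max, in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .disposition import PlasmaCurve
from .engine import ExposureSummary
from .parameters import Route

__all__ = [
    "NCAResult",
    "SensitivityResult",
    "run_nca",
    "fold_error",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class NCAResult:
    cmax: float               # ug/L
    tmax: float               # h
    auc_0t: float             # ug h / L
    auc_inf: Optional[float]  # None when lambda_z could not be estimated
    mrt_0t: float             # h
    mrt_inf: Optional[float]
    lambda_z: Optional[float]  # 1/h
    t_half: Optional[float]    # h
    cl: Optional[float]        # L/h (apparent unless iv)
    vd: Optional[float]        # L
    f_rel: Optional[float]     # %, relative to the iv reference
    n_lambda_points: int = 0
    lambda_r2adj: Optional[float] = None

    def summary(self) -> str:
        fmt = lambda v, u="": ("n/a" if v is None else f"{v:.4g}{u}")
        return "\n".join([
            "Non-compartmental analysis",
            f"  Cmax  {self.cmax:.2f} ug/L at Tmax {self.tmax:.3f} h",
            f"  AUC0-t {self.auc_0t:.2f}  AUC0-inf {fmt(self.auc_inf)} ug*h/L",
            f"  MRT0-t {self.mrt_0t:.3f}  MRT0-inf {fmt(self.mrt_inf)} h",
            f"  lambda_z {fmt(self.lambda_z, ' 1/h')} "
            f"({self.n_lambda_points} pts, adj R2 {fmt(self.lambda_r2adj)})"
            f"  t1/2 {fmt(self.t_half, ' h')}",
            f"  CL {fmt(self.cl, ' L/h')}  Vd {fmt(self.vd, ' L')}"
            f"  F {fmt(self.f_rel, ' %')}",
        ])


def _terminal_slope(t: np.ndarray, c: np.ndarray, i_tmax: int
                    ) -> tuple[Optional[float], int, Optional[float]]:
    """Best-adjusted-R^2 log-linear terminal fit over suffixes of length >=3."""
    start_min = i_tmax + 1  # exclude Tmax and earlier
    best = (None, 0, None)
    best_r2 = -np.inf
    logc = np.log(c)
    for start in range(start_min, t.size - 2):
        tt, yy = t[start:], logc[start:]
        n = tt.size
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and r2adj > best_r2:
            best_r2 = r2adj
            best = (-slope, n, r2adj)
    return best


def run_nca(curve: PlasmaCurve, iv_reference: Optional[PlasmaCurve] = None
            ) -> NCAResult:
    """Non-compartmental endpoints for one plasma curve.

    Censored samples (NaN) are dropped. ``iv_reference`` enables the
    relative bioavailability F = 100 * (AUC/dose) / (AUC_iv/dose_iv).
    """
    keep = np.isfinite(curve.concentrations)
    t, c = curve.times[keep], curve.concentrations[keep]
    pos = c > 0
    if pos.sum() < 5:
        raise ValueError(f"need >=5 positive concentrations, have {int(pos.sum())}")
    # AUC over the observed support (to the last measurable concentration)
    last = int(np.nonzero(pos)[0][-1])
    t, c = t[:last + 1], c[:last + 1]
    if t[0] > 0:
        if curve.route is Route.iv and c[0] > 0 and c[1] > 0 and c[1] < c[0]:
            # iv bolus: back-extrapolate C0 log-linearly from the first two points
            slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
            c0 = float(c[0] * np.exp(-slope * t[0]))
        else:
            c0 = 0.0  # extravascular: no drug in plasma at dosing
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])
    i_tmax = int(np.argmax(c))
    cmax, tmax = float(c[i_tmax]), float(t[i_tmax])
    auc_0t = float(np.trapezoid(c, t))
    aumc_0t = float(np.trapezoid(c * t, t))
    mrt_0t = aumc_0t / auc_0t

    tpos, cpos = t[c > 0], c[c > 0]
    lam, n_pts, r2adj = _terminal_slope(tpos, cpos, int(np.argmax(cpos)))
    if lam is None:
        return NCAResult(cmax=cmax, tmax=tmax, auc_0t=auc_0t, auc_inf=None,
                         mrt_0t=mrt_0t, mrt_inf=None, lambda_z=None, t_half=None,
                         cl=None, vd=None, f_rel=None)
    c_last, t_last = float(cpos[-1]), float(tpos[-1])
    auc_inf = auc_0t + c_last / lam
    aumc_inf = aumc_0t + c_last * t_last / lam + c_last / lam ** 2
    mrt_inf = aumc_inf / auc_inf
    dose_ug = curve.dose * 1000.0
    cl = dose_ug / auc_inf           # L/h (apparent for extravascular routes)
    vd = cl / lam
    f_rel = None
    if iv_reference is not None:
        ref = run_nca(iv_reference)
        if ref.auc_inf:
            f_rel = 100.0 * (auc_inf / curve.dose) / (ref.auc_inf / iv_reference.dose)
    return NCAResult(cmax=cmax, tmax=tmax, auc_0t=auc_0t, auc_inf=auc_inf,
                     mrt_0t=mrt_0t, mrt_inf=mrt_inf, lambda_z=lam,
                     t_half=float(np.log(2.0) / lam), cl=cl, vd=vd, f_rel=f_rel,
                     n_lambda_points=n_pts, lambda_r2adj=r2adj)


def fold_error(observed: float, simulated: float) -> float:
    """max(observed/simulated, simulated/observed); 1.0 at equality.

    A prediction is conventionally deemed accurate when the fold error is
    within two.
    """
    if observed <= 0 or simulated <= 0:
        raise ValueError("fold_error requires positive inputs")
    return max(observed / simulated, simulated / observed)


@dataclass(frozen=True)
class SensitivityResult:
    parameter_name: str
    grid: np.ndarray
    outputs: tuple[ExposureSummary, ...]
    factors: dict[str, float]     # per exposure metric, (max-min)/max

    def summary(self) -> str:
        lines = [f"Sensitivity of exposure to {self.parameter_name} "
                 f"over [{self.grid[0]:g}, {self.grid[-1]:g}] ({self.grid.size} pts)"]
        for k, v in self.factors.items():
            lines.append(f"  {k:>16s}: factor {v:.3f}")
        return "\n".join(lines)


_METRICS = ("tmax", "cmax", "auc_inf", "bioavailability")


def sensitivity_scan(engine: Callable[[float], ExposureSummary],
                     parameter: str, low: float, high: float,
                     n_points: int = 11) -> SensitivityResult:
    """Scan ``engine`` over a uniform parameter grid and score sensitivity.

    ``engine`` maps a parameter value to an :class:`ExposureSummary`; the
    sensitivity factor per metric is (max - min)/max, 0 for a flat response.
    """
    if n_points < 2 or not low < high:
        raise ValueError("need n_points >= 2 and low < high")
    grid = np.linspace(low, high, n_points)
    outputs = []
    for x in grid:
        try:
            outputs.append(engine(float(x)))
        except Exception as exc:
            raise RuntimeError(f"engine failed at {parameter}={x:g}: {exc}") from exc
    factors = {}
    for m in _METRICS:
        vals = np.array([getattr(o, m) for o in outputs], dtype=float)
        vmax = vals.max()
        factors[m] = float((vmax - vals.min()) / vmax) if vmax > 0 else 0.0
    return SensitivityResult(parameter_name=parameter, grid=grid,
                             outputs=tuple(outputs), factors=factors)
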