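"""Oral-cavity compartmental absorption model (six mucosal sites).

A film placed in the mouth dissolves into a shared saliva pool (z-factor
kinetics) that grows with secretion up to the resting capacity of the
mouth. Dissolved drug partitions from saliva into the
epithelium of each permeable site with a Fickian net flux

    J_i = A_i * (D_t / h_i) * (fu * C_saliva - F_ut * C_tissue,i) * u_i * U

(A area, h epithelium thickness, D_t epithelial diffusivity, fu / F_ut the
free fractions in saliva-plasma and oral tissue, u_i the per-site
permeability class factor, U the global uptake scale), and tissue drug
transfers to the systemic circulation at a first-order rate
k_i = (D_t / h_i^2) * T. Under the Hold & Swallow regimen swallowing is
suppressed for the residence time; at its end the entire saliva content
(dissolved + undissolved) is swallowed as one bolus to the stomach, and
drug already in the epithelium continues draining to the systemic
circulation.

``U`` (uptake) and ``T`` (transfer) are the two calibration scales that
absorb the unknown dog oral physiology; they are estimated from the
reported oral-absorption fractions at two residence times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .dissolution import dissolution_rate, solubility_at_ph
from .parameters import ParameterSet, Route

__all__ = [
    "OralCompartment",
    "MouthPhysiology",
    "MucosaScales",
    "OralTrajectory",
    "default_dog_mouth",
    "simulate_oral_hold",
    "oral_absorbed_fraction",
    "calibrate_mucosa_scales",
]

ORAL_SITES = ("buccal", "gingival", "palate", "tongue_top", "tongue_bottom", "mouth_floor")

#: Uptake multiplier for keratinized epithelium relative to non-keratinized.
KERATINIZED_UPTAKE = 0.25


@dataclass(frozen=True)
class OralCompartment:
    name: str
    area: float                  # cm^2
    epithelium_thickness: float  # cm
    keratinized: bool
    permeable: bool = True
    uptake_scale: float = 1.0    # per-site permeability class factor

    def __post_init__(self):
        if self.area <= 0 or self.epithelium_thickness <= 0:
            raise ValueError(f"{self.name}: area and thickness must be positive")
        if self.uptake_scale < 0:
            raise ValueError(f"{self.name}: uptake_scale must be nonnegative")


@dataclass(frozen=True)
class MouthPhysiology:
    """Oral physiology table plus the shared saliva pool parameters.

    During the hold, secretion accrues saliva volume up to
    ``saliva_capacity``, the resting fluid capacity of the mouth beyond
    which reflexive clearance prevents further pooling.
    """

    compartments: tuple[OralCompartment, ...]
    saliva_baseline: float = 1.0      # ml
    saliva_secretion: float = 0.5     # ml/min during the hold
    saliva_capacity: float = 3.0      # ml, maximum pooled volume
    saliva_ph: float = 6.8


@dataclass(frozen=True)
class MucosaScales:
    """Global calibration multipliers on uptake and tissue-to-systemic transfer."""

    uptake_scale: float = 1.0
    transfer_scale: float = 1.0

    def __post_init__(self):
        if self.uptake_scale < 0 or self.transfer_scale < 0:
            raise ValueError("scales must be nonnegative")


def default_dog_mouth() -> MouthPhysiology:
    """Literature-plausible dog oral physiology (a calibration surface).

    Total mucosal area 30 cm^2; keratinized sites (gingival, palate, tongue
    top) get thicker epithelium and a 0.25 uptake factor; baseline saliva
    1 ml with 0.5 ml/min secretion during the hold.
    """
    spec = {  # name: (area cm^2, keratinized)
        "buccal": (9.0, False), "gingival": (5.0, True), "palate": (5.0, True),
        "tongue_top": (5.0, True), "tongue_bottom": (3.0, False),
        "mouth_floor": (3.0, False),
    }
    comps = tuple(
        OralCompartment(name, area, 0.08 if ker else 0.05, ker,
                        uptake_scale=KERATINIZED_UPTAKE if ker else 1.0)
        for name, (area, ker) in spec.items())
    return MouthPhysiology(compartments=comps)


@dataclass(frozen=True)
class OralTrajectory:
    """Oral-cavity mass ledger over time (amounts ug)."""

    times: np.ndarray                  # h
    saliva_undissolved: np.ndarray
    saliva_dissolved: np.ndarray
    tissue: np.ndarray                 # (n_times, n_sites)
    systemic_from_mucosa: np.ndarray   # cumulative
    swallowed: np.ndarray              # cumulative (single bolus at hold end)
    dose: float
    hold_time: float                   # min
    sites: tuple[str, ...]

    #: (undissolved_ug, dissolved_ug) handed to the stomach at the swallow;
    #: set by :func:`simulate_oral_hold`.
    _bolus: tuple[float, float] = (0.0, 0.0)

    @property
    def swallowed_bolus(self) -> tuple[float, float, float]:
        """(time_h, undissolved_ug, dissolved_ug) delivered to the stomach."""
        return (self.hold_time / 60.0, float(self._bolus[0]), float(self._bolus[1]))

    def ledger_error(self) -> float:
        total = (self.saliva_undissolved + self.saliva_dissolved
                 + self.tissue.sum(axis=1) + self.systemic_from_mucosa + self.swallowed)
        return float(np.max(np.abs(total - self.dose)) / self.dose)


def _site_constants(p: ParameterSet, mouth: MouthPhysiology, scales: MucosaScales):
    d_t = p.absorption.mucosa_diffusivity * 3600.0  # cm^2/h
    comps = mouth.compartments
    perm = np.array([c.permeable for c in comps])
    area = np.array([c.area for c in comps])
    thick = np.array([c.epithelium_thickness for c in comps])
    usite = np.array([c.uptake_scale for c in comps]) * perm
    # saliva->tissue conductance (ml/h per unit ug/ml gradient) and
    # tissue->systemic first-order rate (1/h)
    g_up = area * (d_t / thick) * usite * scales.uptake_scale
    k_tr = (d_t / thick ** 2) * scales.transfer_scale
    tissue_vol = area * thick  # cm^3 = ml
    return g_up, k_tr, tissue_vol


def simulate_oral_hold(p: ParameterSet, mouth: MouthPhysiology, scales: MucosaScales,
                       site: Route | str, hold_time: float, z: float,
                       horizon: float = 32.0, n_out: int = 200) -> OralTrajectory:
    """Simulate the Hold & Swallow oral phase.

    ``site`` is ``supralingual`` (film on the tongue top) or ``sublingual``
    (under the tongue: tongue bottom + mouth floor); while undissolved film
    remains, the deposition sites see saturated drug at the film surface in
    addition to the bulk saliva concentration. ``hold_time`` is in minutes;
    ``z`` is the dissolution coefficient fitted in vitro.
    """
    site = Route(site) if not isinstance(site, Route) else site
    if site not in (Route.supralingual, Route.sublingual):
        raise ValueError(f"site must be supralingual or sublingual, got {site}")
    if hold_time < 0:
        raise ValueError("hold_time must be nonnegative")

    comps = mouth.compartments
    names = tuple(c.name for c in comps)
    deposition = {"supralingual": ("tongue_top",),
                  "sublingual": ("tongue_bottom", "mouth_floor")}[site.value]
    dep_mask = np.array([c.name in deposition for c in comps], dtype=float)
    g_up, k_tr, tissue_vol = _site_constants(p, mouth, scales)
    fu, fut = p.drug.fu_plasma, p.absorption.fu_oral_tissue
    cs = solubility_at_ph(p.drug, mouth.saliva_ph)  # mg/ml
    dose = p.dose_ug
    n = len(comps)
    hold_h = hold_time / 60.0
    secretion_h = mouth.saliva_secretion * 60.0  # ml/h

    # state: [saliva_und, saliva_dis, tissue (n), systemic_cum]
    def rhs_hold(t, y):
        und, dis = y[0], y[1]
        tis = y[2:2 + n]
        vol = min(mouth.saliva_baseline + secretion_h * t, mouth.saliva_capacity)
        c_sal = dis / vol
        diss = dissolution_rate(z, und, dose, c_sal, cs)
        c_tis = np.divide(tis, tissue_vol)
        j_bulk = g_up * (fu * c_sal - fut * c_tis)
        # film-contact term: deposition sites see saturated surface while
        # solid film remains; drawn from the solid mass, fading as it dissolves
        w = und / (und + 0.02 * dose) if und > 0 else 0.0
        j_contact = g_up * dep_mask * fu * max(cs * 1000.0 - c_sal, 0.0) * w
        transfer = k_tr * tis
        dy = np.empty(3 + n)
        dy[0] = -diss - j_contact.sum()
        dy[1] = diss - j_bulk.sum()
        dy[2:2 + n] = j_bulk + j_contact - transfer
        dy[2 + n] = transfer.sum()
        return dy

    def rhs_post(_t, y):
        transfer = k_tr * y[2:2 + n]
        dy = np.zeros(3 + n)
        dy[2:2 + n] = -transfer
        dy[2 + n] = transfer.sum()
        return dy

    times_out = np.unique(np.concatenate([
        np.linspace(0.0, max(hold_h, 1e-6), 50), np.linspace(0.0, horizon, n_out)]))
    y0 = np.zeros(3 + n)
    y0[0] = dose

    ts, ys, swallowed = [], [], []
    bolus = (0.0, 0.0)
    if hold_h > 0:
        mask = times_out <= hold_h
        sol = solve_ivp(rhs_hold, (0.0, hold_h), y0, t_eval=times_out[mask],
                        method="LSODA", rtol=1e-10, atol=1e-8, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"oral integration failed: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        swallowed.append(np.zeros(sol.t.size))
        y0 = sol.sol(hold_h)
    bolus = (max(y0[0], 0.0), max(y0[1], 0.0))
    y0 = y0.copy()
    y0[0] = y0[1] = 0.0
    mask = times_out >= hold_h
    sol = solve_ivp(rhs_post, (hold_h, horizon), y0, t_eval=times_out[mask],
                    method="LSODA", rtol=1e-10, atol=1e-8)
    if not sol.success:
        raise RuntimeError(f"oral integration failed: {sol.message}")
    ts.append(sol.t)
    ys.append(sol.y)
    swallowed.append(np.full(sol.t.size, bolus[0] + bolus[1]))

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    sw_all = np.concatenate(swallowed)
    traj = OralTrajectory(
        times=t_all, saliva_undissolved=np.maximum(y_all[0], 0.0),
        saliva_dissolved=np.maximum(y_all[1], 0.0), tissue=y_all[2:2 + n].T,
        systemic_from_mucosa=y_all[2 + n], swallowed=sw_all,
        dose=dose, hold_time=hold_time, sites=names)
    object.__setattr__(traj, "_bolus", bolus)
    return traj


def oral_absorbed_fraction(traj: OralTrajectory) -> float:
    """Fraction of the dose that crossed the saliva-epithelium interface."""
    crossed = traj.tissue[-1].sum() + traj.systemic_from_mucosa[-1]
    return float(crossed / traj.dose)


def calibrate_mucosa_scales(p: ParameterSet, target_2min: float, target_10min: float,
                            mouth: MouthPhysiology | None = None, z: float = None,
                            site: Route = Route.supralingual,
                            tol: float = 1e-4) -> MucosaScales:
    """Estimate (uptake, transfer) scales from two oral-fraction anchors.

    Solves the 2x2 system: oral absorbed fraction at a 2-min hold equals
    ``target_2min`` and at a 10-min hold equals ``target_10min``, each
    within ``tol`` absolute. The two scales are identifiable because the
    transfer rate controls epithelial back-pressure and hence how strongly
    uptake saturates at longer residence times.
    """
    from .dissolution import DEFAULT_Z_FACTOR

    if not 0.0 < target_2min < target_10min < 1.0:
        raise ValueError("targets must satisfy 0 < target_2min < target_10min < 1")
    mouth = mouth or default_dog_mouth()
    z = DEFAULT_Z_FACTOR if z is None else z

    def frac(scales: MucosaScales, hold: float) -> float:
        # the crossed fraction is fixed at the end of the hold (no back-flux
        # afterwards), so the short horizon is exact and cheap
        traj = simulate_oral_hold(p, mouth, scales, site, hold, z,
                                  horizon=hold / 60.0 + 1e-6, n_out=5)
        return oral_absorbed_fraction(traj)

    def residuals(logx):
        scales = MucosaScales(*np.exp(logx))
        return [frac(scales, 2.0) - target_2min, frac(scales, 10.0) - target_10min]

    sol = least_squares(residuals, x0=np.log([30.0, 1.0]), method="lm",
                        xtol=1e-12, ftol=1e-12)
    resid = np.abs(sol.fun)
    if not np.all(resid < tol):
        raise RuntimeError(
            f"mucosa calibration failed: residuals {sol.fun} exceed tol {tol}")
    return MucosaScales(*np.exp(sol.x))
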