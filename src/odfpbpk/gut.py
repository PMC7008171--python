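"""Compartmental absorption-and-transit (CAT-style) gastrointestinal model.

The gut is a chain of nine well-stirred compartments — stomach, seven small
intestine segments, colon — with first-order transit between neighbours.
Within each compartment drug is tracked as undissolved and dissolved mass;
dissolution follows the z-factor law at the local pH solubility,
supersaturated drug precipitates back toward saturation with the mean
precipitation time constant, and dissolved drug in absorbing segments
enters the portal circulation at ka = 2 Peff / R.

The default fasted-beagle physiology table is not measured data: it is a
literature-typical calibration surface (the study's software keeps its dog
physiology internal), fully overridable per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dissolution import dissolution_rate, solubility_at_ph
from .parameters import ParameterSet

__all__ = [
    "GutCompartment",
    "GutTrajectory",
    "default_dog_gut",
    "absorption_rate_constant",
    "simulate_gut",
    "fraction_absorbed",
]


@dataclass(frozen=True)
class GutCompartment:
    name: str
    volume: float        # ml luminal fluid
    ph: float
    radius: float        # cm
    transit_time: float  # h (mean residence; first-order rate 1/transit_time)
    absorbing: bool
    ka_scale: float = 1.0

    def __post_init__(self):
        if min(self.volume, self.radius, self.transit_time) <= 0:
            raise ValueError(f"{self.name}: volume, radius, transit_time must be positive")


#: Total small-intestine transit time, hours (fasted beagle).
DEFAULT_SI_TRANSIT_H = 2.0


def default_dog_gut(si_transit_total: float = DEFAULT_SI_TRANSIT_H) -> list[GutCompartment]:
    """Fasted-beagle default physiology: stomach + 7 SI segments + colon.

    Stomach is non-absorbing (pH 1.5); its 0.15 h mean residence reflects
    the fast fasted-state emptying of liquids in dogs (half-time of a few
    minutes), appropriate because the dose arrives dissolved or as a
    rapidly disintegrated film rather than as a monolithic solid. The seven
    small-intestine segments share ``si_transit_total`` equally with a pH
    gradient 6.2 -> 7.4; the colon absorbs at half the small-intestinal
    ka for its larger radius and mixed contents.
    """
    si_ph = (6.2, 6.2, 6.4, 6.6, 6.8, 7.0, 7.4)
    comps = [GutCompartment("stomach", 50.0, 1.5, 1.0, 0.15, absorbing=False)]
    for i, ph in enumerate(si_ph, start=1):
        comps.append(GutCompartment(f"si{i}", 15.0, ph, 0.5,
                                    si_transit_total / 7.0, absorbing=True))
    comps.append(GutCompartment("colon", 100.0, 6.8, 1.0, 12.0,
                                absorbing=True, ka_scale=0.5))
    return comps


def absorption_rate_constant(peff: float, radius: float) -> float:
    """First-order luminal absorption rate ka = 2 Peff / R, in 1/h.

    ``peff`` in cm/s, ``radius`` in cm; the factor 3600 converts to hours.
    Derives from the surface-to-volume ratio of a cylindrical lumen.
    """
    if peff < 0 or radius <= 0:
        raise ValueError("peff must be nonnegative and radius positive")
    return 2.0 * peff / radius * 3600.0


@dataclass(frozen=True)
class GutTrajectory:
    """Time-resolved gut mass ledger (all amounts ug)."""

    times: np.ndarray               # h
    undissolved: np.ndarray         # (n_times, n_comps)
    dissolved: np.ndarray           # (n_times, n_comps)
    absorbed_per_comp: np.ndarray   # cumulative to portal, (n_times, n_comps)
    fecal: np.ndarray               # cumulative, (n_times,)
    dose_in: float                  # total ug delivered to the lumen
    compartments: tuple[GutCompartment, ...]

    @property
    def absorbed_total(self) -> np.ndarray:
        return self.absorbed_per_comp.sum(axis=1)

    def ledger_error(self) -> float:
        """Max relative deviation of the mass ledger from the delivered dose."""
        if self.dose_in == 0:
            return 0.0
        total = (self.undissolved.sum(axis=1) + self.dissolved.sum(axis=1)
                 + self.absorbed_total + self.fecal)
        return float(np.max(np.abs(total - self.dose_in)) / self.dose_in)


def _gut_rates(p: ParameterSet, gut: Sequence[GutCompartment], z: float):
    """Precompute per-compartment constants for the gut RHS."""
    n = len(gut)
    kt = np.array([1.0 / c.transit_time for c in gut])
    ka = np.array([
        absorption_rate_constant(p.absorption.peff, c.radius) * c.ka_scale
        if c.absorbing else 0.0 for c in gut])
    vol = np.array([c.volume for c in gut])
    cs = np.array([solubility_at_ph(p.drug, c.ph) for c in gut])  # mg/ml
    tau_p = p.drug.precipitation_time / 3600.0  # h
    x0_ref = p.dose_ug

    def rhs(und: np.ndarray, dis: np.ndarray):
        """Return (dund, ddis, absorption rate per comp, fecal rate)."""
        conc = dis / vol  # ug/ml
        diss = np.array([
            dissolution_rate(z, und[i], x0_ref, conc[i], cs[i]) for i in range(n)])
        excess = dis - cs * 1000.0 * vol
        prec = np.where(excess > 0.0, excess / tau_p, 0.0)
        net = diss - prec
        absorbed = ka * dis
        dund = -kt * und - net
        ddis = -kt * dis + net - absorbed
        # transit chain: compartment i feeds i+1; the colon feeds feces
        dund[1:] += kt[:-1] * und[:-1]
        ddis[1:] += kt[:-1] * dis[:-1]
        fecal_rate = kt[-1] * (und[-1] + dis[-1])
        return dund, ddis, absorbed, fecal_rate

    return rhs


def simulate_gut(p: ParameterSet, gut: Sequence[GutCompartment],
                 input_schedule: Sequence[tuple[float, float, float]],
                 z: float, horizon: float = 32.0, n_out: int = 400,
                 ) -> tuple[GutTrajectory, Callable[[float], float]]:
    """Integrate the gut chain for a schedule of stomach boluses.

    ``input_schedule`` is a sequence of ``(time_h, undissolved_ug,
    dissolved_ug)`` deliveries to the stomach. Returns the trajectory and a
    portal-flux interpolant (ug/h of drug crossing the gut wall, before
    first-pass extraction).
    """
    n = len(gut)
    rates = _gut_rates(p, gut, z)

    def ode(_t, y):
        und, dis = y[:n], y[n:2 * n]
        dund, ddis, absorbed, fec = rates(und, dis)
        return np.concatenate([dund, ddis, absorbed, [fec]])

    events = sorted(float(t) for t, *_ in input_schedule)
    if any(a < 0 for a in events):
        raise ValueError("schedule times must be nonnegative")
    y = np.zeros(3 * n + 1)
    dose_in = 0.0
    t_now = 0.0
    times_out = np.linspace(0.0, horizon, n_out)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    segments: list = []
    schedule = sorted(input_schedule)
    for i, (t_b, und_b, dis_b) in enumerate(schedule + [(horizon, 0.0, 0.0)]):
        if t_b > t_now:
            mask = (times_out >= t_now) & (times_out <= t_b)
            sol = solve_ivp(ode, (t_now, t_b), y, t_eval=times_out[mask],
                            method="LSODA", rtol=1e-10, atol=1e-8, dense_output=True)
            if not sol.success:
                raise RuntimeError(f"gut integration failed: {sol.message}")
            segments.append((t_now, t_b, sol.sol))
            ts.append(sol.t)
            ys.append(sol.y)
            y = sol.sol(t_b)
            t_now = t_b
        if i < len(schedule):
            if min(und_b, dis_b) < 0:
                raise ValueError("schedule amounts must be nonnegative")
            y = y.copy()
            y[0] += und_b
            y[n] += dis_b
            dose_in += und_b + dis_b

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[:, idx]
    ka = np.array([
        absorption_rate_constant(p.absorption.peff, c.radius) * c.ka_scale
        if c.absorbing else 0.0 for c in gut])

    def portal_flux(t: float) -> float:
        for lo, hi, interp in segments:
            if lo <= t <= hi:
                return float(ka @ interp(t)[n:2 * n])
        return 0.0

    traj = GutTrajectory(
        times=t_all,
        undissolved=y_all[:n].T, dissolved=y_all[n:2 * n].T,
        absorbed_per_comp=y_all[2 * n:3 * n].T, fecal=y_all[3 * n],
        dose_in=dose_in, compartments=tuple(gut))
    return traj, portal_flux


def fraction_absorbed(traj: GutTrajectory) -> tuple[float, dict[str, float]]:
    """Total and per-compartment fraction of the luminal dose absorbed."""
    if traj.dose_in == 0:
        zeros = {c.name: 0.0 for c in traj.compartments}
        return 0.0, zeros
    per = traj.absorbed_per_comp[-1] / traj.dose_in
    per_comp = {c.name: float(f) for c, f in zip(traj.compartments, per)}
    return float(per.sum()), per_comp
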