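"""Two-tissue compartment (2TC) model for FDG and its macro-parameters.

The 2TC model describes FDG kinetics in brain tissue with rate constants
K1 (plasma -> free tissue pool, mL/min/cm^3), k2 (free pool -> plasma),
k3 (phosphorylation to FDG-6-P) and k4 (dephosphorylation), all in min^-1:

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

The tissue response to a unit plasma impulse is a bi-exponential,
``A1*exp(-l1*t) + A2*exp(-l2*t)`` with ``A1 + A2 = K1``; with k4 = 0 the
slow eigenvalue is exactly zero (irreversible trapping).  The measured PET
signal also contains intravascular activity: the model TAC blends the
tissue response with the whole-blood curve through the fractional blood
volume v_b.

Macro-parameters: the net uptake rate constant ``K_FDG = K1*k3/(k2+k3)``
and the cerebral metabolic rate of glucose
``CMR_glc = K_FDG/LC * Gp * 100`` (umol/min/100 g, with plasma glucose Gp
in mmol/L, lumped constant LC, and tissue density taken as 1 g/cm^3).

Units contract: times in seconds, activities in kBq/cm^3, rate constants
per minute (converted internally at the convolution boundary).  Inputs are
assumed decay-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .curves import FrameTAC, SampledCurve

__all__ = [
    "KineticParams",
    "ImpulseResponse",
    "impulse_response",
    "model_tac",
    "k_fdg",
    "cmr_glc",
]


@dataclass(frozen=True)
class KineticParams:
    """2TC rate constants plus fractional blood volume.

    K1 in mL/min/cm^3; k2, k3, k4 in min^-1; vb dimensionless in [0, 1].
    k4 = 0 gives the irreversible model (no FDG-6-P hydrolysis).
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (0.0 <= self.vb <= 1.0):
            raise ValueError(f"vb must lie in [0, 1], got {self.vb}")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {"K1": self.K1, "k2": self.k2, "k3": self.k3, "k4": self.k4, "vb": self.vb}


@dataclass(frozen=True)
class ImpulseResponse:
    """Bi-exponential tissue impulse response.

    ``rates`` (min^-1, ascending) and ``amplitudes`` such that the response
    to a unit plasma impulse is ``sum_i amplitudes[i]*exp(-rates[i]*t)``.
    A single-term response is represented with one entry.
    """

    rates: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.atleast_1d(np.asarray(self.rates, float)))
        object.__setattr__(self, "amplitudes", np.atleast_1d(np.asarray(self.amplitudes, float)))

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-np.outer(self.rates, t)), axis=0
        ).reshape(t.shape)


def impulse_response(params: KineticParams) -> ImpulseResponse:
    """Closed-form eigen-decomposition of the 2TC system.

    Eigenvalues l1 <= l2 of the tissue system are

        l_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4*k2*k4)] / 2

    with amplitudes ``K1*(k3+k4-l1)/(l2-l1)`` and ``K1*(l2-k3-k4)/(l2-l1)``.
    With k4 = 0, l1 = 0 exactly and its amplitude is ``K1*k3/(k2+k3)``
    (= K_FDG, the trapped fraction of delivery).
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    if s == 0.0:
        # pure integrator: tissue accumulates K1 * integral of plasma
        return ImpulseResponse(np.array([0.0]), np.array([K1]))
    disc = s * s - 4.0 * k2 * k4
    # disc >= (k2 - k4)^2 >= 0 analytically; clip rounding noise
    root = np.sqrt(max(disc, 0.0))
    l1 = 0.5 * (s - root)
    l2 = 0.5 * (s + root)
    if k4 == 0.0:
        l1 = 0.0  # exact: irreversible trapping never decays
    if np.isclose(l1, l2, rtol=1e-12, atol=1e-15):
        # repeated root only when k3 = 0 and k2 = k4: the second compartment
        # is never populated, so the response is a single exponential in k2
        return ImpulseResponse(np.array([l1]), np.array([K1]))
    a1 = K1 * (k3 + k4 - l1) / (l2 - l1)
    a2 = K1 * (l2 - k3 - k4) / (l2 - l1)
    return ImpulseResponse(np.array([l1, l2]), np.array([a1, a2]))


def _conv_exp(amp: float, rate_per_s: float, cp: np.ndarray, dt: float) -> np.ndarray:
    """Convolution of ``amp*exp(-rate*t)`` with a piecewise-linear curve.

    Exact for linear interpolation between grid samples; evaluated with a
    one-pole recursion (``y[i+1] = E*y[i] + g[i]``) so the cost is O(n).
    """
    if amp == 0.0:
        return np.zeros(cp.size)
    c0, c1 = cp[:-1], cp[1:]
    lam = rate_per_s
    if lam * dt < 1e-12:
        g = amp * dt * 0.5 * (c0 + c1)
        e_step = 1.0
    else:
        e_step = np.exp(-lam * dt)
        m = (c1 - c0) / dt
        g = amp * (c0 * (1.0 - e_step) / lam + m * (dt / lam - (1.0 - e_step) / lam**2))
    y = lfilter([1.0], [1.0, -e_step], g)
    return np.concatenate(([0.0], y))


def tissue_response(
    params: KineticParams, plasma: SampledCurve, t_grid: np.ndarray, dt: float
) -> np.ndarray:
    """Instantaneous tissue activity C1+C2 on ``t_grid`` (uniform, step dt)."""
    h = impulse_response(params)
    cp = plasma.interp(t_grid)
    out = np.zeros(t_grid.size)
    # amplitudes carry K1's per-minute units; the grid integrates over
    # seconds, so both rates and amplitudes convert by 1/60 here
    for amp, rate in zip(h.amplitudes, h.rates):
        out += _conv_exp(amp / 60.0, rate / 60.0, cp, dt)
    return out


def model_tac(
    params: KineticParams,
    plasma: SampledCurve,
    blood: SampledCurve,
    frames: FrameTAC,
    *,
    dt: float = 1.0,
    blend: str = "scale_tissue",
) -> FrameTAC:
    """Model TAC for a frame schedule, given plasma IF and whole-blood curve.

    The instantaneous signal is

        C_model(t) = (1 - vb) * (h (*) Cp)(t) + vb * Cb(t)

    (``blend="scale_tissue"``, the convention of common commercial
    kinetic-modeling software) or
    ``(h (*) Cp)(t) + vb*Cb(t)`` with ``blend="additive"`` for cross-tool
    comparison.  The convolution runs on a uniform grid of step ``dt``
    (default 1 s, the blood counter's native resolution) and each frame
    value is the trapezoidal mean of the instantaneous signal over
    [start, end].
    """
    if blend not in ("scale_tissue", "additive"):
        raise ValueError(f"unknown blend {blend!r}")
    t_end = frames.span
    for curve, name in ((plasma, "plasma"), (blood, "blood")):
        if curve.end < t_end - 1e-9:
            raise ValueError(
                f"{name} curve ends at {curve.end} s but frames extend to {t_end} s"
            )
    n = int(round(t_end / dt))
    t_grid = np.arange(n + 1) * dt
    ct = tissue_response(params, plasma, t_grid, dt)
    if params.vb > 0.0:
        cb = blood.interp(t_grid)
        if blend == "scale_tissue":
            inst = (1.0 - params.vb) * ct + params.vb * cb
        else:
            inst = ct + params.vb * cb
    else:
        inst = ct

    # cumulative trapezoid -> exact frame means on the grid
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (inst[:-1] + inst[1:]) * dt)))
    idx_start = np.rint(frames.start / dt).astype(int)
    idx_end = np.rint(frames.end / dt).astype(int)
    if not (
        np.allclose(idx_start * dt, frames.start) and np.allclose(idx_end * dt, frames.end)
    ):
        raise ValueError(f"frame edges must align with the {dt}-s model grid")
    means = (cum[idx_end] - cum[idx_start]) / (frames.end - frames.start)
    return frames.with_values(means)


def k_fdg(params: KineticParams) -> float:
    """Net FDG uptake rate constant ``K1*k3/(k2+k3)`` (mL/min/cm^3).

    Always <= K1; zero when k3 = 0 (no phosphorylation, no net uptake).
    """
    if params.k2 + params.k3 <= 0:
        raise ValueError("k_fdg undefined for k2 = k3 = 0")
    return params.K1 * params.k3 / (params.k2 + params.k3)


def cmr_glc(kfdg: float, lc: float = 0.6, gp: float = 11.9) -> float:
    """Cerebral metabolic rate of glucose, umol/min/100 g.

    ``kfdg`` in mL/min/cm^3, ``lc`` the lumped constant, ``gp`` plasma
    glucose in mmol/L (1 mmol/L = 1 umol/cm^3; tissue density 1 g/cm^3).
    """
    if lc <= 0:
        raise ValueError("lumped constant must be > 0")
    if gp < 0:
        raise ValueError("plasma glucose must be >= 0")
    return kfdg / lc * gp * 100.0
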