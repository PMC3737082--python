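"""Simulated scans for the protocol and sensitivity studies.

Everything the studies need is generated here, with no external data:
frame schedules matching the study's reconstruction rules, protocol input
functions (10-s bolus, 300-s and 900-s equal-dose infusions), matched
whole-blood curves, Gaussian noise with the study's variance model, and
input-function subsampling.

The canonical fixture parameters are package conventions, chosen to
resemble a representative infusion experiment (the source scans are not
published): a tri-exponential IF with amplitudes A=600, B=850, Z=600
kBq/cm^3 and rates (3.0, 0.3, 0.01) min^-1 peaks near 2000 kBq/cm^3 at the
300-s infusion stop, and the default truth rate constants are
K1=0.328 mL/min/cm^3, k2=0.550, k3=0.079, k4=0 min^-1 with vb=0.055.

Noise model: IF samples get additive Gaussian noise with
SD = const + rel*value (defaults 32.5 kBq/cm^3 + 5%, the midpoints of the
25–40 kBq/cm^3 and 4–6% ranges); TAC frames get
SD = value*0.8/frame_length_s.  Post-noise negatives are kept — clipping
would bias low-activity frames upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FrameTAC, SampledCurve
from .input_function import (
    BloodCorrectionMethod,
    TriExpIF,
    blood_from_plasma,
    rescale_protocol,
    triexp_value,
)
from .kinetics import KineticParams, model_tac

__all__ = [
    "ProtocolSpec",
    "NoiseSpec",
    "CANONICAL_IF",
    "DEFAULT_TRUTH",
    "make_frame_schedule",
    "simulate_if",
    "add_if_noise",
    "add_tac_noise",
    "subsample_if",
    "ScanFixture",
    "make_fixture",
]

#: Canonical 300-s infusion IF used by fixtures (package convention,
#: synthetic — not fitted to any published scan).
CANONICAL_IF = TriExpIF(A=600.0, B=850.0, Z=600.0, alpha=3.0, beta=0.3, zeta=0.01, t_i=300.0)

#: Default truth rate constants for fixtures (typical infusion-experiment
#: values) with the study's standard fractional blood volume.
DEFAULT_TRUTH = KineticParams(K1=0.328, k2=0.550, k3=0.079, k4=0.0, vb=0.055)

#: Bolus and infusion durations studied, seconds.
PROTOCOL_DURATIONS = (10.0, 300.0, 900.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Administration protocol: infusion duration and scan length (s)."""

    duration: float = 300.0
    scan_length: float = 2700.0
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.duration < self.scan_length):
            raise ValueError("duration must lie in (0, scan_length)")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise settings for IF samples and TAC frames."""

    if_const_sd: float = 32.5
    if_rel_sd: float = 0.05
    tac_factor: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("if_const_sd", "if_rel_sd", "tac_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _ramp_durations(total: float, n: int, d_min: float = 20.0) -> np.ndarray:
    """n contiguous durations summing to ``total``: a linear ramp from
    ``d_min`` up, rounded to 10-s multiples via cumulative rounding."""
    d_max = 2.0 * total / n - d_min
    if d_max < d_min:
        raise ValueError("infeasible frame ramp")
    ideal = d_min + (d_max - d_min) * np.arange(n) / max(n - 1, 1)
    cum = np.round(np.cumsum(ideal) / 10.0) * 10.0
    cum[-1] = total
    durations = np.diff(np.concatenate(([0.0], cum)))
    return durations


def make_frame_schedule(protocol: ProtocolSpec) -> FrameTAC:
    """Frame schedule covering [0, scan_length]: 10-s frames bracketing the
    infusion stop, shorter->longer frames elsewhere, 33–39 frames total,
    no frame above 240 s."""
    stop = protocol.duration
    total = protocol.scan_length
    short_lo = max(0.0, stop - 30.0)
    short_hi = stop + 60.0
    n_short = int(round((short_hi - short_lo) / 10.0))
    edges = [0.0]
    # pre-stop: equal 10-s-multiple frames
    if short_lo > 0:
        n_pre = min(12, int(short_lo // 60) + 1)
        cum = np.round(np.cumsum(np.full(n_pre, short_lo / n_pre)) / 10.0) * 10.0
        cum[-1] = short_lo
        edges.extend(np.concatenate(([0.0], cum))[1:])
    else:
        n_pre = 0
    # 10-s window around the stop
    edges.extend(short_lo + 10.0 * np.arange(1, n_short + 1))
    # post-stop ramp filling the scan with 36 frames total
    n_post = 36 - n_short - n_pre
    post = _ramp_durations(total - short_hi, n_post)
    edges.extend(short_hi + np.cumsum(post))
    edges = np.asarray(edges)
    start, end = edges[:-1], edges[1:]
    durations = end - start
    n = start.size
    if not (33 <= n <= 39):
        raise ValueError(f"schedule construction yielded {n} frames, outside 33–39")
    if durations.min() < 10.0 - 1e-9 or durations.max() > 240.0 + 1e-9:
        raise ValueError("frame durations violate the 10–240 s constraints")
    return FrameTAC(start, end, np.zeros(n))


def simulate_if(p: TriExpIF, protocol: ProtocolSpec | None = None, dt: float = 1.0) -> SampledCurve:
    """Noise-free plasma IF sampled every ``dt`` s over [0, scan_length].

    If a protocol is given, ``p`` is first rescaled to its duration at
    equal dose (and scaled by ``dose_scale``)."""
    if protocol is not None:
        p = rescale_protocol(p, protocol.duration)
        if protocol.dose_scale != 1.0:
            p = TriExpIF(
                A=p.A * protocol.dose_scale,
                B=p.B * protocol.dose_scale,
                Z=p.Z * protocol.dose_scale,
                alpha=p.alpha,
                beta=p.beta,
                zeta=p.zeta,
                t_i=p.t_i,
            )
        scan_length = protocol.scan_length
    else:
        scan_length = 2700.0
    t = np.arange(0.0, scan_length + dt / 2, dt)
    return SampledCurve(t, triexp_value(p, t), kind="plasma")


def add_if_noise(curve: SampledCurve, spec: NoiseSpec) -> SampledCurve:
    """Additive Gaussian noise, SD = if_const_sd + if_rel_sd*value."""
    rng = np.random.default_rng(spec.seed)
    sd = spec.if_const_sd + spec.if_rel_sd * curve.values
    if np.all(sd == 0):
        return curve
    return curve.with_values(curve.values + rng.normal(0.0, 1.0, curve.values.size) * sd)


def add_tac_noise(tac: FrameTAC, spec: NoiseSpec) -> FrameTAC:
    """Additive Gaussian noise per frame, SD = value*tac_factor/duration_s."""
    rng = np.random.default_rng(spec.seed)
    sd = np.abs(tac.values) * spec.tac_factor / tac.durations
    if np.all(sd == 0):
        return tac
    return tac.with_values(tac.values + rng.normal(0.0, 1.0, tac.values.size) * sd)


def subsample_if(curve: SampledCurve, interval: float) -> SampledCurve:
    """Keep only samples at t = 0, interval, 2*interval, ... (no
    interpolation; downstream fitting interpolates onto its own grid)."""
    spacing = float(np.median(np.diff(curve.times)))
    ratio = interval / spacing
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("interval must be a multiple of the native sample spacing")
    step = int(round(ratio))
    if step <= 1:
        return curve
    keep = np.isclose(np.mod(curve.times - curve.times[0], interval), 0.0) | np.isclose(
        np.mod(curve.times - curve.times[0], interval), interval
    )
    return SampledCurve(curve.times[keep], curve.values[keep], kind=curve.kind)


@dataclass(frozen=True)
class ScanFixture:
    """A self-consistent synthetic scan bundle."""

    seed: int
    protocol: ProtocolSpec
    triexp: TriExpIF
    truth: KineticParams
    plasma: SampledCurve
    blood: SampledCurve
    frames: FrameTAC
    tac: FrameTAC
    noisy_tacs: list = field(default_factory=list)
    noisy_plasma: SampledCurve | None = None


def make_fixture(
    seed: int = 0,
    *,
    protocol: ProtocolSpec | None = None,
    triexp: TriExpIF = CANONICAL_IF,
    truth: KineticParams | None = None,
    truth_jitter: float = 0.0,
    n_replicates: int = 10,
    noise: NoiseSpec | None = None,
    correction: BloodCorrectionMethod = BloodCorrectionMethod.MOUSE_EXP,
) -> ScanFixture:
    """Build a canonical synthetic scan.

    The plasma IF comes from the tri-exponential model rescaled to the
    protocol; the whole-blood curve from the inverse blood-cell
    correction; the noise-free TAC from the 2TC model; plus
    ``n_replicates`` noisy TAC replicates and one noisy IF (the study's
    one-IF-ten-TACs design).  ``truth_jitter`` > 0 draws per-scan truth
    rate constants log-normally around the defaults (vb unchanged), for
    multi-scan studies.  Deterministic given ``seed``.
    """
    protocol = protocol or ProtocolSpec()
    rng = np.random.default_rng(seed)
    base = truth or DEFAULT_TRUTH
    if truth_jitter > 0:
        factors = np.exp(rng.normal(0.0, truth_jitter, 4))
        k4 = base.k4 * factors[3] if base.k4 > 0 else 0.0
        base = KineticParams(
            K1=base.K1 * factors[0],
            k2=base.k2 * factors[1],
            k3=base.k3 * factors[2],
            k4=k4,
            vb=base.vb,
        )
    plasma = simulate_if(triexp, protocol)
    blood = blood_from_plasma(plasma, correction)
    frames = make_frame_schedule(protocol)
    tac = model_tac(base, plasma, blood, frames)
    noise = noise or NoiseSpec()
    # independent substreams per replicate, derived from the fixture seed
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_replicates + 1)
    noisy_tacs = [
        add_tac_noise(tac, NoiseSpec(noise.if_const_sd, noise.if_rel_sd, noise.tac_factor, int(s)))
        for s in child[:-1]
    ]
    noisy_plasma = add_if_noise(
        plasma, NoiseSpec(noise.if_const_sd, noise.if_rel_sd, noise.tac_factor, int(child[-1]))
    )
    return ScanFixture(
        seed=seed,
        protocol=protocol,
        triexp=rescale_protocol(triexp, protocol.duration),
        truth=base,
        plasma=plasma,
        blood=blood,
        frames=frames,
        tac=tac,
        noisy_tacs=noisy_tacs,
        noisy_plasma=noisy_plasma,
    )
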