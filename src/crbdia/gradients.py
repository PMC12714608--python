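"""Gradient programs and linear-solvent-strength retention prediction.

A :class:`GradientProgram` describes the mobile-phase composition phi(t) of one
LC run as a piecewise-linear profile. Retention times are predicted with the
linear-solvent-strength (LSS) law

    log10 k(phi) = log_k0 - S * phi        (RPLC)
    log10 k(phi) = log_k0 - S * (1 - phi)  (HILIC)

integrated over the program: the analyte elutes at the time t_R for which

    integral_0^{t_R - t0} dt / (t0 * k(phi(t))) = 1,

t0 being the column dead time. Under isocratic conditions this reduces to the
familiar t_R = t0 * (1 + k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RPLC = "RPLC"
HILIC = "HILIC"
COLUMN_MODES = (RPLC, HILIC)

#: integration step for the LSS law: 10 ms in minutes
DEFAULT_DT = 10e-3 / 60.0


class NonElutingError(ValueError):
    """The compound does not elute within the gradient program."""


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear solvent program of one LC gradient.

    Parameters
    ----------
    id : str
        Label, ``G1`` ... ``G9``.
    column_mode : {"RPLC", "HILIC"}
    breakpoints : list of (time_min, solvent_fraction)
        Ordered composition nodes; the first time must be 0 and fractions lie
        in [0, 1]. Composition is held constant after the last node.
    dead_time : float
        Column dead time t0, minutes.
    """

    id: str
    column_mode: str
    breakpoints: tuple[tuple[float, float], ...]
    dead_time: float = 1.0

    def __post_init__(self) -> None:
        if self.column_mode not in COLUMN_MODES:
            raise ValueError(f"unknown column mode {self.column_mode!r}")
        times = [t for t, _ in self.breakpoints]
        fracs = [f for _, f in self.breakpoints]
        if not times or times[0] != 0.0:
            raise ValueError("breakpoints must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("solvent fractions must lie in [0, 1]")
        if self.dead_time <= 0:
            raise ValueError("dead_time must be positive")

    @property
    def run_end(self) -> float:
        """Total run duration, minutes (last breakpoint time)."""
        return self.breakpoints[-1][0]

    def solvent_fraction(self, t: float | np.ndarray) -> float | np.ndarray:
        """Composition phi at time ``t`` (held constant beyond the last node)."""
        times = np.array([b[0] for b in self.breakpoints])
        fracs = np.array([b[1] for b in self.breakpoints])
        return np.interp(t, times, fracs)


def default_gradients(
    column_mode: str = RPLC,
    *,
    start_fraction: float = 0.02,
    ramp_minutes: tuple[float, ...] = (10, 12.5, 15, 17.5, 20, 22.5, 25, 27.5, 30),
    hold_minutes: float = 5.0,
    dead_time: float = 1.0,
) -> list[GradientProgram]:
    """Nine-gradient family of linear ramps; G5 (20 min ramp) is the reference.

    RPLC programs ramp the organic fraction linearly from ``start_fraction``
    to 1.0 over the ramp duration and then hold; ramp durations span 10-30 min
    in nine even steps. HILIC programs mirror this (organic from
    ``1 - start_fraction`` down to 0), since HILIC elution strength grows with
    the aqueous fraction.
    """
    programs = []
    for i, ramp in enumerate(ramp_minutes, start=1):
        if column_mode == HILIC:
            bp = (
                (0.0, 1.0 - start_fraction),
                (float(ramp), 0.0),
                (float(ramp) + hold_minutes, 0.0),
            )
        else:
            bp = (
                (0.0, start_fraction),
                (float(ramp), 1.0),
                (float(ramp) + hold_minutes, 1.0),
            )
        programs.append(
            GradientProgram(id=f"G{i}", column_mode=column_mode, breakpoints=bp, dead_time=dead_time)
        )
    return programs


REFERENCE_GRADIENT = "G5"


def retention_factor(log_k0: float, S: float, phi: float | np.ndarray, column_mode: str) -> float | np.ndarray:
    """LSS retention factor k(phi); HILIC uses the mirrored composition 1 - phi."""
    x = (1.0 - phi) if column_mode == HILIC else phi
    return 10.0 ** (log_k0 - S * np.asarray(x, dtype=float))


def compute_retention_time(
    compound,
    gradient: GradientProgram,
    *,
    dt: float = DEFAULT_DT,
) -> float:
    """Retention time (minutes) of ``compound`` under ``gradient``.

    Integrates 1 / (t0 * k(phi(t))) on a uniform grid of step ``dt`` until the
    cumulative migration reaches 1. Raises :class:`NonElutingError` if the
    compound has not eluted by the end of the program.

    ``compound`` needs ``retention_params[column_mode] == (log_k0, S)``.
    """
    log_k0, S = compound.retention_params[gradient.column_mode]
    t0 = gradient.dead_time
    end = gradient.run_end
    n = int(np.ceil(end / dt)) + 1
    t = np.arange(n) * dt
    phi = gradient.solvent_fraction(t)
    k = retention_factor(log_k0, S, phi, gradient.column_mode)
    # trapezoidal cumulative integral of the migration rate 1/(t0 k)
    rate = 1.0 / (t0 * k)
    cum = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)))
    if cum[-1] < 1.0:
        raise NonElutingError(
            f"{getattr(compound, 'name', 'compound')} does not elute within {gradient.id}"
        )
    idx = int(np.searchsorted(cum, 1.0))
    # linear interpolation inside the crossing step
    c0, c1 = cum[idx - 1], cum[idx]
    frac = (1.0 - c0) / (c1 - c0) if c1 > c0 else 0.0
    t_mig = t[idx - 1] + frac * dt
    return float(t0 + t_mig)
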