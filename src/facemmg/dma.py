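"""First-order differential microphone array (DMA) analytics.

A first-order end-fire DMA subtracts the outputs of two microphones a
distance ``d`` apart along the look axis.  With zero inter-element delay
the pattern is a dipole: sound arriving broadside (at +/-90 degrees to
the axis) reaches both elements in phase and cancels, while end-fire
sound (0 or 180 degrees) is differentiated and passes.  Delaying one
element by ``T = d / V`` turns the dipole into a cardioid.

The frequency response of the subtraction has its first peak at the
tuning (null-spacing) frequency ``V / (2 d)`` and its first spectral
null at ``V / d``.  All angles at the public interface are degrees
(0 = end-fire axis); radians are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Speed of sound in air, m/s.
SOUND_SPEED = 343.0


class GeometryError(ValueError):
    """Raised for invalid array geometry (non-positive spacing, etc.)."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry of a two-element end-fire array.

    Parameters
    ----------
    d : float
        Inter-element spacing in metres (> 0).
    W : float
        Largest dimension of a single element's aperture in metres
        (>= 0); used for the far-field (Fraunhofer) criterion.
    Ts : float, optional
        Sampling period in seconds, required when the inter-element
        delay is realised in discrete samples.
    """

    d: float
    W: float = 0.0
    Ts: float | None = None

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise GeometryError(f"inter-element spacing must be > 0, got {self.d}")
        if self.W < 0:
            raise GeometryError(f"aperture dimension must be >= 0, got {self.W}")
        if self.Ts is not None and not self.Ts > 0:
            raise GeometryError(f"sampling period must be > 0, got {self.Ts}")


@dataclass(frozen=True)
class CardioidDelay:
    """Result of a delay-based cardioid design.

    Attributes
    ----------
    T : float
        Ideal inter-element delay d / V in seconds.
    N : int
        Nearest whole number of sample delays, round(T / Ts).
    T_realized : float
        N * Ts when N >= 1, otherwise the ideal T (fractional regime).
    f_null : float
        Null frequency 1 / (2 * T_realized) implied by the delay.
    f_capture : float
        Upper usable bound, f_null / 2.
    fractional : bool
        True when the delay rounds to zero samples, i.e. the design
        would require a fractional-delay filter.
    """

    T: float
    N: int
    T_realized: float
    f_null: float
    f_capture: float
    fractional: bool


def _spacing(geometry: ArrayGeometry | float) -> float:
    if isinstance(geometry, ArrayGeometry):
        return geometry.d
    return float(geometry)


def null_frequency(geometry: ArrayGeometry | float) -> float:
    """Tuning/null-spacing frequency ``V / (2 d)`` in Hz.

    Accepts an :class:`ArrayGeometry` or a bare spacing in metres.
    E.g. 5 cm spacing gives 3430 Hz, 12 cm gives ~1429 Hz.
    """
    d = _spacing(geometry)
    if not d > 0:
        raise GeometryError(f"inter-element spacing must be > 0, got {d}")
    return SOUND_SPEED / (2.0 * d)


def spacing_for_null(f_null: float) -> float:
    """Inverse of :func:`null_frequency`: spacing (m) for a target null (Hz)."""
    if not f_null > 0:
        raise GeometryError(f"null frequency must be > 0, got {f_null}")
    return SOUND_SPEED / (2.0 * f_null)


def dipole_gain(
    theta_deg: float | np.ndarray,
    freq_hz: float | np.ndarray,
    d: float,
) -> float | np.ndarray:
    """Plane-wave gain magnitude of the zero-delay (dipole) subtraction.

    ``|1 - exp(-j 2 pi f d cos(theta) / V)| = 2 |sin(pi f d cos(theta) / V)|``

    Zero at theta = +/-90 degrees, maximal (= 2) on axis at the tuning
    frequency.  Assumes a plane wave; see :func:`fraunhofer_distance`
    for when that holds.
    """
    if not d > 0:
        raise GeometryError(f"inter-element spacing must be > 0, got {d}")
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    f = np.asarray(freq_hz, dtype=float)
    gain = 2.0 * np.abs(np.sin(np.pi * f * d * np.cos(theta) / SOUND_SPEED))
    if np.ndim(theta_deg) == 0 and np.ndim(freq_hz) == 0:
        return float(gain)
    return gain


def cardioid_delay(d: float, Ts: float) -> CardioidDelay:
    """Delay-based cardioid design for spacing ``d`` at sampling period ``Ts``.

    The ideal delay is T = d / V; with discrete sample delays it is
    realised as N = round(T / Ts) samples.  The realised delay implies
    a null at 1 / (2 T) and a usable capture band up to half of that.
    A zero-spacing array degenerates to the dipole (T = 0).
    """
    if d < 0:
        raise GeometryError(f"inter-element spacing must be >= 0, got {d}")
    if not Ts > 0:
        raise GeometryError(f"sampling period must be > 0, got {Ts}")
    T = d / SOUND_SPEED
    if T == 0.0:
        return CardioidDelay(T=0.0, N=0, T_realized=0.0,
                             f_null=math.inf, f_capture=math.inf,
                             fractional=False)
    N = int(round(T / Ts))
    fractional = N == 0
    T_real = N * Ts if N >= 1 else T
    f_null = 1.0 / (2.0 * T_real)
    return CardioidDelay(T=T, N=N, T_realized=T_real,
                         f_null=f_null, f_capture=f_null / 2.0,
                         fractional=fractional)


def fraunhofer_distance(W: float, lambda_: float) -> float:
    """Far-field (Fraunhofer) distance ``2 W^2 / lambda`` in metres.

    Beyond this range (and, rule of thumb, beyond two wavelengths) the
    incident wave may be treated as planar.  W = 0 (point aperture) is
    always far-field.
    """
    if W < 0:
        raise GeometryError(f"aperture dimension must be >= 0, got {W}")
    if not lambda_ > 0:
        raise GeometryError(f"wavelength must be > 0, got {lambda_}")
    return 2.0 * W * W / lambda_


def wavelength(freq_hz: float) -> float:
    """Wavelength (m) of a tone at ``freq_hz`` in air."""
    if not freq_hz > 0:
        raise GeometryError(f"frequency must be > 0, got {freq_hz}")
    return SOUND_SPEED / freq_hz


def polar_table(
    d: float,
    freqs_hz: tuple[float, ...] = (500.0, 1000.0, 3000.0, 5000.0),
    theta_step_deg: float = 5.0,
) -> pd.DataFrame:
    """Tabulated dipole directivity: columns theta_deg, freq_hz, gain."""
    thetas = np.arange(0.0, 360.0, theta_step_deg)
    rows = []
    for f in freqs_hz:
        rows.append(pd.DataFrame({
            "theta_deg": thetas,
            "freq_hz": f,
            "gain": dipole_gain(thetas, f, d),
        }))
    return pd.concat(rows, ignore_index=True)
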