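"""Free-space propagation of sampled complex wavefields.

Angular-spectrum propagation on a uniform grid: multiply the 2-D spectrum by
the exact non-paraxial transfer function ``exp(i k z sqrt(1 - (lambda fx)^2 -
(lambda fy)^2))``. Evanescent components (arguments under the root below
zero) are attenuated with the corresponding real exponential decay. Because
the transfer function has unit modulus for all travelling waves, the
propagator conserves energy on the grid to machine precision, which the
probe-construction code relies on.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft


def angular_spectrum_propagate(
    field: np.ndarray, pixel: float, wavelength: float, distance: float
) -> np.ndarray:
    """Propagate ``field`` by ``distance`` metres in free space.

    Parameters
    ----------
    field : complex ndarray, shape (n, n)
        Input wavefield sampled at pitch ``pixel`` (metres).
    pixel : float
        Grid pitch in metres.
    wavelength : float
        Wavelength in metres.
    distance : float
        Propagation distance in metres (0 returns a copy).
    """
    field = np.asarray(field, dtype=np.complex128)
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    if pixel <= 0 or wavelength <= 0:
        raise ValueError("pixel and wavelength must be positive")
    if distance == 0:
        return field.copy()

    ny, nx = field.shape
    fy = sfft.fftfreq(ny, d=pixel)
    fx = sfft.fftfreq(nx, d=pixel)
    fy2 = (wavelength * fy[:, None]) ** 2
    fx2 = (wavelength * fx[None, :]) ** 2
    arg = 1.0 - fy2 - fx2
    kz = 2.0 * np.pi / wavelength * np.sqrt(np.abs(arg))
    # travelling waves get a pure phase; evanescent ones decay
    transfer = np.where(
        arg >= 0,
        np.exp(1j * kz * distance),
        np.exp(-kz * abs(distance)),
    )
    spectrum = sfft.fft2(field)
    return sfft.ifft2(spectrum * transfer)


def fresnel_number(aperture_diameter: float, wavelength: float, distance: float) -> float:
    """Fresnel number a^2 / (lambda z) with a the aperture *radius*."""
    if distance <= 0:
        return np.inf
    return (aperture_diameter / 2.0) ** 2 / (wavelength * distance)
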