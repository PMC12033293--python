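"""Experiment geometry for far-field scanning diffraction microscopy.

The geometry couples the detector (pixel count and pitch, distance from the
sample) to the real-space sampling of the reconstruction through the usual
far-field relation: one detector frame of side ``N`` sampled at pitch
``delta_det`` at distance ``z`` yields a real-space pixel of
``lambda * z / (N * delta_det)``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: hc in keV * nm (2018 CODATA); wavelength[nm] = HC_KEV_NM / energy[keV]
HC_KEV_NM = 1.23984193


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ExperimentGeometry:
    """Detector/sample geometry with derived wavelength and real-space pitch.

    Parameters
    ----------
    photon_energy : float
        Photon energy in keV.
    detector_side : int
        Detector side length in pixels (must be even).
    detector_pixel : float
        Detector pixel pitch in metres.
    sample_detector_distance : float
        Sample-to-detector distance in metres.
    """

    photon_energy: float
    detector_side: int
    detector_pixel: float
    sample_detector_distance: float

    def __post_init__(self) -> None:
        _require_positive(
            photon_energy=self.photon_energy,
            detector_side=self.detector_side,
            detector_pixel=self.detector_pixel,
            sample_detector_distance=self.sample_detector_distance,
        )
        if self.detector_side % 2 != 0:
            raise ValueError(
                f"detector_side must be even, got {self.detector_side}"
            )

    @property
    def wavelength(self) -> float:
        """Wavelength in metres."""
        return HC_KEV_NM / self.photon_energy * 1e-9

    @property
    def real_space_pixel(self) -> float:
        """Real-space pixel size of the reconstruction in metres."""
        return (
            self.wavelength
            * self.sample_detector_distance
            / (self.detector_side * self.detector_pixel)
        )

    @property
    def wavenumber(self) -> float:
        """Vacuum wavenumber k = 2 pi / lambda in 1/m."""
        import math

        return 2.0 * math.pi / self.wavelength


def make_geometry(
    energy: float, det_side: int, det_pixel: float, distance: float
) -> ExperimentGeometry:
    """Build an :class:`ExperimentGeometry` and derive wavelength and pitch.

    Parameters
    ----------
    energy : float
        Photon energy in keV.
    det_side : int
        Detector side in pixels.
    det_pixel : float
        Detector pixel size in metres.
    distance : float
        Sample-detector distance in metres.
    """
    return ExperimentGeometry(
        photon_energy=energy,
        detector_side=int(det_side),
        detector_pixel=det_pixel,
        sample_detector_distance=distance,
    )
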