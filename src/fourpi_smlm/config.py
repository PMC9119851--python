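"""Optical and pipeline configuration.

Canonical units everywhere: nanometers for lengths, photons for intensities,
seconds for time, radians for phases.  Camera-pixel coordinates appear only
inside the segmentation stage.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

TWO_PI = 2.0 * math.pi

#: Relative interference phases of the four detection channels p1, s1, p2, s2.
DEFAULT_CHANNEL_PHASES = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi)

#: Channel labels in storage order.
CHANNEL_ORDER = ("p1", "s1", "p2", "s2")

#: Indices of the s-polarized channels in :data:`CHANNEL_ORDER`.
S_CHANNEL_INDICES = (1, 3)
P_CHANNEL_INDICES = (0, 2)


@dataclass
class OpticalConfig:
    """Optical constants of the 4Pi interferometric detection path.

    The axial interference modulation has a fringe period of approximately
    ``wavelength_vacuum / (2 * n_sample)`` — the emitter z coordinate is
    encoded modulo this period by the interference phase alone.

    Parameters
    ----------
    wavelength_vacuum : float
        Fluorescence wavelength in vacuum, nm.
    n_sample, n_immersion : float
        Refractive indices of the sample medium and the immersion oil.
    pixel_size_lateral : float
        Effective camera pixel size in sample space, nm/pixel.
    channel_phase_offsets : tuple of 4 floats
        Relative interference phase of channels (p1, s1, p2, s2), radians.
    envelope_axial_sigma : float
        Gaussian sigma of the slowly varying axial focal envelope, nm.
    envelope_lateral_sigma0 : float
        In-focus lateral Gaussian sigma of the PSF, nm.
    defocus_spread_rate : float
        Dimensionless asymptotic widening of the lateral sigma per nm of
        defocus: ``sigma_xy(z) = sigma0 * sqrt(1 + (rate * z / sigma0)^2)``
        (quadratic near focus, slope ``rate`` far from it).
    defocus_asymmetry : float
        Odd (linear in z) component of the lateral sigma, dimensionless.
        The sample/immersion index mismatch induces spherical aberration
        that makes defocus asymmetric about the focal plane; without it the
        PSF would be exactly mirror-symmetric in z, which no real
        microscope PSF is.
    modulation_depth : float
        Interference modulation depth m in (0, 1] at the focal plane.
    modulation_axial_sigma : float
        Gaussian decay length (nm) of the fringe visibility away from
        focus: dispersion and aberrations in the interferometric cavity
        reduce the contrast for defocused emitters, so
        ``m(z) = m * exp(-z^2 / (2 sigma_m^2))``.
    sp_amplitude_ratio : float
        Amplitude scale of the s-polarized channels relative to the
        p-polarized channels (1.0 in the single-color configuration).
    """

    wavelength_vacuum: float = 680.0
    n_sample: float = 1.346
    n_immersion: float = 1.406
    pixel_size_lateral: float = 138.2
    channel_phase_offsets: tuple = DEFAULT_CHANNEL_PHASES
    envelope_axial_sigma: float = 300.0
    envelope_lateral_sigma0: float = 140.0
    defocus_spread_rate: float = 0.25
    defocus_asymmetry: float = 0.1
    modulation_depth: float = 0.9
    modulation_axial_sigma: float = 700.0
    sp_amplitude_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in (0, 1]")
        for name in (
            "wavelength_vacuum",
            "n_sample",
            "n_immersion",
            "pixel_size_lateral",
            "envelope_axial_sigma",
            "envelope_lateral_sigma0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.channel_phase_offsets) != 4:
            raise ValueError("exactly four channel phase offsets required")
        self.channel_phase_offsets = tuple(float(p) for p in self.channel_phase_offsets)
        if self.sp_amplitude_ratio <= 0:
            raise ValueError("sp_amplitude_ratio must be positive")

    @property
    def fringe_period(self) -> float:
        """Axial interference fringe period, nm (≈ λ0 / (2 n_sample))."""
        return self.wavelength_vacuum / (2.0 * self.n_sample)

    @property
    def k_axial(self) -> float:
        """Axial modulation wavenumber 2π / fringe_period, rad/nm."""
        return TWO_PI / self.fringe_period


@dataclass
class IndexWavelengthConfig:
    """Constants for the wavelength and refractive-index z corrections.

    ``lambda_bead`` is the mean detected wavelength of the calibration bead;
    ``lambda_dye`` maps dye labels to their mean detected wavelengths.
    """

    lambda_bead: float = 712.0
    lambda_dye: dict = field(
        default_factory=lambda: {"AF647": 680.0, "Cy5.5": 699.0}
    )
    n_sample: float = 1.346
    n_immersion: float = 1.406

    def __post_init__(self) -> None:
        if self.lambda_bead <= 0 or self.n_sample <= 0 or self.n_immersion <= 0:
            raise ValueError("all optical constants must be positive")
        for dye, lam in self.lambda_dye.items():
            if lam <= 0:
                raise ValueError(f"wavelength for {dye} must be positive")


@dataclass
class FitConfig:
    """Parameters of segmentation and spline fitting."""

    roi_size: int = 7
    detection_threshold_k: float = 6.0
    gaussian_fit_window: int = 11
    z_start_spacing: float | None = None  # nm; default fringe_period / 2
    max_iterations: int = 50
    chi2_rtol: float = 1e-6


@dataclass
class DriftConfig:
    """Parameters of the redundant cross-correlation drift estimator."""

    render_voxel: float = 10.0  # nm
    peak_fit_window: int = 7  # voxels per axis
    window_size: int = 2000  # localizations per time window


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations, YAML-serializable."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    index_wavelength: IndexWavelengthConfig = field(
        default_factory=IndexWavelengthConfig
    )
    fit: FitConfig = field(default_factory=FitConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        if "optics" in d:
            opt = dict(d["optics"])
            if "channel_phase_offsets" in opt:
                opt["channel_phase_offsets"] = tuple(opt["channel_phase_offsets"])
            kwargs["optics"] = OpticalConfig(**opt)
        if "index_wavelength" in d:
            kwargs["index_wavelength"] = IndexWavelengthConfig(**d["index_wavelength"])
        if "fit" in d:
            kwargs["fit"] = FitConfig(**d["fit"])
        if "drift" in d:
            kwargs["drift"] = DriftConfig(**d["drift"])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        d = self.to_dict()
        d["optics"]["channel_phase_offsets"] = list(
            d["optics"]["channel_phase_offsets"]
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def back_projected_pixel_size(physical_pixel_um: float, magnification: float) -> float:
    """Camera pixel size projected into sample space, in nm.

    For the 2x2-binned EMCCD (32 µm effective pixels) at 231.48x
    magnification this evaluates to 138.2 nm.
    """
    if physical_pixel_um <= 0 or magnification <= 0:
        raise ValueError("pixel size and magnification must be positive")
    return physical_pixel_um * 1000.0 / magnification
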