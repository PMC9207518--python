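"""Chromophore and Mie-scattering model of tissue optical properties.

Absorption in the 590-660 nm band is modeled as a linear mix of oxy- and
deoxy-hemoglobin:

    mu_a(lambda) = cTHb * [StO2 * eps_HbO2(lambda) + (1-StO2) * eps_Hb(lambda)]
                   + background

with cTHb the total hemoglobin concentration in mM and extinction
coefficients in natural-log mm^-1 mM^-1.  Reduced scattering follows the
Mie-type power law

    mu_s'(lambda) = a * (lambda / 1000 nm)^(-b)

so the amplitude ``a`` is mu_s' at the 1000 nm reference wavelength in mm^-1
and the power ``b`` is dimensionless.  The diffusion coefficient is
kappa = 1 / (3 (mu_a + mu_s')) in mm.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np

__all__ = [
    "LAMBDA_REF_NM",
    "TissueComposition",
    "ExtinctionTable",
    "OpticalCoefficients",
    "absorption_at",
    "reduced_scattering_at",
    "diffusion_coefficient",
    "optical_coefficients",
    "d_absorption_d_cthb",
]

#: Reference wavelength of the scattering power law (nm).
LAMBDA_REF_NM = 1000.0


@dataclasses.dataclass(frozen=True)
class TissueComposition:
    """Homogeneous tissue parameterization.

    cthb : total hemoglobin concentration (mM), >= 0
    sto2 : oxygen saturation fraction in [0, 1]
    scatter_amplitude : Mie power-law amplitude a (mu_s' at 1000 nm, mm^-1), > 0
    scatter_power : Mie power-law exponent b (dimensionless), >= 0
    background_mua : constant non-hemoglobin absorption (mm^-1), >= 0
    """

    cthb: float
    sto2: float = 0.70
    scatter_amplitude: float = 0.9
    scatter_power: float = 1.3
    background_mua: float = 0.0

    def __post_init__(self) -> None:
        if not self.cthb >= 0:
            raise ValueError(f"cTHb must be >= 0, got {self.cthb}")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError(f"StO2 must be in [0, 1], got {self.sto2}")
        if not self.scatter_amplitude > 0:
            raise ValueError("scatter amplitude must be > 0")
        if not self.scatter_power >= 0:
            raise ValueError("scatter power must be >= 0")
        if not self.background_mua >= 0:
            raise ValueError("background absorption must be >= 0")


@dataclasses.dataclass(frozen=True)
class ExtinctionTable:
    """Tabulated molar extinction spectra (natural log, mm^-1 mM^-1)."""

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        e1 = np.asarray(self.eps_hbo2, dtype=float)
        e2 = np.asarray(self.eps_hb, dtype=float)
        if wl.ndim != 1 or wl.shape != e1.shape or wl.shape != e2.shape:
            raise ValueError("table columns must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(e1 <= 0) or np.any(e2 <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hbo2", e1)
        object.__setattr__(self, "eps_hb", e2)

    @classmethod
    def from_tsv(cls, path) -> "ExtinctionTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line or line.startswith("wavelength"):
                    continue
                rows.append([float(v) for v in line.split()])
        data = np.array(rows)
        return cls(data[:, 0], data[:, 1], data[:, 2])

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The hemoglobin table shipped with the package (580-680 nm)."""
        ref = resources.files("lumitomo.data") / "hemoglobin_extinction.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def interpolate(self, wavelength_nm) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (eps_HbO2, eps_Hb); no extrapolation."""
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength {wl} nm outside table range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return (
            np.interp(wl, self.wavelengths, self.eps_hbo2),
            np.interp(wl, self.wavelengths, self.eps_hb),
        )


@dataclasses.dataclass(frozen=True)
class OpticalCoefficients:
    """Per-wavelength absorption, reduced scattering and diffusion coefficients."""

    wavelengths: np.ndarray  # nm
    mua: np.ndarray  # mm^-1
    musp: np.ndarray  # mm^-1
    kappa: np.ndarray  # mm

    def __post_init__(self) -> None:
        for name in ("wavelengths", "mua", "musp", "kappa"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("mu_a and mu_s' must be positive")
        if not np.allclose(self.kappa, 1.0 / (3.0 * (self.mua + self.musp))):
            raise ValueError("kappa must equal 1/(3(mu_a + mu_s'))")

    def at(self, wavelength_nm: float) -> tuple[float, float, float]:
        idx = int(np.flatnonzero(np.isclose(self.wavelengths, wavelength_nm))[0])
        return float(self.mua[idx]), float(self.musp[idx]), float(self.kappa[idx])


def absorption_at(
    comp: TissueComposition, table: ExtinctionTable, wavelength_nm
) -> np.ndarray | float:
    """Absorption coefficient mu_a (mm^-1) at the given wavelength(s)."""
    e_hbo2, e_hb = table.interpolate(wavelength_nm)
    mua = comp.cthb * (comp.sto2 * e_hbo2 + (1.0 - comp.sto2) * e_hb)
    mua = mua + comp.background_mua
    return float(mua) if np.isscalar(wavelength_nm) else mua


def d_absorption_d_cthb(
    comp: TissueComposition, table: ExtinctionTable, wavelength_nm
) -> np.ndarray | float:
    """d mu_a / d cTHb (mm^-1 mM^-1) at fixed StO2."""
    e_hbo2, e_hb = table.interpolate(wavelength_nm)
    d = comp.sto2 * e_hbo2 + (1.0 - comp.sto2) * e_hb
    return float(d) if np.isscalar(wavelength_nm) else d


def reduced_scattering_at(comp: TissueComposition, wavelength_nm) -> np.ndarray | float:
    """Reduced scattering mu_s' (mm^-1) from the Mie power law."""
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    musp = comp.scatter_amplitude * (wl / LAMBDA_REF_NM) ** (-comp.scatter_power)
    return float(musp) if np.isscalar(wavelength_nm) else musp


def diffusion_coefficient(mua, musp):
    """Diffusion coefficient kappa = 1/(3(mu_a + mu_s')) in mm."""
    total = np.asarray(mua, dtype=float) + np.asarray(musp, dtype=float)
    if np.any(total <= 0):
        raise ValueError("mu_a + mu_s' must be positive")
    kappa = 1.0 / (3.0 * total)
    return float(kappa) if np.isscalar(mua) and np.isscalar(musp) else kappa


def optical_coefficients(
    comp: TissueComposition, table: ExtinctionTable, wavelengths
) -> OpticalCoefficients:
    """Bundle mu_a, mu_s', kappa for a set of wavelengths (nm)."""
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    mua = np.atleast_1d(absorption_at(comp, table, wl))
    musp = np.atleast_1d(reduced_scattering_at(comp, wl))
    if np.any(mua <= 0):
        raise ValueError(
            "mu_a must be positive at every wavelength; with cTHb = 0 supply "
            "a positive background absorption"
        )
    return OpticalCoefficients(wl, mua, musp, diffusion_coefficient(mua, musp))
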