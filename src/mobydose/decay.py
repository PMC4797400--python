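"""Nuclide decay data: half-life, beta spectrum, photon lines.

Provides the physical decay constant and emission sampling needed by the
Monte Carlo transport engine.  The bundled dataset is Lu-177 (half-life
6.647 d; beta branches with end points near 176, 248, 385 and 497 keV;
principal gamma lines at 112.95 and 208.37 keV), stored as plain-text CSV
resources inside the package so runs are reproducible without network
access.  Other nuclides can be supplied by pointing the loaders at
alternative CSV files with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["NuclideData", "lu177", "physical_decay_constant"]

#: Adopted Lu-177 half-life in days.
LU177_HALF_LIFE_DAYS = 6.647

_DATA_PKG = "mobydose.data"


def _read_csv(name_or_path: str | Path, ncols: int) -> np.ndarray:
    """Read a 2-column numeric CSV (comments '#', one header line)."""
    if isinstance(name_or_path, Path) or "/" in str(name_or_path):
        text = Path(name_or_path).read_text()
    else:
        text = resources.files(_DATA_PKG).joinpath(str(name_or_path)).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        try:
            rows.append([float(p) for p in parts[:ncols]])
        except ValueError:
            continue  # header
    return np.asarray(rows, dtype=float)


def physical_decay_constant(half_life_days: float = LU177_HALF_LIFE_DAYS) -> float:
    """Physical decay constant in h^-1 from a half-life in days.

    Returns ``ln 2 / T_half`` with the half-life converted to hours; this is
    the rate that multiplies the bi-exponential biokinetic model inside the
    cumulated-activity integral.
    """
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) / (half_life_days * 24.0))


@dataclass(frozen=True)
class NuclideData:
    """Emission data for one radionuclide.

    Parameters
    ----------
    half_life_days:
        Physical half-life in days.
    beta_energies_kev, beta_density_per_kev:
        Tabulated beta spectrum: bin-center kinetic energies (keV) and
        probability density (per keV, per decay).  The density integrates
        to the total beta yield per decay (~1 for Lu-177).
    photon_lines:
        Array of shape (n, 2): photon energy (keV), intensity per decay.
    """

    half_life_days: float
    beta_energies_kev: np.ndarray
    beta_density_per_kev: np.ndarray
    photon_lines: np.ndarray
    _widths: np.ndarray = field(init=False, repr=False, compare=False)
    _cdf: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.beta_energies_kev, float)
        d = np.asarray(self.beta_density_per_kev, float)
        if e.ndim != 1 or e.shape != d.shape:
            raise ValueError("spectrum energy/density arrays must be 1-D, equal length")
        if np.any(d < 0) or np.any(e < 0):
            raise ValueError("spectrum energies and densities must be non-negative")
        lines = np.asarray(self.photon_lines, float).reshape(-1, 2)
        if np.any(lines <= 0):
            raise ValueError("photon energies and intensities must be positive")
        object.__setattr__(self, "beta_energies_kev", e)
        object.__setattr__(self, "beta_density_per_kev", d)
        object.__setattr__(self, "photon_lines", lines)
        # bin widths (density is piecewise constant over each bin) and CDF
        widths = np.gradient(e) if e.size > 1 else np.ones(1)
        cdf = np.concatenate([[0.0], np.cumsum(d * widths)])
        object.__setattr__(self, "_widths", widths)
        object.__setattr__(self, "_cdf", cdf)

    # -- derived quantities ------------------------------------------------

    @property
    def beta_yield(self) -> float:
        """Total beta particles emitted per decay (spectrum integral)."""
        return float(self._cdf[-1])

    @property
    def mean_beta_energy_kev(self) -> float:
        """Yield-weighted mean kinetic energy of the beta spectrum (keV)."""
        num = float(np.sum(self.beta_density_per_kev * self._widths * self.beta_energies_kev))
        return num / self.beta_yield

    @property
    def mean_photon_energy_kev(self) -> float:
        """Sum of line energy x intensity over all photon lines (keV/decay)."""
        return float(np.sum(self.photon_lines[:, 0] * self.photon_lines[:, 1]))

    @property
    def mean_energy_per_decay_kev(self) -> float:
        """Mean emitted energy per decay: beta mean x yield + photon lines."""
        return self.beta_yield * self.mean_beta_energy_kev + self.mean_photon_energy_kev

    def physical_decay_constant(self) -> float:
        """ln2 / half-life, in h^-1."""
        return physical_decay_constant(self.half_life_days)

    # -- sampling ----------------------------------------------------------

    def sample_beta_energy(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw beta kinetic energies (keV) by inverse-CDF on the binned table.

        ``rng`` must be a seeded :class:`numpy.random.Generator`; anything
        else raises ``TypeError`` so that unseeded (non-reproducible) runs
        fail loudly.
        """
        if not isinstance(rng, np.random.Generator):
            raise TypeError(
                "rng must be a seeded numpy.random.Generator "
                "(e.g. np.random.default_rng(seed)) for reproducibility"
            )
        if size < 1:
            raise ValueError("size must be >= 1")
        e = self.beta_energies_kev
        if e.size == 1:  # degenerate point-mass spectrum
            return np.full(size, e[0])
        widths = self._widths
        edges = np.concatenate([[e[0] - widths[0] / 2], e + widths / 2])
        edges = np.maximum(edges, 0.0)
        u = rng.uniform(0.0, self._cdf[-1], size=size)
        idx = np.clip(np.searchsorted(self._cdf, u, side="right") - 1, 0, e.size - 1)
        lo, hi = self._cdf[idx], self._cdf[idx + 1]
        frac = np.where(hi > lo, (u - lo) / np.where(hi > lo, hi - lo, 1.0), 0.5)
        return edges[idx] + frac * (edges[idx + 1] - edges[idx])


def lu177(
    spectrum_path: str | Path = "lu177_beta_spectrum.csv",
    lines_path: str | Path = "lu177_photon_lines.csv",
    half_life_days: float = LU177_HALF_LIFE_DAYS,
) -> NuclideData:
    """Load the bundled Lu-177 dataset (or a user-supplied override)."""
    spec = _read_csv(spectrum_path, 2)
    lines = _read_csv(lines_path, 2)
    return NuclideData(
        half_life_days=half_life_days,
        beta_energies_kev=spec[:, 0],
        beta_density_per_kev=spec[:, 1],
        photon_lines=lines,
    )
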