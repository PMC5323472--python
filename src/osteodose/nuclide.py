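"""Radionuclide data: decay constants, beta spectra, emitted energies.

The bundled default describes ¹⁸⁶Re: half-life 3.72 d (89.28 h), beta
emission with endpoint 1.07 MeV, and a 137 keV gamma line with 9 %
abundance.  The default beta spectrum is a single-branch allowed-transition
Fermi shape at that endpoint; users may supply a tabulated spectrum from
a nuclear-data compilation instead, either as a continuous probability
density or as discrete lines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BetaSpectrum",
    "NuclideData",
    "RE186",
    "sample_decay_energies",
    "mean_energy_per_decay",
]

_ELECTRON_MC2_MEV = 0.511


class BetaSpectrum:
    """A beta-decay electron energy spectrum.

    Either a continuous probability density sampled on an energy grid
    (``kind='density'``) or a set of discrete lines with probabilities
    (``kind='lines'``).  Energies in MeV.
    """

    def __init__(self, energies_mev, probabilities, kind: str = "density"):
        e = np.asarray(energies_mev, dtype=float)
        p = np.asarray(probabilities, dtype=float)
        if e.size == 0:
            raise ValueError("spectrum table is empty")
        if e.shape != p.shape:
            raise ValueError("energy and probability arrays differ in length")
        if np.any(e < 0):
            raise ValueError("spectrum energies must be >= 0")
        if np.any(p < 0):
            raise ValueError("spectrum probabilities must be >= 0")
        if kind not in ("density", "lines"):
            raise ValueError(f"unknown spectrum kind {kind!r}")
        order = np.argsort(e)
        self.energies = e[order]
        self.probabilities = p[order]
        self.kind = kind
        total = self._total_probability()
        if total > 1.0 + 1e-6 and kind == "lines":
            raise ValueError(f"line probabilities sum to {total:.6f} > 1")

    def _total_probability(self) -> float:
        if self.kind == "lines":
            return float(self.probabilities.sum())
        return float(np.trapezoid(self.probabilities, self.energies))

    @property
    def endpoint_mev(self) -> float:
        return float(self.energies[-1])

    def mean_energy(self) -> float:
        """Mean electron energy per decay of this branch, MeV.

        Trapezoidal integration of E·p(E) for densities; probability-weighted
        mean for discrete lines.  Normalised by the table's own total so a
        table stored up to an arbitrary constant still gives the physical
        mean.
        """
        if self.kind == "lines":
            return float(np.sum(self.energies * self.probabilities) / self.probabilities.sum())
        num = float(np.trapezoid(self.energies * self.probabilities, self.energies))
        return num / self._total_probability()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` electron energies by inverse-CDF sampling."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "lines":
            if self.energies.size == 1:
                return np.full(n, self.energies[0])
            p = self.probabilities / self.probabilities.sum()
            return rng.choice(self.energies, size=n, p=p)
        # continuous density: piecewise-linear CDF on the table grid
        cdf = np.concatenate(
            [[0.0], np.cumsum(np.diff(self.energies) * 0.5 * (self.probabilities[1:] + self.probabilities[:-1]))]
        )
        cdf /= cdf[-1]
        u = rng.random(n)
        return np.interp(u, cdf, self.energies)

    @classmethod
    def fermi_beta(cls, endpoint_mev: float, n_points: int = 512) -> "BetaSpectrum":
        """Allowed-transition Fermi shape: p(E) ∝ pW(E0−E)², W = E + mc²."""
        if endpoint_mev <= 0:
            raise ValueError("endpoint must be > 0")
        e = np.linspace(0.0, endpoint_mev, n_points)
        w = e + _ELECTRON_MC2_MEV
        momentum = np.sqrt(np.maximum(e**2 + 2.0 * e * _ELECTRON_MC2_MEV, 0.0))
        dens = momentum * w * (endpoint_mev - e) ** 2
        area = np.trapezoid(dens, e)
        return cls(e, dens / area, kind="density")

    # CSV interchange: two columns, energy_MeV, probability_density
    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["energy_MeV", "probability_density"])
            for e, p in zip(self.energies, self.probabilities):
                writer.writerow([repr(float(e)), repr(float(p))])

    @classmethod
    def from_csv(cls, path, kind: str = "density") -> "BetaSpectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        arr = np.atleast_2d(arr)
        return cls(arr[:, 0], arr[:, 1], kind=kind)


@dataclass
class NuclideData:
    """Physical decay data for one radionuclide."""

    half_life_h: float = 89.28  # 3.72 days
    beta_endpoint_mev: float = 1.07
    spectrum: BetaSpectrum | None = None
    gamma_energy_kev: float = 137.0
    gamma_abundance: float = 0.09

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.spectrum is None:
            self.spectrum = BetaSpectrum.fermi_beta(self.beta_endpoint_mev)
        if self.spectrum.endpoint_mev > self.beta_endpoint_mev * (1 + 1e-9):
            raise ValueError("spectrum extends beyond the stated beta endpoint")

    @property
    def decay_constant_per_h(self) -> float:
        return float(np.log(2.0) / self.half_life_h)

    def decay_factor(self, t_h) -> np.ndarray | float:
        """exp(−λt): fraction of activity remaining after ``t_h`` hours."""
        return np.exp(-self.decay_constant_per_h * np.asarray(t_h, dtype=float))


RE186 = NuclideData()


def sample_decay_energies(nuclide: NuclideData, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` beta electron energies (MeV) from the nuclide's spectrum."""
    if nuclide.spectrum is None:
        raise ValueError("nuclide has no spectrum configured")
    rng = np.random.default_rng(seed)
    return nuclide.spectrum.sample(n, rng)


def mean_energy_per_decay(nuclide: NuclideData, include_photons: bool = False) -> float:
    """Mean emitted energy per decay in MeV.

    The electron contribution is the spectrum mean; with
    ``include_photons=True`` the gamma line adds energy × abundance.
    """
    e = nuclide.spectrum.mean_energy()
    if include_photons and nuclide.gamma_abundance > 0:
        e += (nuclide.gamma_energy_kev / 1000.0) * nuclide.gamma_abundance
    return float(e)
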