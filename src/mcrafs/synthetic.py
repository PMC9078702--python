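"""Ground-truthed synthetic titration datasets.

Emulates a UV/Vis acid-base titration of a dye with an intermediate dimer:
12 spectra, 401 channels on 200-600 nm, acid axis [0, 1.264e-3] mol/l,
three absorbing species obeying the closure ``c1 + 2 c2 + c3 = c0`` with
``c0 = 9.84269e-4`` mol/l.  Concentration profiles come from the hard
kinetic model (:mod:`mcrafs.kinetics`); pure spectra are Gaussian-band
mixtures whose defaults partially overlap, with the dimer band system
lying strictly inside the support of the other two — the regime in which
the middle component carries the largest rotational ambiguity.  Additive
Gaussian noise models detector noise on the absorbance scale; the default
level (2e-5 of the absorbance maximum, a high but realistic SNR for
averaged UV/Vis spectra) is chosen so that the noise-induced relative
negativity of the reconstructed factors stays below the standard
feasibility tolerance ``epsilon = 2e-4`` — the regime in which an AFS
analysis at that tolerance is meaningful at all.  Rank-estimation behavior
at noisier settings is exercised by passing ``noise_sigma`` explicitly.

The generator retains the true factors, so every reconstruction method in
the package can be validated against ground truth without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import SpectralDataset
from .kinetics import DEFAULT_C0, KineticModel, default_model, simulate_titration

__all__ = ["SyntheticConfig", "gaussian_spectrum", "generate_dataset"]

#: default Gaussian bands (center nm, width nm, height l/mol) per component.
#: Heights ~1e3 l/mol give peak absorbances of order one at c0 ~ 1e-3 mol/l.
DEFAULT_PEAKS = (
    # free dye: UV bands, vanishing above ~450 nm
    ((232.0, 14.0, 450.0), (290.0, 20.0, 700.0), (345.0, 26.0, 1000.0)),
    # protonated dimer: strictly inside the union of the other supports
    ((310.0, 16.0, 500.0), (362.0, 22.0, 950.0), (405.0, 18.0, 550.0)),
    # protonated monomer: visible bands, vanishing below ~260 nm
    ((322.0, 18.0, 400.0), (470.0, 30.0, 1000.0), (545.0, 24.0, 420.0)),
)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic titration experiment."""

    n_conditions: int = 12
    n_channels: int = 401
    wavelength_range: tuple = (200.0, 600.0)
    acid_max: float = 1.264e-3
    c0: float = DEFAULT_C0
    k1: float | None = None  # None -> gauge-normalized default rates
    k2: float | None = None
    peaks: tuple = DEFAULT_PEAKS
    noise_sigma: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2 or self.n_channels < 2:
            raise ValueError("need at least 2 conditions and 2 channels")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength_range must be increasing")
        if self.acid_max <= 0 or self.c0 <= 0 or self.noise_sigma < 0:
            raise ValueError("acid_max, c0 must be > 0 and noise_sigma >= 0")
        for comp in self.peaks:
            for center, width, height in comp:
                if not lo <= center <= hi:
                    raise ValueError(f"peak center {center} outside {lo}-{hi} nm")
                if width <= 0 or height <= 0:
                    raise ValueError("peak widths and heights must be positive")

    @property
    def n_components(self) -> int:
        return len(self.peaks)

    def model(self) -> KineticModel:
        if self.k1 is None or self.k2 is None:
            return default_model(self.c0)
        return KineticModel(k1=self.k1, k2=self.k2, c0=self.c0)

    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_channels)

    def acid_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.acid_max, self.n_conditions)


def gaussian_spectrum(peaks, wavelengths: np.ndarray) -> np.ndarray:
    """Sum of Gaussian absorption bands ``h * exp(-(l - c)^2 / (2 w^2))``."""
    if not len(peaks):
        raise ValueError("need at least one band")
    wavelengths = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wavelengths)
    for center, width, height in peaks:
        out += height * np.exp(-((wavelengths - center) ** 2) / (2.0 * width**2))
    return out


def generate_dataset(config: SyntheticConfig | None = None):
    """Generate ``(dataset, C_true, S_true)`` with ``D = C S^T + noise``.

    ``C_true`` (k x 3, mol/l) obeys the closure exactly; ``S_true``
    (n x 3, l/mol) are the pure molar spectra.  Noise is additive Gaussian
    with standard deviation ``noise_sigma * max(C S^T)``, drawn from the
    seeded generator, so a fixed seed reproduces the dataset bit for bit.
    """
    config = config or SyntheticConfig()
    wl = config.wavelengths()
    acid = config.acid_grid()
    S_true = np.column_stack([gaussian_spectrum(p, wl) for p in config.peaks])
    C_true = simulate_titration(config.model(), acid)
    clean = C_true @ S_true.T
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(scale=config.noise_sigma * np.max(clean), size=clean.shape) \
        if config.noise_sigma > 0 else 0.0
    dataset = SpectralDataset(
        absorbance=clean + noise,
        wavelengths=wl,
        conditions=acid,
        closure_c0=config.c0,
    )
    return dataset, C_true, S_true
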