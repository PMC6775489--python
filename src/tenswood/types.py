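"""Core data containers shared across the pipeline stages.

The containers are deliberately thin: numpy arrays for spectra and
coordinates, pandas for tabular results. Validation happens at
construction so downstream stages can assume well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class Spectrum:
    """A single spectrum on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy())


@dataclass
class SpectralMap:
    """A hyperspectral map: one spectrum per (x, y) voxel on a shared grid.

    ``labels`` optionally carries ground-truth layer labels (synthetic maps)
    and ``true_concentrations`` the planted mixing weights, so unmixing and
    segmentation stages can be scored against known truth.
    """

    wavenumbers: np.ndarray
    coordinates: np.ndarray  # (n, 2) integer voxel indices (x, y), 0-based
    intensities: np.ndarray  # (n, m)
    labels: np.ndarray | None = None
    true_concentrations: np.ndarray | None = None  # (n, k)
    component_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        n, m = self.intensities.shape
        if self.coordinates.shape[0] != n:
            raise ValueError("coordinate/intensity row mismatch")
        if self.wavenumbers.size != m:
            raise ValueError("grid length does not match spectral columns")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        coords = {tuple(c) for c in self.coordinates}
        if len(coords) != n:
            raise ValueError("duplicate voxel coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("label/voxel count mismatch")

    @property
    def n_voxels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i])

    def replace_intensities(self, intensities: np.ndarray,
                            wavenumbers: np.ndarray | None = None) -> "SpectralMap":
        return SpectralMap(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            coordinates=self.coordinates,
            intensities=intensities,
            labels=self.labels,
            true_concentrations=self.true_concentrations,
            component_names=self.component_names,
        )


@dataclass
class StemTrace:
    """Ordered XY polyline of a stem from base to primary bending point.

    y increases upward (height); consecutive duplicate points are collapsed
    at construction.
    """

    tree_id: str
    genotype: str
    day: int
    xy: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        keep = np.ones(len(xy), dtype=bool)
        keep[1:] = np.any(np.diff(xy, axis=0) != 0, axis=1)
        xy = xy[keep]
        if len(xy) < 3:
            raise ValueError("trace needs at least 3 distinct points")
        self.xy = xy


@dataclass
class AzimuthalProfile:
    """Azimuthal (200)-reflection intensity profile: angle phi (deg) vs intensity."""

    phi: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.phi.shape != self.intensity.shape or self.phi.ndim != 1:
            raise ValueError("phi and intensity must be equal-length 1-D arrays")
        steps = np.diff(self.phi)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("phi grid must be regular")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


LAYER_LUMEN = "lumen"
LAYER_MLS = "ML+S"
LAYER_G = "G"
LAYER_S = "S"
LAYERS = (LAYER_LUMEN, LAYER_MLS, LAYER_G, LAYER_S)
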