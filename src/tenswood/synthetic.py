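"""Synthetic-data generators for every pipeline input, with recorded truth.

Each generator emulates one class of raw measurement consumed by the
analysis stages: layered Raman spectral maps, digitized stem traces of an
uplifting experiment, bimodal azimuthal X-ray intensity profiles,
differential-expression tables with planted ethylene-dependent genes, and
promoter sets with planted cis-elements. All generators are deterministic
given a seed, and all return the planted ground truth alongside the data so
downstream stages can be scored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AzimuthalProfile,
    LAYER_G,
    LAYER_LUMEN,
    LAYER_MLS,
    LAYER_S,
    SpectralMap,
    StemTrace,
)

# ---------------------------------------------------------------------------
# Component spectra


@dataclass
class ComponentSpec:
    """A pure-component spectrum defined as a sum of Gaussian bands.

    bands: list of (center cm^-1, width cm^-1, height >= 0).
    """

    name: str
    bands: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r} has no bands")
        for c, w, h in self.bands:
            if w <= 0:
                raise ValueError("band width must be > 0")
            if h < 0:
                raise ValueError("band height must be >= 0")


# Band positions anchored to canonical wood cell-wall assignments:
# cellulose ~1,096/1,120/1,376 cm^-1 (carbohydrate ring / CH bending),
# lignin ~1,600/1,660 cm^-1 (aromatic ring stretch), a carbonyl-bearing
# extractives component at ~1,730 cm^-1, and a broad residual component.
DEFAULT_COMPONENTS = [
    ComponentSpec("cellulose", [(1096.0, 12.0, 1.0), (1120.0, 10.0, 0.7),
                                (1376.0, 11.0, 0.6), (520.0, 15.0, 0.3)]),
    ComponentSpec("lignin", [(1600.0, 12.0, 1.0), (1660.0, 14.0, 0.5),
                             (1270.0, 18.0, 0.3)]),
    ComponentSpec("extractives", [(1730.0, 16.0, 1.0), (850.0, 20.0, 0.3)]),
    ComponentSpec("residual", [(950.0, 20.0, 0.5), (1450.0, 18.0, 0.6),
                               (700.0, 16.0, 0.4)]),
]


def gen_component_profiles(specs: list[ComponentSpec],
                           grid: np.ndarray) -> np.ndarray:
    """Evaluate pure-component profiles on a wavenumber grid.

    Returns a (k, m) matrix; each row is a non-negative Gaussian-band sum,
    area-normalized (trapezoid) to 1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    profiles = np.zeros((len(specs), grid.size))
    for i, spec in enumerate(specs):
        for center, width, height in spec.bands:
            if not (grid[0] <= center <= grid[-1]):
                raise ValueError(
                    f"band center {center} outside grid "
                    f"[{grid[0]}, {grid[-1]}] for component {spec.name!r}")
            profiles[i] += height * np.exp(-0.5 * ((grid - center) / width) ** 2)
        area = np.trapezoid(profiles[i], grid)
        if area <= 0:
            raise ValueError(f"component {spec.name!r} has zero area")
        profiles[i] /= area
    return profiles


# ---------------------------------------------------------------------------
# Layered spectral maps


@dataclass
class LayerLayout:
    """Spatial layer layout of a map plus per-layer component mixing weights."""

    shape: tuple[int, int]  # (rows, cols)
    labels: np.ndarray  # (rows*cols,) layer label per voxel
    weights: dict[str, np.ndarray]  # layer -> (k,) non-negative weights

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size != self.shape[0] * self.shape[1]:
            raise ValueError("label count does not match grid shape")
        for layer in np.unique(self.labels):
            if layer not in self.weights:
                raise ValueError(f"no mixing weights for layer {layer!r}")
        for layer, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if np.any(w < 0):
                raise ValueError(f"negative mixing weight for layer {layer!r}")
            self.weights[layer] = w


def default_layer_layout(tissue: str = "TW", rows: int = 1,
                         cols: int = 70) -> LayerLayout:
    """Radial transect over three fiber cells: lumen - ML+S - wall - ML+S - lumen.

    Mirrors a line map recorded from the lumen of one cell across to the
    lumen of a third, with the inner wall layer being the G-layer in tension
    wood (TW) and the S-layer in normal wood (NW). Weights are over the
    default four components (cellulose, lignin, extractives, residual).
    """
    if tissue not in ("TW", "NW"):
        raise ValueError("tissue must be 'TW' or 'NW'")
    wall = LAYER_G if tissue == "TW" else LAYER_S
    # one cell = lumen(4) ML+S(3) wall(6) ML+S(3); three cells end in lumen
    cell = [LAYER_LUMEN] * 4 + [LAYER_MLS] * 3 + [wall] * 6 + [LAYER_MLS] * 3
    pattern = cell * 3 + [LAYER_LUMEN] * 4
    labels_row = (pattern * ((cols // len(pattern)) + 1))[:cols]
    labels = np.tile(labels_row, rows)
    if tissue == "TW":
        # G-layer: cellulose-rich, with unassigned matrix-gel contributions
        wall_w = np.array([1.0, 0.08, 0.1, 0.7])
    else:
        wall_w = np.array([0.55, 0.45, 0.08, 0.4])  # S-layer: mixed
    weights = {
        # lumina carry no wall polymers but can hold extractive deposits
        # and residual (cell content) signal
        LAYER_LUMEN: np.array([0.0, 0.0, 0.35, 0.25]),
        LAYER_MLS: np.array([0.35, 0.75, 0.05, 0.1]),  # lignin-rich
        wall: wall_w,
    }
    return LayerLayout((rows, cols), labels, weights)


def gen_spectral_map(layout: LayerLayout, profiles: np.ndarray,
                     grid: np.ndarray, noise_sd: float = 0.0,
                     baseline: tuple[float, ...] = (),
                     spike_rate: float = 0.0,
                     weight_jitter: float = 0.15,
                     seed: int = 0,
                     component_names: list[str] | None = None) -> SpectralMap:
    """Generate a spectral map from a layout and pure profiles.

    Each voxel spectrum is weights.T @ profiles plus an optional polynomial
    baseline (coefficients in ascending order, on a [0, 1]-scaled wavenumber
    axis), i.i.d. Gaussian noise with sd = ``noise_sd`` times the global
    maximum of the clean data, and, with probability ``spike_rate`` per
    spectrum, one positive single-channel cosmic spike of 10-50x the local
    amplitude. ``weight_jitter`` applies multiplicative uniform voxel-to-voxel
    variation (fraction) to the layer mixing weights, emulating natural
    within-layer compositional variability; the jittered concentrations are
    the stored truth, so the noiseless map still factorizes exactly. Planted
    concentrations and layer labels are stored on the map.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = np.asarray(grid, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    k = profiles.shape[0]
    rng = np.random.default_rng(seed)
    rows, cols = layout.shape
    n = rows * cols
    conc = np.zeros((n, k))
    for i, layer in enumerate(layout.labels):
        w = layout.weights[str(layer)]
        if w.size != k:
            raise ValueError("mixing weight length does not match profiles")
        conc[i] = w
    if weight_jitter > 0:
        conc = np.clip(conc * (1.0 + weight_jitter
                               * rng.uniform(-1, 1, size=conc.shape)), 0, None)
    clean = conc @ profiles
    data = clean.copy()
    if baseline:
        x = (grid - grid[0]) / (grid[-1] - grid[0])
        base = np.polynomial.polynomial.polyval(x, np.asarray(baseline, float))
        data = data + base
    scale = float(np.max(clean)) if np.max(clean) > 0 else 1.0
    if noise_sd > 0:
        # signal-dependent (shot-noise-like) level: sd scales with each
        # voxel's peak amplitude, with a small detector floor
        vox_scale = np.maximum(clean.max(axis=1, keepdims=True), 0.05 * scale)
        data = data + rng.normal(0.0, 1.0, size=data.shape) * (noise_sd * vox_scale)
    if spike_rate > 0:
        hit = rng.random(n) < spike_rate
        for i in np.nonzero(hit)[0]:
            ch = rng.integers(0, grid.size)
            local = max(abs(data[i, ch]), 0.05 * scale)
            data[i, ch] += rng.uniform(10, 50) * local
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return SpectralMap(
        wavenumbers=grid, coordinates=coords, intensities=data,
        labels=layout.labels.copy(), true_concentrations=conc,
        component_names=component_names,
    )


def default_raman_grid(lo: float = 510.0, hi: float = 1800.0,
                       step: float = 1.0) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


# ---------------------------------------------------------------------------
# Stem traces


@dataclass
class UpliftModel:
    """Per-genotype curvature trajectories of an uplifting experiment.

    ``genotypes`` maps genotype name -> (asymptote degrees, rate per day,
    lag days): curvature(day) = asymptote * (1 - exp(-rate * (day - lag)))
    for day > lag, else 0.
    """

    days: int = 28
    # defaults emulate a strong wild-type uprighting response and a
    # delayed, attenuated response of the ethylene-insensitive line whose
    # final-day lift is about half the wild type's
    genotypes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"WT": (120.0, 0.2, 1.0),
                                 "ETI": (44.7, 0.1, 3.0)})
    stem_length: float = 1.0
    points_per_trace: int = 1000
    trees_per_genotype: int = 6
    curvature_jitter_sd: float = 0.0  # degrees, per tree per day

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.stem_length <= 0:
            raise ValueError("stem length must be > 0")
        for g, (a, r, lag) in self.genotypes.items():
            if not (0 <= a < 360):
                raise ValueError(f"asymptote for {g!r} must be in [0, 360)")

    def curvature_deg(self, genotype: str, day: int) -> float:
        a, r, lag = self.genotypes[genotype]
        if day <= lag:
            return 0.0
        return a * (1.0 - math.exp(-r * (day - lag)))


def arc_trace_xy(curvature_deg: float, length: float, n_points: int) -> np.ndarray:
    """Constant-arc-length circular-arc polyline.

    Base at the origin, first segment horizontal (+x), bending upward.
    Segment headings are spread uniformly from 0 to the total turn, so the
    summed turning angle between consecutive segments equals
    ``curvature_deg`` exactly (not just in the refinement limit), and the
    polyline length equals ``length`` exactly.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    theta = math.radians(curvature_deg)
    ds = length / (n_points - 1)
    if abs(theta) < 1e-15:
        headings = np.zeros(n_points - 1)
    else:
        headings = theta * np.arange(n_points - 1) / (n_points - 2)
    xy = np.zeros((n_points, 2))
    xy[1:, 0] = np.cumsum(ds * np.cos(headings))
    xy[1:, 1] = np.cumsum(ds * np.sin(headings))
    return xy


def analytic_lift(curvature_deg: float) -> float:
    """Normalized lift of a circular arc of given total turning.

    For an arc of turning theta (radians) and unit length starting
    horizontally, the apex height is (1 - cos theta) / theta.
    """
    theta = math.radians(curvature_deg)
    if abs(theta) < 1e-12:
        return 0.0
    return (1.0 - math.cos(theta)) / theta


def gen_stem_traces(model: UpliftModel, seed: int = 0) -> list[StemTrace]:
    """Generate one trace per tree per day per genotype."""
    rng = np.random.default_rng(seed)
    traces: list[StemTrace] = []
    for genotype in model.genotypes:
        for tree in range(model.trees_per_genotype):
            for day in range(1, model.days + 1):
                curv = model.curvature_deg(genotype, day)
                if model.curvature_jitter_sd > 0:
                    curv = max(0.0, curv + rng.normal(0, model.curvature_jitter_sd))
                xy = arc_trace_xy(curv, model.stem_length, model.points_per_trace)
                traces.append(StemTrace(tree_id=f"{genotype}_{tree + 1}",
                                        genotype=genotype, day=day, xy=xy))
    return traces


# ---------------------------------------------------------------------------
# Azimuthal profiles


def azimuthal_mixture(phi: np.ndarray, mu_g: float, sigma_g: float,
                      mu_s: float, sigma_s: float, weight_s: float,
                      background: float, amplitude: float = 1.0) -> np.ndarray:
    """Symmetric two-population azimuthal model.

    Each population contributes a +/-mu pair of Gaussians (unit peak height
    before weighting); ``weight_s`` is the S-layer fraction of the total
    diffracting signal and ``background`` a constant offset.
    """
    def pair(mu: float, sigma: float) -> np.ndarray:
        return 0.5 * (np.exp(-0.5 * ((phi - mu) / sigma) ** 2)
                      + np.exp(-0.5 * ((phi + mu) / sigma) ** 2))

    return amplitude * ((1.0 - weight_s) * pair(mu_g, sigma_g)
                        + weight_s * pair(mu_s, sigma_s)) + background


def gen_azimuthal_profile(mu_g: float = 2.0, sigma_g: float = 4.0,
                          mu_s: float = 38.0, sigma_s: float = 8.0,
                          weight_s: float = 0.6, background: float = 0.05,
                          noise_sd: float = 0.0, seed: int = 0,
                          amplitude: float = 1.0) -> AzimuthalProfile:
    """Bimodal azimuthal profile on phi in [-90, 90] deg, 1-deg steps.

    Emulates the (200)-reflection profile of tension wood: a near-axial
    G-layer population (mu_g ~ 0-5 deg) and an inclined S-layer population
    (mu_s ~ 20-40 deg), mirror-symmetric about the meridian.
    """
    if not (0 <= mu_g < mu_s < 90):
        raise ValueError("require 0 <= mu_g < mu_s < 90")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    phi = np.arange(-90.0, 90.0 + 0.5, 1.0)
    inten = azimuthal_mixture(phi, mu_g, sigma_g, mu_s, sigma_s, weight_s,
                              background, amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0, noise_sd, size=phi.shape)
    return AzimuthalProfile(phi, inten)


# ---------------------------------------------------------------------------
# Differential-expression tables


@dataclass
class RegulatoryTruth:
    """Planted ground truth for the regulatory generators."""

    et_dependent: set[str] = field(default_factory=set)
    shared_drg: set[str] = field(default_factory=set)
    eti_only_drg: set[str] = field(default_factory=set)
    motif_positions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    # motif name -> gene id -> 1-based planted start positions


def gen_de_tables(n_genes: int = 1000, frac_et_dependent: float = 0.3,
                  frac_shared: float = 0.2, frac_eti_only: float = 0.05,
                  effect_loc: float = 1.5, effect_scale: float = 0.7,
                  lfc_cut: float = 0.5, padj_cut: float = 0.05,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, RegulatoryTruth]:
    """Two DE tables (WT and ethylene-insensitive contrasts) with planted truth.

    Planted ethylene-dependent genes pass the fold-change/significance rule
    in the WT table only; ``frac_shared`` genes pass in both, ``frac_eti_only``
    only in the insensitive line, and the remainder pass in neither. Effect
    sizes are drawn as signed |Normal(effect_loc, effect_scale)| log2
    fold-changes bounded away from the cut for passing genes.
    """
    if frac_et_dependent + frac_shared + frac_eti_only > 1:
        raise ValueError("class fractions exceed 1")
    rng = np.random.default_rng(seed)
    genes = [f"Potri.{i:06d}" for i in range(n_genes)]
    n_et = round(n_genes * frac_et_dependent)
    n_sh = round(n_genes * frac_shared)
    n_eo = round(n_genes * frac_eti_only)
    order = rng.permutation(n_genes)
    et_idx = set(order[:n_et])
    sh_idx = set(order[n_et:n_et + n_sh])
    eo_idx = set(order[n_et + n_sh:n_et + n_sh + n_eo])

    def sig_effect() -> tuple[float, float]:
        lfc = max(lfc_cut, abs(rng.normal(effect_loc, effect_scale)))
        lfc *= rng.choice([-1.0, 1.0])
        padj = float(rng.uniform(0, padj_cut * 0.9))
        return lfc, padj

    def null_effect() -> tuple[float, float]:
        lfc = float(rng.normal(0, lfc_cut / 3))
        padj = float(rng.uniform(padj_cut, 1.0))
        return lfc, padj

    rows_wt, rows_eti = [], []
    for i, g in enumerate(genes):
        wt = sig_effect() if (i in et_idx or i in sh_idx) else null_effect()
        eti = sig_effect() if (i in sh_idx or i in eo_idx) else null_effect()
        rows_wt.append((g, *wt))
        rows_eti.append((g, *eti))
    cols = ["gene", "log2FC", "padj"]
    wt_tab = pd.DataFrame(rows_wt, columns=cols)
    eti_tab = pd.DataFrame(rows_eti, columns=cols)
    truth = RegulatoryTruth(
        et_dependent={genes[i] for i in et_idx},
        shared_drg={genes[i] for i in sh_idx},
        eti_only_drg={genes[i] for i in eo_idx},
    )
    return wt_tab, eti_tab, truth


# ---------------------------------------------------------------------------
# Promoters


def gen_promoters(n_genes: int = 100, length: int = 2000,
                  plant: dict[str, dict[str, list[int]]] | None = None,
                  base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
                  seed: int = 0) -> tuple[dict[str, str], RegulatoryTruth]:
    """Promoter sequences with optionally planted motif instances.

    ``plant`` maps motif literal (a concrete ACGT string, not IUPAC) to
    {gene id: [1-based start positions]}. Background bases are i.i.d. with
    ``base_freqs`` over ACGT. Planted positions are recorded in the returned
    truth object.
    """
    if length > 2000:
        raise ValueError("promoter length is at most 2,000 bp")
    if not math.isclose(sum(base_freqs), 1.0, abs_tol=1e-9):
        raise ValueError("base frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for i in range(n_genes):
        gid = f"Potri.{i:06d}"
        seqs[gid] = "".join(rng.choice(bases, size=length, p=base_freqs))
    truth = RegulatoryTruth()
    if plant:
        for motif, targets in plant.items():
            if set(motif) - set("ACGT"):
                raise ValueError("planted motif must be a concrete ACGT string")
            truth.motif_positions[motif] = {}
            for gid, positions in targets.items():
                if gid not in seqs:
                    raise KeyError(f"unknown gene id {gid!r}")
                seq = list(seqs[gid])
                for pos in positions:
                    if not (1 <= pos <= length - len(motif) + 1):
                        raise ValueError(f"plant position {pos} out of range")
                    seq[pos - 1:pos - 1 + len(motif)] = motif
                seqs[gid] = "".join(seq)
                truth.motif_positions[motif][gid] = sorted(positions)
    return seqs, truth
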