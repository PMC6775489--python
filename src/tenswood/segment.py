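"""Voxel classification of MCR concentration maps into cell-wall zones.

Hard k-means with three clusters separates each map into lumen, middle
lamella + S (ML+S), and the inner wall layer (G-layer in tension wood,
S-layer in normal wood), followed by map-level quality control that drops
maps without distinguishable zones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .mcr import MCRModel
from .types import LAYER_G, LAYER_LUMEN, LAYER_MLS, LAYER_S, SpectralMap


@dataclass
class ClusterMap:
    cluster_index: np.ndarray  # (n,) in {0, 1, 2}
    layer: np.ndarray  # (n,) layer label strings
    assignment: dict[int, str]  # cluster index -> layer label
    qc_pass: bool = True
    qc_reason: str = ""


def kmeans_voxels(concentrations: np.ndarray, n_clusters: int = 3,
                  seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Hard k-means labels on the concentration rows, deterministic per seed."""
    x = np.asarray(concentrations, dtype=float)
    if x.shape[0] < n_clusters:
        raise ValueError("fewer voxels than clusters")
    if np.unique(x, axis=0).shape[0] < n_clusters:
        raise ValueError("fewer distinct concentration rows than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(x)


def assign_layers(cluster_index: np.ndarray, model: MCRModel,
                  tissue: str = "TW") -> ClusterMap:
    """Map cluster indices to layer labels from their chemistry.

    The cluster with the lowest mean polymer (cellulose + lignin)
    concentration is the lumen — robust also on area-normalized spectra,
    where total signal no longer distinguishes empty lumina. Of
    the remaining two, the one with the higher cellulose:lignin ratio is
    the cellulose-rich inner wall layer (G in tension wood, S in normal
    wood); the other is ML+S. Requires the model to carry component names
    including 'cellulose' and 'lignin'.
    """
    if tissue not in ("TW", "NW"):
        raise ValueError("tissue must be 'TW' or 'NW'")
    names = model.component_names
    if not names or "cellulose" not in names or "lignin" not in names:
        raise ValueError("model must identify cellulose and lignin components")
    i_cel, i_lig = names.index("cellulose"), names.index("lignin")
    c = model.concentrations
    clusters = np.unique(cluster_index)
    polymer = {int(k): c[cluster_index == k][:, [i_cel, i_lig]].sum(axis=1).mean()
               for k in clusters}
    lumen = min(polymer, key=polymer.get)
    assignment = {lumen: LAYER_LUMEN}
    rest = [int(k) for k in clusters if int(k) != lumen]
    wall_label = LAYER_G if tissue == "TW" else LAYER_S
    if len(rest) == 2:
        eps = 1e-12
        ratios = {k: (c[cluster_index == k, i_cel].mean() + eps)
                  / (c[cluster_index == k, i_lig].mean() + eps) for k in rest}
        hi = max(ratios, key=ratios.get)
        lo = min(ratios, key=ratios.get)
        assignment[hi] = wall_label
        assignment[lo] = LAYER_MLS
    elif len(rest) == 1:
        assignment[rest[0]] = LAYER_MLS
    layer = np.array([assignment[int(k)] for k in cluster_index])
    return ClusterMap(cluster_index=np.asarray(cluster_index), layer=layer,
                      assignment=assignment)


def map_qc(cmap: ClusterMap, concentrations: np.ndarray,
           min_voxels_per_zone: int = 5,
           min_separation: float = 2.0) -> ClusterMap:
    """Flag maps where no zones can be distinguished.

    A map is dropped when any assigned zone has fewer than
    ``min_voxels_per_zone`` voxels, fewer than three zones are present, or
    the minimum between-centroid distance falls below ``min_separation``
    times the pooled within-cluster RMS spread.
    """
    c = np.asarray(concentrations, dtype=float)
    clusters = np.unique(cmap.cluster_index)
    if len(clusters) < 3:
        cmap.qc_pass, cmap.qc_reason = False, "fewer than 3 zones present"
        return cmap
    counts = {int(k): int(np.sum(cmap.cluster_index == k)) for k in clusters}
    small = [k for k, v in counts.items() if v < min_voxels_per_zone]
    if small:
        labels = ", ".join(cmap.assignment[k] for k in small)
        cmap.qc_pass = False
        cmap.qc_reason = f"zone(s) below {min_voxels_per_zone} voxels: {labels}"
        return cmap
    centroids = np.vstack([c[cmap.cluster_index == k].mean(axis=0)
                           for k in clusters])
    within = np.sqrt(np.mean([
        np.sum((c[cmap.cluster_index == k] - centroids[i])**2, axis=1).mean()
        for i, k in enumerate(clusters)]))
    sep = min(np.linalg.norm(centroids[i] - centroids[j])
              for i in range(len(clusters)) for j in range(i + 1, len(clusters)))
    if within > 0 and sep < min_separation * within:
        cmap.qc_pass = False
        cmap.qc_reason = (f"centroid separation {sep:.3g} below "
                          f"{min_separation} x within-spread {within:.3g}")
        return cmap
    cmap.qc_pass, cmap.qc_reason = True, ""
    return cmap


def extract_layer_spectra(smap: SpectralMap, cmap: ClusterMap, layer: str,
                          genotype: str = "", tissue: str = "") -> pd.DataFrame:
    """Spectra of voxels assigned to ``layer``, with sample metadata attached.

    Returns a DataFrame with columns x, y, genotype, tissue, layer followed
    by one column per wavenumber channel.
    """
    mask = cmap.layer == layer
    meta = pd.DataFrame({
        "x": smap.coordinates[mask, 0], "y": smap.coordinates[mask, 1],
        "genotype": genotype, "tissue": tissue, "layer": layer,
    })
    spec = pd.DataFrame(smap.intensities[mask],
                        columns=[f"{nu:.6g}" for nu in smap.wavenumbers],
                        index=meta.index)
    return pd.concat([meta, spec], axis=1)
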