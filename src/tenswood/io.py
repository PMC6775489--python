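"""Text-format readers and writers for every pipeline artifact.

All formats are plain text (TSV/CSV/FASTA/JSON) with locale-independent
decimal points. Files written here carry provenance comment lines
(``# key: value``) recording package version, seed and config hash; the
readers skip comment lines. Voxel coordinates are 0-based; genomic motif
positions are 1-based inclusive.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .types import AzimuthalProfile, SpectralMap, StemTrace


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_lines(seed: int | None = None,
                     config: dict | None = None) -> list[str]:
    lines = [f"# tenswood_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    return lines


def _write_text(path: str | Path, lines: Iterable[str]) -> None:
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spectral maps


def write_spectral_map(smap: SpectralMap, path: str | Path,
                       seed: int | None = None,
                       config: dict | None = None) -> None:
    """TSV: provenance comments, then 'x<TAB>y<TAB>nu1...' header, one voxel/row."""
    lines = provenance_lines(seed, config)
    header = "x\ty\t" + "\t".join(f"{nu:.10g}" for nu in smap.wavenumbers)
    lines.append(header)
    for (x, y), row in zip(smap.coordinates, smap.intensities):
        lines.append(f"{x}\t{y}\t" + "\t".join(f"{v:.12g}" for v in row))
    _write_text(path, lines)


def read_spectral_map(path: str | Path) -> SpectralMap:
    """Read and validate a spectral-map TSV; errors carry line numbers."""
    raw = Path(path).read_text().splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(raw)
            if ln.strip() and not ln.startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty spectral map")
    header_no, header = body[0]
    cols = header.split("\t")
    if cols[:2] != ["x", "y"]:
        raise ValueError(f"{path}:{header_no}: header must start with 'x\\ty'")
    try:
        grid = np.array([float(c) for c in cols[2:]])
    except ValueError as e:
        raise ValueError(f"{path}:{header_no}: non-numeric wavenumber: {e}")
    if grid.size < 1:
        raise ValueError(f"{path}:{header_no}: no wavenumber columns")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError(f"{path}:{header_no}: grid not increasing")
    coords, rows = [], []
    seen: set[tuple[int, int]] = set()
    for line_no, ln in body[1:]:
        parts = ln.split("\t")
        if len(parts) != grid.size + 2:
            raise ValueError(f"{path}:{line_no}: ragged row "
                             f"({len(parts)} fields, expected {grid.size + 2})")
        try:
            xy = (int(parts[0]), int(parts[1]))
            vals = [float(v) for v in parts[2:]]
        except ValueError as e:
            raise ValueError(f"{path}:{line_no}: non-numeric cell: {e}")
        if xy in seen:
            raise ValueError(f"{path}:{line_no}: duplicate voxel {xy}")
        seen.add(xy)
        coords.append(xy)
        rows.append(vals)
    return SpectralMap(wavenumbers=grid, coordinates=np.array(coords),
                       intensities=np.array(rows))


# ---------------------------------------------------------------------------
# Stem traces


def write_traces(traces: list[StemTrace], path: str | Path,
                 seed: int | None = None, config: dict | None = None) -> None:
    """CSV with columns tree_id,genotype,day,point_index,x,y (y up)."""
    lines = provenance_lines(seed, config)
    lines.append("tree_id,genotype,day,point_index,x,y")
    for t in traces:
        for i, (x, y) in enumerate(t.xy):
            lines.append(f"{t.tree_id},{t.genotype},{t.day},{i},{x:.12g},{y:.12g}")
    _write_text(path, lines)


def read_traces(path: str | Path, flip_y: bool = False) -> list[StemTrace]:
    """Read digitized traces; ``flip_y`` negates y for image-pixel convention
    (pixel y grows downward, stem height grows upward)."""
    df = pd.read_csv(path, comment="#")
    required = {"tree_id", "genotype", "day", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (tree, geno, day), grp in df.groupby(["tree_id", "genotype", "day"],
                                             sort=True):
        grp = grp.sort_values("point_index")
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        if flip_y:
            xy = xy * np.array([1.0, -1.0])
        traces.append(StemTrace(tree_id=str(tree), genotype=str(geno),
                                day=int(day), xy=xy))
    return traces


# ---------------------------------------------------------------------------
# Azimuthal profiles


def write_profile(profile: AzimuthalProfile, path: str | Path,
                  seed: int | None = None) -> None:
    lines = provenance_lines(seed)
    lines.append("phi_deg,intensity")
    for p, v in zip(profile.phi, profile.intensity):
        lines.append(f"{p:.10g},{v:.12g}")
    _write_text(path, lines)


def read_profile(path: str | Path) -> AzimuthalProfile:
    df = pd.read_csv(path, comment="#")
    if not {"phi_deg", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: need columns phi_deg,intensity")
    return AzimuthalProfile(df["phi_deg"].to_numpy(), df["intensity"].to_numpy())


# ---------------------------------------------------------------------------
# DE tables


def write_de_table(table: pd.DataFrame, path: str | Path,
                   seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log2FC", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    bad = ~df["padj"].between(0, 1) | ~np.isfinite(df["padj"])
    if bad.any():
        raise ValueError(f"{path}: adjusted p outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# FASTA promoters


def write_fasta(promoters: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="")
               for gid, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """id = first whitespace token of the header; sequence uppercased and
    validated against {A, C, G, T, N}."""
    promoters: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        illegal = set(seq) - set("ACGTN")
        if illegal:
            raise ValueError(
                f"{path}: record {rec.id!r} has illegal characters "
                f"{sorted(illegal)}")
        if rec.id in promoters:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        promoters[rec.id] = seq
    return promoters


# ---------------------------------------------------------------------------
# JSON sidecars


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (bool, np.bool_)):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
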