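"""End-to-end pipeline orchestration with provenance-tracked artifacts.

Three pipelines tie the stages together:

* ``chemotype`` — simulate layered Raman maps for two genotypes,
  preprocess, unmix with MCR-ALS, segment into layers with QC, and run
  OPLS-DA on the wall-layer spectra of the two genotypes.
* ``kinematics`` — simulate multi-day stem traces per genotype and compute
  per-day normalized lift and curvature plus the final-day contrast.
* ``regulatory`` — simulate paired DE tables and promoters, apply the DRG
  rule and the ethylene-dependent set logic, scan cis-elements and score
  hypergeometric enrichment.

Every artifact is written under a temporary directory that is renamed into
place only on success; a JSON manifest records the SHA-256 of every file.
"""
from __future__ import annotations

import hashlib
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemometrics, io, kinematics, mcr, preprocess
from . import regulatory as reg
from . import segment, synthetic

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "pipelines": ["chemotype", "kinematics", "regulatory"],
    "chemotype": {
        "noise_sd": 0.01,
        "spike_rate": 0.05,
        "baseline": [0.0005, 0.001],
        "k": 4,
        "max_iter": 200,
        "n_orth": 2,
        "cv_folds": 7,
        "cols": 70,
    },
    "kinematics": {"days": 28, "points_per_trace": 1000,
                   "curvature_jitter_sd": 3.0},
    "regulatory": {"n_genes": 400, "frac_et_dependent": 0.25,
                   "n_promoters": 120, "promoter_length": 1500},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_chemotype(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["chemotype"]
    grid = synthetic.default_raman_grid()
    # the two genotypes differ in wall-layer chemistry: the ethylene-
    # insensitive line gets a weaker extractives contribution in the wall
    profiles = synthetic.gen_component_profiles(synthetic.DEFAULT_COMPONENTS, grid)
    names = [s.name for s in synthetic.DEFAULT_COMPONENTS]
    layer_tables = []
    summary: dict = {"maps": {}}
    for gi, genotype in enumerate(("WT", "ETI")):
        layout = synthetic.default_layer_layout("TW", cols=c["cols"])
        if genotype == "ETI":
            wg = layout.weights["G"].copy()
            wg[2] *= 0.2  # reduced extractives deposition
            wg[0] *= 0.9
            layout.weights["G"] = wg
        smap = synthetic.gen_spectral_map(
            layout, profiles, grid, noise_sd=c["noise_sd"],
            baseline=tuple(c["baseline"]), spike_rate=c["spike_rate"],
            seed=seed + 11 * gi, component_names=names)
        io.write_spectral_map(smap, outdir / f"map_{genotype}.tsv", seed=seed)
        pre, _qc = preprocess.preprocess_map(smap)
        model = mcr.mcr_als_fit(pre.intensities, pre.wavenumbers, k=c["k"],
                                max_iter=c["max_iter"],
                                component_names=names)
        # attach chemistry identities by matching resolved to planted profiles
        planted = synthetic.gen_component_profiles(
            synthetic.DEFAULT_COMPONENTS, pre.wavenumbers)
        order = mcr.match_components(model.spectra, planted)
        model.spectra = model.spectra[order]
        model.concentrations = model.concentrations[:, order]
        labels = segment.kmeans_voxels(model.concentrations, seed=seed)
        cmap = segment.assign_layers(labels, model, tissue="TW")
        cmap = segment.map_qc(cmap, model.concentrations)
        cluster_df = pd.DataFrame({
            "x": pre.coordinates[:, 0], "y": pre.coordinates[:, 1],
            "cluster": cmap.cluster_index, "layer": cmap.layer})
        cluster_df.to_csv(outdir / f"clusters_{genotype}.tsv", sep="\t",
                          index=False)
        summary["maps"][genotype] = {
            "lof_percent": model.lof_percent,
            "mcr_iterations": model.iterations,
            "qc_pass": cmap.qc_pass, "qc_reason": cmap.qc_reason,
        }
        layer_tables.append(segment.extract_layer_spectra(
            pre, cmap, "G", genotype=genotype, tissue="TW"))
    both = pd.concat(layer_tables, ignore_index=True)
    meta_cols = ["x", "y", "genotype", "tissue", "layer"]
    x = both.drop(columns=meta_cols).to_numpy()
    y = (both["genotype"] == "ETI").astype(int).to_numpy()
    opls = chemometrics.opls_da_fit(x, y, n_orth=c["n_orth"],
                                    cv_folds=c["cv_folds"])
    pca = chemometrics.pca_fit(x, n_components=2)
    pd.DataFrame({"t_pred": opls.t_pred,
                  "genotype": both["genotype"]}).to_csv(
        outdir / "opls_scores.tsv", sep="\t", index=False)
    summary["opls"] = {"r2x_cum": opls.r2x_cum, "r2y_cum": opls.r2y_cum,
                       "q2_cum": opls.q2_cum,
                       "n_obs": int(x.shape[0])}
    summary["pca"] = {"r2x": pca.r2x.tolist(), "r2x_cum": pca.r2x_cum}
    io.write_json(summary, outdir / "chemotype_summary.json")
    return summary


def run_kinematics(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["kinematics"]
    model = synthetic.UpliftModel(
        days=c["days"], points_per_trace=c["points_per_trace"],
        curvature_jitter_sd=c["curvature_jitter_sd"])
    traces = synthetic.gen_stem_traces(model, seed=seed + 101)
    io.write_traces(traces, outdir / "traces.csv", seed=seed)
    summary, contrast = kinematics.series_summary(traces)
    summary.to_csv(outdir / "lift_series.tsv", sep="\t", index=False)
    contrast.to_csv(outdir / "final_day_contrast.tsv", sep="\t", index=False)
    top = contrast.iloc[0].to_dict() if len(contrast) else {}
    out = {"final_day_contrast": top,
           "genotypes": sorted({t.genotype for t in traces})}
    io.write_json(out, outdir / "kinematics_summary.json")
    return out


def run_regulatory(cfg: dict, seed: int, outdir: Path) -> dict:
    c = cfg["regulatory"]
    wt_tab, eti_tab, truth = synthetic.gen_de_tables(
        n_genes=c["n_genes"], frac_et_dependent=c["frac_et_dependent"],
        seed=seed + 211)
    io.write_de_table(wt_tab, outdir / "de_WT.tsv", seed=seed)
    io.write_de_table(eti_tab, outdir / "de_ETI.tsv", seed=seed)
    wt_drgs = reg.classify_drgs(wt_tab)
    eti_drgs = reg.classify_drgs(eti_tab)
    et_set, partition = reg.et_dependent(wt_drgs, eti_drgs)

    n_prom = c["n_promoters"]
    rng = np.random.default_rng(seed + 223)
    prom_genes = sorted(et_set)[: n_prom // 2] \
        + sorted(set(wt_tab["gene"]) - et_set)[: n_prom - n_prom // 2]
    # plant the ethylene-responsive element preferentially in ET-dependent genes
    plant: dict[str, dict[str, list[int]]] = {"ATTTCAAA": {}}
    for g in prom_genes[: n_prom // 2]:
        if rng.random() < 0.7:
            pos = int(rng.integers(1, c["promoter_length"] - 10))
            plant["ATTTCAAA"][g] = [pos]
    all_prom, _ptruth = synthetic.gen_promoters(
        n_genes=n_prom, length=c["promoter_length"], seed=seed + 227)
    promoters = dict(zip(prom_genes, all_prom.values()))
    for motif, targets in plant.items():
        for g, positions in targets.items():
            s = list(promoters[g])
            for p in positions:
                s[p - 1:p - 1 + len(motif)] = motif
            promoters[g] = "".join(s)
    io.write_fasta(promoters, outdir / "promoters.fasta")

    enrich = {}
    universe = set(promoters)
    gene_set = et_set & universe
    for name, motif in reg.MOTIFS.items():
        hits = reg.scan_promoters(promoters, motif)
        has = {g: bool(h) for g, h in hits.items()}
        res = reg.motif_enrichment(gene_set, universe, has, motif=name)
        enrich[name] = {"x": res.with_motif_set, "K": res.with_motif_universe,
                        "n": res.set_size, "N": res.universe_size,
                        "p": res.p_value}
    out = {
        "n_wt_drgs": len(wt_drgs), "n_eti_drgs": len(eti_drgs),
        "n_et_dependent": len(et_set),
        "venn": {k: len(v) for k, v in partition.items()},
        "planted_recovered": len(et_set & truth.et_dependent),
        "planted_total": len(truth.et_dependent),
        "enrichment": enrich,
    }
    io.write_json(out, outdir / "regulatory_summary.json")
    return out


RUNNERS = {"chemotype": run_chemotype, "kinematics": run_kinematics,
           "regulatory": run_regulatory}


def run_pipeline(config: dict | None = None,
                 outdir: str | Path = "tenswood_out") -> dict:
    """Execute the configured pipelines; return the artifact manifest.

    Outputs are staged in ``<outdir>/_tmp`` and moved into ``outdir`` only
    when every stage succeeds, so a failed run leaves no partial artifacts
    outside the marked temporary directory. The manifest records the
    SHA-256 digest of every artifact plus seed, config hash and version.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmp = outdir / "_tmp"
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir()
    summaries = {}
    for name in cfg["pipelines"]:
        if name not in RUNNERS:
            raise ValueError(f"unknown pipeline {name!r}")
        log.info("running pipeline stage: %s", name)
        summaries[name] = RUNNERS[name](cfg, seed, tmp)
    artifacts = {}
    for f in sorted(tmp.iterdir()):
        target = outdir / f.name
        if target.exists():
            target.unlink()
        shutil.move(str(f), target)
        artifacts[f.name] = _sha256(target)
    tmp.rmdir()
    manifest = {"version": __version__, "seed": seed,
                "config_hash": io.config_hash(cfg), "artifacts": artifacts}
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
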