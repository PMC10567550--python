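"""Pipeline configuration, orchestration and reporting.

``run_pipeline`` drives the full analysis in declared stage order
(simulate → filter → normalize → batch-correct → HVG → PCA → cluster →
pseudotime → kernel → trends → modules → enrichment → reversal, with the AFM
and actin branches independent), deriving every stage seed deterministically
from one global seed and recording checksums of all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite

from . import actin as actin_mod
from . import afm as afm_mod
from . import regulons as reg_mod
from . import reversal as rev_mod
from . import sc_core, synth, trajectory

__all__ = ["PipelineConfig", "RunReport", "load_config", "save_config",
           "run_pipeline", "write_report"]

_DOMAINS = {
    "min_genes": lambda v: v >= 0,
    "n_hvg": lambda v: v >= 1,
    "n_pcs": lambda v: v >= 1,
    "k_neighbors": lambda v: v >= 1,
    "resolution": lambda v: v > 0,
    "n_nodes": lambda v: v >= 2,
    "trend_span": lambda v: 0 < v <= 1,
    "module_resolution": lambda v: v > 0,
    "marker": lambda v: isinstance(v, str) and len(v) > 0,
    "threshold": lambda v: np.isfinite(v),
    "fc_threshold": lambda v: v > 0,
    "q_threshold": lambda v: 0 < v <= 1,
    "effect_threshold": lambda v: 0 <= v <= 1,
    "n_perm": lambda v: v >= 1,
    "hertz_window": lambda v: 0 < v[0] < v[1] < 1,
    "nu": lambda v: 0 <= v <= 0.5,
    "afm_r2_min": lambda v: 0 <= v <= 1,
    "afm_E_max": lambda v: v > 0,
    "seed": lambda v: v >= 0,
    "outdir": lambda v: True,
    "counts_dir": lambda v: True,
    "regulon_path": lambda v: True,
    "afm_manifest": lambda v: True,
    "mask_path": lambda v: True,
    "synthetic": lambda v: isinstance(v, bool),
}


@dataclass
class PipelineConfig:
    """All stage parameters with their printed defaults."""

    outdir: str = "dediff_out"
    synthetic: bool = True
    counts_dir: str | None = None
    regulon_path: str | None = None
    afm_manifest: str | None = None
    mask_path: str | None = None
    min_genes: int = 200
    n_hvg: int = 5000
    n_pcs: int = 15
    k_neighbors: int = 20
    resolution: float = 0.5
    n_nodes: int = 20
    trend_span: float = 0.3
    module_resolution: float = 1.0
    marker: str = "Lrig1"
    threshold: float = 1.0
    fc_threshold: float = 1.6
    q_threshold: float = 0.5
    effect_threshold: float = 0.9
    n_perm: int = 99
    hertz_window: tuple[float, float] = (0.2, 0.8)
    nu: float = 0.5
    afm_r2_min: float = 0.9
    afm_E_max: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for key, rule in _DOMAINS.items():
            val = getattr(self, key)
            if val is None and key in ("counts_dir", "regulon_path", "afm_manifest", "mask_path"):
                continue
            try:
                ok = rule(val)
            except Exception:
                ok = False
            if not ok:
                errors.append(f"{key} = {val!r} outside its domain")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, str], counts: dict | None = None) -> None:
        if any(s["name"] == name for s in self.stages):
            raise ValueError(f"stage {name!r} already recorded")
        self.stages.append({"name": name, "outputs": outputs, "counts": counts or {}})

    def checksums(self) -> dict[str, str]:
        out = {}
        for s in self.stages:
            out.update(s["outputs"])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "parameters": self.parameters, "warnings": self.warnings},
            indent=1, sort_keys=True,
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML configuration, applying defaults; unknown keys and
    out-of-domain values are aggregated into one error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = set(PipelineConfig.__dataclass_fields__)
    errors = [f"unknown key {k!r}" for k in raw if k not in known]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    if "hertz_window" in raw and raw["hertz_window"] is not None:
        raw = dict(raw)
        raw["hertz_window"] = tuple(raw["hertz_window"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    d = asdict(cfg)
    d["hertz_window"] = list(d["hertz_window"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return _sha(path)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage in order; all randomness derives from cfg.seed."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2 ** 31))
        for name, s in zip(
            ["synth", "cluster", "graph", "modules", "perm", "afm", "signature"],
            ss.spawn(7),
        )
    }
    report = RunReport(parameters={**{k: (list(v) if isinstance(v, tuple) else v)
                                      for k, v in asdict(cfg).items()},
                                   "stage_seeds": stage_seeds})

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate / load -------------------------------------------------
    truth = None
    try:
        if cfg.synthetic:
            scfg = synth.default_config(seed=stage_seeds["synth"])
            states = synth.synth_cells(scfg)
            counts, meta, truth = synth.synth_counts(states, scfg)
            synth.write_counts_mtx(counts, meta, outdir / "counts", truth=truth)
            outs = {str(p.relative_to(outdir)): _sha(p)
                    for p in sorted((outdir / "counts").glob("*"))}
            report.add_stage("simulate", outs, {"n_cells": counts.n_cells,
                                                "n_genes": counts.n_genes})
        else:
            if cfg.counts_dir is None:
                raise FileNotFoundError("counts_dir not set and synthetic mode disabled")
            cdir = Path(cfg.counts_dir)
            counts = sc_core.read_counts_mtx(cdir / "matrix.mtx", cdir / "genes.tsv",
                                             cdir / "barcodes.tsv")
            meta = sc_core.read_cell_metadata(cdir / "cell_metadata.tsv")
            report.add_stage("load", {}, {"n_cells": counts.n_cells})
    except Exception as e:
        fail("simulate", e)

    # --- single-cell core ------------------------------------------------
    try:
        counts = sc_core.filter_cells(counts, min_genes=cfg.min_genes)
        norm = sc_core.normalize(counts)
        meta_df = meta.aligned_to(norm.cell_ids)
        report.add_stage("filter+normalize", {}, {"cells_kept": counts.n_cells})
    except Exception as e:
        fail("filter+normalize", e)

    try:
        norm = sc_core.batch_correct(norm, meta_df["batch"].to_numpy())
        report.add_stage("batch_correct", {}, {"n_batches": int(meta_df["batch"].nunique())})
    except Exception as e:
        fail("batch_correct", e)

    try:
        hvg = sc_core.select_hvg(norm, n=cfg.n_hvg)
        emb = sc_core.pca_embed(norm, hvg, n_pcs=cfg.n_pcs)
        coords = pd.DataFrame(emb.coordinates,
                              columns=[f"PC{i+1}" for i in range(emb.n_pcs)])
        coords.insert(0, "cell_id", norm.cell_ids)
        sha = _write_tsv(coords, outdir / "pca.tsv")
        report.add_stage("hvg+pca", {"pca.tsv": sha},
                         {"n_hvg": int(hvg.size), "n_pcs": emb.n_pcs})
    except Exception as e:
        fail("hvg+pca", e)

    try:
        clusters = sc_core.cluster_cells(emb, k_neighbors=cfg.k_neighbors,
                                         resolution=cfg.resolution,
                                         seed=stage_seeds["cluster"])
        cl = pd.DataFrame({"cell_id": norm.cell_ids, "cluster": clusters.labels})
        sha = _write_tsv(cl, outdir / "clusters.tsv")
        report.add_stage("cluster", {"clusters.tsv": sha},
                         {"n_clusters": clusters.n_clusters})
    except Exception as e:
        fail("cluster", e)

    # --- trajectory ------------------------------------------------------
    try:
        graph = trajectory.fit_principal_graph(emb, n_nodes=cfg.n_nodes,
                                               seed=stage_seeds["graph"])
        diff_sets = [g for g in norm.gene_ids if g.startswith(("uHF_", "SD_"))] or ["Gata6"]
        score = sc_core.signature_score(norm, diff_sets, seed=stage_seeds["signature"])
        W = sc_core.knn_graph(emb.coordinates, cfg.k_neighbors)
        pt = trajectory.compute_pseudotime(graph, emb.coordinates, root_scores=score,
                                           smooth_graph=W)
        pt_df = pd.DataFrame({"cell_id": norm.cell_ids, "t": pt.t})
        sha = _write_tsv(pt_df, outdir / "pseudotime.tsv")
        report.add_stage("pseudotime", {"pseudotime.tsv": sha},
                         {"root_node": pt.root_node})
    except Exception as e:
        fail("pseudotime", e)

    try:
        tm = trajectory.pseudotime_kernel(W, pt, k_neighbors=cfg.k_neighbors)
        mmwrite(str(outdir / "transition.mtx"), tm.matrix)
        report.add_stage("kernel", {"transition.mtx": _sha(outdir / "transition.mtx")},
                         {"sigma": tm.sigma})
    except Exception as e:
        fail("kernel", e)

    try:
        trends = trajectory.gene_trends(norm, pt, genes=hvg, span=cfg.trend_span)
        modules = trajectory.detect_modules(trends, resolution=cfg.module_resolution,
                                            seed=stage_seeds["modules"])
        mod_df = pd.DataFrame({"gene": modules.gene_ids, "module": modules.labels})
        sha = _write_tsv(mod_df, outdir / "modules.tsv")
        report.add_stage("trends+modules", {"modules.tsv": sha},
                         {"n_modules": modules.n_modules})
    except Exception as e:
        fail("trends+modules", e)

    # --- regulon enrichment ---------------------------------------------
    try:
        regulon_path = cfg.regulon_path
        if regulon_path is None and cfg.synthetic:
            edges = synth.synth_regulons(scfg, counts.gene_ids,
                                         seed=stage_seeds["synth"])
            regulon_path = outdir / "regulons.tsv"
            synth.write_regulons_tsv(edges, regulon_path)
        if regulon_path is not None:
            db = reg_mod.load_regulons(regulon_path)
            background = list(trends.gene_ids)
            tables = []
            for m in range(modules.n_modules):
                et = reg_mod.regulon_enrichment(
                    modules.members(m), db, background,
                    q_threshold=cfg.q_threshold,
                    effect_threshold=cfg.effect_threshold,
                    module_name=f"module_{m}",
                )
                tables.append(et.table)
            enr = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            sha = _write_tsv(enr, outdir / "enrichment.tsv")
            report.add_stage("enrichment", {"enrichment.tsv": sha},
                             {"n_tests": len(enr)})
        else:
            report.add_stage("enrichment", {}, {"skipped": True})
    except Exception as e:
        fail("enrichment", e)

    # --- reversal --------------------------------------------------------
    try:
        anns = sc_core.CellAnnotations(meta_df)
        pops = rev_mod.select_populations(norm, anns, marker=cfg.marker,
                                          threshold=cfg.threshold)
        res = rev_mod.reversal_statistic(pops, norm, n_hvg=cfg.n_hvg)
        p, r_obs, _ = rev_mod.permutation_test(pops, norm, n_perm=cfg.n_perm,
                                               seed=stage_seeds["perm"],
                                               n_hvg=cfg.n_hvg)
        res.permutation_p = p
        sha_g = _write_tsv(res.gene_table, outdir / "reversal_genes.tsv")
        sha_c = _write_tsv(res.loess_curve, outdir / "reversal_loess.csv")
        summary = {
            "R": res.r_pearson, "R_spearman": res.r_spearman,
            "permutation_p": p, "n_genes": res.n_genes,
            "n_differentiating": int(pops.sizes[0]),
            "n_dedifferentiating": int(pops.sizes[1]),
            "options": res.options,
        }
        (outdir / "reversal.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        report.add_stage(
            "reversal",
            {"reversal_genes.tsv": sha_g, "reversal_loess.csv": sha_c,
             "reversal.json": _sha(outdir / "reversal.json")},
            {"R": res.r_pearson, "p": p, "n_genes": res.n_genes},
        )
    except Exception as e:
        fail("reversal", e)

    # --- AFM branch ------------------------------------------------------
    try:
        afm_manifest = cfg.afm_manifest
        if afm_manifest is None and cfg.synthetic:
            synth.synth_afm_dataset(outdir / "afm_synth", shape=(24, 24),
                                    seed=stage_seeds["afm"])
            afm_manifest = outdir / "afm_synth" / "manifest.csv"
        if afm_manifest is not None:
            manifest = pd.read_csv(afm_manifest)
            base = Path(afm_manifest).parent
            fits = []
            for _, row in manifest.iterrows():
                curve = afm_mod.load_curve(base / row["curve"])
                fits.append(afm_mod.fit_curve(curve, window=cfg.hertz_window,
                                              grid_pos=(int(row["row"]), int(row["col"]))))
            accepted, log = afm_mod.qc_filter(fits, r2_min=cfg.afm_r2_min,
                                              E_max=cfg.afm_E_max)
            shape = (int(manifest["row"].max()) + 1, int(manifest["col"].max()) + 1)
            smap = afm_mod.build_stiffness_map(fits, shape=shape)
            np.savetxt(outdir / "stiffness_map.csv", smap.grid / 1e3,
                       delimiter=",", fmt="%.6g")
            (outdir / "stiffness_summary.json").write_text(
                json.dumps(smap.summary(), indent=1, sort_keys=True))
            report.add_stage(
                "afm",
                {"stiffness_map.csv": _sha(outdir / "stiffness_map.csv"),
                 "stiffness_summary.json": _sha(outdir / "stiffness_summary.json")},
                {"curves": len(fits), "accepted": len(accepted),
                 "rejected": len(log)},
            )
        else:
            report.add_stage("afm", {}, {"skipped": True})
    except Exception as e:
        fail("afm", e)

    # --- actin branch ----------------------------------------------------
    try:
        mask_path = cfg.mask_path
        if mask_path is None and cfg.synthetic:
            mask, _truth_len = synth.synth_fiber_scene(seed=stage_seeds["synth"])
            mask_path = outdir / "fiber_mask.png"
            synth.write_mask_png(mask, mask_path)
        if mask_path is not None:
            mask = actin_mod.read_mask(mask_path)
            metrics = actin_mod.compute_metrics(mask)
            (outdir / "actin_metrics.json").write_text(json.dumps({
                "total_length_um": metrics.total_length_um,
                "lacunarity_by_box": {str(k): v for k, v in metrics.lacunarity_by_box.items()},
                "mean_lacunarity": metrics.mean_lacunarity,
            }, indent=1, sort_keys=True))
            report.add_stage("actin",
                             {"actin_metrics.json": _sha(outdir / "actin_metrics.json")},
                             {"total_length_um": metrics.total_length_um})
        else:
            report.add_stage("actin", {}, {"skipped": True})
    except Exception as e:
        fail("actin", e)

    return report


def write_report(report: RunReport, path) -> None:
    """Emit the JSON report plus a human-readable text twin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(report.to_json())
    lines = ["pipeline run report", "===================", ""]
    for s in report.stages:
        lines.append(f"stage {s['name']}")
        for k, v in s["counts"].items():
            lines.append(f"  {k}: {v}")
        for f, h in s["outputs"].items():
            lines.append(f"  wrote {f} sha256:{h[:12]}")
    if report.warnings:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  {w}" for w in report.warnings)
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
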