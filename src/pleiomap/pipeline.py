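"""End-to-end orchestration: config validation, stage execution, manifest.

A single config (YAML or dict) drives the run. Inputs come either from a
``synthdata`` block (generated on the fly, the default) or from a set of
file paths with the package's standard on-disk formats. Stages execute in
dependency order — assoc, pls, network, spatial, enrich, mr — each writing
TSV/JSON outputs plus a manifest recording seeds, parameters, input digests
and wall-times. Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import enrich as enrich_mod
from . import mr as mr_mod
from . import network as net_mod
from . import pls as pls_mod
from . import spatial as spatial_mod
from . import synthdata as synth_mod
from .datatypes import DisorderZVector, GeneZMatrix, ParcelGeometry, write_gmt

log = logging.getLogger("pleiomap")

STAGES = ("assoc", "pls", "network", "spatial", "enrich", "mr")

DEFAULT_PARAMS: dict[str, Any] = {
    "alpha": 0.05,
    "q": 0.05,
    "n_perm": 1000,
    "n_boot": 1000,
    "n_spins": 1000,
    "top_percent": 1.0,
    "min_loci": 5,
    "mr_p_thresh": 5e-8,
    "mr_panel_regions": 6,
}


@dataclasses.dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    synthdata: synth_mod.SyntheticConfig | None = None
    inputs: dict[str, Any] | None = None
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    params: dict[str, Any] = dataclasses.field(default_factory=lambda: dict(DEFAULT_PARAMS))


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Normalize and validate a pipeline config (path to YAML, or dict).

    Fills defaults, checks parameter ranges, and — for file-driven runs —
    verifies every enabled stage's inputs are resolvable before anything
    executes.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    out_dir = Path(raw.get("output_dir", "pleiomap_out"))
    seed = int(raw.get("seed", 0))
    stages = {s: True for s in STAGES}
    stages.update({k: bool(v) for k, v in raw.get("stages", {}).items() if k in STAGES})
    params = dict(DEFAULT_PARAMS)
    params.update(raw.get("params", {}))
    for key in ("n_perm", "n_boot", "n_spins"):
        if int(params[key]) < 100:
            raise ValueError(f"params.{key} must be >= 100")
    if not 0 < float(params["alpha"]) < 1 or not 0 < float(params["q"]) < 1:
        raise ValueError("alpha and q must be in (0, 1)")

    synth_cfg = None
    inputs = raw.get("inputs")
    if "synthdata" in raw or inputs is None:
        block = dict(raw.get("synthdata", {}))
        block.setdefault("seed", seed)
        synth_cfg = synth_mod.SyntheticConfig(**block)
    else:
        required = {
            "assoc": ["zmatrices", "disorder", "phenotypes"],
            "pls": ["zmatrices", "disorder"],
            "network": ["zmatrices", "phenotypes", "geometry"],
            "spatial": ["geometry"],
            "enrich": ["annotations"],
            "mr": ["gwas_exposure", "gwas_outcome"],
        }
        for stage, keys in required.items():
            if not stages.get(stage, False):
                continue
            for key in keys:
                if key not in inputs:
                    raise ValueError(f"stage {stage!r} enabled but input {key!r} missing")
                val = inputs[key]
                paths = val.values() if isinstance(val, dict) else [val]
                for p in paths:
                    if not Path(p).exists():
                        raise ValueError(f"input file for {key!r} not found: {p}")
    return PipelineConfig(
        output_dir=out_dir, seed=seed, synthdata=synth_cfg, inputs=inputs,
        stages=stages, params=params,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig) -> dict[str, Any]:
    if cfg.synthdata is not None:
        sc = cfg.synthdata
        geometry = synth_mod.gen_parcellation(sc)
        annotations = synth_mod.gen_gene_annotations(sc)
        zmats, disorder, truth = synth_mod.gen_gene_assoc(sc, geometry, annotations)
        phenotypes, pheno_truth = synth_mod.gen_phenotypes(sc, geometry)
        dev_panel, dev_meta, ct_panel = synth_mod.gen_expression_panels(sc, annotations)
        exposure, outcome, _ = synth_mod.gen_gwas_sumstats(sc)
        truth.module_assignment = pheno_truth.module_assignment
        return {
            "geometry": geometry,
            "annotations": annotations,
            "zmatrices": {m.metric_id: m for m in zmats},
            "disorder": disorder,
            "phenotypes": phenotypes,
            "dev_panel": dev_panel,
            "dev_meta": dev_meta,
            "celltype_panel": ct_panel,
            "gwas_exposure": exposure,
            "gwas_outcome": outcome,
            "truth": truth,
        }
    inp = cfg.inputs or {}
    data: dict[str, Any] = {}
    if "geometry" in inp:
        data["geometry"] = ParcelGeometry.from_json(inp["geometry"])
    if "annotations" in inp:
        data["annotations"] = pd.read_csv(inp["annotations"], sep="\t")
    if "zmatrices" in inp:
        data["zmatrices"] = {
            m: GeneZMatrix.from_tsv(p, metric_id=m) for m, p in inp["zmatrices"].items()
        }
    if "disorder" in inp:
        data["disorder"] = DisorderZVector.from_tsv(inp["disorder"])
    if "phenotypes" in inp:
        data["phenotypes"] = {
            m: pd.read_csv(p, sep="\t", index_col=0) for m, p in inp["phenotypes"].items()
        }
    for key in ("dev_panel", "celltype_panel"):
        if key in inp:
            data[key] = pd.read_csv(inp[key], sep="\t", index_col=0)
    if "dev_meta" in inp:
        data["dev_meta"] = pd.read_csv(inp["dev_meta"], sep="\t")
    for key in ("gwas_exposure", "gwas_outcome"):
        if key in inp:
            data[key] = pd.read_csv(inp[key], sep="\t")
    # cross-input alignment
    if "zmatrices" in data and "disorder" in data:
        for m in data["zmatrices"].values():
            data["disorder"].align_to(m.gene_ids)
    return data


def run_pipeline(config: PipelineConfig | dict | str | Path, dry_run: bool = False) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    plan = [s for s in STAGES if cfg.stages.get(s, False)]
    if dry_run:
        return {"plan": plan, "seed": cfg.seed, "output_dir": str(cfg.output_dir)}
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "params": cfg.params,
        "stages": {},
        "outputs": {},
    }
    data = _load_inputs(cfg)
    p = cfg.params
    seed = cfg.seed

    def _write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        manifest["outputs"][name] = _sha256(path)

    if data.get("geometry") is not None:
        data["geometry"].to_json(out / "geometry.json")
        manifest["outputs"]["geometry.json"] = _sha256(out / "geometry.json")
    if "truth" in data:
        data["truth"].to_json(out / "truth.json")
        manifest["outputs"]["truth.json"] = _sha256(out / "truth.json")

    sig_results: dict[str, assoc_mod.SignificanceResult] = {}
    pls_models: dict[str, pls_mod.PLSModel] = {}
    influences: dict[str, pls_mod.LOOInfluence] = {}
    sc_nets: dict[str, net_mod.SymmetricNetwork] = {}
    gs_nets: dict[str, net_mod.SymmetricNetwork] = {}
    profiles: dict[str, net_mod.NodeDegreeProfile] = {}

    for stage in plan:
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)

        if stage == "assoc":
            disorder = data["disorder"]
            n_genes_dis = len(disorder.gene_ids)
            thr_dis = assoc_mod.bonferroni_threshold(p["alpha"], n_genes_dis, 1)
            dis_sig = disorder.two_sided_p() < thr_dis
            disorder_set = {g for g, s in zip(disorder.gene_ids, dis_sig) if s}
            rows = []
            metric_sets = {}
            for mid, zm in data["zmatrices"].items():
                pheno = data["phenotypes"][mid]
                sc = net_mod.structural_covariance(pheno, metric_id=mid)
                sc_nets[mid] = sc
                m_eff = assoc_mod.effective_tests(sc.W)
                thr = assoc_mod.bonferroni_threshold(p["alpha"], len(zm.gene_ids), m_eff)
                res = assoc_mod.significant_genes(zm, thr, alpha=p["alpha"], m_eff=m_eff)
                sig_results[mid] = res
                metric_sets[mid] = res.aggregate_set
                row = {
                    "metric_id": mid,
                    "m_eff": m_eff,
                    "threshold": thr,
                    "n_associations": res.n_associations,
                    "aggregate_size": len(res.aggregate_set),
                }
                if disorder_set and res.aggregate_set:
                    ov = assoc_mod.overlap_test(
                        res.aggregate_set, disorder_set, zm.gene_ids,
                        n_perm=p["n_perm"], seed=seed,
                    )
                    row.update(
                        overlap=ov.overlap_count,
                        expected_overlap=ov.expected_overlap,
                        hypergeom_p=ov.hypergeometric_p,
                        perm_z=ov.perm_z,
                        perm_p=ov.perm_p,
                    )
                rows.append(row)
            _write_tsv(pd.DataFrame(rows), "assoc_summary.tsv")
            if len(metric_sets) >= 2 and all(metric_sets.values()):
                venn = assoc_mod.set_intersections(metric_sets)
                _write_tsv(venn, "assoc_intersections.tsv")
                _write_tsv(venn.attrs["specific"], "assoc_specificity.tsv")
            write_gmt(
                {**{f"sig_{m}": s for m, s in metric_sets.items()},
                 "sig_disorder": disorder_set},
                out / "significant_sets.gmt",
            )
            manifest["outputs"]["significant_sets.gmt"] = _sha256(out / "significant_sets.gmt")

        elif stage == "pls":
            summary = []
            for mid, zm in data["zmatrices"].items():
                model = pls_mod.fit_pls1(zm, data["disorder"])
                pls_models[mid] = model
                perm = pls_mod.varexp_perm_test(zm, data["disorder"],
                                                n_perm=p["n_perm"], seed=seed)
                boot = pls_mod.bootstrap_weights(zm, data["disorder"],
                                                 n_boot=p["n_boot"], seed=seed, q=p["q"])
                infl = pls_mod.loo_influence(zm, data["disorder"])
                influences[mid] = infl
                _write_tsv(
                    pd.DataFrame(
                        {
                            "region_id": model.region_ids,
                            "w_x": model.w_x,
                            "boot_z": boot.boot_z,
                            "fdr_flag": boot.fdr_significant,
                        }
                    ),
                    f"pls_weights_{mid}.tsv",
                )
                _write_tsv(
                    pd.DataFrame(
                        {
                            "gene_id": model.gene_ids,
                            "t": model.t_scores,
                            "u": model.u_scores,
                            "delta": infl.delta,
                        }
                    ),
                    f"pls_genes_{mid}.tsv",
                )
                summary.append(
                    {
                        "metric_id": mid,
                        "varexp_y": model.varexp_y,
                        "perm_p": perm.perm_p,
                        "r_tu": infl.r_tu,
                        "r_tu_method": infl.r_tu_method,
                    }
                )
                top = pls_mod.top_pleiotropic(infl, p["top_percent"])
                write_gmt({f"top_{p['top_percent']}pct_{mid}": top},
                          out / f"pls_top_{mid}.gmt")
                manifest["outputs"][f"pls_top_{mid}.gmt"] = _sha256(out / f"pls_top_{mid}.gmt")
            (out / "pls_summary.json").write_text(json.dumps(summary, indent=1))
            manifest["outputs"]["pls_summary.json"] = _sha256(out / "pls_summary.json")

        elif stage == "network":
            geometry = data["geometry"]
            D = spatial_mod.geodesic_distances(geometry)
            rows = []
            for mid, zm in data["zmatrices"].items():
                if mid not in sc_nets:
                    sc_nets[mid] = net_mod.structural_covariance(
                        data["phenotypes"][mid], metric_id=mid
                    )
                gs = net_mod.genetic_similarity(zm)
                gs_nets[mid] = gs
                sc = sc_nets[mid]
                coupling = net_mod.edgewise_coupling(sc, gs)
                adj = net_mod.distance_adjusted_coupling(sc, gs, D)
                r_c, coph_p = net_mod.cophenetic_test(
                    sc, gs, n_perm=p["n_perm"], seed=seed
                )
                part = net_mod.louvain_modules(sc, seed=seed)
                prof = net_mod.degree_profile(sc, part)
                profiles[mid] = prof
                _write_tsv(prof.to_frame().assign(module=part.labels),
                           f"network_degree_{mid}.tsv")
                sc.to_tsv(out / f"sc_{mid}.tsv")
                gs.to_tsv(out / f"gs_{mid}.tsv")
                manifest["outputs"][f"sc_{mid}.tsv"] = _sha256(out / f"sc_{mid}.tsv")
                manifest["outputs"][f"gs_{mid}.tsv"] = _sha256(out / f"gs_{mid}.tsv")
                row = {
                    "metric_id": mid,
                    "edgewise_coupling": coupling,
                    "distance_adjusted_coupling": adj,
                    "cophenetic_r": r_c,
                    "cophenetic_p": coph_p,
                    "modularity": part.modularity,
                    "n_modules": len(set(part.labels)),
                }
                if mid in pls_models:
                    model = pls_models[mid]
                    aligned = model.region_ids == geometry.parcel_ids
                    if aligned:
                        rho, spin_p = net_mod.hub_pleiotropy_coupling(
                            prof, model.w_x, geometry, n_spins=p["n_spins"], seed=seed
                        )
                        row.update(hub_pls_rho=rho, hub_pls_spin_p=spin_p)
                rows.append(row)
            _write_tsv(pd.DataFrame(rows), "network_summary.tsv")

        elif stage == "spatial":
            geometry = data["geometry"]
            null = spatial_mod.build_spin_null(geometry, n_spins=p["n_spins"], seed=seed)
            for atlas, classes in geometry.atlas_class.items():
                for mid, model in pls_models.items():
                    if model.region_ids != geometry.parcel_ids:
                        continue
                    enr = spatial_mod.class_enrichment(model.w_x, classes, null)
                    _write_tsv(enr, f"spatial_pls_{atlas}_{mid}.tsv")
                for kind, nets in (("sc", sc_nets), ("gs", gs_nets)):
                    for mid, net in nets.items():
                        wb = spatial_mod.within_between_edge_test(net, classes, null)
                        _write_tsv(wb, f"spatial_edges_{kind}_{atlas}_{mid}.tsv")

        elif stage == "enrich":
            ann = data["annotations"]
            for mid, infl in influences.items():
                top = pls_mod.top_pleiotropic(infl, p["top_percent"])
                pos = enrich_mod.positional_enrichment(top, ann)
                _write_tsv(pos, f"enrich_positional_{mid}.tsv")
                coef, se, pv = enrich_mod.constrained_enrichment(top, ann)
                (out / f"enrich_constrained_{mid}.json").write_text(
                    json.dumps({"coef": coef, "se": se, "p": pv}, indent=1)
                )
                manifest["outputs"][f"enrich_constrained_{mid}.json"] = _sha256(
                    out / f"enrich_constrained_{mid}.json"
                )
                if "celltype_panel" in data:
                    ct = enrich_mod.celltype_enrichment(data["celltype_panel"], top, ann)
                    _write_tsv(ct, f"enrich_celltype_{mid}.tsv")
                if "dev_panel" in data and "dev_meta" in data:
                    dev = enrich_mod.dev_trajectories(data["dev_panel"], data["dev_meta"], top)
                    _write_tsv(dev, f"enrich_dev_{mid}.tsv")

        elif stage == "mr":
            exposure, outcome = data["gwas_exposure"], data["gwas_outcome"]
            inst = mr_mod.select_instruments(exposure, p_thresh=p["mr_p_thresh"])
            h = mr_mod.harmonize(inst, outcome)
            h = mr_mod.steiger_filter(h)
            results = {}
            if h.n_snps >= 3:
                for name, est in (
                    ("ivw", mr_mod.ivw(h)),
                    ("egger", mr_mod.egger(h)),
                    ("weighted_median", mr_mod.weighted_median(h, seed=seed)),
                ):
                    results[name] = dataclasses.asdict(est)
            (out / "mr_forward.json").write_text(json.dumps(results, indent=1))
            manifest["outputs"]["mr_forward.json"] = _sha256(out / "mr_forward.json")
            _write_tsv(h.exclusions, "mr_exclusions.tsv")

        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "status": "ok",
        }
        log.info("stage %s: done in %.2fs", stage, manifest["stages"][stage]["wall_time_s"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
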