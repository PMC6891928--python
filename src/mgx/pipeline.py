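"""Per-site orchestration of the seven comparison analyses.

``run_all`` reads one flat configuration (dict or YAML path), splits each
body site's samples into its two cohorts and runs the enabled stages in
dependency order: diversity, shared species, heterogeneity scaling (PLE),
diversity-area scaling (DAR/MAD), co-occurrence network comparison, shared
core/periphery, and shared skeletons.  A failure inside one stage is
recorded in that stage's block and does not abort the others.  Outputs are
one TSV per analysis plus a JSON manifest; runs are byte-identical under a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import composition, cpn, diversity, hsn, network, scaling
from .io import (
    OTUTable,
    OTUTableError,
    SampleMetadata,
    TaxonomyMap,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    split_by_group,
)
from .permtest import child_seed

__all__ = ["SiteReport", "run_all", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "otu_table": None,
    "format": "tsv",
    "metadata": None,
    "taxonomy": None,
    "sites": None,  # None = all sites in the metadata
    "group_field": "group",
    "q_values": [0, 1, 2, 3],
    "rarefy_depth": None,
    "n_perm": 1000,
    "n_orders": 100,
    "fdr_alpha": 0.001,
    "min_total": 80,
    "hsn_thresholds": [0.25, 0.5],
    "network_stats": ["density", "mean_degree", "clustering_coefficient"],
    "cpn_restarts": 10,
    "seed": 0,
    "outdir": None,
    "stages": {
        "diversity": True,
        "shared_species": True,
        "ple": True,
        "dar": True,
        "network": True,
        "cpn": True,
        "hsn": True,
    },
}


@dataclass
class SiteReport:
    """All analysis blocks for one body site."""

    site: str
    groups: tuple[str, str]
    n_samples: tuple[int, int]
    blocks: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)


def _load_config(config) -> dict:
    if isinstance(config, str):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    cfg["stages"] = {**DEFAULT_CONFIG["stages"], **dict(config.get("stages", {}))}
    return cfg


def _diversity_block(tA: OTUTable, tB: OTUTable, cfg: dict) -> list[dict]:
    rows = []
    qs = [float(q) for q in cfg["q_values"]]
    profsA = diversity.profiles_per_sample(tA, qs)
    profsB = diversity.profiles_per_sample(tB, qs)
    for qi, q in enumerate(qs):
        a = [p.D[qi] for p in profsA]
        b = [p.D[qi] for p in profsB]
        cmp = diversity.compare_groups(a, b, statistic=f"D(q={q:g})")
        rows.append(
            {
                "q": q,
                "stratum": "community",
                "median_A": cmp.medianA,
                "median_B": cmp.medianB,
                "wilcoxon_p": cmp.wilcoxon_p,
                "cohens_d": cmp.cohens_d,
                "direction": cmp.direction,
            }
        )
    return rows


def _shared_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    out = {}
    for alg, fn in (("A1", composition.shared_null_A1), ("A2", composition.shared_null_A2)):
        res = fn(tA, tB, n_perm=cfg["n_perm"], seed=child_seed(seed, 1 if alg == "A1" else 2))
        out[alg] = {
            "observed_shared": res.observed_shared,
            "null_mean": res.null_mean,
            "null_sd": res.null_sd,
            "p_value": res.p_value,
            "n_specific_A": len(res.specificA),
            "n_specific_B": len(res.specificB),
            "n_perm": res.n_perm,
            "seed": res.seed,
        }
    return out


def _ple_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    out = {}
    for mt in ("I", "III"):
        fitA = scaling.fit_power_law(scaling.ple_points(tA, mt), mt)
        fitB = scaling.fit_power_law(scaling.ple_points(tB, mt), mt)

        def extract(t, _mt=mt):
            return scaling.fit_power_law(scaling.ple_points(t, _mt), _mt).b

        res = scaling.compare_scaling_param(
            tA, tB, extract, n_perm=cfg["n_perm"], seed=child_seed(seed, 10 + ord(mt[0]))
        )
        out[f"type_{mt}"] = {
            "a_A": fitA.a, "b_A": fitA.b, "r2_A": fitA.r_squared,
            "a_B": fitB.a, "b_B": fitB.b, "r2_B": fitB.r_squared,
            "perm_p_b": res.p_value, "n_perm": res.n_perm,
        }
    return out


def _dar_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    out = {}
    for qi, q in enumerate(float(q) for q in cfg["q_values"]):
        row = {}
        for label, t in (("A", tA), ("B", tB)):
            curve = scaling.dar_curve(t, q, cfg["n_orders"], child_seed(seed, 20 + qi))
            fit = scaling.fit_dar(curve, "PLEC", q)
            row[f"c_{label}"] = fit.c
            row[f"z_{label}"] = fit.z
            row[f"d_{label}"] = fit.d
            row[f"r2_{label}"] = fit.r_squared
            if fit.d < 0 and fit.z > 0:
                est = scaling.mad(fit)
                row[f"Dmax_{label}"] = est.D_max
                row[f"Amax_{label}"] = est.A_max
            else:
                row[f"Dmax_{label}"] = float("nan")
                row[f"Amax_{label}"] = float("nan")
        out[f"q={q:g}"] = row
    return out


def _network_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    netA = network.build_scn(tA, cfg["fdr_alpha"], cfg["min_total"])
    netB = network.build_scn(tB, cfg["fdr_alpha"], cfg["min_total"])
    propA, propB = network.properties(netA), network.properties(netB)
    censusA = network.trio_census(netA, tA)
    censusB = network.trio_census(netB, tB)
    null_stats: dict[str, list[tuple[float, float]]] = {s: [] for s in cfg["network_stats"]}
    for pA, pB in network.permutated_pairs(
        tA, tB, cfg["n_perm"], child_seed(seed, 30), cfg["fdr_alpha"], cfg["min_total"]
    ):
        if pA is None:
            continue
        qA, qB = network.properties(pA), network.properties(pB)
        for s in null_stats:
            null_stats[s].append((getattr(qA, s), getattr(qB, s)))
    comparisons = {}
    for s in cfg["network_stats"]:
        try:
            res = network.compare_network_stat(
                getattr(propA, s), getattr(propB, s), null_stats[s]
            )
            comparisons[s] = {"observed_diff": res.observed, "p_value": res.p_value,
                              "n_perm": res.n_perm}
        except OTUTableError as exc:
            comparisons[s] = {"error": str(exc)}
    return {
        "properties_A": propA.as_dict(),
        "properties_B": propB.as_dict(),
        "dlm_A": censusA.dlm,
        "dlm_B": censusB.dlm,
        "mao_A": censusA.mao_id,
        "mao_B": censusB.mao_id,
        "comparisons": comparisons,
    }


def _cpn_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    out = {}
    netA = network.build_scn(tA, cfg["fdr_alpha"], cfg["min_total"])
    netB = network.build_scn(tB, cfg["fdr_alpha"], cfg["min_total"])
    for which in ("core", "periphery"):
        obs = cpn.shared_core_observed(
            netA, netB, cfg["n_perm"], child_seed(seed, 40), which, cfg["cpn_restarts"]
        )
        perm = cpn.shared_core_permutated(
            tA, tB, cfg["n_perm"], child_seed(seed, 41), which,
            cfg["cpn_restarts"], cfg["fdr_alpha"], cfg["min_total"],
        )
        out[which] = {
            "observed_shared": int(obs.observed),
            "p_observed_strategy": obs.p_value,
            "p_permutated_strategy": perm.p_value,
            "n_perm": cfg["n_perm"],
        }
    partA = cpn.detect_core(netA, cfg["cpn_restarts"], child_seed(seed, 42))
    partB = cpn.detect_core(netB, cfg["cpn_restarts"], child_seed(seed, 43))
    out["partition_A"] = {"core": partA.core, "rho": partA.rho}
    out["partition_B"] = {"core": partB.core, "rho": partB.rho}
    return out


def _hsn_block(tA: OTUTable, tB: OTUTable, cfg: dict, seed: int) -> dict:
    out = {}
    for ti, s_star in enumerate(cfg["hsn_thresholds"]):
        res = hsn.shared_skeleton_analysis(
            tA, tB, float(s_star), cfg["n_perm"], child_seed(seed, 50 + ti),
            cfg["fdr_alpha"], cfg["min_total"],
        )
        skelA = res.extra["skeletonA"]
        skelB = res.extra["skeletonB"]
        out[f"s>={s_star:g}"] = {
            "observed_shared_edges": int(res.observed),
            "null_mean": res.null_mean,
            "p_value": res.p_value,
            "edges_A": skelA.n_edges,
            "edges_B": skelB.n_edges,
            "properties_A": hsn.hsn_properties(skelA).as_dict(),
            "properties_B": hsn.hsn_properties(skelB).as_dict(),
        }
    return out


_STAGES = {
    "diversity": _diversity_block,
    "shared_species": _shared_block,
    "ple": _ple_block,
    "dar": _dar_block,
    "network": _network_block,
    "cpn": _cpn_block,
    "hsn": _hsn_block,
}


def run_site(
    table: OTUTable,
    metadata: SampleMetadata,
    site: str,
    cfg: dict,
) -> SiteReport:
    tA, tB = split_by_group(table, metadata, site, cfg["group_field"])
    labels = (metadata.group_of(tA.sample_ids[0]), metadata.group_of(tB.sample_ids[0]))
    report = SiteReport(site, labels, (tA.n_samples, tB.n_samples))
    if cfg.get("rarefy_depth"):
        tA = diversity.rarefy(tA, int(cfg["rarefy_depth"]), child_seed(cfg["seed"], 99))
        tB = diversity.rarefy(tB, int(cfg["rarefy_depth"]), child_seed(cfg["seed"], 98))
    seed = int(cfg["seed"])
    for name, fn in _STAGES.items():
        if not cfg["stages"].get(name, True):
            continue
        try:
            if name == "diversity":
                report.blocks[name] = fn(tA, tB, cfg)
            else:
                report.blocks[name] = fn(tA, tB, cfg, seed)
        except Exception as exc:  # one stage's failure must not sink the rest
            report.errors[name] = f"{type(exc).__name__}: {exc}"
    return report


def run_all(config) -> dict[str, SiteReport]:
    """Run every enabled stage for every requested site.

    ``config`` is a dict or a YAML path; see ``DEFAULT_CONFIG`` for keys.
    Returns site -> SiteReport and, if ``outdir`` is set, writes one JSON
    report per site plus a manifest listing parameters and outputs.
    """
    cfg = _load_config(config)
    if not cfg["otu_table"] or not cfg["metadata"]:
        raise OTUTableError("config must name otu_table and metadata files")
    for key in ("otu_table", "metadata"):
        if not os.path.exists(cfg[key]):
            raise OTUTableError(f"input file not found: {cfg[key]}")
    if cfg["taxonomy"] and not os.path.exists(cfg["taxonomy"]):
        raise OTUTableError(f"input file not found: {cfg['taxonomy']}")
    table = read_otu_table(cfg["otu_table"], cfg["format"])
    metadata = read_metadata(cfg["metadata"])
    _taxonomy = read_taxonomy(cfg["taxonomy"]) if cfg["taxonomy"] else TaxonomyMap()
    sites = cfg["sites"] or metadata.sites
    reports = {site: run_site(table, metadata, site, cfg) for site in sites}
    if cfg["outdir"]:
        os.makedirs(cfg["outdir"], exist_ok=True)
        manifest = {"parameters": {k: v for k, v in cfg.items() if k != "stages"},
                    "stages": cfg["stages"], "sites": {}}
        for site, rep in sorted(reports.items()):
            path = os.path.join(cfg["outdir"], f"{site}_report.json")
            with open(path, "w") as fh:
                json.dump(
                    {"site": rep.site, "groups": rep.groups, "n_samples": rep.n_samples,
                     "blocks": rep.blocks, "errors": rep.errors},
                    fh, indent=2, sort_keys=True, default=_json_default,
                )
                fh.write("\n")
            manifest["sites"][site] = os.path.basename(path)
        with open(os.path.join(cfg["outdir"], "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    return reports


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
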