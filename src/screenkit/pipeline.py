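"""End-to-end pipeline orchestration with seeded stages and run manifests.

Two pipelines mirror the study design: the screen pipeline (simulate or
ingest counts -> enrichment -> hit calling) and the cohort pipeline
(generate or ingest a cohort -> metagene scoring -> subtype assignment ->
marker stratification -> activity correlation -> survival comparison).
Every stochastic stage draws its seed from hash(global_seed, stage_name),
so adding stages never perturbs earlier random streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import io as skio
from .errors import ScreenKitError
from .hit_calling import HitCriteria, call_hits
from .screen_quant import annotate_genes, enrichment
from .signatures import (
    GeneSet,
    activity_correlation,
    assign_subtype,
    build_centroids,
    group_composition,
    metagene_score,
    stratify,
)
from .survival_qpcr import km_estimate, logrank
from .synthetic_data import (
    CohortConfig,
    SimConfig,
    generate_cohort,
    make_library,
    simulate_screen,
)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256(global_seed:stage) truncated below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Run manifest: parameter snapshot, per-stage timings, output hashes."""

    def __init__(self, outdir: Path, params: dict):
        from . import __version__

        self.outdir = Path(outdir)
        self.data = {
            "package_version": __version__,
            "parameters": params,
            "stages": {},
            "outputs": {},
        }

    def stage(self, name: str, seconds: float):
        self.data["stages"][name] = round(seconds, 4)

    def output(self, name: str, path: Path):
        self.data["outputs"][name] = {
            "path": str(path), "sha256": _hash_file(path)
        }

    def write(self):
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
        return path


def run_screen_pipeline(
    outdir,
    seed: int = 0,
    sim: SimConfig | None = None,
    driver_effects: dict | None = None,
    driver_efficacy: float | None = None,
    criteria: HitCriteria = HitCriteria(),
    pseudocount: float = 0.5,
    counts_files: list | None = None,
    control_file=None,
) -> pd.DataFrame:
    """Simulate (or ingest) a screen, quantify enrichment, call hits.

    With ``counts_files``/``control_file`` the simulation stage is skipped
    and TSV count tables are ingested instead.  All intermediates and a
    manifest are written under ``outdir``; returns the hit table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim or SimConfig()
    params = {
        "seed": seed,
        "sim": dataclasses.asdict(sim),
        "criteria": dataclasses.asdict(criteria),
        "driver_effects": driver_effects or {},
        "pseudocount": pseudocount,
    }
    params["sim"]["overdispersion"] = str(params["sim"]["overdispersion"])
    skio.write_config(params, outdir / "config.yaml")
    manifest = Manifest(outdir, params)
    try:
        if counts_files:
            t0 = time.perf_counter()
            control = skio.read_counts(control_file, role="control")
            tumors = [skio.read_counts(f) for f in counts_files]
            ctrl_table = skio.read_table(control_file)
            library = (
                ctrl_table[["shrna_id", "gene", "barcode"]]
                if {"gene", "barcode"} <= set(ctrl_table.columns)
                else None
            )
            manifest.stage("ingest", time.perf_counter() - t0)
        else:
            t0 = time.perf_counter()
            library = make_library(
                n_genes=sim.n_genes,
                shrnas_per_gene=sim.shrnas_per_gene,
                driver_effects=driver_effects,
                driver_efficacy=driver_efficacy,
                seed=derive_seed(seed, "library"),
            )
            cfg = dataclasses.replace(sim, seed=derive_seed(seed, "screen"))
            control, tumors = simulate_screen(library, cfg)
            manifest.stage("simulate", time.perf_counter() - t0)
            skio.write_counts(control, library, outdir / "counts_control.tsv")
            manifest.output("counts_control", outdir / "counts_control.tsv")
            for t in tumors:
                p = outdir / f"counts_{t.sample_id}.tsv"
                skio.write_counts(t, library, p)
                manifest.output(f"counts_{t.sample_id}", p)

        t0 = time.perf_counter()
        table = enrichment(control, tumors, pseudocount)
        if library is not None:
            table = annotate_genes(table, library)
        skio.write_table(table, outdir / "enrichment.tsv")
        manifest.output("enrichment", outdir / "enrichment.tsv")
        manifest.stage("enrichment", time.perf_counter() - t0)

        t0 = time.perf_counter()
        hits = call_hits(table, criteria)
        skio.write_table(hits, outdir / "hits.tsv")
        manifest.output("hits", outdir / "hits.tsv")
        manifest.stage("call_hits", time.perf_counter() - t0)
    except ScreenKitError as err:
        manifest.data["failed_stage"] = str(err)
        manifest.write()
        raise
    manifest.write()
    return hits


def run_cohort_pipeline(
    outdir,
    seed: int = 0,
    cohort: CohortConfig | None = None,
    extreme_n: int = 24,
    expr_file=None,
    gmt_file=None,
    survival_file=None,
    subtype_file=None,
) -> dict:
    """Generate (or ingest) a cohort and run the full marker analysis chain.

    Stages: metagene scoring of the WNT and mesenchymal signatures ->
    centroid training + subtype assignment -> extreme-n marker
    stratification -> WNT/mesenchymal activity correlation on the extreme
    union -> subtype composition of each group -> Kaplan-Meier + log-rank
    between marker-low and the rest.  Returns the result dictionary and
    writes all tables plus a manifest under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ingest = expr_file is not None
    cfg = cohort or CohortConfig()
    params = {"seed": seed, "extreme_n": extreme_n, "ingest": bool(ingest)}
    if not ingest:
        cdict = dataclasses.asdict(cfg)
        cdict["subtype_proportions"] = dict(cdict["subtype_proportions"])
        params["cohort"] = cdict
    skio.write_config(params, outdir / "config.yaml")
    manifest = Manifest(outdir, params)

    t0 = time.perf_counter()
    if ingest:
        if gmt_file is None:
            raise ScreenKitError(
                "cohort ingest requires a GMT file of WNT_ACTIVITY and "
                "MESENCHYMAL gene sets (External Interfaces: gene sets are "
                "user-supplied GMT)"
            )
        expr = skio.read_matrix(expr_file)
        sets = skio.read_gmt(gmt_file)
        survival = skio.read_table(survival_file) if survival_file else None
        subtypes = (
            skio.read_table(subtype_file).set_index("sample_id")["subtype"]
            if subtype_file
            else None
        )
        marker_gene = cfg.marker_gene
    else:
        cfg = dataclasses.replace(cfg, seed=derive_seed(seed, "cohort"))
        syn = generate_cohort(cfg)
        expr, subtypes, survival = syn.expression, syn.subtypes, syn.survival
        sets = {k: GeneSet(k, v) for k, v in syn.gene_sets.items()}
        marker_gene = cfg.marker_gene
        skio.write_matrix(expr, outdir / "expression.tsv")
        skio.write_matrix(syn.copy_number, outdir / "copy_number.tsv")
        skio.write_gmt(sets.values(), outdir / "gene_sets.gmt")
        skio.write_survival(survival, outdir / "survival.tsv")
        skio.write_table(
            subtypes.rename_axis("sample_id").reset_index(), outdir / "subtypes.tsv"
        )
        for name in ("expression", "copy_number", "gene_sets", "survival", "subtypes"):
            ext = "gmt" if name == "gene_sets" else "tsv"
            manifest.output(name, outdir / f"{name}.{ext}")
    manifest.stage("inputs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    wnt = metagene_score(expr, sets["WNT_ACTIVITY"])
    mes = metagene_score(expr, sets["MESENCHYMAL"])
    scores = pd.DataFrame({"wnt": wnt, "mesenchymal": mes}).rename_axis("sample_id")
    manifest.stage("scores", time.perf_counter() - t0)

    t0 = time.perf_counter()
    assigned = None
    if subtypes is not None:
        centroids = build_centroids(expr, subtypes)
        assigned = assign_subtype(expr, centroids)
    manifest.stage("subtype", time.perf_counter() - t0)

    t0 = time.perf_counter()
    groups = stratify(expr, marker_gene, mode="extreme_n", n=extreme_n)
    scores["marker_group"] = groups
    scores["marker_value"] = expr.loc[marker_gene]
    if assigned is not None:
        scores["subtype"] = assigned["subtype"]
    skio.write_table(scores.reset_index(), outdir / "activity_scores.tsv")
    manifest.output("activity_scores", outdir / "activity_scores.tsv")
    manifest.stage("stratify", time.perf_counter() - t0)

    t0 = time.perf_counter()
    union = groups.index[groups != "mid"]
    r, p = activity_correlation(wnt, mes, union)
    result = {"r_extreme": r, "p_extreme": p}
    if subtypes is not None:
        comp_low = group_composition(subtypes, groups.index[groups == "low"])
        comp_high = group_composition(subtypes, groups.index[groups == "high"])
        comp = pd.DataFrame({"low": comp_low, "high": comp_high}).fillna(0.0)
        skio.write_table(comp.rename_axis("subtype").reset_index(), outdir / "composition.tsv")
        manifest.output("composition", outdir / "composition.tsv")
        result["composition"] = comp
    manifest.stage("correlate", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if survival is not None:
        surv = survival.set_index("sample_id")
        surv["group"] = groups.reindex(surv.index).map(
            lambda g: "marker_low" if g == "low" else "rest"
        )
        km = km_estimate(surv, "group")
        chi2, logrank_p = logrank(surv, "marker_low", "rest")
        medians = {k: v["median"] for k, v in km.items()}
        result.update({"km_medians": medians, "logrank_chi2": chi2, "logrank_p": logrank_p})
        curves = pd.concat(
            [v["curve"].assign(group=k) for k, v in km.items()], ignore_index=True
        )
        skio.write_table(curves, outdir / "km_curves.tsv")
        manifest.output("km_curves", outdir / "km_curves.tsv")
    manifest.stage("survival", time.perf_counter() - t0)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {
                k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                for k, v in result.items()
            },
            fh, indent=2, default=float,
        )
    manifest.output("summary", outdir / "summary.json")
    manifest.write()
    result["scores"] = scores
    return result
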