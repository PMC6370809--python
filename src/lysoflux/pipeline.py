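"""Config-driven orchestration of the full analysis.

A single YAML config (or the bundled default) drives: data acquisition
(simulate or ingest) → differential expression with gates → focus-set
overlap and z-score composite → time-course profile clustering → term
enrichment → GSEA → co-expression network and hub ranking → recovery report
(when ground truth is available) → run manifest with per-file checksums.

One global seed reproduces everything: per-stage seeds are derived by stable
hashing of the stage name, so stage order cannot perturb streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import build_network, rank_hubs, write_network
from .diffexp import DEGGates, classify_deg, deg_gene_ids, test_differential
from .enrichment import fisher_enrich, intersect_sets, zscore_composite
from .gsea import gsea_significance, gsea_table
from .io_core import (
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    read_expression_matrix,
    read_gene_sets_gmt,
    read_sample_annotation,
    write_expression_matrix,
    write_results_table,
    write_sample_annotation,
)
from .profiles import (
    assign_profiles,
    enumerate_profiles,
    profile_significance,
    profiles_table,
)
from .synthetic import (
    CoexprSimSpec,
    CountSimSpec,
    TimecourseSimSpec,
    simulate_coexpression,
    simulate_counts,
    simulate_timecourse,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Configuration or prerequisite failure during a pipeline run."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def default_config(seed: int = 0) -> dict:
    """The bundled synthetic end-to-end configuration.

    Simulates all three data shapes with planted truth, runs every stage
    with the source analysis's gates (human contrast FC 1.2/0.833 at
    FDR < 0.2; network edges at FDR < 0.05), and emits a recovery report.
    """
    return {
        "seed": int(seed),
        "counts": {
            "simulate": {
                "n_genes": 1000,
                "samples_per_group": 10,
                "baseline_mean": 100.0,
                "dispersion": 0.1,
                "n_planted": 40,
                "planted_log2_fc": 2.0,
            }
        },
        "timecourse": {
            "simulate": {
                "n_genes": 300,
                "n_planted": 120,
                "noise_sd": 0.25,
                "replicates": 3,
            }
        },
        "coexpr": {
            "simulate": {
                "n_genes": 30,
                "n_samples": 100,
                "module_size": 12,
                "loading_hub": 0.95,
                "loading_member": 0.6,
            }
        },
        "stages": {
            "diffexp": {
                "enabled": True,
                "fc_up": 1.2,
                "fc_down": 0.833,
                "alpha": 0.2,
                "alpha_kind": "fdr",
            },
            "overlap": {"enabled": True},
            "zscore": {"enabled": True},
            "profiles": {"enabled": True, "c": 1, "step_size": 1.0, "n_permutations": 100},
            "enrich": {"enabled": True, "n_random_terms": 10, "term_size": 40},
            "gsea": {"enabled": True, "n_permutations": 200, "weight_p": 1.0},
            "coexpr": {"enabled": True, "fdr_max": 0.05},
        },
        "precision": 6,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _planted_count_spec(sim: dict, seed: int) -> CountSimSpec:
    n_planted = int(sim.get("n_planted", 0))
    lfc = float(sim.get("planted_log2_fc", 2.0))
    return CountSimSpec(
        n_genes=int(sim.get("n_genes", 1000)),
        samples_per_group=int(sim.get("samples_per_group", 10)),
        baseline_mean=float(sim.get("baseline_mean", 100.0)),
        dispersion=float(sim.get("dispersion", 0.1)),
        planted_degs=tuple((i, lfc) for i in range(n_planted)),
        seed=seed,
    )


def _planted_timecourse_spec(sim: dict, seed: int) -> TimecourseSimSpec:
    n_genes = int(sim.get("n_genes", 300))
    n_planted = int(sim.get("n_planted", 0))
    c = int(sim.get("c", 1))
    tps = tuple(sim.get("time_points", ("0h", "2h", "24h", "6d")))
    n_profiles = (2 * c + 1) ** (len(tps) - 1) - 1
    rng = np.random.default_rng(seed ^ 0x5EED)
    planted = tuple(
        (i, int(rng.integers(0, n_profiles))) for i in range(min(n_planted, n_genes))
    )
    return TimecourseSimSpec(
        n_genes=n_genes,
        time_points=tps,
        planted_profiles=planted,
        unit_change_bound=c,
        noise_sd=float(sim.get("noise_sd", 0.25)),
        replicates=int(sim.get("replicates", 3)),
        seed=seed,
    )


def _planted_coexpr_spec(sim: dict, seed: int) -> CoexprSimSpec:
    module_size = int(sim.get("module_size", 12))
    return CoexprSimSpec(
        n_genes=int(sim.get("n_genes", 30)),
        n_samples=int(sim.get("n_samples", 100)),
        module_members=tuple(range(module_size)),
        hub_index=0,
        loading_hub=float(sim.get("loading_hub", 0.95)),
        loading_member=float(sim.get("loading_member", 0.6)),
        seed=seed,
    )


def _require(condition: bool, stage: str, needed: str) -> None:
    if not condition:
        raise PipelineError(
            f"stage {stage!r} requires output of stage {needed!r}, which is neither "
            "enabled nor supplied as a file"
        )


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute enabled stages in dependency order; return the run manifest."""
    t0 = time.monotonic()
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    precision = int(config.get("precision", 6))
    stages_cfg = config.get("stages", {})
    manifest: dict = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": [],
    }
    summary: dict = {}
    outputs: dict[str, Path] = {}

    def record(stage: str, files: list[Path], t_start: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {f.name: _sha256(f) for f in sorted(files)},
                "seconds": round(time.monotonic() - t_start, 3),
            }
        )

    def enabled(stage: str) -> bool:
        return bool(stages_cfg.get(stage, {}).get("enabled", False))

    # --- data acquisition -------------------------------------------------
    counts = counts_ann = counts_truth = None
    ccfg = config.get("counts", {})
    ts = time.monotonic()
    if "simulate" in ccfg:
        spec = _planted_count_spec(ccfg["simulate"], stage_seed(seed, "counts"))
        counts, counts_ann, counts_truth = simulate_counts(spec)
        files = [outdir / "counts.tsv", outdir / "counts_meta.tsv", outdir / "counts_truth.tsv"]
        write_expression_matrix(counts, files[0], precision)
        write_sample_annotation(counts_ann, files[1])
        write_results_table(counts_truth, files[2], precision)
        record("simulate_counts", files, ts)
    elif "path" in ccfg:
        counts = read_expression_matrix(ccfg["path"], ccfg.get("value_kind", "counts"))
        counts_ann = read_sample_annotation(ccfg["annotation"])

    series = series_ann = series_truth = None
    tcfg = config.get("timecourse", {})
    ts = time.monotonic()
    if "simulate" in tcfg:
        tspec = _planted_timecourse_spec(tcfg["simulate"], stage_seed(seed, "timecourse"))
        series, series_ann, series_truth = simulate_timecourse(tspec)
        files = [outdir / "timecourse.tsv", outdir / "timecourse_meta.tsv", outdir / "timecourse_truth.tsv"]
        write_expression_matrix(series, files[0], precision)
        write_sample_annotation(series_ann, files[1])
        write_results_table(series_truth, files[2], precision)
        record("simulate_timecourse", files, ts)
    elif "path" in tcfg:
        series = read_expression_matrix(tcfg["path"], "log2")
        series_ann = read_sample_annotation(
            tcfg["annotation"], time_order=tcfg.get("time_order", ())
        )

    coexpr_mat = coexpr_truth = None
    xcfg = config.get("coexpr", {})
    ts = time.monotonic()
    if "simulate" in xcfg:
        xspec = _planted_coexpr_spec(xcfg["simulate"], stage_seed(seed, "coexpr"))
        coexpr_mat, coexpr_truth = simulate_coexpression(xspec)
        files = [outdir / "coexpr.tsv", outdir / "coexpr_truth.tsv"]
        write_expression_matrix(coexpr_mat, files[0], precision)
        write_results_table(coexpr_truth, files[1], precision)
        record("simulate_coexpr", files, ts)
    elif "path" in xcfg:
        coexpr_mat = read_expression_matrix(xcfg["path"], "log2")

    # focus gene set: supplied GMT, else the planted truth stands in for the
    # curated lysosomal/autophagic list
    focus_set = None
    if "focus_gmt" in config.get("gene_sets", {}):
        focus_set = read_gene_sets_gmt(config["gene_sets"]["focus_gmt"])[0]
    elif counts_truth is not None and len(counts_truth):
        focus_set = GeneSet("FOCUS", "planted differential genes", tuple(counts_truth["gene_id"]))

    # --- diffexp ----------------------------------------------------------
    deg = None
    if enabled("diffexp"):
        _require(counts is not None, "diffexp", "counts input")
        ts = time.monotonic()
        scfg = stages_cfg["diffexp"]
        gates = DEGGates(
            fc_up=float(scfg.get("fc_up", 1.2)),
            fc_down=float(scfg.get("fc_down", 0.833)),
            alpha=float(scfg.get("alpha", 0.2)),
            alpha_kind=scfg.get("alpha_kind", "fdr"),
        )
        deg = classify_deg(test_differential(counts, counts_ann), gates)
        n_up = int((deg["status"] == "up").sum())
        n_down = int((deg["status"] == "down").sum())
        logger.info(
            "diffexp: %d genes tested, %d DEGs (%d up / %d down) at gates "
            "FC>%g or <%g, %s<%g",
            len(deg), n_up + n_down, n_up, n_down,
            gates.fc_up, gates.fc_down, gates.alpha_kind, gates.alpha,
        )
        summary["degs_total"] = n_up + n_down
        summary["degs_up"] = n_up
        summary["degs_down"] = n_down
        f = outdir / "deg.tsv"
        write_results_table(deg, f, precision)
        record("diffexp", [f], ts)

    # --- overlap ----------------------------------------------------------
    if enabled("overlap"):
        _require(deg is not None, "overlap", "diffexp")
        _require(focus_set is not None, "overlap", "focus gene set")
        ts = time.monotonic()
        deg_ids = deg_gene_ids(deg)
        _require(len(deg_ids) > 0, "overlap", "diffexp (no DEGs called)")
        deg_set = GeneSet("DEG", "differential genes", tuple(deg_ids))
        overlap = intersect_sets(deg_set, focus_set)
        logger.info(
            "overlap: %d DEGs ∩ %d focus genes → %d common",
            len(deg_set), len(focus_set), len(overlap.both),
        )
        summary["overlap_common"] = len(overlap.both)
        f = outdir / "overlap.tsv"
        write_results_table(overlap.to_frame(), f, precision)
        record("overlap", [f], ts)

    # --- z-score composite ------------------------------------------------
    if enabled("zscore"):
        _require(counts is not None, "zscore", "counts input")
        _require(focus_set is not None, "zscore", "focus gene set")
        ts = time.monotonic()
        ztab, zp = zscore_composite(counts, focus_set, counts_ann)
        summary["zscore_mannwhitney_p"] = zp
        logger.info("zscore: focus-set composite Mann–Whitney p = %.3g", zp)
        f = outdir / "zscore.tsv"
        write_results_table(ztab, f, precision)
        record("zscore", [f], ts)

    # --- temporal profiles -------------------------------------------------
    assignments = None
    if enabled("profiles"):
        _require(series is not None, "profiles", "timecourse input")
        ts = time.monotonic()
        scfg = stages_cfg["profiles"]
        universe = enumerate_profiles(
            len(series_ann.time_order), int(scfg.get("c", 1))
        )
        assignments = assign_profiles(
            series, series_ann, universe, step_size=float(scfg.get("step_size", 1.0))
        )
        signif = profile_significance(
            assignments,
            series,
            series_ann,
            universe,
            n_permutations=int(scfg.get("n_permutations", 100)),
            seed=stage_seed(seed, "profiles"),
            step_size=float(scfg.get("step_size", 1.0)),
        )
        n_sig = int((signif["fdr"] < 0.05).sum())
        logger.info(
            "profiles: %d model profiles, %d significant at FDR<0.05",
            len(universe), n_sig,
        )
        summary["profiles_significant"] = n_sig
        files = [outdir / "profile_universe.tsv", outdir / "profile_assignments.tsv", outdir / "profile_significance.tsv"]
        write_results_table(profiles_table(universe), files[0], precision)
        write_results_table(assignments, files[1], precision)
        write_results_table(signif, files[2], precision)
        record("profiles", files, ts)

    # --- term enrichment ----------------------------------------------------
    if enabled("enrich"):
        _require(deg is not None, "enrich", "diffexp")
        _require(counts is not None, "enrich", "counts input")
        ts = time.monotonic()
        scfg = stages_cfg["enrich"]
        universe_set = GeneSet("UNIVERSE", "all tested genes", tuple(deg["gene_id"]))
        if "terms_gmt" in config.get("gene_sets", {}):
            terms = read_gene_sets_gmt(config["gene_sets"]["terms_gmt"])
        else:
            # synthetic terms: the focus set plus random same-size terms
            _require(focus_set is not None, "enrich", "focus gene set")
            rng = np.random.default_rng(stage_seed(seed, "enrich"))
            pool = list(universe_set.members)
            terms = [GeneSet("TERM_FOCUS", "planted", focus_set.members)]
            size = int(scfg.get("term_size", 40))
            for i in range(int(scfg.get("n_random_terms", 10))):
                pick = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
                terms.append(
                    GeneSet(f"TERM_RAND{i:02d}", "random", tuple(pool[j] for j in pick))
                )
        query = GeneSet("QUERY", "DEGs", tuple(deg_gene_ids(deg)))
        enr = fisher_enrich(query, terms, universe_set)
        logger.info(
            "enrich: %d terms tested, %d with FDR<0.05",
            len(enr), int((enr["fdr"] < 0.05).sum()),
        )
        f = outdir / "enrichment.tsv"
        write_results_table(enr, f, precision)
        record("enrich", [f], ts)

    # --- GSEA ---------------------------------------------------------------
    if enabled("gsea"):
        _require(counts is not None, "gsea", "counts input")
        _require(focus_set is not None, "gsea", "focus gene set")
        ts = time.monotonic()
        scfg = stages_cfg["gsea"]
        records = gsea_significance(
            counts,
            counts_ann,
            [focus_set],
            n_permutations=int(scfg.get("n_permutations", 200)),
            seed=stage_seed(seed, "gsea"),
            weight_p=float(scfg.get("weight_p", 1.0)),
        )
        gt = gsea_table(records)
        if len(gt):
            summary["gsea_focus_nes"] = float(gt["nes"].iloc[0])
            summary["gsea_focus_p"] = float(gt["p_value"].iloc[0])
            logger.info(
                "gsea: focus set NES %.3f, p %.3g", gt["nes"].iloc[0], gt["p_value"].iloc[0]
            )
        f = outdir / "gsea.tsv"
        write_results_table(gt, f, precision)
        record("gsea", [f], ts)

    # --- co-expression network ----------------------------------------------
    hubs = None
    if enabled("coexpr"):
        _require(coexpr_mat is not None, "coexpr", "coexpr input")
        ts = time.monotonic()
        scfg = stages_cfg["coexpr"]
        net = build_network(
            coexpr_mat,
            fdr_max=float(scfg.get("fdr_max", 0.05)),
            r_min=scfg.get("r_min"),
        )
        hubs = rank_hubs(net)
        logger.info(
            "coexpr: %d nodes, %d edges at FDR<%g; top hub %s",
            net.number_of_nodes(), net.number_of_edges(),
            float(scfg.get("fdr_max", 0.05)),
            hubs["gene_id"].iloc[0] if len(hubs) else "n/a",
        )
        files = [outdir / "network.graphml", outdir / "edges.tsv", outdir / "hubs.tsv"]
        write_network(net, graphml_path=files[0], edges_path=files[1])
        write_results_table(hubs, files[2], precision)
        record("coexpr", files, ts)

    # --- recovery report (ground truth available) ---------------------------
    recovery: dict = {}
    if counts_truth is not None and deg is not None and len(counts_truth):
        called = set(deg_gene_ids(deg))
        planted = set(counts_truth["gene_id"])
        tp = len(called & planted)
        recovery["deg_sensitivity"] = tp / len(planted)
        recovery["deg_false_discoveries"] = len(called - planted)
    if series_truth is not None and assignments is not None:
        merged = assignments.merge(series_truth, on="gene_id")
        planted_rows = merged[merged["true_profile_id"] >= 0]
        if len(planted_rows):
            recovery["profile_recovery"] = float(
                (planted_rows["profile_id"] == planted_rows["true_profile_id"]).mean()
            )
    if coexpr_truth is not None and hubs is not None and len(hubs):
        true_hub = coexpr_truth.loc[coexpr_truth["is_hub"], "gene_id"].iloc[0]
        rank_of_hub = hubs.loc[hubs["gene_id"] == true_hub, "rank"]
        recovery["hub_rank_of_true_hub"] = int(rank_of_hub.iloc[0]) if len(rank_of_hub) else -1
    if recovery:
        ts = time.monotonic()
        f = outdir / "recovery.tsv"
        write_results_table(
            pd.DataFrame({"metric": list(recovery), "value": list(recovery.values())}),
            f,
            precision,
        )
        record("recovery", [f], ts)
        logger.info("recovery: %s", recovery)

    manifest["summary"] = {**summary, **recovery}
    manifest["total_seconds"] = round(time.monotonic() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    return cfg


def manifest_checksums(manifest: dict) -> dict[str, str]:
    """Flatten a manifest's stage outputs into {filename: sha256}."""
    out: dict[str, str] = {}
    for st in manifest["stages"]:
        out.update(st["outputs"])
    return out
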