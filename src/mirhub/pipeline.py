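"""End-to-end orchestration of the hub-gene discovery pipeline.

Stage order follows the screening design: target/DEG overlap -> co-expression
network analysis (with the expression matrix restricted to the overlap genes)
-> meta-analysis of multi-study expression -> interaction-network filtering
-> hub-gene intersection -> diagnostic and prognostic evaluation. Stages
communicate only via files in the run directory so any stage can be re-run
standalone; a machine-readable JSON run report lists every output with a
content hash. Configuration errors are raised before any stage writes a file.

All thresholds default to the field's conventional screening values: p < 0.05 and
|logFC| > 1 for DEGs, >= 3 databases for targets, scale-free R^2 cut 0.8 with
the soft threshold chosen automatically, minimum module size 10, eigengene
merge height 0.25, MM > 0.8 and GS > 0.2 for key genes, interaction score
>= 0.4 and degree >= 8 for the network stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, io, meta, overlap, ppi, synthdata, wgcna

log = logging.getLogger("mirhub")

COHORT_CASES = [78, 9, 9, 3, 8, 4, 3, 372]
COHORT_CONTROLS = [88, 10, 7, 3, 10, 8, 3, 50]


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run.

    Paths are input files per stage; ``None`` disables nothing by itself —
    stage toggles do — but an enabled stage with a missing input fails fast.
    """

    # stage toggles
    run_overlap: bool = True
    run_wgcna: bool = True
    run_meta: bool = True
    run_ppi: bool = True
    run_hub: bool = True
    run_diagnostics: bool = True

    # thresholds (defaults = the conventional screening values)
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    use_q: bool = False
    min_databases: int = 3
    beta: int | None = None  # None = automatic scale-free selection
    r2_cut: float = 0.8
    min_module_size: int = 10
    cut_height: float | None = None  # None = largest-gap heuristic
    merge_cut_height: float = 0.25
    mm_thresh: float = 0.8
    gs_thresh: float = 0.2
    min_score: float = 0.4
    min_degree: int = 8
    alpha: float = 0.05
    egger_alpha: float = 0.1

    # inputs
    diffexpr: str | None = None
    targets: str | None = None
    expression: str | None = None
    trait: str | None = None
    studies: str | None = None
    edges: str | None = None
    survival: str | None = None
    gene_sets: str | None = None
    trait_column: str | None = None
    label_column: str = "tumor"

    outdir: str = "mirhub_run"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if overrides:
            d.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(d)


def _validate(config: PipelineConfig) -> None:
    """Fail-fast checks before any stage runs."""
    if config.run_hub and not (config.run_wgcna and config.run_ppi):
        raise ValueError("hub stage requires both the wgcna and ppi stages to be enabled")
    if config.run_diagnostics and not config.run_hub:
        raise ValueError("diagnostics stage requires the hub stage to be enabled")
    needed = []
    if config.run_overlap:
        needed += [("diffexpr", config.diffexpr), ("targets", config.targets)]
    if config.run_wgcna:
        needed += [("expression", config.expression), ("trait", config.trait)]
    if config.run_meta:
        needed += [("studies", config.studies)]
    if config.run_ppi:
        needed += [("edges", config.edges)]
    if config.run_diagnostics:
        needed += [("expression", config.expression), ("trait", config.trait)]
    for name, path in needed:
        if path is None:
            raise ValueError(f"stage input '{name}' is not configured")
        if not Path(path).exists():
            raise FileNotFoundError(f"stage input '{name}' not found: {path}")


def prepare_outdir(outdir: str | os.PathLike, force: bool = False) -> Path:
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _relativize(value, outdir: Path):
    if isinstance(value, str):
        p = Path(value)
        try:
            return str(p.resolve().relative_to(outdir.resolve()))
        except ValueError:
            return value
    return value


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every enabled stage and write the JSON run report.

    Returns the report dict; raises before writing anything if the
    configuration is inconsistent or an enabled stage's input is missing.
    """
    _validate(config)
    out = prepare_outdir(config.outdir, force=force)
    report: dict = {"config": {}, "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, **kw) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FMT, **kw)
        outputs.append(p)
        return p

    def save_genes(genes, name: str) -> Path:
        p = out / name
        io.write_gene_list(list(genes), p)
        outputs.append(p)
        return p

    def save_json(obj, name: str) -> Path:
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        outputs.append(p)
        return p

    # ----- overlap stage ---------------------------------------------------
    overlap_genes: set[str] | None = None
    if config.run_overlap:
        de = io.read_diffexpr(config.diffexpr)
        tg = io.read_targets(config.targets)
        degs = overlap.select_deg(de, config.p_thresh, config.lfc_thresh, config.use_q)
        targets = overlap.filter_targets(tg, config.min_databases)
        overlap_genes = overlap.overlap_targets(degs, targets)
        save_genes(sorted(overlap_genes), "overlap_genes.txt")
        report["stages"]["overlap"] = {
            "n_deg": len(degs),
            "n_targets": len(targets),
            "n_overlap": len(overlap_genes),
        }
        log.info("overlap: %d DEGs, %d targets, %d overlap genes",
                 len(degs), len(targets), len(overlap_genes))

    # ----- wgcna stage -----------------------------------------------------
    wres: wgcna.WGCNAResult | None = None
    expr = traits = None
    if config.run_wgcna:
        expr = io.read_expression(config.expression)
        traits = io.read_trait(config.trait)
        if overlap_genes is not None:
            keep = [g for g in expr.index if g in overlap_genes]
            expr = expr.loc[keep]
        numeric_traits = traits.select_dtypes(include=[np.number])
        wres = wgcna.run_wgcna(
            expr,
            numeric_traits,
            trait_column=config.trait_column,
            beta=config.beta,
            r2_cut=config.r2_cut,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cut_height=config.merge_cut_height,
            mm_thresh=config.mm_thresh,
            gs_thresh=config.gs_thresh,
        )
        assign = pd.DataFrame({"gene": wres.labels.index, "module": wres.labels.values})
        assign = assign.merge(wres.scores[["gene", "MM", "GS"]], on="gene", how="left")
        save_tsv(assign, "module_assignment.tsv")
        me_out = wres.eigengenes.reset_index(names="module")
        save_tsv(me_out, "eigengenes.tsv")
        save_tsv(wres.module_trait, "module_trait.tsv")
        save_tsv(wres.fit_table, "soft_threshold.tsv")
        save_genes(wres.key_genes, "key_genes.txt")
        report["stages"]["wgcna"] = {
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "beta": int(wres.beta),
            "n_modules": int(wres.labels.max()),
            "trait_module": wres.trait_module,
            "n_key_genes": len(wres.key_genes),
        }
        report["key_genes"] = wres.key_genes
        log.info("wgcna: beta=%d, %d modules, trait module %s, %d key genes",
                 wres.beta, int(wres.labels.max()), wres.trait_module, len(wres.key_genes))

    # ----- meta stage ------------------------------------------------------
    if config.run_meta:
        studies = io.read_studies_long(config.studies)
        effects = meta.effects_from_long(studies)
        res = meta.meta_analyze(effects)
        save_json(res["summary"], "meta_summary.json")
        save_tsv(res["forest"], "forest.tsv")
        report["stages"]["meta"] = {"n_studies": len(effects)}
        report["meta"] = res["summary"]
        log.info("meta: %d studies, pooled %s = %.3f, I2 = %.1f%%",
                 len(effects), res["summary"]["model"], res["summary"]["pooled"],
                 res["summary"]["I2"])

    # ----- ppi stage -------------------------------------------------------
    degree_map: dict[str, int] | None = None
    high_conn: list[str] | None = None
    if config.run_ppi:
        edges = io.read_edge_list(config.edges)
        edges = ppi.dedupe_edges(edges)
        filtered = ppi.filter_edges(edges, config.min_score)
        if len(filtered) == 0:
            raise ValueError("no edges survive the score filter")
        main = ppi.main_component(filtered)
        degree_map = ppi.degrees(main)
        high_conn = ppi.high_connectivity(degree_map, config.min_degree)
        save_tsv(main, "filtered_edges.tsv")
        deg_df = pd.DataFrame(
            sorted(degree_map.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["gene", "degree"],
        )
        save_tsv(deg_df, "degrees.tsv")
        save_genes(high_conn, "high_connectivity.txt")
        report["stages"]["ppi"] = {
            "n_edges_in": len(edges),
            "n_edges_filtered": len(filtered),
            "n_edges_main": len(main),
            "n_nodes_main": len(degree_map),
            "n_high_connectivity": len(high_conn),
        }
        log.info("ppi: %d -> %d edges after score filter, %d nodes in main component, "
                 "%d genes with degree >= %d", len(edges), len(filtered),
                 len(degree_map), len(high_conn), config.min_degree)

    # ----- hub stage -------------------------------------------------------
    hub_genes: list[str] = []
    if config.run_hub:
        hub_genes = ppi.hub_intersect(wres.key_genes, high_conn, degree_map)
        save_genes(hub_genes, "hub_genes.txt")
        report["stages"]["hub"] = {"n_hub_genes": len(hub_genes)}
        report["hub_genes"] = hub_genes
        log.info("hub: %d hub genes", len(hub_genes))

    # ----- diagnostics stage -----------------------------------------------
    if config.run_diagnostics:
        diag: dict = {}
        traits_full = io.read_trait(config.trait)
        expr_full = io.read_expression(config.expression)
        if config.label_column in traits_full.columns and hub_genes:
            labels = traits_full.loc[list(expr_full.columns), config.label_column].to_numpy(dtype=int)
            aucs = {}
            for gene in hub_genes:
                r = diagnostics.roc_auc(expr_full.loc[gene].to_numpy(), labels)
                aucs[gene] = {"auc": r.auc, "p": r.p_value}
                save_tsv(r.curve, f"roc_{gene}.tsv")
            save_json(aucs, "auc.json")
            diag["auc"] = aucs
        if config.survival and Path(config.survival).exists():
            records = io.read_survival(config.survival)
            km, medians = diagnostics.km_curve(records)
            save_tsv(km, "km.tsv")
            lr = diagnostics.logrank(records)
            lr["median_survival"] = {
                str(k): (v if np.isfinite(v) else None) for k, v in medians.items()
            }
            save_json(lr, "logrank.json")
            diag["logrank"] = lr
        if config.gene_sets and Path(config.gene_sets).exists() and wres is not None:
            sets = io.read_gmt(config.gene_sets)
            module_genes = sorted(wres.labels.index[wres.labels == wres.trait_module])
            background = sorted(wres.labels.index)
            if module_genes:
                table = diagnostics.ora(module_genes, background, sets)
                save_tsv(table, "ora.tsv")
                diag["ora_top"] = {
                    "set": str(table["set"].iloc[0]),
                    "count": int(table["count"].iloc[0]),
                    "p": float(table["p"].iloc[0]),
                }
        report["stages"]["diagnostics"] = {k: True for k in diag}
        report["diagnostics"] = diag
        log.info("diagnostics: %s", ", ".join(diag) or "nothing to evaluate")

    # ----- report ----------------------------------------------------------
    resolved = {k: _relativize(v, out) for k, v in config.to_dict().items()}
    resolved["outdir"] = "."
    report["config"] = resolved
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    report["outputs"] = {p.name: _sha256(p) for p in sorted(outputs)}
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# demo: synthetic inputs + full run


def generate_demo_inputs(
    outdir: str | os.PathLike,
    seed: int = 0,
    n_genes: int = 500,
    n_samples: int = 150,
    module_sizes: list[int] | None = None,
    within_module_cor: float = 0.64,
    trait_cor: float = 0.5,
    mean_degree: float = 8.0,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.2,
) -> tuple[PipelineConfig, synthdata.PlantedTruth, pd.DataFrame]:
    """Write a complete synthetic input set and the matching configuration.

    The interaction network is generated over the planted trait-linked
    module's genes (emulating a PPI query with a module gene list); scores
    span [0.2, 1.0] so the 0.4 confidence filter is exercised.
    """
    indir = Path(outdir) / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    if module_sizes is None:
        module_sizes = [60, 50, 40, 30]
    sim = synthdata.SimulationConfig(
        n_genes=n_genes, n_samples=n_samples, module_sizes=module_sizes,
        within_module_cor=within_module_cor, trait_module=0, trait_cor=trait_cor,
        seed=seed,
    )
    expr, truth = synthdata.generate_modular_expression(sim)
    io.write_expression(expr, indir / "expression.tsv")

    trait_df = pd.DataFrame(
        {
            "grade": truth.trait,
            "tumor": (truth.trait > np.median(truth.trait)).astype(int),
        },
        index=expr.columns,
    )
    io.write_trait(trait_df, indir / "trait.tsv")

    rng = np.random.default_rng(seed + 1)
    module_mask = truth.module_label > 0
    is_de = module_mask | (rng.random(n_genes) < 0.3)
    pvals = np.where(is_de, rng.uniform(1e-6, 0.04, n_genes), rng.uniform(0.05, 1.0, n_genes))
    sign = rng.choice([-1.0, 1.0], n_genes)
    lfc = np.where(is_de, sign * rng.uniform(1.5, 3.0, n_genes), sign * rng.uniform(0.0, 0.9, n_genes))
    order = np.argsort(pvals)
    qvals = np.empty(n_genes)
    ranked = pvals[order] * n_genes / (np.arange(n_genes) + 1)
    qvals[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    de_table = pd.DataFrame(
        {"gene": expr.index, "logFC": lfc, "pvalue": pvals, "qvalue": np.clip(qvals, 0, 1)}
    )
    io.write_diffexpr(de_table, indir / "diffexpr.tsv")

    hits = np.where(module_mask, rng.integers(3, 13, n_genes), rng.integers(0, 13, n_genes))
    io.write_targets(pd.DataFrame({"gene": expr.index, "n_databases": hits}), indir / "targets.tsv")

    studies = synthdata.generate_multi_study(
        8, COHORT_CASES, COHORT_CONTROLS, true_smd=0.3, tau=0.4, seed=seed + 2
    )
    io.write_studies_long(synthdata.studies_to_long(studies), indir / "studies.tsv")

    module_genes = truth.trait_module_genes(list(expr.index), trait_module=0)
    edges = synthdata.generate_interaction_network(
        module_genes, mean_degree=mean_degree, score_range=(0.2, 1.0), seed=seed + 3
    )
    io.write_edge_list(edges, indir / "edges.tsv")

    group = diagnostics.dichotomize_median(expr.loc[module_genes[0]])
    surv = synthdata.generate_survival(
        n_samples, group, hazard_ratio=hazard_ratio, censor_rate=censor_rate, seed=seed + 4
    )
    io.write_survival(surv, indir / "survival.tsv")

    sets = synthdata.generate_gene_sets(
        list(expr.index), n_sets=30, set_size_range=(10, 50),
        planted_set=module_genes, seed=seed + 5,
    )
    io.write_gmt(sets, indir / "gene_sets.gmt")

    config = PipelineConfig(
        diffexpr=str(indir / "diffexpr.tsv"),
        targets=str(indir / "targets.tsv"),
        expression=str(indir / "expression.tsv"),
        trait=str(indir / "trait.tsv"),
        studies=str(indir / "studies.tsv"),
        edges=str(indir / "edges.tsv"),
        survival=str(indir / "survival.tsv"),
        gene_sets=str(indir / "gene_sets.gmt"),
        trait_column="grade",
        outdir=str(outdir),
        seed=seed,
    )
    return config, truth, expr


def demo(seed: int = 0, outdir: str | os.PathLike = "mirhub_demo", force: bool = False) -> dict:
    """Generate synthetic inputs with planted truth and run the full pipeline."""
    out = prepare_outdir(outdir, force=force)
    config, _, _ = generate_demo_inputs(out, seed=seed)
    return run_all(config, force=True)
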