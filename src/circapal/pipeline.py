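"""End-to-end orchestration: expression + gene sets -> circadian PAL clusters.

Stage order: map pathways onto the matrix, compute each PAL and its f_P,
filter by permutation significance, drop time-flat PALs (ANOVA), average
replicates, sign-align, cluster by consensus, remove ambiguous pathways at
confidence delta, and sinusoid-fit the final cluster centroids.  Each stage
writes a TSV table plus a run log with parameters, seed and per-stage counts.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus, significance, synthetic
from .data_io import (
    ExpressionMatrix,
    PathwayCollection,
    extract_pathway_matrix,
    rat_liver_design,
    read_design,
    read_expression,
    read_gmt,
)
from .pal import PALResult, compute_pal, normalize_rows
from .rhythm import average_replicates, fit_sinusoid

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and sizes of the full analysis (defaults as published)."""

    alpha_fp: float = 0.05            # permutation p-value cut for f_P
    anova_alpha: float = 0.01         # time-dependence filter
    corr_threshold: float = 0.8       # circadian correlation criterion
    band: tuple[float, float] = (0.24, 0.28)
    delta: float = 0.65               # consensus confidence level
    n_perm: int = 10_000
    k_range: tuple[int, int] = (2, 8)
    min_pathway_size: int = 5
    normalize_policy: str = "drop-constant"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("band", "k_range"):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineReport:
    counts: dict[str, int]
    pal_results: list[PALResult]
    significance: list[significance.SignificanceResult]
    cluster_result: consensus.ClusterResult | None
    output_dir: Path | None


def _write_manifest(outdir: Path, complete: bool, files: list[str]) -> None:
    with open(outdir / "MANIFEST", "w", encoding="utf-8") as fh:
        fh.write(f"complete: {'yes' if complete else 'NO'}\n")
        for f in files:
            fh.write(f"{f}\n")


def run_pathway_pipeline(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    config: PipelineConfig = PipelineConfig(),
    output_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full analysis and (optionally) write its tables.

    Tables written: ``pal_table.tsv`` (pathway, k, f_P, p-value, 54 activity
    values), ``significance.tsv``, ``rhythm.tsv`` (sinusoid fits of retained
    PALs), ``clusters.tsv`` (pathway -> cluster id), ``centroids.tsv``
    (cluster centroid values and fit), and ``run_log.yaml``.
    """
    if len(pathways) == 0:
        raise ValueError("no pathways in the collection")
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {"pathways_in": len(pathways)}
    files: list[str] = []

    try:
        # --- stage 1: map and reduce each pathway to its PAL -------------
        pal_results: list[PALResult] = []
        matrices = {}
        n_small = 0
        for pw in pathways:
            sub = extract_pathway_matrix(
                expr, pw, min_size=config.min_pathway_size
            )
            if sub is None:
                n_small += 1
                continue
            normed = normalize_rows(sub, policy=config.normalize_policy)
            if normed.k < 2:
                n_small += 1
                logger.info("pathway %s skipped: <2 variable genes", pw.name)
                continue
            pal = compute_pal(normed)
            pal_results.append(pal)
            matrices[pw.name] = normed
        counts["skipped_too_small"] = n_small
        counts["pals_computed"] = len(pal_results)
        if not pal_results:
            raise RuntimeError("no pathway produced an activity level")

        # --- stage 2: permutation significance of f_P --------------------
        sig_results = []
        for idx, pal in enumerate(pal_results):
            sig_results.append(significance.permutation_pvalue(
                expr,
                k=matrices[pal.pathway_name].k,
                f_actual=pal.variance_fraction,
                n_perm=config.n_perm,
                seed=config.seed,
                pathway_index=idx,
                pathway_name=pal.pathway_name,
            ))
        significant = set(significance.filter_significant(
            sig_results, config.alpha_fp
        ))
        for r in sig_results:
            logger.info("f_P significance: %s f=%.3f p=%.4f %s",
                        r.pathway_name, r.f_actual, r.p_value,
                        "kept" if r.pathway_name in significant else "dropped")
        counts["significant_fp"] = len(significant)

        # --- stage 3: ANOVA time-dependence filter -----------------------
        anova_pass: list[PALResult] = []
        for pal in pal_results:
            if pal.pathway_name not in significant:
                continue
            keep, p = consensus.anova_filter(
                pal.activity, pal.design, config.anova_alpha
            )
            logger.info("ANOVA: %s p=%.4g %s", pal.pathway_name, p,
                        "kept" if keep else "dropped")
            if keep:
                anova_pass.append(pal)
        counts["anova_passed"] = len(anova_pass)

        # --- stage 4: average replicates, align signs, cluster -----------
        profiles = [
            average_replicates(p.activity, p.design, p.pathway_name)
            for p in anova_pass
        ]
        cluster_result = None
        fits = {
            pr.label: fit_sinusoid(pr, config.corr_threshold, config.band)
            for pr in profiles
        }
        if len(profiles) >= 3:
            aligned = consensus.sign_align(profiles)
            agreement = consensus.run_ensemble(
                aligned, k_range=config.k_range, seed=config.seed
            )
            retained = consensus.select_consistent_subset(
                agreement, config.delta
            )
            counts["retained_after_delta"] = len(retained)
            cluster_result = consensus.final_clusters(
                agreement.restrict(retained),
                aligned,
                k_range=config.k_range,
                delta=config.delta,
                corr_threshold=config.corr_threshold,
                band=config.band,
            )
            counts["final_clusters"] = cluster_result.k_clusters
        else:
            logger.warning("fewer than 3 PALs pass the filters; skipping "
                           "consensus clustering")
            counts["retained_after_delta"] = len(profiles)
            counts["final_clusters"] = 0

        # --- outputs ------------------------------------------------------
        if outdir is not None:
            sample_names = [
                f"T{expr.design.time_points[i]:g}_R{j + 1}"
                for i, j in expr.design.order()
            ]
            p_by_name = {r.pathway_name: r.p_value for r in sig_results}
            pal_tab = pd.DataFrame(
                [p.activity for p in pal_results],
                index=[p.pathway_name for p in pal_results],
                columns=sample_names,
            )
            pal_tab.insert(0, "k", [matrices[p.pathway_name].k
                                    for p in pal_results])
            pal_tab.insert(1, "f_P", [p.variance_fraction
                                      for p in pal_results])
            pal_tab.insert(2, "p_value", [p_by_name[p.pathway_name]
                                          for p in pal_results])
            pal_tab.to_csv(outdir / "pal_table.tsv", sep="\t",
                           index_label="pathway")
            files.append("pal_table.tsv")

            pd.DataFrame({
                "pathway": [r.pathway_name for r in sig_results],
                "k": [matrices[r.pathway_name].k for r in sig_results],
                "f_P": [r.f_actual for r in sig_results],
                "p_value": [r.p_value for r in sig_results],
                "n_perm": [r.n_perm for r in sig_results],
                "seed": [r.seed for r in sig_results],
            }).to_csv(outdir / "significance.tsv", sep="\t", index=False)
            files.append("significance.tsv")

            pd.DataFrame({
                "pathway": list(fits),
                "A": [f.amplitude for f in fits.values()],
                "B": [f.frequency for f in fits.values()],
                "C": [f.phase for f in fits.values()],
                "correlation": [f.correlation for f in fits.values()],
                "is_circadian": [f.is_circadian for f in fits.values()],
            }).to_csv(outdir / "rhythm.tsv", sep="\t", index=False)
            files.append("rhythm.tsv")

            if cluster_result is not None:
                pd.DataFrame({
                    "pathway": cluster_result.retained,
                    "cluster": cluster_result.labels,
                }).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
                files.append("clusters.tsv")
                cent_rows = []
                for c, f in zip(cluster_result.centroids,
                                cluster_result.centroid_fits):
                    row = {"cluster": c.label, "A": f.amplitude,
                           "B": f.frequency, "C": f.phase,
                           "correlation": f.correlation}
                    row.update({f"T{t:g}": v
                                for t, v in zip(c.times, c.values)})
                    cent_rows.append(row)
                pd.DataFrame(cent_rows).to_csv(
                    outdir / "centroids.tsv", sep="\t", index=False
                )
                files.append("centroids.tsv")

            log = {"config": {**asdict(config),
                              "band": list(config.band),
                              "k_range": list(config.k_range)},
                   "counts": counts}
            with open(outdir / "run_log.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(log, fh, sort_keys=True)
            files.append("run_log.yaml")
            _write_manifest(outdir, complete=True, files=files)

        return PipelineReport(counts, pal_results, sig_results,
                              cluster_result, outdir)
    except Exception:
        if outdir is not None:
            _write_manifest(outdir, complete=False, files=files)
        raise


def run_pathway_pipeline_from_files(
    expression_path: str | Path,
    gmt_path: str | Path,
    design_path: str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
    output_dir: str | Path | None = None,
) -> PipelineReport:
    design = read_design(design_path) if design_path else rat_liver_design()
    expr = read_expression(expression_path, design)
    pathways = read_gmt(gmt_path)
    return run_pathway_pipeline(expr, pathways, config, output_dir)


def run_synthetic_study(
    noise_grid: list[int],
    q_values: tuple[float, ...] = (0.1, 0.5, 0.9),
    config: synthetic.SyntheticConfig = synthetic.SyntheticConfig(),
    n_reps: int = 1000,
    n_perm: int = 1000,
) -> pd.DataFrame:
    """Significance-versus-noise tables for gene events and the PAL.

    One row per (noise level, event): the gene events "at least q circadian"
    for each q, the PAL circadian event, and the permutation significance of
    f_P against a pure-noise background — |grid| x (|q| + 2) rows.
    """
    rows = []
    for i in noise_grid:
        cfg = replace(config, noise_level=int(i))
        for q in q_values:
            pt = synthetic.gene_event_pvalue(cfg, q, n_reps=n_reps)
            rows.append((pt.noise_level, pt.event, pt.p_value,
                         pt.significance, pt.n_reps))
    for circ, fp in synthetic.pal_significance_curve(
        [int(i) for i in noise_grid], config, n_reps=n_reps, n_perm=n_perm
    ):
        rows.append((circ.noise_level, circ.event, circ.p_value,
                     circ.significance, circ.n_reps))
        rows.append((fp.noise_level, fp.event, fp.p_value,
                     fp.significance, fp.n_reps))
    frame = pd.DataFrame(
        rows,
        columns=["noise_level", "event", "p_value", "significance", "n_reps"],
    )
    return frame.sort_values(["noise_level", "event"]).reset_index(drop=True)
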