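"""End-to-end analyses: site-based structure, de novo groups, enrichment.

Each run function consumes in-memory objects plus a :class:`PipelineConfig`
and writes every intermediate table as TSV next to a ``summary.json`` so
each summary number is recomputable from the emitted stage files.  The CLI
module wraps these with file loading.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, denovo, sites
from . import markers as marker_sel
from .indval import characteristic_markers, indval as compute_indval
from .dapc import assignment_accuracy, axis_significance, fit_dapc
from .io import MethylRadCounts, RpmMatrix, SampleMetadata, compute_rpm
from .transforms import hellinger

__all__ = [
    "PipelineConfig",
    "run_site_analysis",
    "run_denovo_analysis",
    "run_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunables for the three analyses; defaults follow the reference
    workflow (K-1 retention, FDR 0.05, 1-25 breakpoints, 5 kb window)."""

    schema_version: int = 1
    axes: str = "significant"  # Mahalanobis axis subset: significant | all
    alpha: float = 0.05
    grid_min_step: int = 10
    grid_target_points: int = 40
    max_breakpoints: int = 25
    indval_unit: str = "individual"  # or "site"
    kmeans_k_range: tuple[int, int] = (1, 8)
    kmeans_n_starts: int = 50
    gene_window: int = 5000
    min_term_genes: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kmeans_k_range" in raw:
            raw["kmeans_k_range"] = tuple(raw["kmeans_k_range"])
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        d = asdict(self)
        d["kmeans_k_range"] = list(d["kmeans_k_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _prepare(data: MethylRadCounts):
    rpm = compute_rpm(data)
    hel = hellinger(rpm)
    return rpm, hel


def _write_ranking(ranking, markers, path):
    pd.DataFrame(
        {
            "marker": markers,
            "mahalanobis_d2": ranking.distances,
            "p": ranking.p_values,
            "q": ranking.q_values,
            "significant": ranking.significant,
        }
    ).to_csv(path, sep="\t", index=False)


def _indval_stage(rpm: RpmMatrix, unit_labels, marker_idx, out_dir: Path, prefix: str):
    """IndVal + Jenks on a marker subset; returns per-group characteristic counts."""
    sub = rpm.values[:, marker_idx]
    names = [rpm.markers[j] for j in marker_idx]
    table = compute_indval(sub, unit_labels, markers=names)
    characteristic_markers(table)
    df = table.to_frame()
    df.index.name = "marker"
    df.to_csv(out_dir / f"{prefix}_indval.tsv", sep="\t")
    flags = pd.DataFrame(table.characteristic, index=names, columns=table.groups)
    flags.index.name = "marker"
    flags.to_csv(out_dir / f"{prefix}_characteristic.tsv", sep="\t")
    counts = {str(g): int(c) for g, c in zip(table.groups, table.characteristic.sum(axis=0))}
    pd.DataFrame({"group": list(counts), "n_characteristic": list(counts.values())}).to_csv(
        out_dir / f"{prefix}_characteristic_counts.tsv", sep="\t", index=False
    )
    return counts, table


def _minimal_set_or_fallback(curve, ranking, config):
    """Segmented minimal set; with a too-short curve (< 4 points) every
    significant marker is kept and no fit is reported."""
    if len(curve.sizes) < 4:
        logger.warning(
            "accuracy curve has %d points; keeping all %d significant markers",
            len(curve.sizes),
            ranking.n_significant,
        )
        return None, ranking.top(ranking.n_significant)
    seg, minimal_idx = marker_sel.segmented_minimal_set(
        curve, config.max_breakpoints, seed=config.seed
    )
    return seg, minimal_idx


def run_site_analysis(
    data: MethylRadCounts,
    meta: SampleMetadata,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Site-based workflow: RPM -> Hellinger -> DAPC(sites) -> axis
    significance -> Mahalanobis ranking -> accuracy curve -> segmented
    minimal set -> minimal-set DAPC refit -> UPGMA site clustering ->
    IndVal/Jenks per site cluster.  Returns the summary dict."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.dump(out_dir / "resolved_config.yaml")
    site_labels = meta.sites_of(data.individuals)

    rpm, hel = _prepare(data)
    model = fit_dapc(hel, site_labels)
    sig = axis_significance(model, alpha=config.alpha)
    pd.DataFrame(
        {
            "axis": np.arange(1, model.n_axes + 1),
            "F": sig.f_statistic,
            "p": sig.p_values,
            "q": sig.q_values,
            "significant": sig.significant,
        }
    ).to_csv(out_dir / "axis_significance.tsv", sep="\t", index=False)
    full_accuracy = assignment_accuracy(model, hel, site_labels)

    ranking = marker_sel.mahalanobis_ranking(model, axes=config.axes, alpha=config.alpha)
    _write_ranking(ranking, data.markers, out_dir / "marker_ranking.tsv")
    grid = marker_sel.default_grid(
        ranking.n_significant, config.grid_min_step, config.grid_target_points
    )
    curve = marker_sel.accuracy_curve(hel, site_labels, ranking, grid)
    pd.DataFrame({"n_markers": curve.sizes, "accuracy": curve.accuracy}).to_csv(
        out_dir / "accuracy_curve.tsv", sep="\t", index=False
    )
    seg, minimal_idx = _minimal_set_or_fallback(curve, ranking, config)
    if seg is not None:
        pd.DataFrame(
            [(c["n_breakpoints"], c["rss"], c["aic"]) for c in seg.candidates],
            columns=["n_breakpoints", "rss", "aic"],
        ).to_csv(out_dir / "segmented_aic.tsv", sep="\t", index=False)
        marker_sel.plot_accuracy_curve(curve, seg, out_dir / "accuracy_curve.png")
    minimal_markers = [data.markers[j] for j in minimal_idx]
    pd.DataFrame({"marker": minimal_markers}).to_csv(
        out_dir / "minimal_set.tsv", sep="\t", index=False
    )

    hel_min = hel.values[:, minimal_idx]
    model_min = fit_dapc(hel_min, site_labels)
    min_accuracy = assignment_accuracy(model_min, hel_min, site_labels)
    scores = pd.DataFrame(
        model_min.scores,
        index=data.individuals,
        columns=[f"DA{a + 1}" for a in range(model_min.n_axes)],
    )
    scores.index.name = "individual"
    scores.to_csv(out_dir / "minimal_set_scores.tsv", sep="\t")

    clustering = sites.cluster_sites(model_min)
    with open(out_dir / "site_tree.nwk", "w") as fh:
        fh.write(sites.to_newick(clustering.linkage, clustering.sites))
    pd.DataFrame(
        {"k": clustering.k_candidates, "correlation": clustering.correlations}
    ).to_csv(out_dir / "partition_correlations.tsv", sep="\t", index=False)
    cluster_of_site = dict(zip(clustering.sites, clustering.labels))
    pd.DataFrame(
        {"site": clustering.sites, "cluster": clustering.labels}
    ).to_csv(out_dir / "site_clusters.tsv", sep="\t", index=False)

    unit_labels = np.asarray([cluster_of_site[s] for s in site_labels])
    if config.indval_unit == "site":
        site_rpm = np.vstack(
            [rpm.values[site_labels == s].mean(axis=0) for s in clustering.sites]
        )
        site_rpm = RpmMatrix(list(clustering.sites), list(rpm.markers), site_rpm)
        counts, _ = _indval_stage(
            site_rpm, clustering.labels, minimal_idx, out_dir, "cluster"
        )
    else:
        counts, _ = _indval_stage(rpm, unit_labels, minimal_idx, out_dir, "cluster")

    ccwgg_share = float(np.mean([data.motif[j] == "CCWGG" for j in minimal_idx]))
    summary = {
        "n_individuals": len(data.individuals),
        "n_markers": len(data.markers),
        "n_sites": meta.n_sites,
        "full_model_accuracy": full_accuracy,
        "n_significant_axes": sig.n_significant,
        "n_significant_markers": ranking.n_significant,
        "minimal_set_size": len(minimal_idx),
        "first_breakpoint": seg.first_breakpoint if seg else None,
        "minimal_set_accuracy": min_accuracy,
        "ccwgg_share_minimal_set": ccwgg_share,
        "selected_k": clustering.selected_k,
        "characteristic_counts": counts,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def run_denovo_analysis(
    data: MethylRadCounts,
    meta: SampleMetadata,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """De novo workflow: K-means/BIC grouping on retained PCs -> DAPC on the
    inferred groups -> marker ranking -> minimal set -> IndVal/Jenks per de
    novo group -> per-site group composition."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.dump(out_dir / "resolved_config.yaml")
    site_labels = meta.sites_of(data.individuals)

    rpm, hel = _prepare(data)
    # K-means runs on all PCs: no information is lost, and the per-split WSS
    # gain from chopping noise then stays below the BIC penalty
    from .transforms import center_columns
    from .dapc import fit_pca

    centered, _, zero_var = center_columns(hel.values)
    Xc = centered[:, ~zero_var]
    n_pcs = min(Xc.shape[0] - 1, Xc.shape[1])
    pca = fit_pca(Xc, n_pcs)
    pc_scores = Xc @ pca.loadings

    lo, hi = config.kmeans_k_range
    grouping = denovo.kmeans_bic(
        pc_scores,
        k_range=range(lo, hi + 1),
        n_starts=config.kmeans_n_starts,
        seed=config.seed,
        eigenvalues=pca.eigenvalues,
    )
    pd.DataFrame({"k": grouping.k_candidates, "bic": grouping.bic}).to_csv(
        out_dir / "bic.tsv", sep="\t", index=False
    )
    groups_df = pd.DataFrame(
        {"individual": data.individuals, "group": grouping.labels, "site": site_labels}
    )
    groups_df.to_csv(out_dir / "denovo_groups.tsv", sep="\t", index=False)
    composition = (
        groups_df.groupby(["site", "group"]).size().unstack(fill_value=0)
    )
    composition.to_csv(out_dir / "group_composition.tsv", sep="\t")

    if grouping.selected_k < 2:
        logger.warning("BIC selects a single group; no discriminant structure")
        summary = {
            "selected_k": 1,
            "scree_dimension": grouping.scree_dimension,
            "denovo_accuracy": None,
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return summary

    model, n_report = denovo.denovo_dapc(hel, grouping)
    accuracy = assignment_accuracy(model, hel, grouping.labels)

    ranking = marker_sel.mahalanobis_ranking(model, axes=config.axes, alpha=config.alpha)
    _write_ranking(ranking, data.markers, out_dir / "marker_ranking.tsv")
    grid = marker_sel.default_grid(
        ranking.n_significant, config.grid_min_step, config.grid_target_points
    )
    curve = marker_sel.accuracy_curve(hel, grouping.labels, ranking, grid)
    pd.DataFrame({"n_markers": curve.sizes, "accuracy": curve.accuracy}).to_csv(
        out_dir / "accuracy_curve.tsv", sep="\t", index=False
    )
    seg, minimal_idx = _minimal_set_or_fallback(curve, ranking, config)
    minimal_markers = [data.markers[j] for j in minimal_idx]
    pd.DataFrame({"marker": minimal_markers}).to_csv(
        out_dir / "minimal_set.tsv", sep="\t", index=False
    )
    hel_min = hel.values[:, minimal_idx]
    model_min = fit_dapc(hel_min, grouping.labels)
    min_accuracy = assignment_accuracy(model_min, hel_min, grouping.labels)

    counts, _ = _indval_stage(rpm, grouping.labels, minimal_idx, out_dir, "denovo")

    ccwgg_share = float(np.mean([data.motif[j] == "CCWGG" for j in minimal_idx]))
    summary = {
        "selected_k": grouping.selected_k,
        "scree_dimension": grouping.scree_dimension,
        "n_reported_das": n_report,
        "denovo_accuracy": accuracy,
        "n_significant_markers": ranking.n_significant,
        "minimal_set_size": len(minimal_idx),
        "minimal_set_accuracy": min_accuracy,
        "ccwgg_share_minimal_set": ccwgg_share,
        "characteristic_counts": counts,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def run_enrichment(
    data: MethylRadCounts,
    characteristic: dict[str, list[str]],
    annotation: annotate.GeneAnnotation,
    term_map: dict[str, set[str]],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Per group of characteristic markers: assign genes then Fisher
    enrichment; one result table per group.  ``characteristic`` maps group
    name -> marker IDs.  Markers without coordinates are excluded (count
    logged)."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data.coords is None:
        raise ValueError("marker coordinates are required for enrichment")

    all_markers = sorted({m for lst in characteristic.values() for m in lst})
    with_coords = {m: data.coords[m] for m in all_markers if m in data.coords}
    n_skipped = len(all_markers) - len(with_coords)
    if n_skipped:
        logger.info("%d markers without coordinates excluded", n_skipped)
    assignment = annotate.assign_genes(with_coords, annotation, window=config.gene_window)
    assignment.to_csv(out_dir / "gene_assignment.tsv", sep="\t", index=False)
    gene_of = dict(zip(assignment["marker"], assignment["gene"]))

    summary: dict = {"n_markers_without_coords": n_skipped, "groups": {}}
    for group, mks in characteristic.items():
        study = {gene_of[m] for m in mks if gene_of.get(m)}
        result = annotate.fisher_enrichment(
            study, term_map, alpha=config.alpha, min_genes=config.min_term_genes
        )
        result.to_csv(out_dir / f"enrichment_{group}.tsv", sep="\t", index=False)
        summary["groups"][str(group)] = {
            "n_study_genes": len(study),
            "n_enriched_terms": int(result["enriched"].sum()) if len(result) else 0,
        }
    with open(out_dir / "enrichment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
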