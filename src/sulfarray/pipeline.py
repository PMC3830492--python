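"""End-to-end orchestration: simulate → normalize → select → enrich → cluster.

Every stage reads its inputs from, and writes its outputs to, tab-delimited
files in the run's output directory, so the monolithic :func:`run_full` and
the per-stage CLI subcommands produce byte-identical results.  A flat
key=value manifest records the configuration hash, the seed and the counts
at every stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrayio, cluster, enrichment, normalize, selection, simulate

__all__ = ["RunConfig", "StageError", "run_full"]

log = logging.getLogger("sulfarray")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one run needs, loadable from a YAML file."""

    outdir: str = "sulfarray_run"
    seed: int = 0
    #: simulation block; None → read external data via the paths below
    simulation: dict | None = field(default_factory=dict)
    design: str | None = None
    go_annotations: str | None = None
    gene_annotations: str | None = None
    lowess_span: float = 0.3
    curve: dict = field(default_factory=dict)  # SelectionCurve overrides
    regulation_cutoff: float = 0.5
    crossline_scale: str = "median"
    qc_tolerance: float = 1.5
    min_entries: int = 5
    enrichment_alpha: float = 0.01
    continuity_correction: bool = False
    cluster_metric: str = "correlation"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def selection_curve(self) -> selection.SelectionCurve:
        kwargs = dict(self.curve)
        if "coeffs" in kwargs:
            kwargs["coeffs"] = tuple(kwargs["coeffs"])
        return selection.SelectionCurve(**kwargs)

    def simulation_config(self) -> simulate.SimulationConfig:
        block = dict(self.simulation or {})
        block.setdefault("seed", self.seed)
        return simulate.config_from_dict(block)


# ---------------------------------------------------------------- stages


def stage_simulate(config: RunConfig, outdir: Path) -> Path:
    """Generate a synthetic experiment under ``outdir/data``."""
    sim = config.simulation_config()
    exp = simulate.generate_experiment(sim)
    datadir = simulate.write_experiment(exp, outdir / "data")
    log.info("simulated %d genes × %d arrays", sim.n_genes, len(exp.arrays))
    return datadir / "design.tsv"


def stage_normalize(design_path: Path, span: float, out_path: Path) -> pd.DataFrame:
    """Normalize all hybridization sets and write per-gene statistics."""
    sets, _ = arrayio.read_experiment(design_path)
    stats = pd.concat(
        [normalize.summarize_genes(h, span) for h in sets.values()],
        ignore_index=True,
    )
    arrayio.write_tsv(stats, out_path)
    return stats


def _two_lines(stats: pd.DataFrame) -> list[str]:
    lines = sorted(set(stats["line"]))
    if len(lines) != 2:
        raise StageError(
            "select", f"selection stage needs exactly 2 lines, found {lines}"
        )
    return lines


def stage_select(
    stats_path: Path,
    design_path: Path | None,
    config: RunConfig,
    outdir: Path,
) -> dict:
    """Reliability filter, regulation calls, Venn partition, cross-line
    ratios and median QC.  Returns stage counts for the manifest."""
    stats = pd.read_csv(stats_path, sep="\t", dtype={"gene_id": str})
    curve = config.selection_curve()
    # order lines so the wild type (if present) is line 1, as in the figures
    lines = _two_lines(stats)
    if "WT" in lines:
        lines = ["WT"] + [l for l in lines if l != "WT"]
    s1 = stats[stats["line"] == lines[0]].reset_index(drop=True)
    s2 = stats[stats["line"] == lines[1]].reset_index(drop=True)
    reliable = selection.reliable_intersection(s1, s2, curve)
    calls1 = selection.classify_regulation(s1, reliable, config.regulation_cutoff)
    calls2 = selection.classify_regulation(s2, reliable, config.regulation_cutoff)
    venn = selection.venn_partition(calls1, calls2)

    sel = stats.copy()
    sel["pass_filter"] = selection.passes_filter(
        sel["p_value"], sel["mean_log2_ratio"], curve
    )
    sel["reliable"] = sel["gene_id"].isin(reliable)
    callmap = pd.concat([calls1, calls2]).set_index(["gene_id", "line"])["call"]
    sel["call"] = [
        callmap.get((g, l), "unchanged")
        for g, l in zip(sel["gene_id"], sel["line"])
    ]
    arrayio.write_tsv(sel, outdir / "selection.tsv")
    arrayio.write_tsv(venn.summary(), outdir / "venn_summary.tsv")

    counts = {
        "reliable_genes": len(reliable),
        f"up_{lines[0]}": len(venn.direction_sets("up", lines[0])),
        f"up_{lines[1]}": len(venn.direction_sets("up", lines[1])),
        f"down_{lines[0]}": len(venn.direction_sets("down", lines[0])),
        f"down_{lines[1]}": len(venn.direction_sets("down", lines[1])),
        "up_common": len(venn.up_common),
        "down_common": len(venn.down_common),
        "opposite_direction": len(venn.opposite),
        "go_input_union": len(venn.union),
    }

    if design_path is not None:
        sets, _ = arrayio.read_experiment(design_path)
        h1 = next(h for h in sets.values() if h.line == lines[0])
        h2 = next(h for h in sets.values() if h.line == lines[1])
        ratios = pd.concat(
            [
                selection.cross_line_ratios(h1, h2, cond, config.crossline_scale)
                for cond in (h1.test_condition, h1.ref_condition)
            ],
            ignore_index=True,
        )
        arrayio.write_tsv(ratios, outdir / "cross_line_ratios.tsv")
        qc_table, qc_report = selection.median_stability_qc(
            list(sets.values()), config.qc_tolerance
        )
        arrayio.write_tsv(qc_table, outdir / "qc_median_sums.tsv")
        counts["qc_median_sum_ratio"] = round(qc_report["max_min_ratio"], 6)
        counts["qc_passed"] = int(qc_report["passed"])
    return counts


def _gene_sets_from_selection(sel: pd.DataFrame) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in sorted(set(sel["line"])):
        for direction in ("up", "down"):
            mask = (sel["line"] == line) & (sel["call"] == direction)
            sets[f"{direction}_{line}"] = set(sel.loc[mask, "gene_id"])
    sets["union"] = set().union(*sets.values()) if sets else set()
    return sets


def stage_enrich(
    selection_path: Path, annotation_path: Path, config: RunConfig, outdir: Path
) -> dict:
    """SEA on every regulated gene set against the array background."""
    sel = pd.read_csv(selection_path, sep="\t", dtype={"gene_id": str})
    annotation = arrayio.read_go_annotations(annotation_path)
    background = set(sel["gene_id"])
    gene_sets = _gene_sets_from_selection(sel)
    frames = []
    counts: dict[str, int | str] = {}
    for name, genes in gene_sets.items():
        if not genes:
            log.info("enrichment: set %s empty, skipped", name)
            counts[f"enrichment_skipped_{name}"] = "empty"
            continue
        res = enrichment.run_sea(
            genes,
            annotation,
            background,
            config.min_entries,
            config.enrichment_alpha,
            config.continuity_correction,
        )
        res.insert(0, "gene_set", name)
        frames.append(res)
        counts[f"significant_terms_{name}"] = int(res["significant"].sum())
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene_set", "term_id"])
    )
    arrayio.write_tsv(out, outdir / "enrichment.tsv")
    return counts


def _build_profiles(
    sel: pd.DataFrame,
    ratios: pd.DataFrame | None,
    gene_ann: pd.DataFrame | None,
) -> pd.DataFrame:
    """Profile table of the regulated, annotated genes: one ratio column per
    line plus the cross-line ratio columns when available."""
    regulated = set(sel.loc[sel["call"] != "unchanged", "gene_id"])
    lines = sorted(set(sel["line"]))
    prof = None
    for line in lines:
        sub = sel[(sel["line"] == line) & (sel["gene_id"].isin(regulated))]
        col = sub.set_index("gene_id")["mean_log2_ratio"].rename(f"ratio_{line}")
        prof = col.to_frame() if prof is None else prof.join(col, how="outer")
    if ratios is not None:
        for cond, grp in ratios.groupby("condition", sort=True):
            col = grp.set_index("gene_id")["log2_ratio"].rename(f"crossline_{cond}")
            prof = prof.join(col, how="left")
    prof = prof.reset_index().rename(columns={"index": "gene_id"})
    if gene_ann is not None:
        ann = gene_ann.fillna("")
        extra_cols = [c for c in ann.columns if c != "gene_id"]
        annotated = ann[(ann[extra_cols] != "").any(axis=1)]["gene_id"]
        prof = prof[prof["gene_id"].isin(set(annotated))].reset_index(drop=True)
    return prof


def stage_cluster(
    selection_path: Path,
    ratios_path: Path | None,
    gene_annotation_path: Path | None,
    config: RunConfig,
    outdir: Path,
) -> dict:
    """Cluster regulated annotated genes; write CDT/GTR and leaf order."""
    sel = pd.read_csv(selection_path, sep="\t", dtype={"gene_id": str})
    ratios = (
        pd.read_csv(ratios_path, sep="\t", dtype={"gene_id": str})
        if ratios_path is not None and Path(ratios_path).exists()
        else None
    )
    gene_ann = (
        arrayio.read_gene_annotations(gene_annotation_path)
        if gene_annotation_path is not None and Path(gene_annotation_path).exists()
        else None
    )
    profiles = _build_profiles(sel, ratios, gene_ann)
    if len(profiles) < 2:
        log.info("clustering skipped: %d eligible genes", len(profiles))
        return {"clustered_genes": 0, "clustering_skipped": "fewer than 2 genes"}
    arrayio.write_tsv(profiles, outdir / "profiles.tsv")
    D, profiles = cluster.distance_matrix(profiles, config.cluster_metric)
    tree = cluster.average_linkage(D)
    order = cluster.order_leaves(tree, profiles)
    arrayio.write_cdt_gtr(
        profiles, tree, order, outdir / "clustered.cdt", outdir / "clustered.gtr"
    )
    leaf_table = pd.DataFrame(
        {
            "position": range(len(order)),
            "gene_id": profiles["gene_id"].iloc[order].to_numpy(),
        }
    )
    arrayio.write_tsv(leaf_table, outdir / "leaf_order.tsv")
    return {"clustered_genes": len(profiles)}


# ---------------------------------------------------------------- run_full


def _write_manifest(outdir: Path, entries: dict) -> None:
    with open(outdir / "run_manifest.txt", "w") as fh:
        for k in sorted(entries):
            fh.write(f"{k}={entries[k]}\n")


def run_full(config: RunConfig) -> dict:
    """Run every stage in sequence; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(fh)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    try:
        try:
            if config.simulation is not None:
                design_path = stage_simulate(config, outdir)
                go_path = design_path.parent / "go_annotations.tsv"
                gene_ann_path = design_path.parent / "gene_annotations.tsv"
            else:
                if config.design is None:
                    raise StageError("simulate", "no simulation block and no design path")
                design_path = Path(config.design)
                go_path = Path(config.go_annotations) if config.go_annotations else None
                gene_ann_path = (
                    Path(config.gene_annotations) if config.gene_annotations else None
                )
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", str(e)) from e

        try:
            stats = stage_normalize(
                design_path, config.lowess_span, outdir / "gene_stats.tsv"
            )
            manifest["genes_with_stats"] = stats["gene_id"].nunique()
        except Exception as e:  # noqa: BLE001
            raise StageError("normalize", str(e)) from e

        try:
            manifest.update(
                stage_select(outdir / "gene_stats.tsv", design_path, config, outdir)
            )
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("select", str(e)) from e

        try:
            if go_path is not None:
                manifest.update(
                    stage_enrich(outdir / "selection.tsv", go_path, config, outdir)
                )
        except Exception as e:  # noqa: BLE001
            raise StageError("enrich", str(e)) from e

        try:
            ratios_path = outdir / "cross_line_ratios.tsv"
            manifest.update(
                stage_cluster(
                    outdir / "selection.tsv",
                    ratios_path if ratios_path.exists() else None,
                    gene_ann_path,
                    config,
                    outdir,
                )
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("cluster", str(e)) from e
    finally:
        log.removeHandler(fh)
        fh.close()
    _write_manifest(outdir, manifest)
    return manifest
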