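"""Synthetic two-colour microarray experiments with known ground truth.

Emulates a two-line, one-contrast-per-line dye-swap design: each plant line
(wild type and an antisense line) is hybridized sulphur-deficient (-S)
against sulphur-sufficient (nS) on quadruplicate arrays with the dye
orientation swapped between duplicates.  Channel intensities follow a
log-normal abundance model with multiplicative condition effects,
per-channel replicate noise and a polynomial intensity-dependent dye bias
— the MA-plane curvature that Lowess normalization is meant to remove.

Every generated experiment carries a ground-truth table (per-gene regulation
state per line, per-GO-term planted enrichment flag) so that each downstream
stage of the pipeline can be scored against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "Experiment",
    "ConfigurationError",
    "generate_experiment",
    "inject_dye_bias",
    "generate_go_annotations",
    "write_experiment",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-colour experiment.

    Defaults describe the desk-scale reference design: 1,000 genes, two
    lines with quadruplicate dye-swapped hybridizations of -S against nS,
    5% truly up- and 5% truly down-regulated genes per line at one
    log2 unit, per-channel noise 0.1 log2 units, and a linear
    intensity-dependent dye bias of 0.3 + 0.05*A added to M.
    """

    n_genes: int = 1000
    n_features_per_gene: int = 1
    lines: tuple[str, ...] = ("WT", "AB3")
    test_condition: str = "-S"
    ref_condition: str = "nS"
    replicates_per_contrast: int = 4
    dye_swap_pattern: tuple[str, ...] = ("fwd", "fwd", "rev", "rev")
    frac_up: float = 0.05
    frac_down: float = 0.05
    #: fraction of each line's regulated genes shared with the other lines
    shared_fraction: float = 0.5
    effect_size_log2: float = 1.0
    base_intensity_log2_mean: float = 10.0
    base_intensity_log2_sd: float = 1.5
    noise_sd_log2: float = 0.1
    #: ascending polynomial coefficients; bias added to M as poly(A)
    dye_bias_coeffs: tuple[float, ...] = (0.3, 0.05)
    n_go_terms: int = 50
    genes_per_term_mean: float = 30.0
    #: (term_id, set selector "up|down|regulated[:line]", enrichment odds)
    planted_enriched_terms: tuple[tuple[str, str, float], ...] = (
        ("T0001", "up:WT", 10.0),
    )
    frac_annotated: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_features_per_gene <= 0:
            raise ConfigurationError("gene and probe counts must be positive")
        if self.replicates_per_contrast <= 0:
            raise ConfigurationError("replicates_per_contrast must be positive")
        if len(self.dye_swap_pattern) != self.replicates_per_contrast:
            raise ConfigurationError(
                "dye_swap_pattern length must equal replicates_per_contrast"
            )
        if any(o not in ("fwd", "rev") for o in self.dye_swap_pattern):
            raise ConfigurationError("dye orientations must be 'fwd' or 'rev'")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ConfigurationError("regulated fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ConfigurationError("frac_up + frac_down must not exceed 1")
        if not 0 <= self.shared_fraction <= 1:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if not 0 <= self.frac_annotated <= 1:
            raise ConfigurationError("frac_annotated must lie in [0, 1]")
        if len(self.lines) < 1:
            raise ConfigurationError("at least one line required")
        if self.n_go_terms < 0 or self.genes_per_term_mean <= 0:
            raise ConfigurationError("GO term counts must be positive")
        if self.noise_sd_log2 < 0 or self.base_intensity_log2_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")

    @property
    def contrast(self) -> str:
        return f"{self.test_condition}_vs_{self.ref_condition}"


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``genes``: one row per (gene, line) with ``true_state`` in
    {up, down, unchanged} and ``true_log2fc`` (zero iff unchanged).
    ``terms``: one row per GO term with its ``planted_enriched`` flag.
    """

    genes: pd.DataFrame
    terms: pd.DataFrame

    def regulated_set(self, selector: str) -> set[str]:
        """Resolve a set selector like ``"up:WT"``, ``"down"`` or
        ``"regulated:AB3"`` to a set of gene ids (no line → union of lines)."""
        direction, _, line = selector.partition(":")
        if direction not in ("up", "down", "regulated"):
            raise ConfigurationError(f"unknown set selector {selector!r}")
        g = self.genes
        if line:
            if line not in set(g["line"]):
                raise ConfigurationError(f"unknown line in selector {selector!r}")
            g = g[g["line"] == line]
        if direction == "regulated":
            g = g[g["true_state"] != "unchanged"]
        else:
            g = g[g["true_state"] == direction]
        return set(g["gene_id"])


@dataclass
class Experiment:
    """In-memory simulated experiment: raw array tables plus metadata."""

    arrays: dict[str, pd.DataFrame]
    design: pd.DataFrame
    go_annotations: pd.DataFrame
    gene_annotations: pd.DataFrame
    truth: TruthTable
    config: SimulationConfig


def inject_dye_bias(M, A, coeffs):
    """Add an intensity-dependent bias to the log ratio.

    Returns ``M + sum_k coeffs[k] * A**k`` (coefficients in ascending
    order of power).  Vectorized over M and A.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    bias = np.zeros_like(A)
    for k, c in enumerate(coeffs):
        bias = bias + c * A**k
    return M + bias


def _assign_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthTable:
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    n_up = int(round(config.frac_up * config.n_genes))
    n_down = int(round(config.frac_down * config.n_genes))
    n_up_shared = int(round(config.shared_fraction * n_up))
    n_down_shared = int(round(config.shared_fraction * n_down))

    rows: list[tuple[str, str, str, float]] = []
    perm = rng.permutation(config.n_genes)
    # shared regulated genes drawn once from the front of the permutation
    up_shared = [genes[i] for i in perm[:n_up_shared]]
    down_shared = [genes[i] for i in perm[n_up_shared : n_up_shared + n_down_shared]]
    cursor = n_up_shared + n_down_shared
    for _line in config.lines:
        k_up = n_up - n_up_shared
        k_down = n_down - n_down_shared
        own_up = [genes[i] for i in perm[cursor : cursor + k_up]]
        cursor += k_up
        own_down = [genes[i] for i in perm[cursor : cursor + k_down]]
        cursor += k_down
        up = set(up_shared) | set(own_up)
        down = set(down_shared) | set(own_down)
        for g in genes:
            if g in up:
                rows.append((g, _line, "up", config.effect_size_log2))
            elif g in down:
                rows.append((g, _line, "down", -config.effect_size_log2))
            else:
                rows.append((g, _line, "unchanged", 0.0))
    gene_truth = pd.DataFrame(
        rows, columns=["gene_id", "line", "true_state", "true_log2fc"]
    )
    terms = pd.DataFrame(
        {
            "term_id": [f"T{i:04d}" for i in range(1, config.n_go_terms + 1)],
        }
    )
    planted = {t for t, _sel, _odds in config.planted_enriched_terms}
    terms["planted_enriched"] = terms["term_id"].isin(planted)
    return TruthTable(genes=gene_truth, terms=terms)


def generate_go_annotations(
    config: SimulationConfig, truth: TruthTable, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a gene→term annotation table with optional planted enrichment.

    Background terms annotate genes independently of regulation with
    probability ``genes_per_term_mean / n_genes``; a planted term multiplies
    the membership *odds* of genes in its target regulated set by the
    configured factor.
    """
    genes = sorted(set(truth.genes["gene_id"]))
    n = len(genes)
    p0 = min(1.0, config.genes_per_term_mean / n)
    planted = {t: (sel, odds) for t, sel, odds in config.planted_enriched_terms}
    for term in planted:
        if term not in set(truth.terms["term_id"]):
            raise ConfigurationError(f"planted term {term!r} not in term universe")
    gene_rows: list[tuple[str, str]] = []
    for term in truth.terms["term_id"]:
        prob = np.full(n, p0)
        if term in planted:
            sel, odds = planted[term]
            target = truth.regulated_set(sel)
            unknown = target - set(genes)
            if unknown:
                raise ConfigurationError(
                    f"planted term {term} references unknown genes: {sorted(unknown)[:3]}"
                )
            if p0 < 1.0:
                o = odds * p0 / (1.0 - p0)
                p1 = o / (1.0 + o)
            else:
                p1 = 1.0
            mask = np.fromiter((g in target for g in genes), bool, count=n)
            prob[mask] = p1
        hit = rng.random(n) < prob
        gene_rows.extend((genes[i], term) for i in np.flatnonzero(hit))
    return pd.DataFrame(gene_rows, columns=["gene_id", "term_id"])


def _generate_gene_annotations(
    config: SimulationConfig, genes: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Descriptions / model-species homologues for a configured fraction of
    genes; downstream clustering is restricted to annotated genes."""
    annotated = rng.random(len(genes)) < config.frac_annotated
    desc = [
        f"hypothetical protein {g}" if a else "" for g, a in zip(genes, annotated)
    ]
    homolog = [
        f"AT{1 + (i % 5)}G{10000 + i * 10:05d}" if a else ""
        for i, a in enumerate(annotated)
    ]
    return pd.DataFrame(
        {"gene_id": genes, "description": desc, "arabidopsis_homolog": homolog}
    )


def generate_experiment(config: SimulationConfig) -> Experiment:
    """Simulate one complete experiment.

    Returns raw per-array feature tables (one per line × replicate), the
    design table, GO and gene annotation tables and the ground truth.  On
    forward arrays the test condition (-S) is in channel A and the reference
    (nS) in channel B; dye-swapped arrays are reversed.  Identical config
    (including seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _assign_truth(config, rng)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    # per-gene baseline abundance (log2), shared by all arrays and lines
    base = rng.normal(
        config.base_intensity_log2_mean,
        config.base_intensity_log2_sd,
        config.n_genes,
    )
    lfc = {
        line: (
            truth.genes.query("line == @line")
            .set_index("gene_id")["true_log2fc"]
            .reindex(genes)
            .to_numpy()
        )
        for line in config.lines
    }

    n_feat = config.n_genes * config.n_features_per_gene
    feature_ids = [
        f"{g}_p{j}" for g in genes for j in range(1, config.n_features_per_gene + 1)
    ]
    gene_col = np.repeat(genes, config.n_features_per_gene)
    base_feat = np.repeat(base, config.n_features_per_gene)

    arrays: dict[str, pd.DataFrame] = {}
    design_rows = []
    for line in config.lines:
        lfc_feat = np.repeat(lfc[line], config.n_features_per_gene)
        for r, orient in enumerate(config.dye_swap_pattern, start=1):
            array_id = f"{line}_r{r}"
            noise_t = rng.normal(0.0, config.noise_sd_log2, n_feat)
            noise_r = rng.normal(0.0, config.noise_sd_log2, n_feat)
            log_test = base_feat + lfc_feat + noise_t
            log_ref = base_feat + noise_r
            if orient == "fwd":
                log_a, log_b = log_test, log_ref
            else:
                log_a, log_b = log_ref, log_test
            # dye bias acts in dye (channel) coordinates: split symmetrically
            # so that A is unchanged and M gains poly(A)
            A = 0.5 * (log_a + log_b)
            bias = inject_dye_bias(np.zeros(n_feat), A, config.dye_bias_coeffs)
            log_a = log_a + 0.5 * bias
            log_b = log_b - 0.5 * bias
            arrays[array_id] = pd.DataFrame(
                {
                    "feature_id": feature_ids,
                    "gene_id": gene_col,
                    "ch_a_median": np.exp2(log_a),
                    "ch_b_median": np.exp2(log_b),
                    "flag": 0,
                }
            )
            design_rows.append(
                (array_id, line, config.contrast, orient, f"{array_id}.tsv")
            )
    design = pd.DataFrame(
        design_rows,
        columns=["array_id", "line", "contrast", "dye_orientation", "file_path"],
    )
    go = generate_go_annotations(config, truth, rng)
    gene_ann = _generate_gene_annotations(config, genes, rng)
    return Experiment(
        arrays=arrays,
        design=design,
        go_annotations=go,
        gene_annotations=gene_ann,
        truth=truth,
        config=config,
    )


def write_experiment(exp: Experiment, outdir: str | Path) -> Path:
    """Write an experiment to disk in the pipeline's input formats.

    One tab-delimited GPR-like table per array, a design table referencing
    them, GO and gene annotation tables and the two truth tables.  Output is
    byte-identical for identical experiments.
    """
    from . import arrayio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for array_id, df in exp.arrays.items():
        arrayio.write_array_table(df, outdir / f"{array_id}.tsv")
    arrayio.write_tsv(exp.design, outdir / "design.tsv")
    arrayio.write_tsv(exp.go_annotations, outdir / "go_annotations.tsv")
    arrayio.write_tsv(exp.gene_annotations, outdir / "gene_annotations.tsv")
    arrayio.write_tsv(exp.truth.genes, outdir / "truth_genes.tsv")
    arrayio.write_tsv(exp.truth.terms, outdir / "truth_terms.tsv")
    return outdir


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (e.g. YAML),
    coercing list-valued fields to tuples."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation options: {sorted(unknown)}")
    coerced = {}
    for k, v in d.items():
        if k == "planted_enriched_terms":
            v = tuple((str(t), str(s), float(o)) for t, s, o in v)
        elif isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return SimulationConfig(**coerced)
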