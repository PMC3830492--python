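"""Reliability selection, regulation calling, Venn partitioning and
cross-line raw-channel ratios.

The reliability filter keeps a gene when its replicate p-value satisfies
``p < 0.05`` OR ``p <= poly(x)`` where poly is a fixed quintic and
``x = 20*log2ratio + 1``.  Near zero fold change the polynomial ceiling is
lenient (~0.99), so unregulated genes with reproducible (low-variance)
ratios are retained alongside significantly regulated ones; it tightens
rapidly and clamps to 0 beyond |log2ratio| ≈ 0.4.  Genes passing in both
plant lines form the reliable intersection on which regulation is called at
|log2 ratio| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrayio import HybridizationSet

__all__ = [
    "SelectionCurve",
    "VennPartition",
    "selection_threshold",
    "passes_filter",
    "reliable_intersection",
    "classify_regulation",
    "venn_partition",
    "cross_line_ratios",
    "median_stability_qc",
]

#: quintic coefficients, highest power first (c5..c0)
DEFAULT_COEFFS = (-0.001, 0.0178, -0.1032, 0.2008, -0.2022, 1.0771)


@dataclass(frozen=True)
class SelectionCurve:
    """Fold-change-dependent p-value ceiling.

    ``threshold(r) = clamp(poly(a*|r| + b))`` with the quintic evaluated at
    the transformed log2 ratio.  ``x_transform`` chooses between the
    absolute value (default; symmetric in up/down regulation) and the raw
    signed ratio; ``clamp`` restricts the ceiling to the valid p range.
    """

    alpha: float = 0.05
    coeffs: tuple[float, ...] = DEFAULT_COEFFS
    scale: float = 20.0
    offset: float = 1.0
    x_transform: str = "absolute"
    clamp: bool = True

    def __post_init__(self):
        if self.x_transform not in ("absolute", "signed"):
            raise ValueError(f"unknown x_transform {self.x_transform!r}")


def selection_threshold(log2_ratio, curve: SelectionCurve = SelectionCurve()):
    """Evaluate the p-value ceiling at the given log2 ratio(s)."""
    r = np.asarray(log2_ratio, dtype=float)
    t = np.abs(r) if curve.x_transform == "absolute" else r
    x = curve.scale * t + curve.offset
    val = np.polyval(curve.coeffs, x)
    if curve.clamp:
        val = np.clip(val, 0.0, 1.0)
    return val if val.ndim else float(val)


def passes_filter(p_value, log2_ratio, curve: SelectionCurve = SelectionCurve()):
    """The printed disjunction: ``p < alpha`` OR ``p <= threshold(ratio)``.

    NaN p-values never pass.  Vectorized over both arguments.
    """
    p = np.asarray(p_value, dtype=float)
    thr = np.asarray(selection_threshold(log2_ratio, curve), dtype=float)
    ok = (p < curve.alpha) | (p <= thr)
    ok = ok & ~np.isnan(p)
    return ok if ok.ndim else bool(ok)


def reliable_intersection(
    stats_line1: pd.DataFrame,
    stats_line2: pd.DataFrame,
    curve: SelectionCurve = SelectionCurve(),
) -> pd.Index:
    """Genes passing the reliability filter in BOTH lines.

    Both per-gene statistics tables must cover the same gene universe
    (up to genes dropped for missing replicates).
    """
    s1 = stats_line1.set_index("gene_id")
    s2 = stats_line2.set_index("gene_id")
    common = s1.index.intersection(s2.index)
    if len(common) == 0:
        raise ValueError("gene universes of the two lines are disjoint")
    p1 = passes_filter(
        s1.loc[common, "p_value"], s1.loc[common, "mean_log2_ratio"], curve
    )
    p2 = passes_filter(
        s2.loc[common, "p_value"], s2.loc[common, "mean_log2_ratio"], curve
    )
    return common[np.asarray(p1) & np.asarray(p2)]


def classify_regulation(
    stats: pd.DataFrame, reliable: pd.Index | None = None, cutoff: float = 0.5
) -> pd.DataFrame:
    """Call regulation from the mean log2 ratio: up if > cutoff, down if
    < −cutoff (strict), else unchanged.  Optionally restricted to the
    reliable gene set."""
    df = stats if reliable is None else stats[stats["gene_id"].isin(reliable)]
    r = df["mean_log2_ratio"].to_numpy(float)
    call = np.where(r > cutoff, "up", np.where(r < -cutoff, "down", "unchanged"))
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "line": df["line"].to_numpy(),
            "call": call,
            "mean_log2_ratio": r,
        }
    )


@dataclass
class VennPartition:
    """Two-line partition of regulated genes, per direction.

    For each direction the three sets are pairwise disjoint; genes called
    up in one line and down in the other appear in both directions'
    line-only sets and are reported separately in ``opposite``.
    """

    line1: str
    line2: str
    up_common: set[str] = field(default_factory=set)
    up_line1_only: set[str] = field(default_factory=set)
    up_line2_only: set[str] = field(default_factory=set)
    down_common: set[str] = field(default_factory=set)
    down_line1_only: set[str] = field(default_factory=set)
    down_line2_only: set[str] = field(default_factory=set)
    opposite: set[str] = field(default_factory=set)

    @property
    def union(self) -> set[str]:
        """All regulated genes of either line in either direction — the
        input list for GO enrichment."""
        return (
            self.up_common
            | self.up_line1_only
            | self.up_line2_only
            | self.down_common
            | self.down_line1_only
            | self.down_line2_only
        )

    def direction_sets(self, direction: str, line: str) -> set[str]:
        """All genes called in ``direction`` in ``line`` (common + only)."""
        if direction == "up":
            only = self.up_line1_only if line == self.line1 else self.up_line2_only
            return self.up_common | only
        only = self.down_line1_only if line == self.line1 else self.down_line2_only
        return self.down_common | only

    def summary(self) -> pd.DataFrame:
        rows = [
            ("up_common", len(self.up_common)),
            (f"up_{self.line1}_only", len(self.up_line1_only)),
            (f"up_{self.line2}_only", len(self.up_line2_only)),
            ("down_common", len(self.down_common)),
            (f"down_{self.line1}_only", len(self.down_line1_only)),
            (f"down_{self.line2}_only", len(self.down_line2_only)),
            ("opposite_direction", len(self.opposite)),
            ("union", len(self.union)),
        ]
        return pd.DataFrame(rows, columns=["set", "n_genes"])


def venn_partition(calls_line1: pd.DataFrame, calls_line2: pd.DataFrame) -> VennPartition:
    """Partition regulation calls of two lines into common / line-only sets
    per direction, plus the regulated union."""
    l1 = calls_line1["line"].iloc[0] if len(calls_line1) else "line1"
    l2 = calls_line2["line"].iloc[0] if len(calls_line2) else "line2"
    up1 = set(calls_line1.loc[calls_line1["call"] == "up", "gene_id"])
    dn1 = set(calls_line1.loc[calls_line1["call"] == "down", "gene_id"])
    up2 = set(calls_line2.loc[calls_line2["call"] == "up", "gene_id"])
    dn2 = set(calls_line2.loc[calls_line2["call"] == "down", "gene_id"])
    return VennPartition(
        line1=l1,
        line2=l2,
        up_common=up1 & up2,
        up_line1_only=up1 - up2,
        up_line2_only=up2 - up1,
        down_common=dn1 & dn2,
        down_line1_only=dn1 - dn2,
        down_line2_only=dn2 - dn1,
        opposite=(up1 & dn2) | (dn1 & up2),
    )


def _condition_channel(hset: HybridizationSet, array, condition: str) -> str:
    """Which raw channel (a or b) of an array carries ``condition``."""
    test, ref = hset.test_condition, hset.ref_condition
    if condition not in (test, ref):
        raise ValueError(
            f"condition {condition!r} absent from contrast {hset.contrast!r}"
        )
    fwd = array.dye_orientation == "fwd"
    if condition == test:
        return "ch_a_median" if fwd else "ch_b_median"
    return "ch_b_median" if fwd else "ch_a_median"


def cross_line_ratios(
    hset_line1: HybridizationSet,
    hset_line2: HybridizationSet,
    condition: str,
    scale: str = "median",
) -> pd.DataFrame:
    """Between-line log2 ratios from raw single-channel fluorescence.

    For each gene, log2 of the mean intensity of the ``condition`` channel
    over line-2 arrays divided by the same over line-1 arrays.  With
    ``scale="median"`` (default) each array channel is first divided by its
    median, making arrays comparable at the price of absorbing genuine
    global shifts; ``scale="none"`` compares raw values, which is only
    meaningful when the median-stability QC passes.
    """
    if scale not in ("median", "none"):
        raise ValueError(f"unknown scale {scale!r}")

    def _per_gene(hset: HybridizationSet) -> pd.Series:
        cols = []
        for a in hset.arrays:
            ch = _condition_channel(hset, a, condition)
            vals = a.features.set_index("gene_id")[ch].astype(float)
            vals = vals.groupby(level=0).mean()  # probe → gene
            if scale == "median":
                vals = vals / np.median(vals.to_numpy())
            cols.append(vals)
        return pd.concat(cols, axis=1).mean(axis=1)

    m1 = _per_gene(hset_line1)
    m2 = _per_gene(hset_line2)
    common = m1.index.intersection(m2.index)
    ratio = np.log2(m2.loc[common].to_numpy() / m1.loc[common].to_numpy())
    return pd.DataFrame(
        {
            "gene_id": common.to_numpy(),
            "condition": condition,
            "log2_ratio": ratio,
        }
    )


def median_stability_qc(
    sets: list[HybridizationSet], tolerance: float = 1.5
) -> tuple[pd.DataFrame, dict]:
    """Stability of per-array fluorescence median sums.

    For each array the two channel medians are summed; the report gives the
    max/min ratio of these sums over all arrays and a pass flag at the
    given tolerance.  Cross-line raw-channel comparisons are only credible
    when this ratio is close to 1.
    """
    rows = []
    for hset in sets:
        for a in hset.arrays:
            ma = float(np.median(a.features["ch_a_median"].to_numpy(float)))
            mb = float(np.median(a.features["ch_b_median"].to_numpy(float)))
            rows.append((a.array_id, hset.line, ma, mb, ma + mb))
    table = pd.DataFrame(
        rows, columns=["array_id", "line", "median_ch_a", "median_ch_b", "median_sum"]
    )
    if len(table) < 2:
        raise ValueError("median stability QC needs at least 2 arrays")
    sums = table["median_sum"].to_numpy()
    ratio = float(sums.max() / sums.min())
    report = {
        "max_min_ratio": ratio,
        "tolerance": tolerance,
        "passed": bool(ratio <= tolerance),
    }
    return table, report
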