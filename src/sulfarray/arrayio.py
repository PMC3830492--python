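"""Reading and writing of array tables, design files, annotations and
Cluster-3.0-compatible outputs.

All text tables are tab-delimited with a header row.  Floating point numbers
are written with 6 significant digits so that write→read→write round trips
are bit-exact.  Array files are a simplified GenePix-like format with columns
``feature_id, gene_id, ch_a_median, ch_b_median, flag``; features with a
negative flag are excluded from every downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ArrayData",
    "HybridizationSet",
    "read_array_table",
    "write_array_table",
    "read_design",
    "read_go_annotations",
    "read_gmt",
    "read_gene_annotations",
    "read_experiment",
    "write_tsv",
    "write_cdt_gtr",
    "parse_gtr",
]

ARRAY_COLUMNS = ["feature_id", "gene_id", "ch_a_median", "ch_b_median", "flag"]
DESIGN_COLUMNS = ["array_id", "line", "contrast", "dye_orientation", "file_path"]

#: text-output float format (6 significant digits)
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class ArrayData:
    """One hybridization: identifier, dye orientation and its features."""

    array_id: str
    dye_orientation: str
    features: pd.DataFrame  # unflagged features only


@dataclass
class HybridizationSet:
    """Replicate arrays of one (line, contrast) cell of the design."""

    line: str
    contrast: str
    arrays: list[ArrayData]

    @property
    def test_condition(self) -> str:
        return _split_contrast(self.contrast)[0]

    @property
    def ref_condition(self) -> str:
        return _split_contrast(self.contrast)[1]


def _split_contrast(contrast: str) -> tuple[str, str]:
    if "_vs_" not in contrast:
        raise FormatError(
            f"contrast {contrast!r} must have the form '<test>_vs_<reference>'"
        )
    test, _, ref = contrast.partition("_vs_")
    return test, ref


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_array_table(path: str | Path) -> pd.DataFrame:
    """Read one array file; validates columns, uniqueness and positivity."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_id": str})
    _require_columns(df, ARRAY_COLUMNS, f"array file {path}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise FormatError(f"array file {path}: duplicate feature_id {dup!r}")
    return df[ARRAY_COLUMNS]


def write_array_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline output table in the canonical text format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DESIGN_COLUMNS, f"design file {path}")
    bad = set(df["dye_orientation"]) - {"fwd", "rev"}
    if bad:
        raise FormatError(f"design file {path}: unknown dye_orientation {sorted(bad)}")
    if df["array_id"].duplicated().any():
        raise FormatError(f"design file {path}: duplicate array_id")
    return df[DESIGN_COLUMNS]


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene→term mapping (``gene_id``, ``term_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id", "term_id"], f"annotation file {path}")
    return df[["gene_id", "term_id"]]


def read_gmt(path: str | Path) -> pd.DataFrame:
    """Read GMT gene-set format (term, description, genes...) into the same
    two-column gene→term mapping."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT file {path}: line with < 3 fields")
            term = parts[0]
            rows.extend((g, term) for g in parts[2:] if g)
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["gene_id"], f"gene annotation file {path}")
    return df


def read_experiment(
    design_path: str | Path, annotation_path: str | Path | None = None
) -> tuple[dict[tuple[str, str], HybridizationSet], pd.DataFrame | None]:
    """Read a full experiment as declared by its design table.

    Flagged features (flag < 0) are dropped on read.  Arrays of one
    (line, contrast) cell must share a feature universe; on mismatch the
    intersection is used with a warning so that every gene keeps a complete
    replicate vector.
    """
    design_path = Path(design_path)
    design = read_design(design_path)
    sets: dict[tuple[str, str], HybridizationSet] = {}
    for (line, contrast), grp in design.groupby(["line", "contrast"], sort=True):
        arrays: list[ArrayData] = []
        for row in grp.itertuples(index=False):
            fpath = Path(row.file_path)
            if not fpath.is_absolute():
                fpath = design_path.parent / fpath
            feats = read_array_table(fpath)
            feats = feats[feats["flag"] >= 0].reset_index(drop=True)
            arrays.append(ArrayData(row.array_id, row.dye_orientation, feats))
        universes = [set(a.features["feature_id"]) for a in arrays]
        common = set.intersection(*universes)
        if any(u != common for u in universes):
            n_drop = len(set.union(*universes)) - len(common)
            warnings.warn(
                f"{line}/{contrast}: feature universes differ across arrays; "
                f"using intersection ({n_drop} features dropped)",
                stacklevel=2,
            )
            for a in arrays:
                keep = a.features["feature_id"].isin(common)
                a.features = a.features[keep].reset_index(drop=True)
        sets[(line, contrast)] = HybridizationSet(line, contrast, arrays)
    annotations = None
    if annotation_path is not None:
        annotations = read_go_annotations(annotation_path)
    return sets, annotations


def write_cdt_gtr(
    table: pd.DataFrame,
    tree,
    leaf_order: list[int],
    cdt_path: str | Path,
    gtr_path: str | Path,
) -> None:
    """Write Cluster 3.0 CDT + GTR files loadable by Java TreeView.

    ``table`` has one row per gene in original (pre-clustering) order with a
    ``gene_id`` column, an optional ``name`` column and one column per
    profile value.  ``tree`` is a :class:`~sulfarray.cluster.ClusterTree`
    whose leaves index rows of ``table``; ``leaf_order`` is the display
    permutation.  GTR node heights use TreeView's convention of similarity
    = 1 − distance.
    """
    n = len(table)
    if tree.n_leaves != n or sorted(leaf_order) != list(range(n)):
        raise FormatError("tree leaves must correspond 1:1 to table rows")
    value_cols = [c for c in table.columns if c not in ("gene_id", "name")]
    names = table["name"] if "name" in table.columns else table["gene_id"]
    gid = [f"GENE{i}X" for i in range(n)]

    # node ids: leaves are GENE{i}X, internal nodes NODE{j}X (1-based merge order)
    def _node_label(idx: int) -> str:
        return gid[idx] if idx < n else f"NODE{idx - n + 1}X"

    with open(gtr_path, "w") as fh:
        for j, (left, right, dist) in enumerate(tree.merges, start=1):
            sim = 1.0 - dist
            fh.write(
                f"NODE{j}X\t{_node_label(left)}\t{_node_label(right)}\t{FLOAT_FORMAT % sim}\n"
            )

    with open(cdt_path, "w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(value_cols) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * len(value_cols)) + "\n")
        for i in leaf_order:
            row = table.iloc[i]
            vals = []
            for c in value_cols:
                v = row[c]
                vals.append("" if pd.isna(v) else FLOAT_FORMAT % v)
            fh.write(f"{gid[i]}\t{names.iloc[i]}\t1\t" + "\t".join(vals) + "\n")


def parse_gtr(path: str | Path) -> list[tuple[str, str, str, float]]:
    """Parse a GTR file back into (node, left, right, similarity) rows."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            node, left, right, sim = ln.rstrip("\n").split("\t")
            rows.append((node, left, right, float(sim)))
    return rows
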