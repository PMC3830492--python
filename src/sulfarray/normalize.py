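"""MA transformation, Lowess normalization, dye-swap orientation and
replicate summarization.

Each array's channels are mapped to MA coordinates (M = log2 ratio of the
two channels, A = mean log2 intensity).  Intensity-dependent dye bias is
removed by subtracting a locally weighted regression of M on A (Lowess);
dye-swapped arrays are re-oriented by negating M; replicate arrays are then
summarized per gene into a mean normalized log2 ratio and a two-sided
one-sample t-test p-value of the replicate log ratios against zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .arrayio import HybridizationSet

__all__ = [
    "EmptyArrayError",
    "compute_ma",
    "lowess_normalize",
    "orient_dye_swap",
    "normalize_array",
    "summarize_genes",
]


class EmptyArrayError(ValueError):
    """All features of an array were excluded."""


def compute_ma(features: pd.DataFrame) -> pd.DataFrame:
    """Map raw channel intensities to MA coordinates.

    Features with a non-positive channel are excluded with a warning; an
    array with no usable features raises :class:`EmptyArrayError`.
    """
    ok = (features["ch_a_median"] > 0) & (features["ch_b_median"] > 0)
    if not ok.any():
        raise EmptyArrayError("no features with positive intensities in both channels")
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} features with non-positive channel excluded",
            stacklevel=2,
        )
    f = features[ok]
    la = np.log2(f["ch_a_median"].to_numpy(float))
    lb = np.log2(f["ch_b_median"].to_numpy(float))
    return pd.DataFrame(
        {
            "feature_id": f["feature_id"].to_numpy(),
            "gene_id": f["gene_id"].to_numpy(),
            "M": la - lb,
            "A": 0.5 * (la + lb),
        }
    )


def lowess_normalize(ma: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Subtract a Lowess fit of M on A from M.

    ``span`` is the fraction of points in each local window.  Only M
    changes; A and the feature set are preserved.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if len(ma) < 50:
        warnings.warn("fewer than 50 points; Lowess fit may be unstable", stacklevel=2)
    fitted = _sm_lowess(
        ma["M"].to_numpy(float),
        ma["A"].to_numpy(float),
        frac=span,
        return_sorted=False,
    )
    out = ma.copy()
    out["M"] = ma["M"].to_numpy(float) - fitted
    return out


def orient_dye_swap(ma: pd.DataFrame, orientation: str) -> pd.DataFrame:
    """Resolve dye orientation: negate M on dye-swapped (rev) arrays."""
    if orientation == "fwd":
        return ma
    if orientation == "rev":
        out = ma.copy()
        out["M"] = -out["M"]
        return out
    raise ValueError(f"unknown dye orientation {orientation!r}")


def normalize_array(
    features: pd.DataFrame, orientation: str, span: float = 0.3
) -> pd.DataFrame:
    """MA transform → Lowess correction → orientation, for one array."""
    return orient_dye_swap(lowess_normalize(compute_ma(features), span), orientation)


def _gene_level(ma: pd.DataFrame) -> pd.Series:
    # probe → gene aggregation: mean normalized M per gene within the array
    return ma.groupby("gene_id", sort=True)["M"].mean()


def summarize_genes(hset: HybridizationSet, span: float = 0.3) -> pd.DataFrame:
    """Summarize the replicate arrays of one (line, contrast) cell.

    Returns one row per gene: mean oriented normalized log2 ratio, a
    two-sided one-sample t-test p-value of the replicate values against
    zero, and the number of arrays used.  Genes observed on fewer than two
    arrays are dropped with a warning; genes with zero replicate variance
    and nonzero mean get the smallest positive p rather than zero.
    """
    per_array = [
        _gene_level(normalize_array(a.features, a.dye_orientation, span))
        for a in hset.arrays
    ]
    mat = pd.concat(per_array, axis=1)  # genes × arrays, NaN where missing
    values = mat.to_numpy(float)
    n = np.sum(~np.isnan(values), axis=1)
    few = n < 2
    if few.any():
        warnings.warn(
            f"{int(few.sum())} genes with < 2 replicates dropped", stacklevel=2
        )
        mat = mat[~few]
        values = values[~few]
        n = n[~few]
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    exact_null = zero_var & (mean == 0)
    degenerate = zero_var & (mean != 0)
    p[exact_null] = 1.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes with zero replicate variance and "
            "nonzero mean; p clamped to smallest positive value",
            stacklevel=2,
        )
        p[degenerate] = np.finfo(float).tiny
    return pd.DataFrame(
        {
            "gene_id": mat.index.to_numpy(),
            "line": hset.line,
            "mean_log2_ratio": mean,
            "p_value": p,
            "n_arrays": n,
        }
    ).reset_index(drop=True)
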