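"""Pairwise genetic distances (GDs) from single-cell SNA genotype matrices.

A genotype matrix has one row per cell, one column per variant site,
and calls coded 1 (variant present relative to the germline genome),
0 (absent) or missing (NA).  The genetic difference between two cells
counts sites at which both cells are observed and their calls differ
(pairwise deletion of missing data); dividing by 2 converts the
cell-to-cell difference into a per-lineage distance, since the path
between two cells traverses both lineages since their split.

The per-lineage GD distribution of an individual is summarized by the
midpoint of the modal bin of a 300-bin histogram; the primary peak
tracks the embryonic founder divergence while secondary peaks at
smaller GDs betray late subclonal expansions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "load_sna_matrix",
    "validate_sna_matrix",
    "pairwise_gd",
    "GDDistribution",
    "gd_distribution",
    "gd_peak",
    "sna_count",
]

DEFAULT_BINS = 300


def load_sna_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a cells x sites genotype matrix from delimited text.

    First column = cell identifiers, header row = site identifiers,
    values 0/1 with NA (or empty) for missing calls.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.astype(float)
    validate_sna_matrix(df)
    return df


def validate_sna_matrix(df: pd.DataFrame) -> None:
    if df.shape[0] < 2:
        raise ValueError("SNA matrix needs at least 2 cells")
    if df.index.duplicated().any():
        raise ValueError("duplicate cell identifiers in SNA matrix")
    values = df.to_numpy(dtype=float)
    ok = np.isnan(values) | (values == 0) | (values == 1)
    if not ok.all():
        bad = np.unique(values[~ok])
        raise ValueError(f"genotype calls must be 0, 1 or NA; found {bad}")


def pairwise_gd(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage pairwise GD matrix with pairwise deletion of missing data.

    Entry (i, j) is (number of sites where both cells are observed and
    differ) / 2.  Pairs with no mutually observed site get NaN and a
    warning.  The matrix is symmetric with a zero diagonal.  The
    triangle inequality is *not* guaranteed under pairwise deletion.
    """
    validate_sna_matrix(matrix)
    X = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    A = np.where(observed, X, 0.0)
    O = observed.astype(float)
    both = O @ O.T
    cross = A @ A.T
    s = A @ O.T
    diff = s + s.T - 2.0 * cross
    gd = diff / 2.0
    undefined = both == 0
    np.fill_diagonal(undefined, False)
    if undefined.any():
        n_pairs = int(undefined.sum() // 2)
        warnings.warn(
            f"{n_pairs} cell pair(s) share no mutually observed site; "
            "their GD is reported as missing",
            stacklevel=2,
        )
        gd[undefined] = np.nan
    np.fill_diagonal(gd, 0.0)
    return pd.DataFrame(gd, index=matrix.index, columns=matrix.index)


@dataclasses.dataclass(frozen=True)
class GDDistribution:
    """Histogram summary of a per-lineage GD distribution."""

    distances: np.ndarray   # finite per-lineage distances, one per pair
    bin_edges: np.ndarray   # len(bins) + 1 edges over [0, max distance]
    counts: np.ndarray      # histogram counts, sum == len(distances)

    @property
    def peak(self) -> float:
        """Midpoint of the modal bin (ties resolved toward the lower bin)."""
        i = int(np.argmax(self.counts))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


def _pair_values(gd) -> np.ndarray:
    if isinstance(gd, pd.DataFrame):
        arr = gd.to_numpy(dtype=float)
        iu = np.triu_indices(arr.shape[0], k=1)
        vals = arr[iu]
    else:
        vals = np.asarray(gd, dtype=float).ravel()
    return vals[np.isfinite(vals)]


def gd_distribution(gd, bins: int = DEFAULT_BINS) -> GDDistribution:
    """Histogram a GD matrix (upper triangle) or a flat array of distances.

    Bins are equal-width over [0, max distance]; the upper edge of the
    last bin is inclusive, so a point mass at the maximum lands in the
    top bin.
    """
    vals = _pair_values(gd)
    if vals.size == 0:
        raise ValueError("no finite distances to histogram")
    hi = float(vals.max())
    if hi <= 0:
        hi = 1.0  # degenerate all-zero distribution; peak ~ 0
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, hi))
    return GDDistribution(distances=vals, bin_edges=edges, counts=counts)


def gd_peak(gd, bins: int = DEFAULT_BINS) -> float:
    """Midpoint of the modal histogram bin of the GD distribution."""
    if isinstance(gd, GDDistribution):
        return gd.peak
    return gd_distribution(gd, bins=bins).peak


def sna_count(matrix: pd.DataFrame, cell: str) -> int:
    """Number of SNAs carried by one cell (missing calls not counted)."""
    if cell not in matrix.index:
        raise KeyError(f"unknown cell identifier {cell!r}")
    row = matrix.loc[cell].to_numpy(dtype=float)
    return int(np.nansum(row == 1))
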