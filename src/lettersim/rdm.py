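"""Representational dissimilarity matrices and rank-correlation utilities.

An RDM is a square symmetric matrix of pairwise dissimilarities between
labeled items.  All behavioral and model representations in this package are
reduced to RDMs, compared by Spearman-correlating their strict lower
triangles.  The canonical vectorization order is row-major over the strict
lower triangle: for labels (a, b, c) the pairs are (b,a), (c,a), (c,b).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDM",
    "PairVector",
    "canonical_pairs",
    "lower_triangle",
    "rdm_from_pairs",
    "spearman_rdm",
    "spearman_brown",
    "mds_embed",
]

#: absolute tolerance for symmetry checks
SYMMETRY_ATOL = 1e-8


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix over labeled items.

    Parameters
    ----------
    labels : sequence of str
        Ordered item identifiers (letters, fonts, image ids, ...).
    values : ndarray of shape (n, n)
        Symmetric dissimilarities.  Entries may be NaN to flag missing
        pairs.  The diagonal is conventionally zero; conventions that
        produce a meaningful self-dissimilarity may carry a nonzero
        diagonal, which never enters lower-triangle comparisons.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"RDM values have shape {self.values.shape}, expected ({n}, {n})"
            )
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > SYMMETRY_ATOL:
            raise ValueError(f"RDM is asymmetric (max |A - A.T| = {asym:.3g})")
        # exact symmetry so round-trips are bitwise
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def reorder(self, labels) -> "RDM":
        """Return a copy with rows/columns permuted to ``labels``."""
        idx = [self.labels.index(str(l)) for l in labels]
        return RDM([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])


@dataclass
class PairVector:
    """Lower-triangle vectorization of an RDM in canonical pair order."""

    pairs: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pairs) != self.values.size:
            raise ValueError("pair count does not match value count")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"pair": ["-".join(p) for p in self.pairs], "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairVector":
        df = pd.read_csv(path)
        pairs = [tuple(s.split("-", 1)) for s in df["pair"]]
        return cls(pairs, df["value"].to_numpy())


def canonical_pairs(labels) -> list[tuple[str, str]]:
    """Unordered pairs in row-major strict-lower-triangle order.

    For labels (a, b, c): (b, a), (c, a), (c, b).
    """
    labels = [str(x) for x in labels]
    return [(labels[i], labels[j]) for i in range(1, len(labels)) for j in range(i)]


def lower_triangle(rdm: RDM) -> PairVector:
    """Vectorize the strict lower triangle of a symmetric RDM.

    The inverse operation is :func:`rdm_from_pairs`; the round trip is exact.
    """
    n = rdm.n_items
    i, j = np.tril_indices(n, k=-1)
    return PairVector(canonical_pairs(rdm.labels), rdm.values[i, j])


def rdm_from_pairs(labels, values) -> RDM:
    """Reconstruct a symmetric zero-diagonal RDM from canonical pair values."""
    labels = [str(x) for x in labels]
    values = np.asarray(values, dtype=float)
    n = len(labels)
    expected = n * (n - 1) // 2
    if values.size != expected:
        raise ValueError(f"expected {expected} pair values for {n} labels, got {values.size}")
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    out[i, j] = values
    out[j, i] = values
    return RDM(labels, out)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, (PairVector, RDM)) else np.asarray(x, dtype=float)


def spearman_rdm(a, b) -> float:
    """Spearman rank correlation between two pair vectors.

    Ties are handled by average ranks.  If either input has zero variance
    the correlation is undefined and NaN is returned with a warning, never
    a silent zero.
    """
    av, bv = _as_values(a), _as_values(b)
    if av.shape != bv.shape:
        raise ValueError("pair vectors differ in length")
    if av.size < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("zero-variance input: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(av, bv)
    return float(rho)


def spearman_brown(rho_half: float) -> float:
    """Predict full-sample reliability from half-sample reliability.

    Applies 2*rho / (1 + rho).  Defined on (-1, 1]; negative inputs are
    outside the formula's intended use and trigger a warning.
    """
    if rho_half == -1:
        raise ValueError("Spearman-Brown correction undefined at rho = -1")
    if rho_half < 0:
        warnings.warn("Spearman-Brown applied to a negative half-reliability")
    return 2.0 * rho_half / (1.0 + rho_half)


def mds_embed(rdm: RDM, n_dims: int = 2, seed: int = 0) -> np.ndarray:
    """Metric multidimensional scaling of an RDM, for visualization only.

    Returns an (n_items, n_dims) coordinate array whose pairwise distances
    approximate the RDM under the metric-stress criterion.  Deterministic
    given ``seed``.
    """
    from sklearn.manifold import MDS

    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    vals = np.nan_to_num(rdm.values, nan=0.0)
    if np.all(vals == 0):
        raise ValueError("degenerate all-zero RDM has no embedding")
    kwargs = dict(n_components=n_dims, normalized_stress=False,
                  random_state=seed, n_init=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:  # scikit-learn >= 1.9 naming
            mds = MDS(metric="precomputed", metric_mds=True, init="random",
                      **kwargs)
            return mds.fit_transform(vals)
        except TypeError:
            mds = MDS(dissimilarity="precomputed", metric=True, **kwargs)
            return mds.fit_transform(vals)
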