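"""Noise ceilings via split-half reliability with Spearman-Brown correction.

The ceiling is the best correlation any model can be expected to reach
with data of a given reliability.  Search data are split by font: for each
half-split of the fonts, the per-font pair vectors of each half are
averaged into a half-RDM and the halves are Spearman-correlated; the mean
over splits is the half-sample reliability, corrected upward with
2*rho/(1+rho).  Categorization data are split by measurement: each letter
pair's per-HIT means are partitioned into equal halves, an RDM is fit to
each half with the same mixed-model procedure as the full data, and the
split correlations are averaged and corrected the same way.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .categorization import fit_lme_rdm
from .rdm import PairVector, lower_triangle, spearman_brown

__all__ = [
    "SplitScheme",
    "CeilingResult",
    "count_font_splits",
    "font_splithalf_ceiling",
    "measurement_splithalf_ceiling",
]


@dataclass
class SplitScheme:
    kind: str = "by_font"  # {"by_font", "by_measurement"}
    n_splits: int | str = "exhaustive"
    seed: int = 0


@dataclass
class CeilingResult:
    mean_rho: float
    corrected: float
    n_splits: int
    per_split: np.ndarray = field(repr=False, default=None)


def count_font_splits(n_fonts: int, half: int) -> int:
    """Number of ways to pick a size-``half`` font subset: C(n_fonts, half)."""
    if half > n_fonts or half < 0:
        raise ValueError("half must be in [0, n_fonts]")
    return math.comb(n_fonts, half)


def _rowwise_spearman(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of A with the matching row of b."""
    ra = stats.rankdata(A, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def font_splithalf_ceiling(
    per_font_vectors,
    scheme: SplitScheme | None = None,
) -> CeilingResult:
    """Split-half reliability over fonts, Spearman-Brown corrected.

    Parameters
    ----------
    per_font_vectors : list of (font, PairVector or array)
        One lower-triangle vector per font, all in the same pair order.
    scheme : SplitScheme
        ``n_splits="exhaustive"`` enumerates every half-split (requires an
        even font count); an integer samples that many seeded splits.
        Complementary halves give identical correlations, so enumerating
        all C(n, n/2) subsets double-counts harmlessly.
    """
    scheme = scheme or SplitScheme()
    fonts = [f for f, _ in per_font_vectors]
    F = np.vstack(
        [np.asarray(v.values if isinstance(v, PairVector) else v, dtype=float)
         for _, v in per_font_vectors]
    )
    n = len(fonts)
    if n < 2:
        raise ValueError("need at least 2 fonts for a split-half reliability")

    exhaustive = scheme.n_splits == "exhaustive"
    if exhaustive and n % 2:
        raise ValueError("exhaustive font splits require an even font count")
    half = n // 2
    total = F.sum(axis=0)

    if exhaustive:
        combos = np.array(list(itertools.combinations(range(n), half)))
    else:
        rng = np.random.default_rng(scheme.seed)
        combos = np.array(
            [rng.choice(n, size=half, replace=False) for _ in range(int(scheme.n_splits))]
        )

    rhos = np.empty(len(combos))
    chunk = 4096
    for lo in range(0, len(combos), chunk):
        idx = combos[lo : lo + chunk]
        half1 = F[idx].sum(axis=1) / half
        half2 = (total - half1 * half) / (n - half)
        rhos[lo : lo + chunk] = _rowwise_spearman(half1, half2)
    rhos = rhos[np.isfinite(rhos)]
    mean_rho = float(rhos.mean())
    return CeilingResult(mean_rho, spearman_brown(mean_rho), len(rhos), rhos)


def measurement_splithalf_ceiling(
    pair_means_table: pd.DataFrame,
    n_splits: int,
    seed: int,
    alphabet=None,
    method: str = "ml",
    tol: float = 1e-6,
) -> CeilingResult:
    """Split-half reliability over per-pair measurements, corrected.

    Each split partitions every condition's measurements into equal halves
    (one measurement dropped at random per odd-count condition), fits the
    mixed-model RDM to each half, and Spearman-correlates the halves.
    The mixed model defaults to ML with a relaxed tolerance for speed.
    Deterministic given ``seed``.
    """
    pm = pair_means_table.reset_index(drop=True)
    counts = pm.groupby("condition").size()
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise ValueError(f"condition(s) with fewer than 2 measurements: {few[:5]}")
    rng = np.random.default_rng(seed)
    groups = {c: sub.index.to_numpy() for c, sub in pm.groupby("condition")}

    rhos = []
    for _ in range(n_splits):
        idx1, idx2 = [], []
        for rows in groups.values():
            perm = rng.permutation(rows)
            m = len(perm)
            if m % 2:
                perm = perm[:-1]  # drop one at random (perm is random)
                m -= 1
            idx1.append(perm[: m // 2])
            idx2.append(perm[m // 2 :])
        r1 = fit_lme_rdm(pm.loc[np.concatenate(idx1)], alphabet=alphabet,
                         method=method, tol=tol)
        r2 = fit_lme_rdm(pm.loc[np.concatenate(idx2)], alphabet=alphabet,
                         method=method, tol=tol)
        v1, v2 = lower_triangle(r1).values, lower_triangle(r2).values
        rho, _ = stats.spearmanr(v1, v2)
        rhos.append(rho)
    rhos = np.asarray(rhos, dtype=float)
    mean_rho = float(np.nanmean(rhos))
    return CeilingResult(mean_rho, spearman_brown(mean_rho), len(rhos), rhos)
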