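"""Model RDMs from feature activations, plus baseline models and
letter-preferring subspace selection.

Two task conventions map a (letter x font) grid of pooled activation
vectors onto a letter RDM:

* **search convention** — observers discriminate letters within a font,
  so distances are computed between letters within each font and averaged
  across fonts.
* **categorization convention** — observers compare each presented
  exemplar with a remembered target abstracted over fonts, so each
  letter's across-font mean activation serves as a template, distances run
  from font-specific exemplars to templates, and the two directions of
  each letter pair are averaged into a symmetric RDM.

Baselines: a purely categorical one-hot space over letter identities, and
a hand-rated intuitive feature space (line orientations, curve openings,
intersections, terminations, diacritics, symmetry, closed space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from .rdm import RDM

__all__ = [
    "ActivationSet",
    "FeatureMask",
    "INTUITIVE_FEATURES",
    "pool_feature_maps",
    "search_convention_rdm",
    "categ_convention_rdm",
    "image_level_rdm",
    "categorical_rdm",
    "select_letter_preferring",
    "random_matched_masks",
    "apply_mask",
    "intuitive_rdm",
]

METRICS = ("euclidean", "correlation", "cosine")

#: the 17 hand-rated intuitive letter features
INTUITIVE_FEATURES = [
    "line_vertical", "line_horizontal", "line_slant_right", "line_slant_left",
    "curve_open_right", "curve_open_left", "curve_open_bottom", "curve_open_top",
    "intersection_2way", "intersection_3way", "intersection_4way",
    "termination_right", "termination_left", "termination_bottom", "termination_top",
    "diacritic", "symmetry",
]
# note: "closed space" replaces one slot in some rating schemes; kept as an
# 18th optional column when present
CLOSED_SPACE = "closed_space"


@dataclass
class ActivationSet:
    """Pooled feature activations for one model stage.

    One row per stimulus image, labeled by letter identity and font.
    """

    stage: str
    activations: np.ndarray  # (n_images, n_features)
    letters: np.ndarray
    fonts: np.ndarray

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        self.letters = np.asarray(self.letters, dtype=str)
        self.fonts = np.asarray(self.fonts, dtype=str)
        n = self.activations.shape[0]
        if len(self.letters) != n or len(self.fonts) != n:
            raise ValueError("label arrays must match the number of images")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations must be finite")

    @property
    def n_features(self) -> int:
        return self.activations.shape[1]

    def save_npz(self, path) -> None:
        np.savez(
            path,
            stage=np.asarray(self.stage),
            activations=self.activations,
            letters=self.letters,
            fonts=self.fonts,
        )

    @classmethod
    def load_npz(cls, path) -> "ActivationSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(str(z["stage"]), z["activations"], z["letters"], z["fonts"])


@dataclass
class FeatureMask:
    """Boolean keep-flag per feature with the selection statistics."""

    stage: str
    keep: np.ndarray
    tstat: np.ndarray = field(default=None, repr=False)
    pvalue: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.keep.sum())


def pool_feature_maps(raw: np.ndarray, stage: str = "", letters=None, fonts=None) -> ActivationSet:
    """Reduce spatial activation maps to one scalar per feature by summation.

    ``raw`` has shape (n_images, n_features, height, width); a 2-D input
    is treated as already pooled.  Pooling a 256-feature, 13x13-map layer
    yields a 256-dimensional vector per image.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 2:
        pooled = raw
    elif raw.ndim == 4:
        pooled = raw.sum(axis=(2, 3))
    else:
        raise ValueError(f"expected (images, features, h, w) maps, got ndim={raw.ndim}")
    n = pooled.shape[0]
    letters = np.arange(n).astype(str) if letters is None else letters
    fonts = np.zeros(n).astype(str) if fonts is None else fonts
    return ActivationSet(stage, pooled, letters, fonts)


def _grid(acts: ActivationSet):
    """Activations reshaped to (letters, fonts, features); requires a
    complete one-image-per-cell grid."""
    letters = sorted(set(acts.letters.tolist()))
    fonts = sorted(set(acts.fonts.tolist()))
    X = np.empty((len(letters), len(fonts), acts.n_features))
    li = {l: i for i, l in enumerate(letters)}
    fi = {f: i for i, f in enumerate(fonts)}
    seen = np.zeros((len(letters), len(fonts)), dtype=int)
    for row, (l, f) in enumerate(zip(acts.letters, acts.fonts)):
        X[li[l], fi[f]] = acts.activations[row]
        seen[li[l], fi[f]] += 1
    if not np.all(seen == 1):
        raise ValueError("activation set is not a complete letter x font grid")
    return letters, fonts, X


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")


def search_convention_rdm(acts: ActivationSet, metric: str = "euclidean") -> RDM:
    """Letter RDM under the within-font search convention.

    Pairwise distances between letters are computed within each font and
    averaged across fonts.
    """
    _check_metric(metric)
    letters, fonts, X = _grid(acts)
    acc = np.zeros((len(letters), len(letters)))
    for f in range(len(fonts)):
        acc += squareform(pdist(X[:, f, :], metric=metric))
    return RDM(letters, acc / len(fonts))


def categ_convention_rdm(acts: ActivationSet, metric: str = "euclidean") -> RDM:
    """Letter RDM under the exemplar-to-template categorization convention.

    Each letter's across-font mean activation is its template.  D(i -> j)
    averages, over fonts, the distance from letter i's font exemplar to
    letter j's template; the matrix is symmetrized by averaging the two
    directions, mirroring the behavioral direction-averaging.  The
    (meaningful but unused) self-distances are zeroed so the result
    satisfies the RDM diagonal convention.
    """
    _check_metric(metric)
    letters, fonts, X = _grid(acts)
    templates = X.mean(axis=1)  # (letters, features)
    D = np.zeros((len(letters), len(letters)))
    for f in range(len(fonts)):
        D += cdist(X[:, f, :], templates, metric=metric)
    D /= len(fonts)
    sym = (D + D.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return RDM(letters, sym)


def image_level_rdm(acts: ActivationSet, metric: str = "euclidean") -> RDM:
    """All-pairs distance matrix over individual images."""
    _check_metric(metric)
    if acts.activations.shape[0] < 2:
        raise ValueError("need at least 2 images")
    ids = [f"{l}_{f}_{k}" for k, (l, f) in enumerate(zip(acts.letters, acts.fonts))]
    return RDM(ids, squareform(pdist(acts.activations, metric=metric)))


def categorical_rdm(labels) -> RDM:
    """Image RDM of a purely categorical one-hot identity space.

    Same-letter images are at distance 0; different-letter images at the
    one-hot Euclidean constant sqrt(2).  Any metric monotone in
    same/different yields the same rank structure.
    """
    labels = [str(x) for x in labels]
    arr = np.asarray(labels)
    same = arr[:, None] == arr[None, :]
    values = np.where(same, 0.0, np.sqrt(2.0))
    ids = [f"{l}_{k}" for k, l in enumerate(labels)]
    return RDM(ids, values)


def select_letter_preferring(
    letters: ActivationSet, objects: ActivationSet, alpha: float = 0.05
) -> FeatureMask:
    """Features responding more to letter than object images.

    Per feature, a two-sample Welch t-test compares activations across the
    letter image set and the object image set; features with higher mean
    activation to letters and p < ``alpha`` are kept.  Features with
    undefined variance in both groups (e.g. all-zero) are never selected.
    """
    if letters.n_features != objects.n_features:
        raise ValueError("feature dimensions differ between the two sets")
    if len(letters.activations) < 2 or len(objects.activations) < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            letters.activations, objects.activations, axis=0, equal_var=False
        )
    higher = letters.activations.mean(axis=0) > objects.activations.mean(axis=0)
    keep = higher & (np.nan_to_num(p, nan=1.0) < alpha)
    n_undef = int(np.isnan(p).sum())
    if n_undef:
        warnings.warn(f"{n_undef} feature(s) with undefined variance were not selected")
    return FeatureMask(letters.stage, keep, np.asarray(t), np.asarray(p))


def random_matched_masks(
    mask: FeatureMask, pool: np.ndarray, n_samples: int, seed: int
) -> list[FeatureMask]:
    """Size-matched random feature subsets from an eligible pool.

    ``pool`` flags features eligible for sampling (responsive to letters
    but not letter-preferring).  Each of the ``n_samples`` masks draws
    ``mask.n_selected`` features without replacement; reproducible given
    ``seed``.
    """
    pool = np.asarray(pool, dtype=bool)
    if pool.size != mask.keep.size:
        raise ValueError("pool and mask cover different feature counts")
    k = mask.n_selected
    candidates = np.flatnonzero(pool)
    if len(candidates) < k:
        raise ValueError(f"pool of {len(candidates)} cannot supply {k} features")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        pick = rng.choice(candidates, size=k, replace=False)
        keep = np.zeros_like(pool)
        keep[pick] = True
        out.append(FeatureMask(mask.stage, keep))
    return out


def apply_mask(acts: ActivationSet, mask: FeatureMask) -> ActivationSet:
    """Restrict an activation set to a feature subspace."""
    if mask.n_selected == 0:
        raise ValueError("mask keeps no features")
    return ActivationSet(
        acts.stage, acts.activations[:, mask.keep], acts.letters, acts.fonts
    )


def intuitive_rdm(
    table: pd.DataFrame, convention: str = "search", metric: str = "euclidean"
) -> RDM:
    """Letter RDM from hand-rated intuitive feature counts.

    ``table`` holds one row per letter image with ``letter`` (and
    optionally ``font``) columns plus nonnegative integer feature counts.
    The count vectors are treated exactly like pooled activations and run
    through the requested task convention.
    """
    if "letter" not in table.columns:
        raise ValueError("table must have a 'letter' column")
    feat_cols = [c for c in table.columns if c not in ("letter", "font")]
    if not feat_cols:
        raise ValueError("no feature columns found")
    counts = table[feat_cols].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("feature counts must be nonnegative")
    fonts = table["font"] if "font" in table.columns else np.zeros(len(table), dtype=int)
    acts = ActivationSet("intuitive", counts, table["letter"].to_numpy(dtype=str),
                         np.asarray(fonts, dtype=str))
    if convention == "search":
        return search_convention_rdm(acts, metric)
    if convention == "categ":
        return categ_convention_rdm(acts, metric)
    raise ValueError("convention must be 'search' or 'categ'")
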