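"""Model-behavior correlation curves and bootstrap comparison of feature
spaces.

A model's fit to behavior is the Spearman correlation between its RDM's
lower triangle and the behavioral RDM's lower triangle, traced across a
network's stages.  Two candidate feature spaces are compared by
bootstrapping the set of letter pairs: the pair vector is resampled with
replacement, both models' correlations are recomputed per resample, and
the reported p-value is the proportion of resamples in which the
nominally better model (fixed from the original sample) fails to win.
Ties count against rejection.  An optional two-sided doubling corrects
for the post-hoc choice of direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rdm import RDM, lower_triangle, spearman_rdm

__all__ = [
    "ModelCurve",
    "BootstrapResult",
    "model_behavior_curve",
    "bootstrap_compare",
    "per_font_max_comparison",
]


@dataclass
class ModelCurve:
    model: str
    stages: list[str]
    rho: np.ndarray
    band: np.ndarray | None = field(default=None, repr=False)  # (k, 2) CI


@dataclass
class BootstrapResult:
    kind: str  # {"layerwise", "max_layer"}
    n_resamples: int
    seed: int
    pvalues: np.ndarray  # one per comparison (1 for max_layer, k for layerwise)
    direction: np.ndarray  # +1: model_a better in the original sample, -1: b, 0: tie
    observed_diff: np.ndarray
    n_skipped: int = 0
    best_stage_a: int | None = None
    best_stage_b: int | None = None


def _stage_vectors(behavior: RDM, stages) -> tuple[list[str], np.ndarray]:
    """Lower-triangle vectors for each stage, aligned to the behavior labels."""
    names, vecs = [], []
    items = stages.items() if isinstance(stages, dict) else stages
    for entry in items:
        name, rdm = entry if isinstance(entry, tuple) else (entry.stage, entry)
        if set(rdm.labels) != set(behavior.labels):
            raise ValueError(f"stage {name!r} labels do not match the behavior RDM")
        aligned = rdm.reorder(behavior.labels)
        names.append(str(name))
        vecs.append(lower_triangle(aligned).values)
    return names, np.vstack(vecs)


def _rowwise_spearman(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    rb = stats.rankdata(b, axis=-1)
    rR = stats.rankdata(R, axis=-1)
    rb = rb - rb.mean(axis=-1, keepdims=True)
    rR = rR - rR.mean(axis=-1, keepdims=True)
    num = (rR * rb).sum(axis=-1)
    den = np.sqrt((rR**2).sum(axis=-1) * (rb**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def model_behavior_curve(
    behavior: RDM,
    stages,
    model: str = "model",
    n_boot: int = 0,
    seed: int = 0,
    ci: float = 0.95,
) -> ModelCurve:
    """Spearman correlation between behavior and each model stage.

    ``stages`` is a list of (label, RDM) pairs (or a dict).  With
    ``n_boot`` > 0, a seeded percentile bootstrap over letter pairs adds a
    confidence band per stage.
    """
    names, V = _stage_vectors(behavior, stages)
    bvec = lower_triangle(behavior).values
    rho = np.array([spearman_rdm(bvec, v) for v in V])
    band = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n_pairs = bvec.size
        idx = rng.integers(0, n_pairs, size=(n_boot, n_pairs))
        boots = _rowwise_spearman(V[:, idx], bvec[idx])  # (k, n_boot)
        lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
        band = np.nanpercentile(boots, [lo, hi], axis=1).T
        band[:, 0] = np.minimum(band[:, 0], rho)
        band[:, 1] = np.maximum(band[:, 1], rho)
    return ModelCurve(model, names, rho, band)


def bootstrap_compare(
    behavior: RDM,
    model_a,
    model_b,
    kind: str = "max_layer",
    n: int = 50_000,
    seed: int = 0,
    two_sided: bool = False,
) -> BootstrapResult:
    """Bootstrap test of which feature space better matches behavior.

    The unordered letter pairs are resampled with replacement ``n`` times;
    both models' Spearman correlations with behavior are recomputed per
    resample (duplicated pairs enter the ranks as-is).

    ``kind="max_layer"`` fixes, from the original sample, the stage of
    each model with the highest model-behavior correlation and compares
    those two stages across resamples; ``kind="layerwise"`` compares the
    models stage by stage (requires equal stage counts) and returns one
    p-value per stage.

    The one-sided p-value is the proportion of valid resamples in which
    the originally better model is *not* strictly better (ties count
    against rejection); an observed tie reports p = 1.  ``two_sided``
    doubles the proportion (capped at 1) to correct for choosing the
    direction from the same sample.  Resamples with constant behavior
    ranks are skipped and counted.
    """
    if kind not in ("layerwise", "max_layer"):
        raise ValueError("kind must be 'layerwise' or 'max_layer'")
    if n < 1:
        raise ValueError("need at least 1 resample")
    names_a, Va = _stage_vectors(behavior, model_a)
    names_b, Vb = _stage_vectors(behavior, model_b)
    bvec = lower_triangle(behavior).values
    rho_a = np.array([spearman_rdm(bvec, v) for v in Va])
    rho_b = np.array([spearman_rdm(bvec, v) for v in Vb])

    best_a = best_b = None
    if kind == "max_layer":
        best_a, best_b = int(np.nanargmax(rho_a)), int(np.nanargmax(rho_b))
        Va, Vb = Va[[best_a]], Vb[[best_b]]
        obs = np.array([rho_a[best_a] - rho_b[best_b]])
    else:
        if len(names_a) != len(names_b):
            raise ValueError("layerwise comparison needs equal stage counts")
        obs = rho_a - rho_b

    rng = np.random.default_rng(seed)
    n_pairs = bvec.size
    pvals = np.empty(len(obs))
    n_skipped = 0
    chunk = max(1, min(n, 2_000_000 // max(1, n_pairs)))
    wins = np.zeros(len(obs))
    valid = np.zeros(len(obs))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        idx = rng.integers(0, n_pairs, size=(m, n_pairs))
        bres = bvec[idx]  # (m, n_pairs)
        degenerate = np.ptp(bres, axis=1) == 0
        ra = _rowwise_spearman(Va[:, idx], bres)  # (k, m)
        rbb = _rowwise_spearman(Vb[:, idx], bres)
        diff = ra - rbb
        okmask = ~degenerate & np.all(np.isfinite(diff), axis=0)
        n_skipped += int(m - okmask.sum())
        d = diff[:, okmask]
        sign = np.sign(obs)[:, None]
        wins += np.where(sign == 0, 0.0, (sign * d > 0)).sum(axis=1)
        valid += okmask.sum()
        done += m

    for k in range(len(obs)):
        if obs[k] == 0 or valid[k] == 0:
            pvals[k] = 1.0
        else:
            pvals[k] = 1.0 - wins[k] / valid[k]
            if two_sided:
                pvals[k] = min(1.0, 2.0 * pvals[k])
    return BootstrapResult(
        kind=kind,
        n_resamples=n,
        seed=seed,
        pvalues=pvals,
        direction=np.sign(obs).astype(int),
        observed_diff=obs,
        n_skipped=n_skipped,
        best_stage_a=best_a,
        best_stage_b=best_b,
    )


def per_font_max_comparison(behavior_by_font, model_a, model_b):
    """Paired t-test, across fonts, of the models' max stage correlations.

    Parameters
    ----------
    behavior_by_font : list of (font, RDM)
        One behavioral RDM per font.
    model_a, model_b : list of (label, RDM) stages, or mapping font -> stages
        Stage RDMs; pass a mapping to use font-specific model RDMs.

    Returns
    -------
    (t, dof, p) : paired t-statistic over fonts, its degrees of freedom
    (n_fonts - 1), and the two-sided p-value.
    """
    fonts = [f for f, _ in behavior_by_font]
    if len(fonts) < 2:
        raise ValueError("need at least 2 fonts for a paired comparison")

    def _max_rho(model, font, behavior):
        stages = model[font] if isinstance(model, dict) else model
        _, V = _stage_vectors(behavior, stages)
        bvec = lower_triangle(behavior).values
        return np.nanmax([spearman_rdm(bvec, v) for v in V])

    xs = np.array([_max_rho(model_a, f, b) for f, b in behavior_by_font])
    ys = np.array([_max_rho(model_b, f, b) for f, b in behavior_by_font])
    if np.allclose(xs, ys):
        return 0.0, len(fonts) - 1, 1.0
    t, p = stats.ttest_rel(xs, ys)
    return float(t), len(fonts) - 1, float(p)
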