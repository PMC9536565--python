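"""Categorization pipeline: trial tables -> per-HIT pair means -> LME RDM.

The similarity signal is the time to *reject* a non-matching letter: the
more a presented letter resembles the held-in-mind target, the slower the
"not the target" response.  Because each session (HIT) measures only a
subset of ordered (target, presented) pairs, the full matrix is estimated
with a linear mixed model, RT ~ Condition + (1 | HIT): fixed effects for
the ordered-pair conditions and a random intercept absorbing each HIT's
overall speed.  Estimated RTs for the two directions of each unordered
pair are averaged, negated, and assembled into the RDM.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rdm import RDM, canonical_pairs, rdm_from_pairs

__all__ = ["pair_means", "fit_lme_rdm", "condition_label"]

CATEG_COLUMNS = ["hit_id", "block", "target", "presented", "font", "match", "correct", "rt_ms"]

#: HITs below this overall accuracy are excluded wholesale
MIN_HIT_ACCURACY = 0.90


def condition_label(target: str, presented: str) -> str:
    """Ordered-pair condition name, ``<target>><presented>``."""
    return f"{target}>{presented}"


def pair_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-HIT mean rejection RT for each ordered (target, presented) pair.

    Filtering, in order: HITs under 90% overall accuracy are dropped;
    incorrect trials are dropped; a pair cell is dropped when more than
    half of its scheduled non-match repetitions were answered incorrectly
    (at the full design's 8 repetitions: more than 4 of 8).

    Returns a table with columns ``condition``, ``mean_rt``, ``hit_id``
    (plus ``target`` and ``presented``), one row per retained cell.
    """
    missing = [c for c in CATEG_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")

    acc = trials.groupby("hit_id")["correct"].mean()
    good_hits = acc[acc >= MIN_HIT_ACCURACY].index
    df = trials[trials["hit_id"].isin(good_hits)]

    nm = df[~df["match"].astype(bool)]
    grp = nm.groupby(["hit_id", "target", "presented"])
    stats_df = grp.agg(
        n_trials=("correct", "size"),
        n_correct=("correct", "sum"),
    )
    kept = stats_df[stats_df["n_correct"] >= stats_df["n_trials"] / 2.0].index

    correct_nm = nm[nm["correct"].astype(bool)]
    means = (
        correct_nm.groupby(["hit_id", "target", "presented"])["rt_ms"]
        .mean()
        .loc[lambda s: s.index.isin(kept)]
        .reset_index()
        .rename(columns={"rt_ms": "mean_rt"})
    )
    if means.empty:
        warnings.warn("pair_means produced an empty table")
    means["condition"] = [
        condition_label(t, p) for t, p in zip(means["target"], means["presented"])
    ]
    return means[["condition", "mean_rt", "hit_id", "target", "presented"]]


def _condition_estimates(pm: pd.DataFrame, conditions, method: str, tol: float):
    """Estimated mean RT per condition under the dummy-coded LME.

    The reference condition's estimate (the intercept) is added back to
    every dummy coefficient, so the result is invariant to the choice of
    reference.  With fewer than two HITs the random intercept is
    unidentifiable and the fixed-effects model reduces to ordinary least
    squares, whose dummy-coded estimates are exactly the per-condition
    cell means.
    """
    cond = pd.Categorical(pm["condition"], categories=conditions)
    if cond.isna().any():
        raise ValueError("pair_means contains conditions outside the given universe")
    y = pm["mean_rt"].to_numpy(dtype=float)
    codes = cond.codes
    n_cond = len(conditions)
    X = np.zeros((len(y), n_cond))
    X[np.arange(len(y)), codes] = 1.0
    X[:, 0] = 1.0  # intercept; columns 1.. are dummies relative to conditions[0]

    observed = np.bincount(codes, minlength=n_cond)
    if (observed == 0).any():
        absent = [c for c, n in zip(conditions, observed) if n == 0]
        raise ValueError(f"incomplete design: unobserved condition(s) {absent[:5]}")

    n_groups = pm["hit_id"].nunique()
    if n_groups < 2:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        model = sm.MixedLM(y, X, groups=pm["hit_id"].to_numpy())
        fit = None
        errors = []
        # lbfgs is fastest but can hit a singular profile Hessian when the
        # group variance collapses to the boundary; fall back if it does
        for optimizer in ("lbfgs", "bfgs", "powell"):
            kwargs = {} if optimizer == "powell" else {"gtol": tol}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit(reml=(method == "reml"), method=optimizer,
                                    **kwargs)
                if np.all(np.isfinite(fit.fe_params)):
                    break
                errors.append(f"{optimizer}: non-finite estimates")
                fit = None
            except np.linalg.LinAlgError as exc:
                errors.append(f"{optimizer}: {exc}")
        if fit is None:
            raise RuntimeError(
                "mixed-model fit failed; inspect the design for singularity "
                f"({'; '.join(errors)})"
            )
        beta = np.asarray(fit.fe_params)
    est = beta.copy()
    est[1:] += beta[0]  # add the reference estimate back to every condition
    return est


def fit_lme_rdm(
    pair_means_table: pd.DataFrame,
    alphabet=None,
    method: str = "reml",
    tol: float = 1e-8,
) -> RDM:
    """Estimate the full RDM from per-HIT pair means via a mixed model.

    Parameters
    ----------
    pair_means_table : DataFrame
        Output of :func:`pair_means` (``condition``, ``mean_rt``, ``hit_id``).
    alphabet : sequence of str, optional
        Letter universe; inferred from the conditions when omitted.
    method : {"reml", "ml"}
        Estimation criterion for the mixed model.  REML by default; ML is
        faster and is used inside split-half reliability loops.
    tol : float
        Gradient tolerance passed to the optimizer.

    Returns
    -------
    RDM
        Entry for unordered pair {i, j} = -(est(i->j) + est(j->i)) / 2,
        in the canonical lower-triangle layout.
    """
    pm = pair_means_table
    if alphabet is None:
        alphabet = sorted(set(pm["target"]) | set(pm["presented"]))
    alphabet = [str(x) for x in alphabet]
    conditions = [
        condition_label(t, p) for t in alphabet for p in alphabet if t != p
    ]
    est = _condition_estimates(pm, conditions, method, tol)
    lookup = dict(zip(conditions, est))
    values = [
        -(lookup[condition_label(a, b)] + lookup[condition_label(b, a)]) / 2.0
        for a, b in canonical_pairs(alphabet)
    ]
    return rdm_from_pairs(alphabet, values)
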