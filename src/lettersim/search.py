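"""Visual-search pipeline: trial tables -> RT-based and accuracy-based RDMs.

Reaction times are log-transformed to account for their positive skew and
z-scored within HIT, so each session's overall speed cancels and only the
relative ordering of letter pairs remains.  Trials beyond three within-HIT
standard deviations are excluded.  The RDM entry for a pair is minus the
mean z-scored log RT over all retained trials of that pair: slower search
means a more similar (less dissimilar) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import RDM, canonical_pairs, rdm_from_pairs

__all__ = [
    "preprocess_search",
    "build_search_rdm",
    "build_accuracy_rdm",
    "per_font_rdms",
    "PreprocessReport",
]

SEARCH_COLUMNS = ["hit_id", "letter_a", "letter_b", "target", "font", "correct", "rt_ms"]

#: within-HIT z-score magnitude beyond which a trial is an outlier
Z_CUTOFF = 3.0


@dataclass
class PreprocessReport:
    n_trials: int
    frac_incorrect: float
    frac_outlier: float
    dropped_hits: list[str]


def _check_columns(trials: pd.DataFrame, required) -> None:
    missing = [c for c in required if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def preprocess_search(trials: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop errors, z-score log RTs within HIT, and exclude |z| > 3 outliers.

    Returns the retained trials with a ``z`` column, plus an exclusion
    report.  HITs whose correct-trial log RTs have zero variance are
    degenerate (z undefined) and are dropped with a warning.  z-scores are
    computed once; they are not recomputed after outlier removal.
    """
    _check_columns(trials, SEARCH_COLUMNS)
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")
    n_total = len(trials)
    ok = trials[trials["correct"].astype(bool)].copy()
    frac_incorrect = 1.0 - len(ok) / n_total if n_total else 0.0

    ok["log_rt"] = np.log(ok["rt_ms"].to_numpy(dtype=float))
    g = ok.groupby("hit_id")["log_rt"]
    mu = g.transform("mean")
    sd = g.transform("std")  # ddof=1, matches the usual sample SD

    degenerate = ok.loc[(sd == 0) | sd.isna(), "hit_id"].unique().tolist()
    if degenerate:
        warnings.warn(
            f"dropping {len(degenerate)} degenerate HIT(s) with zero RT variance: "
            f"{degenerate}"
        )
    keep = ~ok["hit_id"].isin(degenerate)
    ok = ok[keep].copy()
    ok["z"] = (ok["log_rt"] - mu[keep]) / sd[keep]

    n_before = len(ok)
    ok = ok[ok["z"].abs() <= Z_CUTOFF]
    frac_outlier = 1.0 - len(ok) / n_before if n_before else 0.0
    report = PreprocessReport(
        n_trials=len(ok),
        frac_incorrect=frac_incorrect,
        frac_outlier=frac_outlier,
        dropped_hits=degenerate,
    )
    return ok.reset_index(drop=True), report


def _pair_key(df: pd.DataFrame) -> pd.Series:
    a = df[["letter_a", "letter_b"]].min(axis=1)
    b = df[["letter_a", "letter_b"]].max(axis=1)
    return a + "|" + b


def _pair_rdm(df: pd.DataFrame, col: str, alphabet, sign: float) -> RDM:
    if alphabet is None:
        alphabet = sorted(set(df["letter_a"]) | set(df["letter_b"]))
    alphabet = [str(x) for x in alphabet]
    means = df.groupby(_pair_key(df))[col].mean()
    values = []
    missing = []
    for hi, lo in canonical_pairs(alphabet):
        key = f"{min(lo, hi)}|{max(lo, hi)}"
        if key in means.index:
            values.append(sign * means[key])
        else:
            values.append(np.nan)
            missing.append((hi, lo))
    if missing:
        warnings.warn(f"{len(missing)} unobserved pair(s) flagged as NaN: {missing[:5]}")
    return rdm_from_pairs(alphabet, values)


def build_search_rdm(trials: pd.DataFrame, alphabet=None) -> RDM:
    """Behavioral RDM: entry(i, j) = -mean(z) over retained trials of {i, j}.

    Expects the output of :func:`preprocess_search` (must carry ``z``).
    Unobserved pairs are flagged NaN, never zero-filled.
    """
    if "z" not in trials.columns:
        raise ValueError("expected a preprocessed table with a 'z' column")
    return _pair_rdm(trials, "z", alphabet, sign=-1.0)


def build_accuracy_rdm(trials: pd.DataFrame, alphabet=None) -> RDM:
    """Accuracy RDM: entry(i, j) = mean accuracy of pair {i, j}.

    Built from the raw trial table (errors included, that is the signal).
    Higher accuracy means easier search, i.e. a more dissimilar pair, so
    entries are stored as accuracy itself, in [0, 1].
    """
    _check_columns(trials, ["letter_a", "letter_b", "correct"])
    df = trials.copy()
    df["acc"] = df["correct"].astype(float)
    return _pair_rdm(df, "acc", alphabet, sign=1.0)


def per_font_rdms(trials: pd.DataFrame, alphabet=None, fonts=None) -> list[tuple[str, RDM]]:
    """One RT-based RDM per font, from that font's HITs only.

    Fonts with incomplete pair coverage yield NaN-flagged entries (warned).
    """
    if "z" not in trials.columns:
        raise ValueError("expected a preprocessed table with a 'z' column")
    present = list(pd.unique(trials["font"]))
    if fonts is None:
        fonts = present
    out = []
    for font in fonts:
        sub = trials[trials["font"] == font]
        if sub.empty:
            warnings.warn(f"font {font!r} absent from trial table")
            continue
        out.append((str(font), build_search_rdm(sub, alphabet=alphabet)))
    return out
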