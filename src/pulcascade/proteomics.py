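"""Semiquantitative proteomics: riBAQ, detection filtering, Welch tests and
permutation-based FDR.

iBAQ intensities are protein x sample, non-negative, with missing values
allowed (NaN). %riBAQ rescales each sample so all proteins in it sum to 100,
making samples comparable. Differential abundance between two conditions is
assessed with Welch's two-sided t-test; significance is controlled by a
permutation-based FDR: group labels are permuted, null statistics pooled
across proteins, and the largest significant set with estimated FDR <= alpha
is reported.

With three replicates per condition, per-protein variance estimates are so
unstable that a handful of tiny-variance null proteins dominates any pooled
|t| null. The default ranking statistic is therefore the SAM-style
variance-moderated |mean difference| / (se + s0) with s0 set to the median
standard error, the same moderation the Perseus permutation FDR applies;
``s0=0`` recovers the plain Welch |t| ranking.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def _check_meta(meta: pd.DataFrame) -> None:
    for col in ("condition", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks column {col!r}")


def compute_ribaq(matrix: pd.DataFrame) -> pd.DataFrame:
    """%riBAQ: per sample, 100 * iBAQ / sum(iBAQ) over non-missing proteins.

    Missing values contribute 0 to the denominator and remain missing in the
    output, so the non-missing values of every sample sum to 100.
    """
    sums = matrix.sum(axis=0, skipna=True)
    dead = sums[(sums <= 0) | sums.isna()]
    if len(dead):
        raise ValueError(
            f"samples without positive intensities: {list(dead.index)}"
        )
    return matrix.div(sums, axis=1) * 100.0


def detection_filter(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    min_detected: int = 2,
    scope: str = "per-condition",
) -> pd.Index:
    """Identified proteins: detected (non-missing) in at least
    ``min_detected`` replicates of at least one condition (default scope),
    or of the whole sample set with ``scope='overall'``."""
    _check_meta(meta)
    detected = matrix.notna()
    if scope == "overall":
        keep = detected.sum(axis=1) >= min_detected
    elif scope == "per-condition":
        per_cond = detected.T.groupby(meta["condition"]).sum().T
        keep = (per_cond >= min_detected).any(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return matrix.index[keep]


def welch_t(group_a, group_b):
    """Welch's two-sample t statistic and Welch-Satterthwaite df.

    Missing values are dropped; each group needs >= 2 observations. With
    zero variance in both groups and equal means, t = 0 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("welch_t needs >= 2 non-missing values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    d = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        return (0.0 if d == 0 else np.copysign(np.inf, d)), float(na + nb - 2)
    t = d / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def _group_stats(X: np.ndarray, idx_a, idx_b):
    """Vectorized per-protein mean difference and Welch standard error with
    NaN-aware counting. Returns (d, se, na, nb, va, vb)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        A, B = X[:, idx_a], X[:, idx_b]
        na = np.sum(~np.isnan(A), axis=1)
        nb = np.sum(~np.isnan(B), axis=1)
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va, vb = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
    d = ma - mb
    se = np.sqrt(va / na + vb / nb)
    return d, se, na, nb, va, vb


def _welch_df(va, vb, na, nb):
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        return num / den


def _null_assignments(n_samples: int, n_a: int, n_perm: int, rng) -> list:
    """Distinct group-label assignments forming the permutation null.

    The identity assignment (and for balanced designs its complement, which
    yields identical |t|) is excluded. Exhaustive when no more than
    ``n_perm`` assignments exist, otherwise a seeded sample.
    """
    identity = frozenset(range(n_a))
    excluded = {identity}
    if 2 * n_a == n_samples:
        excluded.add(frozenset(range(n_a, n_samples)))
    total = comb(n_samples, n_a) - len(excluded)
    if total < 2:
        raise ValueError("fewer than 2 distinct label permutations")
    if comb(n_samples, n_a) <= max(n_perm + len(excluded), 100_000):
        pool = [
            c
            for c in combinations(range(n_samples), n_a)
            if frozenset(c) not in excluded
        ]
        if len(pool) <= n_perm:
            return pool
        picks = rng.choice(len(pool), size=n_perm, replace=False)
        return [pool[i] for i in sorted(picks)]
    seen = set()
    while len(seen) < n_perm:
        c = frozenset(rng.choice(n_samples, size=n_a, replace=False).tolist())
        if c not in excluded:
            seen.add(c)
    return [tuple(sorted(c)) for c in sorted(seen, key=sorted)]


def permutation_fdr(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    conditions=None,
    alpha: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
    s0="median",
    log2_transform: bool = True,
    statistic: str = "moderated",
) -> pd.DataFrame:
    """Two-condition differential-abundance test with permutation FDR.

    Parameters
    ----------
    matrix
        Protein x sample intensities (typically %riBAQ), already
        detection-filtered. Missing values are excluded pairwise.
    meta
        Sample metadata with ``condition`` and ``replicate`` columns.
    conditions
        The two condition labels to compare (first vs second); defaults to
        the two conditions present.
    s0
        Variance-moderation constant: ``"median"`` (median standard error),
        a float, or 0 for the plain |t| ranking (``statistic="t"`` is an
        alias for s0=0).

    Returns
    -------
    DataFrame with one row per protein: Welch ``t``, ``df``, two-sided
    ``p_value``, the ranking ``stat``, per-condition means of the input
    matrix, ``fold_change`` (first/second condition), ``significant`` and
    ``testable`` flags. ``df.attrs`` records conditions, s0, the number of
    permutations and whether they were exhaustive.
    """
    _check_meta(meta)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if conditions is None:
        conditions = tuple(pd.unique(meta["condition"]))
    if len(conditions) != 2:
        raise ValueError("permutation_fdr compares exactly two conditions")
    cond_a, cond_b = conditions
    samples_a = meta.index[meta["condition"] == cond_a]
    samples_b = meta.index[meta["condition"] == cond_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    samples = list(samples_a) + list(samples_b)
    raw = matrix[samples].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        X = np.log2(np.where(raw > 0, raw, np.nan)) if log2_transform else raw
        mean_a = np.nanmean(raw[:, : len(samples_a)], axis=1)
        mean_b = np.nanmean(raw[:, len(samples_a) :], axis=1)

    n_a = len(samples_a)
    idx_a0 = np.arange(n_a)
    idx_b0 = np.arange(n_a, len(samples))
    d, se, na, nb, va, vb = _group_stats(X, idx_a0, idx_b0)
    testable = (na >= 2) & (nb >= 2)

    from scipy import stats as sps

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, d / se, np.where(d == 0, 0.0, np.inf * np.sign(d)))
        df = _welch_df(va, vb, na, nb)
        df = np.where(np.isfinite(df), df, na + nb - 2.0)
        p = 2 * sps.t.sf(np.abs(t), df)
    t[~testable] = np.nan
    p[~testable] = np.nan

    if statistic == "t":
        s0_val = 0.0
    elif statistic != "moderated":
        raise ValueError(f"unknown statistic {statistic!r}")
    elif s0 == "median":
        s0_val = float(np.nanmedian(se[testable])) if testable.any() else 0.0
    else:
        s0_val = float(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.abs(d) / (se + s0_val)
        if s0_val == 0:
            obs = np.where(se > 0, obs, np.where(d == 0, 0.0, np.inf))
    obs[~testable] = np.nan

    rng = np.random.default_rng(seed)
    assignments = _null_assignments(len(samples), n_a, n_perm, rng)
    null_stats = []
    for assign in assignments:
        ia = np.array(assign)
        ib = np.array([i for i in range(len(samples)) if i not in set(assign)])
        dn, sen, nan_, nbn, _, _ = _group_stats(X, ia, ib)
        with np.errstate(divide="ignore", invalid="ignore"):
            sn = np.abs(dn) / (sen + s0_val)
            if s0_val == 0:
                sn = np.where(sen > 0, sn, np.where(dn == 0, 0.0, np.inf))
        sn[(nan_ < 2) | (nbn < 2)] = np.nan
        null_stats.append(sn)
    null_flat = np.concatenate(null_stats)
    null_flat = np.sort(null_flat[~np.isnan(null_flat)])
    n_perm_used = len(assignments)

    obs_valid = np.sort(obs[testable & np.isfinite(obs)])
    significant = np.zeros(len(obs), dtype=bool)
    if alpha > 0 and len(obs_valid):
        cutoffs = np.unique(obs_valid)
        n_obs_ge = len(obs_valid) - np.searchsorted(obs_valid, cutoffs, side="left")
        n_null_ge = len(null_flat) - np.searchsorted(null_flat, cutoffs, side="left")
        # +1 correction (Phipson-Smyth): a permutation estimate is never
        # exactly zero, which keeps the plug-in FDR from being
        # anti-conservative at the extreme observed statistics
        fdr = ((n_null_ge + 1) / (n_perm_used + 1)) / np.maximum(1, n_obs_ge)
        ok = fdr <= alpha
        if ok.any():
            best = np.argmax(n_obs_ge * ok)  # largest significant set
            significant = np.asarray(obs >= cutoffs[best]) & testable

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    out = pd.DataFrame(
        {
            "protein_id": matrix.index,
            "t": t,
            "df": np.where(testable, df, np.nan),
            "p_value": p,
            "stat": obs,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "significant": significant,
            "testable": testable,
        }
    ).set_index("protein_id")
    out.attrs.update(
        conditions=(cond_a, cond_b),
        s0=s0_val,
        n_permutations=n_perm_used,
        exhaustive=n_perm_used == comb(len(samples), n_a) - (2 if len(samples_a) == len(samples_b) else 1),
        alpha=alpha,
        seed=seed,
    )
    return out


def fold_changes(
    ribaq: pd.DataFrame, meta: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Condition fold-changes relative to a reference condition.

    ratio = mean riBAQ(reference) / mean riBAQ(other); ratios > 1 are marked
    positive (induction in the reference condition); a zero denominator is
    reported as infinite with a flag.
    """
    _check_meta(meta)
    conds = list(pd.unique(meta["condition"]))
    if reference not in conds:
        raise ValueError(f"reference condition {reference!r} not in metadata")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = {
            c: np.nanmean(
                ribaq[meta.index[meta["condition"] == c]].to_numpy(float), axis=1
            )
            for c in conds
        }
    rows = []
    for cond in conds:
        if cond == reference:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = means[reference] / means[cond]
        infinite = np.isinf(ratio)
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": ribaq.index,
                    "condition": cond,
                    "ratio": ratio,
                    "positive": ratio > 1,
                    "infinite": infinite,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
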