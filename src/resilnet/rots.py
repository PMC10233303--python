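"""Reproducibility-optimized differential expression for small designs.

For a two-group comparison (e.g. a 3-vs-4 treatment experiment) the
modified statistic d = |m1 - m2| / (a1 + a2 * s) is tuned by scanning a
grid of (a1, a2) pairs — including the ordinary t-statistic limit
(a1 = 0, a2 = 1) — and a ladder of top-list sizes k.  For every candidate
the average overlap of top-k lists across B bootstrap dataset pairs is
standardized against the same overlap computed on group-label-permuted
bootstraps, and the candidate maximizing this standardized reproducibility
is selected.  Per-protein FDR is the permutation plug-in estimate: the
average number of null statistics at or above each observed d, divided by
its rank, with monotonicity enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RotsParams", "two_group_t", "rots", "summarize_de"]


def _default_alpha_grid():
    grid = [(a1, 1.0) for a1 in
            (0.0, 0.01, 0.025, 0.05, 0.1, 0.15, 0.25, 0.35, 0.5,
             0.75, 1.0, 1.5, 2.0, 3.0, 5.0)]
    grid.append((1.0, 0.0))  # pure fold-change limit
    return tuple(grid)


@dataclass
class RotsParams:
    B: int = 100
    K: int = 900
    seed: int = 1
    alpha_grid: tuple = field(default_factory=_default_alpha_grid)
    k_ladder_size: int = 12

    def __post_init__(self):
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if (0.0, 1.0) not in tuple(self.alpha_grid):
            raise ValueError("alpha grid must include the ordinary-t limit (0, 1)")


def _group_indices(groups):
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    g1 = np.flatnonzero(groups == levels[0])
    g2 = np.flatnonzero(groups == levels[1])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two samples per group")
    return levels, g1, g2


def _diff_and_se(X: np.ndarray, g1, g2):
    """Mean difference and pooled standard error per row."""
    n1, n2 = len(g1), len(g2)
    m1 = X[:, g1].mean(axis=1)
    m2 = X[:, g2].mean(axis=1)
    v1 = X[:, g1].var(axis=1, ddof=1)
    v2 = X[:, g2].var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return m1 - m2, se


def two_group_t(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """Classic equal-variance two-sample t-test per protein.

    Returns a frame with the mean difference (group1 - group2 in the
    order the labels first appear), pooled SD, t, and two-sided p.
    Rows with zero variance in both groups and zero difference get
    t = 0, p = 1.
    """
    levels, g1, g2 = _group_indices(groups)
    X = matrix.to_numpy(dtype=float)
    diff, se = _diff_and_se(X, g1, g2)
    df = len(g1) + len(g2) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), 1.0, p)
    n1, n2 = len(g1), len(g2)
    pooled_sd = se / np.sqrt(1.0 / n1 + 1.0 / n2)
    return pd.DataFrame(
        {"diff": diff, "pooled_sd": pooled_sd, "t": t, "p": p},
        index=matrix.index,
    )


def _d_stats(diff, se, alpha_grid):
    """|diff| / (a1 + a2 * se) for every candidate; shape (grid, proteins)."""
    out = np.empty((len(alpha_grid), diff.size))
    ad = np.abs(diff)
    for i, (a1, a2) in enumerate(alpha_grid):
        denom = a1 + a2 * se
        with np.errstate(divide="ignore", invalid="ignore"):
            d = ad / denom
        out[i] = np.where(denom > 0, d, 0.0)
    return out


def _top_ranks(d_row):
    order = np.argsort(-d_row, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(order.size)
    return ranks


def rots(
    matrix: pd.DataFrame,
    groups,
    params: RotsParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Reproducibility-optimized two-group differential expression.

    Returns the per-protein table (diff, t, p, d, fdr) and the chosen
    tuning ``{"alpha1", "alpha2", "k", "z"}``.  Deterministic for a fixed
    seed.
    """
    params = params or RotsParams()
    levels, g1, g2 = _group_indices(groups)
    X = matrix.to_numpy(dtype=float)
    n_prot, n_samp = X.shape
    grid = tuple(params.alpha_grid)
    rng = np.random.default_rng(params.seed)

    ladder = np.unique(
        np.round(
            np.logspace(np.log10(5), np.log10(max(min(params.K, n_prot - 1), 5)),
                        params.k_ladder_size)
        ).astype(int)
    )
    ladder = ladder[ladder >= 1]

    def stat_ranks(cols_g1, cols_g2, Xd):
        diff, se = _diff_and_se(Xd, cols_g1, cols_g2)
        D = _d_stats(diff, se, grid)
        return np.stack([_top_ranks(D[i]) for i in range(len(grid))])

    def bootstrap_dataset(perm_labels: bool):
        if perm_labels:
            cols = rng.permutation(n_samp)
            h1, h2 = cols[: len(g1)], cols[len(g1):]
        else:
            h1, h2 = g1, g2
        b1 = rng.choice(h1, len(h1), replace=True)
        b2 = rng.choice(h2, len(h2), replace=True)
        sub = X[:, np.concatenate([b1, b2])]
        return stat_ranks(np.arange(len(b1)), np.arange(len(b1), len(b1) + len(b2)), sub)

    n_grid, n_k = len(grid), len(ladder)
    obs_overlap = np.zeros((params.B, n_grid, n_k))
    null_overlap = np.zeros((params.B, n_grid, n_k))
    for b in range(params.B):
        rA, rB = bootstrap_dataset(False), bootstrap_dataset(False)
        nA, nB = bootstrap_dataset(True), bootstrap_dataset(True)
        for i in range(n_grid):
            for j, k in enumerate(ladder):
                obs_overlap[b, i, j] = np.sum((rA[i] < k) & (rB[i] < k)) / k
                null_overlap[b, i, j] = np.sum((nA[i] < k) & (nB[i] < k)) / k

    null_sd = null_overlap.std(axis=0, ddof=1)
    z = (obs_overlap.mean(axis=0) - null_overlap.mean(axis=0)) / np.where(
        null_sd > 0, null_sd, np.inf
    )
    i_best, j_best = np.unravel_index(np.argmax(z), z.shape)
    a1, a2 = grid[i_best]
    chosen = {"alpha1": float(a1), "alpha2": float(a2),
              "k": int(ladder[j_best]), "z": float(z[i_best, j_best])}

    # observed statistic with the chosen candidate
    diff, se = _diff_and_se(X, g1, g2)
    d_obs = _d_stats(diff, se, [(a1, a2)])[0]

    # permutation null for the FDR plug-in
    null_d = np.empty((params.B, n_prot))
    for b in range(params.B):
        cols = rng.permutation(n_samp)
        dn, sn = _diff_and_se(X, cols[: len(g1)], cols[len(g1):])
        null_d[b] = _d_stats(dn, sn, [(a1, a2)])[0]
    null_sorted = np.sort(null_d.ravel())
    order = np.argsort(-d_obs, kind="stable")
    n_null = null_sorted.size
    fdr_sorted = np.empty(n_prot)
    for rank, idx in enumerate(order, start=1):
        n_ge = n_null - np.searchsorted(null_sorted, d_obs[idx], side="left")
        fdr_sorted[rank - 1] = (n_ge / params.B) / rank
    fdr_sorted = np.minimum(np.maximum.accumulate(fdr_sorted), 1.0)
    fdr = np.empty(n_prot)
    fdr[order] = fdr_sorted

    t_tab = two_group_t(matrix, groups)
    table = pd.DataFrame(
        {"diff": diff, "t": t_tab["t"], "p": t_tab["p"], "d": d_obs, "fdr": fdr},
        index=matrix.index,
    )
    return table, chosen


def summarize_de(
    de_table: pd.DataFrame,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.1,
) -> dict:
    """Signed significance counts and a volcano-ready export.

    Counts proteins increased/decreased at the raw-p threshold and those
    passing the FDR threshold; the returned ``volcano`` frame carries the
    effect, -log10 p, and both significance flags.
    """
    if de_table.empty:
        return {"n_up": 0, "n_down": 0, "n_fdr": 0,
                "volcano": pd.DataFrame(columns=["diff", "neg_log10_p",
                                                 "significant", "fdr_pass"])}
    sig = de_table["p"] < p_threshold
    up = int((sig & (de_table["diff"] > 0)).sum())
    down = int((sig & (de_table["diff"] < 0)).sum())
    n_fdr = int((de_table.get("fdr", pd.Series(1.0, index=de_table.index))
                 <= fdr_threshold).sum())
    volcano = pd.DataFrame(
        {
            "diff": de_table["diff"],
            "neg_log10_p": -np.log10(np.clip(de_table["p"], 1e-300, 1.0)),
            "significant": sig,
            "fdr_pass": de_table.get("fdr", pd.Series(1.0, index=de_table.index))
            <= fdr_threshold,
        }
    )
    return {"n_up": up, "n_down": down, "n_fdr": n_fdr, "volcano": volcano}
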