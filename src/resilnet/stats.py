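"""Module- and protein-level association statistics.

Relates module eigenproteins and individual proteins to pathological
(amyloid, tangle burden) and clinical (global cognition, cognitive slope)
traits via biweight midcorrelation, and to diagnosis groups via one-way
ANOVA with Tukey HSD or Holm-adjusted pairwise post hoc tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .network import bicor, corr_pvalue

__all__ = [
    "me_trait_correlation",
    "groupwise_anova",
    "variance_explained",
    "protein_de",
]


def _bicor_with_p(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    r = bicor(x, y)
    if not np.isfinite(r):
        return np.nan, np.nan, n
    return r, float(corr_pvalue(r, n)), n


def me_trait_correlation(
    mes_by_region: dict[str, pd.DataFrame],
    traits: pd.DataFrame,
    trait_cols=("amyloid", "tangles", "global_cognition", "cognitive_slope"),
) -> pd.DataFrame:
    """Biweight midcorrelation of eigenproteins with trait columns.

    ``traits`` is indexed by sample id (matching each region's
    eigenprotein index); constant traits produce missing entries.
    Returns a long table (region, module, trait, bicor, p, n).
    """
    rows = []
    for region, mes in mes_by_region.items():
        tr = traits.reindex(mes.index)
        for module in mes.columns:
            for trait in trait_cols:
                if trait not in tr:
                    continue
                r, p, n = _bicor_with_p(mes[module], tr[trait])
                rows.append(
                    dict(region=region, module=module, trait=trait,
                         bicor=r, p=p, n=n)
                )
    return pd.DataFrame(rows)


def groupwise_anova(
    values,
    groups,
    posthoc: str = "tukey",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across diagnosis groups with a post hoc table.

    ``posthoc`` is "tukey" (Tukey HSD), "holm" (all pairwise two-sample
    t-tests, Holm-adjusted), or "both".  Groups with fewer than two
    observations raise a ValueError naming the group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    levels = pd.unique(groups)
    samples = []
    for g in levels:
        v = values[groups == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(v)
    F, p = sps.f_oneway(*samples)
    out = {"F": float(F), "p": float(p), "groups": list(map(str, levels))}

    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    if posthoc in ("holm", "both"):
        raw = []
        for i, j in pairs:
            t, pp = sps.ttest_ind(samples[i], samples[j])
            raw.append(pp)
        adj = multipletests(raw, method="holm")[1] if raw else []
        out["holm"] = pd.DataFrame(
            {
                "group1": [str(levels[i]) for i, _ in pairs],
                "group2": [str(levels[j]) for _, j in pairs],
                "p_raw": raw,
                "p_holm": adj,
            }
        )
    if posthoc in ("tukey", "both"):
        res = pairwise_tukeyhsd(values, groups, alpha=alpha)
        out["tukey"] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return out


def variance_explained(protein, trait) -> float:
    """R^2 of a simple linear regression of the trait on protein abundance."""
    x = np.asarray(protein, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def protein_de(
    matrix: pd.DataFrame,
    groups,
    posthoc: str = "tukey",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein group ANOVA with pairwise contrasts (vectorized).

    Pairwise p-values are Tukey HSD (studentized range on the pooled MSE)
    or pairwise pooled-variance t-tests with Holm adjustment per protein.
    Returns the long contrast table (protein, contrast, mean difference,
    omnibus F/p, pairwise p) and a per-contrast summary of significant
    counts at ``alpha`` (split by sign of the difference).
    """
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    G = len(levels)
    if G < 2:
        raise ValueError("need at least two groups")
    X = matrix.to_numpy(dtype=float)
    obs = np.isfinite(X)
    n_g = np.stack([(obs[:, groups == g]).sum(axis=1) for g in levels], axis=1)
    if np.any(n_g.min(axis=0) < 2):
        bad = levels[int(np.argmin(n_g.min(axis=0)))]
        raise ValueError(f"group {bad!r} has fewer than 2 observations")
    with np.errstate(invalid="ignore"):
        means = np.stack(
            [np.nanmean(X[:, groups == g], axis=1) for g in levels], axis=1
        )
        varis = np.stack(
            [np.nanvar(X[:, groups == g], axis=1, ddof=1) for g in levels], axis=1
        )
    N = n_g.sum(axis=1)
    grand = (n_g * means).sum(axis=1) / N
    ssb = (n_g * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((n_g - 1) * varis).sum(axis=1)
    df_w = N - G
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / (G - 1)) / (ssw / df_w)
    p_omni = sps.f.sf(F, G - 1, df_w)
    mse = ssw / df_w

    pairs = [(i, j) for i in range(G) for j in range(i + 1, G)]
    rows = []
    p_pair = np.empty((X.shape[0], len(pairs)))
    diffs = np.empty_like(p_pair)
    for c, (i, j) in enumerate(pairs):
        diffs[:, c] = means[:, j] - means[:, i]
        if posthoc == "tukey":
            se = np.sqrt(mse / 2.0 * (1.0 / n_g[:, i] + 1.0 / n_g[:, j]))
            with np.errstate(invalid="ignore", divide="ignore"):
                q = np.abs(diffs[:, c]) / se
            p_pair[:, c] = sps.studentized_range.sf(q, G, df_w)
        else:  # holm over pairwise pooled-variance t-tests
            df_ij = n_g[:, i] + n_g[:, j] - 2
            sp2 = ((n_g[:, i] - 1) * varis[:, i] + (n_g[:, j] - 1) * varis[:, j]) / df_ij
            se = np.sqrt(sp2 * (1.0 / n_g[:, i] + 1.0 / n_g[:, j]))
            with np.errstate(invalid="ignore", divide="ignore"):
                t = diffs[:, c] / se
            p_pair[:, c] = 2.0 * sps.t.sf(np.abs(t), df_ij)
    p_pair = np.nan_to_num(p_pair, nan=1.0)
    if posthoc != "tukey":
        order = np.argsort(p_pair, axis=1)
        m = len(pairs)
        adj = np.take_along_axis(p_pair, order, axis=1) * (m - np.arange(m))
        adj = np.minimum(np.maximum.accumulate(adj, axis=1), 1.0)
        p_holm = np.empty_like(p_pair)
        np.put_along_axis(p_holm, order, adj, axis=1)
        p_pair = p_holm
    for c, (i, j) in enumerate(pairs):
        contrast = f"{levels[j]}-{levels[i]}"
        rows.append(pd.DataFrame({
            "protein": matrix.index,
            "contrast": contrast,
            "diff": diffs[:, c],
            "F": F,
            "p_omnibus": p_omni,
            "p_pairwise": p_pair[:, c],
        }))
    table = pd.concat(rows, ignore_index=True)
    if table.empty:
        return table, pd.DataFrame(columns=["contrast", "n_up", "n_down", "n_sig"])
    # volcano convention: a protein is significant for a contrast when the
    # omnibus ANOVA p clears alpha; pairwise p-values qualify the contrast
    sig = table[table["p_omnibus"] < alpha]
    summary = (
        sig.assign(up=sig["diff"] > 0)
        .groupby("contrast")
        .agg(n_up=("up", "sum"), n_sig=("up", "size"))
        .reset_index()
    )
    summary["n_up"] = summary["n_up"].astype(int)
    summary["n_down"] = summary["n_sig"] - summary["n_up"]
    return table, summary[["contrast", "n_up", "n_down", "n_sig"]]
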