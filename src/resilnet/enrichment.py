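"""Gene-set enrichment statistics for modules.

Three flavors are used downstream of network construction:

* one-tailed Fisher exact tests (cell-type markers, cross-species overlap)
  with Benjamini-Hochberg correction;
* a one-proportion Z-score with finite-population correction (ontology
  term reports, significant above 1.96, i.e. two-sided p < 0.05);
* a permutation Z for PWAS summary statistics: the mean p-value score of
  the module's PWAS hits is compared with the mean over random same-size
  symbol draws from the tested background (10,000 permutations), with an
  exact add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "merge_marker_lists",
    "fisher_enrichment",
    "geneset_zscore",
    "pwas_module_enrichment",
    "bh_adjust",
    "SIGNIFICANCE_Z",
]

# standard-normal deviate for the default two-sided enrichment alpha (0.05)
SIGNIFICANCE_Z = float(sps.norm.isf(0.05 / 2.0))


def _upper(symbols: Iterable[str]) -> frozenset:
    return frozenset(str(s).upper() for s in symbols)


@dataclass
class GeneSetCollection:
    """Named symbol sets over a background universe (symbols uppercased)."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sets = {name: _upper(s) for name, s in self.sets.items()}
        universe = _upper(self.universe)
        for s in self.sets.values():
            universe = universe | s
        self.universe = universe

    def harmonized(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to the given universe."""
        uni = _upper(universe)
        return GeneSetCollection(
            sets={n: s & uni for n, s in self.sets.items()},
            universe=uni,
            provenance=dict(self.provenance),
        )

    @classmethod
    def from_labels(cls, labels: pd.Series, provenance: str = "modules"):
        """Build module gene sets from a protein -> module label series
        (protein ids may be "Symbol|Accession")."""
        symbols = labels.index.map(lambda p: str(p).split("|")[0].upper())
        sets: dict[str, set] = {}
        for sym, lab in zip(symbols, labels.values):
            if lab in (0, "M0", None):
                continue
            sets.setdefault(str(lab), set()).add(sym)
        return cls(
            sets={k: frozenset(v) for k, v in sets.items()},
            universe=frozenset(symbols),
            provenance={k: provenance for k in sets},
        )


def merge_marker_lists(
    list_a: Mapping[str, Iterable[str]],
    list_b: Mapping[str, Iterable[str]],
    priority: str = "b",
) -> GeneSetCollection:
    """Merge two cell-type marker lists into one-type-per-symbol sets.

    On conflict (a symbol typed differently by the two lists) the
    priority list's assignment wins, so each symbol ends up affiliated
    with exactly one cell type.
    """
    first, second = (list_a, list_b) if priority == "b" else (list_b, list_a)
    assign: dict[str, str] = {}
    for source in (first, second):  # the later write wins -> priority last
        for ctype, syms in source.items():
            for s in _upper(syms):
                assign[s] = ctype
    sets: dict[str, set] = {}
    for sym, ctype in assign.items():
        sets.setdefault(ctype, set()).add(sym)
    return GeneSetCollection(
        sets={k: frozenset(v) for k, v in sets.items()},
        provenance={k: "merged marker list" for k in sets},
    )


def fisher_enrichment(
    query: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """One-tailed Fisher exact test of query/category overlap.

    Returns (odds ratio, p, fold enrichment); the odds ratio uses a
    Haldane 0.5 correction when any table cell is zero.  Query and
    category are intersected with the universe first.
    """
    uni = _upper(universe)
    if not uni:
        raise ValueError("empty universe")
    q = _upper(query) & uni
    c = _upper(category) & uni
    r = len(q & c)
    a, b = r, len(q) - r
    cc, d = len(c) - r, len(uni) - len(q) - len(c) + r
    _, p = sps.fisher_exact([[a, b], [cc, d]], alternative=alternative)
    if min(a, b, cc, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (cc + 0.5))
    else:
        odds = (a * d) / (b * cc)
    expected = len(q) * len(c) / len(uni)
    fold = r / expected if expected > 0 else float("nan")
    return float(odds), float(p), float(fold)


def geneset_zscore(
    query: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-proportion Z with finite-population correction.

    Z = (r - nR/N) / sqrt(n (R/N)(1 - R/N)(1 - (n-1)/(N-1))) with N the
    universe size, R the category size, n the query size, and r the
    overlap.  Values above 1.96 correspond to two-sided p < 0.05.
    """
    uni = _upper(universe)
    q = _upper(query) & uni
    c = _upper(category) & uni
    N, R, n = len(uni), len(c), len(q)
    if n == 0 or R == 0 or R == N or N < 2:
        return float("nan")
    r = len(q & c)
    pr = R / N
    var = n * pr * (1.0 - pr) * (1.0 - (n - 1) / (N - 1))
    if var <= 0:
        return float("nan")
    return float((r - n * pr) / np.sqrt(var))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pwas_module_enrichment(
    modules: GeneSetCollection,
    pwas: pd.DataFrame,
    direction: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    score: str = "neglog10",
    replace: bool = False,
) -> pd.DataFrame:
    """Permutation Z for enrichment of PWAS hits in each module.

    The observed statistic is the mean score of the PWAS symbols falling
    in the module (score = -log10 p by default, so enrichment for small
    p-values is positive; ``score="raw_mean_p"`` uses the mean p-value
    itself, sign-flipped so enrichment stays positive).  The null is the
    same-size mean over random symbol draws from the full tested
    background (without replacement by default); Z standardizes the
    observed mean against the permutation distribution and the exact
    permutation p uses the add-one estimator.

    Parameters
    ----------
    modules : module gene sets.
    pwas : DataFrame with columns symbol, p_value, direction.
    direction : restrict the hit list to "positive" or "negative"
        associations (None = all).
    """
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations: p-values are coarse")
    tab = pwas.copy()
    tab["symbol"] = tab["symbol"].astype(str).str.upper()
    if direction is not None:
        hits = tab[tab["direction"] == direction]
    else:
        hits = tab
    if hits.empty:
        raise ValueError("no PWAS entries for the requested direction")
    hits = hits.drop_duplicates("symbol")
    if score == "neglog10":
        bg_scores = -np.log10(np.clip(tab["p_value"].to_numpy(float), 1e-300, 1.0))
        hit_scores = pd.Series(
            -np.log10(np.clip(hits["p_value"].to_numpy(float), 1e-300, 1.0)),
            index=hits["symbol"].values,
        )
        sign = 1.0
    elif score == "raw_mean_p":
        bg_scores = tab["p_value"].to_numpy(float)
        hit_scores = pd.Series(
            hits["p_value"].to_numpy(float), index=hits["symbol"].values
        )
        sign = -1.0  # small mean p = enrichment -> positive Z
    else:
        raise ValueError(f"unknown score {score!r}")

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_means(size: int) -> np.ndarray:
        if size not in null_cache:
            if replace:
                draws = rng.choice(bg_scores, (n_perm, size), replace=True)
                means = draws.mean(axis=1)
            else:
                means = np.empty(n_perm)
                for i in range(n_perm):
                    means[i] = bg_scores[
                        rng.choice(bg_scores.size, size, replace=False)
                    ].mean()
            null_cache[size] = means
        return null_cache[size]

    rows = []
    for name, members in modules.sets.items():
        overlap = [s for s in hit_scores.index if s in members]
        row = {"module": name, "overlap": len(overlap)}
        if len(overlap) < 1:
            row.update(observed=np.nan, z=np.nan, p_perm=np.nan,
                       reason="no overlap with PWAS list")
            rows.append(row)
            continue
        obs = float(hit_scores.loc[overlap].mean())
        null = null_means(len(overlap))
        sd = null.std(ddof=1)
        z = sign * (obs - null.mean()) / sd if sd > 0 else np.nan
        if sign > 0:
            n_ge = int(np.sum(null >= obs))
        else:
            n_ge = int(np.sum(null <= obs))
        p_perm = (n_ge + 1) / (n_perm + 1)
        row.update(observed=obs, z=float(z), p_perm=float(p_perm), reason="")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("module")
    out.attrs["score"] = score
    out.attrs["replace"] = replace
    out.attrs["n_perm"] = n_perm
    return out
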