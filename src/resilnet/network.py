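"""Consensus signed weighted co-expression networks.

Builds, for each tissue region, a signed adjacency from biweight
midcorrelations raised to a soft-threshold power, converts it to a
topological overlap matrix (TOM), combines the per-region TOMs into a
consensus (componentwise quantile after 95th-percentile scaling), and
clusters 1 - TOM to obtain co-expression modules, their eigenproteins
(first principal components), module memberships (kME), merged modules,
and permutation-based preservation statistics.

Module detection uses a simplified dynamic-hybrid tree cut: branches of
the average-linkage dendrogram are admitted as modules when they are large
enough, internally tight (low "core scatter" of merge heights), separated
from their surroundings (height gap), and coherent in absolute TOM terms;
borderline proteins are then attached to their nearest module by average
topological overlap (the PAM-style stage).  Exact agreement with the
reference dynamic tree cut is not a goal — recovery of planted structure
is what the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "ModuleSet",
    "ConsensusNetwork",
    "bicor",
    "bicor_matrix",
    "corr_pvalue",
    "signed_adjacency",
    "tom_similarity",
    "consensus_tom",
    "detect_modules",
    "eigenprotein",
    "kme",
    "merge_modules",
    "reassign_proteins",
    "preservation_zsummary",
    "build_consensus_network",
]

# deep_split -> maximum normalized core scatter a module branch may have;
# the required gap is 3/4 of what remains above it
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass
class NetworkParams:
    power: float = 7.0
    deep_split: int = 4
    min_module_size: int = 30
    merge_cut_height: float = 0.07
    tom_denominator: str = "mean"  # or "min"
    consensus_quantile: float = 0.0  # 0 = componentwise minimum
    consensus_scale: bool = True
    pam_stage: bool = True
    reassign_threshold: float = 0.05
    cut_fraction: float = 0.99
    coherence_factor: float = 2.0
    n_preservation_perms: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.power <= 0:
            raise ValueError("power must be positive")
        if not 0 <= self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in [0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.deep_split not in _MAX_CORE_SCATTER:
            raise ValueError("deep_split must be an integer 0-4")


@dataclass
class ModuleSet:
    """Module labels plus the derived per-module quantities.

    Labels are "M1".."Mk" ordered by decreasing size with "M0" for
    unassigned proteins; eigenproteins are unit-variance sample scores
    per region; kME is the consensus (mean across regions) Pearson
    correlation of each protein with each module eigenprotein.
    """

    labels: pd.Series
    eigenproteins: dict[str, pd.DataFrame]
    kme: pd.DataFrame
    kme_by_region: dict[str, pd.DataFrame] = field(default_factory=dict)
    merge_history: list = field(default_factory=list)
    var_explained: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [c for c in self.kme.columns]

    def members(self, name: str) -> list[str]:
        return list(self.labels.index[self.labels == name])

    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        return counts[counts.index != "M0"]

    def to_gmt(self, path, description: str = "consensus module") -> None:
        with open(path, "w") as fh:
            for name in self.module_names:
                syms = sorted({p.split("|")[0].upper() for p in self.members(name)})
                fh.write("\t".join([name, description] + syms) + "\n")


@dataclass
class ConsensusNetwork:
    params: NetworkParams
    proteins: pd.Index
    regions: list[str]
    modules: ModuleSet
    consensus_tom: np.ndarray | None = None
    module_ints: np.ndarray | None = None


# ---------------------------------------------------------------------------
# correlation primitives


def _biweight_terms(x: np.ndarray):
    """Tukey-biweight deviations a_i = w_i * (x_i - med); Pearson fallback
    when the MAD vanishes."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x - x.mean()
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return w * (x - med)


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete).

    Returns NaN when fewer than four paired finite observations remain.
    A vector whose median absolute deviation is zero falls back to
    Pearson centering for that vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        return float("nan")
    a = _biweight_terms(x[ok])
    b = _biweight_terms(y[ok])
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def bicor_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """All-pairs biweight midcorrelation of the rows of ``X``.

    Missing entries are handled by computing each row's biweight terms on
    its observed values and restricting every pairwise sum to the common
    support (medians/MADs are per-row, not per-pair — the usual fast
    approximation).  Rows with zero MAD fall back to Pearson centering.
    """
    X = np.asarray(X, dtype=float)
    obs = np.isfinite(X)
    A = np.zeros_like(X)
    for i in range(X.shape[0]):
        xi = X[i, obs[i]]
        if xi.size == 0:
            continue
        A[i, obs[i]] = _biweight_terms(xi)
    M = obs.astype(float)
    num = A @ A.T
    s = (A * A) @ M.T  # s[i, j] = sum of a_i^2 over samples observed in j
    denom = np.sqrt(s * s.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def corr_pvalue(r, n):
    """Two-sided Student-t p-value for a correlation with n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    return 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))


def signed_adjacency(C: np.ndarray, beta: float = 7.0) -> np.ndarray:
    """Signed soft-threshold adjacency a = ((1 + c) / 2) ** beta."""
    C = np.asarray(C, dtype=float)
    a = ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(A: np.ndarray, denominator: str = "mean") -> np.ndarray:
    """Topological overlap of a symmetric adjacency with unit diagonal.

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (f(k_i, k_j) + 1 - A_ij) with the
    sums excluding i and j, k the off-diagonal connectivity, and f the
    mean (default) or min of the two connectivities.
    """
    A = np.asarray(A, dtype=float)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    shared = A0 @ A0  # sum over all u != i of A_iu A_uj; includes u == j term
    # remove the u == j and u == i contributions (A_ij * A_jj and A_ii * A_ij are
    # not in A0 products since diag is zero; but u == j gives A_ij * 0 = 0)
    num = shared + A0
    k = A0.sum(axis=1)
    if denominator == "mean":
        f = (k[:, None] + k[None, :]) / 2.0
    elif denominator == "min":
        f = np.minimum(k[:, None], k[None, :])
    else:
        raise ValueError(f"unknown TOM denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / (f + 1.0 - A0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def consensus_tom(
    toms: list[np.ndarray],
    quantile: float = 0.0,
    scale: bool = True,
    scale_quantile: float = 0.95,
) -> np.ndarray:
    """Componentwise quantile of per-region TOMs (0 = minimum).

    With ``scale``, every TOM is first rescaled so that its
    ``scale_quantile`` off-diagonal quantile matches the first TOM's,
    removing region-level differences in overall topological overlap.
    """
    shapes = {t.shape for t in toms}
    if len(shapes) != 1:
        raise ValueError("TOMs must share a shape")
    toms = [np.asarray(t, dtype=float) for t in toms]
    if scale and len(toms) > 1:
        iu = np.triu_indices_from(toms[0], k=1)
        ref_q = np.quantile(toms[0][iu], scale_quantile)
        scaled = [toms[0]]
        for t in toms[1:]:
            q = np.quantile(t[iu], scale_quantile)
            scaled.append(t * (ref_q / q) if q > 0 else t)
        toms = scaled
    stack = np.stack(toms)
    cons = np.min(stack, axis=0) if quantile == 0 else np.quantile(stack, quantile, axis=0)
    cons = np.clip(cons, 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return cons


# ---------------------------------------------------------------------------
# module detection


def detect_modules(T: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Cluster 1 - TOM and emit integer module labels (0 = unassigned).

    Average-linkage branches are admitted as module cores when they (a)
    hold at least ``min_module_size`` proteins below the static cut
    height, (b) have normalized core scatter at most the deep-split
    bound, (c) are separated from their merge context by the minimum gap,
    and (d) exceed ``coherence_factor`` times the median off-diagonal TOM
    in mean internal overlap — the absolute check that keeps pure-noise
    branches out.  Rejected branches are descended into recursively.
    Remaining proteins are attached to their nearest core by average TOM
    (PAM stage) when that overlap clears the same coherence bar.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < params.min_module_size:
        return labels
    d = 1.0 - T
    condensed = squareform(d, checks=False)
    Z = average(condensed)
    heights = Z[:, 2]
    h_max = heights.max()
    if h_max <= 0:
        return labels
    cut_h = heights.min() + params.cut_fraction * (h_max - heights.min())
    ref_lo = np.quantile(heights, 0.05)
    span = max(cut_h - ref_lo, 1e-12)

    def norm(h):
        return (h - ref_lo) / span

    mcs = _MAX_CORE_SCATTER[params.deep_split]
    min_gap = (1.0 - mcs) * 0.75
    med_tom = 1.0 - np.median(condensed)
    coh_min = params.coherence_factor * max(med_tom, 1e-12)

    # per-node bookkeeping from the linkage matrix
    counts = np.ones(2 * n - 1)
    counts[n:] = Z[:, 3]
    sum_h = np.zeros(2 * n - 1)
    node_h = np.zeros(2 * n - 1)
    for i in range(n - 1):
        l, r = int(Z[i, 0]), int(Z[i, 1])
        sum_h[n + i] = sum_h[l] + sum_h[r] + Z[i, 2]
        node_h[n + i] = Z[i, 2]

    def leaves_of(node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((int(Z[v - n, 0]), int(Z[v - n, 1])))
        return np.asarray(out)

    def qualifies(node: int, parent_h: float) -> np.ndarray | None:
        if node_h[node] > cut_h:
            return None
        scatter = norm(sum_h[node] / (counts[node] - 1))
        gap = norm(parent_h) - scatter
        if scatter > mcs or gap < min_gap:
            return None
        idx = leaves_of(node)
        # prune hangers-on: members whose overlap with the rest falls far
        # below the branch average are not part of the core (the PAM stage
        # can re-attach them if they genuinely belong); iterate to a fixed
        # point so a core minority is not hidden by a noisy majority
        for _ in range(5):
            sub = T[np.ix_(idx, idx)]
            mean_to_rest = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
            core = mean_to_rest >= 0.3 * mean_to_rest.mean()
            if core.sum() < params.min_module_size:
                return None
            if core.all():
                break
            idx = idx[core]
        sub = T[np.ix_(idx, idx)]
        mean_tom = (sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1))
        return idx if mean_tom >= coh_min else None

    # deepest-qualifying-split policy: a node becomes a module only when no
    # deeper branch qualifies on its own — the gap criterion keeps halves of
    # a homogeneous module from splitting (they join far below their context)
    # while distinct modules glued into one branch do split apart.
    results: dict[int, list[np.ndarray]] = {}
    stack: list[tuple[int, float, bool]] = [(2 * n - 2, h_max, False)]
    while stack:
        node, parent_h, expanded = stack.pop()
        if node < n or counts[node] < params.min_module_size:
            results[node] = []
            continue
        children = (int(Z[node - n, 0]), int(Z[node - n, 1]))
        if not expanded:
            stack.append((node, parent_h, True))
            stack.extend((c, node_h[node], False) for c in children)
            continue
        child_mods = results.pop(children[0]) + results.pop(children[1])
        if child_mods:
            results[node] = child_mods
        else:
            idx = qualifies(node, parent_h)
            results[node] = [idx] if idx is not None else []
    modules = results[2 * n - 2]

    for i, idx in enumerate(modules, start=1):
        labels[idx] = i

    if params.pam_stage and modules:
        labels = _pam_assign(T, labels, coh_min)
    return _renumber_by_size(labels)


def _pam_assign(
    T: np.ndarray, labels: np.ndarray, coh_min: float, pam_ratio: float = 0.3
) -> np.ndarray:
    """Attach unassigned proteins to the nearest module by mean TOM.

    A protein is attached only when its average overlap with the winning
    module clears both the absolute coherence floor and ``pam_ratio``
    times that module's internal mean overlap, so background proteins are
    not vacuumed into modules.
    """
    labels = labels.copy()
    mods = [m for m in np.unique(labels) if m != 0]
    free = np.flatnonzero(labels == 0)
    if len(free) == 0:
        return labels
    internal = np.empty(len(mods))
    for j, m in enumerate(mods):
        idx = np.flatnonzero(labels == m)
        sub = T[np.ix_(idx, idx)]
        internal[j] = (sub.sum() - len(idx)) / max(len(idx) * (len(idx) - 1), 1)
    mean_tom = np.column_stack([T[:, labels == m].mean(axis=1) for m in mods])
    best = mean_tom[free].argmax(axis=1)
    best_val = mean_tom[free, best]
    accept = (best_val >= coh_min) & (best_val >= pam_ratio * internal[best])
    labels[free[accept]] = np.asarray(mods)[best[accept]]
    return labels


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    mods, counts = np.unique(labels[labels != 0], return_counts=True)
    order = mods[np.lexsort((mods, -counts))]
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# eigenproteins, kME, merging, reassignment


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (X - mu) / sd
    return np.where(np.isfinite(z), z, 0.0)  # mean-impute for decomposition only


def eigenprotein(
    m: pd.DataFrame, labels: np.ndarray, module_ids=None
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First-principal-component sample scores per module.

    Module submatrices are standardized per protein (missing values
    mean-imputed only for the decomposition), the leading left singular
    vector of the samples x proteins block gives the eigenprotein, scaled
    to unit variance and oriented so its mean correlation with the member
    proteins is non-negative.  Returns the samples x modules frame and
    the fraction of module variance each eigenprotein explains.
    """
    if module_ids is None:
        module_ids = [v for v in np.unique(labels) if v != 0]
    Z = _standardize_rows(m.to_numpy(dtype=float))
    scores = {}
    var_exp = {}
    for mod in module_ids:
        idx = np.flatnonzero(labels == mod)
        if idx.size == 0:
            raise ValueError(f"module {mod} has no members")
        block = Z[idx].T  # samples x proteins
        if idx.size == 1:
            me = block[:, 0]
            var_exp[mod] = 1.0
        else:
            u, s, _ = np.linalg.svd(block - block.mean(axis=0), full_matrices=False)
            me = u[:, 0] * s[0]
            var_exp[mod] = float(s[0] ** 2 / (s**2).sum())
        sd = me.std(ddof=1)
        me = me / sd if sd > 0 else me
        orient = np.corrcoef(np.vstack([me, block.T]))[0, 1:]
        if np.nanmean(orient) < 0:
            me = -me
        scores[mod] = me
    mes = pd.DataFrame(scores, index=m.columns)
    return mes, var_exp


def kme(m: pd.DataFrame, mes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of proteins with eigenproteins."""
    X = m.to_numpy(dtype=float)
    obs = np.isfinite(X)
    Xz = np.where(obs, X, 0.0)
    M = obs.astype(float)
    out = np.empty((X.shape[0], mes.shape[1]))
    for j, col in enumerate(mes.columns):
        y = mes[col].to_numpy(dtype=float)
        n = M @ np.ones_like(y)
        sx = Xz.sum(axis=1)
        sy = M @ y
        sxy = Xz @ y
        sxx = (Xz**2).sum(axis=1)
        syy = M @ (y**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (n * sxy - sx * sy) / np.sqrt(
                (n * sxx - sx**2) * (n * syy - sy**2)
            )
        out[:, j] = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(out, index=m.index, columns=mes.columns)


def merge_modules(
    data_by_region: dict[str, pd.DataFrame],
    labels: np.ndarray,
    cut_height: float = 0.07,
    max_rounds: int = 10,
) -> tuple[np.ndarray, list]:
    """Merge modules whose eigenproteins are closer than ``cut_height``.

    Dissimilarity between two modules is the maximum over regions of
    1 - cor(ME_a, ME_b) (the consensus convention); modules joining below
    the cut height in an average-linkage tree are merged, eigenproteins
    recomputed, and the procedure repeated until stable.
    """
    labels = labels.copy()
    history: list[dict] = []
    if cut_height <= 0:
        return labels, history
    for round_no in range(max_rounds):
        mods = [v for v in np.unique(labels) if v != 0]
        if len(mods) < 2:
            break
        diss = np.zeros((len(mods), len(mods)))
        for region, data in data_by_region.items():
            mes, _ = eigenprotein(data, labels, module_ids=mods)
            c = np.corrcoef(mes.to_numpy().T)
            diss = np.maximum(diss, 1.0 - c)
        np.fill_diagonal(diss, 0.0)
        Zl = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(Zl, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        merged = {}
        for g in np.unique(groups):
            members = [mods[i] for i in np.flatnonzero(groups == g)]
            if len(members) > 1:
                keep = min(members)
                for mod in members:
                    if mod != keep:
                        labels[labels == mod] = keep
                merged[keep] = members
        history.append({"round": round_no + 1, "merged": merged})
    return _renumber_by_size(labels), history


def reassign_proteins(
    labels: np.ndarray,
    kme_table: pd.DataFrame,
    n_samples: int,
    threshold: float = 0.05,
) -> np.ndarray:
    """Move proteins whose current kME is non-significant to a better module.

    A protein switches to the module of its maximal kME when the p-value
    of its current-module kME exceeds ``threshold`` while the best
    module's kME p-value is at or below it.
    """
    labels = labels.copy()
    mods = list(kme_table.columns)
    K = kme_table.to_numpy(dtype=float)
    P = corr_pvalue(K, n_samples)
    col_of = {m: j for j, m in enumerate(mods)}
    for i in range(len(labels)):
        cur = labels[i]
        if cur == 0 or cur not in col_of:
            continue
        j_cur = col_of[cur]
        j_best = int(np.nanargmax(K[i]))
        if j_best == j_cur:
            continue
        if P[i, j_cur] > threshold and P[i, j_best] <= threshold:
            labels[i] = mods[j_best]
    return labels


# ---------------------------------------------------------------------------
# preservation


def _preservation_stats(A_ref, A_test, idx):
    sub_t = A_test[np.ix_(idx, idx)]
    sub_r = A_ref[np.ix_(idx, idx)]
    s = len(idx)
    mean_adj = (sub_t.sum() - s) / (s * (s - 1))
    k_r = sub_r.sum(axis=1) - 1.0
    k_t = sub_t.sum(axis=1) - 1.0
    cor_kim = _safe_corr(k_r, k_t)
    iu = np.triu_indices(s, k=1)
    cor_adj = _safe_corr(sub_r[iu], sub_t[iu])
    return mean_adj, cor_kim, cor_adj


def _safe_corr(a, b):
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _perm_z(obs, null, cap=1e6):
    null = np.asarray(null, dtype=float)
    mu, sd = null.mean(), null.std(ddof=1)
    if sd < 1e-12:
        if abs(obs - mu) < 1e-9:
            return 0.0
        return cap if obs > mu else -cap
    return float(np.clip((obs - mu) / sd, -cap, cap))


def preservation_zsummary(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    labels: pd.Series,
    n_perms: int = 500,
    seed: int = 0,
    power: float = 7.0,
) -> pd.DataFrame:
    """Permutation Zsummary of module preservation between two datasets.

    For each module (defined on the shared protein universe) one density
    statistic (mean within-module adjacency in the test network) and two
    connectivity statistics (correlation of intramodular connectivities
    and of within-module adjacency patterns between reference and test)
    are standardized against random same-size modules; Zsummary is the
    midpoint of the density Z and the median connectivity Z.  Modules
    with fewer than three shared proteins yield NaN.
    """
    shared = reference.index.intersection(test.index)
    ref = reference.loc[shared]
    tst = test.loc[shared]
    A_ref = signed_adjacency(bicor_matrix(ref.to_numpy()), power)
    A_test = signed_adjacency(bicor_matrix(tst.to_numpy()), power)
    lab = labels.reindex(shared)
    rng = np.random.default_rng(seed)
    n = len(shared)
    rows = []
    for mod in sorted({v for v in lab.dropna().unique() if v not in (0, "M0")},
                      key=str):
        idx = np.flatnonzero((lab == mod).to_numpy())
        if idx.size < 3:
            rows.append({"module": mod, "size": int(idx.size),
                         "z_density": np.nan, "z_connectivity": np.nan,
                         "zsummary": np.nan})
            continue
        obs = _preservation_stats(A_ref, A_test, idx)
        null = np.empty((n_perms, 3))
        for p in range(n_perms):
            ridx = rng.choice(n, idx.size, replace=False)
            null[p] = _preservation_stats(A_ref, A_test, ridx)
        z = [_perm_z(obs[j], null[:, j]) for j in range(3)]
        z_density = z[0]
        z_conn = float(np.median(z[1:]))
        rows.append({
            "module": mod, "size": int(idx.size),
            "z_density": z_density, "z_connectivity": z_conn,
            "zsummary": (z_density + z_conn) / 2.0,
        })
    return pd.DataFrame(rows).set_index("module")


# ---------------------------------------------------------------------------
# end-to-end construction


def build_consensus_network(
    data_by_region: dict[str, pd.DataFrame],
    params: NetworkParams | None = None,
    keep_tom: bool = False,
) -> ConsensusNetwork:
    """Full consensus network construction across regions.

    All region matrices must share the protein index.  Steps: bicor ->
    signed adjacency (power) -> TOM (mean denominator) per region ->
    scaled consensus TOM (componentwise quantile) -> module detection ->
    eigenprotein merge at the cut height -> kME reassignment -> final
    size-ordered labels, eigenproteins, and kME tables.
    """
    params = params or NetworkParams()
    regions = list(data_by_region)
    proteins = data_by_region[regions[0]].index
    for r in regions[1:]:
        if not data_by_region[r].index.equals(proteins):
            raise ValueError("region matrices must share the protein index")

    toms = []
    for r in regions:
        C = bicor_matrix(data_by_region[r].to_numpy())
        A = signed_adjacency(C, params.power)
        toms.append(tom_similarity(A, params.tom_denominator))
    cons = consensus_tom(
        toms, quantile=params.consensus_quantile, scale=params.consensus_scale
    )
    del toms

    ints = detect_modules(cons, params)
    ints, history = merge_modules(data_by_region, ints, params.merge_cut_height)

    mods = [v for v in np.unique(ints) if v != 0]
    if mods:
        kmes = []
        n_min = min(df.shape[1] for df in data_by_region.values())
        for r in regions:
            mes_r, _ = eigenprotein(data_by_region[r], ints, module_ids=mods)
            kmes.append(kme(data_by_region[r], mes_r))
        kme_cons = sum(kmes) / len(kmes)
        ints = reassign_proteins(ints, kme_cons, n_min, params.reassign_threshold)
        ints = _renumber_by_size(ints)

    mods = [v for v in np.unique(ints) if v != 0]
    names = {m: f"M{m}" for m in mods}
    label_series = pd.Series(
        [names.get(v, "M0") if v != 0 else "M0" for v in ints],
        index=proteins, name="module",
    )
    eigen, kme_by_region, var_exp = {}, {}, {}
    kme_cons = pd.DataFrame(index=proteins)
    if mods:
        for r in regions:
            mes_r, ve = eigenprotein(data_by_region[r], ints, module_ids=mods)
            mes_r.columns = [names[m] for m in mes_r.columns]
            eigen[r] = mes_r
            var_exp[r] = {names[m]: ve[m] for m in ve}
            kme_by_region[r] = kme(data_by_region[r], mes_r)
        kme_cons = sum(kme_by_region.values()) / len(regions)

    modules = ModuleSet(
        labels=label_series,
        eigenproteins=eigen,
        kme=kme_cons,
        kme_by_region=kme_by_region,
        merge_history=history,
        var_explained=var_exp,
    )
    return ConsensusNetwork(
        params=params,
        proteins=proteins,
        regions=regions,
        modules=modules,
        consensus_tom=cons if keep_tom else None,
        module_ints=ints,
    )
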