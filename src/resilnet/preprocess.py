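"""Case classification and preprocessing of multi-batch TMT abundances.

The preprocessing chain turns raw linear-scale reporter intensities into the
analysis-ready matrix used for network construction:

1. :func:`normalize_gis` — log2 ratio to the pooled-standard (GIS) channels
   of each batch, then per-sample median centering;
2. :func:`filter_missing` — keep proteins quantified in more than half of
   the samples;
3. :func:`tampor` — iterative two-way median polish removing per-batch
   technical offsets;
4. :func:`connectivity_outliers` — drop samples whose network connectivity
   lies more than a chosen number of SDs from the mean;
5. :func:`bootstrap_regress` — remove age/sex/PMI effects via the median
   coefficient over nonparametric bootstrap refits, protecting diagnosis.

Diagnosis classes follow the semi-quantitative amyloid (CERAD 0-3) /
tangle (Braak 0-6) / cognition (MMSE) rule used in resilience cohorts:
Control and AsymAD are separated by pathology burden, AsymAD and AD by
dementia status (MMSE < 24) at last evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CaseRecord",
    "PreprocessParams",
    "dementia_flag",
    "classify_case",
    "classify_cases",
    "normalize_gis",
    "filter_missing",
    "tampor",
    "connectivity_outliers",
    "bootstrap_regress",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class CaseRecord:
    cerad: int
    braak: int
    mmse: int
    age: float | None = None
    sex: str | int | None = None
    pmi: float | None = None

    def __post_init__(self):
        if self.cerad not in (0, 1, 2, 3):
            raise ValueError(f"CERAD score must be 0-3, got {self.cerad}")
        if self.braak not in range(7):
            raise ValueError(f"Braak stage must be 0-6, got {self.braak}")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"MMSE must be 0-30, got {self.mmse}")


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing chain (defaults follow common practice
    for multiplex TMT cohorts: >50% observed filter, |z| > 3 connectivity
    outliers, 1000 bootstrap refits for covariate regression)."""

    missing_threshold: float = 0.5
    outlier_sd: float = 3.0
    outlier_mode: str = "two-sided"  # or "low-only"
    n_bootstrap: int = 1000
    tampor_max_iter: int = 100
    tampor_tol: float = 1e-4
    gis_central: str = "geometric"  # or "arithmetic"
    protected_factor: str = "diagnosis"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.missing_threshold < 1:
            raise ValueError("missing_threshold must lie in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def dementia_flag(mmse: int) -> bool:
    """Dementia at last evaluation: MMSE below 24."""
    if not 0 <= int(mmse) <= 30:
        raise ValueError(f"MMSE must be 0-30, got {mmse}")
    return int(mmse) < 24


def classify_case(rec: CaseRecord) -> str:
    """Classify one case as Control, AsymAD, AD, or Unclassified.

    Control: CERAD 0-1 and Braak 0-3 without dementia, with the proviso
    that a Braak stage of exactly 3 demands CERAD 0.  AsymAD: CERAD 1-3
    and Braak 3-6 without dementia.  AD: CERAD 2-3 and Braak 3-6 with
    dementia.  Control takes precedence when both Control and AsymAD
    match; anything else is Unclassified.
    """
    dem = dementia_flag(rec.mmse)
    control = (
        rec.cerad in (0, 1)
        and rec.braak <= 3
        and not dem
        and (rec.braak != 3 or rec.cerad == 0)
    )
    asymad = rec.cerad in (1, 2, 3) and 3 <= rec.braak <= 6 and not dem
    ad = rec.cerad in (2, 3) and 3 <= rec.braak <= 6 and dem
    if control:
        return "Control"
    if asymad:
        return "AsymAD"
    if ad:
        return "AD"
    return "Unclassified"


def classify_cases(meta: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_case` over a cerad/braak/mmse frame."""
    labels = [
        classify_case(CaseRecord(int(r.cerad), int(r.braak), int(r.mmse)))
        for r in meta.itertuples()
    ]
    return pd.Series(labels, index=meta.index, name="diagnosis")


def normalize_gis(
    raw: pd.DataFrame,
    gis_mask: pd.Series,
    batch: pd.Series,
    central: str = "geometric",
    median_center: bool = True,
) -> pd.DataFrame:
    """Log2 ratio to the per-batch pooled-standard central tendency.

    Parameters
    ----------
    raw : proteins x samples linear-scale intensities (nonpositive values
        are treated as missing).
    gis_mask, batch : boolean / label per sample (indexed like ``raw``'s
        columns).
    central : "geometric" (default; the mean on the log scale, matching
        ratio semantics) or "arithmetic".

    GIS columns are dropped from the result; samples are median-centered
    afterwards unless ``median_center`` is false.
    """
    gis_mask = gis_mask.reindex(raw.columns)
    batch = batch.reindex(raw.columns)
    vals = raw.where(raw > 0)
    log2 = np.log2(vals)
    out = {}
    for b in batch.unique():
        cols = raw.columns[(batch == b).values]
        gis_cols = [c for c in cols if bool(gis_mask[c])]
        if not gis_cols:
            raise ValueError(f"batch {b!r} has no GIS channel")
        if central == "geometric":
            ref = log2[gis_cols].mean(axis=1)
        elif central == "arithmetic":
            ref = np.log2(vals[gis_cols].mean(axis=1))
        else:
            raise ValueError(f"unknown central tendency {central!r}")
        for c in cols:
            if not bool(gis_mask[c]):
                out[c] = log2[c] - ref
    result = pd.DataFrame(out)
    result = result[[c for c in raw.columns if c in out]]
    if median_center:
        result = result - result.median(axis=0, skipna=True)
    return result


def filter_missing(m: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Keep proteins observed in strictly more than ``threshold`` of samples."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frac = m.notna().mean(axis=1)
    return m.loc[frac > threshold]


def tampor(
    m: pd.DataFrame,
    batch: pd.Series,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Two-way iterative median polish of log2 ratios over batches.

    Alternates between (a) removing, per protein, each batch's median
    offset relative to the protein's median across batch medians, and
    (b) removing per-sample median offsets, until the largest absolute
    adjustment falls below ``tol`` or ``max_iter`` is reached.

    Returns the corrected matrix and a QC dict with the per-iteration
    trace of the maximum absolute adjustment and a convergence flag
    (non-convergence is reported, not raised).
    """
    batch = batch.reindex(m.columns)
    x = m.to_numpy(dtype=float, copy=True)
    groups = [np.flatnonzero((batch == b).values) for b in batch.unique()]
    trace: list[float] = []
    converged = False
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        for _ in range(max_iter):
            batch_medians = np.column_stack(
                [np.nanmedian(x[:, g], axis=1) for g in groups]
            )
            row_ref = np.nanmedian(batch_medians, axis=1)
            max_adj = 0.0
            for j, g in enumerate(groups):
                off = batch_medians[:, j] - row_ref
                off = np.where(np.isnan(off), 0.0, off)
                x[:, g] -= off[:, None]
                if off.size:
                    max_adj = max(max_adj, float(np.max(np.abs(off))))
            col_off = np.nanmedian(x, axis=0)
            col_off = np.where(np.isnan(col_off), 0.0, col_off)
            x -= col_off[None, :]
            if col_off.size:
                max_adj = max(max_adj, float(np.max(np.abs(col_off))))
            trace.append(max_adj)
            if max_adj < tol:
                converged = True
                break
    out = pd.DataFrame(x, index=m.index, columns=m.columns)
    return out, {"trace": trace, "converged": converged, "n_iter": len(trace)}


def connectivity_outliers(
    m: pd.DataFrame,
    sd: float = 3.0,
    mode: str = "two-sided",
) -> tuple[pd.Series, pd.Series]:
    """Flag samples by standardized network connectivity.

    Per-sample connectivity is the sum of signed-weighted sample-sample
    correlations, ((1 + r) / 2) ** 2, excluding self; z-scores are taken
    across samples and samples with |z| > ``sd`` (or z < -sd in
    ``low-only`` mode) are masked.
    """
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    r = np.corrcoef(m.to_numpy().T) if not m.isna().any().any() else m.corr().to_numpy()
    r = np.nan_to_num(r, nan=0.0)  # constant samples carry no connectivity signal
    a = ((1.0 + r) / 2.0) ** 2
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    sdk = k.std(ddof=1)
    if sdk == 0 or np.isnan(sdk):
        z = np.zeros_like(k)
    else:
        z = (k - k.mean()) / sdk
    z = pd.Series(z, index=m.columns, name="connectivity_z")
    if mode == "two-sided":
        mask = z.abs() > sd
    elif mode == "low-only":
        mask = z < -sd
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    return z, mask.rename("is_outlier")


def _design_matrix(meta: pd.DataFrame, covariates, protect: str):
    cols = []
    names = []
    n = len(meta)
    cols.append(np.ones(n))
    names.append("intercept")
    protected_names = []
    if protect is not None and protect in meta:
        levels = [
            lv for lv in ("AsymAD", "AD")
            if lv in set(meta[protect])
        ]
        other = sorted(set(meta[protect]) - {"Control", "AsymAD", "AD"})
        for lv in levels + other:
            cols.append((meta[protect] == lv).to_numpy(float))
            names.append(f"{protect}[{lv}]")
            protected_names.append(f"{protect}[{lv}]")
    centered = {}
    for cov in covariates:
        v = pd.to_numeric(meta[cov], errors="coerce").to_numpy(float)
        mu = np.nanmean(v)
        v = np.where(np.isnan(v), mu, v) - mu
        cols.append(v)
        names.append(cov)
        centered[cov] = v
    X = np.column_stack(cols)
    return X, names, centered


def bootstrap_regress(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    covariates=("age", "sex", "pmi"),
    protect: str = "diagnosis",
    n_bootstrap: int = 1000,
    seed: int = 0,
    case_col: str = "case_id",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Remove covariate effects via median bootstrap coefficients.

    For each protein the model ``abundance ~ diagnosis + covariates`` is
    refit on ``n_bootstrap`` case-level resamples (both regions of a case
    enter or leave together); the median coefficient of each covariate
    across resamples is then subtracted times the centered covariate.
    The protected diagnosis term is estimated but never subtracted.

    With ``n_bootstrap=1`` the single "resample" is the full sample, so
    the adjustment reduces to a plain OLS adjustment.

    Missing abundances are mean-imputed for coefficient estimation only;
    the adjustment is applied to observed cells alone.
    """
    meta = meta.loc[m.columns]
    covariates = list(covariates)
    X, names, centered = _design_matrix(meta, covariates, protect)
    Y = m.to_numpy(dtype=float).T  # samples x proteins
    obs = ~np.isnan(Y)
    col_mean = np.nanmean(Y, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Yf = np.where(obs, Y, col_mean[None, :])

    rng = np.random.default_rng(seed)
    if case_col in meta:
        cases = meta[case_col].fillna("__none__").to_numpy()
    else:
        cases = np.asarray(m.columns)
    unique_cases = pd.unique(cases)
    case_rows = {c: np.flatnonzero(cases == c) for c in unique_cases}

    coefs = np.full((n_bootstrap, len(names), Y.shape[1]), np.nan)
    n_skipped = 0
    for b in range(n_bootstrap):
        if n_bootstrap == 1:
            rows = np.arange(len(meta))
        else:
            draw = rng.choice(len(unique_cases), len(unique_cases), replace=True)
            rows = np.concatenate([case_rows[unique_cases[i]] for i in draw])
        Xb, Yb = X[rows], Yf[rows]
        XtX = Xb.T @ Xb
        try:
            beta = np.linalg.solve(XtX, Xb.T @ Yb)
        except np.linalg.LinAlgError:
            n_skipped += 1
            continue
        coefs[b] = beta
    med = np.nanmedian(coefs, axis=0)  # names x proteins

    adj = Y.copy()
    for cov in covariates:
        i = names.index(cov)
        adj -= np.where(obs, np.outer(centered[cov], med[i]), 0.0)
    out = pd.DataFrame(adj.T, index=m.index, columns=m.columns)
    coef_table = pd.DataFrame(med.T, index=m.index, columns=names)
    return out, coef_table, {"n_skipped": n_skipped}


def preprocess_pipeline(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    params: PreprocessParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing chain on one raw intensity matrix.

    ``meta`` must be indexed by sample id with columns ``is_gis``,
    ``batch``, ``case_id``, ``diagnosis``, ``age``, ``sex``, ``pmi``.
    Returns the adjusted log2 matrix (GIS dropped, outliers removed) and
    a QC dict (convergence trace, outlier z-scores, median coefficients).
    """
    params = params or PreprocessParams()
    meta = meta.loc[[c for c in raw.columns if c in meta.index]]
    log2 = normalize_gis(
        raw, meta["is_gis"].astype(bool), meta["batch"], central=params.gis_central
    )
    kept = filter_missing(log2, params.missing_threshold)
    corrected, tampor_qc = tampor(
        kept, meta.loc[kept.columns, "batch"],
        tol=params.tampor_tol, max_iter=params.tampor_max_iter,
    )
    z, outlier = connectivity_outliers(
        corrected, sd=params.outlier_sd, mode=params.outlier_mode
    )
    corrected = corrected.loc[:, ~outlier]
    adjusted, coef_table, reg_qc = bootstrap_regress(
        corrected,
        meta,
        protect=params.protected_factor,
        n_bootstrap=params.n_bootstrap,
        seed=params.seed,
    )
    qc = {
        "n_proteins_raw": int(raw.shape[0]),
        "n_proteins_kept": int(kept.shape[0]),
        "tampor": tampor_qc,
        "outlier_z": z.to_dict(),
        "outliers_removed": list(outlier.index[outlier]),
        "median_coefficients": coef_table.median().to_dict(),
        "bootstrap_skipped": reg_qc["n_skipped"],
        "median_center": "before TAMPOR (during GIS normalization)",
    }
    return adjusted, qc
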