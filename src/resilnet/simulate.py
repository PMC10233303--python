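"""Synthetic multi-batch TMT cohorts with known ground truth.

This module generates the inputs the analysis pipeline expects — protein
abundance matrices from a multiplexed isobaric-labeling design, per-sample
clinical metadata, PWAS-style summary tables, small treatment experiments,
and ortholog maps — while recording every planted effect so that downstream
operations (batch correction, covariate regression, module detection,
enrichment, differential expression) can be tested for recovery of the truth.

The abundance model is a latent-factor model on the log2 scale::

    log2 x[p, s] = baseline[p]
                 + loading[p] * L[module(p), case(s), region(s)]
                 + batch_offset[p, batch(s)]
                 + sum_c slope[p, c] * (cov[c, s] - mean(cov[c]))
                 + diagnosis_shift[module(p), class(case(s))]
                 + noise

Each planted module is driven by one latent signal per case (partially
shared between the two tissue regions), so that within-module correlation
is controlled by the loadings and the noise standard deviation.  Clinical
scores (CERAD, Braak, MMSE) are generated jointly with a designated
"pathology" latent and a designated "resilience" latent, so the diagnosis
classes emerge from the same classification rule the pipeline applies —
they are never assigned by fiat.  Pooled-standard (GIS) channels carry the
batch-mean profile plus noise, and missingness is injected batch-wise
(a protein drops out of a whole multiplex batch at once).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import classify_cases

__all__ = [
    "SimDesign",
    "GroundTruth",
    "simulate_cohort",
    "simulate_pwas",
    "simulate_treatment",
    "make_ortholog_map",
]


def _default_diagnosis_effects() -> dict:
    # module 1 = "resilience" (down in AD), module 2 = "pathology"
    # (up with amyloid/tau burden), shifts in log2 units
    return {
        1: {"AD": -0.5},
        2: {"AsymAD": 0.4, "AD": 0.6},
    }


@dataclass
class SimDesign:
    """Parameters of a simulated two-region multiplex cohort.

    Defaults emulate the statistical structure of a 109-case, two-region,
    26-batch TMT 11-plex study at desk scale: 2000 proteins with eight
    planted co-expression modules (40-150 members), batch offsets of
    SD 0.5 log2 units, age/sex/PMI covariate effects, class-dependent
    shifts on the designated modules, and batch-structured missingness.
    """

    n_cases: int = 109
    regions: tuple[str, ...] = ("BA6", "BA37")
    n_proteins: int = 2000
    module_sizes: tuple[int, ...] = (150, 130, 110, 90, 75, 60, 50, 40)
    n_batches: int = 26
    channels_per_batch: int = 11
    gis_per_batch: int = 1
    batch_sd: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.2, "pmi": 0.01}
    )
    covariate_fraction: float = 0.3
    diagnosis_effects: Mapping[int, Mapping[str, float]] = field(
        default_factory=_default_diagnosis_effects
    )
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    loading_range: tuple[float, float] = (0.6, 1.0)
    region_latent_cor: float = 0.7
    resilience_module: int = 1
    pathology_module: int = 2
    baseline_range: tuple[float, float] = (20.0, 30.0)
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("module_sizes sum exceeds n_proteins")
        if self.gis_per_batch < 1:
            raise ValueError("each batch needs at least one GIS channel")
        if min(self.batch_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        n_regions = len(self.regions)
        per_region_batches = self.n_batches // n_regions
        capacity = per_region_batches * (self.channels_per_batch - self.gis_per_batch)
        if capacity < self.n_cases:
            raise ValueError(
                f"channel capacity per region ({capacity}) cannot hold "
                f"{self.n_cases} cases"
            )


@dataclass
class GroundTruth:
    """Record of every planted effect in a simulated cohort."""

    module_assignment: pd.Series  # protein id -> module int (0 = none)
    loadings: pd.Series  # protein id -> loading on its module latent
    batch_offsets: pd.DataFrame  # protein x batch
    covariate_slopes: pd.DataFrame  # protein x covariate
    diagnosis_effects: dict
    trait_coefficients: dict
    resilience_module: int
    pathology_module: int
    latents: pd.DataFrame  # case x module (case-level latent signals)
    responder_set: list[str] | None = None
    pwas_enriched_modules: list[int] | None = None

    def module_members(self, module: int) -> list[str]:
        mask = self.module_assignment == module
        return list(self.module_assignment.index[mask])

    def symbols_of(self, module: int) -> list[str]:
        return [p.split("|")[0] for p in self.module_members(module)]

    def to_json(self, path) -> None:
        payload = {
            "module_assignment": self.module_assignment.to_dict(),
            "loadings": self.loadings.to_dict(),
            "batch_offsets": self.batch_offsets.to_dict(),
            "covariate_slopes": self.covariate_slopes.to_dict(),
            "diagnosis_effects": {
                str(k): dict(v) for k, v in self.diagnosis_effects.items()
            },
            "trait_coefficients": self.trait_coefficients,
            "resilience_module": self.resilience_module,
            "pathology_module": self.pathology_module,
            "responder_set": self.responder_set,
            "pwas_enriched_modules": self.pwas_enriched_modules,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _protein_ids(n: int) -> list[str]:
    # "Symbol|Accession" row ids; the symbol is the part before the pipe
    return [f"P{i + 1:04d}|Q{i + 1:05d}" for i in range(n)]


def _clinical_scores(path_latent, cog_latent, rng):
    """CERAD/Braak from the pathology latent, MMSE from the cognition latent.

    Cut points are chosen so the emergent class mix resembles a resilience
    cohort (roughly one quarter Control, one half AsymAD, one quarter AD),
    with CERAD and Braak strongly coupled so few cases fall outside the
    classification rule.
    """
    n = path_latent.size
    cerad_raw = path_latent + 0.25 * rng.standard_normal(n)
    braak_raw = path_latent + 0.25 * rng.standard_normal(n)
    cerad = np.digitize(cerad_raw, [-0.9, -0.3, 0.9])  # 0..3
    braak = np.digitize(braak_raw, [-1.4, -0.9, -0.3, 0.5, 1.1, 1.7])  # 0..6
    mmse = np.clip(np.round(25.5 + 3.0 * cog_latent), 0, 30).astype(int)
    return cerad, braak, mmse


def simulate_cohort(design: SimDesign):
    """Simulate a matched two-region multiplex cohort.

    Returns
    -------
    matrices : dict[str, pandas.DataFrame]
        Per region, a proteins x samples matrix of linear-scale
        intensities (GIS channels included) with batch-wise missing
        values as NaN.  Pass to :func:`resilnet.preprocess.normalize_gis`.
    meta : pandas.DataFrame
        One row per sample (GIS rows flagged ``is_gis``): case id, region,
        batch, channel, clinical scores, diagnosis class, covariates and
        trait values.
    truth : GroundTruth
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_regions = len(design.regions)
    proteins = _protein_ids(design.n_proteins)
    case_ids = [f"case{i + 1:03d}" for i in range(design.n_cases)]

    # --- planted module structure ----------------------------------------
    assignment = np.zeros(design.n_proteins, dtype=int)
    pos = 0
    for m, size in enumerate(design.module_sizes, start=1):
        assignment[pos : pos + size] = m
        pos += size
    lo, hi = design.loading_range
    loadings = rng.uniform(lo, hi, design.n_proteins)
    loadings[assignment == 0] = 0.0

    # case-level latent signal per module; regions see a mixture of the
    # case-level signal and a region-specific innovation
    n_mod = design.n_modules
    latents = rng.standard_normal((n_mod, design.n_cases))
    rho = design.region_latent_cor
    region_latents = {
        r: np.sqrt(rho) * latents
        + np.sqrt(1 - rho) * rng.standard_normal((n_mod, design.n_cases))
        for r in design.regions
    }

    # --- clinical scores, classes, traits ---------------------------------
    # designs without a planted pathology/resilience module still need the
    # clinical latents; they are then independent of every protein
    def _latent_or_free(idx):
        if 1 <= idx <= n_mod:
            return latents[idx - 1]
        return rng.standard_normal(design.n_cases)

    path_lat = _latent_or_free(design.pathology_module)
    res_lat = _latent_or_free(design.resilience_module)
    trait_coeffs = {
        "cognition": {"resilience": 0.7, "pathology": -0.8, "noise": 0.35},
        "slope": {"resilience": 0.6, "pathology": -0.5, "noise": 0.3},
        "amyloid": {"pathology": 1.0, "noise": 0.3},
        "tangles": {"pathology": 0.9, "noise": 0.35},
    }
    cc = trait_coeffs["cognition"]
    cog_lat = (
        cc["resilience"] * res_lat
        + cc["pathology"] * path_lat
        + cc["noise"] * rng.standard_normal(design.n_cases)
    )
    cerad, braak, mmse = _clinical_scores(path_lat, cog_lat, rng)

    case_meta = pd.DataFrame(
        {
            "cerad": cerad,
            "braak": braak,
            "mmse": mmse,
            "age": np.round(rng.normal(85.0, 5.0, design.n_cases), 1),
            "sex": rng.integers(0, 2, design.n_cases),
            "pmi": np.round(np.clip(rng.normal(7.0, 2.0, design.n_cases), 1, None), 1),
        },
        index=pd.Index(case_ids, name="case_id"),
    )
    case_meta["diagnosis"] = classify_cases(case_meta).values

    sc = trait_coeffs["slope"]
    case_meta["global_cognition"] = cog_lat
    case_meta["cognitive_slope"] = (
        sc["resilience"] * res_lat
        + sc["pathology"] * path_lat
        + sc["noise"] * rng.standard_normal(design.n_cases)
    )
    ac, tc = trait_coeffs["amyloid"], trait_coeffs["tangles"]
    case_meta["amyloid"] = np.exp(
        0.5 * (ac["pathology"] * path_lat + ac["noise"] * rng.standard_normal(design.n_cases))
    )
    case_meta["tangles"] = np.exp(
        0.5 * (tc["pathology"] * path_lat + tc["noise"] * rng.standard_normal(design.n_cases))
    )

    # --- covariate and batch effects --------------------------------------
    covariates = list(design.covariate_effects)
    slopes = pd.DataFrame(
        0.0, index=pd.Index(proteins, name="protein"), columns=covariates
    )
    for cov in covariates:
        affected = rng.random(design.n_proteins) < design.covariate_fraction
        signs = rng.choice([-1.0, 1.0], design.n_proteins)
        slopes.loc[affected, cov] = (
            design.covariate_effects[cov] * signs[affected]
        )
    batch_names = [f"b{b + 1:02d}" for b in range(design.n_batches)]
    batch_offsets = pd.DataFrame(
        rng.normal(0.0, design.batch_sd, (design.n_proteins, design.n_batches)),
        index=pd.Index(proteins, name="protein"),
        columns=batch_names,
    )

    # --- batch layout: batches are blocked by region -----------------------
    per_region = design.n_batches // n_regions
    region_batches = {
        r: batch_names[i * per_region : (i + 1) * per_region]
        for i, r in enumerate(design.regions)
    }
    baseline = rng.uniform(*design.baseline_range, design.n_proteins)

    cov_means = case_meta[covariates].mean()
    matrices: dict[str, pd.DataFrame] = {}
    meta_rows = []
    diag_effects = {int(k): dict(v) for k, v in design.diagnosis_effects.items()}

    for r in design.regions:
        order = rng.permutation(design.n_cases)
        slots = design.channels_per_batch - design.gis_per_batch
        cols: list[str] = []
        signal = {}
        batch_of: dict[str, str] = {}
        for j, ci in enumerate(order):
            case = case_ids[ci]
            batch = region_batches[r][j // slots]
            channel = j % slots + 1
            sid = f"{case}.{r}"
            cols.append(sid)
            batch_of[sid] = batch
            x = np.zeros(design.n_proteins)
            in_mod = assignment > 0
            if n_mod:
                x[in_mod] = (
                    loadings[in_mod]
                    * region_latents[r][assignment[in_mod] - 1, ci]
                )
            for cov in covariates:
                x = x + slopes[cov].values * (
                    case_meta.loc[case, cov] - cov_means[cov]
                )
            diag = case_meta.loc[case, "diagnosis"]
            for m, shifts in diag_effects.items():
                if diag in shifts:
                    x = x + np.where(assignment == m, shifts[diag], 0.0)
            x = x + batch_offsets[batch].values
            x = x + rng.normal(0.0, design.noise_sd, design.n_proteins)
            signal[sid] = x
            meta_rows.append(
                dict(
                    sample_id=sid, case_id=case, region=r, batch=batch,
                    channel=channel, is_gis=False,
                )
            )
        mat = pd.DataFrame(signal, index=pd.Index(proteins, name="protein"))
        # GIS channels: batch-mean profile of the real samples plus noise
        for batch in region_batches[r]:
            members = [s for s in cols if batch_of[s] == batch]
            if not members:
                continue
            bmean = mat[members].mean(axis=1)
            for g in range(design.gis_per_batch):
                sid = f"GIS.{batch}.{r}.{g + 1}"
                mat[sid] = bmean + rng.normal(0.0, design.noise_sd, design.n_proteins)
                batch_of[sid] = batch
                meta_rows.append(
                    dict(
                        sample_id=sid, case_id=None, region=r, batch=batch,
                        channel=slots + g + 1, is_gis=True,
                    )
                )
        # batch-structured missingness: a protein drops out of a whole batch
        if design.missing_rate > 0:
            batches_here = sorted(set(batch_of.values()))
            drop = rng.random((design.n_proteins, len(batches_here))) < design.missing_rate
            for bi, batch in enumerate(batches_here):
                bcols = [s for s in mat.columns if batch_of[s] == batch]
                mat.loc[drop[:, bi], bcols] = np.nan
        matrices[r] = np.power(2.0, mat.add(baseline, axis=0))

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    case_cols = [
        "cerad", "braak", "mmse", "age", "sex", "pmi", "diagnosis",
        "amyloid", "tangles", "global_cognition", "cognitive_slope",
    ]
    meta = meta.join(case_meta[case_cols], on="case_id")

    truth = GroundTruth(
        module_assignment=pd.Series(assignment, index=proteins, name="module"),
        loadings=pd.Series(loadings, index=proteins, name="loading"),
        batch_offsets=batch_offsets,
        covariate_slopes=slopes,
        diagnosis_effects=diag_effects,
        trait_coefficients=trait_coeffs,
        resilience_module=design.resilience_module,
        pathology_module=design.pathology_module,
        latents=pd.DataFrame(
            latents.T, index=case_ids, columns=[f"M{m + 1}" for m in range(n_mod)]
        ),
    )
    return matrices, meta, truth


def simulate_pwas(
    truth: GroundTruth,
    enriched_modules: Sequence[int],
    n_background: int,
    seed: int,
    beta_params: tuple[float, float] = (0.1, 1.0),
) -> pd.DataFrame:
    """PWAS-style summary table with planted module enrichment.

    Symbols belonging to ``enriched_modules`` draw p-values from
    Beta(*beta_params*) (concentrated near zero); all other symbols —
    remaining simulated proteins plus ``n_background`` extra symbols —
    draw Uniform(0, 1).  Direction labels are split at random.
    """
    enriched_modules = list(enriched_modules)
    known = set(truth.module_assignment.unique()) - {0}
    missing = [m for m in enriched_modules if m not in known]
    if missing:
        raise ValueError(f"enriched modules not present in ground truth: {missing}")
    rng = np.random.default_rng(seed)

    enriched_syms: list[str] = []
    for m in enriched_modules:
        enriched_syms.extend(truth.symbols_of(m))
    if n_background > 0:
        other = [
            p.split("|")[0]
            for p in truth.module_assignment.index
            if p.split("|")[0] not in set(enriched_syms)
        ]
        extra = [f"BG{i + 1:05d}" for i in range(max(0, n_background - len(other)))]
        background = (other + extra)[:n_background]
    else:
        background = []

    symbols = enriched_syms + background
    a, b = beta_params
    pvals = np.concatenate(
        [
            rng.beta(a, b, len(enriched_syms)),
            rng.uniform(0.0, 1.0, len(background)),
        ]
    )
    direction = rng.choice(["positive", "negative"], len(symbols))
    table = pd.DataFrame(
        {"symbol": symbols, "p_value": np.clip(pvals, 1e-300, 1.0), "direction": direction}
    )
    truth.pwas_enriched_modules = enriched_modules
    return table


def simulate_treatment(
    n_treated: int,
    n_vehicle: int,
    responder_set: Sequence[str],
    effect: float,
    seed: int,
    panel: Sequence[str] | None = None,
    n_proteins: int = 2000,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Small treated-vs-vehicle abundance matrix with planted responders.

    Responder proteins are shifted by ``effect`` log2 units in the treated
    columns; every other protein is null.  Columns are named ``TRT_i`` /
    ``VEH_i`` so the grouping is recoverable from the header.
    """
    if n_treated < 2 or n_vehicle < 2:
        raise ValueError("need at least two samples per group")
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = [f"R{i + 1:04d}" for i in range(n_proteins)]
    panel = list(panel)
    responders = list(responder_set)
    absent = set(responders) - set(panel)
    if absent:
        raise ValueError(f"responder symbols absent from panel: {sorted(absent)[:5]}")
    cols = [f"TRT_{i + 1}" for i in range(n_treated)] + [
        f"VEH_{i + 1}" for i in range(n_vehicle)
    ]
    mat = pd.DataFrame(
        rng.normal(0.0, noise_sd, (len(panel), len(cols))),
        index=pd.Index(panel, name="protein"),
        columns=cols,
    )
    mat.loc[responders, cols[:n_treated]] += effect
    return mat


def make_ortholog_map(
    symbols: Sequence[str],
    unmapped_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic human->rat symbol map (rat casing: Abcd1 for ABCD1).

    ``unmapped_fraction`` drops a random subset, emulating symbols without
    a one-to-one ortholog.
    """
    symbols = list(dict.fromkeys(symbols))
    if unmapped_fraction > 0 and symbols:
        rng = np.random.default_rng(seed)
        n_drop = int(round(unmapped_fraction * len(symbols)))
        drop = set(rng.choice(len(symbols), n_drop, replace=False).tolist())
        symbols = [s for i, s in enumerate(symbols) if i not in drop]
    return pd.DataFrame(
        {
            "rat_symbol": [s[:1].upper() + s[1:].lower() for s in symbols],
            "human_symbol": [s.upper() for s in symbols],
        }
    )
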