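"""End-to-end orchestration: simulate -> preprocess -> network -> statistics.

Each stage writes its outputs plus a provenance JSON (content hashes of its
inputs, the parameters used, the derived stage seed); a rerun with the same
configuration skips stages whose provenance still matches and recomputes
anything whose inputs changed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .crossmap import load_ortholog_map, map_symbols, module_overlap_test
from .enrichment import GeneSetCollection, pwas_module_enrichment
from .network import NetworkParams, build_consensus_network, preservation_zsummary
from .preprocess import PreprocessParams, preprocess_pipeline
from .rots import RotsParams, rots, summarize_de
from .simulate import (
    SimDesign,
    make_ortholog_map,
    simulate_cohort,
    simulate_pwas,
    simulate_treatment,
)
from .stats import me_trait_correlation, protein_de

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class EnrichmentConfig:
    n_perm: int = 10_000
    score: str = "neglog10"
    replace: bool = False


@dataclass
class DiffexpConfig:
    n_treated: int = 3
    n_vehicle: int = 4
    effect: float = 2.0
    n_responders: int = 100
    noise_sd: float = 0.3


@dataclass
class PipelineConfig:
    """Serializable configuration of every stage (unknown keys rejected)."""

    seed: int = 0
    out_dir: str = "resilnet_out"
    simulate: SimDesign = field(default_factory=SimDesign)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    rots: RotsParams = field(default_factory=RotsParams)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    diffexp: DiffexpConfig = field(default_factory=DiffexpConfig)

    _SECTIONS = {
        "simulate": SimDesign,
        "preprocess": PreprocessParams,
        "network": NetworkParams,
        "rots": RotsParams,
        "enrichment": EnrichmentConfig,
        "diffexp": DiffexpConfig,
    }

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "out_dir": self.out_dir}
        for name in self._SECTIONS:
            d[name] = asdict(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for name, typ in cls._SECTIONS.items():
            if name in d:
                section = d.pop(name) or {}
                known = {f.name for f in dataclasses.fields(typ)}
                bad = set(section) - known
                if bad:
                    raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
                # tuples round-trip through YAML as lists; JSON stringifies
                # integer mapping keys
                for f in dataclasses.fields(typ):
                    if f.name in section and isinstance(section[f.name], list):
                        section[f.name] = tuple(
                            tuple(x) if isinstance(x, list) else x
                            for x in section[f.name]
                        )
                if name == "simulate" and "diagnosis_effects" in section:
                    section["diagnosis_effects"] = {
                        int(k): dict(v)
                        for k, v in (section["diagnosis_effects"] or {}).items()
                    }
                kwargs[name] = typ(**section)
        bad = set(d) - {"seed", "out_dir"}
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class _Stage:
    """Provenance-checked stage runner."""

    def __init__(self, out_dir: Path, name: str, params: dict, seed: int):
        self.dir = out_dir / name
        self.name = name
        self.params = params
        self.seed = seed
        self.prov_path = self.dir / "provenance.json"

    def up_to_date(self, inputs: list[Path]) -> bool:
        if not self.prov_path.exists():
            return False
        try:
            prov = json.loads(self.prov_path.read_text())
        except json.JSONDecodeError:
            return False
        if prov.get("params") != json.loads(json.dumps(self.params)):
            return False
        if prov.get("seed") != self.seed:
            return False
        hashes = prov.get("input_hashes", {})
        for p in inputs:
            if not p.exists() or hashes.get(p.name) != rio.file_sha256(p):
                return False
        for out, digest in prov.get("output_hashes", {}).items():
            p = self.dir / out
            if not p.exists() or rio.file_sha256(p) != digest:
                return False
        return True

    def record(self, inputs: list[Path], outputs: list[str]) -> None:
        rio.write_json(
            {
                "stage": self.name,
                "params": self.params,
                "seed": self.seed,
                "input_hashes": {p.name: rio.file_sha256(p) for p in inputs},
                "output_hashes": {
                    o: rio.file_sha256(self.dir / o) for o in outputs
                },
            },
            self.prov_path,
        )


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage, returning a dict of key output paths.

    A stage failure raises with the stage name; prior outputs remain on
    disk so a fixed configuration can resume.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"out_dir": str(out)}
    try:
        report.update(_run_stages(config, out, force))
    except Exception as err:  # noqa: BLE001 - annotate with stage name
        stage = getattr(err, "_stage", "unknown")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return report


def _fail_from(stage):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:
                err._stage = stage
                raise

        return wrapper

    return deco


def _run_stages(config: PipelineConfig, out: Path, force: bool) -> dict:
    report = {}
    regions = list(config.simulate.regions)

    # --- simulate ----------------------------------------------------------
    st = _Stage(out, "simulate", asdict(config.simulate),
                rio.stage_seed(config.seed, "simulate"))
    st.dir.mkdir(exist_ok=True)
    mat_paths = {r: st.dir / f"intensities_{r}.tsv" for r in regions}
    meta_path = st.dir / "meta.csv"
    truth_path = st.dir / "truth.json"
    design = dataclasses.replace(config.simulate, seed=st.seed)
    if force or not st.up_to_date([]):
        _fail_from("simulate")(_do_simulate)(design, mat_paths, meta_path, truth_path)
        st.record([], [p.name for p in mat_paths.values()]
                  + [meta_path.name, truth_path.name])
    matrices = {r: rio.read_matrix(p) for r, p in mat_paths.items()}
    meta = rio.read_meta(meta_path)
    meta["is_gis"] = meta["is_gis"].astype(bool)
    _, _, truth = simulate_cohort(design)  # deterministic regeneration
    report["simulate"] = str(st.dir)

    # --- preprocess --------------------------------------------------------
    st = _Stage(out, "preprocess", asdict(config.preprocess),
                rio.stage_seed(config.seed, "preprocess"))
    st.dir.mkdir(exist_ok=True)
    adj_paths = {r: st.dir / f"adjusted_{r}.tsv" for r in regions}
    if force or not st.up_to_date(list(mat_paths.values()) + [meta_path]):
        params = dataclasses.replace(config.preprocess, seed=st.seed)
        qc_all = {}
        for r in regions:
            adjusted, qc = _fail_from("preprocess")(preprocess_pipeline)(
                matrices[r], meta, params
            )
            rio.write_matrix(adjusted, adj_paths[r])
            qc_all[r] = qc
        rio.write_json(qc_all, st.dir / "qc.json")
        st.record(list(mat_paths.values()) + [meta_path],
                  [p.name for p in adj_paths.values()] + ["qc.json"])
    adjusted = {r: rio.read_matrix(p) for r, p in adj_paths.items()}
    report["preprocess"] = str(st.dir)

    # --- network -----------------------------------------------------------
    st = _Stage(out, "network", asdict(config.network),
                rio.stage_seed(config.seed, "network"))
    st.dir.mkdir(exist_ok=True)
    shared = adjusted[regions[0]].index
    for r in regions[1:]:
        shared = shared.intersection(adjusted[r].index)
    data = {r: adjusted[r].loc[shared] for r in regions}
    net = _fail_from("network")(build_consensus_network)(
        data, dataclasses.replace(config.network, seed=st.seed)
    )
    mods = net.modules
    assign = pd.concat([mods.labels, mods.kme], axis=1)
    assign.to_csv(st.dir / "modules.tsv", sep="\t", index_label="protein")
    for r in regions:
        if r in mods.eigenproteins:
            mods.eigenproteins[r].to_csv(
                st.dir / f"eigenproteins_{r}.tsv", sep="\t", index_label="sample"
            )
    rio.write_json(mods.merge_history, st.dir / "merge_history.json")
    mods.to_gmt(st.dir / "modules.gmt")
    st.record([p for p in adj_paths.values()],
              ["modules.tsv", "modules.gmt", "merge_history.json"])
    report["network"] = str(st.dir)
    report["n_modules"] = len(mods.module_names)

    # --- associations ------------------------------------------------------
    st = _Stage(out, "associate", {}, rio.stage_seed(config.seed, "associate"))
    st.dir.mkdir(exist_ok=True)
    traits = meta.loc[~meta["is_gis"]]
    mt = me_trait_correlation(mods.eigenproteins, traits)
    mt.to_csv(st.dir / "module_trait.tsv", sep="\t", index=False)
    member_idx = mods.labels.index[mods.labels != "M0"]
    de_tables = []
    for r in regions:
        sub = data[r].loc[member_idx]
        groups = traits.reindex(sub.columns)["diagnosis"]
        keep = groups.isin(["Control", "AsymAD", "AD"])
        tab, summary = _fail_from("associate")(protein_de)(
            sub.loc[:, keep.values], groups[keep].to_numpy(), posthoc="holm"
        )
        tab["region"] = r
        de_tables.append(tab)
    pd.concat(de_tables).to_csv(st.dir / "protein_de.tsv", sep="\t", index=False)
    report["associate"] = str(st.dir)

    # --- enrichment (PWAS permutation Z) ------------------------------------
    st = _Stage(out, "enrich", asdict(config.enrichment),
                rio.stage_seed(config.seed, "enrich"))
    st.dir.mkdir(exist_ok=True)
    pwas = simulate_pwas(
        truth, [truth.resilience_module], n_background=4 * config.simulate.n_proteins,
        seed=st.seed,
    )
    pwas.to_csv(st.dir / "pwas.tsv", sep="\t", index=False)
    module_sets = GeneSetCollection.from_labels(mods.labels)
    enr = _fail_from("enrich")(pwas_module_enrichment)(
        module_sets, pwas, n_perm=config.enrichment.n_perm,
        seed=st.seed, score=config.enrichment.score,
        replace=config.enrichment.replace,
    )
    enr.to_csv(st.dir / "pwas_enrichment.tsv", sep="\t")
    report["enrich"] = str(st.dir)

    # --- treatment differential expression ----------------------------------
    st = _Stage(out, "diffexp", asdict(config.diffexp),
                rio.stage_seed(config.seed, "diffexp"))
    st.dir.mkdir(exist_ok=True)
    dx = config.diffexp
    responders_h = truth.symbols_of(truth.resilience_module)[: dx.n_responders]
    omap_df = make_ortholog_map(
        [p.split("|")[0] for p in truth.module_assignment.index], seed=st.seed
    )
    omap = load_ortholog_map(omap_df)
    human_to_rat = {v: k for k, v in omap.items()}
    responders_rat = [human_to_rat[s] for s in responders_h if s in human_to_rat]
    panel = list(omap)
    trt = simulate_treatment(
        dx.n_treated, dx.n_vehicle, responders_rat, dx.effect,
        seed=st.seed, panel=panel, noise_sd=dx.noise_sd,
    )
    groups = ["treated"] * dx.n_treated + ["vehicle"] * dx.n_vehicle
    rparams = dataclasses.replace(config.rots)
    de, chosen = _fail_from("diffexp")(rots)(trt, groups, rparams)
    de.to_csv(st.dir / "de_table.tsv", sep="\t", index_label="protein")
    counts = summarize_de(de)
    rio.write_json({"chosen": chosen, "n_up": counts["n_up"],
                    "n_down": counts["n_down"], "n_fdr": counts["n_fdr"]},
                   st.dir / "rots_params.json")
    omap_df.to_csv(st.dir / "orthologs.tsv", sep="\t", index=False)
    report["diffexp"] = str(st.dir)

    # --- cross-species overlap ----------------------------------------------
    st = _Stage(out, "crossmap", {}, rio.stage_seed(config.seed, "crossmap"))
    st.dir.mkdir(exist_ok=True)
    sig = de[de["p"] < 0.05]
    lists_rat = {
        "all": list(sig.index),
        "up": list(sig.index[sig["diff"] > 0]),
        "down": list(sig.index[sig["diff"] < 0]),
    }
    lists_h = {}
    for name, syms in lists_rat.items():
        mapped, _ = map_symbols(syms, omap)
        lists_h[name] = mapped
    universe_all, _ = map_symbols(list(de.index), omap)
    overlap = _fail_from("crossmap")(module_overlap_test)(
        lists_h, module_sets, universe=set(universe_all) & set(module_sets.universe)
    )
    overlap.to_csv(st.dir / "overlap_matrix.tsv", sep="\t", index=False)
    report["crossmap"] = str(st.dir)

    _write_report(out, report, mt, counts, overlap)
    return report


def _do_simulate(design, mat_paths, meta_path, truth_path):
    matrices, meta, truth = simulate_cohort(design)
    for r, p in mat_paths.items():
        rio.write_matrix(matrices[r], p)
    rio.write_meta(meta, meta_path)
    truth.to_json(truth_path)


def _write_report(out: Path, report: dict, module_trait, de_counts, overlap):
    lines = ["# Pipeline report", ""]
    lines.append(f"Detected modules: {report.get('n_modules', 'n/a')}")
    lines.append("")
    lines.append("## Strongest module-trait correlations")
    if not module_trait.empty:
        top = module_trait.reindex(
            module_trait["bicor"].abs().sort_values(ascending=False).index
        ).head(10)
        lines.append(top.to_string(index=False))
    lines.append("")
    lines.append("## Treatment differential expression")
    lines.append(
        f"up: {de_counts['n_up']}  down: {de_counts['n_down']}  "
        f"FDR<=0.1: {de_counts['n_fdr']}"
    )
    lines.append("")
    lines.append("## Cross-species module overlap (BH-significant cells)")
    sig = overlap[overlap["q"] < 0.05]
    lines.append(sig.to_string(index=False) if not sig.empty else "none")
    (out / "report.md").write_text("\n".join(lines) + "\n")
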