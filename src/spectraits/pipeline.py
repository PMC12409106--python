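"""Configuration-driven orchestration of the full analysis chain.

Stages (in order): spectra preprocessing -> PLSR trait prediction and
PLS-DA classification -> neutral-marker statistics -> P_ST-F_ST scan ->
IBE/IBD variance partitioning -> phylogenetic signal + PGLS.  Each stage
writes long-format delimited tables plus a JSON summary and a run manifest
(seed, config hash) so identical config + seed reproduces identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import phylo as ph
from . import popgen as pg
from . import pstfst as pf
from . import spectra as sp
from . import varpart as vp
from .simulate import SimConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Flat key/value configuration for one pipeline run.

    Either point the six input paths at existing files or leave them None
    and set ``synthetic`` to generate a dataset on the fly.
    """

    # inputs
    spectra_path: str | None = None
    genotypes_path: str | None = None
    metadata_path: str | None = None
    environment_path: str | None = None
    coordinates_path: str | None = None
    tree_path: str | None = None
    traits_path: str | None = None
    synthetic: dict | None = None

    # stage toggles
    run_preprocess: bool = True
    run_chemometrics: bool = True
    run_popgen: bool = True
    run_pstfst: bool = True
    run_varpart: bool = True
    run_phylo: bool = True
    common_garden: bool = False       # disables VIP band selection in the scan

    # thresholds and counts
    vip_primary: float = 0.8
    vip_extended: float = 0.4
    membership_threshold: float = 0.6
    vif_threshold: float = 5.0
    corr_max: float = 0.60
    n_components: int = 10
    n_boot: int = 200
    n_perm: int = 199
    k_profile_bands: int = 0          # 0 = all bands; else thin to this many

    seed: int = 0
    outdir: str = "spectraits_out"

    def __post_init__(self):
        if not (0 < self.vip_extended <= self.vip_primary):
            raise ValueError("need 0 < vip_extended <= vip_primary")
        if not (0 < self.membership_threshold <= 1):
            raise ValueError("membership_threshold must be in (0, 1]")

    # -- round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.synthetic is not None:
        sim = SimConfig(**{**cfg.synthetic, "seed": cfg.seed})
        return simulate_dataset(sim)
    data = {}
    data["spectra"] = sp.read_spectra(cfg.spectra_path)
    data["genotypes"] = pg.read_genotypes(cfg.genotypes_path)
    data["metadata"] = pd.read_csv(cfg.metadata_path, index_col=0)
    data["env"] = pd.read_csv(cfg.environment_path, index_col=0)
    data["geo"] = pd.read_csv(cfg.coordinates_path, index_col=0)
    data["tree"] = ph.read_tree(cfg.tree_path)
    data["traits"] = (pd.read_csv(cfg.traits_path, index_col=0)
                      if cfg.traits_path else None)
    data["truth"] = None
    return data


def validate_inputs(cfg: PipelineConfig) -> dict:
    """Report sample-ID joins across spectra, genotypes, metadata and
    environment; hard-fails on an empty intersection or duplicate IDs."""
    data = _load_inputs(cfg)
    sets = {
        "spectra": list(data["spectra"].sample_ids),
        "genotypes": list(data["genotypes"].sample_ids),
        "metadata": list(data["metadata"].index.astype(str)),
        "environment": list(data["env"].index.astype(str)),
    }
    report = {"duplicates": {}, "orphans": {}, "n": {}}
    for name, ids in sets.items():
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1]
        if not dupes.empty:
            report["duplicates"][name] = list(dupes.index)
        report["n"][name] = len(ids)
    if report["duplicates"]:
        raise ValueError(f"duplicate sample IDs: {report['duplicates']}")
    common = set.intersection(*(set(v) for v in sets.values()))
    if not common:
        raise ValueError("no sample IDs shared across all inputs")
    for name, ids in sets.items():
        orphans = sorted(set(ids) - common)
        if orphans:
            report["orphans"][name] = orphans
    report["n"]["joined"] = len(common)
    return report


class _stage:
    """Context manager labeling failures with the stage they came from;
    partial outputs written before the failure are retained on disk."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, RuntimeError):
            raise RuntimeError(
                f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the report bundle (also written
    to ``cfg.outdir``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(
        ("chem", "popgen", "pstfst", "varpart", "phylo"), rng_master.spawn(5))}
    data = _load_inputs(cfg)
    meta = data["metadata"]
    summary: dict = {"config_hash": cfg.digest(), "seed": cfg.seed,
                     "stage_seeds": stage_seeds}

    # ---------------- preprocessing
    cwt = None
    if cfg.run_preprocess:
        with _stage("preprocess"):
            s = data["spectra"]
            if s.state == "raw":
                s = sp.splice_correct(s)
            if s.state == "spliced":
                s = sp.resample(s)
            cwt = sp.cwt_transform(s)
            summary["preprocess"] = {"n_samples": cwt.n_samples,
                                     "n_bands": cwt.n_bands,
                                     "range_nm": [float(cwt.wavelengths[0]),
                                                  float(cwt.wavelengths[-1])]}

    # ---------------- chemometrics
    vip_mask = None
    predicted = data["traits"]
    if cfg.run_chemometrics and cwt is not None:
        with _stage("chemometrics"):
            X = cwt.values
            species = meta.loc[list(cwt.sample_ids), "species"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plsda_model, cm = chem.fit_plsda(
                    X, species, n_components=min(cfg.n_components, X.shape[0] - 2),
                    seed=stage_seeds["chem"])
            vip = chem.vip_scores(plsda_model)
            vip_mask = chem.select_vip_bands(vip, cfg.vip_primary, cfg.vip_extended)
            cm.percent().to_csv(out / "plsda_confusion_pct.csv")
            summary["plsda"] = {"accuracy": cm.accuracy, "kappa": cm.kappa,
                                "n_vip_bands": int(vip_mask.sum())}
            trait_metrics = {}
            if data["traits"] is not None:
                models = {}
                for trait in data["traits"].columns:
                    y = data["traits"].loc[list(cwt.sample_ids), trait].to_numpy()
                    m = chem.fit_plsr(X, y,
                                      n_components=min(cfg.n_components,
                                                       X.shape[0] - 2),
                                      target=trait, wavelengths=cwt.wavelengths)
                    models[trait] = m
                    trait_metrics[trait] = m.metrics
                predicted = chem.predict_traits(models, X, cwt.sample_ids)
                predicted.to_csv(out / "predicted_traits.csv")
            summary["plsr"] = trait_metrics

    # ---------------- popgen
    fst_results = []
    if cfg.run_popgen:
        with _stage("popgen"):
            g = data["genotypes"]
            am = pg.amova(g, n_perm=0)
            summary["amova"] = {"percentages": am.percentages}
            pairs = pg.pairwise_fst(g, level="species")
            fst_results = [
                pg.fst_bootstrap_ci(g, f.pair, level="species",
                                    n_boot=cfg.n_boot,
                                    seed=stage_seeds["popgen"] + i)
                for i, f in enumerate(pairs)
            ]
            pd.DataFrame([{"pair": "/".join(f.pair), "theta": f.theta,
                           "ci_low": f.ci_low, "ci_high": f.ci_high}
                          for f in fst_results]).to_csv(out / "fst.csv", index=False)
            summary["fst"] = {"/".join(f.pair): f.theta for f in fst_results}

    # ---------------- P_ST-F_ST
    if cfg.run_pstfst and predicted is not None and fst_results:
        with _stage("pstfst"):
            species = meta["species"].reindex(predicted.index).to_numpy()
            _, table = pf.pst_fst_scan(
                predicted, species, fst_results, n_boot=cfg.n_boot,
                seed=stage_seeds["pstfst"])
            table.to_csv(out / "pst_fst_traits.csv", index=False)
            summary["pstfst_traits_flagged_05"] = int(table["flag_0.5"].sum())
            if not cfg.common_garden and vip_mask is not None and cwt is not None:
                bands = cwt.to_frame().loc[:, vip_mask]
                regions = dict(zip(bands.columns,
                                   sp.region_of(bands.columns.to_numpy())))
                _, btable = pf.pst_fst_scan(
                    bands, species, fst_results[:1], n_boot=max(cfg.n_boot // 2, 50),
                    seed=stage_seeds["pstfst"] + 1, regions=regions)
                btable.to_csv(out / "pst_fst_vip_bands.csv", index=False)

    # ---------------- IBE/IBD
    if cfg.run_varpart and predicted is not None:
        with _stage("varpart"):
            env = vp.vif_filter(data["env"], cfg.vif_threshold) \
                if data["env"].shape[1] >= 2 else data["env"]
            geo = vp.spatial_predictors(data["geo"])
            res = vp.variance_partition(
                predicted.to_numpy(), env.loc[predicted.index],
                geo.loc[predicted.index], n_perm=cfg.n_perm,
                seed=stage_seeds["varpart"], label="all", response="traits")
            vp.varpart_table([res]).to_csv(out / "varpart.csv", index=False)
            summary["varpart"] = {"env_given_geo": res.env_given_geo,
                                  "geo_given_env": res.geo_given_env,
                                  "joint": res.joint,
                                  "unexplained": res.unexplained}

    # ---------------- phylogenetic signal + PGLS
    if cfg.run_phylo and predicted is not None and data["tree"] is not None:
        with _stage("phylo"):
            tree = data["tree"]
            if data["truth"] is not None:
                tip_map = {s: data["truth"]["tip_of_population"][p]
                           for s, p in meta["population"].items()}
            else:
                tip_map = dict(zip(meta.index, meta["population"]))
            tips = ph.population_means(predicted, tip_map)
            env_tips = ph.population_means(data["env"], tip_map)
            physig = {}
            for trait in predicted.columns:
                r = ph.k_significance(tree, tips[trait], n_perm=cfg.n_perm,
                                      n_sim=cfg.n_perm,
                                      seed=stage_seeds["phylo"],
                                      trait_name=trait)
                physig[trait] = {"k": r.k, "p_wn": r.p_wn,
                                 "signal": r.signal_present}
            summary["phylo_signal"] = physig
            env_screened = vp.corr_filter(data["env"], cfg.corr_max)
            env_var = env_screened.columns[0]
            pgls = ph.pgls_fit(tree, tips[predicted.columns[0]],
                               env_tips[env_var], predictor=env_var)
            summary["pgls"] = {"trait": predicted.columns[0],
                               "predictor": env_var, "slope": pgls.slope,
                               "p_value": pgls.p_value}
            if cfg.k_profile_bands > 0 and cwt is not None:
                take = np.unique(np.linspace(
                    0, cwt.n_bands - 1, cfg.k_profile_bands).astype(int))
                from dataclasses import replace as _replace
                thin = _replace(cwt, wavelengths=cwt.wavelengths[take],
                                values=cwt.values[:, take])
                prof = ph.spectral_k_profile(
                    tree, thin, tip_map, n_perm=min(cfg.n_perm, 99),
                    n_sim=min(cfg.n_perm, 99), seed=stage_seeds["phylo"])
                prof.to_csv(out / "spectral_k_profile.csv")
                summary["spectral_k"] = {
                    r: float(prof.loc[prof["region"] == r, "k"].median())
                    for r in prof["region"].unique()}

    manifest = {"config": dataclasses.asdict(cfg), "hash": cfg.digest(),
                "stage_seeds": stage_seeds}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float, sort_keys=True))
    return summary
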