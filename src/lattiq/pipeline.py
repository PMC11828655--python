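"""End-to-end analysis pipeline: plot table in, report bundle out.

The pipeline runs the stages in the order of a standard germplasm
variability study: per-trait lattice ANOVA; variance components and
genetic parameters; genotypic/phenotypic correlations; genotypic and
phenotypic path analysis of yield; distance and UPGMA cluster analysis
of adjusted means; correlation-matrix PCA.  Every output is a CSV (plus
one newick tree and a JSON manifest) so a bundle is reproducible and
diffable; identical config and seed give an identical bundle.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova as _anova
from . import assoc as _assoc
from . import diversity as _div
from . import genparams as _gp
from . import path as _path
from . import pca as _pca
from .design import TrialDesign, make_design
from .errors import LattiqError
from .io import read_plot_table
from .simulate import GeneticModel, PlotTable, simulate_trial

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Exactly one of ``input_csv`` or ``model`` (a simulation spec) must be
    given; with a model, a trial is simulated from ``seed`` first.
    """

    output_dir: str
    k: int = 7
    r: int = 2
    input_csv: str | None = None
    model: GeneticModel | None = None
    traits: list[str] | None = None
    yield_trait: str = "GY"
    alpha: float = 0.05
    k_sel: float = _gp.K_SEL_5PCT
    thresholds: _gp.CategoryThresholds = field(default_factory=_gp.CategoryThresholds)
    n_clusters: int = 6
    seed: int = 0
    design_seed: int | None = None
    strip_thousands: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        thresholds = _gp.CategoryThresholds(
            **{k: tuple(v) for k, v in cfg.pop("thresholds", {}).items()}
        )
        model_path = cfg.pop("model", None)
        model = GeneticModel.from_yaml(model_path) if model_path else None
        return cls(model=model, thresholds=thresholds, **cfg)


def _fmt(frame: pd.DataFrame, path: Path, decimals: int | None = None) -> None:
    if decimals is not None:
        frame = frame.round(decimals)
    frame.to_csv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing
    every produced file and the settings used.  On any stage failure the
    partially written bundle is removed and the error re-raised with the
    stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "setup"
    try:
        design = make_design(config.k, config.r, seed=config.design_seed)
        if config.model is not None:
            stage = "simulate"
            plots = simulate_trial(design, config.model, seed=config.seed)
        elif config.input_csv is not None:
            stage = "read"
            plots = read_plot_table(
                config.input_csv,
                traits=config.traits,
                strip_thousands=config.strip_thousands,
            )
        else:
            raise LattiqError("config needs either input_csv or a simulation model")
        traits = list(config.traits or plots.traits)
        if config.yield_trait not in traits:
            raise LattiqError(
                f"yield trait {config.yield_trait!r} not among traits {traits}"
            )
        plots.check_balanced(design)
        if config.n_clusters > design.g:
            raise LattiqError(
                f"n_clusters={config.n_clusters} exceeds {design.g} accessions"
            )

        def save(name: str, frame: pd.DataFrame, decimals: int | None = 2):
            _fmt(frame, out / name, decimals)
            written.append(name)

        stage = "plots"
        plots.to_csv(out / "plot_data.csv")
        written.append("plot_data.csv")

        stage = "anova"
        order, qs = _anova.sequential_projectors(design)
        anovas = {t: _anova.anova_table(plots, design, t, qs=qs) for t in traits}
        ms = pd.DataFrame(
            {t: a.table["MS"] for t, a in anovas.items()}
        )
        stars = pd.DataFrame(
            {
                t: [
                    _anova.significance_stars(p) if np.isfinite(p) else ""
                    for p in a.table["p"]
                ]
                for t, a in anovas.items()
            },
            index=ms.index,
        )
        display = ms.round(2).astype(str) + stars
        display.insert(0, "df", anovas[traits[0]].table["df"].to_numpy())
        display.loc["cv_percent"] = [""] + [
            f"{anovas[t].cv_percent:.1f}" for t in traits
        ]
        save("anova_mean_squares.csv", display, decimals=None)
        tidy = pd.concat(
            {t: a.table for t, a in anovas.items()}, names=["trait", "source"]
        )
        save("anova_full.csv", tidy, decimals=None)

        stage = "adjusted_means"
        adj = {t: _anova.adjusted_means(plots, design, t) for t in traits}
        mean_mat = pd.DataFrame({t: adj[t].means for t in traits})
        save("adjusted_means.csv", mean_mat, decimals=None)

        stage = "tukey"
        ytab = anovas[config.yield_trait]
        letters = _anova.tukey_hsd(
            adj[config.yield_trait],
            ytab.mse,
            ytab.df_error,
            alpha=config.alpha,
            r=config.r,
        )
        save("tukey_yield.csv", letters, decimals=None)

        stage = "genparams"
        rows = {}
        for t in traits:
            vc = _gp.variance_components(
                anovas[t].msg, anovas[t].mse, config.k, config.r
            )
            gp = _gp.derived_parameters(
                vc, anovas[t].grand_mean, config.k_sel, config.thresholds
            )
            rows[t] = {
                "mean": anovas[t].grand_mean,
                "sem": adj[t].sem,
                "sigma2_g": gp.sigma2_g,
                "sigma2_p": gp.sigma2_p,
                "gcv_percent": gp.gcv_percent,
                "pcv_percent": gp.pcv_percent,
                "h2_percent": gp.h2_percent,
                "ga": gp.ga,
                "gam_percent": gp.gam_percent,
                **{f"cat_{k}": v for k, v in gp.categories.items()},
            }
        save("genetic_parameters.csv", pd.DataFrame(rows).T)

        stage = "correlations"
        corr = _assoc.correlation_matrices(plots, design, traits)
        save("correlations_combined.csv", corr.combined_table(), decimals=None)
        save("correlations_genotypic.csv", corr.rg, decimals=None)
        save("correlations_phenotypic.csv", corr.rp, decimals=None)

        stage = "path"
        manifest_path: dict = {}
        for level, rmat in (("genotypic", corr.rg), ("phenotypic", corr.rp)):
            try:
                preds = _path.select_predictors(
                    corr, config.yield_trait, level, config.alpha
                )
            except LattiqError:
                manifest_path[level] = None
                continue
            res = _path.path_coefficients(
                rmat.loc[preds, preds],
                rmat.loc[preds, config.yield_trait],
                preds,
                level=level,
            )
            save(f"path_{level}.csv", res.table(), decimals=3)
            manifest_path[level] = {
                "predictors": preds,
                "residual_effect": res.residual_effect,
                "residual_path": res.residual_path,
            }

        stage = "diversity"
        z, dist = _div.standardize_and_distance(mean_mat)
        save("distance_matrix.csv", dist.to_frame(), decimals=None)
        save("distance_summary.csv", _div.distance_summary(dist))
        dendro, clusters, newick = _div.upgma_cluster(dist, config.n_clusters)
        (out / "dendrogram.nwk").write_text(newick + "\n")
        written.append("dendrogram.nwk")
        memb = pd.DataFrame(
            {
                "cluster": clusters.labels,
            }
        )
        save("cluster_membership.csv", memb, decimals=None)
        save("cluster_means.csv", _div.cluster_means(mean_mat, clusters))

        stage = "pca"
        pres = _pca.pca_correlation(mean_mat)
        save("pca_summary.csv", pres.summary())
        save("pca_scores.csv", pres.scores, decimals=None)

        stage = "manifest"
        manifest = {
            "settings": {
                "k": config.k,
                "r": config.r,
                "traits": traits,
                "yield_trait": config.yield_trait,
                "alpha": config.alpha,
                "k_sel": config.k_sel,
                "n_clusters": config.n_clusters,
                "seed": config.seed,
                "design_seed": config.design_seed,
                "input_csv": config.input_csv,
                "simulated": config.model is not None,
            },
            "path_analysis": manifest_path,
            "pca_retained": list(pres.retained),
            "files": sorted(written),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        for name in written:
            try:
                (out / name).unlink()
            except OSError:
                pass
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
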