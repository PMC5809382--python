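"""End-to-end orchestration of the shape-plasticity analysis.

Runs the full sequence on synthetic or file-based data: outline
preconditioning, harmonic calibration, elliptic Fourier decomposition,
PCA morphospace, MANOVA, optional species LDA, thin-plate-spline
mean-shape comparison, response stacking, collinearity screening (with
the environment-PCA fallback), mixed-model fitting with
variance-structure selection, and effect sizes.  Every artifact is
persisted as plain CSV/JSON plus a run log, and a run is fully
reproducible from its persisted configuration and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminant, efa, gamm, morphospace, outline_io, synth, tps

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (files XOR synthetic input)."""

    outdir: str = "musselshape_run"
    input_dir: str | None = None  # fixture bundle directory, or None for synth
    n_sites: int = 15
    n_per_site: int = 20
    seed: int = 0
    n_harmonics: int | None = 7  # None -> calibrate
    calibration_threshold: float = 0.98
    max_harmonics: int = 12
    resample_points: int | None = None  # None: keep the input sampling
    smooth_iterations: int = 0
    pcs_manova: int = 10
    pcs_gamm: int = 5
    vif_threshold: float = 3.0
    variance_candidates: tuple[str | None, ...] = (None, "temperature", "chla")
    run_lda: bool = True
    env_correlation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_per_site", "pcs_manova", "pcs_gamm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resample_points is not None and self.resample_points < 8:
            raise ValueError("resample_points must be >= 8 or None")


@dataclass
class RunReport:
    """In-memory summary of a completed run."""

    outdir: Path
    manifest: dict = field(default_factory=dict)
    pca: morphospace.MorphospaceModel | None = None
    gamm_fit: gamm.GammFit | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _precondition(outline, cfg: RunConfig):
    o = outline_io.orient_outline(outline)
    if cfg.smooth_iterations:
        o = outline_io.smooth_outline(o, cfg.smooth_iterations)
    if cfg.resample_points is not None:
        o = outline_io.resample_outline(o, cfg.resample_points)
    return o


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and persist artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def log(msg: str) -> None:
        stamp = f"[{time.perf_counter() - t_start:8.2f}s] {msg}"
        log_lines.append(stamp)
        log_path.write_text("\n".join(log_lines) + "\n")

    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": asdict(config)}
    report = RunReport(outdir=outdir, manifest=manifest)
    stage = "setup"
    try:
        log(f"musselshape {__version__}, seed={config.seed}")

        stage = "input"
        if config.input_dir is not None:
            ds = synth.read_fixture_bundle(config.input_dir)
            log(f"loaded fixture bundle from {config.input_dir}")
        else:
            env = synth.generate_environment(
                config.n_sites, seed=config.seed, correlation=config.env_correlation
            )
            gcfg = synth.GeneratorConfig(seed=config.seed)
            ds = synth.generate_dataset(env, config.n_per_site, gcfg)
            log(
                f"generated {len(ds.specimens)} specimens at {len(env)} sites"
            )

        stage = "precondition"
        pre = {
            sid: {v: _precondition(o, config) for v, o in views.items()}
            for sid, views in ds.outlines.items()
        }

        stage = "calibration"
        if config.n_harmonics is None:
            sample = [pre[s]["lateral"] for s in list(pre)[:50]]
            n_harm = efa.calibrate_harmonics(
                sample, config.calibration_threshold, config.max_harmonics
            )
            log(f"calibrated harmonics: {n_harm}")
        else:
            n_harm = config.n_harmonics
            log(f"fixed harmonics: {n_harm}")
        manifest["n_harmonics"] = n_harm

        stage = "efa"
        coeff_map = {
            sid: {
                view: efa.efa_normalize(efa.efa_forward(o, n_harm))
                for view, o in views.items()
            }
            for sid, views in pre.items()
        }
        matrix = efa.assemble_shape_matrix(coeff_map)
        log(f"shape matrix: {matrix.X.shape[0]} specimens x {matrix.X.shape[1]} coeffs")

        stage = "pca"
        model = morphospace.fit_pca(matrix)
        report.pca = model
        pca_tab = pd.DataFrame(
            {
                "pc": [f"PC{i + 1}" for i in range(model.n_pcs)],
                "eigenvalue": model.eigenvalues,
                "pct_variance": model.pct_variance,
            }
        )
        pca_tab.to_csv(outdir / "pca_variance.csv", index=False)
        scores_tab = pd.DataFrame(
            model.scores[:, : config.pcs_manova],
            columns=[f"PC{i + 1}" for i in range(config.pcs_manova)],
        )
        scores_tab.insert(0, "specimen_id", model.specimen_ids)
        scores_tab.to_csv(outdir / "pc_scores.csv", index=False)
        report.tables["pca_variance"] = pca_tab
        log(
            "PC1-2 variance: "
            f"{model.pct_variance[0]:.1f}% + {model.pct_variance[1]:.1f}%"
        )

        stage = "manova"
        meta = ds.specimens.set_index("specimen_id").loc[model.specimen_ids]
        k = config.pcs_manova
        res_site = morphospace.manova_wilks(
            model.scores[:, :k], meta["site_id"].to_numpy(), "site"
        )
        res_len = morphospace.manova_wilks(
            model.scores[:, :k], meta["length"].to_numpy(dtype=float), "length"
        )
        manova_tab = pd.DataFrame(
            [vars(res_site), vars(res_len)]
        )
        manova_tab.to_csv(outdir / "manova.csv", index=False)
        report.tables["manova"] = manova_tab
        log(
            f"MANOVA site Wilks lambda={res_site.wilks_lambda:.3f}, "
            f"length lambda={res_len.wilks_lambda:.3f}"
        )

        stage = "lda"
        species = meta["species"].astype(str)
        labelled = species[species != "unknown"]
        if config.run_lda and labelled.nunique() == 2 and labelled.value_counts().min() >= 4:
            mask = (species != "unknown").to_numpy()
            lda_model = discriminant.fit_lda(
                model.scores[mask, :k], species[mask].to_numpy()
            )
            cv = discriminant.loocv_classify(
                model.scores[mask, :k], species[mask].to_numpy()
            )
            cv.to_frame().to_csv(outdir / "lda_confusion.csv")
            coefs = discriminant.standardized_coefficients(lda_model)
            coefs.to_csv(outdir / "lda_coefficients.csv", index=False)
            report.tables["lda_confusion"] = cv.to_frame()
            report.tables["lda_coefficients"] = coefs
            manifest["lda_overall_pct"] = cv.overall_pct
            log(f"LDA LOOCV overall correct: {cv.overall_pct:.1f}%")
        else:
            manifest["lda_overall_pct"] = None
            log("LDA stage skipped: no two labelled species with >= 4 specimens")

        stage = "tps"
        mean_lat, _ = morphospace.reconstruct_at(model, 0, -3.0, n_harm, 100)
        plus_lat, _ = morphospace.reconstruct_at(model, 0, +3.0, n_harm, 100)
        warp = tps.fit_tps(mean_lat.points, plus_lat.points)
        field_ = tps.deformation_field(warp)
        pd.DataFrame(
            {
                "x": field_.grid_x.ravel(),
                "y": field_.grid_y.ravel(),
                "warped_x": field_.warped_x.ravel(),
                "warped_y": field_.warped_y.ravel(),
                "displacement": field_.magnitude.ravel(),
            }
        ).to_csv(outdir / "tps_pc1_grid.csv", index=False)
        manifest["tps_bending_energy"] = warp.bending_energy
        log(f"TPS PC1 -3SD to +3SD bending energy: {warp.bending_energy:.4g}")

        stage = "stacking"
        table = gamm.stack_scores(
            model.scores,
            model.specimen_ids,
            ds.specimens[["specimen_id", "site_id", "length"]],
            ds.env[["site_id", "temperature", "salinity", "chla"]],
            k_pcs=config.pcs_gamm,
        )

        stage = "collinearity"
        site_cov = ds.env[["temperature", "salinity", "chla"]]
        vif_tab = gamm.vif(site_cov, config.vif_threshold)
        vif_tab.to_csv(outdir / "vif.csv", index=False)
        report.tables["vif"] = vif_tab
        use_env_pca = bool(vif_tab["collinear"].any())
        if use_env_pca:
            epcs = gamm.env_pca(site_cov, ds.env["site_id"])
            scores_env = epcs.scores.rename(
                columns=lambda c: c.replace("enviro-PC", "enviro_pc")
            )
            long = table.data.merge(scores_env, on="site_id", how="left")
            smooth_terms = tuple(
                c for c in scores_env.columns if c.startswith("enviro_pc")
            )
            table = gamm.LongShapeTable(
                long, covariates=smooth_terms + ("length",)
            )
            formula = gamm.FormulaSpec(
                smooth_terms=smooth_terms, linear_terms=("length",)
            )
            epcs.loadings.to_csv(outdir / "enviro_pca_loadings.csv")
            variance_candidates = (None,)
            log(f"high collinearity: using {len(smooth_terms)} enviro-PCs")
        else:
            formula = gamm.FormulaSpec()
            variance_candidates = config.variance_candidates
            log("collinearity low (all VIF < threshold); raw covariates kept")
        manifest["used_env_pca"] = use_env_pca
        manifest["gamm_smooth_terms"] = list(formula.smooth_terms)

        stage = "gamm"
        fit, comp = gamm.select_variance_structure(
            table, formula, candidates=variance_candidates
        )
        report.gamm_fit = fit
        comp.reset_index().to_csv(outdir / "variance_selection.csv", index=False)
        fit.term_table.to_csv(outdir / "gamm_terms.csv", index=False)
        manifest["variance_structure"] = fit.variance.kind
        manifest["variance_covariate"] = fit.variance.covariate
        manifest["sigma2_site"] = fit.sigma2_site
        manifest["sigma2"] = fit.sigma2
        if fit.variance.delta is not None:
            manifest["delta"] = [float(d) for d in fit.variance.delta]
        log(
            f"GAMM variance structure: {fit.variance.kind}"
            + (f"({fit.variance.covariate})" if fit.variance.covariate else "")
        )

        stage = "effect_sizes"
        eff = gamm.effect_sizes(fit, table)
        eff.to_csv(outdir / "effect_sizes.csv", index=False)
        report.tables["effect_sizes"] = eff
        report.tables["gamm_terms"] = fit.term_table
        log(f"effect sizes: {len(eff)} covariate x PC estimates")

        stage = "finalize"
        manifest["tables"] = sorted(p.name for p in outdir.glob("*.csv"))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log("run complete")
        report.manifest = manifest
        return report
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        log(f"FAILED at stage {stage}: {exc}")
        raise PipelineError(stage, exc) from exc


def _stars(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.01:
        return "*"
    return "n.s."


def report(run_directory: str | Path) -> str:
    """Render a plain-text summary of a completed run directory."""
    run_dir = Path(run_directory)
    manifest_path = run_dir / "manifest.json"
    required = ["pca_variance.csv", "manova.csv", "gamm_terms.csv", "effect_sizes.csv"]
    missing = [
        f for f in [manifest_path.name, *required] if not (run_dir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {run_dir}: missing {missing}"
        )
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"musselshape run (seed {manifest['seed']}, "
        f"{manifest['n_harmonics']} harmonics)",
        "",
        "PCA % variance (first 5 PCs):",
    ]
    pca = pd.read_csv(run_dir / "pca_variance.csv").head(5)
    for _, r in pca.iterrows():
        lines.append(f"  {r.pc}: {r.pct_variance:5.1f}%")
    man = pd.read_csv(run_dir / "manova.csv")
    lines.append("")
    lines.append("MANOVA (Wilks lambda):")
    for _, r in man.iterrows():
        lines.append(
            f"  {r.predictor}: lambda={r.wilks_lambda:.3f}, "
            f"F={r.approx_f:.2f}, p={r.p_value:.2g} {_stars(r.p_value)}"
        )
    if manifest.get("lda_overall_pct") is not None:
        lines.append("")
        lines.append(
            f"Species LDA (LOOCV): {manifest['lda_overall_pct']:.1f}% correct"
        )
    terms = pd.read_csv(run_dir / "gamm_terms.csv")
    lines.append("")
    lines.append(
        f"GAMM ({manifest['variance_structure']} variance"
        + (
            f", covariate {manifest['variance_covariate']}"
            if manifest.get("variance_covariate")
            else ""
        )
        + f"); sigma2_site={manifest['sigma2_site']:.4f}:"
    )
    for _, r in terms.iterrows():
        lines.append(
            f"  {r.term} x {r.pc}: edf={r.edf:.0f}, F={r.F:.2f}, "
            f"p={r.p:.2g} {_stars(r.p)}"
        )
    eff = pd.read_csv(run_dir / "effect_sizes.csv")
    lines.append("")
    lines.append("Effect sizes (per covariate SD, 95% CI):")
    for _, r in eff.iterrows():
        star = "*" if r.significant else "n.s."
        lines.append(
            f"  {r.covariate} on {r.pc}: {r.estimate:+.3f} "
            f"[{r.ci_lower:+.3f}, {r.ci_upper:+.3f}] {star}"
        )
    return "\n".join(lines)
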