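"""End-to-end orchestration of the stress-response quantitative-genetic
analysis: simulate (or ingest) a study, fit the univariate ladder of animal
models, the cortisol character-state (GxE) sequence, and the multivariate G
model; decompose G and attach bootstrap uncertainty; emit report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import animal_model as am
from . import defaults, gmatrix, simulate
from .pedigree import RelationshipMatrix, additive_relationship_matrix

log = logging.getLogger("stressg")

#: fixed effects used for every behavioural trait
BEHAVIOUR_FIXED = ["repeat_c", "order_c", "temperature_z", "time_z", "age_z", "sex", "generation"]
#: extra fixed effects for cortisol (context mean shift, body-mass control)
CORTISOL_FIXED = ["order_c", "temperature_z", "time_z", "age_z", "sex", "context3",
                  "mass_z", "sex:mass_z"]

UNIVARIATE_TRAITS = [
    "relative_area", "time_in_middle", "track_length", "sqrt_freezings",
    "ln_emergence", "shoaling", "ln_cortisol",
]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study analysis run."""

    seed: int = 1
    # breeding design
    n_generations: int = 2
    n_sires: int = 25
    dams_per_sire: int = 3
    offspring_per_dam: int = 4
    unknown_paternity: float = 0.0
    # model switches
    standardized: bool = False
    include_gxe: bool = True
    include_shoaling: bool = True
    univariate_traits: list = field(default_factory=lambda: list(UNIVARIATE_TRAITS))
    multivariate: bool = True
    multivariate_n_sires: int = 8
    negate_emergence: bool = True
    bootstrap_reps: int = 50
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def prepare_analysis_table(pheno: pd.DataFrame, negate_emergence: bool = True) -> pd.DataFrame:
    """Apply the multivariate-model conventions to a tidy phenotype table:
    ln emergence time is multiplied by -1 (high = fast emergence) and the
    generation column is treated as categorical."""
    df = pheno.copy()
    if negate_emergence and (df["trait"] == "ln_emergence").any():
        m = df["trait"] == "ln_emergence"
        df.loc[m, "value"] = -df.loc[m, "value"]
        df.loc[m, "trait"] = "neg_ln_emergence"
    df["generation"] = df["generation"].astype(str)
    return df


def _univariate_spec(trait: str, diag_genetic: bool = True) -> am.ModelSpec:
    fixed_terms = CORTISOL_FIXED if trait == "ln_cortisol" else BEHAVIOUR_FIXED
    random = [
        am.RandomTerm("animal", "id", None, am.Unstructured(1), pedigree=True),
        am.RandomTerm("pe", "id", None, am.Unstructured(1)),
        am.RandomTerm("group", "group", None, am.Unstructured(1)),
    ]
    return am.ModelSpec(
        [trait], random, am.ResidualSpec("trial", am.Unstructured(1)),
        {trait: list(fixed_terms)},
    )


def run_univariate_ladder(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    traits: list | None = None,
    **fit_kw,
) -> dict:
    """Fit each trait's univariate animal model, partitioning phenotypic
    variance into additive genetic, permanent environment, housing group and
    residual components, and test the genetic term by a boundary
    likelihood-ratio test (equal chi2_0 / chi2_1 mixture)."""
    traits = traits or [t for t in UNIVARIATE_TRAITS if t in set(pheno["trait"])]
    out = {}
    for trait in traits:
        sub = pheno[pheno["trait"] == trait]
        if not len(sub):
            log.warning("no data for trait %s; skipped", trait)
            continue
        t0 = time.perf_counter()
        spec = _univariate_spec(trait)
        fit = am.reml_fit(spec, sub, A, **fit_kw)
        spec0 = am.ModelSpec(
            [trait], [r for r in spec.random if r.name != "animal"],
            spec.residual, spec.fixed,
        )
        fit0 = am.reml_fit(spec0, sub, None, **fit_kw)
        test = am.lrt(fit, fit0, boundary=True)
        h2, h2_se = am.heritability(fit, trait)
        R, R_se = am.repeatability(fit, trait)
        out[trait] = {
            "fit": fit, "fit_reduced": fit0, "lrt": test,
            "h2": h2, "h2_se": h2_se, "repeatability": R, "repeatability_se": R_se,
            "wall_time": time.perf_counter() - t0,
        }
        log.info("univariate %s: Va=%.4g h2=%.3f chi2=%.2f p=%.2g (%.1fs)",
                 trait, fit.varcomp.scalar("animal"), h2, test.statistic,
                 test.p_value, out[trait]["wall_time"])
    return out


def univariate_table(ladder: dict) -> pd.DataFrame:
    """Assemble the univariate results into a components table (one row per
    trait: Va, Vpe, Vgroup, Vresidual, h2, chi2, p)."""
    rows = []
    for trait, res in ladder.items():
        vc = res["fit"].varcomp
        rows.append({
            "trait": trait,
            "Va": vc.scalar("animal"),
            "Vpe": vc.scalar("pe"),
            "Vgroup": vc.scalar("group"),
            "Vresidual": vc.scalar("residual"),
            "h2": res["h2"],
            "h2_se": res["h2_se"],
            "repeatability": res["repeatability"],
            "chi2_01": res["lrt"].statistic,
            "p": res["lrt"].p_value,
        })
    return pd.DataFrame(rows)


def run_gxe(pheno: pd.DataFrame, A: RelationshipMatrix, **fit_kw) -> dict:
    """The cortisol two-context character-state model sequence."""
    cort = pheno[pheno["trait"] == "ln_cortisol"]
    return am.gxe_model_sequence(cort, A, **fit_kw)


def multivariate_spec(traits: list[str], standardize: bool = True) -> am.ModelSpec:
    """Model specification for the multivariate G estimate: unstructured G,
    PE and GROUP over the traits; residual covariances only among the
    co-observed open-field traits (emergence and cortisol are recorded in
    separate trials, so their residual covariances are structural zeros);
    cortisol enters as a single repeated trait with a context fixed effect."""
    oft = [i for i, t in enumerate(traits) if t in simulate.OFT_TRAITS]
    blocks = [oft] + [[i] for i in range(len(traits)) if i not in oft]
    fixed = {}
    for t in traits:
        fixed[t] = list(CORTISOL_FIXED) if t == "ln_cortisol" else list(BEHAVIOUR_FIXED)
    q = len(traits)
    random = [
        am.RandomTerm("animal", "id", "trait", am.Unstructured(q), pedigree=True),
        am.RandomTerm("pe", "id", "trait", am.Unstructured(q)),
        am.RandomTerm("group", "group", "trait", am.Unstructured(q)),
    ]
    return am.ModelSpec(
        traits, random, am.ResidualSpec("trial", am.BlockDiagonal(q, blocks)),
        fixed, standardize=standardize,
    )


def run_multivariate_g(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    traits: list[str] | None = None,
    include_genetic_term: bool = True,
    integration_test: bool = True,
    **fit_kw,
) -> dict:
    """Fit the multivariate animal model (traits standardised to SD units),
    estimate G, and test overall genetic integration by comparing against a
    model with G constrained diagonal (df = number of genetic covariances).

    ``include_genetic_term=False`` runs the among-individual variant (no
    genetic term, PE absorbs all among-individual covariance), which is the
    model used to include traits without detectable genetic variance."""
    traits = traits or [t for t in defaults.G_TRAITS if t in set(pheno["trait"])]
    sub = pheno[pheno["trait"].isin(traits)]
    spec = multivariate_spec(traits)
    if not include_genetic_term:
        spec.random = [r for r in spec.random if r.name != "animal"]
        fit = am.reml_fit(spec, sub, None, **fit_kw)
        return {"fit": fit, "traits": traits}
    t0 = time.perf_counter()
    fit = am.reml_fit(spec, sub, A, **fit_kw)
    log.info("multivariate fit: %d iters, %.1fs", fit.n_iter, time.perf_counter() - t0)
    out = {"fit": fit, "traits": traits}
    if integration_test:
        spec_diag = multivariate_spec(traits)
        spec_diag.random[0] = am.RandomTerm(
            "animal", "id", "trait", am.Diagonal(len(traits)), pedigree=True
        )
        fit_diag = am.reml_fit(spec_diag, sub, A, **fit_kw)
        q = len(traits)
        out["fit_diagonal"] = fit_diag
        out["lrt_integration"] = am.lrt(fit, fit_diag, df=q * (q - 1) // 2)
    out["G"] = gmatrix.GEstimate.from_fit(fit)
    out["eigen"] = gmatrix.eigen_decomposition(out["G"])
    out["correlations"] = gmatrix.genetic_correlations(out["G"])
    return out


def g_covariance_correlation_table(
    G: gmatrix.GEstimate, reps: gmatrix.BootstrapReplicates | None = None
) -> pd.DataFrame:
    """Covariance-correlation matrix in the reporting layout: genetic
    variances on the diagonal, covariances below, correlations above, with
    bootstrap 95% percentile intervals when replicates are supplied."""
    q = len(G.traits)
    corr = gmatrix.genetic_correlations(G).to_numpy()
    M = G.G
    vals = np.where(np.triu(np.ones((q, q)), 1) > 0, corr, M)
    df = pd.DataFrame(vals, index=G.traits, columns=G.traits)
    if reps is not None and len(reps.usable()) >= 2:
        lo = np.empty((q, q))
        hi = np.empty((q, q))
        stack_cov = np.stack(reps.usable())
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(np.einsum("rii->ri", stack_cov))
            stack_corr = stack_cov / (sd[:, :, None] * sd[:, None, :])
        for i in range(q):
            for j in range(q):
                arr = stack_cov[:, i, j] if j <= i else stack_corr[:, i, j]
                arr = arr[np.isfinite(arr)]
                lo[i, j], hi[i, j] = np.quantile(arr, [0.025, 0.975])
        lo_df = pd.DataFrame(lo, index=G.traits, columns=G.traits)
        hi_df = pd.DataFrame(hi, index=G.traits, columns=G.traits)
        df = pd.concat({"estimate": df, "lo95": lo_df, "hi95": hi_df}, axis=0)
    return df


def emit_report(out_dir, config: PipelineConfig | None = None, ladder=None,
                gxe=None, multi=None, reps=None, eigen_ci=None,
                ellipses: dict | None = None) -> dict:
    """Write CSV/JSON report tables; returns the mapping of written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def _write_json(name, obj):
        p = out / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, default=float)
        written[name] = str(p)

    if config is not None:
        provenance = {
            "config": asdict(config), "config_hash": config.hash(),
            "package_version": __import__("stressg").__version__,
        }
        _write_json("provenance.json", provenance)
    if ladder is not None:
        tab = univariate_table(ladder)
        tab.to_csv(out / "univariate_components.csv", index=False)
        written["univariate_components.csv"] = str(out / "univariate_components.csv")
    if gxe is not None:
        _write_json("cortisol_gxe.json", {
            "Va": gxe["Va"], "h2": gxe["h2"], "ra13": gxe["ra13"],
            "lrt_va": asdict(gxe["lrt_va"]),
            "lrt_gxe": asdict(gxe["lrt_gxe"]),
            "lrt_correlation": asdict(gxe["lrt_correlation"]),
            "converged": {k: f.converged for k, f in gxe["fits"].items()},
        })
    if multi is not None:
        G = multi["G"]
        tab = g_covariance_correlation_table(G, reps)
        tab.to_csv(out / "G_covariance_correlation.csv")
        written["G_covariance_correlation.csv"] = str(out / "G_covariance_correlation.csv")
        eigen = eigen_ci if eigen_ci is not None else multi["eigen"]
        _write_json("eigen_summary.json", eigen.to_dict())
        eigen.loadings_frame().to_csv(out / "eigen_loadings.csv", index=False)
        written["eigen_loadings.csv"] = str(out / "eigen_loadings.csv")
        if "lrt_integration" in multi:
            _write_json("integration_lrt.json", asdict(multi["lrt_integration"]))
        if reps is not None:
            _write_json("bootstrap_log.json", {
                "n_reps": len(reps), "n_failed": reps.n_failed, "seeds": reps.seeds,
            })
    if ellipses:
        for name, pts in ellipses.items():
            p = out / f"ellipse_{name}.csv"
            pd.DataFrame(pts, columns=["x", "y"]).to_csv(p, index=False)
            written[p.name] = str(p)
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Full desk-scale analysis: simulate, fit everything, emit the report."""
    rng = np.random.default_rng(config.seed)
    t_start = time.perf_counter()
    model = simulate.default_trait_model(standardized=config.standardized)
    gxe_model = simulate.CortisolGxEModel() if config.include_gxe else None
    shoal = simulate.shoaling_trait_model() if config.include_shoaling else None
    study = simulate.generate_study(
        model, simulate.StudyDesign(), gxe_model, shoal,
        n_generations=config.n_generations, n_sires=config.n_sires,
        dams_per_sire=config.dams_per_sire,
        offspring_per_dam=config.offspring_per_dam,
        unknown_paternity=config.unknown_paternity,
        seed=int(rng.integers(2**31)),
    )
    A = additive_relationship_matrix(study.pedigree)
    pheno = prepare_analysis_table(study.phenotypes, config.negate_emergence)
    log.info("simulated %d fish, %d observations", pheno["id"].nunique(), len(pheno))

    traits_present = set(pheno["trait"])
    uni_traits = [
        ("neg_ln_emergence" if t == "ln_emergence" and config.negate_emergence else t)
        for t in config.univariate_traits
    ]
    ladder = run_univariate_ladder(
        pheno, A, [t for t in uni_traits if t in traits_present]
    )
    gxe = run_gxe(pheno, A) if config.include_gxe else None

    multi = reps = eigen_ci = None
    if config.multivariate:
        # smaller sub-study for the multivariate stage (configurable)
        study_m = simulate.generate_study(
            simulate.default_trait_model(standardized=True),
            n_generations=config.n_generations,
            n_sires=config.multivariate_n_sires,
            dams_per_sire=config.dams_per_sire,
            offspring_per_dam=config.offspring_per_dam,
            seed=int(rng.integers(2**31)),
        )
        A_m = additive_relationship_matrix(study_m.pedigree)
        pheno_m = prepare_analysis_table(study_m.phenotypes, True)
        multi = run_multivariate_g(pheno_m, A_m)
        if config.bootstrap_reps > 0:
            reps = gmatrix.parametric_bootstrap(
                multi["fit"], n_reps=config.bootstrap_reps,
                seed=int(rng.integers(2**31)),
            )
            eigen_ci = gmatrix.loading_intervals(reps, multi["eigen"])
    ellipses = {}
    if multi is not None:
        G = multi["G"]
        traits = G.traits
        if "ln_cortisol" in traits:
            ci = traits.index("ln_cortisol")
            for j, t in enumerate(traits):
                if j == ci:
                    continue
                pair = G.G[np.ix_([ci, j], [ci, j])]
                ellipses[f"ln_cortisol_{t}"] = gmatrix.confidence_ellipse(pair)
    written = emit_report(config.out_dir, config, ladder, gxe, multi, reps,
                          eigen_ci, ellipses)
    log.info("pipeline complete in %.1fs", time.perf_counter() - t_start)
    return {
        "study": study, "A": A, "ladder": ladder, "gxe": gxe, "multi": multi,
        "bootstrap": reps, "eigen_ci": eigen_ci, "written": written,
    }
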