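"""Synthetic study generator.

Builds complete synthetic studies — breeding-design pedigree, housing groups,
repeated behavioural trials, and two-context cortisol assays — with the
statistical structure the downstream animal models assume: additive genetic
effects with covariance ``A (x) G``, permanent-environment and housing-group
effects shared across an individual's (or group's) observations, and residuals
correlated only among traits measured in the same trial.

Traits are simulated directly on their transformed analysis scales (ln
cortisol, square-root freezings, ln emergence time); an inverse-transform
emitter produces raw-scale values for exercising the transformation code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .pedigree import Pedigree, additive_relationship_matrix, simulate_pedigree

OFT_TRAITS = ["relative_area", "time_in_middle", "track_length", "sqrt_freezings"]


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() < -tol:
        raise ValueError(f"{name} must be positive semi-definite")


@dataclass
class TraitModel:
    """Generating model for a set of traits: per-random-term covariance
    matrices (additive genetic G, permanent environment PE, housing group
    GROUP, residual R), trait means, and fixed-effect coefficient maps
    (covariate column -> coefficient, per trait).
    """

    trait_names: list[str]
    G: np.ndarray
    PE: np.ndarray
    GROUP: np.ndarray
    R: np.ndarray
    means: dict[str, float] = field(default_factory=dict)
    fixed_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        q = len(self.trait_names)
        if len(set(self.trait_names)) != q:
            raise ValueError("trait names must be unique")
        for name in ("G", "PE", "GROUP", "R"):
            M = np.asarray(getattr(self, name), dtype=float)
            if M.shape != (q, q):
                raise ValueError(f"{name} must be {q}x{q}")
            _check_psd(M, name)
            setattr(self, name, M)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def phenotypic_covariance(self) -> np.ndarray:
        return self.G + self.PE + self.GROUP + self.R


@dataclass
class CortisolGxEModel:
    """Two-context cortisol model: context means (ln ng/hr), context-specific
    additive genetic variances, cross-context genetic correlation, and group /
    residual variances per context."""

    mu1: float = defaults.CORTISOL_GXE["mu1"]
    mu3: float = defaults.CORTISOL_GXE["mu3"]
    Va1: float = defaults.CORTISOL_GXE["Va1"]
    Va3: float = defaults.CORTISOL_GXE["Va3"]
    ra13: float = defaults.CORTISOL_GXE["ra13"]
    Vgroup1: float = defaults.CORTISOL_GXE["Vgroup1"]
    Vgroup3: float = defaults.CORTISOL_GXE["Vgroup3"]
    Vr1: float = defaults.CORTISOL_GXE["Vr1"]
    Vr3: float = defaults.CORTISOL_GXE["Vr3"]

    def __post_init__(self):
        for k in ("Va1", "Va3", "Vgroup1", "Vgroup3", "Vr1", "Vr3"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")
        if abs(self.ra13) > 1:
            raise ValueError("|ra13| must be <= 1")

    def genetic_covariance(self) -> np.ndarray:
        cov = self.ra13 * np.sqrt(self.Va1 * self.Va3)
        return np.array([[self.Va1, cov], [cov, self.Va3]])


@dataclass
class StudyDesign:
    """Housing and assay design: group sizes, per-assay repeat counts and
    inclusion probabilities, covariate generators."""

    group_size_range: tuple[int, int] = (16, 20)
    oft_repeats: tuple[int, int] = (2, 4)
    et_repeats: int = 2
    st_repeats: int = 2
    cortisol_contexts: tuple[int, ...] = (1, 3)
    inclusion: dict[str, float] = field(
        default_factory=lambda: dict(defaults.ASSAY_INCLUSION)
    )
    temperature_mean: float = 24.0
    temperature_sd: float = 0.4
    behaviour_time_range: tuple[float, float] = (540.0, 1020.0)  # minutes from midnight
    cortisol_time_range: tuple[float, float] = (720.0, 840.0)
    age_range: tuple[float, float] = (180.0, 350.0)  # days at first assay
    mass_log_mean: float = np.log(0.25)  # grams
    mass_log_sd: float = 0.15


def default_trait_model(standardized: bool = False) -> TraitModel:
    """Reference generating model for the six G-matrix traits.

    ``standardized=False``: traits on their transformed analysis scales, with
    per-term variances from the univariate reference components and a genetic
    correlation structure from the standardised reference G (the emergence row
    is sign-flipped because the raw-scale trait is un-negated ln emergence).
    ``standardized=True``: unit phenotypic variance per trait with G exactly
    the standardised reference matrix; PE/GROUP/R diagonal, scaled so each
    trait's total variance is 1.
    """
    corr = defaults.g_correlation_matrix()
    if standardized:
        names = list(defaults.G_TRAITS)
        G = defaults.default_g_matrix()
        comps = {
            t: defaults.UNIVARIATE_COMPONENTS[t if t != "neg_ln_emergence" else "ln_emergence"]
            for t in names
        }
        pe, grp, res = [], [], []
        for i, t in enumerate(names):
            c = comps[t]
            vp = c["Va"] + c["Vpe"] + c["Vgroup"] + c["Vr"]
            rest = 1.0 - G[i, i]
            w = c["Vpe"] + c["Vgroup"] + c["Vr"]
            pe.append(rest * c["Vpe"] / w)
            grp.append(rest * c["Vgroup"] / w)
            res.append(rest * c["Vr"] / w)
            del vp
        model = TraitModel(names, G, np.diag(pe), np.diag(grp), np.diag(res))
    else:
        names = ["relative_area", "time_in_middle", "track_length", "sqrt_freezings",
                 "ln_emergence", "ln_cortisol"]
        flip = np.ones(6)
        flip[4] = -1.0  # reference correlations are for -ln emergence
        corr = corr * np.outer(flip, flip)
        va = np.array([defaults.UNIVARIATE_COMPONENTS[t]["Va"] for t in names])
        G = corr * np.sqrt(np.outer(va, va))
        PE = np.diag([defaults.UNIVARIATE_COMPONENTS[t]["Vpe"] for t in names])
        GR = np.diag([defaults.UNIVARIATE_COMPONENTS[t]["Vgroup"] for t in names])
        R = np.diag([defaults.UNIVARIATE_COMPONENTS[t]["Vr"] for t in names])
        model = TraitModel(names, G, PE, GR, R)
    model.means = {
        "relative_area": 0.0,
        "time_in_middle": 60.0,
        "track_length": 1500.0,
        "sqrt_freezings": 2.0,
        "ln_emergence": 5.0,
        "neg_ln_emergence": -5.0,
        "ln_cortisol": 8.47,
    }
    model.means = {t: model.means[t] if not standardized else 0.0 for t in names}
    sd = np.sqrt(np.diag(model.phenotypic_covariance()))
    for i, t in enumerate(names):
        model.fixed_effects[t] = {
            "temperature_z": 0.05 * sd[i],
            "time_z": -0.05 * sd[i],
            "age_z": 0.10 * sd[i],
            "sex_m": -0.15 * sd[i],
            "repeat_c": -0.10 * sd[i],
            "order_c": -0.02 * sd[i],
        }
        if t == "ln_cortisol":
            model.fixed_effects[t]["context3"] = (
                defaults.CORTISOL_GXE["mu3"] - defaults.CORTISOL_GXE["mu1"]
            ) * (1.0 if not standardized else 1.0 / np.sqrt(0.26))
            model.fixed_effects[t]["mass_z"] = 0.05 * sd[i]
    return model


def shoaling_trait_model() -> TraitModel:
    """Univariate generating model for shoaling tendency (no genetic variance)."""
    c = defaults.UNIVARIATE_COMPONENTS["shoaling"]
    one = lambda v: np.array([[float(v)]])
    m = TraitModel(["shoaling"], one(c["Va"]), one(c["Vpe"]), one(c["Vgroup"]), one(c["Vr"]))
    m.means = {"shoaling": 20.0}
    m.fixed_effects = {"shoaling": {"sex_m": -10.0, "repeat_c": -5.0}}
    return m


# ---------------------------------------------------------------------------
# breeding values


def sample_breeding_values(
    ped: Pedigree, G: np.ndarray, seed: int = 0, inbreeding: np.ndarray | None = None
) -> pd.DataFrame:
    """Sample multivariate additive genetic deviations down the pedigree.

    Founders are MVN(0, G).  A non-founder receives the mean of its known
    parents' values plus a Mendelian-sampling deviation with covariance
    ``(1 - k - 0.25 * (F_sire + F_dam)) * G`` where k is 0.25 per known
    parent; stacked over individuals the values have covariance ``A (x) G``.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    _check_psd(G, "G")
    q = G.shape[0]
    rng = np.random.default_rng(seed)
    if inbreeding is None:
        inbreeding = additive_relationship_matrix(ped).values.diagonal() - 1.0
    idx = ped.index()
    n = len(ped)
    vals = np.zeros((n, q))
    if np.allclose(G, 0):
        return pd.DataFrame(vals, index=ped.ids)
    # Cholesky with PSD fallback
    w, U = np.linalg.eigh(G)
    L = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    for i, rec in enumerate(ped.records):
        s = idx.get(rec.sire, -1)
        d = idx.get(rec.dam, -1)
        mean = np.zeros(q)
        scale = 1.0
        for p in (s, d):
            if p >= 0:
                mean += 0.5 * vals[p]
                scale -= 0.25 * (1.0 + inbreeding[p])
        vals[i] = mean + np.sqrt(max(scale, 0.0)) * (L @ rng.standard_normal(q))
    return pd.DataFrame(vals, index=ped.ids)


# ---------------------------------------------------------------------------
# housing groups


def assign_groups(individuals: pd.DataFrame, design: StudyDesign | None = None, seed: int = 0) -> pd.Series:
    """Assign adults to mixed-family housing groups.

    ``individuals`` needs columns ``id``, ``sex`` and ``family`` (full-sib
    family label, e.g. the dam).  Group sizes fall within the design range,
    sexes are balanced to within one fish, and families are dispersed across
    groups by round-robin allocation.  Returns a Series of group labels
    indexed by id.
    """
    design = design or StudyDesign()
    lo, hi = design.group_size_range
    n = len(individuals)
    if n < lo:
        raise ValueError(f"insufficient individuals ({n}) for one group of >= {lo}")
    g_min = int(np.ceil(n / hi))
    g_max = int(n // lo)
    if g_min > g_max:
        raise ValueError(f"cannot split {n} fish into groups of {lo}-{hi}")
    n_groups = g_min  # prefer larger groups (fewer of them)
    rng = np.random.default_rng(seed)
    labels = [f"grp{k}" for k in range(n_groups)]
    out: dict[str, str] = {}
    offset = 0
    for sex in sorted(individuals["sex"].unique()):
        sub = individuals[individuals["sex"] == sex].copy()
        fam_order = {f: i for i, f in enumerate(rng.permutation(sub["family"].unique()))}
        sub = sub.sort_values(by="family", key=lambda s: s.map(fam_order), kind="stable")
        for j, fid in enumerate(sub["id"]):
            out[fid] = labels[(j + offset) % n_groups]
        offset += len(sub)
    return pd.Series(out, name="group")


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(trials: pd.DataFrame, design: StudyDesign | None = None, seed: int = 0) -> pd.DataFrame:
    """Attach assay covariates to a trial skeleton.

    ``trials`` needs columns ``id``, ``group``, ``assay`` and ``repeat``.
    Adds: order caught (an exact permutation within each group x assay x
    repeat), water temperature, time of day, age, sex-independent body mass,
    each emitted raw and mean-centred/scaled (``*_z`` / ``*_c`` columns).
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    df = trials.copy()
    n = len(df)
    df["temperature"] = np.clip(
        rng.normal(design.temperature_mean, design.temperature_sd, n), 23.0, 25.0
    )
    is_cort = df["assay"].eq("cortisol").to_numpy()
    t_lo = np.where(is_cort, design.cortisol_time_range[0], design.behaviour_time_range[0])
    t_hi = np.where(is_cort, design.cortisol_time_range[1], design.behaviour_time_range[1])
    df["time_of_day"] = rng.uniform(t_lo, t_hi)
    base_age = pd.Series(
        rng.uniform(*design.age_range, size=df["id"].nunique()),
        index=df["id"].unique(),
    )
    df["age"] = base_age.reindex(df["id"]).to_numpy() + 2.0 * (df["repeat"].to_numpy() - 1)
    mass = pd.Series(
        np.exp(rng.normal(design.mass_log_mean, design.mass_log_sd, df["id"].nunique())),
        index=df["id"].unique(),
    )
    df["body_mass"] = mass.reindex(df["id"]).to_numpy()
    df["order"] = 0
    for _, idx in df.groupby(["group", "assay", "repeat"], sort=True).groups.items():
        df.loc[idx, "order"] = rng.permutation(len(idx)) + 1
    for col, zname in [
        ("temperature", "temperature_z"),
        ("time_of_day", "time_z"),
        ("age", "age_z"),
        ("body_mass", "mass_z"),
    ]:
        v = df[col].to_numpy(dtype=float)
        sdv = v.std()
        df[zname] = (v - v.mean()) / (sdv if sdv > 0 else 1.0)
    df["order_c"] = df["order"] - df["order"].mean()
    df["repeat_c"] = df["repeat"] - df["repeat"].mean()
    return df


# ---------------------------------------------------------------------------
# phenotypes


def _mvn_draws(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    w, U = np.linalg.eigh(np.atleast_2d(cov))
    L = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return rng.standard_normal((n, len(w))) @ L.T


def _trial_skeleton(
    ids: list[str], groups: pd.Series, design: StudyDesign, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    inc = design.inclusion
    for fid in ids:
        grp = groups[fid]
        if rng.random() < inc.get("oft", 1.0):
            n_oft = int(rng.integers(design.oft_repeats[0], design.oft_repeats[1] + 1))
            for r in range(1, n_oft + 1):
                rows.append((fid, grp, "oft", r))
        if rng.random() < inc.get("et", 1.0):
            for r in range(1, design.et_repeats + 1):
                rows.append((fid, grp, "et", r))
        if rng.random() < inc.get("st", 1.0):
            for r in range(1, design.st_repeats + 1):
                rows.append((fid, grp, "st", r))
        if rng.random() < inc.get("cortisol", 1.0):
            for r, ctx in enumerate(design.cortisol_contexts, start=1):
                rows.append((fid, grp, "cortisol", r))
    df = pd.DataFrame(rows, columns=["id", "group", "assay", "repeat"])
    df["trial"] = [f"{a}_{i}_{r}" for a, i, r in zip(df["assay"], df["id"], df["repeat"])]
    return df


def simulate_phenotypes(
    ped: Pedigree,
    breeding_values: pd.DataFrame,
    groups: pd.Series,
    model: TraitModel,
    design: StudyDesign | None = None,
    cortisol_gxe: CortisolGxEModel | None = None,
    shoaling: TraitModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the tidy long-format phenotype table.

    Each observation is fixed-effect linear predictor + additive genetic
    deviation + individual permanent-environment draw + housing-group draw +
    residual draw; repeated trials of an individual share the genetic, PE and
    group components, and traits recorded in the same trial share a residual
    unit.  If ``cortisol_gxe`` is given, the two cortisol contexts get
    context-specific genetic variances with cross-context genetic correlation
    ``ra13`` (the shared component is the trait-model cortisol merit, so
    genetic integration with behaviour is preserved up to sqrt(ra13)).
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    ids = [i for i in breeding_values.index if i in groups.index]
    q = model.n_traits
    traits = model.trait_names
    if breeding_values.shape[1] != q:
        raise ValueError("breeding values do not match trait count")
    bv = pd.DataFrame(breeding_values.to_numpy(), index=breeding_values.index, columns=traits)

    skel = _trial_skeleton(ids, groups, design, rng)
    cov = simulate_covariates(skel, design, seed=int(rng.integers(2**31)))
    sex_map = pd.Series({r.id: r.sex for r in ped.records})
    cov["sex_m"] = sex_map.reindex(cov["id"]).eq("M").to_numpy().astype(float)
    cov["context"] = np.where(
        cov["assay"].eq("cortisol"),
        cov["repeat"].map(dict(enumerate(design.cortisol_contexts, start=1))),
        np.nan,
    )
    cov["context3"] = (cov["context"] == 3).astype(float)

    pe = pd.DataFrame(_mvn_draws(rng, model.PE, len(ids)), index=ids, columns=traits)
    grp_labels = sorted(groups.unique())
    ge = pd.DataFrame(_mvn_draws(rng, model.GROUP, len(grp_labels)), index=grp_labels, columns=traits)

    # context-specific genetic deviations for cortisol under GxE
    gxe_dev = None
    if cortisol_gxe is not None and "ln_cortisol" in traits:
        m = cortisol_gxe
        vg_cort = model.G[traits.index("ln_cortisol"), traits.index("ln_cortisol")]
        zc = bv["ln_cortisol"] / np.sqrt(vg_cort) if vg_cort > 0 else bv["ln_cortisol"] * 0.0
        w1 = sample_breeding_values(ped, np.array([[1.0]]), seed=int(rng.integers(2**31)))[0]
        w3 = sample_breeding_values(ped, np.array([[1.0]]), seed=int(rng.integers(2**31)))[0]
        lam = {1: np.sqrt(m.ra13 * m.Va1), 3: np.sqrt(m.ra13 * m.Va3)}
        delta = {1: np.sqrt((1 - m.ra13) * m.Va1), 3: np.sqrt((1 - m.ra13) * m.Va3)}
        gxe_dev = {
            1: lam[1] * zc + delta[1] * w1.reindex(zc.index),
            3: lam[3] * zc + delta[3] * w3.reindex(zc.index),
        }

    assay_traits = {
        "oft": [t for t in OFT_TRAITS if t in traits],
        "et": [t for t in ("ln_emergence", "neg_ln_emergence") if t in traits],
        "cortisol": ["ln_cortisol"] if "ln_cortisol" in traits else [],
    }
    # union of fixed-effect covariate columns -> coefficient matrix per trait
    fx_cols = sorted({c for m_ in model.fixed_effects.values() for c in m_})
    coef = np.zeros((q, len(fx_cols)))
    for i, t in enumerate(traits):
        for j, c in enumerate(fx_cols):
            coef[i, j] = model.fixed_effects.get(t, {}).get(c, 0.0)

    blocks = []
    for assay, tl in assay_traits.items():
        if not tl:
            continue
        sub = cov[cov["assay"] == assay]
        if not len(sub):
            continue
        sel = [traits.index(t) for t in tl]
        resid = _mvn_draws(rng, model.R[np.ix_(sel, sel)], len(sub))
        for k, t in enumerate(tl):
            blk = sub.copy()
            blk["trait"] = t
            blk["_resid"] = resid[:, k]
            blocks.append(blk)
    obs = pd.concat(blocks, ignore_index=True)

    t_of = obs["trait"].map({t: i for i, t in enumerate(traits)}).to_numpy()
    id_of = obs["id"].map({i: k for k, i in enumerate(ids)}).to_numpy()
    grp_of = obs["group"].map({g: k for k, g in enumerate(grp_labels)}).to_numpy()
    X = obs.reindex(columns=fx_cols, fill_value=0.0).to_numpy(dtype=float)
    X = np.nan_to_num(X)
    fx = np.einsum("ij,ij->i", coef[t_of], X)
    mu = obs["trait"].map(lambda t: model.means.get(t, 0.0)).to_numpy(dtype=float)
    gval = bv.loc[ids].to_numpy()[id_of, t_of]
    peval = pe.to_numpy()[id_of, t_of]
    geval = ge.to_numpy()[grp_of, t_of]
    resid = obs["_resid"].to_numpy()

    if gxe_dev is not None:
        m = cortisol_gxe
        is_cort = (obs["trait"] == "ln_cortisol").to_numpy()
        ctx = obs["context"].to_numpy()
        base_g = model.GROUP[traits.index("ln_cortisol"), traits.index("ln_cortisol")]
        for c in (1, 3):
            mask = is_cort & (ctx == c)
            if not mask.any():
                continue
            gval[mask] = gxe_dev[c].loc[ids].to_numpy()[id_of[mask]]
            gvar = m.Vgroup1 if c == 1 else m.Vgroup3
            rvar = m.Vr1 if c == 1 else m.Vr3
            geval[mask] = (
                geval[mask] * np.sqrt(gvar / base_g) if base_g > 0
                else _mvn_draws(rng, np.array([[gvar]]), mask.sum())[:, 0]
            )
            resid[mask] = rng.normal(0.0, np.sqrt(rvar), mask.sum())

    obs["value"] = mu + fx + gval + peval + geval + resid
    pheno = obs.drop(columns=["_resid"])

    if shoaling is not None:
        st = cov[cov["assay"] == "st"]
        if len(st):
            bv_s = sample_breeding_values(ped, shoaling.G, seed=int(rng.integers(2**31)))[0]
            pe_s = pd.Series(_mvn_draws(rng, shoaling.PE, len(ids))[:, 0], index=ids)
            ge_s = pd.Series(_mvn_draws(rng, shoaling.GROUP, len(grp_labels))[:, 0], index=grp_labels)
            fxs = shoaling.fixed_effects.get("shoaling", {})
            Xs = st.reindex(columns=sorted(fxs), fill_value=0.0).to_numpy(dtype=float)
            cs = np.array([fxs[c] for c in sorted(fxs)])
            sh = st.copy()
            sh["trait"] = "shoaling"
            sh["value"] = (
                shoaling.means.get("shoaling", 0.0)
                + (np.nan_to_num(Xs) @ cs if len(cs) else 0.0)
                + bv_s.reindex(sh["id"]).to_numpy()
                + pe_s.reindex(sh["id"]).to_numpy()
                + ge_s.reindex(sh["group"]).to_numpy()
                + rng.normal(0.0, np.sqrt(shoaling.R[0, 0]), len(sh))
            )
            pheno = pd.concat([pheno, sh], ignore_index=True)

    pheno["sex"] = sex_map.reindex(pheno["id"]).to_numpy()
    pheno["generation"] = pheno["id"].map({r.id: r.generation for r in ped.records})
    keep = [
        "id", "group", "assay", "repeat", "trial", "trait", "value", "context",
        "context3", "order", "order_c", "repeat_c", "temperature", "temperature_z",
        "time_of_day", "time_z", "age", "age_z", "body_mass", "mass_z",
        "sex", "sex_m", "generation",
    ]
    return pheno[keep].reset_index(drop=True)


def validate_phenotypes(pheno: pd.DataFrame, ped: Pedigree) -> None:
    known = set(ped.ids)
    missing = set(pheno["id"]) - known
    if missing:
        raise ValueError(f"phenotyped ids missing from pedigree: {sorted(missing)[:5]}")
    cort = pheno[pheno["trait"] == "ln_cortisol"]
    if len(cort) and not cort["context"].isin([1, 3]).all():
        raise ValueError("cortisol rows must carry context 1 or 3")


def to_raw_scale(pheno: pd.DataFrame, emergence_max: float = 900.0) -> pd.DataFrame:
    """Invert the analysis transformations to produce raw-scale fixtures:
    freezing counts from their square roots, emergence seconds (censored at
    the trial maximum) and cortisol ng/hr from logs."""
    out = pheno.copy()
    v = out["value"].to_numpy(dtype=float).copy()
    tr = out["trait"]
    v[tr == "sqrt_freezings"] = np.round(np.clip(v[tr == "sqrt_freezings"], 0, None) ** 2)
    v[tr == "ln_emergence"] = np.minimum(np.exp(v[tr == "ln_emergence"]), emergence_max)
    v[tr == "neg_ln_emergence"] = np.minimum(np.exp(-v[tr == "neg_ln_emergence"]), emergence_max)
    v[tr == "ln_cortisol"] = np.exp(v[tr == "ln_cortisol"])
    out["value"] = v
    out["trait"] = tr.replace(
        {
            "sqrt_freezings": "freezings",
            "ln_emergence": "emergence_s",
            "neg_ln_emergence": "emergence_s",
            "ln_cortisol": "cortisol_ng_hr",
        }
    )
    return out


# ---------------------------------------------------------------------------
# whole-study wrapper


@dataclass
class SyntheticStudy:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    groups: pd.Series
    breeding_values: pd.DataFrame
    truth: dict

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(d / "pedigree.csv")
        self.phenotypes.to_csv(d / "phenotypes.csv", index=False)
        with open(d / "truth.yaml", "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=False)


def generate_study(
    model: TraitModel | None = None,
    design: StudyDesign | None = None,
    cortisol_gxe: CortisolGxEModel | None = None,
    shoaling: TraitModel | None = None,
    n_generations: int = 2,
    n_sires: int = 25,
    dams_per_sire: int = 3,
    offspring_per_dam: int = 4,
    unknown_paternity: float = 0.0,
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a complete study: pedigree, housing groups, phenotypes.

    Defaults give ~600 phenotype-eligible fish over two measured generations,
    in maternal full-sib families nested within paternal half-sib groups,
    housed in mixed-family groups of 16-20.
    """
    model = model or default_trait_model()
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(
        n_generations, n_sires, dams_per_sire, offspring_per_dam,
        unknown_paternity=unknown_paternity, seed=int(rng.integers(2**31)),
    )
    bv = sample_breeding_values(ped, model.G, seed=int(rng.integers(2**31)))
    bv.columns = model.trait_names
    offspring = ped.to_frame().query("generation > 0")
    indiv = pd.DataFrame(
        {"id": offspring["id"], "sex": offspring["sex"], "family": offspring["dam"]}
    )
    groups = assign_groups(indiv, design, seed=int(rng.integers(2**31)))
    pheno = simulate_phenotypes(
        ped, bv, groups, model, design, cortisol_gxe, shoaling,
        seed=int(rng.integers(2**31)),
    )
    truth = {
        "trait_names": model.trait_names,
        "G": model.G.tolist(),
        "PE": model.PE.tolist(),
        "GROUP": model.GROUP.tolist(),
        "R": model.R.tolist(),
        "means": {k: float(v) for k, v in model.means.items()},
        "cortisol_gxe": asdict(cortisol_gxe) if cortisol_gxe else None,
        "seed": seed,
    }
    return SyntheticStudy(ped, pheno, groups, bv, truth)
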