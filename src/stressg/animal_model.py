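"""Pedigree-based linear mixed "animal models" fitted by REML.

The observation model is

    y = X b + sum_j Z_j u_j + e,     u_j ~ N(0, Sigma_j (x) K_j),

where each random term j has a covariance matrix ``Sigma_j`` over its axes
(traits, or environmental contexts in a character-state model) and a known
relationship structure ``K_j`` over its levels — the additive relationship
matrix A for the genetic term, identity for permanent-environment and
housing-group terms.  Residuals are correlated only among traits recorded in
the same residual unit (trial); covariances between never-co-observed traits
are structurally zero.

Restricted maximum likelihood is computed through the mixed-model equations
(coefficient matrix C), using

    -2 l_R = log|R| + sum_j log|Sigma_j (x) K_j| + log|C| + y'Py + (n-p) log 2pi.

Estimation is average-information (AI) REML with a few initial
expectation-maximisation steps for stability, step halving against the
restricted likelihood, and eigenvalue bending to keep every covariance matrix
(weakly) positive definite.  Standard errors come from the inverse AI matrix
at the optimum; the delta method propagates them to heritabilities,
repeatabilities and correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.stats import chi2, f as f_dist

from .pedigree import RelationshipMatrix

__all__ = [
    "Unstructured", "Diagonal", "BlockDiagonal", "SharedLoadings",
    "RandomTerm", "ResidualSpec", "ModelSpec", "VarianceComponents",
    "FitResult", "LRTResult", "reml_fit", "heritability", "repeatability",
    "lrt", "wald_fixed", "blup", "gxe_model_sequence", "simulate_response",
    "refit",
]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# covariance structures


class CovStructure:
    """Parameterised symmetric PSD matrix over a term's axes."""

    dim: int

    @property
    def n_params(self) -> int:
        raise NotImplementedError

    def init(self, scale: np.ndarray, frac: float) -> np.ndarray:
        raise NotImplementedError

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dsigma(self, theta: np.ndarray) -> list[np.ndarray]:
        """Derivative matrices dSigma/dtheta_k."""
        raise NotImplementedError

    def repair(self, theta: np.ndarray, floor: float) -> np.ndarray:
        return theta

    def labels(self, axes: Sequence) -> list[str]:
        raise NotImplementedError


def _bend(M: np.ndarray, floor: float) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(M)
    if w.min() >= floor:
        return M
    return (U * np.clip(w, floor, None)) @ U.T


class Unstructured(CovStructure):
    """Free symmetric PSD matrix; parameters are the lower-triangle elements."""

    def __init__(self, dim: int):
        self.dim = dim
        self._tril = np.tril_indices(dim)

    @property
    def n_params(self) -> int:
        return self.dim * (self.dim + 1) // 2

    def init(self, scale, frac):
        return self.sigma_to_theta(np.diag(frac * scale))

    def sigma_to_theta(self, S):
        return np.asarray(S)[self._tril].copy()

    def sigma(self, theta):
        S = np.zeros((self.dim, self.dim))
        S[self._tril] = theta
        return S + np.tril(S, -1).T

    def dsigma(self, theta):
        out = []
        for r, c in zip(*self._tril):
            E = np.zeros((self.dim, self.dim))
            E[r, c] = E[c, r] = 1.0
            out.append(E)
        return out

    def repair(self, theta, floor):
        return self.sigma_to_theta(_bend(self.sigma(theta), floor))

    def labels(self, axes):
        return [f"({axes[r]},{axes[c]})" if r != c else f"({axes[r]})"
                for r, c in zip(*self._tril)]


class Diagonal(CovStructure):
    """Independent variances per axis (covariances fixed at zero)."""

    def __init__(self, dim: int):
        self.dim = dim

    @property
    def n_params(self) -> int:
        return self.dim

    def init(self, scale, frac):
        return frac * np.asarray(scale, dtype=float)

    def sigma(self, theta):
        return np.diag(theta)

    def dsigma(self, theta):
        out = []
        for k in range(self.dim):
            E = np.zeros((self.dim, self.dim))
            E[k, k] = 1.0
            out.append(E)
        return out

    def repair(self, theta, floor):
        return np.clip(theta, floor, None)

    def labels(self, axes):
        return [f"({a})" for a in axes]


class BlockDiagonal(CovStructure):
    """Unstructured within listed axis blocks, zero between blocks.

    Used for residual covariance where only co-observed traits may covary.
    """

    def __init__(self, dim: int, blocks: Sequence[Sequence[int]]):
        self.dim = dim
        self.blocks = [list(b) for b in blocks]
        covered = sorted(i for b in self.blocks for i in b)
        if covered != list(range(dim)):
            raise ValueError("blocks must partition the axes")
        self._subs = [Unstructured(len(b)) for b in self.blocks]

    @property
    def n_params(self) -> int:
        return sum(s.n_params for s in self._subs)

    def _split(self, theta):
        out, k = [], 0
        for s in self._subs:
            out.append(np.asarray(theta[k: k + s.n_params]))
            k += s.n_params
        return out

    def init(self, scale, frac):
        scale = np.asarray(scale, dtype=float)
        return np.concatenate(
            [s.init(scale[b], frac) for s, b in zip(self._subs, self.blocks)]
        )

    def sigma(self, theta):
        S = np.zeros((self.dim, self.dim))
        for s, b, th in zip(self._subs, self.blocks, self._split(theta)):
            S[np.ix_(b, b)] = s.sigma(th)
        return S

    def dsigma(self, theta):
        out = []
        for s, b, th in zip(self._subs, self.blocks, self._split(theta)):
            for E in s.dsigma(th):
                F = np.zeros((self.dim, self.dim))
                F[np.ix_(b, b)] = E
                out.append(F)
        return out

    def repair(self, theta, floor):
        return np.concatenate(
            [s.repair(th, floor) for s, th in zip(self._subs, self._split(theta))]
        )

    def labels(self, axes):
        out = []
        for s, b in zip(self._subs, self.blocks):
            out.extend(s.labels([axes[i] for i in b]))
        return out


class SharedLoadings(CovStructure):
    """Rank-one covariance ``lambda lambda'`` via a single shared factor.

    Implements the constraint that a genetic correlation equals one across
    axes (e.g. contexts) while axis variances ``lambda_c**2`` may differ; the
    loadings are carried in the design matrix so the factor itself has unit
    variance and the mixed-model equations stay non-singular.
    """

    def __init__(self, dim: int):
        self.dim = dim

    @property
    def n_params(self) -> int:
        return self.dim

    def init(self, scale, frac):
        return np.sqrt(frac * np.asarray(scale, dtype=float))

    def sigma(self, theta):
        return np.outer(theta, theta)

    def dsigma(self, theta):
        out = []
        for c in range(self.dim):
            E = np.zeros((self.dim, self.dim))
            E[c, :] += theta
            E[:, c] += theta
            out.append(E)
        return out

    def repair(self, theta, floor):
        # keep loadings away from exactly zero so AI steps stay informative
        theta = np.asarray(theta, dtype=float).copy()
        tiny = np.sqrt(max(floor, 1e-12))
        small = np.abs(theta) < tiny
        theta[small] = np.where(theta[small] >= 0, tiny, -tiny)
        return theta

    def labels(self, axes):
        return [f"loading({a})" for a in axes]


# ---------------------------------------------------------------------------
# model specification


@dataclass
class RandomTerm:
    """One random effect: its grouping column, axis column (None = one shared
    effect across all observations of a level), covariance structure, and
    whether levels are related through the pedigree."""

    name: str
    level_col: str
    axis_col: str | None = None
    structure: CovStructure | None = None
    pedigree: bool = False


@dataclass
class ResidualSpec:
    """Residual covariance: observations sharing ``unit_col`` are co-observed
    and may covary according to ``structure`` over the model's traits."""

    unit_col: str = "trial"
    structure: CovStructure | None = None


def _structure_to_dict(s: CovStructure | None):
    if s is None:
        return None
    if isinstance(s, BlockDiagonal):
        return {"kind": "blockdiag", "dim": s.dim, "blocks": s.blocks}
    kind = {Unstructured: "unstructured", Diagonal: "diagonal",
            SharedLoadings: "loadings"}[type(s)]
    return {"kind": kind, "dim": s.dim}


def _structure_from_dict(d) -> CovStructure | None:
    if d is None:
        return None
    kind = d["kind"]
    if kind == "blockdiag":
        return BlockDiagonal(d["dim"], d["blocks"])
    return {"unstructured": Unstructured, "diagonal": Diagonal,
            "loadings": SharedLoadings}[kind](d["dim"])


@dataclass
class ModelSpec:
    """Specification of a (multi-)trait animal model on tidy long data."""

    traits: list
    random: list[RandomTerm]
    residual: ResidualSpec
    fixed: dict = field(default_factory=dict)  # trait -> list of formula terms
    trait_col: str = "trait"
    value_col: str = "value"
    standardize: bool = False

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "traits": list(self.traits),
            "random": [
                {"name": r.name, "level_col": r.level_col, "axis_col": r.axis_col,
                 "structure": _structure_to_dict(r.structure), "pedigree": r.pedigree}
                for r in self.random
            ],
            "residual": {"unit_col": self.residual.unit_col,
                         "structure": _structure_to_dict(self.residual.structure)},
            "fixed": {k: list(v) for k, v in self.fixed.items()},
            "trait_col": self.trait_col,
            "value_col": self.value_col,
            "standardize": self.standardize,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            traits=d["traits"],
            random=[RandomTerm(r["name"], r["level_col"], r.get("axis_col"),
                               _structure_from_dict(r.get("structure")),
                               bool(r.get("pedigree", False)))
                    for r in d.get("random", [])],
            residual=ResidualSpec(d["residual"]["unit_col"],
                                  _structure_from_dict(d["residual"].get("structure"))),
            fixed=d.get("fixed", {}),
            trait_col=d.get("trait_col", "trait"),
            value_col=d.get("value_col", "value"),
            standardize=bool(d.get("standardize", False)),
        )


# ---------------------------------------------------------------------------
# design-matrix construction (minimal formula language)


def _encode_factor(df: pd.DataFrame, name: str):
    col = df[name]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        cats = pd.Categorical(col)
        levels = list(cats.categories)
        mats, names = [], []
        for lev in levels[1:]:
            mats.append((cats == lev).astype(float)[:, None])
            names.append(f"{name}[{lev}]")
        if not mats:
            return np.zeros((len(df), 0)), []
        return np.hstack(mats), names
    return col.to_numpy(dtype=float)[:, None], [name]


def build_design(df: pd.DataFrame, terms: Sequence[str]):
    """Build a fixed-effect design matrix from a list of term names.

    Terms are column names (categoricals are dummy-encoded dropping the first
    level), ``a:b`` interactions (elementwise products of the encoded parts),
    and an implicit intercept (suppressed if ``"0"`` appears).
    """
    mats = []
    names = []
    if "0" not in terms:
        mats.append(np.ones((len(df), 1)))
        names.append("(Intercept)")
    for t in terms:
        if t in ("0", "1"):
            continue
        parts = t.split(":")
        M, nm = _encode_factor(df, parts[0])
        for pnext in parts[1:]:
            M2, nm2 = _encode_factor(df, pnext)
            M = np.einsum("ij,ik->ijk", M, M2).reshape(len(df), -1)
            nm = [f"{a}:{b}" for a in nm for b in nm2]
        mats.append(M)
        names.extend(nm)
    X = np.hstack(mats) if mats else np.zeros((len(df), 0))
    return X, names


def _drop_aliased(X: np.ndarray, names: list[str]):
    if X.shape[1] == 0:
        return X, names
    _, Rm, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(Rm))
    tol = max(X.shape) * np.finfo(float).eps * (d.max() if len(d) else 0.0)
    rank = int(np.sum(d > tol))
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
    return X[:, keep], [names[i] for i in keep]


# ---------------------------------------------------------------------------
# assembled model


class _TermData:
    def __init__(self, name, structure, levels, axis_values, rows_level, rows_axis,
                 K, K_inv, K_logdet, is_loadings, pedigree):
        self.name = name
        self.structure = structure
        self.levels = levels            # level labels, in order
        self.axis_values = axis_values  # axis labels (len q)
        self.rows_level = rows_level    # per-obs level index
        self.rows_axis = rows_axis      # per-obs axis index
        self.K = K                      # None => identity
        self.K_inv = K_inv
        self.K_logdet = K_logdet
        self.is_loadings = is_loadings
        self.pedigree = pedigree

    @property
    def m(self):
        return len(self.levels)

    @property
    def q(self):
        return len(self.axis_values)

    @property
    def n_effects(self):
        return self.m if self.is_loadings else self.m * self.q

    def Z(self, theta):
        n = len(self.rows_level)
        if self.is_loadings:
            lam = np.asarray(theta, dtype=float)
            data = lam[self.rows_axis]
            return sp.csr_matrix((data, (np.arange(n), self.rows_level)), shape=(n, self.m))
        cols = self.rows_axis * self.m + self.rows_level
        return sp.csr_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, self.m * self.q))

    def Z_axis(self, c):
        """Plain incidence of axis c onto levels (for loadings terms)."""
        n = len(self.rows_level)
        mask = (self.rows_axis == c).astype(float)
        return sp.csr_matrix((mask, (np.arange(n), self.rows_level)), shape=(n, self.m))


class _Model:
    """Assembled matrices and bookkeeping for one REML fit."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, A: RelationshipMatrix | None):
        self.spec = spec
        data = data.reset_index(drop=True)
        keep = data[spec.trait_col].isin(spec.traits)
        data = data.loc[keep].reset_index(drop=True)
        if not len(data):
            raise ValueError("no observations for the requested traits")
        self.data = data
        self.traits = list(spec.traits)
        self.trait_idx = data[spec.trait_col].map(
            {t: i for i, t in enumerate(self.traits)}
        ).to_numpy()
        y = data[spec.value_col].to_numpy(dtype=float)
        self.scale = np.ones(len(self.traits))
        if spec.standardize:
            for i in range(len(self.traits)):
                sd = y[self.trait_idx == i].std()
                self.scale[i] = sd if sd > 0 else 1.0
            y = y / self.scale[self.trait_idx]
        self.y = y
        self.n = len(y)

        # fixed design, per trait
        Xblocks, names = [], []
        Xfull = np.zeros((self.n, 0))
        for i, t in enumerate(self.traits):
            rows = np.flatnonzero(self.trait_idx == i)
            terms = spec.fixed.get(t, spec.fixed.get("*", ["1"]))
            Xt, nm = build_design(data.iloc[rows], terms)
            Xt, nm = _drop_aliased(Xt, nm)
            blk = np.zeros((self.n, Xt.shape[1]))
            blk[rows] = Xt
            Xfull = np.hstack([Xfull, blk])
            names.extend([f"{t}:{x}" for x in nm])
        Xfull, names = _drop_aliased(Xfull, names)
        self.X = sp.csr_matrix(Xfull)
        self.fixed_names = names
        self.p = len(names)

        # per-trait phenotypic variance for initialisation
        self.vp = np.array([
            np.var(self.y[self.trait_idx == i]) if np.any(self.trait_idx == i) else 1.0
            for i in range(len(self.traits))
        ])
        self.floor = 1e-8 * float(self.vp.mean())

        # random terms
        self.terms: list[_TermData] = []
        for rt in spec.random:
            lev_ser = data[rt.level_col].astype(str)
            levels = list(dict.fromkeys(lev_ser))
            lmap = {l: i for i, l in enumerate(levels)}
            rows_level = lev_ser.map(lmap).to_numpy()
            if rt.axis_col is None:
                axis_values = ["all"]
                rows_axis = np.zeros(self.n, dtype=int)
            elif rt.axis_col == spec.trait_col:
                axis_values = list(self.traits)
                rows_axis = self.trait_idx
            else:
                vals = data[rt.axis_col]
                axis_values = sorted(vals.unique())
                rows_axis = vals.map({v: i for i, v in enumerate(axis_values)}).to_numpy()
            structure = rt.structure or Unstructured(len(axis_values))
            if structure.dim != len(axis_values):
                raise ValueError(
                    f"term {rt.name!r}: structure dim {structure.dim} != {len(axis_values)} axes"
                )
            K = K_inv = None
            K_logdet = 0.0
            if rt.pedigree:
                if A is None:
                    raise ValueError(f"term {rt.name!r} needs a relationship matrix")
                missing = [l for l in levels if l not in set(A.individuals)]
                if missing:
                    raise ValueError(f"ids not in relationship matrix: {missing[:5]}")
                K = A.submatrix(levels).values
                cf = sla.cho_factor(K + 1e-10 * np.eye(len(levels)))
                K_logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                K_inv = sla.cho_solve(cf, np.eye(len(levels)))
            self.terms.append(_TermData(
                rt.name, structure, levels, axis_values, rows_level, rows_axis,
                K, K_inv, K_logdet, isinstance(structure, SharedLoadings), rt.pedigree,
            ))

        # residual units
        res = spec.residual
        self.res_structure = res.structure or Unstructured(len(self.traits))
        if self.res_structure.dim != len(self.traits):
            raise ValueError("residual structure dimension must equal trait count")
        units = data[res.unit_col].astype(str)
        self.unit_patterns = []  # (trait_tuple, row_matrix (n_units, k))
        frame = pd.DataFrame({"unit": units, "trait": self.trait_idx,
                              "row": np.arange(self.n)})
        dup = frame.duplicated(subset=["unit", "trait"])
        if dup.any():
            raise ValueError("a residual unit contains the same trait twice")
        grouped = frame.sort_values(["unit", "trait"]).groupby("unit", sort=True)
        pat_rows: dict[tuple, list] = {}
        for _, g in grouped:
            pat = tuple(g["trait"].tolist())
            pat_rows.setdefault(pat, []).append(g["row"].to_numpy())
        for pat, rows in sorted(pat_rows.items()):
            self.unit_patterns.append((pat, np.vstack(rows)))

        self.theta_slices = []
        k = 0
        for td in self.terms:
            self.theta_slices.append(slice(k, k + td.structure.n_params))
            k += td.structure.n_params
        self.res_slice = slice(k, k + self.res_structure.n_params)
        self.n_params = k + self.res_structure.n_params

    # -- parameter helpers ---------------------------------------------------

    def init_theta(self) -> np.ndarray:
        n_var_terms = len(self.terms)
        frac_term = 0.5 / max(n_var_terms, 1)
        parts = []
        for td in self.terms:
            if td.axis_values == ["all"]:
                scale = np.array([self.vp.mean()])
            elif td.axis_values == list(self.traits):
                scale = self.vp
            else:
                scale = np.full(td.q, self.vp.mean())
            parts.append(td.structure.init(scale, frac_term))
        parts.append(self.res_structure.init(self.vp, 0.5))
        return np.concatenate(parts)

    def param_labels(self) -> list[str]:
        out = []
        for td, sl in zip(self.terms, self.theta_slices):
            for lab in td.structure.labels(td.axis_values):
                out.append(f"{td.name}{lab}")
        for lab in self.res_structure.labels(self.traits):
            out.append(f"residual{lab}")
        return out

    def repair(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float).copy()
        for td, sl in zip(self.terms, self.theta_slices):
            theta[sl] = td.structure.repair(theta[sl], self.floor)
        theta[self.res_slice] = self.res_structure.repair(theta[self.res_slice], self.floor)
        return theta

    # -- core evaluation ------------------------------------------------------

    def _rinv(self, R0: np.ndarray):
        """Sparse blockwise R^-1 and log|R| over residual units."""
        rows_i, rows_j, vals = [], [], []
        logdet = 0.0
        pat_inv = {}
        for pat, rows in self.unit_patterns:
            sub = R0[np.ix_(pat, pat)]
            sub = _bend(sub, self.floor * 1e-2)
            cf = sla.cho_factor(sub)
            inv = sla.cho_solve(cf, np.eye(len(pat)))
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0]))) * rows.shape[0]
            pat_inv[pat] = inv
            k = len(pat)
            ii = np.repeat(np.arange(k), k)
            jj = np.tile(np.arange(k), k)
            rows_i.append(rows[:, ii].ravel())
            rows_j.append(rows[:, jj].ravel())
            vals.append(np.tile(inv.ravel(), rows.shape[0]))
        Rinv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(rows_j))),
            shape=(self.n, self.n),
        )
        return Rinv, logdet, pat_inv

    def assemble(self, theta: np.ndarray):
        """Build W, C (dense), its Cholesky, solutions and P y."""
        sigmas = [td.structure.sigma(theta[sl]) for td, sl in zip(self.terms, self.theta_slices)]
        R0 = self.res_structure.sigma(theta[self.res_slice])
        Rinv, logdetR, pat_inv = self._rinv(R0)

        Zs = [td.Z(theta[sl]) for td, sl in zip(self.terms, self.theta_slices)]
        W = sp.hstack([self.X] + Zs, format="csr")
        dim = W.shape[1]
        WtRinv = (W.T @ Rinv).tocsr()
        C = (WtRinv @ W).toarray()

        logdetG = 0.0
        off = self.p
        priors = []
        for td, S in zip(self.terms, sigmas):
            if td.is_loadings:
                Ginv = td.K_inv if td.K is not None else np.eye(td.m)
                logdetG += td.K_logdet
                block = Ginv
            else:
                S = _bend(S, self.floor)
                cfS = sla.cho_factor(S)
                Sinv = sla.cho_solve(cfS, np.eye(td.q))
                logdetS = 2.0 * np.sum(np.log(np.diag(cfS[0])))
                logdetG += td.m * logdetS + td.q * td.K_logdet
                Kinv = td.K_inv if td.K is not None else np.eye(td.m)
                block = np.kron(Sinv, Kinv)
            C[off: off + td.n_effects, off: off + td.n_effects] += block
            priors.append((off, td))
            off += td.n_effects

        cf = sla.cho_factor(C, lower=True)
        rhs = WtRinv @ self.y
        sol = sla.cho_solve(cf, rhs)
        resid = self.y - W @ sol
        Py = Rinv @ resid
        yPy = float(self.y @ Py)
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        minus2ll = logdetR + logdetG + logdetC + yPy + (self.n - self.p) * _LOG2PI
        return {
            "theta": theta, "sigmas": sigmas, "R0": R0, "Rinv": Rinv,
            "pat_inv": pat_inv, "W": W, "WtRinv": WtRinv, "C": C, "chol": cf,
            "sol": sol, "Py": Py, "resid": resid, "minus2ll": minus2ll,
            "offsets": priors, "Zs": Zs, "dim": dim,
        }

    def minus2ll(self, theta: np.ndarray) -> float:
        return self.assemble(theta)["minus2ll"]


# ---------------------------------------------------------------------------
# score / AI computations


def _within_unit_sandwich(model: _Model, Mat: sp.csr_matrix, Cinv: np.ndarray,
                          chunk_units: int = 512):
    """For each residual-unit pattern, the per-unit k x k blocks of
    ``Mat Cinv Mat'`` (only within-unit entries are ever needed)."""
    out = {}
    Mat = Mat.tocsr()
    dim = Mat.shape[1]
    for pat, rows in model.unit_patterns:
        k = len(pat)
        n_u = rows.shape[0]
        blocks = np.empty((n_u, k, k))
        for lo in range(0, n_u, chunk_units):
            hi = min(lo + chunk_units, n_u)
            flat = rows[lo:hi].ravel()
            sub = Mat[flat]
            MC = np.asarray(sub @ Cinv).reshape(hi - lo, k, dim)
            subd = sub.toarray().reshape(hi - lo, k, dim)
            blocks[lo:hi] = np.einsum("uad,ubd->uab", MC, subd)
        out[pat] = blocks
    return out


def _scores_and_ai(model: _Model, state):
    """Score vector and average-information matrix at the current state."""
    theta = state["theta"]
    Cinv = sla.cho_solve(state["chol"], np.eye(state["dim"]))
    Py = state["Py"]
    Rinv = state["Rinv"]
    W = state["W"]

    n_par = model.n_params
    score = np.zeros(n_par)
    hvecs = np.zeros((model.n, n_par))

    off = model.p
    for td, sl, S in zip(model.terms, model.theta_slices, state["sigmas"]):
        th = theta[sl]
        dS = td.structure.dsigma(th)
        if not td.is_loadings:
            m, q = td.m, td.q
            block = Cinv[off: off + m * q, off: off + m * q]
            Sb = _bend(S, model.floor)
            Sinv = np.linalg.inv(Sb)
            Kinv = td.K_inv if td.K is not None else np.eye(m)
            Ginv = np.kron(Sinv, Kinv)
            M = Ginv - Ginv @ block @ Ginv  # Z' P Z
            K = td.K if td.K is not None else None
            # TrK[s,t] = tr(K M_ts)
            TrK = np.empty((q, q))
            for s in range(q):
                for t in range(s, q):
                    Mst = M[t * m:(t + 1) * m, s * m:(s + 1) * m]
                    TrK[s, t] = TrK[t, s] = (
                        float(np.sum(K * Mst)) if K is not None else float(np.trace(Mst))
                    )
            Zth = td.Z(th)
            v = (Zth.T @ Py).reshape(q, m)
            Kv = v @ K if K is not None else v  # rows: K v_t (K symmetric)
            quadM = v @ Kv.T  # quadM[s,t] = v_s' K v_t
            for j, E in enumerate(dS):
                score[sl][j] = -0.5 * (np.sum(E * TrK) - np.sum(E * quadM))
                u = E @ Kv  # (q, m)
                hvecs[:, sl.start + j] = Zth @ u.reshape(-1)
        else:
            # shared-factor term with loadings in the design:
            # dV/dlambda_c = Zc K Zlam' + Zlam K Zc'
            m, q = td.m, td.q
            lam = th
            K = td.K if td.K is not None else np.eye(m)
            Zc = [td.Z_axis(c) for c in range(q)]
            Zlam = td.Z(th)
            RinvW = state["WtRinv"].T.tocsr()  # Rinv W (Rinv symmetric)
            B = [np.asarray((zc.T @ RinvW).todense()) for zc in Zc]  # Zc' Rinv W
            BC = [Bc @ Cinv for Bc in B]
            vv = [np.asarray(zc.T @ Py) for zc in Zc]
            # S[c][d] = Zc' P Zd ; TrKmat[c,d] = tr(K Zd' P Zc) = sum(K * S[c][d])
            TrKmat = np.empty((q, q))
            quadM = np.empty((q, q))
            for c in range(q):
                for d in range(q):
                    Scd = np.asarray((Zc[c].T @ Rinv @ Zc[d]).todense()) - BC[c] @ B[d].T
                    TrKmat[c, d] = float(np.sum(K * Scd))
                    quadM[c, d] = float(vv[c] @ (K @ vv[d]))
            for cidx in range(q):
                tr_term = 2.0 * float(TrKmat[cidx] @ lam)
                quad = 2.0 * float(quadM[cidx] @ lam)
                score[sl][cidx] = -0.5 * (tr_term - quad)
                hv = Zc[cidx] @ (K @ np.asarray(Zlam.T @ Py)) + Zlam @ (K @ vv[cidx])
                hvecs[:, sl.start + cidx] = hv
        off += td.n_effects

    # residual parameters
    dR = model.res_structure.dsigma(theta[model.res_slice])
    Q = state["WtRinv"].T.tocsr()  # Rinv W, rows per obs
    SW = _within_unit_sandwich(model, W, Cinv)  # (W Cinv W') per unit
    pat_inv = state["pat_inv"]
    res_sl = model.res_slice
    for j, E in enumerate(dR):
        tr_acc = 0.0
        quad_acc = 0.0
        for pat, rows in model.unit_patterns:
            Epat = E[np.ix_(pat, pat)]
            if not Epat.any():
                continue
            rinv_u = pat_inv[pat]
            # P block = Rinv_u - Rinv_u (W Cinv W')_u Rinv_u
            blocks = SW[pat]
            Pu = rinv_u[None] - np.einsum("ab,ubc,cd->uad", rinv_u, blocks, rinv_u)
            tr_acc += float(np.einsum("uab,ba->", Pu, Epat))
            pyu = Py[rows]
            quad_acc += float(np.einsum("ua,ab,ub->", pyu, Epat, pyu))
            hv = np.einsum("ab,ub->ua", Epat, pyu)
            hvecs[rows.ravel(), res_sl.start + j] += hv.ravel()
        score[res_sl.start + j] = -0.5 * (tr_acc - quad_acc)

    # AI matrix: 0.5 * h_k' P h_l
    WtRinv_h = state["WtRinv"] @ hvecs
    tmp = sla.cho_solve(state["chol"], WtRinv_h)
    Ph = Rinv @ (hvecs - W @ tmp)
    AI = 0.5 * (hvecs.T @ Ph)
    return score, AI, Cinv


def _em_update(model: _Model, state, Cinv):
    """One EM step for unstructured/diagonal terms and the residual."""
    theta = state["theta"].copy()
    off = model.p
    for td, sl in zip(model.terms, model.theta_slices):
        if td.is_loadings:
            off += td.n_effects
            continue
        m, q = td.m, td.q
        U = state["sol"][off: off + m * q].reshape(q, m)
        block = Cinv[off: off + m * q, off: off + m * q]
        Kinv = td.K_inv if td.K is not None else None
        Snew = np.empty((q, q))
        for s in range(q):
            for t in range(s, q):
                Cst = block[s * m:(s + 1) * m, t * m:(t + 1) * m]
                if Kinv is not None:
                    quad = float(U[s] @ (Kinv @ U[t]))
                    trc = float(np.sum(Kinv * Cst.T))
                else:
                    quad = float(U[s] @ U[t])
                    trc = float(np.trace(Cst))
                Snew[s, t] = Snew[t, s] = (quad + trc) / m
        if isinstance(td.structure, Diagonal):
            theta[sl] = np.diag(Snew)
        elif isinstance(td.structure, Unstructured):
            theta[sl] = td.structure.sigma_to_theta(Snew)
        off += td.n_effects

    # residual EM: R_new = mean over units of (e_hat e_hat' + (W Cinv W')_u)
    SW = _within_unit_sandwich(model, state["W"], Cinv)
    q = len(model.traits)
    num = np.zeros((q, q))
    cnt = np.zeros((q, q))
    ehat = state["resid"]
    for pat, rows in model.unit_patterns:
        e_u = ehat[rows]
        acc = np.einsum("ua,ub->ab", e_u, e_u) + SW[pat].sum(axis=0)
        ij = np.ix_(pat, pat)
        num[ij] += acc
        cnt[ij] += rows.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        Rnew = np.where(cnt > 0, num / np.maximum(cnt, 1), 0.0)
    cur = model.res_structure.sigma(theta[model.res_slice])
    Rnew = np.where(cnt > 0, Rnew, cur)
    if isinstance(model.res_structure, Diagonal):
        theta[model.res_slice] = np.diag(Rnew)
    elif isinstance(model.res_structure, Unstructured):
        theta[model.res_slice] = model.res_structure.sigma_to_theta(Rnew)
    elif isinstance(model.res_structure, BlockDiagonal):
        parts = []
        for s, b in zip(model.res_structure._subs, model.res_structure.blocks):
            parts.append(s.sigma_to_theta(Rnew[np.ix_(b, b)]))
        theta[model.res_slice] = np.concatenate(parts)
    return model.repair(theta)


# ---------------------------------------------------------------------------
# results


@dataclass
class VarianceComponents:
    """Per-random-term covariance matrices among traits (or contexts)."""

    terms: dict  # name -> (axis labels, matrix)

    def matrix(self, term: str) -> np.ndarray:
        return self.terms[term][1]

    def scalar(self, term: str, axis=None) -> float:
        labels, M = self.terms[term]
        if axis is None:
            if M.shape != (1, 1):
                raise ValueError(f"term {term!r} is not univariate")
            return float(M[0, 0])
        i = labels.index(axis)
        return float(M[i, i])

    def names(self):
        return list(self.terms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, (labels, M) in self.terms.items():
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if j < i:
                        continue
                    rows.append({"term": name, "axis1": a, "axis2": b, "value": M[i, j]})
        return pd.DataFrame(rows)


@dataclass
class FitResult:
    loglik: float
    varcomp: VarianceComponents
    fixed_effects: pd.DataFrame
    theta: np.ndarray
    param_names: list[str]
    param_cov: np.ndarray | None
    converged: bool
    n_iter: int
    n_obs: int
    n_fixed: int
    trace: list[float]
    model: "_Model"
    state: dict

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "n_fixed": self.n_fixed,
            "varcomp": self.varcomp.to_frame().to_dict(orient="records"),
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
        }


@dataclass
class LRTResult:
    statistic: float
    df: float | None
    boundary: bool
    p_value: float


# ---------------------------------------------------------------------------
# fitting


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    A: RelationshipMatrix | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
    n_em: int = 3,
    n_restarts: int = 1,
    init_theta: np.ndarray | None = None,
    error_on_failure: bool = False,
    seed: int = 0,
) -> FitResult:
    """Fit the animal model by EM-stabilised average-information REML.

    ``n_restarts > 1`` re-runs from jittered initial values and keeps the best
    restricted likelihood.  ``init_theta`` warm-starts (used by the bootstrap).
    """
    model = _Model(spec, data, A)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        theta0 = model.init_theta() if init_theta is None else np.asarray(init_theta, float).copy()
        if r > 0:
            theta0 = model.repair(theta0 * np.exp(rng.normal(0.0, 0.2, len(theta0))))
        res = _fit_once(model, model.repair(theta0), max_iter, tol,
                        n_em if init_theta is None else 0)
        if best is None or res["minus2ll"] < best["minus2ll"] - 1e-10:
            best = res
    if not best["converged"]:
        msg = (f"REML did not converge in {max_iter} iterations "
               f"(last -2logl change {best['last_change']:.3e}); trace tail "
               f"{[round(v, 4) for v in best['trace'][-4:]]}")
        if error_on_failure:
            raise ConvergenceError(msg)
        warnings.warn(msg)
    return _package(model, best)


def _fit_once(model: _Model, theta, max_iter, tol, n_em):
    state = model.assemble(theta)
    trace = [state["minus2ll"]]
    converged = False
    last_change = np.inf
    it = 0
    plateau = 0
    step_scale = max(model.vp.mean(), 1e-8)
    for it in range(1, max_iter + 1):
        if it <= n_em:
            Cinv = sla.cho_solve(state["chol"], np.eye(state["dim"]))
            new_theta = _em_update(model, state, Cinv)
            new_state = model.assemble(new_theta)
            if new_state["minus2ll"] <= state["minus2ll"] + 1e-8:
                last_change = state["minus2ll"] - new_state["minus2ll"]
                state = new_state
                trace.append(state["minus2ll"])
                continue
        score, AI, Cinv = _scores_and_ai(model, state)
        # Levenberg-Marquardt step control on the AI matrix: increase the
        # ridge (shading toward small gradient-ascent steps) until the
        # restricted likelihood improves.  The ridge is remembered across
        # iterations, and a per-component cap guards against wild steps from
        # a near-singular AI matrix.  Total trial evaluations are budgeted.
        diag_mean = max(float(np.trace(AI)) / len(AI), 1e-12)
        improved = False
        full_step = False
        ridge = getattr(model, "_ridge", 0.0)
        evals = 0
        while evals < 10:
            try:
                step = np.linalg.solve(AI + ridge * diag_mean * np.eye(len(AI)), score)
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-6)
                continue
            cap = 2.0 * (np.abs(state["theta"]) + 0.05 * step_scale)
            factor = min(1.0, float(np.min(cap / np.maximum(np.abs(step), 1e-300))))
            step = step * factor
            for h in range(2):
                cand = model.repair(state["theta"] + step * (0.5 ** h))
                evals += 1
                try:
                    cand_state = model.assemble(cand)
                except np.linalg.LinAlgError:
                    continue
                if cand_state["minus2ll"] <= state["minus2ll"] + 1e-12:
                    last_change = state["minus2ll"] - cand_state["minus2ll"]
                    full_step = (h == 0 and ridge == 0.0 and factor == 1.0)
                    state = cand_state
                    trace.append(state["minus2ll"])
                    improved = True
                    break
            if improved:
                model._ridge = ridge / 10.0 if ridge > 1e-8 else 0.0
                break
            ridge = max(ridge * 10.0, 1e-6)
        if not improved:
            model._ridge = min(max(ridge, 1e-4), 1e4)
            # no uphill AI step found: EM fallback
            cand = _em_update(model, state, Cinv)
            cand_state = model.assemble(cand)
            if cand_state["minus2ll"] < state["minus2ll"] - 1e-12:
                last_change = state["minus2ll"] - cand_state["minus2ll"]
                state = cand_state
                trace.append(state["minus2ll"])
            else:
                converged = True
                break
        rel = last_change / (1.0 + abs(state["minus2ll"]))
        if rel < tol and (full_step or improved is False):
            converged = True
            break
        # plateau exit: progress stalled across several iterations (typical
        # when a covariance matrix sits on the positive-semidefinite boundary)
        plateau = plateau + 1 if rel < max(100.0 * tol, 1e-8) else 0
        if plateau >= 3:
            converged = True
            break
    return {
        "state": state, "theta": state["theta"], "minus2ll": state["minus2ll"],
        "trace": trace, "converged": converged, "n_iter": it,
        "last_change": last_change,
    }


def _package(model: _Model, res) -> FitResult:
    state = res["state"]
    theta = state["theta"]
    # parameter covariance from AI at the optimum
    try:
        score, AI, _ = _scores_and_ai(model, state)
        w, U = np.linalg.eigh(0.5 * (AI + AI.T))
        w = np.clip(w, 1e-12 * max(w.max(), 1.0), None)
        param_cov = (U / w) @ U.T
    except Exception:  # pragma: no cover - degenerate information
        param_cov = None

    # scale variance components back to the data scale if standardised
    scl = model.scale
    tmap = {t: i for i, t in enumerate(model.traits)}
    terms = {}
    for td, sl in zip(model.terms, model.theta_slices):
        S = td.structure.sigma(theta[sl])
        if td.axis_values == list(model.traits):
            s = np.array([scl[tmap[t]] for t in td.axis_values])
            S = S * np.outer(s, s)
        elif td.axis_values == ["all"]:
            S = S * scl.mean() ** 2
        terms[td.name] = (list(td.axis_values), S)
    R0 = model.res_structure.sigma(theta[model.res_slice])
    terms["residual"] = (list(model.traits), R0 * np.outer(scl, scl))
    vc = VarianceComponents(terms)

    b = state["sol"][: model.p]
    Cinv_bb = sla.cho_solve(state["chol"], np.eye(state["dim"]))[: model.p, : model.p]
    se = np.sqrt(np.clip(np.diag(Cinv_bb), 0.0, None))
    # un-standardise fixed effects (each belongs to exactly one trait)
    fscale = np.array([
        scl[tmap[nm.split(":", 1)[0]]] if nm.split(":", 1)[0] in tmap else 1.0
        for nm in model.fixed_names
    ])
    fixed = pd.DataFrame({
        "name": model.fixed_names,
        "estimate": b * fscale,
        "se": se * fscale,
    })
    return FitResult(
        loglik=-0.5 * state["minus2ll"],
        varcomp=vc,
        fixed_effects=fixed,
        theta=theta.copy(),
        param_names=model.param_labels(),
        param_cov=param_cov,
        converged=res["converged"],
        n_iter=res["n_iter"],
        n_obs=model.n,
        n_fixed=model.p,
        trace=res["trace"],
        model=model,
        state=state,
    )


# ---------------------------------------------------------------------------
# derived quantities


def _ratio_delta(fit: FitResult, trait, numer_terms, denom_terms):
    """Ratio of summed diagonal components with a delta-method SE."""
    model = fit.model
    tmap = {t: i for i, t in enumerate(model.traits)}

    def components(theta):
        vals = {}
        for td, sl in zip(model.terms, model.theta_slices):
            S = td.structure.sigma(theta[sl])
            if td.axis_values == list(model.traits):
                i = tmap[trait]
            elif td.axis_values == ["all"]:
                i = 0
            elif trait in td.axis_values:
                i = td.axis_values.index(trait)
            else:
                i = None
            vals[td.name] = float(S[i, i]) if i is not None else 0.0
        R0 = model.res_structure.sigma(theta[model.res_slice])
        vals["residual"] = float(R0[tmap[trait], tmap[trait]])
        return vals

    def ratio(theta):
        c = components(theta)
        num = sum(c.get(t, 0.0) for t in numer_terms)
        den = sum(c.get(t, 0.0) for t in denom_terms)
        if den <= 0:
            raise ValueError("total variance is zero; ratio undefined")
        return num / den

    val = ratio(fit.theta)
    se = np.nan
    if fit.param_cov is not None:
        h = 1e-6 * (1.0 + np.abs(fit.theta))
        grad = np.zeros(len(fit.theta))
        for k in range(len(fit.theta)):
            tp = fit.theta.copy()
            tm = fit.theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            try:
                grad[k] = (ratio(tp) - ratio(tm)) / (2 * h[k])
            except ValueError:
                grad[k] = 0.0
        se = float(np.sqrt(max(grad @ fit.param_cov @ grad, 0.0)))
    return val, se


def heritability(fit_or_vc, trait=None):
    """Adjusted heritability h2 = Va / (Va + Vpe + Vgroup + Vresidual).

    Accepts a :class:`FitResult` (returns value and delta-method SE) or a
    :class:`VarianceComponents` (value only).  Terms absent from the model
    simply contribute zero.
    """
    if isinstance(fit_or_vc, FitResult):
        fit = fit_or_vc
        names = fit.varcomp.names()
        val, se = _ratio_delta(fit, trait or fit.model.traits[0], ["animal"], names)
        return val, se
    vc: VarianceComponents = fit_or_vc
    total = 0.0
    va = 0.0
    for name in vc.names():
        labels, M = vc.terms[name]
        i = labels.index(trait) if (trait is not None and trait in labels) else 0
        v = float(M[i, i])
        total += v
        if name == "animal":
            va = v
    if total <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return va / total


def repeatability(fit_or_vc, trait=None):
    """Repeatability R = (Va + Vpe) / (Va + Vpe + Vgroup + Vresidual)."""
    if isinstance(fit_or_vc, FitResult):
        fit = fit_or_vc
        names = fit.varcomp.names()
        numer = [n for n in ("animal", "pe") if n in names]
        return _ratio_delta(fit, trait or fit.model.traits[0], numer, names)
    vc: VarianceComponents = fit_or_vc
    total = 0.0
    num = 0.0
    for name in vc.names():
        labels, M = vc.terms[name]
        i = labels.index(trait) if (trait is not None and trait in labels) else 0
        v = float(M[i, i])
        total += v
        if name in ("animal", "pe"):
            num += v
    if total <= 0:
        raise ValueError("total variance is zero; repeatability undefined")
    return num / total


def variance_component_intervals(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Confidence intervals for the diagonal variance parameters.

    Variance estimates have right-skewed sampling distributions, so the
    interval is symmetric on the log scale (the standard lognormal Wald
    construction): ``est * exp(+- z * SE / est)``.  Off-diagonal covariance
    parameters keep plain Wald intervals.
    """
    from scipy.stats import norm

    if fit.param_cov is None:
        raise ValueError("fit has no parameter covariance")
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.clip(np.diag(fit.param_cov), 0.0, None))
    rows = []
    for k, (name, est, s) in enumerate(zip(fit.param_names, fit.theta, se)):
        is_variance = "," not in name and "loading" not in name
        if is_variance and est > 0:
            rel = z * s / est
            lo, hi = est * np.exp(-rel), est * np.exp(rel)
        else:
            lo, hi = est - z * s, est + z * s
        rows.append({"parameter": name, "estimate": est, "se": s,
                     "lo": lo, "hi": hi, "scale": "log" if is_variance else "linear"})
    return pd.DataFrame(rows)


def lrt(full, reduced, df: float | None = None, boundary: bool = False) -> LRTResult:
    """Likelihood-ratio test of nested REML fits.

    ``boundary=True`` uses the equal mixture of chi2_0 and chi2_1 appropriate
    when a single variance is tested on its boundary: p = 0.5 * P(chi2_1 >= x)
    (0.5 at x = 0).  Otherwise p comes from chi2 with ``df`` degrees of
    freedom (defaulting to the parameter-count difference).
    """
    ll_full = full.loglik if isinstance(full, FitResult) else float(full)
    ll_red = reduced.loglik if isinstance(reduced, FitResult) else float(reduced)
    stat = 2.0 * (ll_full - ll_red)
    if stat < -1e-6 * max(1.0, abs(ll_full)):
        warnings.warn(
            f"reduced model has higher restricted likelihood ({ll_red:.4f} > "
            f"{ll_full:.4f}); possible convergence failure"
        )
    stat = max(stat, 0.0)
    if boundary:
        p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 0.5
        return LRTResult(stat, 1.0, True, p)
    if df is None:
        if isinstance(full, FitResult) and isinstance(reduced, FitResult):
            df = len(full.theta) - len(reduced.theta)
        else:
            raise ValueError("df required when passing raw log-likelihoods")
    p = float(chi2.sf(stat, df))
    return LRTResult(stat, float(df), False, p)


def mixture_chi2_p(stat: float) -> float:
    """p-value under the equal chi2_0 / chi2_1 mixture (boundary test)."""
    return 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 0.5


def wald_fixed(fit: FitResult, contrast, satterthwaite: bool = True):
    """Wald F test of a linear combination of fixed effects.

    ``contrast`` is a vector over the fixed-effect columns or the name of a
    single column.  Returns (F, ddf, p).  The denominator degrees of freedom
    use a Satterthwaite-type approximation: ddf = 2 (c'Vb c)^2 / Var(c'Vb c),
    with the variance obtained by the delta method over the variance
    parameters (finite-difference gradient of c'Vb(theta) c).
    """
    model = fit.model
    if isinstance(contrast, str):
        c = np.zeros(model.p)
        c[model.fixed_names.index(contrast)] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)
        if len(c) != model.p:
            raise ValueError("contrast length does not match fixed effects")

    def cvc(theta):
        st = model.assemble(theta)
        Cinv_bb = sla.cho_solve(st["chol"], np.eye(st["dim"]))[: model.p, : model.p]
        return float(c @ Cinv_bb @ c), st

    v0, st0 = cvc(fit.theta)
    if v0 <= 0:
        raise ValueError("contrast is not estimable")
    b = st0["sol"][: model.p]
    F = float((c @ b) ** 2 / v0)
    ddf = np.inf
    if satterthwaite and fit.param_cov is not None:
        h = 1e-5 * (1.0 + np.abs(fit.theta))
        grad = np.zeros(len(fit.theta))
        for k in range(len(fit.theta)):
            tp = fit.theta.copy()
            tp[k] += h[k]
            tm = fit.theta.copy()
            tm[k] -= h[k]
            grad[k] = (cvc(model.repair(tp))[0] - cvc(model.repair(tm))[0]) / (2 * h[k])
        var_v = float(grad @ fit.param_cov @ grad)
        if var_v > 0:
            ddf = 2.0 * v0 ** 2 / var_v
    p = float(f_dist.sf(F, 1, ddf)) if np.isfinite(ddf) else float(chi2.sf(F, 1))
    return F, ddf, p


def blup(fit: FitResult, term: str = "animal", A: RelationshipMatrix | None = None) -> pd.DataFrame:
    """Predicted random effects (BLUPs given estimated components).

    With ``A`` supplied, individuals present in A but without phenotypes get
    predictions through the pedigree: a_un = A_cross A_obs^-1 a_obs.
    """
    model = fit.model
    off = model.p
    for td in model.terms:
        if td.name == term:
            break
        off += td.n_effects
    else:
        raise KeyError(f"no random term named {term!r}")
    sol = fit.state["sol"]
    if td.is_loadings:
        U = sol[off: off + td.m][:, None]
        cols = ["factor"]
    else:
        U = sol[off: off + td.m * td.q].reshape(td.q, td.m).T
        cols = [str(a) for a in td.axis_values]
    # rescale to data units
    if td.axis_values == list(model.traits):
        U = U * model.scale[None, :]
    df = pd.DataFrame(U, index=td.levels, columns=cols)
    if A is not None and td.pedigree:
        obs = list(td.levels)
        others = [i for i in A.individuals if i not in set(obs)]
        if others:
            idx = {l: i for i, l in enumerate(A.individuals)}
            Aoo = A.values[np.ix_([idx[i] for i in obs], [idx[i] for i in obs])]
            Axo = A.values[np.ix_([idx[i] for i in others], [idx[i] for i in obs])]
            pred = Axo @ np.linalg.solve(Aoo, U.to_numpy() if hasattr(U, "to_numpy") else U)
            df = pd.concat([df, pd.DataFrame(pred, index=others, columns=cols)])
    return df


# ---------------------------------------------------------------------------
# simulation from a fitted model (parametric bootstrap support)


def simulate_response(fit: FitResult, seed: int = 0) -> np.ndarray:
    """Draw a new response vector from the fitted model (on the analysis
    scale of the original data): X b_hat + random draws for every term and
    the residual."""
    model = fit.model
    state = fit.state
    rng = np.random.default_rng(seed)
    theta = fit.theta
    y = np.asarray(model.X @ state["sol"][: model.p])
    for td, sl in zip(model.terms, model.theta_slices):
        S = td.structure.sigma(theta[sl])
        if td.K is not None:
            w, U = np.linalg.eigh(td.K)
            LK = (U * np.sqrt(np.clip(w, 0.0, None)))
        else:
            LK = None
        if td.is_loadings:
            u = rng.standard_normal(td.m)
            u = LK @ u if LK is not None else u
            y += np.asarray(td.Z(theta[sl]) @ u)
        else:
            wS, US = np.linalg.eigh(_bend(S, 0.0))
            LS = US * np.sqrt(np.clip(wS, 0.0, None))
            Nm = rng.standard_normal((td.m, td.q))
            u = (LK @ Nm if LK is not None else Nm) @ LS.T  # (m, q)
            y += np.asarray(td.Z(theta[sl]) @ u.T.reshape(-1))
    R0 = model.res_structure.sigma(theta[model.res_slice])
    for pat, rows in model.unit_patterns:
        sub = _bend(R0[np.ix_(pat, pat)], 0.0)
        wR, UR = np.linalg.eigh(sub)
        LR = UR * np.sqrt(np.clip(wR, 0.0, None))
        draws = rng.standard_normal((rows.shape[0], len(pat))) @ LR.T
        y[rows] += draws
    return y


def refit(fit: FitResult, new_y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> FitResult:
    """Refit the same model to a new response vector (warm start at the
    current estimates); used by the parametric bootstrap."""
    model = fit.model
    data = model.data.copy()
    # new_y is on the (possibly standardised) analysis scale; undo for input
    data[model.spec.value_col] = np.asarray(new_y) * model.scale[model.trait_idx]
    A = None
    spec = model.spec
    # reuse relationship structure by passing through a shim RelationshipMatrix
    for td in model.terms:
        if td.pedigree:
            A = RelationshipMatrix(td.levels, td.K)
            break
    return reml_fit(spec, data, A, max_iter=max_iter, tol=tol,
                    init_theta=fit.theta, n_em=0)


# ---------------------------------------------------------------------------
# the cortisol character-state (GxE) model ladder


GXE_FIXED = ["order_c", "temperature_z", "time_z", "age_z", "sex", "mass_z", "sex:mass_z"]


def gxe_model_sequence(
    cort_data: pd.DataFrame,
    A: RelationshipMatrix,
    fixed_terms: Sequence[str] | None = None,
    models: Sequence[str] = ("no_genetics", "common_genetics",
                             "context_variances", "free_correlation"),
    **fit_kw,
):
    """Fit the nested bivariate character-state models for cortisol across
    two stressor-exposure contexts and the associated likelihood-ratio tests.

    Model 0: housing group + residual (context-specific), no genetics.
    Model 1: + additive genetic effect constrained equal across contexts
             (Va1 = Va3, cross-context genetic correlation = 1).
    Model 2: context-specific genetic variances, correlation still 1
             (shared factor with context loadings) — tests GxE in variances.
    Model 3: free 2x2 genetic covariance — tests correlation < 1.

    Each individual may appear at most once per context; the residual unit is
    the individual, so the cross-context residual covariance absorbs
    non-genetic among-individual covariance.  Returns a dict with fits,
    LRTs and context-specific heritabilities.
    """
    df = cort_data.copy()
    if "context" not in df.columns:
        raise ValueError("cortisol data needs a 'context' column")
    df = df[df["context"].notna()].copy()
    df["context"] = df["context"].astype(int)
    counts = df.groupby(["id", "context"]).size()
    if (counts > 1).any():
        raise ValueError("an individual has more than one observation per context")
    df["ctx_trait"] = "cortisol_" + df["context"].astype(str)
    traits = sorted(df["ctx_trait"].unique())
    terms = list(fixed_terms) if fixed_terms is not None else [
        t for t in GXE_FIXED if t.split(":")[0] in df.columns
    ]
    fixed = {t: list(terms) for t in traits}

    def base_random():
        return [RandomTerm("group", "group", "ctx_trait", Unstructured(2))]

    residual = ResidualSpec("id", Unstructured(2))
    common = dict(trait_col="ctx_trait", value_col="value")

    genetic_term = {
        "no_genetics": None,
        "common_genetics": RandomTerm("animal", "id", None, Unstructured(1), pedigree=True),
        "context_variances": RandomTerm("animal", "id", "ctx_trait", SharedLoadings(2),
                                        pedigree=True),
        "free_correlation": RandomTerm("animal", "id", "ctx_trait", Unstructured(2),
                                       pedigree=True),
    }
    fits: dict[str, FitResult] = {}
    for name in models:
        term = genetic_term[name]
        random = base_random() + ([term] if term is not None else [])
        spec = ModelSpec(traits, random, residual, fixed, **common)
        fits[name] = reml_fit(spec, df, A if term is not None else None, **fit_kw)

    out: dict = {"fits": fits}
    if {"common_genetics", "no_genetics"} <= fits.keys():
        out["lrt_va"] = lrt(fits["common_genetics"], fits["no_genetics"], boundary=True)
    if {"context_variances", "common_genetics"} <= fits.keys():
        out["lrt_gxe"] = lrt(fits["context_variances"], fits["common_genetics"],
                             boundary=True)
    if {"free_correlation", "context_variances"} <= fits.keys():
        out["lrt_correlation"] = lrt(fits["free_correlation"], fits["context_variances"],
                                     df=1)

    if "context_variances" in fits:
        m2 = fits["context_variances"]
        G2 = m2.varcomp.matrix("animal")
        GR = m2.varcomp.matrix("group")
        RR = m2.varcomp.matrix("residual")
        out["h2"] = {
            t: G2[i, i] / (G2[i, i] + GR[i, i] + RR[i, i]) for i, t in enumerate(traits)
        }
        out["Va"] = {t: float(G2[i, i]) for i, t in enumerate(traits)}
    if "free_correlation" in fits:
        G3 = fits["free_correlation"].varcomp.matrix("animal")
        ra13 = np.nan
        if G3[0, 0] > 0 and G3[1, 1] > 0:
            ra13 = G3[0, 1] / np.sqrt(G3[0, 0] * G3[1, 1])
        out["ra13"] = float(ra13)
    return out
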