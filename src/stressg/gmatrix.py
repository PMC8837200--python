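"""Eigen-analysis of the additive genetic covariance matrix G.

Integration of stress-response traits is quantified by the structure of G:
pairwise genetic correlations, the proportion of genetic variance on the
leading eigenvector g_max, and parametric-bootstrap uncertainty on loadings
and variance proportions (simulate a full data set from the fitted model,
refit, and eigen-decompose each replicate G).  Bivariate 95% genetic
confidence ellipses support visualisation of trait pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import animal_model as am

__all__ = [
    "GEstimate", "EigenSummary", "BootstrapReplicates",
    "genetic_correlations", "eigen_decomposition", "parametric_bootstrap",
    "loading_intervals", "confidence_ellipse",
]


@dataclass
class GEstimate:
    """Labelled additive genetic covariance matrix."""

    traits: list[str]
    G: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        q = len(self.traits)
        if self.G.shape != (q, q):
            raise ValueError("G shape does not match trait labels")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValueError("G must be symmetric")

    @classmethod
    def from_fit(cls, fit: am.FitResult, term: str = "animal") -> "GEstimate":
        labels, M = fit.varcomp.terms[term]
        return cls([str(t) for t in labels], M, source=term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.traits, columns=self.traits)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_g_csv(path) -> GEstimate:
    df = pd.read_csv(path, index_col=0)
    return GEstimate([str(c) for c in df.columns], df.to_numpy(dtype=float))


def genetic_correlations(G: GEstimate | np.ndarray) -> pd.DataFrame:
    """Genetic correlation matrix r_a(x,y) = cov_a(x,y) / sqrt(Va_x Va_y).

    Traits with (numerically) zero genetic variance yield NaN correlations
    rather than fabricated values.
    """
    if isinstance(G, GEstimate):
        traits, M = G.traits, G.G
    else:
        M = np.asarray(G, dtype=float)
        traits = [f"t{i}" for i in range(M.shape[0])]
    v = np.diag(M).copy()
    ok = v > 0
    if not ok.all():
        warnings.warn(
            f"traits with zero genetic variance: {[t for t, o in zip(traits, ok) if not o]}; "
            "their correlations are undefined (NaN)"
        )
    sd = np.sqrt(np.where(ok, v, np.nan))
    C = M / np.outer(sd, sd)
    np.fill_diagonal(C, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(C, index=traits, columns=traits)


@dataclass
class EigenSummary:
    """Eigen decomposition of G: eigenvalues (descending), proportion of
    genetic variance per axis, unit-norm loadings (columns = axes), and
    bootstrap percentile intervals when attached."""

    traits: list[str]
    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: np.ndarray  # (trait, axis)
    loading_intervals: np.ndarray | None = None  # (trait, axis, 2)
    proportion_intervals: np.ndarray | None = None  # (axis, 2)
    n_boot_used: int = 0

    def loadings_frame(self) -> pd.DataFrame:
        rows = []
        q = len(self.traits)
        for a in range(q):
            for t in range(q):
                row = {"axis": a + 1, "trait": self.traits[t],
                       "loading": self.loadings[t, a]}
                if self.loading_intervals is not None:
                    row["lo"] = self.loading_intervals[t, a, 0]
                    row["hi"] = self.loading_intervals[t, a, 1]
                rows.append(row)
        return pd.DataFrame(rows)

    def gmax(self) -> pd.Series:
        return pd.Series(self.loadings[:, 0], index=self.traits, name="gmax")

    def to_dict(self) -> dict:
        out = {
            "traits": self.traits,
            "eigenvalues": self.eigenvalues.tolist(),
            "proportions": self.proportions.tolist(),
            "loadings": self.loadings.tolist(),
        }
        if self.proportion_intervals is not None:
            out["proportion_intervals"] = self.proportion_intervals.tolist()
        if self.loading_intervals is not None:
            out["loading_intervals"] = self.loading_intervals.tolist()
            out["n_boot_used"] = self.n_boot_used
        return out


def eigen_decomposition(G: GEstimate | np.ndarray, traits=None) -> EigenSummary:
    """Eigenpairs of G sorted by descending eigenvalue.

    Proportions are eigenvalue / sum of positive eigenvalues (negative
    eigenvalues, possible in REML estimates near the PSD boundary, are
    clipped to zero for the proportion accounting but reported raw).
    Reporting sign convention: each eigenvector's largest-magnitude loading
    is positive.
    """
    if isinstance(G, GEstimate):
        traits, M = G.traits, G.G
    else:
        M = np.asarray(G, dtype=float)
        traits = list(traits) if traits is not None else [f"t{i}" for i in range(M.shape[0])]
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w = w[order]
    U = U[:, order]
    for a in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, a]))
        if U[k, a] < 0:
            U[:, a] = -U[:, a]
    pos = np.clip(w, 0.0, None)
    total = pos.sum()
    props = pos / total if total > 0 else np.zeros_like(pos)
    return EigenSummary(list(traits), w, props, U)


@dataclass
class BootstrapReplicates:
    """Replicate G matrices from the parametric bootstrap, with convergence
    flags (failed refits are recorded, never silently dropped)."""

    traits: list[str]
    matrices: list[np.ndarray] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_failed(self) -> int:
        return int(sum(not c for c in self.converged))

    def usable(self) -> list[np.ndarray]:
        return [M for M, c in zip(self.matrices, self.converged) if c]


def parametric_bootstrap(
    fit: am.FitResult,
    n_reps: int = 500,
    seed: int = 0,
    term: str = "animal",
    max_iter: int = 60,
    tol: float = 1e-7,
) -> BootstrapReplicates:
    """Parametric bootstrap of G: for each replicate, simulate a complete
    response vector from the fitted model over the same pedigree and design,
    refit the model (warm-started at the point estimate), and store the
    replicate's genetic covariance matrix.  Non-converged refits are flagged
    and excluded from interval computation, with the count reported.
    """
    labels, _ = fit.varcomp.terms[term]
    reps = BootstrapReplicates([str(t) for t in labels])
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        y_new = am.simulate_response(fit, seed=rep_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                refit = am.refit(fit, y_new, max_iter=max_iter, tol=tol)
                ok = bool(refit.converged)
                M = refit.varcomp.matrix(term)
            except Exception:
                ok = False
                M = np.full_like(fit.varcomp.matrix(term), np.nan)
        reps.matrices.append(M)
        reps.converged.append(ok)
        reps.seeds.append(rep_seed)
    if reps.n_failed:
        warnings.warn(f"{reps.n_failed} of {n_reps} bootstrap refits did not converge")
    return reps


def loading_intervals(
    reps: BootstrapReplicates, reference: EigenSummary, coverage: float = 0.95
) -> EigenSummary:
    """Percentile bootstrap intervals on loadings and variance proportions.

    Replicate eigenvectors are matched to reference axes by rank and
    sign-aligned to the reference (flipped when the dot product is negative)
    before taking percentiles; a loading whose interval excludes zero is
    deemed significant.
    """
    usable = reps.usable()
    if len(usable) < 2:
        raise ValueError("need at least 2 converged bootstrap replicates")
    q = len(reference.traits)
    alpha = (1.0 - coverage) / 2.0
    load_stack = np.empty((len(usable), q, q))
    prop_stack = np.empty((len(usable), q))
    for r, M in enumerate(usable):
        es = eigen_decomposition(M, traits=reference.traits)
        L = es.loadings.copy()
        for a in range(q):
            if float(L[:, a] @ reference.loadings[:, a]) < 0:
                L[:, a] = -L[:, a]
        load_stack[r] = L
        prop_stack[r] = es.proportions
    lo = np.quantile(load_stack, alpha, axis=0)
    hi = np.quantile(load_stack, 1.0 - alpha, axis=0)
    pl = np.quantile(prop_stack, alpha, axis=0)
    ph = np.quantile(prop_stack, 1.0 - alpha, axis=0)
    return EigenSummary(
        reference.traits,
        reference.eigenvalues,
        reference.proportions,
        reference.loadings,
        loading_intervals=np.stack([lo, hi], axis=-1),
        proportion_intervals=np.stack([pl, ph], axis=-1),
        n_boot_used=len(usable),
    )


def confidence_ellipse(G2: np.ndarray, coverage: float = 0.95, n_points: int = 256):
    """Boundary of the region expected to contain ``coverage`` of a bivariate
    N(0, G2) distribution: { x : x' G2^-1 x <= q }, q the chi-square(2)
    quantile.  Returns an (n_points, 2) array ordered counter-clockwise from
    the major axis; a singular G2 collapses to a line segment (flagged by a
    warning).
    """
    G2 = np.asarray(G2, dtype=float)
    if G2.shape != (2, 2) or not np.allclose(G2, G2.T, atol=1e-8):
        raise ValueError("G2 must be a symmetric 2x2 matrix")
    w, U = np.linalg.eigh(G2)
    if w.min() < -1e-8:
        raise ValueError("G2 must be positive semi-definite")
    w = np.clip(w, 0.0, None)
    if w.min() == 0.0:
        warnings.warn("singular 2x2 genetic covariance; ellipse degenerates to a segment")
    r = np.sqrt(chi2.ppf(coverage, df=2))
    # order axes: major first
    order = np.argsort(w)[::-1]
    w = w[order]
    U = U[:, order]
    if np.linalg.det(U) < 0:  # keep a proper rotation so points run CCW
        U[:, 1] = -U[:, 1]
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circ = np.column_stack([np.cos(t), np.sin(t)])
    pts = (circ * (r * np.sqrt(w))) @ U.T
    return pts
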