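"""Reference parameter values for the guppy stress-response study design.

These are the point estimates from the study population that the synthetic
generator emulates: univariate variance components per trait (on the
transformed analysis scales), the standardised 6-trait additive genetic
covariance matrix, and the two-context cortisol model.  They serve two roles:
defaults for the simulator (so recovery experiments target known truth) and
inputs for derived-quantity computations (heritabilities, genetic
correlations, eigenstructure).
"""

from __future__ import annotations

import numpy as np

#: traits in the order used by the multivariate G model (all transformed;
#: emergence time is ln-transformed and sign-flipped so high = fast)
G_TRAITS = [
    "relative_area",
    "time_in_middle",
    "track_length",
    "sqrt_freezings",
    "neg_ln_emergence",
    "ln_cortisol",
]

#: univariate variance components on the raw (transformed) trait scales:
#: additive genetic, permanent environment, housing group, residual
UNIVARIATE_COMPONENTS = {
    "relative_area": {"Va": 42.87, "Vpe": 56.16, "Vgroup": 19.17, "Vr": 203.17},
    "time_in_middle": {"Va": 554.78, "Vpe": 473.24, "Vgroup": 196.94, "Vr": 2002.06},
    "track_length": {"Va": 23584.54, "Vpe": 26587.74, "Vgroup": 3173.34, "Vr": 76140.49},
    "sqrt_freezings": {"Va": 0.34, "Vpe": 0.18, "Vgroup": 0.08, "Vr": 1.13},
    "ln_emergence": {"Va": 0.12, "Vpe": 0.06, "Vgroup": 0.05, "Vr": 1.07},
    "shoaling": {"Va": 0.0, "Vpe": 2457.36, "Vgroup": 708.87, "Vr": 9900.95},
    "ln_cortisol": {"Va": 0.08, "Vpe": 0.02, "Vgroup": 0.01, "Vr": 0.15},
}

#: published adjusted heritabilities (h2 = Va / (Va+Vpe+Vgroup+Vr)) per trait
PUBLISHED_H2 = {
    "relative_area": 0.13,
    "time_in_middle": 0.17,
    "track_length": 0.18,
    "sqrt_freezings": 0.20,
    "ln_emergence": 0.09,
    "shoaling": 0.0,
    "ln_cortisol": 0.31,
}

#: published repeatability for shoaling tendency ((Va+Vpe)/Vp)
PUBLISHED_SHOALING_REPEATABILITY = 0.19

#: standardised additive genetic covariance matrix over G_TRAITS
#: (variances on the diagonal, covariances off-diagonal)
G_MATRIX = np.array(
    [
        [0.115, 0.103, -0.071, 0.020, -0.041, -0.044],
        [0.103, 0.145, -0.096, 0.059, -0.016, -0.082],
        [-0.071, -0.096, 0.147, -0.132, 0.065, 0.057],
        [0.020, 0.059, -0.132, 0.185, -0.057, -0.083],
        [-0.041, -0.016, 0.065, -0.057, 0.076, -0.002],
        [-0.044, -0.082, 0.057, -0.083, -0.002, 0.121],
    ]
)

#: published genetic correlations (upper triangle of the covariance-correlation
#: table), keyed by trait-index pair in G_TRAITS order
PUBLISHED_GENETIC_CORRELATIONS = {
    (0, 1): 0.795,
    (0, 2): -0.549,
    (0, 3): 0.139,
    (0, 4): -0.438,
    (0, 5): -0.376,
    (1, 2): -0.658,
    (1, 3): 0.363,
    (1, 4): -0.153,
    (1, 5): -0.617,
    (2, 3): -0.801,
    (2, 4): 0.61,
    (2, 5): 0.425,
    (3, 4): -0.483,
    (3, 5): -0.556,
    (4, 5): -0.020,
}

#: published proportions of genetic variance on each eigen-axis of G (%)
PUBLISHED_EIGEN_PROPORTIONS = [59.5, 20.2, 14.1, 4.5, 1.0, 0.7]

#: two-context cortisol model (ln ng/hr scale): context means, context-specific
#: additive genetic variances, cross-context genetic correlation, group and
#: residual variances per context
CORTISOL_GXE = {
    "mu1": 8.47,
    "mu3": 8.02,
    "Va1": 0.081,
    "Va3": 0.041,
    "ra13": 0.83,
    "Vgroup1": 0.038,
    "Vgroup3": 0.032,
    "Vr1": 0.164,
    "Vr3": 0.237,
}

#: published context-specific cortisol heritabilities (Va/(Va+Vgroup+Vr))
PUBLISHED_CORTISOL_H2 = {"context1": 0.285, "context3": 0.131}

#: published likelihood-ratio statistics (for reference computations)
PUBLISHED_LRT = {
    "shoaling_repeatability_chi2_01": 20.01,
    "gxe_variance_chi2_01": 3.8,
    "integration_chi2_df15": 91.06,
}

#: assay inclusion probabilities, calibrated to the study's phenotyping counts
#: (1365/1384 fish with open-field data, 806 with emergence, 532 with shoaling,
#: 629 with cortisol assays)
ASSAY_INCLUSION = {"oft": 1365 / 1384, "et": 806 / 1384, "st": 532 / 1384, "cortisol": 629 / 1384}


def default_g_matrix() -> np.ndarray:
    """Copy of the standardised 6-trait G matrix."""
    return G_MATRIX.copy()


def g_correlation_matrix() -> np.ndarray:
    """Genetic correlation matrix implied by the standardised G."""
    sd = np.sqrt(np.diag(G_MATRIX))
    return G_MATRIX / np.outer(sd, sd)
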