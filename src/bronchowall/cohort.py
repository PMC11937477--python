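"""Synthetic asthma-cohort tables with the study's statistical structure.

Each severity group is drawn from a multivariate Gaussian whose marginals
reproduce the printed group means/SDs (BrWall_T2-MIS 74 +/- 12 in severe vs
49 +/- 14 in non-severe; PFTs, FeNO and blood eosinophils from the cohort
table, the latter two log-normal).  Correlations with the biomarker are
induced by a single-factor model: each covariate loads on the biomarker's
latent factor with its target correlation, which guarantees a positive
semi-definite joint correlation matrix and exact target marginal
correlations by construction.  Exacerbation counts follow a Poisson model
whose log-rate is linear in the biomarker, so the frequent-exacerbator
outcome (annual exacerbation rate >= 2) carries a known odds-ratio-style
association for the regression layer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: continuous covariates: (column, severe (mean, sd), non-severe (mean, sd), log-scale?)
#: log-scale entries give geometric mean / geometric SD
DEFAULT_COVARIATES = {
    "age": ((51.0, 16.0), (50.0, 15.0), False),
    "fev1_pp": ((80.0, 26.0), (101.0, 18.0), False),
    "fvc_pp": ((94.0, 21.0), (108.0, 15.0), False),
    "fev1_fvc": ((0.68, 0.10), (0.78, 0.06), False),
    "fef2575_pp": ((51.0, 36.0), (83.0, 34.0), False),
    "pef": ((314.0, 116.0), (418.0, 106.0), False),
    "feno": ((21.0, 1.6), (21.0, 1.5), True),
    "eos": ((165.0, 3.0), (128.0, 2.0), True),
}

#: within-group Pearson correlations between the biomarker and each covariate
#: (log scale for log-normal covariates); anchored on the severe-group column
#: of the study's correlation table, with obstruction indices negative and
#: eosinophils positive
DEFAULT_CORRELATIONS = {
    "age": 0.0,
    "fev1_pp": -0.53,
    "fvc_pp": -0.47,
    "fev1_fvc": -0.44,
    "fef2575_pp": -0.38,
    "pef": -0.16,
    "feno": 0.2,
    "eos": 0.52,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic two-group cohort."""

    n_per_group: int = 15
    #: BrWall_T2-MIS (Au): (mean, SD) per group
    biomarker_severe: tuple[float, float] = (74.0, 12.0)
    biomarker_nonsevere: tuple[float, float] = (49.0, 14.0)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    #: exacerbation model: count ~ Poisson(exp(intercept + slope * biomarker))
    exacerbation_intercept: float = -7.0
    exacerbation_slope: float = np.log(1.11)
    #: women per group out of n (the study enrolled 14 women / 1 man per group)
    female_fraction: float = 14.0 / 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [k for k, r in self.correlations.items() if abs(r) > 1]
        if bad:
            raise ValueError(f"correlations out of [-1, 1]: {bad}")
        unknown = set(self.correlations) - set(self.covariates)
        if unknown:
            raise ValueError(f"correlations reference unknown covariates: {sorted(unknown)}")
        if not np.all(np.linalg.eigvalsh(self.correlation_matrix()) > -1e-10):
            raise ValueError("correlation matrix is not positive semi-definite")

    def correlation_matrix(self) -> np.ndarray:
        """Joint correlation matrix implied by the single-factor model.

        Ordering: biomarker first, then covariates in insertion order.
        PSD by construction (Gram matrix of unit vectors), included so
        user-overridden loadings are validated explicitly.
        """
        names = list(self.covariates)
        r = np.array([self.correlations.get(k, 0.0) for k in names])
        k = len(names) + 1
        c = np.eye(k)
        c[0, 1:] = r
        c[1:, 0] = r
        c[1:, 1:] = np.outer(r, r) + np.diag(1.0 - r**2)
        return c


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a two-group cohort table, one row per patient.

    Columns: subject id, severity group, sex, biomarker ``brwall_t2_mis``,
    the covariates of :class:`CohortSpec`, exacerbation counts ``aer_next``
    (following 12 months) and the frequent-exacerbator flag ``aer_ge2``.
    Fixed seeds reproduce the table exactly; group sample sizes match
    ``n_per_group`` by construction.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    names = list(spec.covariates)
    loadings = np.array([spec.correlations.get(k, 0.0) for k in names])
    for group, (bm_mean, bm_sd) in (
        ("severe", spec.biomarker_severe),
        ("non-severe", spec.biomarker_nonsevere),
    ):
        n = spec.n_per_group
        z_factor = rng.standard_normal(n)  # biomarker latent
        biomarker = bm_mean + bm_sd * z_factor
        cols = {"group": group, "brwall_t2_mis": biomarker}
        for name, load in zip(names, loadings):
            (m_sev, s_sev), (m_non, s_non), logscale = spec.covariates[name]
            m, s = (m_sev, s_sev) if group == "severe" else (m_non, s_non)
            z = load * z_factor + np.sqrt(1.0 - load**2) * rng.standard_normal(n)
            if logscale:
                cols[name] = np.exp(np.log(m) + np.log(s) * z)
            else:
                cols[name] = m + s * z
        lam = np.exp(spec.exacerbation_intercept + spec.exacerbation_slope * biomarker)
        cols["aer_next"] = rng.poisson(lam)
        n_female = int(round(spec.female_fraction * n))
        sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
        cols["sex"] = sex
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject", [f"S{i:03d}" for i in range(len(df))])
    df["aer_ge2"] = (df["aer_next"] >= 2).astype(int)
    return df
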