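"""Shared statistics: ambient PCA, nested mixed model, contingency analysis.

Three tools used by both the acoustic and morphometric stages:

* :func:`ambient_pca` summarizes air temperature and humidity into a single
  "ambient factor" (PC1 of the 2-variable correlation-matrix PCA);
* :func:`nested_mixed_model` fits ``response ~ region + covariate`` with a
  random intercept for locality nested in region (REML), reporting an
  F-test for the region effect with containment denominator degrees of
  freedom (number of localities minus number of regions);
* :func:`contingency_association` runs a Pearson chi-square (no continuity
  correction) with per-cell adjusted standardized residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "PCAResult",
    "MixedModelResult",
    "AssociationResult",
    "ambient_pca",
    "nested_mixed_model",
    "contingency_association",
]


@dataclass
class PCAResult:
    loadings: np.ndarray  # variable x component
    scores: np.ndarray  # sample x component
    eigenvalues: np.ndarray


@dataclass
class MixedModelResult:
    fixed_effects: dict[str, float]
    F_stat: float
    df_num: int
    df_den: int
    p_value: float
    locality_variance: float
    residual_variance: float


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    adjusted_residuals: np.ndarray | None = None

    def report(self) -> str:
        return f"chi2 = {self.chi2:.1f}, d.f. = {self.df}, p = {self.p_value:.4g}"


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def ambient_pca(temp: np.ndarray, humidity: np.ndarray) -> tuple[np.ndarray, PCAResult]:
    """PC1 scores of the temperature/humidity correlation-matrix PCA.

    Eigenvalues of the 2x2 correlation matrix are 1+r and 1-|r| is not
    reported separately: they come out of the closed-form eigendecomposition.
    PC1's sign is fixed so temperature loads positively.  If one variable is
    constant the other's z-scores are returned with a warning.
    """
    temp = np.asarray(temp, dtype=float)
    humidity = np.asarray(humidity, dtype=float)
    if temp.size != humidity.size or temp.size < 3:
        raise ValueError("need >= 3 paired temperature/humidity samples")
    t_const = np.ptp(temp) == 0
    h_const = np.ptp(humidity) == 0
    if t_const and h_const:
        raise ValueError("both ambient variables are constant")
    if t_const or h_const:
        warnings.warn("one ambient variable is constant; using the other's z-scores")
        z = _zscore(humidity if t_const else temp)
        load = np.array([[0.0], [1.0]]) if t_const else np.array([[1.0], [0.0]])
        return z, PCAResult(loadings=load, scores=z[:, None], eigenvalues=np.array([1.0]))

    Z = np.column_stack([_zscore(temp), _zscore(humidity)])
    r = float(np.corrcoef(Z.T)[0, 1])
    # closed form for a 2x2 correlation matrix: eigenvalues 1 +/- |r|
    s = np.sqrt(0.5)
    if r >= 0:
        v1, v2 = np.array([s, s]), np.array([-s, s])
    else:
        v1, v2 = np.array([s, -s]), np.array([s, s])
    eig = np.array([1.0 + abs(r), 1.0 - abs(r)])
    loadings = np.column_stack([v1, v2])
    if loadings[0, 0] < 0:
        loadings[:, 0] *= -1
    scores = Z @ loadings
    return scores[:, 0], PCAResult(loadings=loadings, scores=scores, eigenvalues=eig)


def nested_mixed_model(
    response: np.ndarray,
    region: np.ndarray,
    locality: np.ndarray,
    covariate: np.ndarray | None = None,
    alpha: float = 0.05,
) -> MixedModelResult:
    """REML fit of ``response ~ region (+ covariate)`` with locality intercepts.

    Localities must nest in regions (each locality maps to exactly one
    region) and there must be more localities than regions, otherwise the
    fixed region effect and the random locality effect are confounded.
    The region F-test uses the containment denominator df
    ``n_localities - n_regions``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = pd.DataFrame({
        "response": np.asarray(response, dtype=float),
        "region": np.asarray(region).astype(str),
        "locality": np.asarray(locality).astype(str),
    })
    nesting = df.groupby("locality")["region"].nunique()
    if (nesting > 1).any():
        bad = nesting[nesting > 1].index.tolist()
        raise ValueError(f"localities {bad} appear in more than one region")
    n_loc = df["locality"].nunique()
    n_reg = df["region"].nunique()
    if n_reg < 2:
        raise ValueError("need >= 2 regions")
    if n_loc <= n_reg:
        raise ValueError(
            "region and locality are confounded: need more localities than regions"
        )

    formula = "response ~ C(region)"
    if covariate is not None:
        df["ambient"] = np.asarray(covariate, dtype=float)
        formula += " + ambient"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["locality"])
        res = model.fit(reml=True)

    names = list(res.fe_params.index)
    region_idx = [i for i, nm in enumerate(names) if nm.startswith("C(region)")]
    q = len(region_idx)
    beta = res.fe_params.values[region_idx]
    cov = np.asarray(res.cov_params())[np.ix_(region_idx, region_idx)]
    try:
        wald = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        wald = float(beta @ np.linalg.pinv(cov) @ beta)
    F = wald / q
    df_den = n_loc - n_reg
    p = float(sstats.f.sf(F, q, df_den))

    return MixedModelResult(
        fixed_effects=dict(zip(names, res.fe_params.values)),
        F_stat=float(F),
        df_num=q,
        df_den=df_den,
        p_value=p,
        locality_variance=float(np.asarray(res.cov_re)[0, 0]),
        residual_variance=float(res.scale),
    )


def contingency_association(table: np.ndarray, with_residuals: bool = True) -> AssociationResult:
    """Pearson chi-square of a 2-D count table with adjusted residuals.

    Adjusted standardized residual per cell:
    ``(O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N))``.
    Zero margins are rejected.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row/column margin")
    chi2, p, dof, expected = sstats.chi2_contingency(table, correction=False)
    residuals = None
    if with_residuals:
        N = table.sum()
        denom = np.sqrt(expected * np.outer(1 - rows / N, 1 - cols / N))
        residuals = (table - expected) / denom
    return AssociationResult(chi2=float(chi2), df=int(dof), p_value=float(p),
                             adjusted_residuals=residuals)
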