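"""SVL-standardized morphometrics, PCA retention, and discriminant accuracy.

Nineteen standard measurements are taken per specimen (all in mm): SVL,
HL, HW, EL, IO, IC, END, UEW, FLL, FAL, HAL, F1L, F3L, HLL, TL, TTL, iMTL,
T1L, T4L.  The 18 non-SVL traits are divided by SVL to remove body-size
scaling before multivariate analysis.  PCA runs on the correlation matrix
with Kaiser retention (eigenvalue > 1); group separability is summarized
by linear-discriminant resubstitution accuracy with equal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA

from .stats_core import PCAResult

__all__ = [
    "MEASUREMENTS",
    "HOLOTYPE_MEASUREMENTS_MM",
    "MorphRecord",
    "standardize",
    "diagnostic_ratios",
    "morph_pca",
    "lda_assignment_accuracy",
]

MEASUREMENTS = (
    "SVL", "HL", "HW", "EL", "IO", "IC", "END", "UEW", "FLL", "FAL",
    "HAL", "F1L", "F3L", "HLL", "TL", "TTL", "iMTL", "T1L", "T4L",
)

# column aliases used in field spreadsheets (digits-first finger/toe names)
_ALIASES = {"1FL": "F1L", "3FL": "F3L", "1TL": "T1L", "4TL": "T4L"}

#: The *B. otai* holotype (NMNS 19819) measurement series, in mm.
HOLOTYPE_MEASUREMENTS_MM = {
    "SVL": 26.7, "HL": 10.4, "HW": 10.1, "EL": 4.1, "IO": 2.5, "IC": 4.4,
    "END": 2.6, "UEW": 2.6, "FLL": 19.9, "FAL": 6.9, "HAL": 7.9, "F1L": 2.1,
    "F3L": 4.6, "HLL": 52.2, "TL": 16.6, "TTL": 21.6, "iMTL": 1.3,
    "T1L": 3.0, "T4L": 10.4,
}

#: named diagnostic ratios reported in species descriptions
DIAGNOSTIC_PAIRS = (
    ("HL", "HW"), ("EL", "HL"), ("IO", "HL"), ("IO", "HW"), ("TL", "SVL"),
    ("TTL", "SVL"), ("FAL", "SVL"), ("HAL", "SVL"), ("FAL", "HAL"),
    ("F1L", "F3L"), ("T1L", "T4L"),
)


@dataclass
class MorphRecord:
    specimen_id: str
    sex: str
    measurements: dict[str, float]  # keys from MEASUREMENTS
    group_label: str = ""

    def __post_init__(self) -> None:
        self.measurements = {
            _ALIASES.get(k, k): float(v) for k, v in self.measurements.items()
        }
        for k, v in self.measurements.items():
            if v <= 0:
                raise ValueError(f"{self.specimen_id}: measurement {k} must be positive")


def standardize(record: MorphRecord | dict[str, float]) -> dict[str, float]:
    """Divide each non-SVL measurement by SVL (dimensionless ratios).

    Scale-invariant: multiplying every measurement by a constant leaves the
    output unchanged.
    """
    m = record.measurements if isinstance(record, MorphRecord) else {
        _ALIASES.get(k, k): float(v) for k, v in record.items()
    }
    svl = m.get("SVL", 0.0)
    if svl <= 0:
        raise ValueError("SVL must be positive")
    return {k: v / svl for k, v in m.items() if k != "SVL"}


def _pct(x: float) -> float:
    """Percentage with half-up rounding to one decimal."""
    return float(Decimal(x * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def diagnostic_ratios(record: MorphRecord | dict[str, float]) -> pd.DataFrame:
    """Named diagnostic ratio table (ratio and rounded percentage).

    Ratios whose fields are missing are omitted and listed in the frame's
    ``attrs['missing']``.
    """
    m = record.measurements if isinstance(record, MorphRecord) else {
        _ALIASES.get(k, k): float(v) for k, v in record.items()
    }
    rows, missing = [], []
    for num, den in DIAGNOSTIC_PAIRS:
        name = f"{num}/{den}"
        if num not in m or den not in m:
            missing.append(name)
            continue
        ratio = m[num] / m[den]
        rows.append({"ratio": name, "value": ratio, "percent": _pct(ratio)})
    out = pd.DataFrame(rows).set_index("ratio")
    out.attrs["missing"] = missing
    if missing:
        warnings.warn(f"missing measurements; omitted ratios: {missing}")
    return out


def morph_pca(standardized: pd.DataFrame) -> tuple[PCAResult, int]:
    """Correlation-matrix PCA of standardized traits with Kaiser retention.

    Returns the full decomposition and the number of components with
    eigenvalue strictly greater than 1.  Constant columns are dropped with
    a warning.
    """
    X = standardized.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 variables")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping constant variables: "
                      f"{list(standardized.columns[~keep])}")
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(Z)
    eig = pca.explained_variance_
    n_retained = int(np.sum(eig > 1.0))
    return (
        PCAResult(loadings=pca.components_.T, scores=scores, eigenvalues=eig),
        n_retained,
    )


def lda_assignment_accuracy(
    scores: np.ndarray,
    labels: np.ndarray,
    ridge: float = 1e-8,
) -> float:
    """Resubstitution accuracy (%) of an equal-priors linear discriminant.

    A singular within-class scatter falls back to an eigen solver with
    small shrinkage (warned).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    priors = np.full(classes.size, 1.0 / classes.size)
    lda = LinearDiscriminantAnalysis(priors=priors, solver="svd")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", UserWarning)
            lda.fit(scores, labels)
    except (np.linalg.LinAlgError, UserWarning):
        warnings.warn("singular within-class scatter; using shrinkage LDA")
        lda = LinearDiscriminantAnalysis(priors=priors, solver="eigen",
                                         shrinkage=max(ridge, 1e-4))
        lda.fit(scores, labels)
    return float((lda.predict(scores) == labels).mean() * 100.0)
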