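"""Phenoprints and cross-condition comparison by correlation-matrix PCA.

A phenoprint condenses all QC-passed sections of one genotype x timepoint
into 8 numbers: total cell count, total transverse area, the proportions of
the five cell-type categories, and the median incline angle (medians across
sections).  Phenoprints are scaled to unit range per variable (division by
the per-variable maximum) and compared by principal component analysis of
the correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CLASS_NAMES

PHENOPRINT_FIELDS = ["n_cells", "total_area_um2"] + \
    [f"prop_{c}" for c in CLASS_NAMES] + ["median_incline"]


@dataclass
class Phenoprint:
    genotype: str
    timepoint: str
    values: pd.Series  # indexed by PHENOPRINT_FIELDS

    def as_row(self) -> pd.Series:
        row = self.values.copy()
        row.name = f"{self.genotype}_{self.timepoint}"
        return row


def compute_phenoprint(tables: list[pd.DataFrame], genotype: str = "synthetic",
                       timepoint: str = "NA") -> Phenoprint:
    """Summarize classified, QC-passed section tables into 8 statistics.

    Per section: cell count, summed cell area (um^2), the five class
    proportions and the median incline; the phenoprint takes the median of
    each statistic across sections.  Class proportions sum to 1.
    """
    if not tables:
        raise ValueError("at least one classified section table is required")
    per_section = []
    for t in tables:
        if "class" not in t:
            raise ValueError("tables must carry a 'class' column")
        props = t["class"].astype(str).value_counts(normalize=True)
        rec = {"n_cells": float(len(t)), "total_area_um2": float(t["area"].sum())}
        for c in CLASS_NAMES:
            rec[f"prop_{c}"] = float(props.get(c, 0.0))
        rec["median_incline"] = float(t["incline"].median())
        per_section.append(rec)
    med = pd.DataFrame(per_section).median()
    # medians of proportions need not sum to 1 across sections; renormalize
    prop_cols = [f"prop_{c}" for c in CLASS_NAMES]
    s = med[prop_cols].sum()
    if s > 0:
        med[prop_cols] = med[prop_cols] / s
    return Phenoprint(genotype, str(timepoint), med[PHENOPRINT_FIELDS])


def phenoprint_matrix(phenoprints: list[Phenoprint]) -> pd.DataFrame:
    """Rows = genotype x timepoint, columns = the 8 phenoprint variables."""
    return pd.DataFrame([p.as_row() for p in phenoprints])


def normalize_unit_range(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each variable by its maximum to obtain a unit range.

    Requires non-negative values and a positive maximum per column; the
    result has column maxima exactly 1.
    """
    matrix = matrix.astype(float)
    if (matrix < 0).any().any():
        raise ValueError("unit-range scaling expects non-negative values")
    maxima = matrix.max(axis=0)
    zero = maxima[maxima <= 0]
    if len(zero):
        raise ValueError(f"all-zero variables cannot be scaled: "
                         f"{', '.join(zero.index)}")
    return matrix / maxima


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    loadings: pd.DataFrame           # variables x components
    scores: pd.DataFrame             # samples x components
    proportion_variance: np.ndarray  # sums to 1
    dropped: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def pca_correlation(matrix: pd.DataFrame) -> PCAResult:
    """PCA by eigendecomposition of the correlation matrix.

    Columns are standardized (mean 0, sd 1 with the 1/(n-1) convention);
    eigenvalues of their correlation matrix sum to the number of variables;
    scores are the standardized data projected on the eigenvectors, so the
    score variance along component k equals eigenvalue k.  Zero-variance
    variables are dropped with a warning.  Loading signs are fixed so the
    largest-magnitude entry of each component is positive.
    """
    matrix = matrix.astype(float)
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 samples")
    sd = matrix.std(axis=0, ddof=1)
    dropped = list(sd[sd == 0].index)
    if dropped:
        warnings.warn(f"zero-variance variables dropped: {dropped}")
        matrix = matrix.drop(columns=dropped)
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables with variance")
    Z = (matrix - matrix.mean(axis=0)) / matrix.std(axis=0, ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest |loading| per component positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{k + 1}" for k in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=matrix.index,
                          columns=comp_names)
    return PCAResult(evals, loadings, scores, evals / evals.sum(), dropped)


def plot_biplot(result: PCAResult, ax=None, scale: float = 2.0):
    """Biplot of the first two components: sample scores plus variable
    loading arrows (angles between arrows reflect variable correlation)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    sc = result.scores
    ax.scatter(sc["PC1"], sc["PC2"], s=30, color="tab:blue")
    for name, row in sc.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=8)
    for var, row in result.loadings.iterrows():
        ax.arrow(0, 0, scale * row["PC1"], scale * row["PC2"],
                 color="tab:red", head_width=0.05, length_includes_head=True)
        ax.annotate(var, (scale * row["PC1"], scale * row["PC2"]),
                    fontsize=8, color="tab:red")
    pv = result.proportion_variance
    ax.set_xlabel(f"PC1 ({100 * pv[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * pv[1]:.0f}%)")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    return ax
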