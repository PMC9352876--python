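"""Gene-wise Wald differential expression under a plate/buffer/treatment design.

Each (cell line, drug) condition is analyzed separately against its matched
vehicle control (H2O for propranolol, DMSO for primidone): genes failing the
low-abundance filter are dropped, every remaining gene is fit by OLS of
log2(abundance + 0.5) on intercept + plate + buffer + treatment dummies, and
the treatment coefficient's Wald statistic yields the per-gene p-value, which
is Benjamini-Hochberg adjusted across retained genes.

With the default ``reference="t"`` the two-sided p comes from the Student-t
distribution on the residual degrees of freedom and the reported z is the
signed standard-normal quantile of that p — a null-calibrated Z-score suitable
for Stouffer combination even at three replicates per arm. With
``reference="normal"`` the p comes from the normal reference and z equals
log2fc/se exactly (the raw Wald convention; anticonservative at small n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExperimentMatrix",
    "GeneFit",
    "DesignError",
    "MissingArmError",
    "NoGenesRetainedError",
    "filter_low_expression",
    "fit_gene_model",
    "run_de",
    "bh_adjust",
    "CONTROL_FOR",
]

# Matched vehicle control for each drug arm.
CONTROL_FOR = {"propranolol": "H2O", "primidone": "DMSO"}

_FACTORS = ("plate", "buffer", "treatment")
_MIN_P = 1e-300  # floor before inverse-normal, keeps z finite (~37)


class DesignError(ValueError):
    """The design matrix is rank-deficient or otherwise unusable."""


class MissingArmError(KeyError):
    """A requested treatment arm or control level is absent."""


class NoGenesRetainedError(ValueError):
    """The abundance filter removed every gene."""


@dataclass
class ExperimentMatrix:
    """Gene-by-sample abundance plus per-sample design factors.

    ``abundance`` rows are genes, columns are samples; ``sample_meta`` is
    indexed by sample id with columns cell_type, treatment, buffer, plate.
    """

    abundance: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.isna().any().any():
            raise ValueError("abundance contains missing values")
        if not self.abundance.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta rows must align with abundance columns")
        missing = [c for c in ("cell_type", "treatment") if c not in self.sample_meta]
        if missing:
            raise ValueError(f"sample_meta missing required columns: {missing}")
        if not self.abundance.index.is_unique:
            raise ValueError("gene ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]


class GeneFit(NamedTuple):
    log2fc: float
    se: float
    z: float
    p: float


def filter_low_expression(
    matrix: ExperimentMatrix,
    min_abundance: float = 10.0,
    min_fraction: float = 0.9,
) -> ExperimentMatrix:
    """Keep genes with abundance >= ``min_abundance`` in >= ceil(min_fraction * n) samples.

    The default 10-in-90%-of-samples mirrors the usual scaled-reads-per-base
    QC cut for bulk RNA-seq quantifications.
    """
    if min_abundance < 0:
        raise ValueError("min_abundance must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n = matrix.n_samples
    required = math.ceil(min_fraction * n - 1e-9)
    ok = (matrix.abundance >= min_abundance).sum(axis=1) >= required
    if not ok.any():
        raise NoGenesRetainedError(
            f"no genes retained at min_abundance={min_abundance}, "
            f"min_fraction={min_fraction}"
        )
    return ExperimentMatrix(matrix.abundance.loc[ok], matrix.sample_meta)


def _design_matrix(
    design: pd.DataFrame, treatment_control: str | None
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design: intercept + non-constant plate/buffer + treatment.

    The treatment factor must have exactly two levels; the control level is
    the reference so the treatment coefficient is drug-vs-control.
    """
    missing = [f for f in _FACTORS if f not in design.columns]
    if missing:
        raise DesignError(f"design missing factor columns: {missing}")
    cols: list[np.ndarray] = [np.ones(len(design))]
    names = ["intercept"]
    for factor in ("plate", "buffer"):
        levels = pd.unique(design[factor])
        for level in levels[1:]:  # first level is the reference
            cols.append((design[factor] == level).to_numpy(float))
            names.append(f"{factor}[{level}]")
    t_levels = list(pd.unique(design["treatment"]))
    if len(t_levels) != 2:
        raise DesignError(
            f"treatment must have exactly 2 levels, got {t_levels!r}"
        )
    if treatment_control is None:
        treatment_control = t_levels[0]
    if treatment_control not in t_levels:
        raise MissingArmError(f"control level {treatment_control!r} not in design")
    treated_level = next(l for l in t_levels if l != treatment_control)
    cols.append((design["treatment"] == treated_level).to_numpy(float))
    names.append(f"treatment[{treated_level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            "rank-deficient design: confounded factors among "
            f"{names[1:]} (e.g. a factor aliased with treatment)"
        )
    if X.shape[0] - X.shape[1] < 1:
        raise DesignError("need at least one residual degree of freedom")
    return X, names


def _wald_many(
    Y: np.ndarray, X: np.ndarray, reference: str = "t"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every row of Y on X; Wald stats for the last column.

    Returns (beta, se, z, p) arrays of length n_genes. The last column of X
    is the treatment dummy by construction.
    """
    if reference not in ("t", "normal"):
        raise ValueError("reference must be 't' or 'normal'")
    n, p_cols = X.shape
    df = n - p_cols
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T  # (p, n)
    B = Y @ proj.T  # (genes, p)
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    scale = np.maximum(1.0, np.abs(Y).max(axis=1) ** 2)
    exact = rss <= 1e-10 * scale  # zero residual variance sentinel
    sigma2 = np.where(exact, 0.0, rss / df)
    beta = B[:, -1]
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])

    z = np.zeros_like(beta)
    p = np.ones_like(beta)
    ok = se > 0
    tstat = np.zeros_like(beta)
    tstat[ok] = beta[ok] / se[ok]
    if reference == "t":
        p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
        p_ok = np.clip(p[ok], _MIN_P, 1.0)
        z[ok] = np.sign(beta[ok]) * stats.norm.isf(p_ok / 2.0)
    else:
        z[ok] = tstat[ok]
        p[ok] = 2.0 * stats.norm.sf(np.abs(tstat[ok]))
    # exact-fit path: nonzero effect with zero residual noise
    hit = (~ok) & (np.abs(beta) > 0)
    z[hit] = np.sign(beta[hit]) * np.inf
    p[hit] = 0.0
    return beta, se, z, p


def fit_gene_model(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    treatment_control: str | None = None,
    reference: str = "t",
) -> GeneFit:
    """OLS Wald test of the treatment effect for one gene.

    ``y`` is the per-sample response on the log2 scale (callers transform
    raw abundance as log2(x + 0.5)); ``design`` holds the plate, buffer and
    treatment factor columns, one row per sample. Returns the treatment
    coefficient (log2 fold change), its standard error, the Wald z and the
    two-sided p. A zero-residual fit returns se = 0 with z = ±inf, p = 0
    (or z = 0, p = 1 when the effect itself is zero).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError("y must be one value per design row")
    X, _ = _design_matrix(design, treatment_control)
    beta, se, z, p = _wald_many(y[None, :], X, reference=reference)
    return GeneFit(float(beta[0]), float(se[0]), float(z[0]), float(p[0]))


def run_de(
    matrix: ExperimentMatrix,
    cell_type: str,
    drug: str,
    min_abundance: float = 10.0,
    min_fraction: float = 0.9,
    reference: str = "t",
    control: str | None = None,
) -> pd.DataFrame:
    """Differential expression for one (cell line, drug) condition.

    Subsets the matrix to the cell line's drug arm plus its matched vehicle
    control, applies the low-abundance filter, fits every gene, and
    BH-adjusts p across retained genes. Returns a DataFrame with columns
    gene_id, log2fc, se, z, p, q sorted by q ascending (gene_id breaks ties).
    """
    if control is None:
        if drug not in CONTROL_FOR:
            raise MissingArmError(
                f"no matched control known for drug {drug!r}; pass control="
            )
        control = CONTROL_FOR[drug]
    meta = matrix.sample_meta
    in_ct = meta["cell_type"] == cell_type
    if not in_ct.any():
        raise MissingArmError(f"cell type {cell_type!r} absent from sample metadata")
    for level in (drug, control):
        if not (in_ct & (meta["treatment"] == level)).any():
            raise MissingArmError(
                f"treatment level {level!r} absent for cell type {cell_type!r}"
            )
    keep = in_ct & meta["treatment"].isin([drug, control])
    sub = ExperimentMatrix(matrix.abundance.loc[:, keep.to_numpy()], meta.loc[keep])
    sub = filter_low_expression(sub, min_abundance, min_fraction)

    X, _ = _design_matrix(sub.sample_meta[list(_FACTORS)], treatment_control=control)
    Y = np.log2(sub.abundance.to_numpy(float) + 0.5)
    beta, se, z, p = _wald_many(Y, X, reference=reference)
    out = pd.DataFrame(
        {
            "gene_id": sub.abundance.index,
            "log2fc": beta,
            "se": se,
            "z": z,
            "p": p,
            "q": bh_adjust(p),
        }
    )
    return out.sort_values(["q", "gene_id"], kind="mergesort").reset_index(drop=True)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(np.isnan(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
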