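"""Regression of TWAS gene Z-scores on drug-effect Z-scores.

Tests whether the transcriptomic footprint of a drug lines up with the
genetically predicted expression effects of common trait variants: per
tissue, TWAS Z is regressed on the drug (meta-analysis) Z with gene length
and GC fraction as covariates, in an unweighted and a significance-weighted
form. Weighting replaces both Z vectors by z*|z| (magnitude squared, sign
kept) so highly significant genes dominate without discarding direction; a
``literal_squared`` mode squares outright (sign discarded) for comparison.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .convergence import CONDITION_SETS, weighted_z
from .diffexpr import bh_adjust

__all__ = ["TwasFit", "fit_twas_model", "run_twas_scan"]


class TwasFit(NamedTuple):
    coef: float
    se: float
    p: float
    n: int


def _drug_design(
    twas_z: pd.Series,
    drug_z: pd.Series,
    ann: pd.DataFrame,
    weighted: bool,
    literal_squared: bool,
    log_length: bool,
) -> tuple[pd.Series, pd.DataFrame]:
    common = twas_z.index.intersection(drug_z.index).intersection(ann.index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} genes shared; need >= 10")
    y = twas_z.loc[common].astype(float)
    x = drug_z.loc[common].astype(float)
    if weighted:
        if literal_squared:
            y, x = y**2, x**2
        else:
            y = pd.Series(weighted_z(y.to_numpy()), index=common)
            x = pd.Series(weighted_z(x.to_numpy()), index=common)
    length = ann.loc[common, "gene_length"].astype(float)
    if log_length:
        length = np.log10(length)
    X = pd.DataFrame(
        {
            "drug_z": x,
            "gene_length": length,
            "gc_fraction": ann.loc[common, "gc_fraction"].astype(float),
        }
    )
    if (X.std() == 0).any():
        bad = list(X.columns[X.std() == 0])
        raise ValueError(f"constant predictor columns: {bad}")
    return y, X


def fit_twas_model(
    twas_z: pd.Series,
    drug_z: pd.Series,
    ann: pd.DataFrame,
    weighted: bool = False,
    literal_squared: bool = False,
    log_length: bool = False,
) -> TwasFit:
    """OLS of TWAS Z on drug Z + gene length + GC fraction (+ intercept).

    All three inputs are gene-indexed and intersected before fitting.
    Returns the drug-term coefficient, its standard error, the two-sided p
    and the number of genes used. Raises on < 10 shared genes, constant or
    collinear covariates.
    """
    y, X = _drug_design(twas_z, drug_z, ann, weighted, literal_squared, log_length)
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear covariates in the TWAS design")
    fit = sm.OLS(y, Xc).fit()
    return TwasFit(
        coef=float(fit.params["drug_z"]),
        se=float(fit.bse["drug_z"]),
        p=float(fit.pvalues["drug_z"]),
        n=len(y),
    )


def run_twas_scan(
    twas: pd.DataFrame,
    conv: pd.DataFrame,
    ann: pd.DataFrame,
    condition_sets: Sequence[str] | None = None,
    weighted_modes: Sequence[bool] = (False, True),
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every (tissue, condition set, weighting) combination; BH overall.

    ``twas`` is tidy with columns gene_id, tissue, z; ``conv`` is the
    gene-indexed convergence table whose z_<set> columns supply the drug Z
    for each condition set. Pairs with an insufficient gene intersection are
    reported as rows with NaN statistics rather than aborting the scan. BH
    is applied across the full scan's non-missing p-values.
    """
    for col in ("gene_id", "tissue", "z"):
        if col not in twas.columns:
            raise ValueError(f"twas table missing column {col!r}")
    if condition_sets is None:
        condition_sets = [s for s in CONDITION_SETS if f"z_{s}" in conv.columns]
    if not condition_sets:
        raise ValueError("no condition sets available in the convergence table")

    rows = []
    for tissue, sub in twas.groupby("tissue", sort=True):
        tz = sub.set_index("gene_id")["z"]
        if not tz.index.is_unique:
            raise ValueError(f"duplicate gene ids within tissue {tissue!r}")
        for cset in condition_sets:
            dz = conv[f"z_{cset}"]
            for weighted in weighted_modes:
                row = {"tissue": tissue, "condition_set": cset, "weighted": weighted}
                try:
                    fit = fit_twas_model(tz, dz, ann, weighted=weighted, **fit_kwargs)
                    row.update(coef=fit.coef, se=fit.se, p=fit.p, n=fit.n)
                except ValueError:
                    row.update(coef=np.nan, se=np.nan, p=np.nan, n=0)
                rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
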