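"""Stouffer's-Z convergence meta-analysis across treatment conditions.

Per-condition gene Z-scores (one column per (cell line, drug) condition) are
combined over five condition sets — each drug across both cell lines ("prop",
"prim"), each cell line across both drugs ("daoy", "npc"), and all four
conditions at once ("all") — by Stouffer's method: sum the Z's and divide by
sqrt(k). A gene pushed the same way in every condition accumulates evidence;
opposite-signed effects cancel, which is exactly what "convergent" is meant
to exclude. BH adjustment is applied within each condition set across genes.

The module also provides the weighted/unweighted cross-condition Pearson
correlations, where weighting replaces each Z by z*|z| so that the most
significant genes dominate while the sign (direction of regulation) is kept.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "CONDITIONS",
    "CONDITION_SETS",
    "stouffer_combine",
    "weighted_z",
    "correlate_conditions",
    "condition_correlation_matrix",
    "zpanel_from_de",
    "run_convergence",
    "convergent_genes",
]

#: The four per-condition Z columns a full panel carries.
CONDITIONS = ("daoy_prop", "daoy_prim", "npc_prop", "npc_prim")

#: Condition sets combined by the meta-analysis.
CONDITION_SETS: dict[str, tuple[str, ...]] = {
    "prop": ("daoy_prop", "npc_prop"),
    "prim": ("daoy_prim", "npc_prim"),
    "daoy": ("daoy_prop", "daoy_prim"),
    "npc": ("npc_prop", "npc_prim"),
    "all": CONDITIONS,
}


def stouffer_combine(z: Sequence[float] | np.ndarray, normalize: bool = True) -> float:
    """Combine k Z-scores as (sum z_i) / sqrt(k).

    ``normalize=False`` returns the raw sum (the literal "summed" reading;
    not N(0,1)-calibrated and only useful for inspection).
    """
    arr = np.asarray(z, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot combine an empty Z-score vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("Z-scores must be finite")
    s = float(arr.sum())
    return s / np.sqrt(arr.size) if normalize else s


def weighted_z(z):
    """Significance weighting z -> z * |z|: sign kept, magnitude squared."""
    arr = np.asarray(z, dtype=float)
    out = arr * np.abs(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def correlate_conditions(
    z1: Sequence[float] | np.ndarray,
    z2: Sequence[float] | np.ndarray,
    weighted: bool = False,
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two conditions' Z vectors.

    ``weighted=True`` correlates z*|z|-transformed vectors, emphasizing the
    most significant genes while keeping direction.
    """
    a = np.asarray(z1, dtype=float)
    b = np.asarray(z2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("z1 and z2 must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 genes to correlate")
    if weighted:
        a, b = weighted_z(a), weighted_z(b)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a Z vector; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def condition_correlation_matrix(
    panel: pd.DataFrame, weighted: bool = False
) -> pd.DataFrame:
    """Pairwise cross-condition Pearson r over the panel's common genes."""
    cols = list(panel.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            r, _ = correlate_conditions(panel[ci], panel[cj], weighted=weighted)
            out.loc[ci, cj] = out.loc[cj, ci] = r
    return out


def zpanel_from_de(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble a gene-by-condition Z panel from per-condition DE tables.

    ``results`` maps condition label -> DE table (gene_id, z columns).
    Genes are intersected: only genes retained in every condition enter the
    meta-analysis, since a gene filtered out of one condition has no Z there.
    """
    if not results:
        raise ValueError("no DE results given")
    series = {}
    for cond, table in results.items():
        s = table.set_index("gene_id")["z"] if "gene_id" in table else table["z"]
        series[cond] = s
    panel = pd.concat(series, axis=1, join="inner")
    panel.index.name = "gene_id"
    if not np.all(np.isfinite(panel.to_numpy())):
        raise ValueError("Z panel contains non-finite entries")
    return panel


def run_convergence(
    panel: pd.DataFrame,
    condition_sets: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Stouffer-combine the panel over each condition set, BH within set.

    Returns a gene-indexed table with z_<set>, p_<set>, q_<set> columns for
    every set in ``condition_sets`` (default: prop, prim, daoy, npc, all).
    """
    if condition_sets is None:
        condition_sets = CONDITION_SETS
    out = pd.DataFrame(index=panel.index.copy())
    for name, members in condition_sets.items():
        missing = [m for m in members if m not in panel.columns]
        if missing:
            raise KeyError(f"condition set {name!r}: missing panel columns {missing}")
        block = panel[list(members)].to_numpy(float)
        z = block.sum(axis=1) / np.sqrt(len(members))
        p = 2.0 * stats.norm.sf(np.abs(z))
        out[f"z_{name}"] = z
        out[f"p_{name}"] = p
        out[f"q_{name}"] = bh_adjust(p)
    return out


def convergent_genes(
    table: pd.DataFrame,
    condition_set: str = "all",
    alpha: float = 0.05,
    direction: str | None = None,
) -> pd.Index:
    """Genes significant in a condition set (q < alpha), optionally sign-split.

    ``direction`` of "up"/"down" restricts to positive/negative combined Z.
    """
    qcol, zcol = f"q_{condition_set}", f"z_{condition_set}"
    if qcol not in table.columns:
        raise KeyError(f"no such condition set in table: {condition_set!r}")
    mask = table[qcol] < alpha
    if direction == "up":
        mask &= table[zcol] > 0
    elif direction == "down":
        mask &= table[zcol] < 0
    elif direction is not None:
        raise ValueError("direction must be None, 'up' or 'down'")
    return table.index[mask]
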