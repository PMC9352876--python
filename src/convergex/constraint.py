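"""Loss-of-function constraint comparison with propensity-score matching.

Asks whether drug-targeted genes are more mutationally constrained (lower
LoF observed/expected, "o/e") than background genes, while accounting for
the fact that long, GC-atypical genes are both easier to call differentially
expressed and easier to accumulate LoF variants in. The procedure:

1. logistic propensity model of DEG membership on CDS length + GC fraction;
2. nearest-neighbor matching on the propensity score, with replacement, at a
   fixed matches-per-DEG ratio (by default the maximum, floor(n_bg/n_deg));
3. Wilcoxon rank-sum test of o/e between the DEG set and its matched
   background, with medians reported on the raw o/e scale.

o/e scores can be displayed as percentages (0.25 -> 25%) with scores over
10 capped at 100%, for histogram comparison.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "oe_to_percent",
    "propensity_scores",
    "nn_match_with_replacement",
    "wilcoxon_rank_sum",
    "run_constraint_analysis",
]

_EXACT_LIMIT = 12  # exact rank-sum enumeration up to this combined n


def oe_to_percent(score):
    """o/e ratio as a percentage: score*100, capped at 100 for scores > 10."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("o/e scores must be >= 0")
    out = np.where(arr > 10.0, 100.0, arr * 100.0)
    return float(out) if arr.ndim == 0 else out


def propensity_scores(ann: pd.DataFrame, deg_flags: pd.Series) -> pd.Series:
    """Fitted P(DEG | cds_length, gc_fraction) from a logistic model.

    ``deg_flags`` is a boolean Series aligned to ``ann``'s gene index. Both
    classes must be non-empty. Constant covariate columns are dropped (with
    all covariates constant the fit is intercept-only and every score equals
    the DEG prevalence). Perfect separation raises with advice to inspect
    the covariates.
    """
    flags = deg_flags.reindex(ann.index)
    if flags.isna().any():
        raise ValueError("deg_flags must cover every annotated gene")
    y = flags.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both DEG and background classes must be non-empty")
    X = ann[["cds_length", "gc_fraction"]].astype(float)
    X = X.loc[:, X.std() > 0]
    if not X.empty:
        X = (X - X.mean()) / X.std()  # conditioning only; fit is affine-invariant
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        try:  # Newton can overshoot; quasi-Newton is sturdier
            fit = sm.Logit(y, Xc).fit(disp=0, method="bfgs", maxiter=500)
        except Exception as e:
            raise ValueError(
                "propensity model failed (perfect separation?); inspect covariates"
            ) from e
    return pd.Series(np.asarray(fit.predict(Xc)), index=ann.index, name="propensity")


def nn_match_with_replacement(
    treated_scores: np.ndarray | pd.Series,
    control_scores: np.ndarray | pd.Series,
    ratio: int,
) -> np.ndarray:
    """Nearest-neighbor matches on a score: ``ratio`` controls per treated unit.

    Matching is with replacement across treated units (a control may serve
    several treated units) but without replacement within one treated unit's
    match set. Ties in |score difference| break to the smallest control
    index, so the result is deterministic. Returns an integer array of shape
    (n_treated, ratio) of positions into ``control_scores``.
    """
    t = np.asarray(treated_scores, dtype=float)
    c = np.asarray(control_scores, dtype=float)
    if c.size == 0:
        raise ValueError("control scores are empty")
    if t.size == 0:
        raise ValueError("treated scores are empty")
    if not 1 <= ratio <= c.size:
        raise ValueError(f"ratio must be in [1, {c.size}]")
    dist = np.abs(c[None, :] - t[:, None])  # (n_treated, n_controls)
    # stable argsort: equal distances keep ascending control index
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :ratio]


def _rank_sum_exact_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum of a size-n_x subset of ``ranks``."""
    total = comb(len(ranks), n_x)
    le = ge = 0
    for subset in combinations(ranks, n_x):
        s = sum(subset)
        if s <= w_obs + 1e-9:
            le += 1
        if s >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_rank_sum(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; W is the rank-sum of the first sample.

    Midranks handle ties. The two-sided p is exact (enumeration over all
    rank assignments) when n_x + n_y <= 12, otherwise a normal approximation
    with tie correction and a 0.5 continuity correction. Note W conventions
    differ between software packages: here W = sum of x's ranks, which
    equals the Mann-Whitney U plus n_x(n_x+1)/2.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = xa.size, ya.size
    n = n_x + n_y
    ranks = stats.rankdata(np.concatenate([xa, ya]))
    w = float(ranks[:n_x].sum())
    if n <= _EXACT_LIMIT:
        p = _rank_sum_exact_p(ranks, n_x, w)
        return w, p
    mu = n_x * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([xa, ya]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return w, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return w, min(1.0, p)


class ConstraintComparison(NamedTuple):
    name: str
    n_deg: int
    ratio: int
    median_deg_oe: float
    median_bg_oe: float
    W: float
    p: float


def run_constraint_analysis(
    ann: pd.DataFrame,
    deg_sets: Mapping[str, Iterable[str]],
    ratio: int | None = None,
) -> pd.DataFrame:
    """Constraint comparison of each DEG set against matched background.

    ``deg_sets`` maps a comparison name (conventionally "all"/"up"/"down")
    to gene ids; each set must hold >= 5 annotated genes. ``ratio=None``
    uses the maximum number of matches floor(n_background / n_deg) per set.
    Returns one row per set: n_deg, ratio, medians of o/e (raw scale and as
    percentages), Wilcoxon W and p for DEG-vs-matched-background o/e.
    """
    required = {"cds_length", "gc_fraction", "oe_score"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    rows = []
    for name, genes in deg_sets.items():
        deg_idx = ann.index.intersection(pd.Index(list(set(genes))))
        if len(deg_idx) < 5:
            raise ValueError(
                f"DEG set {name!r} has {len(deg_idx)} annotated genes; need >= 5"
            )
        flags = pd.Series(ann.index.isin(deg_idx), index=ann.index)
        scores = propensity_scores(ann, flags)
        bg_idx = ann.index[~flags]
        set_ratio = ratio if ratio is not None else len(bg_idx) // len(deg_idx)
        set_ratio = max(1, min(set_ratio, len(bg_idx)))
        matches = nn_match_with_replacement(
            scores.loc[deg_idx].to_numpy(), scores.loc[bg_idx].to_numpy(), set_ratio
        )
        matched_oe = ann.loc[bg_idx, "oe_score"].to_numpy()[matches.ravel()]
        deg_oe = ann.loc[deg_idx, "oe_score"].to_numpy()
        W, p = wilcoxon_rank_sum(deg_oe, matched_oe)
        rows.append(
            {
                "comparison": name,
                "n_deg": len(deg_idx),
                "ratio": set_ratio,
                "median_deg_oe": float(np.median(deg_oe)),
                "median_bg_oe": float(np.median(matched_oe)),
                "median_deg_pct": float(np.median(oe_to_percent(deg_oe))),
                "median_bg_pct": float(np.median(oe_to_percent(matched_oe))),
                "W": W,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
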