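"""Seeded generators for synthetic drug-transcriptomics inputs.

The generators emulate the derived data a convergent drug-screen analysis
consumes: a gene-by-sample abundance matrix with plate/buffer/treatment
structure for two cell lines (a cerebellar medulloblastoma line and cortical
neural progenitors) treated with propranolol (H2O-buffered) or primidone
(DMSO-buffered); per-gene annotation including loss-of-function constraint
scores; TWAS Z-score vectors at a chosen correlation with the drug effect;
and cell-type average-expression profiles with spiked-in enriched gene sets.

Every generator takes an explicit integer seed and is byte-deterministic.
Ground truth (which genes carry effects, which are constrained, which sets
are enriched where) is returned alongside the data so downstream stages can
be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExperimentMatrix

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "generate_experiment",
    "generate_gene_annotation",
    "generate_twas",
    "generate_sc_profiles",
    "DRUGS",
    "CONTROL_FOR",
    "BUFFER_FOR",
    "condition_label",
]

#: Drug arms and their matched vehicle controls.
DRUGS = ("propranolol", "primidone")
CONTROL_FOR = {"propranolol": "H2O", "primidone": "DMSO"}
#: Buffer shared by a drug arm and its control.
BUFFER_FOR = {"propranolol": "H2O", "H2O": "H2O", "primidone": "DMSO", "DMSO": "DMSO"}


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid range."""


def condition_label(cell_type: str, drug: str) -> str:
    """Short condition name, e.g. ('daoy', 'propranolol') -> 'daoy_prop'."""
    return f"{cell_type}_{drug[:4]}"


@dataclass(frozen=True)
class SimulationConfig:
    """World description for :func:`generate_experiment`.

    Defaults mirror the experimental design being emulated: two cell lines,
    four arms (two drugs, two vehicle controls), three replicates per
    (cell line, arm). Count noise is negative-binomial on a log-linear mean
    with gene-specific plate and buffer nuisance effects; true treatment
    effects are placed on a convergent fraction (shared across all four
    conditions) and a condition-specific fraction of genes.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    cell_types: tuple[str, ...] = ("daoy", "npc")
    drugs: tuple[str, ...] = DRUGS
    frac_convergent: float = 0.05
    frac_condition_specific: float = 0.05
    effect_size_log2: float = 1.0
    dispersion: float = 0.1
    plate_sd: float = 0.1
    buffer_sd: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.2
    twas_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        for drug in self.drugs:
            if drug not in CONTROL_FOR:
                raise ConfigurationError(
                    f"drugs: no control buffer known for arm {drug!r}"
                )
        for name in ("frac_convergent", "frac_condition_specific"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_convergent + self.frac_condition_specific > 1.0 + 1e-12:
            raise ConfigurationError(
                "frac_convergent + frac_condition_specific must be <= 1"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        for name in ("plate_sd", "buffer_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 <= self.twas_rho <= 1.0:
            raise ConfigurationError("twas_rho must be in [-1, 1]")

    @property
    def arms(self) -> tuple[str, ...]:
        out: list[str] = []
        for drug in self.drugs:
            out.extend([drug, CONTROL_FOR[drug]])
        return tuple(out)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(
            condition_label(ct, drug) for ct in self.cell_types for drug in self.drugs
        )


def _gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def generate_experiment(
    config: SimulationConfig,
) -> tuple[ExperimentMatrix, pd.DataFrame]:
    """Simulate a drug-treatment experiment and its ground truth.

    Counts are negative-binomial with
    ``log2 mean = baseline + plate + buffer + treatment``, where the
    treatment term is nonzero only for truth-flagged genes in their flagged
    conditions. Returns the experiment matrix (abundance + sample metadata
    with cell_type/treatment/buffer/plate) and a truth table with one row
    per gene: ``is_convergent``, ``is_condition_specific`` and the true
    log2 effect per condition (columns ``true_log2fc_<condition>``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    conditions = list(config.conditions)

    # Sample sheet: replicates alternate over two plates, buffer follows arm.
    rows = []
    for ct in config.cell_types:
        for arm in config.arms:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{ct}_{arm}_{rep}",
                        "cell_type": ct,
                        "treatment": arm,
                        "buffer": BUFFER_FOR[arm],
                        "plate": f"P{(rep - 1) % 2 + 1}",
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")

    n_conv = round(config.frac_convergent * config.n_genes)
    n_spec = round(config.frac_condition_specific * config.n_genes)
    flagged = rng.choice(config.n_genes, size=n_conv + n_spec, replace=False)
    conv_idx = flagged[:n_conv]
    spec_idx = flagged[n_conv:]

    effects = np.zeros((config.n_genes, len(conditions)))
    signs = rng.choice([-1.0, 1.0], size=n_conv)
    effects[conv_idx, :] = (signs * config.effect_size_log2)[:, None]
    spec_cond = rng.integers(0, len(conditions), size=n_spec)
    spec_signs = rng.choice([-1.0, 1.0], size=n_spec)
    effects[spec_idx, spec_cond] = spec_signs * config.effect_size_log2

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    plate_eff = rng.normal(0.0, config.plate_sd, config.n_genes)
    buffer_eff = rng.normal(0.0, config.buffer_sd, config.n_genes)

    cond_of_sample = np.full(len(meta), -1)
    for j, (_, row) in enumerate(meta.iterrows()):
        if row["treatment"] in config.drugs:
            cond_of_sample[j] = conditions.index(
                condition_label(row["cell_type"], row["treatment"])
            )
    on_p2 = (meta["plate"] == "P2").to_numpy()
    on_dmso = (meta["buffer"] == "DMSO").to_numpy()

    log2_mu = baseline[:, None] + np.zeros((config.n_genes, len(meta)))
    log2_mu += plate_eff[:, None] * on_p2[None, :]
    log2_mu += buffer_eff[:, None] * on_dmso[None, :]
    treated = cond_of_sample >= 0
    log2_mu[:, treated] += effects[:, cond_of_sample[treated]]

    mu = np.exp2(log2_mu)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    abundance = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene_id"), columns=meta.index
    )
    truth = pd.DataFrame(
        {
            "is_convergent": np.isin(np.arange(config.n_genes), conv_idx),
            "is_condition_specific": np.isin(np.arange(config.n_genes), spec_idx),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    for k, cond in enumerate(conditions):
        truth[f"true_log2fc_{cond}"] = effects[:, k]

    return ExperimentMatrix(abundance=abundance, sample_meta=meta), truth


def generate_gene_annotation(
    n_genes: int,
    frac_constrained: float = 0.2,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene annotation with a mutationally constrained subpopulation.

    Columns: ``gene_length`` (bp), ``gc_fraction`` in (0,1), ``cds_length``
    (bp, <= gene_length), ``oe_score`` (loss-of-function observed/expected,
    >= 0) and the truth flag ``constrained``. Constrained genes draw their
    o/e from a low-centred lognormal (median ~0.15) versus ~0.6 for the
    tolerant remainder, echoing the bimodality of population constraint
    scores. With ``frac_constrained=0`` the o/e distribution is unimodal.
    """
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    if not 0.0 <= frac_constrained <= 1.0:
        raise ConfigurationError("frac_constrained must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = _gene_ids(n_genes)
    elif len(gene_ids) != n_genes:
        raise ConfigurationError("gene_ids length must equal n_genes")

    gene_length = np.maximum(200, rng.lognormal(np.log(2e4), 0.8, n_genes)).round()
    gc_fraction = np.clip(rng.beta(20, 28, n_genes), 1e-3, 1 - 1e-3)
    cds_length = np.clip(
        (gene_length * rng.beta(2, 8, n_genes)).round(), 90, gene_length
    )

    n_con = round(frac_constrained * n_genes)
    constrained = np.zeros(n_genes, dtype=bool)
    constrained[rng.choice(n_genes, size=n_con, replace=False)] = True
    oe = rng.lognormal(np.log(0.6), 0.5, n_genes)
    oe[constrained] = rng.lognormal(np.log(0.15), 0.4, n_con)

    return pd.DataFrame(
        {
            "gene_length": gene_length,
            "gc_fraction": gc_fraction,
            "cds_length": cds_length,
            "oe_score": oe,
            "constrained": constrained,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def generate_twas(
    drug_z: pd.Series | np.ndarray, rho: float, seed: int = 0
) -> pd.Series:
    """TWAS Z-score vector correlated with ``drug_z`` at target ``rho``.

    Linear-Gaussian construction on the standardized drug-Z vector:
    ``rho * std(drug_z) + sqrt(1 - rho^2) * eps``, so the population Pearson
    correlation equals ``rho`` exactly and at |rho| = 1 the output is an
    affine transform of the input.
    """
    z = np.asarray(drug_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ConfigurationError("drug_z must be finite")
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("rho must be in [-1, 1]")
    sd = z.std()
    if sd == 0:
        raise ConfigurationError("drug_z has zero variance")
    x = (z - z.mean()) / sd
    rng = np.random.default_rng(seed)
    twas = rho * x + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(z))
    index = drug_z.index if isinstance(drug_z, pd.Series) else pd.RangeIndex(len(z))
    return pd.Series(twas, index=index, name="twas_z")


def generate_sc_profiles(
    n_genes: int,
    cell_types: Sequence[str],
    enriched_sets: Mapping[str, tuple[Iterable[str], str]] | None = None,
    fold: float = 2.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    baseline_log_sd: float = 0.5,
    noise_log_sd: float = 0.3,
) -> pd.DataFrame:
    """Cell-type average-expression profile with spiked enriched gene sets.

    ``enriched_sets`` maps a gene-set name to ``(gene_ids, target cell
    type)``; members get a multiplicative ``fold`` bump in their target
    column. Baseline expression is a gene-level lognormal shared across
    columns with per-cell-type lognormal noise, so columns are exchangeable
    when nothing is enriched. The default baseline spread (log-sd 0.5) is
    moderate by design: the one-sample enrichment Z carries an intrinsic
    negative bias of order skewness/(2*sqrt(n_set)) on right-skewed
    profiles, so heavier tails (real profiles can reach log-sd > 1) degrade
    its null calibration; both scales are exposed so tests can probe that
    regime explicitly.
    """
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    if fold <= 1.0:
        raise ConfigurationError("fold must be > 1 (no enrichment expressible)")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = _gene_ids(n_genes)
    gene_index = pd.Index(gene_ids, name="gene_id")

    base = rng.lognormal(np.log(5.0), baseline_log_sd, n_genes)
    noise = rng.lognormal(0.0, noise_log_sd, (n_genes, len(cell_types)))
    values = base[:, None] * noise

    profile = pd.DataFrame(values, index=gene_index, columns=list(cell_types))
    if enriched_sets:
        for name, (members, target) in enriched_sets.items():
            members = list(members)
            present = profile.index.intersection(members)
            if len(present) == 0:
                raise ConfigurationError(
                    f"enriched set {name!r} has no genes in the profile"
                )
            if target not in profile.columns:
                raise ConfigurationError(
                    f"enriched set {name!r} targets unknown cell type {target!r}"
                )
            profile.loc[present, target] *= fold
    return profile
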