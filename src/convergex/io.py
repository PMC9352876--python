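"""Plain-text readers/writers for the pipeline's tables.

Everything is tab-separated text: the abundance matrix (genes x samples)
with a sample-metadata sidecar, gene annotation, DE/convergence/TWAS result
tables, and cell-type profiles either as TSV or MatrixMarket triplets with
row/column label sidecars. Gene sets use GMT (see sc_enrichment).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .diffexpr import ExperimentMatrix

__all__ = [
    "write_experiment",
    "read_experiment",
    "write_table",
    "read_table",
    "write_profile_mtx",
    "read_profile_mtx",
]


def write_experiment(matrix: ExperimentMatrix, out_dir: str | Path) -> None:
    """Write abundance.tsv (genes x samples) and sample_meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.abundance.to_csv(out / "abundance.tsv", sep="\t", index_label="gene_id")
    matrix.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t", index_label="sample_id")


def read_experiment(in_dir: str | Path) -> ExperimentMatrix:
    """Read an experiment written by :func:`write_experiment`."""
    src = Path(in_dir)
    abundance = pd.read_csv(src / "abundance.tsv", sep="\t", index_col="gene_id")
    meta = pd.read_csv(src / "sample_meta.tsv", sep="\t", index_col="sample_id")
    return ExperimentMatrix(abundance=abundance, sample_meta=meta)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV."""
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a TSV result table."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_profile_mtx(profile: pd.DataFrame, out_dir: str | Path) -> None:
    """Cell-type profile as MatrixMarket + gene/cell-type label sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "profile.mtx", csr_matrix(profile.to_numpy()))
    (out / "genes.txt").write_text("\n".join(profile.index) + "\n")
    (out / "cell_types.txt").write_text("\n".join(profile.columns) + "\n")


def read_profile_mtx(in_dir: str | Path) -> pd.DataFrame:
    """Read a profile written by :func:`write_profile_mtx`."""
    src = Path(in_dir)
    mat = mmread(src / "profile.mtx").toarray()
    genes = (src / "genes.txt").read_text().splitlines()
    cts = (src / "cell_types.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=cts)
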