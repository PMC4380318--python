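"""Readers and writers for the package's table formats.

All tables are comma-separated UTF-8 text with a mandatory header row
and '.' decimal separator.  Descriptor tables carry one row per grain
or per accession with an ``id`` column followed by the 4N-3 coefficient
columns a2..aN, b2..bN, c2..cN, d1..dN, mirroring the layout of public
varietal-average EFD datasets; genotype tables are accessions x markers
with the accession id in the first column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .efd import ShapeVector
from .evaluation import CVReport
from .models import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "descriptor_columns",
    "infer_harmonics",
    "read_genotypes",
    "write_genotypes",
    "read_descriptors",
    "write_descriptors",
    "read_contour",
    "write_contour",
    "load_dataset",
    "write_cv_report",
    "read_cv_summary",
]


def descriptor_columns(N: int) -> list[str]:
    """Column names of the 4N-3 shape-vector layout."""
    return (
        [f"a{n}" for n in range(2, N + 1)]
        + [f"b{n}" for n in range(2, N + 1)]
        + [f"c{n}" for n in range(2, N + 1)]
        + [f"d{n}" for n in range(1, N + 1)]
    )


def infer_harmonics(n_columns: int) -> int:
    """Harmonic count N from a descriptor column count of the form 4N-3."""
    if n_columns < 5 or (n_columns + 3) % 4 != 0:
        raise ValueError(
            f"descriptor table has {n_columns} coefficient columns, which is not "
            f"of the form 4N-3 for an integer N >= 2"
        )
    return (n_columns + 3) // 4


@dataclass
class Dataset:
    """Aligned genotype and averaged-descriptor tables of one collection."""

    genotypes: GenotypeMatrix
    shape_values: np.ndarray  # accessions x (4N-3)
    accession_ids: list[str]
    N: int
    per_grain: dict[str, np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape_values = np.asarray(self.shape_values, dtype=float)
        if self.shape_values.shape != (len(self.accession_ids), 4 * self.N - 3):
            raise ValueError("shape table does not match accession count / N")
        if self.genotypes.accession_ids != self.accession_ids:
            raise ValueError("genotype and shape accession ids are not aligned")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def shape_vector(self, i: int) -> ShapeVector:
        return ShapeVector(values=self.shape_values[i], N=self.N)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    scores = df.to_numpy(dtype=float)
    if np.isnan(scores).any():
        n_missing = int(np.isnan(scores).sum())
        logger.warning("%d missing genotype scores mean-imputed on load", n_missing)
        from .models import mean_impute

        scores = mean_impute(scores)
    return GenotypeMatrix(scores, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_genotypes(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.scores, index=G.accession_ids, columns=G.marker_ids)
    df.index.name = "id"
    df.to_csv(path)


def read_descriptors(path, column_map: dict[str, str] | None = None):
    """Read a descriptor table; returns (ids, values, N).

    ``column_map`` renames non-canonical column headers (e.g. from an
    external export) onto the canonical a2..dN names before validation.
    """
    df = pd.read_csv(path, index_col=0)
    if column_map:
        df = df.rename(columns=column_map)
    N = infer_harmonics(df.shape[1])
    expected = descriptor_columns(N)
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(
                f"descriptor table lacks expected columns (first missing: {missing[0]})"
            )
        df = df[expected]
    return [str(i) for i in df.index], df.to_numpy(dtype=float), N


def write_descriptors(ids, values: np.ndarray, path, N: int | None = None) -> None:
    values = np.asarray(values, dtype=float)
    if N is None:
        N = infer_harmonics(values.shape[1])
    df = pd.DataFrame(values, index=list(ids), columns=descriptor_columns(N))
    df.index.name = "id"
    df.to_csv(path)


def read_contour(path):
    from .efd import ContourSequence

    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError("contour table needs 'x' and 'y' columns")
    return ContourSequence(df[["x", "y"]].to_numpy(dtype=float))


def write_contour(contour, path) -> None:
    pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(path, index=False)


def load_dataset(
    genotype_path, descriptor_path, column_map: dict[str, str] | None = None
) -> Dataset:
    """Load and inner-join a genotype table and an averaged-descriptor table.

    Accessions present in only one of the two tables are dropped with a
    log message; fewer than two shared accessions is an error.
    """
    G = read_genotypes(genotype_path)
    ids, values, N = read_descriptors(descriptor_path, column_map=column_map)
    shape_index = {a: i for i, a in enumerate(ids)}
    shared = [a for a in G.accession_ids if a in shape_index]
    dropped = (set(G.accession_ids) | set(ids)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d accessions absent from one of the tables: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    if len(shared) < 2:
        raise ValueError("fewer than 2 accessions shared between the two tables")
    g_index = {a: i for i, a in enumerate(G.accession_ids)}
    g_rows = np.array([g_index[a] for a in shared])
    s_rows = np.array([shape_index[a] for a in shared])
    Gs = GenotypeMatrix(G.scores[g_rows], shared, G.marker_ids)
    return Dataset(
        genotypes=Gs,
        shape_values=values[s_rows],
        accession_ids=shared,
        N=N,
        metadata={
            "genotype_path": str(genotype_path),
            "descriptor_path": str(descriptor_path),
            "n_dropped": len(dropped),
        },
    )


def write_cv_report(report: CVReport, out_dir, prefix: str | None = None) -> Path:
    """Serialize a CVReport: per-accession error CSV + JSON summary.

    Returns the path of the summary file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"{report.method}_{report.scheme}"
    errors = pd.DataFrame(
        {"id": report.accession_ids, "squared_shape_error": report.per_accession_errors}
    )
    errors.to_csv(out_dir / f"{prefix}_errors.csv", index=False)
    summary = {
        "method": report.method,
        "scheme": report.scheme,
        "seed": report.seed,
        "n_accessions": len(report.accession_ids),
        "n_folds": report.n_folds,
        "press": report.press_value,
        "q2": report.q2,
        "per_rep_q2": report.per_rep_q2,
        "per_rep_press": report.per_rep_press,
    }
    path = out_dir / f"{prefix}_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    return path


def read_cv_summary(path) -> dict:
    return json.loads(Path(path).read_text())
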