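"""Core data containers and text-format I/O.

The canonical in-memory orientation is spots x genes: ``counts[i, g]`` is the
UMI count for gene ``g`` at spot ``i``.  Readers accept MatrixMarket sparse
triplets (with ``features.tsv``/``barcodes.tsv`` sidecars, CellRanger-style
genes x spots orientation) or dense TSV, and align coordinates to counts by
spot identifier rather than by row position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("spotweight")

__all__ = [
    "CountsDataset",
    "RankTable",
    "FormatError",
    "AlignmentError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "rank_from_statistic",
    "read_rank_table",
    "write_rank_table",
    "read_weights",
    "write_weights",
    "read_coords",
    "write_coords",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class AlignmentError(ValueError):
    """Identifiers in two files that must correspond do not."""


class ValidationError(ValueError):
    """Data violates a container invariant."""


@dataclass
class CountsDataset:
    """A spot-by-gene UMI count matrix with spot coordinates.

    Attributes
    ----------
    counts
        Integer array of shape ``(n_spots, n_genes)``; non-negative.
    coords
        Float array of shape ``(n_spots, 2)`` of planar spot locations,
        row-aligned with ``counts``.
    gene_ids, spot_ids
        Identifier lists; ``spot_ids`` must be unique.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, G = self.counts.shape
        if n < 2:
            raise ValidationError(f"need at least 2 spots, got {n}")
        if G < 1:
            raise ValidationError("need at least 1 gene")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_float)):
                raise ValidationError("counts contain non-finite entries")
            if np.any(as_float != np.round(as_float)):
                raise ValidationError("counts must be integers")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.coords.shape != (n, 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coords contain non-finite entries")
        if len(self.gene_ids) != G:
            raise ValidationError("gene_ids length does not match counts")
        if len(self.spot_ids) != n:
            raise ValidationError("spot_ids length does not match counts")
        if len(set(self.spot_ids)) != n:
            raise ValidationError("duplicated spot_ids")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "CountsDataset":
        """Return a new dataset restricted to genes where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_genes,):
            raise ValidationError("gene mask has wrong length")
        return CountsDataset(
            counts=self.counts[:, keep],
            coords=self.coords.copy(),
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            spot_ids=list(self.spot_ids),
        )


@dataclass
class RankTable:
    """Per-gene scores and 1-based ranks (rank 1 = strongest spatial signal)."""

    gene_ids: list[str]
    statistic: np.ndarray
    rank: np.ndarray
    pvalue: np.ndarray | None = None
    method_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.rank = np.asarray(self.rank, dtype=np.int64)
        G = len(self.gene_ids)
        if G < 1:
            raise ValidationError("rank table needs at least one gene")
        if self.statistic.shape != (G,) or self.rank.shape != (G,):
            raise ValidationError("statistic/rank length mismatch")
        if sorted(self.rank.tolist()) != list(range(1, G + 1)):
            raise ValidationError("rank must be a permutation of 1..G")
        if self.pvalue is not None:
            self.pvalue = np.asarray(self.pvalue, dtype=float)
            if self.pvalue.shape != (G,):
                raise ValidationError("pvalue length mismatch")
            finite = self.pvalue[np.isfinite(self.pvalue)]
            if np.any((finite < 0) | (finite > 1)):
                raise ValidationError("pvalues must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def rank_from_statistic(statistic: np.ndarray) -> np.ndarray:
    """1-based ranks, largest statistic first, ties broken by first occurrence."""
    statistic = np.asarray(statistic, dtype=float)
    order = np.argsort(-statistic, kind="stable")
    ranks = np.empty(len(statistic), dtype=np.int64)
    ranks[order] = np.arange(1, len(statistic) + 1)
    return ranks


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

def _read_id_column(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing sidecar file for {what}: {path}")
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    if not ids:
        raise FormatError(f"{path} is empty")
    return ids


def _read_counts_mtx(counts_path: Path, transpose: bool):
    try:
        mat = scipy.io.mmread(counts_path)
    except Exception as exc:  # pragma: no cover - message depends on scipy
        raise FormatError(f"could not parse MatrixMarket file {counts_path}: {exc}")
    mat = scipy.sparse.coo_matrix(mat).toarray()
    parent = counts_path.parent
    feat_path = parent / "features.tsv"
    if not feat_path.exists():
        feat_path = parent / "genes.tsv"
    gene_ids = _read_id_column(feat_path, "gene ids")
    spot_ids = _read_id_column(parent / "barcodes.tsv", "spot barcodes")
    # CellRanger convention: rows are features, columns are barcodes
    if not transpose:
        mat = mat.T
    return mat, gene_ids, spot_ids


def _read_counts_tsv(counts_path: Path, transpose: bool):
    try:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse TSV file {counts_path}: {exc}")
    if df.shape[1] < 1:
        raise FormatError(f"{counts_path} has no data columns")
    if transpose:
        df = df.T
    return df.to_numpy(), [str(c) for c in df.columns], [str(i) for i in df.index]


def read_coords(coords_path: Path | str) -> pd.DataFrame:
    """Read a spot coordinate table with columns ``spot_id,x,y``."""
    coords_path = Path(coords_path)
    try:
        df = pd.read_csv(coords_path)
    except Exception as exc:
        raise FormatError(f"could not parse coords CSV {coords_path}: {exc}")
    missing = {"spot_id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(
            f"coords file {coords_path} lacks column(s) {sorted(missing)}"
        )
    df["spot_id"] = df["spot_id"].astype(str)
    if df["spot_id"].duplicated().any():
        dup = df["spot_id"][df["spot_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicated spot_id in {coords_path}: {dup!r}")
    return df


def read_counts(
    counts_path: Path | str,
    coords_path: Path | str,
    transpose: bool = False,
) -> CountsDataset:
    """Read counts (MatrixMarket or dense TSV) plus a coordinate CSV.

    Coordinate rows are aligned to the counts matrix by ``spot_id``; spots
    present in the counts but absent from the coordinates raise
    :class:`AlignmentError`.

    Parameters
    ----------
    transpose
        For ``.mtx`` input, set when the file is already spots x genes
        (default assumes the CellRanger genes x spots layout).  For TSV
        input, set when rows are genes rather than spots.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat, gene_ids, spot_ids = _read_counts_mtx(counts_path, transpose)
    else:
        mat, gene_ids, spot_ids = _read_counts_tsv(counts_path, transpose)

    cdf = read_coords(coords_path).set_index("spot_id")
    missing = [s for s in spot_ids if s not in cdf.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} spot id(s) in counts are absent from coords "
            f"(first: {missing[0]!r})"
        )
    coords = cdf.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)
    ds = CountsDataset(mat, coords, gene_ids, spot_ids)
    logger.info("read %d spots x %d genes from %s", ds.n_spots, ds.n_genes, counts_path)
    return ds


def write_counts(data: CountsDataset, out_prefix: Path | str) -> dict[str, Path]:
    """Write a dataset as ``counts.mtx`` + sidecars + ``coords.csv``.

    The MatrixMarket file uses the genes x spots orientation so that it
    round-trips through :func:`read_counts` with default options.
    """
    out = Path(out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "coords": out / "coords.csv",
    }
    sp = scipy.sparse.csr_matrix(data.counts.T)
    scipy.io.mmwrite(paths["counts"], sp, field="integer")
    paths["features"].write_text("\n".join(data.gene_ids) + "\n", encoding="utf-8")
    paths["barcodes"].write_text("\n".join(data.spot_ids) + "\n", encoding="utf-8")
    write_coords(data, paths["coords"])
    return paths


def write_coords(data: CountsDataset, path: Path | str) -> None:
    df = pd.DataFrame(
        {"spot_id": data.spot_ids, "x": data.coords[:, 0], "y": data.coords[:, 1]}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rank table I/O
# ---------------------------------------------------------------------------

def write_rank_table(table: RankTable, path: Path | str) -> None:
    """Write a rank table as TSV (columns gene_id, statistic, pvalue, rank)."""
    df = pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "statistic": table.statistic,
            "pvalue": table.pvalue if table.pvalue is not None else np.nan,
            "rank": table.rank,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        if table.method_label:
            fh.write(f"# method: {table.method_label}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_rank_table(path: Path | str) -> RankTable:
    method_label = ""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# method: "):
            method_label = first[len("# method: "):].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    for col in ("gene_id", "statistic", "rank"):
        if col not in df.columns:
            raise FormatError(f"rank table {path} lacks column {col!r}")
    pvals = df["pvalue"].to_numpy(dtype=float) if "pvalue" in df.columns else None
    if pvals is not None and np.all(np.isnan(pvals)):
        pvals = None
    return RankTable(
        gene_ids=[str(g) for g in df["gene_id"]],
        statistic=df["statistic"].to_numpy(dtype=float),
        rank=df["rank"].to_numpy(dtype=np.int64),
        pvalue=pvals,
        method_label=method_label,
    )


# ---------------------------------------------------------------------------
# weights I/O
# ---------------------------------------------------------------------------

def _validate_weights(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("weights must be a 2-D matrix")
    if not np.all(np.isfinite(values)):
        raise ValidationError("weights contain non-finite entries")
    if np.any(values <= 0):
        raise ValidationError("weights must be strictly positive")
    return values


def write_weights(values: np.ndarray, path: Path | str) -> None:
    """Write an n_spots x n_genes positive weight matrix (.mtx array or TSV)."""
    values = _validate_weights(values)
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, values, precision=17)
    else:
        pd.DataFrame(values).to_csv(path, sep="\t", header=False, index=False,
                                    float_format="%.17g")


def read_weights(path: Path | str) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".mtx":
        values = np.asarray(scipy.io.mmread(path))
        if scipy.sparse.issparse(values):  # pragma: no cover
            values = values.toarray()
    else:
        values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return _validate_weights(values)
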