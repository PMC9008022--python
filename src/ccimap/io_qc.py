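"""Expression-matrix IO, quality-control filtering and normalization.

Readers accept 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv, plain or gzipped) and dense TSV/CSV tables.
Gene sets travel as GMT.  All matrices are held dense in memory; the
package targets desk-scale cohorts (thousands of cells), not atlases.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

logger = logging.getLogger(__name__)

Layer = Literal["raw_counts", "lognorm", "external_normalized"]


class MatrixFormatError(ValueError):
    """Malformed input matrix (bad header, dimension mismatch, duplicates)."""


class EmptyFilterError(ValueError):
    """QC filtering removed every observation or every gene."""


class GMTFormatError(ValueError):
    """Malformed GMT line (fewer than 3 fields or empty gene list)."""


@dataclass
class ExpressionMatrix:
    """Genes-by-observations expression values plus identifiers.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_obs)`` float array.  Nonnegative when
        ``layer == "raw_counts"``.
    gene_ids, obs_ids
        Unique row / column identifiers.
    layer
        ``raw_counts`` for integer UMI-style counts, ``lognorm`` for
        library-size-scaled log1p values, ``external_normalized`` for
        matrices normalized upstream (bulk TPM, microarray).
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    layer: Layer = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise MatrixFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        for name, ids in (("gene", self.gene_ids), ("observation", self.obs_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise MatrixFormatError(f"duplicate {name} identifiers: {dupes[:5]}")
        if self.layer == "raw_counts" and (self.values < 0).any():
            raise MatrixFormatError("raw_counts layer contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        """Uppercased gene id -> row index (case-insensitive matching)."""
        return {g.upper(): i for i, g in enumerate(self.gene_ids)}

    def subset(self, gene_mask: np.ndarray | None = None, obs_mask: np.ndarray | None = None) -> "ExpressionMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        om = np.ones(self.n_obs, bool) if obs_mask is None else np.asarray(obs_mask, bool)
        return ExpressionMatrix(
            self.values[np.ix_(gm, om)],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [o for o, k in zip(self.obs_ids, om) if k],
            layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)


@dataclass
class SignatureSet:
    """A named, duplicate-free gene list."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise GMTFormatError(f"signature {self.name!r} has an empty gene list")
        if len(set(g.upper() for g in self.genes)) != len(self.genes):
            raise GMTFormatError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_companion(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {list(stems)} found in {directory}")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_matrix(
    path: str | os.PathLike,
    format: Literal["mtx_triplet", "dense_table"] = "mtx_triplet",
    *,
    layer: Layer | None = None,
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``mtx_triplet`` expects ``path`` to be the ``.mtx`` file (or a directory
    containing ``matrix.mtx``) with companion ``features.tsv``/``genes.tsv``
    and ``barcodes.tsv`` next to it; the result is ``raw_counts``.
    ``dense_table`` reads a TSV/CSV with a header row of observation ids and
    gene ids in the first column; the result defaults to
    ``external_normalized``.  ``layer`` overrides the default tag.

    Raises
    ------
    MatrixFormatError
        On malformed headers, dimension mismatches between the triplet
        header and companion tables, or duplicate identifiers.
    """
    path = Path(path)
    if format == "mtx_triplet":
        if path.is_dir():
            mtx_path = _find_companion(path, ["matrix.mtx"])
        else:
            mtx_path = path
        if not mtx_path.exists():
            raise FileNotFoundError(mtx_path)
        directory = mtx_path.parent
        features_path = _find_companion(directory, ["features.tsv", "genes.tsv"])
        barcodes_path = _find_companion(directory, ["barcodes.tsv"])
        try:
            if str(mtx_path).endswith(".gz"):
                with _open_maybe_gz(mtx_path) as fh:
                    mat = scipy_io.mmread(fh)
            else:
                mat = scipy_io.mmread(str(mtx_path))
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise MatrixFormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
        mat = sparse.coo_matrix(mat)
        gene_ids = _read_id_column(features_path)
        obs_ids = _read_id_column(barcodes_path)
        if mat.shape != (len(gene_ids), len(obs_ids)):
            raise MatrixFormatError(
                f"triplet header declares {mat.shape} but companions list "
                f"{len(gene_ids)} features and {len(obs_ids)} barcodes"
            )
        return ExpressionMatrix(mat.toarray(), gene_ids, obs_ids, layer=layer or "raw_counts")

    if format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not genes_in_rows:
            df = df.T
        if df.index.duplicated().any():
            raise MatrixFormatError(
                f"duplicate gene identifiers: {sorted(df.index[df.index.duplicated()].unique())[:5]}"
            )
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            layer=layer or "external_normalized",
        )

    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike, format: Literal["mtx_triplet", "dense_table"] = "dense_table") -> None:
    """Write a matrix as a dense TSV or a 10x-style MTX triplet directory."""
    path = Path(path)
    if format == "dense_table":
        m.to_frame().to_csv(path, sep="\t")
        return
    path.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(m.values)
    with open(path / "matrix.mtx", "wb") as fh:
        scipy_io.mmwrite(fh, coo)
    (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (path / "barcodes.tsv").write_text("".join(f"{o}\n" for o in m.obs_ids))


def qc_filter(
    m: ExpressionMatrix,
    min_genes: int = 200,
    max_genes: int = 7500,
    max_mito_frac: float = 0.20,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Remove poor-quality cells, then poor-quality genes, from raw counts.

    A cell is removed when its detected-gene count (entries > 0) is strictly
    below ``min_genes`` or strictly above ``max_genes``, or when its
    mitochondrial count fraction strictly exceeds ``max_mito_frac``
    (mitochondrial genes are those whose id starts with ``mito_prefix``,
    case-insensitive).  A gene is then removed when detected in fewer than
    ``min_cells_per_gene`` surviving cells.  Bounds are strict, so cells at
    exactly 200 or 7500 detected genes survive.  Row/column order is
    preserved.
    """
    if m.layer != "raw_counts":
        raise ValueError(f"qc_filter requires raw counts, got layer={m.layer!r}")
    detected = m.values > 0
    genes_per_cell = detected.sum(axis=0)
    prefix = mito_prefix.upper()
    mito_mask = np.array([g.upper().startswith(prefix) for g in m.gene_ids])
    totals = m.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.values[mito_mask].sum(axis=0) / np.maximum(totals, 1e-300), 0.0)
    keep_obs = (genes_per_cell >= min_genes) & (genes_per_cell <= max_genes) & (mito_frac <= max_mito_frac)
    if not keep_obs.any():
        raise EmptyFilterError("no observation survives the cell-level QC filters")
    cells_per_gene = detected[:, keep_obs].sum(axis=1)
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise EmptyFilterError("no gene survives the gene-level QC filter")
    n_obs_dropped = int((~keep_obs).sum())
    n_gene_dropped = int((~keep_genes).sum())
    if n_obs_dropped or n_gene_dropped:
        logger.info("qc_filter removed %d observations and %d genes", n_obs_dropped, n_gene_dropped)
    return m.subset(keep_genes, keep_obs)


def lognormalize(m: ExpressionMatrix, scale_total: float = 1e4, base: Literal["e", "2"] = "e") -> ExpressionMatrix:
    """Scale each observation to ``scale_total`` total counts, then log1p.

    Natural log by default; ``base="2"`` gives log2(x+1) for bulk use.
    """
    if m.layer != "raw_counts":
        raise ValueError(f"lognormalize requires raw counts, got layer={m.layer!r}")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        bad = [o for o, t in zip(m.obs_ids, totals) if t <= 0]
        raise ValueError(f"zero-count observations: {bad[:5]}")
    scaled = m.values * (scale_total / totals)
    out = np.log1p(scaled)
    if base == "2":
        out = out / np.log(2.0)
    return ExpressionMatrix(out, list(m.gene_ids), list(m.obs_ids), layer="lognorm")


def read_gmt(path: str | os.PathLike) -> list[SignatureSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[SignatureSet] = []
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise GMTFormatError(f"{path}:{lineno}: gene list for {name!r} is empty")
            sets.append(SignatureSet(name=name, genes=genes, description=desc))
    return sets


def write_gmt(sets: Iterable[SignatureSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def match_signature_genes(m: ExpressionMatrix, s: SignatureSet, min_match_frac: float = 0.5) -> np.ndarray:
    """Row indices of signature genes found in the matrix (case-insensitive).

    Unmatched genes are logged and dropped; if fewer than ``min_match_frac``
    of the set matches, a ValueError is raised.
    """
    index = m.gene_index()
    rows, missing = [], []
    for g in s.genes:
        i = index.get(g.upper())
        (rows if i is not None else missing).append(i if i is not None else g)
    if missing:
        logger.warning("signature %s: %d/%d genes not in matrix (e.g. %s)", s.name, len(missing), len(s), missing[:3])
    if len(rows) < min_match_frac * len(s.genes):
        raise ValueError(
            f"signature {s.name!r}: only {len(rows)}/{len(s.genes)} genes matched (< {min_match_frac:.0%})"
        )
    if not rows:
        raise ValueError(f"signature {s.name!r}: no gene matched the matrix")
    return np.array(rows, dtype=int)


# --- observation metadata -------------------------------------------------

METADATA_COLUMNS = ["obs_id", "sample_id", "group", "subtype", "stage"]
VALID_GROUPS = {"normal_SE", "malignant_SE", "other"}
VALID_SUBTYPES = {"BS", "BK", "DK", "unknown"}
VALID_STAGES = {"I", "II_III"}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation-metadata table.

    Requires unique ``obs_id``, known ``group`` levels, and subtype set only
    for ``normal_SE`` observations.  Returns the frame indexed by obs_id.
    """
    missing = [c for c in ("obs_id", "group") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["obs_id"].duplicated().any():
        raise ValueError("metadata contains duplicate obs_id rows")
    bad_groups = set(meta["group"].unique()) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if "subtype" in meta.columns:
        typed = meta["subtype"].notna()
        offender = typed & (meta["group"] != "normal_SE")
        if offender.any():
            raise ValueError("subtype may be set only for normal_SE observations")
        bad = set(meta.loc[typed, "subtype"].unique()) - VALID_SUBTYPES
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
    if "stage" in meta.columns:
        staged = meta["stage"].notna()
        bad = set(meta.loc[staged, "stage"].unique()) - VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return meta.set_index("obs_id", drop=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)
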