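"""Dataset container, standard-format IO, named-fixture registry and splitting.

The central type is :class:`SCDataset`: a cells x genes expression matrix with
per-cell and per-gene annotation tables, named layers (``"raw"`` always holds
the integer counts) and an append-only log of every transform applied to it.
Cells are rows and genes are columns everywhere in this package; the 10x-style
Matrix Market triplet on disk is genes x cells and is transposed on load.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when data violates a dataset invariant."""


def _densify(M):
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def _check_matrix(M, name: str):
    A = _densify(M)
    if not np.all(np.isfinite(A)):
        raise ValidationError(f"{name} contains non-finite entries")
    if A.size and A.min() < 0:
        raise ValidationError(f"{name} contains negative entries")


@dataclass
class SCDataset:
    """Cells x genes expression matrix with annotations and a transform log.

    Parameters
    ----------
    X
        Dense or sparse non-negative matrix, cells as rows.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    layers
        Named matrices of identical shape. ``"raw"`` is reserved for the
        original integer counts, ``"normalized"`` for library-size normalized
        values.
    cell_table, gene_table
        Per-cell / per-gene records (``cell_type``, ``batch``, ``split``,
        ``x_coord``/``y_coord`` for spots).
    log
        Append-only list of ``(transform name, parameter dict)`` tuples.
    """

    X: object
    cell_ids: list
    gene_ids: list
    layers: dict = field(default_factory=dict)
    cell_table: pd.DataFrame = None
    gene_table: pd.DataFrame = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.cell_table is None:
            self.cell_table = pd.DataFrame(index=self.cell_ids)
        if self.gene_table is None:
            self.gene_table = pd.DataFrame(index=self.gene_ids)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self):
        n, g = self.shape
        if len(self.cell_ids) != n:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell ids not unique")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene ids not unique")
        _check_matrix(self.X, "X")
        for name, L in self.layers.items():
            if L.shape != self.shape:
                raise ValidationError(f"layer {name!r} shape {L.shape} != {self.shape}")
            _check_matrix(L, f"layer {name!r}")
        if "raw" in self.layers:
            raw = _densify(self.layers["raw"])
            if raw.size and not np.allclose(raw, np.round(raw)):
                raise ValidationError("layer 'raw' must contain integers")

    @property
    def shape(self):
        return self.X.shape

    @property
    def n_cells(self):
        return self.X.shape[0]

    @property
    def n_genes(self):
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        return _densify(self.X)

    def layer_dense(self, name: str) -> np.ndarray:
        return _densify(self.layers[name])

    def raw(self) -> np.ndarray:
        """Raw counts: layer 'raw' if present, else X."""
        return self.layer_dense("raw") if "raw" in self.layers else self.dense()

    def copy(self) -> "SCDataset":
        return SCDataset(
            X=self.X.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            layers={k: v.copy() for k, v in self.layers.items()},
            cell_table=self.cell_table.copy(),
            gene_table=self.gene_table.copy(),
            log=list(self.log),
        )

    def with_log(self, name: str, **params) -> "SCDataset":
        self.log.append((name, dict(params)))
        return self

    def subset(self, cell_idx=None, gene_idx=None) -> "SCDataset":
        """New dataset restricted to the given positional indices."""
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        X = self.X[ci][:, gi]
        layers = {k: v[ci][:, gi] for k, v in self.layers.items()}
        return SCDataset(
            X=X,
            cell_ids=[self.cell_ids[i] for i in ci],
            gene_ids=[self.gene_ids[j] for j in gi],
            layers=layers,
            cell_table=self.cell_table.iloc[ci].copy(),
            gene_table=self.gene_table.iloc[gi].copy(),
            log=list(self.log),
        )


@dataclass
class MaskedDataset:
    """A dataset with simulated dropouts for imputation benchmarking.

    ``mask`` is true exactly at the positions whose original positive raw
    value was zeroed out; ``held_out`` maps (cell, gene) index pairs to those
    original values.  The working matrix in ``base`` never contains them.
    """

    base: SCDataset
    mask: np.ndarray
    held_out: dict

    def __post_init__(self):
        raw = self.base.raw()
        if raw[self.mask].any():
            raise ValidationError("masked positions must be zero in the working matrix")
        keys = set(zip(*np.nonzero(self.mask)))
        if keys != set(self.held_out):
            raise ValidationError("held_out keys must equal the set of masked positions")


# -- readers / writers ---------------------------------------------------

def load_matrix_market(directory, genes_in_rows: bool = True) -> SCDataset:
    """Read a CellRanger-style triplet bundle (matrix.mtx, barcodes.tsv, features.tsv).

    The on-disk matrix is genes x cells by convention (``genes_in_rows=True``)
    and is transposed so that the returned dataset is cells x genes.
    """
    directory = Path(directory)
    for fname in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {directory}")
    M = scipy.io.mmread(str(directory / "matrix.mtx"))
    M = sp.csr_matrix(M)
    barcodes = (directory / "barcodes.tsv").read_text().split()
    features = (directory / "features.tsv").read_text().split()
    if genes_in_rows:
        M = M.T.tocsr()
    if M.shape[0] != len(barcodes):
        raise ValidationError(
            f"matrix has {M.shape[0]} cells but barcodes.tsv has {len(barcodes)} lines")
    if M.shape[1] != len(features):
        raise ValidationError(
            f"matrix has {M.shape[1]} genes but features.tsv has {len(features)} lines")
    ds = SCDataset(X=M, cell_ids=barcodes, gene_ids=features, layers={"raw": M.copy()})
    return ds.with_log("load_matrix_market", directory=str(directory))


def load_csv_matrix(path, cells_in_rows: bool = True, delimiter: str = ",") -> SCDataset:
    """Read a dense numeric CSV with id header row and id first column."""
    df = pd.read_csv(path, index_col=0, sep=delimiter)
    X = df.to_numpy(dtype=np.float64)
    if not cells_in_rows:
        df = df.T
        X = X.T
    _check_matrix(X, "X")
    layers = {}
    if np.allclose(X, np.round(X)):
        layers["raw"] = X.copy()
    ds = SCDataset(X=X, cell_ids=list(df.index), gene_ids=list(df.columns), layers=layers)
    return ds.with_log("load_csv_matrix", path=str(path), cells_in_rows=cells_in_rows)


def write_bundle(ds: SCDataset, directory) -> Path:
    """Write a dataset as matrix.mtx + barcodes/features.tsv + cell_table.tsv + meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    M = sp.coo_matrix(ds.X).T  # genes x cells on disk, 10x convention
    scipy.io.mmwrite(str(directory / "matrix.mtx"), M)
    (directory / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    (directory / "features.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    ds.cell_table.to_csv(directory / "cell_table.tsv", sep="\t")
    ds.gene_table.to_csv(directory / "gene_table.tsv", sep="\t")
    meta = {"log": [[n, p] for n, p in ds.log], "layers": sorted(ds.layers)}
    for name in ds.layers:
        scipy.io.mmwrite(str(directory / f"layer_{name}.mtx"), sp.coo_matrix(ds.layers[name]).T)
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_bundle(directory) -> SCDataset:
    """Inverse of :func:`write_bundle` (exact for integer data, 1e-12 for floats)."""
    directory = Path(directory)
    if not (directory / "meta.json").exists():
        raise FileNotFoundError(f"{directory} is not a dataset bundle (no meta.json)")
    ds = load_matrix_market(directory)
    meta = json.loads((directory / "meta.json").read_text())
    ds.layers = {}
    for name in meta["layers"]:
        L = sp.csr_matrix(scipy.io.mmread(str(directory / f"layer_{name}.mtx"))).T.tocsr()
        ds.layers[name] = L
    for attr, fname in (("cell_table", "cell_table.tsv"), ("gene_table", "gene_table.tsv")):
        p = directory / fname
        if p.exists():
            tbl = pd.read_csv(p, sep="\t", index_col=0)
            tbl.index = tbl.index.astype(str)
            setattr(ds, attr, tbl)
    ds.log = [(n, p) for n, p in meta["log"]]
    ds.validate()
    return ds


# -- fixture registry ----------------------------------------------------

_REGISTRY: dict = {}
_MEMO: dict = {}


def register_dataset(name: str, factory):
    """Register a zero-argument factory returning an SCDataset."""
    _REGISTRY[name] = factory


def list_datasets() -> list:
    _ensure_builtin()
    return sorted(_REGISTRY)


def _cache_dir() -> Path:
    return Path(os.environ.get("SCBENCH_CACHE", Path.home() / ".cache" / "scbench"))


def _ensure_builtin():
    if "synth_blobs4" in _REGISTRY:
        return
    from . import synthetic  # deferred to avoid an import cycle

    register_dataset("synth_blobs4", synthetic.blobs4_fixture)
    register_dataset("synth_hard4", synthetic.hard4_fixture)
    register_dataset("synth_mix4", synthetic.mix4_spots_fixture)
    register_dataset("synth_mix4_ref", synthetic.mix4_reference_fixture)


def get_dataset(name: str) -> SCDataset:
    """Fetch a named fixture; deterministic (fixtures embed their seed).

    Generated fixtures are cached on disk on first use; the cache is an
    optimization only and results are identical without it.
    """
    _ensure_builtin()
    if name not in _REGISTRY:
        raise KeyError(f"unknown dataset {name!r}; available: {', '.join(sorted(_REGISTRY))}")
    if name in _MEMO:
        return _MEMO[name].copy()
    cache = _cache_dir() / name
    ds = None
    if (cache / "meta.json").exists():
        try:
            ds = read_bundle(cache)
        except Exception:
            ds = None
    if ds is None:
        ds = _REGISTRY[name]()
        try:
            write_bundle(ds, cache)
        except OSError:
            pass
    _MEMO[name] = ds
    return ds.copy()


# -- splitting -----------------------------------------------------------

def split(ds: SCDataset, test_fraction: float, stratify_by: str = None,
          seed: int = 0):
    """Disjoint, exhaustive train/test cell partition, stratified if asked.

    Stratified splits keep per-class proportions within +-1 cell.  The split
    tag is recorded in each part's ``cell_table['split']``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if ds.n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    n = ds.n_cells
    if stratify_by is None:
        groups = [np.arange(n)]
    else:
        col = ds.cell_table[stratify_by].to_numpy()
        groups = [np.flatnonzero(col == v) for v in pd.unique(col)]
        for g in groups:
            if len(g) < 2:
                raise ValueError(
                    "a stratification class has a single member; use an unstratified split")
    test_idx = []
    for g in groups:
        g = g.copy()
        rng.shuffle(g)
        k = int(round(test_fraction * len(g)))
        k = min(max(k, 1), len(g) - 1)
        test_idx.extend(g[:k])
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    train = ds.subset(cell_idx=train_idx)
    test = ds.subset(cell_idx=test_idx)
    train.cell_table["split"] = "train"
    test.cell_table["split"] = "test"
    train.with_log("split", part="train", test_fraction=test_fraction,
                   stratify_by=stratify_by, seed=seed)
    test.with_log("split", part="test", test_fraction=test_fraction,
                  stratify_by=stratify_by, seed=seed)
    return train, test
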