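"""Core data model and preprocessing for timepoint-resolved single-cell data.

A :class:`TimeCourse` wraps a single :class:`anndata.AnnData` whose ``obs``
carries a numeric timepoint column (days) and, optionally, an anatomical
compartment label (e.g. circulating vs tissue-resident). All preprocessing
(cell/gene filters, CPM + log1p normalization, highly-variable-gene
selection, global and per-timepoint-pair local PCA) operates on this
container and records its state so that scale-sensitive operations can guard
against being run on the wrong scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from sklearn.decomposition import PCA

from ._utils import as_dense

_FLAG = "fateflow_normalized"


@dataclass
class TimeCourse:
    """Timepoint-ordered single-cell expression container.

    Parameters
    ----------
    adata
        Cells x genes. ``obs[timepoint_key]`` must be numeric days.
    timepoint_key
        Column in ``obs`` holding the timepoint (days).
    compartment_key
        Optional column in ``obs`` holding a categorical compartment label.
    """

    adata: ad.AnnData
    timepoint_key: str = "timepoint"
    compartment_key: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint_key not in self.adata.obs:
            raise KeyError(f"timepoint column {self.timepoint_key!r} absent from obs")
        tp = pd.to_numeric(self.adata.obs[self.timepoint_key], errors="coerce")
        if tp.isna().any():
            raise ValueError(f"non-numeric or missing timepoints in {self.timepoint_key!r}")
        self.adata.obs[self.timepoint_key] = tp.astype(float)
        if not self.adata.obs_names.is_unique:
            raise ValueError("cell ids are not unique")
        if _FLAG not in self.adata.uns:
            self.adata.uns[_FLAG] = False

    # -- structure ---------------------------------------------------------
    @property
    def timepoints(self) -> np.ndarray:
        """Strictly increasing array of observed days."""
        return np.unique(self.adata.obs[self.timepoint_key].to_numpy())

    @property
    def gene_index(self) -> pd.Index:
        return self.adata.var_names

    @property
    def is_normalized(self) -> bool:
        return bool(self.adata.uns.get(_FLAG, False))

    def mask(self, timepoint: float, compartment: str | None = None) -> np.ndarray:
        m = self.adata.obs[self.timepoint_key].to_numpy() == float(timepoint)
        if compartment is not None:
            if self.compartment_key is None:
                raise ValueError("TimeCourse has no compartment_key")
            m &= self.adata.obs[self.compartment_key].to_numpy() == compartment
        return m

    def snapshot(self, timepoint: float, compartment: str | None = None) -> ad.AnnData:
        """AnnData view of the cells observed at one timepoint (and compartment)."""
        m = self.mask(timepoint, compartment)
        if not m.any():
            raise ValueError(f"no cells at timepoint {timepoint} (compartment={compartment})")
        return self.adata[m]

    def copy(self) -> "TimeCourse":
        return TimeCourse(self.adata.copy(), self.timepoint_key, self.compartment_key)

    def write(self, path: str | Path) -> None:
        self.adata.write_h5ad(Path(path))


@dataclass
class EmbeddingBasis:
    """A fitted PCA basis with per-cell coordinates.

    ``kind`` is ``"global_pca"`` (all cells) or ``"local_pca"`` (cells from
    one adjacent timepoint pair only, sharing the parent HVG set).
    """

    kind: str
    n_components: int
    coords: np.ndarray
    cell_ids: pd.Index
    loadings: np.ndarray
    hvg_list: list[str] = field(default_factory=list)
    timepoint_pair: tuple[float, float] | None = None

    def coords_of(self, ids) -> np.ndarray:
        pos = self.cell_ids.get_indexer(pd.Index(ids))
        if (pos < 0).any():
            raise KeyError("some cell ids are not in this basis")
        return self.coords[pos]


# -- io --------------------------------------------------------------------

def load_timecourse(
    path: str | Path,
    timepoint_key: str = "timepoint",
    compartment_key: str | None = None,
) -> TimeCourse:
    """Load a time course from an H5AD file or an MTX directory.

    An MTX directory must contain ``matrix.mtx`` (cells x genes or its
    transpose with matching barcode count), ``barcodes.tsv``,
    ``features.tsv`` (or ``genes.tsv``) and ``metadata.csv`` indexed by
    barcode with at least the timepoint column.
    """
    path = Path(path)
    if path.is_dir():
        adata = _read_mtx_dir(path)
    elif path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
    else:
        raise ValueError(f"cannot read {path}: expected .h5ad file or MTX directory")
    return TimeCourse(adata, timepoint_key=timepoint_key, compartment_key=compartment_key)


def _read_mtx_dir(path: Path) -> ad.AnnData:
    import scipy.io

    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"{mtx} not found")
    X = sp.csr_matrix(scipy.io.mmread(mtx))
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    feat_file = path / "features.tsv"
    if not feat_file.exists():
        feat_file = path / "genes.tsv"
    genes = pd.read_csv(feat_file, header=None, sep="\t")[0].astype(str)
    if X.shape[0] != len(barcodes):
        if X.shape[1] == len(barcodes):
            X = X.T.tocsr()
        else:
            raise ValueError("matrix dimensions match neither barcodes nor features")
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes.to_numpy(), name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes.to_numpy(), name="gene")),
    )
    meta_file = path / "metadata.csv"
    if meta_file.exists():
        meta = pd.read_csv(meta_file, index_col=0)
        meta.index = meta.index.astype(str)
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ValueError(f"{len(missing)} barcodes absent from metadata.csv")
        adata.obs = meta.loc[adata.obs_names]
    return adata


# -- preprocessing ---------------------------------------------------------

def filter_cells(
    tc: TimeCourse,
    max_mito_frac: float = 0.10,
    min_counts: int = 1500,
    mito_prefix: str = "mt-",
) -> TimeCourse:
    """Remove low-quality cells.

    Keeps cells with mitochondrial fraction <= ``max_mito_frac`` and total
    counts >= ``min_counts`` (both boundaries inclusive: the removed cells
    are those with *greater than* the mito threshold or *fewer than*
    ``min_counts`` reads). Requires raw counts.
    """
    if tc.is_normalized:
        raise ValueError("filter_cells requires raw counts (data already normalized)")
    X = tc.adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    is_mito = tc.gene_index.str.lower().str.startswith(mito_prefix.lower())
    if is_mito.any():
        mito = np.asarray(X[:, np.where(is_mito)[0]].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 1.0)
    keep = (frac <= max_mito_frac) & (total >= min_counts)
    out = tc.adata[keep].copy()
    out.obs["total_counts"] = total[keep]
    out.obs["mito_frac"] = frac[keep]
    return TimeCourse(out, tc.timepoint_key, tc.compartment_key)


def filter_genes(tc: TimeCourse, min_cells: int = 2) -> TimeCourse:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells, pooled
    across all timepoints."""
    X = tc.adata.X
    if sp.issparse(X):
        ncells = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        ncells = (np.asarray(X) > 0).sum(axis=0)
    keep = ncells >= min_cells
    out = tc.adata[:, keep].copy()
    return TimeCourse(out, tc.timepoint_key, tc.compartment_key)


def normalize_log1p(tc: TimeCourse, target_sum: float = 1e6) -> TimeCourse:
    """Counts-per-``target_sum`` normalization followed by log1p.

    Errors if a cell has zero total counts (it should have been filtered) or
    if the data were already normalized.
    """
    if tc.is_normalized:
        raise ValueError("data already normalized; normalize_log1p applied twice")
    adata = tc.adata.copy()
    total = np.asarray(adata.X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError(f"{int((total <= 0).sum())} cells have zero total counts")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    adata.uns[_FLAG] = True
    return TimeCourse(adata, tc.timepoint_key, tc.compartment_key)


def select_hvg(tc: TimeCourse, n_top: int = 3000) -> list[str]:
    """Top-``n_top`` highly variable genes by normalized dispersion.

    Requires log-normalized data. Ranking is by scanpy's normalized
    dispersion (mean-binned variance stabilization) with a deterministic
    gene-id tie-break.
    """
    if not tc.is_normalized:
        raise ValueError("select_hvg requires log-normalized data")
    n_genes = tc.adata.n_vars
    if n_top >= n_genes:
        if n_top > n_genes:
            warnings.warn(f"n_top={n_top} > {n_genes} genes; returning all genes")
        return list(tc.gene_index)
    adata = tc.adata
    df = sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top, inplace=False)
    disp = pd.Series(
        np.nan_to_num(df["dispersions_norm"].to_numpy(), nan=-np.inf),
        index=tc.gene_index,
    )
    order = disp.to_frame("d").assign(g=disp.index).sort_values(["d", "g"], ascending=[False, True])
    return list(order.index[:n_top])


def fit_basis(
    tc: TimeCourse,
    kind: str = "global_pca",
    n_components: int = 30,
    hvg: list[str] | None = None,
    timepoint_pair: tuple[float, float] | None = None,
    seed: int = 0,
) -> EmbeddingBasis:
    """Fit a centered PCA basis on HVG-restricted log-normalized data.

    ``local_pca`` restricts to the cells of one adjacent timepoint pair but
    inherits the HVG set of the parent dataset. Randomized SVD with a fixed
    seed; centering only (no per-gene scaling).
    """
    if kind not in ("global_pca", "local_pca"):
        raise ValueError(f"unknown basis kind {kind!r}")
    if kind == "local_pca":
        if timepoint_pair is None:
            raise ValueError("local_pca requires a timepoint_pair")
        m = tc.mask(timepoint_pair[0]) | tc.mask(timepoint_pair[1])
        adata = tc.adata[m]
    else:
        adata = tc.adata
    if hvg is not None:
        hvg = [g for g in hvg if g in tc.gene_index]
        adata = adata[:, hvg]
    X = as_dense(adata.X)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={min(X.shape)}; "
            "use a smaller local PCA"
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(X)
    return EmbeddingBasis(
        kind=kind,
        n_components=n_components,
        coords=coords,
        cell_ids=adata.obs_names,
        loadings=pca.components_,
        hvg_list=list(hvg) if hvg is not None else [],
        timepoint_pair=timepoint_pair,
    )
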