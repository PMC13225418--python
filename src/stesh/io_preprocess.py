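"""Loading, filtering, HVG selection and normalization of spatial data.

A :class:`SpatialDataset` bundles the spot-by-gene count matrix, the spot
pixel coordinates (full-resolution, 0-based, x = image column / y = image
row), the optional H&E image and per-spot metadata.  Preprocessing follows
the standard spatial-transcriptomics recipe: drop spots outside the tissue,
drop all-zero genes, keep the top highly variable genes, and depth-normalize
each spot to a common scale of 10^4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sparse

__all__ = [
    "SpatialDataset",
    "FeatureMatrix",
    "load_dataset",
    "filter_spots",
    "select_hvg",
    "normalize_counts",
    "save_processed",
]

TARGET_SCALE = 1e4


@dataclass
class SpatialDataset:
    """Counts, coordinates and optional image for one tissue section."""

    counts: np.ndarray  # (n_spots, n_genes), nonnegative integers
    coords: np.ndarray  # (n_spots, 2) pixel positions, columns (x, y)
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    in_tissue: np.ndarray | None = None
    image: np.ndarray | None = None  # (H, W, 3) uint8
    labels: np.ndarray | None = None  # optional reference domain labels
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = _densify(self.counts)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("spot/gene identifier lengths do not match counts")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.in_tissue is not None:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if len(self.in_tissue) != n:
                raise ValueError("in_tissue length does not match counts")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match counts")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=sparse.csr_matrix(self.counts),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids.astype(str), name="spot")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.in_tissue is not None:
            adata.obs["in_tissue"] = self.in_tissue
        if self.labels is not None:
            adata.obs["domain"] = pd.Categorical(self.labels.astype(str))
        adata.uns["stesh"] = {"coordinate_system": "pixel_xy_0based", **self.meta}
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, image=None) -> "SpatialDataset":
        if "spatial" not in adata.obsm:
            raise ValueError("AnnData has no obsm['spatial'] coordinates")
        labels = None
        if "domain" in adata.obs:
            labels = adata.obs["domain"].to_numpy()
        in_tissue = None
        if "in_tissue" in adata.obs:
            in_tissue = adata.obs["in_tissue"].to_numpy(dtype=bool)
        meta = dict(adata.uns.get("stesh", {}))
        meta.pop("coordinate_system", None)
        return cls(
            counts=_densify(adata.X),
            coords=np.asarray(adata.obsm["spatial"], dtype=np.float64),
            spot_ids=adata.obs_names.to_numpy(),
            gene_ids=adata.var_names.to_numpy(),
            in_tissue=in_tissue,
            image=image,
            labels=labels,
            meta=meta,
        )


@dataclass
class FeatureMatrix:
    """Normalized expression matrix X with provenance of the normalization."""

    X: np.ndarray
    hvg_names: np.ndarray
    scale_factors: np.ndarray  # per-spot s_i
    norm_mode: str = "per_spot_total"
    log_transformed: bool = False


def _densify(x) -> np.ndarray:
    if sparse.issparse(x):
        x = x.toarray()
    return np.asarray(x)


def _read_image(image_path) -> np.ndarray:
    from PIL import Image

    img = np.asarray(Image.open(image_path).convert("RGB"))
    return img


def load_dataset(path, image_path=None) -> SpatialDataset:
    """Load a dataset from an h5ad file or a 10x-style MTX directory.

    The MTX directory must contain ``matrix.mtx``, ``barcodes.tsv``,
    ``features.tsv`` and a ``positions.csv`` with columns
    ``barcode,x,y[,in_tissue]`` (pixel units).
    """
    path = Path(path)
    image = _read_image(image_path) if image_path is not None else None
    if path.is_dir():
        ds = _load_mtx_dir(path, image)
    elif path.suffix == ".h5ad":
        ds = SpatialDataset.from_anndata(ad.read_h5ad(path), image=image)
    else:
        raise ValueError(f"unrecognized input {path}: expected .h5ad or MTX directory")
    if ds.image is not None:
        h, w = ds.image.shape[:2]
        x, y = ds.coords[:, 0], ds.coords[:, 1]
        outside = (x < 0) | (x >= w) | (y < 0) | (y >= h)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} spot coordinates fall outside the image bounds"
            )
            ds.meta["coords_outside_image"] = int(outside.sum())
    return ds


def _load_mtx_dir(path: Path, image) -> SpatialDataset:
    from scipy.io import mmread

    mtx = path / "matrix.mtx"
    barcodes = path / "barcodes.tsv"
    features = path / "features.tsv"
    positions = path / "positions.csv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise FileNotFoundError(f"missing {f.name} in {path}")
    if not positions.exists():
        raise FileNotFoundError(
            f"missing positions.csv in {path}: spot coordinates are required"
        )
    # matrix.mtx is genes x spots in 10x convention
    counts = _densify(mmread(mtx)).T
    spot_ids = pd.read_csv(barcodes, header=None, sep="\t")[0].to_numpy()
    gene_ids = pd.read_csv(features, header=None, sep="\t")[0].to_numpy()
    pos = pd.read_csv(positions)
    pos = pos.set_index("barcode")
    missing = [b for b in spot_ids if b not in pos.index]
    if missing:
        raise ValueError(
            "barcodes missing from positions.csv: " + ", ".join(map(str, missing[:10]))
        )
    pos = pos.loc[spot_ids]
    in_tissue = (
        pos["in_tissue"].to_numpy(dtype=bool) if "in_tissue" in pos.columns else None
    )
    return SpatialDataset(
        counts=counts,
        coords=pos[["x", "y"]].to_numpy(dtype=np.float64),
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        in_tissue=in_tissue,
        image=image,
    )


def filter_spots(ds: SpatialDataset) -> SpatialDataset:
    """Keep in-tissue spots, then drop genes with zero total count."""
    keep = (
        ds.in_tissue if ds.in_tissue is not None else np.ones(ds.n_spots, dtype=bool)
    )
    if not keep.any():
        raise ValueError("no spots remain after tissue filtering")
    counts = ds.counts[keep]
    gene_keep = counts.sum(axis=0) > 0
    return replace(
        ds,
        counts=counts[:, gene_keep],
        coords=ds.coords[keep],
        spot_ids=ds.spot_ids[keep],
        gene_ids=ds.gene_ids[gene_keep],
        in_tissue=np.ones(int(keep.sum()), dtype=bool),
        labels=None if ds.labels is None else ds.labels[keep],
    )


def select_hvg(ds: SpatialDataset, n_top: int = 3000) -> SpatialDataset:
    """Keep the top ``n_top`` highly variable genes.

    Ranking uses the normalized-dispersion statistic of the Cell Ranger /
    Seurat lineage (dispersion of depth-normalized counts, z-scored within
    mean-quantile bins), which is robust to the gene-mean distribution.
    Original gene order is preserved among the selected genes, and ties in
    the statistic resolve by gene order.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    if n_top > ds.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds the {ds.n_genes} available genes; keeping all"
        )
        n_top = ds.n_genes
    if n_top == ds.n_genes:
        return replace(ds)
    adata = ad.AnnData(X=sparse.csr_matrix(ds.counts.astype(np.float32)))
    sc.pp.normalize_total(adata, target_sum=TARGET_SCALE)
    sc.pp.highly_variable_genes(adata, flavor="cell_ranger", n_top_genes=n_top)
    disp = adata.var["dispersions_norm"].to_numpy()
    # deterministic ranking: dispersion descending, gene position ascending
    order = np.lexsort((np.arange(ds.n_genes), -disp))
    keep = np.zeros(ds.n_genes, dtype=bool)
    keep[order[:n_top]] = True
    return replace(ds, counts=ds.counts[:, keep], gene_ids=ds.gene_ids[keep])


def normalize_counts(
    ds: SpatialDataset,
    norm_mode: str = "per_spot_total",
    log_transform: bool = False,
) -> FeatureMatrix:
    """Depth-normalize: X_ij = count_ij / s_i * 10^4.

    ``per_spot_total`` uses s_i = total count of spot i, so every row of X
    sums to 10^4.  ``median_ratio`` uses s_i = total_i / median(total), which
    preserves the overall count scale while equalizing depth.
    """
    totals = ds.counts.sum(axis=1).astype(np.float64)
    if np.any(totals == 0):
        warnings.warn(f"{int((totals == 0).sum())} zero-total spots removed")
        ds = replace(
            ds,
            counts=ds.counts[totals > 0],
            coords=ds.coords[totals > 0],
            spot_ids=ds.spot_ids[totals > 0],
            in_tissue=None if ds.in_tissue is None else ds.in_tissue[totals > 0],
            labels=None if ds.labels is None else ds.labels[totals > 0],
        )
        totals = totals[totals > 0]
    if norm_mode == "per_spot_total":
        s = totals
        X = ds.counts / s[:, None] * TARGET_SCALE
    elif norm_mode == "median_ratio":
        s = totals / np.median(totals)
        X = ds.counts / s[:, None]
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    if log_transform:
        X = np.log1p(X)
    return FeatureMatrix(
        X=X.astype(np.float64),
        hvg_names=ds.gene_ids.copy(),
        scale_factors=s,
        norm_mode=norm_mode,
        log_transformed=log_transform,
    )


def save_processed(ds: SpatialDataset, fm: FeatureMatrix, path) -> None:
    """Write the processed matrix and provenance to h5ad."""
    adata = ds.to_anndata()
    adata = adata[:, [str(g) for g in fm.hvg_names]].copy()
    adata.layers["counts"] = adata.X.copy()
    adata.X = sparse.csr_matrix(fm.X)
    adata.obs["scale_factor"] = fm.scale_factors
    adata.uns["stesh"].update(
        {"norm_mode": fm.norm_mode, "log_transformed": fm.log_transformed}
    )
    adata.write_h5ad(Path(path))
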