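"""In-memory containers for CITE-seq and spatial datasets.

These are deliberately light wrappers around numpy arrays and pandas frames.
:meth:`CiteSeqDataset.to_anndata` bridges to the scanpy/anndata ecosystem for
users who want to continue analysis there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CiteSeqDataset:
    """Cells x (genes, antibody tags, hashtags) counts with per-cell metadata.

    Attributes
    ----------
    counts : ndarray of shape (n_cells, n_genes)
        Raw RNA UMI counts.
    gene_names : list of str
    adt : ndarray of shape (n_cells, n_tags) or None
        Antibody-derived-tag (surface protein) counts.
    adt_names : list of str
    hashtags : ndarray of shape (n_cells, n_hashtags) or None
        Sample-hashing tag counts.
    hashtag_names : list of str
    obs : DataFrame indexed by cell barcode
        Per-cell metadata: cluster, donor, reaction, treated flag and QC
        covariates (total_counts, detection_rate, mito_pct, ribo_pct,
        cell-cycle scores/phase) where available.
    embedding : ndarray of shape (n_cells, n_dims) or None
        Batch-integrated reduced-dimension components (consumed as input;
        the synthetic generator produces its own).
    """

    counts: np.ndarray
    gene_names: list
    obs: pd.DataFrame
    adt: Optional[np.ndarray] = None
    adt_names: list = field(default_factory=list)
    hashtags: Optional[np.ndarray] = None
    hashtag_names: list = field(default_factory=list)
    embedding: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, mask: np.ndarray) -> "CiteSeqDataset":
        """Return a new dataset restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_cells:
            raise ValueError("mask length does not match number of cells")
        return CiteSeqDataset(
            counts=self.counts[mask],
            gene_names=list(self.gene_names),
            obs=self.obs.iloc[mask] if mask.dtype == bool else self.obs.iloc[mask],
            adt=None if self.adt is None else self.adt[mask],
            adt_names=list(self.adt_names),
            hashtags=None if self.hashtags is None else self.hashtags[mask],
            hashtag_names=list(self.hashtag_names),
            embedding=None if self.embedding is None else self.embedding[mask],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (ADT/hashtags in ``obsm``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        if self.adt is not None:
            adata.obsm["adt"] = pd.DataFrame(
                self.adt, index=adata.obs_names, columns=self.adt_names
            )
        if self.hashtags is not None:
            adata.obsm["hashtag"] = pd.DataFrame(
                self.hashtags, index=adata.obs_names, columns=self.hashtag_names
            )
        if self.embedding is not None:
            adata.obsm["X_embed"] = self.embedding
        return adata


@dataclass
class SpatialMap:
    """Spot- or cell-resolution spatial expression map.

    Attributes
    ----------
    coords : ndarray of shape (n_locations, 2)
        2-D coordinates; units must be consistent with any distance cutoffs
        applied downstream.
    expr : DataFrame of shape (n_locations, n_genes)
        Expression values (counts or normalized) per location.
    obs : DataFrame indexed like ``expr``
        Per-location metadata: ``slide`` (or FOV id), optional ``region``,
        ``condition``, ``cell_type``, ``crypt_axis`` score and
        ``detection_rate`` columns.
    """

    coords: np.ndarray
    expr: pd.DataFrame
    obs: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape[0] != self.expr.shape[0]:
            raise ValueError("coords and expr disagree on the number of locations")

    @property
    def n_locations(self) -> int:
        return self.coords.shape[0]

    @property
    def slides(self) -> np.ndarray:
        if "slide" in self.obs.columns:
            return self.obs["slide"].to_numpy()
        return np.zeros(self.n_locations, dtype=int)

    def detection_rate(self) -> np.ndarray:
        """Per-location gene detection rate (fraction of genes with signal)."""
        if "detection_rate" in self.obs.columns:
            return self.obs["detection_rate"].to_numpy(dtype=float)
        return (self.expr.to_numpy() > 0).mean(axis=1)


@dataclass
class GroundTruth:
    """Ground-truth labels attached to a simulated dataset.

    ``cells`` holds per-cell/per-location truth (bound, doublet, sample of
    origin, niche label — whichever the generator produces); for spatial
    simulations ``planted_positive`` marks (location, receptor-ligand pair)
    combinations inside a planted microdomain.
    """

    cells: pd.DataFrame
    planted_positive: Optional[pd.DataFrame] = None
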