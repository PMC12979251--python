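"""Synthetic CITE-seq, hashed-pool and spatial datasets with ground truth.

The generators reproduce the statistical structure the downstream analyses
assume, not full transcriptome biology:

* ``simulate_citeseq`` — T cells with a latent per-cell PD-1 propensity that
  drives both PDCD1 mRNA and the anti-PD-1 antibody-tag (ADT) count.  Drug
  binding competes with the detection antibody for the epitope, so in bound
  cells the ADT mean is multiplied by a blocking factor while the mRNA is
  untouched.  Embedding components carry cluster identity plus one component
  linearly loaded on the propensity.
* ``simulate_hashtags`` — pooled samples with per-sample hashing tags;
  doublet tag profiles are sums of two singlet draws.
* ``simulate_spatial`` — hex or square lattices (or the same machinery for
  segmented-cell maps) with i.i.d. negative-binomial expression, planted
  receptor-ligand microdomains and geometric niche regions with
  niche-specific cell-type composition.

All count noise is negative binomial parameterized by mean ``mu`` and shape
``theta`` (variance ``mu + mu**2 / theta``); larger ``theta`` means less
overdispersion.  Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import CiteSeqDataset, GroundTruth, SpatialMap

__all__ = [
    "SimCiteSeqConfig",
    "SimSpatialConfig",
    "PlantedPair",
    "simulate_citeseq",
    "simulate_hashtags",
    "simulate_spatial",
]


def _nb_draw(rng: np.random.Generator, mu, theta: float):
    """Negative binomial with mean mu and shape theta (gamma-Poisson mixture)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("negative binomial mean must be non-negative")
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    out = rng.poisson(lam)
    out[mu == 0] = 0
    return out


# ---------------------------------------------------------------------------
# CITE-seq
# ---------------------------------------------------------------------------


@dataclass
class SimCiteSeqConfig:
    """Study conditions for the CITE-seq occupancy simulation.

    Defaults give five T-cell states spanning low to high PD-1 expression,
    half the cells from drug-treated donors, and an 8-fold suppression of
    ADT detection on bound cells (blocking_factor 0.125).
    """

    n_cells: int = 5000
    n_clusters: int = 5
    cluster_props: Optional[Sequence[float]] = None
    n_embed_dims: int = 30
    #: expected PDCD1 mRNA UMI per cell for each cluster
    pdcd1_mu_by_cluster: Optional[Sequence[float]] = None
    #: expected ADT tag count per unit of latent propensity
    adt_gain: float = 25.0
    #: multiplies the ADT mean for drug-bound cells (epitope blocking), in (0, 1]
    blocking_factor: float = 0.125
    bound_prob_by_cluster: Optional[Sequence[float]] = None
    frac_treated: float = 0.5
    #: NB shape theta; variance = mu + mu^2/theta
    nb_dispersion: float = 10.0
    n_reactions: int = 2
    n_donors: int = 8
    n_background_genes: int = 100
    #: lognormal sd of the latent propensity around its cluster mean
    propensity_sigma: float = 0.5
    #: loading of the propensity on the first embedding component
    embed_propensity_loading: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        if self.cluster_props is None:
            self.cluster_props = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_props = np.asarray(self.cluster_props, dtype=float)
        if len(self.cluster_props) != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(self.cluster_props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        if self.pdcd1_mu_by_cluster is None:
            # geometric ladder from PD-1-low to PD-1-high states
            self.pdcd1_mu_by_cluster = 0.25 * 2.0 ** np.arange(self.n_clusters)
        self.pdcd1_mu_by_cluster = np.asarray(self.pdcd1_mu_by_cluster, dtype=float)
        if np.any(self.pdcd1_mu_by_cluster < 0):
            raise ValueError("pdcd1_mu_by_cluster rates must be non-negative")
        if self.bound_prob_by_cluster is None:
            self.bound_prob_by_cluster = np.full(self.n_clusters, 0.3)
        self.bound_prob_by_cluster = np.asarray(self.bound_prob_by_cluster, dtype=float)
        if not (0 < self.blocking_factor <= 1):
            raise ValueError("blocking_factor must lie in (0, 1]")
        if self.adt_gain <= 0:
            raise ValueError("adt_gain must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def simulate_citeseq(config: SimCiteSeqConfig):
    """Simulate a CITE-seq dataset where drug binding suppresses ADT counts.

    Returns
    -------
    (CiteSeqDataset, GroundTruth)
        The truth frame carries ``bound``, ``treated``, ``cluster``, ``donor``
        and the latent ``propensity`` per cell.  At fixed propensity the mRNA
        distribution of bound and unbound cells is identical by construction;
        only the ADT mean differs (multiplied by ``blocking_factor``).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    theta = cfg.nb_dispersion

    if n == 0:
        obs = pd.DataFrame(index=pd.Index([], name="barcode"))
        ds = CiteSeqDataset(
            counts=np.zeros((0, cfg.n_background_genes + 1), dtype=int),
            gene_names=_gene_names(cfg.n_background_genes),
            obs=obs,
            adt=np.zeros((0, 4), dtype=int),
            adt_names=["PD1", "CD3", "CD4", "CD8"],
            embedding=np.zeros((0, cfg.n_embed_dims)),
        )
        return ds, GroundTruth(cells=obs.copy())

    cluster = rng.choice(cfg.n_clusters, size=n, p=cfg.cluster_props)

    # donors carry treatment status; cells inherit it
    n_treated_donors = int(round(cfg.frac_treated * cfg.n_donors))
    donor_treated = np.zeros(cfg.n_donors, dtype=bool)
    donor_treated[:n_treated_donors] = True
    donor = rng.integers(0, cfg.n_donors, size=n)
    treated = donor_treated[donor]

    bound = treated & (rng.random(n) < cfg.bound_prob_by_cluster[cluster])

    # latent PD-1 propensity: lognormal around the cluster mean (mean-preserving)
    sig = cfg.propensity_sigma
    propensity = cfg.pdcd1_mu_by_cluster[cluster] * np.exp(
        sig * rng.standard_normal(n) - sig**2 / 2
    )

    # background transcriptome: per-gene base rates; first blocks mito/ribo
    gene_names = _gene_names(cfg.n_background_genes)
    base = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=cfg.n_background_genes)
    base[:5] *= 8.0  # MT- genes are high-abundance
    base[5:10] *= 12.0  # ribosomal protein genes even more so
    # mild cluster modulation so the transcriptome is not perfectly homogeneous
    mod = rng.lognormal(mean=0.0, sigma=0.3, size=(cfg.n_clusters, cfg.n_background_genes))
    # per-cell library size factor
    size_factor = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    mu_bg = size_factor[:, None] * mod[cluster] * base[None, :]
    counts_bg = _nb_draw(rng, mu_bg, theta)

    pdcd1 = _nb_draw(rng, size_factor * propensity, theta)
    counts = np.column_stack([counts_bg, pdcd1]).astype(int)
    gene_names = gene_names + ["PDCD1"]

    # ADT panel: PD-1 is propensity-driven and blocked when drug-bound
    adt_names = ["PD1", "CD3", "CD4", "CD8"]
    adt_mu_pd1 = cfg.adt_gain * propensity * np.where(bound, cfg.blocking_factor, 1.0)
    other_mu = rng.lognormal(
        mean=np.log(30.0), sigma=0.4, size=(cfg.n_clusters, len(adt_names) - 1)
    )
    adt_mu = np.column_stack([adt_mu_pd1, other_mu[cluster]])
    adt = _nb_draw(rng, adt_mu, theta)

    # embedding: cluster centroids + isotropic noise; comp 0 loaded on propensity
    centroids = rng.normal(0.0, 3.0, size=(cfg.n_clusters, cfg.n_embed_dims))
    embedding = centroids[cluster] + rng.standard_normal((n, cfg.n_embed_dims))
    logp = np.log(propensity + 1e-9)
    z = (logp - logp.mean()) / max(logp.std(), 1e-9)
    embedding[:, 0] += cfg.embed_propensity_loading * z

    reaction = rng.integers(0, cfg.n_reactions, size=n)

    total = counts.sum(axis=1)
    detection = (counts > 0).mean(axis=1)
    mito = counts[:, :5].sum(axis=1) / np.maximum(total, 1) * 100
    ribo = counts[:, 5:10].sum(axis=1) / np.maximum(total, 1) * 100

    # cell-cycle scores: most cells G1; cycling cells get elevated S/G2M scores
    phase_code = rng.choice(3, size=n, p=[0.8, 0.1, 0.1])  # G1, S, G2M
    s_score = rng.normal(-0.05, 0.05, size=n) + np.where(phase_code == 1, 0.4, 0.0)
    g2m_score = rng.normal(-0.05, 0.05, size=n) + np.where(phase_code == 2, 0.4, 0.0)
    phase = np.array(["G1", "S", "G2M"])[phase_code]

    barcodes = pd.Index([f"cell_{i:05d}" for i in range(n)], name="barcode")
    obs = pd.DataFrame(
        {
            "cluster": cluster,
            "donor": donor,
            "reaction": reaction,
            "treated": treated,
            "total_counts": total,
            "detection_rate": detection,
            "mito_pct": mito,
            "ribo_pct": ribo,
            "s_score": s_score,
            "g2m_score": g2m_score,
            "phase": phase,
        },
        index=barcodes,
    )

    truth = pd.DataFrame(
        {
            "cluster": cluster,
            "donor": donor,
            "treated": treated,
            "bound": bound,
            "propensity": propensity,
        },
        index=barcodes,
    )

    ds = CiteSeqDataset(
        counts=counts,
        gene_names=gene_names,
        obs=obs,
        adt=adt,
        adt_names=adt_names,
        embedding=embedding,
    )
    return ds, GroundTruth(cells=truth)


def _gene_names(n_bg: int):
    names = []
    for i in range(n_bg):
        if i < 5:
            names.append(f"MT-G{i}")
        elif i < 10:
            names.append(f"RPL{i}")
        else:
            names.append(f"GENE{i}")
    return names


# ---------------------------------------------------------------------------
# Hashtags
# ---------------------------------------------------------------------------


def simulate_hashtags(
    n_cells: int,
    n_samples: int,
    doublet_rate: float,
    mu_pos: float = 500.0,
    mu_neg: float = 10.0,
    dispersion: float = 50.0,
    seed: int = 0,
):
    """Simulate a hashed pool with between-sample doublets.

    Each singlet expresses one tag at ``mu_pos`` and the rest at ``mu_neg``;
    a doublet's tag profile is the sum of two singlet draws from distinct
    samples (droplet physics).  Returns ``(tag count DataFrame, GroundTruth)``
    where the truth has ``sample_a``, ``sample_b`` (NA for singlets) and
    ``doublet`` columns.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if not (0 <= doublet_rate <= 1):
        raise ValueError("doublet_rate must lie in [0, 1]")
    if mu_pos <= mu_neg:
        raise ValueError("mu_pos must exceed mu_neg")
    rng = np.random.default_rng(seed)

    doublet = rng.random(n_cells) < doublet_rate
    sample_a = rng.integers(0, n_samples, size=n_cells)
    shift = rng.integers(1, n_samples, size=n_cells)
    sample_b = np.where(doublet, (sample_a + shift) % n_samples, -1)

    mu = np.full((n_cells, n_samples), mu_neg, dtype=float)
    mu[np.arange(n_cells), sample_a] = mu_pos
    counts = _nb_draw(rng, mu, dispersion)
    # a doublet is the superposition of a second droplet's draw
    mu2 = np.full((n_cells, n_samples), mu_neg, dtype=float)
    mu2[np.arange(n_cells), np.where(sample_b >= 0, sample_b, 0)] = mu_pos
    second = _nb_draw(rng, mu2, dispersion)
    counts = counts + np.where(doublet[:, None], second, 0)

    barcodes = pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="barcode")
    tags = pd.DataFrame(
        counts, index=barcodes, columns=[f"HTO{j+1}" for j in range(n_samples)]
    )
    truth = pd.DataFrame(
        {
            "sample_a": sample_a,
            "sample_b": pd.array(
                np.where(doublet, sample_b, pd.NA), dtype="Int64"
            ),
            "doublet": doublet,
        },
        index=barcodes,
    )
    return tags, GroundTruth(cells=truth)


# ---------------------------------------------------------------------------
# Spatial
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    """A receptor-ligand pair co-elevated inside a circular microdomain."""

    ligand: str
    receptor: str
    center: tuple
    radius: float
    fold_change: float = 5.0

    def __post_init__(self):
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")


@dataclass
class SimSpatialConfig:
    """Study conditions for the spatial lattice / cell-map simulation."""

    lattice: str = "hex"
    n_rows: int = 20
    n_cols: int = 25
    #: center-to-center spacing between adjacent locations
    pitch: float = 1.0
    n_genes: int = 40
    planted_pairs: list = field(default_factory=list)
    #: number of geometric niche bands; 0 disables niche/type generation
    n_niches: int = 0
    n_cell_types: int = 0
    #: probability a cell carries its niche's anchor type
    niche_anchor_prob: float = 0.7
    #: NB mean of baseline expression per gene (lognormal spread applied)
    base_mean: float = 2.0
    nb_dispersion: float = 10.0
    #: coordinate jitter as a fraction of pitch (for cell-map emulation)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.lattice not in ("hex", "square"):
            raise ValueError("lattice must be 'hex' or 'square'")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.n_cell_types == 0 and self.n_niches > 0:
            self.n_cell_types = self.n_niches + 2


def lattice_coords(lattice: str, n_rows: int, n_cols: int, pitch: float) -> np.ndarray:
    """Coordinates of a hex (offset rows) or square lattice, spacing = pitch."""
    r, c = np.mgrid[0:n_rows, 0:n_cols]
    r = r.ravel()
    c = c.ravel()
    if lattice == "hex":
        x = c * pitch + (r % 2) * pitch / 2.0
        y = r * pitch * np.sqrt(3) / 2.0
    else:
        x = c * pitch
        y = r * pitch
    return np.column_stack([x, y]).astype(float)


def simulate_spatial(config: SimSpatialConfig):
    """Simulate a spatial map with planted RL microdomains and niches.

    Returns ``(SpatialMap, GroundTruth)``.  Truth rows carry ``niche_label``
    (and ``cell_type``) when niches are generated; ``planted_positive`` is a
    locations x pairs boolean frame marking microdomain membership.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    coords = lattice_coords(cfg.lattice, cfg.n_rows, cfg.n_cols, cfg.pitch)
    n = coords.shape[0]
    if cfg.jitter > 0:
        coords = coords + rng.normal(0, cfg.jitter * cfg.pitch, size=coords.shape)

    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    for p in cfg.planted_pairs:
        cx, cy = p.center
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise ValueError(f"microdomain center {p.center} lies outside the lattice")

    gene_names = [f"G{i}" for i in range(cfg.n_genes)]
    needed = {g for p in cfg.planted_pairs for g in (p.ligand, p.receptor)}
    missing = sorted(needed - set(gene_names))
    gene_names = gene_names + missing

    base = cfg.base_mean * rng.lognormal(mean=0.0, sigma=0.3, size=len(gene_names))
    mu = np.tile(base, (n, 1))

    # reject planted regions that disagree about a shared gene's mean
    masks = {}
    touched = {}
    for p in cfg.planted_pairs:
        d = np.hypot(coords[:, 0] - p.center[0], coords[:, 1] - p.center[1])
        inside = d <= p.radius
        masks[(p.ligand, p.receptor)] = inside
        for g in (p.ligand, p.receptor):
            prev = touched.get(g)
            if prev is not None and np.any(prev[0] & inside) and prev[1] != p.fold_change:
                raise ValueError(
                    f"overlapping planted regions assign conflicting fold-changes to {g}"
                )
            touched[g] = (inside if prev is None else (prev[0] | inside), p.fold_change)
        gi = [gene_names.index(p.ligand), gene_names.index(p.receptor)]
        mu[np.ix_(inside, gi)] *= p.fold_change

    counts = _nb_draw(rng, mu, cfg.nb_dispersion)
    expr = pd.DataFrame(counts, columns=gene_names)

    obs = pd.DataFrame({"slide": np.zeros(n, dtype=int)})
    obs["detection_rate"] = (counts > 0).mean(axis=1)

    truth = pd.DataFrame(index=expr.index)
    if cfg.n_niches > 0:
        # vertical bands across the lattice
        edges = np.linspace(xmin - 1e-9, xmax + 1e-9, cfg.n_niches + 1)
        niche = np.clip(np.searchsorted(edges, coords[:, 0]) - 1, 0, cfg.n_niches - 1)
        props = np.full((cfg.n_niches, cfg.n_cell_types),
                        (1 - cfg.niche_anchor_prob) / (cfg.n_cell_types - 1))
        props[np.arange(cfg.n_niches), np.arange(cfg.n_niches)] = cfg.niche_anchor_prob
        u = rng.random(n)
        cum = props.cumsum(axis=1)
        cell_type = (u[:, None] > cum[niche]).sum(axis=1)
        obs["cell_type"] = [f"T{t}" for t in cell_type]
        obs["region"] = niche
        truth["niche_label"] = niche
        truth["cell_type"] = obs["cell_type"].to_numpy()

    planted = pd.DataFrame(
        {f"{l}->{r}": m for (l, r), m in masks.items()}, index=expr.index
    )
    if planted.empty:
        planted = pd.DataFrame(index=expr.index)

    smap = SpatialMap(coords=coords, expr=expr, obs=obs)
    return smap, GroundTruth(cells=truth, planted_positive=planted)
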