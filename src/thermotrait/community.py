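"""Linking amplicon community composition to temperature traits.

Covers alpha diversity (Shannon, richness), the beta-diversity workflow
(minimum-count ASV filtering, deterministic even-depth scaling, Bray-Curtis,
non-metric multidimensional scaling), envfit-style permutation vector
fitting of environmental variables and trait indices onto the ordination,
and the per-ASV screen correlating relative abundance with Tmin to flag
warm- and cold-adapted taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AsvTable",
    "OrdinationResult",
    "VectorFit",
    "shannon",
    "richness",
    "filter_asvs",
    "even_depth_transform",
    "bray_curtis",
    "nmds",
    "fit_vector",
    "asv_trait_screen",
]


@dataclass
class AsvTable:
    """Samples x ASVs count matrix with optional taxonomy.

    ``counts`` is a DataFrame indexed by sample id with one column per ASV.
    Raw tables hold integer counts; the even-depth transform produces
    proportion-scaled floats with a common row sum.
    """

    counts: pd.DataFrame
    marker: str = "16S"
    taxonomy: pd.Series | None = None

    def __post_init__(self):
        if self.marker not in ("16S", "ITS"):
            raise ValueError("marker must be '16S' or 'ITS'")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self):
        return list(self.counts.index)

    @property
    def asv_ids(self):
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centred at the origin
    stress: float
    converged: bool
    seed: int


@dataclass
class VectorFit:
    variable: str
    direction: np.ndarray  # unit vector in ordination space
    r_squared: float
    p_perm: float
    n_permutations: int

    def __post_init__(self):
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-8
        assert self.p_perm >= 1.0 / (self.n_permutations + 1) - 1e-12


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) for one sample."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty sample: total count is zero")
    return float(_skbio_shannon(counts, base=np.e))


def richness(counts) -> int:
    """Number of taxa with non-zero abundance in one sample."""
    return int((np.asarray(counts) > 0).sum())


def filter_asvs(table: AsvTable, min_count: int = 5) -> AsvTable:
    """Drop ASVs whose total count across samples is below ``min_count``."""
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= min_count].index
    if len(keep) == 0:
        raise ValueError("all ASVs removed by the minimum-count filter")
    tax = table.taxonomy.loc[keep] if table.taxonomy is not None else None
    return AsvTable(table.counts[keep].copy(), table.marker, tax)


def even_depth_transform(table: AsvTable) -> AsvTable:
    """Scale each sample to the minimum sample depth (deterministic).

    Each sample's counts are multiplied by depth_min/depth_sample, so every
    row sums to the common minimum depth.  No subsampling is involved and no
    zeros are created, so richness is preserved.
    """
    depths = table.depths()
    if (depths <= 0).any():
        bad = depths.index[depths <= 0][0]
        raise ValueError(f"zero-depth sample {bad!r}")
    scaled = table.counts.mul(depths.min() / depths, axis=0)
    return AsvTable(scaled, table.marker, table.taxonomy)


def bray_curtis(table: AsvTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i), in [0, 1] with zero diagonal.
    Bray-Curtis is a semi-metric: the triangle inequality may fail.
    """
    X = table.counts.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (X.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero samples: dissimilarity undefined")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.sample_ids, columns=table.sample_ids)


def nmds(dissimilarity: pd.DataFrame, k: int = 2, seed: int = 0,
         max_iter: int = 500, n_starts: int = 20) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Kruskal-style stress minimisation (SMACOF with monotone regression),
    best of ``n_starts`` seeded random starts; reports normalised stress-1.
    Coordinates are centred at the origin.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("dissimilarity must be a square symmetric matrix")
    mds = MDS(n_components=k, metric_mds=False, dissimilarity="precomputed",
              init="random", n_init=n_starts, max_iter=max_iter,
              random_state=seed, normalized_stress=True, eps=1e-9)
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    converged = bool(mds.n_iter_ < max_iter)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    frame = pd.DataFrame(coords, index=list(dissimilarity.index), columns=cols)
    return OrdinationResult(frame, float(mds.stress_), converged, seed)


def _vector_r_squared(Q, v):
    """R^2 of regressing v on an orthonormal basis Q of the centred coordinates."""
    vc = v - v.mean()
    denom = float(vc @ vc)
    proj = Q.T @ vc
    return float(proj @ proj) / denom


def fit_vector(ordination: OrdinationResult, values, name: str = "variable",
               n_perm: int = 999, seed: int = 0) -> VectorFit:
    """Fit an external variable onto the ordination (envfit-style).

    Least-squares regression of the variable on the ordination coordinates
    gives the direction of steepest increase and its R^2; significance comes
    from permuting the variable across samples:
    p = (1 + #{permuted R^2 >= observed}) / (n_perm + 1).
    """
    coords = ordination.coordinates.to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    if v.shape[0] != coords.shape[0]:
        raise ValueError("one value per sample required")
    if np.ptp(v) == 0:
        raise ValueError(f"variable {name!r} is constant across samples")
    Xc = coords - coords.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    beta, *_ = np.linalg.lstsq(Xc, v - v.mean(), rcond=None)
    direction = beta / np.linalg.norm(beta)
    r2 = _vector_r_squared(Q, v)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(v) for _ in range(n_perm)])
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", pc @ Q, pc @ Q)
    den = np.einsum("ij,ij->i", pc, pc)
    r2_perm = num / den
    p = (1.0 + float((r2_perm >= r2 - 1e-12).sum())) / (n_perm + 1.0)
    return VectorFit(name, direction, r2, p, n_perm)


def asv_trait_screen(table: AsvTable, t_min, alpha: float = 0.05,
                     method: str = "pearson") -> dict:
    """Correlate each ASV's relative abundance with per-sample Tmin.

    Warm-adapted taxa are ASVs with a significant positive correlation,
    cold-adapted taxa a significant negative one, at level ``alpha`` on the
    raw p-value.  Benjamini-Hochberg adjusted p-values are reported
    alongside.  Zero-variance ASVs are skipped with a log entry.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = table.counts.to_numpy(dtype=float)
    rel = X / X.sum(axis=1, keepdims=True)
    y = np.asarray(t_min, dtype=float)
    if y.shape[0] != rel.shape[0]:
        raise ValueError("one t_min value per sample required")
    if method == "spearman":
        rel = stats.rankdata(rel, axis=0)
        y = stats.rankdata(y)

    n = rel.shape[0]
    sd = rel.std(axis=0)
    usable = sd > 1e-12 * max(float(np.abs(rel).max()), 1e-300)
    if (~usable).any():
        logger.info("skipping %d zero-variance ASVs", int((~usable).sum()))
    Z = (rel[:, usable] - rel[:, usable].mean(axis=0)) / sd[usable]
    yz = (y - y.mean()) / y.std()
    r = (Z * yz[:, None]).mean(axis=0)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_adj = multipletests(p, method="fdr_bh")[1]

    ids = np.asarray(table.asv_ids)[usable]
    results = pd.DataFrame({"r": r, "p_value": p, "p_adjusted": p_adj}, index=ids)
    warm = list(ids[(p < alpha) & (r > 0)])
    cold = list(ids[(p < alpha) & (r < 0)])
    return {"results": results, "warm": warm, "cold": cold}
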