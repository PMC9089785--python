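"""Hashtag demultiplexing, QC, normalization, feature selection and PCA.

The stages mirror the standard single-cell workflow up to the clustering
input: the 70%-of-HTO-UMIs singlet rule, the <200-detected-genes / >10%
mitochondrial-fraction cell filter, per-cell library-size normalization
(×10,000, log2), binned-dispersion variable-gene selection, covariate
regression with per-gene z-scaling, and PCA.

All stages are deterministic given input and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io_formats import CountMatrix, HTOCounts


@dataclass
class QCThresholds:
    min_genes: int = 200
    max_mito_frac: float = 0.10
    scale_factor: float = 10_000.0
    log_base: float = 2.0


# ---------------------------------------------------------------------------
# hashtag demultiplexing
# ---------------------------------------------------------------------------

def clr_normalize_hto(hto: HTOCounts) -> np.ndarray:
    """Centered log-ratio per cell: ln(1+c) minus the cell's mean of ln(1+c)."""
    logc = np.log1p(np.asarray(hto.counts, dtype=float))
    return logc - logc.mean(axis=1, keepdims=True)


def call_singlets(
    hto: HTOCounts,
    singlet_threshold: float = 0.70,
    min_total: int = 10,
    use_clr: bool = False,
) -> pd.DataFrame:
    """Classify each cell as singlet(hashtag), doublet or negative.

    A cell is a singlet when its top hashtag carries strictly more than
    ``singlet_threshold`` of its total HTO UMIs; otherwise a doublet.
    Cells with fewer than ``min_total`` total HTO UMIs are negative
    (too little signal to call).  The fraction is computed on raw UMIs by
    default; ``use_clr`` shifts CLR values to be non-negative per cell
    first (an alternative reading, off by default).
    """
    counts = np.asarray(hto.counts, dtype=float)
    if use_clr:
        v = clr_normalize_hto(hto)
        v = v - v.min(axis=1, keepdims=True)
    else:
        v = counts
    total_umi = counts.sum(axis=1)
    denom = v.sum(axis=1)
    top = v.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, v[np.arange(len(v)), top] / denom, 0.0)
    call = np.where(total_umi < min_total, "negative",
                    np.where(frac > singlet_threshold, "singlet", "doublet"))
    hashtag = np.where(call == "singlet",
                       np.asarray(hto.hashtags, dtype=object)[top], None)
    return pd.DataFrame(
        {"call": call, "hashtag": hashtag, "max_fraction": frac,
         "total": total_umi.astype(int)},
        index=pd.Index(hto.barcodes, name="barcode"))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def resolve_mito_genes(m: CountMatrix, prefix: str = "mt-") -> np.ndarray:
    """Indices of mitochondrial genes by symbol prefix (case-insensitive)."""
    syms = pd.Series(m.symbols).str.lower()
    return np.flatnonzero(syms.str.startswith(prefix.lower()))


def qc_filter(
    m: CountMatrix,
    mito_gene_ids: np.ndarray | list | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CountMatrix, dict]:
    """Remove cells with <``min_genes`` detected genes or a mitochondrial
    UMI fraction strictly above ``max_mito_frac``."""
    if mito_gene_ids is None:
        mito_gene_ids = resolve_mito_genes(m)
    mito_gene_ids = np.asarray(mito_gene_ids, dtype=int)

    counts = m.counts.tocsr()
    detected = counts.getnnz(axis=1)
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = (np.asarray(counts[:, mito_gene_ids].sum(axis=1)).ravel()
            if len(mito_gene_ids) else np.zeros(m.shape[0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / total, 0.0)

    low_genes = detected < thresholds.min_genes
    high_mito = mito_frac > thresholds.max_mito_frac
    keep = ~(low_genes | high_mito)
    report = {
        "input_cells": int(m.shape[0]),
        "removed_low_genes": int(low_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_total": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    if report["kept"] == 0:
        warnings.warn("QC filter removed every cell", stacklevel=2)
    filtered = CountMatrix(
        [b for b, k in zip(m.barcodes, keep) if k],
        m.features.copy(),
        counts[keep],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log_normalize(m: CountMatrix,
                  thresholds: QCThresholds = QCThresholds()) -> sp.csr_matrix:
    """log_base(1 + count / cell total × scale factor), sparse in, sparse out."""
    counts = m.counts.tocsr().astype(float)
    total = np.asarray(counts.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("all-zero cell encountered; run qc_filter first")
    norm = counts.multiply(thresholds.scale_factor / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data) / np.log(thresholds.log_base)
    return norm


def compute_covariates(
    m: CountMatrix,
    mito_prefix: str = "mt-",
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl"),
    hemo_prefixes: tuple[str, ...] = ("Hba", "Hbb"),
) -> pd.DataFrame:
    """Per-cell technical covariates: total UMI, mito fraction and the
    ribosomal / hemoglobin content scores (fraction of the cell's UMIs in
    genes matching the respective symbol prefixes)."""
    counts = m.counts.tocsr()
    total = np.asarray(counts.sum(axis=1)).ravel()
    safe_total = np.where(total > 0, total, 1.0)

    def prefix_frac(prefixes) -> np.ndarray:
        syms = pd.Series(m.symbols)
        mask = np.zeros(len(syms), dtype=bool)
        for p in prefixes:
            mask |= syms.str.startswith(p).to_numpy()
        if not mask.any():
            return np.zeros(m.shape[0])
        return np.asarray(counts[:, mask].sum(axis=1)).ravel() / safe_total

    return pd.DataFrame(
        {
            "total_umi": total,
            "mito_frac": prefix_frac((mito_prefix, mito_prefix.capitalize())),
            "ribo_score": prefix_frac(ribo_prefixes),
            "hemo_score": prefix_frac(hemo_prefixes),
        },
        index=pd.Index(m.barcodes, name="barcode"))


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def select_variable_genes(
    norm_matrix,
    n_bins: int = 20,
    dispersion_z_min: float = 1.0,
    mean_bounds: tuple[float, float] = (0.1, 8.0),
) -> np.ndarray:
    """Binned-dispersion variable genes.

    Per gene: mean and dispersion (log of variance/mean) of the normalized
    values; genes are placed in ``n_bins`` equal-frequency bins by mean and
    the dispersion is z-scored within each bin.  Genes with z ≥
    ``dispersion_z_min`` and mean inside ``mean_bounds`` are returned,
    ordered by descending z.
    """
    X = norm_matrix.toarray() if sp.issparse(norm_matrix) else np.asarray(
        norm_matrix, dtype=float)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < n_bins:
        raise ValueError(
            f"need at least {n_bins} genes with nonzero mean and variance")
    disp = np.full(len(mean), -np.inf)
    disp[ok] = np.log(var[ok] / mean[ok])

    idx = np.flatnonzero(ok)
    order = idx[np.argsort(mean[idx], kind="stable")]
    bins = np.full(len(mean), -1)
    bins[order] = np.minimum((np.arange(len(order)) * n_bins) // len(order),
                             n_bins - 1)
    z = np.zeros(len(mean))
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if len(members) < 2:
            continue  # a single-gene bin has z defined as 0
        d = disp[members]
        sd = d.std(ddof=0)
        if sd > 0:
            z[members] = (d - d.mean()) / sd
    selected = np.flatnonzero(
        (z >= dispersion_z_min) & (mean >= mean_bounds[0])
        & (mean <= mean_bounds[1]) & ok)
    return selected[np.argsort(-z[selected], kind="stable")]


# ---------------------------------------------------------------------------
# regression + scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledMatrix:
    """Covariate-adjusted per-gene z-scores over the variable genes."""

    values: np.ndarray  # cells × variable genes, clipped
    clip: float
    gene_indices: np.ndarray | None = None
    dropped_covariates: list[str] = field(default_factory=list)


def regress_and_scale(
    norm_matrix,
    covariates: pd.DataFrame | np.ndarray,
    clip: float = 10.0,
    gene_indices: np.ndarray | None = None,
) -> ScaledMatrix:
    """OLS-residualize each gene on the covariates, then z-score and clip.

    Zero-variance covariates carry no information and are dropped with a
    warning; rank deficiency among the rest is tolerated via least-squares
    (minimum-norm) fitting.
    """
    Y = norm_matrix.toarray() if sp.issparse(norm_matrix) else np.asarray(
        norm_matrix, dtype=float)
    if gene_indices is not None:
        Y = Y[:, gene_indices]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        names = [f"cov{i}" for i in range(C.shape[1])]
    if not np.isfinite(C).all():
        raise ValueError("covariates contain non-finite values")

    keep = C.std(axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}",
                      stacklevel=2)
    X = np.column_stack([np.ones(len(Y)), C[:, keep]])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    sd = resid.std(axis=0, ddof=0)
    # residual variance at machine-noise level means the gene was fully
    # explained by the covariates; its scaled column is identically zero
    degenerate = sd <= 1e-10 * (np.abs(Y).max(axis=0) + 1.0)
    sd[degenerate] = 1.0
    scaled = (resid - resid.mean(axis=0)) / sd
    scaled[:, degenerate] = 0.0
    np.clip(scaled, -clip, clip, out=scaled)
    return ScaledMatrix(values=scaled, clip=clip, gene_indices=gene_indices,
                        dropped_covariates=dropped)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    embedding: np.ndarray  # cells × components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    def elbow_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": np.arange(1, len(self.explained_variance) + 1),
             "variance": self.explained_variance,
             "variance_ratio": self.explained_variance_ratio})


def run_pca(scaled: ScaledMatrix | np.ndarray,
            n_components: int = 50) -> PCAResult:
    """Deterministic (full-SVD) PCA of the scaled matrix."""
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(
        scaled, dtype=float)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    return PCAResult(embedding=emb,
                     explained_variance=pca.explained_variance_,
                     explained_variance_ratio=pca.explained_variance_ratio_)
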