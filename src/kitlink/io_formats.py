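"""Readers and writers for the external formats the pipeline consumes and emits.

Supported inputs: 10x-style Matrix Market count directories (matrix.mtx[.gz]
plus barcodes.tsv[.gz] and features.tsv[.gz]/genes.tsv[.gz]), cell×hashtag
UMI CSV tables, 10x ``filtered_contig_annotations.csv`` TCR contig tables,
and GMT gene-signature files.  Outputs are plain TSV/JSON with a manifest.

No scientific computation lives here.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """A file is missing, malformed, or has an unexpected layout."""


class IntegrityError(ValueError):
    """Parsed components disagree with each other (e.g. dimension mismatch)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse cells × genes UMI count matrix with identifier sidecars.

    ``features`` is a DataFrame with columns ``gene_id`` and ``symbol``;
    symbols are what signatures match against, ids define gene identity.
    """

    barcodes: list[str]
    features: pd.DataFrame
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells or len(self.features) != n_genes:
            raise IntegrityError(
                f"matrix is {n_cells}x{n_genes} but sidecars have "
                f"{len(self.barcodes)} barcodes / {len(self.features)} features"
            )
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("duplicate barcodes")
        if self.features["gene_id"].duplicated().any():
            raise IntegrityError("duplicate feature ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def symbols(self) -> np.ndarray:
        return self.features["symbol"].to_numpy()


@dataclass
class HTOCounts:
    """Cells × hashtags UMI count table."""

    barcodes: list[str]
    hashtags: list[str]
    counts: np.ndarray  # dense; hashtag panels are tiny

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.hashtags) < 2:
            raise IntegrityError("need at least 2 hashtags to demultiplex")
        if self.counts.shape != (len(self.barcodes), len(self.hashtags)):
            raise IntegrityError("HTO matrix shape does not match sidecars")
        if self.counts.size and self.counts.min() < 0:
            raise IntegrityError("negative HTO counts")


@dataclass(frozen=True)
class TcrContig:
    """One assembled TCR chain for one cell barcode."""

    barcode: str
    chain: str  # "TRA" or "TRB"
    productive: bool
    cdr3_nt: str
    cdr3_aa: str = ""


@dataclass
class GeneSignature:
    """A named set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise FormatError(f"signature {self.name!r} is empty")

    def intersect(self, symbols: Iterable[str]) -> tuple["GeneSignature", float]:
        """Drop genes absent from ``symbols``; return (restricted, retained fraction)."""
        present = self.genes & set(symbols)
        if not present:
            raise FormatError(
                f"signature {self.name!r} shares no genes with the matrix"
            )
        return GeneSignature(self.name, present), len(present) / len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_sidecar(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {directory}")


def read_count_matrix(directory_path: str | os.PathLike,
                      orientation: str = "auto") -> CountMatrix:
    """Read a 10x-style Matrix Market directory into a cells × genes matrix.

    On-disk 10x matrices are genes × cells; orientation is auto-detected by
    matching dimensions to sidecar lengths.  ``orientation`` may be forced to
    ``"cells_by_genes"`` or ``"genes_by_cells"`` for square matrices, where
    auto-detection is ambiguous.
    """
    directory = Path(directory_path)
    mtx_path = _find_sidecar(directory, ["matrix.mtx"])
    bc_path = _find_sidecar(directory, ["barcodes.tsv"])
    ft_path = _find_sidecar(directory, ["features.tsv", "genes.tsv"])

    with _open_maybe_gz(mtx_path) as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(ft_path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # 10x v2 ships 2 columns (id, symbol); v3 adds feature_type
    features = pd.DataFrame(
        {"gene_id": [r[0] for r in rows],
         "symbol": [r[1] if len(r) > 1 else r[0] for r in rows]}
    )

    n_bc, n_ft = len(barcodes), len(features)
    if mat.shape == (n_ft, n_bc) and mat.shape == (n_bc, n_ft):
        if orientation == "auto":
            raise FormatError(
                "square matrix: orientation ambiguous, pass orientation="
                "'cells_by_genes' or 'genes_by_cells'"
            )
        if orientation == "genes_by_cells":
            mat = mat.T.tocsr()
    elif mat.shape == (n_ft, n_bc):
        mat = mat.T.tocsr()
    elif mat.shape != (n_bc, n_ft):
        raise IntegrityError(
            f"matrix shape {mat.shape} matches neither orientation for "
            f"{n_bc} barcodes x {n_ft} features"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise IntegrityError("non-integral counts in matrix")
    mat.data = np.asarray(np.round(mat.data), dtype=np.int64)
    return CountMatrix(barcodes, features, mat)


def write_count_matrix(m: CountMatrix, directory_path: str | os.PathLike) -> None:
    """Write in the 10x on-disk convention (genes × cells + sidecars)."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), m.counts.T.tocoo(),
                     field="integer")
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in m.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{r.gene_id}\t{r.symbol}\tGene Expression\n"
                for r in m.features.itertuples()))


def read_hto_counts(csv_path: str | os.PathLike) -> HTOCounts:
    """Read a cell×hashtag UMI CSV (first column = barcode)."""
    df = pd.read_csv(csv_path, index_col=0)
    return HTOCounts(
        barcodes=[str(b) for b in df.index],
        hashtags=[str(h) for h in df.columns],
        counts=df.to_numpy(dtype=np.int64),
    )


def write_hto_counts(hto: HTOCounts, csv_path: str | os.PathLike) -> None:
    pd.DataFrame(hto.counts, index=hto.barcodes, columns=hto.hashtags).to_csv(
        csv_path, index_label="barcode")


_CONTIG_REQUIRED = ["barcode", "chain", "productive", "cdr3", "cdr3_nt"]
_AB_CHAINS = {"TRA", "TRB"}


def read_contigs(csv_path: str | os.PathLike) -> tuple[list[TcrContig], int]:
    """Parse a 10x ``filtered_contig_annotations.csv`` table.

    Returns (contigs, n_dropped) where dropped rows are those whose chain is
    outside {TRA, TRB} (γδ, IG and multi-chain artifacts).  The 10x
    ``productive`` column encodes "True"/"False"/"None"; anything but a true
    value is treated as not productive.
    """
    df = pd.read_csv(csv_path, dtype=str)
    missing = [c for c in _CONTIG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"contig table missing required column(s): {missing}")
    keep = df["chain"].isin(_AB_CHAINS)
    n_dropped = int((~keep).sum())
    contigs = [
        TcrContig(
            barcode=row.barcode,
            chain=row.chain,
            productive=str(row.productive).strip().lower() == "true",
            cdr3_nt="" if pd.isna(row.cdr3_nt) else str(row.cdr3_nt),
            cdr3_aa="" if pd.isna(row.cdr3) else str(row.cdr3),
        )
        for row in df[keep].itertuples()
    ]
    return contigs, n_dropped


def write_contigs(contigs: list[TcrContig], csv_path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "barcode": [c.barcode for c in contigs],
            "chain": [c.chain for c in contigs],
            "productive": [str(c.productive) for c in contigs],
            "cdr3": [c.cdr3_aa for c in contigs],
            "cdr3_nt": [c.cdr3_nt for c in contigs],
        }
    ).to_csv(csv_path, index=False)


def read_gmt(path: str | os.PathLike) -> list[GeneSignature]:
    """Read gene signatures from a GMT file (name, description, genes...)."""
    sigs = []
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)")
            sigs.append(GeneSignature(fields[0], frozenset(fields[2:])))
    return sigs


def write_gmt(sigs: list[GeneSignature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    """Tables (written as TSV) and summaries (written as JSON) to persist."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)


def write_results(bundle: ResultsBundle,
                  directory_path: str | os.PathLike) -> dict:
    """Write a bundle to disk; returns (and writes) a manifest with row counts."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": []}
    for name in sorted(bundle.tables):
        fname = f"{name}.tsv"
        df = bundle.tables[name]
        df.to_csv(directory / fname, sep="\t", index=False)
        manifest["files"].append({"file": fname, "rows": int(len(df))})
    for name in sorted(bundle.summaries):
        fname = f"{name}.json"
        with open(directory / fname, "w") as fh:
            json.dump(bundle.summaries[name], fh, indent=1, default=_jsonify)
        manifest["files"].append({"file": fname, "rows": None})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
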