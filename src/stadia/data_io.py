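"""Reading, normalization, and assembly of multi-slice spatial expression data.

Each slice arrives as a spot × gene count matrix (10x MTX triplet or dense
CSV/TSV) plus 2-D spot coordinates.  Slices are library-size normalized,
log-transformed, restricted to a shared highly-variable-gene panel, and
globally mean-centered per gene before model fitting.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PLATFORMS = ("ST", "Visium", "SlideSeqV2")

#: Default intra-slice spatial-neighborhood parameters per platform:
#: ST and Visium use K-nearest neighbors, Slide-seqV2 a fixed radius.
PLATFORM_GRAPH_DEFAULTS = {
    "ST": {"method": "knn", "K": 4},
    "Visium": {"method": "knn", "K": 6},
    "SlideSeqV2": {"method": "radius", "r": 50.0},
}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class SliceData:
    """One slice: counts, coordinates, platform tag, and (after
    preprocessing) normalized log expression over the shared panel."""

    counts: np.ndarray | sp.spmatrix | None
    coords: np.ndarray
    platform: str
    batch_id: str
    barcodes: list[str]
    genes: list[str]
    expr: np.ndarray | None = None

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        if self.counts is not None:
            mat = self.counts
            if (mat.min() if not sp.issparse(mat) else mat.min()) < 0:
                raise ValidationError("counts must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]


@dataclass
class MultiSliceDataset:
    """Ordered collection of slices sharing one gene panel.

    ``global_index[(b, i)]`` maps slice ``b``, spot ``i`` to a row of the
    stacked expression matrix; the map is a bijection onto 0..n_total-1.
    """

    slices: list[SliceData]
    genes: list[str] = field(default_factory=list)
    centering: np.ndarray | None = None  # per-gene mean removed by center_genes

    @property
    def n_total(self) -> int:
        return sum(s.n_spots for s in self.slices)

    @property
    def n_batches(self) -> int:
        return len(self.slices)

    @property
    def batch_ids(self) -> list[str]:
        return [s.batch_id for s in self.slices]

    def global_index(self, b: int, i: int) -> int:
        if not (0 <= b < len(self.slices)) or not (0 <= i < self.slices[b].n_spots):
            raise ValidationError(f"no spot ({b}, {i}) in dataset")
        return sum(s.n_spots for s in self.slices[:b]) + i

    def batch_of_spot(self) -> np.ndarray:
        """Integer batch label for every global spot index."""
        return np.repeat(np.arange(len(self.slices)), [s.n_spots for s in self.slices])

    def stacked_expr(self) -> np.ndarray:
        """n_total × p matrix of normalized expression, slices stacked in order."""
        mats = []
        for s in self.slices:
            if s.expr is None:
                raise ValidationError(f"slice {s.batch_id!r} is not normalized")
            mats.append(s.expr)
        return np.vstack(mats)

    def stacked_coords(self) -> np.ndarray:
        return np.vstack([s.coords for s in self.slices])

    def spot_table(self) -> pd.DataFrame:
        rows = []
        for s in self.slices:
            rows.append(
                pd.DataFrame(
                    {
                        "barcode": s.barcodes,
                        "batch": s.batch_id,
                        "x": s.coords[:, 0],
                        "y": s.coords[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# loading


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path, col: int = 0) -> list[str]:
    out = []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append(parts[col])
    return out


def _find_10x_file(d: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = d / (stem + suffix)
            if p.exists():
                return p
    raise IOError(f"none of {stems} found under {d}")


def _load_counts_mtx(counts_path: Path):
    """10x triplet: matrix.mtx + barcodes.tsv + features/genes.tsv.

    ``counts_path`` may point at the directory or at matrix.mtx itself.
    The MTX is genes × spots (10x convention); we return spots × genes.
    """
    d = counts_path if counts_path.is_dir() else counts_path.parent
    mtx = _find_10x_file(d, ("matrix.mtx",))
    barcodes = _read_tsv_column(_find_10x_file(d, ("barcodes.tsv",)))
    features_path = _find_10x_file(d, ("features.tsv", "genes.tsv"))
    genes = _read_tsv_column(features_path, col=0)
    with _open_maybe_gz(mtx) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat.T)  # spots × genes
    if mat.shape != (len(barcodes), len(genes)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match {len(barcodes)} barcodes × "
            f"{len(genes)} features in {d}"
        )
    return mat, barcodes, genes


def _load_counts_dense(counts_path: Path):
    """Dense CSV/TSV, spots in rows with a barcode index column, genes in header."""
    sep = "\t" if counts_path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(b) for b in df.index], [str(g) for g in df.columns]


def _load_coords(coords_path: Path):
    """Coordinates CSV ``barcode,x,y`` or a 10x tissue_positions file."""
    df = pd.read_csv(coords_path, header=None, dtype=str)
    first = df.iloc[0, 0]
    has_header = not _is_number(df.iloc[0, 1] if df.shape[1] > 1 else "")
    if has_header:
        df = pd.read_csv(coords_path, dtype=str)
    if df.shape[1] >= 6:
        # 10x tissue_positions_list: barcode, in_tissue, row, col, pxl_row, pxl_col
        barcodes = [str(b) for b in df.iloc[:, 0]]
        xy = df.iloc[:, [4, 5]].astype(float).to_numpy()
    elif df.shape[1] >= 3:
        barcodes = [str(b) for b in df.iloc[:, 0]]
        xy = df.iloc[:, [1, 2]].astype(float).to_numpy()
    else:
        raise ValidationError(
            f"coordinates file {coords_path} needs a barcode column and 2 numeric columns"
        )
    del first
    return barcodes, xy


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def load_slice(
    counts_path, coords_path, platform: str, batch_id: str | None = None
) -> SliceData:
    """Load one slice, aligning counts and coordinates by barcode.

    Spots present in only one of the two files are dropped (logged).
    Raises ``IOError`` for unreadable paths and ``ValidationError`` when no
    barcodes overlap.
    """
    counts_path = Path(counts_path)
    coords_path = Path(coords_path)
    if not counts_path.exists():
        raise IOError(f"counts path not found: {counts_path}")
    if not coords_path.exists():
        raise IOError(f"coordinates path not found: {coords_path}")

    if counts_path.is_dir() or counts_path.name.startswith("matrix.mtx"):
        counts, barcodes, genes = _load_counts_mtx(counts_path)
    else:
        counts, barcodes, genes = _load_counts_dense(counts_path)
    coord_barcodes, xy = _load_coords(coords_path)

    pos_in_coords = {b: i for i, b in enumerate(coord_barcodes)}
    keep = [(i, pos_in_coords[b]) for i, b in enumerate(barcodes) if b in pos_in_coords]
    if not keep:
        raise ValidationError(
            f"no overlapping barcodes between {counts_path} and {coords_path}"
        )
    n_dropped = (len(barcodes) - len(keep)) + (len(coord_barcodes) - len(keep))
    if n_dropped:
        logger.info(
            "slice %s: dropped %d spots absent from counts or coordinates",
            batch_id or counts_path.name,
            n_dropped,
        )
    rows = [i for i, _ in keep]
    counts = counts[rows] if not sp.issparse(counts) else counts[rows, :]
    coords = xy[[j for _, j in keep]]
    kept_barcodes = [barcodes[i] for i in rows]

    return SliceData(
        counts=counts,
        coords=coords,
        platform=platform,
        batch_id=batch_id or counts_path.stem,
        barcodes=kept_barcodes,
        genes=list(genes),
    )


# ---------------------------------------------------------------------------
# preprocessing


def normalize_log(slice_: SliceData, scale: float = 1e4) -> SliceData:
    """Library-size normalize to ``scale`` counts per spot and log1p-transform.

    expr[i, j] = log(1 + scale * counts[i, j] / libsize_i).  Spots with a
    zero library are removed (logged).
    """
    if slice_.counts is None:
        raise ValidationError("normalize_log requires raw counts")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    counts = slice_.counts
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    lib = dense.sum(axis=1)
    if np.all(lib == 0):
        raise ValidationError(f"slice {slice_.batch_id!r}: all spots have zero counts")
    keep = lib > 0
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("slice %s: removed %d zero-library spots", slice_.batch_id, n_removed)
    dense = dense[keep]
    lib = lib[keep]
    expr = np.log1p(scale * dense / lib[:, None])
    return SliceData(
        counts=counts[keep] if not sp.issparse(counts) else counts[np.flatnonzero(keep)],
        coords=slice_.coords[keep],
        platform=slice_.platform,
        batch_id=slice_.batch_id,
        barcodes=[b for b, k in zip(slice_.barcodes, keep) if k],
        genes=slice_.genes,
        expr=expr,
    )


def _restrict_to_panel(slice_: SliceData, panel: list[str]) -> SliceData:
    idx = [slice_.genes.index(g) for g in panel]
    counts = slice_.counts
    if counts is not None:
        counts = counts[:, idx]
    expr = slice_.expr[:, idx] if slice_.expr is not None else None
    return SliceData(
        counts=counts,
        coords=slice_.coords,
        platform=slice_.platform,
        batch_id=slice_.batch_id,
        barcodes=slice_.barcodes,
        genes=list(panel),
        expr=expr,
    )


def assemble_dataset(slices: list[SliceData]) -> MultiSliceDataset:
    """Restrict all slices to the strict intersection of their gene panels
    (a shared loading matrix requires a common panel) and stack them."""
    if not slices:
        raise ValidationError("no slices supplied")
    shared = set(slices[0].genes)
    for s in slices[1:]:
        shared &= set(s.genes)
    if not shared:
        raise ValidationError("slices share no genes")
    panel = [g for g in slices[0].genes if g in shared]
    return MultiSliceDataset(
        slices=[_restrict_to_panel(s, panel) for s in slices], genes=panel
    )


def _dispersion_ranks(expr: np.ndarray, genes: list[str]) -> np.ndarray:
    """Per-slice HVG ranking by standardized dispersion (Seurat flavor)."""
    import anndata
    import scanpy as sc

    ad = anndata.AnnData(X=expr.copy(), var=pd.DataFrame(index=genes))
    n_bins = min(20, max(2, expr.shape[1] // 5))
    sc.pp.highly_variable_genes(ad, flavor="seurat", n_bins=n_bins)
    score = ad.var["dispersions_norm"].to_numpy()
    score = np.where(np.isfinite(score), score, -np.inf)
    order = np.argsort(-score, kind="stable")
    ranks = np.empty(len(genes))
    ranks[order] = np.arange(len(genes))
    return ranks


def select_hvgs(dataset: MultiSliceDataset, n_genes: int = 2000) -> list[str]:
    """Top highly variable genes on the shared panel.

    Standardized dispersion is scored per slice; slices are combined by the
    median of per-slice ranks (robust to one aberrant batch).  Ties break by
    gene-name order for determinism.
    """
    p = len(dataset.genes)
    if n_genes > p:
        raise ValidationError(f"n_genes={n_genes} exceeds shared panel size {p}")
    rank_mat = np.vstack(
        [_dispersion_ranks(s.expr, dataset.genes) for s in dataset.slices]
    )
    med = np.median(rank_mat, axis=0)
    order = sorted(range(p), key=lambda j: (med[j], dataset.genes[j]))
    chosen = set(order[:n_genes])
    return [g for j, g in enumerate(dataset.genes) if j in chosen]


def restrict_dataset(dataset: MultiSliceDataset, panel: list[str]) -> MultiSliceDataset:
    missing = [g for g in panel if g not in set(dataset.genes)]
    if missing:
        raise ValidationError(f"{len(missing)} requested genes absent from panel")
    return MultiSliceDataset(
        slices=[_restrict_to_panel(s, panel) for s in dataset.slices], genes=list(panel)
    )


def center_genes(dataset: MultiSliceDataset) -> MultiSliceDataset:
    """Remove each gene's global mean (over all spots of all slices).

    The centering vector is stored for the inverse transform; with centered
    data the latent cluster-mean prior can be centered at zero.  Idempotent.
    """
    Y = dataset.stacked_expr()
    mean = Y.mean(axis=0)
    new_slices = []
    for s in dataset.slices:
        new_slices.append(
            SliceData(
                counts=s.counts,
                coords=s.coords,
                platform=s.platform,
                batch_id=s.batch_id,
                barcodes=s.barcodes,
                genes=s.genes,
                expr=s.expr - mean,
            )
        )
    prev = dataset.centering if dataset.centering is not None else 0.0
    return MultiSliceDataset(slices=new_slices, genes=list(dataset.genes), centering=prev + mean)


def uncenter(dataset: MultiSliceDataset) -> MultiSliceDataset:
    """Inverse of :func:`center_genes`."""
    if dataset.centering is None:
        return dataset
    new_slices = []
    for s in dataset.slices:
        new_slices.append(
            SliceData(
                counts=s.counts,
                coords=s.coords,
                platform=s.platform,
                batch_id=s.batch_id,
                barcodes=s.barcodes,
                genes=s.genes,
                expr=s.expr + dataset.centering,
            )
        )
    return MultiSliceDataset(slices=new_slices, genes=list(dataset.genes), centering=None)


# ---------------------------------------------------------------------------
# on-disk bundle (open formats: CSV + MTX)


def write_bundle(dataset: MultiSliceDataset, out_dir) -> None:
    """Write the assembled dataset as open-format files.

    ``genes.csv``, ``spots.csv`` (barcode, batch, x, y, platform) and one
    ``expr_<batch>.csv`` matrix per slice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(dataset.genes, name="gene").to_csv(out / "genes.csv", index=False)
    tab = dataset.spot_table()
    tab["platform"] = np.repeat(
        [s.platform for s in dataset.slices], [s.n_spots for s in dataset.slices]
    )
    tab.to_csv(out / "spots.csv", index=False)
    for s in dataset.slices:
        df = pd.DataFrame(s.expr, index=s.barcodes, columns=dataset.genes)
        df.to_csv(out / f"expr_{s.batch_id}.csv")


def read_bundle(in_dir) -> MultiSliceDataset:
    """Read a dataset written by :func:`write_bundle`."""
    d = Path(in_dir)
    genes = pd.read_csv(d / "genes.csv")["gene"].astype(str).tolist()
    spots = pd.read_csv(d / "spots.csv", dtype={"barcode": str, "batch": str})
    slices = []
    for batch_id, grp in spots.groupby("batch", sort=False):
        df = pd.read_csv(d / f"expr_{batch_id}.csv", index_col=0)
        df.index = df.index.astype(str)
        df = df.loc[grp["barcode"].tolist()]
        slices.append(
            SliceData(
                counts=None,
                coords=grp[["x", "y"]].to_numpy(float),
                platform=grp["platform"].iloc[0],
                batch_id=str(batch_id),
                barcodes=grp["barcode"].tolist(),
                genes=genes,
                expr=df.to_numpy(float),
            )
        )
    return MultiSliceDataset(slices=slices, genes=genes)
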