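"""Chromosomal expression pattern (CEP): a CNV proxy from scRNA-seq expression.

Aneuploid tumor cells over- or under-express contiguous blocks of genes along
the genome. The CEP estimates this by (1) Z-normalizing each autosomal gene
across cells and clamping to [-3, 3], (2) averaging over a sliding window of
150 genome-ordered genes within each chromosome, and (3) centering each cell's
profile. The mean of squares (MS) of a cell's CEP values summarizes its
copy-number instability: near zero for diploid cells, elevated in tumor cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CEPResult",
    "read_gene_annotation",
    "zscore_clip",
    "compute_cep",
    "cnv_instability_ms",
    "cep_correlation_clusters",
    "compare_ms_groups",
]

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(range(1, 23))


class CEPError(ValueError):
    pass


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV with columns gene_id, chrom, start (1-based).

    Chromosome labels may carry a "chr" prefix; only autosomes 1-22 are kept
    (CEP excludes sex chromosomes). Returns a DataFrame indexed by gene_id
    with integer ``chrom`` and ``start`` columns.
    """
    ann = pd.read_csv(path, sep="\t", dtype={0: str})
    ann.columns = [c.lower() for c in ann.columns]
    if not {"gene_id", "chrom", "start"}.issubset(ann.columns):
        raise CEPError("annotation needs columns: gene_id, chrom, start")
    return normalize_annotation(ann)


def normalize_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Coerce an annotation frame to autosome-only, gene_id-indexed form."""
    ann = ann.copy()
    if "gene_id" in ann.columns:
        ann = ann.set_index("gene_id")
    ann.index = ann.index.astype(str)
    if ann.index.duplicated().any():
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise CEPError(f"duplicate gene_id in annotation: {dups[:5]}")
    chrom = ann["chrom"].astype(str).str.replace("^chr", "", regex=True)
    numeric = pd.to_numeric(chrom, errors="coerce")
    keep = numeric.isin(AUTOSOMES)
    out = ann.loc[keep, ["start"]].copy()
    out.insert(0, "chrom", numeric[keep].astype(int))
    out["start"] = out["start"].astype(int)
    return out


@dataclass
class CEPResult:
    """Window x cell CEP matrix with per-cell instability scores.

    Attributes
    ----------
    windows
        One row per window: chromosome, the genomic span covered, and the
        first/last gene id in the window (genome order).
    cep
        Window x cell matrix of centered moving-average Z values.
    ms
        Per-cell mean of squared CEP values (copy-number instability).
    params
        Window size, clip bound, Z ddof, and counts of genes used/dropped.
    """

    windows: pd.DataFrame
    cep: pd.DataFrame
    ms: pd.Series
    params: dict = field(default_factory=dict)


def zscore_clip(
    E,
    annotation: pd.DataFrame | None = None,
    clip: float = 3.0,
) -> pd.DataFrame:
    """Per-gene Z-normalization across cells, clamped to [-clip, +clip].

    ``E`` may be an :class:`~asceco.io_qc.ExpressionMatrix` or a plain
    genes x cells DataFrame. If ``annotation`` is given, the matrix is first
    restricted to annotated autosomal genes. Zero-variance genes map to
    all-zero rows. The standard deviation uses ddof=0.
    """
    values = E if isinstance(E, pd.DataFrame) else E.values
    if values.shape[1] < 2:
        raise CEPError("Z-normalization needs >= 2 cells")
    if annotation is not None:
        shared = values.index.intersection(annotation.index)
        dropped = len(values.index) - len(shared)
        if dropped:
            logger.info("zscore_clip: dropping %d genes absent from the autosome annotation", dropped)
        values = values.loc[shared]

    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    z = np.zeros_like(arr)
    nz = sd[:, 0] > 0
    z[nz] = (arr[nz] - mu[nz]) / sd[nz]
    np.clip(z, -clip, clip, out=z)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def compute_cep(
    Z: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = 150,
) -> CEPResult:
    """Moving-average smoothing of genome-ordered Z values, then per-cell centering.

    Within each chromosome, genes are sorted by start coordinate (ties broken
    by gene id) and averaged over every fully contained window of ``window``
    consecutive genes (step 1). Chromosomes with fewer genes than the window
    contribute no windows. Each cell's genome-wide mean over all windows is
    then subtracted, removing cell-level baseline shifts.
    """
    if window < 1:
        raise CEPError("window must be >= 1")
    shared = Z.index.intersection(annotation.index)
    n_dropped = Z.shape[0] - len(shared)
    if n_dropped:
        logger.info("compute_cep: %d genes lack annotation and are dropped", n_dropped)
    ann = annotation.loc[shared]
    order = ann.sort_values(["chrom", "start"]).index
    # deterministic tie-break on (chrom, start) by gene id
    ann = ann.loc[order]
    ann = ann.iloc[np.lexsort((ann.index, ann["start"], ann["chrom"]))]
    Zs = Z.loc[ann.index].to_numpy(dtype=float)

    rows = []
    win_meta = []
    skipped = []
    for chrom in AUTOSOMES:
        idx = np.flatnonzero(ann["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            continue
        if idx.size < window:
            skipped.append(int(chrom))
            continue
        block = Zs[idx]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        ma = (csum[window:] - csum[:-window]) / window  # valid windows, step 1
        rows.append(ma)
        genes = ann.index[idx]
        starts = ann["start"].to_numpy()[idx]
        for w in range(ma.shape[0]):
            win_meta.append(
                (int(chrom), int(starts[w]), int(starts[w + window - 1]), genes[w], genes[w + window - 1])
            )
    if not rows:
        raise CEPError(
            f"no chromosome has >= {window} annotated genes; use a smaller window"
        )
    if skipped:
        logger.info("compute_cep: chromosomes %s shorter than window %d, skipped", skipped, window)

    cep = np.vstack(rows)
    cep = cep - cep.mean(axis=0, keepdims=True)  # per-cell centering
    windows = pd.DataFrame(
        win_meta, columns=["chrom", "start", "end", "first_gene", "last_gene"]
    )
    cep_df = pd.DataFrame(cep, columns=Z.columns)
    ms = pd.Series((cep**2).mean(axis=0), index=Z.columns, name="ms")
    params = {
        "window": window,
        "step": 1,
        "centering": "per_cell_mean",
        "z_ddof": 0,
        "n_genes_used": int(len(ann)),
        "n_genes_dropped": int(n_dropped),
        "chromosomes_skipped": skipped,
    }
    return CEPResult(windows=windows, cep=cep_df, ms=ms, params=params)


def cnv_instability_ms(result: CEPResult) -> pd.Series:
    """Per-cell mean of squared CEP values (MS); higher in aneuploid cells."""
    if result.cep.shape[0] < 1:
        raise CEPError("no windows in CEP result")
    ms = pd.Series((result.cep.to_numpy() ** 2).mean(axis=0), index=result.cep.columns, name="ms")
    result.ms = ms
    return ms


def cep_correlation_clusters(
    result: CEPResult,
    k: int,
    linkage: str = "average",
) -> tuple[pd.DataFrame, pd.Series]:
    """Hierarchically cluster cells on Pearson correlation of CEP profiles.

    Correlation is computed over the window dimension; cells with a
    zero-variance profile get correlation 0 to every other cell (with a
    warning). Agglomerative clustering uses distance 1 - r and the given
    linkage, cut at ``k`` clusters. Returns (cell x cell correlation matrix,
    integer cluster labels 1..k).
    """
    X = result.cep.to_numpy()
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise CEPError("need >= 2 cells and >= 2 windows for correlation clustering")
    sd = X.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) have zero-variance CEP; correlations set to 0"
        )
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=result.cep.columns, columns=result.cep.columns)

    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return corr, pd.Series(labels, index=result.cep.columns, name="cluster")


def compare_ms_groups(
    ms: pd.Series,
    labels: pd.Series,
    group1: str,
    group2: str,
) -> tuple[float, float]:
    """Welch two-sample t-test on MS between two named cell groups.

    Cells outside the two groups are ignored (e.g. a small mesothelial
    population excluded from testing). Returns (t statistic, two-sided p);
    t > 0 means group1 has the larger mean MS.
    """
    labels = labels.loc[ms.index]
    a = ms[labels == group1].to_numpy()
    b = ms[labels == group2].to_numpy()
    for name, x in ((group1, a), (group2, b)):
        if x.size < 2:
            raise CEPError(f"group {name!r} has {x.size} cell(s); need >= 2")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
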