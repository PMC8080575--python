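"""M1/M2 macrophage signature extraction, scoring, and polarization assessment.

Signature genes are extracted by differential expression between in-vitro
differentiated M1 (LPS/IFN-gamma) and M2 (IL-4/IL-10) reference macrophages,
run independently per donor and under two normalization schemes (TMM and
median-of-ratios), and intersected across both schemes and both donors so
that only robust, donor-independent markers survive.

The DE engine is a negative-binomial GLM likelihood-ratio test:

    y_gj ~ NB(mu_gj, alpha_g),   log mu_gj = beta_g' x_j + log s_j

with per-cell size factors s_j, full model = intercept + group, null model =
intercept only, LRT statistic 2(ll_full - ll_null) ~ chi2(1), and BH FDR over
the tested genes. Per-gene dispersions alpha_g come from a method-of-moments
estimator shrunk toward a mean-dispersion trend.

Signature scores are the mean E over a gene set's detected members:
E_s,j(S) = average(E_1..n,j). Scores may be affinely rescaled to [-1, 1]
across the scored population for display, and an OLS fit of M2 score on M1
score summarizes polarization toward the M2 axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "SignatureSet",
    "SignatureScore",
    "PolarizationFit",
    "size_factors",
    "nb_lrt_de",
    "extract_signature",
    "signature_score",
    "rescale_scores",
    "polarization_fit",
    "overlap_with_reference",
    "read_gmt",
    "write_gmt",
    "DISSOCIATION_GENES",
]

logger = logging.getLogger(__name__)

# Dissociation-induced stress genes; optional exclusion filter for signatures.
DISSOCIATION_GENES = (
    "EGR1", "FOS", "FOSB", "JUN", "JUNB", "SOCS3",
    "HSP90AA1", "HSPA1A", "HSPA1B", "HSPA8",
)

_ALPHA_MIN, _ALPHA_MAX = 1e-8, 10.0


class SignatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame, scheme: str = "tmm") -> pd.Series:
    """Per-cell normalization factors, scaled to geometric mean 1.

    ``tmm``: trimmed mean of M-values against a reference cell (the cell whose
    library size is closest to the median), trimming 30% two-sided on M and 5%
    on A, with inverse-variance precision weights; the factor multiplies the
    library size (effective size = total x TMM factor).

    ``median_ratio``: per-cell median of count ratios to the per-gene
    geometric mean, over genes with all-positive counts.
    """
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        bad = counts.columns[totals <= 0].tolist()
        raise SignatureError(f"cells with zero total counts: {bad}")

    if scheme == "median_ratio":
        positive = (arr > 0).all(axis=1)
        if not positive.any():
            raise SignatureError(
                "median_ratio: no gene has all-positive counts; "
                "use scheme='tmm' or a pseudo-reference fallback"
            )
        logs = np.log(arr[positive])
        ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
        sf = np.exp(np.median(logs - ref, axis=0))
    elif scheme == "tmm":
        ref_cell = int(np.argmin(np.abs(totals - np.median(totals))))
        f = np.ones(arr.shape[1])
        p = arr / totals  # per-cell proportions
        pr = p[:, ref_cell]
        for j in range(arr.shape[1]):
            if j == ref_cell:
                continue
            ok = (p[:, j] > 0) & (pr > 0)
            if not ok.any():
                continue
            m = np.log2(p[ok, j] / pr[ok])
            a = 0.5 * np.log2(p[ok, j] * pr[ok])
            # asymptotic variance of M (binomial delta method)
            w = (1 - p[ok, j]) / (arr[ok, j]) + (1 - pr[ok]) / (arr[ok, ref_cell])
            keep = _doubletrim(m, a, m_trim=0.30, a_trim=0.05)
            if not keep.any():
                continue
            f[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        sf = f * totals
    else:
        raise SignatureError(f"unknown scheme {scheme!r}; use 'tmm' or 'median_ratio'")

    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=counts.columns, name=f"size_factor_{scheme}")


def _doubletrim(m: np.ndarray, a: np.ndarray, m_trim: float, a_trim: float) -> np.ndarray:
    """Joint trimming mask: drop the extreme m_trim of M and a_trim of A, each side."""
    n = m.size
    lo_m, hi_m = np.floor(n * m_trim) + 1, n + 1 - (np.floor(n * m_trim) + 1)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n + 1 - (np.floor(n * a_trim) + 1)
    rm = stats.rankdata(m, method="average")
    ra = stats.rankdata(a, method="average")
    return (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)


# ---------------------------------------------------------------------------
# NB-GLM likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Rowwise NB2 log-likelihood; y, mu are (G, n), alpha is (G,)."""
    a = alpha[:, None]
    r = 1.0 / a
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - r * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def _fit_intercept(y: np.ndarray, log_sf: np.ndarray, alpha: np.ndarray,
                   tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Newton solve of the intercept-only NB GLM with offsets, per gene (vectorized).

    Returns beta (G,) such that mu = exp(beta + log_sf) maximizes the NB
    likelihood at fixed alpha.
    """
    sf = np.exp(log_sf)[None, :]
    beta = np.log((y.sum(axis=1) + 0.5) / sf.sum())
    a = alpha[:, None]
    for _ in range(max_iter):
        mu = np.exp(beta[:, None]) * sf
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + a * y) / denom**2).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -3.0, 3.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _moment_dispersion(y: np.ndarray, sf: np.ndarray, group_idx: Sequence[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion per gene, pooled over groups.

    Works on normalized counts q = y / s; within each group,
    Var(q) ~= mean(q) * mean(1/s) + alpha * mean(q)^2.
    """
    G = y.shape[0]
    num = np.zeros(G)
    den = np.zeros(G)
    for idx in group_idx:
        q = y[:, idx] / sf[idx][None, :]
        m = q.mean(axis=1)
        v = q.var(axis=1, ddof=1)
        inv_s = np.mean(1.0 / sf[idx])
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * inv_s) / m**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += w * a
        den += w
    return num / np.maximum(den, 1.0)


def _shrink_dispersion(raw: np.ndarray, mean_norm: np.ndarray, weight: float) -> np.ndarray:
    """Shrink log-dispersions toward a log-linear mean-dispersion trend."""
    clipped = np.clip(raw, _ALPHA_MIN, _ALPHA_MAX)
    use = (raw > 1e-4) & (mean_norm > 0)
    if use.sum() >= 10:
        x = np.log(mean_norm[use])
        z = np.log(clipped[use])
        b, a = np.polyfit(x, z, 1)
        trend = np.exp(a + b * np.log(np.maximum(mean_norm, 1e-8)))
    else:
        trend = np.full_like(raw, np.exp(np.mean(np.log(clipped))))
    trend = np.clip(trend, _ALPHA_MIN, _ALPHA_MAX)
    return np.exp((1.0 - weight) * np.log(clipped) + weight * np.log(trend))


@dataclass
class DEResult:
    """Per-gene differential-expression table from one (donor, scheme) analysis.

    ``table`` columns: log2fc (contrast group over baseline group), stat
    (LRT), p, fdr (BH), mean_norm. Metadata identifies the donor and the
    normalization scheme, and records the contrast orientation.
    """

    table: pd.DataFrame
    donor: str
    scheme: str
    contrast: tuple[str, str]  # (baseline, contrast): log2fc > 0 means higher in contrast
    excluded_genes: list[str] = field(default_factory=list)


def nb_lrt_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    scheme: str = "tmm",
    contrast: tuple[str, str] | None = None,
    donor: str = "",
    dispersion_shrink: float = 0.35,
) -> DEResult:
    """Negative-binomial GLM likelihood-ratio test per gene between two groups.

    ``counts`` may be fractional expected counts (RSEM-style); the NB
    likelihood needs integers, so counts are rounded half-even. Genes with all
    zero counts are excluded (recorded on the result). ``contrast`` =
    (baseline, contrast) fixes the sign: log2fc > 0 means higher in the
    contrast group. Log2 fold changes use normalized group means with a 0.5
    pseudocount. ``dispersion_shrink`` is the weight pulling per-gene moment
    dispersions toward the fitted mean-dispersion trend.
    """
    groups = groups.astype(str).loc[counts.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise SignatureError(f"need exactly 2 groups, got {levels}")
    if contrast is None:
        contrast = (levels[0], levels[1])
    base, alt = contrast
    if {base, alt} != set(levels):
        raise SignatureError(f"contrast {contrast} does not match groups {levels}")
    for g in levels:
        if (groups == g).sum() < 2:
            raise SignatureError(f"group {g!r} has < 2 cells")

    y_all = np.rint(counts.to_numpy(dtype=float))  # round half-even
    nonzero = y_all.sum(axis=1) > 0
    excluded = counts.index[~nonzero].tolist()
    y = y_all[nonzero]
    gene_ids = counts.index[nonzero]

    sf = size_factors(counts, scheme=scheme).to_numpy()
    log_sf = np.log(sf)
    idx_base = np.flatnonzero((groups == base).to_numpy())
    idx_alt = np.flatnonzero((groups == alt).to_numpy())

    raw_alpha = _moment_dispersion(y, sf, [idx_base, idx_alt])
    q = y / sf[None, :]
    mean_norm = q.mean(axis=1)
    alpha = _shrink_dispersion(raw_alpha, mean_norm, weight=dispersion_shrink)

    # Full model = intercept per group (the two-level factor saturates into
    # independent intercept fits); null = common intercept.
    beta_null = _fit_intercept(y, log_sf, alpha)
    beta_b = _fit_intercept(y[:, idx_base], log_sf[idx_base], alpha)
    beta_a = _fit_intercept(y[:, idx_alt], log_sf[idx_alt], alpha)

    sfv = np.exp(log_sf)
    ll_null = _nb_loglik(y, np.exp(beta_null)[:, None] * sfv[None, :], alpha)
    ll_full = (
        _nb_loglik(y[:, idx_base], np.exp(beta_b)[:, None] * sfv[idx_base][None, :], alpha)
        + _nb_loglik(y[:, idx_alt], np.exp(beta_a)[:, None] * sfv[idx_alt][None, :], alpha)
    )
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    fdr = multipletests(p, method="fdr_bh")[1]

    m_base = q[:, idx_base].mean(axis=1)
    m_alt = q[:, idx_alt].mean(axis=1)
    log2fc = np.log2((m_alt + 0.5) / (m_base + 0.5))

    table = pd.DataFrame(
        {"log2fc": log2fc, "stat": lrt, "p": p, "fdr": fdr, "mean_norm": mean_norm},
        index=gene_ids,
    )
    return DEResult(table=table, donor=donor, scheme=scheme, contrast=(base, alt),
                    excluded_genes=excluded)


# ---------------------------------------------------------------------------
# signature extraction and scoring
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """A named gene set with extraction provenance."""

    name: str
    genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(dict.fromkeys(self.genes))  # unique, order kept

    def __len__(self) -> int:
        return len(self.genes)

    def drop(self, gene: str) -> "SignatureSet":
        return SignatureSet(self.name, tuple(g for g in self.genes if g != gene),
                            dict(self.provenance, left_out=gene))

    def without(self, exclude: Iterable[str]) -> "SignatureSet":
        ex = set(exclude)
        return SignatureSet(self.name, tuple(g for g in self.genes if g not in ex),
                            dict(self.provenance, excluded=sorted(ex & set(self.genes))))


def extract_signature(
    de_results: Sequence[DEResult],
    lfc_min: float = 2.0,
    fdr_max: float = 0.05,
    names: tuple[str, str] = ("up", "down"),
) -> tuple[SignatureSet, SignatureSet]:
    """Dual-method, dual-donor intersection of DE calls into signature sets.

    Per donor, up-candidates are the genes with log2fc > ``lfc_min`` and
    FDR < ``fdr_max`` under *both* normalization schemes; the final up
    signature is the intersection across all donors (analogously for down,
    log2fc < -``lfc_min``). Empty intersections are returned as empty sets
    with a warning, not an error.
    """
    by_donor: dict[str, list[DEResult]] = {}
    for de in de_results:
        by_donor.setdefault(de.donor, []).append(de)
    if not by_donor:
        raise SignatureError("no DE results supplied")
    up_sets, down_sets = [], []
    for donor, des in sorted(by_donor.items()):
        schemes = sorted(d.scheme for d in des)
        if len(des) != 2 or len(set(schemes)) != 2:
            raise SignatureError(
                f"donor {donor!r} needs exactly 2 schemes, got {schemes}"
            )
        up = None
        down = None
        for de in des:
            t = de.table
            u = set(t.index[(t["log2fc"] > lfc_min) & (t["fdr"] < fdr_max)])
            d = set(t.index[(t["log2fc"] < -lfc_min) & (t["fdr"] < fdr_max)])
            up = u if up is None else (up & u)
            down = d if down is None else (down & d)
        up_sets.append(up)
        down_sets.append(down)
    final_up = sorted(set.intersection(*up_sets))
    final_down = sorted(set.intersection(*down_sets))
    if not final_up or not final_down:
        logger.warning("extract_signature: empty intersection (up=%d, down=%d)",
                       len(final_up), len(final_down))
    prov = {
        "donors": sorted(by_donor),
        "schemes": sorted({d.scheme for d in de_results}),
        "lfc_min": lfc_min,
        "fdr_max": fdr_max,
        "contrast": de_results[0].contrast,
    }
    return (
        SignatureSet(names[0], tuple(final_up), dict(prov, side="up")),
        SignatureSet(names[1], tuple(final_down), dict(prov, side="down")),
    )


def extract_m1_m2(
    counts: pd.DataFrame,
    donors: pd.Series,
    polarization: pd.Series,
    lfc_min: float = 2.0,
    fdr_max: float = 0.05,
    schemes: tuple[str, str] = ("tmm", "median_ratio"),
) -> tuple[SignatureSet, SignatureSet, list[DEResult]]:
    """Run the full dual-method, dual-donor M1/M2 extraction on reference counts.

    Per donor, M1 vs M2 DE is run under both normalization schemes with the
    contrast oriented so log2fc > 0 means higher in M1; the intersections give
    the M1 (up) and M2 (down) signatures. Returns the two signatures and the
    per-(donor, scheme) DE tables.
    """
    donors = donors.astype(str).loc[counts.columns]
    polarization = polarization.astype(str).loc[counts.columns]
    des: list[DEResult] = []
    for donor in sorted(donors.unique()):
        cells = donors.index[donors == donor]
        for scheme in schemes:
            des.append(
                nb_lrt_de(
                    counts[cells], polarization.loc[cells], scheme=scheme,
                    contrast=("M2", "M1"), donor=donor,
                )
            )
    m1, m2 = extract_signature(des, lfc_min=lfc_min, fdr_max=fdr_max, names=("M1", "M2"))
    return m1, m2, des


@dataclass
class SignatureScore:
    """Per cell/sample signature scores E_s(S) = mean E over detected genes."""

    scores: pd.Series
    genes_used: int
    missing_genes: tuple[str, ...] = ()
    rescaled: pd.Series | None = None


def signature_score(E, signature: SignatureSet | Sequence[str]) -> SignatureScore:
    """Mean E over the signature genes detected in the matrix, per cell/sample."""
    values = E if isinstance(E, pd.DataFrame) else E.values
    genes = list(signature.genes) if isinstance(signature, SignatureSet) else list(signature)
    present = [g for g in genes if g in values.index]
    missing = tuple(g for g in genes if g not in values.index)
    if not present:
        raise SignatureError(f"no signature gene detected in the matrix; missing: {missing}")
    scores = values.loc[present].mean(axis=0)
    scores.name = signature.name if isinstance(signature, SignatureSet) else "score"
    return SignatureScore(scores=scores, genes_used=len(present), missing_genes=missing)


def rescale_scores(scores: pd.Series) -> pd.Series:
    """Affine map of scores onto [-1, 1]: observed min -> -1, max -> +1."""
    x = np.asarray(scores, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise SignatureError("constant scores: the [-1, 1] rescale is undefined")
    out = 2.0 * (x - lo) / (hi - lo) - 1.0
    return pd.Series(out, index=scores.index, name=scores.name)


@dataclass
class PolarizationFit:
    """OLS of M2 score on M1 score; summarizes inclination toward the M2 axis."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    mean_m2_minus_m1: float
    n: int


def polarization_fit(m1_scores: pd.Series, m2_scores: pd.Series) -> PolarizationFit:
    """OLS regression of M2 score (y) on M1 score (x) with a 95% slope CI.

    Inclination toward the M2 axis is summarized both by the slope and by the
    mean difference M2 - M1 over cells.
    """
    import statsmodels.api as sm

    x = np.asarray(m1_scores, dtype=float)
    y = np.asarray(m2_scores, dtype=float)
    if x.size != y.size:
        raise SignatureError("score vectors differ in length")
    if x.size < 3:
        raise SignatureError("need >= 3 cells for the polarization fit")
    if np.var(x) == 0:
        raise SignatureError("M1 scores are constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return PolarizationFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        mean_m2_minus_m1=float(np.mean(y - x)),
        n=int(x.size),
    )


def overlap_with_reference(
    sig: SignatureSet,
    refs: Mapping[str, Iterable[str]],
) -> dict[str, dict]:
    """Case-sensitive intersection of a signature with named reference gene sets."""
    s = set(sig.genes)
    out = {}
    for name, genes in refs.items():
        inter = sorted(s & set(genes))
        out[name] = {"count": len(inter), "genes": inter}
    return out


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes... per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SignatureError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]] | Sequence[SignatureSet], path: str | Path) -> None:
    lines = []
    if isinstance(sets, Mapping):
        items = [(k, list(v), "") for k, v in sets.items()]
    else:
        items = [(s.name, list(s.genes), "asceco") for s in sets]
    for name, genes, desc in items:
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")
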