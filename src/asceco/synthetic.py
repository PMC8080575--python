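"""Synthetic data generators emulating the malignant-ascites study design.

Three generators cover every pipeline stage:

* :func:`simulate_ascites` — an ascites-like mixture of patient-specific
  tumor clones carrying contiguous copy-number segments, macrophages with
  planted ligand-receptor programs (CCL3/CCR1, IL1B -> IL1R2, IL10/IL10RA),
  and a small mesothelial population, as negative-binomial expected counts
  with genes laid out on autosomes 1-22.
* :func:`simulate_reference_macrophages` — two-donor M1/M2 reference data
  with shared planted DE genes, donor-specific decoys, and donor baseline
  shifts.
* :func:`simulate_bulk_cohort` — a bulk cohort whose exponential hazard
  depends on a latent M2 activity expressed through the signature genes.

All generators are pure functions of (config, seed): the same config yields
bit-identical output. Counts are negative-binomial with log-normal gene
means; zero inflation is deliberately not simulated (the DE engine does not
model it either).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .interactions import PairDatabase
from .survival import SurvivalCohort

__all__ = [
    "CellGroupSpec",
    "CNVSegment",
    "AscitesConfig",
    "ReferenceConfig",
    "CohortConfig",
    "SimulatedAscites",
    "SimulatedReference",
    "simulate_ascites",
    "simulate_reference_macrophages",
    "simulate_bulk_cohort",
    "default_pair_database",
]


class ConfigError(ValueError):
    pass


# Autosome gene-count weights (approximate human protein-coding proportions);
# genes are assigned to chromosomes 1..22 in contiguous blocks by these weights.
_CHR_WEIGHTS = np.array(
    [2000, 1200, 1060, 750, 850, 1000, 900, 650, 780, 730,
     1300, 1000, 320, 600, 600, 800, 1150, 270, 1400, 540, 230, 440],
    dtype=float,
)

# Named genes planted with group-specific programs in the ascites simulation.
_MARKER_MEANS: dict[str, dict[str, float]] = {
    # macrophage markers / ligands
    "CD86": {"macrophage": 300.0, "default": 0.0},
    "CD68": {"macrophage": 400.0, "default": 0.0},
    "CD163": {"macrophage": 250.0, "default": 0.0},
    "CCL3": {"macrophage": 400.0, "default": 1.0},
    "CCR1": {"macrophage": 350.0, "default": 1.0},
    "IL1B": {"macrophage": 450.0, "default": 1.0},
    "IL10": {"macrophage": 300.0, "default": 1.0},
    "IL10RA": {"macrophage": 300.0, "default": 1.0},
    # epithelial / tumor markers and the IL1B decoy receptor
    "EPCAM": {"tumor": 300.0, "default": 0.0},
    "KRT8": {"tumor": 350.0, "mesothelial": 120.0, "default": 0.0},
    "IL1R2": {"tumor": 400.0, "default": 1.0},
    # mesothelial marker, also the macrophage-rule exclusion gene
    "MUC16": {"mesothelial": 300.0, "tumor": 25.0, "default": 0.0},
    # absent lineage (no T cells in the simulation)
    "CD3D": {"default": 0.0},
}


@dataclass(frozen=True)
class CellGroupSpec:
    """One simulated cell population: name, size, and cell-type label."""

    name: str
    n_cells: int
    cell_type: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError(f"group {self.name!r}: n_cells must be >= 1")


@dataclass(frozen=True)
class CNVSegment:
    """A contiguous copy-number segment: genes [start_gene, start_gene+n_genes)
    of ``chrom`` (chromosome-local genome order) have their means multiplied
    by ``factor`` in cells of ``group``."""

    chrom: int
    start_gene: int
    n_genes: int
    factor: float
    group: str

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ConfigError("CNV factor must be > 0")


def _default_ascites_groups() -> tuple[CellGroupSpec, ...]:
    # Four patient-specific tumor clones, one macrophage pool, a small
    # mesothelial population: 162 cells in total.
    return (
        CellGroupSpec("tumor_P1", 25, "tumor", "P1"),
        CellGroupSpec("tumor_P2", 25, "tumor", "P2"),
        CellGroupSpec("tumor_P3", 25, "tumor", "P3"),
        CellGroupSpec("tumor_P4", 25, "tumor", "P4"),
        CellGroupSpec("macrophage", 57, "macrophage", "mixed"),
        CellGroupSpec("mesothelial", 5, "mesothelial", "mixed"),
    )


def _default_segments() -> tuple[CNVSegment, ...]:
    # Patient-specific gains/losses on distinct chromosomes so that CEP
    # correlation clustering separates the clones.
    return (
        CNVSegment(1, 50, 300, 1.5, "tumor_P1"),
        CNVSegment(7, 20, 200, 0.6, "tumor_P1"),
        CNVSegment(2, 20, 280, 1.6, "tumor_P2"),
        CNVSegment(11, 40, 250, 0.6, "tumor_P2"),
        CNVSegment(3, 10, 250, 1.5, "tumor_P3"),
        CNVSegment(17, 20, 200, 1.7, "tumor_P3"),
        CNVSegment(5, 10, 200, 0.6, "tumor_P4"),
        CNVSegment(19, 50, 250, 1.6, "tumor_P4"),
    )


@dataclass(frozen=True)
class AscitesConfig:
    """Configuration of the ascites mixture simulation.

    Gene means are log-normal in TPM-like units (median ~30, sigma 1.3);
    per-gene NB dispersion is log-normal around 0.3, typical of full-length
    single-cell data; per-cell depth factors are log-normal (sigma 0.2).
    """

    seed: int = 0
    n_genes: int = 5000
    groups: tuple[CellGroupSpec, ...] = field(default_factory=_default_ascites_groups)
    cnv_segments: tuple[CNVSegment, ...] = field(default_factory=_default_segments)
    marker_means: Mapping[str, Mapping[str, float]] | None = None  # None -> built-in panel
    mean_log_mu: float = np.log(30.0)
    mean_log_sigma: float = 1.3
    dispersion_median: float = 0.3
    dispersion_log_sigma: float = 0.5
    depth_log_sigma: float = 0.2


@dataclass
class SimulatedAscites:
    counts: pd.DataFrame  # genes x cells, NB expected counts (TPM-like units)
    cell_meta: pd.DataFrame  # group, cell_type, sample per cell
    annotation: pd.DataFrame  # chrom, start per gene (autosomes 1..22)
    truth: dict


def _make_annotation(gene_ids: Sequence[str]) -> pd.DataFrame:
    n = len(gene_ids)
    sizes = np.floor(_CHR_WEIGHTS / _CHR_WEIGHTS.sum() * n).astype(int)
    sizes[: n - sizes.sum()] += 1  # distribute the remainder
    chroms = np.repeat(np.arange(1, 23), sizes)
    starts = np.concatenate([100_000 * (np.arange(s) + 1) for s in sizes])
    return pd.DataFrame(
        {"chrom": chroms, "start": starts},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _chrom_offsets(annotation: pd.DataFrame) -> dict[int, np.ndarray]:
    return {
        c: np.flatnonzero(annotation["chrom"].to_numpy() == c)
        for c in range(1, 23)
    }


def simulate_ascites(cfg: AscitesConfig) -> SimulatedAscites:
    """Simulate an ascites cell mixture with planted CNV and signaling programs.

    Returns NB expected counts (genes x cells), per-cell truth labels, the
    autosome annotation, and a truth dict (segments, planted pairs, marker
    panel) sufficient for every downstream recovery check.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = dict(cfg.marker_means) if cfg.marker_means is not None else dict(_MARKER_MEANS)

    named = list(markers)
    if cfg.n_genes <= len(named):
        raise ConfigError("n_genes must exceed the marker panel size")
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    step = cfg.n_genes // (len(named) + 1)
    named_pos = {name: (i + 1) * step for i, name in enumerate(named)}
    for name, pos in named_pos.items():
        gene_ids[pos] = name
    annotation = _make_annotation(gene_ids)

    mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=cfg.n_genes)
    alpha = rng.lognormal(np.log(cfg.dispersion_median), cfg.dispersion_log_sigma, size=cfg.n_genes)

    chrom_idx = _chrom_offsets(annotation)
    for seg in cfg.cnv_segments:
        idx = chrom_idx.get(seg.chrom, np.empty(0, dtype=int))
        if seg.start_gene + seg.n_genes > idx.size:
            raise ConfigError(
                f"segment {seg} exceeds chromosome {seg.chrom} ({idx.size} genes)"
            )
        if not any(g.name == seg.group for g in cfg.groups):
            raise ConfigError(f"segment group {seg.group!r} not among cell groups")

    cells = []
    meta_rows = []
    for g in cfg.groups:
        for k in range(g.n_cells):
            cells.append(f"{g.name}_c{k + 1:03d}")
            meta_rows.append((g.name, g.cell_type, g.sample))
    cell_meta = pd.DataFrame(
        meta_rows, columns=["group", "cell_type", "sample"],
        index=pd.Index(cells, name="cell_id"),
    )

    counts = np.zeros((cfg.n_genes, len(cells)))
    col = 0
    for g in cfg.groups:
        means = mu.copy()
        # group-specific marker/ligand programs
        for name, prog in markers.items():
            means[named_pos[name]] = prog.get(g.cell_type, prog.get("default", 0.0))
        # copy-number segments for this group
        for seg in cfg.cnv_segments:
            if seg.group == g.name:
                idx = chrom_idx[seg.chrom][seg.start_gene : seg.start_gene + seg.n_genes]
                means[idx] = means[idx] * seg.factor
        depth = rng.lognormal(0.0, cfg.depth_log_sigma, size=g.n_cells)
        m = means[:, None] * depth[None, :]
        counts[:, col : col + g.n_cells] = _nb_draw(rng, m, alpha[:, None])
        col += g.n_cells

    counts_df = pd.DataFrame(counts, index=annotation.index, columns=cells)
    truth = {
        "segments": cfg.cnv_segments,
        "markers": markers,
        "marker_positions": named_pos,
        "planted_pairs": {
            ("CCL3", "CCR1"): ("macrophage", "macrophage"),
            ("IL1B", "IL1R2"): ("macrophage", "tumor"),
            ("IL10", "IL10RA"): ("macrophage", "macrophage"),
        },
        "gene_means": mu,
        "dispersions": alpha,
    }
    return SimulatedAscites(counts_df, cell_meta, annotation, truth)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 sampling via gamma-Poisson; alpha -> 0 degenerates to Poisson."""
    mean = np.broadcast_to(mean, np.broadcast_shapes(mean.shape, alpha.shape)).astype(float)
    alpha = np.broadcast_to(alpha, mean.shape).astype(float)
    out = np.zeros_like(mean)
    pos = mean > 0
    a = np.maximum(alpha[pos], 1e-8)
    m = mean[pos]
    lam = rng.gamma(shape=1.0 / a, scale=a * m)
    out[pos] = rng.poisson(lam)
    return out


def default_pair_database(sim: SimulatedAscites, n_decoys: int = 25) -> PairDatabase:
    """A FANTOM5-style pair list for a simulated dataset: the planted
    cytokine/chemokine pairs plus decoy pairs drawn from moderately expressed
    background genes (baseline mean in [5, 30] TPM-like units), so decoys are
    real but weaker competitors.

    Deterministic given the simulation (decoys are picked by a seed derived
    from the simulation config seed).
    """
    planted = [
        ("CCL3", "CCR1", "cytokine_supp"),
        ("IL1B", "IL1R2", "cytokine_supp"),
        ("IL10", "IL10RA", "cytokine_supp"),
    ]
    mu = sim.truth["gene_means"]
    named = set(sim.truth["marker_positions"])
    background = [
        g for g, m in zip(sim.counts.index, mu)
        if g not in named and 5.0 <= m <= 30.0
    ]
    rng = np.random.default_rng(len(background))  # deterministic in the gene layout
    pick = rng.choice(len(background), size=min(2 * n_decoys, len(background)), replace=False)
    decoys = [
        (background[pick[2 * i]], background[pick[2 * i + 1]], "fantom5")
        for i in range(len(pick) // 2)
    ]
    return PairDatabase(pd.DataFrame(planted + decoys, columns=["ligand", "receptor", "source"]))


# ---------------------------------------------------------------------------
# M1/M2 reference macrophages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceConfig:
    """Two-donor M1/M2 reference simulation.

    Cell numbers default to the reference design (97 M1 and 45 M2 cells over
    two donors). ``n_m1_up``/``n_m2_up`` genes are planted with the same
    log2 fold change in both donors; ``n_decoys_per_donor`` genes are DE in
    one donor only (half M1-up, half M2-up). A per-donor log-normal baseline
    shift (sigma ``donor_shift_sd``) emulates donor-specific expression
    variability.
    """

    seed: int = 0
    n_genes: int = 2000
    donors: tuple[str, ...] = ("donor1", "donor2")
    n_m1_per_donor: tuple[int, ...] = (49, 48)
    n_m2_per_donor: tuple[int, ...] = (23, 22)
    n_m1_up: int = 60
    n_m2_up: int = 20
    n_decoys_per_donor: int = 15
    planted_log2fc: float = 3.0
    dispersion: float = 0.2
    donor_shift_sd: float = 0.3
    depth_log_sigma: float = 0.3
    mean_log_mu: float = np.log(50.0)
    mean_log_sigma: float = 1.2


@dataclass
class SimulatedReference:
    counts: pd.DataFrame  # genes x cells (expected counts)
    cell_meta: pd.DataFrame  # donor, polarization per cell
    truth: dict  # m1_up, m2_up, decoys per donor


def simulate_reference_macrophages(cfg: ReferenceConfig) -> SimulatedReference:
    """Simulate the two-donor M1/M2 reference experiment with planted DE truth."""
    if len(cfg.donors) < 2:
        raise ConfigError("need >= 2 donors")
    if len(cfg.n_m1_per_donor) != len(cfg.donors) or len(cfg.n_m2_per_donor) != len(cfg.donors):
        raise ConfigError("per-donor cell counts must match the donor list")
    n_planted = cfg.n_m1_up + cfg.n_m2_up + cfg.n_decoys_per_donor * len(cfg.donors)
    if n_planted > cfg.n_genes:
        raise ConfigError("more planted genes than genes")

    rng = np.random.default_rng(cfg.seed)
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(cfg.n_genes)], name="gene_id")
    mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=cfg.n_genes)

    pool = rng.permutation(cfg.n_genes)
    m1_up = np.sort(pool[: cfg.n_m1_up])
    m2_up = np.sort(pool[cfg.n_m1_up : cfg.n_m1_up + cfg.n_m2_up])
    decoys: dict[str, np.ndarray] = {}
    off = cfg.n_m1_up + cfg.n_m2_up
    for donor in cfg.donors:
        decoys[donor] = np.sort(pool[off : off + cfg.n_decoys_per_donor])
        off += cfg.n_decoys_per_donor

    fc = 2.0 ** cfg.planted_log2fc
    half = np.sqrt(fc)  # split the fold change symmetrically around baseline

    cells, meta_rows, cols = [], [], []
    for d, donor in enumerate(cfg.donors):
        shift = rng.lognormal(0.0, cfg.donor_shift_sd, size=cfg.n_genes)
        for pol, n_cells in (("M1", cfg.n_m1_per_donor[d]), ("M2", cfg.n_m2_per_donor[d])):
            means = mu * shift
            if pol == "M1":
                means[m1_up] *= half
                means[m2_up] /= half
            else:
                means[m1_up] /= half
                means[m2_up] *= half
            dec = decoys[donor]
            dec_up_m1 = dec[: len(dec) // 2]
            dec_up_m2 = dec[len(dec) // 2 :]
            if pol == "M1":
                means[dec_up_m1] *= half
                means[dec_up_m2] /= half
            else:
                means[dec_up_m1] /= half
                means[dec_up_m2] *= half
            depth = rng.lognormal(0.0, cfg.depth_log_sigma, size=n_cells)
            m = means[:, None] * depth[None, :]
            cols.append(_nb_draw(rng, m, np.full((cfg.n_genes, 1), cfg.dispersion)))
            for k in range(n_cells):
                cells.append(f"{donor}_{pol}_c{k + 1:03d}")
                meta_rows.append((donor, pol))

    counts = pd.DataFrame(np.hstack(cols), index=gene_ids, columns=cells)
    meta = pd.DataFrame(meta_rows, columns=["donor", "polarization"],
                        index=pd.Index(cells, name="cell_id"))
    truth = {
        "m1_up": gene_ids[m1_up].tolist(),
        "m2_up": gene_ids[m2_up].tolist(),
        "decoys": {d: gene_ids[ix].tolist() for d, ix in decoys.items()},
        "planted_log2fc": cfg.planted_log2fc,
    }
    return SimulatedReference(counts, meta, truth)


# ---------------------------------------------------------------------------
# bulk survival cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Bulk cohort whose hazard depends on a latent M2 activity.

    Each sample has a latent standard-normal M2 activity z; signature genes
    express base + slope * z (slopes uniform in [0.3, 0.7], E units, noise sd
    0.4), background genes are noise around their base. Survival is
    exponential with hazard = baseline_hazard * exp(quartile_log_hr * z /
    delta), where delta is the expected top-minus-bottom-quartile mean gap of
    a standard normal (~2.542), so exp(quartile_log_hr) is the planted hazard
    ratio between the high and low quartile groups. Censoring is independent
    Uniform(0, tau) with tau solved so the expected censored fraction matches
    ``censoring_fraction``.
    """

    seed: int = 0
    n_samples: int = 300
    n_background_genes: int = 200
    baseline_hazard: float = np.log(2.0) / 730.0  # median survival ~2 years
    quartile_log_hr: float = float(np.log(2.5))
    censoring_fraction: float = 0.2
    signature_slope_range: tuple[float, float] = (0.3, 0.7)
    noise_sd: float = 0.4
    tag: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ConfigError("censoring_fraction must lie in [0, 1)")
        if not np.isfinite(self.quartile_log_hr):
            raise ConfigError("quartile_log_hr must be finite")


def _quartile_gap() -> float:
    q = stats.norm.ppf(0.75)
    return float(2.0 * stats.norm.pdf(q) / 0.25)


def simulate_bulk_cohort(
    cfg: CohortConfig,
    signature_genes: Sequence[str],
) -> tuple[SurvivalCohort, dict]:
    """Simulate a bulk cohort with signature-linked hazard; returns (cohort, truth)."""
    rng = np.random.default_rng(cfg.seed)
    sig = list(dict.fromkeys(signature_genes))
    if not sig:
        raise ConfigError("need at least one signature gene")
    samples = pd.Index([f"S{i + 1:04d}" for i in range(cfg.n_samples)], name="sample_id")

    z = rng.standard_normal(cfg.n_samples)
    lo, hi = cfg.signature_slope_range
    slopes = rng.uniform(lo, hi, size=len(sig))
    base_sig = rng.uniform(1.0, 4.0, size=len(sig))
    sig_expr = (
        base_sig[:, None]
        + slopes[:, None] * z[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(sig), cfg.n_samples))
    )
    bg_ids = [f"BG{i + 1:05d}" for i in range(cfg.n_background_genes)]
    base_bg = rng.uniform(0.5, 4.0, size=cfg.n_background_genes)
    bg_expr = base_bg[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_background_genes, cfg.n_samples))

    expr = np.clip(np.vstack([sig_expr, bg_expr]), 0.0, None)  # E units are >= 0
    expression = pd.DataFrame(expr, index=pd.Index(sig + bg_ids, name="gene_id"), columns=samples)

    delta = _quartile_gap()
    lam = cfg.baseline_hazard * np.exp(cfg.quartile_log_hr * z / delta)
    t_event = rng.exponential(1.0 / lam)

    if cfg.censoring_fraction > 0:
        def mean_censored(tau: float) -> float:
            lt = lam * tau
            return float(np.mean((1.0 - np.exp(-lt)) / lt))

        lo_t, hi_t = 1e-6, 1e12
        tau = optimize.brentq(lambda t: mean_censored(t) - cfg.censoring_fraction, lo_t, hi_t)
        c = rng.uniform(0.0, tau, size=cfg.n_samples)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time = t_event
        event = np.ones(cfg.n_samples, dtype=int)
    time = np.maximum(time, 1e-6)  # survival times must be > 0

    clinical = pd.DataFrame(
        {"os_days": time, "os_event": event, "stage": "IV"},
        index=samples,
    )
    cohort = SurvivalCohort(expression, clinical, tag=cfg.tag)
    truth = {"z": pd.Series(z, index=samples), "lambda": pd.Series(lam, index=samples),
             "quartile_gap": delta, "signature_genes": sig}
    return cohort, truth


def with_seed(cfg, seed: int):
    """Copy a frozen config with a new seed."""
    return replace(cfg, seed=seed)
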