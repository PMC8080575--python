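"""Signature-based survival stratification in bulk cohorts.

Samples are scored with a gene signature (mean E over detected signature
genes, E = log2(TPM/10 + 1)), stratified into a 'high' group (score above the
75th percentile) and a 'low' group (below the 25th percentile) with the
middle half excluded, and compared by Kaplan-Meier curves and the two-group
log-rank test. Per-gene and leave-one-out variants probe how much of a
signature's prognostic value rests on individual genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .signatures import SignatureSet, signature_score

__all__ = [
    "SurvivalCohort",
    "KMResult",
    "quartile_groups",
    "km_logrank",
    "signature_survival",
    "gene_level_survival",
    "leave_one_out_signature_survival",
    "read_cohort",
]


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalCohort:
    """Bulk expression plus survival metadata for one cohort.

    ``expression`` is genes x samples in E units (log2(TPM/10+1));
    ``clinical`` is indexed by sample id with columns ``os_days`` (> 0),
    ``os_event`` (1 = death) and optionally ``stage``. Stage is carried as
    metadata only.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.clinical.index.is_unique:
            raise SurvivalError("duplicate sample ids in clinical table")
        missing = self.expression.columns.difference(self.clinical.index)
        if len(missing):
            raise SurvivalError(f"samples missing clinical data: {missing.tolist()[:5]}")
        self.clinical = self.clinical.loc[self.expression.columns]
        if (self.clinical["os_days"] <= 0).any():
            raise SurvivalError("survival times must be > 0")
        if not self.clinical["os_event"].isin([0, 1]).all():
            raise SurvivalError("os_event must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class KMResult:
    """Quartile-group assignment, per-group KM curves, and the log-rank test."""

    groups: pd.Series  # high / low / excluded per sample
    curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    statistic: float
    p: float
    thresholds: dict = field(default_factory=dict)


def quartile_groups(scores: pd.Series) -> pd.Series:
    """Stratify scores: 'high' strictly above the 75th percentile, 'low'
    strictly below the 25th, everything else (incl. boundary ties) 'excluded'.

    Percentiles use linear interpolation.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 8:
        raise SurvivalError(f"need >= 8 samples for quartile stratification, got {x.size}")
    if np.all(x == x[0]):
        raise SurvivalError("all scores identical; quartile groups undefined")
    q25, q75 = np.percentile(x, [25, 75])
    labels = np.where(x > q75, "high", np.where(x < q25, "low", "excluded"))
    return pd.Series(labels, index=scores.index, name="group")


def km_logrank(cohort: SurvivalCohort, groups: pd.Series) -> KMResult:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``groups`` maps each sample to high/low/excluded; excluded samples are
    ignored. The log-rank chi-square has 1 df; ties are handled by the
    simultaneous-risk-set convention with the standard hypergeometric
    variance.
    """
    groups = groups.loc[cohort.sample_ids]
    curves: dict[str, pd.DataFrame] = {}
    subsets = {}
    for g in ("high", "low"):
        ids = groups.index[groups == g]
        if len(ids) == 0:
            raise SurvivalError(f"group {g!r} is empty")
        subsets[g] = cohort.clinical.loc[ids]
    if int(subsets["high"]["os_event"].sum() + subsets["low"]["os_event"].sum()) < 1:
        raise SurvivalError("no events in either group; log-rank undefined")

    for g, clin in subsets.items():
        kmf = KaplanMeierFitter()
        kmf.fit(clin["os_days"], clin["os_event"], label=g)
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[g].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )

    res = logrank_test(
        subsets["high"]["os_days"], subsets["low"]["os_days"],
        event_observed_A=subsets["high"]["os_event"],
        event_observed_B=subsets["low"]["os_event"],
    )
    full_groups = groups.reindex(cohort.sample_ids).fillna("excluded")
    return KMResult(
        groups=full_groups,
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        thresholds={"rule": "strict 25th/75th percentile"},
    )


def signature_survival(cohort: SurvivalCohort, signature: SignatureSet) -> KMResult:
    """Score the cohort with a signature, stratify by quartiles, and test."""
    score = signature_score(cohort.expression, signature)
    groups = quartile_groups(score.scores)
    return km_logrank(cohort, groups)


def gene_level_survival(cohort: SurvivalCohort, gene_id: str) -> KMResult:
    """Quartile stratification and log-rank test on a single gene's expression."""
    if gene_id not in cohort.expression.index:
        raise SurvivalError(f"gene {gene_id!r} not in cohort expression")
    groups = quartile_groups(cohort.expression.loc[gene_id])
    return km_logrank(cohort, groups)


def leave_one_out_signature_survival(
    cohort: SurvivalCohort,
    signature: SignatureSet,
) -> pd.DataFrame:
    """Log-rank p after dropping each signature gene in turn.

    Probes whether the signature's association with survival hinges on any
    single gene. Returns a table indexed by the left-out gene with the
    log-rank statistic and p of the reduced signature.
    """
    if len(signature) < 2:
        raise SurvivalError("need a signature of >= 2 genes for leave-one-out")
    rows = []
    for gene in signature.genes:
        reduced = signature.drop(gene)
        res = signature_survival(cohort, reduced)
        rows.append((gene, res.statistic, res.p))
    return pd.DataFrame(rows, columns=["left_out", "statistic", "p"]).set_index("left_out")


def read_cohort(
    expression_tsv: str | Path,
    clinical_tsv: str | Path,
    tag: str = "",
) -> SurvivalCohort:
    """Read a cohort from a genes x samples expression TSV and a clinical TSV.

    The clinical table needs columns sample_id, os_days, os_event (and
    optionally stage).
    """
    expr = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    clin = pd.read_csv(clinical_tsv, sep="\t").set_index("sample_id")
    return SurvivalCohort(expr, clin, tag=tag)
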