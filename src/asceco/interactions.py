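"""Ligand-receptor interaction enumeration between cell groups.

A curated pair list (FANTOM5-style, optionally extended with cytokine and
chemokine pairs) is intersected with binary expression calls (E > 1). An
ordered cell pair (c1, c2), c1 != c2, with c1 expressing the ligand and c2
the receptor counts as one "intercellular interaction" for the direction
senderGroup > receiverGroup; a single cell expressing both genes counts as
"self-sufficient signaling" for its group. A cell expressing both still
partners in intercellular counts with other cells — the two tallies are
independent categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairDatabase",
    "InteractionTally",
    "read_pairs_tsv",
    "binarize_expression",
    "count_interactions",
    "rank_top_pairs",
    "label_salient_genes",
]

logger = logging.getLogger(__name__)


class InteractionError(ValueError):
    pass


@dataclass
class PairDatabase:
    """Curated ligand-receptor pairs with a source tag per pair.

    ``pairs`` columns: ligand, receptor, source. (ligand, receptor) pairs are
    unique; merging databases keeps the first source seen for a duplicate.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"ligand", "receptor", "source"}
        if not need.issubset(self.pairs.columns):
            raise InteractionError(f"pair table needs columns {sorted(need)}")
        p = self.pairs.astype({"ligand": str, "receptor": str, "source": str})
        if (p["ligand"].str.len() == 0).any() or (p["receptor"].str.len() == 0).any():
            raise InteractionError("empty gene id in pair table")
        self.pairs = p.drop_duplicates(subset=["ligand", "receptor"], keep="first").reset_index(drop=True)

    def merge(self, other: "PairDatabase") -> "PairDatabase":
        return PairDatabase(pd.concat([self.pairs, other.pairs], ignore_index=True))

    def __len__(self) -> int:
        return len(self.pairs)


def read_pairs_tsv(path: str | Path, source: str | None = None) -> PairDatabase:
    """Read a pair table (TSV, header ``ligand  receptor  source``).

    A two-column file is accepted if ``source`` is given explicitly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if "source" not in df.columns:
        if source is None:
            raise InteractionError("pair table lacks a source column and no source tag given")
        df["source"] = source
    return PairDatabase(df[["ligand", "receptor", "source"]])


@dataclass
class InteractionTally:
    """Interaction counts per pair and direction.

    Attributes
    ----------
    intercellular
        Long-format counts with columns ligand, receptor, sender, receiver,
        count — ordered distinct cell pairs (sender expresses ligand,
        receiver expresses receptor).
    self_sufficient
        Columns ligand, receptor, group, count — single cells expressing both.
    threshold
        The E threshold used for the binary expression call.
    skipped_pairs
        Pairs whose ligand or receptor was absent from the matrix.
    """

    intercellular: pd.DataFrame
    self_sufficient: pd.DataFrame
    threshold: float
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def directions(self) -> list[tuple[str, str]]:
        return sorted(
            set(zip(self.intercellular["sender"], self.intercellular["receiver"]))
        )


def binarize_expression(E, threshold: float = 1.0) -> pd.DataFrame:
    """Binary expression call: True iff E strictly exceeds ``threshold``."""
    if threshold < 0:
        raise InteractionError("threshold must be >= 0")
    values = E if isinstance(E, pd.DataFrame) else E.values
    return values > threshold


def count_interactions(
    binary: pd.DataFrame,
    db: PairDatabase,
    groups: pd.Series,
    threshold: float = 1.0,
) -> InteractionTally:
    """Tally intercellular and self-sufficient expression pairs per group pair.

    For each (ligand L, receptor R) and ordered group pair (g1, g2):
    intercellular = #{(c1, c2): c1 != c2, c1 in g1 expresses L, c2 in g2
    expresses R}; self-sufficient(g) = #{c in g expressing both L and R}.
    Pairs with either gene absent from the matrix are skipped and logged.
    """
    groups = groups.astype(str)
    unlabeled = binary.columns.difference(groups.index)
    if len(unlabeled):
        raise InteractionError(f"unlabeled cells: {unlabeled.tolist()[:5]}")
    groups = groups.loc[binary.columns]
    group_names = sorted(groups.unique())

    # per-group expresser counts for every gene: group x gene
    arr = binary.to_numpy()
    gidx = {g: np.flatnonzero((groups == g).to_numpy()) for g in group_names}
    expr_per_group = {g: arr[:, idx] for g, idx in gidx.items()}
    n_expr = pd.DataFrame(
        {g: m.sum(axis=1) for g, m in expr_per_group.items()}, index=binary.index
    )

    inter_rows = []
    self_rows = []
    skipped = []
    present = set(binary.index)
    for lig, rec in zip(db.pairs["ligand"], db.pairs["receptor"]):
        if lig not in present or rec not in present:
            skipped.append((lig, rec))
            continue
        lrow = binary.loc[lig].to_numpy()
        rrow = binary.loc[rec].to_numpy()
        both = lrow & rrow
        for g in group_names:
            self_rows.append((lig, rec, g, int(both[gidx[g]].sum())))
        for g1 in group_names:
            nl = int(n_expr.at[lig, g1])
            for g2 in group_names:
                nr = int(n_expr.at[rec, g2])
                count = nl * nr
                if g1 == g2:
                    count -= int(both[gidx[g1]].sum())  # remove c1 == c2
                inter_rows.append((lig, rec, g1, g2, count))
    if skipped:
        logger.info("count_interactions: %d pairs skipped (gene absent): %s",
                    len(skipped), skipped[:5])

    inter = pd.DataFrame(inter_rows, columns=["ligand", "receptor", "sender", "receiver", "count"])
    self_df = pd.DataFrame(self_rows, columns=["ligand", "receptor", "group", "count"])
    return InteractionTally(inter, self_df, threshold=threshold, skipped_pairs=skipped)


def rank_top_pairs(
    tally: InteractionTally,
    direction: tuple[str, str],
    n: int = 10,
) -> pd.DataFrame:
    """Top-n pairs for one sender > receiver direction, by descending count.

    Ties are broken by (ligand, receptor) lexicographic order. Returns at most
    ``n`` rows with columns ligand, receptor, count.
    """
    if n < 1:
        raise InteractionError("n must be >= 1")
    sender, receiver = direction
    sub = tally.intercellular
    known = set(zip(sub["sender"], sub["receiver"]))
    if (sender, receiver) not in known:
        raise InteractionError(
            f"unknown direction {direction}; known: {sorted(known)}"
        )
    sub = sub[(sub["sender"] == sender) & (sub["receiver"] == receiver)]
    sub = sub.sort_values(
        ["count", "ligand", "receptor"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return sub.head(n)[["ligand", "receptor", "count"]]


def label_salient_genes(
    E,
    genes: Sequence[str],
    q: float = 0.95,
    min_frac: float = 0.75,
    cells: Sequence[str] | None = None,
    expr_threshold: float = 1.0,
) -> list[str]:
    """Genes both strongly and commonly expressed within a cell group.

    Among ``genes``, returns those whose mean E across the group's cells
    strictly exceeds the ``q``-quantile of the subset's mean-E distribution
    (linear-interpolation quantile) AND whose fraction of expressing cells
    (E > ``expr_threshold``) strictly exceeds ``min_frac``.
    """
    if not 0 <= q <= 1 or not 0 <= min_frac <= 1:
        raise InteractionError("q and min_frac must lie in [0, 1]")
    values = E if isinstance(E, pd.DataFrame) else E.values
    genes = [g for g in genes if g in values.index]
    if not genes:
        raise InteractionError("empty gene subset (no subset gene found in the matrix)")
    sub = values.loc[genes]
    if cells is not None:
        sub = sub[list(cells)]
    mean_e = sub.mean(axis=1)
    cutoff = float(np.quantile(mean_e.to_numpy(), q))  # type-7 linear interpolation
    frac = (sub > expr_threshold).mean(axis=1)
    keep = (mean_e > cutoff) & (frac > min_frac)
    return mean_e.index[keep].tolist()
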