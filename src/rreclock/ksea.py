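"""Kinase-substrate enrichment scoring of phosphoproteome tables.

Site abundances are normalized per site to the mean of that site's WT
samples and log2-transformed; a kinase's activity score is the plain mean
of the log2 fold changes of its mapped substrate sites in the condition of
interest (positive = increased substrate phosphorylation).  Shared
substrates count for every kinase listing them, and no minimum-substrate
filter is applied — the substrate count is reported so users can filter.

Zero abundances are treated as missing before the log; missing values are
excluded pairwise from every mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ("site_id", "protein", "residue", "position")
VALID_RESIDUES = frozenset("STY")


def validate_phospho_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the site metadata columns and residue letters."""
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phospho table lacks column(s) {missing}")
    bad = set(table["residue"].unique()) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid phospho-residue letter(s): {sorted(bad)}")
    return table


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in SITE_COLUMNS]


def condition_of(column: str) -> str:
    """Condition label of a sample column (prefix before the last '_')."""
    return column.rsplit("_", 1)[0]


def normalize_to_wt_mean(
    table: pd.DataFrame, wt_condition: str = "WT"
) -> pd.DataFrame:
    """Per-site log2 fold change versus the site's WT-sample mean.

    Sites whose WT mean is zero or entirely missing are dropped (the count
    is logged).  Returns a frame indexed by site_id with the original sample
    columns.
    """
    validate_phospho_table(table)
    cols = sample_columns(table)
    wt_cols = [c for c in cols if condition_of(c) == wt_condition]
    if not wt_cols:
        raise ValueError(f"no sample columns for condition {wt_condition!r}")
    values = table[cols].astype(float).where(lambda v: v > 0)  # 0 -> missing
    wt_mean = values[wt_cols].mean(axis=1)
    keep = wt_mean > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d site(s) with zero/missing WT mean", n_dropped
        )
    if not keep.any():
        raise ValueError("all sites dropped during WT normalization")
    log2fc = np.log2(values[keep].div(wt_mean[keep], axis=0))
    log2fc.index = pd.Index(table.loc[keep, "site_id"], name="site_id")
    return log2fc


@dataclass(frozen=True)
class KinaseScore:
    kinase: str
    score: float  # mean substrate log2 fold change
    n_substrates: int


def load_kinase_map(path: str | Path) -> dict[str, set[str]]:
    """Read a kinase -> substrate-site map from a 2-column TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"kinase", "site_id"} <= set(df.columns):
        raise ValueError("kinase map needs 'kinase' and 'site_id' columns")
    out: dict[str, set[str]] = {}
    for kinase, grp in df.groupby("kinase"):
        sites = set(grp["site_id"].astype(str))
        if sites:
            out[str(kinase)] = sites
    return out


def kinase_activity_scores(
    log2fc: pd.DataFrame,
    kinase_map: dict[str, set[str]],
    condition: str = "MUT",
) -> list[KinaseScore]:
    """Mean substrate log2FC per kinase for one condition's samples.

    Per substrate site, the condition's samples are averaged first (missing
    excluded pairwise); the kinase score is the mean over its measured
    substrates.  Kinases with no measured substrate are omitted and logged.
    """
    cols = [c for c in log2fc.columns if condition_of(c) == condition]
    if not cols:
        raise ValueError(f"no sample columns for condition {condition!r}")
    site_fc = log2fc[cols].mean(axis=1)
    scores = []
    for kinase in sorted(kinase_map):
        hit = site_fc.loc[site_fc.index.intersection(kinase_map[kinase])].dropna()
        if hit.empty:
            logger.info("kinase %s has no measured substrates; omitted", kinase)
            continue
        scores.append(KinaseScore(kinase, float(hit.mean()), int(hit.size)))
    return scores


def scores_to_frame(scores: list[KinaseScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.kinase, s.score, s.n_substrates) for s in scores],
        columns=["kinase", "score", "n_substrates"],
    )


def residue_composition(table: pd.DataFrame) -> dict[str, float]:
    """Fractions of phosphosites by residue (S/T/Y), summing to 1."""
    validate_phospho_table(table)
    if len(table) == 0:
        raise ValueError("empty phospho table")
    counts = table["residue"].value_counts()
    total = float(counts.sum())
    return {res: float(n) / total for res, n in counts.items()}
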