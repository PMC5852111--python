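"""Differentially abundant membrane protein (DAMP) calling and accounting.

A consensus membrane protein quantified in all replicate sets is called
up-regulated at a time point when its mean reporter ratio is at or above
the fold cutoff (default 1.4) with p at or below the threshold (default
0.05), down-regulated at or below the reciprocal (1/1.4 = 0.714), and
unchanged otherwise.  Cross-genotype overlap tables stratify counts by
time point and direction; common membership requires the same protein
ID and matching direction.  Functional-category tabulation and a
hypergeometric enrichment test operate on a user-supplied annotation
table.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CutoffParams

TIMEPOINTS = ("3h", "6h")
DIRECTIONS = ("up", "down")

CALL_COLUMNS = ["protein_id", "genotype", "timepoint", "direction", "fold", "p"]


def round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (printed-percentage style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def union_percentage(total_a: int, total_b: int, common: int) -> int:
    """Integer percentage of common members over the union of two sets."""
    denom = total_a + total_b - common
    if denom == 0:
        return 0
    return round_half_away(100.0 * common / denom)


def call_damps(
    quant: pd.DataFrame,
    membrane_ids: Iterable[str],
    cutoff: CutoffParams | None = None,
    n_replicate_sets: int = 3,
) -> pd.DataFrame:
    """Call DAMPs from a quantitation table with p-values attached.

    Eligible proteins are consensus membrane proteins quantified in all
    ``n_replicate_sets`` sets of a genotype.  The fold per time point is
    the mean of the per-set weighted-average ratios; thresholds are
    inclusive (fold >= cutoff / fold <= 1/cutoff, p <= threshold).
    Returns one row per eligible protein and time point, including
    direction "unchanged"; proteins missing a replicate set are counted
    in ``result.attrs["n_excluded_missing_sets"]``.
    """
    cutoff = cutoff or CutoffParams()
    membrane = set(membrane_ids)
    rows = []
    n_excluded = 0
    for (genotype, pid), sub in quant.groupby(["genotype", "protein_id"], sort=True):
        if pid not in membrane:
            continue
        if sub["replicate_set"].nunique() < n_replicate_sets:
            n_excluded += 1
            continue
        for tp, rcol, pcol in (("3h", "r115", "p_3h"), ("6h", "r116", "p_6h")):
            fold = float(sub[rcol].mean())
            p = float(sub[pcol].iloc[0])
            if p <= cutoff.p_threshold and fold >= cutoff.fold_cutoff:
                direction = "up"
            elif p <= cutoff.p_threshold and fold <= cutoff.down_cutoff:
                direction = "down"
            else:
                direction = "unchanged"
            rows.append((pid, genotype, tp, direction, fold, p))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls.attrs["n_excluded_missing_sets"] = n_excluded
    return calls


def _direction_map(calls: pd.DataFrame, timepoint: str) -> dict[str, str]:
    sub = calls[(calls["timepoint"] == timepoint) & (calls["direction"] != "unchanged")]
    return dict(zip(sub["protein_id"], sub["direction"]))


def overlap_table(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    match_direction: bool = True,
) -> pd.DataFrame:
    """Cross-genotype DAMP overlap counts per time point and direction.

    For each stratum: total_a, unique_a, total_b, unique_b, common, and
    the common percentage over the union (nearest integer).  "Common"
    requires the same protein ID and, by default, the same direction;
    the per-time-point "total" stratum sums direction-matched commons.
    With ``match_direction=False`` common membership is by protein ID
    alone.
    """
    rows = []
    for tp in TIMEPOINTS:
        da = _direction_map(calls_a, tp)
        db = _direction_map(calls_b, tp)
        if match_direction:
            common_ids = {p for p in da.keys() & db.keys() if da[p] == db[p]}
        else:
            common_ids = da.keys() & db.keys()
        for stratum, keep in (
            ("total", DIRECTIONS),
            ("up", ("up",)),
            ("down", ("down",)),
        ):
            a_ids = {p for p, d in da.items() if d in keep}
            b_ids = {p for p, d in db.items() if d in keep}
            if stratum == "total":
                common = len(common_ids)
            elif match_direction:
                common = len({p for p in common_ids if da[p] == stratum})
            else:
                common = len(a_ids & b_ids)
            rows.append(
                {
                    "timepoint": tp,
                    "stratum": stratum,
                    "total_a": len(a_ids),
                    "unique_a": len(a_ids) - common,
                    "total_b": len(b_ids),
                    "unique_b": len(b_ids) - common,
                    "common": common,
                    "common_pct": union_percentage(len(a_ids), len(b_ids), common),
                }
            )
    return pd.DataFrame(rows)


def damp_protein_summary(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Distinct-protein DAMP accounting across time points and genotypes."""
    a = set(calls_a.loc[calls_a["direction"] != "unchanged", "protein_id"])
    b = set(calls_b.loc[calls_b["direction"] != "unchanged", "protein_id"])
    common = a & b
    return {
        "total_a": len(a),
        "total_b": len(b),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
        "common": len(common),
        "total_distinct": len(a | b),
    }


def category_counts(
    calls: pd.DataFrame, annotation: Mapping[str, Iterable[str]] | pd.DataFrame
) -> pd.DataFrame:
    """Distinct DAMPs per functional category (multi-label; per genotype).

    ``annotation`` maps protein_id -> category labels (or a two-column
    DataFrame).  A protein with k labels contributes to k categories;
    DAMPs without any label land in "unannotated".
    """
    if isinstance(annotation, pd.DataFrame):
        ann: dict[str, list[str]] = {}
        for pid, label in zip(annotation.iloc[:, 0], annotation.iloc[:, 1]):
            ann.setdefault(str(pid), []).append(str(label))
    else:
        ann = {pid: list(labels) for pid, labels in annotation.items()}
    damps = calls[calls["direction"] != "unchanged"]
    rows = []
    for genotype, sub in damps.groupby("genotype"):
        for pid in sorted(set(sub["protein_id"])):
            labels = ann.get(pid) or ["unannotated"]
            for label in set(labels):
                rows.append((genotype, label, pid))
    frame = pd.DataFrame(rows, columns=["genotype", "category", "protein_id"])
    out = (
        frame.groupby(["genotype", "category"])["protein_id"]
        .nunique()
        .reset_index(name="n_damps")
    )
    return out


def enrich(
    category_members: Iterable[str],
    selected: Iterable[str],
    background: Iterable[str],
) -> float:
    """One-sided hypergeometric upper-tail p-value for over-representation.

    P(X >= k) where k = |category ∩ selected|, drawing |selected| from a
    background of which |category| are category members.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    cat = set(category_members)
    sel = set(selected)
    if not cat <= bg or not sel <= bg:
        raise ValueError("category and selection must be subsets of the background")
    k = len(cat & sel)
    return float(stats.hypergeom.sf(k - 1, len(bg), len(cat), len(sel)))


def adjust_bh(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is default)."""
    return stats.false_discovery_control(np.asarray(list(pvalues), dtype=float))
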