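"""PSM filtering by score and target-decoy FDR; protein inference.

The false-discovery rate at a score threshold is estimated with the
target-decoy strategy as (decoys passing) / (targets passing), computed
independently within each replicate set.  PSMs are retained at the most
permissive score cutoff at or above the floor (default 20) whose
estimated FDR is at or below the limit (default 2%); ties at the cutoff
are kept.  Confident proteins must have at least two unique (single-
parent) peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FilterParams:
    min_score: float = 20.0
    max_fdr: float = 0.02
    min_unique_peptides: int = 2

    def __post_init__(self):
        if not 0.0 < self.max_fdr < 1.0:
            raise ValueError("max_fdr must lie in (0, 1)")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")


def estimate_fdr(psms: pd.DataFrame, score_threshold: float) -> float | None:
    """Target-decoy FDR = decoys passing / targets passing.

    Returns 0.0 when no decoy passes and ``None`` (the "no
    identifications" outcome) when no target passes.
    """
    if len(psms) == 0:
        return None
    passing = psms[psms["score"] >= score_threshold]
    n_target = int((~passing["is_decoy"]).sum())
    if n_target == 0:
        return None
    return float(passing["is_decoy"].sum()) / n_target


def _group_cutoff(group: pd.DataFrame, params: FilterParams) -> tuple[float, float] | None:
    """Smallest score cutoff >= min_score with FDR <= max_fdr, or None.

    Evaluated at min_score and every distinct observed score above it;
    cumulative counts on the score-sorted table make the scan O(n log n).
    """
    scores = group["score"].to_numpy()
    decoy = group["is_decoy"].to_numpy()
    order = np.argsort(scores)[::-1]  # descending
    s_sorted = scores[order]
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    candidates = np.unique(s_sorted[s_sorted >= params.min_score])  # ascending
    candidates = np.concatenate(([params.min_score], candidates))
    for c in candidates:
        k = np.searchsorted(-s_sorted, -c, side="right")  # PSMs with score >= c
        if k == 0 or t_cum[k - 1] == 0:
            continue
        fdr = d_cum[k - 1] / t_cum[k - 1]
        if fdr <= params.max_fdr:
            return float(c), float(fdr)
    return None


def filter_psms(
    psms: pd.DataFrame,
    params: FilterParams | None = None,
    return_report: bool = False,
):
    """Score + FDR filter, per (genotype, replicate set); decoys removed.

    The returned table is always a subset of the input.  With
    ``return_report=True`` also returns a per-group report of the chosen
    cutoff, achieved FDR, and counts.
    """
    params = params or FilterParams()
    kept: list[pd.DataFrame] = []
    report_rows = []
    if len(psms):
        for (genotype, rep), group in psms.groupby(
            ["genotype", "replicate_set"], sort=True
        ):
            found = _group_cutoff(group, params)
            if found is None:
                report_rows.append(
                    dict(genotype=genotype, replicate_set=rep, cutoff=np.nan,
                         achieved_fdr=np.nan, n_in=len(group), n_out=0)
                )
                continue
            cutoff, fdr = found
            out = group[(group["score"] >= cutoff) & ~group["is_decoy"]]
            kept.append(out)
            report_rows.append(
                dict(genotype=genotype, replicate_set=rep, cutoff=cutoff,
                     achieved_fdr=fdr, n_in=len(group), n_out=len(out))
            )
    filtered = (
        pd.concat(kept).sort_index() if kept else psms.iloc[0:0]
    )
    if return_report:
        return filtered, pd.DataFrame(
            report_rows,
            columns=["genotype", "replicate_set", "cutoff", "achieved_fdr",
                     "n_in", "n_out"],
        )
    return filtered


def _shared_peptides(psms: pd.DataFrame) -> set[str]:
    """Peptides whose PSMs map to more than one (target) protein."""
    parents = psms.groupby("peptide")["protein_id"].nunique()
    return set(parents.index[parents > 1])


def infer_proteins(
    filtered: pd.DataFrame, min_unique_peptides: int = 2
) -> dict[tuple[str, str], dict[str, frozenset[str]]]:
    """Confident proteins per (genotype, replicate set).

    Peptides mapping to more than one protein are discarded entirely
    (the uniqueness rule); a protein is retained in a replicate set when
    it has at least ``min_unique_peptides`` distinct unique peptides
    there.  Returns {(genotype, set): {protein_id: peptide set}}.
    """
    out: dict[tuple[str, str], dict[str, frozenset[str]]] = {}
    if len(filtered) == 0:
        return out
    unique = filtered[~filtered["peptide"].isin(_shared_peptides(filtered))]
    grouped = unique.groupby(["genotype", "replicate_set", "protein_id"])["peptide"]
    for (genotype, rep, pid), peps in grouped:
        distinct = frozenset(peps)
        if len(distinct) >= min_unique_peptides:
            out.setdefault((genotype, rep), {})[pid] = distinct
    return out


def quantifiable_psms(
    filtered: pd.DataFrame,
    inferred: dict[tuple[str, str], dict[str, frozenset[str]]],
) -> pd.DataFrame:
    """Restrict filtered PSMs to unique peptides of confident proteins."""
    if len(filtered) == 0:
        return filtered
    shared = _shared_peptides(filtered)
    mask = np.zeros(len(filtered), dtype=bool)
    keys = list(
        zip(filtered["genotype"], filtered["replicate_set"], filtered["protein_id"])
    )
    for i, ((g, r, pid), pep) in enumerate(zip(keys, filtered["peptide"])):
        if pep in shared:
            continue
        retained = inferred.get((g, r), {})
        mask[i] = pid in retained
    return filtered[mask]
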