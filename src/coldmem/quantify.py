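"""Reporter-ratio quantitation, replicate concordance, and cutoffs.

Peptide-level reporter ratios (115/114 for 3 h vs 0 h, 116/114 for 6 h
vs 0 h) roll up to protein ratios as an intensity-weighted average.
Replicate concordance is summarised by pairwise OLS slopes of log2
ratios, the significance fold cutoff derives from the mean absolute
pairwise log2 deviation across replicate sets (the "internal error"),
and differential abundance is tested with a two-sided equal-variance
two-sample t-test on log2 channel intensities across replicate sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CutoffParams:
    """Fold-change and p-value thresholds for differential calling.

    ``d_log2`` is the average internal replicate error on the log2
    scale; the fold cutoff is exactly ``2**d_log2``.  The default is the
    published criterion of a 1.4-fold change (d_log2 = log2 1.4), with a
    raw p <= 0.05.
    """

    d_log2: float = field(default_factory=lambda: math.log2(1.4))
    p_threshold: float = 0.05

    def __post_init__(self):
        if self.d_log2 < 0:
            raise ValueError("d_log2 must be >= 0")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")

    @property
    def fold_cutoff(self) -> float:
        return 2.0 ** self.d_log2

    @property
    def down_cutoff(self) -> float:
        return 2.0 ** -self.d_log2


class SlopeResult(NamedTuple):
    slope: float
    intercept: float
    n: int


def peptide_ratios(i114: float, i115: float, i116: float) -> tuple[float, float]:
    """Reporter ratios (115/114, 116/114) for one PSM.

    A zero reference channel makes the PSM unquantifiable (raises).
    """
    if i114 <= 0:
        raise ValueError("reference channel i114 is zero; PSM unquantifiable")
    return i115 / i114, i116 / i114


def protein_ratio(
    ratios: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted average of peptide ratios; lies in [min, max] of inputs."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no peptide ratios for this protein/set")
    if weights is None:
        return float(r.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != r.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match ratios")
    return float(np.average(r, weights=w))


def replicate_slope(x: Sequence[float], y: Sequence[float]) -> SlopeResult | None:
    """OLS slope with free intercept for paired per-protein log2 ratios.

    Returns None (insufficient data) with fewer than 3 shared proteins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired by protein")
    if x.size < 3:
        return None
    fit = stats.linregress(x, y)
    return SlopeResult(float(fit.slope), float(fit.intercept), int(x.size))


def internal_error_cutoff(
    ratio_sets: Sequence[Sequence[float]] | np.ndarray,
    p_threshold: float = 0.05,
) -> CutoffParams:
    """Derive the fold cutoff from replicate-to-replicate variation.

    ``ratio_sets`` holds one log2-ratio vector per replicate set over a
    common protein panel (aligned by position).  The internal error of a
    protein for a set pair is the absolute difference of its log2
    ratios; each pair is averaged over proteins and d_log2 is the mean
    over all pairs.  Invariant to set permutation and to adding a
    constant to every set.
    """
    mat = np.asarray(ratio_sets, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 replicate sets of aligned log2 ratios")
    pair_means = [
        float(np.mean(np.abs(mat[i] - mat[j])))
        for i, j in itertools.combinations(range(mat.shape[0]), 2)
    ]
    return CutoffParams(d_log2=float(np.mean(pair_means)), p_threshold=p_threshold)


def differential_test(ctrl: Sequence[float], trt: Sequence[float]) -> float:
    """Two-sided, equal-variance two-sample t-test p-value.

    ``ctrl``/``trt`` are log2 intensities of the 0 h and treated channel
    across replicate sets.  Degenerate zero-variance inputs: p = 1 when
    the means are also equal, else the p -> 0 limit.
    """
    a = np.asarray(ctrl, dtype=float)
    b = np.asarray(trt, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite intensity")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(b, a, equal_var=True).pvalue)


def protein_quant_table(
    psms: pd.DataFrame,
    weighting: str = "intensity",
    normalize: bool = False,
) -> pd.DataFrame:
    """Per (genotype, replicate set, protein) quantitation rollup.

    Input: quantifiable PSMs (filtered, unique peptides of confident
    proteins).  PSMs with a zero reference channel are dropped.  Ratios
    are averaged in linear space with weight = summed reporter intensity
    of the PSM (``weighting="intensity"``) or unweighted
    (``weighting="none"``).  ``normalize`` median-centres log2 ratios
    within each (genotype, set) — off by default.

    Columns: protein_id, genotype, replicate_set, r115, r116,
    n_peptides, i114, i115, i116 (channel sums).
    """
    if weighting not in ("intensity", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    q = psms[psms["i114"] > 0].copy()
    q["_r115"] = q["i115"] / q["i114"]
    q["_r116"] = q["i116"] / q["i114"]
    q["_w"] = (
        q["i114"] + q["i115"] + q["i116"] if weighting == "intensity" else 1.0
    )
    q["_wr115"] = q["_w"] * q["_r115"]
    q["_wr116"] = q["_w"] * q["_r116"]
    g = q.groupby(["genotype", "replicate_set", "protein_id"], sort=True)
    out = g.agg(
        n_peptides=("peptide", "nunique"),
        i114=("i114", "sum"),
        i115=("i115", "sum"),
        i116=("i116", "sum"),
        _w=("_w", "sum"),
        _wr115=("_wr115", "sum"),
        _wr116=("_wr116", "sum"),
    ).reset_index()
    out["r115"] = out["_wr115"] / out["_w"]
    out["r116"] = out["_wr116"] / out["_w"]
    if normalize:
        for col in ("r115", "r116"):
            log = np.log2(out[col])
            med = log.groupby(
                [out["genotype"], out["replicate_set"]]
            ).transform("median")
            out[col] = np.exp2(log - med)
    return out[
        ["protein_id", "genotype", "replicate_set", "r115", "r116",
         "n_peptides", "i114", "i115", "i116"]
    ]


def add_pvalues(quant: pd.DataFrame, n_replicate_sets: int = 3) -> pd.DataFrame:
    """Attach p_3h/p_6h per (genotype, protein) present in every set.

    The t-test compares log2 channel-114 sums against log2 channel-115
    (3 h) or -116 (6 h) sums across the replicate sets.  Proteins
    missing any set get NaN p-values.
    """
    quant = quant.copy()
    quant["p_3h"] = np.nan
    quant["p_6h"] = np.nan
    for (_, _), idx in quant.groupby(["genotype", "protein_id"]).groups.items():
        sub = quant.loc[idx]
        if sub["replicate_set"].nunique() < n_replicate_sets:
            continue
        ctrl = np.log2(sub["i114"].to_numpy())
        quant.loc[idx, "p_3h"] = differential_test(ctrl, np.log2(sub["i115"].to_numpy()))
        quant.loc[idx, "p_6h"] = differential_test(ctrl, np.log2(sub["i116"].to_numpy()))
    return quant


def ratio_matrix(
    quant: pd.DataFrame, genotype: str, ratio: str = "r115"
) -> pd.DataFrame:
    """Proteins x replicate sets matrix of log2 ratios (complete cases)."""
    sub = quant[quant["genotype"] == genotype]
    wide = sub.pivot(index="protein_id", columns="replicate_set", values=ratio)
    wide = wide.dropna()
    return np.log2(wide)


def qc_report(quant: pd.DataFrame, genotype: str) -> dict:
    """Replicate-concordance slopes and the derived internal-error cutoff."""
    report: dict = {"genotype": genotype, "slopes": {}}
    mats = {}
    for ratio in ("r115", "r116"):
        mat = ratio_matrix(quant, genotype, ratio)
        mats[ratio] = mat
        sets = list(mat.columns)
        for a, b in itertools.combinations(sets, 2):
            res = replicate_slope(mat[a], mat[b])
            report["slopes"][f"{ratio} {a}/{b}"] = (
                None if res is None else round(res.slope, 4)
            )
    stacked = np.hstack(
        [mats["r115"].to_numpy().T, mats["r116"].to_numpy().T]
    )
    if stacked.shape[1] >= 10 and stacked.shape[0] >= 2:
        cut = internal_error_cutoff(stacked)
        report["d_log2"] = cut.d_log2
        report["fold_cutoff"] = cut.fold_cutoff
        report["n_common_proteins"] = int(min(len(mats["r115"]), len(mats["r116"])))
    else:
        report["d_log2"] = None
        report["fold_cutoff"] = None
    return report
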