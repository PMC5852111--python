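"""Transmembrane-segment prediction and the 2-of-3 membrane consensus.

Three independent predictor families are implemented, mirroring the
three families commonly combined for membrane-proteome filtering:

* ``hydropathy`` — sliding-window Kyte-Doolittle hydropathy (the classic
  window-19 / threshold-1.6 strong-transmembrane setting);
* ``dg_scale`` — windowed sum of apparent free energies of membrane
  insertion; windows with dG <= 0 kcal/mol favour insertion;
* ``hmm`` — a hand-parameterised topology hidden Markov model (inside
  loop / membrane helix / outside loop) decoded with Viterbi, where the
  helix macro-state is a chain of duplicated states enforcing a minimum
  helix length.

A protein is deemed a membrane protein (MP) when at least two of the
three predictors report at least one transmembrane segment.  Residue
coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scales import (
    AMINO_ACIDS,
    DG_INSERTION,
    KYTE_DOOLITTLE,
    residue_indices,
    scale_values,
)

Segment = tuple[int, int]

PREDICTORS = ("hydropathy", "dg_scale", "hmm")


@dataclass(frozen=True)
class TopologyPrediction:
    protein_id: str
    predictor: str
    segments: tuple[Segment, ...]

    @property
    def is_membrane(self) -> bool:
        return len(self.segments) > 0


def build_topology_hmm(
    min_helix_len: int = 15,
    p_enter: float = 0.015,
    p_exit: float = 0.15,
    helix_sharpness: float = 0.5,
) -> dict:
    """Hand-set topology HMM: two loop states and a helix chain.

    States 0 (inside loop) and 1 (outside loop) self-loop and may enter
    the helix chain (states 2 .. 1+min_helix_len); the chain advances
    deterministically so any decoded helix visit lasts at least
    ``min_helix_len`` residues (unless the sequence ends first), and the
    terminal chain state self-loops with exit probability ``p_exit`` to
    either loop.  Helix emissions are proportional to
    exp(helix_sharpness * Kyte-Doolittle); loop emissions are uniform.
    Probabilities are hand-set rather than trained so the model is fully
    specified and verifiable by exhaustive path enumeration.
    """
    m = int(min_helix_len)
    if m < 1:
        raise ValueError("min_helix_len must be >= 1")
    n_states = 2 + m
    A = np.zeros((n_states, n_states))
    for loop in (0, 1):
        A[loop, loop] = 1.0 - p_enter
        A[loop, 2] = p_enter
    for k in range(m - 1):
        A[2 + k, 3 + k] = 1.0
    last = 1 + m
    A[last, last] = 1.0 - p_exit
    A[last, 0] = p_exit / 2
    A[last, 1] = p_exit / 2
    pi = np.zeros(n_states)
    pi[0] = pi[1] = 0.5

    kd = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS])
    helix_emit = np.exp(helix_sharpness * kd)
    helix_emit /= helix_emit.sum()
    loop_emit = np.full(20, 1.0 / 20)
    E = np.vstack([loop_emit, loop_emit] + [helix_emit] * m)

    with np.errstate(divide="ignore"):
        return {
            "n_states": n_states,
            "min_helix_len": m,
            "log_start": np.log(pi),
            "log_trans": np.log(A),
            "log_emit": np.log(E),
            "is_helix": np.array([False, False] + [True] * m),
        }


@dataclass
class PredictorParams:
    """Shared knobs for the three predictors.

    window
        sliding-window width (odd); 19 is the classical strong-TM choice.
    hydropathy_threshold
        Kyte-Doolittle window mean above which a window centre seeds a
        hydrophobic segment (1.6 = stringent transmembrane setting).
    dg_threshold
        windowed insertion free energy (kcal/mol) at or below which a
        window seeds a segment; 0.0 = insertion is favourable.
    min_helix_len
        minimum reported segment length in residues.
    merge_gap
        adjacent seeded segments closer than this many residues are merged.
    """

    window: int = 19
    hydropathy_threshold: float = 1.6
    dg_threshold: float = 0.0
    min_helix_len: int = 15
    merge_gap: int = 3
    hmm: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.window < 9:
            raise ValueError("window must be >= 9")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.min_helix_len < 1:
            raise ValueError("min_helix_len must be >= 1")

    def get_hmm(self) -> dict:
        if self.hmm is None:
            self.hmm = build_topology_hmm(self.min_helix_len)
        return self.hmm


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def _window_runs_to_segments(
    runs: list[tuple[int, int]], window: int, min_len: int, merge_gap: int
) -> tuple[Segment, ...]:
    """Extend seed-window runs to window bounds, merge, filter by length."""
    spans = [[a, b + window - 1] for a, b in runs]  # 0-based residue spans
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple(
        (s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len
    )


def hydropathy_segments(
    seq: str, params: PredictorParams | None = None, protein_id: str = ""
) -> TopologyPrediction:
    """Sliding-window Kyte-Doolittle hydropathy predictor."""
    params = params or PredictorParams()
    w = params.window
    if len(seq) < w:
        if seq:
            scale_values(seq, KYTE_DOOLITTLE)  # still validate residues
        return TopologyPrediction(protein_id, "hydropathy", ())
    vals = scale_values(seq, KYTE_DOOLITTLE)
    means = np.convolve(vals, np.full(w, 1.0 / w), mode="valid")
    runs = _mask_runs(means > params.hydropathy_threshold)
    segs = _window_runs_to_segments(runs, w, params.min_helix_len, params.merge_gap)
    return TopologyPrediction(protein_id, "hydropathy", segs)


def dg_segments(
    seq: str, params: PredictorParams | None = None, protein_id: str = ""
) -> TopologyPrediction:
    """Insertion-free-energy predictor (windowed dG sum <= threshold)."""
    params = params or PredictorParams()
    w = params.window
    if len(seq) < w:
        if seq:
            scale_values(seq, DG_INSERTION)
        return TopologyPrediction(protein_id, "dg_scale", ())
    vals = scale_values(seq, DG_INSERTION)
    sums = np.convolve(vals, np.ones(w), mode="valid")
    runs = _mask_runs(sums <= params.dg_threshold)
    segs = _window_runs_to_segments(runs, w, params.min_helix_len, params.merge_gap)
    return TopologyPrediction(protein_id, "dg_scale", segs)


def viterbi_path(
    obs: np.ndarray,
    log_start: np.ndarray,
    log_trans: np.ndarray,
    log_emit: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log probability."""
    T = len(obs)
    n = len(log_start)
    delta = log_start + log_emit[:, obs[0]]
    back = np.zeros((T, n), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(n)] + log_emit[:, obs[t]]
    path = np.zeros(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    logp = float(delta[path[-1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


def hmm_topology(
    seq: str, params: PredictorParams | None = None, protein_id: str = ""
) -> TopologyPrediction:
    """Viterbi decoding of the topology HMM; helix runs become segments."""
    params = params or PredictorParams()
    if not seq:
        return TopologyPrediction(protein_id, "hmm", ())
    model = params.get_hmm()
    obs = residue_indices(seq)
    path, _ = viterbi_path(
        obs, model["log_start"], model["log_trans"], model["log_emit"]
    )
    helix = model["is_helix"][path]
    segs = tuple(
        (a + 1, b + 1)
        for a, b in _mask_runs(helix)
        if b - a + 1 >= params.min_helix_len
    )
    return TopologyPrediction(protein_id, "hmm", segs)


def consensus(preds: Sequence[TopologyPrediction]) -> bool:
    """Membrane verdict: at least 2 of exactly 3 predictors vote membrane."""
    if len(preds) != 3:
        raise ValueError(f"consensus requires exactly 3 predictions, got {len(preds)}")
    ids = {p.protein_id for p in preds}
    if len(ids) != 1:
        raise ValueError(f"predictions span multiple proteins: {sorted(ids)}")
    return sum(p.is_membrane for p in preds) >= 2


def predict_protein(
    seq: str, params: PredictorParams | None = None, protein_id: str = ""
) -> tuple[dict[str, TopologyPrediction], bool]:
    """Run all three predictors on one sequence and vote."""
    params = params or PredictorParams()
    preds = {
        "hydropathy": hydropathy_segments(seq, params, protein_id),
        "dg_scale": dg_segments(seq, params, protein_id),
        "hmm": hmm_topology(seq, params, protein_id),
    }
    return preds, consensus(list(preds.values()))


def _format_segments(preds: Mapping[str, TopologyPrediction]) -> str:
    parts = []
    for name in PREDICTORS:
        segs = ";".join(f"{s}-{e}" for s, e in preds[name].segments)
        parts.append(f"{name}:{segs}" if segs else f"{name}:-")
    return "|".join(parts)


def scan_proteome(
    proteome: Mapping[str, str], params: PredictorParams | None = None
) -> pd.DataFrame:
    """Predict every protein; one row per protein with votes and verdict."""
    params = params or PredictorParams()
    rows = []
    for pid, seq in proteome.items():
        preds, verdict = predict_protein(seq, params, pid)
        row = {"protein_id": pid}
        for name in PREDICTORS:
            row[f"vote_{name}"] = preds[name].is_membrane
        row["is_membrane"] = verdict
        row["segments"] = _format_segments(preds)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            *(f"vote_{n}" for n in PREDICTORS),
            "is_membrane",
            "segments",
        ],
    )


def membrane_ids(scan: pd.DataFrame) -> set[str]:
    return set(scan.loc[scan["is_membrane"], "protein_id"])
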