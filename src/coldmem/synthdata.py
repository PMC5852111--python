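"""Synthetic proteomes, PSM tables, and planted ground truth.

The study's raw spectra are not publicly deposited, so the pipeline is
validated end-to-end on synthetic data that reproduces the statistical
structure the downstream analysis assumes:

* a proteome mixing soluble proteins and membrane proteins with planted
  hydrophobic transmembrane segments (17-25 residues, Leu/Ile/Val/Phe/
  Ala/Met-enriched) flanked by polar loops;
* three biological replicate sets per genotype, each a 3-channel
  isobaric-reporter experiment (channels 114/115/116 = 0/3/6 h of cold
  treatment);
* log-normal reporter noise around a per-protein log-normal baseline,
  with planted log2 effects for a subset of membrane proteins;
* decoy PSMs from reversed sequences, with target and decoy search
  scores drawn from two configurable Gaussians.

All randomness flows from ``SimulationConfig.seed`` through distinct
sub-streams per stage, so every output is byte-reproducible.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mrm import tryptic_digest
from .scales import AMINO_ACIDS, KYTE_DOOLITTLE

GENOTYPES = ("A", "B")

PSM_COLUMNS = [
    "psm_id",
    "peptide",
    "protein_id",
    "is_decoy",
    "score",
    "i114",
    "i115",
    "i116",
    "replicate_set",
    "genotype",
]

# Residue frequencies for soluble stretches / loops: polar- and
# charged-biased, with enough K/R that tryptic peptides stay short.
_LOOP_FREQS = {
    "A": 0.07, "R": 0.05, "N": 0.05, "D": 0.06, "C": 0.01,
    "Q": 0.05, "E": 0.08, "G": 0.08, "H": 0.02, "I": 0.03,
    "L": 0.05, "K": 0.08, "M": 0.01, "F": 0.03, "P": 0.05,
    "S": 0.10, "T": 0.06, "W": 0.01, "Y": 0.03, "V": 0.04,
}

# Residue frequencies inside planted transmembrane segments.
_TM_FREQS = {
    "L": 0.28, "I": 0.16, "V": 0.15, "F": 0.11, "A": 0.14,
    "M": 0.05, "G": 0.04, "S": 0.03, "T": 0.03, "W": 0.02,
    "Y": 0.02, "C": 0.01,
}

_POLAR_REPLACEMENTS = "DENQSTK"


def _freq_arrays(freqs: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(freqs))
    p = np.array([freqs[a] for a in letters], dtype=float)
    return letters, p / p.sum()


_LOOP_LETTERS, _LOOP_P = _freq_arrays(_LOOP_FREQS)
_TM_LETTERS, _TM_P = _freq_arrays(_TM_FREQS)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one protein in one genotype."""

    protein_id: str
    is_membrane: bool
    tm_segments: tuple[tuple[int, int], ...]  # 1-based inclusive
    log2_effect_3h: float
    log2_effect_6h: float
    genotype: str


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the triplicate, 3-channel cold-stress design: three
    biological replicate sets per genotype, reporter channels 114/115/116
    for 0/3/6 h, ~30% membrane proteins, 2-fold planted effects on 10%
    of membrane proteins, and 0.15 log2 units of reporter noise.
    """

    n_proteins: int = 1000
    frac_membrane: float = 0.3
    frac_differential: float = 0.1  # fraction of *membrane* proteins
    n_replicate_sets: int = 3
    noise_sd_log2: float = 0.15
    effect_log2: float = 1.0
    decoy_mode: str = "reverse"
    target_score_mean: float = 40.0
    target_score_sd: float = 10.0
    decoy_score_mean: float = 12.0
    decoy_score_sd: float = 5.0
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    peptide_sd_log2: float = 1.0  # per-peptide ionisation offset
    dropout_prob: float = 0.0  # P(protein absent from a replicate set)
    min_peptide_len: int = 6
    seed: int = 0
    genotype: str = "A"

    def __post_init__(self):
        for name in ("frac_membrane", "frac_differential", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.n_replicate_sets < 2:
            raise ValueError("n_replicate_sets must be >= 2")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.decoy_mode != "reverse":
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")


def _sanitize_polar(residues: list[str], rng: np.random.Generator,
                    window: int = 9, max_mean: float = 1.2) -> None:
    """Break hydrophobic runs so soluble stretches stay below threshold.

    Ensures no ``window``-residue run has mean Kyte-Doolittle hydropathy
    above ``max_mean`` (kept below the predictors' 1.6 threshold with
    margin) by swapping the most hydrophobic residue of an offending
    window for a polar one.
    """
    if len(residues) < window:
        return
    kd = np.array([KYTE_DOOLITTLE[r] for r in residues])
    kernel = np.full(window, 1.0 / window)
    while True:
        means = np.convolve(kd, kernel, mode="valid")
        bad = np.flatnonzero(means > max_mean)
        if bad.size == 0:
            return
        i = int(bad[0])
        pos = i + int(np.argmax(kd[i : i + window]))
        new = rng.choice(list(_POLAR_REPLACEMENTS))
        residues[pos] = new
        kd[pos] = KYTE_DOOLITTLE[new]


def _random_stretch(rng: np.random.Generator, n: int,
                    letters: np.ndarray, p: np.ndarray) -> list[str]:
    return list(rng.choice(letters, size=n, p=p))


def _membrane_sequence(rng: np.random.Generator) -> tuple[str, tuple[tuple[int, int], ...]]:
    n_seg = int(rng.integers(1, 4))
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    for k in range(n_seg + 1):
        loop = _random_stretch(rng, int(rng.integers(25, 81)), _LOOP_LETTERS, _LOOP_P)
        _sanitize_polar(loop, rng)
        parts.append("".join(loop))
        pos += len(loop)
        if k < n_seg:
            seg_len = int(rng.integers(17, 26))
            seg = _random_stretch(rng, seg_len, _TM_LETTERS, _TM_P)
            parts.append("".join(seg))
            segments.append((pos + 1, pos + seg_len))
            pos += seg_len
    return "".join(parts), tuple(segments)


def _soluble_sequence(rng: np.random.Generator) -> str:
    res = _random_stretch(rng, int(rng.integers(120, 361)), _LOOP_LETTERS, _LOOP_P)
    _sanitize_polar(res, rng)
    return "".join(res)


def _assign_effects(
    truths: list[PlantedTruth], cfg: SimulationConfig, genotype: str
) -> list[PlantedTruth]:
    rng = np.random.default_rng([cfg.seed, 3, GENOTYPES.index(genotype)])
    mem_idx = [i for i, t in enumerate(truths) if t.is_membrane]
    n_diff = int(round(cfg.frac_differential * len(mem_idx)))
    chosen = rng.choice(mem_idx, size=n_diff, replace=False) if n_diff else []
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    out = [replace(t, genotype=genotype) for t in truths]
    for i, s in zip(chosen, signs):
        eff = float(s * cfg.effect_log2)
        out[i] = replace(out[i], log2_effect_3h=eff, log2_effect_6h=eff)
    return out


def _build_proteome(cfg: SimulationConfig) -> tuple[dict[str, str], list[PlantedTruth]]:
    rng = np.random.default_rng([cfg.seed, 1])
    n_mem = int(round(cfg.frac_membrane * cfg.n_proteins))
    proteome: dict[str, str] = {}
    truths: list[PlantedTruth] = []
    for i in range(cfg.n_proteins):
        pid = f"P{i + 1:06d}"
        if i < n_mem:
            seq, segs = _membrane_sequence(rng)
        else:
            seq, segs = _soluble_sequence(rng), ()
        proteome[pid] = seq
        truths.append(
            PlantedTruth(pid, bool(segs), segs, 0.0, 0.0, cfg.genotype)
        )
    return proteome, truths


def proteome_to_fasta(proteome: Mapping[str, str]) -> str:
    """Standard FASTA text, 60-column wrapping."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def read_fasta(path_or_handle) -> dict[str, str]:
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_handle, "fasta")
    }


def generate_proteome(cfg: SimulationConfig) -> tuple[str, list[PlantedTruth]]:
    """Generate the synthetic proteome and its planted truth.

    Returns FASTA text (60-column) and one :class:`PlantedTruth` per
    protein for ``cfg.genotype``.  Deterministic given ``cfg.seed``.
    """
    proteome, truths = _build_proteome(cfg)
    truths = _assign_effects(truths, cfg, cfg.genotype)
    return proteome_to_fasta(proteome), truths


def simulate_psms(
    truths: Sequence[PlantedTruth],
    proteome: Mapping[str, str],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Simulate the PSM table for one genotype's replicate sets.

    Each tryptic peptide (length >= ``cfg.min_peptide_len``) of each
    protein yields 1-3 PSMs per replicate set.  Channel 114 is log-normal
    around the protein baseline (plus a per-peptide ionisation offset);
    channels 115/116 multiply in 2**log2_effect at 3/6 h and independent
    log-normal noise.  Decoy PSMs come from reversed sequences with
    scores from the decoy distribution; decoy peptides colliding with any
    target peptide are dropped.
    """
    if not truths:
        raise ValueError("truth list is empty")
    genotype = truths[0].genotype
    rng = np.random.default_rng([cfg.seed, 2, GENOTYPES.index(genotype)])

    pep_seqs: list[str] = []
    pep_protein: list[int] = []
    eff3 = np.zeros(len(truths))
    eff6 = np.zeros(len(truths))
    omitted: list[str] = []
    target_pepset: set[str] = set()
    for j, t in enumerate(truths):
        peps = [
            p.seq
            for p in tryptic_digest(proteome[t.protein_id])
            if len(p.seq) >= cfg.min_peptide_len
        ]
        if not peps:
            warnings.warn(
                f"{t.protein_id}: no tryptic peptide of length >= "
                f"{cfg.min_peptide_len}; omitted from PSM table",
                stacklevel=2,
            )
            omitted.append(t.protein_id)
            continue
        eff3[j] = t.log2_effect_3h
        eff6[j] = t.log2_effect_6h
        pep_seqs.extend(peps)
        pep_protein.extend([j] * len(peps))
        target_pepset.update(peps)

    pep_protein_arr = np.asarray(pep_protein, dtype=np.intp)
    n_pep = len(pep_seqs)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(truths))
    pep_offset = rng.normal(0.0, cfg.peptide_sd_log2, n_pep)
    present = rng.random((len(truths), cfg.n_replicate_sets)) >= cfg.dropout_prob

    # Decoy peptides from reversed sequences, minus any target collision.
    dec_seqs: list[str] = []
    dec_protein: list[int] = []
    for j, t in enumerate(truths):
        if t.protein_id in omitted:
            continue
        for p in tryptic_digest(proteome[t.protein_id][::-1]):
            if len(p.seq) >= cfg.min_peptide_len and p.seq not in target_pepset:
                dec_seqs.append(p.seq)
                dec_protein.append(j)
    dec_protein_arr = np.asarray(dec_protein, dtype=np.intp)
    dec_offset = rng.normal(0.0, cfg.peptide_sd_log2, len(dec_seqs))

    frames: list[pd.DataFrame] = []
    pep_seq_arr = np.asarray(pep_seqs, dtype=object)
    dec_seq_arr = np.asarray(dec_seqs, dtype=object)
    for s in range(cfg.n_replicate_sets):
        set_label = f"set{s + 1}"
        keep = present[pep_protein_arr, s]
        idx = np.flatnonzero(keep)
        counts = rng.integers(1, 4, size=idx.size)
        rep = np.repeat(idx, counts)
        prot = pep_protein_arr[rep]
        mu = baseline[prot] + pep_offset[rep]
        eps = rng.normal(0.0, cfg.noise_sd_log2, (rep.size, 3)) if cfg.noise_sd_log2 > 0 else np.zeros((rep.size, 3))
        i114 = np.exp2(mu + eps[:, 0])
        i115 = np.exp2(mu + eff3[prot] + eps[:, 1])
        i116 = np.exp2(mu + eff6[prot] + eps[:, 2])
        scores = rng.normal(cfg.target_score_mean, cfg.target_score_sd, rep.size)
        tgt = pd.DataFrame(
            {
                "peptide": pep_seq_arr[rep],
                "protein_id": np.asarray([truths[j].protein_id for j in prot], dtype=object),
                "is_decoy": False,
                "score": scores,
                "i114": i114,
                "i115": i115,
                "i116": i116,
                "replicate_set": set_label,
                "genotype": genotype,
            }
        )
        frames.append(tgt)

        if dec_seq_arr.size:
            dkeep = np.flatnonzero(present[dec_protein_arr, s])
            dprot = dec_protein_arr[dkeep]
            dmu = baseline[dprot] + dec_offset[dkeep]
            deps = rng.normal(0.0, cfg.noise_sd_log2, (dkeep.size, 3)) if cfg.noise_sd_log2 > 0 else np.zeros((dkeep.size, 3))
            dec = pd.DataFrame(
                {
                    "peptide": dec_seq_arr[dkeep],
                    "protein_id": np.asarray(
                        ["DECOY_" + truths[j].protein_id for j in dprot], dtype=object
                    ),
                    "is_decoy": True,
                    "score": rng.normal(cfg.decoy_score_mean, cfg.decoy_score_sd, dkeep.size),
                    "i114": np.exp2(dmu + deps[:, 0]),
                    "i115": np.exp2(dmu + deps[:, 1]),
                    "i116": np.exp2(dmu + deps[:, 2]),
                    "replicate_set": set_label,
                    "genotype": genotype,
                }
            )
            frames.append(dec)

    psms = pd.concat(frames, ignore_index=True)
    psms.insert(
        0,
        "psm_id",
        [f"{genotype}.{i:07d}" for i in range(len(psms))],
    )
    psms.attrs["omitted_proteins"] = omitted
    return psms[PSM_COLUMNS]


def generate_study(cfg: SimulationConfig) -> tuple[
    dict[str, str], dict[str, list[PlantedTruth]], pd.DataFrame
]:
    """One shared proteome, two genotypes with independent planted effects.

    Returns (proteome, truth per genotype, combined PSM table).  Both
    genotypes share the protein-ID space, so cross-genotype overlap
    accounting is meaningful; their differential subsets are drawn
    independently and overlap only by chance.
    """
    proteome, base = _build_proteome(cfg)
    truths: dict[str, list[PlantedTruth]] = {}
    tables = []
    for g in GENOTYPES:
        truths[g] = _assign_effects(base, cfg, g)
        tables.append(simulate_psms(truths[g], proteome, cfg))
    psms = pd.concat(tables, ignore_index=True)
    return proteome, truths, psms


def truth_table(truths: Sequence[PlantedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truths],
            "genotype": [t.genotype for t in truths],
            "is_membrane": [t.is_membrane for t in truths],
            "tm_segments": [
                ";".join(f"{s}-{e}" for s, e in t.tm_segments) for t in truths
            ],
            "log2_effect_3h": [t.log2_effect_3h for t in truths],
            "log2_effect_6h": [t.log2_effect_6h for t in truths],
        }
    )


def write_psm_table(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psm_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str})
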