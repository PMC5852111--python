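"""MRM (multiple reaction monitoring) transition-list design.

In-silico tryptic digestion, monoisotopic peptide and b/y fragment m/z,
and a deterministic selector emitting three proteotypic peptides per
protein with three y-ion transitions per peptide.

Coordinates are 1-based inclusive throughout.  Masses come from the
standard monoisotopic residue table (via pyteomics); peptides are
assumed unmodified (MRM validation runs on unlabeled samples; isobaric
tag masses can be added by the caller if needed).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from pyteomics import mass as _pmass

from .scales import validate_sequence

PROTON = 1.00727646688

# Cleave C-terminal to K or R, except when the next residue is P.
_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


class DigestPeptide(NamedTuple):
    """A tryptic peptide with its 1-based inclusive parent coordinates."""

    seq: str
    start: int
    end: int
    missed: int


@dataclass(frozen=True)
class Transition:
    """One precursor -> product ion pair of an MRM assay."""

    protein_id: str
    peptide: str
    precursor_mz: float
    precursor_charge: int
    fragment_ion: str  # e.g. "y4"
    fragment_mz: float
    fragment_charge: int
    rank: int  # 1..3 within the peptide, by descending fragment m/z


def tryptic_digest(seq: str, missed_cleavages: int = 0) -> list[DigestPeptide]:
    """Digest ``seq`` with trypsin specificity (K/R, not before P).

    With ``missed_cleavages = m`` every concatenation of up to ``m + 1``
    adjacent fully-cleaved fragments is emitted, in order of start
    position.  The 0-missed peptides concatenate back to ``seq``.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not seq:
        return []
    validate_sequence(seq)
    pieces = [p for p in _TRYPSIN.split(seq) if p]  # trailing cut -> empty tail
    starts: list[int] = []
    pos = 1
    for p in pieces:
        starts.append(pos)
        pos += len(p)
    out: list[DigestPeptide] = []
    n = len(pieces)
    for i in range(n):
        for m in range(missed_cleavages + 1):
            j = i + m
            if j >= n:
                break
            pep = "".join(pieces[i : j + 1])
            out.append(DigestPeptide(pep, starts[i], starts[i] + len(pep) - 1, m))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def peptide_mz(peptide: str, charge: int = 2) -> float:
    """Monoisotopic m/z of the [M + charge*H]^charge+ peptide ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if not peptide:
        raise ValueError("empty peptide")
    validate_sequence(peptide)
    return _pmass.fast_mass(peptide, charge=charge)


def fragment_mz(peptide: str, series: str, index: int, charge: int = 1) -> float:
    """Monoisotopic m/z of the b_index or y_index fragment ion.

    ``index`` counts residues from the N terminus for b ions and from the
    C terminus for y ions; valid indices are 1..len(peptide)-1.
    """
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    n = len(peptide)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} out of range for length-{n} peptide")
    validate_sequence(peptide)
    sub = peptide[:index] if series == "b" else peptide[n - index :]
    return _pmass.fast_mass(sub, ion_type=series, charge=charge)


def _eligible(pep: str, min_len: int, max_len: int, banned: str) -> bool:
    return min_len <= len(pep) <= max_len and not any(aa in pep for aa in banned)


def select_transitions(
    protein_id: str,
    peptides: Sequence[DigestPeptide] | Sequence[str],
    peptide_counts: Mapping[str, int] | None = None,
    n_peptides: int = 3,
    n_transitions: int = 3,
    precursor_charge: int = 2,
    min_len: int = 7,
    max_len: int = 25,
    banned_residues: str = "CM",
    target_len: int = 12,
) -> list[Transition]:
    """Pick up to 3 assay peptides x 3 y-ion transitions for one protein.

    Eligible peptides are 7-25 residues, free of Cys/Met (oxidation- and
    alkylation-prone), and — when ``peptide_counts`` (peptide -> number of
    parent proteins in the proteome) is given — proteotypic.  Peptides are
    ranked by closeness of length to ``target_len``, ties lexicographic.
    For each chosen peptide the three highest-m/z singly charged y ions
    above the precursor m/z are taken (falling back to the highest-m/z y
    ions when fewer than three clear the precursor).  Output order is
    deterministic.
    """
    seqs = [p.seq if isinstance(p, DigestPeptide) else p for p in peptides]
    pool = sorted(
        {
            s
            for s in seqs
            if _eligible(s, min_len, max_len, banned_residues)
            and (peptide_counts is None or peptide_counts.get(s, 1) == 1)
        },
        key=lambda s: (abs(len(s) - target_len), s),
    )
    if not pool:
        warnings.warn(f"{protein_id}: no MRM-eligible tryptic peptide", stacklevel=2)
        return []
    if len(pool) < n_peptides:
        warnings.warn(
            f"{protein_id}: only {len(pool)} eligible peptide(s), "
            f"fewer than the requested {n_peptides}",
            stacklevel=2,
        )
    out: list[Transition] = []
    for pep in pool[:n_peptides]:
        prec = peptide_mz(pep, precursor_charge)
        ions = [
            (fragment_mz(pep, "y", j, 1), j) for j in range(1, len(pep))
        ]
        above = sorted((mz, j) for mz, j in ions if mz > prec)[::-1]
        chosen = above[:n_transitions]
        if len(chosen) < n_transitions:
            rest = sorted(set(ions) - set(chosen))[::-1]
            chosen += rest[: n_transitions - len(chosen)]
        for rank, (mz, j) in enumerate(chosen, start=1):
            out.append(
                Transition(
                    protein_id=protein_id,
                    peptide=pep,
                    precursor_mz=prec,
                    precursor_charge=precursor_charge,
                    fragment_ion=f"y{j}",
                    fragment_mz=mz,
                    fragment_charge=1,
                    rank=rank,
                )
            )
    return out


def design_transitions(
    proteome: Mapping[str, str],
    protein_ids: Iterable[str] | None = None,
    **kwargs,
) -> list[Transition]:
    """Design transitions for selected proteins against a full proteome.

    The whole proteome is digested once to establish which peptides are
    proteotypic (map to exactly one protein).
    """
    counts: dict[str, int] = {}
    digests: dict[str, list[DigestPeptide]] = {}
    for pid, seq in proteome.items():
        digests[pid] = tryptic_digest(seq)
        for pep in {p.seq for p in digests[pid]}:
            counts[pep] = counts.get(pep, 0) + 1
    targets = list(protein_ids) if protein_ids is not None else list(proteome)
    out: list[Transition] = []
    for pid in targets:
        out.extend(select_transitions(pid, digests[pid], peptide_counts=counts, **kwargs))
    return out
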