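"""Oligo thermodynamics: nearest-neighbor melting temperature and dimers.

Duplex Tm uses the unified nearest-neighbor parameter set as implemented in
``Bio.SeqUtils.MeltingTemp.Tm_NN`` with an entropy-based monovalent-salt
correction.  Default conditions are 50 nM oligo and 50 mM monovalent salt.

Primer-dimer risk is scored as the Tm of the strongest contiguous
Watson-Crick complementary segment across all ungapped antiparallel
registers of the two oligos (self-dimer: an oligo against itself); a pair
passes when that Tm stays below the constraint ceiling (30 °C in the
stringent design preset).
"""

from __future__ import annotations

import math

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "melting_temp",
    "dimer_tm",
    "reverse_complement",
    "DIMER_TM_NONE",
    "validate_dna",
]

#: Sentinel returned when two oligos share no Watson-Crick register at all.
DIMER_TM_NONE = -math.inf

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

DEFAULT_OLIGO_NM = 50.0
DEFAULT_MONOVALENT_MM = 50.0


def validate_dna(sequence: str, context: str = "sequence") -> str:
    """Uppercase and check strict ACGT alphabet, naming the bad position."""
    seq = str(sequence).upper()
    if not seq:
        raise ValueError(f"{context} is empty")
    for i, base in enumerate(seq):
        if base not in _COMPLEMENT:
            raise ValueError(
                f"{context} has non-ACGT character {base!r} at position {i + 1}"
            )
    return seq


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def melting_temp(
    sequence: str,
    oligo_nM: float = DEFAULT_OLIGO_NM,
    monovalent_mM: float = DEFAULT_MONOVALENT_MM,
) -> float:
    """Nearest-neighbor duplex Tm (°C) of an oligo with its perfect complement.

    Sequences must be plain ACGT and at least 8 nt (shorter oligos are not
    meaningful primers); ambiguity codes must be resolved (consensus
    refinement) before Tm evaluation.
    """
    seq = validate_dna(sequence, "primer")
    if len(seq) < 8:
        raise ValueError(f"primer too short for Tm estimation ({len(seq)} < 8 nt)")
    return _segment_tm(seq, oligo_nM, monovalent_mM)


def _segment_tm(seq: str, oligo_nM: float, monovalent_mM: float) -> float:
    # dnac1 = concentration of the excess strand; dnac2=0 models primer excess
    return float(
        _mt.Tm_NN(
            Seq(seq),
            dnac1=oligo_nM,
            dnac2=0.0,
            Na=monovalent_mM,
            saltcorr=5,
        )
    )


def _complementary_runs(a: str, rb: str) -> list[str]:
    """Maximal match runs of a against rb over all ungapped shifts.

    ``rb`` is the reverse complement of the partner oligo, so a character
    match here is a Watson-Crick pair in the antiparallel duplex.
    """
    runs: list[str] = []
    la, lb = len(a), len(rb)
    for shift in range(-(lb - 1), la):
        start = max(0, shift)
        stop = min(la, shift + lb)
        run_start = None
        for i in range(start, stop):
            if a[i] == rb[i - shift]:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None:
                    runs.append(a[run_start:i])
                    run_start = None
        if run_start is not None:
            runs.append(a[run_start:stop])
    return runs


def dimer_tm(
    seq_a: str,
    seq_b: str,
    oligo_nM: float = DEFAULT_OLIGO_NM,
    monovalent_mM: float = DEFAULT_MONOVALENT_MM,
) -> float:
    """Tm (°C) of the strongest ungapped complementary segment of two oligos.

    Scans every antiparallel register of ``seq_a`` against ``seq_b``, takes
    each maximal contiguous complementary run, and reports the highest
    nearest-neighbor Tm among runs of >= 2 nt (a single pair has no
    nearest-neighbor stack).  Returns ``DIMER_TM_NONE`` when no such
    segment exists.  ``dimer_tm(seq, seq)`` scores self-dimerisation.
    """
    a = validate_dna(seq_a, "seq_a")
    b = validate_dna(seq_b, "seq_b")
    rb = reverse_complement(b)
    best = DIMER_TM_NONE
    seen: set[str] = set()
    for run in _complementary_runs(a, rb):
        if len(run) < 2 or run in seen:
            continue
        seen.add(run)
        tm = _segment_tm(run, oligo_nM, monovalent_mM)
        if tm > best:
            best = tm
    return best
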