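"""Candidate primer generation and constraint screening.

Dosage qPCR needs primers sensitive enough to resolve a single cycle, so
candidates are screened hard: size/Tm/GC windows, a 3'-terminal G/C clamp,
a homopolymer ceiling, product-size limits, and self/cross dimer Tm.  The
two shipped presets reflect the two design routes the assay panel came
from: a stringent interactive set (``geneious2025``: 20 nt / 59 °C / 50 %
GC optima, 100-200 bp products, clamp 1, poly-X <= 3, dimer Tm <= 30 °C)
and a consensus-pipeline set (``ceph_pipeline``: 60 °C optimum, 150-300 bp
products, poly-X <= 5).

``design_candidates`` enumerates every primer window on both strands of a
target, hard-filters, and returns the single lowest-penalty compliant pair
per target with deterministic tie-breaks — one pair per FASTA entry, so a
panel of 12 autosomal + 12 sex targets yields 24 assays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from zdose import thermo
from zdose.thermo import reverse_complement, validate_dna

__all__ = [
    "PrimerConstraints",
    "PenaltyWeights",
    "PrimerMetrics",
    "Primer",
    "PairReport",
    "DesignResult",
    "PRESETS",
    "primer_metrics",
    "make_primer",
    "evaluate_pair",
    "design_candidates",
    "refine_to_consensus",
    "RefinedPrimer",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PrimerConstraints:
    """Design constraint set; ``None`` disables a check."""

    size_min: int = 18
    size_opt: int = 20
    size_max: int = 24
    tm_opt: float = 59.0
    tm_min: float = 54.0
    tm_max: float = 64.0
    gc_opt: float = 50.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    product_range: tuple[int, int] = (100, 200)
    gc_clamp: int = 1
    max_polyx: int = 3
    max_dimer_tm: float | None = 30.0

    def __post_init__(self) -> None:
        if not self.size_min <= self.size_opt <= self.size_max:
            raise ValueError("need size_min <= size_opt <= size_max")
        lo, hi = self.product_range
        if lo > hi or lo < 1:
            raise ValueError("product_range must be a non-empty positive interval")


PRESETS: dict[str, PrimerConstraints] = {
    "geneious2025": PrimerConstraints(),
    "ceph_pipeline": PrimerConstraints(
        tm_opt=60.0,
        tm_min=55.0,
        tm_max=65.0,
        product_range=(150, 300),
        gc_clamp=0,
        max_polyx=5,
        max_dimer_tm=None,
    ),
}


@dataclass(frozen=True)
class PenaltyWeights:
    """Soft-constraint weights: penalty = sum of weight * |metric - optimum|."""

    tm: float = 1.0       # per °C deviation from tm_opt
    gc: float = 0.5       # per % deviation from gc_opt
    size: float = 1.0     # per nt deviation from size_opt


@dataclass(frozen=True)
class PrimerMetrics:
    length: int
    gc_percent: float
    max_homopolymer: int
    gc_clamp_run: int  # consecutive G/C at the 3' terminus

    def clamp_ok(self, required: int) -> bool:
        return self.gc_clamp_run >= required


@dataclass(frozen=True)
class Primer:
    """A candidate oligo; metrics are always recomputed from the sequence."""

    name: str
    sequence: str
    metrics: PrimerMetrics
    tm: float


def primer_metrics(sequence: str) -> PrimerMetrics:
    """Compositional metrics of one oligo (strict ACGT input)."""
    seq = validate_dna(sequence, "primer")
    gc = 100.0 * sum(seq.count(b) for b in "GC") / len(seq)
    max_run = max(len(list(g)) for _, g in itertools.groupby(seq))
    clamp_run = 0
    for base in reversed(seq):
        if base in "GC":
            clamp_run += 1
        else:
            break
    return PrimerMetrics(
        length=len(seq),
        gc_percent=gc,
        max_homopolymer=max_run,
        gc_clamp_run=clamp_run,
    )


def make_primer(name: str, sequence: str) -> Primer:
    seq = validate_dna(sequence, f"primer {name!r}")
    return Primer(
        name=name,
        sequence=seq,
        metrics=primer_metrics(seq),
        tm=thermo.melting_temp(seq),
    )


def primer_penalty(
    primer: Primer,
    constraints: PrimerConstraints,
    weights: PenaltyWeights = PenaltyWeights(),
) -> float:
    m = primer.metrics
    return (
        weights.tm * abs(primer.tm - constraints.tm_opt)
        + weights.gc * abs(m.gc_percent - constraints.gc_opt)
        + weights.size * abs(m.length - constraints.size_opt)
    )


def _passes_single(primer: Primer, c: PrimerConstraints) -> dict[str, bool]:
    m = primer.metrics
    return {
        "size": c.size_min <= m.length <= c.size_max,
        "tm": c.tm_min <= primer.tm <= c.tm_max,
        "gc": c.gc_min <= m.gc_percent <= c.gc_max,
        "clamp": m.clamp_ok(c.gc_clamp),
        "polyx": m.max_homopolymer <= c.max_polyx,
    }


@dataclass(frozen=True)
class PairReport:
    """Per-constraint verdicts and the soft-penalty score of one pair."""

    fwd: Primer
    rev: Primer
    product_length: int | None
    checks: dict[str, bool]
    penalty: float

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values())


def _locate_pair(
    fwd_seq: str, rev_seq: str, template: str
) -> tuple[int, int] | None:
    """Plus-strand product coordinates (0-based start, end-exclusive)."""
    f = template.find(fwd_seq)
    if f < 0:
        return None
    rc = reverse_complement(rev_seq)
    r = template.find(rc, f)
    if r < 0:
        return None
    return f, r + len(rc)


def evaluate_pair(
    fwd: Primer | str,
    rev: Primer | str,
    template: str,
    constraints: PrimerConstraints,
    weights: PenaltyWeights = PenaltyWeights(),
) -> PairReport:
    """Score a primer pair on its template against a constraint set.

    The forward primer must occur verbatim on the template plus strand and
    the reverse primer (as its reverse complement) downstream of it;
    product length is the distance between the two 5' ends, inclusive.
    Checks: per-primer size/Tm/GC/clamp/poly-X, self- and cross-dimer Tm,
    and product size.  Penalty is the weighted sum of deviations of Tm, GC
    and size from their optima across both primers.
    """
    if isinstance(fwd, str):
        fwd = make_primer("fwd", fwd)
    if isinstance(rev, str):
        rev = make_primer("rev", rev)
    template = validate_dna(template, "template")
    loc = _locate_pair(fwd.sequence, rev.sequence, template)
    if loc is None:
        raise ValueError(
            f"primer pair {fwd.name!r}/{rev.name!r} not found on template"
        )
    product_length = loc[1] - loc[0]

    checks: dict[str, bool] = {}
    for label, primer in (("fwd", fwd), ("rev", rev)):
        for check, ok in _passes_single(primer, constraints).items():
            checks[f"{label}_{check}"] = ok
    lo, hi = constraints.product_range
    checks["product_size"] = lo <= product_length <= hi
    if constraints.max_dimer_tm is not None:
        ceiling = constraints.max_dimer_tm
        checks["self_dimer_fwd"] = thermo.dimer_tm(fwd.sequence, fwd.sequence) <= ceiling
        checks["self_dimer_rev"] = thermo.dimer_tm(rev.sequence, rev.sequence) <= ceiling
        checks["cross_dimer"] = thermo.dimer_tm(fwd.sequence, rev.sequence) <= ceiling

    penalty = primer_penalty(fwd, constraints, weights) + primer_penalty(
        rev, constraints, weights
    )
    return PairReport(
        fwd=fwd,
        rev=rev,
        product_length=product_length,
        checks=checks,
        penalty=penalty,
    )


@dataclass(frozen=True)
class DesignResult:
    target_name: str
    fwd: Primer | None
    rev: Primer | None
    product_start: int | None  # 1-based on the target
    product_length: int | None
    penalty: float | None
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.failure is None


@dataclass(frozen=True)
class _Candidate:
    start: int  # 0-based on target plus strand
    length: int
    sequence: str  # primer 5'->3'
    tm: float
    penalty: float


def _enumerate_candidates(
    target: str,
    constraints: PrimerConstraints,
    weights: PenaltyWeights,
    reverse: bool,
) -> list[_Candidate]:
    out: list[_Candidate] = []
    n = len(target)
    for size in range(constraints.size_min, constraints.size_max + 1):
        for start in range(0, n - size + 1):
            window = target[start : start + size]
            seq = reverse_complement(window) if reverse else window
            m = primer_metrics(seq)
            # cheap compositional filters before any Tm computation
            if not (constraints.gc_min <= m.gc_percent <= constraints.gc_max):
                continue
            if m.max_homopolymer > constraints.max_polyx:
                continue
            if not m.clamp_ok(constraints.gc_clamp):
                continue
            tm = thermo.melting_temp(seq)
            if not constraints.tm_min <= tm <= constraints.tm_max:
                continue
            penalty = (
                weights.tm * abs(tm - constraints.tm_opt)
                + weights.gc * abs(m.gc_percent - constraints.gc_opt)
                + weights.size * abs(size - constraints.size_opt)
            )
            out.append(_Candidate(start, size, seq, tm, penalty))
    return out


def _design_one(
    name: str,
    target: str,
    constraints: PrimerConstraints,
    weights: PenaltyWeights,
    max_dimer_checks: int,
) -> DesignResult:
    lo, hi = constraints.product_range
    if len(target) < lo:
        return DesignResult(name, None, None, None, None, None, "target shorter than minimum product")
    fwd_cands = _enumerate_candidates(target, constraints, weights, reverse=False)
    rev_cands = _enumerate_candidates(target, constraints, weights, reverse=True)
    if not fwd_cands or not rev_cands:
        return DesignResult(name, None, None, None, None, None, "no compliant primer window")

    pairs: list[tuple[float, int, int, _Candidate, _Candidate]] = []
    for f in fwd_cands:
        for r in rev_cands:
            product = r.start + r.length - f.start
            if r.start < f.start + f.length or not lo <= product <= hi:
                continue
            pairs.append((f.penalty + r.penalty, f.start, product, f, r))
    if not pairs:
        return DesignResult(name, None, None, None, None, None, "no pair within product range")
    # deterministic ranking: penalty, then leftmost forward, then shortest product
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    ceiling = constraints.max_dimer_tm
    for penalty, fstart, product, f, r in pairs[:max_dimer_checks]:
        if ceiling is not None:
            if thermo.dimer_tm(f.sequence, f.sequence) > ceiling:
                continue
            if thermo.dimer_tm(r.sequence, r.sequence) > ceiling:
                continue
            if thermo.dimer_tm(f.sequence, r.sequence) > ceiling:
                continue
        return DesignResult(
            target_name=name,
            fwd=make_primer(f"{name}_F", f.sequence),
            rev=make_primer(f"{name}_R", r.sequence),
            product_start=fstart + 1,
            product_length=product,
            penalty=penalty,
        )
    return DesignResult(name, None, None, None, None, None, "all ranked pairs failed dimer screen")


def design_candidates(
    targets: Sequence[tuple[str, str]],
    constraints: PrimerConstraints,
    weights: PenaltyWeights = PenaltyWeights(),
    max_dimer_checks: int = 200,
) -> list[DesignResult]:
    """Design the single best primer pair for each (name, sequence) target.

    Exhaustively enumerates forward and reverse windows in the allowed size
    range, hard-filters on GC window, poly-X, clamp and Tm window, ranks
    feasible pairs by summed soft penalty (ties: leftmost forward, then
    shortest product), and returns the first pair that also passes the
    dimer screen.  Targets with no valid pair come back as failures, not
    errors.  ``max_dimer_checks`` bounds the dimer screening effort per
    target; ranking below that depth is unaffected.
    """
    if not targets:
        raise ValueError("empty target list")
    results = []
    for name, seq in targets:
        seq = validate_dna(seq, f"target {name!r}")
        results.append(_design_one(name, seq, constraints, weights, max_dimer_checks))
    return results


@dataclass(frozen=True)
class RefinedPrimer:
    primer: Primer
    substitutions: int
    seed_warning: bool  # a substitution fell in the 3'-terminal seed


def refine_to_consensus(
    primer: Primer | str,
    ref_start: int,
    consensus_sequence: str,
    strand: str = "+",
    seed_len: int = 5,
    name: str | None = None,
) -> RefinedPrimer:
    """Replace primer bases with species-specific consensus variants.

    A primer designed on a related reference genome is mapped onto a
    consensus of the actual target species, aligned to the same
    coordinates: ``ref_start`` is the 1-based position of the primer
    footprint's leftmost base on that coordinate system, ``strand`` the
    footprint strand (minus-strand primers read the reverse complement of
    the slice).  Concrete consensus mismatches are substituted and counted;
    an ambiguity code that includes the primer base (or N) keeps the primer
    base; a gap or an incompatible ambiguity under the footprint means the
    primer cannot be refined and must be redesigned.  Substitutions in the
    3'-terminal ``seed_len`` bases raise a warning flag since they sit in
    the extension-critical seed.
    """
    if isinstance(primer, str):
        primer = make_primer(name or "primer", primer)
    length = primer.metrics.length
    if ref_start < 1 or ref_start - 1 + length > len(consensus_sequence):
        raise ValueError("primer footprint outside the consensus sequence")
    slice_ = consensus_sequence[ref_start - 1 : ref_start - 1 + length].upper()
    if strand == "-":
        footprint = "".join(reversed(slice_))
        footprint = "".join(
            {"A": "T", "T": "A", "G": "C", "C": "G"}.get(b, b) for b in footprint
        )
    elif strand == "+":
        footprint = slice_
    else:
        raise ValueError("strand must be '+' or '-'")

    new_bases: list[str] = []
    substitutions = 0
    seed_warning = False
    for i, (p_base, c_base) in enumerate(zip(primer.sequence, footprint)):
        if c_base == "-":
            raise ValueError(
                f"consensus gap under primer footprint at primer position {i + 1}; "
                "redesign the primer"
            )
        allowed = _IUPAC.get(c_base)
        if allowed is None:
            raise ValueError(
                f"invalid consensus character {c_base!r} under footprint"
            )
        if c_base in "ACGT":
            if c_base != p_base:
                substitutions += 1
                if i >= length - seed_len:
                    seed_warning = True
            new_bases.append(c_base)
        else:
            # ambiguous consensus: keep the primer base when compatible
            if p_base not in allowed and c_base != "N":
                raise ValueError(
                    f"consensus ambiguity {c_base!r} at primer position {i + 1} "
                    f"incompatible with primer base {p_base!r}; redesign"
                )
            new_bases.append(p_base)
    refined = make_primer(name or primer.name, "".join(new_bases))
    return RefinedPrimer(
        primer=refined, substitutions=substitutions, seed_warning=seed_warning
    )
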