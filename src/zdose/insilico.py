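"""In-silico PCR: predict amplicons and verify single-product specificity.

A dosage assay must produce exactly one template-dependent product, so
every candidate pair is searched against the supplied template set (e.g.
the extracted target panel or desk-scale genome contigs).  A primer binds
where its 3'-terminal seed matches the template exactly and the whole
oligo accumulates at most ``max_mismatch`` mismatches; opposite-strand
sites of any primer combination (including a primer with itself) within
``max_product_len`` define an amplicon.  The pair is specific iff exactly
one amplicon exists overall and, when a product range is given, its length
falls inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from zdose.thermo import reverse_complement, validate_dna

__all__ = ["PcrPolicy", "BindingSite", "Amplicon", "InsilicoResult", "insilico_pcr"]


@dataclass(frozen=True)
class PcrPolicy:
    """Binding-site tolerance; defaults are deliberately conservative."""

    max_mismatch: int = 2
    seed_len: int = 5
    max_product_len: int = 5000


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str        # '+': primer extends rightward; '-': leftward
    start: int         # 1-based leftmost template position of the footprint
    mismatches: int
    primer_name: str


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    start: int     # 1-based, inclusive (5' end of the plus-strand primer)
    end: int       # 1-based, inclusive (5' end of the minus-strand primer)
    length: int
    sequence: str


@dataclass(frozen=True)
class InsilicoResult:
    amplicons: tuple[Amplicon, ...]
    specific: bool


def _scan_sites(
    primer_name: str,
    primer_seq: str,
    template_id: str,
    template: str,
    policy: PcrPolicy,
) -> list[BindingSite]:
    """All binding sites of one primer on both strands of one template."""
    sites: list[BindingSite] = []
    plen = len(primer_seq)
    seed = min(policy.seed_len, plen)
    rc = reverse_complement(primer_seq)
    n = len(template)
    for start in range(0, n - plen + 1):
        window = template[start : start + plen]
        # plus strand: primer 3' end at the right edge of the footprint
        if window[plen - seed :] == primer_seq[plen - seed :]:
            mm = sum(a != b for a, b in zip(window, primer_seq))
            if mm <= policy.max_mismatch:
                sites.append(
                    BindingSite(template_id, "+", start + 1, mm, primer_name)
                )
        # minus strand: primer binds the reverse complement; its 3' end maps
        # to the left edge of the plus-strand footprint
        if window[:seed] == rc[:seed]:
            mm = sum(a != b for a, b in zip(window, rc))
            if mm <= policy.max_mismatch:
                sites.append(
                    BindingSite(template_id, "-", start + 1, mm, primer_name)
                )
    return sites


def insilico_pcr(
    fwd: str,
    rev: str,
    templates: Mapping[str, str],
    policy: PcrPolicy = PcrPolicy(),
    product_range: tuple[int, int] | None = None,
    fwd_name: str = "fwd",
    rev_name: str = "rev",
) -> InsilicoResult:
    """Predict all amplicons of a primer pair over a template set.

    ``templates`` maps record id to sequence (e.g. parsed from FASTA).  All
    four strand pairings are considered, including single-primer products.
    The verdict is specific iff exactly one amplicon is found and — when
    ``product_range`` is given — its length lies within it.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    fseq = validate_dna(fwd, "forward primer")
    rseq = validate_dna(rev, "reverse primer")
    primers = {fwd_name: fseq, rev_name: rseq}
    if fwd_name == rev_name:
        raise ValueError("fwd and rev primer names must differ")

    amplicons: list[Amplicon] = []
    for tid, raw_seq in templates.items():
        seq = validate_dna(raw_seq, f"template {tid!r}")
        sites: list[BindingSite] = []
        for pname, pseq in primers.items():
            sites.extend(_scan_sites(pname, pseq, tid, seq, policy))
        plus = [s for s in sites if s.strand == "+"]
        minus = [s for s in sites if s.strand == "-"]
        for ps in plus:
            for ms in minus:
                p_len = len(primers[ps.primer_name])
                m_len = len(primers[ms.primer_name])
                start = ps.start
                end = ms.start + m_len - 1
                length = end - start + 1
                # polymerases extend inward: the minus-strand 3' end must lie
                # downstream of the plus-strand 3' end
                if ms.start < ps.start + p_len:
                    continue
                if length > policy.max_product_len:
                    continue
                amplicons.append(
                    Amplicon(
                        template_id=tid,
                        fwd_site=ps,
                        rev_site=ms,
                        start=start,
                        end=end,
                        length=length,
                        sequence=seq[start - 1 : end],
                    )
                )
    specific = len(amplicons) == 1
    if specific and product_range is not None:
        lo, hi = product_range
        specific = lo <= amplicons[0].length <= hi
    return InsilicoResult(amplicons=tuple(amplicons), specific=specific)
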