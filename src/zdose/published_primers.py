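"""Validated qPCR sex-genotyping primer panel for seven cephalopod species.

Each species has one autosomal control pair and one Z-linked ("sex") pair;
the Illex pair works in both *Illex illecebrosus* and *Illex argentinus*.
Sequences are written 5'→3'.  The five chromosome-assembly species were
designed under the stringent interactive constraint preset
(``geneious2025``); the Illex pair came from the consensus-based
command-line pipeline preset (``ceph_pipeline``).
"""

from __future__ import annotations

PRIMER_PANEL: dict[str, dict[str, str]] = {
    "Ascarosepion bandense": {
        "Abandense_qPCR_auto_F": "GGTGTTGTTCGCTCAGTTATC",
        "Abandense_qPCR_auto_R": "GTGTTCATGTCGCCATCTTATC",
        "Abandense_qPCR_sex_F": "GGCCGTCCTCTACTTGTAATG",
        "Abandense_qPCR_sex_R": "AGTAGCTGTGTGGTTGAGAAG",
    },
    "Octopus bimaculoides": {
        "Obimaculoides_qPCR_auto_F": "TTGTTTGGACCTTGGGCTTATAG",
        "Obimaculoides_qPCR_auto_R": "CTGTCATGAACCCTGGTGTATTC",
        "Obimaculoides_qPCR_sex_F": "CCTCACCACTGGATGCAATTAAG",
        "Obimaculoides_qPCR_sex_R": "GCCAATCCGTCCAACCTATAC",
    },
    "Sepia officinalis": {
        "Sofficinalis_qPCR_auto_F": "TTTGCCACTGTGTCCCTTTATAC",
        "Sofficinalis_qPCR_auto_R": "ACACACACAGGCTGCTTATTG",
        "Sofficinalis_qPCR_sex_F": "TTTCAACCCATCTGCGTCTATAG",
        "Sofficinalis_qPCR_sex_R": "ACTCCTCTCGTTGCATGATTAC",
    },
    "Euprymna berryi": {
        "Eberryi_qPCR_auto_F": "CTTTCGCCACGCCTGATATAC",
        "Eberryi_qPCR_auto_R": "CAGCAGCTTCTTTCCCAGATAAG",
        "Eberryi_qPCR_sex_F": "CTGCCCAGCGAATTGTTTATTG",
        "Eberryi_qPCR_sex_R": "TCCGGCGTCTAGGGATTTAG",
    },
    "Doryteuthis pealeii": {
        "Dpealeii_qPCR_auto_F": "CACTTCAGCCCGATGGAATAAG",
        "Dpealeii_qPCR_auto_R": "CTTTGTAAATGCCGCACCTATATC",
        "Dpealeii_qPCR_sex_F": "GGAGTCTGAGGTCCGAGATATAG",
        "Dpealeii_qPCR_sex_R": "GCCGAGACCACAAACAATAAC",
    },
    "Illex illecebrosus & Illex argentinus": {
        "Illex_qPCR_auto_F": "AAAACTCCCGACGTCTTGAA",
        "Illex_qPCR_auto_R": "GGCCATCCTGGTAGACAAGA",
        "Illex_qPCR_sex_F": "AATCACCCCAACCAGATGAA",
        "Illex_qPCR_sex_R": "CTCCTGGACCTGGAATGAAA",
    },
}

ILLEX_SPECIES = "Illex illecebrosus & Illex argentinus"


def all_primers() -> dict[str, str]:
    """Flat name → sequence map over the whole panel."""
    return {
        name: seq
        for primers in PRIMER_PANEL.values()
        for name, seq in primers.items()
    }


def non_illex_primers() -> dict[str, str]:
    """The 20 primers designed under the stringent interactive preset."""
    return {
        name: seq
        for species, primers in PRIMER_PANEL.items()
        if species != ILLEX_SPECIES
        for name, seq in primers.items()
    }


def illex_primers() -> dict[str, str]:
    """The consensus-refined Illex pair set (pipeline preset)."""
    return dict(PRIMER_PANEL[ILLEX_SPECIES])
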