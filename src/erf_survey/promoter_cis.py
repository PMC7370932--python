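"""Promoter cis-element scanning against a curated consensus dictionary.

Elements are short IUPAC-degenerate consensi matched exactly (PlantCARE
style, no mismatches) on both strands; overlapping and nested matches are
all reported.  Minus-strand hits are reported at the plus-strand coordinate
of the match start.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str          # development | hormone | stress
    source: str            # literature | curated

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes {sorted(bad)}")


@dataclass
class CisHit:
    gene_id: str
    element: str
    position: int          # 1-based start on the plus strand
    strand: str            # + | -


@dataclass
class CisProfile:
    gene_id: str
    counts: dict[str, int]


def default_dictionary() -> list[CisElement]:
    """The survey's element set.

    Eight consensi with literature-sequenced patterns, plus two curated
    PlantCARE-style entries (O2-site, as-1) completing the nine-element
    promoter panel; the latter are overridable by a user dictionary.
    """
    return [
        CisElement("Sp1", "GGGCGG", "development", "literature"),
        CisElement("G-box", "CACGTC", "development", "literature"),
        CisElement("MBS", "CAACTG", "stress", "literature"),
        CisElement("ABRE", "ACGTG", "hormone", "literature"),
        CisElement("LTR", "CCGAAA", "stress", "literature"),
        CisElement("ARE", "AAACCA", "stress", "literature"),
        CisElement("DRE-core", "RCCGAC", "stress", "literature"),
        CisElement("GCC-box", "AGCCGCC", "hormone", "literature"),
        CisElement("O2-site", "GATGAYRTGR", "development", "curated"),
        CisElement("as-1", "TGACG", "hormone", "curated"),
    ]


def _iupac_complement(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str):
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def iupac_matches(sequence: str, consensus: str) -> list[int]:
    """0-based start positions where ``consensus`` matches exactly
    (overlaps included); an N in the sequence matches nothing."""
    return [m.start() for m in _iupac_regex(consensus).finditer(sequence)]


def scan_promoter(
    promoter: str,
    dictionary: Sequence[CisElement] | None = None,
    both_strands: bool = True,
    gene_id: str = "",
) -> list[CisHit]:
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise ValueError(f"promoter contains non-ACGTN characters {sorted(bad)}")
    dictionary = dictionary if dictionary is not None else default_dictionary()
    hits: list[CisHit] = []
    for el in dictionary:
        for i in iupac_matches(promoter, el.consensus):
            hits.append(CisHit(gene_id, el.name, i + 1, "+"))
        if both_strands:
            for i in iupac_matches(promoter, _iupac_complement(el.consensus)):
                hits.append(CisHit(gene_id, el.name, i + 1, "-"))
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def profile_genes(
    promoters: Mapping[str, str],
    dictionary: Sequence[CisElement] | None = None,
    both_strands: bool = True,
) -> tuple[list[CisProfile], pd.DataFrame]:
    """Per-gene element-count profiles plus a genes × elements count matrix."""
    dictionary = dictionary if dictionary is not None else default_dictionary()
    names = [el.name for el in dictionary]
    if len(set(promoters)) != len(list(promoters)):
        raise ValueError("duplicate gene ids in promoter mapping")
    profiles = []
    rows = []
    for gene_id, seq in promoters.items():
        if not seq:
            warnings.warn(f"gene {gene_id}: empty promoter, all-zero profile", stacklevel=2)
            hits = []
        else:
            hits = scan_promoter(seq, dictionary, both_strands, gene_id=gene_id)
        counts = {n: 0 for n in names}
        for h in hits:
            counts[h.element] += 1
        profiles.append(CisProfile(gene_id=gene_id, counts=counts))
        rows.append(counts)
    matrix = pd.DataFrame(rows, index=list(promoters.keys()), columns=names)
    matrix.index.name = "gene_id"
    return profiles, matrix


def hits_table(hits: Iterable[CisHit], dictionary: Sequence[CisElement] | None = None) -> pd.DataFrame:
    """BED-like table of hits (1-based inclusive coordinates)."""
    dictionary = dictionary if dictionary is not None else default_dictionary()
    length = {el.name: len(el.consensus) for el in dictionary}
    rows = [
        {
            "gene_id": h.gene_id,
            "start": h.position,
            "end": h.position + length[h.element] - 1,
            "element": h.element,
            "strand": h.strand,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "element", "strand"])
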