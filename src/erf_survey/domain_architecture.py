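"""AP2 domain detection, subfamily decision tree, EAR census, physicochemistry.

The AP2/ERF superfamily splits on domain architecture: two AP2 domains →
AP2 subfamily; AP2 + B3 → RAV; a single AP2 → ERF or DREB, discriminated
by the AAEIRD signature inside the domain.  The internal detector is a
consensus position-class scorer over the 21-residue core window shared by
ERF and DREB domains (the AAEIRD block is scored as wildcard so both are
detected); a per-domain hit table from a profile-HMM search can be used
instead and is the higher-fidelity path.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io_formats import DomainTableRow, ProteinRecord

#: consensus position classes of the ERF/DREB core window; the AAEIRD block
#: (positions 11-16, 1-based) is a wildcard during detection so DREB-type
#: domains score equally.
AP2_CONSENSUS_CLASSES: tuple[str, ...] = (
    "G", "V", "R", "RQK", "R", "P", "W", "G", "KR", "WYF",
    "*", "*", "*", "*", "*", "*",          # AAEIRD in ERF members
    "P", "A", "KR", "KG", "AGV",
)
AP2_WINDOW = len(AP2_CONSENSUS_CLASSES)
ERF_SIGNATURE = "AAEIRD"

#: EAR repression motif (L/F)DLN(L/F)xP
EAR_REGEX = re.compile(r"(?=([LF]DLN[LF].P))")


@dataclass
class DomainHit:
    protein_id: str
    kind: str              # "AP2" | "B3"
    start: int             # 1-based inclusive
    end: int
    score: float
    source: str            # "table" | "internal"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: hit start {self.start} > end {self.end}")


@dataclass
class FamilyCall:
    protein_id: str
    n_ap2: int
    has_b3: bool
    family: str            # AP2 | RAV | ERF | DREB | other
    aaeird_present: bool


@dataclass
class EarHit:
    protein_id: str
    start: int             # 1-based
    matched_text: str


@dataclass
class PhysicoChem:
    length_aa: int
    molecular_weight: float
    isoelectric_point: float
    gravy: float
    approximate: bool = False   # True when X residues were ignored


# ---------------------------------------------------------------------------
# internal AP2 detector

def _class_lookup() -> np.ndarray:
    """(window, 128) boolean table: does ASCII code c satisfy position k."""
    table = np.zeros((AP2_WINDOW, 128), dtype=bool)
    for k, cls in enumerate(AP2_CONSENSUS_CLASSES):
        if cls == "*":
            continue
        for aa in cls:
            table[k, ord(aa)] = True
    return table


_LOOKUP = _class_lookup()
_CONSTRAINED = [k for k, c in enumerate(AP2_CONSENSUS_CLASSES) if c != "*"]
MAX_SCORE = len(_CONSTRAINED)


def detect_ap2_internal(
    protein: ProteinRecord, score_fraction: float = 0.8
) -> list[DomainHit]:
    """Scan a protein for the ERF/DREB core window.

    Windows scoring at least ``score_fraction`` of the maximum (number of
    constrained consensus positions matched) are hits; overlapping windows
    are resolved greedily by score, ties to the leftmost.
    """
    seq = protein.sequence
    n = len(seq) - AP2_WINDOW + 1
    if n <= 0:
        return []
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    scores = np.zeros(n, dtype=np.int32)
    for k in _CONSTRAINED:
        scores += _LOOKUP[k][codes[k : k + n]]
    cutoff = score_fraction * MAX_SCORE
    candidates = np.flatnonzero(scores >= cutoff)
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) >= AP2_WINDOW for j in chosen):
            chosen.append(i)
    return [
        DomainHit(
            protein_id=protein.id,
            kind="AP2",
            start=int(i) + 1,
            end=int(i) + AP2_WINDOW,
            score=float(scores[i]) / MAX_SCORE,
            source="internal",
        )
        for i in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# architecture decision tree

def classify_architecture(
    hits: Sequence[DomainHit],
    protein: ProteinRecord,
    signature_slack: int = 3,
) -> FamilyCall:
    """Label a protein by its domain architecture.

    Two or more AP2 domains → AP2; any B3 domain → RAV; exactly one AP2 and
    no B3 → ERF when the AAEIRD signature lies within the hit span (±
    ``signature_slack`` residues), else DREB; no AP2 → other.
    """
    for h in hits:
        if h.protein_id != protein.id:
            raise ValueError(f"hit for {h.protein_id!r} given with protein {protein.id!r}")
        if h.end > len(protein):
            raise ValueError(
                f"{protein.id}: hit span ({h.start},{h.end}) exceeds length {len(protein)}"
            )
    ap2 = sorted((h for h in hits if h.kind == "AP2"), key=lambda h: h.start)
    has_b3 = any(h.kind == "B3" for h in hits)
    aaeird = False
    for h in ap2:
        lo = max(0, h.start - 1 - signature_slack)
        hi = min(len(protein), h.end + signature_slack)
        if ERF_SIGNATURE in protein.sequence[lo:hi]:
            aaeird = True
            break
    if len(ap2) >= 2:
        family = "AP2"
    elif has_b3:
        family = "RAV"
    elif len(ap2) == 1:
        family = "ERF" if aaeird else "DREB"
    else:
        family = "other"
    return FamilyCall(
        protein_id=protein.id,
        n_ap2=len(ap2),
        has_b3=has_b3,
        family=family,
        aaeird_present=aaeird,
    )


def scan_ear(protein: ProteinRecord) -> list[EarHit]:
    """All (overlapping) matches of the EAR motif (L/F)DLN(L/F)xP."""
    return [
        EarHit(protein_id=protein.id, start=m.start() + 1, matched_text=m.group(1))
        for m in EAR_REGEX.finditer(protein.sequence)
    ]


# ---------------------------------------------------------------------------
# physicochemistry (ExPASy-style: Bjellqvist pKa set, Kyte-Doolittle GRAVY)

def compute_physicochem(protein: ProteinRecord) -> PhysicoChem:
    seq = protein.sequence
    approximate = "X" in seq
    clean = seq.replace("X", "")       # X contributes zero mass/charge/hydropathy
    if not clean:
        raise ValueError(f"{protein.id}: no standard residues")
    pa = ProteinAnalysis(clean)
    return PhysicoChem(
        length_aa=len(seq),
        molecular_weight=pa.molecular_weight(),
        isoelectric_point=pa.isoelectric_point(),
        gravy=pa.gravy(),
        approximate=approximate,
    )


# ---------------------------------------------------------------------------
# the identification funnel

def _hits_from_table(rows: Iterable[DomainTableRow]) -> dict[str, list[DomainHit]]:
    by_protein: dict[str, list[DomainHit]] = {}
    for r in rows:
        name = r.domain_name.upper()
        kind = "B3" if "B3" in name else "AP2"
        by_protein.setdefault(r.protein_id, []).append(
            DomainHit(
                protein_id=r.protein_id,
                kind=kind,
                start=r.env_start,
                end=r.env_end,
                score=r.evalue,
                source="table",
            )
        )
    return by_protein


def identify_erf_set(
    proteome: Sequence[ProteinRecord],
    table: Optional[Sequence[DomainTableRow]] = None,
    score_fraction: float = 0.8,
) -> list[FamilyCall]:
    """Run the identification funnel over a proteome.

    With a domain table the table hits drive the decision tree (the
    profile-HMM path); otherwise the internal consensus detector is used.
    Returns one call per protein with at least one domain hit.
    """
    ids = {p.id for p in proteome}
    if table is not None:
        unknown = sorted({r.protein_id for r in table} - ids)
        if unknown:
            raise ValueError(f"domain table references unknown proteins: {unknown}")
        by_protein = _hits_from_table(table)
    else:
        by_protein = {}
        for p in proteome:
            hits = detect_ap2_internal(p, score_fraction=score_fraction)
            if hits:
                by_protein[p.id] = hits
    lookup = {p.id: p for p in proteome}
    calls = [
        classify_architecture(hits, lookup[pid])
        for pid, hits in by_protein.items()
        if hits
    ]
    return calls


def family_counts(calls: Iterable[FamilyCall]) -> Counter:
    return Counter(c.family for c in calls)
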