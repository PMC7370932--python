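"""Duplicate-pair classification and Ka/Ks under the Nei-Gojobori (1986) model.

Site counting weights each codon position by the fraction of its one-step
changes that are synonymous; mutational neighbours that create a stop codon
are excluded from the denominator, so S + N = 3 x (paired codons) always
holds.  Differences in multi-difference codons are averaged over all
minimal substitution pathways, excluding pathways that pass through a stop
codon (weights renormalised; if every pathway is blocked, all minimal
pathways are used).  Proportions are corrected for multiple hits with
Jukes-Cantor, d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from math import log
from typing import Mapping, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .io_formats import CdsRecord, GeneModel

_TABLE = unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
_BASES = "ACGT"


@dataclass
class GenePair:
    gene_a: str
    gene_b: str
    relationship: str = "unknown"   # tandem | segmental | unknown

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a


@dataclass
class KaKsResult:
    pair: Optional[GenePair]
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    purifying: Optional[bool]
    n_codons: int
    sites_syn: float = 0.0
    sites_nonsyn: float = 0.0
    method: str = "NG86"
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pair classification

def classify_pair(
    pair: GenePair,
    models: Mapping[str, GeneModel],
    max_intervening: int = 5,
    max_span: int = 100_000,
) -> GenePair:
    """Tandem vs segmental from coordinates.

    Tandem: same chromosome and either at most ``max_intervening`` family
    genes between the two, or a genomic span of at most ``max_span`` bp.
    """
    a = models.get(pair.gene_a)
    b = models.get(pair.gene_b)
    if a is None or b is None:
        warnings.warn(
            f"pair ({pair.gene_a},{pair.gene_b}): missing coordinates", stacklevel=2
        )
        pair.relationship = "unknown"
        return pair
    if a.chromosome != b.chromosome:
        pair.relationship = "segmental"
        return pair
    lo, hi = min(a.start, b.start), max(a.end, b.end)
    intervening = sum(
        1
        for g in models.values()
        if g.chromosome == a.chromosome
        and g.gene_id not in (a.gene_id, b.gene_id)
        and g.start > min(a.end, b.end)
        and g.end < max(a.start, b.start)
    )
    pair.relationship = (
        "tandem" if (intervening <= max_intervening or hi - lo <= max_span) else "segmental"
    )
    return pair


# ---------------------------------------------------------------------------
# codon alignment

def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def codon_align(
    cds_a: CdsRecord | str,
    cds_b: CdsRecord | str,
    protein_alignment: tuple[str, str],
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment into paired codon columns.

    Gap columns are dropped; a terminal stop codon is trimmed; an internal
    stop is an error naming the codon position.
    """
    seqs = []
    for cds in (cds_a, cds_b):
        raw = cds.sequence if isinstance(cds, CdsRecord) else cds.upper()
        raw = _strip_terminal_stop(raw)
        if len(raw) % 3 != 0:
            raise ValueError("CDS length not a multiple of 3 after stop trimming")
        prot = str(Seq(raw).translate())
        if "*" in prot:
            raise ValueError(f"internal stop codon at codon {prot.index('*') + 1}")
        seqs.append((raw, prot))
    aligned_a, aligned_b = protein_alignment
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    for (raw, prot), aligned in zip(seqs, (aligned_a, aligned_b)):
        ungapped = aligned.replace("-", "")
        if ungapped != prot:
            for k, (x, y) in enumerate(zip(ungapped, prot), 1):
                if x != y:
                    raise ValueError(
                        f"CDS translation mismatch at residue {k}: {y!r} vs aligned {x!r}"
                    )
            raise ValueError("CDS/protein alignment length mismatch")
    pairs = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            pairs.append((seqs[0][0][3 * ia : 3 * ia + 3], seqs[1][0][3 * ib : 3 * ib + 3]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


# ---------------------------------------------------------------------------
# NG86

def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one sense codon.

    Each position contributes 1 site, split by the fraction of its non-stop
    one-step changes that preserve the amino acid.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over allowed minimal pathways."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        paths.append((blocked, steps))
    allowed = [steps for blocked, steps in paths if not blocked]
    if not allowed:
        allowed = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in allowed:
        for before, after in steps:
            if GENETIC_CODE[before] == GENETIC_CODE[after]:
                sd += 1
            else:
                nd += 1
    k = len(allowed)
    return sd / k, nd / k


def jukes_cantor(p: float) -> Optional[float]:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return 0.0 if p == 0 else -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86(
    paired_codons: Sequence[tuple[str, str]], pair: Optional[GenePair] = None
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks on paired codon columns."""
    if not paired_codons:
        raise ValueError("no paired codons")
    sa = na = sb = nb = sd = nd = 0.0
    for ca, cb in paired_codons:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in paired column ({ca},{cb})")
        s1, n1 = syn_nonsyn_sites(ca)
        s2, n2 = syn_nonsyn_sites(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        d_s, d_n = _pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    S = (sa + sb) / 2.0
    N = (na + nb) / 2.0
    notes: list[str] = []
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        notes.append(f"ks undefined: ps={ps:.3f} >= 3/4 (Jukes-Cantor saturated)")
    if ka is None:
        notes.append(f"ka undefined: pn={pn:.3f} >= 3/4 (Jukes-Cantor saturated)")
    ratio = purifying = None
    if ka is not None and ks is not None:
        if ks > 0:
            ratio = ka / ks
            purifying = ratio < 1.0
        else:
            notes.append("ratio undefined: ks = 0")
    return KaKsResult(
        pair=pair,
        ka=ka,
        ks=ks,
        ratio=ratio,
        purifying=purifying,
        n_codons=len(paired_codons),
        sites_syn=S,
        sites_nonsyn=N,
        notes=notes,
    )
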