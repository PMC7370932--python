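"""Seeded generators with planted ground truth.

Every generator is a pure function of its parameters and seed and returns,
alongside the data, a truth object sufficient to score recovery without
inspecting generator internals.  Backgrounds are reject-resampled against
the motif dictionaries in play, so planted feature counts are exact truth,
not approximate truth.

Defaults mirror the study conditions of the maize ERF survey: 2-kb
promoters, three expression replicates per condition, fold-10 tissue
elevation, two-fold DE cutoff exercised with planted fold-4 genes, and
2^-ddCt qPCR tables with Gaussian replicate noise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .domain_architecture import AP2_CONSENSUS_CLASSES, EAR_REGEX, ERF_SIGNATURE
from .duplication_selection import GENETIC_CODE, SENSE_CODONS, STOP_CODONS
from .expression_profiles import ExpressionMatrix
from .io_formats import CdsRecord, DomainTableRow, GeneModel, ProteinRecord
from .phylogeny_grouping import DistanceMatrix
from .promoter_cis import CisElement, default_dictionary, iupac_matches, _iupac_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AAEIRD_RE = re.compile("(?=(AAEIRD))")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# proteome with planted domain architectures

@dataclass
class ProteomeTruth:
    family: dict[str, str]
    domains: dict[str, list[tuple[int, int, str]]]   # 1-based spans
    ear_positions: dict[str, list[int]]
    seed: int


def _ap2_segment(rng: np.random.Generator, erf: bool) -> str:
    """A consensus-conforming core window; ERF members carry AAEIRD, the
    DREB-type variant carries a non-matching core."""
    out = []
    for k, cls in enumerate(AP2_CONSENSUS_CLASSES):
        if cls == "*":
            continue
        out.append(cls[rng.integers(0, len(cls))])
        if k == 9:   # insert the 6-residue core after position 10
            out.append(ERF_SIGNATURE if erf else "SAEVGE")
    return "".join(out)


def _ear_heptamer(rng: np.random.Generator) -> str:
    x = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    first = "LF"[rng.integers(0, 2)]
    fifth = "LF"[rng.integers(0, 2)]
    return f"{first}DLN{fifth}{x}P"


def _clean_background(rng: np.random.Generator, length: int) -> str:
    """Uniform-composition residues screened against EAR and AAEIRD."""
    seq = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)
    )
    while True:
        spots = [m.start() for m in EAR_REGEX.finditer(seq)]
        spots += [m.start() for m in _AAEIRD_RE.finditer(seq)]
        if not spots:
            return seq
        chars = list(seq)
        for s in spots:
            for k in range(s, min(len(chars), s + 7)):
                chars[k] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        seq = "".join(chars)


def _assemble(
    rng: np.random.Generator, length: int, segments: Sequence[str]
) -> tuple[str, list[tuple[int, int]]]:
    """Place segments at non-overlapping random positions inside screened
    background; returns sequence and 1-based segment spans."""
    total_seg = sum(len(s) for s in segments)
    if total_seg > length:
        raise ValueError("segments longer than protein")
    n_gaps = len(segments) + 1
    free = length - total_seg
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1))
    gaps = np.diff(np.concatenate([[0], cuts, [free]]))
    parts = []
    spans = []
    pos = 0
    for seg, gap in zip(segments, gaps[:-1]):
        parts.append(_clean_background(rng, int(gap)))
        pos += int(gap)
        spans.append((pos + 1, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
    parts.append(_clean_background(rng, int(gaps[-1])))
    return "".join(parts), spans


def generate_proteome(
    n: int,
    family_proportions: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    ear_fraction: float = 0.5,
    length: int = 300,
) -> tuple[list[ProteinRecord], list[DomainTableRow], ProteomeTruth]:
    """Synthetic proteome with planted AP2/ERF architectures.

    ERF proteins embed one consensus core containing AAEIRD; DREB proteins
    the variant core; AP2-family proteins two variant cores; RAV proteins a
    variant core plus a B3 domain recorded only in the emitted domain table
    (B3 has no sequence signature here); 'other' proteins are pure
    background.  A fraction of ERFs carry one EAR heptamer.
    """
    if n < 1:
        raise ValueError("n must be positive")
    props = dict(
        family_proportions
        or {"ERF": 0.2, "DREB": 0.2, "AP2": 0.1, "RAV": 0.05, "other": 0.45}
    )
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("family proportions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = {f: int(math.floor(p * n)) for f, p in props.items()}
    remainder = n - sum(counts.values())
    for f in sorted(props, key=lambda f: -(props[f] * n - counts[f]))[:remainder]:
        counts[f] += 1
    labels = [f for f, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)
    records, rows = [], []
    truth = ProteomeTruth(family={}, domains={}, ear_positions={}, seed=seed)
    for i, family in enumerate(labels, 1):
        pid = f"P{i:05d}"
        segments: list[str] = []
        kinds: list[str] = []
        if family == "ERF":
            segments.append(_ap2_segment(rng, erf=True))
            kinds.append("AP2")
        elif family == "DREB":
            segments.append(_ap2_segment(rng, erf=False))
            kinds.append("AP2")
        elif family == "AP2":
            segments += [_ap2_segment(rng, erf=False), _ap2_segment(rng, erf=False)]
            kinds += ["AP2", "AP2"]
        elif family == "RAV":
            segments.append(_ap2_segment(rng, erf=False))
            kinds.append("AP2")
        ear_here = family == "ERF" and rng.random() < ear_fraction
        if ear_here:
            segments.append(_ear_heptamer(rng))
            kinds.append("EAR")
        seq, spans = _assemble(rng, length, segments)
        records.append(ProteinRecord(pid, seq))
        truth.family[pid] = family
        truth.domains[pid] = []
        truth.ear_positions[pid] = []
        for kind, (a, b) in zip(kinds, spans):
            if kind == "EAR":
                truth.ear_positions[pid].append(a)
            else:
                truth.domains[pid].append((a, b, "AP2"))
                rows.append(
                    DomainTableRow(pid, "AP2", float(10.0 ** rng.uniform(-30, -6)), a, b)
                )
        if family == "RAV":
            b3_start = 1 if spans[0][0] > 60 else spans[0][1] + 5
            b3_end = min(length, b3_start + 49)
            truth.domains[pid].append((b3_start, b3_end, "B3"))
            rows.append(
                DomainTableRow(pid, "B3", float(10.0 ** rng.uniform(-30, -6)), b3_start, b3_end)
            )
    return records, rows, truth


# ---------------------------------------------------------------------------
# genome with planted promoter elements

@dataclass
class PromoterTruth:
    counts: dict[str, dict[str, int]]                  # gene -> element -> hits
    planted: dict[str, list[tuple[str, int]]]          # gene -> (element, offset)
    seed: int


def _scan_all(seq: str, dictionary: Sequence[CisElement]) -> list[tuple[str, int, int]]:
    """(element, 0-based start, length) on both strands, regex speed."""
    out = []
    for el in dictionary:
        k = len(el.consensus)
        for i in iupac_matches(seq, el.consensus):
            out.append((el.name, i, k))
        for i in iupac_matches(seq, _iupac_complement(el.consensus)):
            out.append((el.name, i, k))
    return out


def _clean_dna(rng: np.random.Generator, length: int, dictionary) -> str:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    for _ in range(200):
        hits = _scan_all(seq, dictionary)
        if not hits:
            return seq
        chars = list(seq)
        for _, i, k in hits:
            for j in range(i, min(length, i + k)):
                chars[j] = "ACGT"[rng.integers(0, 4)]
        seq = "".join(chars)
    raise RuntimeError("could not screen background against dictionary")


def _resolve(consensus: str, rng: np.random.Generator) -> str:
    from .promoter_cis import IUPAC

    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in consensus)


def generate_genome_with_promoters(
    genes: Sequence[str] | int,
    element_rates: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    promoter_length: int = 2000,
    gene_length: int = 900,
    dictionary: Optional[Sequence[CisElement]] = None,
) -> tuple[dict[str, str], list[GeneModel], PromoterTruth]:
    """Genome FASTA + gene models with planted promoter cis-elements.

    ``element_rates`` maps element name to the number of copies planted per
    gene promoter.  Backgrounds (promoter and gene body) are screened so
    every dictionary hit in a promoter is attributable to a planted
    insertion; planted copies of one element may deterministically imply a
    hit of another (overlapping consensi), and the recorded per-gene truth
    is the exact hit count of the assembled promoter.
    """
    if isinstance(genes, int):
        genes = [f"G{i:04d}" for i in range(1, genes + 1)]
    dictionary = list(dictionary) if dictionary is not None else default_dictionary()
    rates = dict(element_rates or {})
    unknown = set(rates) - {el.name for el in dictionary}
    if unknown:
        raise ValueError(f"rates for unknown elements: {sorted(unknown)}")
    if any(v < 0 for v in rates.values()):
        raise ValueError("element rates must be non-negative")
    by_name = {el.name: el for el in dictionary}
    rng = np.random.default_rng(seed)
    max_len = max((len(el.consensus) for el in dictionary), default=10)
    truth = PromoterTruth(counts={}, planted={}, seed=seed)
    models = []
    chrom_parts: dict[str, list[str]] = {}
    offsets: dict[str, int] = {}
    n_chrom = max(1, min(5, len(genes) // 20))
    from .io_formats import reverse_complement

    for gi, gene_id in enumerate(genes):
        chrom = f"chr{gi % n_chrom + 1}"
        chrom_parts.setdefault(chrom, [])
        offsets.setdefault(chrom, 0)
        strand = "+" if rng.random() < 0.5 else "-"
        # build the promoter in promoter orientation
        for _attempt in range(50):
            promoter = list(_clean_dna(rng, promoter_length, dictionary))
            planted = []
            taken: list[tuple[int, int]] = []
            ok = True
            for name, copies in rates.items():
                for _ in range(copies):
                    literal = _resolve(by_name[name].consensus, rng)
                    for _try in range(200):
                        pos = int(rng.integers(0, promoter_length - len(literal) + 1))
                        lo, hi = pos - max_len, pos + len(literal) + max_len
                        if all(hi <= a or lo >= b for a, b in taken):
                            break
                    else:
                        ok = False
                        break
                    promoter[pos : pos + len(literal)] = literal
                    taken.append((pos, pos + len(literal)))
                    planted.append((name, pos + 1))
                if not ok:
                    break
            if not ok:
                continue
            promoter_seq = "".join(promoter)
            hits = _scan_all(promoter_seq, dictionary)
            # every hit must overlap a planted window (background is clean)
            if all(
                any(i < b + max_len and i + k > a - max_len for a, b in taken)
                for _, i, k in hits
            ):
                break
        else:
            raise RuntimeError(f"gene {gene_id}: could not plant elements cleanly")
        counts: dict[str, int] = {el.name: 0 for el in dictionary}
        for name, _i, _k in hits:
            counts[name] += 1
        truth.counts[gene_id] = counts
        truth.planted[gene_id] = planted
        body = _clean_dna(rng, gene_length, dictionary)
        spacer = _clean_dna(rng, 100, dictionary)
        base = offsets[chrom]
        if strand == "+":
            block = promoter_seq + body + spacer
            start = base + promoter_length + 1
            end = start + gene_length - 1
        else:
            block = spacer + body + reverse_complement(promoter_seq)
            start = base + 100 + 1
            end = start + gene_length - 1
        chrom_parts[chrom].append(block)
        offsets[chrom] += len(block)
        n_exons = int(rng.integers(1, 5))
        bounds = sorted(rng.choice(np.arange(1, gene_length), size=2 * n_exons - 2, replace=False)) if n_exons > 1 else []
        rel = [0] + [int(b) for b in bounds] + [gene_length - 1]
        exons = [
            (start + rel[2 * k], start + rel[2 * k + 1]) for k in range(n_exons)
        ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                exon_intervals=exons,
            )
        )
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    return genome, models, truth


# ---------------------------------------------------------------------------
# CDS pair evolved with known Ka/Ks

@dataclass
class CdsPairTruth:
    ks_target: float
    ka_target: float
    n_syn_changes: int
    n_nonsyn_changes: int
    seed: int


def _jc_forward(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _codon_change_sets(codon: str) -> list[tuple[list[str], list[str]]]:
    """Per position: (synonymous, non-synonymous) non-stop single changes."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        syn, nonsyn = [], []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            (syn if GENETIC_CODE[alt] == aa else nonsyn).append(alt)
        out.append((syn, nonsyn))
    return out


def generate_cds_pair(
    n_codons: int, ks_target: float, ka_target: float, seed: int = 0
) -> tuple[CdsRecord, CdsRecord, CdsPairTruth]:
    """An ancestor CDS and a derived copy with planted substitution rates.

    Each codon position is substituted at most once; synonymous positions
    differ with the proportion implied by the Jukes-Cantor forward map of
    ``ks_target`` (likewise non-synonymous with ``ka_target``), so NG86 on
    the pair is an unbiased estimate of the targets.
    """
    if ks_target < 0 or ka_target < 0:
        raise ValueError("targets must be non-negative")
    p_s, p_n = _jc_forward(ks_target), _jc_forward(ka_target)
    if p_s >= 0.74 or p_n >= 0.74:
        raise ValueError("target rates are at Jukes-Cantor saturation")
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    derived = []
    n_syn = n_non = 0
    for codon in ancestor:
        per_pos = _codon_change_sets(codon)
        probs = []
        for syn, nonsyn in per_pos:
            valid = len(syn) + len(nonsyn)
            f_syn = len(syn) / valid if valid else 0.0
            probs.append(f_syn * p_s + (1.0 - f_syn) * p_n)
        u = rng.random()
        acc = 0.0
        new = codon
        for pos, (p_sub, (syn, nonsyn)) in enumerate(zip(probs, per_pos)):
            if u < acc + p_sub:
                valid = len(syn) + len(nonsyn)
                f_syn = len(syn) / valid if valid else 0.0
                p_syn_here = f_syn * p_s
                if (u - acc) < p_syn_here and syn:
                    new = syn[rng.integers(0, len(syn))]
                    n_syn += 1
                elif nonsyn:
                    new = nonsyn[rng.integers(0, len(nonsyn))]
                    n_non += 1
                break
            acc += p_sub
        derived.append(new)
    a = CdsRecord("ancestor", "".join(ancestor), frame_checked=True)
    b = CdsRecord("derived", "".join(derived), frame_checked=True)
    return a, b, CdsPairTruth(ks_target, ka_target, n_syn, n_non, seed)


# ---------------------------------------------------------------------------
# expression matrix with planted tissue-specific and DE genes

@dataclass
class ExpressionTruth:
    specific_tissue: dict[str, Optional[str]]
    de_direction: dict[tuple[str, str], dict[str, str]]   # contrast -> gene -> up/down/none
    seed: int


def generate_expression(
    n_genes: int = 500,
    tissues: Sequence[str] = ("root", "leaf", "ear", "embryo", "endosperm", "pollen"),
    de_spec: Optional[Mapping[tuple[str, str], tuple[float, float, float]]] = None,
    n_reps: int = 3,
    specific_fraction: float = 0.1,
    specific_fold: float = 10.0,
    noise_sd: float = 0.2,
    baseline_log_mean: float = math.log(20.0),
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """FPKM matrix over tissues (and stress conditions when ``de_spec`` is
    given) with log-normal baselines and multiplicative replicate noise.

    ``de_spec`` maps (treatment, control) to (fraction up, fraction down,
    fold); the control condition is added automatically.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates per condition")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    de_spec = dict(de_spec or {})
    conditions: list[str] = list(tissues)
    for (t, c) in de_spec:
        for cond in (c, t):
            if cond not in conditions:
                conditions.append(cond)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    mean = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(conditions))), index=genes, columns=conditions
    )
    truth = ExpressionTruth(specific_tissue={g: None for g in genes}, de_direction={}, seed=seed)
    n_specific = int(round(specific_fraction * n_genes))
    specific_genes = rng.choice(genes, size=n_specific, replace=False)
    for g in specific_genes:
        tis = tissues[rng.integers(0, len(tissues))]
        mean.loc[g, tis] *= specific_fold
        truth.specific_tissue[g] = tis
    assigned: set[str] = set()
    for (treatment, control), (f_up, f_down, fold) in de_spec.items():
        if fold <= 0:
            raise ValueError("DE fold must be positive")
        direction = {g: "none" for g in genes}
        pool = [g for g in genes if g not in assigned]
        n_up, n_down = int(round(f_up * n_genes)), int(round(f_down * n_genes))
        chosen = rng.choice(pool, size=n_up + n_down, replace=False)
        for g in chosen[:n_up]:
            mean.loc[g, treatment] *= fold
            direction[g] = "up"
        for g in chosen[n_up:]:
            mean.loc[g, treatment] /= fold
            direction[g] = "down"
        assigned.update(chosen)
        truth.de_direction[(treatment, control)] = direction
    cols = {}
    condition_of_sample = {}
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            sample = f"{cond}_r{rep}"
            noise = np.exp(rng.normal(0.0, noise_sd, size=n_genes)) if noise_sd > 0 else 1.0
            cols[sample] = mean[cond].to_numpy() * noise
            condition_of_sample[sample] = (cond, rep)
    values = pd.DataFrame(cols, index=genes)
    return ExpressionMatrix(values=values, condition_of_sample=condition_of_sample), truth


# ---------------------------------------------------------------------------
# qPCR Ct table with planted fold changes

@dataclass
class CtTruth:
    fold_changes: dict[str, dict[str, float]]
    reference_gene: str
    control_condition: str
    seed: int


def generate_ct_table(
    genes: Sequence[str],
    fold_changes: Mapping[str, Mapping[str, float]],
    n_reps: int = 6,
    noise_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "reference",
    control_condition: str = "0h",
    base_ct: float = 24.0,
    reference_ct: float = 20.0,
) -> tuple[pd.DataFrame, CtTruth]:
    """Replicated Ct table: the reference gene is constant across
    conditions; target Ct shifts by -log2(fold) under treatment."""
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    conditions = [control_condition] + sorted(
        {c for folds in fold_changes.values() for c in folds if c != control_condition}
    )
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "gene": reference_gene,
                    "condition": cond,
                    "replicate": rep,
                    "ct": reference_ct + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                }
            )
    truth_fc: dict[str, dict[str, float]] = {}
    for gene in genes:
        folds = dict(fold_changes.get(gene, {}))
        for f in folds.values():
            if f <= 0:
                raise ValueError(f"{gene}: fold must be positive")
        truth_fc[gene] = {c: folds.get(c, 1.0) for c in conditions}
        truth_fc[gene][control_condition] = 1.0
        for cond in conditions:
            shift = -math.log2(truth_fc[gene][cond])
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": base_ct
                        + shift
                        + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                    }
                )
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return table, CtTruth(truth_fc, reference_gene, control_condition, seed)


# ---------------------------------------------------------------------------
# additive distance matrices and grouped families (phylogeny truth)

def generate_additive_matrix(
    n: int, seed: int = 0, branch_range: tuple[float, float] = (0.1, 1.0)
) -> tuple[DistanceMatrix, set[frozenset]]:
    """A random unrooted binary tree's additive distance matrix plus its
    internal bipartitions (canonical: the side without the first label)."""
    if n < 4:
        raise ValueError("need at least four taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i:03d}" for i in range(n)]
    edges: list[tuple[int, int, float]] = []
    nxt = n

    def bl() -> float:
        return float(rng.uniform(*branch_range))

    edges = [(0, n, bl()), (1, n, bl()), (2, n, bl())]
    nxt = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v, ln = edges.pop(k)
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8)) * ln
        edges += [(u, mid, split), (v, mid, ln - split), (leaf, mid, bl())]
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, ln in edges:
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    d = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            node = stack.pop()
            for nbr, ln in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + ln
                    stack.append(nbr)
        for t in range(n):
            d[s, t] = dist[t]
    bps = set()
    for u, v, _ in edges:
        stack, seen, side = [v], {u, v}, set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nbr, _ln in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if 2 <= len(side) <= n - 2:
            if 0 in side:
                side = set(range(n)) - side
            bps.add(frozenset(labels[i] for i in side))
    return DistanceMatrix(labels=labels, d=d), bps


def generate_grouped_proteins(
    n_groups: int = 6,
    per_group: int = 8,
    seed: int = 0,
    length: int = 60,
    within_mutation: float = 0.04,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Families of similar sequences: independent random ancestors per
    group, members derived by light point mutation.  Returns (id, sequence)
    pairs and the id → group truth."""
    rng = np.random.default_rng(seed)
    seqs = []
    truth = {}
    for g in range(n_groups):
        group = f"B{g + 1}"
        ancestor = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
        for m in range(per_group):
            member = list(ancestor)
            for k in range(length):
                if rng.random() < within_mutation:
                    member[k] = AMINO_ACIDS[rng.integers(0, 20)]
            name = f"{group}_m{m + 1}"
            seqs.append((name, "".join(member)))
            truth[name] = group
    return seqs, truth


# ---------------------------------------------------------------------------
# synthetic stand-in for the deposited 76-member ZmERF set

EAR_MEMBER_NUMBERS = (7, 21, 22, 26, 32, 33, 34, 46, 47, 58, 63, 64, 65, 76)
LENGTH_EXTREMES = {44: 183, 24: 1425}     # member number -> length (aa)
PI_EXTREMES = {11: 4.44, 46: 10.46}       # member number -> target pI


@dataclass
class StandinTruth:
    ear_members: tuple[str, ...]
    lengths: dict[str, int]
    pi_targets: dict[str, float]
    seed: int


def _composition_pi(counts: Mapping[str, int], fixed: str) -> float:
    # glycine sentinels pin the terminal pKa values, making pI a pure
    # function of composition (assembly order then cannot shift it)
    seq = "G" + fixed + "".join(aa * c for aa, c in counts.items()) + "G"
    return ProteinAnalysis(seq).isoelectric_point()


def _design_filler(
    target_pi: float, n_filler: int, fixed: str, rng: np.random.Generator
) -> str:
    """Charged-residue counts hit the target isoelectric point; the rest of
    the filler is neutral.  Coarse-to-fine grid over (D, E, K) counts."""
    best = None
    max_charged = min(n_filler, 90)
    for nk in range(0, min(40, max_charged)):
        for nd in range(0, max_charged - nk):
            for ne in (0, 1, 2, 3):
                if nk + nd + ne > max_charged:
                    continue
                pi = _composition_pi({"D": nd, "E": ne, "K": nk}, fixed)
                err = abs(pi - target_pi)
                if best is None or err < best[0]:
                    best = (err, nd, ne, nk)
        if best and best[0] < 0.002:
            break
    err, nd, ne, nk = best
    if err > 0.005:
        raise RuntimeError(f"pI design missed target {target_pi} by {err:.3f}")
    neutral = "GASTV"
    filler = list("D" * nd + "E" * ne + "K" * nk) + [
        neutral[i] for i in rng.integers(0, len(neutral), size=n_filler - nd - ne - nk)
    ]
    rng.shuffle(filler)
    return "".join(filler)


def zmerf_standin(seed: int = 0) -> tuple[list[ProteinRecord], StandinTruth]:
    """Synthetic stand-in for the deposited 76-member maize ERF protein set.

    These are NOT the published sequences (which are not redistributed
    here): they are constructed proteins whose planted summary properties
    match the published facts about that set — 76 members each carrying one
    AP2 core window with the AAEIRD signature, EAR motifs in exactly the 14
    enumerated members, protein lengths spanning 183 to 1,425 residues on
    the named members, and isoelectric points spanning 4.44 to 10.46 by
    composition design.  Everything downstream treats the set like any
    other protein FASTA.
    """
    rng = np.random.default_rng(seed)
    ear_ids = tuple(f"ZmERF{k}" for k in EAR_MEMBER_NUMBERS)
    records = []
    lengths: dict[str, int] = {}
    pi_targets = {f"ZmERF{k}": v for k, v in PI_EXTREMES.items()}
    for k in range(1, 77):
        pid = f"ZmERF{k}"
        length = LENGTH_EXTREMES.get(k, int(rng.integers(200, 701)))
        lengths[pid] = length
        segments = [_ap2_segment(rng, erf=True)]
        if pid in ear_ids:
            segments.append(_ear_heptamer(rng))
        if k in PI_EXTREMES:
            fixed = "".join(segments)
            filler = _design_filler(
                PI_EXTREMES[k], length - len(fixed) - 2, fixed, rng
            )
            for _ in range(100):
                # splice segments into the (pI-neutral) shuffled filler;
                # glycine sentinels match the design's terminal model
                cut = int(rng.integers(0, len(filler) + 1))
                seq = filler[:cut] + segments[0] + filler[cut:]
                if len(segments) > 1:
                    cut2 = int(rng.integers(0, cut + 1))
                    seq = seq[:cut2] + segments[1] + seq[cut2:]
                seq = "G" + seq + "G"
                n_ear = len(EAR_REGEX.findall(seq))
                want_ear = 1 if pid in ear_ids else 0
                if len(_AAEIRD_RE.findall(seq)) == 1 and n_ear == want_ear:
                    break
                filler_list = list(filler)
                rng.shuffle(filler_list)
                filler = "".join(filler_list)
            else:
                raise RuntimeError(f"{pid}: could not assemble designed sequence")
        else:
            for _ in range(100):
                seq, _spans = _assemble(rng, length, segments)
                pi = ProteinAnalysis(seq).isoelectric_point()
                if 4.60 < pi < 10.25:
                    break
            else:
                raise RuntimeError(f"{pid}: could not screen pI into range")
        records.append(ProteinRecord(pid, seq, "synthetic stand-in"))
    return records, StandinTruth(ear_ids, lengths, pi_targets, seed)
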