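"""The one-shot survey: run every stage whose inputs are present.

Stages: identification (domain table or internal detector) → annotation
(EAR census, physicochemistry) → phylogeny and grouping → promoter
cis-elements → duplication Ka/Ks → expression and qPCR.  Outputs are flat
TSV (plus newick for trees); a run log records seeds and per-stage counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import (
    domain_architecture as da,
    duplication_selection as ds,
    expression_profiles as ep,
    io_formats as io,
    phylogeny_grouping as pg,
    promoter_cis as pc,
)

logger = logging.getLogger("erf_survey")


@dataclass
class PipelineConfig:
    proteins: Optional[str] = None
    domain_table: Optional[str] = None
    cds: Optional[str] = None
    genome: Optional[str] = None
    gff3: Optional[str] = None
    pairs: Optional[str] = None              # TSV gene_a, gene_b
    expression: Optional[str] = None         # matrix TSV
    sample_map: Optional[str] = None
    ct_table: Optional[str] = None
    reference_groups: Optional[str] = None   # TSV id, group
    out_dir: str = "survey_out"
    evalue_max: float = 1e-5
    expressed_threshold: float = 1.0
    de_fold: float = 2.0
    promoter_length: int = 2000
    bootstrap_replicates: int = 1000
    seed: int = 0
    qpcr_reference: str = "reference"
    qpcr_control: str = "0h"
    de_contrasts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.evalue_max <= 1):
            raise ValueError("evalue_max out of range")
        if self.promoter_length <= 0 or self.bootstrap_replicates < 0:
            raise ValueError("bad threshold configuration")


def _setup_log(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler()]
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fh)


def run_survey(config: PipelineConfig) -> Path:
    """Execute all stages with available inputs; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out)
    logger.info("survey start; seed=%d", config.seed)

    proteome = None
    calls = None
    if config.proteins:
        proteome = io.read_fasta(config.proteins, kind="protein")
        table = (
            io.read_domain_table(config.domain_table, evalue_max=config.evalue_max)
            if config.domain_table
            else None
        )
        calls = da.identify_erf_set(proteome, table)
        lookup = {p.id: p for p in proteome}
        rows = []
        for c in sorted(calls, key=lambda c: c.protein_id):
            p = lookup[c.protein_id]
            ear = da.scan_ear(p)
            phys = da.compute_physicochem(p)
            rows.append(
                {
                    "id": c.protein_id,
                    "n_ap2": c.n_ap2,
                    "has_b3": c.has_b3,
                    "family": c.family,
                    "aaeird_present": c.aaeird_present,
                    "ear_hit_count": len(ear),
                    "ear_positions": ",".join(str(h.start) for h in ear),
                    "length": phys.length_aa,
                    "mw": round(phys.molecular_weight, 2),
                    "pi": round(phys.isoelectric_point, 2),
                    "gravy": round(phys.gravy, 3),
                }
            )
        pd.DataFrame(rows).to_csv(out / "identification.tsv", sep="\t", index=False)
        counts = da.family_counts(calls)
        logger.info("identification: %s", dict(counts))

        erfs = [
            lookup[c.protein_id] for c in calls if c.family == "ERF"
        ]
        if len(erfs) >= 4:
            dm = pg.distance_matrix([(p.id, p.sequence) for p in erfs])
            msa = pg.center_star_msa([(p.id, p.sequence) for p in erfs])
            tree = pg.bootstrap_support(
                msa, n_replicates=config.bootstrap_replicates, seed=config.seed,
                tree=pg.neighbor_joining(dm),
            )
            (out / "tree.nwk").write_text(tree.newick() + "\n")
            logger.info("phylogeny: %d leaves", len(tree.leaf_names))
            if config.reference_groups:
                refs = [
                    (str(r["id"]), str(r["group"]))
                    for _, r in pd.read_csv(config.reference_groups, sep="\t").iterrows()
                ]
                groups = pg.assign_groups(tree, refs)
                pd.DataFrame(
                    [
                        {
                            "id": g.protein_id,
                            "group": g.group,
                            "evidence": g.evidence,
                            "support": g.support,
                        }
                        for g in groups
                    ]
                ).to_csv(out / "groups.tsv", sep="\t", index=False)
        else:
            logger.info("phylogeny skipped: fewer than 4 ERFs")
    else:
        logger.info("identification skipped: no protein input")

    if config.genome and config.gff3:
        genome = io.read_genome(config.genome)
        models = io.read_gff3(config.gff3)
        promoters = {
            m.gene_id: io.extract_promoter(genome, m, config.promoter_length)
            for m in models
        }
        profiles, matrix = pc.profile_genes(promoters)
        matrix.to_csv(out / "cis_counts.tsv", sep="\t")
        exons = pd.DataFrame(
            [{"gene_id": m.gene_id, "n_exons": io.count_exons(m)} for m in models]
        )
        exons.to_csv(out / "exon_counts.tsv", sep="\t", index=False)
        logger.info("cis: %d genes, %d total hits", len(profiles), int(matrix.values.sum()))
    else:
        logger.info("cis stage skipped: genome/annotation missing")

    if config.pairs and config.cds:
        cds = {r.id: r for r in io.read_fasta(config.cds, kind="cds")}
        models_by_id = (
            {m.gene_id: m for m in io.read_gff3(config.gff3)} if config.gff3 else {}
        )
        pair_df = pd.read_csv(config.pairs, sep="\t")
        rows = []
        for _, r in pair_df.iterrows():
            pair = ds.GenePair(str(r["gene_a"]), str(r["gene_b"]))
            if models_by_id:
                ds.classify_pair(pair, models_by_id)
            a, b = cds[pair.gene_a], cds[pair.gene_b]
            from Bio.Seq import Seq

            pa = str(Seq(ds._strip_terminal_stop(a.sequence)).translate())
            pb = str(Seq(ds._strip_terminal_stop(b.sequence)).translate())
            aligned_a, aligned_b, _ = pg.pairwise_global_align(pa, pb)
            result = ds.ng86(ds.codon_align(a, b, (aligned_a, aligned_b)), pair)
            rows.append(
                {
                    "gene_a": pair.gene_a,
                    "gene_b": pair.gene_b,
                    "relationship": pair.relationship,
                    "ka": result.ka,
                    "ks": result.ks,
                    "ratio": result.ratio,
                    "purifying": result.purifying,
                    "n_codons": result.n_codons,
                    "method": result.method,
                }
            )
        pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
        logger.info("kaks: %d pairs", len(rows))
    else:
        logger.info("duplication stage skipped: pairs/CDS missing")

    if config.expression and config.sample_map:
        matrix = ep.read_expression_matrix(config.expression, config.sample_map)
        expressed = ep.call_expressed(matrix, config.expressed_threshold)
        expressed.to_csv(out / "expressed.tsv", sep="\t")
        de_rows = []
        for treatment, control in config.de_contrasts:
            calls_de = ep.call_de(matrix, treatment, control, fold=config.de_fold)
            summary = ep.de_summary(calls_de)
            logger.info("DE %s vs %s: %s", treatment, control, summary)
            for c in calls_de:
                de_rows.append(
                    {
                        "gene_id": c.gene_id,
                        "treatment": treatment,
                        "control": control,
                        "log10_ratio": c.log10_ratio,
                        "direction": c.direction,
                    }
                )
        if de_rows:
            pd.DataFrame(de_rows).to_csv(out / "de_calls.tsv", sep="\t", index=False)
    else:
        logger.info("expression stage skipped: matrix/sample map missing")

    if config.ct_table:
        ct = ep.read_ct_table(config.ct_table)
        rows = []
        for gene in sorted(set(ct["gene"]) - {config.qpcr_reference}):
            for r in ep.ddct(ct, gene, config.qpcr_reference, config.qpcr_control):
                rows.append(
                    {
                        "gene_id": r.gene_id,
                        "timepoint": r.timepoint,
                        "ddct": r.delta_delta_ct,
                        "rq": r.relative_quantity,
                        "p_value": r.p_value,
                        "significance": r.significance,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "qpcr.tsv", sep="\t", index=False)
        logger.info("qpcr: %d results", len(rows))
    else:
        logger.info("qPCR stage skipped: no Ct table")

    logger.info("survey done")
    return out
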