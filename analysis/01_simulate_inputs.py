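#!/usr/bin/env python
"""Generate the synthetic survey inputs.

Writes a full input bundle to results/data/: a 2,000-protein proteome with
planted AP2/ERF architectures plus its profile-HMM-style domain table, the
76-member stand-in ERF protein set, a 500-gene genome with planted promoter
elements (FASTA + GFF3), simulated duplicate CDS pairs, an expression
matrix with planted DE genes, and a qPCR Ct table.
"""

from pathlib import Path

import pandas as pd

from erf_survey import io_formats as io, synthetic_data as sd

SEED = 2020
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = sd.spawn_seeds(SEED, 6)

    records, rows, truth = sd.generate_proteome(2000, seed=seeds[0])
    io.write_fasta(records, OUT / "proteome.fasta")
    io.write_domain_table(rows, OUT / "domain_table.tsv")
    pd.DataFrame(
        [{"id": pid, "family": fam} for pid, fam in truth.family.items()]
    ).to_csv(OUT / "truth_families.tsv", sep="\t", index=False)
    print(f"proteome: {len(records)} proteins, {len(rows)} domain-table rows")

    standin, st = sd.zmerf_standin(seed=seeds[1])
    io.write_fasta(standin, OUT / "zmerf_standin.fasta")
    print(f"stand-in ERF set: {len(standin)} proteins, {len(st.ear_members)} EAR carriers planted")

    genome, models, ptruth = sd.generate_genome_with_promoters(
        500, {"ABRE": 2, "Sp1": 1, "MBS": 1}, seed=seeds[2]
    )
    io.write_fasta([io.CdsRecord(c, s) for c, s in genome.items()], OUT / "genome.fasta")
    io.write_gff3(models, OUT / "genes.gff3")
    pd.DataFrame(ptruth.counts).T.rename_axis("gene_id").to_csv(
        OUT / "truth_cis_counts.tsv", sep="\t"
    )
    print(f"genome: {len(genome)} contigs, {len(models)} genes with 2-kb promoters")

    pair_rows = []
    for k, (ks, ka) in enumerate([(0.3, 0.1), (0.5, 0.05), (0.2, 0.15)], 1):
        a, b, _ = sd.generate_cds_pair(2000, ks, ka, seed=seeds[3] + k)
        a.id, b.id = f"dup{k}a", f"dup{k}b"
        io.write_fasta([a, b], OUT / f"pair{k}.fasta")
        pair_rows.append({"gene_a": a.id, "gene_b": b.id, "ks_target": ks, "ka_target": ka})
    pd.DataFrame(pair_rows).to_csv(OUT / "pairs.tsv", sep="\t", index=False)
    print(f"duplicate pairs: {len(pair_rows)} simulated CDS pairs")

    matrix, etruth = sd.generate_expression(
        500, de_spec={("salt", "control"): (0.1, 0.1, 4.0),
                      ("drought", "control"): (0.08, 0.04, 4.0)},
        seed=seeds[4],
    )
    matrix.values.rename_axis("gene_id").to_csv(OUT / "expression.tsv", sep="\t")
    pd.DataFrame(
        [{"sample": s, "condition": c, "replicate": r}
         for s, (c, r) in matrix.condition_of_sample.items()]
    ).to_csv(OUT / "sample_map.tsv", sep="\t", index=False)
    de = pd.DataFrame(etruth.de_direction).rename_axis("gene_id")
    de.columns = ["__".join(c) for c in de.columns]
    de.to_csv(OUT / "truth_de.tsv", sep="\t")
    print(f"expression: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")

    genes = [f"q{i}" for i in range(1, 15)]
    folds = {g: {"3h": 8.0, "6h": 4.0, "12h": 2.0} for g in genes[:10]}
    folds.update({g: {"3h": 0.5, "6h": 0.5, "12h": 1.0} for g in genes[10:]})
    ct, _ = sd.generate_ct_table(genes, folds, n_reps=6, noise_sd=0.1, seed=seeds[5])
    ct.to_csv(OUT / "ct_table.tsv", sep="\t", index=False)
    print(f"qPCR: {len(genes)} target genes, 4 timepoints, 6 replicates")


if __name__ == "__main__":
    main()
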