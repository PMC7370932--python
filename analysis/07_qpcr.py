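#!/usr/bin/env python
"""qPCR relative quantification.

2^-ddCt analysis of the simulated Ct table (reference-normalised, control
timepoint 0h) with Welch t-tests and significance stars.  Writes
results/qpcr.tsv.
"""

from pathlib import Path

import pandas as pd

from erf_survey import expression_profiles as ep

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    ct = ep.read_ct_table(DATA / "ct_table.tsv")
    rows = []
    for gene in sorted(set(ct["gene"]) - {"reference"}):
        for r in ep.ddct(ct, gene, "reference", "0h"):
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "timepoint": r.timepoint,
                    "ddct": round(r.delta_delta_ct, 3),
                    "rq": round(r.relative_quantity, 3),
                    "p_value": None if r.p_value is None else round(r.p_value, 5),
                    "significance": r.significance,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "qpcr.tsv", sep="\t", index=False)
    induced = df[(df.timepoint == "3h") & (df.rq >= 2) & (df.significance != "ns")]
    print(f"genes significantly induced >=2-fold at 3h: {len(induced)} "
          f"of {df.gene_id.nunique()}")
    print(df[df.timepoint == '3h'][['gene_id', 'rq', 'significance']]
          .to_string(index=False))


if __name__ == "__main__":
    main()
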