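#!/usr/bin/env python
"""Target prediction for the called matures, including self/host targeting.

Scans each discovered mature miRNA against the host-gene sequences of the
synthetic genome at the DNA level (both strands).  Because an intronic
miRNA's precursor sits inside its host gene, every 24-nt-style mature
trivially has a perfect site at its own locus — the own_locus flag marks
these self-methylation-type hits, mirroring how intronic miRNAs can direct
DNA methylation at their own precursor.
"""

import argparse
from pathlib import Path

import pandas as pd

from intromir import genome_io
from intromir.target_predict import scan_targets


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--calls", type=Path, default=Path("results/discovery/calls.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/targets.tsv"))
    ap.add_argument("--max-mirnas", type=int, default=4,
                    help="matures to scan (DNA-level scans are quadratic)")
    args = ap.parse_args()

    genome = genome_io.read_fasta(args.data / "genome.fa")
    models = genome_io.read_gene_models(args.data / "annotation.gff3")
    calls = pd.read_csv(args.calls, sep="\t").head(args.max_mirnas)

    gene_seqs = {
        m.gene_id: genome[m.chrom][m.span[0] : m.span[1]] for m in models
    }
    span_by_gene = {m.gene_id: m.span for m in models}

    rows = []
    for _, call in calls.iterrows():
        host = call["host_gene"]
        hits = scan_targets(
            call["mature_sequence"],
            gene_seqs,
            mirna_id=f"{call['precursor_id']}{call['product']}",
            include_dna_level=True,
            host_gene=host,
        )
        for h in hits:
            rows.append(
                {
                    "mirna_id": h.mirna_id,
                    "gene_id": h.gene_id,
                    "start": h.start + span_by_gene[h.gene_id][0],
                    "end": h.end + span_by_gene[h.gene_id][0],
                    "strand": h.strand,
                    "score": h.score,
                    "self_target": h.self_target,
                }
            )
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    n_self = int(df["self_target"].sum()) if len(df) else 0
    print(f"{len(df)} passing sites from {len(calls)} matures; "
          f"{n_self} in the miRNA's own host gene")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
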