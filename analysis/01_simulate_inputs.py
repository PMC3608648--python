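#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/synthetic/: a 100 kb multi-contig genome with 30
planted CDS (FASTA + GFF3), an annotation with 20% of CDS dropped and the
corresponding anomaly ledger (the stand-in for an annotation-QC report),
error-free 150 bp shotgun reads at 30x, and an observed-peptide sample
(80% detection, linear retention times with Gaussian noise and 5% outliers).
"""

import logging
from pathlib import Path

from thermoclades import io as tio
from thermoclades import proteogenomics as pg
from thermoclades import synthdata as sd
from thermoclades.types import genome_statistics

logging.basicConfig(level=logging.INFO, format="%(message)s")
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20130326  # publication date of the study this emulates


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    contigs, truth = sd.generate_genome(
        sd.GenomeSpec(total_length=100_000, n_cds=30, seed=SEED + 1)
    )
    stats = genome_statistics(contigs)
    print(f"genome: {stats.n_contigs} contigs, {stats.total_length} bp, "
          f"G+C {stats.gc_percent:.2f}% (target 34.35%), {len(truth)} CDS")

    annotation, ledger = sd.corrupt_annotation(
        truth, sd.AnomalySpec(drop_fraction=0.2, truncate_fraction=0.0, seed=SEED + 2)
    )
    print(f"annotation: {len(annotation)} CDS survive; ledger holds "
          f"{len(ledger)} anomalies")

    reads = sd.simulate_reads(
        contigs,
        sd.ReadSimSpec(read_length=150, coverage=30.0, error_rate=0.0, seed=SEED + 3),
    )
    print(f"reads: {len(reads)} x 150 bp (30x, error-free)")

    true_db = pg.build_annotated_db(contigs, truth)
    observed = sd.simulate_observed_peptides(
        true_db, sd.PeptideObsSpec(detect_fraction=0.8, seed=SEED + 4),
        pg.KROKHIN_2004_COEFFICIENTS,
    )
    print(f"observed peptides: {len(observed)} of {len(true_db)} true tryptic "
          f"peptides (detect 0.8)")

    tio.write_fasta(contigs, OUT / "contigs.fasta")
    tio.write_gff3(truth, OUT / "true_cds.gff3")
    tio.write_gff3(annotation, OUT / "annotation.gff3")
    tio.write_anomaly_ledger(ledger, OUT / "anomaly_ledger.tsv")
    tio.write_fasta(reads, OUT / "reads.fasta")
    tio.write_observed_peptides(observed, OUT / "observed_peptides.tsv")
    print(f"wrote inputs under {OUT}")


if __name__ == "__main__":
    main()
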