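"""Top-level orchestration: chain the stages into one reproducible run.

``run_full_pipeline`` executes, per stage selection, the synthetic-data
generation, proteogenomic annotation validation, functional-profile
clustering, pathway/phenotype concordance and protein-family phylogenetics
stages, writes every stage's tables under the output directory, and records
a manifest (config hash + per-file checksums) so deterministic stages can be
verified byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as tio
from . import pathways as tpath
from . import phylo as tphylo
from . import profiles as tprof
from . import proteogenomics as tproteo
from . import synthdata as tsynth
from .types import genome_statistics

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

ALL_STAGES = ("synth", "proteo", "profiles", "pathways", "phylo")


@dataclass
class RunConfig:
    """All stage parameters with documented defaults.

    The per-stage specs carry their own seeds (derived from ``seed`` when
    left at None) so there is no hidden global randomness.
    """

    out_dir: str = "results/run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    genome: tsynth.GenomeSpec | None = None
    anomaly: tsynth.AnomalySpec | None = None
    reads: tsynth.ReadSimSpec | None = None
    peptides: tsynth.PeptideObsSpec | None = None
    clades: tsynth.CladeProfileSpec | None = None
    family: tsynth.FamilySimSpec | None = None
    digest: tproteo.DigestConfig = field(default_factory=tproteo.DigestConfig)
    min_support: int = 2
    outlier_sd: float = 3.0
    metric: str = "correlation"
    normalize: str = "relative"
    linkage: str = "average"
    k_clades: int = 3
    bootstrap_reps: int = 100
    cluster_support_threshold: float = 70.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # fill per-stage specs with seeds derived deterministically from the
        # run seed (kept below 2**31)
        base = self.seed % (2**31 - 11)
        if self.genome is None:
            self.genome = tsynth.GenomeSpec(seed=base + 1)
        if self.anomaly is None:
            self.anomaly = tsynth.AnomalySpec(seed=base + 2)
        if self.reads is None:
            self.reads = tsynth.ReadSimSpec(seed=base + 3)
        if self.peptides is None:
            self.peptides = tsynth.PeptideObsSpec(seed=base + 4)
        if self.clades is None:
            self.clades = tsynth.CladeProfileSpec(seed=base + 5)
        if self.family is None:
            self.family = tsynth.FamilySimSpec(seed=base + 6)

    def to_json(self) -> str:
        """Parameter serialization for hashing; output paths excluded so the
        hash identifies the scientific configuration, not its destination."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    checksums: dict[str, str]
    timestamps: dict[str, float]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages and write tables + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps: dict[str, float] = {}
    need_synth_inputs = {"proteo"} & set(config.stages)
    if need_synth_inputs and "synth" not in config.stages:
        raise ValueError("proteo stage requires the synth stage in this configuration")

    artifacts: dict[str, object] = {}

    if "synth" in config.stages:
        t0 = time.time()
        contigs, truth = tsynth.generate_genome(config.genome)
        annotation, ledger = tsynth.corrupt_annotation(truth, config.anomaly)
        reads = tsynth.simulate_reads(contigs, config.reads)
        stats = genome_statistics(contigs)
        logger.info(
            "synth: %d contigs, %d bp, G+C %.2f%%, %d true CDS, %d anomalies, %d reads",
            stats.n_contigs, stats.total_length, stats.gc_percent,
            len(truth), len(ledger), len(reads),
        )
        tio.write_fasta(contigs, out / "contigs.fasta")
        tio.write_gff3(truth, out / "true_cds.gff3")
        tio.write_gff3(annotation, out / "annotation.gff3")
        tio.write_anomaly_ledger(ledger, out / "anomaly_ledger.tsv")
        tio.write_fasta(reads, out / "reads.fasta")
        artifacts.update(
            contigs=contigs, truth=truth, annotation=annotation,
            ledger=ledger, reads=reads,
        )
        timestamps["synth"] = time.time() - t0

    if "proteo" in config.stages:
        t0 = time.time()
        contigs = artifacts["contigs"]
        truth = artifacts["truth"]
        annotation = artifacts["annotation"]
        reads = artifacts["reads"]
        ledger = artifacts["ledger"]
        naive = tproteo.build_naive_db(reads, config.digest)
        annotated = tproteo.build_annotated_db(contigs, annotation, config.digest)
        true_db = tproteo.build_annotated_db(contigs, truth, config.digest)
        observed = tsynth.simulate_observed_peptides(
            true_db, config.peptides, tproteo.KROKHIN_2004_COEFFICIENTS
        )
        report = tproteo.classify_peptides(observed, naive, annotated)
        fit = tproteo.fit_retention(observed, outlier_sd=config.outlier_sd)
        index = tproteo.SixFrameIndex(contigs, config.digest.collapse_il)
        loci = {
            o.id: index.find(o.sequence)
            for o in observed
            if report.labels[o.id] == tproteo.LABEL_NAIVE_UNIQUE
        }
        calls = tproteo.adjudicate_anomalies(
            report, fit, loci, observed, ledger, config.min_support
        )
        tio.write_peptide_db(naive, out / "naive_db.tsv")
        tio.write_peptide_db(annotated, out / "annotated_db.tsv")
        tio.write_observed_peptides(observed, out / "observed_peptides.tsv")
        tio.write_match_report(report, out / "match_report.tsv")
        tio.write_retention_summary(fit, out / "retention_fit.tsv")
        tio.write_anomaly_calls(calls, out / "anomaly_calls.tsv")
        artifacts["calls"] = calls
        timestamps["proteo"] = time.time() - t0

    if "profiles" in config.stages:
        t0 = time.time()
        profile, labels = tsynth.simulate_profiles(config.clades)
        dist = tprof.profile_distance(profile, config.metric, config.normalize)
        dend = tprof.hierarchical_cluster(dist, config.linkage)
        clades = tprof.cut_clades(dend, config.k_clades)
        tio.write_matrix_tsv(profile, out / "profile_matrix.tsv")
        (out / "profile_dendrogram.nwk").write_text(
            tprof.dendrogram_to_newick(dend) + "\n"
        )
        tio.write_matrix_tsv(
            __import__("pandas").DataFrame(
                {"planted_clade": labels, "recovered_clade": clades}
            ),
            out / "clade_assignments.tsv",
        )
        logger.info("profiles: %d genomes clustered into %d clades",
                    len(profile), config.k_clades)
        timestamps["profiles"] = time.time() - t0

    if "pathways" in config.stages:
        t0 = time.time()
        pred, pheno = tpath.load_table3()
        report = tpath.concordance(pred, pheno)
        tio.write_matrix_tsv(report.verdicts, out / "concordance_verdicts.tsv")
        (out / "concordance_summary.tsv").write_text(
            "n_total\tn_agree\tn_disagree\tn_not_reported\n"
            f"{report.n_total}\t{report.n_agree}\t{report.n_disagree}\t"
            f"{report.n_not_reported}\n"
        )
        counts, _families = tpath.summarize_extracellular(
            tpath.load_table1(), genomes=list(pred.index)
        )
        counts.rename("n_extracellular_cazymes").to_frame().to_csv(
            out / "extracellular_cazymes.tsv", sep="\t", index_label="genome"
        )
        logger.info(
            "pathways: %d/%d agree, %d disagree, %d not reported",
            report.n_agree, report.n_total, report.n_disagree, report.n_not_reported,
        )
        timestamps["pathways"] = time.time() - t0

    if "phylo" in config.stages:
        t0 = time.time()
        family = tsynth.simulate_protein_family(config.family)
        aln = tphylo.ProteinAlignment.from_dict(family)
        tree = tphylo.bootstrap_support(
            aln, config.bootstrap_reps, seed=config.family.seed
        )
        clusters = tphylo.assign_sequence_clusters(
            tree, config.cluster_support_threshold
        )
        tphylo.write_newick(tree, str(out / "family_tree.nwk"))
        tio._write_tsv(
            out / "sequence_clusters.tsv",
            ["sequence", "cluster"],
            [[name, str(c)] for name, c in sorted(clusters.items())],
        )
        logger.info("phylo: %d sequences, %d clusters at support >= %g",
                    len(aln.labels), len(set(clusters.values())),
                    config.cluster_support_threshold)
        timestamps["phylo"] = time.time() - t0

    config_hash = hashlib.sha256(config.to_json().encode()).hexdigest()
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__,
        config_hash=config_hash,
        checksums=checksums,
        timestamps=timestamps,
    )
    manifest.write(out / "manifest.json")
    return manifest
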