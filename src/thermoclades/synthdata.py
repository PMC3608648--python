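"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its spec (the spec carries its own
seed), so repeated calls are byte-identical.  The generators emulate the
inputs of the real analysis: a small multi-contig genome with planted CDS,
an annotation corrupted by ledgered anomalies, error-bearing sequencing
reads, tryptic observed-peptide samples with a linear retention-time model,
clade-structured functional-term count profiles, and protein families
evolved under a Poisson substitution process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq

from .types import (
    MISSING_GENE,
    TRUNCATED_GENE,
    AnomalyRecord,
    CdsFeature,
    CdsSet,
    Contig,
    ContigSet,
    ObservedPeptide,
    Read,
    ReadSet,
)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# genome generation


@dataclass(frozen=True)
class GenomeSpec:
    n_contigs: int = 3
    total_length: int = 100_000
    gc_target: float = 0.3435
    n_cds: int = 30
    cds_length_range: tuple[int, int] = (300, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0,1)")
        if self.n_contigs < 1 or self.total_length < 1 or self.n_cds < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.cds_length_range
        if not 6 <= lo <= hi:
            raise ValueError("cds_length_range must satisfy 6 <= lo <= hi")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


_STOP_FIX = {"TAA": "TAT", "TAG": "TAT", "TGA": "TGT"}  # single-base edits


def generate_genome(spec: GenomeSpec) -> tuple[ContigSet, CdsSet]:
    """Generate contigs with non-overlapping planted CDS.

    Background bases are drawn i.i.d. at the G+C target; planted CDS regions
    are made coding by setting an ATG start, a stop codon at the 3' end, and
    editing away internal in-frame stops with minimal single-base changes (so
    the empirical G+C stays within sampling error of the target).
    """
    rng = np.random.default_rng(spec.seed)

    # near-equal contig lengths
    base = spec.total_length // spec.n_contigs
    contig_lengths = [base] * spec.n_contigs
    contig_lengths[-1] += spec.total_length - base * spec.n_contigs

    lo, hi = spec.cds_length_range
    cds_lengths = [
        int(rng.integers(lo // 3, hi // 3 + 1)) * 3 for _ in range(spec.n_cds)
    ]
    if sum(cds_lengths) > spec.total_length:
        raise ValueError(
            f"infeasible packing: {sum(cds_lengths)} CDS bases exceed "
            f"genome length {spec.total_length}"
        )

    # greedy packing: largest CDS to the contig with most remaining space
    per_contig: list[list[int]] = [[] for _ in range(spec.n_contigs)]
    free = list(contig_lengths)
    for length in sorted(cds_lengths, reverse=True):
        target = max(range(spec.n_contigs), key=lambda ci: free[ci])
        if free[target] < length:
            raise ValueError(
                f"infeasible packing: CDS of {length} bp does not fit any contig"
            )
        per_contig[target].append(length)
        free[target] -= length

    contigs: list[Contig] = []
    features: list[CdsFeature] = []
    cds_counter = 0
    for ci in range(spec.n_contigs):
        clen = contig_lengths[ci]
        seq = _random_bases(rng, clen, spec.gc_target)
        lengths = per_contig[ci]
        # place sequentially with random slack split between the gaps
        slack = clen - sum(lengths)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths))) if lengths else []
        pos = 0
        prev_cut = 0
        for li, length in enumerate(lengths):
            gap = int(cuts[li]) - prev_cut
            prev_cut = int(cuts[li])
            start = pos + gap
            end = start + length
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            coding = seq[start:end].tobytes().decode()
            coding = _make_coding(coding, rng)
            if strand == "-":
                insert = str(Seq(coding).reverse_complement())
            else:
                insert = coding
            seq[start:end] = np.frombuffer(insert.encode(), dtype="S1")
            features.append(
                CdsFeature(
                    id=f"cds_{cds_counter:04d}",
                    contig=f"contig_{ci}",
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            cds_counter += 1
        contigs.append(Contig(id=f"contig_{ci}", seq=seq.tobytes().decode()))

    return ContigSet(contigs), CdsSet(features)


def _make_coding(nt: str, rng: np.random.Generator) -> str:
    """Minimally edit a nucleotide stretch into a valid CDS on its own frame:
    ATG start, terminal stop, no internal in-frame stop."""
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    codons[0] = "ATG"
    codons[-1] = STOP_CODONS[int(rng.integers(0, 3))]
    for i in range(1, len(codons) - 1):
        if codons[i] in STOP_CODONS:
            codons[i] = _STOP_FIX[codons[i]]
    return "".join(codons)


# ---------------------------------------------------------------------------
# annotation corruption


@dataclass(frozen=True)
class AnomalySpec:
    drop_fraction: float = 0.2
    truncate_fraction: float = 0.0
    truncate_amount: float = 0.3  # fraction of CDS length clipped at the 3' end
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_fraction", "truncate_fraction", "truncate_amount"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


def corrupt_annotation(
    truth: CdsSet, spec: AnomalySpec
) -> tuple[CdsSet, list[AnomalyRecord]]:
    """Return a corrupted annotation plus the full anomaly ledger.

    ``round(drop_fraction * n)`` CDS are removed outright (missing_gene);
    of the survivors, ``round(truncate_fraction * n_survivors)`` are clipped
    at the 3' end by ``truncate_amount`` of their length, rounded down to
    whole codons (truncated_gene).  The ledger records the true interval of
    every corrupted feature, so ledger + surviving annotation reconstructs
    the truth exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ids = sorted(truth.ids)
    n_drop = int(round(spec.drop_fraction * len(ids)))
    dropped = set(rng.choice(ids, size=n_drop, replace=False)) if n_drop else set()
    survivors = [i for i in ids if i not in dropped]
    n_trunc = int(round(spec.truncate_fraction * len(survivors)))
    truncated = (
        set(rng.choice(survivors, size=n_trunc, replace=False)) if n_trunc else set()
    )

    ledger: list[AnomalyRecord] = []
    out: list[CdsFeature] = []
    counter = 0
    for cds_id in ids:
        f = truth[cds_id]
        if cds_id in dropped:
            ledger.append(
                AnomalyRecord(
                    anomaly_id=f"anom_{counter:04d}",
                    category=MISSING_GENE,
                    contig=f.contig,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                )
            )
            counter += 1
            continue
        if cds_id in truncated:
            clip = (int(len(f) * spec.truncate_amount) // 3) * 3
            clip = min(clip, len(f) - 6)  # keep at least start + one codon
            anomaly_id = f"anom_{counter:04d}"
            counter += 1
            ledger.append(
                AnomalyRecord(
                    anomaly_id=anomaly_id,
                    category=TRUNCATED_GENE,
                    contig=f.contig,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                )
            )
            if f.strand == "+":
                out.append(
                    CdsFeature(f.id, f.contig, f.start, f.end - clip, f.strand,
                               anomaly_id=anomaly_id)
                )
            else:  # 3' end of a - strand feature is the interval start
                out.append(
                    CdsFeature(f.id, f.contig, f.start + clip, f.end, f.strand,
                               anomaly_id=anomaly_id)
                )
            continue
        out.append(f)
    return CdsSet(out), ledger


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadSimSpec:
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0,1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


def simulate_reads(contigs: ContigSet, spec: ReadSimSpec) -> ReadSet:
    """Uniform substitution-only shotgun reads from both strands.

    ``n_reads = ceil(coverage * total_length / read_length)``; start positions
    are uniform over valid windows, contigs chosen proportional to the number
    of valid start positions.  Indels and quality strings are out of scope.
    """
    shortest = min(len(c) for c in contigs)
    if spec.read_length > shortest:
        raise ValueError(
            f"read_length {spec.read_length} exceeds shortest contig ({shortest})"
        )
    rng = np.random.default_rng(spec.seed)
    total = contigs.total_length
    n_reads = math.ceil(spec.coverage * total / spec.read_length)

    ids = contigs.ids
    starts_per_contig = np.array(
        [len(contigs[i]) - spec.read_length + 1 for i in ids], dtype=float
    )
    p = starts_per_contig / starts_per_contig.sum()
    contig_idx = rng.choice(len(ids), size=n_reads, p=p)
    reads: list[Read] = []
    for r in range(n_reads):
        cid = ids[contig_idx[r]]
        cseq = contigs[cid].seq
        start = int(rng.integers(0, len(cseq) - spec.read_length + 1))
        seq = cseq[start : start + spec.read_length]
        if rng.random() < 0.5:
            seq = str(Seq(seq).reverse_complement())
        if spec.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(spec.read_length) < spec.error_rate)[0]
            for h in hits:
                cur = arr[h].decode()
                alternatives = [b for b in BASES if b != cur]
                arr[h] = alternatives[int(rng.integers(0, 3))].encode()
            seq = arr.tobytes().decode()
        reads.append(Read(id=f"read_{r:06d}", seq=seq))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# observed-peptide simulation


@dataclass(frozen=True)
class PeptideObsSpec:
    detect_fraction: float = 0.8
    rt_slope: float = 1.0  # minutes per hydrophobicity unit
    rt_intercept: float = 5.0  # minutes
    rt_noise_sd: float = 0.5  # minutes
    outlier_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.detect_fraction <= 1:
            raise ValueError("detect_fraction must be in (0,1]")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0,1]")


def simulate_observed_peptides(
    proteome, spec: PeptideObsSpec, coeffs: dict[str, float]
) -> list[ObservedPeptide]:
    """Sample observed peptides from a peptide database.

    ``round(detect_fraction * N)`` peptides are observed, each once, with
    ``rt = slope * H(p) + intercept + Normal(0, sd)``; a deterministic count
    ``round(outlier_fraction * n_detected)`` instead receive retention times
    uniform over the observed range (ground-truth outlier flags retained).
    ``proteome`` is a ``PeptideDB`` (or any mapping of peptide sequences).
    """
    from .proteogenomics import hydrophobicity  # local import: no cycle at load

    sequences = sorted(proteome.sequences() if hasattr(proteome, "sequences") else proteome)
    if not sequences:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(spec.seed)
    n_detect = int(round(spec.detect_fraction * len(sequences)))
    n_detect = max(n_detect, 1)
    chosen = sorted(rng.choice(sequences, size=n_detect, replace=False))

    h = np.array([hydrophobicity(s, coeffs) for s in chosen])
    rt = spec.rt_slope * h + spec.rt_intercept
    if spec.rt_noise_sd > 0:
        rt = rt + rng.normal(0.0, spec.rt_noise_sd, size=n_detect)
    n_out = int(round(spec.outlier_fraction * n_detect))
    outlier_idx = set(
        rng.choice(n_detect, size=n_out, replace=False).tolist() if n_out else []
    )
    lo, hi = float(rt.min()), float(rt.max())
    peptides: list[ObservedPeptide] = []
    for i, seq in enumerate(chosen):
        is_out = i in outlier_idx
        value = float(rng.uniform(lo, hi)) if is_out else float(rt[i])
        peptides.append(
            ObservedPeptide(
                id=f"obs_{i:05d}", sequence=seq, retention_time=value, is_outlier=is_out
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# clade-structured functional profiles


@dataclass(frozen=True)
class CladeProfileSpec:
    clade_sizes: tuple[int, ...] = (6, 2, 3)
    n_terms: int = 200
    within_clade_dispersion: float = 1.0
    between_clade_separation: float = 5.0
    centroid_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clade_sizes) < 2 or sum(self.clade_sizes) < 2:
            raise ValueError("need >=2 clades and >=2 genomes")
        if self.within_clade_dispersion < 0 or self.between_clade_separation < 0:
            raise ValueError("dispersions must be nonnegative")


def simulate_profiles(spec: CladeProfileSpec) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genome x term count matrix with planted clade structure.

    Each clade gets a term-count centroid ``max(0, N(centroid_mean,
    between_clade_separation))`` per term; genomes are the centroid plus
    ``N(0, within_clade_dispersion)`` noise, rounded and truncated at zero.
    Returns the integer count matrix and the planted genome -> clade labels.
    """
    rng = np.random.default_rng(spec.seed)
    terms = [f"T{t:04d}" for t in range(spec.n_terms)]
    rows = {}
    labels: dict[str, int] = {}
    g = 0
    for clade, size in enumerate(spec.clade_sizes):
        centroid = np.maximum(
            0.0,
            rng.normal(spec.centroid_mean, spec.between_clade_separation, spec.n_terms),
        )
        for _ in range(size):
            name = f"genome_{g:02d}"
            noise = (
                rng.normal(0.0, spec.within_clade_dispersion, spec.n_terms)
                if spec.within_clade_dispersion > 0
                else 0.0
            )
            counts = np.maximum(0, np.rint(centroid + noise)).astype(int)
            rows[name] = counts
            labels[name] = clade
            g += 1
    profile = pd.DataFrame.from_dict(rows, orient="index", columns=terms)
    return profile, labels


# ---------------------------------------------------------------------------
# protein-family evolution under a Poisson substitution process


@dataclass(frozen=True)
class FamilySimSpec:
    guide_tree: str = "((A:0.05,B:0.05,C:0.05):0.4,(D:0.05,E:0.05,F:0.05):0.4);"
    root_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be positive")


def _parse_guide_tree(newick: str) -> Tree:
    import io as _io

    from Bio import Phylo

    return Phylo.read(_io.StringIO(newick), "newick")


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Site-wise substitution: each site substitutes with probability
    ``1 - exp(-d)``; the replacement is uniform over the other 19 residues."""
    if d < 0:
        raise ValueError("negative branch length")
    child = seq.copy()
    if d == 0:
        return child
    hits = np.nonzero(rng.random(len(seq)) < 1.0 - math.exp(-d))[0]
    for h in hits:
        choices = [a for a in range(20) if a != child[h]]
        child[h] = choices[int(rng.integers(0, 19))]
    return child


def simulate_protein_family(spec: FamilySimSpec) -> dict[str, str]:
    """Evolve a gap-free protein alignment down a guide tree.

    The root is uniform over the 20 residues; every branch applies the
    Poisson-process update of :func:`_evolve`.  Returns leaf name -> sequence
    (all of ``root_length``; no indels by construction).
    """
    rng = np.random.default_rng(spec.seed)
    tree = _parse_guide_tree(spec.guide_tree)
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            raise ValueError("negative branch length in guide tree")
    root_seq = rng.integers(0, 20, size=spec.root_length)

    leaves: dict[str, str] = {}

    def walk(clade: Clade, seq: np.ndarray) -> None:
        d = clade.branch_length or 0.0
        child_seq = _evolve(seq, d, rng)
        if clade.is_terminal():
            leaves[clade.name] = "".join(AMINO_ACIDS[a] for a in child_seq)
        else:
            for sub in clade.clades:
                walk(sub, child_seq)

    root = tree.root
    for sub in root.clades:
        walk(sub, root_seq)
    if root.is_terminal():  # degenerate single-leaf tree
        leaves[root.name] = "".join(AMINO_ACIDS[a] for a in root_seq)
    return leaves
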