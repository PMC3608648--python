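"""Assembly-independent ("naive") peptide-database annotation validation.

The workflow translates raw sequencing reads in all six frames, splits the
translations at stop codons into stop-free elements, digests those elements
in silico with trypsin into a naive peptide database, and compares observed
peptides against both this naive database and the database derived from the
annotated CDS.  Peptides unique to the naive database point at coding
sequence the annotation missed; combined with a retention-time concordance
filter they adjudicate ledgered annotation anomalies (missing or truncated
genes) as supported or lacking evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

from .types import AnomalyRecord, CdsSet, ContigSet, ObservedPeptide, ReadSet

logger = logging.getLogger(__name__)

# standard (NCBI table 1) codon table; codons containing N translate to X
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

STOP = "*"
UNKNOWN = "X"
FRAMES = (1, 2, 3, -1, -2, -3)


def translate(nt: str) -> str:
    """Translate a nucleotide string (trailing partial codon ignored)."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        out.append(_CODON_TO_AA.get(nt[i : i + 3], UNKNOWN))
    return "".join(out)


# ---------------------------------------------------------------------------
# six-frame elements


@dataclass(frozen=True)
class SixFrameElement:
    """Maximal stop-free stretch of one reading frame of one read.

    ``aa_offset`` indexes the first residue within that frame's full
    translation, so concatenating a frame's elements with single stop
    separators reproduces the frame translation (losslessness).
    """

    read_id: str
    frame: int  # one of +-1, +-2, +-3
    aa_offset: int
    sequence: str


def six_frame_elements(read: str, read_id: str = "") -> list[SixFrameElement]:
    """All stop-free translated elements of a read in all six frames."""
    read = read.upper()
    rc = str(Seq(read).reverse_complement())
    elements: list[SixFrameElement] = []
    for frame in FRAMES:
        src = read if frame > 0 else rc
        offset = abs(frame) - 1
        aa = translate(src[offset:])
        pos = 0
        for chunk in aa.split(STOP):
            if chunk:
                elements.append(
                    SixFrameElement(
                        read_id=read_id, frame=frame, aa_offset=pos, sequence=chunk
                    )
                )
            pos += len(chunk) + 1
    return elements


# ---------------------------------------------------------------------------
# tryptic digestion


@dataclass(frozen=True)
class DigestConfig:
    """In-silico digestion and peptide-normalization policy.

    Defaults follow common proteomic practice: trypsin with up to two missed
    cleavages, peptides of 6-40 residues, and I/L collapsed to a single
    symbol because the two residues are isobaric and indistinguishable by
    MS/MS.
    """

    missed_cleavages: int = 2
    min_len: int = 6
    max_len: int = 40
    collapse_il: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def normalize(self, peptide: str) -> str:
        return peptide.replace("I", "L") if self.collapse_il else peptide


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cleaves: C-terminal to K or R, except
    when the next residue is P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str, missed_cleavages: int = 0, min_len: int = 1, max_len: int = 10**9
) -> list[tuple[str, int]]:
    """Tryptic peptides of ``sequence`` as ``(peptide, offset)`` pairs.

    Returns every product with up to ``missed_cleavages`` internal uncleaved
    sites whose length falls within ``[min_len, max_len]``, in order of
    offset then length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    peptides: list[tuple[str, int]] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            if min_len <= end - start <= max_len:
                peptides.append((sequence[start:end], start))
    return peptides


# ---------------------------------------------------------------------------
# peptide databases

NAIVE = "naive"
ANNOTATED = "annotated"


class PeptideDB:
    """Exact-match peptide collection keyed by normalized sequence.

    ``entries`` maps the normalized peptide to its provenance list of
    ``(source_id, residue_offset)`` pairs; duplicates merge provenance.
    """

    def __init__(self, source: str, config: DigestConfig):
        self.source = source
        self.config = config
        self.entries: dict[str, list[tuple[str, int]]] = {}

    def add(self, peptide: str, provenance: tuple[str, int]) -> None:
        if UNKNOWN in peptide:
            return  # undetermined residues cannot be observed by MS
        key = self.config.normalize(peptide)
        self.entries.setdefault(key, []).append(provenance)

    def __contains__(self, peptide: str) -> bool:
        return self.config.normalize(peptide) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[str]:
        return list(self.entries)


def build_naive_db(reads: ReadSet, config: DigestConfig | None = None) -> PeptideDB:
    """Union of tryptic digests over all six-frame elements of all reads."""
    config = config or DigestConfig()
    db = PeptideDB(NAIVE, config)
    for read in reads:
        for el in six_frame_elements(read.seq, read.id):
            for pep, off in tryptic_digest(
                el.sequence, config.missed_cleavages, config.min_len, config.max_len
            ):
                db.add(pep, (f"{el.read_id}|{el.frame:+d}|{el.aa_offset}", off))
    logger.info("naive DB: %d reads -> %d peptides", len(reads), len(db))
    return db


def translate_cds(contigs: ContigSet, cds) -> str:
    """Protein sequence of a CDS (terminal stop dropped).  Raises on internal
    stops, which signal a corrupt annotation input."""
    nt = cds.coding_sequence(contigs)
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS {cds.id} length {len(nt)} not divisible by 3")
    aa = translate(nt)
    if aa.endswith(STOP):
        aa = aa[:-1]
    if STOP in aa:
        raise ValueError(f"internal stop codon in CDS {cds.id}")
    return aa


def build_annotated_db(
    contigs: ContigSet, cds_set: CdsSet, config: DigestConfig | None = None
) -> PeptideDB:
    """Tryptic peptide database of the translated annotated CDS."""
    config = config or DigestConfig()
    db = PeptideDB(ANNOTATED, config)
    for cds in cds_set:
        aa = translate_cds(contigs, cds)
        if not aa:
            continue
        for pep, off in tryptic_digest(
            aa, config.missed_cleavages, config.min_len, config.max_len
        ):
            db.add(pep, (cds.id, off))
    logger.info("annotated DB: %d CDS -> %d peptides", len(cds_set), len(db))
    return db


# ---------------------------------------------------------------------------
# classification of observed peptides

LABEL_ANNOTATED = "annotated"
LABEL_NAIVE_UNIQUE = "naive_unique"
LABEL_UNMATCHED = "unmatched"


@dataclass
class MatchReport:
    labels: dict[str, str]  # observed peptide id -> label
    n_annotated: int
    n_naive_unique: int
    n_unmatched: int

    @property
    def total(self) -> int:
        return self.n_annotated + self.n_naive_unique + self.n_unmatched


def classify_peptides(
    observed: list[ObservedPeptide], naive: PeptideDB, annotated: PeptideDB
) -> MatchReport:
    """Partition observed peptides into annotated / naive_unique / unmatched.

    A peptide found in both databases counts as annotated (precedence rule);
    one found only in the naive database is the interesting class, pointing
    at unannotated coding sequence.
    """
    if naive.config != annotated.config:
        raise ValueError("digest/normalization config mismatch between databases")
    labels: dict[str, str] = {}
    counts = {LABEL_ANNOTATED: 0, LABEL_NAIVE_UNIQUE: 0, LABEL_UNMATCHED: 0}
    for obs in observed:
        if obs.sequence in annotated:
            label = LABEL_ANNOTATED
        elif obs.sequence in naive:
            label = LABEL_NAIVE_UNIQUE
        else:
            label = LABEL_UNMATCHED
        labels[obs.id] = label
        counts[label] += 1
    logger.info(
        "classified %d peptides: %d annotated, %d naive-unique, %d unmatched",
        len(observed), counts[LABEL_ANNOTATED], counts[LABEL_NAIVE_UNIQUE],
        counts[LABEL_UNMATCHED],
    )
    return MatchReport(
        labels=labels,
        n_annotated=counts[LABEL_ANNOTATED],
        n_naive_unique=counts[LABEL_NAIVE_UNIQUE],
        n_unmatched=counts[LABEL_UNMATCHED],
    )


# ---------------------------------------------------------------------------
# retention-time concordance

# Additive per-residue retention coefficients for peptide RP-HPLC, after the
# 2004 SSRCalc model (the published 100 A / 0.1% TFA values).  Arbitrary
# units; the table is pluggable wherever a hydrophobicity table is accepted.
KROKHIN_2004_COEFFICIENTS: dict[str, float] = {
    "W": 11.0, "F": 10.5, "L": 9.6, "I": 8.4, "M": 5.8,
    "V": 5.0, "Y": 4.0, "A": 0.8, "T": 0.4, "P": 0.2,
    "E": 0.0, "D": -0.5, "C": -0.8, "S": -0.8, "Q": -0.9,
    "G": -0.9, "N": -1.2, "R": -1.3, "H": -1.3, "K": -1.9,
}


def hydrophobicity(peptide: str, table: dict[str, float] | None = None) -> float:
    """Additive hydrophobicity: sum of per-residue retention coefficients."""
    table = table if table is not None else KROKHIN_2004_COEFFICIENTS
    if not peptide:
        raise ValueError("empty peptide")
    try:
        return float(sum(table[a] for a in peptide))
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from exc


CONCORDANT = "concordant"
OUTLIER = "outlier"


@dataclass
class RetentionFit:
    """Least-squares fit of retention time on hydrophobicity with per-peptide
    concordant/outlier flags (|residual| > threshold)."""

    slope: float
    intercept: float
    correlation: float
    residual_threshold: float
    flags: dict[str, str]  # observed peptide id -> concordant | outlier

    @property
    def n_outliers(self) -> int:
        return sum(1 for v in self.flags.values() if v == OUTLIER)

    def is_concordant(self, peptide_id: str) -> bool:
        return self.flags.get(peptide_id) == CONCORDANT


def fit_retention(
    observed: list[ObservedPeptide],
    table: dict[str, float] | None = None,
    outlier_sd: float = 3.0,
) -> RetentionFit:
    """OLS of rt ~ hydrophobicity; flags peptides whose absolute residual
    exceeds ``outlier_sd`` standard deviations of the residuals."""
    if len(observed) < 3:
        raise ValueError("need at least 3 peptides to fit retention")
    h = np.array([hydrophobicity(o.sequence, table) for o in observed])
    rt = np.array([o.retention_time for o in observed])
    if np.ptp(h) == 0:
        raise ValueError("zero variance in hydrophobicity")
    res = stats.linregress(h, rt)
    residuals = rt - (res.slope * h + res.intercept)
    sd = float(residuals.std())
    threshold = outlier_sd * sd
    flags = {}
    for o, r in zip(observed, residuals):
        # sd == 0 means a perfect fit: everything concordant
        flags[o.id] = OUTLIER if (sd > 0 and abs(r) > threshold) else CONCORDANT
    fit = RetentionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        residual_threshold=float(threshold),
        flags=flags,
    )
    logger.info(
        "retention fit: slope=%.4g intercept=%.4g r=%.4f outliers=%d/%d",
        fit.slope, fit.intercept, fit.correlation, fit.n_outliers, len(observed),
    )
    return fit


# ---------------------------------------------------------------------------
# peptide -> genome mapping


@dataclass(frozen=True)
class PeptideLocus:
    contig: str
    start: int  # nucleotide coordinates, 0-based half-open, forward strand
    end: int
    strand: str
    frame: int


class SixFrameIndex:
    """Cached six-frame translations of a contig set for exact peptide search."""

    def __init__(self, contigs: ContigSet, collapse_il: bool = True):
        self.contigs = contigs
        self.collapse_il = collapse_il
        self._frames: list[tuple[str, int, int, str]] = []  # contig, frame, L, aa
        for contig in contigs:
            rc = str(Seq(contig.seq).reverse_complement())
            for frame in FRAMES:
                src = contig.seq if frame > 0 else rc
                aa = translate(src[abs(frame) - 1 :])
                if collapse_il:
                    aa = aa.replace("I", "L")
                self._frames.append((contig.id, frame, len(contig.seq), aa))

    def find(self, peptide: str) -> list[PeptideLocus]:
        query = peptide.replace("I", "L") if self.collapse_il else peptide
        loci: list[PeptideLocus] = []
        for contig_id, frame, length, aa in self._frames:
            offset = abs(frame) - 1
            pos = aa.find(query)
            while pos != -1:
                nt_start = offset + 3 * pos
                nt_end = nt_start + 3 * len(query)
                if frame > 0:
                    loci.append(
                        PeptideLocus(contig_id, nt_start, nt_end, "+", frame)
                    )
                else:
                    loci.append(
                        PeptideLocus(
                            contig_id, length - nt_end, length - nt_start, "-", frame
                        )
                    )
                pos = aa.find(query, pos + 1)
        return loci


def map_peptide_to_genome(
    peptide: str, contigs: ContigSet | SixFrameIndex, collapse_il: bool = True
) -> list[PeptideLocus]:
    """All exact translated occurrences of a peptide over six frames of all
    contigs, as nucleotide intervals.  Accepts a prebuilt index for bulk use."""
    if not peptide:
        raise ValueError("empty peptide")
    index = (
        contigs
        if isinstance(contigs, SixFrameIndex)
        else SixFrameIndex(contigs, collapse_il)
    )
    return index.find(peptide)


# ---------------------------------------------------------------------------
# anomaly adjudication

SUPPORTED = "supported"
NO_EVIDENCE = "no_evidence"


@dataclass
class AnomalyCall:
    anomaly_id: str
    verdict: str
    supporting_peptides: list[str]  # observed peptide ids


def adjudicate_anomalies(
    report: MatchReport,
    fit: RetentionFit,
    loci_by_peptide: dict[str, list[PeptideLocus]],
    observed: list[ObservedPeptide],
    anomalies: list[AnomalyRecord],
    min_support: int = 2,
) -> list[AnomalyCall]:
    """Call each ledgered anomaly supported or no_evidence.

    An anomaly is supported iff at least ``min_support`` distinct
    naive-unique, retention-concordant peptides map (exactly, in any frame)
    to loci overlapping the anomaly interval by >= 1 base on the anomaly's
    strand.  Absence of peptides never refutes: the negative verdict is
    "no evidence", not "refuted".
    """
    obs_by_id = {o.id: o for o in observed}
    # candidate evidence: naive-unique and retention-concordant
    candidates = [
        oid
        for oid, label in report.labels.items()
        if label == LABEL_NAIVE_UNIQUE and fit.is_concordant(oid)
    ]
    calls: list[AnomalyCall] = []
    for anom in anomalies:
        support: set[str] = set()
        supporting_seqs: set[str] = set()
        for oid in candidates:
            seq = obs_by_id[oid].sequence
            if seq in supporting_seqs:
                continue
            for locus in loci_by_peptide.get(oid, []):
                if (
                    locus.contig == anom.contig
                    and locus.strand == anom.strand
                    and locus.start < anom.end
                    and locus.end > anom.start
                ):
                    support.add(oid)
                    supporting_seqs.add(seq)
                    break
        verdict = SUPPORTED if len(supporting_seqs) >= min_support else NO_EVIDENCE
        calls.append(
            AnomalyCall(
                anomaly_id=anom.anomaly_id,
                verdict=verdict,
                supporting_peptides=sorted(support),
            )
        )
    n_sup = sum(1 for c in calls if c.verdict == SUPPORTED)
    logger.info("adjudicated %d anomalies: %d supported", len(calls), n_sup)
    return calls
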