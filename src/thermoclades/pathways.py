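"""Carbohydrate-utilization pathway scoring and phenotype concordance.

A pathway definition is a conjunction of term groups, each group a
disjunction of acceptable functional-term ids: a genome is scored "+" for a
substrate iff every group is hit by at least one of its terms.  The
predicted presence/absence matrix is then compared against a reported
phenotype table ("+", "-", or NR for not reported) to count agreements,
disagreements and untested cells.  Extracellular carbohydrate-active-enzyme
(CAZyme) inventories with modular architectures (e.g. GH10, CBM22-CBM22-
GH10-CBM9-CBM9-SLH-SLH-SLH) are summarized per genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

PRESENT = "+"
ABSENT = "-"
NOT_REPORTED = "NR"

_MINUS_VARIANTS = {"−", "–", "—"}  # unicode minus / dashes


def _norm_symbol(s: str) -> str:
    s = s.strip()
    return ABSENT if s in _MINUS_VARIANTS else s


@dataclass(frozen=True)
class PathwayDef:
    """AND-of-ORs requirement: every group must be satisfied by >= 1 term."""

    pathway_id: str
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError(f"pathway {self.pathway_id} has no groups")
        if any(not g for g in self.groups):
            raise ValueError(f"pathway {self.pathway_id} has an empty group")

    def satisfied_by(self, terms: set[str]) -> bool:
        return all(any(t in terms for t in group) for group in self.groups)


def load_pathway_defs(path=None) -> list[PathwayDef]:
    """Read pathway definitions from YAML (packaged defaults when ``path`` is
    None).  The format supports named shared ``term_sets`` (e.g. the
    glycolysis backbone) referenced from pathways via ``requires``."""
    if path is None:
        text = (resources.files("thermoclades.data") / "pathways.yaml").read_text()
    else:
        text = open(path).read()
    doc = yaml.safe_load(text)
    shared = {
        name: [tuple(group) for group in groups]
        for name, groups in (doc.get("term_sets") or {}).items()
    }
    defs = []
    for pid, body in doc["pathways"].items():
        groups: list[tuple[str, ...]] = []
        for ref in body.get("requires", []) or []:
            groups.extend(shared[ref])
        for group in body.get("groups", []) or []:
            groups.append(tuple(group))
        defs.append(PathwayDef(pathway_id=pid, groups=tuple(groups)))
    return defs


def score_pathway_presence(
    terms_by_genome: dict[str, set[str]], defs: list[PathwayDef]
) -> pd.DataFrame:
    """Genome x pathway presence matrix of "+" / "-" calls."""
    data = {
        genome: {
            d.pathway_id: PRESENT if d.satisfied_by(terms) else ABSENT for d in defs
        }
        for genome, terms in terms_by_genome.items()
    }
    matrix = pd.DataFrame.from_dict(data, orient="index")
    return matrix[[d.pathway_id for d in defs]]


AGREE = "agree"
DISAGREE = "disagree"
VERDICT_NOT_REPORTED = "not_reported"


@dataclass
class ConcordanceReport:
    n_total: int
    n_agree: int
    n_disagree: int
    n_not_reported: int
    verdicts: pd.DataFrame  # genome x substrate of agree/disagree/not_reported

    def disagreements(self) -> list[tuple[str, str]]:
        out = []
        for genome in self.verdicts.index:
            for substrate in self.verdicts.columns:
                if self.verdicts.loc[genome, substrate] == DISAGREE:
                    out.append((genome, substrate))
        return out


def concordance(pred: pd.DataFrame, pheno: pd.DataFrame) -> ConcordanceReport:
    """Cell-by-cell agreement of genomic predictions with reported phenotypes.

    agree: prediction equals a non-NR phenotype; disagree: it opposes one
    (both directions count); not_reported: phenotype is NR.  The three counts
    partition ``genomes * substrates``.
    """
    if list(pred.index) != list(pheno.index) or list(pred.columns) != list(
        pheno.columns
    ):
        raise ValueError("prediction and phenotype tables must share indexes")
    verdicts = pd.DataFrame(index=pred.index, columns=pred.columns, dtype=object)
    counts = {AGREE: 0, DISAGREE: 0, VERDICT_NOT_REPORTED: 0}
    for g in pred.index:
        for s in pred.columns:
            p = _norm_symbol(str(pred.loc[g, s]))
            f = _norm_symbol(str(pheno.loc[g, s]))
            if p not in (PRESENT, ABSENT):
                raise ValueError(f"bad prediction symbol {p!r} at ({g}, {s})")
            if f == NOT_REPORTED:
                v = VERDICT_NOT_REPORTED
            elif f in (PRESENT, ABSENT):
                v = AGREE if p == f else DISAGREE
            else:
                raise ValueError(f"bad phenotype symbol {f!r} at ({g}, {s})")
            verdicts.loc[g, s] = v
            counts[v] += 1
    return ConcordanceReport(
        n_total=pred.size,
        n_agree=counts[AGREE],
        n_disagree=counts[DISAGREE],
        n_not_reported=counts[VERDICT_NOT_REPORTED],
        verdicts=verdicts,
    )


# ---------------------------------------------------------------------------
# CAZyme architectures

MODULE_CLASSES = ("GH", "CE", "PL", "CBM", "SLH")
_TOKEN_RE = re.compile(r"^([A-Za-z]+?)(\d+)?$")


@dataclass(frozen=True)
class ModuleToken:
    module_class: str  # GH | CE | PL | CBM | SLH | other
    family: int | None
    raw: str


def parse_architecture(text: str) -> list[ModuleToken]:
    """Split a modular architecture string like "GH66-CBM35-CBM35-GH15" on
    "-" into ordered, classified module tokens."""
    if not text:
        raise ValueError("empty architecture string")
    tokens = []
    for raw in text.split("-"):
        if not raw:
            raise ValueError(f"empty module token in {text!r}")
        m = _TOKEN_RE.match(raw)
        if not m:
            raise ValueError(f"unparseable module token {raw!r}")
        prefix, number = m.group(1).upper(), m.group(2)
        cls = prefix if prefix in MODULE_CLASSES else "other"
        tokens.append(
            ModuleToken(
                module_class=cls,
                family=int(number) if number else None,
                raw=raw,
            )
        )
    return tokens


EXTRACELLULAR = "extracellular"
LOCALIZATIONS = (EXTRACELLULAR, "intracellular", "cell-bound", "unknown")


@dataclass(frozen=True)
class CazymeEntry:
    genome: str
    locus_tag: str
    architecture: str
    localization: str

    def __post_init__(self) -> None:
        parse_architecture(self.architecture)  # validates
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.localization!r}")


def summarize_extracellular(
    entries: list[CazymeEntry], genomes: list[str] | None = None
) -> tuple[pd.Series, dict[str, list[str]]]:
    """Per-genome counts of extracellular entries and a family -> genome map.

    ``genomes`` fixes the index (genomes with zero entries included); the
    family map keys are the leading-module family strings (e.g. "GH10") of
    extracellular entries.
    """
    extra = [e for e in entries if e.localization == EXTRACELLULAR]
    index = genomes if genomes is not None else sorted({e.genome for e in entries})
    counts = pd.Series(0, index=index, dtype=int)
    family_map: dict[str, list[str]] = {}
    for e in extra:
        if e.genome in counts.index:
            counts[e.genome] += 1
        for token in parse_architecture(e.architecture):
            if token.module_class in ("GH", "CE", "PL") and token.family is not None:
                key = f"{token.module_class}{token.family}"
                family_map.setdefault(key, [])
                if e.genome not in family_map[key]:
                    family_map[key].append(e.genome)
    return counts, family_map


# ---------------------------------------------------------------------------
# packaged reference tables


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("thermoclades.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def load_table3() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published 11-genome x 7-substrate prediction and phenotype
    matrices (genomes as rows)."""
    pred = _read_packaged_tsv("table3_predictions.tsv")
    pheno = _read_packaged_tsv("table3_phenotypes.tsv")
    return pred, pheno


def load_table1() -> list[CazymeEntry]:
    """The published extracellular CAZyme inventory (one row per genome/locus)."""
    df = _read_packaged_tsv("table1_cazymes.tsv").reset_index()
    return [
        CazymeEntry(
            genome=r.genome,
            locus_tag=r.locus_tag,
            architecture=r.architecture,
            localization=r.localization,
        )
        for r in df.itertuples()
    ]
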