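"""Readers and writers for the tabular formats the pipeline consumes.

Every parser returns a typed in-memory object with validated invariants so
downstream modules never touch raw text.  All formats are UTF-8,
tab-separated; lines starting with ``#`` are skipped.

Formats
-------
* 12-column pairwise-alignment hit tables (BLAST ``outfmt 6`` dialect)
* MITAB-like PPI tables with PSI-MI term annotations and PubMed ids
* GMT gene-set files
* expression matrices (genes x samples, log2 scale) plus a group line
* clinical tables (patient, months, event)
* organism distance tables (orgA, orgB, normalized distance)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("campnets")

#: E-values printed as "0.0" are floored here so -log10 stays finite.
EVALUE_FLOOR = 1e-180


class ParseError(ValueError):
    """A malformed line or field in an input table."""


class ValidationError(ValueError):
    """A parsed value violating a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One pairwise-alignment hit.

    ``identity`` is a fraction in [0, 1] (parsed from percent), ``evalue``
    the alignment E-value floored at :data:`EVALUE_FLOOR`.
    """

    query_id: str
    subject_id: str
    identity: float
    aligned_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity {self.identity} outside [0,1]")
        if self.aligned_length < 1:
            raise ValidationError(f"aligned_length {self.aligned_length} < 1")
        if self.evalue < 0:
            raise ValidationError(f"negative E-value {self.evalue}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with its topology annotation.

    ``cytoplasmic_regions`` are 1-based inclusive [start, end] intervals
    (UniProt convention), sorted and non-overlapping.
    """

    id: str
    species: str
    length: int
    cytoplasmic_regions: tuple[tuple[int, int], ...] = ()
    is_mp: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.id}: length {self.length} < 1")
        regions = tuple(sorted(tuple(r) for r in self.cytoplasmic_regions))
        object.__setattr__(self, "cytoplasmic_regions", regions)
        prev_end = 0
        for start, end in regions:
            if start < 1 or end > self.length or start > end:
                raise ValidationError(
                    f"{self.id}: region ({start},{end}) outside [1,{self.length}]")
            if start <= prev_end:
                raise ValidationError(f"{self.id}: overlapping cytoplasmic regions")
            prev_end = end


@dataclass
class PathwayCollection:
    """Named gene sets plus a designated cancer-related subset."""

    pathways: dict[str, frozenset[str]]
    cancer_related: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} is empty")
        missing = set(self.cancer_related) - set(self.pathways)
        if missing:
            raise ValidationError(f"cancer_related ids not in collection: {sorted(missing)}")
        self.cancer_related = frozenset(self.cancer_related)


@dataclass
class ExpressionMatrix:
    """A log2-scale expression matrix with per-sample tumor/normal labels."""

    values: pd.DataFrame          # genes x samples
    group: pd.Series              # sample -> "tumor" | "normal"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite expression values")
        bad = set(self.group.unique()) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if list(self.group.index) != list(self.values.columns):
            self.group = self.group.reindex(self.values.columns)
            if self.group.isna().any():
                raise ValidationError("samples missing a group label")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tumor(self) -> pd.DataFrame:
        return self.values.loc[:, self.group == "tumor"]

    def normal(self) -> pd.DataFrame:
        return self.values.loc[:, self.group == "normal"]


@dataclass
class SurvivalTable:
    """Overall-survival follow-up: one row per patient."""

    table: pd.DataFrame           # columns: patient, months, event

    def __post_init__(self) -> None:
        t = self.table
        for col in ("patient", "months", "event"):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if t["patient"].duplicated().any():
            raise ValidationError("duplicate patient ids")
        if (t["months"] <= 0).any():
            raise ValidationError("survival months must be positive")
        if not set(t["event"].unique()) <= {0, 1}:
            raise ValidationError("event flags must be 0 or 1")
        self.table = t.reset_index(drop=True)

    @property
    def patients(self) -> list[str]:
        return list(self.table["patient"])


@dataclass
class DistanceTable:
    """Normalized evolutionary distances between organisms, symmetric in [0, 1]."""

    pairs: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        out: dict[tuple[str, str], float] = {}
        for (a, b), d in self.pairs.items():
            if not 0.0 <= d <= 1.0:
                raise ValidationError(f"distance {d} for ({a},{b}) outside [0,1]")
            if a == b and d != 0.0:
                raise ValidationError(f"nonzero self-distance for {a}")
            key = (a, b) if a <= b else (b, a)
            if key in out and not math.isclose(out[key], d):
                raise ValidationError(f"asymmetric distance for {key}")
            out[key] = d
        self.pairs = out

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        return self.pairs[key]


@dataclass(frozen=True)
class RawInteraction:
    """One deduplicated MITAB record (unordered pair + species)."""

    protein_a: str
    protein_b: str
    species: tuple[str, ...]
    detection_methods: frozenset[str]
    interaction_types: frozenset[str]
    references: frozenset[str]

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _check_mi(code: str) -> str:
    code = code.strip()
    if not code.startswith("MI:"):
        raise ValidationError(f"MI term {code!r} lacks 'MI:' prefix")
    return code


# ---------------------------------------------------------------------------
# alignment hit tables
# ---------------------------------------------------------------------------

def read_alignment_hits(path: str | Path) -> set[AlignmentHit]:
    """Parse a 12-column alignment hit table (BLAST outfmt-6 dialect).

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  Percent identity is divided by
    100; literal E-value 0.0 is floored at :data:`EVALUE_FLOOR`.
    """
    hits: set[AlignmentHit] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) != 12:
            raise ParseError(
                f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
        try:
            pident = float(fields[2])
            length = int(fields[3])
            evalue = float(fields[10])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if evalue < 0:
            raise ValidationError(f"{path}:{lineno}: negative E-value {evalue}")
        if evalue == 0.0:
            evalue = EVALUE_FLOOR
        hits.add(AlignmentHit(
            query_id=fields[0], subject_id=fields[1],
            identity=pident / 100.0, aligned_length=length, evalue=evalue))
    return hits


def write_alignment_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    rows = sorted(hits)
    with open(path, "w", encoding="utf-8") as fh:
        for h in rows:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.identity * 100.0:.2f}",
                str(h.aligned_length), "0", "0", "0", "0", "0", "0",
                f"{h.evalue:.6g}", "0",
            ]) + "\n")


# ---------------------------------------------------------------------------
# MITAB-like interaction tables
# ---------------------------------------------------------------------------

MITAB_COLUMNS = ("protein_a", "protein_b", "species_a", "species_b",
                 "detection_methods", "interaction_types", "pubmed_ids")


def read_mitab(path: str | Path) -> set[RawInteraction]:
    """Parse a MITAB-like table, deduplicating on unordered pair + species.

    Required columns (extra columns are ignored): the two interactor
    accessions, the two species, pipe-separated MI detection-method and
    interaction-type codes, and pipe-separated PubMed ids.  Rows missing
    an accession are skipped with a logged warning; duplicate rows are
    merged by evidence union.
    """
    merged: dict[tuple[frozenset[str], tuple[str, ...]], dict] = {}
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 7:
            raise ParseError(
                f"{path}:{lineno}: expected >=7 tab-separated columns, got {len(fields)}")
        a, b, sp_a, sp_b = (f.strip() for f in fields[:4])
        if not a or not b or a == "-" or b == "-":
            skipped += 1
            continue
        methods = frozenset(_check_mi(c) for c in fields[4].split("|") if c.strip())
        types = frozenset(_check_mi(c) for c in fields[5].split("|") if c.strip())
        refs = frozenset(r.strip() for r in fields[6].split("|") if r.strip())
        species = tuple(sorted({sp_a, sp_b}))
        key = (frozenset((a, b)), species)
        if key in merged:
            rec = merged[key]
            rec["detection_methods"] |= methods
            rec["interaction_types"] |= types
            rec["references"] |= refs
        else:
            merged[key] = {
                "protein_a": min(a, b), "protein_b": max(a, b), "species": species,
                "detection_methods": set(methods), "interaction_types": set(types),
                "references": set(refs),
            }
    if skipped:
        logger.warning("read_mitab: skipped %d rows missing an accession", skipped)
    return {
        RawInteraction(
            protein_a=r["protein_a"], protein_b=r["protein_b"], species=r["species"],
            detection_methods=frozenset(r["detection_methods"]),
            interaction_types=frozenset(r["interaction_types"]),
            references=frozenset(r["references"]))
        for r in merged.values()
    }


def write_mitab(records: Iterable[RawInteraction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(MITAB_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.protein_a, r.protein_b, r.species)):
            species = list(r.species) * 2
            fh.write("\t".join([
                r.protein_a, r.protein_b, species[0], species[1],
                "|".join(sorted(r.detection_methods)),
                "|".join(sorted(r.interaction_types)),
                "|".join(sorted(r.references)),
            ]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path,
                       cancer_related: Iterable[str] = ()) -> PathwayCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    pathways: dict[str, frozenset[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
        name = fields[0]
        if name in pathways:
            raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ParseError(f"{path}:{lineno}: pathway {name!r} has no genes")
        pathways[name] = genes
    return PathwayCollection(pathways=pathways,
                             cancer_related=frozenset(cancer_related))


def write_gene_sets_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.pathways):
            genes = sorted(collection.pathways[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# expression + clinical
# ---------------------------------------------------------------------------

def read_expression(expr_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV and a two-column (sample, group) TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0, comment="#")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{expr_path}: non-numeric expression cell ({exc})") from exc
    groups = pd.read_csv(groups_path, sep="\t", comment="#",
                         names=["sample", "group"], header=None, dtype=str)
    group = groups.set_index("sample")["group"]
    return ExpressionMatrix(values=values, group=group)


def write_expression(expr: ExpressionMatrix, expr_path: str | Path,
                     groups_path: str | Path) -> None:
    expr.values.to_csv(expr_path, sep="\t")
    expr.group.to_csv(groups_path, sep="\t", header=False)


def read_clinical(path: str | Path) -> SurvivalTable:
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"patient": str})
    return SurvivalTable(table=t[["patient", "months", "event"]])


def write_clinical(surv: SurvivalTable, path: str | Path) -> None:
    surv.table.to_csv(path, sep="\t", index=False)


def read_expression_and_clinical(
        expr_path: str | Path, groups_path: str | Path,
        clinical_path: str | Path) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Read expression and clinical tables and intersect on patients.

    Tumor samples without a clinical record are dropped with a warning;
    zero overlap is an error.  Normal samples are kept regardless (they
    carry no survival information).
    """
    expr = read_expression(expr_path, groups_path)
    surv = read_clinical(clinical_path)
    tumor_samples = set(expr.values.columns[expr.group == "tumor"])
    clinical_patients = set(surv.patients)
    overlap = tumor_samples & clinical_patients
    if not overlap:
        raise ValidationError("no overlap between tumor samples and clinical patients")
    extra = tumor_samples - clinical_patients
    if extra:
        logger.warning("dropping %d tumor samples without clinical records", len(extra))
        keep = [s for s in expr.samples if s not in extra]
        expr = ExpressionMatrix(values=expr.values[keep], group=expr.group[keep])
    surv = SurvivalTable(table=surv.table[surv.table["patient"].isin(overlap)])
    return expr, surv


# ---------------------------------------------------------------------------
# distance tables
# ---------------------------------------------------------------------------

def read_distance_table(path: str | Path) -> DistanceTable:
    """Read a 3-column (orgA, orgB, distance) TSV of normalized distances."""
    pairs: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        a, b = fields[0], fields[1]
        try:
            d = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        pairs[(a, b)] = d
    return DistanceTable(pairs=pairs)


def write_distance_table(dist: DistanceTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), d in sorted(dist.pairs.items()):
            fh.write(f"{a}\t{b}\t{d:.6g}\n")


def normalize_tree_distances(raw: Mapping[tuple[str, str], float]) -> DistanceTable:
    """Normalize raw pairwise tree distances by the maximum pairwise distance."""
    dmax = max(raw.values()) if raw else 1.0
    if dmax <= 0:
        dmax = 1.0
    return DistanceTable(pairs={k: v / dmax for k, v in raw.items()})


# ---------------------------------------------------------------------------
# protein tables
# ---------------------------------------------------------------------------

def read_proteins(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein annotation table.

    Columns: id, species, length, cytoplasmic regions as
    ``start-end[,start-end...]`` (or ``-`` for none), is_mp flag (0/1).
    """
    out: dict[str, ProteinRecord] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns")
        pid, species, length_s, regions_s, mp_s = fields
        regions: list[tuple[int, int]] = []
        if regions_s not in ("-", ""):
            for chunk in regions_s.split(","):
                start_s, _, end_s = chunk.partition("-")
                regions.append((int(start_s), int(end_s)))
        if pid in out:
            raise ParseError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        out[pid] = ProteinRecord(id=pid, species=species, length=int(length_s),
                                 cytoplasmic_regions=tuple(regions),
                                 is_mp=mp_s.strip() == "1")
    return out


def write_proteins(proteins: Mapping[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(proteins):
            p = proteins[pid]
            regions = ",".join(f"{s}-{e}" for s, e in p.cytoplasmic_regions) or "-"
            fh.write(f"{p.id}\t{p.species}\t{p.length}\t{regions}\t{int(p.is_mp)}\n")
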