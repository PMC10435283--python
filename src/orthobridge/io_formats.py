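"""Readers, writers and domain types for every external input format.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package; any half-open arithmetic is confined inside individual
operations.  Chromosome identifiers must be unique across the whole
multi-species collection, which is why chromosome-ID conversion is strict:
a chromosome missing from a supplied conversion table is a hard error
rather than a silent passthrough (passthrough would hide ID collisions
between species).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "TranscriptFeature",
    "GenomeAnnotation",
    "OrthogroupSet",
    "QTLRecord",
    "ExpressionMatrix",
    "ConditionAnnotation",
    "Ontology",
    "FunctionalAnnotationRecord",
    "read_gff3",
    "write_gff3",
    "select_longest_isoform",
    "read_orthogroups",
    "write_orthogroups",
    "read_collinearity",
    "write_collinearity",
    "read_qtl_table",
    "write_qtl_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_condition_metadata",
    "write_condition_metadata",
    "read_obo",
    "write_obo",
    "read_functional_annotations",
    "write_functional_annotations",
    "read_chromosome_conversion",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene locus with 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TranscriptFeature:
    """An mRNA isoform; CDS segments are 1-based inclusive and disjoint."""

    transcript_id: str
    gene_id: str
    cds_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping CDS segments"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class GenomeAnnotation:
    """Gene/transcript structure of one species genome."""

    species: str
    chromosomes: list[tuple[str, int]]
    genes: list[GeneFeature]
    transcripts: list[TranscriptFeature]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        chrom_len = dict(self.chromosomes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(f"duplicated gene ID: {g.gene_id}")
            seen.add(g.gene_id)
            if g.chromosome in chrom_len and g.end > chrom_len[g.chromosome]:
                raise FormatError(
                    f"gene {g.gene_id} extends beyond chromosome "
                    f"{g.chromosome} ({g.end} > {chrom_len[g.chromosome]})"
                )
        for t in self.transcripts:
            if t.gene_id not in seen:
                raise FormatError(
                    f"transcript {t.transcript_id} references unknown gene {t.gene_id}"
                )

    def transcripts_of(self, gene_id: str) -> list[TranscriptFeature]:
        return [t for t in self.transcripts if t.gene_id == gene_id]

    def genes_by_chromosome(self) -> dict[str, list[GeneFeature]]:
        """Genes grouped per chromosome, sorted by (start, end, ID)."""
        out: dict[str, list[GeneFeature]] = {}
        for g in self.genes:
            out.setdefault(g.chromosome, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out


class OrthogroupSet:
    """Partition of genes into cross-species homology groups.

    Maintains the forward mapping ``orthogroup -> species -> [genes]`` and a
    reverse index ``gene -> orthogroup``; a gene may belong to at most one
    orthogroup.
    """

    def __init__(self, groups: Mapping[str, Mapping[str, Sequence[str]]]):
        self.groups: dict[str, dict[str, list[str]]] = {
            og: {sp: list(genes) for sp, genes in sp_map.items() if genes}
            for og, sp_map in groups.items()
        }
        self.gene_to_group: dict[str, str] = {}
        self.gene_to_species: dict[str, str] = {}
        for og, sp_map in self.groups.items():
            for sp, genes in sp_map.items():
                for g in genes:
                    if g in self.gene_to_group:
                        raise FormatError(
                            f"gene {g} listed in both {self.gene_to_group[g]} and {og}"
                        )
                    self.gene_to_group[g] = og
                    self.gene_to_species[g] = sp

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp_map in self.groups.values():
            for sp in sp_map:
                seen.setdefault(sp)
        return list(seen)

    def members(self, orthogroup: str) -> list[str]:
        """All member genes of one orthogroup, across species."""
        sp_map = self.groups.get(orthogroup, {})
        return [g for genes in sp_map.values() for g in genes]

    def group_of(self, gene_id: str) -> str | None:
        return self.gene_to_group.get(gene_id)

    def same_group(self, gene_a: str, gene_b: str) -> bool:
        ga = self.gene_to_group.get(gene_a)
        return ga is not None and ga == self.gene_to_group.get(gene_b)

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class QTLRecord:
    """A trait-associated locus defined by one to three markers.

    Loci mapped in biparental populations carry two flanking markers and
    optionally a peak marker inside the interval; association-panel (GWAS)
    loci are defined by a single peak marker.  The confidence interval is
    the closed span between the outermost flanking markers.
    """

    qtl_id: str
    trait: str
    study_type: str  # "biparental" | "diversity panel"
    chromosome: str
    flank_left: int | None = None
    flank_right: int | None = None
    peak: int | None = None
    population: str | None = None
    site: str | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.flank_left is None and self.flank_right is None and self.peak is None:
            raise FormatError(f"QTL {self.qtl_id}: no marker position given")
        if self.study_type not in ("biparental", "diversity panel"):
            raise FormatError(
                f"QTL {self.qtl_id}: unknown study type {self.study_type!r}"
            )
        if (
            self.flank_left is not None
            and self.flank_right is not None
            and self.flank_left > self.flank_right
        ):
            raise FormatError(f"QTL {self.qtl_id}: flank_left > flank_right")
        if self.peak is not None and self.flank_left is not None and self.flank_right is not None:
            if not (self.flank_left <= self.peak <= self.flank_right):
                raise FormatError(f"QTL {self.qtl_id}: peak outside flanking interval")

    @property
    def interval(self) -> tuple[int, int] | None:
        """Confidence interval = hull of the flanking markers, or None for
        single-marker (point) records."""
        flanks = [p for p in (self.flank_left, self.flank_right) if p is not None]
        if not flanks:
            return None
        return min(flanks), max(flanks)

    @property
    def is_point(self) -> bool:
        return self.interval is None


class ExpressionMatrix:
    """Gene x sample TPM matrix with an optional parallel count matrix."""

    def __init__(self, tpm: pd.DataFrame, counts: pd.DataFrame | None = None):
        if tpm.index.duplicated().any():
            raise FormatError("duplicated gene IDs in expression matrix")
        if tpm.columns.duplicated().any():
            raise FormatError("duplicated sample IDs in expression matrix")
        if (tpm.to_numpy() < 0).any():
            raise FormatError("negative TPM values in expression matrix")
        self.tpm = tpm.astype(float)
        self.counts = counts

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if not self.tpm.equals(other.tpm):
            return False
        if (self.counts is None) != (other.counts is None):
            return False
        return self.counts is None or self.counts.equals(other.counts)


@dataclass(frozen=True)
class ConditionAnnotation:
    """A biological condition: replicate samples sharing tissue/treatment,
    annotated with Plant Ontology (tissue) and PECO (treatment) terms."""

    condition_id: str
    samples: tuple[str, ...]
    po_terms: tuple[str, ...] = ()
    peco_terms: tuple[str, ...] = ()
    area: str | None = None


class Ontology:
    """A DAG of terms with ``is_a``/``part_of`` child-to-parent edges."""

    PREDICATES = ("is_a", "part_of")

    def __init__(
        self,
        source: str,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str, str]],
    ):
        self.source = source
        self.terms: dict[str, str] = dict(terms)
        self.edges: list[tuple[str, str, str]] = []
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, pred in edges:
            if pred not in self.PREDICATES:
                raise FormatError(f"unsupported ontology predicate {pred!r}")
            if child == parent:
                raise FormatError(f"term {child} is its own parent")
            for t in (child, parent):
                if t not in self.terms:
                    raise FormatError(f"ontology edge references unknown term {t}")
            self.edges.append((child, parent, pred))
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"cyclic ontology: {cycle}")
        self._graph = g

    def parents(self, term: str, predicates: Sequence[str] = PREDICATES) -> list[str]:
        preds = set(predicates)
        return sorted({p for c, p, pr in self.edges if c == term and pr in preds})


@dataclass(frozen=True)
class FunctionalAnnotationRecord:
    """One functional annotation assignment (domain, family, GO term, bin).

    ``is_hidden`` is only meaningful for GO records: annotation-propagation
    tools emit the full ancestor closure of each assigned term and flag every
    non-leaf (redundant) term with ``is_hidden = 1``; keeping only the
    ``is_hidden = 0`` records retains the most specific terms.
    """

    subject_id: str
    source_db: str
    accession: str
    description: str = ""
    domain_start: int | None = None
    domain_end: int | None = None
    is_hidden: int | None = None

    def __post_init__(self) -> None:
        if (
            self.domain_start is not None
            and self.domain_end is not None
            and self.domain_start > self.domain_end
        ):
            raise FormatError(
                f"annotation {self.accession} on {self.subject_id}: "
                "domain start > end"
            )
        if self.is_hidden is not None and self.source_db != "GO":
            raise FormatError("is_hidden flag is only valid on GO records")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)ID=([^;]+)")


def read_chromosome_conversion(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping original chromosome IDs to database IDs."""
    table: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        old, new = line.split("\t")[:2]
        table[old] = new
    return table


def read_gff3(
    path: str | Path,
    id_conversion: Mapping[str, str] | None = None,
    species: str | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 annotation (gene/mRNA/CDS features) into a
    :class:`GenomeAnnotation`.

    When ``id_conversion`` is given every chromosome ID must appear in it;
    a missing entry is a hard error.  Chromosome lengths are taken from
    ``##sequence-region`` directives when present, else from the gene hull.
    """
    path = Path(path)
    if species is None:
        species = path.stem

    text = path.read_text()
    # Named duplicate-ID check up front: the loader below would silently
    # uniquify colliding IDs.
    gene_ids: set[str] = set()
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) >= 9 and cols[2] == "gene":
            m = _ID_RE.search(cols[8])
            if m:
                gid = m.group(1)
                if gid in gene_ids:
                    raise FormatError(f"duplicated gene ID: {gid}")
                gene_ids.add(gid)

    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    def convert(chrom: str) -> str:
        if id_conversion is None:
            return chrom
        if chrom not in id_conversion:
            raise FormatError(
                f"chromosome {chrom!r} absent from the conversion table"
            )
        return id_conversion[chrom]

    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        m = re.match(r"sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", directive)
        if m:
            chrom_lengths[convert(m.group(1))] = int(m.group(3))

    genes: list[GeneFeature] = []
    transcripts: list[TranscriptFeature] = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        name = f.attributes.get("Name", [None])[0]
        genes.append(
            GeneFeature(
                gene_id=f.attributes["ID"][0],
                chromosome=convert(f.seqid),
                start=f.start,
                end=f.end,
                strand=f.strand,
                name=name,
            )
        )
    for f in db.features_of_type("mRNA", order_by=("seqid", "start")):
        parent = f.attributes.get("Parent", [None])[0]
        if parent is None or parent not in gene_ids:
            raise FormatError(
                f"mRNA {f.attributes['ID'][0]} has no resolvable parent gene"
            )
        tid = f.attributes["ID"][0]
        segs = tuple(
            sorted((c.start, c.end) for c in db.children(f, featuretype="CDS"))
        )
        transcripts.append(TranscriptFeature(tid, parent, segs))

    for g in genes:
        chrom_lengths.setdefault(g.chromosome, 0)
        chrom_lengths[g.chromosome] = max(chrom_lengths[g.chromosome], g.end)

    return GenomeAnnotation(
        species=species,
        chromosomes=sorted(chrom_lengths.items()),
        genes=genes,
        transcripts=transcripts,
    )


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize a :class:`GenomeAnnotation` back to GFF3."""
    lines = ["##gff-version 3"]
    for chrom, length in annotation.chromosomes:
        lines.append(f"##sequence-region {chrom} 1 {length}")
    by_gene: dict[str, list[TranscriptFeature]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for g in sorted(annotation.genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
        attrs = f"ID={g.gene_id}"
        if g.name:
            attrs += f";Name={g.name}"
        lines.append(
            f"{g.chromosome}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for t in sorted(by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
            t_start = min((s for s, _ in t.cds_segments), default=g.start)
            t_end = max((e for _, e in t.cds_segments), default=g.end)
            lines.append(
                f"{g.chromosome}\t.\tmRNA\t{t_start}\t{t_end}\t.\t{g.strand}\t.\t"
                f"ID={t.transcript_id};Parent={g.gene_id}"
            )
            for s, e in t.cds_segments:
                lines.append(
                    f"{g.chromosome}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def select_longest_isoform(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Keep one transcript per gene: greatest total CDS length, ties broken
    by lexicographically smallest transcript ID.  Idempotent."""
    by_gene: dict[str, list[TranscriptFeature]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    kept: list[TranscriptFeature] = []
    for g in annotation.genes:
        ts = by_gene.get(g.gene_id)
        if not ts:
            logger.warning("gene %s has no transcript; kept without one", g.gene_id)
            continue
        kept.append(min(ts, key=lambda t: (-t.cds_length, t.transcript_id)))
    return GenomeAnnotation(
        species=annotation.species,
        chromosomes=list(annotation.chromosomes),
        genes=list(annotation.genes),
        transcripts=kept,
    )


# ---------------------------------------------------------------------------
# Orthogroups (OrthoFinder Orthogroups.tsv layout)
# ---------------------------------------------------------------------------


def read_orthogroups(path: str | Path) -> OrthogroupSet:
    """TSV: first column orthogroup ID, one column per species, cells of
    comma-separated gene IDs (possibly empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        sp_map: dict[str, list[str]] = {}
        for sp in species:
            genes = [g.strip() for g in row[sp].split(",") if g.strip()]
            if genes:
                sp_map[sp] = genes
        groups[row[og_col]] = sp_map
    return OrthogroupSet(groups)


def write_orthogroups(
    ogs: OrthogroupSet, path: str | Path, species: Sequence[str] | None = None
) -> None:
    species = list(species) if species is not None else ogs.species
    rows = []
    for og in sorted(ogs.groups):
        row = {"Orthogroup": og}
        for sp in species:
            row[sp] = ", ".join(ogs.groups[og].get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Collinearity files (MCScanX .collinearity layout)
# ---------------------------------------------------------------------------

_BLOCK_HEADER_RE = re.compile(
    r"^##\s*Alignment\s+(\S+):\s*score=(\S+)\s+e_value=(\S+)\s+N=(\d+)\s+"
    r"(\S+)&(\S+)\s+(\S+)"
)


def read_collinearity(path: str | Path):
    """Parse an MCScanX-style collinearity file into SyntenyBlock objects.

    Each block header ``## Alignment k: score=.. e_value=.. N=n chrA&chrB
    plus|minus`` must be followed by exactly ``n`` gene-pair lines.
    """
    from .structural import SyntenyBlock  # local import to avoid a cycle

    blocks: list[SyntenyBlock] = []
    header: re.Match | None = None
    pairs: list[tuple[str, str]] = []

    def flush() -> None:
        nonlocal header, pairs
        if header is None:
            return
        n = int(header.group(4))
        if len(pairs) != n:
            raise FormatError(
                f"block {header.group(1)}: header says N={n} "
                f"but {len(pairs)} pair lines found"
            )
        orientation = header.group(7)
        if orientation not in ("plus", "minus"):
            raise FormatError(f"unknown orientation token {orientation!r}")
        blocks.append(
            SyntenyBlock(
                block_id=f"block_{header.group(1)}",
                chromosome_a=header.group(5),
                chromosome_b=header.group(6),
                orientation=orientation,
                pairs=tuple(pairs),
                score=float(header.group(2)),
            )
        )
        header, pairs = None, []

    for line in Path(path).read_text().splitlines():
        m = _BLOCK_HEADER_RE.match(line)
        if m:
            flush()
            header = m
        elif line.startswith("#") or not line.strip():
            continue
        else:
            fields = line.replace(":", "\t").split()
            # pair lines look like "k-i:  geneA  geneB  e-value"
            genes = [f for f in fields if not re.fullmatch(r"[\d\-eE.+]+:?", f)]
            if len(genes) < 2:
                raise FormatError(f"unparseable pair line: {line!r}")
            pairs.append((genes[0], genes[1]))
    flush()
    return blocks


def write_collinearity(blocks, path: str | Path) -> None:
    lines = ["## MCScanX-style collinearity"]
    for i, b in enumerate(blocks):
        lines.append(
            f"## Alignment {i}: score={b.score or 0:.1f} e_value=0 "
            f"N={len(b.pairs)} {b.chromosome_a}&{b.chromosome_b} {b.orientation}"
        )
        for j, (ga, gb) in enumerate(b.pairs):
            lines.append(f"{i}-{j}:\t{ga}\t{gb}\t0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------

#: Default CSV column names; callers can remap since upstream QTL tables
#: are hand-curated and column naming varies between sources.
QTL_COLUMNS = {
    "qtl_id": "qtl_id",
    "trait": "trait",
    "study_type": "study_type",
    "chromosome": "chromosome",
    "flank_left": "flank_left",
    "flank_right": "flank_right",
    "peak": "peak",
    "population": "population",
    "site": "site",
    "reference": "reference",
}

_STUDY_TYPES = {
    "biparental": "biparental",
    "biparental population": "biparental",
    "qtl mapping": "biparental",
    "diversity panel": "diversity panel",
    "gwas": "diversity panel",
}


def read_qtl_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[QTLRecord]:
    """Read curated QTL records from CSV.

    The identifier, trait name, study type, chromosome and at least one
    marker are mandatory; records failing validation are rejected with a
    logged reason rather than aborting the whole load.
    """
    cols = dict(QTL_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str)
    records: list[QTLRecord] = []
    for idx, row in df.iterrows():
        def get(key: str) -> str | None:
            col = cols[key]
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) or str(v).strip() == "" else str(v).strip()

        def get_pos(key: str) -> int | None:
            v = get(key)
            return None if v is None else int(float(v))

        try:
            qtl_id, trait, chrom = get("qtl_id"), get("trait"), get("chromosome")
            if not qtl_id or not trait or not chrom:
                raise FormatError("missing mandatory field")
            raw_type = (get("study_type") or "").lower()
            if raw_type not in _STUDY_TYPES:
                raise FormatError(f"unknown study type {raw_type!r}")
            records.append(
                QTLRecord(
                    qtl_id=qtl_id,
                    trait=trait,
                    study_type=_STUDY_TYPES[raw_type],
                    chromosome=chrom,
                    flank_left=get_pos("flank_left"),
                    flank_right=get_pos("flank_right"),
                    peak=get_pos("peak"),
                    population=get("population"),
                    site=get("site"),
                    reference=get("reference"),
                )
            )
        except (FormatError, ValueError) as exc:
            logger.warning("QTL row %d rejected: %s", idx, exc)
    return records


def write_qtl_table(records: Sequence[QTLRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "qtl_id": r.qtl_id,
                "trait": r.trait,
                "study_type": r.study_type,
                "chromosome": r.chromosome,
                "flank_left": r.flank_left,
                "flank_right": r.flank_right,
                "peak": r.peak,
                "population": r.population,
                "site": r.site,
                "reference": r.reference,
            }
        )
    df = pd.DataFrame(rows, columns=list(QTL_COLUMNS))
    for c in ("flank_left", "flank_right", "peak"):
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression matrices and condition metadata
# ---------------------------------------------------------------------------


def read_expression_matrix(
    tpm_path: str | Path, counts_path: str | Path | None = None
) -> ExpressionMatrix:
    """Gene x sample TSV of TPM values, optionally paired with counts."""
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    counts = (
        pd.read_csv(counts_path, sep="\t", index_col=0)
        if counts_path is not None
        else None
    )
    return ExpressionMatrix(tpm, counts)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    tpm_path: str | Path,
    counts_path: str | Path | None = None,
) -> None:
    matrix.tpm.rename_axis("gene_id").to_csv(tpm_path, sep="\t")
    if counts_path is not None and matrix.counts is not None:
        matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")


def read_condition_metadata(
    path: str | Path, matrix: ExpressionMatrix | None = None
) -> list[ConditionAnnotation]:
    """Sample metadata TSV: one row per sample with its condition and the
    PO/PECO terms the condition is annotated with.

    Every sample must belong to exactly one condition; a metadata sample
    absent from ``matrix`` (when given) only triggers a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    seen_samples: dict[str, str] = {}
    agg: dict[str, dict] = {}
    for _, row in df.iterrows():
        cond, sample = row["condition_id"], row["sample_id"]
        if sample in seen_samples and seen_samples[sample] != cond:
            raise FormatError(
                f"sample {sample} assigned to two conditions "
                f"({seen_samples[sample]}, {cond})"
            )
        seen_samples[sample] = cond
        if matrix is not None and sample not in matrix.samples:
            logger.warning("sample %s not present in expression matrix", sample)
        entry = agg.setdefault(
            cond,
            {"samples": [], "po": row.get("po_terms", ""), "peco": row.get("peco_terms", ""), "area": row.get("area", "")},
        )
        entry["samples"].append(sample)
    out = []
    for cond, entry in agg.items():
        out.append(
            ConditionAnnotation(
                condition_id=cond,
                samples=tuple(entry["samples"]),
                po_terms=tuple(t for t in entry["po"].split(";") if t),
                peco_terms=tuple(t for t in entry["peco"].split(";") if t),
                area=entry["area"] or None,
            )
        )
    return out


def write_condition_metadata(
    conditions: Sequence[ConditionAnnotation], path: str | Path
) -> None:
    rows = []
    for c in conditions:
        for s in c.samples:
            rows.append(
                {
                    "sample_id": s,
                    "condition_id": c.condition_id,
                    "po_terms": ";".join(c.po_terms),
                    "peco_terms": ";".join(c.peco_terms),
                    "area": c.area or "",
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "condition_id", "po_terms", "peco_terms", "area"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------


def read_obo(path: str | Path, source: str | None = None) -> Ontology:
    """Load an OBO 1.4 ontology; acyclicity is verified on load."""
    graph = obonet.read_obo(str(path))
    if source is None:
        ns = graph.graph.get("ontology", "")
        source = str(ns).upper() or "ONTOLOGY"
    terms = {t: data.get("name", t) for t, data in graph.nodes(data=True)}
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key in Ontology.PREDICATES:
            edges.append((child, parent, key))
    return Ontology(source=source, terms=terms, edges=edges)


def write_obo(ontology: Ontology, path: str | Path) -> None:
    lines = ["format-version: 1.4", f"ontology: {ontology.source.lower()}", ""]
    by_term: dict[str, list[tuple[str, str]]] = {}
    for child, parent, pred in ontology.edges:
        by_term.setdefault(child, []).append((pred, parent))
    for term in sorted(ontology.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {ontology.terms[term]}")
        for pred, parent in sorted(by_term.get(term, [])):
            if pred == "is_a":
                lines.append(f"is_a: {parent} ! {ontology.terms[parent]}")
            else:
                lines.append(
                    f"relationship: part_of {parent} ! {ontology.terms[parent]}"
                )
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Functional annotation tables
# ---------------------------------------------------------------------------


def read_functional_annotations(path: str | Path) -> list[FunctionalAnnotationRecord]:
    """TSV of functional annotation assignments (one record per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    def opt_int(v: str) -> int | None:
        return None if v == "" else int(float(v))

    records = []
    for _, row in df.iterrows():
        records.append(
            FunctionalAnnotationRecord(
                subject_id=row["subject_id"],
                source_db=row["source_db"],
                accession=row["accession"],
                description=row.get("description", ""),
                domain_start=opt_int(row.get("domain_start", "")),
                domain_end=opt_int(row.get("domain_end", "")),
                is_hidden=opt_int(row.get("is_hidden", "")),
            )
        )
    return records


def write_functional_annotations(
    records: Sequence[FunctionalAnnotationRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "source_db": r.source_db,
                "accession": r.accession,
                "description": r.description,
                "domain_start": "" if r.domain_start is None else r.domain_start,
                "domain_end": "" if r.domain_end is None else r.domain_end,
                "is_hidden": "" if r.is_hidden is None else r.is_hidden,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "source_db",
            "accession",
            "description",
            "domain_start",
            "domain_end",
            "is_hidden",
        ],
    ).to_csv(path, sep="\t", index=False)
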