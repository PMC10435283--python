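"""Synthetic multi-species dataset generators.

Two generators are provided:

* :func:`generate_toy_dataset` — parameterized random genomes with planted
  collinear segments, a planted QTL, planted expression conditions and
  mini-ontologies.  Every planted truth is recorded in the returned
  :class:`FixtureManifest` and is re-derivable from the emitted files by a
  brute-force oracle.

* :func:`generate_fta1_fixture` — a hand-shaped reconstruction of the
  flowering-time use case: the *FTa1* orthogroup of *Medicago truncatula*
  (*MtFTa1*), pea, lentil and faba bean, collinear chromosome regions on
  Mt07/Ps03/Lc06/Vf05, eight flowering-related QTL placed inside the
  syntenic spans (only ``qDTF.6-2_1`` containing the lentil ortholog in its
  confidence interval), a Plant Ontology mini-hierarchy under
  "shoot system", and expression data placing *MtFTa1* highest in
  vegetative shoot apex conditions.

All randomness flows from the single explicit seed; identical seeds yield
byte-identical file trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    ConditionAnnotation,
    FunctionalAnnotationRecord,
    GeneFeature,
    GenomeAnnotation,
    Ontology,
    OrthogroupSet,
    QTLRecord,
    TranscriptFeature,
)
from .structural import SyntenyBlock

__all__ = ["FixtureManifest", "generate_toy_dataset", "generate_fta1_fixture"]

DATASET_FILE = "dataset.json"


@dataclass
class FixtureManifest:
    """Planted ground truth of a generated dataset."""

    seed: int
    directory: Path
    species: list[str]
    files: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)

    def dataset_description(self) -> dict:
        return {"species": self.species, "files": self.files}

    def write_dataset_json(self) -> Path:
        path = self.directory / DATASET_FILE
        path.write_text(json.dumps(self.dataset_description(), indent=1, sort_keys=True))
        return path


def _write_dataset(
    out_dir: Path,
    seed: int,
    species: list[str],
    annotations: dict[str, GenomeAnnotation],
    conversions: dict[str, dict[str, str]],
    orthogroups: OrthogroupSet,
    qtls: list[QTLRecord],
    tpm: pd.DataFrame,
    counts: pd.DataFrame,
    conditions: list[ConditionAnnotation],
    ontologies: dict[str, Ontology],
    annotations_records: list[FunctionalAnnotationRecord],
    blocks: list[SyntenyBlock] | None,
    planted: dict,
) -> FixtureManifest:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict = {"gff3": {}, "chromosome_conversion": {}, "ontologies": {}}
    for sp in species:
        # GFF3 carries the *original* chromosome IDs; the conversion table
        # renames them to database-wide unique IDs at load time.
        original = annotations[sp]
        inverse = {v: k for k, v in conversions[sp].items()}
        raw = GenomeAnnotation(
            species=sp,
            chromosomes=[(inverse[c], l) for c, l in original.chromosomes],
            genes=[
                GeneFeature(g.gene_id, inverse[g.chromosome], g.start, g.end, g.strand, g.name)
                for g in original.genes
            ],
            transcripts=list(original.transcripts),
        )
        gff = f"{sp}.gff3"
        conv = f"{sp}.chrom_map.tsv"
        iof.write_gff3(raw, out_dir / gff)
        (out_dir / conv).write_text(
            "".join(f"{old}\t{new}\n" for old, new in sorted(conversions[sp].items()))
        )
        files["gff3"][sp] = gff
        files["chromosome_conversion"][sp] = conv
    iof.write_orthogroups(orthogroups, out_dir / "orthogroups.tsv", species=species)
    files["orthogroups"] = "orthogroups.tsv"
    iof.write_qtl_table(qtls, out_dir / "qtl.csv")
    files["qtl"] = "qtl.csv"
    matrix = iof.ExpressionMatrix(tpm, counts)
    iof.write_expression_matrix(matrix, out_dir / "tpm.tsv", out_dir / "counts.tsv")
    files["tpm"] = "tpm.tsv"
    files["counts"] = "counts.tsv"
    iof.write_condition_metadata(conditions, out_dir / "conditions.tsv")
    files["conditions"] = "conditions.tsv"
    for source, onto in ontologies.items():
        fname = f"{source.lower()}.obo"
        iof.write_obo(onto, out_dir / fname)
        files["ontologies"][source] = fname
    iof.write_functional_annotations(annotations_records, out_dir / "annotations.tsv")
    files["functional_annotations"] = "annotations.tsv"
    if blocks is not None:
        iof.write_collinearity(blocks, out_dir / "collinearity.txt")
        files["collinearity"] = "collinearity.txt"
    manifest = FixtureManifest(
        seed=seed, directory=out_dir, species=species, files=files, planted=planted
    )
    manifest.write_dataset_json()
    return manifest


# ---------------------------------------------------------------------------
# Mini-ontologies shared by both generators
# ---------------------------------------------------------------------------


def _mini_po() -> Ontology:
    terms = {
        "PO:0009006": "shoot system",
        "PO:0000037": "shoot apex",
        "PO:0004715": "vegetative shoot apex",
        "PO:0008016": "reproductive shoot apex",
        "PO:0025607": "vegetative shoot system",
        "PO:0009047": "stem",
        "PO:0009053": "peduncle",
        "PO:0025034": "leaf",
        "PO:0009025": "vascular leaf",
        "PO:0025361": "leaf tendril",
        "PO:0009001": "pod",
        "PO:0025025": "root system",
        "PO:0009005": "root",
    }
    edges = [
        ("PO:0000037", "PO:0009006", "is_a"),
        ("PO:0004715", "PO:0000037", "is_a"),
        ("PO:0008016", "PO:0000037", "is_a"),
        ("PO:0025607", "PO:0009006", "is_a"),
        ("PO:0009047", "PO:0009006", "is_a"),
        ("PO:0009053", "PO:0009047", "is_a"),
        ("PO:0025034", "PO:0009006", "is_a"),
        ("PO:0009025", "PO:0025034", "is_a"),
        ("PO:0025361", "PO:0025034", "is_a"),
        ("PO:0009001", "PO:0009006", "part_of"),
        ("PO:0009005", "PO:0025025", "is_a"),
    ]
    return Ontology("PO", terms, edges)


def _mini_peco() -> Ontology:
    terms = {
        "PECO:0001000": "plant exposure",
        "PECO:0007203": "far-red light regimen",
        "PECO:0007189": "control exposure",
    }
    edges = [
        ("PECO:0007203", "PECO:0001000", "is_a"),
        ("PECO:0007189", "PECO:0001000", "is_a"),
    ]
    return Ontology("PECO", terms, edges)


def _mini_go() -> Ontology:
    terms = {
        "GO:0008150": "biological_process",
        "GO:0032502": "developmental process",
        "GO:0009908": "flower development",
        "GO:0009909": "regulation of flower development",
        "GO:0006950": "response to stress",
    }
    edges = [
        ("GO:0032502", "GO:0008150", "is_a"),
        ("GO:0009908", "GO:0032502", "is_a"),
        ("GO:0009909", "GO:0009908", "is_a"),
        ("GO:0006950", "GO:0008150", "is_a"),
    ]
    return Ontology("GO", terms, edges)


# ---------------------------------------------------------------------------
# Toy generator
# ---------------------------------------------------------------------------


def _make_transcript(gene: GeneFeature) -> TranscriptFeature:
    mid = (gene.start + gene.end) // 2
    segs = ((gene.start, mid - 1), (mid + 1, gene.end))
    return TranscriptFeature(f"{gene.gene_id}.t1", gene.gene_id, segs)


def generate_toy_dataset(
    out_dir: str | Path,
    n_species: int = 3,
    genes_per_chromosome: int = 60,
    n_blocks: int = 1,
    noise_rate: float = 0.1,
    seed: int = 0,
    block_length: int = 12,
    segment_separation: int = 30,
    n_shuffled_orthogroups: int = 0,
) -> FixtureManifest:
    """Generate a fully synthetic dataset with planted truths.

    Each species has one chromosome.  ``n_blocks`` collinear segments of
    ``block_length`` orthologous genes are laid down in identical order in
    every species; after each collinear gene a species-private noise gene
    is inserted with probability ``noise_rate``, and consecutive segments
    are separated by ``segment_separation`` private genes (more than the
    detector's default rank gap, so segments cannot merge).
    ``n_shuffled_orthogroups`` adds cross-species gene families placed in an
    *independently shuffled* order per species — shared content without
    conserved order, i.e. homology noise that should never assemble into a
    block of the default minimum size.  Remaining slots up to
    ``genes_per_chromosome`` are filled with private genes.
    """
    if not (0 <= noise_rate < 1):
        raise ValueError("noise_rate must be in [0, 1)")
    if n_species < 1 or genes_per_chromosome < 1 or block_length < 2:
        raise ValueError("infeasible configuration")
    min_needed = n_blocks * block_length + max(0, n_blocks - 1) * segment_separation
    if min_needed + n_shuffled_orthogroups > genes_per_chromosome:
        raise ValueError(
            f"configuration infeasible: needs {min_needed + n_shuffled_orthogroups} "
            f"slots but genes_per_chromosome={genes_per_chromosome}"
        )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    species = [f"sp{i + 1}" for i in range(n_species)]

    # orthogroup layout
    segment_ogs = [
        [f"OGS{b:02d}{j:03d}" for j in range(block_length)] for b in range(n_blocks)
    ]
    shuffled_ogs = [f"OGN{j:03d}" for j in range(n_shuffled_orthogroups)]

    og_members: dict[str, dict[str, list[str]]] = {
        og: {} for og in [*(o for seg in segment_ogs for o in seg), *shuffled_ogs]
    }
    annotations: dict[str, GenomeAnnotation] = {}
    conversions: dict[str, dict[str, str]] = {}
    planted_segments: list[dict] = []
    per_species_segment_genes: dict[int, dict[str, list[str]]] = {
        b: {} for b in range(n_blocks)
    }

    for sp in species:
        chrom = f"{sp}Chr1"
        conversions[sp] = {"chr1": chrom}
        # slot sequence: (kind, payload)
        slots: list[tuple[str, object]] = []
        for b in range(n_blocks):
            if b > 0:
                slots.extend(("noise", None) for _ in range(segment_separation))
            for og in segment_ogs[b]:
                slots.append(("og", (b, og)))
                if rng.random() < noise_rate:
                    slots.append(("noise", None))
        order = rng.permutation(len(shuffled_ogs))
        for idx in order:
            slots.append(("og", (None, shuffled_ogs[idx])))
        while len(slots) < genes_per_chromosome:
            slots.append(("noise", None))

        genes: list[GeneFeature] = []
        transcripts: list[TranscriptFeature] = []
        for pos, (kind, payload) in enumerate(slots):
            start = 1000 + pos * 2000
            length = int(rng.integers(600, 1400))
            gene = GeneFeature(
                gene_id=f"{sp}g{pos:04d}",
                chromosome=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
            genes.append(gene)
            transcripts.append(_make_transcript(gene))
            if kind == "og":
                b, og = payload  # type: ignore[misc]
                og_members[og].setdefault(sp, []).append(gene.gene_id)
                if b is not None:
                    per_species_segment_genes[b].setdefault(sp, []).append(gene.gene_id)
        annotations[sp] = GenomeAnnotation(
            species=sp,
            chromosomes=[(chrom, 1000 + len(slots) * 2000)],
            genes=genes,
            transcripts=transcripts,
        )

    for b in range(n_blocks):
        planted_segments.append(
            {
                "orthogroups": segment_ogs[b],
                "genes": per_species_segment_genes[b],
                "expected_pairs": block_length,
            }
        )
    orthogroups = OrthogroupSet(og_members)

    # planted QTL over genes 5..9 of species 1 (slot positions are bp-determined)
    sp1 = species[0]
    sp1_genes = annotations[sp1].genes
    lo_gene, hi_gene = sp1_genes[5], sp1_genes[9]
    qtl = QTLRecord(
        qtl_id="toyQTL_1",
        trait="days to flowering",
        study_type="biparental",
        chromosome=f"{sp1}Chr1",
        flank_left=lo_gene.start - 10,
        flank_right=hi_gene.end + 10,
        peak=(sp1_genes[7].start + sp1_genes[7].end) // 2,
        population="toy_population",
        site="toy_site",
    )
    gwas = QTLRecord(
        qtl_id="toyGWAS_1",
        trait="seed weight",
        study_type="diversity panel",
        chromosome=f"{sp1}Chr1",
        peak=(sp1_genes[12].start + sp1_genes[12].end) // 2,
    )
    qtls = [qtl, gwas]
    planted_coloc = {
        "toyQTL_1": [g.gene_id for g in sp1_genes[5:10]],
        "toyGWAS_1": [sp1_genes[12].gene_id],
    }

    # expression: two tissue conditions x two samples, all genes
    all_genes = [g.gene_id for sp in species for g in annotations[sp].genes]
    samples = ["S_leaf_1", "S_leaf_2", "S_root_1", "S_root_2"]
    tpm = pd.DataFrame(
        np.round(rng.lognormal(mean=1.5, sigma=1.0, size=(len(all_genes), 4)), 3),
        index=pd.Index(all_genes, name="gene_id"),
        columns=samples,
    )
    # plant two below-threshold genes (row sum <= 5) as filter ground truth
    low_genes = [annotations[sp1].genes[0].gene_id, annotations[sp1].genes[1].gene_id]
    tpm.loc[low_genes[0]] = [1.0, 1.0, 1.0, 1.0]
    tpm.loc[low_genes[1]] = [5.0, 0.0, 0.0, 0.0]
    counts = np.round(tpm * rng.integers(20, 40), 0).astype(int)
    conditions = [
        ConditionAnnotation(
            "cond_leaf", ("S_leaf_1", "S_leaf_2"), ("PO:0025034",), ("PECO:0007189",), "greenhouse"
        ),
        ConditionAnnotation(
            "cond_root", ("S_root_1", "S_root_2"), ("PO:0009005",), ("PECO:0007189",), "greenhouse"
        ),
    ]

    # functional annotations: 100 GO records, exactly 90 flagged as hidden
    hidden_flags = np.array([1] * 90 + [0] * 10)
    rng.shuffle(hidden_flags)
    go_terms = ["GO:0008150", "GO:0032502", "GO:0009908", "GO:0009909", "GO:0006950"]
    fa_records: list[FunctionalAnnotationRecord] = []
    for i in range(100):
        gene = all_genes[int(rng.integers(0, len(all_genes)))]
        fa_records.append(
            FunctionalAnnotationRecord(
                subject_id=gene,
                source_db="GO",
                accession=go_terms[int(rng.integers(0, len(go_terms)))],
                description="",
                is_hidden=int(hidden_flags[i]),
            )
        )
    for g in sp1_genes[5:8]:
        fa_records.append(
            FunctionalAnnotationRecord(
                subject_id=f"{g.gene_id}.t1.p",
                source_db="PANTHER",
                accession="PTHR00000",
                description="TOY PROTEIN FAMILY",
                domain_start=1,
                domain_end=100,
            )
        )

    # planted segments doubled as a ready-made collinearity file, so the
    # detector-free ingest path can be exercised on the same ground truth
    blocks: list[SyntenyBlock] = []
    counter = 0
    for ia, sp_a in enumerate(species):
        for sp_b in species[ia + 1 :]:
            for b in range(n_blocks):
                genes_a = per_species_segment_genes[b].get(sp_a, [])
                genes_b = per_species_segment_genes[b].get(sp_b, [])
                if not genes_a or not genes_b:
                    continue
                counter += 1
                blocks.append(
                    SyntenyBlock(
                        block_id=f"planted_{counter}",
                        chromosome_a=f"{sp_a}Chr1",
                        chromosome_b=f"{sp_b}Chr1",
                        orientation="plus",
                        pairs=tuple(zip(genes_a, genes_b)),
                    )
                )

    planted = {
        "segments": planted_segments,
        "colocalizations": planted_coloc,
        "low_expression_genes": low_genes,
        "condition_tissues": {"cond_leaf": "PO:0025034", "cond_root": "PO:0009005"},
        "n_go_records": 100,
        "n_go_hidden": 90,
    }
    return _write_dataset(
        out_dir,
        seed,
        species,
        annotations,
        conversions,
        orthogroups,
        qtls,
        tpm,
        counts,
        conditions,
        {"PO": _mini_po(), "PECO": _mini_peco(), "GO": _mini_go()},
        fa_records,
        blocks,
        planted,
    )


# ---------------------------------------------------------------------------
# FTa1 use-case reconstruction
# ---------------------------------------------------------------------------

FTA1_GENES = {
    "mtru": "MtrunA17Chr7_39606925_39618489",
    "psat": ("Psat3g090680", "Psat3g090720"),  # tandem pair; 090720 is FTa1
    "lcul": "Lcu.2RBY.6g043850",
    "vfab": "Vfaba.Hedin2.R1.5g087000",
}

FTA1_ORTHOGROUP = "OG0001618"

_N_SLOTS = 20
_FTA1_SLOT = 10

_LAYOUT = {
    # species: (chromosome, region start, gene spacing, gene length)
    "mtru": ("Mt07", 39_406_925, 20_000, 12_000),
    "psat": ("Ps03", 40_000_000, 100_000, 4_000),
    "lcul": ("Lc06", 330_000_000, 80_000, 3_500),
    "vfab": ("Vf05", 1_200_000_000, 150_000, 5_000),
}

_ORIGINAL_CHROM = {"mtru": "chr7", "psat": "chr3", "lcul": "chr6", "vfab": "chr5"}

FLOWERING_QTL_IDS = (
    "DF50_09-10(2)_1",
    "DF1_07-08(3)_1",
    "DF1_06-07(2)_1",
    "PR15_26_1",
    "DTF3_1",
    "DTF3_3",
    "qDTF.6-2_1",
    "qDTFL-6A_1",
)


def _psat_gene_id(slot: int) -> str:
    # the FTa1 slot holds the tandem pair 090680/090720, so the numbering
    # shifts by one position past it
    base = 90280 + 40 * slot if slot < _FTA1_SLOT else 90320 + 40 * slot
    return f"Psat3g{base:06d}"


def _lcul_gene_id(slot: int) -> str:
    return f"Lcu.2RBY.6g{43750 + 10 * slot:06d}"


def _vfab_gene_id(slot: int) -> str:
    return f"Vfaba.Hedin2.R1.5g{86600 + 40 * slot:06d}"


def generate_fta1_fixture(out_dir: str | Path, seed: int = 0) -> FixtureManifest:
    """Reconstruct the flowering-time use case as a synthetic dataset.

    Twenty orthologous gene slots are laid out collinearly on Mt07, Ps03,
    Lc06 and Vf05; the *FTa1* family occupies slot 10 and in pea comprises
    the adjacent tandem pair *Psat3g090680*/*Psat3g090720*.  Flowering QTL
    are placed inside the syntenic spans so that only ``qDTF.6-2_1``
    contains the lentil ortholog in its confidence interval; one additional
    flowering QTL far outside any block and one non-flowering QTL act as
    negative controls for the query filters.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    species = ["mtru", "psat", "lcul", "vfab"]

    slot_names = {_FTA1_SLOT: "FTa1"}
    og_ids = {s: (FTA1_ORTHOGROUP if s == _FTA1_SLOT else f"OG{1000 + s:07d}") for s in range(_N_SLOTS)}

    annotations: dict[str, GenomeAnnotation] = {}
    conversions: dict[str, dict[str, str]] = {}
    og_members: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids.values()}
    slot_genes: dict[str, dict[int, list[str]]] = {sp: {} for sp in species}

    for sp in species:
        chrom, region_start, spacing, gene_len = _LAYOUT[sp]
        conversions[sp] = {_ORIGINAL_CHROM[sp]: chrom}
        genes: list[GeneFeature] = []
        transcripts: list[TranscriptFeature] = []

        def add_gene(gene_id: str, start: int, end: int, name: str | None = None) -> None:
            g = GeneFeature(gene_id, chrom, start, end, "+" if rng.random() < 0.7 else "-", name)
            genes.append(g)
            transcripts.append(_make_transcript(g))

        def slot_start(slot: int) -> int:
            return region_start + slot * spacing

        # two private flanking genes either side of the collinear region
        for slot in (-2, -1, _N_SLOTS, _N_SLOTS + 1):
            start = slot_start(slot)
            if sp == "mtru":
                gid = f"MtrunA17Chr7_{start}_{start + gene_len}"
            elif sp == "psat":
                gid = _psat_gene_id(slot)
            elif sp == "lcul":
                gid = _lcul_gene_id(slot)
            else:
                gid = _vfab_gene_id(slot)
            add_gene(gid, start, start + gene_len)

        for slot in range(_N_SLOTS):
            start = slot_start(slot)
            name = slot_names.get(slot)
            if sp == "mtru":
                if slot == _FTA1_SLOT:
                    gid, end = FTA1_GENES["mtru"], 39_618_489
                    start = 39_606_925
                else:
                    gid, end = f"MtrunA17Chr7_{start}_{start + gene_len}", start + gene_len
                add_gene(gid, start, end, name)
                og_members[og_ids[slot]].setdefault(sp, []).append(gid)
                slot_genes[sp].setdefault(slot, []).append(gid)
            elif sp == "psat":
                if slot == _FTA1_SLOT:
                    # adjacent tandem duplicates of the FTa1 family
                    for gid, offset, nm in (
                        ("Psat3g090680", 0, "FTa2"),
                        ("Psat3g090720", 40_000, "FTa1"),
                    ):
                        add_gene(gid, start + offset, start + offset + gene_len, nm)
                        og_members[og_ids[slot]].setdefault(sp, []).append(gid)
                        slot_genes[sp].setdefault(slot, []).append(gid)
                else:
                    gid = _psat_gene_id(slot)
                    add_gene(gid, start, start + gene_len, name)
                    og_members[og_ids[slot]].setdefault(sp, []).append(gid)
                    slot_genes[sp].setdefault(slot, []).append(gid)
            else:
                gid = _lcul_gene_id(slot) if sp == "lcul" else _vfab_gene_id(slot)
                add_gene(gid, start, start + gene_len, name)
                og_members[og_ids[slot]].setdefault(sp, []).append(gid)
                slot_genes[sp].setdefault(slot, []).append(gid)

        genes_sorted = sorted(genes, key=lambda g: g.start)
        chrom_len = genes_sorted[-1].end + spacing
        annotations[sp] = GenomeAnnotation(
            species=sp,
            chromosomes=[(chrom, chrom_len)],
            genes=genes_sorted,
            transcripts=transcripts,
        )
    orthogroups = OrthogroupSet(og_members)

    # ----- QTL ------------------------------------------------------------
    def span(sp: str, slot_lo: int, slot_hi: int, pad: int = 5_000) -> tuple[int, int]:
        chrom, region_start, spacing, gene_len = _LAYOUT[sp]
        return region_start + slot_lo * spacing - pad, region_start + slot_hi * spacing + gene_len + pad

    vf_lo, vf_hi = span("vfab", 2, 5)
    ps_lo1, ps_hi1 = span("psat", 0, 3)
    ps_lo2, ps_hi2 = span("psat", 6, 9)
    lc_lo, lc_hi = span("lcul", 9, 11)
    ps_npc_lo, ps_npc_hi = span("psat", 5, 7)

    lcul_fta1 = FTA1_GENES["lcul"]
    lcul_fta1_start = _LAYOUT["lcul"][1] + _FTA1_SLOT * _LAYOUT["lcul"][2]

    qtls = [
        QTLRecord("DF50_09-10(2)_1", "days to 50% flowering", "biparental", "Vf05",
                  vf_lo, vf_hi, population="Vf_RIL_1", site="field_station_1"),
        QTLRecord("DF1_07-08(3)_1", "days to first flower", "biparental", "Vf05",
                  vf_lo, vf_hi, population="Vf_RIL_1", site="field_station_1"),
        QTLRecord("DF1_06-07(2)_1", "days to first flower", "biparental", "Vf05",
                  vf_lo, vf_hi, population="Vf_RIL_1", site="field_station_1"),
        QTLRecord("PR15_26_1", "days to flowering", "biparental", "Ps03",
                  ps_lo1, ps_hi1, population="Ps_RIL_1", site="field_station_2"),
        QTLRecord("DTF3_1", "days to flowering", "biparental", "Ps03",
                  ps_lo2, ps_hi2, peak=(ps_lo2 + ps_hi2) // 2, population="Ps_RIL_2"),
        QTLRecord("DTF3_3", "nodes to first flower in long days", "biparental", "Ps03",
                  ps_lo2, ps_hi2, peak=(ps_lo2 + ps_hi2) // 2, population="Ps_RIL_2"),
        QTLRecord("qDTF.6-2_1", "days to flowering", "biparental", "Lc06",
                  lc_lo, lc_hi, peak=lcul_fta1_start + 1_000, population="Lc_RIL_1"),
        QTLRecord("qDTFL-6A_1", "days to flowering under low red/far-red", "diversity panel",
                  "Lc06", peak=_LAYOUT["lcul"][1] + 13 * _LAYOUT["lcul"][2] + 500),
        # negative controls: flowering QTL far from any block; non-flowering QTL in-block
        QTLRecord("DTF_Mt_far_1", "days to flowering", "biparental", "Mt07",
                  1_000_000, 1_500_000),
        QTLRecord("SPC_15_1", "seed protein content", "biparental", "Ps03",
                  ps_npc_lo, ps_npc_hi, population="Ps_RIL_1"),
    ]

    # ----- expression -----------------------------------------------------
    condition_setup = [
        # (condition, species, tissue PO, PECO, planted mean TPM of the FTa1 gene)
        ("cond_mt_veg_shoot_apex", "mtru", "PO:0004715", "PECO:0007189", 120.0),
        ("cond_mt_rep_shoot_apex", "mtru", "PO:0008016", "PECO:0007189", 80.0),
        ("cond_mt_veg_shoot_system", "mtru", "PO:0025607", "PECO:0007189", 50.0),
        ("cond_mt_root", "mtru", "PO:0009005", "PECO:0007189", 1.5),
        ("cond_ps_peduncle", "psat", "PO:0009053", "PECO:0007189", 90.0),
        ("cond_ps_stem", "psat", "PO:0009047", "PECO:0007189", 60.0),
        ("cond_ps_tendril", "psat", "PO:0025361", "PECO:0007189", 40.0),
        ("cond_lc_leaf_fr", "lcul", "PO:0025034", "PECO:0007203", 70.0),
        ("cond_lc_leaf_ctrl", "lcul", "PO:0025034", "PECO:0007189", 25.0),
        ("cond_vf_vascular_leaf", "vfab", "PO:0009025", "PECO:0007189", 85.0),
        ("cond_vf_pod", "vfab", "PO:0009001", "PECO:0007189", 55.0),
        ("cond_vf_stem", "vfab", "PO:0009047", "PECO:0007189", 35.0),
    ]
    fta1_by_species = {
        "mtru": [FTA1_GENES["mtru"]],
        "psat": ["Psat3g090720", "Psat3g090680"],
        "lcul": [FTA1_GENES["lcul"]],
        "vfab": [FTA1_GENES["vfab"]],
    }
    all_genes = [g.gene_id for sp in species for g in annotations[sp].genes]
    sample_ids: list[str] = []
    conditions: list[ConditionAnnotation] = []
    tpm = pd.DataFrame(
        0.0, index=pd.Index(all_genes, name="gene_id"), columns=pd.Index([], dtype=str)
    )
    species_genes = {sp: [g.gene_id for g in annotations[sp].genes] for sp in species}
    for cond_id, sp, po_term, peco_term, fta1_mean in condition_setup:
        cond_samples = tuple(f"{cond_id}_r{i + 1}" for i in range(2))
        conditions.append(
            ConditionAnnotation(cond_id, cond_samples, (po_term,), (peco_term,), "growth chamber")
        )
        for s in cond_samples:
            sample_ids.append(s)
            col = pd.Series(0.0, index=tpm.index)
            base = rng.lognormal(mean=1.2, sigma=0.8, size=len(species_genes[sp]))
            col.loc[species_genes[sp]] = np.round(base, 3)
            for gid in fta1_by_species[sp]:
                col.loc[gid] = np.round(fta1_mean * float(np.exp(rng.normal(0, 0.05))), 3)
            tpm[s] = col
    counts = np.round(tpm * 30, 0).astype(int)

    # ----- functional annotations ----------------------------------------
    fa_records: list[FunctionalAnnotationRecord] = []
    for sp in species:
        for gid in fta1_by_species[sp]:
            fa_records.append(
                FunctionalAnnotationRecord(
                    subject_id=f"{gid}.t1.p",
                    source_db="PANTHER",
                    accession="PTHR12565",
                    description="PHOSPHATIDYLETHANOLAMINE-BINDING PROTEIN",
                    domain_start=5,
                    domain_end=170,
                )
            )
            fa_records.append(
                FunctionalAnnotationRecord(
                    subject_id=gid, source_db="GO", accession="GO:0009909",
                    description="regulation of flower development", is_hidden=0,
                )
            )
            fa_records.append(
                FunctionalAnnotationRecord(
                    subject_id=gid, source_db="GO", accession="GO:0008150",
                    description="biological_process", is_hidden=1,
                )
            )

    mt_fta1 = FTA1_GENES["mtru"]
    planted = {
        "fta1_genes": {sp: list(fta1_by_species[sp]) for sp in species},
        "fta1_orthogroup": FTA1_ORTHOGROUP,
        "orthologs_of_mtfta1": sorted(
            set(sum(fta1_by_species.values(), [])) - {mt_fta1}
        ),
        "flowering_qtl": list(FLOWERING_QTL_IDS),
        "qtl_containing_ortholog": {"qDTF.6-2_1": lcul_fta1},
        "top_mtru_shoot_conditions": [
            "cond_mt_veg_shoot_apex",
            "cond_mt_rep_shoot_apex",
            "cond_mt_veg_shoot_system",
        ],
        "n_slots": _N_SLOTS,
    }
    return _write_dataset(
        out_dir,
        seed,
        species,
        annotations,
        conversions,
        orthogroups,
        qtls,
        tpm,
        counts,
        conditions,
        {"PO": _mini_po(), "PECO": _mini_peco(), "GO": _mini_go()},
        fa_records,
        None,
        planted,
    )
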