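"""Readers and writers for genome annotation formats.

GTF (GENCODE dialect, 1-based inclusive) is parsed with :mod:`gffutils`;
repeatMasker ``.out`` and BED6 repeat files are parsed directly (no
established Python parser exists for the ``.out`` dialect).  All records
are converted to the package's 0-based half-open convention at this
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import (
    Gene,
    GenomicInterval,
    LabeledFragment,
    RepeatElement,
    Strand,
)

__all__ = [
    "AnnotatedGenome",
    "read_gtf",
    "write_gtf",
    "read_repeatmasker_out",
    "read_repeat_bed",
    "write_repeat_bed",
    "read_bed6",
    "write_bed6",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "standard_chromosome_filter",
]

#: Default "standard chromosome" filter: reject names with "_" and the
#: usual unplaced/alt/random decorations.  Configurable everywhere it is
#: used, because the canonical chromosome list is assembly-specific.
STANDARD_CHROM_EXCLUDE = re.compile(r"(_|random|alt|Un|hap|fix)", re.IGNORECASE)


def standard_chromosome_filter(chrom: str) -> bool:
    """True for names that look like standard (placed, primary) chromosomes."""
    return STANDARD_CHROM_EXCLUDE.search(chrom) is None


@dataclass
class AnnotatedGenome:
    """Genes, repeats and sequences for one assembly."""

    genes: dict[str, Gene] = field(default_factory=dict)
    repeats: list[RepeatElement] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedGenome):
            return NotImplemented
        return (
            self.genes == other.genes
            and sorted(self.repeats, key=lambda r: (r.interval, r.family))
            == sorted(other.repeats, key=lambda r: (r.interval, r.family))
            and self.sequences == other.sequences
        )


def _gtf_strand(s: str) -> str:
    return s if s in ("+", "-") else Strand.UNSTRANDED


def read_gtf(path: str | Path, standard_chroms_only: bool = False) -> dict[str, Gene]:
    """Load gene models from a GENCODE-dialect GTF.

    Uses gene and exon records only (no transcript model); exons are
    flattened per gene.  1-based inclusive GTF coordinates become 0-based
    half-open internally.
    """
    import copy

    from gffutils import constants

    # explicit GTF dialect: gffutils' per-file dialect inference samples
    # attribute columns and can mis-split multi-attribute lines when most
    # records carry a single attribute
    dialect = copy.deepcopy(constants.dialect)
    dialect.update(
        {
            "fmt": "gtf",
            "quoted GFF2 values": True,
            "keyval separator": " ",
            "field separator": "; ",
            "trailing semicolon": True,
            "order": ["gene_id"],
        }
    )
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        dialect=dialect,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, Gene] = {}
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[GenomicInterval, str]] = {}
    for feat in db.all_features():
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"record without gene_id at {feat.seqid}:{feat.start}")
        if standard_chroms_only and not standard_chromosome_filter(feat.seqid):
            continue
        if feat.end < feat.start:
            raise ValueError(
                f"coordinate inversion at {feat.seqid}:{feat.start}-{feat.end}"
            )
        iv = GenomicInterval(
            feat.seqid, feat.start - 1, feat.end, _gtf_strand(feat.strand)
        )
        if feat.featuretype == "gene":
            biotype = feat.attributes.get(
                "gene_type", feat.attributes.get("gene_biotype", ["protein_coding"])
            )[0]
            meta[gene_id] = (iv, biotype)
        elif feat.featuretype == "exon":
            exons_by_gene.setdefault(gene_id, []).append(iv)
    for gene_id, exons in exons_by_gene.items():
        if gene_id in meta:
            iv, biotype = meta[gene_id]
        else:
            start = min(e.start for e in exons)
            end = max(e.end for e in exons)
            iv = GenomicInterval(exons[0].chrom, start, end, exons[0].strand)
            biotype = "protein_coding"
        genes[gene_id] = Gene(gene_id, iv, exons, biotype)
    return genes


def write_gtf(genes: Iterable[Gene], path: str | Path, source: str = "te_exonize") -> None:
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id)):
            attrs = f'gene_id "{gene.gene_id}"; gene_type "{gene.biotype}";'
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        source,
                        "gene",
                        str(gene.interval.start + 1),
                        str(gene.interval.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for exon in gene.exons:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_repeatmasker_out(path: str | Path) -> list[RepeatElement]:
    """Parse a repeatMasker ``.out`` file.

    Dialect notes: a 3-line header; 1-based inclusive coordinates; strand
    column is ``+`` or ``C`` (complement, mapped to ``-``); the
    repeat class/family column is ``class/family``.
    """
    repeats: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header / blank
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = Strand.MINUS if fields[8] == "C" else Strand.PLUS
                name = fields[9]
                class_family = fields[10]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}") from exc
            if start >= end:
                raise ValueError(f"{path}: coordinate inversion at line {lineno}")
            if "/" in class_family:
                class_name, family = class_family.split("/", 1)
            else:
                class_name, family = class_family, class_family
            _ = name
            repeats.append(
                RepeatElement(GenomicInterval(chrom, start, end, strand), family, class_name)
            )
    return repeats


def read_repeat_bed(path: str | Path) -> list[RepeatElement]:
    """BED6 repeat annotation: name field is ``family`` or ``class/family``."""
    repeats = []
    for iv, name in _iter_bed6(path):
        if "/" in name:
            class_name, family = name.split("/", 1)
        else:
            class_name, family = name, name
        repeats.append(RepeatElement(iv, family, class_name))
    return repeats


def write_repeat_bed(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start)):
            name = (
                f"{rep.class_name}/{rep.family}"
                if rep.class_name and rep.class_name != rep.family
                else rep.family
            )
            iv = rep.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def _iter_bed6(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
            if start >= end:
                raise ValueError(f"{path}: coordinate inversion at line {lineno}")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else Strand.UNSTRANDED
            yield GenomicInterval(fields[0], start, end, strand), name


def read_bed6(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED6 file as (interval, name) pairs, coordinates used natively."""
    return list(_iter_bed6(path))


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_annotation(
    gtf_path: str | Path,
    repeat_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    standard_chroms_only: bool = False,
) -> AnnotatedGenome:
    """Assemble an :class:`AnnotatedGenome` from standard files."""
    genes = read_gtf(gtf_path, standard_chroms_only=standard_chroms_only)
    repeats: list[RepeatElement] = []
    if repeat_path is not None:
        text = Path(repeat_path).name
        if text.endswith(".out"):
            repeats = read_repeatmasker_out(repeat_path)
        else:
            repeats = read_repeat_bed(repeat_path)
    sequences = read_fasta(fasta_path) if fasta_path is not None else {}
    return AnnotatedGenome(genes=genes, repeats=repeats, sequences=sequences)


def write_annotation(genome: AnnotatedGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write a genome to ``out_dir`` as GTF + repeat BED6 (+ FASTA)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "genes.gtf",
        "repeats": out / "repeats.bed",
    }
    write_gtf(genome.genes.values(), paths["gtf"])
    write_repeat_bed(genome.repeats, paths["repeats"])
    if genome.sequences:
        paths["fasta"] = out / "genome.fa"
        write_fasta(genome.sequences, paths["fasta"])
    return paths


def write_fragments(fragments: Iterable[LabeledFragment], path: str | Path) -> None:
    """TSV writer for priority fragments."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tsource_id\thost_gene\tstrand\n")
        for fr in fragments:
            iv = fr.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fr.label}\t{fr.source_id}"
                f"\t{fr.host_gene}\t{iv.strand}\n"
            )
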