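"""SNV records and the VCF dialect that carries their evidence.

The pipeline consumes somatic SNVs annotated with per-caller status, tumor
allele fraction, mate-specific alt read counts, RNA coverage and gene
expression. All of that evidence travels in INFO fields of a VCF 4.x
subset (biallelic SNVs only):

======== ======= ==========================================================
key      type    meaning
======== ======= ==========================================================
CALLERS  String  ``caller:status`` entries joined by ``~`` with status
                 accepted|rejected; callers not listed are treated as absent
AF       Float   tumor-DNA allele fraction in [0, 1]
R1ALT    Integer alt-supporting reads that are read 1 of their pair
R2ALT    Integer alt-supporting reads that are read 2 of their pair
RNADP    Integer RNA-seq read depth covering the position
RNAALT   Integer RNA-seq reads supporting the ALT allele
RNASPAN  Integer RNA-seq reads spanning (but not covering) the position
GEXP     Float   gene-level expression value (metric caller-defined)
GENE     String  gene identifier
TRANSCRIPTS String comma list of transcript identifiers
PPOS     Integer 1-based position of the substituted residue in the protein
PAA      String  protein change as ``ref/alt`` one-letter codes, e.g. R/Q
======== ======= ==========================================================

CALLERS, AF, R1ALT and R2ALT are mandatory; the rest are optional and
recorded as absent (``None``) when missing, never as zero.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

CALLER_NAMES = ("mutect", "muse", "radia", "sniper", "strelka")
MANDATORY_KEYS = ("CALLERS", "AF", "R1ALT", "R2ALT")

_INFO_DEFS = [
    ("CALLERS", "1", "String", "Per-caller status caller:STATUS entries joined by ~ (STATUS is accepted or rejected)"),
    ("AF", "1", "Float", "Tumor DNA allele fraction"),
    ("R1ALT", "1", "Integer", "Alt reads from read 1"),
    ("R2ALT", "1", "Integer", "Alt reads from read 2"),
    ("RNADP", "1", "Integer", "RNA-seq depth at position"),
    ("RNAALT", "1", "Integer", "RNA-seq alt-supporting reads"),
    ("RNASPAN", "1", "Integer", "RNA-seq reads spanning the position"),
    ("GEXP", "1", "Float", "Gene expression value"),
    ("GENE", "1", "String", "Gene identifier"),
    ("TRANSCRIPTS", ".", "String", "Transcript identifiers"),
    ("PPOS", "1", "Integer", "1-based protein position of the substitution"),
    ("PAA", "1", "String", "Protein change ref/alt one-letter codes"),
]

_BASES = set("ACGT")


@dataclasses.dataclass
class VariantRecord:
    """One somatic SNV with the evidence the filter chain judges."""

    chrom: str
    pos: int  # 1-based genomic
    ref_base: str
    alt_base: str
    caller_status: dict[str, str]  # name -> accepted|rejected (absent = missing)
    allele_fraction: float
    alt_read1_count: int
    alt_read2_count: int
    rna_depth: int | None = None
    rna_alt_count: int | None = None
    rna_spanning_reads: int | None = None
    gene_expression: float | None = None
    gene_id: str | None = None
    transcript_ids: tuple[str, ...] = ()
    protein_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.key}: REF equals ALT")
        if not (0.0 <= self.allele_fraction <= 1.0):
            raise ValueError(
                f"{self.key}: allele fraction {self.allele_fraction} "
                "outside [0, 1]"
            )
        for name in ("alt_read1_count", "alt_read2_count", "rna_depth",
                     "rna_alt_count", "rna_spanning_reads"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{self.key}: {name} is negative")
        for status in self.caller_status.values():
            if status not in ("accepted", "rejected"):
                raise ValueError(
                    f"{self.key}: caller status {status!r} not "
                    "accepted|rejected"
                )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref_base}>{self.alt_base}"

    @property
    def is_oxog_consistent(self) -> bool:
        """True for the C>A / G>T substitution classes typical of
        guanine-oxidation library artifacts."""
        return (self.ref_base, self.alt_base) in {("C", "A"), ("G", "T")}


def make_vcf_header(contigs: list[str] | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for key, number, vtype, desc in _INFO_DEFS:
        header.add_meta(
            "INFO",
            items=[("ID", key), ("Number", number), ("Type", vtype),
                   ("Description", desc)],
        )
    for contig in contigs or []:
        header.contigs.add(contig)
    return header


def _parse_callers(raw: str) -> dict[str, str]:
    status: dict[str, str] = {}
    for item in raw.split("~"):
        item = item.strip()
        if not item:
            continue
        name, _, state = item.partition(":")
        status[name.lower()] = state
    return status


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read the VCF subset into VariantRecords.

    Non-SNV rows (indels, MNVs, multi-allelic) are skipped with a logged
    count; a row missing a mandatory INFO key is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            alts = row.alts or ()
            if (len(alts) != 1 or len(row.ref) != 1 or len(alts[0]) != 1
                    or row.ref not in _BASES or alts[0] not in _BASES):
                skipped += 1
                continue
            info = dict(row.info)
            missing = [k for k in MANDATORY_KEYS if k not in info]
            if missing:
                raise ValueError(
                    f"{path}: {row.chrom}:{row.pos} missing mandatory "
                    f"INFO keys {missing}"
                )
            transcripts = info.get("TRANSCRIPTS", ())
            if isinstance(transcripts, str):
                transcripts = (transcripts,)
            paa = info.get("PAA")
            ref_aa = alt_aa = None
            if paa:
                ref_aa, _, alt_aa = str(paa).partition("/")
            records.append(VariantRecord(
                chrom=row.chrom,
                pos=row.pos,
                ref_base=row.ref,
                alt_base=alts[0],
                caller_status=_parse_callers(str(info["CALLERS"])),
                allele_fraction=float(info["AF"]),
                alt_read1_count=int(info["R1ALT"]),
                alt_read2_count=int(info["R2ALT"]),
                rna_depth=(int(info["RNADP"]) if "RNADP" in info else None),
                rna_alt_count=(int(info["RNAALT"]) if "RNAALT" in info
                               else None),
                rna_spanning_reads=(int(info["RNASPAN"]) if "RNASPAN" in info
                                    else None),
                gene_expression=(float(info["GEXP"]) if "GEXP" in info
                                 else None),
                gene_id=info.get("GENE"),
                transcript_ids=tuple(transcripts),
                protein_pos=(int(info["PPOS"]) if "PPOS" in info else None),
                ref_aa=ref_aa or None,
                alt_aa=alt_aa or None,
            ))
    if skipped:
        logger.warning("%s: skipped %d non-SNV row(s)", path, skipped)
    return records


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    contigs = sorted({v.chrom for v in records})
    header = make_vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in records:
            row = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref_base, v.alt_base),
            )
            row.info["CALLERS"] = "~".join(
                f"{name}:{status}" for name, status in v.caller_status.items()
            )
            row.info["AF"] = v.allele_fraction
            row.info["R1ALT"] = v.alt_read1_count
            row.info["R2ALT"] = v.alt_read2_count
            if v.rna_depth is not None:
                row.info["RNADP"] = v.rna_depth
            if v.rna_alt_count is not None:
                row.info["RNAALT"] = v.rna_alt_count
            if v.rna_spanning_reads is not None:
                row.info["RNASPAN"] = v.rna_spanning_reads
            if v.gene_expression is not None:
                row.info["GEXP"] = v.gene_expression
            if v.gene_id is not None:
                row.info["GENE"] = v.gene_id
            if v.transcript_ids:
                row.info["TRANSCRIPTS"] = v.transcript_ids
            if v.protein_pos is not None:
                row.info["PPOS"] = v.protein_pos
            if v.ref_aa and v.alt_aa:
                row.info["PAA"] = f"{v.ref_aa}/{v.alt_aa}"
            out.write(row)
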