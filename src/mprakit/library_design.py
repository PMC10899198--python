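"""Design of the MPRA oligo library.

Each candidate variant contributes two 230 bp library members ("elements"):
one carrying the reference allele and one the alternate, with the variant
base centred inside 200 bp of genomic context and a fixed 15 bp synthesis
adapter on either end.  Centering an even-length window is ambiguous by one
base; this module fixes 99 bases upstream and 100 downstream of the variant
(0-based ``variant_offset`` 99) so that element sequences are reproducible
byte for byte.

Only single-nucleotide substitutions are supported; indel alleles are
rejected.  Elements are always built on the forward strand of the supplied
genome, and soft-masked (lowercase) genome bases are uppercased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ADAPTER5 = "ACTGGCCGCTTGACG"
ADAPTER3 = "CACTGCGGCTCCTGC"
INSERT_LEN = 200
FLANK_UP = 99  # bases before the variant inside the insert
FLANK_DOWN = INSERT_LEN - FLANK_UP - 1
ELEMENT_LEN = len(ADAPTER5) + INSERT_LEN + len(ADAPTER3)

VALID_BASES = frozenset("ACGT")
CATEGORIES = ("gwas_ld", "park_intragenic", "park_eqtl", "microglia", "control")


class LibraryDesignError(ValueError):
    """Invalid variant input or genome disagreement during library design."""


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant nominated for the assay."""

    variant_id: str
    chrom: str
    pos: int  # 1-based coordinate of the variant base
    ref_allele: str
    alt_allele: str
    category: str = "gwas_ld"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise LibraryDesignError(f"{self.variant_id}: pos must be >= 1")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if len(allele) != 1 or allele.upper() not in VALID_BASES:
                raise LibraryDesignError(
                    f"{self.variant_id}: unsupported {name} allele {allele!r} "
                    "(only single-nucleotide substitutions are assayed)"
                )
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise LibraryDesignError(f"{self.variant_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class OligoElement:
    """One synthesized library member: adapter + 200 bp insert + adapter."""

    element_id: str
    variant_id: str
    allele: str  # "ref" | "alt"
    chrom: str
    pos: int
    insert: str
    variant_offset: int = FLANK_UP

    @property
    def full_sequence(self) -> str:
        return ADAPTER5 + self.insert + ADAPTER3


@dataclass
class LibraryDesign:
    """The complete oligo library keyed by element id."""

    elements: dict[str, OligoElement] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements.values())

    def __getitem__(self, element_id: str) -> OligoElement:
        return self.elements[element_id]

    def pairs(self) -> dict[str, tuple[str, str]]:
        """variant_id -> (ref element_id, alt element_id) for complete pairs."""
        by_variant: dict[str, dict[str, str]] = {}
        for el in self:
            by_variant.setdefault(el.variant_id, {})[el.allele] = el.element_id
        return {
            v: (d["ref"], d["alt"]) for v, d in by_variant.items() if {"ref", "alt"} <= d.keys()
        }


def element_id_for(variant_id: str, allele: str) -> str:
    return f"{variant_id}_{allele}"


def split_element_id(element_id: str) -> tuple[str, str]:
    """Invert :func:`element_id_for`; raises on ids without an allele suffix."""
    variant_id, _, allele = element_id.rpartition("_")
    if allele not in ("ref", "alt") or not variant_id:
        raise LibraryDesignError(f"element id {element_id!r} has no ref/alt suffix")
    return variant_id, allele


def build_element(
    variant: VariantRecord, genome: Mapping[str, str], allele: str
) -> OligoElement:
    """Build one allele's element around ``variant``.

    ``genome`` maps contig name to sequence. The insert is 99 upstream bases,
    the allele base, then 100 downstream bases, all uppercased. Raises
    :class:`LibraryDesignError` when the variant sits within 100 bp of a
    contig end or the genome base at ``pos`` disagrees with ``ref_allele``.
    """
    if allele not in ("ref", "alt"):
        raise LibraryDesignError(f"allele must be 'ref' or 'alt', got {allele!r}")
    try:
        contig = genome[variant.chrom]
    except KeyError:
        raise LibraryDesignError(f"{variant.variant_id}: contig {variant.chrom!r} not in genome")
    seq = str(contig).upper()
    i = variant.pos - 1  # 0-based variant index
    if i - FLANK_UP < 0 or i + FLANK_DOWN + 1 > len(seq):
        raise LibraryDesignError(
            f"{variant.variant_id}: fewer than {FLANK_UP + 1} bp of flank on contig "
            f"{variant.chrom} (pos {variant.pos}, contig length {len(seq)})"
        )
    genome_base = seq[i]
    if genome_base != variant.ref_allele.upper():
        raise LibraryDesignError(
            f"{variant.variant_id}: genome base {genome_base} at {variant.chrom}:"
            f"{variant.pos} does not match ref allele {variant.ref_allele}"
        )
    base = (variant.ref_allele if allele == "ref" else variant.alt_allele).upper()
    insert = seq[i - FLANK_UP : i] + base + seq[i + 1 : i + 1 + FLANK_DOWN]
    return OligoElement(
        element_id=element_id_for(variant.variant_id, allele),
        variant_id=variant.variant_id,
        allele=allele,
        chrom=variant.chrom,
        pos=variant.pos,
        insert=insert,
    )


def build_library(
    variants: Iterable[VariantRecord],
    genome: Mapping[str, str],
    controls: Mapping[str, str] | None = None,
) -> tuple[LibraryDesign, pd.DataFrame]:
    """Build ref+alt elements for every variant plus optional pre-made controls.

    ``controls`` maps element_id to a full 230 bp sequence (adapters included),
    e.g. ubiquitous-enhancer positives or scrambled negatives. Returns the
    library and a one-row-per-element design report. Duplicate full sequences
    between elements raise a warning but both elements are kept.
    """
    variants = list(variants)
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LibraryDesignError(f"duplicate variant ids: {dupes}")

    library = LibraryDesign()
    rows = []
    for variant in variants:
        for allele in ("ref", "alt"):
            el = build_element(variant, genome, allele)
            library.elements[el.element_id] = el
            rows.append(
                {
                    "element_id": el.element_id,
                    "variant_id": el.variant_id,
                    "allele": el.allele,
                    "chrom": el.chrom,
                    "pos": el.pos,
                    "category": variant.category,
                    "length": len(el.full_sequence),
                }
            )
    for element_id, seq in (controls or {}).items():
        if element_id in library.elements:
            raise LibraryDesignError(f"control id {element_id!r} collides with a variant element")
        seq = seq.upper()
        if len(seq) != ELEMENT_LEN:
            raise LibraryDesignError(
                f"control {element_id!r} is {len(seq)} bp, expected {ELEMENT_LEN}"
            )
        library.elements[element_id] = OligoElement(
            element_id=element_id,
            variant_id=element_id,
            allele="control",
            chrom="",
            pos=0,
            insert=seq[len(ADAPTER5) : len(ADAPTER5) + INSERT_LEN],
        )
        rows.append(
            {
                "element_id": element_id,
                "variant_id": element_id,
                "allele": "control",
                "chrom": "",
                "pos": 0,
                "category": "control",
                "length": ELEMENT_LEN,
            }
        )

    report = pd.DataFrame(
        rows,
        columns=["element_id", "variant_id", "allele", "chrom", "pos", "category", "length"],
    )
    seqs: dict[str, str] = {}
    for el in library:
        if el.full_sequence in seqs:
            warnings.warn(
                f"elements {seqs[el.full_sequence]} and {el.element_id} have identical "
                "sequences; both kept",
                stacklevel=2,
            )
        else:
            seqs[el.full_sequence] = el.element_id
    return library, report


# ---------------------------------------------------------------------------
# I/O


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV with columns chrom, pos, variant_id, ref, alt, category."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str})
    required = {"chrom", "pos", "variant_id", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryDesignError(f"variant table missing columns: {sorted(missing)}")
    if "category" not in df.columns:
        df["category"] = "gwas_ld"
    return [
        VariantRecord(
            variant_id=r.variant_id,
            chrom=r.chrom,
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            category=str(r.category),
        )
        for r in df.itertuples()
    ]


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_library_fasta(library: LibraryDesign, path: str | Path) -> None:
    """Write the library deterministically (insertion order) as FASTA."""
    records = [
        SeqRecord(
            Seq(el.full_sequence),
            id=el.element_id,
            description=f"variant={el.variant_id} allele={el.allele} locus={el.chrom}:{el.pos}",
        )
        for el in library
    ]
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(path: str | Path) -> LibraryDesign:
    library = LibraryDesign()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not (seq.startswith(ADAPTER5) and seq.endswith(ADAPTER3)):
            raise LibraryDesignError(f"element {rec.id} lacks the library adapters")
        fields = dict(
            f.split("=", 1) for f in rec.description.split()[1:] if "=" in f
        )
        chrom, _, pos = fields.get("locus", ":0").partition(":")
        library.elements[rec.id] = OligoElement(
            element_id=rec.id,
            variant_id=fields.get("variant", rec.id),
            allele=fields.get("allele", "ref"),
            chrom=chrom,
            pos=int(pos or 0),
            insert=seq[len(ADAPTER5) : len(seq) - len(ADAPTER3)],
        )
    return library
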