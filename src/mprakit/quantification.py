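"""Barcode counting in DNA/RNA sequencing and aggregation to element counts.

DNA (plasmid) and RNA (cDNA) libraries are sequenced paired-end per
replicate; each read carries one transcribed barcode between assay-specific
guide sequences.  Counts are aggregated per element after two filters taken
from standard MPRA practice:

* a barcode contributes only if it is present (DNA count >= 1) in every
  replicate — DNA witnesses plasmid delivery, and an RNA zero is then a
  meaningful expression observation, so the presence rule consults DNA by
  default (``require_rna`` extends it to both assays);
* elements represented by fewer than ``min_barcodes`` (default 5)
  contributing barcodes are dropped.  Ref and alt elements of a variant are
  filtered independently, so a variant can lose one allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .barcode_association import (
    BARCODE_LEN,
    BarcodeMap,
    _find_flanked,
    iter_read_pairs,
    reverse_complement,
)

# Guide sequences flanking the barcode in count sequencing, per assay and
# read orientation (left flank, right flank). Reverse-read hits are
# reverse-complemented back to the canonical (forward) barcode orientation.
RNA_GUIDES_FWD = ("CCGACGCTCTTCCGATCT", "TCTAGAATTATTACACGG")
RNA_GUIDES_REV = ("GTAATAATTCTAGA", "AGATCGGAAGAGCGTC")
DNA_GUIDES_FWD = ("CCGACGCTCTTCCGATCT", "TCTAGAATTATTACACGG")
DNA_GUIDES_REV = ("TCGCCGTGTAATAATTCTAGA", "AGATCGGAAGAGCG")

ASSAYS = ("dna", "rna")


class QuantificationError(ValueError):
    pass


@dataclass
class CountStats:
    reads_total: int = 0
    barcode_found: int = 0
    barcode_mapped: int = 0
    orphans: int = 0


@dataclass
class BarcodeCountTable:
    """Barcode-level counts: ``counts[(assay, replicate)][barcode] -> int``."""

    replicates: tuple[int, ...]
    counts: dict[tuple[str, int], dict[str, int]] = field(default_factory=dict)
    stats: dict[tuple[str, int], CountStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for assay in ASSAYS:
            for rep in self.replicates:
                self.counts.setdefault((assay, rep), {})
                self.stats.setdefault((assay, rep), CountStats())

    def get(self, assay: str, replicate: int, barcode: str) -> int:
        return self.counts[(assay, replicate)].get(barcode, 0)

    def increment(self, assay: str, replicate: int, barcode: str, by: int = 1) -> None:
        cell = self.counts[(assay, replicate)]
        cell[barcode] = cell.get(barcode, 0) + by

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: assay, replicate, barcode, count."""
        rows = [
            (assay, rep, barcode, n)
            for (assay, rep), cell in sorted(self.counts.items())
            for barcode, n in sorted(cell.items())
        ]
        return pd.DataFrame(rows, columns=["assay", "replicate", "barcode", "count"])


def extract_count_barcode(read_fwd: str, read_rev: str | None, assay: str) -> str | None:
    """Extract the barcode from a count-sequencing read pair.

    The forward read is searched with the assay's forward-orientation guides;
    the reverse read with the reverse-orientation guides (hit
    reverse-complemented).  If both reads yield barcodes they must agree,
    otherwise the pair is inconsistent and dropped.
    """
    if assay not in ASSAYS:
        raise QuantificationError(f"assay must be one of {ASSAYS}, got {assay!r}")
    fwd_guides, rev_guides = (
        (RNA_GUIDES_FWD, RNA_GUIDES_REV) if assay == "rna" else (DNA_GUIDES_FWD, DNA_GUIDES_REV)
    )
    fwd_hit = _find_flanked(read_fwd, *fwd_guides) if read_fwd else None
    rev_hit = None
    if read_rev:
        raw = _find_flanked(read_rev, *rev_guides)
        if raw is not None:
            rev_hit = reverse_complement(raw)
    if fwd_hit is not None and rev_hit is not None and fwd_hit != rev_hit:
        return None
    return fwd_hit if fwd_hit is not None else rev_hit


def count_barcodes(
    fastq_sets: Mapping[tuple[str, int], tuple[str | Path, str | Path | None]],
    bc_map: BarcodeMap,
) -> BarcodeCountTable:
    """Count mapped barcodes per assay/replicate from FASTQ pairs.

    ``fastq_sets`` maps (assay, replicate) to (forward FASTQ, reverse FASTQ or
    None).  Barcodes absent from ``bc_map`` are tallied as orphans, never
    counted.  Both assays must declare the same replicate labels.
    """
    if not bc_map.entries:
        raise QuantificationError("barcode map is empty")
    reps = {assay: sorted(r for a, r in fastq_sets if a == assay) for assay in ASSAYS}
    if reps["dna"] != reps["rna"] or not reps["dna"]:
        raise QuantificationError(
            f"replicate labels differ between assays: dna={reps['dna']} rna={reps['rna']}"
        )
    table = BarcodeCountTable(replicates=tuple(reps["dna"]))
    for (assay, rep), (fq_fwd, fq_rev) in sorted(fastq_sets.items()):
        stats = table.stats[(assay, rep)]
        if fq_rev is not None:
            pair_iter: Iterable[tuple[str, str | None]] = iter_read_pairs(fq_fwd, fq_rev)
        else:
            from Bio import SeqIO

            pair_iter = ((str(rec.seq).upper(), None) for rec in SeqIO.parse(str(fq_fwd), "fastq"))
        for read_fwd, read_rev in pair_iter:
            stats.reads_total += 1
            barcode = extract_count_barcode(read_fwd, read_rev, assay)
            if barcode is None:
                continue
            stats.barcode_found += 1
            if barcode in bc_map.entries:
                stats.barcode_mapped += 1
                table.increment(assay, rep, barcode)
            else:
                stats.orphans += 1
    return table


def aggregate_elements(
    table: BarcodeCountTable,
    bc_map: BarcodeMap,
    min_barcodes: int = 5,
    require_rna: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate barcode counts to element counts and apply the filters.

    Returns ``(elements, dropped)``: ``elements`` is indexed by element_id
    with columns ``n_barcodes, dna_1..R, rna_1..R``; ``dropped`` logs the
    element ids removed by the minimum-barcode rule and why.
    """
    reps = table.replicates
    if len(reps) < 2:
        raise QuantificationError("need at least 2 replicates to aggregate")

    by_element = bc_map.barcodes_by_element()
    rows = []
    dropped = []
    for element_id in sorted(by_element):
        contributing = []
        for barcode in by_element[element_id]:
            present = all(table.get("dna", r, barcode) >= 1 for r in reps)
            if present and require_rna:
                present = all(table.get("rna", r, barcode) >= 1 for r in reps)
            if present:
                contributing.append(barcode)
        n = len(contributing)
        if n < min_barcodes:
            dropped.append(
                {
                    "element_id": element_id,
                    "n_barcodes": n,
                    "reason": f"fewer than {min_barcodes} barcodes present in all replicates",
                }
            )
            continue
        row: dict[str, object] = {"element_id": element_id, "n_barcodes": n}
        for assay in ASSAYS:
            for r in reps:
                row[f"{assay}_{r}"] = sum(table.get(assay, r, b) for b in contributing)
        rows.append(row)

    columns = ["element_id", "n_barcodes"] + [f"{a}_{r}" for a in ASSAYS for r in reps]
    elements = pd.DataFrame(rows, columns=columns).set_index("element_id")
    elements = elements.astype({c: np.int64 for c in elements.columns})
    drop_log = pd.DataFrame(dropped, columns=["element_id", "n_barcodes", "reason"])
    return elements, drop_log


def replicates_of(elements: pd.DataFrame) -> tuple[int, ...]:
    """Recover the replicate labels from an element-count table's columns."""
    return tuple(
        sorted(int(c.split("_")[1]) for c in elements.columns if c.startswith("dna_"))
    )


def write_element_counts(elements: pd.DataFrame, path: str | Path) -> None:
    elements.to_csv(path, sep="\t")


def read_element_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="element_id")
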