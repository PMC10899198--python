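"""Barcode-to-oligo association mapping from paired-end reads of the inert library.

The inert (pre-promoter) library is sequenced paired-end: read 1 enters the
oligo through the amplification adapter, read 2 covers the 20 bp random
barcode between two fixed guide sequences.  Matching is deliberately exact —
no mismatches, no indels, no quality use — so a sequencing error drops the
read rather than risking a misassignment.  A barcode observed with more than
one element is assigned to the majority element only when that element holds
at least ``dominance`` of the barcode's support (default 0.9); otherwise the
barcode is discarded as ambiguous.
"""

from __future__ import annotations

import gzip
import json
from bisect import bisect_left
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .library_design import ADAPTER3, LibraryDesign

ASSOC_ADAPTER = "GGCCTAACTGGCCGCTTGACG"
GUIDE_LEFT = "CGCCGAGGCCCGACGCTCTTCCGATCT"
GUIDE_RIGHT = "TCTAGAGGTACCGCAGGAGCCGCAGTG"
BARCODE_LEN = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AssocStats:
    """Per-stage read tallies for the association run."""

    pairs_total: int = 0
    adapter_trimmed: int = 0
    element_matched: int = 0
    barcode_found: int = 0
    pairs_used: int = 0
    barcodes_total: int = 0
    barcodes_mapped: int = 0
    barcodes_ambiguous: int = 0


@dataclass
class BarcodeMap:
    """Resolved barcode -> (element_id, support) association."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)
    stats: AssocStats = field(default_factory=AssocStats)

    def __len__(self) -> int:
        return len(self.entries)

    def element_of(self, barcode: str) -> str | None:
        hit = self.entries.get(barcode)
        return hit[0] if hit else None

    def barcodes_by_element(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for barcode, (element_id, _) in self.entries.items():
            out.setdefault(element_id, []).append(barcode)
        return out


def trim_assoc_adapter(read: str) -> str | None:
    """Strip the exact 21-mer amplification adapter from the 5' end, or reject."""
    if read.startswith(ASSOC_ADAPTER):
        return read[len(ASSOC_ADAPTER):]
    return None


class ElementMatcher:
    """Exact-prefix lookup of trimmed reads against post-adapter references.

    The association adapter ends with the library's 5' synthesis adapter, so a
    trimmed read starts at the insert; each element's reference here is
    ``insert + ADAPTER3``.  Lookup is a binary search over the sorted
    references: a trimmed read matches an element iff the reference starts
    with it, and matches are ambiguous when shared by >1 reference (e.g. a
    read too short to reach the variant base of an allele pair).
    """

    def __init__(self, library: LibraryDesign):
        refs = sorted((el.insert + ADAPTER3, el.element_id) for el in library)
        self._keys = [r[0] for r in refs]
        self._ids = [r[1] for r in refs]

    def match(self, trimmed: str) -> str | None:
        if not trimmed:
            return None
        lo = bisect_left(self._keys, trimmed)
        hi = bisect_left(self._keys, trimmed + "\x7f", lo=lo)
        if hi - lo != 1:
            return None  # no exact hit, or prefix shared by several elements
        return self._ids[lo]


def match_element(trimmed: str, library: LibraryDesign | ElementMatcher) -> str | None:
    matcher = library if isinstance(library, ElementMatcher) else ElementMatcher(library)
    return matcher.match(trimmed)


def _find_flanked(seq: str, left: str, right: str, length: int = BARCODE_LEN) -> str | None:
    """First ``length``-mer bounded exactly by ``left`` and ``right`` in ``seq``."""
    start = 0
    while True:
        i = seq.find(left, start)
        if i < 0:
            return None
        j = i + len(left)
        candidate = seq[j : j + length]
        if len(candidate) == length and seq.startswith(right, j + length):
            if set(candidate) <= {"A", "C", "G", "T"}:
                return candidate
            return None  # N inside the barcode
        start = i + 1


def extract_assoc_barcode(read: str) -> str | None:
    """Pull the 20 bp barcode between the association guides; tries both strands."""
    barcode = _find_flanked(read, GUIDE_LEFT, GUIDE_RIGHT)
    if barcode is None:
        barcode = _find_flanked(reverse_complement(read), GUIDE_LEFT, GUIDE_RIGHT)
    return barcode


def iter_read_pairs(
    fastq1: str | Path, fastq2: str | Path
) -> Iterator[tuple[str, str]]:
    """Yield (read1, read2) sequences from a pair of (optionally gzipped) FASTQs."""

    def _open(path):
        path = str(path)
        if path.endswith(".gz"):
            return gzip.open(path, "rt")
        return open(path)

    with _open(fastq1) as h1, _open(fastq2) as h2:
        for rec1, rec2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq"), strict=True
        ):
            yield str(rec1.seq).upper(), str(rec2.seq).upper()


def observe_pairs(
    pairs: Iterable[tuple[str, str]],
    library: LibraryDesign,
    stats: AssocStats | None = None,
) -> Iterator[tuple[str, str]]:
    """Turn read pairs into (barcode, element_id) observations.

    A pair contributes only if read 1 trims and matches an element exactly and
    read 2 yields a clean barcode.
    """
    stats = stats if stats is not None else AssocStats()
    matcher = ElementMatcher(library)
    for read1, read2 in pairs:
        stats.pairs_total += 1
        trimmed = trim_assoc_adapter(read1)
        if trimmed is None:
            continue
        stats.adapter_trimmed += 1
        element_id = matcher.match(trimmed)
        if element_id is None:
            continue
        stats.element_matched += 1
        barcode = extract_assoc_barcode(read2)
        if barcode is None:
            continue
        stats.barcode_found += 1
        stats.pairs_used += 1
        yield barcode, element_id


def build_barcode_map(
    observations: Iterable[tuple[str, str]],
    dominance: float = 0.9,
    min_support: int = 1,
    stats: AssocStats | None = None,
) -> BarcodeMap:
    """Aggregate observations and resolve multi-element barcodes by dominance.

    A barcode seen with several elements is kept for its top element when that
    element's support fraction is >= ``dominance``; otherwise it is dropped.
    """
    if not 0.5 < dominance <= 1.0:
        raise ValueError("dominance must lie in (0.5, 1]")
    support: dict[str, dict[str, int]] = {}
    for barcode, element_id in observations:
        if len(barcode) != BARCODE_LEN:
            raise ValueError(f"barcode {barcode!r} is not {BARCODE_LEN} bp")
        per_element = support.setdefault(barcode, {})
        per_element[element_id] = per_element.get(element_id, 0) + 1

    result = BarcodeMap(stats=stats if stats is not None else AssocStats())
    result.stats.barcodes_total = len(support)
    for barcode in support:
        per_element = support[barcode]
        total = sum(per_element.values())
        top_element, top_support = max(per_element.items(), key=lambda kv: (kv[1], kv[0]))
        if top_support < min_support:
            continue
        if len(per_element) > 1 and top_support / total < dominance:
            result.stats.barcodes_ambiguous += 1
            continue
        result.entries[barcode] = (top_element, top_support)
    result.stats.barcodes_mapped = len(result.entries)
    return result


def map_barcodes(
    fastq1: str | Path,
    fastq2: str | Path,
    library: LibraryDesign,
    dominance: float = 0.9,
    min_support: int = 1,
) -> BarcodeMap:
    """End-to-end association: paired FASTQ -> resolved BarcodeMap."""
    stats = AssocStats()
    observations = observe_pairs(iter_read_pairs(fastq1, fastq2), library, stats)
    return build_barcode_map(observations, dominance, min_support, stats=stats)


# ---------------------------------------------------------------------------
# I/O


def write_barcode_map(bc_map: BarcodeMap, path: str | Path, stats_path: str | Path | None = None) -> None:
    df = pd.DataFrame(
        [(b, e, s) for b, (e, s) in sorted(bc_map.entries.items())],
        columns=["barcode", "element_id", "support"],
    )
    df.to_csv(path, sep="\t", index=False)
    if stats_path is not None:
        Path(stats_path).write_text(json.dumps(asdict(bc_map.stats), indent=2) + "\n")


def read_barcode_map(path: str | Path) -> BarcodeMap:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "element_id": str})
    bc_map = BarcodeMap()
    for r in df.itertuples():
        bc_map.entries[r.barcode] = (r.element_id, int(r.support))
    bc_map.stats.barcodes_mapped = len(bc_map.entries)
    return bc_map
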