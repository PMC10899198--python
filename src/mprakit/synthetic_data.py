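"""Synthetic MPRA data with known ground truth.

Generates everything the pipeline consumes — genome, variant table, oligo
library, association read pairs, and DNA/RNA barcode counts (optionally
wrapped in FASTQ) — under the generative model the analysis assumes:

* barcode multiplicity per element is log-normal (heavy right tail, mean
  ~449 per element, truncated to 1–9333), with log-normal per-barcode
  abundance weights;
* DNA counts per replicate are multinomial draws of the sequencing depth
  over barcode weights;
* RNA expectation per barcode is ``w_b * 2**(alpha_e + beta_v*[alt] + u_r)``
  with element baseline activity alpha (log2 scale, nonzero only for planted
  enhancers), allelic effect beta (alt minus ref, nonzero only for planted
  allele-specific variants), and a replicate effect u_r shared by both
  alleles within a replicate (so paired differences cancel it by design);
  counts are negative-binomial around the scaled expectation via a
  gamma-Poisson mixture, collapsing to a multinomial when dispersion is 0;
* sequencing errors are uniform per-base substitutions.

One master seed drives an independent, splittable stream per stage, so
stages can be regenerated separately and a fixed seed yields byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import quantification as quant
from .barcode_association import (
    ASSOC_ADAPTER,
    BARCODE_LEN,
    GUIDE_LEFT,
    GUIDE_RIGHT,
    BarcodeMap,
    reverse_complement,
)
from .library_design import (
    ADAPTER3,
    LibraryDesign,
    VariantRecord,
    build_library,
    split_element_id,
)
from .quantification import BarcodeCountTable

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the assayed design: three replicates, ~449 barcodes per
    element (range 1–9333), a small minority of true enhancers (~3%, cf.
    138 calls among ~5000 tested elements) and a smaller minority with
    allele-specific effects (~0.5%, cf. 27/5254 variants).
    """

    n_variants: int = 200
    frac_enhancer: float = 0.03
    frac_allelic: float = 0.005
    barcode_mean: float = 449.0
    barcode_range: tuple[int, int] = (1, 9333)
    replicates: int = 3
    depth: int = 20_000_000  # reads per assay per replicate
    nb_dispersion: float = 0.05
    replicate_sd: float = 0.1
    read_error_rate: float = 0.001
    reads_per_barcode: int = 3  # association coverage
    read_length: int = 150
    enhancer_alpha: tuple[float, float] = (2.0, 0.5)  # Normal(mean, sd), log2
    allelic_beta: tuple[float, float] = (1.5, 0.3)  # ±Normal(mean, sd), log2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_enhancer <= 1 and 0 <= self.frac_allelic <= 1):
            raise SimulationError("fractions must lie in [0, 1]")
        if self.depth <= 0 or self.n_variants < 1 or self.replicates < 1:
            raise SimulationError("depth, n_variants and replicates must be positive")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream for one pipeline stage."""
        offsets = {"library": 0, "assoc": 1, "counts": 2, "fastq": 3}
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(offsets[stage],))
        )


#: Desk-test preset: small library, shallow sequencing, runs in seconds.
TINY = SimConfig(
    n_variants=200,
    barcode_mean=30.0,
    barcode_range=(1, 200),
    depth=300_000,
    reads_per_barcode=2,
)

#: Full study-scale conditions (library of 5254 allele pairs).
PAPER_SCALE = SimConfig(n_variants=5254)

PRESETS = {"tiny": TINY, "paper-scale": PAPER_SCALE}


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    variants: list[VariantRecord]
    genome: dict[str, str]
    alpha: dict[str, float]  # element_id -> baseline log2 activity
    beta: dict[str, float]  # variant_id -> allelic effect (alt - ref)
    barcode_to_element: dict[str, str]
    weights: dict[str, float] = field(default_factory=dict)  # sums to 1

    def n_barcodes(self, element_id: str) -> int:
        return sum(1 for e in self.barcode_to_element.values() if e == element_id)

    def true_barcode_map(self) -> BarcodeMap:
        bc_map = BarcodeMap()
        for barcode, element_id in self.barcode_to_element.items():
            bc_map.entries[barcode] = (element_id, 1)
        return bc_map

    def to_frame(self) -> pd.DataFrame:
        counts: dict[str, int] = {}
        for element_id in self.barcode_to_element.values():
            counts[element_id] = counts.get(element_id, 0) + 1
        rows = []
        for element_id in sorted(self.alpha):
            variant_id, allele = split_element_id(element_id)
            rows.append(
                {
                    "element_id": element_id,
                    "alpha": self.alpha[element_id],
                    "beta": self.beta.get(variant_id, 0.0) if allele == "alt" else 0.0,
                    "n_barcodes": counts.get(element_id, 0),
                }
            )
        return pd.DataFrame(rows).set_index("element_id")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_library(config: SimConfig) -> tuple[LibraryDesign, SimTruth]:
    """Random genome, variants, library, barcodes, and planted effects."""
    rng = config.stage_rng("library")
    spacing, margin = 230, 150
    contig = "chrS1"
    genome = {contig: _random_sequence(rng, margin * 2 + spacing * config.n_variants)}

    variants = []
    for i in range(config.n_variants):
        pos = margin + i * spacing + 1  # 1-based
        ref = genome[contig][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(
            VariantRecord(
                variant_id=f"var{i:05d}", chrom=contig, pos=pos, ref_allele=ref, alt_allele=alt
            )
        )
    library, _ = build_library(variants, genome)

    n_enh = int(round(config.frac_enhancer * config.n_variants))
    n_all = int(round(config.frac_allelic * config.n_variants))
    enhancer_ids = rng.choice(config.n_variants, size=n_enh, replace=False)
    allelic_ids = rng.choice(config.n_variants, size=n_all, replace=False)

    alpha = {el.element_id: 0.0 for el in library}
    for i in enhancer_ids:
        a = rng.normal(*config.enhancer_alpha)
        for allele in ("ref", "alt"):
            alpha[f"{variants[i].variant_id}_{allele}"] = a
    beta = {v.variant_id: 0.0 for v in variants}
    for i in allelic_ids:
        beta[variants[i].variant_id] = float(
            rng.choice([-1, 1]) * rng.normal(*config.allelic_beta)
        )

    # log-normal barcode multiplicity tuned so that E[n] = barcode_mean
    sigma = 1.0
    mu = np.log(config.barcode_mean) - sigma**2 / 2
    n_elements = len(library)
    n_bc = np.clip(
        np.round(rng.lognormal(mu, sigma, size=n_elements)).astype(int),
        *config.barcode_range,
    )
    total = int(n_bc.sum())
    if total > 0.01 * 4**BARCODE_LEN:
        raise SimulationError("barcode space exhausted: expected collision rate > 1%")
    codes = rng.integers(0, 4, size=(total, BARCODE_LEN))
    barcodes = ["".join(row) for row in _BASES[codes]]
    while len(set(barcodes)) < total:  # resolve rare collisions
        seen: set[str] = set()
        for i, b in enumerate(barcodes):
            if b in seen:
                barcodes[i] = _random_sequence(rng, BARCODE_LEN)
            seen.add(barcodes[i])

    barcode_to_element: dict[str, str] = {}
    k = 0
    for el, n in zip(library, n_bc):
        for _ in range(n):
            barcode_to_element[barcodes[k]] = el.element_id
            k += 1
    raw_w = rng.lognormal(0.0, 0.5, size=total)
    weights = dict(zip(barcodes, raw_w / raw_w.sum()))

    truth = SimTruth(
        variants=variants,
        genome=genome,
        alpha=alpha,
        beta=beta,
        barcode_to_element=barcode_to_element,
        weights=weights,
    )
    return library, truth


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        arr[i] = rng.choice([b for b in "ACGT" if b != current]).encode()
    return arr.tobytes().decode()


def simulate_assoc_reads(
    library: LibraryDesign, truth: SimTruth, config: SimConfig
) -> Iterator[tuple[str, str]]:
    """Paired association reads: read1 = adapter+oligo, read2 = guided barcode."""
    rng = config.stage_rng("assoc")
    rlen = config.read_length
    for barcode in sorted(truth.barcode_to_element):
        element = library[truth.barcode_to_element[barcode]]
        ref = ASSOC_ADAPTER + element.insert + ADAPTER3
        core = GUIDE_LEFT + barcode + GUIDE_RIGHT
        for _ in range(config.reads_per_barcode):
            read1 = ref[:rlen]
            pad = _random_sequence(rng, max(0, rlen - len(core)))
            read2 = (core + pad)[:rlen]
            yield (
                _inject_errors(read1, config.read_error_rate, rng),
                _inject_errors(read2, config.read_error_rate, rng),
            )


def write_fastq_pairs(
    pairs: Iterator[tuple[str, str]], path1: str | Path, path2: str | Path, prefix: str = "pair"
) -> int:
    """Write read pairs as two plain FASTQ files; returns the pair count."""
    n = 0
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for i, (r1, r2) in enumerate(pairs):
            h1.write(f"@{prefix}{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            h2.write(f"@{prefix}{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")
            n += 1
    return n


def simulate_counts(truth: SimTruth, config: SimConfig) -> BarcodeCountTable:
    """Draw DNA/RNA barcode counts per replicate under the planted effects."""
    rng = config.stage_rng("counts")
    barcodes = sorted(truth.barcode_to_element)
    w = np.array([truth.weights[b] for b in barcodes])
    w = w / w.sum()
    log2_effect = np.array(
        [
            truth.alpha[truth.barcode_to_element[b]]
            + (
                truth.beta.get(split_element_id(truth.barcode_to_element[b])[0], 0.0)
                if split_element_id(truth.barcode_to_element[b])[1] == "alt"
                else 0.0
            )
            for b in barcodes
        ]
    )
    table = BarcodeCountTable(replicates=tuple(range(1, config.replicates + 1)))
    for rep in table.replicates:
        dna = rng.multinomial(config.depth, w)
        u_r = rng.normal(0.0, config.replicate_sd)
        expect = w * np.exp2(log2_effect + u_r)
        p = expect / expect.sum()
        if config.nb_dispersion > 0:
            lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * config.depth * p)
            rna = rng.poisson(lam)
        else:
            rna = rng.multinomial(config.depth, p)
        for assay, counts in (("dna", dna), ("rna", rna)):
            cell = table.counts[(assay, rep)]
            for barcode, n in zip(barcodes, counts):
                if n > 0:
                    cell[barcode] = int(n)
    return table


def write_count_fastq(
    table: BarcodeCountTable, out_dir: str | Path, config: SimConfig
) -> dict[tuple[str, int], tuple[Path, Path]]:
    """Wrap a count table in guide-flanked paired FASTQ, one pair per read.

    Returns the (assay, replicate) -> (forward, reverse) path mapping in the
    shape ``count_barcodes`` consumes.  Intended for small configurations;
    emits one read pair per counted molecule.
    """
    rng = config.stage_rng("fastq")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rlen = config.read_length
    paths: dict[tuple[str, int], tuple[Path, Path]] = {}
    for (assay, rep), cell in sorted(table.counts.items()):
        fwd_guides = quant.RNA_GUIDES_FWD if assay == "rna" else quant.DNA_GUIDES_FWD
        rev_guides = quant.RNA_GUIDES_REV if assay == "rna" else quant.DNA_GUIDES_REV
        p1 = out_dir / f"{assay}_rep{rep}_R1.fastq"
        p2 = out_dir / f"{assay}_rep{rep}_R2.fastq"
        with open(p1, "w") as h1, open(p2, "w") as h2:
            i = 0
            for barcode in sorted(cell):
                fwd_core = fwd_guides[0] + barcode + fwd_guides[1]
                rev_core = rev_guides[0] + reverse_complement(barcode) + rev_guides[1]
                for _ in range(cell[barcode]):
                    pad1 = _random_sequence(rng, max(0, rlen - len(fwd_core)))
                    pad2 = _random_sequence(rng, max(0, rlen - len(rev_core)))
                    r1 = _inject_errors(
                        (fwd_core + pad1)[:rlen], config.read_error_rate, rng
                    )
                    r2 = _inject_errors(
                        (rev_core + pad2)[:rlen], config.read_error_rate, rng
                    )
                    h1.write(f"@{assay}{rep}_{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                    h2.write(f"@{assay}{rep}_{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")
                    i += 1
        paths[(assay, rep)] = (p1, p2)
    return paths


def null_config(base: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``base`` with no planted effects (all alpha = beta = 0)."""
    base = base or TINY
    return replace(base, frac_enhancer=0.0, frac_allelic=0.0, **overrides)
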