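"""Run manifest and the staged pipeline driver.

A run manifest is a YAML file declaring the inputs (genome, variant table,
FASTQ sets per assay/replicate, annotation tracks), the tunable parameters,
and an output directory.  ``run_pipeline`` executes the requested stages in
dependency order

    design -> map -> count -> aggregate -> call -> annotate

writing plain-text TSV artifacts and a run log; re-running with identical
inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import activity_stats, annotation, barcode_association, library_design, quantification

log = logging.getLogger("mprakit")

STAGES = ("design", "map", "count", "aggregate", "call", "annotate")

# artifact each stage needs from the one before it
_REQUIRES = {
    "map": ("design", "library.fasta"),
    "count": ("map", "barcode_map.tsv"),
    "aggregate": ("count", "barcode_counts.tsv"),
    "call": ("aggregate", "element_counts.tsv"),
}


class ManifestError(ValueError):
    """Invalid manifest contents (exit code 2)."""


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing (exit code 3)."""


@dataclass
class RunManifest:
    genome: Path | None = None
    variants: Path | None = None
    output_dir: Path = Path("mprakit_out")
    assoc_fastq: tuple[Path, Path] | None = None
    count_fastq: dict[tuple[str, int], tuple[Path, Path | None]] = field(default_factory=dict)
    dr_track: Path | None = None
    tfbs_scores: Path | None = None
    intervals: Path | None = None
    min_barcodes: int = 5
    z_threshold: float = 3.0
    two_sided: bool = False
    dominance: float = 0.9
    flank: int = 100
    tfbs_cutoff: float = 0.8
    require_rna_presence: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent

        def _p(value):
            return None if value is None else (base / value if not Path(value).is_absolute() else Path(value))

        counts: dict[tuple[str, int], tuple[Path, Path | None]] = {}
        for assay, reps in (raw.get("counts") or {}).items():
            for rep, files in reps.items():
                files = files if isinstance(files, list) else [files]
                fwd = _p(files[0])
                rev = _p(files[1]) if len(files) > 1 else None
                counts[(str(assay), int(rep))] = (fwd, rev)
        assoc = raw.get("assoc_fastq")
        params = raw.get("params") or {}
        manifest = cls(
            genome=_p(raw.get("genome")),
            variants=_p(raw.get("variants")),
            output_dir=_p(raw.get("output_dir")) or base / "mprakit_out",
            assoc_fastq=(_p(assoc[0]), _p(assoc[1])) if assoc else None,
            count_fastq=counts,
            dr_track=_p((raw.get("annotations") or {}).get("dr_track")),
            tfbs_scores=_p((raw.get("annotations") or {}).get("tfbs_scores")),
            intervals=_p((raw.get("annotations") or {}).get("intervals")),
            **{k: v for k, v in params.items()},
        )
        return manifest

    def validate(self, stages: Sequence[str]) -> None:
        problems = []
        if not 0.5 < self.dominance <= 1:
            problems.append(f"dominance {self.dominance} outside (0.5, 1]")
        if self.min_barcodes < 1:
            problems.append("min_barcodes must be >= 1")
        if self.flank < 0:
            problems.append("flank must be >= 0")
        if not 0 < self.tfbs_cutoff <= 1:
            problems.append(f"tfbs_cutoff {self.tfbs_cutoff} outside (0, 1]")
        needed_files: list[tuple[str, Path | None]] = []
        if "design" in stages:
            needed_files += [("genome", self.genome), ("variants", self.variants)]
        if "map" in stages and self.assoc_fastq:
            needed_files += [("assoc_fastq", p) for p in self.assoc_fastq]
        if "count" in stages:
            for key, (fwd, rev) in self.count_fastq.items():
                needed_files.append((f"counts {key}", fwd))
                if rev is not None:
                    needed_files.append((f"counts {key}", rev))
        for label, p in needed_files:
            if p is None:
                problems.append(f"{label}: path not set")
            elif not Path(p).exists():
                problems.append(f"{label}: {p} does not exist")
        if problems:
            raise ManifestError("; ".join(problems))


def _artifact(manifest: RunManifest, name: str) -> Path:
    return Path(manifest.output_dir) / name


def run_pipeline(manifest: RunManifest, stages: Sequence[str] | None = None) -> dict[str, Path]:
    """Execute the requested stages; returns the artifact paths written."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ManifestError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    manifest.validate(stages)
    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    for stage in stages:
        dep = _REQUIRES.get(stage)
        if dep and dep[0] not in stages and not _artifact(manifest, dep[1]).exists():
            raise DependencyError(
                f"stage {stage!r} needs {dep[1]} from stage {dep[0]!r}; run it first"
            )

    if "design" in stages:
        variants = library_design.read_variant_table(manifest.variants)
        genome = library_design.read_genome_fasta(manifest.genome)
        library, report = library_design.build_library(variants, genome)
        library_design.write_library_fasta(library, _artifact(manifest, "library.fasta"))
        report.to_csv(_artifact(manifest, "design_report.tsv"), sep="\t", index=False)
        artifacts["library"] = _artifact(manifest, "library.fasta")
        artifacts["design_report"] = _artifact(manifest, "design_report.tsv")
        log.info("design: %d variants in -> %d elements out", len(variants), len(library))

    if "map" in stages:
        library = library_design.read_library_fasta(_artifact(manifest, "library.fasta"))
        if not manifest.assoc_fastq:
            raise ManifestError("map stage requires assoc_fastq")
        bc_map = barcode_association.map_barcodes(
            *manifest.assoc_fastq, library, dominance=manifest.dominance
        )
        barcode_association.write_barcode_map(
            bc_map,
            _artifact(manifest, "barcode_map.tsv"),
            _artifact(manifest, "assoc_stats.json"),
        )
        artifacts["barcode_map"] = _artifact(manifest, "barcode_map.tsv")
        s = bc_map.stats
        log.info(
            "map: %d pairs in -> %d barcodes mapped + %d ambiguous dropped",
            s.pairs_total, s.barcodes_mapped, s.barcodes_ambiguous,
        )

    if "count" in stages:
        bc_map = barcode_association.read_barcode_map(_artifact(manifest, "barcode_map.tsv"))
        table = quantification.count_barcodes(manifest.count_fastq, bc_map)
        table.to_frame().to_csv(_artifact(manifest, "barcode_counts.tsv"), sep="\t", index=False)
        artifacts["barcode_counts"] = _artifact(manifest, "barcode_counts.tsv")
        for key, st in sorted(table.stats.items()):
            log.info(
                "count %s: %d reads in -> %d mapped + %d orphans + %d unreadable",
                key, st.reads_total, st.barcode_mapped, st.orphans,
                st.reads_total - st.barcode_found,
            )

    if "aggregate" in stages:
        bc_map = barcode_association.read_barcode_map(_artifact(manifest, "barcode_map.tsv"))
        long = pd.read_csv(_artifact(manifest, "barcode_counts.tsv"), sep="\t")
        reps = tuple(sorted(long["replicate"].unique()))
        table = quantification.BarcodeCountTable(replicates=reps)
        for _, r in long.iterrows():
            table.increment(r["assay"], int(r["replicate"]), r["barcode"], int(r["count"]))
        elements, dropped = quantification.aggregate_elements(
            table, bc_map, min_barcodes=manifest.min_barcodes,
            require_rna=manifest.require_rna_presence,
        )
        quantification.write_element_counts(elements, _artifact(manifest, "element_counts.tsv"))
        dropped.to_csv(_artifact(manifest, "dropped_elements.tsv"), sep="\t", index=False)
        artifacts["element_counts"] = _artifact(manifest, "element_counts.tsv")
        log.info(
            "aggregate: %d elements in -> %d retained + %d dropped",
            len(elements) + len(dropped), len(elements), len(dropped),
        )

    if "call" in stages:
        elements = quantification.read_element_counts(_artifact(manifest, "element_counts.tsv"))
        activity = activity_stats.compute_activity(elements)
        activity.to_csv(_artifact(manifest, "activity.tsv"), sep="\t")
        general = activity_stats.call_general_enhancers(
            activity, z_threshold=manifest.z_threshold, two_sided=manifest.two_sided
        )
        general.to_csv(_artifact(manifest, "general_enhancers.tsv"), sep="\t")
        pairs = {}
        for element_id in elements.index:
            try:
                variant_id, allele = library_design.split_element_id(element_id)
            except library_design.LibraryDesignError:
                continue
            pairs.setdefault(variant_id, {})[allele] = element_id
        complete = {
            v: (d["ref"], d["alt"]) for v, d in pairs.items() if {"ref", "alt"} <= d.keys()
        }
        allelic = activity_stats.fit_allelic_model(activity, complete)
        allelic.to_csv(_artifact(manifest, "allelic_results.tsv"), sep="\t")
        artifacts["general_enhancers"] = _artifact(manifest, "general_enhancers.tsv")
        artifacts["allelic_results"] = _artifact(manifest, "allelic_results.tsv")
        prior = allelic.attrs.get("moderation")
        tiers = allelic["tier"].value_counts().to_dict() if len(allelic) else {}
        skipped = len(pairs) - len(complete)
        log.info(
            "call: %d elements in -> %d enhancers, %d/%d pairs tested (%d one-allele pairs "
            "skipped), d0=%s s0_sq=%s tiers=%s",
            len(elements), int(general["is_enhancer"].sum()), len(allelic), len(pairs),
            skipped, getattr(prior, "d0", None), getattr(prior, "s0_sq", None), tiers,
        )

    if "annotate" in stages:
        if manifest.variants is None:
            raise ManifestError("annotate stage requires the variant table")
        variants = library_design.read_variant_table(manifest.variants)
        annotated = pd.DataFrame(index=pd.Index([v.variant_id for v in variants], name="variant_id"))
        if manifest.dr_track is not None:
            track = pd.read_csv(manifest.dr_track, sep="\t")
            annotated["dr_mean"] = annotation.dr_mean_table(variants, track)
        if manifest.tfbs_scores is not None:
            scores = pd.read_csv(manifest.tfbs_scores, sep="\t")
            _, flags = annotation.filter_tfbs(scores, cutoff=manifest.tfbs_cutoff)
            annotated["disrupts_tfbs"] = flags.reindex(annotated.index, fill_value=False)
        if manifest.intervals is not None:
            intervals = pd.read_csv(
                manifest.intervals, sep="\t", header=None,
                names=["chrom", "start", "end", "track"],
            )
            overlaps = annotation.overlap_flank(variants, intervals, flank=manifest.flank)
            annotated = annotated.join(overlaps)
        annotated.to_csv(_artifact(manifest, "annotated_variants.tsv"), sep="\t")
        artifacts["annotated_variants"] = _artifact(manifest, "annotated_variants.tsv")
        log.info("annotate: %d variants in -> %d annotated out", len(variants), len(annotated))

    meta = {"stages": stages, "seed": manifest.seed}
    _artifact(manifest, "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return artifacts
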