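"""Packaged reference tables from the Parkinson's-disease MPRA screen.

Three small TSVs ship with the package:

* ``allelic_enhancers.tsv`` — published per-variant summary statistics for
  the 27 allele-specific enhancers called at FDR < 0.05 in HEK293 cells
  (logFC, moderated t, p, BH-adjusted p, B, nomination category);
* ``allelic_tfbs_scores_synthetic.tsv`` — per-TF binding-site delta-score
  rows for the allele-specific enhancer variants.  Variant IDs, positions,
  TF names and FDR bins are the published values; the signed scores are
  synthetic placeholders (±0.8 boundary magnitude for published
  high-confidence hits, -0.3 for variants published without any hit),
  because the underlying signed scores were not released;
* ``epigenetic_mark_overlap.tsv`` — counts of variants per enhancer group
  overlapping four epigenetic annotation classes (promoter/enhancer
  chromatin states, DNase I hypersensitivity, protein binding), with group
  sizes; the background group is every assayed non-enhancer element.

These are the worked-example inputs for the annotation arithmetic and the
proportion tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PACKAGE = "mprakit.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PACKAGE).joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_allelic_enhancers() -> pd.DataFrame:
    """The 27 allele-specific enhancer calls (FDR < 0.05) with statistics."""
    return _read("allelic_enhancers.tsv")


def load_tfbs_scores() -> pd.DataFrame:
    """Per-TF delta-score rows for allele-specific enhancer variants.

    Scores are placeholder magnitudes (see module docstring); suitable for
    exercising the high-confidence filter, not for reanalysing effect sizes.
    """
    return _read("allelic_tfbs_scores_synthetic.tsv")


def load_overlap_counts() -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Epigenetic-mark overlap counts as (group_counts, group_sizes)."""
    df = _read("epigenetic_mark_overlap.tsv")
    group_counts: dict[str, dict[str, int]] = {}
    group_sizes: dict[str, int] = {}
    for _, r in df.iterrows():
        group_counts.setdefault(r["group"], {})[r["annotation_class"]] = int(r["count"])
        group_sizes[r["group"]] = int(r["size"])
    return group_counts, group_sizes
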