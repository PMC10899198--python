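"""Enhancer activity scores, z-score enhancer calls, and the allelic model.

Activity of element *e* in replicate *r* is the depth-normalised log ratio

    a_er = log2( ((rna_er + 1) / N_rna_r) / ((dna_er + 1) / N_dna_r) )

with N the per-replicate assay totals over retained elements and a +1
pseudocount keeping activities finite.  Pooled activity A_e uses counts
summed over replicates with the same formula.

General enhancers are elements whose pooled activity is >= 3 sample standard
deviations above the library mean (one-sided by default; a two-sided mode
flags |z| >= threshold).

Allele-specific activity uses an empirical-Bayes moderated t-test on the
per-replicate paired differences d_r = a_alt,r - a_ref,r.  Replicate is the
block, so any additive per-replicate effect shared by the two alleles
cancels exactly; for this balanced two-allele common-replicate design the
paired formulation is equivalent to the mixed correlated-groups model.  The
per-variant variance of d_r is shrunk toward a prior (d0, s0^2) estimated
from all variants by the standard method of moments on log variances: with
e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2),

    trigamma(d0/2) = max(0, var(e) * n/(n-1) - mean(trigamma(d_g/2)))
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))

(d0 = inf when the excess dispersion is <= 0, with s0^2 = exp(mean(e))).
The moderated statistic is t = betahat / (s_tilde * sqrt(1/R)) on
d0 + R - 1 degrees of freedom, with s_tilde^2 the weighted pool of prior
and sample variances.  P-values are adjusted by Benjamini-Hochberg and
variants are tiered: active (adj_p < 0.05), suggestive (0.05 <= adj_p <
0.1), ns otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from .quantification import replicates_of

TIER_ACTIVE = "active"
TIER_SUGGESTIVE = "suggestive"
TIER_NS = "ns"


class ActivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Activity


def compute_activity(elements: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate and pooled activity from an element-count table.

    Input is the aggregated table from :func:`mprakit.quantification.
    aggregate_elements` (retained elements only).  Returns a frame indexed by
    element_id with columns ``activity_1..R`` and pooled ``activity``.
    """
    reps = replicates_of(elements)
    out = pd.DataFrame(index=elements.index)
    for r in reps:
        dna = elements[f"dna_{r}"].to_numpy(float)
        rna = elements[f"rna_{r}"].to_numpy(float)
        n_dna, n_rna = dna.sum(), rna.sum()
        if n_dna == 0 or n_rna == 0:
            raise ActivityError(f"replicate {r} has zero total counts in one assay")
        out[f"activity_{r}"] = np.log2(((rna + 1) / n_rna) / ((dna + 1) / n_dna))
    dna_pool = elements[[f"dna_{r}" for r in reps]].sum(axis=1).to_numpy(float)
    rna_pool = elements[[f"rna_{r}" for r in reps]].sum(axis=1).to_numpy(float)
    out["activity"] = np.log2(
        ((rna_pool + 1) / rna_pool.sum()) / ((dna_pool + 1) / dna_pool.sum())
    )
    return out


def call_general_enhancers(
    activity: pd.DataFrame, z_threshold: float = 3.0, two_sided: bool = False
) -> pd.DataFrame:
    """Standardise pooled activity and flag elements beyond the z threshold.

    Returns a frame with columns ``activity, z, is_enhancer``.  When the
    library has no activity spread (sd = 0) all z are defined as 0 and
    nothing is called.
    """
    if len(activity) < 2:
        raise ActivityError("need at least 2 elements to standardise")
    pooled = activity["activity"].to_numpy(float)
    sd = pooled.std(ddof=1)
    z = np.zeros_like(pooled) if sd == 0 else (pooled - pooled.mean()) / sd
    flagged = (np.abs(z) >= z_threshold) if two_sided else (z >= z_threshold)
    return pd.DataFrame(
        {"activity": pooled, "z": z, "is_enhancer": flagged & (sd != 0)},
        index=activity.index,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom and variance for variance shrinkage."""

    d0: float  # may be math.inf
    s0_sq: float

    def moderate(self, s_sq: np.ndarray, d_g: np.ndarray) -> np.ndarray:
        """Posterior (shrunken) variances given sample variances and dfs."""
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, float), self.s0_sq)
        return (self.d0 * self.s0_sq + d_g * s_sq) / (self.d0 + d_g)


def estimate_moderation(s_sq: Sequence[float], d_g: Sequence[float] | float) -> ModerationParams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior."""
    s_sq = np.asarray(s_sq, float)
    n = s_sq.size
    d = np.broadcast_to(np.asarray(d_g, float), s_sq.shape)
    if n < 3:
        raise ActivityError(f"need >= 3 variances to estimate the prior, got {n}")
    if np.any(d < 1):
        raise ActivityError("residual degrees of freedom must be >= 1")
    if np.all(s_sq == 0):
        raise ActivityError("all sample variances are zero; prior is degenerate")
    # zero variances would send log s^2 to -inf; floor them far below the rest
    floor = s_sq[s_sq > 0].min() * 1e-8
    e = np.log(np.maximum(s_sq, floor)) - digamma(d / 2) + np.log(d / 2)
    target = e.var(ddof=0) * n / (n - 1) - float(np.mean(polygamma(1, d / 2)))
    if target <= polygamma(1, 1e6 / 2):
        d0 = math.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        lo = 1e-4
        if polygamma(1, lo / 2) < target:  # more dispersed than the bracket allows
            d0 = lo
        else:
            d0 = brentq(lambda x: polygamma(1, x / 2) - target, lo, 1e6, xtol=1e-8)
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2)))
    return ModerationParams(d0=float(d0), s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Allelic model


def moderated_t(
    beta: np.ndarray,
    s_sq: np.ndarray,
    d_g: np.ndarray,
    v_g: np.ndarray,
    prior: ModerationParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t, its degrees of freedom, and two-sided p-values."""
    beta = np.asarray(beta, float)
    s_tilde_sq = prior.moderate(np.asarray(s_sq, float), np.asarray(d_g, float))
    se = np.sqrt(s_tilde_sq * np.asarray(v_g, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    df = np.asarray(d_g, float) + (0.0 if math.isinf(prior.d0) else prior.d0)
    if math.isinf(prior.d0):
        p = 2 * sstats.norm.sf(np.abs(t))
        df = np.full_like(t, math.inf)
    else:
        p = 2 * sstats.t.sf(np.abs(t), df)
    return t, df, np.clip(p, np.nextafter(0, 1), 1.0)


def _log_odds(
    t: np.ndarray, df: np.ndarray, v_g: np.ndarray, prior: ModerationParams,
    proportion: float = 0.01,
) -> np.ndarray:
    """Log-odds of differential activity (B statistic).

    Uses the standard two-component scale-mixture form with the prior variance
    of the effect, v0, set by moment matching on the upper ``proportion`` tail
    of the t statistics (an approximation to the full mixture fit; B is
    reported for ranking only and is off by default).
    """
    t = np.asarray(t, float)
    df = np.asarray(df, float)
    v = np.asarray(v_g, float)
    m = t.size
    ntop = max(1, int(np.ceil(proportion * m)))
    top_t2 = np.sort(t**2)[::-1][:ntop]
    df_med = float(np.median(df))
    null_e = df_med / (df_med - 2) if df_med > 2 else 3.0
    ratio = max(float(top_t2.mean()) / null_e, 1.0)
    v0 = (ratio - 1.0) * float(np.median(v)) * prior.s0_sq
    r = (v + v0 / prior.s0_sq) / v  # total/residual variance ratio of betahat
    kernel = (t**2 + df) / (t**2 / r + df)
    return (
        math.log(proportion / (1 - proportion))
        - 0.5 * np.log(r)
        + 0.5 * (df + 1) * np.log(kernel)
    )


def tier_of(adj_p: float) -> str:
    if adj_p < 0.05:
        return TIER_ACTIVE
    if adj_p < 0.1:
        return TIER_SUGGESTIVE
    return TIER_NS


def fit_allelic_model(
    activity: pd.DataFrame,
    pairs: Mapping[str, tuple[str, str]],
    prior: ModerationParams | None = None,
    compute_b: bool = False,
    prior_proportion: float = 0.01,
) -> pd.DataFrame:
    """Test every complete ref/alt pair for allele-specific activity.

    ``activity`` is the per-replicate frame from :func:`compute_activity`;
    ``pairs`` maps variant_id to (ref element_id, alt element_id), e.g. from
    ``LibraryDesign.pairs``.  Pairs whose elements are not both present are
    skipped.  When ``prior`` is None the moderation hyperparameters are
    estimated from all tested variants.  Returns a frame indexed by
    variant_id with columns ``logFC, t, p, adj_p, B, tier`` plus the fitted
    ``s_sq``.
    """
    rep_cols = sorted(
        (c for c in activity.columns if c.startswith("activity_")),
        key=lambda c: int(c.split("_")[1]),
    )
    n_rep = len(rep_cols)
    if n_rep < 2:
        raise ActivityError("allelic testing needs >= 2 replicates")

    variant_ids, betas, s_sqs = [], [], []
    for variant_id, (ref_id, alt_id) in sorted(pairs.items()):
        if ref_id not in activity.index or alt_id not in activity.index:
            continue
        d = (
            activity.loc[alt_id, rep_cols].to_numpy(float)
            - activity.loc[ref_id, rep_cols].to_numpy(float)
        )
        variant_ids.append(variant_id)
        betas.append(d.mean())
        s_sqs.append(d.var(ddof=1))

    if not variant_ids:
        return pd.DataFrame(
            columns=["logFC", "t", "p", "adj_p", "B", "tier", "s_sq"]
        ).rename_axis("variant_id")

    beta = np.array(betas)
    s_sq = np.array(s_sqs)
    d_g = np.full(beta.shape, float(n_rep - 1))
    v_g = np.full(beta.shape, 1.0 / n_rep)
    if prior is None:
        prior = estimate_moderation(s_sq, d_g)
    t, df, p = moderated_t(beta, s_sq, d_g, v_g, prior)
    adj = adjust_fdr(p)
    b = _log_odds(t, df, v_g, prior, prior_proportion) if compute_b else np.full_like(t, np.nan)
    result = pd.DataFrame(
        {
            "logFC": beta,
            "t": t,
            "p": p,
            "adj_p": adj,
            "B": b,
            "tier": [tier_of(a) for a in adj],
            "s_sq": s_sq,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    result.attrs["moderation"] = prior
    result.attrs["n_replicates"] = n_rep
    return result


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ActivityError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
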