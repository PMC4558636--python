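"""Upper-quartile count normalization and expression-abundance classification.

Libraries are scaled so that the q-quantile (default q = 0.75) of their
nonzero gene counts agrees; the common value is the geometric mean of the
per-library quantiles, which keeps normalized magnitudes near the raw
counts.  Group means over replicates then drive two classifications:

* abundance — how many genes exceed read thresholds (>10, >500, >1000 by
  default; strict inequality) per group and for "either group";
* specificity — for a pair of groups, a gene is unique to A when its mean
  is above the presence threshold in A and at or below the absence
  threshold in B; genes above the presence threshold in both are common;
  genes below it in both are absent; everything else is ambiguous.

``category_join`` finally crosses motif-target calls with abundance strata
and user gene lists (transcription factors, RNA-binding proteins, ...) to
produce the stratified count tables typical of such screens.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "upper_quantile_factors",
    "upper_quantile_normalize",
    "group_means",
    "classify_abundance",
    "classify_specificity",
    "category_join",
]


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("count table is empty")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count table contains negative values")


def upper_quantile_factors(counts: pd.DataFrame, q: float = 0.75) -> pd.Series:
    """Per-library scale factor: the q-quantile of that library's nonzero counts.

    Quantiles use linear interpolation.  An all-zero library is an error
    (its quantile is undefined) and is named in the message.
    """
    if not 0 < q <= 1:
        raise ValueError("quantile q must be in (0, 1]")
    _validate_counts(counts)
    factors = {}
    for lib in counts.columns:
        col = counts[lib].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"library {lib!r} has no nonzero counts; cannot normalize")
        factors[lib] = float(np.quantile(nonzero, q))
    return pd.Series(factors, name="scale_factor")


def upper_quantile_normalize(counts: pd.DataFrame, q: float = 0.75) -> pd.DataFrame:
    """Scale each library by (geometric mean of factors) / (its own factor).

    After normalization the q-quantile of nonzero counts is identical across
    libraries, and re-normalizing is the identity map.
    """
    factors = upper_quantile_factors(counts, q)
    gmean = float(np.exp(np.log(factors.to_numpy()).mean()))
    return counts.astype(float) * (gmean / factors)


def group_means(
    normalized: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic per-gene mean over each group's replicate libraries."""
    missing = [lib for lib in normalized.columns if lib not in groups]
    if missing:
        raise ValueError(f"libraries with no group assignment: {missing}")
    by_group: dict[str, list[str]] = {}
    for lib in normalized.columns:
        by_group.setdefault(groups[lib], []).append(lib)
    return pd.DataFrame(
        {g: normalized[libs].mean(axis=1) for g, libs in sorted(by_group.items())}
    )


def classify_abundance(
    means: pd.DataFrame, thresholds: Sequence[float] = (10, 500, 1000)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene abundance class labels and per-threshold exceedance counts.

    Returns ``(classes, counts)``: ``classes`` holds one label per gene per
    group (``undetected`` for a zero mean, ``low`` below the first threshold,
    otherwise ``>t`` for the highest threshold strictly exceeded);
    ``counts`` tabulates ``n(mean > t)`` per group plus an ``either`` column
    (the gene exceeds t in at least one group).  Inequalities are strict.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")

    def label(x: float) -> str:
        for t in reversed(thresholds):
            if x > t:
                return f">{t:g}"
        return "undetected" if x == 0 else "low"

    classes = means.map(label)
    counts = pd.DataFrame(
        {
            g: [int((means[g] > t).sum()) for t in thresholds]
            for g in means.columns
        },
        index=[f">{t:g}" for t in thresholds],
    )
    counts["either"] = [
        int((means > t).any(axis=1).sum()) for t in thresholds
    ]
    return classes, counts


def classify_specificity(
    means: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    present_threshold: float = 10,
    absent_threshold: float = 0,
) -> pd.Series:
    """Unique / common / absent / ambiguous labels for a pair of groups.

    ``unique-to-A`` requires mean_A > present_threshold and
    mean_B <= absent_threshold (and symmetrically for B); ``common`` means
    both groups exceed the presence threshold; ``absent`` means neither
    does and neither is unique; genes in the undefined zone (present in one
    group, nonzero but below presence in the other) are ``ambiguous``.
    """
    if groups is None:
        if means.shape[1] != 2:
            raise ValueError(
                "specificity is a pairwise comparison; pass groups=(a, b) "
                "and invoke once per pair"
            )
        a, b = means.columns
    else:
        a, b = groups
    ma, mb = means[a], means[b]
    labels = pd.Series("ambiguous", index=means.index, name="specificity")
    labels[(ma > present_threshold) & (mb <= absent_threshold)] = f"unique-to-{a}"
    labels[(mb > present_threshold) & (ma <= absent_threshold)] = f"unique-to-{b}"
    labels[(ma > present_threshold) & (mb > present_threshold)] = "common"
    labels[(ma <= present_threshold) & (mb <= present_threshold)] = "absent"
    return labels


def category_join(
    means: pd.DataFrame,
    motif_targets: pd.DataFrame,
    gene_lists: Mapping[str, Iterable[str]] | None = None,
    de_labels: pd.Series | None = None,
    abundance_thresholds: Sequence[float] = (10, 500),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross motif-target calls with abundance strata and gene-list categories.

    ``motif_targets`` is a boolean genes x motifs table.  Strata are the
    whole gene universe (the index of ``means``), ``>t in either group`` for
    each abundance threshold, one stratum per user gene list (plus its
    intersections with the abundance strata), and — when differential-
    expression labels are supplied — the DE subset.  Returns
    ``(per_gene, counts)``: a long-format per-gene label table and a
    motif x stratum count table of motif-positive genes.

    Genes present in ``motif_targets`` but missing from ``means`` are logged
    and excluded from the stratified counts.
    """
    gene_lists = dict(gene_lists or {})
    universe = means.index

    stray = motif_targets.index.difference(universe)
    if len(stray):
        logger.warning(
            "%d gene(s) in motif calls are absent from the expression table "
            "and were excluded (e.g. %s)",
            len(stray), list(stray[:3]),
        )
    targets = motif_targets.astype(bool).reindex(universe, fill_value=False)

    strata: dict[str, pd.Series] = {
        "whole_genome": pd.Series(True, index=universe)
    }
    for t in abundance_thresholds:
        strata[f">{t:g}_either"] = (means > t).any(axis=1)
    for name, members in gene_lists.items():
        mask = universe.isin(set(members))
        strata[name] = pd.Series(mask, index=universe)
        for t in abundance_thresholds:
            strata[f"{name}_>{t:g}_either"] = strata[name] & strata[f">{t:g}_either"]
    if de_labels is not None:
        de = de_labels.reindex(universe).fillna(False).astype(bool)
        strata["de"] = de
        for t in abundance_thresholds:
            strata[f"de_>{t:g}_either"] = de & strata[f">{t:g}_either"]

    counts = pd.DataFrame(
        {
            stratum: {
                motif: int((targets[motif] & mask).sum())
                for motif in targets.columns
            }
            for stratum, mask in strata.items()
        }
    )
    counts.index.name = "motif"

    per_gene = pd.concat(
        [means.add_prefix("mean_"), targets.add_prefix("target_")], axis=1
    )
    for stratum, mask in strata.items():
        if stratum == "whole_genome":
            continue
        per_gene[f"in_{stratum}"] = mask
    per_gene.index.name = "gene_id"
    return per_gene, counts
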