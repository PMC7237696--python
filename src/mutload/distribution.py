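"""Enrichment and depletion of mutations in genomic region sets.

For a region set R and callable regions C, the expected count under uniform
placement is total * |R ∩ C| / |C|; the observed count is compared with a
one-sided exact binomial test in the observed direction.  The CDS result
yields the depletion factor dp = observed / expected that multiplies the
coding mutation rate in the oncogenic-risk model (a 2% depletion gives
dp = 0.98).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .regions import CallableRegionSet, RegionSet


@dataclass
class EnrichmentResult:
    region_name: str
    observed: int
    expected: float
    log2_ratio: float
    p_value: float
    direction: str  # "enriched" | "depleted" | "undefined"
    significant: bool
    total: int
    region_fraction: float


@dataclass
class DepletionFactor:
    dp: float

    def __post_init__(self):
        if self.dp < 0:
            raise ValueError("depletion factor must be non-negative")


def _count_in_region(mutations, region: RegionSet) -> int:
    if isinstance(mutations, pd.DataFrame):
        df = mutations
    else:
        df = pd.DataFrame(
            {"chrom": [m.contig for m in mutations], "pos": [m.position for m in mutations]}
        )
    n = 0
    for contig, sub in df.groupby("chrom", sort=False):
        n += int(region.contains(contig, sub["pos"].to_numpy()).sum())
    return n


def enrichment_test(
    mutations,
    region: RegionSet,
    callable_set: CallableRegionSet,
    region_name: str = "region",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided binomial test of mutation counts in a region set.

    ``mutations`` is a DataFrame with chrom/pos columns or a sequence of
    records; only its size and positions matter.  The tail is chosen by the
    observed direction: lower tail when observed < expected, upper tail
    otherwise.  An empty region-callable overlap yields an undefined, flagged
    result.
    """
    if isinstance(mutations, pd.DataFrame):
        total = len(mutations)
    else:
        mutations = list(mutations)
        total = len(mutations)
    if total < 1:
        raise ValueError("enrichment test needs at least one mutation")
    if callable_set.total_length == 0:
        raise ValueError("callable region set is empty")
    overlap = region.intersect(callable_set)
    frac = overlap.total_length / callable_set.total_length
    if frac == 0:
        return EnrichmentResult(
            region_name=region_name,
            observed=0,
            expected=0.0,
            log2_ratio=-math.inf,
            p_value=float("nan"),
            direction="undefined",
            significant=False,
            total=total,
            region_fraction=0.0,
        )
    observed = _count_in_region(mutations, overlap)
    expected = total * frac
    if observed >= expected:
        p = float(stats.binom.sf(observed - 1, total, frac))  # P(X >= observed)
        direction = "enriched"
    else:
        p = float(stats.binom.cdf(observed, total, frac))  # P(X <= observed)
        direction = "depleted"
    log2_ratio = -math.inf if observed == 0 else math.log2(observed / expected)
    return EnrichmentResult(
        region_name=region_name,
        observed=observed,
        expected=expected,
        log2_ratio=log2_ratio,
        p_value=p,
        direction=direction,
        significant=p < alpha,
        total=total,
        region_fraction=frac,
    )


def enrichment_table(
    mutations,
    regions: Dict[str, RegionSet],
    callable_set: CallableRegionSet,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Marginal enrichment tests over several (possibly overlapping) region sets.

    Region sets are tested independently; with ``bonferroni`` the
    significance threshold is divided by the number of sets.
    """
    thr = alpha / len(regions) if (bonferroni and regions) else alpha
    rows = []
    for name in regions:
        res = enrichment_test(mutations, regions[name], callable_set, region_name=name, alpha=thr)
        rows.append(
            {
                "region": name,
                "observed": res.observed,
                "expected": res.expected,
                "log2_ratio": res.log2_ratio,
                "p": res.p_value,
                "direction": res.direction,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def depletion_factor(cds_result: EnrichmentResult) -> DepletionFactor:
    """dp = observed / expected from the CDS enrichment result."""
    if cds_result.expected <= 0:
        raise ValueError("depletion factor undefined: expected count is zero")
    return DepletionFactor(dp=cds_result.observed / cds_result.expected)
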