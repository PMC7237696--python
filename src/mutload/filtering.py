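"""Identification of culture-acquired mutations from reference/clone/subclone
call sets, and conversion of counts to per-doubling and per-year rates.

The SBS chain retains subclone calls that lie in the joint callable regions,
pass site quality (>100) and depth (>20) thresholds, are clonal in the
subclone (VAF >= 0.3), show no evidence in the reference (alt depth 0), are
not clonal in the clone (VAF < 0.3), and are not at recurrent-artifact or
known-SNP blacklist positions.  Indels follow the analogous chain with PASS
status, genotype quality >= 99 and per-sample depth in [10, 60].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import MutationRecord, TrioDataset, records_from_frame
from .regions import CallableRegionSet, RegionSet
from .risk import HOURS_PER_YEAR

logger = logging.getLogger(__name__)

PositionKey = Tuple[str, int]


@dataclass
class SBSFilterParams:
    min_site_quality: float = 100.0  # strict: QUAL > 100
    min_depth: int = 20  # strict: DP > 20 in the subclone
    vaf_threshold: float = 0.3  # inclusive: subclone VAF >= 0.3
    clone_vaf_threshold: float = 0.3  # clonal-in-clone exclusion: clone VAF >= this
    blacklist_min_individuals: int = 3
    max_reference_alt_depth: int = 0

    def __post_init__(self):
        if not (0 < self.vaf_threshold < 1):
            raise ValueError("vaf_threshold must be in (0, 1)")
        if not (0 < self.clone_vaf_threshold < 1):
            raise ValueError("clone_vaf_threshold must be in (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be at least 1")


@dataclass
class IndelFilterParams:
    min_genotype_quality: int = 99
    min_support: int = 10
    max_support: int = 60
    vaf_threshold: float = 0.3  # strict: subclone VAF > 0.3
    require_pass: bool = True

    def __post_init__(self):
        if self.min_support >= self.max_support:
            raise ValueError("min_support must be below max_support")


@dataclass
class RateEstimate:
    genome_wide_count: float
    doublings: float
    mu: float
    per_year: Optional[float] = None


@dataclass
class ClonalityReport:
    median_vaf: float
    fraction_in_03_07: float
    passed: bool


@dataclass
class RateComparison:
    test: str  # "anova" | "t"
    statistic: float
    p_value: float
    group_sizes: Dict[str, int]


# ---------------------------------------------------------------------------
# callable regions


def compute_callable(
    coverage,
    min_base_quality: float = 10,
    min_mapping_quality: float = 10,
    min_depth: float = 20,
) -> CallableRegionSet:
    """Callable-loci regions from a per-interval coverage summary.

    ``coverage`` is a DataFrame with columns chrom/start/end/depth/
    base_quality/mapping_quality; intervals meeting every threshold
    (inclusive) are retained.  A :class:`RegionSet` is accepted as-is
    (pass-through mode for user-provided callable BEDs).
    """
    if isinstance(coverage, RegionSet):
        return CallableRegionSet(dict(coverage.intervals))
    if coverage is None:
        raise ValueError("provide a coverage summary table or a callable region set")
    needed = {"chrom", "start", "end", "depth", "base_quality", "mapping_quality"}
    missing = needed - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage summary missing columns: {sorted(missing)}")
    ok = (
        (coverage["depth"] >= min_depth)
        & (coverage["base_quality"] >= min_base_quality)
        & (coverage["mapping_quality"] >= min_mapping_quality)
    )
    kept = coverage[ok]
    if kept.empty:
        return CallableRegionSet({})
    return CallableRegionSet.from_intervals(
        zip(kept["chrom"], kept["start"], kept["end"])
    )


def intersect_callable(sets: Sequence[CallableRegionSet]) -> CallableRegionSet:
    """Intersection of callable regions across samples (associative, commutative)."""
    if len(sets) == 0:
        raise ValueError("need at least one callable region set")
    out = sets[0]
    for s in sets[1:]:
        out = out.intersect(s)
    return CallableRegionSet(dict(out.intervals))


# ---------------------------------------------------------------------------
# blacklist


def build_blacklist(
    panel: Iterable[pd.DataFrame],
    min_individuals: int = 3,
    extra_positions: Optional[Iterable[PositionKey]] = None,
) -> Set[PositionKey]:
    """Positions variable in >= ``min_individuals`` unrelated individuals,
    plus any externally supplied (e.g. known-SNP) positions."""
    counts: Dict[PositionKey, int] = {}
    for indiv in panel:
        for key in set(zip(indiv["chrom"], indiv["pos"])):
            counts[key] = counts.get(key, 0) + 1
    black = {k for k, c in counts.items() if c >= min_individuals}
    if extra_positions is not None:
        black |= {(c, int(p)) for c, p in extra_positions}
    return black


# ---------------------------------------------------------------------------
# filters


def _in_callable(df: pd.DataFrame, callable_set: CallableRegionSet) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    for contig, sub in df.groupby("chrom", sort=False):
        mask[df.index.get_indexer(sub.index)] = callable_set.contains(
            contig, sub["pos"].to_numpy()
        )
    return mask


def _blacklisted(df: pd.DataFrame, blacklist: Set[PositionKey]) -> np.ndarray:
    if not blacklist:
        return np.zeros(len(df), dtype=bool)
    keys = list(zip(df["chrom"], df["pos"].astype(int)))
    return np.array([k in blacklist for k in keys])


def _sorted_records(df: pd.DataFrame) -> List[MutationRecord]:
    df = df.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    return records_from_frame(df)


def filter_sbs(
    trio: TrioDataset,
    callable_set: CallableRegionSet,
    blacklist: Optional[Set[PositionKey]] = None,
    params: SBSFilterParams = SBSFilterParams(),
) -> List[MutationRecord]:
    """Culture-acquired SBS: subclone-unique clonal substitutions.

    Returns records sorted by (contig, position, alt).  An empty callable set
    yields an empty result with a logged warning.
    """
    blacklist = blacklist or set()
    df = trio.calls[trio.calls["var_class"] == "SBS"].reset_index(drop=True)
    if callable_set.total_length == 0:
        logger.warning("filter_sbs: empty callable region set; no calls retained")
        return []
    if df.empty:
        return []
    vaf_sub = trio_vafs(df, "subclone")
    vaf_clone = trio_vafs(df, "clone")
    keep = (
        _in_callable(df, callable_set)
        & (df["qual"].to_numpy(float) > params.min_site_quality)
        & (df["dp_subclone"].to_numpy(int) > params.min_depth)
        & (vaf_sub >= params.vaf_threshold)
        & (df["ad_reference"].to_numpy(int) <= params.max_reference_alt_depth)
        & (vaf_clone < params.clone_vaf_threshold)
        & ~_blacklisted(df, blacklist)
    )
    return _sorted_records(df[keep])


def filter_indels(
    trio: TrioDataset,
    callable_set: CallableRegionSet,
    blacklist: Optional[Set[PositionKey]] = None,
    params: IndelFilterParams = IndelFilterParams(),
    contigs: Optional[Sequence[str]] = None,
) -> List[MutationRecord]:
    """Culture-acquired indels: PASS, high genotype quality, balanced support.

    ``contigs`` restricts to an allow-list (e.g. autosomes); None keeps all.
    """
    blacklist = blacklist or set()
    df = trio.calls[trio.calls["var_class"] == "indel"].reset_index(drop=True)
    if callable_set.total_length == 0:
        logger.warning("filter_indels: empty callable region set; no calls retained")
        return []
    if contigs is not None:
        df = df[df["chrom"].isin(set(contigs))].reset_index(drop=True)
    if df.empty:
        return []
    vaf_sub = trio_vafs(df, "subclone")
    vaf_clone = trio_vafs(df, "clone")
    vaf_ref = trio_vafs(df, "reference")
    keep = _in_callable(df, callable_set) & ~_blacklisted(df, blacklist)
    if params.require_pass:
        keep &= (df["filter"] == "PASS").to_numpy()
    for role in ("reference", "clone", "subclone"):
        keep &= df[f"gq_{role}"].to_numpy(int) >= params.min_genotype_quality
        dp = df[f"dp_{role}"].to_numpy(int)
        keep &= (dp >= params.min_support) & (dp <= params.max_support)
    keep &= vaf_sub > params.vaf_threshold
    keep &= vaf_clone <= params.vaf_threshold
    keep &= vaf_ref <= params.vaf_threshold
    return _sorted_records(df[keep])


def trio_vafs(df: pd.DataFrame, role: str) -> np.ndarray:
    dp = df[f"dp_{role}"].to_numpy(float)
    ad = df[f"ad_{role}"].to_numpy(float)
    out = np.zeros(len(df))
    nz = dp > 0
    out[nz] = ad[nz] / dp[nz]
    return out


# ---------------------------------------------------------------------------
# clonality, extrapolation, rates


def check_clonality(vafs: Sequence[float]) -> ClonalityReport:
    """Verify a clonal culture by the VAF distribution centring on 0.5."""
    vafs = np.asarray(list(vafs), dtype=float)
    if len(vafs) == 0:
        raise ValueError("clonality is undefined for an empty VAF list")
    med = float(np.median(vafs))
    frac = float(((vafs >= 0.3) & (vafs <= 0.7)).mean())
    return ClonalityReport(median_vaf=med, fraction_in_03_07=frac, passed=0.4 <= med <= 0.6)


def extrapolate_genome_wide(count: float, callable_length: float, genome_length: float) -> float:
    """Scale a callable-region mutation count to the whole genome."""
    if callable_length <= 0:
        raise ValueError("callable length must be positive")
    if callable_length > genome_length:
        raise ValueError("callable length cannot exceed the genome length")
    return count * genome_length / callable_length


def estimate_rates(
    genome_wide_count: float,
    doublings: float,
    doubling_time_hours: Optional[float] = None,
) -> RateEstimate:
    """Mutations per genome per population doubling, and optionally per year."""
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    mu = genome_wide_count / doublings
    per_year = None
    if doubling_time_hours is not None:
        if doubling_time_hours <= 0:
            raise ValueError("doubling time must be positive")
        per_year = mu * HOURS_PER_YEAR / doubling_time_hours
    return RateEstimate(
        genome_wide_count=genome_wide_count,
        doublings=doublings,
        mu=mu,
        per_year=per_year,
    )


def compare_rates(groups: Dict[str, Sequence[float]]) -> RateComparison:
    """One-way ANOVA across >= 3 groups; Student's two-sided t-test for 2."""
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    sizes = {k: len(v) for k, v in arrays.items()}
    values = list(arrays.values())
    if len(values) == 2:
        res = stats.ttest_ind(values[0], values[1], equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # identical constant groups
            stat, p = 0.0, 1.0
        return RateComparison(test="t", statistic=stat, p_value=p, group_sizes=sizes)
    res = stats.f_oneway(*values)
    stat, p = float(res.statistic), float(res.pvalue)
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return RateComparison(test="anova", statistic=stat, p_value=p, group_sizes=sizes)
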