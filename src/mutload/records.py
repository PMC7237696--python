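"""Variant records and the reference/clone/subclone trio container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .regions import CallableRegionSet

SAMPLE_ROLES = ("reference", "clone", "subclone")

#: Columns of the trio call table.  Positions are internal 0-based; VCF
#: emission converts to 1-based.
CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "filter",
    "var_class",  # "SBS" | "indel"
    "dp_reference",
    "ad_reference",
    "gq_reference",
    "dp_clone",
    "ad_clone",
    "gq_clone",
    "dp_subclone",
    "ad_subclone",
    "gq_subclone",
]


@dataclass
class MutationRecord:
    """One variant call with per-sample evidence and filter provenance."""

    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    var_class: str  # "SBS" | "indel"
    qual: float
    filter_status: str
    depth: Dict[str, int]
    alt_depth: Dict[str, int]
    genotype_quality: Dict[str, int]

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.var_class == "SBS" and not (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValueError("SBS records require single-base ref and alt")

    def vaf(self, sample: str) -> float:
        dp = self.depth[sample]
        return self.alt_depth[sample] / dp if dp > 0 else 0.0


def records_from_frame(calls: pd.DataFrame) -> List[MutationRecord]:
    out = []
    for row in calls.itertuples(index=False):
        out.append(
            MutationRecord(
                contig=row.chrom,
                position=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                var_class=row.var_class,
                qual=float(row.qual),
                filter_status=row.filter,
                depth={r: int(getattr(row, f"dp_{r}")) for r in SAMPLE_ROLES},
                alt_depth={r: int(getattr(row, f"ad_{r}")) for r in SAMPLE_ROLES},
                genotype_quality={r: int(getattr(row, f"gq_{r}")) for r in SAMPLE_ROLES},
            )
        )
    return out


def frame_from_records(records: List[MutationRecord]) -> pd.DataFrame:
    rows = []
    for m in records:
        row = {
            "chrom": m.contig,
            "pos": m.position,
            "ref": m.ref,
            "alt": m.alt,
            "qual": m.qual,
            "filter": m.filter_status,
            "var_class": m.var_class,
        }
        for r in SAMPLE_ROLES:
            row[f"dp_{r}"] = m.depth[r]
            row[f"ad_{r}"] = m.alt_depth[r]
            row[f"gq_{r}"] = m.genotype_quality[r]
        rows.append(row)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class TrioDataset:
    """Joint call table of a reference/clone/subclone trio.

    ``calls`` holds one row per variant with per-sample depth (dp), alt depth
    (ad) and genotype quality (gq).  ``callable_regions`` maps sample role to
    its callable-loci set.  ``panel`` holds the call positions of simulated
    (or externally supplied) unrelated individuals, used for the
    recurrent-artifact blacklist.
    """

    calls: pd.DataFrame
    callable_regions: Dict[str, CallableRegionSet] = field(default_factory=dict)
    panel: List[pd.DataFrame] = field(default_factory=list)
    sample_names: Dict[str, str] = field(
        default_factory=lambda: {r: r.upper() for r in SAMPLE_ROLES}
    )

    def __post_init__(self):
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"trio call table missing columns: {missing}")

    def vaf(self, role: str) -> pd.Series:
        if role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample role {role!r}; expected one of {SAMPLE_ROLES}")
        dp = self.calls[f"dp_{role}"].to_numpy(float)
        ad = self.calls[f"ad_{role}"].to_numpy(float)
        out = pd.Series(0.0, index=self.calls.index)
        nz = dp > 0
        out[nz] = ad[nz] / dp[nz]
        return out
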