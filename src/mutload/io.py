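"""Readers and writers for the formats the pipeline touches.

VCF 4.2 (multi-sample, FORMAT GT:DP:AD:GQ) for trio call sets, BED3 for
regions, FASTA for the toy reference, and TSV for truth tables, signature
matrices, driver catalogs and derived results.  Every writer stamps a
comment header with the seed and configuration hash it was given, so
outputs are reproducible and diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .channels import CHANNELS_96
from .records import CALL_COLUMNS, MutationRecord, SAMPLE_ROLES, TrioDataset
from .regions import CallableRegionSet, RegionSet
from .risk import DriverCatalog
from .spectra import Profile96, SignatureSet

logger = logging.getLogger(__name__)


def _meta_lines(meta: Optional[Dict], prefix: str = "#") -> List[str]:
    if not meta:
        return []
    return [f"{prefix} {k}={v}" for k, v in meta.items()]


# ---------------------------------------------------------------------------
# FASTA


def write_reference_fasta(ref, path, width: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(ref.sequences):
            fh.write(f">{name}\n")
            seq = ref.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reference_fasta(path):
    """Load a FASTA (via pyfaidx) as a ToyReference with sequences in memory."""
    import pyfaidx

    from .synthetic import ToyReference

    fa = pyfaidx.Fasta(str(path))
    return ToyReference(
        sequences={name: str(fa[name][:]).upper() for name in fa.keys()}
    )


# ---------------------------------------------------------------------------
# VCF


def write_trio_vcf(
    trio: TrioDataset,
    path,
    contig_lengths: Optional[Dict[str, int]] = None,
    meta: Optional[Dict] = None,
) -> None:
    """Emit the trio call table as a three-sample VCF 4.2 (GT:DP:AD:GQ).

    Internal 0-based positions are converted to 1-based VCF coordinates.
    """
    path = Path(path)
    calls = trio.calls
    if contig_lengths is None:
        contig_lengths = {
            c: int(calls.loc[calls["chrom"] == c, "pos"].max()) + 2
            for c in calls["chrom"].unique()
        }
    sample_names = [trio.sample_names[r] for r in SAMPLE_ROLES]
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutload\n")
        for line in _meta_lines(meta, prefix="##"):
            fh.write(line.replace("## ", "##mutload_") + "\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        ordered = calls.sort_values(["chrom", "pos", "alt"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            fields = [
                row.chrom,
                str(int(row.pos) + 1),
                ".",
                row.ref,
                row.alt,
                f"{row.qual:g}",
                row.filter,
                ".",
                "GT:DP:AD:GQ",
            ]
            for role in SAMPLE_ROLES:
                dp = int(getattr(row, f"dp_{role}"))
                ad = int(getattr(row, f"ad_{role}"))
                gq = int(getattr(row, f"gq_{role}"))
                if ad == 0:
                    gt = "0/0"
                elif dp > 0 and ad / dp >= 0.9:
                    gt = "1/1"
                else:
                    gt = "0/1"
                fields.append(f"{gt}:{dp}:{max(dp - ad, 0)},{ad}:{gq}")
            fh.write("\t".join(fields) + "\n")


def read_trio_vcf(path, roles: Optional[Dict[str, str]] = None) -> TrioDataset:
    """Read a three-sample VCF back into a trio call table.

    ``roles`` maps sample role -> VCF sample name; by default the names
    REFERENCE/CLONE/SUBCLONE are matched case-insensitively, falling back to
    column order.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) < 3:
        raise ValueError("trio VCF requires three samples")
    if roles is None:
        lowered = {s.lower(): s for s in samples}
        if all(r in lowered for r in SAMPLE_ROLES):
            roles = {r: lowered[r] for r in SAMPLE_ROLES}
        else:
            roles = dict(zip(SAMPLE_ROLES, samples))
    rows = []
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        alt = rec.alts[0]
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos - 1,
            "ref": rec.ref,
            "alt": alt,
            "qual": float(rec.qual) if rec.qual is not None else 0.0,
            "filter": ";".join(rec.filter.keys()) if list(rec.filter) else "PASS",
            "var_class": "SBS" if len(rec.ref) == 1 and len(alt) == 1 else "indel",
        }
        ok = True
        for role in SAMPLE_ROLES:
            smp = rec.samples[roles[role]]
            dp = smp.get("DP")
            ad = smp.get("AD")
            if dp is None or ad is None:
                ok = False
                break
            row[f"dp_{role}"] = int(dp)
            row[f"ad_{role}"] = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
            gq = smp.get("GQ")
            row[f"gq_{role}"] = int(gq) if gq is not None else 0
        if not ok:
            skipped += 1
            continue
        rows.append(row)
    if skipped:
        logger.warning("read_trio_vcf: skipped %d record(s) missing DP/AD", skipped)
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return TrioDataset(calls=calls, sample_names={r: roles[r] for r in SAMPLE_ROLES})


def read_mutations(path) -> List[MutationRecord]:
    """Read any GT:DP:AD VCF into mutation records keyed by sample name."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    out: List[MutationRecord] = []
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        alt = rec.alts[0]
        depth, alt_depth, gq = {}, {}, {}
        ok = True
        for s in samples:
            smp = rec.samples[s]
            dp, ad = smp.get("DP"), smp.get("AD")
            if dp is None or ad is None:
                ok = False
                break
            depth[s] = int(dp)
            alt_depth[s] = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
            g = smp.get("GQ")
            gq[s] = int(g) if g is not None else 0
        if not ok:
            skipped += 1
            continue
        out.append(
            MutationRecord(
                contig=rec.chrom,
                position=rec.pos - 1,
                ref=rec.ref,
                alt=alt,
                var_class="SBS" if len(rec.ref) == 1 and len(alt) == 1 else "indel",
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                filter_status=";".join(rec.filter.keys()) if list(rec.filter) else "PASS",
                depth=depth,
                alt_depth=alt_depth,
                genotype_quality=gq,
            )
        )
    if skipped:
        logger.warning("read_mutations: skipped %d record(s) missing DP/AD", skipped)
    return out


def write_mutations_tsv(records: Sequence[MutationRecord], path, meta=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("chrom\tpos\tref\talt\tclass\tqual\tfilter\tvaf_subclone\n")
        for m in records:
            vaf = m.vaf("subclone") if "subclone" in m.depth else ""
            fh.write(
                f"{m.contig}\t{m.position}\t{m.ref}\t{m.alt}\t{m.var_class}\t"
                f"{m.qual:g}\t{m.filter_status}\t{vaf}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_regions(path) -> RegionSet:
    """BED3 (0-based half-open) into a merged, sorted region set."""
    intervals = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    if not intervals:
        return RegionSet({})
    return RegionSet.from_intervals(intervals)


def write_regions(region: RegionSet, path, meta=None) -> None:
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        for contig, start, end in region:
            fh.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_truth_tsv(truth, path, meta=None) -> None:
    table = truth.table.rename(columns={"vaf_reference": "vaf_ref"})
    cols = ["chrom", "pos", "ref", "alt", "class", "vaf_ref", "vaf_clone", "vaf_subclone"]
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        table[cols].to_csv(fh, sep="\t", index=False)


def read_truth_tsv(path):
    from .synthetic import PlantedTruth

    table = pd.read_csv(path, sep="\t", comment="#")
    table = table.rename(columns={"vaf_ref": "vaf_reference"})
    return PlantedTruth(table=table)


def write_signature_matrix(sigs: SignatureSet, path, meta=None) -> None:
    """96-row TSV; first column 'channel' in the documented fixed order."""
    frame = sigs.as_frame()
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("# channel order: substitution-major (C>A..T>G), context-minor (5' then 3', ACGT)\n")
        frame.rename_axis("channel").to_csv(fh, sep="\t")


def read_signature_matrix(path, source: str = "reference") -> SignatureSet:
    """Load a 96-row signature TSV; rows are reordered by the channel column.

    Columns off normalization by more than 1e-6 are renormalized with a
    warning; a wrong row count is a hard error.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if len(frame) != 96:
        raise ValueError(f"signature table must have 96 data rows, found {len(frame)}")
    missing = set(CHANNELS_96) - set(frame.index)
    if missing:
        raise ValueError(f"signature table missing channels, e.g. {sorted(missing)[:3]}")
    frame = frame.loc[list(CHANNELS_96)]
    sums = frame.sum(axis=0)
    off = (sums - 1.0).abs() > 1e-6
    if off.any():
        logger.warning(
            "read_signature_matrix: renormalizing columns off by > 1e-6: %s",
            list(sums.index[off]),
        )
    return SignatureSet(names=list(frame.columns), matrix=frame.to_numpy(), source=source)


def write_profile_tsv(profile: Profile96, path, meta=None) -> None:
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("channel\tweight\n")
        for name, w in zip(CHANNELS_96, profile.weights):
            fh.write(f"{name}\t{w:.10g}\n")


def read_profile_tsv(path) -> Profile96:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame = frame.loc[list(CHANNELS_96)]
    return Profile96(weights=frame.iloc[:, 0].to_numpy())


def write_driver_catalog(catalog: DriverCatalog, path, meta=None) -> None:
    """Per-site records when available, aggregate counts otherwise; the CDS
    length rides in a '# cds_length=' comment."""
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write(f"# cds_length={catalog.L}\n")
        if catalog.sites is not None and len(catalog.sites):
            catalog.sites.to_csv(fh, sep="\t", index=False)
        else:
            fh.write("type\tcount\n")
            for t, n in catalog.counts.items():
                fh.write(f"{t}\t{n}\n")


def read_driver_catalog(path) -> DriverCatalog:
    from .channels import pyrimidine_context

    L = None
    with Path(path).open() as fh:
        header_comments = []
        for line in fh:
            if line.startswith("#"):
                header_comments.append(line)
            else:
                break
    for line in header_comments:
        if "cds_length=" in line:
            L = int(line.split("cds_length=")[1].strip())
    if L is None:
        raise ValueError("driver catalog is missing the '# cds_length=' header")
    frame = pd.read_csv(path, sep="\t", comment="#")
    if {"type", "count"} <= set(frame.columns):
        counts = dict(zip(frame["type"], frame["count"].astype(int)))
        return DriverCatalog(L=L, counts=counts)
    needed = {"chrom", "pos", "ref", "alt"}
    if not needed <= set(frame.columns):
        raise ValueError("driver catalog needs chrom/pos/ref/alt or type/count columns")
    counts: Dict[str, int] = {}
    for row in frame.itertuples(index=False):
        _, r, _, a = pyrimidine_context("N", row.ref, "N", row.alt)
        t = f"{r}>{a}"
        counts[t] = counts.get(t, 0) + 1
    return DriverCatalog(L=L, counts=counts, sites=frame)


def write_panel_tsv(panel: Iterable[pd.DataFrame], path, meta=None) -> None:
    """Unrelated-individual call positions as one long TSV with an individual id."""
    frames = []
    for i, indiv in enumerate(panel):
        f = indiv.copy()
        f.insert(0, "individual", i)
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["individual", "chrom", "pos", "ref", "alt", "vaf"]
    )
    with Path(path).open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        merged.to_csv(fh, sep="\t", index=False)


def read_panel_tsv(path) -> List[pd.DataFrame]:
    merged = pd.read_csv(path, sep="\t", comment="#")
    if merged.empty:
        return []
    return [g.drop(columns="individual").reset_index(drop=True) for _, g in merged.groupby("individual")]
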