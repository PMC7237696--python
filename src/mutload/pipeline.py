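"""End-to-end pipeline: simulate (optional) -> filter -> rates -> spectra ->
signatures -> genomic distribution -> oncogenic risk.

Every stage failure is re-raised with the stage name; outputs are TSV/VCF
files plus a machine-readable JSON summary, all stamped with the seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import io as mio
from .distribution import depletion_factor, enrichment_table
from .filtering import (
    IndelFilterParams,
    SBSFilterParams,
    build_blacklist,
    check_clonality,
    estimate_rates,
    extrapolate_genome_wide,
    filter_indels,
    filter_sbs,
    intersect_callable,
)
from .records import frame_from_records
from .risk import RiskParams, cells_per_event, oncogenic_count, oncogenic_probability, risk_curve
from .spectra import collapse_spectrum7, profile96
from .synthetic import (
    TrioSimConfig,
    generate_driver_catalog,
    generate_reference,
    generate_region_sets,
    simulate_trio,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: str = "mutload_out"
    seed: int = 0
    # synthetic mode (used when trio_vcf is not given)
    simulate: bool = True
    reference_length: int = 100_000
    gc_fraction: float = 0.41
    sim: Dict = field(default_factory=dict)  # TrioSimConfig overrides
    region_fractions: Dict[str, float] = field(
        default_factory=lambda: {"genic": 0.40, "CDS": 0.015, "promoter": 0.02, "LAD": 0.30}
    )
    driver_sites_per_type: Dict[str, int] = field(default_factory=lambda: {"C>T": 2})
    # file mode
    trio_vcf: Optional[str] = None
    reference_fasta: Optional[str] = None
    callable_beds: Dict[str, str] = field(default_factory=dict)
    blacklist_tsv: Optional[str] = None
    region_beds: Dict[str, str] = field(default_factory=dict)
    driver_catalog: Optional[str] = None
    # analysis parameters
    doublings: float = 40.0
    doubling_time_hours: float = 44.0
    genome_length: Optional[float] = None
    risk_cells: float = 1e8
    sbs_filter: Dict = field(default_factory=dict)
    indel_filter: Dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the configured stages and return the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    summary: Dict = {"seed": config.seed, "config_hash": meta["config_hash"]}

    # --- inputs -----------------------------------------------------------
    if config.trio_vcf is None and config.simulate:
        ref = generate_reference(config.reference_length, config.gc_fraction, seed=config.seed)
        cfg = TrioSimConfig(seed=config.seed, **config.sim)
        trio, truth = _stage("simulate")(simulate_trio)(ref, cfg)
        regions = generate_region_sets(ref, config.region_fractions, seed=config.seed + 1)
        catalog = None
        if config.driver_sites_per_type and "CDS" in regions:
            catalog = generate_driver_catalog(
                ref, regions["CDS"], config.driver_sites_per_type, seed=config.seed + 2
            )
        mio.write_reference_fasta(ref, out / "reference.fa")
        mio.write_trio_vcf(
            trio,
            out / "trio.vcf",
            contig_lengths={c: len(s) for c, s in ref.sequences.items()},
            meta=meta,
        )
        mio.write_truth_tsv(truth, out / "truth.tsv", meta=meta)
        for name, rs in regions.items():
            mio.write_regions(rs, out / f"regions_{name}.bed", meta=meta)
        if catalog is not None:
            mio.write_driver_catalog(catalog, out / "driver_catalog.tsv", meta=meta)
        blacklist = build_blacklist(trio.panel)
    else:
        if config.trio_vcf is None:
            raise ValueError("either enable simulate or provide trio_vcf")
        trio = _stage("read_trio")(mio.read_trio_vcf)(config.trio_vcf)
        ref = (
            mio.read_reference_fasta(config.reference_fasta)
            if config.reference_fasta
            else None
        )
        regions = {name: mio.read_regions(p) for name, p in config.region_beds.items()}
        catalog = (
            mio.read_driver_catalog(config.driver_catalog) if config.driver_catalog else None
        )
        if config.callable_beds:
            trio.callable_regions = {
                role: mio.read_regions(p) for role, p in config.callable_beds.items()
            }
        blacklist = set()
        if config.blacklist_tsv:
            import pandas as pd

            bl = pd.read_csv(config.blacklist_tsv, sep="\t", comment="#")
            blacklist = set(zip(bl["chrom"], bl["pos"].astype(int)))

    # --- filtering --------------------------------------------------------
    if not trio.callable_regions:
        raise ValueError("no callable regions available (provide callable_beds)")
    joint_callable = _stage("intersect_callable")(intersect_callable)(
        list(trio.callable_regions.values())
    )
    sbs_params = SBSFilterParams(**config.sbs_filter)
    indel_params = IndelFilterParams(**config.indel_filter)
    sbs = _stage("filter_sbs")(filter_sbs)(trio, joint_callable, blacklist, sbs_params)
    indels = _stage("filter_indels")(filter_indels)(trio, joint_callable, blacklist, indel_params)
    mio.write_mutations_tsv(sbs, out / "sbs_filtered.tsv", meta=meta)
    mio.write_mutations_tsv(indels, out / "indels_filtered.tsv", meta=meta)
    summary["n_sbs"] = len(sbs)
    summary["n_indels"] = len(indels)

    if sbs:
        clon = check_clonality([m.vaf("subclone") for m in sbs])
        summary["clonality"] = asdict(clon)

    # --- rates ------------------------------------------------------------
    genome_length = config.genome_length or joint_callable.total_length
    gw = extrapolate_genome_wide(len(sbs), joint_callable.total_length, genome_length)
    rates = estimate_rates(gw, config.doublings, config.doubling_time_hours)
    summary["rates"] = asdict(rates)

    # --- spectra ----------------------------------------------------------
    dp_value = None
    if sbs and ref is not None:
        prof = _stage("profile")(profile96)(frame_from_records(sbs), ref)
        spec7 = collapse_spectrum7(prof)
        mio.write_profile_tsv(prof, out / "profile96.tsv", meta=meta)
        summary["spectrum7"] = {k: float(v) for k, v in spec7.as_dict().items()}

        # --- genomic distribution ----------------------------------------
        if regions:
            dist = _stage("distribution")(enrichment_table)(
                frame_from_records(sbs), regions, joint_callable
            )
            dist.to_csv(out / "distribution.tsv", sep="\t", index=False)
            summary["distribution"] = dist.to_dict(orient="records")
            if "CDS" in regions:
                cds_row = dist[dist["region"] == "CDS"].iloc[0]
                if cds_row["expected"] > 0:
                    dp_value = float(cds_row["observed"] / cds_row["expected"])
                    summary["dp"] = dp_value

        # --- risk ---------------------------------------------------------
        if catalog is not None:
            params = RiskParams(
                mu=rates.mu,
                dp=dp_value if dp_value is not None else 1.0,
                D=config.doubling_time_hours,
                spectrum=spec7,
            )
            curve = risk_curve(
                np.logspace(4, np.log10(config.risk_cells), 9), params, catalog
            )
            curve.to_csv(out / "risk_curve.tsv", sep="\t", index=False)
            per_event, finite = cells_per_event(params, catalog)
            summary["risk"] = {
                "M_active_at_N": oncogenic_count(config.risk_cells, params, catalog),
                "P_at_least_one_at_N": oncogenic_probability(config.risk_cells, params, catalog),
                "cells_per_event": per_event if finite else None,
                "N": config.risk_cells,
            }

    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
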