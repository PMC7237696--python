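"""Synthetic trio call sets, growth curves, region sets, and driver catalogs
with planted ground truth.

The generator emulates the clone -> subclone experimental design: a clonal
line is grown from one cell, cultured while mutations accumulate, and a
second single-cell (subclone) step is performed.  Variants fall into five
classes with distinct true-VAF structure:

``germline``
    present in all three samples at VAF 0.5 (het) or 1.0 (hom).
``pre_clonal``
    acquired before the first clonal step: VAF 0.5 in clone and subclone,
    absent from the reference.
``culture``
    acquired between the two clonal steps — the measurement target: VAF 0.5
    in the subclone only.
``post_clonal``
    acquired after the subclone step; subclonal VAF in the subclone only.
    True VAFs follow the branching structure of the expansion (each later
    generation contributes twice as many mutations at half the cell
    fraction), capped at ``subclonal_vaf_max``.
``artifact``
    recurrent-artifact positions: clonal-looking in the subclone, and called
    at low VAF (0.05-0.15) in three or more simulated unrelated individuals,
    so the recurrence blacklist is what removes them.

Observed evidence is sampled as depth ~ Poisson(mean_depth) truncated at
>= 1 and alt reads ~ Binomial(depth, true VAF); ``exact_vafs=True`` replaces
the sampling by fixed depth and rounded alt counts for noise-free tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    CHANNELS_96,
    complement,
    parse_channel,
    pyrimidine_context,
)
from .records import CALL_COLUMNS, SAMPLE_ROLES, TrioDataset
from .regions import CallableRegionSet, RegionSet
from .risk import DriverCatalog
from .spectra import Profile96, Spectrum7

#: Default culture-acquired spectrum: the oxidative-stress-dominated in vitro
#: pattern (~40% C>T, mostly outside CpG) seen in cultured stem cells.
DEFAULT_CULTURE_SPECTRUM = Spectrum7.from_dict(
    {
        "C>A": 0.10,
        "C>G": 0.08,
        "C>T at CpG": 0.05,
        "C>T other": 0.35,
        "T>A": 0.10,
        "T>C": 0.22,
        "T>G": 0.10,
    }
)

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class ToyReference:
    """Small in-memory reference genome (stands in for a real assembly)."""

    sequences: Dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not set(seq) <= set(BASES):
                raise ValueError(f"contig {name} contains non-ACGT characters")
        if self.total_length < 3:
            raise ValueError("reference must be at least 3 bases (trinucleotide contexts)")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gc_fraction(self) -> float:
        gc = sum(s.count("G") + s.count("C") for s in self.sequences.values())
        return gc / self.total_length


def generate_reference(total_length: int, gc_fraction: float, seed: int) -> ToyReference:
    """Random single-contig reference with i.i.d. bases at the given GC content."""
    if total_length < 1000:
        raise ValueError("total_length must be at least 1000")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    codes = rng.choice(4, size=total_length, p=p)
    seq = "".join(BASES[c] for c in codes)
    return ToyReference(sequences={"toy_1": seq})


@dataclass
class TrioSimConfig:
    """Planted-variant counts and sequencing-noise settings for one trio."""

    n_germline: int = 100
    n_culture: int = 50
    n_subclonal: int = 30
    n_artifact_positions: int = 5
    n_pre_clonal: int = 0
    n_germline_indels: int = 0
    n_culture_indels: int = 0
    culture_spectrum: object = None  # Spectrum7 | Profile96 | dict; default above
    mean_depth: float = 30.0
    subclonal_vaf_max: float = 0.25
    het_fraction: float = 2 / 3
    exact_vafs: bool = False
    n_panel_individuals: int = 3
    seed: int = 0

    def __post_init__(self):
        counts = [
            self.n_germline,
            self.n_culture,
            self.n_subclonal,
            self.n_artifact_positions,
            self.n_pre_clonal,
            self.n_germline_indels,
            self.n_culture_indels,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("planted-variant counts must be non-negative")
        if not (0 < self.subclonal_vaf_max < 0.3):
            raise ValueError("subclonal_vaf_max must be in (0, 0.3)")
        if self.mean_depth < 20:
            raise ValueError("mean_depth must be at least 20")
        if self.n_panel_individuals < 3 and self.n_artifact_positions > 0:
            raise ValueError("artifact positions need at least 3 panel individuals")


@dataclass
class PlantedTruth:
    """Ground-truth labels and true per-sample VAFs of every planted variant."""

    table: pd.DataFrame  # chrom, pos, ref, alt, var_class, class, vaf_reference, vaf_clone, vaf_subclone

    def of_class(self, label: str, var_class: Optional[str] = None) -> pd.DataFrame:
        sub = self.table[self.table["class"] == label]
        if var_class is not None:
            sub = sub[sub["var_class"] == var_class]
        return sub.reset_index(drop=True)

    def keys_of_class(self, label: str, var_class: Optional[str] = None) -> set:
        sub = self.of_class(label, var_class)
        return set(zip(sub["chrom"], sub["pos"], sub["alt"]))


def _coerce_profile(spectrum) -> Profile96:
    if spectrum is None:
        spectrum = DEFAULT_CULTURE_SPECTRUM
    if isinstance(spectrum, Profile96):
        return spectrum
    if isinstance(spectrum, Spectrum7):
        return spectrum.to_profile96()
    if isinstance(spectrum, dict):
        total = sum(spectrum.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"culture spectrum is not normalized (sums to {total})")
        if len(spectrum) == 7 or len(spectrum) == 6:
            return Spectrum7.from_dict(
                spectrum
                if len(spectrum) == 7
                else {
                    "C>A": spectrum.get("C>A", 0),
                    "C>G": spectrum.get("C>G", 0),
                    "C>T at CpG": 0.0,
                    "C>T other": spectrum.get("C>T", 0),
                    "T>A": spectrum.get("T>A", 0),
                    "T>C": spectrum.get("T>C", 0),
                    "T>G": spectrum.get("T>G", 0),
                }
            ).to_profile96()
        return Profile96(weights=np.array([spectrum.get(c, 0.0) for c in CHANNELS_96]))
    raise TypeError("culture_spectrum must be a Spectrum7, Profile96, or dict")


def _context_classes(ref: ToyReference):
    """Index interior positions by pyrimidine-strand trinucleotide context.

    Returns {(five, pyr_base, three): [(contig, pos), ...]} with strand
    collapse applied (a G or A at pos is classified via the reverse
    complement of its context).
    """
    classes: Dict[Tuple[str, str, str], List[Tuple[str, int]]] = {}
    for contig, seq in ref.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.zeros(len(arr), dtype=np.int8)
        for b, i in _BASE_CODE.items():
            code[arr == ord(b)] = i
        five, mid, three = code[:-2], code[1:-1], code[2:]
        comp = 3 - code
        is_pur = (mid == 0) | (mid == 2)  # A or G
        f = np.where(is_pur, comp[2:], five)
        m = np.where(is_pur, 3 - mid, mid)
        t = np.where(is_pur, comp[:-2], three)
        key_id = f * 16 + m * 4 + t
        for kid in np.unique(key_id):
            pos = np.flatnonzero(key_id == kid) + 1
            key = (BASES[kid // 16], BASES[(kid % 16) // 4], BASES[kid % 4])
            classes.setdefault(key, []).extend((contig, int(p)) for p in pos)
    return classes


def _truncated_poisson(rng, lam: float, size: int) -> np.ndarray:
    out = rng.poisson(lam, size=size)
    while (out == 0).any():
        zeros = out == 0
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))
    return out


def simulate_trio(ref: ToyReference, cfg: TrioSimConfig) -> Tuple[TrioDataset, PlantedTruth]:
    """Simulate a reference/clone/subclone trio with planted ground truth.

    Culture mutations are placed at positions whose trinucleotide context
    matches a channel drawn from ``cfg.culture_spectrum`` (pyrimidine-strand
    convention); other classes are placed uniformly.  Raises if a requested
    channel has no remaining eligible positions, naming the channel.
    """
    rng = np.random.default_rng(cfg.seed)
    profile = _coerce_profile(cfg.culture_spectrum)

    classes = _context_classes(ref)
    used: set = set()
    all_interior = [
        (contig, p)
        for contig, seq in sorted(ref.sequences.items())
        for p in range(1, len(seq) - 1)
    ]
    n_total = (
        cfg.n_germline
        + cfg.n_culture
        + cfg.n_subclonal
        + cfg.n_artifact_positions
        + cfg.n_pre_clonal
        + cfg.n_germline_indels
        + cfg.n_culture_indels
    )
    if n_total > len(all_interior):
        raise ValueError("more planted variants requested than distinct positions available")

    rows = []  # (chrom, pos, ref, alt, var_class, class, vafs...)

    def base_at(contig, pos):
        return ref.sequences[contig][pos]

    # --- culture SBS: context-aware placement -----------------------------
    channel_counts = rng.multinomial(cfg.n_culture, profile.weights)
    for ci in np.flatnonzero(channel_counts):
        k = int(channel_counts[ci])
        name = CHANNELS_96[ci]
        five, pyr, alt_pyr, three = parse_channel(name)
        pool = [xy for xy in classes.get((five, pyr, three), []) if xy not in used]
        if len(pool) < k:
            raise ValueError(
                f"insufficient eligible context positions for channel {name}: "
                f"need {k}, have {len(pool)}"
            )
        picks = rng.choice(len(pool), size=k, replace=False)
        for idx in picks:
            contig, pos = pool[idx]
            used.add((contig, pos))
            ref_base = base_at(contig, pos)
            alt = alt_pyr if ref_base == pyr else complement(alt_pyr)
            rows.append((contig, pos, ref_base, alt, "SBS", "culture", 0.0, 0.0, 0.5))

    # --- uniformly placed classes -----------------------------------------
    free = [xy for xy in all_interior if xy not in used]
    rng.shuffle(free)
    cursor = 0

    def take(n):
        nonlocal cursor
        picks = free[cursor : cursor + n]
        cursor += n
        used.update(picks)
        return picks

    def random_alt(ref_base):
        choices = [b for b in BASES if b != ref_base]
        return choices[rng.integers(0, 3)]

    for contig, pos in take(cfg.n_germline):
        ref_base = base_at(contig, pos)
        vaf = 0.5 if rng.random() < cfg.het_fraction else 1.0
        rows.append((contig, pos, ref_base, random_alt(ref_base), "SBS", "germline", vaf, vaf, vaf))

    for contig, pos in take(cfg.n_pre_clonal):
        ref_base = base_at(contig, pos)
        rows.append((contig, pos, ref_base, random_alt(ref_base), "SBS", "pre_clonal", 0.0, 0.5, 0.5))

    # post-clonal VAFs: generation g contributes weight 2^g at VAF 0.5 / 2^g
    gens = np.arange(1, 6)
    vaf_levels = 0.5 / 2.0**gens
    keep = vaf_levels <= cfg.subclonal_vaf_max
    vaf_levels, weights = vaf_levels[keep], (2.0**gens)[keep]
    weights = weights / weights.sum()
    for contig, pos in take(cfg.n_subclonal):
        ref_base = base_at(contig, pos)
        v = float(rng.choice(vaf_levels, p=weights))
        rows.append((contig, pos, ref_base, random_alt(ref_base), "SBS", "post_clonal", 0.0, 0.0, v))

    artifact_records = []
    for contig, pos in take(cfg.n_artifact_positions):
        ref_base = base_at(contig, pos)
        alt = random_alt(ref_base)
        rows.append((contig, pos, ref_base, alt, "SBS", "artifact", 0.0, 0.0, 0.5))
        artifact_records.append((contig, pos, ref_base, alt))

    # --- indels ------------------------------------------------------------
    def make_indel(contig, pos):
        seq = ref.sequences[contig]
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5 and pos + length + 1 < len(seq):  # deletion
            return seq[pos : pos + length + 1], seq[pos]
        ins = "".join(BASES[rng.integers(0, 4)] for _ in range(length))
        return seq[pos], seq[pos] + ins

    for contig, pos in take(cfg.n_germline_indels):
        r, a = make_indel(contig, pos)
        vaf = 0.5 if rng.random() < cfg.het_fraction else 1.0
        rows.append((contig, pos, r, a, "indel", "germline", vaf, vaf, vaf))

    for contig, pos in take(cfg.n_culture_indels):
        r, a = make_indel(contig, pos)
        rows.append((contig, pos, r, a, "indel", "culture", 0.0, 0.0, 0.5))

    # --- observed evidence --------------------------------------------------
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "var_class",
            "class",
            "vaf_reference",
            "vaf_clone",
            "vaf_subclone",
        ],
    ).sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)

    n = len(truth)
    calls = truth[["chrom", "pos", "ref", "alt", "var_class"]].copy()
    calls["qual"] = 500.0
    calls["filter"] = "PASS"
    for role in SAMPLE_ROLES:
        true_vaf = truth[f"vaf_{role}"].to_numpy(float)
        if cfg.exact_vafs:
            dp = np.full(n, int(round(cfg.mean_depth)))
            ad = np.rint(dp * true_vaf).astype(int)
        else:
            dp = _truncated_poisson(rng, cfg.mean_depth, n)
            ad = rng.binomial(dp, true_vaf)
        calls[f"dp_{role}"] = dp
        calls[f"ad_{role}"] = ad
        calls[f"gq_{role}"] = 99
    calls = calls[CALL_COLUMNS]

    # drop calls with no alt evidence in any sample (a caller never emits
    # them); the truth table keeps every planted variant
    has_alt = (calls[["ad_reference", "ad_clone", "ad_subclone"]].sum(axis=1) > 0).to_numpy()
    calls = calls[has_alt].reset_index(drop=True)

    # --- unrelated-individual panel for the recurrence blacklist ------------
    panel = []
    for _ in range(cfg.n_panel_individuals):
        prows = []
        for contig, pos, ref_base, alt in artifact_records:
            prows.append(
                {
                    "chrom": contig,
                    "pos": pos,
                    "ref": ref_base,
                    "alt": alt,
                    "vaf": float(rng.uniform(0.05, 0.15)),
                }
            )
        # a few private calls so the blacklist rule has negatives to ignore
        for contig, pos in take(min(5, max(0, len(free) - cursor))):
            ref_base = base_at(contig, pos)
            prows.append(
                {
                    "chrom": contig,
                    "pos": pos,
                    "ref": ref_base,
                    "alt": random_alt(ref_base),
                    "vaf": float(rng.uniform(0.3, 0.6)),
                }
            )
        panel.append(pd.DataFrame(prows, columns=["chrom", "pos", "ref", "alt", "vaf"]))

    callable_full = CallableRegionSet.from_intervals(
        (contig, 0, len(seq)) for contig, seq in sorted(ref.sequences.items())
    )
    trio = TrioDataset(
        calls=calls,
        callable_regions={role: callable_full for role in SAMPLE_ROLES},
        panel=panel,
    )
    return trio, PlantedTruth(table=truth)


# ---------------------------------------------------------------------------
# growth curves


@dataclass
class GrowthCurve:
    times: np.ndarray  # hours
    counts: np.ndarray  # cells

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must align")


def simulate_growth_curve(
    D_hours: float,
    T_hours: float,
    X0: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_points: int = 25,
) -> GrowthCurve:
    """Exponential growth X0 * 2^(t/D) with multiplicative lognormal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative noise;
    zero gives the exact deterministic curve.
    """
    if D_hours <= 0 or T_hours <= 0:
        raise ValueError("doubling time and duration must be positive")
    if X0 < 1:
        raise ValueError("initial cell count must be at least 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, T_hours, max(2, n_points))
    expected = X0 * 2.0 ** (times / D_hours)
    if noise_cv == 0:
        return GrowthCurve(times=times, counts=expected)
    sigma2 = math.log(1 + noise_cv**2)
    noise = rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=len(times))
    return GrowthCurve(times=times, counts=expected * noise)


# ---------------------------------------------------------------------------
# region sets and driver catalogs

_BLOCK = 500  # bp tile used to assemble region sets


def generate_region_sets(
    ref: ToyReference, fractions: Dict[str, float], seed: int
) -> Dict[str, RegionSet]:
    """Random region sets covering requested genome fractions.

    Each set is assembled from non-overlapping 500-bp tiles sampled
    independently per set (sets may therefore overlap each other, as genic
    regions contain CDS in real annotations).  Realized fraction is within
    1% of the request for references >= 1e5 bp.
    """
    if len(set(fractions)) != len(fractions):
        raise ValueError("region names must be unique")
    for name, f in fractions.items():
        if not (0 < f < 1):
            raise ValueError(f"fraction for {name!r} must be in (0, 1)")
    if sum(fractions.values()) > 1:
        raise ValueError("region fractions sum to more than the genome")
    rng = np.random.default_rng(seed)
    out: Dict[str, RegionSet] = {}
    for name in sorted(fractions):
        frac = fractions[name]
        intervals = []
        for contig, seq in sorted(ref.sequences.items()):
            n_blocks = len(seq) // _BLOCK
            want = int(round(frac * len(seq) / _BLOCK))
            want = min(max(want, 1), n_blocks)
            picks = rng.choice(n_blocks, size=want, replace=False)
            for b in picks:
                intervals.append((contig, int(b) * _BLOCK, (int(b) + 1) * _BLOCK))
        out[name] = RegionSet.from_intervals(intervals)
    return out


def sample_positions_uniform(
    ref: ToyReference,
    n: int,
    seed: int,
    thin_region: Optional[RegionSet] = None,
    keep_prob: float = 1.0,
) -> pd.DataFrame:
    """Uniform random SBS positions, optionally thinned inside a region.

    With ``thin_region`` and ``keep_prob`` < 1, candidate mutations falling in
    the region are retained with probability ``keep_prob`` — a direct way to
    plant a known depletion factor.
    """
    rng = np.random.default_rng(seed)
    contigs = sorted(ref.sequences)
    lengths = np.array([len(ref.sequences[c]) - 2 for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    frames = []
    remaining = n
    while remaining > 0:
        batch = max(remaining * 2, 1000)
        ci = rng.choice(len(contigs), size=batch, p=probs)
        for k, contig in enumerate(contigs):
            m = int((ci == k).sum())
            if m == 0:
                continue
            pos = rng.integers(1, len(ref.sequences[contig]) - 1, size=m)
            if thin_region is not None and keep_prob < 1.0:
                inside = thin_region.contains(contig, pos)
                drop = inside & (rng.random(m) > keep_prob)
                pos = pos[~drop]
            seq = ref.sequences[contig]
            ref_bases = np.array([seq[p] for p in pos])
            offsets = rng.integers(0, 3, size=len(pos))
            alts = np.array(
                [
                    [b for b in BASES if b != rb][o]
                    for rb, o in zip(ref_bases, offsets)
                ]
            ) if len(pos) else np.array([], dtype=str)
            frames.append(
                pd.DataFrame(
                    {"chrom": contig, "pos": pos, "ref": ref_bases, "alt": alts}
                )
            )
        got = sum(len(f) for f in frames)
        remaining = n - got
    out = pd.concat(frames, ignore_index=True).head(n)
    return out


def generate_driver_catalog(
    ref: ToyReference,
    region: RegionSet,
    n_per_type: Dict[str, int],
    seed: int,
) -> DriverCatalog:
    """Plant activating driver positions of requested substitution types inside
    a (CDS) region; the catalog's L is the region length."""
    from .channels import SUB_TYPES

    unknown = set(n_per_type) - set(SUB_TYPES)
    if unknown:
        raise ValueError(f"unknown substitution types: {sorted(unknown)}")
    if any(v < 0 for v in n_per_type.values()):
        raise ValueError("driver counts must be non-negative")
    rng = np.random.default_rng(seed)
    # bucket region positions by pyrimidine-collapsed reference base
    by_base: Dict[str, List[Tuple[str, int]]] = {"C": [], "T": []}
    for contig, start, end in region:
        seq = ref.sequences[contig]
        for pos in range(max(start, 1), min(end, len(seq) - 1)):
            b = seq[pos]
            pyr = b if b in "CT" else complement(b)
            by_base[pyr].append((contig, pos))
    used: set = set()
    rows = []
    counts = {t: 0 for t in SUB_TYPES}
    gene_i = 0
    for t in SUB_TYPES:
        k = int(n_per_type.get(t, 0))
        if k == 0:
            continue
        x, y = t.split(">")
        pool = [xy for xy in by_base[x] if xy not in used]
        if len(pool) < k:
            raise ValueError(
                f"requested {k} driver sites of type {t} but only {len(pool)} "
                f"compatible positions in the region"
            )
        picks = rng.choice(len(pool), size=k, replace=False)
        for idx in picks:
            contig, pos = pool[idx]
            used.add((contig, pos))
            ref_base = ref.sequences[contig][pos]
            alt = y if ref_base == x else complement(y)
            gene_i += 1
            rows.append(
                {"chrom": contig, "pos": pos, "ref": ref_base, "alt": alt, "gene": f"GENE{gene_i}"}
            )
        counts[t] = k
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene"])
    return DriverCatalog(L=region.total_length, counts=counts, sites=sites)
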