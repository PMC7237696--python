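"""Closed-form model of mutation accumulation and oncogenic risk in expanding
cell cultures, with an independent branching-lineage Monte-Carlo oracle.

The model takes an empirically measured mutation rate ``mu`` (single-base
substitutions per genome per population doubling), a coding-sequence
depletion factor ``dp`` (observed/expected mutations in CDS, ~0.98 for a 2%
depletion), the coding fraction of the genome (0.015), a six-type
substitution spectrum P_{X->Y}, and a driver catalog giving the number of
positions n_{X->Y} whose X->Y substitution activates an oncogene within a
coding sequence of length L.

Expected activating mutations after producing N cells:

    M_active(N) = 0.015 * dp * mu * N * sum_{X->Y} P_{X->Y} * n_{X->Y} / L

Probability of at least one activating mutation:

    P(Z >= 1) = 1 - ( prod_{X->Y} ((L - n_{X->Y}) / L)^{P_{X->Y}} )^{0.015 * dp * mu * N}

The in vivo variant replaces mu * N in the exponent by
``n_stem_cells * annual_rate * t_years``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .channels import SUB_TYPES
from .spectra import Spectrum7

#: Hours per Julian year (365.25 days); used for per-year rate conversions.
HOURS_PER_YEAR = 8766.0


@dataclass
class DriverCatalog:
    """Activating driver positions per substitution type over a CDS of length L."""

    L: int
    counts: Dict[str, int]
    sites: Optional[pd.DataFrame] = None  # chrom, pos, ref, alt, gene

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("CDS length L must be positive")
        clean = {}
        for t in SUB_TYPES:
            n = int(self.counts.get(t, 0))
            if n < 0:
                raise ValueError(f"negative driver count for {t}")
            if n > self.L:
                raise ValueError(f"driver count for {t} exceeds CDS length L")
            clean[t] = n
        unknown = set(self.counts) - set(SUB_TYPES)
        if unknown:
            raise ValueError(f"unknown substitution types in driver catalog: {sorted(unknown)}")
        self.counts = clean

    @property
    def total_sites(self) -> int:
        return sum(self.counts.values())

    def activation_density(self, probs: Dict[str, float]) -> float:
        """sum_{X->Y} P_{X->Y} * n_{X->Y} / L — activating fraction of a random
        coding mutation drawn from the spectrum."""
        return sum(probs[t] * self.counts[t] / self.L for t in SUB_TYPES)


def _six_type_probs(spectrum) -> Dict[str, float]:
    if isinstance(spectrum, Spectrum7):
        return spectrum.six_type()
    if isinstance(spectrum, dict):
        missing = [t for t in SUB_TYPES if t not in spectrum]
        if missing:
            raise ValueError(f"spectrum missing substitution types: {missing}")
        total = sum(spectrum[t] for t in SUB_TYPES)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"six-type spectrum must sum to 1 (got {total})")
        return {t: float(spectrum[t]) for t in SUB_TYPES}
    if hasattr(spectrum, "weights") and len(spectrum.weights) == 96:
        from .spectra import collapse_spectrum7

        return collapse_spectrum7(spectrum).six_type()
    raise TypeError("spectrum must be a Spectrum7, Profile96, or six-type dict")


@dataclass
class RiskParams:
    """Parameters of the oncogenic-risk model.

    mu
        mutations per genome per population doubling.
    dp
        CDS depletion factor (observed/expected; 1 = no depletion).
    coding_fraction
        fraction of the genome that is protein-coding (default 0.015).
    N0
        initial number of cells.
    D
        population doubling time, hours.
    mt
        cell cycle length, hours (used only by the per-lineage generation
        mode of :func:`coding_mutations_over_time`).
    spectrum
        six-type substitution probabilities P_{X->Y} (a Spectrum7, a 96-channel
        profile, or a dict over the six types).
    """

    mu: float
    dp: float = 1.0
    coding_fraction: float = 0.015
    N0: float = 1.0
    D: Optional[float] = None
    mt: Optional[float] = None
    spectrum: object = None

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0 < self.coding_fraction < 1):
            raise ValueError("coding_fraction must be in (0, 1)")
        if not (0 <= self.dp <= 2):
            raise ValueError("dp must be in [0, 2]")
        if self.N0 < 1:
            raise ValueError("N0 must be at least one cell")

    @property
    def six_probs(self) -> Dict[str, float]:
        if self.spectrum is None:
            raise ValueError("risk parameters carry no substitution spectrum")
        return _six_type_probs(self.spectrum)


# ---------------------------------------------------------------------------
# growth


def doubling_time(T: float, Xb: float, Xe: float) -> float:
    """Population doubling time D = T * ln(2) / ln(Xe / Xb).

    ``T`` is the incubation time in any unit; the result carries that unit.
    Exact on power-of-two growth.
    """
    if T <= 0:
        raise ValueError("incubation time must be positive")
    if Xb <= 0 or Xe <= Xb:
        raise ValueError("need Xe > Xb > 0 (no growth measured)")
    return T * math.log(2) / math.log(Xe / Xb)


def fit_doubling_time(times, counts) -> float:
    """Least-squares doubling time from a growth curve (log2 counts vs time)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two growth-curve points")
    if (c <= 0).any():
        raise ValueError("cell counts must be positive")
    slope, _ = np.polyfit(t, np.log2(c), 1)
    if slope <= 0:
        raise ValueError("no growth: non-positive fitted slope")
    return 1.0 / slope


def population_size(t: float, params: RiskParams) -> float:
    """N(t) = N0 * 2^(t/D)."""
    if params.D is None or params.D <= 0:
        raise ValueError("population size over time requires a positive doubling time D")
    return params.N0 * 2.0 ** (t / params.D)


def coding_mutations_over_time(t: float, params: RiskParams, mode: str = "population") -> float:
    """Expected coding mutations M(t) accumulated while expanding to time t.

    Default ("population") mode: M(t) = coding_fraction * dp * mu * N(t) with
    N(t) = N0 * 2^(t/D).  The "generations" mode expresses the exponent as
    (mt/D) * G(t) with G(t) = t/mt generations of length mt, which reduces to
    the same t/D exponent; it is kept for transparency of the two readings.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if mode == "population":
        n = population_size(t, params)
    elif mode == "generations":
        if params.mt is None or params.mt <= 0:
            raise ValueError("generations mode requires a positive cell cycle length mt")
        generations = t / params.mt
        n = params.N0 * 2.0 ** ((params.mt / params.D) * generations)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return params.coding_fraction * params.dp * params.mu * n


# ---------------------------------------------------------------------------
# oncogenic risk, closed form


def oncogenic_count(N: float, params: RiskParams, catalog: DriverCatalog) -> float:
    """Expected number of activating driver mutations after producing N cells."""
    if N < 1:
        raise ValueError("N must be at least one cell")
    density = catalog.activation_density(params.six_probs)
    return params.coding_fraction * params.dp * params.mu * N * density


def _log_survival_per_unit(params: RiskParams, catalog: DriverCatalog) -> float:
    """sum_{X->Y} P_{X->Y} * log((L - n_{X->Y}) / L); -inf when any n == L with P > 0."""
    probs = params.six_probs
    total = 0.0
    for t in SUB_TYPES:
        n = catalog.counts[t]
        p = probs[t]
        if p == 0:
            continue
        if n >= catalog.L:
            return -math.inf
        total += p * math.log1p(-n / catalog.L)
    return total


def oncogenic_probability(N: float, params: RiskParams, catalog: DriverCatalog) -> float:
    """P(Z >= 1): probability of at least one activating mutation at N cells.

    Computed in log space; satisfies P <= min(1, M_active).
    """
    if N < 1:
        raise ValueError("N must be at least one cell")
    log_surv = _log_survival_per_unit(params, catalog)
    if log_surv == -math.inf:
        return 1.0
    exponent = params.coding_fraction * params.dp * params.mu * N
    return -math.expm1(exponent * log_surv)


def probability_from_per_cell_rate(rate_per_cell: float, N: float) -> float:
    """P(at least one event) = 1 - (1 - r)^N for a per-cell event rate r."""
    if not (0 <= rate_per_cell <= 1):
        raise ValueError("per-cell rate must be a probability")
    if N < 0:
        raise ValueError("N must be non-negative")
    if rate_per_cell == 1:
        return 1.0 if N > 0 else 0.0
    return -math.expm1(N * math.log1p(-rate_per_cell))


def in_vivo_probability(
    t_years: float,
    params: RiskParams,
    catalog: DriverCatalog,
    n_stem_cells: float = 1e8,
    annual_rate: float = 40.0,
) -> float:
    """P(Z >= 1) for a resident stem cell pool over ``t_years`` of adult life.

    The in vitro exponent's mu * N is replaced by
    n_stem_cells * annual_rate * t_years; the spectrum in ``params`` should be
    the in vivo spectrum.
    """
    if t_years < 0:
        raise ValueError("time must be non-negative")
    log_surv = _log_survival_per_unit(params, catalog)
    if log_surv == -math.inf:
        return 1.0 if t_years > 0 else 0.0
    exponent = params.coding_fraction * params.dp * n_stem_cells * annual_rate * t_years
    return -math.expm1(exponent * log_surv)


def cells_per_event(params: RiskParams, catalog: DriverCatalog):
    """Cells produced per one expected activating mutation: 1 / M_active(N=1).

    Returns ``(value, finite)``; for a zero rate the value is ``math.inf`` and
    ``finite`` is False.
    """
    m1 = oncogenic_count(1, params, catalog)
    if m1 == 0:
        return math.inf, False
    return 1.0 / m1, True


def equivalent_exposure_time(
    P_target: float,
    params: RiskParams,
    catalog: DriverCatalog,
    n_stem_cells: float = 1e8,
    annual_rate: float = 40.0,
) -> float:
    """Years of in vivo exposure with the same P(Z >= 1) as ``P_target``.

    Root of in_vivo_probability(t) = P_target, unique by strict monotonicity;
    solved by bracketed bisection to 1e-9 relative tolerance.
    """
    if not (0 < P_target < 1):
        raise ValueError("P_target must be strictly between 0 and 1")
    log_surv = _log_survival_per_unit(params, catalog)
    if log_surv >= 0 or log_surv == -math.inf:
        raise ValueError("in vivo probability is degenerate for this catalog/spectrum")

    def f(t):
        return (
            in_vivo_probability(t, params, catalog, n_stem_cells, annual_rate) - P_target
        )

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the exposure time")
    return brentq(f, 0.0, hi, rtol=1e-9, xtol=1e-300)


def risk_curve(N_grid, params: RiskParams, catalog: DriverCatalog) -> pd.DataFrame:
    """M_active and P(Z >= 1) over a grid of cells produced."""
    rows = []
    for N in np.asarray(N_grid, dtype=float):
        rows.append(
            {
                "N": N,
                "M_active": oncogenic_count(N, params, catalog),
                "P_at_least_one": oncogenic_probability(N, params, catalog),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


@dataclass
class LineageOracleResult:
    mean_count: float
    se_count: float
    p_any: float
    se_p: float
    n_replicates: int
    counts: np.ndarray = field(repr=False, default=None)


def simulate_lineage_oracle(
    params: RiskParams,
    catalog: DriverCatalog,
    N_target: int,
    n_replicates: int = 1000,
    seed: int = 0,
) -> LineageOracleResult:
    """Branching-lineage simulation of activating-mutation accumulation.

    Synchronous doublings expand N0 cells to N_target (a power of two times
    N0).  Each cell division produces one new cell and Poisson(mu) new
    genome-wide mutations; each mutation is coding with probability
    coding_fraction * dp, and each coding mutation activates a driver with
    probability sum P_{X->Y} * n_{X->Y} / L.  Independent of the closed-form
    path; deterministic for a fixed seed.
    """
    if n_replicates < 10:
        raise ValueError("fewer than 10 replicates gives meaningless error bars")
    if N_target > 2**16:
        raise ValueError("oracle is desk-scale: N_target must be <= 2^16")
    ratio = N_target / params.N0
    g = math.log2(ratio)
    if ratio < 2 or abs(g - round(g)) > 1e-9:
        raise ValueError("N_target must be a power of 2 times N0")

    rng = np.random.default_rng(seed)
    n_divisions = int(N_target - params.N0)
    p_coding = params.coding_fraction * params.dp
    q_activating = catalog.activation_density(params.six_probs)
    if not (0 <= q_activating <= 1):
        raise ValueError("activation density must be a probability")

    total = rng.poisson(params.mu * n_divisions, size=n_replicates)
    coding = rng.binomial(total, p_coding)
    hits = rng.binomial(coding, q_activating)

    mean = float(hits.mean())
    se = float(hits.std(ddof=1) / math.sqrt(n_replicates))
    p_any = float((hits >= 1).mean())
    se_p = float(math.sqrt(max(p_any * (1 - p_any), 1e-12) / n_replicates))
    return LineageOracleResult(
        mean_count=mean,
        se_count=se,
        p_any=p_any,
        se_p=se_p,
        n_replicates=n_replicates,
        counts=hits,
    )
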