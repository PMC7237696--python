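"""Mutation spectra, 96-channel profiles, signature extraction and refitting.

The seven-type spectrum splits C>T by CpG context; the 96-channel profile
resolves each of the six pyrimidine-strand substitution types by its
trinucleotide context.  De novo signatures are extracted by non-negative
matrix factorization under a generalized Kullback-Leibler objective;
observed profiles are refit against a reference catalog by non-negative
least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .channels import (
    CHANNELS_96,
    CHANNEL_SPECTRUM7,
    SPECTRUM7_TYPES,
    SUB_TYPES,
    channel_index,
)

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


def _normalize(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        return w.astype(float)
    return w / total


@dataclass
class Profile96:
    """Normalized distribution over the 96 trinucleotide substitution channels."""

    weights: np.ndarray
    count: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (96,):
            raise ValueError("Profile96 requires exactly 96 channel weights")
        if (w < -_NORM_TOL).any():
            raise ValueError("channel weights must be non-negative")
        self.weights = _normalize(np.clip(w, 0, None))

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Profile96":
        counts = np.asarray(counts, dtype=float)
        return cls(weights=counts, count=int(round(counts.sum())))

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(CHANNELS_96))


@dataclass
class Spectrum7:
    """Distribution over {C>A, C>G, C>T at CpG, C>T other, T>A, T>C, T>G}."""

    weights: np.ndarray
    count: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (7,):
            raise ValueError("Spectrum7 requires exactly 7 weights")
        if (w < -_NORM_TOL).any():
            raise ValueError("spectrum weights must be non-negative")
        self.weights = _normalize(np.clip(w, 0, None))

    @classmethod
    def from_dict(cls, probs: Dict[str, float], count: int = 0) -> "Spectrum7":
        w = np.array([probs.get(t, 0.0) for t in SPECTRUM7_TYPES], dtype=float)
        return cls(weights=w, count=count)

    def as_dict(self) -> Dict[str, float]:
        return {t: float(w) for t, w in zip(SPECTRUM7_TYPES, self.weights)}

    def six_type(self) -> Dict[str, float]:
        """Collapse the CpG split: probabilities over the six substitution types.

        Used as P_{X->Y} by the oncogenic-risk model; collapsing preserves
        total C>T mass.
        """
        w = self.weights
        return {
            "C>A": w[0],
            "C>G": w[1],
            "C>T": w[2] + w[3],
            "T>A": w[4],
            "T>C": w[5],
            "T>G": w[6],
        }

    def to_profile96(self) -> Profile96:
        """Expand to 96 channels, spreading each type uniformly over its contexts."""
        ch7 = np.asarray(CHANNEL_SPECTRUM7)
        w = np.zeros(96)
        for k in range(7):
            mask = ch7 == k
            n = mask.sum()
            w[mask] = self.weights[k] / n
        return Profile96(weights=w, count=self.count)


@dataclass
class SignatureSet:
    """Named collection of 96-channel signatures (each sums to 1)."""

    names: List[str]
    matrix: np.ndarray  # (96, n_signatures), columns normalized
    source: str = "reference"  # "de novo" | "reference"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 96:
            raise ValueError("signature matrix must have 96 rows")
        if m.shape[1] != len(self.names):
            raise ValueError("one name per signature column required")
        sums = m.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("signatures must have positive mass")
        self.matrix = m / sums

    def __len__(self) -> int:
        return len(self.names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS_96), columns=self.names)


@dataclass
class ContributionVector:
    """Non-negative signature weights fit to one profile."""

    names: List[str]
    weights: np.ndarray  # raw NNLS weights
    residual_cosine: float  # cosine(reconstruction, original profile)

    @property
    def relative(self) -> np.ndarray:
        return _normalize(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.relative, index=self.names)


# ---------------------------------------------------------------------------
# profile construction


def _flanks(reference, contig: str, pos: int):
    """(5' base, ref base, 3' base) at 0-based pos, or None at a contig edge."""
    if hasattr(reference, "sequences"):  # ToyReference
        seq = reference.sequences[contig]
        if pos < 1 or pos >= len(seq) - 1:
            return None
        return seq[pos - 1], seq[pos], seq[pos + 1]
    # pyfaidx.Fasta-like
    rec = reference[contig]
    if pos < 1 or pos >= len(rec) - 1:
        return None
    tri = str(rec[pos - 1 : pos + 2]).upper()
    return tri[0], tri[1], tri[2]


def _iter_sbs(mutations) -> Iterable:
    if isinstance(mutations, pd.DataFrame):
        for row in mutations.itertuples(index=False):
            yield row.chrom, int(row.pos), row.ref, row.alt
    else:
        for m in mutations:
            yield m.contig, int(m.position), m.ref, m.alt


def profile96(mutations, reference) -> Profile96:
    """Build the 96-channel profile of a set of SBS calls.

    ``mutations`` is a DataFrame with columns chrom/pos/ref/alt (0-based pos)
    or a sequence of :class:`~mutload.records.MutationRecord`.  ``reference``
    is a :class:`~mutload.synthetic.ToyReference` or a ``pyfaidx.Fasta``.
    Purine-reference calls are collapsed onto the pyrimidine strand.  Records
    whose flanks fall outside the contig are skipped and counted in a logged
    warning.
    """
    counts = np.zeros(96)
    skipped = 0
    for contig, pos, ref, alt in _iter_sbs(mutations):
        if len(ref) != 1 or len(alt) != 1:
            continue
        flanks = _flanks(reference, contig, pos)
        if flanks is None:
            skipped += 1
            continue
        five, ref_base, three = flanks
        if ref_base != ref:
            raise ValueError(
                f"reference base mismatch at {contig}:{pos}: VCF {ref}, sequence {ref_base}"
            )
        counts[channel_index(five, ref, three, alt)] += 1
    if skipped:
        logger.warning("profile96: skipped %d record(s) with flanks outside contig", skipped)
    return Profile96.from_counts(counts)


def collapse_spectrum7(profile: Profile96) -> Spectrum7:
    """Collapse a 96-channel profile to the seven-type spectrum.

    CpG status is read off the 3' flank of the C>T channels.
    """
    ch7 = np.asarray(CHANNEL_SPECTRUM7)
    w = np.zeros(7)
    for k in range(7):
        w[k] = profile.weights[ch7 == k].sum()
    return Spectrum7(weights=w, count=profile.count)


def centroid(profiles: Sequence[Profile96]) -> Profile96:
    """Per-channel arithmetic mean of normalized profiles, renormalized."""
    if len(profiles) == 0:
        raise ValueError("centroid of an empty profile list is undefined")
    stack = np.stack([p.weights for p in profiles])
    return Profile96(weights=stack.mean(axis=0), count=sum(p.count for p in profiles))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative profiles; in [0, 1]."""
    va = a.weights if hasattr(a, "weights") else np.asarray(a, dtype=float)
    vb = b.weights if hasattr(b, "weights") else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


# ---------------------------------------------------------------------------
# signature extraction and refitting


def extract_signatures_nmf(
    profile_matrix,
    rank: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
):
    """De novo signature extraction by NMF with KL multiplicative updates.

    ``profile_matrix`` is (n_samples, 96) mutation counts.  The best of
    ``n_restarts`` random initializations by the beta-divergence objective is
    kept; signatures are column-normalized and contributions rescaled to
    preserve the product.  Deterministic for a fixed ``seed``.

    Returns ``(SignatureSet, contributions)`` with contributions of shape
    (n_samples, rank).
    """
    X = np.asarray(profile_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != 96:
        raise ValueError("profile_matrix must be (n_samples, 96)")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(X.shape[0], 96):
        raise ValueError("rank exceeds min(n_samples, 96)")
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if X.sum() == 0:
        raise ValueError("all-zero profile matrix")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for rs in restart_seeds:
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rs),
        )
        with warnings.catch_warnings():
            # hitting the iteration cap is acceptable; restarts are compared
            # on the objective below
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    _, W, H = best
    scale = H.sum(axis=1)  # per-signature mass
    scale[scale == 0] = 1.0
    H = H / scale[:, None]
    W = W * scale[None, :]
    names = [chr(ord("A") + i) for i in range(rank)]
    sigs = SignatureSet(names=names, matrix=H.T, source="de novo")
    return sigs, W


def refit_contributions(profile: Profile96, refs: SignatureSet) -> ContributionVector:
    """Reconstruct a profile as a non-negative combination of reference signatures."""
    if len(refs) == 0:
        raise ValueError("reference signature set is empty")
    weights, _ = nnls(refs.matrix, profile.weights)
    recon = refs.matrix @ weights
    if recon.sum() == 0:
        res = 0.0
    else:
        res = cosine_similarity(recon, profile.weights)
    return ContributionVector(names=list(refs.names), weights=weights, residual_cosine=res)


def select_signatures(
    contributions: Dict[str, ContributionVector] | Sequence[ContributionVector],
    threshold: float = 0.10,
) -> List[str]:
    """Signatures whose relative contribution reaches ``threshold`` in at least
    one centroid (inclusive at the threshold)."""
    if isinstance(contributions, dict):
        vectors = list(contributions.values())
    else:
        vectors = list(contributions)
    selected: List[str] = []
    for vec in vectors:
        rel = vec.relative
        for name, w in zip(vec.names, rel):
            if w >= threshold and name not in selected:
                selected.append(name)
    # stable, catalog-ordered output
    if vectors:
        order = {n: i for i, n in enumerate(vectors[0].names)}
        selected.sort(key=lambda n: order.get(n, len(order)))
    return selected


def cluster_by_cosine(similarity: np.ndarray, labels: Sequence[str] | None = None):
    """Average-linkage agglomerative clustering on distance 1 - cosine.

    Returns ``(linkage_matrix, leaf_labels_in_dendrogram_order)``.  A single
    sample yields an empty linkage and a trivial ordering.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = S.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("one label per row required")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if n == 1:
        return np.empty((0, 4)), list(labels)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(Z)
    return Z, [labels[i] for i in order]


def greedy_match(extracted: SignatureSet, truth: SignatureSet):
    """Greedy maximum-cosine bipartite assignment of extracted to true signatures.

    Returns a list of ``(extracted_name, true_name, cosine)`` triples, one per
    true signature (extraction order is arbitrary, so tests match by shape).
    """
    sim = np.zeros((len(extracted), len(truth)))
    for i in range(len(extracted)):
        for j in range(len(truth)):
            sim[i, j] = cosine_similarity(extracted.matrix[:, i], truth.matrix[:, j])
    pairs = []
    used_e, used_t = set(), set()
    flat = sorted(
        ((sim[i, j], i, j) for i in range(sim.shape[0]) for j in range(sim.shape[1])),
        reverse=True,
    )
    for s, i, j in flat:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        pairs.append((extracted.names[i], truth.names[j], float(s)))
        if len(used_t) == len(truth):
            break
    return pairs


def compare_spectra_chisq(counts_a, counts_b):
    """Pearson chi-squared comparison of two aligned spectrum count vectors.

    Channels empty in both samples are dropped; no continuity correction.
    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must be aligned")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both samples need at least one mutation")
    keep = (a + b) > 0
    table = np.stack([a[keep], b[keep]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        logger.warning("compare_spectra_chisq: expected count < 5 in some cell")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
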