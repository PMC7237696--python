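"""Spectra, 96-channel profiles, NMF signatures, refitting, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from mutload import (
    CHANNELS_96,
    Profile96,
    SignatureSet,
    Spectrum7,
    centroid,
    cluster_by_cosine,
    collapse_spectrum7,
    compare_spectra_chisq,
    cosine_similarity,
    extract_signatures_nmf,
    profile96,
    refit_contributions,
    select_signatures,
)
from mutload.channels import revcomp
from mutload.spectra import ContributionVector, greedy_match
from mutload.synthetic import ToyReference


def one_hot(channel: str, count: int = 1) -> Profile96:
    w = np.zeros(96)
    w[CHANNELS_96.index(channel)] = count
    return Profile96.from_counts(w)


class TestProfile96:
    def test_single_mutation_lands_on_its_channel(self):
        ref = ToyReference(sequences={"c": "AAAACGAAAA" * 100})
        # position 4 is C with 5' A and 3' G
        muts = pd.DataFrame([{"chrom": "c", "pos": 4, "ref": "C", "alt": "T"}])
        prof = profile96(muts, ref)
        assert prof.weights[CHANNELS_96.index("A[C>T]G")] == 1.0

    def test_purine_reference_collapses_to_pyrimidine_strand(self):
        # C G T on the forward strand: the G>A at pos 1 is A[C>T]G reverse-complemented
        ref = ToyReference(sequences={"c": "ACGTA" * 200})
        muts = pd.DataFrame([{"chrom": "c", "pos": 2, "ref": "G", "alt": "A"}])
        prof = profile96(muts, ref)
        assert prof.weights[CHANNELS_96.index("A[C>T]G")] == 1.0

    def test_strand_symmetry(self, ref100k):
        rng = np.random.default_rng(3)
        seq = ref100k.sequences["toy_1"]
        pos = rng.integers(1, len(seq) - 1, size=400)
        rows = []
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for p in np.unique(pos):
            ref_base = seq[p]
            alt = [b for b in "ACGT" if b != ref_base][rng.integers(0, 3)]
            rows.append({"chrom": "toy_1", "pos": int(p), "ref": ref_base, "alt": alt})
        fwd = profile96(pd.DataFrame(rows), ref100k)
        # the same mutations seen on the reverse-complemented genome
        rc_ref = ToyReference(sequences={"toy_1": revcomp(seq)})
        rc_rows = [
            {
                "chrom": "toy_1",
                "pos": len(seq) - 1 - r["pos"],
                "ref": comp[r["ref"]],
                "alt": comp[r["alt"]],
            }
            for r in rows
        ]
        rev = profile96(pd.DataFrame(rc_rows), rc_ref)
        np.testing.assert_allclose(fwd.weights, rev.weights)

    def test_edge_positions_skipped(self):
        ref = ToyReference(sequences={"c": "ACGT" * 10})
        muts = pd.DataFrame(
            [
                {"chrom": "c", "pos": 0, "ref": "A", "alt": "C"},
                {"chrom": "c", "pos": 5, "ref": "C", "alt": "T"},
            ]
        )
        prof = profile96(muts, ref)
        assert prof.count == 1

    def test_normalization_invariant(self, ref100k, trio_exact):
        _, truth = trio_exact
        prof = profile96(truth.of_class("culture", var_class="SBS"), ref100k)
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestCollapse:
    def test_all_cpg_profile(self):
        prof = one_hot("A[C>T]G", 10)
        spec = collapse_spectrum7(prof)
        assert spec.as_dict()["C>T at CpG"] == pytest.approx(1.0)

    def test_uniform_profile_splits_evenly(self):
        spec = collapse_spectrum7(Profile96(weights=np.full(96, 1 / 96)))
        d = spec.as_dict()
        c_mass = d["C>A"] + d["C>G"] + d["C>T at CpG"] + d["C>T other"]
        assert c_mass == pytest.approx(0.5)
        assert d["T>A"] + d["T>C"] + d["T>G"] == pytest.approx(0.5)
        # one of four 3' bases is G
        assert d["C>T at CpG"] == pytest.approx(1 / 6 * 1 / 4)

    def test_six_type_collapse_preserves_ct_mass(self):
        spec = Spectrum7.from_dict(
            {"C>A": 0.1, "C>G": 0.1, "C>T at CpG": 0.15, "C>T other": 0.25,
             "T>A": 0.1, "T>C": 0.2, "T>G": 0.1}
        )
        six = spec.six_type()
        assert six["C>T"] == pytest.approx(0.40)
        assert sum(six.values()) == pytest.approx(1.0)

    def test_planted_ct_fraction_roundtrip(self, ref300k):
        from mutload import TrioSimConfig, simulate_trio

        spec = Spectrum7.from_dict(
            {"C>A": 0.2, "C>G": 0.1, "C>T at CpG": 0.05, "C>T other": 0.35,
             "T>A": 0.1, "T>C": 0.1, "T>G": 0.1}
        )
        cfg = TrioSimConfig(n_culture=4000, n_germline=0, n_subclonal=0,
                            n_artifact_positions=0, culture_spectrum=spec, seed=21)
        _, truth = simulate_trio(ref300k, cfg)
        prof = profile96(truth.of_class("culture"), ref300k)
        d = collapse_spectrum7(prof).as_dict()
        assert d["C>T at CpG"] + d["C>T other"] == pytest.approx(0.40, abs=0.03)


class TestCentroidCosine:
    def test_centroid_of_identical_profiles(self):
        p = one_hot("A[C>A]A")
        c = centroid([p, p, p])
        np.testing.assert_allclose(c.weights, p.weights)

    def test_centroid_of_two_one_hots(self):
        c = centroid([one_hot("A[C>A]A"), one_hot("T[T>G]T")])
        assert c.weights[CHANNELS_96.index("A[C>A]A")] == pytest.approx(0.5)
        assert c.weights[CHANNELS_96.index("T[T>G]T")] == pytest.approx(0.5)

    def test_centroid_matches_hand_average(self):
        rng = np.random.default_rng(1)
        profiles = [Profile96(weights=rng.dirichlet(np.ones(96))) for _ in range(5)]
        c = centroid(profiles)
        hand = np.mean([p.weights for p in profiles], axis=0)
        np.testing.assert_allclose(c.weights, hand / hand.sum())

    def test_centroid_empty_rejected(self):
        with pytest.raises(ValueError):
            centroid([])

    def test_cosine_self_is_one(self):
        p = Profile96(weights=np.random.default_rng(0).dirichlet(np.ones(96)))
        assert cosine_similarity(p, p) == pytest.approx(1.0)

    def test_cosine_disjoint_is_zero(self):
        assert cosine_similarity(one_hot("A[C>A]A"), one_hot("T[T>G]T")) == 0.0

    def test_cosine_worked_example(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([1.0, 1.0, 0.0])
        assert cosine_similarity(a, b) == pytest.approx(1 / math.sqrt(2))

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestNMF:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(0)
        sig = rng.dirichlet(np.ones(96))
        exposures = rng.uniform(500, 3000, size=8)
        X = np.outer(exposures, sig)
        sigs, W = extract_signatures_nmf(X, rank=1, n_restarts=3, seed=0)
        assert cosine_similarity(sigs.matrix[:, 0], sig) >= 0.999
        assert W.shape == (8, 1)

    def test_rank_three_mixture_recovery(self):
        rng = np.random.default_rng(42)
        true = rng.dirichlet(np.full(96, 0.3), size=3).T
        truth_set = SignatureSet(names=["S1", "S2", "S3"], matrix=true)
        exposures = rng.dirichlet(np.full(3, 0.5), size=15)
        X = np.vstack([rng.multinomial(5000, true @ e) for e in exposures])
        sigs, _ = extract_signatures_nmf(X, rank=3, seed=0)
        pairs = greedy_match(sigs, truth_set)
        assert len(pairs) == 3
        assert min(c for _, _, c in pairs) >= 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(20, size=(6, 96)).astype(float)
        a, wa = extract_signatures_nmf(X, rank=2, n_restarts=3, seed=9)
        b, wb = extract_signatures_nmf(X, rank=2, n_restarts=3, seed=9)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(wa, wb)

    @pytest.mark.parametrize("bad_rank", [0, -1, 97])
    def test_invalid_rank(self, bad_rank):
        X = np.ones((5, 96))
        with pytest.raises(ValueError):
            extract_signatures_nmf(X, rank=bad_rank)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            extract_signatures_nmf(np.zeros((5, 96)), rank=2)


class TestRefit:
    def make_refs(self, k=3, seed=0):
        rng = np.random.default_rng(seed)
        return SignatureSet(
            names=[f"S{i}" for i in range(k)],
            matrix=rng.dirichlet(np.full(96, 0.3), size=k).T,
        )

    def test_exact_member_gets_full_weight(self):
        refs = self.make_refs()
        prof = Profile96(weights=refs.matrix[:, 1])
        contrib = refit_contributions(prof, refs)
        assert contrib.relative[1] >= 0.98
        assert contrib.residual_cosine >= 0.999

    def test_known_mixture_recovered(self):
        refs = self.make_refs(k=2, seed=3)
        mix = 0.6 * refs.matrix[:, 0] + 0.4 * refs.matrix[:, 1]
        contrib = refit_contributions(Profile96(weights=mix), refs)
        assert contrib.relative[0] == pytest.approx(0.6, abs=0.02)
        assert contrib.relative[1] == pytest.approx(0.4, abs=0.02)

    def test_off_support_profile_has_zero_residual_cosine(self):
        w = np.zeros((96, 2))
        w[0, 0] = 1.0
        w[1, 1] = 1.0
        refs = SignatureSet(names=["a", "b"], matrix=w)
        prof = one_hot(CHANNELS_96[5])
        contrib = refit_contributions(prof, refs)
        assert contrib.residual_cosine <= 0.01


class TestSelectSignatures:
    def vec(self, weights):
        return ContributionVector(
            names=[f"S{i}" for i in range(len(weights))],
            weights=np.asarray(weights, dtype=float),
            residual_cosine=1.0,
        )

    def test_all_below_threshold_empty(self):
        assert select_signatures([self.vec([0.05] * 20)]) == []

    def test_threshold_inclusive(self):
        got = select_signatures([self.vec([0.10, 0.90])])
        assert got == ["S0", "S1"]

    def test_union_over_centroids(self):
        vectors = [
            self.vec([0.50, 0.30, 0.15, 0.05]),
            self.vec([0.05, 0.80, 0.05, 0.10]),
            self.vec([0.95, 0.02, 0.02, 0.01]),
        ]
        got = select_signatures(vectors)
        # brute-force union
        want = set()
        for v in vectors:
            rel = v.weights / v.weights.sum()
            want |= {n for n, w in zip(v.names, rel) if w >= 0.10}
        assert set(got) == want


class TestClustering:
    def test_identical_pair_merges_first(self):
        S = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        Z, order = cluster_by_cosine(S, labels=["a", "b", "c"])
        assert set(map(int, Z[0, :2])) == {0, 1}

    def test_block_structure_recovered(self):
        S = np.full((6, 6), 0.1)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    S[i, j] = 0.95
        np.fill_diagonal(S, 1.0)
        _, order = cluster_by_cosine(S, labels=list("abcdef"))
        assert {"".join(sorted(order[:3])), "".join(sorted(order[3:]))} == {"abc", "def"}

    def test_single_sample_trivial(self):
        Z, order = cluster_by_cosine(np.array([[1.0]]), labels=["only"])
        assert Z.shape == (0, 4) and order == ["only"]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_cosine(np.ones((2, 3)))


class TestChiSquared:
    def test_identical_counts(self):
        stat, p = compare_spectra_chisq([10, 5, 3], [10, 5, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_channel_closed_form(self):
        stat, _ = compare_spectra_chisq([10, 0], [0, 10])
        assert stat == pytest.approx(20.0)

    def test_empty_channels_dropped(self):
        stat_a, p_a = compare_spectra_chisq([10, 0, 5], [8, 0, 7])
        stat_b, p_b = compare_spectra_chisq([10, 5], [8, 7])
        assert stat_a == pytest.approx(stat_b)
        assert p_a == pytest.approx(p_b)

    def test_same_spectrum_not_systematically_rejected(self):
        rng = np.random.default_rng(8)
        probs = np.array([0.1, 0.08, 0.05, 0.35, 0.1, 0.22, 0.1])
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            a = rng.multinomial(300, probs)
            b = rng.multinomial(300, probs)
            _, p = compare_spectra_chisq(a, b)
            rejections += p < 0.05
        assert rejections / n_sims < 0.10
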