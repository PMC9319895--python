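"""K2P / Nei distances against hand values and brute-force oracles."""

import numpy as np
import pytest

import taxodelim as td
from taxodelim.snp import IUPAC_PAIRS

from conftest import codes_matrix

TRANSITIONS = ({"A", "G"}, {"C", "T"})


def k2p_oracle(codes_i, codes_j):
    """Site-by-site K2P with pairwise deletion, no vectorization."""
    P = Q = m = 0
    for a, b in zip(codes_i, codes_j):
        if a not in "ACGT" or b not in "ACGT":
            continue
        m += 1
        if a == b:
            continue
        if {a, b} in ({"A", "G"}, {"C", "T"}):
            P += 1
        else:
            Q += 1
    if m == 0:
        return None
    P, Q = P / m, Q / m
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def nei_oracle(codes_i, codes_j):
    """Per-site allele-frequency vectors, explicit loops."""

    def freqs(c, pair):
        if c in IUPAC_PAIRS:
            return {al: 0.5 for al in IUPAC_PAIRS[c]}
        return {c: 1.0}

    jxy = jx = jy = 0.0
    m = 0
    for a, b in zip(codes_i, codes_j):
        if a in "N-" or b in "N-":
            continue
        m += 1
        fa, fb = freqs(a, None), freqs(b, None)
        jxy += sum(fa.get(al, 0) * fb.get(al, 0) for al in set(fa) | set(fb))
        jx += sum(v * v for v in fa.values())
        jy += sum(v * v for v in fb.values())
    if m == 0:
        return None
    identity = (jxy / m) / np.sqrt((jx / m) * (jy / m))
    if identity <= 0:
        return None
    return -np.log(min(identity, 1.0))


class TestK2P:
    def test_identical_sequences(self):
        m = codes_matrix(["ACGT", "ACGT"])
        assert td.k2p_distance(m).d[0, 1] == 0.0

    def test_hand_transition_case(self):
        """One A<->G transition in five sites: d = -ln(0.6)/2."""
        m = codes_matrix(["AACGT", "AGCGT"])
        d = td.k2p_distance(m)
        assert d.d[0, 1] == pytest.approx(-0.5 * np.log(0.6), abs=1e-10)
        assert d.d[0, 1] == pytest.approx(0.25541, abs=1e-5)

    def test_no_shared_sites_flagged(self):
        m = codes_matrix(["ANN", "NAC"])
        d = td.k2p_distance(m)
        assert d.undefined[0, 1]
        assert ("s0", "s1") in d.undefined_pairs()

    def test_saturated_pair_flagged(self):
        # all transversions: 1 - 2Q <= 0
        m = codes_matrix(["AAAA", "CCCC"])
        assert td.k2p_distance(m).undefined[0, 1]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACGT") + ["R", "Y", "N"]
        for _ in range(5):
            rows = [
                "".join(rng.choice(alphabet, size=50, p=[0.4, 0.3, 0.1, 0.1,
                                                         0.03, 0.03, 0.04]))
                for _ in range(6)
            ]
            m = codes_matrix(rows)
            d = td.k2p_distance(m)
            for i in range(6):
                for j in range(i + 1, 6):
                    expect = k2p_oracle(rows[i], rows[j])
                    if expect is None:
                        assert d.undefined[i, j]
                    else:
                        assert d.d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_permutation_equivariance(self, three_pop_matrix):
        m, _ = three_pop_matrix
        m = m.subset(m.sample_ids[:6])
        d = td.k2p_distance(m)
        perm = [3, 0, 5, 1, 4, 2]
        dp = td.k2p_distance(m.subset([m.sample_ids[i] for i in perm]))
        assert np.allclose(dp.d, d.d[np.ix_(perm, perm)])


class TestNei:
    def test_identical_homozygotes(self):
        m = codes_matrix(["ACGT", "ACGT"])
        assert td.nei_snp_distance(m).d[0, 1] == 0.0

    def test_hand_het_vs_hom(self):
        """One site, x = (.5,.5), y = (1,0): I = 0.5/sqrt(0.5)."""
        m = codes_matrix(["R", "A"])
        d = td.nei_snp_distance(m)
        expect = -np.log(0.5 / np.sqrt(0.5))
        assert d.d[0, 1] == pytest.approx(expect, abs=1e-10)
        assert d.d[0, 1] == pytest.approx(0.34657, abs=1e-5)

    def test_opposite_homozygotes_undefined(self):
        m = codes_matrix(["A", "G"])
        assert td.nei_snp_distance(m).undefined[0, 1]

    def test_matches_bruteforce_oracle(self):
        from taxodelim.snp import PAIR_TO_IUPAC

        rng = np.random.default_rng(1)
        bases = list("ACGT")
        for _ in range(5):
            cols = []
            for _site in range(50):
                a, b = rng.choice(bases, size=2, replace=False)
                het = PAIR_TO_IUPAC[frozenset((a, b))]
                cols.append(rng.choice([a, b, het, "N"], size=6,
                                       p=[0.4, 0.3, 0.2, 0.1]))
            rows = ["".join(col[i] for col in cols) for i in range(6)]
            m = codes_matrix(rows)
            d = td.nei_snp_distance(m)
            for i in range(6):
                for j in range(i + 1, 6):
                    expect = nei_oracle(rows[i], rows[j])
                    if expect is None:
                        assert d.undefined[i, j]
                    else:
                        assert d.d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_reference_relabel_invariance(self):
        """Swapping which allele is called 'reference' leaves d unchanged."""
        rows = ["AARA", "AGRC", "GGAA"]
        swapped = ["GGRG", "GART", "AAGG"]  # A<->G, C<->T per site
        d1 = td.nei_snp_distance(codes_matrix(rows))
        d2 = td.nei_snp_distance(codes_matrix(swapped))
        assert np.allclose(d1.d, d2.d, atol=1e-12)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        """Euclidean distances from 10 plane points embed exactly."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import cdist

        dist = td.DistanceMatrix(
            [str(i) for i in range(10)], cdist(pts, pts),
            np.zeros((10, 10), bool),
        )
        res = td.pcoa(dist)
        assert (res.eigenvalues > 1e-10).sum() == 2
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coords[:, :2])
        assert disparity < 1e-8

    def test_all_zero_distances_degenerate(self):
        dist = td.DistanceMatrix(
            list("abc"), np.zeros((3, 3)), np.zeros((3, 3), bool)
        )
        res = td.pcoa(dist)
        assert res.retained_axes == 1
        assert np.allclose(res.coords, 0.0)

    def test_retention_rule_cumulative_sum(self):
        """Eigenvalues (6,2,1,1) at threshold 0.8 retain exactly 2 axes."""
        rng = np.random.default_rng(3)
        n = 12
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)  # orthonormal, centered
        X = q * np.sqrt([6.0, 2.0, 1.0, 1.0])
        from scipy.spatial.distance import cdist

        dist = td.DistanceMatrix(
            [str(i) for i in range(n)], cdist(X, X), np.zeros((n, n), bool)
        )
        res = td.pcoa(dist, variance_threshold=0.8)
        assert np.allclose(res.eigenvalues[:4], [6, 2, 1, 1], atol=1e-8)
        # cumulative-sum oracle
        frac = np.cumsum(res.eigenvalues) / res.eigenvalues.sum()
        expect = int(np.argmax(frac >= 0.8 - 1e-12)) + 1
        assert res.retained_axes == expect == 2

    def test_undefined_cells_rejected(self):
        und = np.zeros((3, 3), bool)
        und[0, 1] = und[1, 0] = True
        dist = td.DistanceMatrix(list("abc"), np.zeros((3, 3)), und)
        with pytest.raises(ValueError, match=r"\('a', 'b'\)"):
            td.pcoa(dist)

    def test_drop_undefined_samples_helper(self):
        und = np.zeros((4, 4), bool)
        und[0, 1] = und[1, 0] = und[1, 2] = und[2, 1] = True
        dist = td.DistanceMatrix(list("abcd"), np.zeros((4, 4)), und)
        cleaned = dist.drop_undefined_samples()
        assert "b" not in cleaned.labels  # 'b' offends twice, dropped first
        assert not cleaned.has_undefined()

    def test_square_matrix_roundtrip(self, tmp_path, three_pop_matrix):
        m, _ = three_pop_matrix
        d = td.k2p_distance(m.subset(m.sample_ids[:5]))
        d.undefined[0, 1] = d.undefined[1, 0] = True
        path = tmp_path / "dist.phy"
        d.write_phylip(path)
        back = td.DistanceMatrix.read_phylip(path)
        assert back.labels == d.labels
        assert np.array_equal(back.undefined, d.undefined)
        valid = ~d.undefined
        assert np.allclose(back.d[valid], d.d[valid], atol=1e-9)

    def test_agrees_with_skbio(self, three_pop_matrix):
        """Independent cross-check of the embedding eigenvalues."""
        skbio = pytest.importorskip("skbio")
        m, _ = three_pop_matrix
        d = td.k2p_distance(m.subset(m.sample_ids[:8]))
        res = td.pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.d, d.labels)
        )
        ref_eig = np.asarray(ref.eigvals)
        ref_eig = ref_eig[ref_eig > 1e-10]
        assert np.allclose(res.eigenvalues[: len(ref_eig)], ref_eig, rtol=1e-6)
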