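from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from cueloop import features, io
from cueloop.features import BandSet, Cluster, ClusterFeatureSet
from cueloop.montage import chain_adjacency

FS = 250.0


def _epochs(data, labels=None, fs=FS):
    data = np.asarray(data, float)
    labels = labels if labels is not None else ["smoking"] * data.shape[0]
    return io.EpochSet(
        data=data,
        times_ms=np.arange(data.shape[2]) / fs * 1000.0 - 200.0,
        labels=np.array(labels, dtype=object),
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
        sampling_rate=fs,
    )


class TestBandSet:
    def test_defaults(self):
        bs = BandSet()
        assert bs["alpha"] == (8.0, 13.0)
        assert bs["high_gamma"] == (52.0, 80.0)
        assert len(bs.names()) == 5

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            BandSet({"bad": (20.0, 10.0)})
        with pytest.raises(ValueError, match="overlap"):
            BandSet({"a": (8.0, 14.0), "b": (12.0, 20.0)})


class TestBandPower:
    def test_pure_10hz_dominates_alpha(self):
        t = np.arange(300) / FS
        data = np.sin(2 * np.pi * 10 * t)[None, None, :]
        bp = features.band_power(_epochs(data))
        mid = slice(20, 40)  # avoid edges
        means = {b: bp.band(b)[0, 0, mid].mean() for b in bp.band_names}
        for b in ("low_beta", "high_beta", "low_gamma", "high_gamma"):
            assert means["alpha"] >= 10 * means[b]

    def test_zero_signal_zero_power(self):
        bp = features.band_power(_epochs(np.zeros((2, 3, 300))))
        np.testing.assert_allclose(bp.data, 0.0, atol=1e-20)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 2, 300))
        bp1 = features.band_power(_epochs(data))
        bp2 = features.band_power(_epochs(2 * data))
        np.testing.assert_allclose(bp2.data, 4 * bp1.data, rtol=1e-10)

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            features.band_power(
                _epochs(np.zeros((1, 1, 300))), BandSet({"huge": (100.0, 130.0)})
            )

    def test_decimation(self):
        bp = features.band_power(_epochs(np.zeros((1, 1, 300))))
        assert bp.data.shape[-1] == 60  # 300 / 5
        assert bp.times_ms[0] == -200.0


def _enumeration_oracle(g1, g2):
    """Brute-force two-tailed permutation p per point over all label splits."""
    n1 = g1.shape[0]
    pooled = np.concatenate([g1, g2])
    n = pooled.shape[0]
    obs = stats.ttest_ind(g1, g2, axis=0).statistic
    count = np.zeros(obs.shape)
    total = 0
    for idx in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        t = stats.ttest_ind(pooled[sel], pooled[~sel], axis=0).statistic
        count += np.abs(t) >= np.abs(obs) - 1e-12
        total += 1
    return count / total


class TestPointwisePermutation:
    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(7)
        g1 = rng.standard_normal((4, 2, 3))
        g2 = rng.standard_normal((4, 2, 3)) + 0.8
        sm = features.pointwise_permutation(g1, g2, n_perm=100, alpha=0.05, seed=0)
        assert sm.exact
        assert sm.perm_t.shape[0] == 70  # C(8, 4)
        oracle_p = _enumeration_oracle(g1, g2)
        np.testing.assert_allclose(sm.p, oracle_p, atol=1e-12)

    def test_t_matches_scipy(self):
        rng = np.random.default_rng(8)
        g1 = rng.standard_normal((10, 3, 4))
        g2 = rng.standard_normal((12, 3, 4))
        sm = features.pointwise_permutation(g1, g2, n_perm=50, seed=0)
        ref = stats.ttest_ind(g1, g2, axis=0).statistic
        np.testing.assert_allclose(sm.tvals, ref, rtol=1e-9)

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        flags, total = 0, 0
        for _ in range(300):
            g1 = rng.standard_normal((10, 1, 4))
            g2 = rng.standard_normal((10, 1, 4))
            sm = features.pointwise_permutation(
                g1, g2, n_perm=400, alpha=0.05, seed=int(rng.integers(1 << 31))
            )
            flags += sm.sig_mask.sum()
            total += sm.sig_mask.size
        rate = flags / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 3 * se + 0.005

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(10)
        detected = 0
        for _ in range(40):
            g1 = rng.standard_normal((20, 2, 3))
            g2 = rng.standard_normal((20, 2, 3))
            g1[:, 1, 1] += 3.0  # 3 SD shift at one point
            sm = features.pointwise_permutation(
                g1, g2, n_perm=300, seed=int(rng.integers(1 << 31))
            )
            detected += bool(sm.sig_mask[1, 1])
        assert detected >= 39

    def test_degenerate_points(self):
        g1 = np.zeros((4, 1, 2))
        g2 = np.zeros((4, 1, 2))
        sm = features.pointwise_permutation(g1, g2, n_perm=50, seed=0)
        np.testing.assert_array_equal(sm.tvals, 0.0)
        np.testing.assert_array_equal(sm.p, 1.0)

    def test_too_few_trials(self):
        with pytest.raises(ValueError, match="2 trials"):
            features.pointwise_permutation(
                np.zeros((1, 1, 1)), np.zeros((4, 1, 1)), n_perm=10
            )


def _flood_fill_oracle(tvals, mask, adjacency):
    """Independent BFS cluster decomposition (sign-split, 4-ish connectivity)."""
    n_ch, n_t = tvals.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if not mask[c0, t0] or seen[c0, t0]:
                continue
            sign = 1 if tvals[c0, t0] > 0 else -1
            stack, members = [(c0, t0)], []
            seen[c0, t0] = True
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                neigh = [(c, t - 1), (c, t + 1)] + [
                    (c2, t) for c2 in range(n_ch) if adjacency[c, c2]
                ]
                for c2, t2 in neigh:
                    if (
                        0 <= c2 < n_ch
                        and 0 <= t2 < n_t
                        and mask[c2, t2]
                        and not seen[c2, t2]
                        and (1 if tvals[c2, t2] > 0 else -1) == sign
                    ):
                        seen[c2, t2] = True
                        stack.append((c2, t2))
            mass = sum(tvals[c, t] for c, t in members)
            out.append((frozenset(members), mass, sign))
    return out


class TestFindClusters:
    def test_single_point(self):
        tv = np.zeros((3, 4))
        tv[1, 2] = 2.5
        mask = tv != 0
        cl = features.find_clusters(tv, mask, chain_adjacency(3))
        assert len(cl) == 1
        pairs, mass, sign = cl[0]
        assert pairs.tolist() == [[1, 2]]
        assert mass == 2.5 and sign == 1

    def test_time_adjacent_merge(self):
        tv = np.zeros((2, 5))
        tv[0, 1] = 2.0
        tv[0, 2] = 3.0
        cl = features.find_clusters(tv, tv != 0, chain_adjacency(2))
        assert len(cl) == 1
        assert cl[0][1] == 5.0

    def test_channel_adjacency_respected(self):
        tv = np.zeros((3, 3))
        tv[0, 1] = 1.0
        tv[2, 1] = 1.0  # channels 0 and 2 not adjacent in a chain
        cl = features.find_clusters(tv, tv != 0, chain_adjacency(3))
        assert len(cl) == 2

    def test_signs_do_not_merge(self):
        tv = np.zeros((1, 4))
        tv[0, 1] = 2.0
        tv[0, 2] = -2.0
        cl = features.find_clusters(tv, tv != 0, None)
        assert len(cl) == 2
        assert sorted(s for _, _, s in cl) == [-1, 1]

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        adj = chain_adjacency(6)
        for _ in range(20):
            tv = rng.standard_normal((6, 20))
            mask = np.abs(tv) > 1.0
            ours = {
                (frozenset(map(tuple, pairs.tolist())), round(mass, 9), sign)
                for pairs, mass, sign in features.find_clusters(tv, mask, adj)
            }
            oracle = {
                (m, round(mass, 9), sign)
                for m, mass, sign in _flood_fill_oracle(tv, mask, adj)
            }
            assert ours == oracle


class TestClusterMass:
    def test_planted_cluster_significant(self):
        rng = np.random.default_rng(12)
        g1 = rng.standard_normal((30, 4, 20))
        g2 = rng.standard_normal((30, 4, 20))
        g1[:, 1:3, 5:12] += 1.5
        sm = features.pointwise_permutation(g1, g2, n_perm=300, seed=1)
        cfs = features.cluster_mass(sm, chain_adjacency(4))
        assert len(cfs) >= 1
        big = max(cfs.clusters, key=lambda c: abs(c.mass))
        assert big.sign == 1
        assert big.corrected_p < 0.05
        covered = {tuple(p) for p in big.member_idx}
        planted = {(c, t) for c in (1, 2) for t in range(5, 12)}
        assert len(covered & planted) >= 10

    def test_empty_mask_empty_set(self):
        g = np.random.default_rng(13).standard_normal((10, 2, 5))
        sm = features.pointwise_permutation(g, g + 0.0, n_perm=200, seed=2)
        sm.sig_mask[:] = False
        cfs = features.cluster_mass(sm, None)
        assert len(cfs) == 0

    def test_keep_all_returns_every_observed_cluster(self):
        rng = np.random.default_rng(14)
        g1 = rng.standard_normal((8, 2, 6))
        g2 = rng.standard_normal((8, 2, 6))
        sm = features.pointwise_permutation(g1, g2, n_perm=200, alpha=0.4, seed=3)
        all_c = features.cluster_mass(sm, None, keep="all")
        obs = features.find_clusters(sm.tvals, sm.sig_mask, None)
        assert len(all_c) == len(obs)


class TestAssembleFeatures:
    def _cluster(self, members, domain="amplitude", sign=1):
        return Cluster(
            domain=domain,
            sign=sign,
            members=members,
            member_idx=np.empty((0, 2), int),
            mass=1.0,
            corrected_p=0.01,
        )

    def test_single_point_cluster(self):
        data = np.arange(2 * 3 * 300, dtype=float).reshape(2, 3, 300)
        ep = _epochs(data)
        ms = float(ep.times_ms[100])
        cfs = ClusterFeatureSet([self._cluster([("ch1", ms)])])
        X = features.assemble_features(ep, cfs)
        np.testing.assert_allclose(X[:, 0], data[:, 1, 100])

    def test_vector_length_equals_n_clusters(self):
        ep = _epochs(np.zeros((4, 2, 300)))
        ms = float(ep.times_ms[10])
        cfs = ClusterFeatureSet(
            [self._cluster([("ch0", ms)]), self._cluster([("ch1", ms)])]
        )
        assert features.assemble_features(ep, cfs).shape == (4, 2)

    def test_amplitude_linearity(self):
        rng = np.random.default_rng(15)
        a = rng.standard_normal((3, 2, 300))
        b = rng.standard_normal((3, 2, 300))
        ep = _epochs(a)
        ms = [float(m) for m in ep.times_ms[40:45]]
        cfs = ClusterFeatureSet([self._cluster([("ch0", m) for m in ms])])
        fa = features.assemble_features(_epochs(a), cfs)
        fb = features.assemble_features(_epochs(b), cfs)
        fab = features.assemble_features(_epochs(a + b), cfs)
        np.testing.assert_allclose(fab, fa + fb, atol=1e-12)

    def test_empty_clusters_error(self):
        with pytest.raises(ValueError, match="no discriminative features"):
            features.assemble_features(_epochs(np.zeros((2, 1, 300))), ClusterFeatureSet([]))

    def test_window_features_drop_prestimulus(self):
        w = np.zeros((2, 250))
        w[1, 25] = 10.0  # 100 ms
        cfs = ClusterFeatureSet(
            [self._cluster([("ch1", 100.0), ("ch1", -50.0)])]  # -50 ms dropped
        )
        v = features.assemble_window_features(w, FS, ["ch0", "ch1"], cfs)
        # window is mean-centred per channel first
        expected = 10.0 - 10.0 / 250.0
        np.testing.assert_allclose(v, [expected], atol=1e-9)

    def test_json_round_trip(self):
        cfs = ClusterFeatureSet(
            [self._cluster([("PZ", 300.0), ("CZ", 304.0)], domain="band:alpha", sign=-1)],
            alpha=0.05,
        )
        back = ClusterFeatureSet.from_json(cfs.to_json())
        assert back.alpha == 0.05
        assert back.clusters[0].domain == "band:alpha"
        assert back.clusters[0].members == [("PZ", 300.0), ("CZ", 304.0)]


class TestSelectFeatures:
    def test_finds_planted_amplitude_effect(self, cue_epochs):
        cfs = features.select_features(
            cue_epochs, domains=("amplitude",), n_perm=200, seed=4
        )
        assert len(cfs) >= 1
        pos = [c for c in cfs.clusters if c.sign == 1]
        assert pos, "expected a smoking>neutral amplitude cluster"
        chans = {lab for c in pos for lab, _ in c.members}
        assert "PZ" in chans or "CPZ" in chans or "CZ" in chans
        times = [ms for c in pos for _, ms in c.members]
        assert 250.0 < np.median(times) < 650.0
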