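import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dielomics.diurnal import (
    call_cyclic,
    cluster_cyclic,
    cross_level_correlation,
    filter_genes,
    log2_center,
    relative_amplitude,
    turnover_trend,
)
from tests.conftest import make_sample_sheet


def level_table(meta, level, values_by_gene):
    cols = meta[meta["level"] == level]["sample_id"]
    return pd.DataFrame(
        {c: v for c, v in zip(cols, np.asarray(values_by_gene).T)},
        index=[f"g{i}" for i in range(np.asarray(values_by_gene).shape[0])],
    )


def brute_force_bh(p):
    """Textbook step-up definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFilterGenes:
    def make_tables(self, meta, n=5, value=10.0):
        return {
            level: level_table(
                meta, level, np.full((n, (meta["level"] == level).sum()), value)
            )
            for level in ("mrna", "ribo", "protein")
        }

    def test_low_count_genes_removed(self, sample_sheet):
        tables = self.make_tables(sample_sheet)
        genes = tables["mrna"].index
        mrna_counts = pd.Series([29, 30, 100, 100, 100], index=genes)
        ribo_counts = pd.Series([100, 100, 59, 60, 100], index=genes)
        retained, report = filter_genes(
            tables, sample_sheet, mrna_counts, ribo_counts
        )
        assert list(retained) == ["g1", "g3", "g4"]
        assert report.set_index("filter").loc["mrna_min_reads", "n_removed"] == 1

    def test_noisy_protein_removed_on_any_timepoint(self, sample_sheet):
        tables = self.make_tables(sample_sheet, n=2)
        prot = tables["protein"].copy()
        # gene g0: log2 SD ~1.5 at time point 3 only
        c1, c2 = "protein_t3_r1", "protein_t3_r2"
        prot.loc["g0", c1] = 10.0 * 2 ** (1.5 / np.sqrt(2))
        prot.loc["g0", c2] = 10.0 * 2 ** (-1.5 / np.sqrt(2))
        tables["protein"] = prot
        retained, _ = filter_genes(tables, sample_sheet)
        assert list(retained) == ["g1"]

    def test_missing_replicates_removed(self, sample_sheet):
        tables = self.make_tables(tables_meta := sample_sheet, n=3)
        ribo = tables["ribo"].copy()
        ribo.loc["g2", "ribo_t4_r2"] = 0.0  # only one positive replicate left
        tables["ribo"] = ribo
        retained, _ = filter_genes(tables, sample_sheet)
        assert list(retained) == ["g0", "g1"]

    def test_empty_intersection_raises_with_report(self, sample_sheet):
        tables = self.make_tables(sample_sheet, n=2)
        counts = pd.Series([0, 0], index=tables["mrna"].index)
        with pytest.raises(ValueError, match="attrition"):
            filter_genes(tables, sample_sheet, counts, None)


class TestLog2Center:
    def test_constant_row_centers_to_zero(self):
        out = log2_center(pd.DataFrame([[2.0, 2.0, 2.0]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_geometric_symmetry(self):
        out = log2_center(pd.DataFrame([[1.0, 2.0, 4.0]]))
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_row_means_zero(self, rng):
        values = pd.DataFrame(rng.lognormal(size=(20, 10)))
        out = log2_center(values)
        assert np.max(np.abs(out.mean(axis=1))) < 1e-12

    def test_idempotent(self, rng):
        values = pd.DataFrame(rng.lognormal(size=(5, 8)))
        once = log2_center(values)
        twice = log2_center(2.0 ** once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_nonpositive_value_names_gene(self):
        values = pd.DataFrame([[1.0, 0.0]], index=["gene_x"])
        with pytest.raises(ValueError, match="gene_x"):
            log2_center(values)


class TestCallCyclic:
    def meta(self):
        return make_sample_sheet(levels=("mrna",))

    def test_flat_gene_not_cyclic(self, rng):
        meta = self.meta()
        flat = rng.normal(0, 0.1, size=(10, 10))
        calls = call_cyclic(level_table(meta, "mrna", flat), meta)
        assert not calls["cyclic"].any()

    def test_all_values_equal_gives_p_one(self):
        meta = self.meta()
        calls = call_cyclic(level_table(meta, "mrna", np.zeros((3, 10))), meta)
        assert np.all(calls["p_value"] == 1.0)
        assert not calls["cyclic"].any()

    def test_zero_within_variance_with_differing_means(self):
        meta = self.meta()
        x = np.repeat([[0.0, 0.0, 2.0, 0.0, 0.0]], 2, axis=0).T.ravel()
        calls = call_cyclic(level_table(meta, "mrna", x[None, :]), meta)
        assert calls["p_value"].iloc[0] == 0.0
        assert calls["cyclic"].iloc[0]

    def test_planted_spike_called_cyclic(self, rng):
        meta = self.meta()
        base = rng.normal(0, 0.05, size=(40, 10))
        spike = base.copy()
        spike[0, 4:6] += 2.0  # time point 3 up by 2 log2 units
        calls = call_cyclic(level_table(meta, "mrna", spike), meta)
        assert calls["cyclic"].iloc[0]
        assert calls["max_abs_log2fc"].iloc[0] == pytest.approx(2.0, abs=0.2)

    def test_anova_matches_scipy(self, rng):
        meta = self.meta()
        x = rng.normal(size=(25, 10))
        calls = call_cyclic(level_table(meta, "mrna", x), meta)
        groups = [x[:, 2 * i : 2 * i + 2] for i in range(5)]
        f_ref, p_ref = stats.f_oneway(*groups, axis=1)
        assert np.allclose(calls["F"], f_ref)
        assert np.allclose(calls["p_value"], p_ref)

    def test_conjunction_rule(self, rng):
        """Significance alone or fold change alone is not enough."""
        meta = self.meta()
        x = rng.normal(0, 0.01, size=(30, 10))
        x[0, 4:6] += 0.5  # highly significant, FC < 1
        x[1] += np.repeat(rng.normal(0, 1.5, 5), 2)  # large FC, but so noisy
        calls = call_cyclic(level_table(meta, "mrna", x), meta)
        assert calls["q_value"].iloc[0] < 0.1
        assert calls["max_abs_log2fc"].iloc[0] < 1.0
        assert not calls["cyclic"].iloc[0]

    def test_single_replicate_rejected(self):
        meta = make_sample_sheet(levels=("mrna",), n_reps=1)
        with pytest.raises(ValueError, match="2 replicates"):
            call_cyclic(level_table(meta, "mrna", np.ones((3, 5))), meta)


class TestBenjaminiHochberg:
    def test_equal_spaced_p_values(self):
        meta = make_sample_sheet(levels=("mrna",))
        # classic example: p = (.01,.02,.03,.04), m=4 -> all q = .04
        q = brute_force_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        p=st.lists(
            st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40
        )
    )
    def test_statsmodels_matches_step_up_definition(self, p):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(np.asarray(p), method="fdr_bh")
        assert np.allclose(q, brute_force_bh(p), atol=1e-12)


class TestClusterCyclic:
    def profiles(self, rng, n_per_group=12, noise=0.05):
        hours = np.array([23.0, 1.0, 6.0, 11.0, 13.0])
        omega = 2 * np.pi / 24.0
        rows, labels = [], []
        for g, peak in enumerate([0.0, 6.0, 12.0, 18.0]):
            for _ in range(n_per_group):
                rows.append(
                    np.cos(omega * (hours - peak)) + rng.normal(0, noise, 5)
                )
                labels.append(g)
        idx = [f"g{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx, columns=hours), np.array(labels)

    def test_identical_profiles_cluster_together(self, rng):
        hours = np.array([23.0, 1.0, 6.0, 11.0, 13.0])
        a = np.sin(hours / 4.0)
        b = np.cos(hours / 4.0)
        profiles = pd.DataFrame(
            [a, a, b, b], index=list("wxyz"), columns=hours
        )
        labels, sil = cluster_cyclic(profiles, hours, k=2)
        assert labels["w"] == labels["x"]
        assert labels["y"] == labels["z"]
        assert labels["w"] != labels["y"]

    def test_recovers_planted_phase_groups(self, rng):
        from sklearn.metrics import rand_score

        profiles, truth = self.profiles(rng)
        labels, sil = cluster_cyclic(profiles, np.asarray(profiles.columns), k=4)
        assert rand_score(truth, labels.to_numpy()) > 0.95
        assert sil is not None and sil > 0.5

    def test_labels_ordered_by_peak_time(self, rng):
        profiles, truth = self.profiles(rng, noise=0.01)
        labels, _ = cluster_cyclic(profiles, np.asarray(profiles.columns), k=4)
        # group peaking at t=1 h (planted peak 0) must be G1, and so on
        peak_by_label = {}
        hours = np.asarray(profiles.columns)
        for lab in sorted(labels.unique()):
            mean = profiles[labels == lab].mean(axis=0).to_numpy()
            peak_by_label[lab] = hours[np.argmax(mean)]
        ordered = [peak_by_label[f"G{i}"] for i in range(1, 5)]
        assert ordered == sorted(ordered)

    def test_single_cluster_has_no_silhouette(self, rng):
        profiles, _ = self.profiles(rng, n_per_group=2)
        labels, sil = cluster_cyclic(profiles, np.asarray(profiles.columns), k=1)
        assert set(labels) == {"G1"} and sil is None

    def test_constant_profile_warns(self, rng):
        profiles, _ = self.profiles(rng, n_per_group=2)
        profiles.iloc[0] = 1.0
        with pytest.warns(UserWarning, match="constant profile"):
            cluster_cyclic(profiles, np.asarray(profiles.columns), k=2)

    def test_too_few_profiles_rejected(self):
        profiles = pd.DataFrame(np.eye(3), columns=[0.0, 6.0, 12.0])
        with pytest.raises(ValueError, match="at least k"):
            cluster_cyclic(profiles, k=4)


class TestAmplitudeAndCorrelation:
    def test_relative_amplitude_examples(self):
        means = pd.DataFrame(
            [np.log2([1, 2, 4, 2, 1]), np.zeros(5)], index=["up", "flat"]
        )
        ra = relative_amplitude(means)
        assert ra["up"] == pytest.approx(2.0)
        assert ra["flat"] == 0.0

    def test_identical_matrices_give_r_one(self, rng):
        a = pd.DataFrame(rng.normal(size=(10, 5)))
        assert cross_level_correlation(a, a)[0] == pytest.approx(1.0)
        assert cross_level_correlation(a, -a)[0] == pytest.approx(-1.0)

    def test_too_few_points_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError, match="3 pooled points"):
            cross_level_correlation(a, a)

    def test_planted_noise_level_recovered(self, rng):
        # correlation of x and x+noise matches the analytic attenuation
        signal = rng.normal(0, 1.0, size=(400, 5))
        noise = rng.normal(0, 0.5, size=(400, 5))
        r, _ = cross_level_correlation(
            pd.DataFrame(signal), pd.DataFrame(signal + noise)
        )
        assert r == pytest.approx(1 / np.sqrt(1.25), abs=0.02)


class TestTurnoverTrend:
    def test_constant_proxy_rejected(self):
        amp = pd.Series([0.1, 0.2, 0.3, 0.4])
        proxy = pd.Series([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero variance"):
            turnover_trend(amp, proxy)

    def test_planted_positive_dependence(self, rng):
        n = 200
        proxy = pd.Series(2.0 ** rng.normal(0, 1, n))
        amp = 0.3 * np.log2(proxy) + rng.normal(0, 0.3, n)
        r, p = turnover_trend(pd.Series(amp), proxy)
        assert r > 0 and p < 0.05

    def test_permutation_null_is_uniform(self, rng):
        n = 200
        proxy = pd.Series(2.0 ** rng.normal(0, 1, n))
        amp = pd.Series(0.3 * np.log2(proxy) + rng.normal(0, 0.3, n))
        p_values = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(proxy.to_numpy()))
            _, p = turnover_trend(amp, perm)
            p_values.append(p)
        p_values = np.array(p_values)
        assert np.abs(np.mean(p_values) - 0.5) < 0.1
        assert np.mean(p_values < 0.05) < 0.12

    def test_nonpositive_proxy_needs_linear_scale(self):
        amp = pd.Series([0.1, 0.2, 0.3])
        proxy = pd.Series([1.0, -1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            turnover_trend(amp, proxy)
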