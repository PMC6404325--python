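"""Expression-representation checks: TPM math, filters, clustering, QC."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xenodissect import InvalidInputError
from xenodissect.containers import CountMatrix, ExpressionMatrix
from xenodissect.normalize import (
    correlation_qc,
    de_prefilter,
    drop_all_zero_genes,
    filter_by_mapped_reads,
    hcluster,
    log_transform,
    median_center_rows,
    merge_cohorts,
    nearest_centroid,
    pca_scores,
    top_variable_genes,
    tpm,
    upper_quantile_normalize,
)


def _cm(counts, lengths, organism="human"):
    df = pd.DataFrame(counts)
    return CountMatrix(df, pd.Series(lengths, index=df.index), organism)


def _em(values, transforms=("TPM", "log2")):
    return ExpressionMatrix(pd.DataFrame(values), "human", transforms)


class TestTPM:
    def test_two_gene_closed_form(self):
        cm = _cm({"s1": [100, 100]}, [1000.0, 2000.0])
        t = tpm(cm).values["s1"]
        assert t.iloc[0] == pytest.approx(2e6 / 3)
        assert t.iloc[1] == pytest.approx(1e6 / 3)

    def test_scale_invariance_per_column(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, (30, 4))
        lengths = rng.integers(200, 3000, 30).astype(float)
        a = tpm(_cm(pd.DataFrame(counts), lengths))
        b = tpm(_cm(pd.DataFrame(counts * 7), lengths))
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_columns_sum_to_one_million(self, de_fixture):
        t = tpm(de_fixture.counts_human)
        sums = t.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_all_zero_column_flagged_and_kept_zero(self):
        cm = _cm({"s1": [10, 20], "s2": [0, 0]}, [100.0, 100.0])
        with pytest.warns(UserWarning, match="all-zero"):
            t = tpm(cm)
        assert (t.values["s2"] == 0).all()

    def test_human_tpm_insensitive_to_mouse_fraction(self):
        """Within-species TPM removes the species-mixture scaling.

        Two samples with identical human-side composition but opposite
        human/mouse fractions must have equal mean human TPM per gene, up
        to the NB noise envelope, averaged over replicate pairs.
        """
        from xenodissect.simulate import SampleSpec, SimDesign, simulate_counts

        n_rep = 100
        diffs, means = [], []
        for rep in range(n_rep):
            design = SimDesign(
                n_genes={"human": 200, "mouse": 50},
                samples=[
                    SampleSpec("hi", "L", "MGT", human_fraction=0.8, library_size=300_000),
                    SampleSpec("lo", "L", "MGT", human_fraction=0.2, library_size=300_000),
                ],
                dispersion=0.05,
                seed=20_000 + rep,
            )
            human, _, _, _ = simulate_counts(design)
            t = tpm(human).values
            diffs.append((t["hi"] - t["lo"]).to_numpy())
            means.append(t.mean(axis=1).to_numpy())
        mean_diff = np.mean(diffs, axis=0)
        mean_tpm = np.mean(means, axis=0)
        # SE of the mean paired difference under the NB model
        se = np.std(diffs, axis=0, ddof=1) / np.sqrt(n_rep)
        assert (np.abs(mean_diff) <= 4 * se + 1e-6 * mean_tpm).all()


class TestLogAndFilters:
    def test_log_transform_known_values(self):
        em = ExpressionMatrix(
            pd.DataFrame({"s": [0.0, 1.0, 1e6]}), "human", ("TPM",)
        )
        lg = log_transform(em).values["s"]
        assert lg.iloc[0] == 0.0
        assert lg.iloc[1] == 1.0
        assert lg.iloc[2] == pytest.approx(np.log2(1e6 + 1))

    def test_log_requires_tpm_tag(self):
        with pytest.raises(InvalidInputError):
            log_transform(_em({"s": [1.0]}, transforms=("TPM", "log2")))

    def test_drop_all_zero_genes(self):
        em = _em({"a": [0, 1, 0, 2, 0], "b": [0, 0, 0, 1, 3]})
        out = drop_all_zero_genes(em)
        assert list(out.values.index) == [1, 3, 4]
        # no zero rows -> identity; all-zero -> empty with sample axis kept
        assert drop_all_zero_genes(out).values.equals(out.values)
        empty = drop_all_zero_genes(_em({"a": [0], "b": [0]}))
        assert empty.values.shape == (0, 2)

    def test_prefilter_worked_examples(self):
        # 20 samples; gene0 all zero; gene1 exceeds 0.5 in exactly 2 samples
        # (2 == ceil(0.1*20) -> kept); gene2 constant positive -> kept
        data = np.zeros((3, 20))
        data[1, :2] = 5.0
        data[2, :] = 3.0
        df = pd.DataFrame(data)
        kept, log = de_prefilter(df)
        assert list(kept.index) == [1, 2]
        assert list(log.dropped) == [0]


class TestUpperQuantileAndCentering:
    def test_shift_removed_and_percentiles_equalized(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, (50, 6))
        base[:, 3] += 1.0  # one column shifted by +1 (log scale, i.e. 2x linear)
        em = _em(pd.DataFrame(base))
        out = upper_quantile_normalize(em)
        qs = [np.percentile(out.values[c][out.values[c] != 0], 75) for c in out.values]
        np.testing.assert_allclose(qs, qs[0], atol=1e-9)

    def test_identical_columns_unchanged_up_to_constant(self):
        col = np.arange(1.0, 11.0)
        em = _em(pd.DataFrame({"a": col, "b": col}))
        out = upper_quantile_normalize(em)
        np.testing.assert_allclose(out.values["a"], out.values["b"])

    def test_upper_quantile_idempotent(self):
        rng = np.random.default_rng(2)
        em = _em(pd.DataFrame(rng.uniform(0.5, 8, (40, 5))))
        once = upper_quantile_normalize(em)
        twice = upper_quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )

    def test_median_center_hand_example_even_row(self):
        em = _em(pd.DataFrame([[1.0, 2.0, 3.0, 10.0]]))
        out = median_center_rows(em).values.iloc[0]
        assert list(out) == [-1.5, -0.5, 0.5, 7.5]

    @given(arrays(np.float64, (6, 4), elements=st.floats(-50, 50)))
    def test_median_centering_idempotent(self, arr):
        em = _em(pd.DataFrame(arr))
        once = median_center_rows(em)
        twice = median_center_rows(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )


class TestVariableGenesAndClustering:
    def test_matches_bruteforce_variance_ranking(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"g{i}" for i in range(10)])
        em = _em(df)
        got = top_variable_genes(em, 4)
        var = df.var(axis=1)
        expect = sorted(df.index, key=lambda g: (-var[g], g))[:4]
        assert got == expect

    def test_full_list_and_constant_gene_ordering(self):
        df = pd.DataFrame(
            {"a": [1.0, 5.0], "b": [1.0, 9.0], "c": [1.0, 2.0]}, index=["flat", "vary"]
        )
        em = _em(df)
        assert top_variable_genes(em, 2) == ["vary", "flat"]

    def test_merge_order_matches_bruteforce_ward(self):
        """Agglomeration order equals an O(n^3) Lance-Williams reference."""
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 8)))
        em = _em(df)
        res = hcluster(em)
        # brute-force ward.D2 agglomeration on d = 1 - r
        corr = np.corrcoef(df.to_numpy().T)
        d2 = (1 - corr) ** 2
        n = 8
        active = {i: [i] for i in range(n)}
        sizes = {i: 1 for i in range(n)}
        dist = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
        merges = []
        next_id = n
        for _ in range(n - 1):
            (i, j), _dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
            merges.append(frozenset(active[i] + active[j]))
            new = next_id
            next_id += 1
            for k in list(active):
                if k in (i, j):
                    continue
                dik = dist[tuple(sorted((i, k)))]
                djk = dist[tuple(sorted((j, k)))]
                dij = dist[tuple(sorted((i, j)))]
                ni, nj, nk = sizes[i], sizes[j], sizes[k]
                dnew = (
                    (ni + nk) * dik + (nj + nk) * djk - nk * dij
                ) / (ni + nj + nk)
                dist[tuple(sorted((new, k)))] = dnew
            active[new] = active.pop(i) + active.pop(j)
            sizes[new] = sizes.pop(i) + sizes.pop(j)
            dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        members = {i: frozenset([i]) for i in range(n)}
        got = []
        for mi, row in enumerate(res.linkage):
            merged = members[int(row[0])] | members[int(row[1])]
            members[n + mi] = merged
            got.append(merged)
        assert got == merges

    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        df = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=20), "d": rng.normal(size=20)}
        )
        res = hcluster(_em(df))
        first = res.linkage[0, :2].astype(int)
        assert set(first) == {0, 1}


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (40, 1))
        df = pd.DataFrame(
            np.hstack([a + 0, a + 0.05, a + 5, a + 5.05]) + rng.normal(0, 0.01, (40, 4)),
            columns=["a1", "a2", "b1", "b2"],
        )
        scores = pca_scores(_em(df), 2)
        pc1 = scores["PC1"]
        assert np.sign(pc1["a1"]) == np.sign(pc1["a2"])
        assert np.sign(pc1["b1"]) == np.sign(pc1["b2"])
        assert np.sign(pc1["a1"]) != np.sign(pc1["b1"])

    def test_scores_orthogonal_and_variance_bounded(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(30, 6)))
        scores = pca_scores(_em(df), 3)
        g = scores.to_numpy()
        gram = g.T @ g
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert scores.attrs["explained_variance_ratio"].sum() <= 1.0 + 1e-12


class TestQCAndMisc:
    def test_planted_label_swap_detected_as_crossing_pair(self):
        rng = np.random.default_rng(8)
        profile = {ln: rng.normal(0, 1, 50) for ln in ("L1", "L2")}
        cols, lines = {}, {}
        for ln in ("L1", "L2"):
            # s1 and s2 are replicate profiles (nearest neighbors of each
            # other); s0 is the sample whose tray label will be swapped
            rep = profile[ln] + rng.normal(0, 0.05, 50)
            cols[f"{ln}_s1"] = rep
            cols[f"{ln}_s2"] = rep + rng.normal(0, 0.01, 50)
            cols[f"{ln}_s0"] = profile[ln] + rng.normal(0, 0.05, 50)
            for i in range(3):
                lines[f"{ln}_s{i}"] = ln
        lines["L1_s0"], lines["L2_s0"] = lines["L2_s0"], lines["L1_s0"]
        meta = pd.DataFrame({"line_id": pd.Series(lines)})
        em = _em(pd.DataFrame(cols))
        flagged, pairs = correlation_qc(em, meta)
        assert set(flagged) == {"L1_s0", "L2_s0"}
        assert len(pairs) == 1 and set(pairs[0]) == {"L1_s0", "L2_s0"}

    def test_no_swap_no_flags_even_with_duplicates(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=30)
        em = _em(pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=30)}))
        meta = pd.DataFrame({"line_id": ["L1", "L1", "L1"]}, index=["a", "b", "c"])
        flagged, pairs = correlation_qc(em, meta)
        assert flagged == [] and pairs == []

    def test_merge_cohorts_bitwise_and_missing_report(self):
        a = _em(pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"]))
        b = _em(pd.DataFrame({"s2": [3.0, 4.0]}, index=["g2", "g3"]))
        merged, origin, missing = merge_cohorts(a, b, ["g1", "g2", "g3"])
        assert list(merged.values.index) == ["g2"]
        assert merged.values.loc["g2", "s1"] == 2.0
        assert merged.values.loc["g2", "s2"] == 3.0
        assert origin.to_dict() == {"s1": "a", "s2": "b"}
        assert missing == {"a": ["g3"], "b": ["g1"]}

    def test_mapped_read_filter_is_strict(self):
        meta = pd.DataFrame(
            {"mapped_human_reads": [10_000_000, 10_000_001, 5]},
            index=["at", "above", "below"],
        )
        assert filter_by_mapped_reads(meta) == ["above"]
        assert filter_by_mapped_reads(meta.iloc[:0]) == []

    def test_nearest_centroid_recovers_simulated_classes(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(50)]
        centroids = pd.DataFrame(
            rng.normal(size=(50, 3)), index=genes, columns=["c1", "c2", "c3"]
        )
        cols, truth = {}, {}
        for i in range(60):
            cls = ["c1", "c2", "c3"][i % 3]
            cols[f"s{i}"] = centroids[cls] + rng.normal(0, 0.1, 50)
            truth[f"s{i}"] = cls
        result = nearest_centroid(pd.DataFrame(cols), centroids)
        acc = np.mean([result.loc[s, "label"] == truth[s] for s in cols])
        assert acc >= 0.95

    def test_nearest_centroid_exact_match_and_scores(self):
        rng = np.random.default_rng(11)
        centroids = pd.DataFrame(
            rng.normal(size=(20, 2)), index=[f"g{i}" for i in range(20)], columns=["x", "y"]
        )
        sample = pd.DataFrame({"s": centroids["x"]})
        res = nearest_centroid(sample, centroids)
        assert res.loc["s", "label"] == "x"
        assert res.loc["s", "score"] == pytest.approx(1.0)
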