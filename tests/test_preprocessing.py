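import gzip
import io

import numpy as np
import pandas as pd
import pytest

from ippscreen.preprocessing import (
    assemble_cohort,
    load_cohort,
    map_probes_to_genes,
    quantile_normalize,
    quantile_normalize_pooled,
    read_clinical,
    read_expression,
    read_mapping,
)


def probe_df(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=samples)


class TestProbeCollapsing:
    def test_two_probes_averaged(self):
        expr = probe_df([[1, 3], [3, 5]])
        mapping = pd.DataFrame({"probe": ["p0", "p1"], "gene": ["G", "G"]})
        out = map_probes_to_genes(expr, mapping)
        assert list(out.loc["G"]) == [2.0, 4.0]

    def test_single_probe_copied(self):
        expr = probe_df([[1.5, 2.5]])
        mapping = pd.DataFrame({"probe": ["p0"], "gene": ["G"]})
        out = map_probes_to_genes(expr, mapping)
        assert out.shape == (1, 2)
        assert list(out.loc["G"]) == [1.5, 2.5]

    def test_unmapped_probes_dropped(self):
        expr = probe_df([[1, 2], [3, 4]])
        mapping = pd.DataFrame({"probe": ["p0"], "gene": ["G"]})
        assert list(map_probes_to_genes(expr, mapping).index) == ["G"]

    def test_multi_mapped_probe_contributes_to_each_gene(self):
        expr = probe_df([[1, 2]])
        mapping = pd.DataFrame({"probe": ["p0", "p0"], "gene": ["A", "B"]})
        out = map_probes_to_genes(expr, mapping)
        assert sorted(out.index) == ["A", "B"]
        assert (out.loc["A"] == out.loc["B"]).all()

    def test_matches_brute_force_groupby_mean(self, rng):
        expr = probe_df(rng.standard_normal((50, 8)))
        genes = rng.choice([f"g{i}" for i in range(12)], size=50)
        mapping = pd.DataFrame({"probe": expr.index, "gene": genes})
        out = map_probes_to_genes(expr, mapping)
        for g in np.unique(genes):
            members = [p for p, gg in zip(expr.index, genes) if gg == g]
            expected = expr.loc[members].to_numpy().mean(axis=0)
            assert np.allclose(out.loc[g].to_numpy(), expected)

    def test_disjoint_mapping_rejected(self):
        expr = probe_df([[1, 2]])
        mapping = pd.DataFrame({"probe": ["absent"], "gene": ["G"]})
        with pytest.raises(ValueError, match="mapping"):
            map_probes_to_genes(expr, mapping)


def reference_quantile_normalize(values):
    """Independently coded quantile normalization (per-column loop)."""
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        for v in np.unique(col):
            block = col == v
            assigned[block] = assigned[block].mean()
        out[:, j] = assigned
    return out


class TestQuantileNormalize:
    def test_two_columns_become_rank_means(self):
        df = probe_df(np.array([[2, 1], [4, 3], [6, 5]]))
        out = quantile_normalize(df)
        assert np.allclose(out.to_numpy().T, [[1.5, 3.5, 5.5], [1.5, 3.5, 5.5]])

    def test_idempotent_on_normalized_matrix(self, rng):
        df = probe_df(rng.standard_normal((20, 6)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_columns_share_sorted_values_and_match_reference(self, rng):
        df = probe_df(rng.standard_normal((20, 10)))
        out = quantile_normalize(df).to_numpy()
        first = np.sort(out[:, 0])
        for j in range(1, 10):
            assert np.allclose(np.sort(out[:, j]), first)
        assert np.allclose(out, reference_quantile_normalize(df.to_numpy()))

    def test_ties_receive_block_mean(self):
        df = probe_df(np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]]))
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert np.isclose(out.iloc[0, 0], (ref[0] + ref[1]) / 2)
        assert np.isclose(out.iloc[1, 0], (ref[0] + ref[1]) / 2)

    def test_column_means_equal_grand_reference_mean(self, rng):
        # without ties every column mean equals the reference mean
        df = probe_df(rng.standard_normal((30, 5)))
        out = quantile_normalize(df)
        ref_mean = np.sort(df.to_numpy(), axis=0).mean(axis=1).mean()
        assert np.allclose(out.mean(axis=0), ref_mean)

    def test_commutes_with_sample_permutation(self, rng):
        df = probe_df(rng.standard_normal((15, 6)))
        perm = rng.permutation(df.columns)
        a = quantile_normalize(df)[perm]
        b = quantile_normalize(df[perm])
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(probe_df([[1], [2]]))

    def test_pooled_normalization_splits_back_per_cohort(self, rng):
        a = probe_df(rng.standard_normal((10, 4)), samples=[f"a{i}" for i in range(4)])
        b = probe_df(rng.standard_normal((10, 3)) + 5, samples=[f"b{i}" for i in range(3)])
        na, nb = quantile_normalize_pooled([a, b])
        assert list(na.columns) == list(a.columns)
        assert list(nb.columns) == list(b.columns)
        # pooled: all 7 samples share one sorted distribution
        assert np.allclose(np.sort(na.iloc[:, 0]), np.sort(nb.iloc[:, 0]))


class TestAssembleCohort:
    def clin(self, ids, time=None, event=None):
        n = len(ids)
        return pd.DataFrame({
            "sample_id": ids,
            "time": time if time is not None else np.arange(1.0, n + 1),
            "event": event if event is not None else [1] * n,
        })

    def test_full_match(self, rng):
        genes = probe_df(rng.standard_normal((3, 5)))
        c = assemble_cohort("X", genes, self.clin(list(genes.columns)))
        assert c.n == 5

    def test_partial_overlap_keeps_intersection(self, rng):
        genes = probe_df(rng.standard_normal((3, 5)))
        c = assemble_cohort("X", genes, self.clin(list(genes.columns[:3])))
        assert c.n == 3

    def test_row_order_invariance(self, rng):
        genes = probe_df(rng.standard_normal((3, 5)))
        clin = self.clin(list(genes.columns), time=rng.uniform(1, 9, 5),
                         event=[0, 1, 0, 1, 1])
        a = assemble_cohort("X", genes, clin)
        b = assemble_cohort("X", genes, clin.sample(frac=1, random_state=1))
        assert a.expr.equals(b.expr)
        assert a.time.equals(b.time)

    def test_zero_overlap_rejected(self, rng):
        genes = probe_df(rng.standard_normal((3, 4)))
        with pytest.raises(ValueError, match="overlap"):
            assemble_cohort("X", genes, self.clin(["z1", "z2"]))

    def test_non_binary_event_codes_rejected(self, rng):
        genes = probe_df(rng.standard_normal((3, 4)))
        clin = self.clin(list(genes.columns), event=[1, 0, 2, 1])
        with pytest.raises(ValueError, match="2"):
            assemble_cohort("X", genes, clin)


class TestReaders:
    def test_round_trip_including_gzip(self, rng, tmp_path):
        expr = probe_df(rng.standard_normal((4, 3)))
        expr.index.name = "probe_id"
        plain = tmp_path / "e.tsv"
        expr.to_csv(plain, sep="\t")
        gz = tmp_path / "e.tsv.gz"
        with gzip.open(gz, "wt") as fh:
            expr.to_csv(fh, sep="\t")
        assert np.allclose(read_expression(plain).to_numpy(), expr.to_numpy())
        assert np.allclose(read_expression(gz).to_numpy(), expr.to_numpy())

    def test_missing_values_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("probe\ts1\ts2\npA\t1.0\t\n")
        with pytest.raises(ValueError, match="missing"):
            read_expression(p)

    def test_clinical_requires_columns(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\ttime\nA\t3\n")
        with pytest.raises(ValueError, match="event"):
            read_clinical(p)

    def test_mapping_tolerates_header(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probe\tgene\npA\tG1\npB\tG2\n")
        m = read_mapping(p)
        assert list(m["gene"]) == ["G1", "G2"]

    def test_load_cohort_end_to_end(self, rng, tmp_path):
        expr = probe_df(rng.standard_normal((6, 5)))
        expr.index.name = "probe_id"
        (tmp_path / "e.tsv").write_text(expr.to_csv(sep="\t"))
        mapping = pd.DataFrame({"p": expr.index, "g": [f"G{i//2}" for i in range(6)]})
        (tmp_path / "m.tsv").write_text(mapping.to_csv(sep="\t", header=False, index=False))
        clin = pd.DataFrame({"sample_id": expr.columns,
                             "time": np.arange(1.0, 6.0), "event": [1, 0, 1, 1, 0]})
        (tmp_path / "c.tsv").write_text(clin.to_csv(sep="\t", index=False))
        c = load_cohort("X", tmp_path / "e.tsv", tmp_path / "c.tsv",
                        mapping_path=tmp_path / "m.tsv")
        assert c.expr.shape == (3, 5)
        assert c.n == 5
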