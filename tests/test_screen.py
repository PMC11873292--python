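import math

import numpy as np
import pytest

from panrc.core import ClusterLabeling, ExpressionMatrix, ValidationError
from panrc.screen import (
    normalize,
    pairwise_logfc,
    pan_marker_screen,
    pct_expressing,
)
from panrc.synthetic import PlantedMarker, SyntheticSpec, generate_counts

from conftest import random_labeling, random_matrix


# --- independent brute-force oracles ---------------------------------------

def oracle_normalize(counts, scale, base):
    out = np.zeros(counts.shape, dtype=float)
    for i in range(counts.shape[0]):
        depth = counts[i].sum()
        for j in range(counts.shape[1]):
            out[i, j] = math.log(1 + counts[i, j] * scale / depth, base)
    return out


def oracle_pct(counts, cell_clusters, cluster):
    n_pos = 0
    n_tot = 0
    frac = []
    for j in range(counts.shape[1]):
        n_pos = sum(
            1 for i in range(counts.shape[0])
            if cell_clusters[i] == cluster and counts[i, j] > 0
        )
        n_tot = sum(1 for c in cell_clusters if c == cluster)
        frac.append(n_pos / n_tot)
    return np.array(frac)


def oracle_logfc(counts, cell_clusters, target, other, scale, pseudo):
    lfc = []
    for j in range(counts.shape[1]):
        means = {}
        for grp in (target, other):
            vals = [
                counts[i, j] * scale / counts[i].sum()
                for i in range(counts.shape[0]) if cell_clusters[i] == grp
            ]
            means[grp] = sum(vals) / len(vals)
        lfc.append(math.log2((means[target] + pseudo) / (means[other] + pseudo)))
    return np.array(lfc)


def oracle_screen(counts, cell_clusters, target, min_pct, min_logfc, scale,
                  pseudo):
    clusters = []
    for c in cell_clusters:
        if c not in clusters:
            clusters.append(c)
    pct = oracle_pct(counts, cell_clusters, target)
    lfcs = {
        o: oracle_logfc(counts, cell_clusters, target, o, scale, pseudo)
        for o in clusters if o != target
    }
    out = {}
    for j in range(counts.shape[1]):
        mn = min(v[j] for v in lfcs.values())
        out[j] = (pct[j], mn, pct[j] > min_pct and mn > min_logfc)
    return out


# --- tests ------------------------------------------------------------------

class TestNormalize:
    def test_zero_count_normalizes_to_zero(self, rng):
        m = random_matrix(rng, 5, 4)
        counts = m.dense()
        counts[:, 0] += 1  # keep every cell's depth positive
        m = ExpressionMatrix(counts, m.gene_ids, m.cell_ids)
        nm = normalize(m)
        assert np.all((m.dense() == 0) == (nm.values == 0))

    def test_closed_form_single_entry(self):
        m = ExpressionMatrix(np.array([[10]]), ["g"], ["c"])
        nm = normalize(m, scale_total=10_000)
        assert nm.values[0, 0] == pytest.approx(math.log(1 + 10_000))

    def test_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 10, size=(20, 30))
        counts[:, 0] += 1  # no zero-depth cells
        m = ExpressionMatrix(counts, [f"g{j}" for j in range(30)],
                             [f"c{i}" for i in range(20)])
        nm = normalize(m, scale_total=10_000, log_base=math.e)
        np.testing.assert_allclose(
            nm.values, oracle_normalize(counts, 10_000, math.e), rtol=1e-12
        )

    def test_zero_depth_cell_named_in_error(self):
        m = ExpressionMatrix(np.array([[1], [0]]), ["g"], ["cA", "cB"])
        with pytest.raises(ValidationError, match="cB"):
            normalize(m)


class TestPctExpressing:
    def test_all_zero_gene_is_zero(self):
        m = ExpressionMatrix(np.array([[0, 1], [0, 2]]), ["g0", "g1"],
                             ["c1", "c2"])
        lab = ClusterLabeling.from_sequences(["c1", "c2"], ["A", "A"])
        pct = pct_expressing(m, lab, "A")
        assert pct["g0"] == 0.0
        assert pct["g1"] == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            m = random_matrix(rng, 15, 8)
            lab = random_labeling(rng, m, 3)
            clusters = [lab.labels[c] for c in m.cell_ids]
            for k in lab.clusters:
                np.testing.assert_allclose(
                    pct_expressing(m, lab, k).to_numpy(),
                    oracle_pct(m.dense(), clusters, k),
                )

    def test_unknown_cluster_rejected(self, rng):
        m = random_matrix(rng, 4, 2)
        lab = random_labeling(rng, m, 2)
        with pytest.raises(ValidationError, match="unknown cluster"):
            pct_expressing(m, lab, "missing")


class TestPairwiseLogfc:
    def test_identical_distributions_give_zero(self, rng):
        counts = rng.integers(0, 9, size=(6, 5)) + 1
        doubled = np.vstack([counts, counts])
        m = ExpressionMatrix(doubled, [f"g{j}" for j in range(5)],
                             [f"c{i}" for i in range(12)])
        lab = ClusterLabeling.from_sequences(
            m.cell_ids, ["A"] * 6 + ["B"] * 6
        )
        lfc = pairwise_logfc(normalize(m), lab, "A", "B")
        np.testing.assert_allclose(lfc.to_numpy(), 0.0, atol=1e-12)

    def test_antisymmetry(self, rng):
        m = random_matrix(rng, 12, 6)
        counts = m.dense()
        counts[:, 0] += 1
        m = ExpressionMatrix(counts, m.gene_ids, m.cell_ids)
        lab = random_labeling(rng, m, 2)
        nm = normalize(m)
        a, b = lab.clusters
        ab = pairwise_logfc(nm, lab, a, b).to_numpy()
        ba = pairwise_logfc(nm, lab, b, a).to_numpy()
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 12, size=(14, 7))
            counts[:, -1] += 1
            m = ExpressionMatrix(counts, [f"g{j}" for j in range(7)],
                                 [f"c{i}" for i in range(14)])
            lab = random_labeling(rng, m, 2)
            clusters = [lab.labels[c] for c in m.cell_ids]
            a, b = lab.clusters
            got = pairwise_logfc(normalize(m), lab, a, b).to_numpy()
            want = oracle_logfc(counts, clusters, a, b, 10_000, 1.0)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_planted_fold_change_recovered(self):
        # planted fold change 8 should come back as logFC ~ log2(8) = 3
        for seed in range(20):
            spec = SyntheticSpec(
                clusters=[("A", 800), ("B", 800)],
                n_genes=1000, baseline_mean=0.5, dispersion=2.0,
                planted_markers=[PlantedMarker("M", "A", 0.9, 8.0, 2.0)],
                seed=seed,
            )
            m, lab = generate_counts(spec)
            lfc = pairwise_logfc(normalize(m), lab, "A", "B")["M"]
            assert abs(lfc - 3.0) <= 0.3, f"seed {seed}: {lfc}"


class TestPanMarkerScreen:
    def test_planted_pan_marker_sole_top_hit(self):
        hits = 0
        for seed in range(20):
            spec = SyntheticSpec(
                clusters=[(k, 150) for k in ["RC", "B", "C", "D", "E"]],
                n_genes=300, baseline_mean=0.5, dispersion=1.0,
                planted_markers=[PlantedMarker("Pan", "RC", 0.95, 16.0, 0.5)],
                seed=seed,
            )
            m, lab = generate_counts(spec)
            res = pan_marker_screen(m, lab, "RC")
            passing = [r for r in res if r.passes]
            if len(passing) == 1 and passing[0].gene_id == "Pan" \
                    and passing[0].rank == 1:
                hits += 1
        assert hits >= 19

    def test_subset_marker_excluded_by_positivity(self):
        spec = SyntheticSpec(
            clusters=[("RC", 200), ("B", 200)], n_genes=50,
            planted_markers=[PlantedMarker("Sub", "RC", 0.17, 16.0, 0.05)],
            seed=3,
        )
        m, lab = generate_counts(spec)
        res = {r.gene_id: r for r in pan_marker_screen(m, lab, "RC")}
        assert not res["Sub"].passes
        assert res["Sub"].pct_in < 0.90

    def test_thresholds_are_strict(self):
        # pct_in exactly at threshold and logFC exactly at threshold both fail
        counts = np.array([[1, 3], [0, 3], [1, 1], [1, 1]])
        m = ExpressionMatrix(counts, ["gA", "gB"], list("abcd"))
        lab = ClusterLabeling.from_sequences(list("abcd"), ["T", "T", "O", "O"])
        res = {r.gene_id: r for r in
               pan_marker_screen(m, lab, "T", min_pct=0.5, min_logfc=0.0)}
        assert res["gA"].pct_in == 0.5
        assert not res["gA"].passes  # 0.5 > 0.5 is false

    def test_single_cluster_rejected(self, rng):
        m = random_matrix(rng, 4, 3)
        lab = ClusterLabeling.from_sequences(m.cell_ids, ["A"] * 4)
        with pytest.raises(ValidationError, match="2 clusters"):
            pan_marker_screen(m, lab, "A")

    def test_matches_brute_force_screen(self, rng):
        for _ in range(30):
            n_cells = int(rng.integers(6, 20))
            n_genes = int(rng.integers(2, 10))
            m = random_matrix(rng, n_cells, n_genes)
            counts = m.dense()
            counts[:, 0] += 1
            m = ExpressionMatrix(counts, m.gene_ids, m.cell_ids)
            lab = random_labeling(rng, m, int(rng.integers(2, 4)))
            target = lab.clusters[0]
            res = pan_marker_screen(m, lab, target, min_pct=0.5,
                                    min_logfc=0.25)
            want = oracle_screen(counts, [lab.labels[c] for c in m.cell_ids],
                                 target, 0.5, 0.25, 10_000, 1.0)
            for r in res:
                j = m.gene_ids.index(r.gene_id)
                w_pct, w_min, w_pass = want[j]
                assert r.pct_in == pytest.approx(w_pct)
                assert r.min_logfc == pytest.approx(w_min, rel=1e-9)
                assert r.passes == w_pass

    def test_invariant_to_cell_and_gene_order(self, rng):
        m = random_matrix(rng, 12, 6)
        counts = m.dense()
        counts[:, 0] += 1
        lab_list = ["A"] * 6 + ["B"] * 6
        m1 = ExpressionMatrix(counts, m.gene_ids, m.cell_ids)
        lab1 = ClusterLabeling.from_sequences(m1.cell_ids, lab_list)
        cperm = rng.permutation(12)
        gperm = rng.permutation(6)
        m2 = ExpressionMatrix(counts[np.ix_(cperm, gperm)],
                              [m.gene_ids[j] for j in gperm],
                              [m.cell_ids[i] for i in cperm])
        lab2 = ClusterLabeling.from_sequences(
            m2.cell_ids, [lab_list[i] for i in cperm]
        )
        r1 = {r.gene_id: r for r in pan_marker_screen(m1, lab1, "A",
                                                      min_pct=0.1,
                                                      min_logfc=0.1)}
        r2 = {r.gene_id: r for r in pan_marker_screen(m2, lab2, "A",
                                                      min_pct=0.1,
                                                      min_logfc=0.1)}
        for g in m.gene_ids:
            assert r1[g].pct_in == pytest.approx(r2[g].pct_in)
            assert r1[g].min_logfc == pytest.approx(r2[g].min_logfc)
            assert r1[g].rank == r2[g].rank

    def test_threshold_monotonicity(self, rng):
        m = random_matrix(rng, 20, 10)
        counts = m.dense()
        counts[:, 0] += 1
        m = ExpressionMatrix(counts, m.gene_ids, m.cell_ids)
        lab = random_labeling(rng, m, 3)
        target = lab.clusters[0]

        def passing(min_pct, min_logfc):
            return {r.gene_id for r in
                    pan_marker_screen(m, lab, target, min_pct, min_logfc)
                    if r.passes}

        base = passing(0.1, 0.0)
        assert passing(0.3, 0.0) <= base
        assert passing(0.1, 0.5) <= base
        assert passing(0.3, 0.5) <= base
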