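import numpy as np
import pytest

from deltasketch.delta import ExactBackend, SketchBackend, delta_union, delta_value
from deltasketch.similarity import DistanceMatrix, all_pairs, jaccard_k, kij
from deltasketch.simdata import simulate_graded_divergence

from _oracles import jaccard as oracle_jaccard
from conftest import make_genome, random_dna


def _kij_exact(ga, gb):
    be = ExactBackend()
    ra = delta_value([ga], be)
    rb = delta_value([gb], be)
    ru = delta_union([([ga], ra), ([gb], rb)], be)
    return kij(ra, rb, ru)


def test_kij_identity_is_one(rng):
    g = make_genome(random_dna(rng, 500))
    assert _kij_exact(g, g) == 1.0


def test_kij_symmetry(rng):
    ga = make_genome(random_dna(rng, 400))
    gb = make_genome(random_dna(rng, 400))
    assert _kij_exact(ga, gb) == _kij_exact(gb, ga)


def test_kij_disjoint_content_is_zero():
    # poly-A and poly-C share no canonical k-mer at any k, so the union
    # cardinalities add exactly and KIJ collapses to 0
    ga = make_genome("A" * 100)
    gb = make_genome("C" * 100)
    assert _kij_exact(ga, gb) == 0.0


def test_kij_in_unit_interval_without_clamping(small_pangenome):
    be = ExactBackend()
    results = [delta_value([g], be) for g in small_pangenome[:4]]
    for i in range(4):
        for j in range(i + 1, 4):
            a, b = small_pangenome[i], small_pangenome[j]
            u = delta_union([([a], results[i]), ([b], results[j])], be)
            assert max(results[i].delta, results[j].delta) <= u.delta
            assert u.delta <= results[i].delta + results[j].delta
            value = kij(results[i], results[j], u, clamp=False)
            assert 0.0 <= value <= 1.0


def test_jaccard_k_worked_example():
    # A=ACGT -> canonical 2-mer set {AC, CG}; B=ACGA -> {AC, CG, GA}
    ga, gb = make_genome("ACGT"), make_genome("ACGA")
    j = jaccard_k([ga], [gb], 2, ExactBackend())
    assert j == pytest.approx(2 / 3, abs=1e-12)
    assert jaccard_k([ga], [ga], 2, ExactBackend()) == 1.0


def test_jaccard_inclusion_exclusion_matches_set_oracle(rng):
    be = ExactBackend()
    for _ in range(15):
        sa = random_dna(rng, 300)
        sb = random_dna(rng, 300)
        for k in (3, 7, 11):
            ours = jaccard_k([make_genome(sa)], [make_genome(sb)], k, be)
            assert ours == pytest.approx(oracle_jaccard([sa], [sb], k), abs=1e-12)


def test_all_pairs_identical_genomes_zero_matrix(rng):
    s = random_dna(rng, 400)
    inputs = [(lab, make_genome(s)) for lab in ("a", "b", "c")]
    m = all_pairs(inputs, ExactBackend(), metric="one_minus_kij")
    assert np.allclose(m.values, 0.0)
    assert m.labels == ("a", "b", "c")


def test_all_pairs_invariant_to_input_order(rng):
    genomes = [(lab, make_genome(random_dna(rng, 300)))
               for lab in ("x", "y", "z")]
    m1 = all_pairs(genomes, ExactBackend())
    m2 = all_pairs(genomes[::-1], ExactBackend())
    assert m1.labels == m2.labels
    assert np.array_equal(m1.values, m2.values)


def test_all_pairs_duplicate_labels_rejected(rng):
    g = make_genome(random_dna(rng, 100))
    with pytest.raises(ValueError, match="duplicate"):
        all_pairs([("a", g), ("a", g)], ExactBackend())


def test_distance_increases_with_divergence():
    genomes = simulate_graded_divergence(
        base_length=20_000, snp_rates=(0.002, 0.01, 0.02, 0.05), seed=4
    )
    inputs = [(g.label, g) for g in genomes]
    m = all_pairs(inputs, ExactBackend(), metric="one_minus_kij")
    dists = [m["anc", f"div{i}"] for i in range(4)]
    assert dists == sorted(dists)
    assert dists[0] < dists[-1]


def test_all_pairs_jk_metric(rng):
    genomes = [(lab, make_genome(random_dna(rng, 300)))
               for lab in ("a", "b", "c")]
    m = all_pairs(genomes, ExactBackend(), metric="one_minus_jk", k=5)
    assert m.metric == "one_minus_jk(5)"
    for i, la in enumerate(m.labels):
        for j, lb in enumerate(m.labels):
            if i < j:
                expected = 1 - jaccard_k(
                    [dict(genomes)[la]], [dict(genomes)[lb]], 5, ExactBackend()
                )
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_approximate_kij_close_to_exact(small_pangenome):
    inputs = [(g.label, g) for g in small_pangenome[:5]]
    exact = all_pairs(inputs, ExactBackend())
    approx = all_pairs(inputs, SketchBackend(p=14))
    assert np.abs(exact.values - approx.values).max() <= 0.02


def test_approximate_out_of_range_values_clamped_with_warning():
    from deltasketch.delta import DeltaResult

    a = DeltaResult(delta=10.0, k_star=3, trace={3: 30.0}, mode="approximate")
    b = DeltaResult(delta=10.0, k_star=3, trace={3: 30.0}, mode="approximate")
    u = DeltaResult(delta=9.5, k_star=3, trace={3: 28.5}, mode="approximate")
    with pytest.warns(UserWarning, match="clamped"):
        assert kij(a, b, u) == 1.0


def test_distance_matrix_validation_and_writers(tmp_path):
    labels = ("alpha", "averyverylongname", "c")
    vals = np.array([[0, 0.25, 0.5], [0.25, 0, 0.125], [0.5, 0.125, 0]])
    m = DistanceMatrix(labels=labels, values=vals, metric="one_minus_kij")

    phy = tmp_path / "m.phylip"
    m.write_phylip(phy)
    lines = phy.read_text().splitlines()
    assert lines[0] == "3"
    for line, label in zip(lines[1:], labels):
        assert line[:10].strip() == label[:10]
    parsed = np.array([[float(x) for x in l[10:].split()] for l in lines[1:]])
    assert np.allclose(parsed, vals)
    assert np.allclose(parsed, parsed.T)

    tsv = tmp_path / "m.tsv"
    m.write_tsv(tsv)
    body = [l for l in tsv.read_text().splitlines() if not l.startswith("#")]
    assert len(body) - 1 == 3  # upper triangle only

    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0, 1], [0.5, 0]]), "one_minus_kij")
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[0.1, 0], [0, 0.1]]), "one_minus_kij")
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        DistanceMatrix(("a", "b"), np.array([[0, 2.0], [2.0, 0]]), "one_minus_kij")
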