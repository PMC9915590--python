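import itertools
import math

import numpy as np
import pytest

from deltasketch.delta import ExactBackend, delta_value
from deltasketch.growth import (
    fit_heaps,
    mean_delta_curve,
    progressive,
    sample_orderings,
    write_progressive_tsv,
)

from conftest import make_genome, random_dna


def test_orderings_exhaust_when_norder_exceeds_factorial():
    perms = sample_orderings(3, 100, seed=1)
    assert len(perms) == 6
    assert len(set(perms)) == 6
    assert set(perms) == set(itertools.permutations(range(3)))


def test_orderings_deterministic_and_seed_sensitive():
    a = sample_orderings(10, 90, seed=5)
    b = sample_orderings(10, 90, seed=5)
    c = sample_orderings(10, 90, seed=6)
    assert a == b
    assert a != c
    assert len(set(a)) == 90


def test_orderings_validation():
    with pytest.raises(ValueError):
        sample_orderings(0, 5, seed=0)
    with pytest.raises(ValueError):
        sample_orderings(5, 0, seed=0)


def _tiny_genomes(rng, n, length=400):
    return [make_genome(random_dna(rng, length), label=f"g{i}")
            for i in range(n)]


def test_progressive_record_count_and_final_union_identical(rng):
    genomes = _tiny_genomes(rng, 3)
    records = progressive(genomes, 100, seed=0, backend=ExactBackend())
    assert len(records) == 6 * 3  # all 3! orderings, 3 steps each
    finals = {r.delta for r in records if r.step == 3}
    assert len(finals) == 1
    final_kstars = {r.k_star for r in records if r.step == 3}
    assert len(final_kstars) == 1


def test_progressive_delta_nondecreasing_within_ordering(rng):
    genomes = _tiny_genomes(rng, 4)
    records = progressive(genomes, 24, seed=0, backend=ExactBackend())
    by_ordering = {}
    for r in records:
        by_ordering.setdefault(r.ordering_id, []).append(r)
    for recs in by_ordering.values():
        deltas = [r.delta for r in sorted(recs, key=lambda r: r.step)]
        assert all(b >= a for a, b in zip(deltas, deltas[1:]))


def test_progressive_identical_genomes_flat(rng):
    s = random_dna(rng, 300)
    g1, g2 = make_genome(s, label="a"), make_genome(s, label="b")
    records = progressive([g1, g2], 2, seed=0, backend=ExactBackend())
    step1 = {r.delta for r in records if r.step == 1}
    step2 = {r.delta for r in records if r.step == 2}
    assert step1 == step2


def test_mean_curve_matches_subset_average(rng):
    # with all orderings, the step-i mean equals the uniform average of
    # delta over all size-i subsets
    genomes = _tiny_genomes(rng, 4)
    backend = ExactBackend()
    records = progressive(genomes, math.factorial(4), seed=0, backend=backend)
    curve = dict(mean_delta_curve(records))
    for i in range(1, 5):
        subset_deltas = [
            delta_value([genomes[j] for j in subset], backend).delta
            for subset in itertools.combinations(range(4), i)
        ]
        assert curve[i] == pytest.approx(float(np.mean(subset_deltas)), rel=1e-12)


def test_progressive_needs_two_genomes(rng):
    with pytest.raises(ValueError):
        progressive(_tiny_genomes(rng, 1), 1, seed=0, backend=ExactBackend())


def _curve_from_increments(K, alpha, n, delta1=100.0):
    deltas = [delta1]
    for i in range(2, n + 1):
        deltas.append(deltas[-1] + K * i ** (-alpha))
    return list(zip(range(1, n + 1), deltas))


def test_heaps_fit_recovers_noise_free_power_law():
    fit = fit_heaps(_curve_from_increments(5.0, 0.9, 30))
    assert fit.alpha == pytest.approx(0.9, abs=1e-6)
    assert fit.K == pytest.approx(5.0, rel=1e-6)
    assert fit.openness == "open"
    assert fit.fit_range == tuple(range(2, 31))


def test_heaps_fit_openness_branches():
    assert fit_heaps(_curve_from_increments(2.0, 1.3, 25)).openness == "closed"
    assert fit_heaps(_curve_from_increments(3.0, 0.5, 25)).openness == "open"
    flat = fit_heaps(_curve_from_increments(4.0, 0.0, 25))
    assert flat.alpha == pytest.approx(0.0, abs=1e-9)
    assert flat.openness == "open"


def test_heaps_fit_drops_nonpositive_increments():
    pts = _curve_from_increments(5.0, 0.9, 20)
    # flatten one step: its increment becomes zero and must be dropped
    broken = [(i, d if i != 10 else pts[8][1]) for i, d in pts]
    with pytest.warns(UserWarning, match="step 10"):
        fit = fit_heaps(broken)
    assert 10 not in fit.fit_range
    assert fit.alpha == pytest.approx(0.9, abs=0.05)


def test_heaps_fit_input_validation():
    with pytest.raises(ValueError):
        fit_heaps([(1, 1.0), (2, 2.0)])
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="usable"):
            fit_heaps([(1, 3.0), (2, 2.0), (3, 1.0)])  # all decreasing


def test_heaps_alpha_recovery_under_noise():
    rng = np.random.default_rng(7)
    errs = []
    for _ in range(100):
        noise = rng.normal(0, 0.05, size=29)
        deltas = [50.0]
        for i, eps in zip(range(2, 31), noise):
            deltas.append(deltas[-1] + 4.0 * i ** (-0.8) * np.exp(eps))
        fit = fit_heaps(list(zip(range(1, 31), deltas)))
        errs.append(abs(fit.alpha - 0.8))
    assert float(np.mean(errs)) <= 0.03


def test_tsv_writer_shape_and_header(tmp_path, rng):
    genomes = _tiny_genomes(rng, 3)
    records = progressive(genomes, 6, seed=0, backend=ExactBackend())
    out = tmp_path / "prog.tsv"
    write_progressive_tsv(records, out, header_meta={"seed": 0, "norder": 6})
    lines = out.read_text().splitlines()
    meta = [l for l in lines if l.startswith("#")]
    body = [l for l in lines if not l.startswith("#")]
    assert "# seed=0" in meta
    assert body[0].split("\t") == [
        "ordering_id", "step", "genome_label", "genome_digest", "delta", "k_star"
    ]
    assert len(body) - 1 == 6 * 3
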