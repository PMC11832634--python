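import numpy as np
import pytest

from tcassign import lda, synthetic
from tcassign.peaklists import AMINO_ACIDS
from tcassign.synthetic import (
    GeneratorConfig,
    SyntheticError,
    benchmark_statistics,
    default_statistics,
    make_benchmark,
    random_sequence,
    sample_chains,
    sample_protein,
)


def test_same_seed_identical_outputs():
    cfg = GeneratorConfig(length=40)
    p1 = sample_protein(cfg, seed=5)
    p2 = sample_protein(cfg, seed=5)
    assert p1.sequence == p2.sequence
    assert p1.truth.equals(p2.truth)
    for key in p1.peaklists:
        for a, b in zip(p1.peaklists[key], p2.peaklists[key]):
            assert a.positions == b.positions


def test_alanine_draws_clt_bound():
    cfg = GeneratorConfig(sequence="A" * 1000)
    p = sample_protein(cfg, seed=13)
    mean, sd = cfg.stats.get("A", "CA")
    sample_mean = p.truth["CA_base"].mean()
    assert abs(sample_mean - mean) < 4 * sd / np.sqrt(1000)


def test_noise_free_tcs_recovered_exactly():
    cfg = GeneratorConfig(length=60)  # noise defaults to zero
    p = sample_protein(cfg, seed=21)
    truth = p.truth.set_index("res_num")
    for s in p.base_systems.values():
        for feat, measured in s.tcs.items():
            assert measured == pytest.approx(truth.loc[s.res_num, f"{feat}_true"], abs=1e-9)


def test_default_statistics_schema():
    table = default_statistics()
    assert len(table.types) == 20
    assert all(sd > 0 for _, sd in table.stats.values())
    assert not table.has("G", "CB") and not table.has("G", "TC1_CB")
    assert not table.has("P", "HN") and not table.has("P", "TC1_HN")
    for t in table.types:
        if t not in ("G", "P"):
            assert all(table.has(t, n) for n in ("HN", "N", "C", "CA", "CB"))
    assert default_statistics().to_frame().equals(table.to_frame())  # deterministic


def test_benchmark_statistics_pairs_share_shifts():
    table = benchmark_statistics(pairs=(("E", "Q"),), tc_separation_sd=3.0)
    for n in ("HN", "N", "C", "CA", "CB"):
        assert table.get("E", n) == table.get("Q", n)
        me, sd = table.get("E", f"TC1_{n}")
        mq, _ = table.get("Q", f"TC1_{n}")
        assert abs(mq - me) == pytest.approx(3.0 * sd)


def test_random_sequence_composition():
    rng = np.random.default_rng(8)
    seq = random_sequence(rng, length=239)
    assert len(seq) == 239
    assert seq.count("P") == 26 and seq.count("G") == 28
    assert set(seq) <= set(AMINO_ACIDS)
    other_counts = [seq.count(t) for t in AMINO_ACIDS if t not in ("P", "G")]
    assert max(other_counts) - min(other_counts) <= 1  # near-balanced


def test_prolines_have_no_spin_system_glycines_no_cb(protein):
    base = protein.base_systems
    for i, t in enumerate(protein.sequence, start=1):
        if t == "P":
            assert f"P{i}" not in base
        elif t == "G":
            assert "CB" not in base[f"G{i}"].shifts


def test_missingness_removes_shifts_and_dependent_tcs():
    cfg = GeneratorConfig(length=120, missingness={"CB": 0.5})
    p = sample_protein(cfg, seed=3)
    n_missing = sum(
        1
        for s in p.base_systems.values()
        if s.res_type != "G" and "CB" not in s.shifts
    )
    assert n_missing > 10
    for s in p.base_systems.values():
        if "CB" not in s.shifts:
            assert all(not f.endswith("_CB") for f in s.tcs)


def test_benchmark_partition_and_rounding(protein):
    eligible = [s for s in protein.base_systems.values() if s.res_type not in ("G", "P")]
    bench = make_benchmark(protein, train_fraction=0.65, seed=4)
    # stratified split: per-type rounding, summed
    per_type = {}
    for s in eligible:
        per_type[s.res_type] = per_type.get(s.res_type, 0) + 1
    assert len(bench.train) == sum(round(0.65 * n) for n in per_type.values())
    assert len(bench.train) + len(bench.queries) == len(eligible)
    train_types = {s.res_type for s in bench.train}
    assert train_types == set(per_type)  # every type keeps training members
    assert all(s.res_type is not None for s in bench.train)
    assert all(s.res_type is None for s in bench.queries)

    with pytest.raises(SyntheticError):
        make_benchmark(protein, train_fraction=0.999999, seed=4)
    with pytest.raises(SyntheticError):
        make_benchmark(protein, train_fraction=1.5, seed=4)


def test_benchmark_chains_match_sequence(protein):
    bench = make_benchmark(protein, train_fraction=0.65, seed=4)
    assert bench.chains
    seq = protein.sequence
    for chain in bench.chains:
        start = bench.chain_starts[chain.name]
        for offset, s in enumerate(chain.systems):
            true_type, res_num = bench.truth[s.id]
            assert res_num == start + offset
            assert seq[res_num - 1] == true_type
        left = start - 1
        if chain.left_boundary == "proline":
            assert seq[left - 1] == "P"
        elif chain.left_boundary == "terminus":
            assert left == 0


def test_sampled_chains_avoid_excluded_types(protein):
    chains, starts = sample_chains(protein, n=20, seed=9)
    for chain in chains:
        start = starts[chain.name]
        window = protein.sequence[start - 1 : start - 1 + len(chain)]
        assert "P" not in window and "G" not in window


def test_uninformative_tcs_add_nothing():
    """With zero TC separation the degenerate pairs stay unresolvable."""
    stats = benchmark_statistics(pairs=(("E", "Q"),), tc_separation_sd=0.0)
    seq = ("E" * 25 + "Q" * 25)
    accs = {}
    for sub in ("iv", "v"):
        correct = total = 0
        for seed in range(5):
            p = sample_protein(GeneratorConfig(sequence=seq, stats=stats), seed=seed)
            members = sorted(p.base_systems.values(), key=lambda s: s.res_num)
            train = [s for s in members if s.res_num % 2 == 0]
            test = [s for s in members if s.res_num % 2 == 1]
            model = lda.fit(train, sub, min_class_size=2)
            for s in test:
                correct += lda.posterior(model, s).ranking[0] == s.res_type
                total += 1
        accs[sub] = correct / total
    # both are coin flips on interchangeable classes; agreement within sampling error
    assert abs(accs["v"] - accs["iv"]) < 0.10
    assert accs["iv"] < 0.75 and accs["v"] < 0.75


def test_unknown_residue_letter_errors():
    with pytest.raises(SyntheticError):
        sample_protein(GeneratorConfig(sequence="AXA"), seed=0)


def test_config_validation():
    with pytest.raises(SyntheticError):
        GeneratorConfig(temperatures=(10.0, 5.0))
    with pytest.raises(SyntheticError):
        GeneratorConfig(missingness={"CB": 1.5})
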