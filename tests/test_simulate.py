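"""Pool simulation, selection dynamics, read synthesis and the genome fixture."""

import edlib
import numpy as np
import pytest

from scramblekit._rng import stage_rng
from scramblekit.design import Genotype, RecombinationEvent, apply_event, revcomp
from scramblekit.simulate import (
    ErrorModel,
    FitnessModel,
    Pool,
    PoolConfig,
    PoolEntry,
    facs_gate,
    grow_select,
    make_genome_fixture,
    pcr_sample,
    run_iterative_rounds,
    simulate_induction,
    synthesize_reads,
    true_key_from_read_id,
)


# ---------------------------------------------------------------------------
# induction


def test_no_events_yields_parental_only(toy_design):
    cfg = PoolConfig(n_cells=500, lambda_events=0.0, p_cre_active=1.0, seed=3)
    pool = simulate_induction(toy_design.parental_genotype(), toy_design, cfg)
    assert set(pool.entries) == {toy_design.parental_genotype().key}


def test_no_cre_no_leak_means_no_gfp(toy_design):
    cfg = PoolConfig(n_cells=500, p_cre_active=0.0, p_leak=0.0, seed=3)
    pool = simulate_induction(toy_design.parental_genotype(), toy_design, cfg)
    assert all(e.gfp_positive_fraction == 0.0 for e in pool.entries.values())


def test_poisson_event_fraction(toy_design):
    """Fraction of cells with >=1 event ~ 1 - exp(-lambda) (binomial error)."""
    lam, n = 1.5, 10_000
    cfg = PoolConfig(n_cells=n, lambda_events=lam, p_cre_active=1.0, seed=5)
    pool = simulate_induction(toy_design.parental_genotype(), toy_design, cfg)
    parental_frac = pool.frequencies().get(toy_design.parental_genotype().key, 0.0)
    # cells with >=1 event can still return to parental only via duplication+
    # deletion chains; treat parental frequency as an upper bound on exp(-lam)
    expect = np.exp(-lam)
    se = np.sqrt(expect * (1 - expect) / n)
    assert parental_frac == pytest.approx(expect, abs=5 * se + 0.01)


def test_induction_reproducible(toy_design):
    cfg = PoolConfig(n_cells=1000, seed=11)
    a = simulate_induction(toy_design.parental_genotype(), toy_design, cfg)
    b = simulate_induction(toy_design.parental_genotype(), toy_design, cfg)
    assert a.to_rows() == b.to_rows()


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        PoolConfig(p_cre_active=1.2)
    with pytest.raises(ValueError):
        PoolConfig(type_weights={"deletion": 0.5, "inversion": 0.6})


# ---------------------------------------------------------------------------
# gate and selection


def make_pool(**entries):
    return Pool({k: PoolEntry(*v) for k, v in entries.items()})


def test_facs_gate_reweights_and_drops():
    pool = make_pool(a=(100, 1.0), b=(100, 0.5), c=(100, 0.0))
    gated = facs_gate(pool)
    assert set(gated.entries) == {"a", "b"}
    assert gated.entries["b"].abundance == pytest.approx(50)
    assert gated.total_abundance < pool.total_abundance


def test_facs_gate_all_negative_errors():
    with pytest.raises(ValueError, match="GFP"):
        facs_gate(make_pool(a=(10, 0.0)))


def test_grow_select_exponential_ratio(toy_design):
    """mu ratio 2:1 over 10 generations multiplies the abundance ratio by 2^5."""
    fm = FitnessModel(
        medium="minus_his",
        essential_segments=frozenset({"GENA"}),
        dosage_gene="GENA",
        mu_of_copy={0: 0.0, 1: 0.5, 2: 1.0},
    )
    pool = make_pool(**{"+1": (100, 1.0), "+1,+1": (100, 1.0)})
    out = grow_select(pool, toy_design, fm, generations=10)
    ratio = out.entries["+1,+1"].abundance / out.entries["+1"].abundance
    assert ratio == pytest.approx(2**5)


def test_grow_select_zero_generations_identity(toy_design):
    fm = FitnessModel(essential_segments=frozenset({"GENA"}), dosage_gene="GENA")
    pool = make_pool(**{"+1": (42, 1.0)})
    out = grow_select(pool, toy_design, fm, generations=0)
    assert out.entries["+1"].abundance == pytest.approx(42)


def test_essential_deletion_dies_without_histidine(toy_design):
    fm = FitnessModel(
        essential_segments=frozenset({"GENA", "GENB"}), dosage_gene="GENA"
    )
    pool = make_pool(**{"+1,+2": (10, 1.0), "+1": (10, 1.0)})  # GENB lost in '+1'
    out = grow_select(pool, toy_design, fm, generations=5)
    assert "+1" not in out.entries
    carry = grow_select(pool, toy_design, fm, generations=5, dead_carryover=0.1)
    assert carry.entries["+1"].abundance == pytest.approx(1.0)


def test_grow_select_creates_no_new_genotypes(toy_design):
    fm = FitnessModel(essential_segments=frozenset({"GENA"}), dosage_gene="GENA")
    pool = make_pool(**{"+1,+2": (10, 1.0), "+1,+1": (5, 1.0)})
    out = grow_select(pool, toy_design, fm, generations=3)
    assert set(out.entries) <= set(pool.entries)


def test_all_dead_raises(toy_design):
    fm = FitnessModel(essential_segments=frozenset({"GENA"}), dosage_gene="GENA")
    with pytest.raises(ValueError, match="survived"):
        grow_select(make_pool(**{"+2": (10, 1.0)}), toy_design, fm, generations=5)


# ---------------------------------------------------------------------------
# PCR sampling


def test_pcr_sample_unbiased_converges(toy_design):
    pool = make_pool(**{"+1": (70, 1.0), "+1,+2": (30, 1.0)})
    draws = pcr_sample(pool, toy_design, 50_000, length_bias_beta=0.0, seed=9)
    freq = draws.count("+1") / len(draws)
    assert freq == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / 50_000))


def test_pcr_length_bias_prefers_short(toy_design):
    short = ""  # empty-genotype amplicon
    long = "+1,+2,+3,+4"
    pool = make_pool(**{short: (50, 1.0), long: (50, 1.0)})
    draws = pcr_sample(pool, toy_design, 5000, length_bias_beta=1.0, seed=9)
    assert draws.count(short) > draws.count(long)


def test_pcr_single_genotype(toy_design):
    draws = pcr_sample(make_pool(**{"+1": (1, 1.0)}), toy_design, 100, seed=9)
    assert set(draws) == {"+1"}


# ---------------------------------------------------------------------------
# read synthesis


def test_error_free_reads_match_amplicon(toy_design):
    from scramblekit.design import render_sequence

    key = "+1,-3"
    reads = synthesize_reads(
        [key] * 10, toy_design, ErrorModel.error_free(), rng=stage_rng(1, "x")
    )
    amplicon = render_sequence(toy_design, Genotype.from_key(key))
    for r in reads:
        assert str(r.seq) in (amplicon, revcomp(amplicon))
        assert true_key_from_read_id(r.id) == key
        assert len(r.letter_annotations["phred_quality"]) == len(r.seq)


def test_substitution_rate_sets_edit_distance(toy_design):
    """sub_rate 0.03 on the parental amplicon -> mean edit distance ~ 0.03 L."""
    em = ErrorModel(sub_rate=0.03, ins_rate=0.0, del_rate=0.0, p_truncate=0.0)
    key = toy_design.parental_genotype().key
    from scramblekit.design import render_sequence

    amplicon = render_sequence(toy_design, Genotype.from_key(key))
    reads = synthesize_reads([key] * 30, toy_design, em, rng=stage_rng(2, "x"))
    dists = []
    for r in reads:
        seq = str(r.seq)
        d = min(
            edlib.align(seq, amplicon, mode="NW")["editDistance"],
            edlib.align(revcomp(seq), amplicon, mode="NW")["editDistance"],
        )
        dists.append(d)
    expected = 0.03 * len(amplicon)
    assert np.mean(dists) == pytest.approx(expected, rel=0.25)


def test_truncation_always_shortens(toy_design):
    em = ErrorModel(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, p_truncate=1.0)
    key = toy_design.parental_genotype().key
    amp_len = toy_design.amplicon_length(Genotype.from_key(key))
    reads = synthesize_reads([key] * 20, toy_design, em, rng=stage_rng(3, "x"))
    assert all(len(r.seq) < amp_len for r in reads)


def test_error_rate_bounds():
    with pytest.raises(ValueError):
        ErrorModel(sub_rate=0.3)


# ---------------------------------------------------------------------------
# genome fixture


def test_genome_fixture_structure(toy_design):
    records, gff = make_genome_fixture(toy_design, n_filler_genes=3, seed=4)
    by_id = {r.id: r for r in records}
    assert gff[0].startswith("##gff-version")
    lengths = {r.id: len(r.seq) for r in records}
    pads = [l for l in gff if "\tlanding_pad\t" in l]
    assert len(pads) == toy_design.n_segments
    for line in gff[1:]:
        contig, _, ftype, start, end = line.split("\t")[:5]
        start, end = int(start), int(end)
        assert 1 <= start <= end <= lengths[contig]
        if ftype == "landing_pad":
            assert end - start + 1 == toy_design.landing_pad_length == 23
    # module genes present with 3'UTRs
    genes = [l for l in gff if "\tgene\t" in l and "module_locus" in l]
    utrs = [l for l in gff if "\tthree_prime_UTR\t" in l]
    assert len(genes) == toy_design.n_segments
    assert len(utrs) == toy_design.n_segments
    # seeding contract: different sequences, same structure
    records2, gff2 = make_genome_fixture(toy_design, n_filler_genes=3, seed=5)
    assert [r.id for r in records2] == [r.id for r in records]
    assert str(records2[0].seq) != str(records[0].seq)
    assert make_genome_fixture(toy_design, 3, seed=4)[1] == gff


# ---------------------------------------------------------------------------
# iterative rounds


@pytest.fixture(scope="module")
def his_fitness():
    return FitnessModel()


def test_single_round_matches_manual_pipeline(his_design, his_fitness):
    cfg = PoolConfig(n_cells=2000, seed=21)
    pools, summary = run_iterative_rounds(
        his_design.parental_genotype(), his_design, cfg, his_fitness,
        n_rounds=1, generations=20, seed=21,
    )
    assert len(pools) == 1 and len(summary) == 1
    assert summary[0]["round"] == 1
    assert 0 < summary[0]["dominant_frequency"] <= 1
    # every survivor keeps all essential genes
    from scramblekit.design import copy_numbers

    for key in pools[0].entries:
        counts = copy_numbers(Genotype.from_key(key), his_design)
        assert (counts > 0).all()


def test_mean_dosage_copy_non_decreasing(his_design, his_fitness):
    cfg = PoolConfig(n_cells=4000, seed=8)
    _, summary = run_iterative_rounds(
        his_design.parental_genotype(), his_design, cfg, his_fitness,
        n_rounds=2, generations=20, seed=8,
    )
    assert summary[1]["mean_dosage_copy"] >= summary[0]["mean_dosage_copy"]
    assert all(s["mean_dosage_copy"] >= 2.0 for s in summary)
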