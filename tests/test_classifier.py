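"""CR-relative asymmetry classification: sign logic, genome states, invariants."""

import numpy as np
import pytest

from mitoskew import (
    ClassifierParams,
    RearrangementEvent,
    SkewResult,
    SyntheticSpec,
    classify_gene,
    classify_genome,
    cohort_report,
    expected_signature,
    reverse_complement_genome,
    simulate_genome,
)
from mitoskew.errors import UndeterminedCRError
from mitoskew.simulate import fixture_specs


def _result(at, gc, n=100):
    counts = {"a": 30, "c": 30, "g": 20, "t": 20}
    return SkewResult(gene="nad1", strand="+", n_fourfold=n, at_skew=at,
                      gc_skew=gc, **counts)


@pytest.mark.parametrize(
    "gene_strand,cr_strand,expected",
    [
        ("+", "+", (-1, 1)),
        ("-", "+", (1, -1)),
        ("+", "-", (1, -1)),
        ("-", "-", (-1, 1)),
    ],
)
def test_expected_signature_truth_table(gene_strand, cr_strand, expected):
    """Co-orientation with the CR implies AT<0 / GC>0; counter-orientation flips."""
    assert expected_signature(gene_strand, cr_strand) == expected


def test_expected_signature_undetermined_cr_raises():
    with pytest.raises(UndeterminedCRError):
        expected_signature("+", "undetermined")


@pytest.mark.parametrize(
    "at,gc,n,expected,state",
    [
        (-0.3, 0.4, 100, (-1, 1), "concordant"),
        (0.3, -0.4, 100, (-1, 1), "reversed"),
        (-0.01, 0.02, 100, (-1, 1), "ambiguous"),  # sub-threshold
        (-0.3, -0.4, 100, (-1, 1), "ambiguous"),   # axes disagree
        (-0.3, 0.4, 5, (-1, 1), "ambiguous"),      # too few fourfold codons
        (None, 0.4, 100, (-1, 1), "ambiguous"),    # undefined skew
    ],
)
def test_classify_gene(at, gc, n, expected, state):
    assert classify_gene(_result(at, gc, n), expected) == state


def test_classify_gene_monotone_in_tau():
    """Raising tau can only demote calls to ambiguous, never flip them."""
    r = _result(-0.2, 0.15)
    states = [
        classify_gene(r, (-1, 1), ClassifierParams(tau=t))
        for t in (0.01, 0.1, 0.16, 0.5)
    ]
    assert states[0] == states[1] == states[2] == "concordant"
    assert states[3] == "ambiguous"
    flipped = [
        classify_gene(_result(0.2, -0.15), (-1, 1), ClassifierParams(tau=t))
        for t in (0.01, 0.16, 0.5)
    ]
    assert flipped == ["reversed", "reversed", "ambiguous"]


def test_standard_genome_classifies_standard(standard_pair):
    genome, truth = standard_pair
    call = classify_genome(genome)
    assert call.genome_state == "standard" == truth.genome_state
    states = {g.gene: g.state for g in call.per_gene}
    assert len(states) == 13
    assert all(s == "concordant" for s in states.values())


def test_cr_flip_with_reequilibrated_composition_is_reversed():
    """CR inverted and all gene compositions matching it: full reversal."""
    genome, truth = simulate_genome(SyntheticSpec(seed=51, cr_strand="-"))
    call = classify_genome(genome)
    assert truth.genome_state == "reversed"
    assert call.genome_state == "reversed"
    # every gene is in equilibrium with the (flipped) CR
    assert all(g.state == "concordant" for g in call.per_gene)


def test_cr_flip_without_reequilibration_is_disrupted():
    """CR inverted but compositions still standard: the transitory state."""
    genome, truth = simulate_genome(
        SyntheticSpec(seed=52, cr_strand="-", equilibrated=False)
    )
    call = classify_genome(genome)
    assert truth.genome_state == "disrupted"
    assert call.genome_state == "disrupted"
    assert all(g.state == "reversed" for g in call.per_gene)


def test_trematominae_like_nad1_is_the_only_concordant_gene():
    """With the CR and nad1 inverted together and no re-equilibration, nad1
    alone keeps its CR-relative pattern while every other PCG mismatches."""
    genome, truth = simulate_genome(fixture_specs()["trematominae_like"])
    call = classify_genome(genome)
    assert call.genome_state == "disrupted" == truth.genome_state
    states = {g.gene: g.state for g in call.per_gene}
    assert states["nad1"] == "concordant"
    assert all(s == "reversed" for gene, s in states.items() if gene != "nad1")


def test_inverted_block_with_matched_composition_is_standard():
    genome, truth = simulate_genome(fixture_specs()["argyropelecus_like"])
    call = classify_genome(genome)
    assert call.genome_state == "standard" == truth.genome_state
    by_gene = {g.gene: g for g in call.per_gene}
    assert by_gene["nad1"].strand == "-"
    assert by_gene["nad1"].state == "concordant"


def test_undetermined_without_csb(standard_pair):
    from mitoskew import CSB2_REFERENCE, MitoGenome

    genome, _ = standard_pair
    seq = genome.sequence.replace(CSB2_REFERENCE, "A" * len(CSB2_REFERENCE))
    g = MitoGenome(genome.identifier, genome.species, seq,
                   features=list(genome.features))
    call = classify_genome(g)
    assert call.genome_state == "undetermined"
    # per-gene signs are still reported
    assert len(call.per_gene) == 13
    assert all(g.observed_signs != (0, 0) for g in call.per_gene)


def test_representation_invariance(standard_pair):
    """The call depends only on relative polarity, not the deposited strand."""
    genome, _ = standard_pair
    flipped = reverse_complement_genome(genome)
    assert classify_genome(flipped).genome_state == classify_genome(genome).genome_state


def test_duplicated_pcg_uses_longest_copy(standard_pair):
    from mitoskew import apply_rearrangement

    genome, _ = standard_pair
    g = apply_rearrangement(genome, RearrangementEvent("duplication", ["nad3"]))
    call = classify_genome(g)
    assert sum(1 for pg in call.per_gene if pg.gene == "nad3") == 1
    assert call.genome_state == "standard"


def test_every_pcg_has_exactly_one_state(standard_pair):
    genome, _ = standard_pair
    call = classify_genome(genome)
    genes = [g.gene for g in call.per_gene]
    assert sorted(genes) == sorted(set(genes))
    assert all(g.state in ("concordant", "reversed", "ambiguous") for g in call.per_gene)


def test_cohort_report_counts():
    calls = [
        classify_genome(simulate_genome(spec)[0])
        for spec in (
            SyntheticSpec(identifier="STD", seed=61),
            SyntheticSpec(identifier="REV", seed=62, cr_strand="-"),
            SyntheticSpec(identifier="DIS", seed=63, cr_strand="-", equilibrated=False),
        )
    ]
    long, summary = cohort_report(calls)
    counts = dict(zip(summary["genome_state"], summary["n_genomes"]))
    assert counts == {"standard": 1, "reversed": 1, "disrupted": 1}
    assert set(long["genome"]) == {"STD", "REV", "DIS"}
    assert len(long) == 39  # 3 genomes x 13 PCGs


def test_end_to_end_recovery_random_conditions():
    """Ground-truth agreement across randomized polarities and effect sizes.

    Clearly-signed genomes must classify exactly; weakly-signed ones may
    degrade only conservatively (to disrupted/undetermined), never flip
    between the standard and reversed states.
    """
    rng = np.random.default_rng(99)
    N = 30
    for _ in range(N):
        cr = "+" if rng.random() < 0.5 else "-"
        eq = bool(rng.random() < 0.5)
        mag_a = float(rng.uniform(0.15, 0.5))
        mag_g = float(rng.uniform(0.15, 0.5))
        spec = SyntheticSpec(
            seed=int(rng.integers(0, 2**31)),
            cr_strand=cr,
            equilibrated=eq,
            target_at_skew=-mag_a,
            target_gc_skew=mag_g,
        )
        genome, truth = simulate_genome(spec)
        called = classify_genome(genome).genome_state
        if {truth.genome_state, called} <= {"standard", "reversed"}:
            assert called == truth.genome_state
        if min(mag_a, mag_g) >= 0.3:
            assert called == truth.genome_state
        else:
            assert called in (truth.genome_state, "disrupted", "undetermined")
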