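"""Fourfold-site skew statistic: worked examples, oracle equivalence, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoskew import (
    FOURFOLD_PREFIXES,
    SyntheticSpec,
    compute_skews,
    fourfold_third_counts,
    gene_skew_table,
    infer_frame,
    simulate_genome,
    single_gene_skew,
)
from mitoskew.errors import FrameError
from mitoskew.skew import TABLE2_STOPS

# ---------------------------------------------------------------------------
# Independent oracle: a literal vertebrate-mitochondrial (table 2) codon
# table; fourfold families are *derived* from it, not taken from the package.
# ---------------------------------------------------------------------------
_T2_BASES = "TCAG"
_T2_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
T2_CODON_TABLE = {
    b1 + b2 + b3: _T2_AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_T2_BASES)
    for j, b2 in enumerate(_T2_BASES)
    for k, b3 in enumerate(_T2_BASES)
}


def oracle_counts(cds):
    """Explicit codon loop: retain codons whose family is fourfold under table 2."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    n = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            continue
        family = {T2_CODON_TABLE[codon[:2] + b] for b in "ACGT"}
        if len(family) == 1 and "*" not in family:
            counts[codon[2]] += 1
            n += 1
    return counts, n


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_RC)[::-1]


def test_worked_example_counts_and_skews():
    """18-mer with codons ATG,GCA,GCG,GCT,CCA,TAA: four retained codons."""
    counts = fourfold_third_counts("ATGGCAGCGGCTCCATAA")
    assert (counts.a, counts.g, counts.t, counts.c) == (2, 1, 1, 0)
    assert counts.n == 4
    at, gc = compute_skews(counts)
    assert at == pytest.approx(1 / 3)
    assert gc == pytest.approx(1.0)


def test_no_family_prefix_gives_zero():
    counts = fourfold_third_counts("ATGTGATAA")
    assert counts.n == 0


def test_ambiguous_third_base_excluded():
    counts = fourfold_third_counts("GCN")
    assert counts.n == 0


def test_ambiguity_anywhere_excludes_codon():
    """An ambiguity code in positions 1-2 also disqualifies the codon."""
    assert fourfold_third_counts("NCA").n == 0
    assert fourfold_third_counts("GNA").n == 0


def test_frame_error_on_partial_codon():
    with pytest.raises(FrameError):
        fourfold_third_counts("GCAG")


def test_undefined_skews_not_coerced():
    """Zero denominators yield None, distinct from a balanced 0."""
    counts = fourfold_third_counts("GGGGGCCGGCGC")  # thirds G,C,G,C; no A/T
    at, gc = compute_skews(counts)
    assert at is None
    assert gc == 0.0


def test_no_table2_stop_matches_a_family():
    """Defensive check: stop codons can never enter the fourfold counts."""
    assert all(stop[:2] not in FOURFOLD_PREFIXES for stop in TABLE2_STOPS)


def test_oracle_equivalence_random_sequences():
    """Production counting equals the literal-table oracle on random CDSs."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGTN"))
    for _ in range(300):
        n_codons = int(rng.integers(2, 120))
        seq = "".join(rng.choice(bases, size=3 * n_codons, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        counts = fourfold_third_counts(seq)
        ocounts, on = oracle_counts(seq)
        assert (counts.a, counts.c, counts.g, counts.t) == (
            ocounts["A"], ocounts["C"], ocounts["G"], ocounts["T"])
        assert counts.n == on


@settings(max_examples=120, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from(sorted(FOURFOLD_PREFIXES)), st.sampled_from("ACGT")),
        min_size=4,
        max_size=100,
    )
)
def test_antisymmetry_on_complementary_strand(codons):
    """Complementing the retained third-position sites negates both skews.

    This is the sign flip the classifier attributes to genes exposed to the
    opposite-strand mutational regime; it holds at the site level (reverse-
    complement *codon* re-reading retains a different site set entirely).
    """
    from mitoskew.skew import FourfoldCounts

    seq = "".join(p + b for p, b in codons)
    counts = fourfold_third_counts(seq)
    mirrored = FourfoldCounts(a=counts.t, c=counts.g, g=counts.c, t=counts.a)
    at_f, gc_f = compute_skews(counts)
    at_r, gc_r = compute_skews(mirrored)
    if at_f is None:
        assert at_r is None
    else:
        assert at_r == pytest.approx(-at_f)
    if gc_f is None:
        assert gc_r is None
    else:
        assert gc_r == pytest.approx(-gc_f)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("ACGT"), min_size=9, max_size=240))
def test_count_conservation_and_filter_invariance(bases):
    """Counts sum to n; deleting non-fourfold codons leaves the result fixed."""
    seq = "".join(bases)
    seq = seq[: len(seq) - len(seq) % 3]
    counts = fourfold_third_counts(seq)
    assert counts.a + counts.c + counts.g + counts.t == counts.n
    kept = "".join(
        seq[i : i + 3]
        for i in range(0, len(seq), 3)
        if seq[i : i + 2] in FOURFOLD_PREFIXES
    )
    filtered = fourfold_third_counts(kept)
    assert (filtered.a, filtered.c, filtered.g, filtered.t, filtered.n) == (
        counts.a, counts.c, counts.g, counts.t, counts.n)


def test_infer_frame_recovers_shifts():
    """A clean CDS infers frame 0; prepending one base shifts to frame 1."""
    genome, _ = simulate_genome(SyntheticSpec(seed=21))
    from mitoskew import extract_cds

    cds = extract_cds(genome, next(f for f in genome.features if f.label == "cox1"))
    frame, confidence, low = infer_frame(cds)
    assert frame == 0 and not low and confidence >= 1
    frame1, _, low1 = infer_frame("G" + cds)
    assert frame1 == 1 and not low1


def test_infer_frame_low_confidence_on_random():
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    _, _, low = infer_frame(seq)
    assert low


def test_single_gene_skew_frame_modes():
    r = single_gene_skew("ATGGCAGCGGCTCCATAA" * 4, assume_frame=0)
    assert r.at_skew == pytest.approx(1 / 3)
    assert r.gc_skew == pytest.approx(1.0)
    r2 = single_gene_skew("AAA" * 30, assume_frame=0)
    assert r2.n_fourfold == 0 and r2.at_skew is None and r2.gc_skew is None


def test_gene_skew_table_one_row_per_pcg(standard_pair, template):
    genome, truth = standard_pair
    table = gene_skew_table(genome, template=template)
    assert len(table) == 13
    assert [r.gene for r in table] == [
        e.label for e in template.entries if e.ftype == "PCG"
    ]


def test_gene_skew_table_duplicated_pcg_copies(template):
    """A duplicated nad3 yields two rows distinguished by copy index."""
    from mitoskew import RearrangementEvent, apply_rearrangement

    genome, _ = simulate_genome(SyntheticSpec(seed=8))
    genome = apply_rearrangement(genome, RearrangementEvent("duplication", ["nad3"]))
    table = gene_skew_table(genome, template=template)
    nad3 = [r for r in table if r.gene == "nad3"]
    assert sorted(r.copy_index for r in nad3) == [1, 2]
    assert len(table) == 14


def test_recovery_within_binomial_error(standard_pair):
    """Per-gene estimates sit within 3 binomial SEs of the simulated targets."""
    genome, truth = standard_pair
    table = gene_skew_table(genome)
    for r in table:
        info = truth.per_gene[r.gene]
        n_at = r.a + r.t
        n_gc = r.g + r.c
        # SE of a skew estimated from n Bernoulli draws: 2*sqrt(p(1-p)/n)
        p_at = (1 + info["target_at"]) / 2
        p_gc = (1 + info["target_gc"]) / 2
        se_at = 2 * np.sqrt(p_at * (1 - p_at) / n_at)
        se_gc = 2 * np.sqrt(p_gc * (1 - p_gc) / n_gc)
        assert abs(r.at_skew - info["target_at"]) <= 3 * max(se_at, 1e-9) + 1e-9
        assert abs(r.gc_skew - info["target_gc"]) <= 3 * max(se_gc, 1e-9) + 1e-9


def test_empty_pcg_table_warns():
    from mitoskew import MitoGenome

    g = MitoGenome("x", "sp", "ACGT" * 100, features=[])
    with pytest.warns(UserWarning):
        assert gene_skew_table(g) == []
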