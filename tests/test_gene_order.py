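"""Order signatures and rearrangement-event typing against the template."""

import numpy as np
import pytest

from mitoskew import (
    MitoGenome,
    RearrangementEvent,
    SyntheticSpec,
    apply_rearrangement,
    classify_events,
    order_signature,
    render_linear,
    simulate_genome,
    template_signature,
)

HATCHETFISH_BLOCK = ["F", "rrnS", "V", "rrnL", "L1", "nad1", "I", "M", "nad2"]


def test_signature_matches_template(standard_genome, template):
    sig = order_signature(standard_genome)
    assert sig.entries == template_signature(template).entries


def test_signature_rotation_invariance(standard_genome):
    """Rotating the genome in sequence space leaves the signature unchanged."""
    shift = 5000
    L = standard_genome.length
    rotated_feats = []
    for f in standard_genome.features:
        ns, ne = (f.start - shift) % L, (f.end - shift) % L
        rotated_feats.append(
            type(f)(f.label, f.ftype, ns, ne, f.strand, f.codon_start,
                    wraps_origin=ns > ne, copy_index=f.copy_index)
        )
    rotated = MitoGenome(
        "rot", standard_genome.species,
        standard_genome.sequence[shift:] + standard_genome.sequence[:shift],
        features=rotated_feats,
    )
    assert order_signature(rotated).entries == order_signature(standard_genome).entries


def test_signature_records_duplicate_copies(standard_genome):
    g = apply_rearrangement(standard_genome, RearrangementEvent("duplication", ["C"]))
    sig = order_signature(g)
    copies = [(e.label, e.copy_index) for e in sig.entries if e.label == "C"]
    assert copies == [("C", 1), ("C", 2)]


def test_identity_yields_no_events(standard_genome, template):
    assert classify_events(order_signature(standard_genome), template) == []


def test_hatchetfish_block_inversion(standard_genome, template):
    """The nine-gene inverted fragment is reported as one inversion event."""
    g = apply_rearrangement(
        standard_genome, RearrangementEvent("inversion", list(HATCHETFISH_BLOCK))
    )
    events = classify_events(order_signature(g), template)
    assert len(events) == 1
    ev = events[0]
    assert ev.etype == "inversion"
    # Q sits inside the segment and flips with it
    assert set(ev.genes) == set(HATCHETFISH_BLOCK) | {"Q"}


def test_nad6_trnE_shuffle(standard_genome, template):
    """An adjacent nad6/E exchange keeping strands is a shuffle of both."""
    g = apply_rearrangement(standard_genome, RearrangementEvent("shuffle", ["nad6", "E"]))
    events = classify_events(order_signature(g), template)
    assert len(events) == 1
    assert events[0].etype == "shuffle"
    assert set(events[0].genes) == {"nad6", "E"}


def test_distant_translocation(standard_genome, template):
    g = apply_rearrangement(
        standard_genome,
        RearrangementEvent("translocation", ["D"], insert_after="cob"),
    )
    events = classify_events(order_signature(g), template)
    assert [(e.etype, e.genes) for e in events] == [("translocation", ["D"])]


def test_loss_detection(standard_genome, template):
    g = MitoGenome(
        standard_genome.identifier, standard_genome.species,
        standard_genome.sequence,
        features=[f for f in standard_genome.features if f.label != "atp8"],
    )
    events = classify_events(order_signature(g), template)
    assert [(e.etype, e.genes) for e in events] == [("loss", ["atp8"])]


def test_cr_inversion_is_reportable(template):
    """A CR polarity flip alone appears as an inversion event over CR."""
    g, _ = simulate_genome(SyntheticSpec(seed=41, cr_strand="-"))
    events = classify_events(order_signature(g), template)
    assert [(e.etype, e.genes) for e in events] == [("inversion", ["CR"])]


def test_inversion_applied_twice_is_identity(standard_genome, template):
    ev = RearrangementEvent("inversion", ["cox2", "K", "atp8", "atp6"])
    g2 = apply_rearrangement(apply_rearrangement(standard_genome, ev), ev)
    assert classify_events(order_signature(g2), template) == []
    assert g2.sequence == standard_genome.sequence


def test_tandem_duplication_pattern(standard_genome, template):
    """Stacked tRNA duplications reproduce a C-A / C-A / C tandem pattern."""
    g = apply_rearrangement(standard_genome, RearrangementEvent("shuffle", ["N", "C"]))
    # now ... A, C, N ...: duplicate the A-C pair, then C once more
    g = apply_rearrangement(g, RearrangementEvent("duplication", ["A", "C"]))
    g = apply_rearrangement(g, RearrangementEvent("duplication", ["C"]))
    sig = order_signature(g)
    labels = [e.label for e in sig.entries]
    assert labels.count("C") == 3 and labels.count("A") == 2
    events = classify_events(sig, template)
    assert any(e.etype == "duplication" for e in events)


def test_render_linear(standard_genome):
    text = render_linear(order_signature(standard_genome))
    assert text.startswith("cox1(+)")
    assert "nad6(-)" in text and "CR(+)" in text
    g = apply_rearrangement(standard_genome, RearrangementEvent("duplication", ["C"]))
    assert "C.2(-)" in render_linear(order_signature(g))


@pytest.mark.parametrize("case_seed", range(40))
def test_single_event_recovery(case_seed, template):
    """One random edit of each class is recovered as exactly that event."""
    rng = np.random.default_rng(1000 + case_seed)
    genome, _ = simulate_genome(SyntheticSpec(seed=int(rng.integers(0, 2**31))))
    labels = [e.label for e in template.entries if e.ftype in ("PCG", "tRNA", "rRNA")]
    kind = ["inversion", "translocation", "shuffle", "duplication"][case_seed % 4]
    if kind == "inversion":
        start = int(rng.integers(0, len(labels) - 6))
        block = labels[start : start + int(rng.integers(1, 7))]
        ev = RearrangementEvent("inversion", [block[0], block[-1]])
        expected_genes = set(block)
    elif kind == "translocation":
        i = int(rng.integers(0, len(labels)))
        gene = labels[i]
        far = labels[(i + int(rng.integers(6, len(labels) - 8))) % len(labels)]
        ev = RearrangementEvent("translocation", [gene], insert_after=far)
        expected_genes = {gene}
    elif kind == "shuffle":
        i = int(rng.integers(0, len(labels) - 1))
        ev = RearrangementEvent("shuffle", [labels[i], labels[i + 1]])
        expected_genes = {labels[i], labels[i + 1]}
    else:
        i = int(rng.integers(0, len(labels)))
        ev = RearrangementEvent("duplication", [labels[i]])
        expected_genes = {labels[i]}
    edited = apply_rearrangement(genome, ev)
    events = classify_events(order_signature(edited), template)
    assert len(events) == 1, (kind, ev.genes, events)
    got = events[0]
    assert got.etype == kind
    assert expected_genes <= set(got.genes)
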