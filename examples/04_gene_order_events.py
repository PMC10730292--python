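"""Type gene-order rearrangements against the standard vertebrate template.

Applies three documented edit classes to a standard synthetic mitogenome —
the nine-gene hatchetfish-style block inversion, an adjacent nad6/tRNA-Glu
exchange, and a tRNA translocation — and shows how each is recovered as a
typed rearrangement event from the resulting gene order alone.
"""

from mitoskew import (
    RearrangementEvent,
    SyntheticSpec,
    apply_rearrangement,
    classify_events,
    order_signature,
    render_linear,
    simulate_genome,
)

genome, _ = simulate_genome(SyntheticSpec(seed=7))
cases = {
    "block inversion": RearrangementEvent(
        "inversion", ["F", "rrnS", "V", "rrnL", "L1", "nad1", "I", "M", "nad2"]),
    "adjacent shuffle": RearrangementEvent("shuffle", ["nad6", "E"]),
    "translocation": RearrangementEvent("translocation", ["D"], insert_after="cob"),
}
for name, edit in cases.items():
    edited = apply_rearrangement(genome, edit)
    events = classify_events(order_signature(edited))
    print(f"{name}:")
    for ev in events:
        print(f"  {ev.etype}: {', '.join(ev.genes)}  ({ev.detail})")

print("\nLinearized standard architecture for reference:")
print(render_linear(order_signature(genome)))
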