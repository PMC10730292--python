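"""Signed circular gene orders and rearrangement typing.

A genome's architecture is reduced to an :class:`OrderSignature` — the
circular sequence of (label, strand, copy) triples, canonically rotated —
and deviations from the standard vertebrate template are decomposed into
typed events:

* ``inversion``    — a maximal contiguous run of genes whose coding strand
  differs from the template (genes switched to the complementary strand);
* ``shuffle``      — a strand-preserving move of at most *k* template
  positions (a "local position change", default window k = 2);
* ``translocation``— a strand-preserving move beyond that window;
* ``duplication`` / ``loss`` — copy-number deviations.

The decomposition is a deliberate greedy heuristic, not a minimal
rearrangement-distance solver: displaced genes are those left out of a
maximal circular common backbone between observed and template orders, and
compound histories are reported best-effort with a note. The control region
participates as a non-gene entry so a CR inversion is itself a reportable
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GENE_FTYPES, GeneOrderTemplate, MitoGenome, load_template

DEFAULT_SHUFFLE_WINDOW = 2


@dataclass(frozen=True)
class SignatureEntry:
    label: str
    strand: str
    copy_index: int = 1


@dataclass
class OrderSignature:
    """Rotation-canonical signed circular gene order."""

    entries: list[SignatureEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


@dataclass
class RearrangementEvent:
    etype: str  # shuffle | translocation | inversion | duplication | loss
    genes: list[str]
    segment: bool = True
    detail: str = ""
    insert_after: str | None = None  # used when *applying* translocations

    def key(self) -> tuple:
        return (self.etype, tuple(self.genes))


def _canonical_rotation(entries: list[SignatureEntry]) -> list[SignatureEntry]:
    anchor = None
    for i, e in enumerate(entries):
        if e.label == "cox1" and e.strand == "+" and e.copy_index == 1:
            anchor = i
            break
    if anchor is None:
        anchor = min(
            range(len(entries)),
            key=lambda i: (entries[i].label, entries[i].strand, entries[i].copy_index),
        )
    return entries[anchor:] + entries[:anchor]


def order_signature(genome: MitoGenome) -> OrderSignature:
    """Signature of a genome: gene features plus CR, sorted by start, rotated."""
    feats = [
        f
        for f in genome.sorted_features()
        if f.ftype in GENE_FTYPES or f.ftype == "CR"
    ]
    if not any(f.ftype in GENE_FTYPES for f in feats):
        raise ValueError(f"genome {genome.identifier} has no gene features")
    # A feature wrapping the origin sorts by its start, i.e. at the end.
    entries = [SignatureEntry(f.label, f.strand, f.copy_index) for f in feats]
    return OrderSignature(_canonical_rotation(entries))


def template_signature(template: GeneOrderTemplate) -> OrderSignature:
    entries = [SignatureEntry(e.label, e.strand, 1) for e in template.entries]
    return OrderSignature(_canonical_rotation(entries))


def render_linear(signature: OrderSignature) -> str:
    """One-line textual architecture diagram, e.g. ``cox1(+) -S1(-) ...``."""
    parts = []
    for e in signature.entries:
        name = e.label if e.copy_index == 1 else f"{e.label}.{e.copy_index}"
        parts.append(f"{name}({e.strand})")
    return " ".join(parts)


def _lcs_kept(a: list[str], b: list[str]) -> list[str]:
    """Longest common subsequence of two label lists (labels unique)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    kept = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            kept.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return kept


def _circular_backbone(tmpl: list[str], obs: list[str]) -> list[str]:
    """Maximal common backbone of two circular label sequences.

    Takes the best linear LCS over all rotations of the observed order
    (deterministic: first rotation achieving the maximum).
    """
    best: list[str] = []
    for r in range(len(obs)):
        rot = obs[r:] + obs[:r]
        kept = _lcs_kept(tmpl, rot)
        if len(kept) > len(best):
            best = kept
        if len(best) == min(len(tmpl), len(obs)):
            break
    return best


def _runs_circular(flags: list[bool]) -> list[list[int]]:
    """Maximal runs of True positions on a circle, as index lists."""
    n = len(flags)
    if all(flags):
        return [list(range(n))]
    runs = []
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            runs.append(list(range(i, j)))
            i = j
        else:
            i += 1
    # merge the wrap-around run (circle: last run adjacent to first)
    if len(runs) >= 2 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs = [runs[-1] + runs[0]] + runs[1:-1]
    return runs


def classify_events(
    observed: OrderSignature,
    template: GeneOrderTemplate | None = None,
    k: int = DEFAULT_SHUFFLE_WINDOW,
) -> list[RearrangementEvent]:
    """Decompose the deviation of *observed* from the template into events."""
    if template is None:
        template = load_template()
    tmpl_sig = template_signature(template)
    tmpl_labels = tmpl_sig.labels()
    tmpl_strand = {e.label: e.strand for e in tmpl_sig.entries}

    events: list[RearrangementEvent] = []

    # --- copy-number deviations -------------------------------------------
    obs_counts: dict[str, int] = {}
    for e in observed.entries:
        obs_counts[e.label] = max(obs_counts.get(e.label, 0), e.copy_index)
    extra_positions = [i for i, e in enumerate(observed.entries) if e.copy_index > 1]
    if extra_positions:
        flags = [e.copy_index > 1 for e in observed.entries]
        for run in _runs_circular(flags):
            genes = [observed.entries[i].label for i in run]
            events.append(
                RearrangementEvent(
                    etype="duplication",
                    genes=genes,
                    detail="tandem extra copies in observed order",
                )
            )
    lost = [l for l in tmpl_labels if obs_counts.get(l, 0) == 0]
    if lost:
        events.append(RearrangementEvent(etype="loss", genes=lost, segment=False))

    # --- strand flips -> inversions ---------------------------------------
    primary = [e for e in observed.entries if e.copy_index == 1 and e.label in tmpl_strand]
    flipped_flags = [e.strand != tmpl_strand[e.label] for e in primary]
    flipped_set = {e.label for e, fl in zip(primary, flipped_flags) if fl}
    for run in _runs_circular(flipped_flags):
        if not run or not flipped_flags[run[0]]:
            continue
        genes = [primary[i].label for i in run]
        events.append(
            RearrangementEvent(
                etype="inversion",
                genes=genes,
                detail="strand flipped relative to template",
            )
        )

    # --- strand-preserving displacements ----------------------------------
    shared = [
        e.label
        for e in primary
        if e.label not in flipped_set and e.label in tmpl_strand
    ]
    tmpl_shared = [l for l in tmpl_labels if l in set(shared)]
    obs_shared = shared  # observed order
    backbone = _circular_backbone(tmpl_shared, obs_shared)
    backbone_set = set(backbone)
    moved = [l for l in obs_shared if l not in backbone_set]
    if moved and backbone:
        nb = len(backbone)
        tmpl_slot = {}
        obs_slot = {}
        # slot of a moved gene = index (in backbone) of its nearest preceding
        # backbone gene, circularly, in each ordering
        for seq, slot in ((tmpl_shared, tmpl_slot), (obs_shared, obs_slot)):
            last = None
            # find last backbone gene before sequence start (circular)
            for l in reversed(seq):
                if l in backbone_set:
                    last = l
                    break
            for l in seq:
                if l in backbone_set:
                    last = l
                elif l in moved:
                    slot[l] = backbone.index(last)
        moved_set = set(moved)
        obs_positions = {l: i for i, l in enumerate(obs_shared)}
        flags = [l in moved_set for l in obs_shared]
        for run in _runs_circular(flags):
            if not run or not flags[run[0]]:
                continue
            genes = [obs_shared[i] for i in run]
            s_t = tmpl_slot[genes[0]]
            s_o = obs_slot[genes[0]]
            d_fwd = (s_o - s_t) % nb
            d_bwd = (s_t - s_o) % nb
            d = min(d_fwd, d_bwd)
            if d == 0:
                continue  # LCS tie artefact, not a real displacement
            if d <= k:
                if d == d_fwd:
                    hopped = [backbone[(s_t + i) % nb] for i in range(1, d + 1)]
                else:
                    hopped = [backbone[(s_o + i) % nb] for i in range(1, d + 1)]
                events.append(
                    RearrangementEvent(
                        etype="shuffle",
                        genes=genes + hopped,
                        detail=f"local exchange, displacement {d}",
                    )
                )
            else:
                events.append(
                    RearrangementEvent(
                        etype="translocation",
                        genes=genes,
                        detail=f"moved {d} template positions",
                    )
                )

    def sort_key(ev: RearrangementEvent):
        order = {"inversion": 0, "shuffle": 1, "translocation": 2,
                 "duplication": 3, "loss": 4}
        try:
            first = min(
                template.index_of(g) for g in ev.genes if g in template
            )
        except ValueError:
            first = len(template)
        return (order.get(ev.etype, 9), first, tuple(ev.genes))

    return sorted(events, key=sort_key)


def events_table_frame(events: list[RearrangementEvent], genome_id: str):
    import pandas as pd

    rows = [
        {
            "genome": genome_id,
            "event_type": e.etype,
            "genes": ",".join(e.genes),
            "detail": e.detail,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=["genome", "event_type", "genes", "detail"])
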