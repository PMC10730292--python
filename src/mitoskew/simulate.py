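"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the statistical structure the strand-asymmetry
analysis rests on, and nothing else: a 37-gene circular vertebrate
mitogenome in the standard arrangement whose protein-coding genes carry a
controlled compositional bias at fourfold third positions, a control region
containing the CSB-II consensus in a chosen orientation, and optional
architectural edits (inversion, translocation, shuffle, duplication).

Protein-coding genes are built codon-wise: with probability ``fourfold_prop``
a fourfold-family codon whose third base is drawn from

    P(A) = f(1+a)/2,  P(T) = f(1-a)/2,  P(G) = (1-f)(1+g)/2,  P(C) = (1-f)(1-g)/2

with ``f = at_content`` and ``(a, g)`` the target AT/GC skews; otherwise a
codon from a fixed non-fourfold set with an unbiased third position, so only
fourfold sites carry signal. Genes co-oriented with the CR receive the
targets as given; counter-oriented genes the negated targets — the
compositional regime the asymmetric-replication model predicts. Composition
and architecture are *independently* controllable (``equilibrated``): edits
move sequence without touching it, so an inverted gene keeps its old
composition unless the spec says the genome has re-equilibrated. That makes
the transitory state (architecture flipped, composition lagging)
constructible by design.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import copy as _copy
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .csb import CSB2_REFERENCE
from .errors import SimulationSpecError
from .gene_order import RearrangementEvent
from .model import GeneFeature, GeneOrderTemplate, MitoGenome, load_template
from .nomenclature import PCG_LABELS
from .skew import fourfold_third_counts
from . import io as mio

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


#: Fourfold-degenerate codon prefixes (signal carriers).
_FOURFOLD = ("GC", "CC", "TC", "AC", "CG", "GG", "CT", "GT")

#: Non-fourfold prefixes that cannot form a table-2 stop with any third base.
_NONFOURFOLD = ("AT", "TT", "AA", "CA", "GA", "TG")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mitogenome."""

    identifier: str = "SYN000001"
    species: str = "Synthetica exempli"
    template: GeneOrderTemplate | None = None
    pcg_length: int = 200  # codons, including start and stop
    trna_length: int = 70
    rrns_length: int = 950
    rrnl_length: int = 1600
    cr_length: int = 900
    spacer_length: int = 25
    target_at_skew: float = -0.35
    target_gc_skew: float = 0.35
    at_content: float = 0.6
    fourfold_prop: float = 0.5
    cr_strand: str = "+"
    equilibrated: bool = True
    edits: list[RearrangementEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.target_at_skew) < 1 and abs(self.target_gc_skew) < 1):
            raise SimulationSpecError("target skews must lie in (-1, 1)")
        if not (0 < self.at_content < 1):
            raise SimulationSpecError("at_content must lie in (0, 1)")
        if min(self.pcg_length, self.trna_length, self.rrns_length,
               self.rrnl_length, self.cr_length) <= 0:
            raise SimulationSpecError("all lengths must be positive")
        if self.cr_strand not in ("+", "-"):
            raise SimulationSpecError("cr_strand must be '+' or '-'")
        if self.pcg_length < 3:
            raise SimulationSpecError("pcg_length must be at least 3 codons")


@dataclass
class GroundTruth:
    """What the generator actually built, for test oracles."""

    gene_order: list[tuple[str, str, int]]  # (label, strand, copy_index)
    cr_strand: str
    per_gene: dict[str, dict]  # label -> strand/targets/n_fourfold/state
    genome_state: str
    edits: list[RearrangementEvent] = field(default_factory=list)


# --------------------------------------------------------------------------
# abstract order transforms (predict post-edit strands before generating)
# --------------------------------------------------------------------------

def _span_indices(labels: list[str], genes: list[str], what: str) -> tuple[int, int]:
    idx = [labels.index(g) for g in genes if g in labels]
    if len(idx) != len(genes):
        missing = [g for g in genes if g not in labels]
        raise SimulationSpecError(f"{what} references absent gene(s): {missing}")
    return min(idx), max(idx)


def _apply_to_order(entries: list[tuple[str, str]], event: RearrangementEvent
                    ) -> list[tuple[str, str]]:
    """Apply one event to a linear (label, strand) list."""
    labels = [l for l, _ in entries]
    if event.etype == "inversion":
        lo, hi = _span_indices(labels, event.genes, "inversion")
        seg = [(l, "-" if s == "+" else "+") for l, s in entries[lo : hi + 1]][::-1]
        return entries[:lo] + seg + entries[hi + 1 :]
    if event.etype == "translocation":
        lo, hi = _span_indices(labels, event.genes, "translocation")
        if event.insert_after is None:
            raise SimulationSpecError("translocation requires insert_after")
        seg = entries[lo : hi + 1]
        rest = entries[:lo] + entries[hi + 1 :]
        rest_labels = [l for l, _ in rest]
        if event.insert_after not in rest_labels:
            raise SimulationSpecError(
                f"translocation insert_after {event.insert_after!r} unavailable"
            )
        at = rest_labels.index(event.insert_after) + 1
        return rest[:at] + seg + rest[at:]
    if event.etype == "shuffle":
        if len(event.genes) != 2:
            raise SimulationSpecError("shuffle exchanges exactly two features")
        i, j = sorted(labels.index(g) for g in event.genes)
        if j != i + 1:
            raise SimulationSpecError("shuffle requires adjacent features")
        out = list(entries)
        out[i], out[j] = out[j], out[i]
        return out
    if event.etype == "duplication":
        lo, hi = _span_indices(labels, event.genes, "duplication")
        seg = entries[lo : hi + 1]
        return entries[: hi + 1] + seg + entries[hi + 1 :]
    raise SimulationSpecError(f"unknown event type {event.etype!r}")


# --------------------------------------------------------------------------
# sequence-level edits
# --------------------------------------------------------------------------

@dataclass
class _Block:
    seq: str
    feature: GeneFeature | None = None  # None = intergenic spacer


def _to_blocks(genome: MitoGenome) -> list[_Block]:
    blocks: list[_Block] = []
    pos = 0
    for f in genome.sorted_features():
        if f.wraps_origin:
            raise SimulationSpecError(
                "rearrangement edits require wrap-free feature layouts"
            )
        if f.start < pos:
            raise SimulationSpecError("overlapping features in edit segment")
        if f.start > pos:
            blocks.append(_Block(genome.sequence[pos : f.start]))
        blocks.append(_Block(genome.feature_span(f), _copy.deepcopy(f)))
        pos = f.end
    if pos < genome.length:
        blocks.append(_Block(genome.sequence[pos:]))
    return blocks


def _from_blocks(genome: MitoGenome, blocks: list[_Block]) -> MitoGenome:
    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    for b in blocks:
        if b.feature is not None:
            f = b.feature
            f.start, f.end = pos, pos + len(b.seq)
            f.wraps_origin = False
            feats.append(f)
        seq_parts.append(b.seq)
        pos += len(b.seq)
    seen: dict[str, int] = {}
    for f in feats:
        seen[f.label] = seen.get(f.label, 0) + 1
        f.copy_index = seen[f.label]
    return MitoGenome(
        identifier=genome.identifier,
        species=genome.species,
        sequence="".join(seq_parts),
        circular=genome.circular,
        features=feats,
    )


def _feature_block_indices(blocks: list[_Block], genes: list[str],
                           what: str) -> tuple[int, int]:
    idx = []
    wanted = set(genes)
    found = set()
    for i, b in enumerate(blocks):
        if b.feature is not None and b.feature.label in wanted and b.feature.copy_index == 1:
            idx.append(i)
            found.add(b.feature.label)
    if found != wanted:
        raise SimulationSpecError(f"{what} references absent gene(s): {sorted(wanted - found)}")
    return min(idx), max(idx)


def _invert_block(b: _Block) -> _Block:
    nb = _Block(_revcomp(b.seq), _copy.deepcopy(b.feature))
    if nb.feature is not None:
        nb.feature.strand = "-" if nb.feature.strand == "+" else "+"
    return nb


def apply_rearrangement(genome: MitoGenome, event: RearrangementEvent) -> MitoGenome:
    """Apply one architectural edit to a genome, remapping all coordinates.

    inversion      reverse-complement the minimal contiguous segment covering
                   the listed genes and flip their strands;
    translocation  excise that segment and reinsert it after the feature named
                   by ``event.insert_after`` (strands kept);
    shuffle        exchange two adjacent features (any spacer between them
                   stays in place);
    duplication    tandem-copy the segment; new copies get incremented
                   copy indices.

    Sequence length is conserved except under duplication.
    """
    blocks = _to_blocks(genome)
    if event.etype == "inversion":
        lo, hi = _feature_block_indices(blocks, event.genes, "inversion")
        seg = [_invert_block(b) for b in blocks[lo : hi + 1]][::-1]
        out = blocks[:lo] + seg + blocks[hi + 1 :]
    elif event.etype == "translocation":
        lo, hi = _feature_block_indices(blocks, event.genes, "translocation")
        if event.insert_after is None:
            raise SimulationSpecError("translocation requires insert_after")
        seg = blocks[lo : hi + 1]
        rest = blocks[:lo] + blocks[hi + 1 :]
        at = None
        for i, b in enumerate(rest):
            if b.feature is not None and b.feature.label == event.insert_after:
                at = i + 1
        if at is None:
            raise SimulationSpecError(
                f"translocation insert_after {event.insert_after!r} unavailable"
            )
        out = rest[:at] + seg + rest[at:]
    elif event.etype == "shuffle":
        if len(event.genes) != 2:
            raise SimulationSpecError("shuffle exchanges exactly two features")
        fidx = [
            i for i, b in enumerate(blocks)
            if b.feature is not None and b.feature.label in event.genes
            and b.feature.copy_index == 1
        ]
        if len(fidx) != 2:
            raise SimulationSpecError(f"shuffle genes not found: {event.genes}")
        i, j = sorted(fidx)
        between = [b for b in blocks[i + 1 : j] if b.feature is not None]
        if between:
            raise SimulationSpecError("shuffle requires adjacent features")
        out = list(blocks)
        out[i], out[j] = out[j], out[i]
    elif event.etype == "duplication":
        lo, hi = _feature_block_indices(blocks, event.genes, "duplication")
        seg = [_Block(b.seq, _copy.deepcopy(b.feature)) for b in blocks[lo : hi + 1]]
        out = blocks[: hi + 1] + seg + blocks[hi + 1 :]
    else:
        raise SimulationSpecError(f"unknown event type {event.etype!r}")
    return _from_blocks(genome, out)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _draw_pcg(rng: np.random.Generator, n_codons: int, a: float, g: float,
              f: float, fourfold_prop: float) -> str:
    thirds_p = np.array(
        [f * (1 + a) / 2, (1 - f) * (1 - g) / 2, (1 - f) * (1 + g) / 2,
         f * (1 - a) / 2]
    )  # order A, C, G, T
    thirds_p = thirds_p / thirds_p.sum()
    codons = ["ATG"]
    n_mid = n_codons - 2
    is_ff = rng.random(n_mid) < fourfold_prop
    ff_prefix = rng.integers(0, len(_FOURFOLD), size=n_mid)
    nf_prefix = rng.integers(0, len(_NONFOURFOLD), size=n_mid)
    ff_third = rng.choice(4, size=n_mid, p=thirds_p)
    nf_third = rng.integers(0, 4, size=n_mid)
    bases = "ACGT"
    for i in range(n_mid):
        if is_ff[i]:
            codons.append(_FOURFOLD[ff_prefix[i]] + bases[ff_third[i]])
        else:
            codons.append(_NONFOURFOLD[nf_prefix[i]] + bases[nf_third[i]])
    codons.append("TAA")
    return "".join(codons)


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _expected_gene_state(target_at: float, target_gc: float, strand: str,
                         cr_strand: str) -> str:
    from .classifier import expected_signature

    sa = 0 if target_at == 0 else (1 if target_at > 0 else -1)
    sg = 0 if target_gc == 0 else (1 if target_gc > 0 else -1)
    exp = expected_signature(strand, cr_strand)
    if (sa, sg) == exp:
        return "concordant"
    if (sa, sg) == (-exp[0], -exp[1]):
        return "reversed"
    return "ambiguous"


def _genome_state_from(per_gene: dict[str, dict], cr_strand: str) -> str:
    states = [v["expected_state"] for v in per_gene.values()]
    strands = [v["strand"] for v in per_gene.values()]
    classifiable = [s for s in states if s != "ambiguous"]
    if not classifiable:
        return "undetermined"
    plus = sum(1 for s in strands if s == "+")
    majority = "+" if plus > len(strands) - plus else "-"
    if all(s == "concordant" for s in classifiable):
        return "standard" if cr_strand == majority else "reversed"
    return "disrupted"


def simulate_genome(spec: SyntheticSpec) -> tuple[MitoGenome, GroundTruth]:
    """Build one annotated synthetic mitogenome plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    template = spec.template or load_template()

    # Predict post-edit strands so 'equilibrated' composition can anticipate
    # the final architecture (edits move sequence, never rewrite it).
    final = [(e.label, e.strand) for e in template.entries]
    if spec.cr_strand == "-":
        # the CR is *built* inverted; motif orientation follows below
        final = [(l, ("-" if s == "+" else "+") if l == "CR" else s) for l, s in final]
    for ev in spec.edits:
        final = _apply_to_order(final, ev)
    final_strand: dict[str, str] = {}
    for l, s in final:
        final_strand.setdefault(l, s)
    cr_final = final_strand.get("CR", spec.cr_strand)

    a, g = spec.target_at_skew, spec.target_gc_skew
    per_gene: dict[str, dict] = {}
    pos = 0
    feats: list[GeneFeature] = []
    seq_parts: list[str] = []

    def _push(seq: str, feature: GeneFeature | None) -> None:
        nonlocal pos
        if feature is not None:
            feature.start, feature.end = pos, pos + len(seq)
            feats.append(feature)
        seq_parts.append(seq)
        pos += len(seq)

    for entry in template.entries:
        label, tmpl_strand, ftype = entry.label, entry.strand, entry.ftype
        built_strand = tmpl_strand
        if label == "CR" and spec.cr_strand == "-":
            built_strand = "-"
        if ftype == "PCG":
            if spec.equilibrated:
                comp_strand, comp_cr = final_strand[label], cr_final
            else:
                comp_strand, comp_cr = tmpl_strand, "+"
            ga, gg = (a, g) if comp_strand == comp_cr else (-a, -g)
            coding = _draw_pcg(rng, spec.pcg_length, ga, gg,
                               spec.at_content, spec.fourfold_prop)
            counts = fourfold_third_counts(coding)
            per_gene[label] = {
                "strand": final_strand[label],
                "target_at": ga,
                "target_gc": gg,
                "n_fourfold": counts.n,
                "expected_state": _expected_gene_state(
                    ga, gg, final_strand[label], cr_final
                ),
            }
            block_seq = coding if built_strand == "+" else _revcomp(coding)
            _push(block_seq, GeneFeature(label, "PCG", 0, 0, built_strand))
        elif ftype == "tRNA":
            _push(_background(rng, spec.trna_length),
                  GeneFeature(label, "tRNA", 0, 0, built_strand))
        elif ftype == "rRNA":
            n = spec.rrns_length if label == "rrnS" else spec.rrnl_length
            _push(_background(rng, n), GeneFeature(label, "rRNA", 0, 0, built_strand))
        elif ftype == "CR":
            cr = list(_background(rng, spec.cr_length))
            motif = CSB2_REFERENCE if built_strand == "+" else _revcomp(CSB2_REFERENCE)
            mid = (spec.cr_length - len(motif)) // 2
            cr[mid : mid + len(motif)] = motif
            _push("".join(cr), GeneFeature(label, "CR", 0, 0, built_strand))
        _push(_background(rng, spec.spacer_length), None)

    genome = MitoGenome(
        identifier=spec.identifier,
        species=spec.species,
        sequence="".join(seq_parts),
        circular=True,
        features=feats,
    )
    for ev in spec.edits:
        genome = apply_rearrangement(genome, ev)

    order = [
        (f.label, f.strand, f.copy_index)
        for f in genome.sorted_features()
        if f.ftype in ("PCG", "tRNA", "rRNA", "CR")
    ]
    truth = GroundTruth(
        gene_order=order,
        cr_strand=cr_final,
        per_gene=per_gene,
        genome_state=_genome_state_from(per_gene, cr_final),
        edits=list(spec.edits),
    )
    return genome, truth


# --------------------------------------------------------------------------
# named fixtures
# --------------------------------------------------------------------------

#: The large inverted fragment shared by the rearranged hatchetfish
#: architectures (two PCGs, both rRNAs and several tRNAs).
HATCHETFISH_INVERSION_BLOCK = ["F", "rrnS", "V", "rrnL", "L1", "nad1", "I", "M", "nad2"]


def fixture_specs(seed: int = 20230181) -> dict[str, SyntheticSpec]:
    """The four canonical study conditions."""
    return {
        "standard": SyntheticSpec(identifier="SYNSTD01", seed=seed),
        "sternoptyx_like": SyntheticSpec(
            identifier="SYNREV01", cr_strand="-", equilibrated=True, seed=seed + 1
        ),
        "argyropelecus_like": SyntheticSpec(
            identifier="SYNINV01",
            edits=[RearrangementEvent("inversion", list(HATCHETFISH_INVERSION_BLOCK))],
            equilibrated=True,
            seed=seed + 2,
        ),
        "trematominae_like": SyntheticSpec(
            identifier="SYNTRA01",
            cr_strand="-",
            edits=[RearrangementEvent(
                "inversion", ["F", "rrnS", "V", "rrnL", "L1", "nad1"]
            )],
            equilibrated=False,
            seed=seed + 3,
        ),
    }


def _truth_sidecar(truth: GroundTruth) -> str:
    lines = [
        f"cr_strand={truth.cr_strand}",
        f"genome_state={truth.genome_state}",
        "gene_order=" + ";".join(f"{l}:{s}:{c}" for l, s, c in truth.gene_order),
        "edits=" + ";".join(f"{e.etype}:{','.join(e.genes)}" for e in truth.edits),
    ]
    for gene in sorted(truth.per_gene):
        v = truth.per_gene[gene]
        lines.append(
            f"gene.{gene}={v['strand']}:{v['target_at']:+.3f}:{v['target_gc']:+.3f}"
            f":{v['n_fourfold']}:{v['expected_state']}"
        )
    return "\n".join(lines) + "\n"


def write_fixture_set(outdir: str, seed: int = 20230181) -> dict:
    """Emit the four named fixtures as GenBank + FASTA/GFF3 + truth sidecars."""
    os.makedirs(outdir, exist_ok=True)
    manifest = {"version": 1, "seed": seed, "fixtures": []}
    for name, spec in fixture_specs(seed).items():
        genome, truth = simulate_genome(spec)
        gb = os.path.join(outdir, f"{name}.gb")
        fa = os.path.join(outdir, f"{name}.fasta")
        gff = os.path.join(outdir, f"{name}.gff3")
        sidecar = os.path.join(outdir, f"{name}.truth.txt")
        mio.write_genbank(genome, gb)
        mio.write_fasta_gff(genome, fa, gff)
        with open(sidecar, "w") as fh:
            fh.write(_truth_sidecar(truth))
        manifest["fixtures"].append(
            {
                "name": name,
                "identifier": genome.identifier,
                "genbank": os.path.basename(gb),
                "fasta": os.path.basename(fa),
                "gff3": os.path.basename(gff),
                "truth": os.path.basename(sidecar),
                "genome_state": truth.genome_state,
            }
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
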