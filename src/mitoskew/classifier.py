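"""CR-polarity-based classification of mitochondrial strand asymmetry.

The model: under asymmetric (strand-displacement) replication, the mutational
regime a gene experiences is set by its coding polarity **relative to the
control region** (which hosts the heavy-strand replication origin). A gene
co-oriented with the CR is expected to show the baseline fourfold-site
signature AT skew < 0, GC skew > 0 on its coding strand; a counter-oriented
gene the negated signature. No gene is special-cased — the minority-strand
nad6 gets its expectation from its strand exactly like every other PCG.

Per-gene states compare observed skew signs with that CR-relative
expectation: ``concordant`` (composition in equilibrium with the current CR
polarity), ``reversed`` (composition matching the *opposite* CR polarity —
the fingerprint of a recent architectural change that composition has not
caught up with), or ``ambiguous`` (insufficient sites or sub-threshold
magnitudes).

Genome-level call:

* ``standard``     — all classifiable genes concordant and the CR co-oriented
  with the majority coding strand (the classic vertebrate state);
* ``reversed``     — all classifiable genes concordant but the CR
  counter-oriented to the majority strand: the architecture is inverted and
  the composition has fully re-equilibrated (the *Sternoptyx* state);
* ``disrupted``    — classifiable genes mix states, are predominantly
  ambiguous, or are uniformly out of equilibrium with the present CR (the
  transitory Trematominae state, e.g. a freshly inverted CR with every gene
  still carrying the old signature);
* ``undetermined`` — CR polarity unknown or too few classifiable genes.

The thresholds (tau, n_min, quorum) operationalize what is a qualitative
sign reading in comparative studies; the defaults classify clearly-signed
data deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .csb import ControlRegionCall, locate_control_region
from .errors import UndeterminedCRError
from .model import MitoGenome, load_template
from .skew import SkewResult, gene_skew_table

GENE_STATES = ("concordant", "reversed", "ambiguous")
GENOME_STATES = ("standard", "reversed", "disrupted", "undetermined")


@dataclass
class ClassifierParams:
    """Thresholds for sign-based classification.

    tau: minimum absolute skew magnitude (on at least one axis) for a gene to
        count as signed; dimensionless, default 0.05.
    n_min: minimum fourfold codons per gene, default 10.
    quorum: fraction of skew-yielding PCGs that must be classifiable for a
        genome-level call, default 0.8.
    """

    tau: float = 0.05
    n_min: int = 10
    quorum: float = 0.8

    def __post_init__(self) -> None:
        if self.tau < 0 or self.n_min < 1 or not (0 < self.quorum <= 1):
            raise ValueError("invalid classifier parameters")


@dataclass
class PerGeneCall:
    gene: str
    strand: str
    at_skew: float | None
    gc_skew: float | None
    observed_signs: tuple[int, int]
    expected_signs: tuple[int, int] | None
    state: str


@dataclass
class AsymmetryCall:
    genome: str
    genome_state: str
    cr_strand: str
    majority_strand: str | None
    per_gene: list[PerGeneCall] = field(default_factory=list)


def expected_signature(gene_strand: str, cr_strand: str) -> tuple[int, int]:
    """Expected (AT-sign, GC-sign) for a gene given CR-relative polarity.

    Co-oriented with the CR -> (-1, +1); counter-oriented -> (+1, -1).
    """
    if cr_strand not in ("+", "-"):
        raise UndeterminedCRError(
            "control-region polarity undetermined; genome call is undetermined"
        )
    if gene_strand not in ("+", "-"):
        raise ValueError(f"invalid gene strand {gene_strand!r}")
    return (-1, 1) if gene_strand == cr_strand else (1, -1)


def _sign(x: float | None) -> int:
    if x is None or x == 0:
        return 0
    return 1 if x > 0 else -1


def classify_gene(
    result: SkewResult,
    expected: tuple[int, int],
    params: ClassifierParams | None = None,
) -> str:
    """Per-gene state against an expected sign signature."""
    params = params or ClassifierParams()
    if result.n_fourfold < params.n_min:
        return "ambiguous"
    if result.at_skew is None or result.gc_skew is None:
        return "ambiguous"
    if max(abs(result.at_skew), abs(result.gc_skew)) < params.tau:
        return "ambiguous"
    at_s, gc_s = _sign(result.at_skew), _sign(result.gc_skew)
    exp_at, exp_gc = expected
    if at_s == exp_at and gc_s == exp_gc:
        return "concordant"
    if at_s == -exp_at and gc_s == -exp_gc:
        return "reversed"
    return "ambiguous"  # the two axes disagree


def _majority_strand(pcg_strands: list[str]) -> str | None:
    plus = sum(1 for s in pcg_strands if s == "+")
    minus = len(pcg_strands) - plus
    if plus == minus:
        return None
    return "+" if plus > minus else "-"


def classify_genome(
    genome: MitoGenome,
    params: ClassifierParams | None = None,
    cr_call: ControlRegionCall | None = None,
    template=None,
) -> AsymmetryCall:
    """End-to-end asymmetry call: skew table + CR polarity + sign logic.

    Duplicated PCGs contribute only their longest copy.
    """
    params = params or ClassifierParams()
    if template is None:
        template = load_template()
    if cr_call is None:
        cr_call = locate_control_region(genome)
    results = gene_skew_table(genome, template=template)

    # keep only the longest copy per label
    pcg_feats = {(f.label, f.copy_index): f for f in genome.features_of_type("PCG")}
    best_copy: dict[str, SkewResult] = {}
    best_len: dict[str, int] = {}
    for r in results:
        feat = pcg_feats.get((r.gene, r.copy_index))
        flen = feat.length(genome.length) if feat else 0
        if r.gene not in best_copy or flen > best_len[r.gene]:
            best_copy[r.gene] = r
            best_len[r.gene] = flen
    kept = list(best_copy.values())

    cr_strand = cr_call.cr_strand
    per_gene: list[PerGeneCall] = []
    for r in kept:
        observed = (_sign(r.at_skew), _sign(r.gc_skew))
        if cr_strand in ("+", "-"):
            expected = expected_signature(r.strand, cr_strand)
            state = classify_gene(r, expected, params)
        else:
            expected, state = None, "ambiguous"
        per_gene.append(
            PerGeneCall(
                gene=r.gene,
                strand=r.strand,
                at_skew=r.at_skew,
                gc_skew=r.gc_skew,
                observed_signs=observed,
                expected_signs=expected,
                state=state,
            )
        )

    majority = _majority_strand([g.strand for g in per_gene])
    if cr_strand not in ("+", "-"):
        return AsymmetryCall(genome.identifier, "undetermined", cr_strand,
                             majority, per_gene)

    classifiable = [g for g in per_gene if g.state != "ambiguous"]
    if not classifiable:
        return AsymmetryCall(genome.identifier, "undetermined", cr_strand,
                             majority, per_gene)
    if len(classifiable) / len(per_gene) < params.quorum:
        # below quorum: distinguish "too little usable data" (undetermined)
        # from "signal present but predominantly washed out despite adequate
        # site counts" (the attenuated flavour of the transitory state)
        ambiguous_adequate = [
            g for g in per_gene
            if g.state == "ambiguous"
            and best_copy[g.gene].n_fourfold >= params.n_min
            and g.at_skew is not None
            and g.gc_skew is not None
        ]
        state = "disrupted" if len(ambiguous_adequate) > len(per_gene) / 2 else "undetermined"
        return AsymmetryCall(genome.identifier, state, cr_strand, majority, per_gene)

    states = {g.state for g in classifiable}
    if states == {"concordant"}:
        if majority is None:
            genome_state = "undetermined"
        elif cr_strand == majority:
            genome_state = "standard"
        else:
            genome_state = "reversed"
    else:
        # any gene out of equilibrium with the present CR (including all of
        # them, the CR-just-flipped case) marks the transitory state
        genome_state = "disrupted"
    return AsymmetryCall(genome.identifier, genome_state, cr_strand, majority, per_gene)


def asymmetry_table_frame(call: AsymmetryCall):
    import pandas as pd

    rows = [
        {
            "genome": call.genome,
            "gene": g.gene,
            "strand": g.strand,
            "at_skew": g.at_skew,
            "gc_skew": g.gc_skew,
            "expected_at_sign": g.expected_signs[0] if g.expected_signs else "",
            "expected_gc_sign": g.expected_signs[1] if g.expected_signs else "",
            "gene_state": g.state,
            "genome_state": call.genome_state,
            "cr_strand": call.cr_strand,
        }
        for g in call.per_gene
    ]
    return pd.DataFrame(
        rows,
        columns=["genome", "gene", "strand", "at_skew", "gc_skew",
                 "expected_at_sign", "expected_gc_sign", "gene_state",
                 "genome_state", "cr_strand"],
    )


def cohort_report(calls: list[AsymmetryCall]):
    """Long-format genome x gene table plus genome-state summary counts."""
    import pandas as pd

    if not calls:
        raise ValueError("cohort_report requires at least one genome call")
    long = pd.concat([asymmetry_table_frame(c) for c in calls], ignore_index=True)
    all_genes = sorted(long["gene"].unique())
    frames = []
    for c in calls:
        present = {g.gene for g in c.per_gene}
        for gene in all_genes:
            if gene not in present:
                frames.append(
                    {"genome": c.genome, "gene": gene, "strand": "", "at_skew": None,
                     "gc_skew": None, "expected_at_sign": "", "expected_gc_sign": "",
                     "gene_state": "missing", "genome_state": c.genome_state,
                     "cr_strand": c.cr_strand}
                )
    if frames:
        long = pd.concat([long, pd.DataFrame(frames)], ignore_index=True)
    long = long.sort_values(["genome", "gene"]).reset_index(drop=True)
    summary = (
        long.drop_duplicates("genome")[["genome", "genome_state"]]
        .groupby("genome_state")
        .size()
        .rename("n_genomes")
        .reset_index()
    )
    return long, summary
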