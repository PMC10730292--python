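"""AT/GC skew at fourfold-degenerate third codon positions.

The central statistic of the package. Under the vertebrate mitochondrial
genetic code (translation table 2) eight codon families are fourfold
degenerate — Ala (GCN), Pro (CCN), Ser (TCN), Thr (ACN), Arg (CGN), Gly
(GGN), Leu (CTN) and Val (GTN) — so their third positions evolve essentially
free of amino-acid-level selection and record the strand-specific mutational
regime. For each protein-coding gene the third bases of retained codons are
counted on the gene's own coding strand and summarized as

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

both dimensionless in [-1, 1]. A zero denominator leaves the corresponding
skew *undefined* (``None``), never coerced to 0, since 0 means perfect
balance. Codons containing any ambiguity code (in any position) are excluded
entirely: family membership must be certain. Start codons are not
special-cased — a GTG start is simply a valine-family codon — and no stop
codon under table 2 matches any of the eight prefixes (asserted by a test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import FrameError
from .model import MitoGenome
from . import io as mio

#: The eight fourfold-degenerate two-base codon prefixes under table 2.
FOURFOLD_PREFIXES = frozenset(
    {"GC", "CC", "TC", "AC", "CG", "GG", "CT", "GT"}
)

#: Stop codons of the vertebrate mitochondrial code.
TABLE2_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_BASES = "ACGT"


@dataclass
class FourfoldCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0

    @property
    def n(self) -> int:
        return self.a + self.c + self.g + self.t


@dataclass
class SkewResult:
    """Per-gene fourfold third-position counts and skew statistics."""

    gene: str
    strand: str
    n_fourfold: int
    a: int
    c: int
    g: int
    t: int
    at_skew: float | None
    gc_skew: float | None
    copy_index: int = 1
    frame: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def defined_at(self) -> bool:
        return self.at_skew is not None

    @property
    def defined_gc(self) -> bool:
        return self.gc_skew is not None


def fourfold_third_counts(cds: str) -> FourfoldCounts:
    """Count third bases of fourfold-family codons in an in-frame CDS.

    A codon is retained iff its first two bases exactly match one of the
    eight family prefixes and its third base is an unambiguous A/C/G/T.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    counts = FourfoldCounts()
    for i in range(0, len(cds), 3):
        prefix = cds[i : i + 2]
        third = cds[i + 2]
        if prefix in FOURFOLD_PREFIXES and third in _BASES:
            setattr(counts, third.lower(), getattr(counts, third.lower()) + 1)
    return counts


def compute_skews(counts: FourfoldCounts) -> tuple[float | None, float | None]:
    """(AT skew, GC skew) from third-position counts; None when undefined."""
    at = (counts.a - counts.t) / (counts.a + counts.t) if counts.a + counts.t else None
    gc = (counts.g - counts.c) / (counts.g + counts.c) if counts.g + counts.c else None
    return at, gc


def infer_frame(seq: str) -> tuple[int, int, bool]:
    """Infer the reading frame of an unannotated CDS fragment.

    Evaluates all three frames under table 2 and returns
    ``(frame, confidence, low_confidence)`` where *frame* minimizes internal
    stop codons (the final codon of each frame is not counted as internal),
    *confidence* is the stop-count margin to the runner-up, and
    *low_confidence* is set when even the best frame has at least one stop
    per 100 codons. Ties break by most fourfold codons, then lowest frame.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 60:
        raise ValueError("frame inference requires at least 60 bases")
    stats = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        codons = [sub[i : i + 3] for i in range(0, len(sub), 3)]
        internal = codons[:-1]
        stops = sum(1 for c in internal if c in TABLE2_STOPS)
        fourfold = sum(
            1 for c in codons if c[:2] in FOURFOLD_PREFIXES and c[2] in _BASES
        )
        stats.append((stops, -fourfold, frame, len(codons)))
    ranked = sorted(stats)
    best_stops, _, best_frame, best_ncod = ranked[0]
    confidence = ranked[1][0] - best_stops
    low_confidence = all(s[0] / max(s[3], 1) >= 0.01 for s in stats)
    return best_frame, confidence, low_confidence


def single_gene_skew(
    seq: str,
    assume_frame: int | None = None,
    gene: str = "unknown",
    strand: str = "+",
) -> SkewResult:
    """Skew of a single (possibly unannotated) CDS, inferring frame if needed."""
    seq = seq.upper().replace("U", "T")
    flags: list[str] = []
    if assume_frame is not None:
        frame = assume_frame
    else:
        frame, _confidence, low = infer_frame(seq)
        if low:
            flags.append("low_confidence_frame")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    counts = fourfold_third_counts(sub)
    at, gc = compute_skews(counts)
    return SkewResult(
        gene=gene,
        strand=strand,
        n_fourfold=counts.n,
        a=counts.a,
        c=counts.c,
        g=counts.g,
        t=counts.t,
        at_skew=at,
        gc_skew=gc,
        frame=frame,
        flags=flags,
    )


def gene_skew_table(
    genome: MitoGenome, template=None
) -> list[SkewResult]:
    """One :class:`SkewResult` per PCG feature (every copy), template-ordered."""
    from .model import load_template

    if template is None:
        template = load_template()
    pcgs = genome.features_of_type("PCG")
    if not pcgs:
        import warnings

        warnings.warn(f"genome {genome.identifier} has no PCG features", stacklevel=2)
        return []

    def order_key(f):
        try:
            ti = template.index_of(f.label)
        except (StopIteration, ValueError):
            ti = len(template)
        return (ti, f.copy_index, f.start)

    results = []
    for f in sorted(pcgs, key=order_key):
        cds = mio.extract_cds(genome, f)
        counts = fourfold_third_counts(cds)
        at, gc = compute_skews(counts)
        results.append(
            SkewResult(
                gene=f.label,
                strand=f.strand,
                n_fourfold=counts.n,
                a=counts.a,
                c=counts.c,
                g=counts.g,
                t=counts.t,
                at_skew=at,
                gc_skew=gc,
                copy_index=f.copy_index,
                frame=0,
            )
        )
    return results


def skew_table_frame(results: list[SkewResult], genome_id: str):
    """Long-format pandas DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "genome": genome_id,
                "gene": r.gene,
                "copy": r.copy_index,
                "strand": r.strand,
                "n_fourfold": r.n_fourfold,
                "A": r.a,
                "C": r.c,
                "G": r.g,
                "T": r.t,
                "at_skew": r.at_skew,
                "gc_skew": r.gc_skew,
                "frame": r.frame,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome", "gene", "copy", "strand", "n_fourfold",
            "A", "C", "G", "T", "at_skew", "gc_skew", "frame", "flags",
        ],
    )
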