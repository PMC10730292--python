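"""Locating CSB-II in non-coding regions to orient the Control Region.

CSB-II (conserved sequence block II) is a poly-C / TA / poly-C motif inside
the vertebrate control region, typically six or more cytosines, one thymine
and one adenine ending with five or more cytosines (reference form
5'-CCCCCCTACCCCC-3'). Because the motif is strongly strand-asymmetric it
doubles as a polarity marker: the strand carrying the C-rich reading is taken
as the CR's orientation, the quantity that organizes the strand-asymmetry
analysis. The scan is a deterministic consensus-pattern search with one
cytosine of slack on each flank (defaults ``C{5,}TAC{4,}``), run on both
strands of every sufficiently long non-coding region.

CSB-III is less conserved, often absent in fish, and is only searched as an
optional secondary pattern downstream of a CSB-II hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .model import GENE_FTYPES, MitoGenome

#: Reference CSB-II consensus (C-rich strand).
CSB2_REFERENCE = "CCCCCCTACCCCC"

#: Loose CSB-III pattern (C-rich strand), searched only on request.
CSB3_PATTERN = r"C{3,}T{1,2}AC{2,}"

DEFAULT_MIN_C5 = 5
DEFAULT_MIN_C3 = 4
DEFAULT_MIN_NONCODING_LEN = 200


@dataclass
class CSBHit:
    motif: str  # "CSB-II" or "CSB-III"
    start: int
    end: int
    strand: str
    matched: str
    score: int
    in_noncoding: bool = True


@dataclass
class ControlRegionCall:
    cr_interval: tuple[int, int] | None
    cr_strand: str  # '+', '-' or 'undetermined'
    supporting_hits: list[CSBHit] = field(default_factory=list)


def noncoding_regions(
    genome: MitoGenome, min_len: int = DEFAULT_MIN_NONCODING_LEN
) -> list[tuple[int, int, bool]]:
    """Intervals not covered by any gene feature, as (start, end, wraps).

    Complements the union of PCG/tRNA/rRNA features on the circle; annotated
    CR features are non-coding and do not mask their interval. Intervals
    shorter than *min_len* are dropped (spacer suppression).
    """
    L = genome.length
    covered = bytearray(L)
    for f in genome.features_of_type(*GENE_FTYPES):
        if f.wraps_origin:
            for i in range(f.start, L):
                covered[i] = 1
            for i in range(0, f.end):
                covered[i] = 1
        else:
            for i in range(f.start, f.end):
                covered[i] = 1
    runs: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if not covered[i]:
            j = i
            while j < L and not covered[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    wrapped: list[tuple[int, int, bool]] = []
    if (
        genome.circular
        and len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][1] == L
    ):
        first, last = runs[0], runs[-1]
        runs = runs[1:-1]
        wrapped.append((last[0], first[1], True))
    elif genome.circular and len(runs) == 1 and runs[0] == (0, L):
        wrapped.append((0, L, False))
        runs = []
    out = [(s, e, False) for s, e in runs] + wrapped
    result = []
    for s, e, w in out:
        length = (L - s) + e if w else e - s
        if length >= min_len:
            result.append((s, e, w))
    return sorted(result, key=lambda t: t[0])


def scan_csb2(
    seq: str,
    min_c5: int = DEFAULT_MIN_C5,
    min_c3: int = DEFAULT_MIN_C3,
    offset: int = 0,
    genome_length: int | None = None,
) -> list[CSBHit]:
    """All maximal non-overlapping CSB-II matches on both strands of *seq*.

    Coordinates are reported relative to the forward strand, shifted by
    *offset* (and wrapped modulo *genome_length* when given), so callers can
    scan extracted subregions and still get genome coordinates.
    """
    seq = seq.upper().replace("U", "T")
    pattern = re.compile(rf"C{{{min_c5},}}TAC{{{min_c3},}}")
    hits: list[CSBHit] = []
    L = len(seq)

    def _coord(x: int) -> int:
        x += offset
        if genome_length is not None:
            x %= genome_length
        return x

    for m in pattern.finditer(seq):
        hits.append(
            CSBHit(
                motif="CSB-II",
                start=_coord(m.start()),
                end=_coord(m.end()),  # end < start encodes a wrap across the origin
                strand="+",
                matched=m.group(),
                score=len(m.group()),
            )
        )
    rc = str(Seq(seq).reverse_complement())
    for m in pattern.finditer(rc):
        start, end = L - m.end(), L - m.start()
        hits.append(
            CSBHit(
                motif="CSB-II",
                start=_coord(start),
                end=_coord(end),
                strand="-",
                matched=m.group(),
                score=len(m.group()),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    return hits


def scan_csb3(seq: str, offset: int = 0) -> list[CSBHit]:
    """Optional loose CSB-III scan (both strands), off the default path."""
    seq = seq.upper().replace("U", "T")
    pattern = re.compile(CSB3_PATTERN)
    hits = []
    for m in pattern.finditer(seq):
        hits.append(
            CSBHit("CSB-III", offset + m.start(), offset + m.end(), "+",
                   m.group(), len(m.group()))
        )
    rc = str(Seq(seq).reverse_complement())
    L = len(seq)
    for m in pattern.finditer(rc):
        hits.append(
            CSBHit("CSB-III", offset + L - m.end(), offset + L - m.start(), "-",
                   m.group(), len(m.group()))
        )
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    return hits


def _dedupe(hits: list[CSBHit]) -> list[CSBHit]:
    seen = set()
    out = []
    for h in hits:
        key = (h.start, h.strand, h.score)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def locate_control_region(
    genome: MitoGenome,
    min_c5: int = DEFAULT_MIN_C5,
    min_c3: int = DEFAULT_MIN_C3,
    min_noncoding_len: int = DEFAULT_MIN_NONCODING_LEN,
    include_csb3: bool = False,
) -> ControlRegionCall:
    """Identify the control region and its polarity via the best CSB-II hit.

    An annotated CR/D-loop feature is scanned first; if it yields no hit the
    search falls back to every non-coding region of at least
    *min_noncoding_len* bases. Best hit = longest match, ties broken by
    longest host region then smallest start. No hit at all leaves the call
    ``undetermined`` (the situation reported for records lacking a
    recognisable CSB-II).
    """
    L = genome.length
    candidates: list[tuple[int, int, bool]] = []
    annotated = [f for f in genome.sorted_features() if f.ftype == "CR"]
    regions = noncoding_regions(genome, min_len=min_noncoding_len)

    def region_hits(region_list):
        all_hits = []
        for s, e, w in region_list:
            seq = genome.slice_interval(s, e, w)
            hits = scan_csb2(seq, min_c5, min_c3, offset=s, genome_length=L)
            rlen = len(seq)
            for h in hits:
                all_hits.append((h, rlen, s))
        return all_hits

    scored: list[tuple[CSBHit, int, int]] = []
    if annotated:
        ann_regions = [(f.start, f.end, f.wraps_origin) for f in annotated]
        scored = region_hits(ann_regions)
    if not scored:
        scored = region_hits(regions)
    if not scored:
        return ControlRegionCall(
            cr_interval=(annotated[0].start, annotated[0].end) if annotated else None,
            cr_strand="undetermined",
            supporting_hits=[],
        )
    scored.sort(key=lambda t: (-t[0].score, -t[1], t[0].start, t[0].strand))
    best, _rlen, rstart = scored[0]
    hits = _dedupe([h for h, _, _ in scored])
    if include_csb3:
        for s, e, w in ([(f.start, f.end, f.wraps_origin) for f in annotated] or regions):
            hits.extend(scan_csb3(genome.slice_interval(s, e, w), offset=s))
    host = None
    for s, e, w in ([(f.start, f.end, f.wraps_origin) for f in annotated] or regions):
        end_resolved = e if not w else e + L
        b = best.start if best.start >= s else best.start + L
        if s <= b < end_resolved:
            host = (s, e)
            break
    return ControlRegionCall(
        cr_interval=host,
        cr_strand=best.strand,
        supporting_hits=hits,
    )


def csb_table_frame(call: ControlRegionCall, genome_id: str):
    """Long-format DataFrame of supporting hits for TSV export."""
    import pandas as pd

    rows = [
        {
            "genome": genome_id,
            "motif": h.motif,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "matched": h.matched,
            "in_noncoding": h.in_noncoding,
        }
        for h in call.supporting_hits
    ]
    return pd.DataFrame(
        rows, columns=["genome", "motif", "start", "end", "strand", "matched", "in_noncoding"]
    )
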