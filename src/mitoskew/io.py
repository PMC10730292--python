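"""Reading and writing annotated mitogenomes.

GenBank flat files are the primary interchange format; FASTA + GFF3 pairs are
accepted as well (and written for simulator output). All coordinates are
converted to the package-internal 0-based half-open convention on ingest, and
features joined across the circular origin collapse to a single entry with
``wraps_origin=True``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import InputFormatError, MissingSequenceError, TooShortError
from .model import GeneFeature, MitoGenome
from .nomenclature import (
    OTHER,
    PCG_LABELS,
    canonical_label,
    ftype_of_label,
)

log = logging.getLogger(__name__)

_GB_TYPE_MAP = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}

# Template neighbours used to resolve bare L/S tRNA paralogs by position.
_PARALOG_NEIGHBOURS = {
    "L": {"L1": {"rrnL", "nad1"}, "L2": {"S2", "nad5"}},
    "S": {"S1": {"cox1", "D"}, "S2": {"H", "L2"}},
}


def _amino_one_letter(label: str) -> str:
    return label[0] if label and label[0] in "LS" and label[1:] in ("", "1", "2") else label


def _resolve_paralogs(features: list[GeneFeature]) -> None:
    """Assign L1/L2 and S1/S2 to bare leucine/serine tRNAs.

    Anticodons were already honoured by the nomenclature layer; remaining bare
    labels are resolved by their neighbours relative to the standard template,
    and finally by order of appearance.
    """
    ordered = sorted(features, key=lambda f: f.start)
    labels = [f.label for f in ordered]
    for base in ("L", "S"):
        taken = {f.label for f in ordered if f.label in (base + "1", base + "2")}
        unresolved = [f for f in ordered if f.label == base]
        for f in unresolved:
            i = labels.index(f.label) if f.label in labels else None
            idx = ordered.index(f)
            neighbours = set()
            if idx > 0:
                neighbours.add(ordered[idx - 1].label)
            if idx + 1 < len(ordered):
                neighbours.add(ordered[idx + 1].label)
            choice = None
            for variant, expected in _PARALOG_NEIGHBOURS[base].items():
                if variant not in taken and neighbours & expected:
                    choice = variant
                    break
            if choice is None:
                for variant in (base + "1", base + "2"):
                    if variant not in taken:
                        choice = variant
                        break
            f.label = choice or base + "1"
            taken.add(f.label)


def _assign_copy_indices(features: list[GeneFeature]) -> None:
    seen: dict[str, int] = {}
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        seen[f.label] = seen.get(f.label, 0) + 1
        f.copy_index = seen[f.label]


def _location_to_coords(location, genome_length: int) -> tuple[int, int, bool]:
    """Convert a Biopython location to (start, end, wraps_origin)."""
    parts = sorted(location.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end), False
    if (
        len(parts) == 2
        and int(parts[1].end) == genome_length
        and int(parts[0].start) == 0
    ):
        # join(x..L, 1..y): single feature across the origin.
        return int(parts[1].start), int(parts[0].end), True
    # Other compound locations (rare in mitogenomes): use the outer envelope.
    return int(parts[0].start), int(parts[-1].end), False


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "D-loop"
    return None


def read_genbank(path: str) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Record length is preserved exactly; features with unmappable names are
    kept as ``ftype=other`` with a warning, never silently dropped.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subtypes
        raise InputFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    return _record_to_genome(record, source=path)


def _record_to_genome(record: SeqRecord, source: str = "") -> MitoGenome:
    try:
        seq = str(record.seq)
    except Exception as exc:
        raise MissingSequenceError(f"record {record.id} has no sequence") from exc
    if not seq:
        raise MissingSequenceError(f"record {record.id} has no sequence")
    L = len(seq)
    circular = record.annotations.get("topology", "circular") == "circular"

    features: list[GeneFeature] = []
    claimed: set[tuple[int, int]] = set()
    gene_feats = []
    for feat in record.features:
        if feat.type == "gene":
            gene_feats.append(feat)
            continue
        if feat.type not in _GB_TYPE_MAP and feat.type != "misc_feature":
            continue
        raw = _feature_name(feat)
        label = canonical_label(raw) if raw is not None else OTHER
        if feat.type == "misc_feature" and label != "CR":
            continue
        ftype = "CR" if label == "CR" else _GB_TYPE_MAP.get(feat.type, "other")
        if label == OTHER:
            ftype = "other"
            log.warning("unmappable feature name %r in %s kept as OTHER", raw, source)
        start, end, wraps = _location_to_coords(feat.location, L)
        codon_start = int(feat.qualifiers.get("codon_start", ["1"])[0])
        features.append(
            GeneFeature(
                label=label,
                ftype=ftype,
                start=start,
                end=end,
                strand="-" if feat.location.strand == -1 else "+",
                codon_start=codon_start,
                wraps_origin=wraps,
                raw_name=raw,
            )
        )
        claimed.add((start, end))
    # 'gene' features only contribute where no typed feature claimed the span.
    for feat in gene_feats:
        start, end, wraps = _location_to_coords(feat.location, L)
        if any(not (end <= s or start >= e) for s, e in claimed):
            continue
        raw = _feature_name(feat)
        label = canonical_label(raw) if raw is not None else OTHER
        ftype = ftype_of_label(label)
        if label == OTHER:
            log.warning("unmappable gene name %r in %s kept as OTHER", raw, source)
        features.append(
            GeneFeature(
                label=label,
                ftype=ftype,
                start=start,
                end=end,
                strand="-" if feat.location.strand == -1 else "+",
                wraps_origin=wraps,
                raw_name=raw,
            )
        )
        claimed.add((start, end))

    _resolve_paralogs(features)
    _assign_copy_indices(features)
    organism = record.annotations.get("organism", record.description or record.id)
    genome = MitoGenome(
        identifier=record.id or source,
        species=organism,
        sequence=seq,
        circular=circular,
        features=sorted(features, key=lambda f: (f.start, f.end, f.label)),
    )
    return genome


def read_fasta_gff(fasta: str, gff: str) -> MitoGenome:
    """Read a single-record FASTA plus a GFF3 annotation file."""
    import gffutils

    records = list(SeqIO.parse(fasta, "fasta"))
    if len(records) != 1:
        raise InputFormatError(f"expected exactly one FASTA record in {fasta}")
    record = records[0]
    seq = str(record.seq).upper()
    if not seq:
        raise MissingSequenceError(f"record {record.id} has no sequence")
    L = len(seq)

    raw_feats: dict[str, list] = {}
    n_lines = 0
    for f in gffutils.DataIterator(gff):
        n_lines += 1
        if f.seqid != record.id:
            raise InputFormatError(
                f"GFF seqid {f.seqid!r} does not match FASTA record {record.id!r}"
            )
        if f.end > L or f.start < 1:
            raise InputFormatError(
                f"feature {f.id or f.attributes} out of range for length {L}"
            )
        fid = (f.attributes.get("ID") or [f"_anon{n_lines}"])[0]
        raw_feats.setdefault(fid, []).append(f)
    if n_lines == 0:
        warnings.warn(f"GFF file {gff} contains no features", stacklevel=2)

    features: list[GeneFeature] = []
    for fid, parts in raw_feats.items():
        parts = sorted(parts, key=lambda p: p.start)
        first = parts[0]
        raw = (first.attributes.get("Name") or first.attributes.get("gene") or [None])[0]
        label = canonical_label(raw) if raw is not None else OTHER
        gtype = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(first.featuretype)
        if gtype is None:
            gtype = "CR" if label == "CR" or first.featuretype in ("D_loop", "D-loop") else "other"
        if label == OTHER and gtype != "CR":
            log.warning("unmappable GFF feature name %r kept as OTHER", raw)
            gtype = "other"
        if len(parts) == 2 and parts[1].end == L and parts[0].start == 1:
            start, end, wraps = parts[1].start - 1, parts[0].end, True
            phase = parts[1].frame
        else:
            start, end, wraps = first.start - 1, first.end, False
            phase = first.frame
        codon_start = int(phase) + 1 if phase not in (None, ".", "") else 1
        features.append(
            GeneFeature(
                label=label,
                ftype=gtype,
                start=start,
                end=end,
                strand=first.strand if first.strand in "+-" else "+",
                codon_start=codon_start,
                wraps_origin=wraps,
                raw_name=raw,
            )
        )
    _resolve_paralogs(features)
    _assign_copy_indices(features)
    return MitoGenome(
        identifier=record.id,
        species=record.description.split(None, 1)[-1] if record.description else record.id,
        sequence=seq,
        circular=True,
        features=sorted(features, key=lambda f: (f.start, f.end, f.label)),
    )


def extract_cds(genome: MitoGenome, feature: GeneFeature) -> str:
    """In-frame coding-strand sequence of a PCG feature.

    Reverse-complements minus-strand features, trims ``codon_start - 1`` bases
    at the 5' end, and drops any incomplete terminal codon.
    """
    if feature.ftype != "PCG":
        raise ValueError(f"extract_cds requires a PCG feature, got {feature.ftype}")
    seq = genome.coding_sequence(feature)
    seq = seq[feature.codon_start - 1 :]
    seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) < 3:
        raise TooShortError(
            f"CDS of {feature.label} shorter than one codon after trimming"
        )
    return seq


_GB_WRITE_TYPES = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop", "other": "misc_feature"}

_TRNA_PRODUCT = {
    "A": "tRNA-Ala", "R": "tRNA-Arg", "N": "tRNA-Asn", "D": "tRNA-Asp",
    "C": "tRNA-Cys", "Q": "tRNA-Gln", "E": "tRNA-Glu", "G": "tRNA-Gly",
    "H": "tRNA-His", "I": "tRNA-Ile", "K": "tRNA-Lys", "M": "tRNA-Met",
    "F": "tRNA-Phe", "P": "tRNA-Pro", "T": "tRNA-Thr", "W": "tRNA-Trp",
    "Y": "tRNA-Tyr", "V": "tRNA-Val",
    "L1": "tRNA-Leu (UUR)", "L2": "tRNA-Leu (CUN)",
    "S1": "tRNA-Ser (UCN)", "S2": "tRNA-Ser (AGY)",
}


def _feature_to_seqfeature(f: GeneFeature, L: int) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    if f.wraps_origin:
        loc = CompoundLocation(
            [SimpleLocation(f.start, L, strand), SimpleLocation(0, f.end, strand)]
        )
    else:
        loc = SimpleLocation(f.start, f.end, strand)
    quals: dict[str, list[str]] = {}
    if f.ftype == "tRNA":
        quals["gene"] = [f"trn{f.label}"]
        quals["product"] = [_TRNA_PRODUCT.get(f.label, f"tRNA-{f.label}")]
    elif f.ftype == "CR":
        quals["note"] = ["control region"]
    else:
        quals["gene"] = [f.raw_name or f.label]
        if f.ftype == "PCG":
            quals["codon_start"] = [str(f.codon_start)]
            quals["transl_table"] = ["2"]
    return SeqFeature(location=loc, type=_GB_WRITE_TYPES[f.ftype], qualifiers=quals)


def write_genbank(genome: MitoGenome, path: str) -> None:
    """Emit a GenBank flat file that round-trips through :func:`read_genbank`."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier.split(".")[0][:16] or "MITOGENOME",
        description=f"{genome.species} mitochondrion",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
            "date": "01-JAN-1980",  # fixed so identical genomes emit identical bytes
        },
    )
    record.features = [
        _feature_to_seqfeature(f, genome.length) for f in genome.sorted_features()
    ]
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def write_fasta_gff(genome: MitoGenome, fasta: str, gff: str) -> None:
    """Write the genome as FASTA plus GFF3 (wrap features split in two rows)."""
    with open(fasta, "w") as fh:
        SeqIO.write(
            SeqRecord(Seq(genome.sequence), id=genome.identifier,
                      description=genome.species),
            fh,
            "fasta",
        )
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D_loop", "other": "region"}
    lines = ["##gff-version 3", f"##sequence-region {genome.identifier} 1 {genome.length}"]
    for i, f in enumerate(genome.sorted_features()):
        ftype = type_map[f.ftype]
        fid = f"{f.label}.{f.copy_index}"
        attrs = f"ID={fid};Name={f.label}"
        phase = str(f.codon_start - 1) if f.ftype == "PCG" else "."
        if f.wraps_origin:
            spans = [(f.start + 1, genome.length, phase), (1, f.end, ".")]
        else:
            spans = [(f.start + 1, f.end, phase)]
        for s, e, ph in spans:
            lines.append(
                "\t".join(
                    [genome.identifier, "mitoskew", ftype, str(s), str(e), ".",
                     f.strand, ph, attrs]
                )
            )
    with open(gff, "w") as fh:
        fh.write("\n".join(lines) + "\n")
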