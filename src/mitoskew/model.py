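"""Core in-memory containers: annotated mitogenomes and the gene-order template.

Coordinates are 0-based half-open on the stored forward strand throughout the
package; GenBank I/O converts to and from 1-based inclusive coordinates. A
feature that spans the origin of the circular molecule is stored as a single
entry with ``wraps_origin=True`` and ``start > end``: it occupies
``[start, genome_length) + [0, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from Bio.Seq import Seq

GENE_FTYPES = ("PCG", "tRNA", "rRNA")
FTYPES = GENE_FTYPES + ("CR", "other")


@dataclass
class GeneFeature:
    """One annotated feature on the stored forward strand."""

    label: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    codon_start: int = 1
    wraps_origin: bool = False
    copy_index: int = 1
    raw_name: str | None = None

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start

    def key(self) -> tuple[str, int]:
        return (self.label, self.copy_index)


@dataclass
class MitoGenome:
    """A circular (or linear) annotated mitochondrial genome."""

    identifier: str
    species: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_span(self, feature: GeneFeature) -> str:
        """Forward-strand subsequence covered by *feature* (wrap-aware)."""
        if feature.wraps_origin:
            return self.sequence[feature.start :] + self.sequence[: feature.end]
        return self.sequence[feature.start : feature.end]

    def coding_sequence(self, feature: GeneFeature) -> str:
        """Sequence of *feature* on its own coding strand (no frame trimming)."""
        seq = self.feature_span(feature)
        if feature.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def slice_interval(self, start: int, end: int, wraps: bool = False) -> str:
        if wraps:
            return self.sequence[start:] + self.sequence[:end]
        return self.sequence[start:end]

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end, f.label))

    def features_of_type(self, *ftypes: str) -> list[GeneFeature]:
        return [f for f in self.sorted_features() if f.ftype in ftypes]


@dataclass(frozen=True)
class TemplateEntry:
    label: str
    ftype: str
    strand: str


@dataclass
class GeneOrderTemplate:
    """The standard vertebrate arrangement: 37 genes plus the control region."""

    entries: list[TemplateEntry]
    version: str = "1"

    def __post_init__(self) -> None:
        genes = [e for e in self.entries if e.ftype in GENE_FTYPES]
        n_pcg = sum(1 for e in genes if e.ftype == "PCG")
        n_trna = sum(1 for e in genes if e.ftype == "tRNA")
        n_rrna = sum(1 for e in genes if e.ftype == "rRNA")
        if not (len(genes) == 37 and n_pcg == 13 and n_trna == 22 and n_rrna == 2):
            raise ValueError(
                "template must contain 37 genes (13 PCG, 22 tRNA, 2 rRNA); got "
                f"{len(genes)} ({n_pcg}/{n_trna}/{n_rrna})"
            )
        if sum(1 for e in self.entries if e.ftype == "CR") != 1:
            raise ValueError("template must contain exactly one CR entry")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def strand_of(self, label: str) -> str:
        return next(e.strand for e in self.entries if e.label == label)

    def ftype_of(self, label: str) -> str:
        return next(e.ftype for e in self.entries if e.label == label)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def pcg_labels(self) -> list[str]:
        return [e.label for e in self.entries if e.ftype == "PCG"]

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.entries)


def load_template(path: str | None = None) -> GeneOrderTemplate:
    """Load the packaged standard vertebrate template, or one from *path*.

    The template file is two-plus-column TSV (label, ftype, strand) with ``#``
    comment lines; it ships as a versioned data file rather than constants so
    the canonical arrangement is auditable.
    """
    if path is None:
        text = (
            resources.files("mitoskew.data")
            .joinpath("vertebrate_template.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    entries: list[TemplateEntry] = []
    version = "unversioned"
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "template_version:" in line:
                version = line.split("template_version:")[1].strip()
            continue
        parts = line.split("\t")
        if parts[0] == "label":
            continue
        if len(parts) < 3:
            raise ValueError(f"bad template line: {line!r}")
        entries.append(TemplateEntry(parts[0], parts[1], parts[2]))
    return GeneOrderTemplate(entries=entries, version=version)


def reverse_complement_genome(genome: MitoGenome) -> MitoGenome:
    """Reverse-complement the stored sequence and remap every feature.

    Used to check representation invariance: biological conclusions must not
    depend on which strand a record happens to be deposited on.
    """
    L = genome.length
    seq = str(Seq(genome.sequence).reverse_complement())
    feats = []
    for f in genome.features:
        if f.wraps_origin:
            new_start, new_end = L - f.end, L - f.start
        else:
            new_start, new_end = L - f.end, L - f.start
        feats.append(
            GeneFeature(
                label=f.label,
                ftype=f.ftype,
                start=new_start % L if f.wraps_origin else new_start,
                end=new_end % L if f.wraps_origin else new_end,
                strand="-" if f.strand == "+" else "+",
                codon_start=f.codon_start,
                wraps_origin=f.wraps_origin,
                copy_index=f.copy_index,
                raw_name=f.raw_name,
            )
        )
    return MitoGenome(
        identifier=genome.identifier,
        species=genome.species,
        sequence=seq,
        circular=genome.circular,
        features=sorted(feats, key=lambda f: (f.start, f.end, f.label)),
    )
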