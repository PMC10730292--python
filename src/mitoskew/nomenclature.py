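"""Normalization of mitochondrial gene names to a canonical 37-gene vocabulary.

Deposited mitogenome records are wildly inconsistent (``ND1``/``NADH1``/
``nad1``; ``COI``/``COX1``/``CO1``; ``trnF``/``tRNA-Phe``), so every label
entering the package passes through :func:`canonical_label`.

Canonical vocabulary
--------------------
PCGs: nad1..nad6, nad4l, cox1..cox3, cob, atp6, atp8.
tRNAs: one-letter amino-acid codes, with the leucine and serine paralogs split
as L1 = Leu(UUR), L2 = Leu(CUN), S1 = Ser(UCN), S2 = Ser(AGY) — numbered by
order of appearance in the standard vertebrate gene order (the convention used
for the hatchetfish architectures this package models; note it is the reverse
of the MITOS trnL1/trnL2 numbering). An anticodon given in the raw name takes
precedence; a bare ``L``/``S`` is returned for later positional resolution.
rRNAs: rrnS (12S), rrnL (16S). Control region: CR. Anything else: OTHER.
"""

from __future__ import annotations

import re

PCG_LABELS = (
    "nad1",
    "nad2",
    "nad3",
    "nad4",
    "nad4l",
    "nad5",
    "nad6",
    "cox1",
    "cox2",
    "cox3",
    "cob",
    "atp6",
    "atp8",
)

TRNA_LABELS = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L1", "L2", "K", "M", "F", "P", "S1", "S2", "T", "W", "Y", "V",
)

RRNA_LABELS = ("rrnS", "rrnL")

OTHER = "OTHER"

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Direct synonyms, lower-case, punctuation stripped.
_SYNONYMS: dict[str, str] = {}
for _i in range(1, 7):
    _SYNONYMS.update(
        {
            f"nad{_i}": f"nad{_i}",
            f"nd{_i}": f"nad{_i}",
            f"nadh{_i}": f"nad{_i}",
            f"nadhdehydrogenasesubunit{_i}": f"nad{_i}",
        }
    )
_SYNONYMS.update(
    {
        "nad4l": "nad4l",
        "nd4l": "nad4l",
        "nadh4l": "nad4l",
        "nadhdehydrogenasesubunit4l": "nad4l",
        "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
        "cytochromecoxidasesubunit1": "cox1", "cytochromecoxidasesubuniti": "cox1",
        "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
        "cytochromecoxidasesubunit2": "cox2", "cytochromecoxidasesubunitii": "cox2",
        "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
        "cytochromecoxidasesubunit3": "cox3", "cytochromecoxidasesubunitiii": "cox3",
        "cob": "cob", "cytb": "cob", "cytochromeb": "cob", "cotb": "cob",
        "atp6": "atp6", "atpase6": "atp6", "atpsynthasef0subunit6": "atp6",
        "atp8": "atp8", "atpase8": "atp8", "atpsynthasef0subunit8": "atp8",
        "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "12sribosomalrna": "rrnS",
        "srrna": "rrnS", "smallsubunitribosomalrna": "rrnS", "ssurrna": "rrnS",
        "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "16sribosomalrna": "rrnL",
        "lrrna": "rrnL", "largesubunitribosomalrna": "rrnL", "lsurrna": "rrnL",
        "dloop": "CR", "controlregion": "CR", "cr": "CR", "putativecontrolregion": "CR",
        "misccontrolregion": "CR",
    }
)

_TRNA_RE = re.compile(r"^trn([a-z])([12])?$")
_TRNA_LONG_RE = re.compile(r"^trna([a-z]{3})$")
_ANTICODON_RE = re.compile(r"\(([acgtu]{3})\)|\b([acgtu]ur|[acgtu]un|ag[ynacgtu])\b")


def _squash(raw: str) -> str:
    return re.sub(r"[^a-z0-9]", "", raw.lower())


def _leu_ser_variant(base: str, raw_lower: str) -> str:
    """Resolve L/S paralogs from an anticodon or codon-family tag, if present."""
    m = re.search(r"\(([a-z]{3})\)", raw_lower)
    tag = m.group(1) if m else None
    if tag is None:
        m = re.search(r"\b(uur|cun|ucn|agy|agn|taa|tag|uaa|uag|tga|uga|gct|gcu|tgg)\b",
                      raw_lower)
        tag = m.group(1) if m else None
    if tag is None:
        return base
    tag = tag.replace("u", "t")
    if base == "L":
        # Leu(UUR) anticodon TAA; Leu(CUN) anticodon TAG.
        if tag in ("ttr", "tta", "ttg", "taa"):
            return "L1"
        if tag in ("ctn", "cta", "ctg", "ctc", "ctt", "tag"):
            return "L2"
    if base == "S":
        # Ser(UCN) anticodon TGA; Ser(AGY) anticodon GCT.
        if tag in ("tcn", "tca", "tcg", "tcc", "tct", "tga"):
            return "S1"
        if tag in ("agy", "agn", "aga", "agc", "agg", "agt", "gct"):
            return "S2"
    return base


def canonical_label(raw: str) -> str:
    """Map a raw gene/product name to the canonical vocabulary.

    Total function: unknown names map to ``OTHER`` (the caller keeps the raw
    string alongside). Leucine/serine tRNAs without an anticodon hint come
    back as bare ``L``/``S`` for positional resolution by the reader.
    """
    if raw is None:
        return OTHER
    raw_lower = raw.strip().lower()
    squashed = _squash(raw_lower)
    if squashed in _SYNONYMS:
        return _SYNONYMS[squashed]
    # Explicit numbered paralogs: trnL1 / tRNA-Leu1 / L1 ...
    m = _TRNA_RE.match(squashed)
    if m:
        aa, num = m.group(1).upper(), m.group(2)
        if aa in "LS" and num:
            return f"{aa}{num}"
        if aa in "LS":
            return _leu_ser_variant(aa, raw_lower)
        if aa in _AA3_TO_1.values():
            return aa
    m = _TRNA_LONG_RE.match(squashed)
    if m and m.group(1) in _AA3_TO_1:
        aa = _AA3_TO_1[m.group(1)]
        if aa in "LS":
            return _leu_ser_variant(aa, raw_lower)
        return aa
    # "tRNA-Leu (UUR)" style with trailing decoration.
    m = re.match(r"^trna([a-z]{3})", squashed)
    if m and m.group(1) in _AA3_TO_1:
        aa = _AA3_TO_1[m.group(1)]
        if aa in "LS":
            variant = _leu_ser_variant(aa, raw_lower)
            if variant == aa:
                m2 = re.match(r"^trna[a-z]{3}([12])$", squashed)
                if m2:
                    return f"{aa}{m2.group(1)}"
            return variant
        return aa
    if squashed in ("l1", "l2", "s1", "s2"):
        return squashed.upper()
    if len(squashed) == 1 and squashed.upper() in _AA3_TO_1.values():
        aa = squashed.upper()
        return aa if aa not in "LS" else aa
    return OTHER


def ftype_of_label(label: str) -> str:
    """Feature type implied by a canonical label."""
    if label in PCG_LABELS:
        return "PCG"
    if label in TRNA_LABELS or label in ("L", "S"):
        return "tRNA"
    if label in RRNA_LABELS:
        return "rRNA"
    if label == "CR":
        return "CR"
    return "other"
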