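"""Protein sequences, per-residue feature annotations and missense variants.

Coordinates follow the UniProt convention at every file boundary: feature
intervals are 1-based and inclusive on both ends, and variant positions are
1-based.  Internal label/probability vectors are plain 0-based NumPy arrays of
length equal to the protein length; the conversion happens exactly once, in
:func:`build_label_track` and the variant constructors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

__all__ = [
    "FEATURE_VOCABULARY",
    "FEATURE_GROUPS",
    "ProteinRecord",
    "FeatureAnnotation",
    "LabelTrack",
    "VariantRecord",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "build_label_track",
    "parse_protein_variant",
    "format_protein_variant",
    "apply_variant",
    "read_variant_table",
    "write_variant_table",
]

#: The closed, 20-name feature vocabulary, grouped the way curated protein
#: databases organise them.  Every feature name used anywhere in the package
#: must come from this set.
FEATURE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "functional": ("active site", "binding site", "DNA binding site"),
    "subcellular location": ("topological domain", "trans-membrane"),
    "PTM & processing": (
        "disulfide bond",
        "modified residue",
        "propeptide",
        "signal peptide",
        "transit peptide",
    ),
    "structure": ("beta-strand", "alpha-helix", "turn"),
    "family & domain": (
        "coiled coil",
        "compositional bias",
        "domain",
        "motif",
        "region",
        "repeat",
        "zinc finger",
    ),
}

FEATURE_VOCABULARY: frozenset[str] = frozenset(
    name for names in FEATURE_GROUPS.values() for name in names
)

# 20 standard residues; X is tolerated in sequences but masked out of
# training and evaluation.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_SEQ_CHARS = frozenset(AMINO_ACIDS + "X")

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {k: v.capitalize() for k, v in protein_letters_1to3.items()}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent sequence/annotation/variant input."""


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_SEQ_CHARS
        if bad:
            raise AnnotationError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class FeatureAnnotation:
    """One feature interval on one protein, 1-based inclusive."""

    protein_id: str
    feature: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_VOCABULARY:
            raise AnnotationError(
                f"unknown feature name {self.feature!r} "
                f"(must be one of the {len(FEATURE_VOCABULARY)} controlled names)"
            )
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.protein_id}/{self.feature}: invalid interval "
                f"[{self.start}, {self.end}] (1-based inclusive, start <= end)"
            )


@dataclasses.dataclass
class LabelTrack:
    """Per-residue binary presence of one feature along one protein.

    ``mask`` marks residues whose annotation status is known; a protein with
    no information for a feature gets an all-zero mask (it is a prediction
    target, never a source of negative labels).
    """

    protein_id: str
    feature: str
    labels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.labels.shape != self.mask.shape or self.labels.ndim != 1:
            raise AnnotationError("labels and mask must be 1-D and equal-length")
        if np.any((self.labels == 1) & (self.mask == 0)):
            raise AnnotationError("a residue may be labelled 1 only where mask is 1")

    @property
    def length(self) -> int:
        return int(self.labels.shape[0])


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """A missense substitution on a protein, 1-based position."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise AnnotationError(
                f"{self.protein_id} position {self.position}: "
                f"ref and alt amino acid are both {self.ref_aa!r}"
            )
        for aa, which in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in AMINO_ACIDS:
                raise AnnotationError(f"invalid {which} amino acid {aa!r}")
        if self.position < 1:
            raise AnnotationError(f"position must be >= 1, got {self.position}")
        if self.label not in {"pathogenic", "benign", "VUS", "unlabeled"}:
            raise AnnotationError(f"invalid variant label {self.label!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; sequences are
    uppercased.  Duplicate ids raise :class:`AnnotationError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AnnotationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[FeatureAnnotation]:
    """Read a TSV of ``protein_id  feature  start  end`` rows (header required).

    Every row is validated against the protein lengths and the controlled
    vocabulary; all offending rows are collected and reported together.
    """
    lengths = {p.id: p.length for p in proteins}
    annotations: list[FeatureAnnotation] = []
    problems: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "feature", "start", "end"]
        if header[:4] != expected:
            raise AnnotationError(
                f"{path}: expected header {expected}, got {header[:4]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                problems.append(f"line {lineno}: expected 4 columns, got {len(parts)}")
                continue
            pid, feature, start_s, end_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                problems.append(f"line {lineno}: non-integer coordinates")
                continue
            if pid not in lengths:
                problems.append(f"line {lineno}: unknown protein {pid!r}")
                continue
            try:
                ann = FeatureAnnotation(pid, feature, start, end)
            except AnnotationError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            if end > lengths[pid]:
                problems.append(
                    f"line {lineno}: end {end} exceeds length {lengths[pid]} of {pid}"
                )
                continue
            annotations.append(ann)
    if problems:
        raise AnnotationError(
            f"{path}: {len(problems)} invalid feature rows:\n  " + "\n  ".join(problems)
        )
    return annotations


def write_feature_table(
    annotations: Iterable[FeatureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfeature\tstart\tend\n")
        for ann in annotations:
            fh.write(f"{ann.protein_id}\t{ann.feature}\t{ann.start}\t{ann.end}\n")


def build_label_track(
    protein: ProteinRecord,
    annotations: Iterable[FeatureAnnotation],
    feature: str,
    annotated: bool = True,
) -> LabelTrack:
    """Convert feature intervals into a per-residue binary label track.

    ``labels[i] = 1`` iff residue ``i+1`` falls inside any annotated
    ``[start, end]`` interval (overlaps union).  Disulfide bonds are the
    exception: their annotations name a residue *pair*, so only the two
    bonded cysteines are labelled, never the stretch between them.  When
    ``annotated`` is False the protein lacks information for this feature:
    both labels and mask are all zero, marking every residue as a
    prediction-only target.
    """
    if feature not in FEATURE_VOCABULARY:
        raise AnnotationError(f"unknown feature name {feature!r}")
    labels = np.zeros(protein.length, dtype=np.int8)
    for ann in annotations:
        if ann.protein_id != protein.id or ann.feature != feature:
            raise AnnotationError(
                f"annotation {ann.protein_id}/{ann.feature} does not belong to "
                f"{protein.id}/{feature}"
            )
        if ann.end > protein.length:
            raise AnnotationError(
                f"{protein.id}: interval end {ann.end} exceeds length {protein.length}"
            )
        if feature == "disulfide bond":
            labels[ann.start - 1] = 1
            labels[ann.end - 1] = 1
        else:
            labels[ann.start - 1 : ann.end] = 1
    if not annotated:
        return LabelTrack(protein.id, feature, np.zeros_like(labels), np.zeros_like(labels))
    mask = np.ones(protein.length, dtype=np.int8)
    # Nonstandard residues are never trained or scored on.
    for i, aa in enumerate(protein.sequence):
        if aa == "X":
            mask[i] = 0
            labels[i] = 0
    return LabelTrack(protein.id, feature, labels, mask)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def parse_protein_variant(
    hgvs: str, proteins: Sequence[ProteinRecord], label: str = "unlabeled"
) -> VariantRecord:
    """Parse ``"<id>:p.<Ref3><pos><Alt3>"`` protein-level substitution notation.

    Three-letter codes are mapped to one-letter, the position is validated
    against the protein length and the stated reference amino acid is checked
    against the actual sequence.
    """
    by_id = {p.id: p for p in proteins}
    try:
        pid, change = hgvs.split(":p.", maxsplit=1)
    except ValueError:
        raise AnnotationError(f"{hgvs!r}: expected '<id>:p.<Ref><pos><Alt>' notation")
    if pid not in by_id:
        raise AnnotationError(f"{hgvs!r}: unknown protein {pid!r}")
    if len(change) < 7:
        raise AnnotationError(f"{hgvs!r}: malformed substitution {change!r}")
    ref3, pos_s, alt3 = change[:3], change[3:-3], change[-3:]
    for code in (ref3, alt3):
        if code.upper() not in _THREE_TO_ONE:
            raise AnnotationError(f"{hgvs!r}: unknown three-letter code {code!r}")
    try:
        position = int(pos_s)
    except ValueError:
        raise AnnotationError(f"{hgvs!r}: non-integer position {pos_s!r}")
    protein = by_id[pid]
    if not (1 <= position <= protein.length):
        raise AnnotationError(
            f"{hgvs!r}: position {position} outside 1..{protein.length}"
        )
    ref_aa = _THREE_TO_ONE[ref3.upper()]
    alt_aa = _THREE_TO_ONE[alt3.upper()]
    actual = protein.sequence[position - 1]
    if actual != ref_aa:
        raise AnnotationError(
            f"{hgvs!r}: reference mismatch — sequence has {actual} at "
            f"position {position}, not {ref_aa}"
        )
    return VariantRecord(pid, position, ref_aa, alt_aa, label)


def format_protein_variant(variant: VariantRecord) -> str:
    """Serialise a variant back to ``"<id>:p.<Ref3><pos><Alt3>"`` notation."""
    ref3 = _ONE_TO_THREE[variant.ref_aa]
    alt3 = _ONE_TO_THREE[variant.alt_aa]
    return f"{variant.protein_id}:p.{ref3}{variant.position}{alt3}"


def apply_variant(protein: ProteinRecord, variant: VariantRecord) -> ProteinRecord:
    """Return the alternate-allele protein: one substitution, length unchanged."""
    if variant.protein_id != protein.id:
        raise AnnotationError(
            f"variant belongs to {variant.protein_id!r}, not {protein.id!r}"
        )
    if not (1 <= variant.position <= protein.length):
        raise AnnotationError(f"position {variant.position} outside protein")
    i = variant.position - 1
    if protein.sequence[i] != variant.ref_aa:
        raise AnnotationError(
            f"{protein.id}: reference mismatch at {variant.position} "
            f"({protein.sequence[i]} != {variant.ref_aa})"
        )
    seq = protein.sequence[:i] + variant.alt_aa + protein.sequence[i + 1 :]
    return ProteinRecord(id=protein.id, sequence=seq)


def read_variant_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[VariantRecord]:
    """Read a TSV of ``protein_id  hgvs_p  label`` rows (header required)."""
    variants: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein_id", "hgvs_p", "label"]:
            raise AnnotationError(
                f"{path}: expected header protein_id/hgvs_p/label, got {header[:3]}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, hgvs, label = line.split("\t")[:3]
            variant = parse_protein_variant(hgvs, proteins, label=label)
            if variant.protein_id != pid:
                raise AnnotationError(
                    f"{path}: row protein_id {pid!r} disagrees with {hgvs!r}"
                )
            variants.append(variant)
    return variants


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\thgvs_p\tlabel\n")
        for v in variants:
            fh.write(f"{v.protein_id}\t{format_protein_variant(v)}\t{v.label}\n")
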