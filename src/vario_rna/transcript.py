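"""Transcript context, codon arithmetic and translation.

Positions throughout are CDS-relative and 1-based: position 1 is the first
base of the initiation codon (AUG), matching the coordinate convention of
the worked coding examples (codon_index(954) = 318, codon_index(1559) = 520).
When a transcript carries 5' UTR sequence, ``cds_start`` shifts transcript
coordinates into this frame.

Translation uses the standard genetic code (Biopython) over the RNA
alphabet and stops at the first stop codon; mitochondrial code differences
are out of scope — ``m.`` variants are classified at RNA level only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .hgvs import RnaVariant

STOP_CODONS = frozenset({"uaa", "uag", "uga"})

EFFECT_LABELS = (
    "missense",
    "nonsense",
    "silent",
    "initiation_codon_change",
    "termination_codon_change",
    "frameshift",
    "in_frame_indel",
)


class ContextError(ValueError):
    """Inconsistent or insufficient transcript context."""


@dataclass(frozen=True)
class TranscriptContext:
    """Sequence and CDS layout of one transcript.

    ``sequence`` (lowercase RNA alphabet) is optional: annotation from
    explicit reference codons is possible without it.  ``cds_start`` /
    ``cds_end`` delimit initiation codon through termination codon,
    inclusive, in transcript coordinates.  ``rna_class`` tags the molecule
    with a typing-vocabulary name such as "mRNA" or "microRNA".
    """

    transcript_id: str
    sequence: Optional[str] = None
    cds_start: int = 1
    cds_end: Optional[int] = None
    exon_ends: Optional[tuple[int, ...]] = None
    rna_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.sequence is not None:
            seq = self.sequence.lower().replace("t", "u")
            object.__setattr__(self, "sequence", seq)
            bad = set(seq) - set("acgu")
            if bad:
                raise ContextError(f"non-RNA letters in sequence: {sorted(bad)}")
            if self.cds_end is not None:
                self._check_cds(seq)
        if self.exon_ends is not None:
            ends = tuple(self.exon_ends)
            if list(ends) != sorted(set(ends)):
                raise ContextError("exon_ends must be strictly increasing")
            if self.sequence is not None and ends and ends[-1] > len(self.sequence):
                raise ContextError("exon_ends exceed sequence length")
            object.__setattr__(self, "exon_ends", ends)

    def _check_cds(self, seq: str) -> None:
        n = self.cds_end - self.cds_start + 1
        if n <= 0 or n % 3:
            raise ContextError(f"CDS length {n} is not a positive multiple of 3")
        if self.cds_start < 1 or self.cds_end > len(seq):
            raise ContextError("CDS outside sequence bounds")
        if seq[self.cds_start - 1 : self.cds_start + 2] != "aug":
            raise ContextError("CDS does not start with aug")
        if seq[self.cds_end - 3 : self.cds_end] not in STOP_CODONS:
            raise ContextError("CDS does not end with a stop codon")

    @property
    def is_coding(self) -> bool:
        return self.rna_class in ("mRNA", "pre-mRNA") or self.cds_end is not None

    @property
    def cds_length(self) -> Optional[int]:
        if self.cds_end is None:
            return None
        return self.cds_end - self.cds_start + 1

    @property
    def cds_sequence(self) -> Optional[str]:
        if self.sequence is None or self.cds_end is None:
            return None
        return self.sequence[self.cds_start - 1 : self.cds_end]

    def codon_at(self, index: int) -> Optional[str]:
        """The *index*-th codon of the CDS (1-based), if sequence is known."""
        cds = self.cds_sequence
        if cds is None:
            return None
        if not 1 <= index <= len(cds) // 3:
            raise ContextError(f"codon index {index} outside CDS")
        return cds[3 * (index - 1) : 3 * index]


@dataclass(frozen=True)
class CodingEffect:
    """Coding-level consequence of one variant.

    ``frame_status`` is ``in_frame`` iff the net length change of a
    CDS-overlapping, length-changing variant is divisible by three;
    substitutions are length-preserving and also in frame.
    """

    frame_status: str  # in_frame | out_of_frame | not_applicable
    effect_label: Optional[str] = None
    codon_index: Optional[int] = None
    codon_last: Optional[int] = None
    codon_phase: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    protein_del_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.effect_label is not None and self.effect_label not in EFFECT_LABELS:
            raise ValueError(f"unknown effect label {self.effect_label!r}")
        if self.protein_del_range is not None:
            first, last = self.protein_del_range
            if not (1 <= first <= last):
                raise ValueError(f"bad residue range {self.protein_del_range}")

    def summary(self) -> str:
        parts = [self.frame_status]
        if self.effect_label:
            parts.append(self.effect_label)
        if self.codon_index is not None:
            c = str(self.codon_index)
            if self.codon_last is not None and self.codon_last != self.codon_index:
                c += f"-{self.codon_last}"
            parts.append(f"codon {c}")
        if self.protein_del_range:
            parts.append("residues %d-%d" % self.protein_del_range)
        return "; ".join(parts)


def codon_index(p: int) -> int:
    """Codon number containing CDS-relative position *p* (1-based)."""
    if p < 1:
        raise ValueError(f"CDS-relative position must be >= 1, got {p}")
    return math.ceil(p / 3)


def codon_phase(p: int) -> int:
    """Position of *p* within its codon: 1, 2 or 3."""
    if p < 1:
        raise ValueError(f"CDS-relative position must be >= 1, got {p}")
    return (p - 1) % 3 + 1


def net_length_change(v: RnaVariant) -> int:
    """Signed nucleotide length change the variant causes in the molecule."""
    if v.kind == "substitution" or v.kind == "inversion":
        return 0
    if v.kind == "deletion":
        return -v.span
    if v.kind == "insertion":
        return len(v.alt_bases)
    if v.kind == "delins":
        return len(v.alt_bases) - v.span
    return 0  # translocation: sequence moved, length retained


def protein_del_range(start: int, end: int) -> tuple[int, int]:
    """Residue range removed by the in-frame deletion of CDS positions
    ``start..end``.

    With ``k = (end - start + 1) / 3`` deleted codons-worth of sequence: a
    phase-1 start removes whole codons from ``codon_index(start)``.  For a
    phase-2/3 start the 5' partial codon is reconstituted as a hybrid codon
    from the flanks and, by convention, assigned to the flanking residue,
    so the deleted range starts one codon later.  (When sequence is
    available the translate-and-diff oracle can override this convention if
    the hybrid codon changes the flanking residue.)
    """
    n = end - start + 1
    if start < 1 or end < start:
        raise ValueError(f"bad deletion interval {start}_{end}")
    if n % 3:
        raise ValueError(f"deletion of {n} nt is not in frame")
    k = n // 3
    first = codon_index(start) if codon_phase(start) == 1 else codon_index(start) + 1
    return first, first + k - 1


def translate(seq: str) -> tuple[str, bool]:
    """Translate an RNA string with the standard code.

    Returns ``(protein, stop_reached)``; translation proceeds codon by
    codon from the first base and halts at (excluding) the first stop.
    Trailing bases short of a full codon are ignored.
    """
    seq = seq.lower()
    bad = set(seq) - set("acgu")
    if bad:
        raise ValueError(f"non-RNA letters: {sorted(bad)}")
    usable = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(usable).translate())
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], True
    return aa, False


def splice_site_offset_class(offset: int, side: str) -> str:
    """Classify an intronic offset as canonical or non-canonical.

    The donor (five-prime) site dinucleotide occupies intron positions +1/+2
    and the acceptor (three-prime) site -2/-1; every other intronic offset
    on the matching side is non-canonical.
    """
    if side not in ("donor", "acceptor"):
        raise ValueError(f"side must be donor or acceptor, got {side!r}")
    if offset == 0:
        raise ValueError("offset 0 is exonic, not a splice-site offset")
    if side == "donor":
        if offset < 0:
            raise ValueError("negative offsets lie upstream of an acceptor, not a donor")
        return "canonical" if offset in (1, 2) else "non_canonical"
    if offset > 0:
        raise ValueError("positive offsets lie downstream of a donor, not an acceptor")
    return "canonical" if offset in (-1, -2) else "non_canonical"


def apply_variant(sequence: str, v: RnaVariant, *, one_based_shift: int = 0) -> str:
    """Return *sequence* with *v* applied.

    *v*'s coordinates are interpreted as 1-based positions into *sequence*
    after adding ``one_based_shift`` (use ``cds_start - 1`` for CDS-relative
    variants on a transcript with 5' UTR).  Intronic variants cannot be
    applied to a spliced sequence.
    """
    if v.is_intronic:
        raise ValueError("cannot apply an intronic variant to a spliced sequence")
    s = v.start + one_based_shift
    e = v.end + one_based_shift
    if s < 1 or e > len(sequence):
        raise ValueError(f"variant {v.raw or v.kind} outside sequence bounds")
    if v.kind == "substitution":
        if v.prefix == "r" and sequence[s - 1] != v.ref_bases:
            raise ValueError(
                f"reference mismatch at {v.start}: sequence has "
                f"{sequence[s - 1]!r}, variant states {v.ref_bases!r}"
            )
        return sequence[: s - 1] + v.alt_bases + sequence[s:]
    if v.kind == "deletion":
        return sequence[: s - 1] + sequence[e:]
    if v.kind == "insertion":
        return sequence[:s] + v.alt_bases + sequence[s:]
    if v.kind == "delins":
        return sequence[: s - 1] + v.alt_bases + sequence[e:]
    if v.kind == "inversion":
        comp = str.maketrans("acgu", "ugca")
        inv = sequence[s - 1 : e].translate(comp)[::-1]
        return sequence[: s - 1] + inv + sequence[e:]
    raise ValueError(f"cannot apply variant of kind {v.kind}")
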