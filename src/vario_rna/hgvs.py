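"""Parsing and formatting of RNA/coding variant description strings.

Handles the ``r.`` (RNA), ``c.`` (coding DNA), ``m.`` (mitochondrial) and
``g.`` (genomic) prefixes with substitution, deletion, insertion, delins
and inversion syntax, plus intronic offsets (``c.839+5G>A``) for c./g.
coordinates.  Protein (``p.``) descriptions are a different molecule level
and are rejected.

Coordinates are 1-based fully closed intervals; an insertion is anchored
between two adjacent positions.  Bases are normalised to lowercase; for
``r.`` strings a ``t`` is read as ``u``.  Both the ASCII hyphen and the
typographic en-dash/minus are accepted in negative intronic offsets, since
published text frequently prints the latter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

PREFIXES = ("r", "c", "m", "g")
KINDS = (
    "substitution",
    "deletion",
    "insertion",
    "delins",
    "inversion",
    "translocation",
)

_RNA_ALPHABET = set("acgu")
_DNA_ALPHABET = set("acgtu")


class VariantSyntaxError(ValueError):
    """Malformed or unsupported variant description."""


class UnsupportedMoleculeError(VariantSyntaxError):
    """Raised for p.-prefixed (protein-level) descriptions."""


@dataclass(frozen=True)
class RnaVariant:
    """A structured variant description.

    ``start``/``end`` are 1-based inclusive; for substitutions start == end,
    for insertions (start, end) are the two flanking positions.  Intronic
    offsets are signed and 0 for exonic positions.
    """

    prefix: str
    kind: str
    start: int
    end: int
    start_offset: int = 0
    end_offset: int = 0
    ref_bases: str = ""
    alt_bases: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        if self.prefix not in PREFIXES:
            raise VariantSyntaxError(f"unknown prefix {self.prefix!r}")
        if self.kind not in KINDS:
            raise VariantSyntaxError(f"unknown kind {self.kind!r}")
        if self.start < 1 or self.end < 1:
            raise VariantSyntaxError(
                f"positions must be positive, got {self.start}_{self.end}"
            )
        if (self.start, self.start_offset) > (self.end, self.end_offset):
            raise VariantSyntaxError(
                f"end before start in {self.start}_{self.end}"
            )
        alphabet = _RNA_ALPHABET if self.prefix == "r" else _DNA_ALPHABET
        for b in self.ref_bases + self.alt_bases:
            if b not in alphabet:
                raise VariantSyntaxError(f"invalid base {b!r}")
        if self.kind == "substitution":
            if self.start != self.end:
                raise VariantSyntaxError("substitution must be single-position")
            if len(self.ref_bases) != 1 or len(self.alt_bases) != 1:
                raise VariantSyntaxError("substitution needs one ref and one alt base")
            if self.ref_bases == self.alt_bases:
                raise VariantSyntaxError("substitution with identical ref and alt")
        elif self.kind == "insertion":
            adjacent = (
                self.end == self.start + 1
                if not (self.start_offset or self.end_offset)
                # intronic anchors: adjacent offsets, or an exon/intron boundary
                else (self.end == self.start and self.end_offset == self.start_offset + 1)
                or self.end == self.start + 1
            )
            if not adjacent:
                raise VariantSyntaxError(
                    "insertion must be anchored between adjacent positions"
                )
            if not self.alt_bases:
                raise VariantSyntaxError("insertion without inserted bases")
            if self.ref_bases:
                raise VariantSyntaxError("insertion carries no reference bases")
        elif self.kind == "deletion":
            if self.alt_bases:
                raise VariantSyntaxError("deletion carries no alternate bases")
        elif self.kind == "delins":
            if not self.alt_bases:
                raise VariantSyntaxError("delins without inserted bases")
        if self.start_offset or self.end_offset:
            if self.prefix not in ("c", "g"):
                raise VariantSyntaxError(
                    f"intronic offsets are not meaningful for {self.prefix}. "
                    "coordinates (spliced/ungapped molecule)"
                )

    @property
    def span(self) -> int:
        """Number of reference positions covered (0 for insertions)."""
        if self.kind == "insertion":
            return 0
        return self.end - self.start + 1

    @property
    def is_intronic(self) -> bool:
        return bool(self.start_offset or self.end_offset)


# en-dash / minus sign variants seen in print
_DASHES = {"–": "-", "−": "-", "‒": "-", "—": "-"}

_POS = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^{_POS}([a-z])>([a-z])$")
_RANGE = rf"{_POS}(?:_{_POS})?"
_DEL_RE = re.compile(rf"^{_RANGE}del([a-z]*)$")
_DELINS_RE = re.compile(rf"^{_RANGE}delins([a-z]+)$")
_INS_RE = re.compile(rf"^{_POS}_{_POS}ins([a-z]+)$")
_INV_RE = re.compile(rf"^{_RANGE}inv$")


def _normalise_bases(bases: str, prefix: str, token: str) -> str:
    bases = bases.lower()
    if prefix == "r":
        bases = bases.replace("t", "u")
    for b in bases:
        if b not in (_RNA_ALPHABET if prefix == "r" else _DNA_ALPHABET):
            raise VariantSyntaxError(f"invalid base {b!r} in {token!r}")
    return bases


def parse_variant(s: str) -> RnaVariant:
    """Parse a variant description string into an :class:`RnaVariant`.

    >>> parse_variant("r.777_839del").span
    63
    >>> parse_variant("c.839+5G>A").start_offset
    5
    """
    if not s or not s.strip():
        raise VariantSyntaxError("empty variant description")
    raw = s.strip()
    norm = raw
    for d, repl in _DASHES.items():
        norm = norm.replace(d, repl)
    if norm[:2] == "p.":
        raise UnsupportedMoleculeError(
            "p. describes a protein-level variant; RNA/coding descriptions expected"
        )
    if len(norm) < 3 or norm[1] != ".":
        raise VariantSyntaxError(f"missing molecule prefix in {raw!r}")
    prefix, body = norm[0], norm[2:]
    if prefix not in PREFIXES:
        raise VariantSyntaxError(f"unsupported molecule prefix {prefix!r}")
    body_lc = body.lower()

    def pos(tok_pos: str, tok_off: str | None, what: str) -> tuple[int, int]:
        p = int(tok_pos)
        if p < 1:
            raise VariantSyntaxError(f"non-positive position in {what}: {tok_pos}")
        return p, int(tok_off) if tok_off else 0

    m = _SUB_RE.match(body_lc)
    if m:
        start, soff = pos(m.group(1), m.group(2), raw)
        ref = _normalise_bases(m.group(3), prefix, raw)
        alt = _normalise_bases(m.group(4), prefix, raw)
        return RnaVariant(prefix, "substitution", start, start, soff, soff,
                          ref, alt, raw=raw)

    m = _DELINS_RE.match(body_lc)
    if m:
        start, soff = pos(m.group(1), m.group(2), raw)
        end, eoff = (start, soff) if m.group(3) is None else pos(m.group(3), m.group(4), raw)
        alt = _normalise_bases(m.group(5), prefix, raw)
        return RnaVariant(prefix, "delins", start, end, soff, eoff,
                          "", alt, raw=raw)

    m = _DEL_RE.match(body_lc)
    if m:
        start, soff = pos(m.group(1), m.group(2), raw)
        end, eoff = (start, soff) if m.group(3) is None else pos(m.group(3), m.group(4), raw)
        deleted = _normalise_bases(m.group(5), prefix, raw)
        v = RnaVariant(prefix, "deletion", start, end, soff, eoff,
                       deleted, "", raw=raw)
        if deleted and len(deleted) != v.span:
            raise VariantSyntaxError(
                f"deleted bases {deleted!r} do not match span {v.span} in {raw!r}"
            )
        return v

    m = _INS_RE.match(body_lc)
    if m:
        start, soff = pos(m.group(1), m.group(2), raw)
        end, eoff = pos(m.group(3), m.group(4), raw)
        alt = _normalise_bases(m.group(5), prefix, raw)
        return RnaVariant(prefix, "insertion", start, end, soff, eoff,
                          "", alt, raw=raw)

    m = _INV_RE.match(body_lc)
    if m:
        start, soff = pos(m.group(1), m.group(2), raw)
        end, eoff = (start, soff) if m.group(3) is None else pos(m.group(3), m.group(4), raw)
        return RnaVariant(prefix, "inversion", start, end, soff, eoff, raw=raw)

    raise VariantSyntaxError(f"cannot parse variant description {raw!r}")


def _fmt_pos(p: int, off: int) -> str:
    return f"{p}{off:+d}" if off else str(p)


def format_variant(v: RnaVariant) -> str:
    """Render *v* in canonical lowercase notation.

    ``parse_variant(format_variant(v))`` is structurally *v* (modulo ``raw``).
    """
    start = _fmt_pos(v.start, v.start_offset)
    end = _fmt_pos(v.end, v.end_offset)
    rng = start if (v.start, v.start_offset) == (v.end, v.end_offset) else f"{start}_{end}"
    if v.kind == "substitution":
        body = f"{start}{v.ref_bases}>{v.alt_bases}"
    elif v.kind == "deletion":
        body = f"{rng}del{v.ref_bases}"
    elif v.kind == "delins":
        body = f"{rng}delins{v.alt_bases}"
    elif v.kind == "insertion":
        body = f"{start}_{end}ins{v.alt_bases}"
    elif v.kind == "inversion":
        body = f"{rng}inv"
    else:
        raise VariantSyntaxError(
            f"no single-variant notation for kind {v.kind!r}"
        )
    return f"{v.prefix}.{body}"
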