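"""Rule-based assignment of VariO terms to parsed variants.

Each rule family maps an observable property of the variant (and optional
transcript context) to term *names*; accessions are resolved against the
Hierarchy so that numbering stays data, not code.  Origin, function,
property and typing terms are never inferred from a variant string — the
underlying knowledge is experimental — but caller-supplied metadata terms
are validated against the hierarchy and appended with ``basis="metadata"``.

Term order in an annotation is stable (kind, chemistry, coding effect,
splice, metadata) so that emitted output is diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import ontology
from .hgvs import RnaVariant
from .ontology import Hierarchy
from .transcript import (
    CodingEffect,
    ContextError,
    TranscriptContext,
    codon_index,
    codon_phase,
    net_length_change,
    protein_del_range,
    splice_site_offset_class,
    translate,
)

PURINES = frozenset("ag")
PYRIMIDINES = frozenset("cu")

# effect label -> term name
_EFFECT_TERMS = {
    "missense": "missense variation",
    "nonsense": "nonsense variation",
    "silent": "silent variation",
    "initiation_codon_change": "initiation codon change",
    "termination_codon_change": "termination codon change",
}

_KIND_TERMS = {
    "deletion": "RNA deletion",
    "insertion": "RNA insertion",
    "delins": "RNA indel",
    "inversion": "RNA inversion",
    "translocation": "RNA translocation",
    "substitution": "RNA substitution",
}

_FRAME_SUBTERMS = {
    ("deletion", True): "in-frame deletion",
    ("deletion", False): "out-of-frame deletion",
    ("insertion", True): "in-frame insertion",
    ("insertion", False): "out-of-frame insertion",
    ("delins", True): "in-frame indel",
    ("delins", False): "out-of-frame indel",
}

# sibling families that must never co-occur in one annotation
EXCLUSIVE_FAMILIES: tuple[frozenset[str], ...] = (
    frozenset({"transition", "transversion"}),
    frozenset({"purine transition", "pyrimidine transition"}),
    frozenset({"in-frame deletion", "out-of-frame deletion"}),
    frozenset({"in-frame insertion", "out-of-frame insertion"}),
    frozenset({"in-frame indel", "out-of-frame indel"}),
    frozenset(_EFFECT_TERMS.values()),
    frozenset({
        "variation at canonical five prime splice site",
        "variation at non canonical five prime splice site",
    }),
    frozenset({
        "variation at canonical three prime splice site",
        "variation at non canonical three prime splice site",
    }),
    frozenset({
        "variation at five prime splice site",
        "variation at three prime splice site",
    }),
    frozenset({
        "short non-coding RNA", "long non-coding RNA", "very long non-coding RNA",
    }),
)


class MetadataError(ValueError):
    """Caller-supplied metadata terms not present in the hierarchy."""


@dataclass(frozen=True)
class AnnotationTerm:
    accession: str
    name: str
    basis: str  # rule | metadata

    def rendered(self) -> str:
        return f"{self.accession} {self.name}"


@dataclass
class Annotation:
    """Ordered, accession-unique set of VariO terms for one variant."""

    variant: RnaVariant
    terms: list[AnnotationTerm] = field(default_factory=list)
    coding_effect: Optional[CodingEffect] = None

    def add(self, term: AnnotationTerm) -> None:
        if all(t.accession != term.accession for t in self.terms):
            self.terms.append(term)

    def accessions(self) -> list[str]:
        return [t.accession for t in self.terms]

    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def rendered(self) -> list[str]:
        return [t.rendered() for t in self.terms]


def _rule(h: Hierarchy, name: str) -> AnnotationTerm:
    t = h.by_name(name)
    return AnnotationTerm(t.accession, t.name, "rule")


def classify_substitution_chemistry(ref: str, alt: str) -> list[str]:
    """Chemistry terms for a base substitution (term names).

    Always includes "RNA substitution"; a purine<->purine or
    pyrimidine<->pyrimidine exchange is a transition (with its purine /
    pyrimidine subterm), anything crossing the ring classes a transversion.
    ``t`` is treated as ``u`` so c./g. descriptions classify identically.
    """
    ref, alt = ref.lower().replace("t", "u"), alt.lower().replace("t", "u")
    for b in (ref, alt):
        if b not in PURINES | PYRIMIDINES:
            raise ValueError(f"not an RNA base: {b!r}")
    if ref == alt:
        raise ValueError("reference and alternate base are identical")
    names = ["RNA substitution"]
    if ref in PURINES and alt in PURINES:
        names += ["transition", "purine transition"]
    elif ref in PYRIMIDINES and alt in PYRIMIDINES:
        names += ["transition", "pyrimidine transition"]
    else:
        names.append("transversion")
    return names


def _cds_relative(v: RnaVariant, ctx: TranscriptContext) -> tuple[int, int]:
    """Variant interval in CDS-relative coordinates (may exceed the CDS)."""
    shift = 0 if ctx.cds_start == 1 else -(ctx.cds_start - 1)
    if v.prefix in ("r", "c"):
        # r./c. numbering is CDS-relative already (position 1 = first base of AUG)
        return v.start, v.end
    return v.start + shift, v.end + shift


def classify_coding_effect(
    v: RnaVariant,
    ctx: TranscriptContext,
    *,
    ref_codon: Optional[str] = None,
) -> CodingEffect:
    """Coding-level consequence of *v* in context *ctx*.

    Substitutions in the initiation codon are initiation codon changes; in
    the termination codon they are termination codon changes when the new
    codon is sense (a stop-to-stop exchange stays silent).  Elsewhere the
    reference codon (from *ctx.sequence* or the explicit *ref_codon*)
    decides silent / nonsense / missense.  Length-changing variants are
    labelled by the divisibility-by-three rule, and in-frame deletions get
    a residue range.
    """
    if v.is_intronic or not ctx.is_coding:
        return CodingEffect("not_applicable")
    start, end = _cds_relative(v, ctx)
    length = ctx.cds_length
    if start < 1 or (length is not None and start > length):
        return CodingEffect("not_applicable")

    change = net_length_change(v)
    if v.kind in ("inversion", "translocation"):
        return CodingEffect("not_applicable")
    if change != 0 or v.kind != "substitution":
        in_frame = change % 3 == 0
        first = codon_index(start)
        last = codon_index(min(end, length) if length else end)
        eff = "in_frame_indel" if in_frame else "frameshift"
        del_range = None
        if in_frame and v.kind == "deletion" and (length is None or end <= length):
            del_range = protein_del_range(start, end)
        return CodingEffect(
            "in_frame" if in_frame else "out_of_frame",
            effect_label=eff,
            codon_index=first,
            codon_last=last,
            codon_phase=codon_phase(start),
            protein_del_range=del_range,
        )

    # substitution
    idx = codon_index(start)
    phase = codon_phase(start)
    if idx == 1:
        return CodingEffect("in_frame", "initiation_codon_change", 1, 1, phase)
    if ref_codon is None:
        try:
            ref_codon = ctx.codon_at(idx)
        except ContextError:
            ref_codon = None
    if ref_codon is None:
        if length is not None and idx == length // 3:
            # stop codon hit but no codon available: cannot decide sense vs stop
            raise ContextError(
                f"stop-codon substitution at {v.raw or start} needs the reference codon"
            )
        raise ContextError(
            f"substitution at CDS position {start} needs a reference codon "
            "(provide ctx.sequence or ref_codon)"
        )
    ref_codon = ref_codon.lower().replace("t", "u")
    if len(ref_codon) != 3:
        raise ContextError(f"reference codon {ref_codon!r} is not 3 bases")
    if ref_codon[phase - 1] != v.ref_bases.replace("t", "u"):
        raise ContextError(
            f"reference codon {ref_codon!r} disagrees with variant base "
            f"{v.ref_bases!r} at phase {phase}"
        )
    alt_codon = (
        ref_codon[: phase - 1] + v.alt_bases.replace("t", "u") + ref_codon[phase:]
    )
    ref_aa, ref_stop = translate(ref_codon)
    alt_aa, alt_stop = translate(alt_codon)
    is_stop_codon = ref_stop  # reference codon is a stop => terminator position
    if is_stop_codon:
        label = "silent" if alt_stop else "termination_codon_change"
    elif alt_stop:
        # new stop strictly before the natural one
        label = "nonsense"
    elif ref_aa == alt_aa:
        label = "silent"
    else:
        label = "missense"
    return CodingEffect(
        "in_frame", label, idx, idx, phase, ref_codon=ref_codon, alt_codon=alt_codon
    )


def classify_kind_terms(
    v: RnaVariant, ctx: Optional[TranscriptContext] = None
) -> list[str]:
    """Variation-classification terms for the variant kind (term names).

    In-frame / out-of-frame subterms apply only to length-changing variants
    overlapping the coding region of an mRNA; non-coding molecules carry
    the base term alone.
    """
    if v.kind == "substitution":
        return []  # chemistry terms cover substitutions
    names = [_KIND_TERMS[v.kind]]
    key = (v.kind, net_length_change(v) % 3 == 0)
    if key in _FRAME_SUBTERMS and ctx is not None and not v.is_intronic:
        if ctx.is_coding:
            start, end = _cds_relative(v, ctx)
            length = ctx.cds_length
            if start >= 1 and (length is None or start <= length):
                names.append(_FRAME_SUBTERMS[key])
    return names


def classify_splice_variant(
    v: RnaVariant, *, recursive_site: bool = False
) -> list[str]:
    """Splice-site terms for a variant with an intronic offset (term names).

    A positive offset lies downstream of a donor (five-prime) site, a
    negative offset upstream of an acceptor (three-prime) site; the
    canonical subterm covers the nearly invariant GT/AG dinucleotides at
    +1/+2 and -2/-1.
    """
    off = v.start_offset
    if off == 0:
        raise ValueError("not an intronic variant (offset 0)")
    side = "donor" if off > 0 else "acceptor"
    cls = splice_site_offset_class(off, side)
    if side == "donor":
        names = ["variation at five prime splice site",
                 "variation at canonical five prime splice site"
                 if cls == "canonical"
                 else "variation at non canonical five prime splice site"]
    else:
        names = ["variation at three prime splice site",
                 "variation at canonical three prime splice site"
                 if cls == "canonical"
                 else "variation at non canonical three prime splice site"]
    if recursive_site:
        names.append("variation at recursive splice site")
    return names


def classify_ncrna_size(length: int) -> str:
    """Size-class term name for a non-coding RNA of *length* nucleotides.

    Short non-coding RNAs are shorter than 200 nt and very long ones longer
    than 10 kb; everything from 200 to 10000 nt inclusive is long.
    """
    if length < 1:
        raise ValueError(f"RNA length must be positive, got {length}")
    if length < 200:
        return "short non-coding RNA"
    if length > 10_000:
        return "very long non-coding RNA"
    return "long non-coding RNA"


def classify_full(
    v: RnaVariant,
    ctx: Optional[TranscriptContext] = None,
    meta: Optional[Sequence[str]] = None,
    *,
    hierarchy: Optional[Hierarchy] = None,
    ref_codon: Optional[str] = None,
    recursive_site: bool = False,
) -> Annotation:
    """Full rule-derived annotation of one variant, plus validated metadata.

    *meta* is a sequence of accessions (or exact term names) the caller
    asserts from experimental knowledge — origin, function, property or
    typing terms; they are validated against the hierarchy, never inferred.
    """
    h = hierarchy if hierarchy is not None else default_hierarchy()
    ann = Annotation(variant=v)

    for name in classify_kind_terms(v, ctx):
        ann.add(_rule(h, name))
    if v.kind == "substitution":
        for name in classify_substitution_chemistry(v.ref_bases, v.alt_bases):
            ann.add(_rule(h, name))
    if not v.is_intronic and ctx is not None and ctx.is_coding:
        effect = classify_coding_effect(v, ctx, ref_codon=ref_codon)
        ann.coding_effect = effect
        if effect.effect_label in _EFFECT_TERMS:
            ann.add(_rule(h, _EFFECT_TERMS[effect.effect_label]))
    if v.is_intronic:
        for name in classify_splice_variant(v, recursive_site=recursive_site):
            ann.add(_rule(h, name))
    if (
        ctx is not None
        and not ctx.is_coding
        and ctx.sequence is not None
    ):
        ann.add(_rule(h, classify_ncrna_size(len(ctx.sequence))))

    unknown = []
    for m in meta or ():
        if m in h:
            t = h.get(m)
        else:
            try:
                t = h.by_name(m)
            except ontology.UnknownAccessionError:
                unknown.append(m)
                continue
        ann.add(AnnotationTerm(t.accession, t.name, "metadata"))
    if unknown:
        raise MetadataError(f"metadata terms not in hierarchy: {unknown}")
    return ann


_DEFAULT_HIERARCHY: Optional[Hierarchy] = None


def default_hierarchy() -> Hierarchy:
    """The bundled registry, loaded once per process."""
    global _DEFAULT_HIERARCHY
    if _DEFAULT_HIERARCHY is None:
        _DEFAULT_HIERARCHY = ontology.load_registry()
    return _DEFAULT_HIERARCHY


def check_no_contradictions(ann: Annotation) -> list[tuple[str, str]]:
    """Pairs of mutually exclusive sibling terms present in *ann*, if any."""
    names = set(ann.names())
    bad = []
    for family in EXCLUSIVE_FAMILIES:
        hit = sorted(names & family)
        if len(hit) > 1:
            bad.extend((a, b) for a, b in zip(hit, hit[1:]))
    return bad
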