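"""Seeded synthetic transcripts and variants with oracle-known consequences.

The generator builds random transcripts with a valid CDS (AUG start, no
internal in-frame stop, terminal stop codon) and samples variants whose
coding consequence is computed independently of the rule-based classifier:
the oracle applies the variant to the sequence, translates both molecules
and labels the effect by direct protein comparison.  That makes every
classifier rule testable without downloading any reference data, and the
oracle/classifier pair a genuine dual-route check.

All randomness flows through one ``numpy`` Generator seeded explicitly; no
global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hgvs import RnaVariant, format_variant
from .transcript import (
    STOP_CODONS,
    TranscriptContext,
    apply_variant,
    net_length_change,
    translate,
)

BASES = "acgu"

SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SyntheticCase:
    """One generated variant with its translate-and-diff consequence."""

    ctx: TranscriptContext
    variant: RnaVariant
    oracle_label: str
    oracle_protein_diff: str
    seed: int


def generate_transcript(
    seed: int,
    cds_codons: int = 100,
    utr5: int = 20,
    utr3: int = 30,
) -> TranscriptContext:
    """Random transcript with a valid CDS; deterministic per seed.

    ``cds_codons`` counts initiation through termination codon inclusive,
    so the translated product has ``cds_codons - 1`` residues.
    """
    if cds_codons < 2:
        raise ValueError("a CDS needs at least start and stop codons")
    if utr5 < 0 or utr3 < 0:
        raise ValueError("UTR lengths must be non-negative")
    rng = np.random.default_rng(seed)
    utr5_seq = "".join(rng.choice(list(BASES), size=utr5)) if utr5 else ""
    utr3_seq = "".join(rng.choice(list(BASES), size=utr3)) if utr3 else ""
    body = "".join(rng.choice(SENSE_CODONS, size=cds_codons - 2))
    stop = str(rng.choice(sorted(STOP_CODONS)))
    seq = utr5_seq + "aug" + body + stop + utr3_seq
    return TranscriptContext(
        transcript_id=f"synth-{seed}",
        sequence=seq,
        cds_start=utr5 + 1,
        cds_end=utr5 + 3 * cds_codons,
        rna_class="mRNA",
    )


def oracle_effect(ctx: TranscriptContext, v: RnaVariant) -> tuple[str, str]:
    """Label *v* by applying it to the sequence and diffing the proteins.

    Returns ``(label, protein_diff)``.  Length-changing variants are
    labelled ``in_frame_indel``/``frameshift`` from the measured length
    change of the molecule; substitutions are labelled purely from the
    translated products (positional checks only for the initiation codon,
    which any reference-changing hit disrupts).
    """
    if ctx.sequence is None or ctx.cds_end is None:
        raise ValueError("oracle needs a full transcript sequence and CDS")
    shift = ctx.cds_start - 1  # variant coordinates are CDS-relative
    var_seq = apply_variant(ctx.sequence, v, one_based_shift=shift)
    measured = len(var_seq) - len(ctx.sequence)
    assert measured == net_length_change(v)

    ref_prot, _ = translate(ctx.sequence[ctx.cds_start - 1 :])

    if v.kind != "substitution":
        # indel path: the label is the frame consequence, measured on the
        # molecule itself (a net-zero delins is still an in-frame indel)
        var_prot, _ = translate(var_seq[ctx.cds_start - 1 :])
        label = "in_frame_indel" if measured % 3 == 0 else "frameshift"
        return label, _diff(ref_prot, var_prot)

    # substitution: start codon intact?
    if var_seq[ctx.cds_start - 1 : ctx.cds_start + 2] != "aug":
        return "initiation_codon_change", "no initiation"
    var_prot, _ = translate(var_seq[ctx.cds_start - 1 :])
    if var_prot == ref_prot:
        return "silent", ""
    if len(var_prot) < len(ref_prot):
        return "nonsense", f"premature stop after {len(var_prot)} residues"
    if len(var_prot) > len(ref_prot):
        return "termination_codon_change", f"read-through to {len(var_prot)} residues"
    return "missense", _diff(ref_prot, var_prot)


def _diff(ref: str, alt: str) -> str:
    """Compact description of the residue-level difference."""
    if ref == alt:
        return ""
    if len(ref) == len(alt):
        sites = [i + 1 for i, (a, b) in enumerate(zip(ref, alt)) if a != b]
        return ";".join(f"{ref[i - 1]}{i}{alt[i - 1]}" for i in sites)
    # strip common flanks to locate an indel
    lead = 0
    while lead < min(len(ref), len(alt)) and ref[lead] == alt[lead]:
        lead += 1
    trail = 0
    while (
        trail < min(len(ref), len(alt)) - lead
        and ref[len(ref) - 1 - trail] == alt[len(alt) - 1 - trail]
    ):
        trail += 1
    if len(ref) > len(alt):
        first, last = lead + 1, len(ref) - trail
        return f"del_residues:{first}-{last}"
    first, last = lead + 1, len(alt) - trail
    return f"ins_residues:{first}-{last}"


def generate_variants(
    ctx: TranscriptContext,
    seed: int,
    n: int,
    kinds: Sequence[str] = ("substitution",),
    *,
    indel_lengths: Sequence[int] = tuple(range(1, 10)),
) -> list[SyntheticCase]:
    """Sample *n* variants uniformly over *kinds* and CDS positions.

    Variant coordinates are CDS-relative (position 1 = first base of AUG).
    Deletions/delins spans and insertion lengths are drawn uniformly from
    ``indel_lengths``.  Deterministic per (ctx, seed, n, kinds).
    """
    if ctx.sequence is None or ctx.cds_end is None:
        raise ValueError("variant generation needs a sequenced transcript")
    rng = np.random.default_rng(seed)
    cds = ctx.cds_sequence
    assert cds is not None
    L = len(cds)
    cases: list[SyntheticCase] = []
    for _ in range(n):
        kind = str(rng.choice(list(kinds)))
        if kind == "substitution":
            p = int(rng.integers(1, L + 1))
            ref = cds[p - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            v = RnaVariant("r", "substitution", p, p, ref_bases=ref, alt_bases=alt)
        elif kind == "deletion":
            span = int(rng.choice(list(indel_lengths)))
            start = int(rng.integers(1, L - span + 2))
            v = RnaVariant("r", "deletion", start, start + span - 1)
        elif kind == "insertion":
            start = int(rng.integers(1, L))
            ins = "".join(rng.choice(list(BASES),
                                     size=int(rng.choice(list(indel_lengths)))))
            v = RnaVariant("r", "insertion", start, start + 1, alt_bases=ins)
        elif kind == "delins":
            span = int(rng.choice(list(indel_lengths)))
            start = int(rng.integers(1, L - span + 2))
            ins = "".join(rng.choice(list(BASES),
                                     size=int(rng.choice(list(indel_lengths)))))
            v = RnaVariant("r", "delins", start, start + span - 1, alt_bases=ins)
        else:
            raise ValueError(f"cannot generate kind {kind!r}")
        v = RnaVariant(
            v.prefix, v.kind, v.start, v.end,
            ref_bases=v.ref_bases, alt_bases=v.alt_bases,
            raw=format_variant(v),
        )
        label, diff = oracle_effect(ctx, v)
        cases.append(SyntheticCase(ctx, v, label, diff, seed))
    return cases
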