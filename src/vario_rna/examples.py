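"""Bundled worked examples from the RNA variation literature.

Each row pairs a published variant description (BTK, KISS1R, NPC1, SERPING1
and MIR140 cases) with the transcript context needed to classify it and the
VariO terms stated for it, serving as the package's regression fixture: the
classifier's output must be a superset of the stated terms with no
contradictory sibling.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .classifier import Annotation, classify_full
from .ontology import Hierarchy
from .transcript import TranscriptContext


@dataclass(frozen=True)
class WorkedExample:
    variant: str
    transcript_id: str
    ctx: Optional[TranscriptContext]
    ref_codon: Optional[str]
    meta: tuple[str, ...]
    expected: tuple[str, ...]
    description: str


def load_examples() -> list[WorkedExample]:
    """Read the bundled example table."""
    text = resources.files("vario_rna.data").joinpath("examples.tsv").read_text()
    reader = csv.DictReader(
        (ln for ln in io.StringIO(text) if not ln.startswith("#")),
        delimiter="\t",
    )
    out = []
    for row in reader:
        cds_len = row["cds_len"].strip()
        ctx = TranscriptContext(
            transcript_id=row["transcript_id"],
            cds_start=1,
            cds_end=int(cds_len) if cds_len else None,
            rna_class=row["rna_class"] or "mRNA",
        )
        out.append(
            WorkedExample(
                variant=row["variant"],
                transcript_id=row["transcript_id"],
                ctx=ctx,
                ref_codon=row["ref_codon"] or None,
                meta=tuple(m for m in row["meta"].split("|") if m),
                expected=tuple(e for e in row["expected"].split("|") if e),
                description=row["description"],
            )
        )
    return out


def annotate_example(
    ex: WorkedExample, hierarchy: Optional[Hierarchy] = None
) -> Annotation:
    """Run the classifier on one worked example."""
    from .hgvs import parse_variant

    v = parse_variant(ex.variant)
    return classify_full(
        v, ex.ctx, meta=ex.meta, hierarchy=hierarchy, ref_codon=ex.ref_codon
    )
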