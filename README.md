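# vario-rna

Systematic annotation of RNA and coding variants with Variation Ontology
(VariO) terms.

Variation Ontology describes variation types, effects and mechanisms at the
DNA, RNA and protein levels with accessioned terms (`VariO:NNNN name`); a
systematic annotation such as `VariO:0319 RNA deletion` is readable by both
people and programs. This package makes the RNA part of that vocabulary
executable: it parses HGVS-style variant descriptions (`r.`/`c.`/`m.`/`g.`
prefixes), classifies them against the RNA term hierarchy, computes
coding-level consequences, and emits the combined annotation in text, TSV or
JSON. It is aimed at curators of variant databases and at pipelines that
want machine-checkable RNA-level annotations alongside DNA and protein ones.

## What it computes

For a parsed variant the rule engine assigns, where decidable from the
description and transcript context alone:

- **Variation classification** — `RNA substitution` / `RNA deletion` /
  `RNA insertion` / `RNA indel` / `RNA inversion`, with substitution
  chemistry (`transition` with its purine/pyrimidine subterm, or
  `transversion`): a purine↔purine (a↔g) or pyrimidine↔pyrimidine (c↔u)
  exchange is a transition, anything crossing the ring classes a
  transversion (4 of the 12 ordered base pairs are transitions, 8
  transversions).
- **Coding consequence** — with the CDS-relative convention (position 1 =
  first base of the AUG), the codon containing position *p* is ⌈*p*/3⌉ and
  its phase (*p*−1) mod 3 + 1. Substitutions are labelled initiation /
  termination codon change positionally, otherwise silent, nonsense or
  missense from the reference codon. Length-changing variants are in frame
  iff their net length change is divisible by three; an in-frame deletion
  of CDS positions *s..e* removes (*e*−*s*+1)/3 residues starting at codon
  ⌈*s*/3⌉ (phase 1) or ⌈*s*/3⌉+1 (the 5′-flank hybrid-codon rule).
- **Splice-site class** — an intronic offset +*n* lies at a five-prime
  (donor) site, −*n* at a three-prime (acceptor) site; offsets +1/+2 and
  −1/−2 are the canonical GT/AG dinucleotides, everything else
  non-canonical.
- **Non-coding RNA size class** — shorter than 200 nt `short`, longer than
  10 kb `very long`, otherwise `long non-coding RNA`.

Origin, function, property and typing terms (e.g. `artificial RNA
variation`, `microRNA`, `exon skipping`) rest on experimental knowledge;
they are accepted as caller metadata and validated against the hierarchy,
never inferred.

The bundled registry carries 151 RNA terms in seven hierarchy levels
(depth 0–6), resolved against the accession collisions present in the
source text via a documented conflict table (see the registry file header);
an official OBO release can be substituted with `--obo`.

## Worked example

```
$ printf 'r.777_839del\tBTK\nc.839+5G>A\tBTK\n' > variants.tsv
$ printf 'transcript_id\tcds_start\tcds_end\texon_ends\trna_class\nBTK\t1\t1980\t\tmRNA\n' > config.tsv
$ vario-rna annotate variants.tsv --config config.tsv
# vario-rna annotate format=text strict=False
r.777_839del [BTK]
  VariO:0319 RNA deletion
  VariO:0320 in-frame deletion
  coding effect: in_frame; in_frame_indel; codon 259-280; residues 260-280
c.839+5G>A [BTK]
  VariO:0312 RNA substitution
  VariO:0313 transition
  VariO:0315 purine transition
  VariO:0367 variation at five prime splice site
  VariO:0369 variation at non canonical five prime splice site
annotated 2 variants (0 errors)
```

The 63-nt deletion is in frame (63 = 21 codons) and removes protein
residues 260–280 — the deletion starts at phase 3 of codon 259, so the
hybrid-codon rule assigns the reconstituted codon to the flanking residue
259 and the deleted range starts at 260. The intronic substitution at donor
offset +5 is outside the canonical +1/+2 dinucleotide, hence
non-canonical five-prime.

Other subcommands: `vario-rna terms VariO:0314` (render a term with its
ancestry), `vario-rna validate-ontology` (integrity check), `vario-rna
synth` (seeded synthetic transcript/variant fixtures with
translate-and-diff oracle labels).

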