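# Naive registry transcribed verbatim from the published text, WITHOUT the
# conflict table: accessions are kept exactly as printed, so the duplicate
# assignments (VariO:0468, VariO:0502, VariO:0308) survive.  Used to show
# that integrity scanning flags them.
accession	name
VariO:0312	RNA substitution
VariO:0313	transition
VariO:0308	missense variation
VariO:0310	nonsense variation
VariO:0318	silent variation
VariO:0468	translation-related non-coding RNA
VariO:0493	ribosomal RNA
VariO:0468	transfer RNA
VariO:0502	loss of exon fragment
VariO:0502	exon skipping
VariO:0308	variation affecting RNA structure
VariO:0319	RNA deletion
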