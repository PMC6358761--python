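# Promoter cis-element library. Entries keyed by PLACE identifiers; the IUPAC
# consensus strings are editable and were populated from the PLACE records of
# the five elements shared across the rice trihelix promoters.
element_id	iupac_consensus	annotation
GATABOX	GATA	light-responsive
ACGTATERD1	ACGT	dehydration-responsive
GT1CONSENSUS	GRWAAW	light-responsive
INRNTPSADB	YTCANTYY	light-responsive
GT1GMSCAM4	GAAAAA	dehydration-responsive (core)
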