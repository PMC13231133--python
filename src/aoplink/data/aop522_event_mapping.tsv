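# Event-term mapping for the autism AOP (AOP:522): each event of the
# pathway is mapped to curated-vocabulary equivalents — genes, a gene-symbol
# wildcard, GO phenotypes, or a disease restricted to marker/mechanism
# direct evidence.
event_id	term_kind	term	evidence_filter
MIE:112	gene	GENE:2099
MIE:112	gene	GENE:2100
MIE:112	phenotype	GO:0030520
MIE:112	phenotype	GO:0030284
KE:2207	gene	GENE:5594
KE:2207	gene	GENE:5595
KE:2207	phenotype	GO:0070371
KE:2207	phenotype	GO:0004707
KE:195	gene_pattern	GRIN*
KE:195	phenotype	GO:0004972
KE:195	phenotype	GO:0017146
KE:195	phenotype	GO:0098989
KE:195	phenotype	GO:2000310
KE:2208	phenotype	GO:0045202
KE:2208	phenotype	GO:0007416
KE:2208	phenotype	GO:0050808
KE:2208	phenotype	GO:0099536
KE:386	phenotype	GO:0007399
KE:386	phenotype	GO:0050877
AO:2209	disease	MESH:D000067877	marker_mechanism
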