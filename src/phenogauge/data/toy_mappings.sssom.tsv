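subject_id	predicate_id	object_id
OMIM:231050	skos:exactMatch	MONDO:0099001
OMIM:614185	skos:exactMatch	MONDO:0013612
OMIM:617809	skos:exactMatch	MONDO:0099003
ORPHA:2623	skos:exactMatch	MONDO:0000127
OMIM:102370	skos:exactMatch	MONDO:0099010
OMIM:154700	skos:exactMatch	MONDO:0099011
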