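# term_id	entity_type	canonical_name	synonyms (pipe-separated)
mutation	variant	mutations	mutations|variant|variants
expression	variant	expression	expression|overexpression|over-expression|underexpression
methylation	variant	methylation	methylation|promoter methylation|hypermethylation|promoter hypermethylation
deletion	variant	deletion	deletion|deletions
amplification	variant	amplification	amplification|amplifications
loss of function	variant	loss of function	loss of function|loss-of-function
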