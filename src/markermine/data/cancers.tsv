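# term_id	entity_type	canonical_name	synonyms (pipe-separated)
DOID:1612	cancer	breast cancer	breast cancer|breast carcinoma
DOID:3908	cancer	non-small cell lung cancer	non-small cell lung cancer|non-small cell lung carcinoma|non small cell lung cancer|NSCLC
DOID:1324	cancer	lung cancer	lung cancer
DOID:2226	cancer	myeloproliferative neoplasm	myeloproliferative neoplasm|myeloproliferative neoplasms
DOID:768	cancer	retinoblastoma	retinoblastoma
DOID:1909	cancer	melanoma	melanoma
DOID:9256	cancer	colorectal cancer	colorectal cancer|colorectal carcinoma
DOID:8552	cancer	chronic myeloid leukemia	chronic myeloid leukemia|chronic myelogenous leukemia|CML
DOID:10534	cancer	stomach cancer	stomach cancer|gastric cancer
DOID:5517	cancer	stomach carcinoma	stomach carcinoma|gastric carcinoma
DOID:2394	cancer	ovarian cancer	ovarian cancer|ovarian carcinoma
DOID:10283	cancer	prostate cancer	prostate cancer|prostate carcinoma
DOID:3068	cancer	glioblastoma	glioblastoma|glioblastoma multiforme
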