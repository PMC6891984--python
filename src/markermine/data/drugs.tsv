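# term_id	entity_type	canonical_name	synonyms (pipe-separated)
Q418369	drug	erlotinib	erlotinib|Tarceva
Q417169	drug	gefitinib	gefitinib|Iressa
Q177094	drug	imatinib	imatinib|Gleevec
Q412415	drug	cisplatin	cisplatin
Q423762	drug	paclitaxel	paclitaxel|Taxol
Q412323	drug	tamoxifen	tamoxifen
Q423040	drug	vemurafenib	vemurafenib
Q412203	drug	trastuzumab	trastuzumab|Herceptin
Q415588	drug	temozolomide	temozolomide
Q419764	drug	doxorubicin	doxorubicin
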