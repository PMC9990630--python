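# Static annotation: primary molecular target per canonical drug name.
# Informational metadata only; not used by the statistics.
erlotinib	EGFR
lenvatinib	VEGFR
nintedanib	VEGFR
pazopanib	VEGFR
regorafenib	VEGFR
sorafenib	VEGFR
sunitinib	VEGFR
trametinib	MEK
vandetanib	VEGFR
zanubrutinib	Bruton's tyrosine kinase
atezolizumab	PD-L1
durvalumab	PD-L1
nivolumab	PD-1
pembrolizumab	PD-1
ipilimumab	CTLA-4
bevacizumab	VEGF
cetuximab	EGFR
daratumumab	CD38
panitumumab	EGFR
rituximab	CD20
axicabtagene ciloleucel	CD19-expressing cells
temsirolimus	mTOR
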