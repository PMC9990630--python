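# Starter synonym dictionary: novel antineoplastic agents (generic + common
# trade names) plus common co-medication ingredients used as background
# drugs.  Columns: synonym<TAB>canonical ('|'-separated for combinations).
AVASTIN	bevacizumab
MVASI	bevacizumab
ZIRABEV	bevacizumab
ERBITUX	cetuximab
LENVIMA	lenvatinib
KISPLYX	lenvatinib
TECENTRIQ	atezolizumab
IMFINZI	durvalumab
OPDIVO	nivolumab
KEYTRUDA	pembrolizumab
YERVOY	ipilimumab
DARZALEX	daratumumab
VECTIBIX	panitumumab
RITUXAN	rituximab
MABTHERA	rituximab
TARCEVA	erlotinib
OFEV	nintedanib
VARGATEF	nintedanib
VOTRIENT	pazopanib
STIVARGA	regorafenib
NEXAVAR	sorafenib
SUTENT	sunitinib
MEKINIST	trametinib
CAPRELSA	vandetanib
BRUKINSA	zanubrutinib
YESCARTA	axicabtagene ciloleucel
TORISEL	temsirolimus
CYRAMZA	ramucirumab
ZALTRAP	aflibercept
EYLEA	aflibercept
TAFINLAR	dabrafenib
TAGRISSO	osimertinib
IRESSA	gefitinib
GILOTRIF	afatinib
CABOMETYX	cabozantinib
COMETRIQ	cabozantinib
INLYTA	axitinib
IMBRUVICA	ibrutinib
AFINITOR	everolimus
LYNPARZA	olaparib
IBRANCE	palbociclib
XALKORI	crizotinib
TAXOL	paclitaxel
ABRAXANE	paclitaxel
PARAPLATIN	carboplatin
TYLENOL	acetaminophen
PARACETAMOL	acetaminophen
ASPIRIN	aspirin
ACETYLSALICYLIC ACID	aspirin
GLUCOPHAGE	metformin
PRILOSEC	omeprazole
LIPITOR	atorvastatin
ZESTRIL	lisinopril
PRINIVIL	lisinopril
LASIX	furosemide
DECADRON	dexamethasone
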