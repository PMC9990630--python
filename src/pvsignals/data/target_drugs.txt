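erlotinib
lenvatinib
nintedanib
pazopanib
regorafenib
sorafenib
sunitinib
trametinib
vandetanib
zanubrutinib
atezolizumab
durvalumab
nivolumab
pembrolizumab
ipilimumab
bevacizumab
cetuximab
daratumumab
panitumumab
rituximab
axicabtagene ciloleucel
temsirolimus
ramucirumab
aflibercept
dabrafenib
osimertinib
gefitinib
afatinib
cabozantinib
axitinib
ibrutinib
everolimus
olaparib
palbociclib
crizotinib
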