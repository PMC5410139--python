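taxon,areas
Cryptomys_hottentotus,"SZ,SL"
F_zechi,WA
F_bocagei,WK
F_mechowii,WK
F_vandewoestijneae,WK
F_livingstoni,ER
F_darlingi,SZ
F_damarensis,"SZ,SL"
F_micklemi,EK
F_hanangensis,ER
F_whytei,MTJ
Lufubu,EK
East_Bangweulu,EK
West_Bangweulu,WK
F_amatus,EK
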