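(Cryptomys_hottentotus:10.5,(F_zechi:8.18,((F_bocagei:3.91,(F_mechowii:1.96,F_vandewoestijneae:1.96):1.95):1.96,(F_livingstoni:3.55,((F_darlingi:1.97,(F_damarensis:0.99,F_micklemi:0.99):0.98):0.99,(F_hanangensis:2.36,((F_whytei:1.18,(Lufubu:0.59,East_Bangweulu:0.59):0.59):0.59,(West_Bangweulu:0.89,F_amatus:0.89):0.88):0.59):0.6):0.59):2.32):2.31):2.32);
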