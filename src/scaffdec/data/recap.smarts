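# Classical RECAP bond types as two-atom SMARTS; the cleavable bond is the one
# between the first and second matched atoms. Lines: name<TAB>SMARTS.
amide	[C;!R;$(C=O);!$(C(=O)[O,S])]-!@[N;!$(N=*);!$(N[!#6;!#1])]
ester	[C;!R;$(C=O)]-!@[O;D2;$(O([#6])[#6]);!$(O=*)]
amine	[N;!$(N=*);!$(N[C,S]=[O,S,N]);!$(N[!#6;!#1])]-!@[C;!$(C=*);!$(C[!#6;!#1])]
urea	[#7;$([#7]C(=O)[#7])]-!@[C;$(C(=O)[#7])]
ether	[O;D2;!$(O=*);!$(OC=O)]-!@[#6]
olefin	[C;!R]=!@[C;!R]
quaternary_nitrogen	[N;+1;D4]-!@[#6]
aromatic_nitrogen_aliphatic_carbon	[n]-!@[C]
lactam_nitrogen_aliphatic_carbon	[N;R;$([N;R]@[C;R]=O)]-!@[C;!$(C=O)]
aromatic_carbon_aromatic_carbon	[c]-!@[c]
sulfonamide	[#7;!$([#7]=*)]-!@[S;$(S(=O)=O)]
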