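# BRICS-style cleavage environments, re-encoded as mapped SMARTS over
# the bond to break (atom maps :1 and :2).  This is a condensed
# re-encoding of the published link environments, not a byte-exact copy
# of any distributed rule file.
acyl_heteroatom	[C;$(C=O):1][O,N;!$([O,N]=*):2]
alkyl_O	[C;!$(C=O);!R:1][O;!$(O=*);$(O[C,c]):2]
alkyl_N	[C;!$(C=O);!R:1][N;!$(N=*);$(N[C,c]):2]
aryl_N	[c:1][N;!$(N=*):2]
aryl_O	[c:1][O;!$(O=*):2]
aryl_aryl	[c:1][c:2]
aryl_alkyl	[c:1][C;!$(C=O);!R:2]
amide_N_C	C(=O)[N:1][C;!$(C=O):2]
olefin_C	[C;$(C=C):1][C;!$(C=O);!R:2]
sulfonyl	[S;$(S(=O)=O):1][N,c:2]
ring_attachment	[C;R:1][C;!R;!$(C=O):2]
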