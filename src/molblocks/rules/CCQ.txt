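# CCQ-style cleavage rules, re-encoded as mapped SMARTS (atom maps :1
# and :2 mark the cleavable bond).  Approximate re-encoding of the
# commercial rule classes; not a byte-exact copy.
amide	[C:1](=O)[N:2]
ester	C(=O)[O:1][C:2]
carbamate	O=C([O:1])[N:2]
carbonate	OC(=O)[O:1][C:2]
sulfonamide	[S;$(S(=O)=O):1][N:2]
amine	[N;!$(N=*);!$(NC=O):1][C;!$(C=O):2]
ether	[C;!$(C=O):1][O:2][C;!$(C=O)]
thioether	[C;!$(C=S):1][S;!$(S=*);!$(S(=O)):2]
olefin	[C:1]=[C:2]
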