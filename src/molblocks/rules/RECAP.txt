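# RECAP-style retrosynthetic bond classes, re-encoded as mapped SMARTS.
# Atom maps :1 and :2 mark the two atoms of the cleavable bond.
# These are an approximate re-encoding of the published bond classes,
# not a byte-exact copy of any distributed rule file.
amide	[C:1](=O)[N:2]
ester	C(=O)[O:1][C:2]
amine	[N;!$(N=*);!$(NC=O);!$(N[O,N]):1][C;!$(C=O):2]
urea	[N:1][C:2](=O)N
ether	[C;!$(C=O):1][O:2][C;!$(C=O)]
olefin	[C:1]=[C:2]
quaternary_N	[N+:1][C:2]
aromatic_N_aliphatic_C	[n:1][C:2]
lactam_N_aliphatic_C	[N;$(NC=O);R:1][C;!$(C=O);!R:2]
biaryl	[c:1][c:2]
sulfonamide	[S;$(S(=O)=O):1][N:2]
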