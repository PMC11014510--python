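# Default gene-family blacklist: families whose one-to-one orthology calls are
# notoriously unreliable in whole-genome alignments (uncharacterised ORFs,
# beta-defensins, FAM genes, histones, keratins and keratin-associated
# proteins, NPIP A/B, PRAME, solute carriers, SPATA, ubiquitin-specific
# peptidases, zinc-finger families, UDP-glucuronosyltransferases).
# Shell-style glob patterns, one per line, matched against gene symbols.
C*orf*
DEFB*
FAM*
HIST*
H1-*
H2A*
H2B*
H3C*
H4C*
KRT*
KRTAP*
NPIPA*
NPIPB*
PRAME*
SLC*
SPATA*
USP*
ZNF*
ZFP*
ZSCAN*
UGT*
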