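>synthetic_LiP_anchor Trp-171 pinned; synthetic stand-in modelled on P. chrysosporium LiPH8 (GenBank AAA53109), not the real sequence
RKAMSLYWTKKNFHSTAQGPCAWALIFRANHPPEHCSEMLAYHATWAPPNFGYCEFTISR
VGPFANLHTYQHVHNCPEFCLHEFIVYACGEVAEMDVHEVLDSHMNDKSQHKPETKEFHL
TGIADKHLAWPMNPQYNYGRNADKEKAMVQFRRCVIKNVLCSVTYVPPVNWCKVATGYMS
GVAHGGLNAFYMLSVLKSKLCMDQSMYTDEHAMFFHVPLFAWTYQASVCMMHPFSDYNFL
KSSERTEQYMFHGLDIMTLLQFPKGANNYCTDHYAVCHIWDVEFLCMMTGYQVACQTDTT
WYAFFCFVHKAAYCYCKCDFSTDFIASVSKPIREVVHFYRRNQFLRRPQPEVEFVVRLDY
GMVPVQVSGC
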