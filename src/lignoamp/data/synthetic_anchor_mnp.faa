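>synthetic_MnP_anchor Asp-175 pinned; synthetic stand-in modelled on P. chrysosporium MnP1 (GenBank AAA33744), not the real sequence
RLAMSCYWTKTNFHSTAQGPCACALIFRANHPPEHDSEMSAYRATWAPPNFYYVEFTISR
VGPFANLHTYQHVHNCPEFCYTEFIIYLCGEYAEMDLHSVLDGHMNDKSQEAPETKDFHL
TGIADKHLAWPMNYQMNAGRNAGKEQAMVMFRRCVIKNVLCSVTYVPPVNACKVDTGYMS
GVAHGGLNAFYMMSVLKSKPCMIQSMYTDEHAMFFHVPLRAQMYQAGVCMMHPFSMYNFW
KYYERRKQPMFHGLDIMALFQKPKGANNYCTDHYAVDHIWRVEMLCMGTGYQVACQTDTT
WYAFFCFKHKAAYCYCKCDFSTDFAASVSKPIREVVHFYRRNFFLNRPQPEVEFVVRCDY
GMVPHQVSGC
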