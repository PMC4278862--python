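family	name	sequence	orientation	expected_product_length	targeted_groups
GH7	fungcbhI-F	ACCAAYTGCTAYACIRGYAA	forward	515	Basidiomycota;Ascomycota
GH7	fungcbhI-R	GCYTCCCAIATRTCCATC	reverse	515	Basidiomycota;Ascomycota
GH5-5	fungGH5-5-F	GARATGCAYCARTACCTYGA	forward	248	Basidiomycota;Ascomycota
GH5-5	fungGH5-5-R	CANGGICCRGCRGCCCACCA	reverse	248	Basidiomycota;Ascomycota
GH11	fungGH11-F	GGVAAGGGITGGAAYCCNGG	forward	281	Basidiomycota;Ascomycota
GH11	fungGH11-R	TGKCGRACIGACCARTAYTG	reverse	281	Basidiomycota;Ascomycota
AA2	basidioAA2-F	GGYGGIGGIGCBGAYGGYTC	forward	398	Basidiomycota
AA2	basidioAA2-R	GGRGTIGAGTCRAANGG	reverse	398	Basidiomycota
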