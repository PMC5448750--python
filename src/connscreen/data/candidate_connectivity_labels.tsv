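screen	gene
conserved	Clstn1
conserved	Clstn2
conserved	Igsf9b
conserved	Kirrel3
conserved	Neto1
conserved	Neto2
conserved	Odz1
conserved	Odz2
conserved	Odz3
conserved	Odz4
conserved	Sdk2
atlas	Alcam
atlas	Astn2
atlas	Bmp3
atlas	Cadm1
atlas	Cbln2
atlas	Cbln4
atlas	Cd47
atlas	Cdh2
atlas	Cdh4
atlas	Cdh6
atlas	Cdh7
atlas	Cdh8
atlas	Cdh9
atlas	Cdh10
atlas	Cdh11
atlas	Cdh12
atlas	Cdh13
atlas	Cdh24
atlas	Clstn1
atlas	Clstn2
atlas	Cntn6
atlas	Cntnap4
atlas	Dlk1
atlas	Dner
atlas	EfnA2
atlas	EfnA5
atlas	EfnB3
atlas	EphA1
atlas	EphA3
atlas	EphA4
atlas	EphA6
atlas	EphA8
atlas	EphA10
atlas	EphB1
atlas	EphB2
atlas	EphB6
atlas	Fat3
atlas	Flt3
atlas	Fzd7
atlas	Gfra1
atlas	Gfra2
atlas	Gpc3
atlas	Igfbp5
atlas	Inhba
atlas	Kit
atlas	Lgi2
atlas	Lrp8
atlas	Lrrn3
atlas	Lypd1
atlas	Mdga1
atlas	Nrn
atlas	Ntng1
atlas	Ntng2
atlas	Ntrk2
atlas	Ntrk3
atlas	Pcdh1
atlas	Pcdh10
atlas	Pcdh11X
atlas	Pcdh19
atlas	Pcdh21
atlas	PlxnA1
atlas	PlxnA2
atlas	PlxnC1
atlas	Ptpru
atlas	Ret
atlas	Rtn4rl1
atlas	Sema3F
atlas	Sema6A
atlas	Sema7A
atlas	Odz3
atlas	Tgfb2
atlas	Trp53i11
atlas	Vgf
atlas	Wif1
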