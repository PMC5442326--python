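# Nearest-neighbour molar extinction coefficients at 260 nm for
# single-stranded DNA, M^-1 cm^-1.
# Source: Cantor, Warshaw & Shapiro (1970) Biopolymers 9:1059, as commonly
# tabulated for oligonucleotide quantification.
# kind: mono = single deoxynucleotide, di = stacked dinucleotide pair
kind	key	epsilon
mono	A	15400
mono	C	7400
mono	G	11500
mono	T	8700
di	AA	27400
di	AC	21200
di	AG	25000
di	AT	22800
di	CA	21200
di	CC	14600
di	CG	18000
di	CT	15200
di	GA	25200
di	GC	17600
di	GG	21600
di	GT	20000
di	TA	23400
di	TC	16200
di	TG	19000
di	TT	16800
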