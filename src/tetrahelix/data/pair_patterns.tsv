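# Hydrogen-bond donor/acceptor patterns defining base-pair geometry classes.
# Each row is one expected hydrogen bond; role 1/2 assigns the bond's donor
# to the first or second residue of the pair class (base1/base2 give the
# residue types of the two roles).  A pair is assigned the class whose
# pattern it matches with at least two bonds (and no residue-type mismatch).
# I denotes hypoxanthine (2'-deoxyinosine, residue DI).
class	base1	base2	donor_role	donor_atom	acceptor_role	acceptor_atom
WC_GC	DG	DC	1	N1	2	N3
WC_GC	DG	DC	1	N2	2	O2
WC_GC	DG	DC	2	N4	1	O6
GG_N1_CARBONYL	DG	DG	1	N1	2	O6
GG_N1_CARBONYL	DG	DG	2	N1	1	O6
GA_N1N7_CARBONYLAMINO	DG	DA	1	N1	2	N7
GA_N1N7_CARBONYLAMINO	DG	DA	2	N6	1	O6
G_I_HOOGSTEEN	DG	DI	1	N1	2	O6
G_I_HOOGSTEEN	DG	DI	1	N2	2	N7
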