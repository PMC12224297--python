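# Biosynthesis-associated Pfam domain names used to score candidate regions.
# Editable stand-in for a full curated set: these are the enzyme classes most
# characteristic of secondary-metabolite pathways (NRPS/PKS machinery, tailoring
# enzymes). One domain name per line.
Condensation
AMP-binding
ketoacyl-synt
Ketoacyl-synt_C
PKS_KS
PKS_AT
Thioesterase
PP-binding
Methyltransf_11
Methyltransf_12
p450
Aminotran_1_2
Aminotran_3
Glycos_transf_1
Glycos_transf_2
Radical_SAM
FAD_binding_3
adh_short
Epimerase
polyprenyl_synt
Terpene_synth_C
Lant_dehydr_N
DUF692
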