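# Functional-class assignment of published (p)ppGpp-receptor complexes (PDB id -> class).
# Classes: synthetase, nucleotide_metabolic, gtpase, rna_polymerase, riboswitch, other.
pdb_id	functional_class
5DED	synthetase
6EX0	synthetase
6S2T	synthetase
6CZF	nucleotide_metabolic
6D9S	nucleotide_metabolic
6W1I	nucleotide_metabolic
4QRH	nucleotide_metabolic
6GFM	nucleotide_metabolic
5VOG	nucleotide_metabolic
1LNZ	gtpase
4ZCM	gtpase
6G14	gtpase
6G15	gtpase
5A9Y	gtpase
1SMY	rna_polymerase
4JK1	rna_polymerase
4JKR	rna_polymerase
5TMC	rna_polymerase
4JK2	rna_polymerase
5VSW	rna_polymerase
6WRG	rna_polymerase
6WRD	rna_polymerase
6CK4	riboswitch
6DMC	riboswitch
6DMD	riboswitch
6DME	riboswitch
2J4R	other
6PC1	other
3VR1	other
4HNX	other
4XPD	other
4Y49	other
4EDV	other
4EDT	other
3N75	other
6GTM	other
5U51	other
6VCL	other
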