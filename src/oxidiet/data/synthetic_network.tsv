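# Synthetic protein-interaction fixture: edge list CONSTRUCTED to the
# published structural summary (23 nodes, 52 interactions at medium
# confidence >= 0.4) with subnetworks for beta-oxidation, urea cycle,
# glycolysis, amino-acid metabolism and redox defense around a Tkt hub.
# Not retrieved from STRING; individual edges are NOT authoritative.
protein_a	protein_b	evidence	score
Hsd17b10	Acadl	physical	0.9
Hsd17b10	Acaa2	physical	0.9
Hsd17b10	Echs1	physical	0.9
Acadl	Acaa2	physical	0.9
Acadl	Echs1	physical	0.9
Acaa2	Echs1	physical	0.9
Cps1	Otc	physical	0.85
Cps1	Ass1	physical	0.85
Otc	Ass1	physical	0.85
Aldob	Pgk1	physical	0.8
Aldob	Gapdh	physical	0.8
Aldob	Tpi1	physical	0.8
Pgk1	Gapdh	physical	0.8
Pgk1	Tpi1	physical	0.8
Gapdh	Tpi1	physical	0.8
Pc	Aldob	functional	0.6
Pc	Gk	functional	0.6
Pc	Pgk1	functional	0.55
Gk	Aldob	functional	0.5
Gk	Gapdh	functional	0.5
Glud1	Abat	functional	0.7
Glud1	Cps1	functional	0.65
Glud1	Ass1	functional	0.6
Abat	Aldh6a1	functional	0.6
Pah	Fah	functional	0.7
Fah	Ass1	functional	0.45
Aldh6a1	Cps1	functional	0.5
Aldh6a1	Echs1	functional	0.5
Tkt	Hsd17b10	functional	0.6
Tkt	Acaa2	functional	0.6
Tkt	Aldob	functional	0.6
Tkt	Pgk1	functional	0.6
Tkt	Gapdh	functional	0.6
Tkt	Tpi1	functional	0.6
Tkt	Gk	functional	0.6
Tkt	Pc	functional	0.6
Tkt	Glud1	functional	0.6
Tkt	Mdh1	functional	0.6
Tkt	Cat	functional	0.6
Tkt	Gstm2	functional	0.6
Cat	Prdx6	physical	0.8
Cat	Gstm2	functional	0.6
Prdx6	Gstm2	functional	0.6
Cat	Mdh1	functional	0.45
Mdh1	Pc	functional	0.7
Mdh1	Glud1	functional	0.5
Mdh1	Gapdh	functional	0.5
Acadl	Aldh6a1	functional	0.55
Acaa2	Pc	functional	0.45
Otc	Glud1	functional	0.5
Pah	Glud1	functional	0.45
Fah	Aldob	functional	0.4
Prdx6	Tpi1	functional	0.25
Gstm2	Aldob	functional	0.2
Abat	Pgk1	functional	0.15
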