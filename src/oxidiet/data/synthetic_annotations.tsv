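# Synthetic protein-annotation fixture: term assignments CONSTRUCTED to the
# published aggregate facet proportions of the carbonylated-protein list
# (cellular component: mitochondrion 28.6%, cytoplasm 57.1%; molecular
# function: catalytic 75.0%, oxidoreductase 45%, transferase 25%, hydrolase
# 10%, ligase 7.5%; biological process: metabolic ~46%). Not retrieved from
# PANTHER; per-protein assignments are NOT authoritative.
gene	uniprot	cellular_component	molecular_function	protein_class	biological_process
Cps1	P07756	mitochondrion	catalytic activity;hydrolase;ligase	metabolite interconversion enzyme	metabolic process;cellular amino acid metabolic process
Pc	P52873	mitochondrion	catalytic activity;ligase	metabolite interconversion enzyme	cellular homeostasis
Dmgdh	Q63342	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	
Alb	P02770	extracellular region	binding;transporter activity		transport
Tkt	P50137	cytoplasm	catalytic activity;oxidoreductase;transferase	oxidoreductase	metabolic process
Cat	P04762	peroxisome	catalytic activity;oxidoreductase	oxidoreductase	response to oxidative stress
Pdia3	P11598	endoplasmic reticulum	binding		cell redox homeostasis
Hspd1	P63039	mitochondrion	binding		protein folding
Gk	Q63060	cytoplasm	catalytic activity;transferase	transferase	metabolic process
Ftcd	O88618		catalytic activity;transferase;hydrolase	transferase	
Aldh2	P11884	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	response to stress
Pah	P04176	cytoplasm	binding		metabolic process;cellular amino acid metabolic process
Aldh6a1	Q02253	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	
Dld	Q6P6R2	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	cellular homeostasis
Aldh7a1	Q64057	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	response to stress
Glud1	P10860	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	metabolic process;cellular amino acid metabolic process
Abat	P50554		catalytic activity;transferase	transferase	metabolic process;cellular amino acid metabolic process
Hmgcs2	P22791		catalytic activity;transferase	transferase	metabolic process;lipid metabolic process
Pgd	P85968	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	metabolic process
Actb	P60711	cytoplasm	structural molecule activity		cell motility
Idh1	P41562	cytoplasm	binding		response to stress
Upb1	Q03248		catalytic activity;hydrolase	metabolite interconversion enzyme	metabolic process
Acadl	P15650		catalytic activity;oxidoreductase	oxidoreductase	metabolic process;lipid metabolic process
Fah	P25093	cytoplasm	binding		metabolic process;cellular amino acid metabolic process
Ass1	P09034	cytoplasm	catalytic activity;ligase	metabolite interconversion enzyme	metabolic process;cellular amino acid metabolic process
Pgk1	P16617	cytoplasm	catalytic activity;transferase	transferase	metabolic process;carbohydrate metabolic process
Acaa2	P13437	mitochondrion	catalytic activity;transferase	transferase	metabolic process;lipid metabolic process
Adh1	P06757	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	response to stress
Aldob	P00884	cytoplasm	binding		metabolic process;carbohydrate metabolic process
Akr1d1	P31210		catalytic activity;oxidoreductase	oxidoreductase	response to oxidative stress
Otc	P00481		catalytic activity;transferase	transferase	metabolic process;cellular amino acid metabolic process
Rgn	Q03336	cytoplasm	catalytic activity;hydrolase	metabolite interconversion enzyme	calcium ion homeostasis
Gapdh	P04797	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	metabolic process;carbohydrate metabolic process
Tst	P24329		catalytic activity;transferase	transferase	sulfur compound transport
Mdh1	O88989	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	metabolic process
Haao	P46953	cytoplasm	catalytic activity;oxidoreductase	oxidoreductase	cellular homeostasis
Nit2	Q497B0	cytoplasm	binding		cellular homeostasis
Ca3	P14141	cytoplasm	binding		response to oxidative stress
Gstm2	P08010	cytoplasm	catalytic activity;oxidoreductase;transferase	oxidoreductase	cellular detoxification
Hsd17b10	O70351	mitochondrion	catalytic activity;oxidoreductase	oxidoreductase	
Prdx6	O35244	lysosome	catalytic activity;oxidoreductase	oxidoreductase	response to oxidative stress
Gstm1	P04905	cytoplasm	catalytic activity;oxidoreductase;transferase	oxidoreductase	cellular detoxification
Tpi1	P48500		binding		response to stress
Echs1	P14604				metabolic process;lipid metabolic process
Park7	O88767	nucleus			response to oxidative stress
Abhd14b	Q5XI64				
Hgd	P97519		catalytic activity;oxidoreductase	oxidoreductase	
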