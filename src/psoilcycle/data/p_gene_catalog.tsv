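gene_symbol	ko_ids	category	product	system_group
phoR	K07636	starvation_regulation	two-component sensor histidine kinase PhoR	none
phoB	K07657	starvation_regulation	two-component response regulator PhoB	none
phoU	K02039	starvation_regulation	phosphate transport system regulatory protein PhoU	none
gcd	K00117	solubilization_mineralization	quinoprotein glucose dehydrogenase (PQQGDH)	none
phoA	K01077	solubilization_mineralization	alkaline phosphatase	none
phoD	K01113	solubilization_mineralization	alkaline phosphatase D	none
phoN	K09474	solubilization_mineralization	acid phosphatase (class A)	none
aphA	K03788	solubilization_mineralization	acid phosphatase (class B)	none
appA	K01093	solubilization_mineralization	4-phytase / acid phosphatase	none
ppa	K01507	solubilization_mineralization	inorganic pyrophosphatase	none
ppx	K01524	solubilization_mineralization	exopolyphosphatase	none
opd	K07048	solubilization_mineralization	phosphotriesterase	none
ugpQ	K01126	solubilization_mineralization	glycerophosphoryl diester phosphodiesterase (cytoplasmic, GDP)	none
glpQ	K01565	solubilization_mineralization	glycerophosphoryl diester phosphodiesterase (periplasmic, GDP)	none
phnW	K03430	solubilization_mineralization	2-aminoethylphosphonate-pyruvate transaminase (2APT)	none
phnX	K05306	solubilization_mineralization	phosphonoacetaldehyde hydrolase	none
phnA	K19670	solubilization_mineralization	phosphonoacetate hydrolase	none
phnF	K02043	solubilization_mineralization	C-P lyase operon transcriptional regulator PhnF	cp_lyase_subunit
phnG	K06166	solubilization_mineralization	C-P lyase subunit PhnG	cp_lyase_subunit
phnH	K06165	solubilization_mineralization	C-P lyase subunit PhnH	cp_lyase_subunit
phnI	K06164	solubilization_mineralization	C-P lyase subunit PhnI	cp_lyase_subunit
phnJ	K06163	solubilization_mineralization	C-P lyase subunit PhnJ	cp_lyase_subunit
phnK	K05781	solubilization_mineralization	C-P lyase subunit PhnK	cp_lyase_subunit
phnL	K05780	solubilization_mineralization	C-P lyase subunit PhnL	cp_lyase_subunit
phnM	K06162	solubilization_mineralization	C-P lyase subunit PhnM	cp_lyase_subunit
phnN	K05774	solubilization_mineralization	C-P lyase subunit PhnN	cp_lyase_subunit
phnO	K09994	solubilization_mineralization	C-P lyase subunit PhnO	cp_lyase_subunit
phnP	K06167	solubilization_mineralization	C-P lyase subunit PhnP	cp_lyase_subunit
pit	K03306	uptake_transport	low-affinity inorganic phosphate transporter Pit	none
pstS	K02040	uptake_transport	phosphate ABC transporter substrate-binding protein PstS	pst_transporter
pstC	K02037	uptake_transport	phosphate ABC transporter permease PstC	pst_transporter
pstA	K02038	uptake_transport	phosphate ABC transporter permease PstA	pst_transporter
pstB	K02036	uptake_transport	phosphate ABC transporter ATP-binding protein PstB	pst_transporter
ugpB	K05813	uptake_transport	sn-glycerol 3-phosphate ABC transporter substrate-binding protein UgpB	ugp_transporter
ugpA	K05814	uptake_transport	sn-glycerol 3-phosphate ABC transporter permease UgpA	ugp_transporter
ugpE	K05815	uptake_transport	sn-glycerol 3-phosphate ABC transporter permease UgpE	ugp_transporter
ugpC	K05816	uptake_transport	sn-glycerol 3-phosphate ABC transporter ATP-binding protein UgpC	ugp_transporter
phnC	K02041	uptake_transport	phosphonate ABC transporter ATP-binding protein PhnC	phn_transporter
phnD	K02044	uptake_transport	phosphonate ABC transporter substrate-binding protein PhnD	phn_transporter
phnE	K02042	uptake_transport	phosphonate ABC transporter permease PhnE	phn_transporter
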