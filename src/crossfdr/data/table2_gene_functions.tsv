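gene	full_name	function
AGBL2	AGBL carboxypeptidase 2	Catalyzes the deglutamylation of polyglutamate side chains generated by post-translational polyglutamylation in proteins
CELF1	CUGBP Elav-like family member 1	Pre-mRNA alternative splicing, mRNA translation and stability
FAM180B	Family with sequence similarity 180 member B	Enables protein binding
MTCH2	Mitochondrial carrier 2	Induces mitochondrial depolarization
MYBPC3	Myosin binding protein C3	Modifies the activity of actin-activated myosin ATPase
NDUFS3	NADH:ubiquinone oxidoreductase core subunit S3	Core subunit of the mitochondrial membrane respiratory chain NADH dehydrogenase (Complex I)
PSMC3	Proteasome 26S subunit, ATPase 3	Maintenance of protein homeostasis by removing misfolded or damaged proteins
PTPMT1	Protein tyrosine phosphatase mitochondrial 1	Prevent intrinsic apoptosis, probably by regulating mitochondrial membrane integrity
RAPSN	Receptor associated protein of the synapse	Postsynaptic protein required for clustering of nicotinic acetylcholine receptors (nAChRs) at the neuromuscular junction
SLC39A13	Solute carrier family 39 member 13	Transmembrane protein functions as a zinc transporter
SPI1	Spi-1 proto-oncogene	Transcriptional activator that may be specifically involved in the differentiation or activation of macrophages or B-cells
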