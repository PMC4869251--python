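# Bundled reference-repeat bank: direct-repeat sequences recalled from the
# CRISPR literature, in validated 5'->3' orientation.  This is a small,
# documented approximation of a full curated bank; supply your own TSV via
# --repeat-bank for production use.
# columns: sequence	family	cas_type	source
GTGTTCCCCGCGCCAGCGGGGATAAACCG	Ecoli-IE	I-E	E. coli K-12 CRISPR 2.1/2.3
GTGTTCCCCACGCCTGTGGGGATGAACCG	Senterica-IE	I-E	Salmonella enterica
GTTCACTGCCGTATAGGCAGCTAAGAAA	Paeruginosa-IF	I-F	Pseudomonas aeruginosa
GTTCACTGCCGTACAGGCAGCTTAGAAA	Ypestis-IF	I-F	Yersinia pestis
GTTTTAGAGCTATGCTGTTTTGAATGGTCCCAAAAC	Spyogenes-IIA	II-A	Streptococcus pyogenes
GTTTTTGTACTCTCAAGATTTAAGTAACTGTACAAC	Sthermophilus-IIA	II-A	S. thermophilus CRISPR1
GTTTTAGTACTCTGTAATTTTAGGTATGAGGTAGAC	Saureus-IIA	II-A	Staphylococcus aureus
GATCGATACCCACCCCGAAGAAAAGGGGACGAGAAC	Sepidermidis-IIIA	III-A	Staphylococcus epidermidis
GTTTCCGTCCCCTCTCGGGGTTTTGGGTCTGACGAC	Mtuberculosis-IIIA	III-A	M. tuberculosis spoligotype DR
GTCTAAGAACTTTAAATAATTTCTACTGTTGTAGAT	Fnovicida-VA	V-A	Francisella novicida Cas12a
GTTCCAATAAGACTAAAATAGAATTGAAAG	Pfuriosus-IB	I-B	Pyrococcus furiosus
GATTAATCCCAAAAGGAATTGAAAG	Ssolfataricus-IA	I-A	Sulfolobus solfataricus
GTTGCAAGGGATTGAGCCCCGTAAGGGGATTGCGAC	Mruminantium-IB	I-B	Methanobrevibacter ruminantium
GAAGTGGTACCGTTATCAGTCCCATTGAAAC	Hvolcanii-IB	I-B	Haloferax volcanii
CGGTTCATCCCCGCGGGAGCGGGGATAAGCC	Mjannaschii-IB	I-B	Methanocaldococcus jannaschii
GTCGCGCCCCGCACGGGCGCGTGGATTGAAAC	Csakazakii-IE	I-E	Cronobacter sakazakii
GTCGCACTCTACATGAGTGCGTGGATTGAAAT	Lpneumophila-IC	I-C	Legionella pneumophila
GTCGCGTCCTCACGGGCGCGTGGATTGAAAC	Bhalodurans-IC	I-C	Bacillus halodurans
GTTGTGGTTTGATTACCTATTAGTTTTGAAAC	Wvirosa-IIC	II-C	Weeksella virosa
GTTGTAGCTCCCTTTCTCATTTCGCAGTGCTACAAT	Nmeningitidis-IIC	II-C	Neisseria meningitidis
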