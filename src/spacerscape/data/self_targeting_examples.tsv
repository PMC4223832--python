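strain	gene	spacer	chromosomal_region
S. arenicola CNH-964/CNP-105	Adenylosuccinate lyase	GCCCACCTTGCCGTGCCACCACGCCTCCCGCACCTCGTTG	TGCTGCTGCCCACCTTGCCGTGCCACCACGCCTCCCGCACCTCGTTGAACTCCG
S. arenicola CNH-964/CNP-105	23S rRNA methyltransferase	CCGAGCGGGTCGAGCTGACCGTCGGGGCGGTGGCCCCGGG	GCGGAGGCCGAGCGGGTCGAGCTGACCGTCGGGGCGGTGGCCCCGGGCGGGCAC
S. arenicola CNX-481	Cytochrome P450	TACCGACGCAGCCATAACTCGTGCTAGGACGGCTGATGGC	TACCGACGCAGCCATAACTCGTGCTAGGACGGTGCCCGCG
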