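term	impact
transcript_ablation	high
splice_acceptor_variant	high
splice_donor_variant	high
stop_gained	high
frameshift_variant	high
stop_lost	high
start_lost	high
transcript_amplification	high
feature_elongation	high
feature_truncation	high
inframe_insertion	moderate
inframe_deletion	moderate
missense_variant	moderate
protein_altering_variant	moderate
splice_donor_5th_base_variant	low
splice_region_variant	low
splice_donor_region_variant	low
splice_polypyrimidine_tract_variant	low
incomplete_terminal_codon_variant	low
start_retained_variant	low
stop_retained_variant	low
synonymous_variant	low
coding_sequence_variant	modifier
mature_miRNA_variant	modifier
5_prime_UTR_variant	modifier
3_prime_UTR_variant	modifier
non_coding_transcript_exon_variant	modifier
intron_variant	modifier
NMD_transcript_variant	modifier
non_coding_transcript_variant	modifier
coding_transcript_variant	modifier
upstream_gene_variant	modifier
downstream_gene_variant	modifier
TFBS_ablation	modifier
TFBS_amplification	modifier
TF_binding_site_variant	modifier
regulatory_region_ablation	modifier
regulatory_region_amplification	modifier
regulatory_region_variant	modifier
intergenic_variant	modifier
sequence_variant	modifier
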