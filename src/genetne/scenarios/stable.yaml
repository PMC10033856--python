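# Demographically stable, diverse population dominated by clonal
# replication (sexual:clonal recruitment near 1:200).  Final census on
# the order of 500 ramets carried by ~60 genets.
name: stable
founder_size: 60
clonality_rate: 0.995
growth_rate: 0.2
flowering_fraction: 0.5
selfing_rate: 0.02
n_years: 40
ancestral_ne: 200
n_generations: 20
n_loci_ssr: 11
n_loci_snp: 200
ssr_repeat_length: 2
ssr_mutation_rate: 0.0005
missing_rate: 0.005
scoring_error_rate: 0.0
seed: 1
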