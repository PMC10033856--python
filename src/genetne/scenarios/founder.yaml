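# Founder-bottlenecked, expanding population: few founding genets,
# abundant sexual recruitment, final census on the order of 600 ramets
# across ~170 genets.
name: founder
founder_size: 6
clonality_rate: 0.55
growth_rate: 0.25
flowering_fraction: 0.5
selfing_rate: 0.02
n_years: 60
ancestral_ne: 200
n_generations: 20
n_loci_ssr: 11
n_loci_snp: 200
ssr_repeat_length: 2
ssr_mutation_rate: 0.0005
missing_rate: 0.005
scoring_error_rate: 0.0
seed: 2
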