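# Tiny configuration for quick demos and tests.
seed: 0
n_scanners: 3
n_sites: 2
n_core_parameter_tuples: 30
synonym_noise_rate: 0.3
site_specific_sequence_rate: 0.2
protocols_per_scanner: 12
regions:
  spine:
    n_protocols: 4
    n_exams: 60
    code_vocabulary_size: 20
    cardinality_distribution: {1: 0.9, 2: 0.1}
    protocol_frequency_range: [6, 30]
    planted_overlaps:
      - [TOY/A, TOY/B, 0.5]
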