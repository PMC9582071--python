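# Study-scale synthetic configuration.
#
# Spine: 727 exams over 12 protocols (frequencies 6-341), 127-code
# vocabulary, cardinality mean 1.1; two planted overlaps mirror the
# cervical (0.5) and lumbar (1/6, printing as 0.17) protocol pairs.
# Brain/head: 249 exams, 98 codes, cardinality mean 1.2.
# Trees: 3 scanners on 2 sites, 200 shared core parameter tuples.
seed: 0
n_scanners: 3
n_sites: 2
n_core_parameter_tuples: 200
synonym_noise_rate: 0.15
site_specific_sequence_rate: 0.15
protocols_per_scanner: 100
regions:
  spine:
    n_protocols: 12
    n_exams: 727
    code_vocabulary_size: 127
    cardinality_distribution: {1: 0.9, 2: 0.1}
    protocol_frequency_range: [6, 341]
    planted_overlaps:
      - [CERVICAL/WITHOUT, CERVICAL/POST OP METAL, 0.5]
      - [LUMBAR/WITHOUT, LUMBAR/LUMBAR METAL, 0.16666666666666666]
  brain/head:
    n_protocols: 10
    n_exams: 249
    code_vocabulary_size: 98
    cardinality_distribution: {1: 0.8, 2: 0.2}
    protocol_frequency_range: [6, 42]
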