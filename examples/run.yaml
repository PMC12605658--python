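simulation: {n_exposed: 400, n_control_pool: 1200, n_waves: 8}
outcomes: [memory_z]
candidate_terms: [post2]
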