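# Truncation study parameter set (same problem as colonization_success).
growth: {kind: exponential, L0: 1.0, alpha: 0.1}
lineage: {k: [0.1, 0.2, 0.3, 0.0], m: 2}
D: 1.0e-2
initial_condition: {kind: block, C0: 1.0, gamma: 0.2}
method: series
terms: 1000
times: [20]
grid: {kind: xi, points: 201}
output: {dir: out/truncation}
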