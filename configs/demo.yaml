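# Small end-to-end demonstration pipeline (mirrors pipeline.demo_config()).
# Run with:  myoturnover run --config configs/demo.yaml --out results/demo
seed: 0
out_dir: results/demo
frap_n_traces: 3
photoconversion_n_fibrils: 2
photoconversion_duration_min: 120.0
pulse_chase_times_min: [15.0]
pulse_chase_n_sarcomeres: 24
pulse_chase_n_myotubes: 3
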