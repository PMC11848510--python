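"""Compare ADCR with least-cost-path SCR and basic SCR on simulated movement.

Runs a reduced version of the simulation experiment (two iterations on a
28 x 28 grid): each iteration simulates movement-based capture data, fits all
three estimators, and scores density recovery plus the overlap between true
and predicted home ranges.
"""
from adcr.experiments import baseline_config, run_experiment, summarize_report

cfg = baseline_config(
    "desk", n_iterations=2, nx=28, ny=28, patch_area_range=(31, 78),
    det_lo=4, det_hi=24, det_spacing=4, T=1500, overlap_stride=3,
    master_seed=11, fit_options={"compute_se": True})

table = run_experiment(cfg)
print(summarize_report(table, cfg))
print("ADCR's overlap with the true home ranges should exceed both SCR")
print("variants, while all three recover log density comparably well.")
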