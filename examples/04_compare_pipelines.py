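"""Benchmark several named pipelines on one simulated mock community.

Runs length-trimmed merge-only (LMp), merge-plus-concatenate (LBp) and
concatenate-all (LCs) over a mixed-length amplicon library - some
amplicons overlap, some do not - and prints the genus-level metrics.
"""

from concatseq import (BenchmarkInput, PipelineConfig, SimConfig,
                       compare_pipelines, simulate_mock)

config = SimConfig(n_genera=8, n_pairs=4000, amplicon_length=(200, 540),
                   read_length=250, seed=19)
truth, reads = simulate_mock(config)

dataset = BenchmarkInput(name="mixed", pairs=reads.pairs,
                         mock=truth.to_mock_composition(), truth=truth)
frame = compare_pipelines(
    ["LMp", "LBp", "LCs"], [dataset], thresholds=[0.0, 0.0001],
    config=PipelineConfig(fwd_primer=config.fwd_primer,
                          rev_primer=config.rev_primer))
print(frame.to_string(index=False))
print("\nGenera on amplicons longer than 2*read_length - 20 are invisible to"
      " LMp but recovered by LBp and LCs, so the concatenating pipelines"
      " post equal or higher recall and F-measure.")
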