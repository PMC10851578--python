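"""Detect understory saplings end-to-end and score them against truth.

Runs the full workflow on a synthetic stand: fine normalization (true/pseudo
ground), stratification at 5 m, overstory removal with 1.5 x DBH trunk
buffers, isolated-point denoising, the 0.05 m sapling CHM, and
adaptive-bandwidth mean shift.  Prints the detection/matching/commission
rates and the height accuracy of the matched saplings.
"""

from understory import RunConfig, StandConfig, generate_stand, run_on_stand

stand = generate_stand(
    StandConfig(extent_m=(25.0, 25.0), canopy_closure_target=0.3, rng_seed=5)
)
result = run_on_stand(stand, RunConfig(rng_seed=0), output_dir="sapling_run")

print(f"mature trees removed: {result.counts.get('mature_trees', 0)}")
print(f"saplings detected:    {len(result.sapling_table)}")
print(result.report.summary())
# A detection rate slightly above 100% with high matching means nearly every
# planted sapling was found with few spurious extras; the height RMSE is
# dominated by the terminal leader shoot the scanner cannot see (~0.1 m).
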