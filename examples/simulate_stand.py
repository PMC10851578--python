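"""Generate a labeled two-layer stand and write its point cloud + inventory.

The generator emulates a planted stand: a gridded conifer overstory with a
target canopy closure, understory saplings on a 3 m planting grid, grass
clutter and gentle terrain.  Every point carries a truth label, so the file
pair is a complete test bed for the segmentation pipeline.
"""

from understory import StandConfig, generate_stand
from understory.io import write_inventory, write_points

config = StandConfig(
    extent_m=(30.0, 30.0),
    canopy_closure_target=0.4,
    point_density=120.0,  # pts/m^2
    rng_seed=1,
)
stand = generate_stand(config)

write_points(stand.cloud, "stand_points.csv")
write_inventory(stand.inventory, "stand_truth.csv")

n_over = (stand.inventory["layer"] == "overstory").sum()
n_sap = (stand.inventory["layer"] == "sapling").sum()
print(f"points:            {len(stand.cloud)}")
print(f"overstory trees:   {n_over}")
print(f"saplings:          {n_sap}")
print(f"achieved closure:  {stand.closure:.2f} (target {config.canopy_closure_target})")
# The closure is the fraction of 0.5 m cells whose canopy height exceeds 5 m;
# it controls how much laser light reaches the saplings below.
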