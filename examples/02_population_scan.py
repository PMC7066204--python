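"""Population dependence of self-generated chemotaxis.

The key collective parameter is the total degradation capacity (cell count
x per-cell Vmax).  At a saturating background (10 uM) small populations
cannot metabolize the attractant flux, so their response collapses; at a
lower background (500 nM) the same small populations do fine.  Prints the
response score per population at both backgrounds.
"""

from sggrad import build_population_scan, run_scenario
from sggrad.assays import total_vmax

POPULATIONS = [12, 50, 200]

for background in (10_000.0, 500.0):
    print(f"\nbackground {background/1000:g} uM:")
    for spec in build_population_scan(background, POPULATIONS, base_seed=3):
        _, score = run_scenario(spec)
        print(
            f"  n = {spec.cell_init.count:3d}  "
            f"(total Vmax {total_vmax(spec):.2g} nM um^2/min): "
            f"response score = {score.response_score:.2f}"
        )

print(
    "\nAt 10 uM the smallest population collapses; at 500 nM the same"
    "\npopulation is rescued because less attractant must be degraded."
)
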