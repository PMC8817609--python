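"""Simulate one stenosed synthetic LAD and read off the wave-free index.

Builds a ~120 mm left-anterior-descending-like vessel with a 60% diameter
stenosis at 45 mm, solves the resting and hyperemic pressure fields, and
prints the computed index at the conventional sensor position 30 mm distal
to the throat.
"""

from ctifr import BoundaryConditions, TreeParams, compute_index, \
    generate_synthetic_tree

tree = generate_synthetic_tree(
    TreeParams(stenoses=((45.0, 12.0, 60.0),)), seed=7)
bc = BoundaryConditions(Pa_diastolic=80.0, LV_mass=60.0)  # LAD-subtended mass
result, solution = compute_index(tree, bc)

print(f"measured anatomic severity : {result.ds_percent:5.1f} % DS")
print(f"wave-free index (resting)  : {result.accuifrct:6.4f} "
      f"-> significant (<= 0.89): {result.significant}")
print(f"FFR surrogate (hyperemic)  : {result.ffr_surrogate:6.4f} "
      f"-> significant (<= 0.80): {result.ffr_significant}")
print(f"sensor position            : {result.measurement_arclength:5.1f} mm "
      "from the vessel inlet")
# The resting index stays higher than the hyperemic surrogate because
# pressure losses grow with flow; both fall as the stenosis tightens.
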