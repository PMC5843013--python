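"""Collapse the 16 joint classes into 4 composite clinical groups.

Starting from the published joint class table, the deterministic collapse
yields the headline epidemiological quantities: the four composite-group
shares, the split of soilers into with/without constipation, and the
overall constipation prevalence.
"""

from trajlca import (
    any_constipation_prevalence,
    composite_proportions,
    soiler_split,
)
from trajlca.calibration import COMPOSITE_CLASS_NAMES, REPORTED_JOINT_PERCENT

shares = composite_proportions(REPORTED_JOINT_PERCENT)
print("Composite clinical groups (percent of children):")
for name, share in zip(COMPOSITE_CLASS_NAMES, shares):
    print(f"  {name:<26} {share:5.1f}")

alone, with_con = soiler_split(shares)
print(f"\nAmong soilers: {alone}% soiling alone, {with_con}% with constipation")
print(f"Any constipation: {any_constipation_prevalence(shares):.1f}%")
# From the published joint table this prints 74.5/13.2/7.5/4.8, a 61/39
# soiler split and 18.0% overall constipation -- soiling without
# constipation is the *more* common soiling presentation.
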