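"""Project a native-space abundance table into a common feature space.

Builds a tiny 3-sample profile in a profiler's native catalogue, maps it
through a weighted feature correspondence (with a summed pair, a split
feature and an unmapped feature) and prints the converted table together
with the per-sample losses.
"""

import pandas as pd

from profspace import AbundanceTable, FeatureMapping, project

native = AbundanceTable(pd.DataFrame(
    {
        "sample1": {"spA": 0.30, "spB": 0.20, "spC": 0.40, "spD": 0.10},
        "sample2": {"spA": 0.50, "spB": 0.10, "spC": 0.30, "spD": 0.10},
        "sample3": {"spA": 0.25, "spB": 0.25, "spC": 0.25, "spD": 0.25},
    }
), normalized=True)

# spA and spB collapse into the same common species, spC is ambiguous and
# split 50/50 between two common species, spD has no correspondence.
mapping = FeatureMapping([
    ("spA", "X", 1.0),
    ("spB", "X", 1.0),
    ("spC", "Y", 0.5),
    ("spC", "Z", 0.5),
])

result = project(native, mapping)
print("projected (columns re-closed to sum 1):")
print(result.projected.data.round(4))
print("\nlost abundance per sample (mass of unmapped features):")
print(result.lost_abundance.round(4).to_dict())
print("lost features per sample:", result.lost_features.to_dict())
# sample1 keeps 0.9 of its mass: X = (0.3+0.2)/0.9, Y = Z = 0.2/0.9.
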