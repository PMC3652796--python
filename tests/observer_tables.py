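"""Published per-observer cells of the bone-age observer study.

Three observers rated three sets of 160 hand radiographs each: shown raw
(Set 1), after GHE (Set 2), and after MBOBHE (Set 3).  DISCREPANCY holds the
average absolute error in years between deduced bone age and chronological
age; TIME the average assessment minutes per radiograph.  Columns split the
rating into carpal bones and RUS (radius, ulna, short bones).
"""

import pandas as pd

DISCREPANCY = pd.DataFrame(
    [
        ("Set 1", 1, 0.66, 0.43), ("Set 1", 2, 0.69, 0.58), ("Set 1", 3, 0.54, 0.49),
        ("Set 2", 1, 0.78, 0.65), ("Set 2", 2, 0.82, 0.72), ("Set 2", 3, 0.67, 0.62),
        ("Set 3", 1, 0.60, 0.44), ("Set 3", 2, 0.68, 0.56), ("Set 3", 3, 0.50, 0.48),
    ],
    columns=["set", "observer", "carpal", "rus"],
)

TIME = pd.DataFrame(
    [
        ("Set 1", 1, 3.43, 5.35), ("Set 1", 2, 3.41, 4.82), ("Set 1", 3, 3.49, 5.12),
        ("Set 2", 1, 3.22, 5.83), ("Set 2", 2, 3.27, 4.43), ("Set 2", 3, 3.21, 5.02),
        ("Set 3", 1, 2.21, 3.66), ("Set 3", 2, 2.58, 3.25), ("Set 3", 3, 2.24, 3.61),
    ],
    columns=["set", "observer", "carpal", "rus"],
)
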