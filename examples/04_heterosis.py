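"""Better-parent heterosis (heterobeltiosis) with direction-aware parents.

For days to heading the *earlier* parent is the better one, so a negative
percentage means the hybrid flowers earlier than both parents — the desirable
outcome.  Stars compare the F1-vs-better-parent gap against the LSD.
"""

import linetester as lt

means = lt.load_fixture("table3_means")
design = lt.RICE_DESIGN

for trait in ("GYPP", "DTH"):
    ms = lt.load_fixture("table2_ms")[(trait, "normal")]
    table = lt.heterosis_table(means, design, trait, "normal", ms.ms_error, ms.df_error)
    best = (
        table["heterobeltiosis"].idxmax()
        if lt.trait_direction(trait) == "higher_better"
        else table["heterobeltiosis"].idxmin()
    )
    row = table.loc[best]
    print(
        f"{trait}: best cross {best}: F1 {row['f1']:.2f} vs better parent "
        f"{row['better_parent']:.2f} -> {row['heterobeltiosis']:+.2f}% {row['stars']}"
    )
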