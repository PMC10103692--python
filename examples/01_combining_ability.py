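"""GCA and SCA effects from the packaged trial's cross means.

A parent's general combining ability (GCA) is the average deviation its
crosses show from the grand mean of all crosses; a cross's specific combining
ability (SCA) is what its mean does beyond its parents' GCAs.  Positive GCA
for relative water content marks a parent that transmits better water status
to its hybrids.
"""

import linetester as lt

means = lt.load_fixture("table3_means")
ms = lt.load_fixture("table2_ms")[("RWC", "normal")]

cross_means = means.cross_matrix("RWC", "normal")
gca, sca = lt.combining_ability(cross_means, ms.ms_error, ms.r, ms.df_error)

print("Grand mean of the 21 crosses (RWC %, normal):", round(gca.grand_mean, 2))
print("\nLine GCA effects (trait units; ** = significant at 1%):")
for parent, effect in gca.line_effects.items():
    print(f"  {parent:<10} {effect:+6.2f} {gca.line_stars[parent]}")
print("\nBest specific combination:")
best = sca.effects.stack().idxmax()
print(
    f"  {best[0]} x {best[1]}: SCA {sca.effects.loc[best]:+.2f}"
    f" {sca.stars.loc[best]}"
)
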