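"""Genetic variance components and heritabilities for one trait.

From the four mean squares of the line x tester analysis: sigma2_SCA =
(MS_LxT - MS_error)/r captures non-additive gene action, GCA variance the
additive part.  With fully inbred parents sigma2_A = 2*sigma2_GCA and
sigma2_D = sigma2_SCA; heritabilities express those as shares of the total.
"""

import linetester as lt

ms = lt.load_fixture("table2_ms")[("RWC", "normal")]
vc = lt.variance_components(ms)

print("sigma2_SCA           :", round(vc.sigma2_sca, 2))
print("sigma2_GCA (pooled)  :", round(vc.sigma2_gca, 2))
print("  from lines         :", round(vc.sigma2_gca_lines, 2))
print("  from testers       :", round(vc.sigma2_gca_testers, 2))
print("sigma2_A / sigma2_D  :", round(vc.sigma2_A, 2), "/", round(vc.sigma2_D, 2))
print("h2 broad / narrow (%):", round(vc.h2_broad, 1), "/", round(vc.h2_narrow, 1))
print(
    "contributions l/t/lxt:",
    round(vc.contrib_lines, 1),
    round(vc.contrib_testers, 1),
    round(vc.contrib_lxt, 1),
)
if vc.nonadditive_predominant:
    print("GCA:SCA ratio < 1 -> non-additive gene action predominates")
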