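"""ANOVA partition of genotype variation, rebuilt from published means.

The genotype sum of squares splits into parents, crosses and the 1-df
parents-vs-crosses contrast; the cross variation splits further into lines,
testers and their interaction.  Stars test each source against the pooled
RCBD error mean square.
"""

import linetester as lt

means = lt.load_fixture("table3_means")
ms = lt.load_fixture("table2_ms")[("RWC", "normal")]

table = lt.anova_from_means(
    means, lt.RICE_DESIGN, "RWC", "normal", ms.ms_error, ms.df_error
)
print(table[["source", "df", "ms", "F", "stars"]].round(2).to_string(index=False))
print(
    "\nLSD (5%) between two genotype means:",
    round(lt.lsd_genotype_means(ms.ms_error, 3, ms.df_error, 0.05), 2),
)
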