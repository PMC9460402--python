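"""Reproducibility assessment of Mw populations by one-way ANOVA.

Replicated Mw values measured at different temperatures should agree if the
method is temperature-independent: a p-value above 0.05 fails to reject equal
population means.  Works from raw replicates or from published (n, mean, sd)
summaries.
"""

import rheomwd as rm

# three replicate Mw values (g/mol) per test temperature for one sample
raw = {
    "23C": [6.6e5, 6.8e5, 6.7e5],
    "28C": [6.9e5, 6.7e5, 6.8e5],
    "32C": [6.7e5, 7.0e5, 6.8e5],
}
res = rm.one_way_anova(raw)
print(f"raw replicates: F = {res.f_statistic:.2f}, p = {res.p_value:.3f}")
print(" ", res.decision)

# the same analysis from summary statistics alone
import statistics

summaries = [(label, len(v), statistics.fmean(v), statistics.stdev(v))
             for label, v in raw.items()]
res2 = rm.anova_from_summaries(summaries)
print(f"from summaries: F = {res2.f_statistic:.2f}, p = {res2.p_value:.3f} "
      "(identical by construction)")
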