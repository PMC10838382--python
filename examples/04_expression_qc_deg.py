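"""Expression-screen QC and the fold/FDR DEG filter.

Generates triplicate counts for a parental/resistant pair with six
configured expression shifts (including a transporter gene up ~3000x
from near-silence), runs the four-statistic sample QC and the
differential-expression filter (moderated t, BH FDR < 0.05, >= 2-fold).
"""

from effluxkit import expression
from effluxkit.simulate import SyntheticTruth, gen_counts

counts, samples = gen_counts(SyntheticTruth(seed=0))
groups = samples.set_index("sample")["group"]
logexpr = expression.log_cpm(counts)

report = expression.outlier_stats(logexpr)
print("outlier flags:", report.flagged_samples or "none")
print(report.table[["sum_euclidean", "mean_pearson", "ks_stat"]].round(3))

table = expression.deg_filter(expression.two_group_test(logexpr, groups))
degs = table[table["is_deg"]].sort_values("fold_change", ascending=False)
print(f"\n{len(degs)} DEGs of {len(table)} genes; top by fold:")
print(degs[["fold_change", "q_value"]].head(6).round(4))
print("\nThe transporter gene tops the fold ranking, mirroring its role")
print("as the dominant up-regulation in acquired taxane resistance.")
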