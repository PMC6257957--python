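"""Call A/B compartments in both conditions and detect switching.

PC1 of the O/E correlation matrix gives the compartment signal; its sign
is oriented by expressed-gene density. A bin switches when its PC1 sign
flips between conditions AND its interaction pattern decorrelates
(R < 0.6). Switching should be biased toward compartment B.
"""

from hicsqueeze import (BASELINE, CONSTRICTED, ice_balance, make_truth,
                        observed_expected, simulate_de, simulate_map)
from hicsqueeze.compartments import (call_switches, compartment_profile,
                                     correlation_diff, correlation_matrix,
                                     switch_compartment_test)
from hicsqueeze.expression import active_bins

truth = make_truth(seed=1)
de = simulate_de(truth, seed=2)
activity = {c: v.astype(float) for c, v in active_bins(de, truth.binning).items()}

corrs, profiles = {}, {}
for k, cond in enumerate((BASELINE, CONSTRICTED)):
    bal = ice_balance(simulate_map(truth, cond, 3_000_000, seed=10 + k))
    corrs[cond] = correlation_matrix(observed_expected(bal))
    profiles[cond] = compartment_profile(corrs[cond], activity, truth.binning)

rdiff = correlation_diff(corrs[BASELINE], corrs[CONSTRICTED])
table = call_switches(profiles[BASELINE], profiles[CONSTRICTED], rdiff)
print("bin status counts:", table["status"].value_counts().to_dict())

res = switch_compartment_test(table, seed=3)
boot = res.aux["bootstrap"]
print(f"\nlogistic regression, switching ~ source compartment:")
print(f"  B coefficient (log odds) = {res.statistic:.2f}, p = {res.pvalue:.2g}")
for comp in ("A", "B"):
    r = boot[comp]
    print(f"  {comp}: switch rate {r['rate']:.1%} "
          f"(99% bootstrap CI {r['ci'][0]:.1%}-{r['ci'][1]:.1%}, n={r['n']})")
print("\nA positive B coefficient means B-compartment bins switch more often —")
print("the planted perturbation concentrates flips in heterochromatin.")
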