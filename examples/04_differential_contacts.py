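"""Call significant and differential contacts, then test where losses fall.

Contacts are counted in 100-kb windows on a 40-kb lattice; the universe
of significant contacts (Poisson vs a distance x coverage background,
FDR < 0.05) is compared between conditions with a conditional binomial
test (FDR < 0.1). The headline check: decreased short-range (< 1 Mb)
contacts are enriched in compartment B by a 10,000-rep bootstrap.
"""

from hicsqueeze import (BASELINE, CONSTRICTED, downsample_to_common_total,
                        make_truth, simulate_de, simulate_map)
from hicsqueeze.compartments import CompartmentProfile
from hicsqueeze.contacts import (annotate_contacts, bootstrap_proportions,
                                 call_significant, differential_contacts,
                                 pooled_windowed, range_proportion_test,
                                 window_counts)
from hicsqueeze.expression import active_bins
import numpy as np

truth = make_truth(seed=1)
maps = [simulate_map(truth, cond, 3_000_000, seed=40 + k, binsize=20_000)
        for k, cond in enumerate((BASELINE, CONSTRICTED))]
mb, mc = downsample_to_common_total(maps, seed=41)
wb, wc = window_counts(mb), window_counts(mc)

sig = call_significant(pooled_windowed(wb, wc))
diff = differential_contacts(wc, wb, sig)  # constricted vs baseline
print(f"{len(sig)} significant contacts; direction counts:",
      diff["direction"].value_counts().to_dict())

for cls, res in range_proportion_test(diff).items():
    print(f"  {cls}-range: {res.aux['decreased']} decreased vs "
          f"{res.aux['increased']} increased (p = {res.pvalue:.2g})")

# annotate with planted compartments + activity, then bootstrap B enrichment
binning = truth.binning
prof = CompartmentProfile(
    binning,
    {c: np.where(truth.labels[BASELINE][c] == "A", 1.0, -1.0) for c in binning.chroms},
    {c: truth.labels[BASELINE][c].copy() for c in binning.chroms},
    {c: 1.0 for c in binning.chroms}, {c: False for c in binning.chroms},
    {c: False for c in binning.chroms})
de = simulate_de(truth, seed=2)
act = active_bins(de, binning)
sig_ann = annotate_contacts(sig, prof, act)
dec = annotate_contacts(diff, prof, act).query("direction == 'decreased'")

boot = bootstrap_proportions(sig_ann, dec, seed=42)
print("\ndistance bin (Mb)   pool B-prop   decreased B-prop   99% CI      enriched")
for _, r in boot.iterrows():
    print(f"{r.edge_lo/1e6:5.2f}-{r.edge_hi/1e6:5.2f} {r.pool_b_prop:12.2f} "
          f"{r.obs_b_prop:15.2f}   [{r.ci_lo:.2f}, {r.ci_hi:.2f}]   "
          f"{'YES' if r.b_enriched else 'no'}")
print("\nShort-range (< 1 Mb) losses concentrate in B-B contacts — the planted")
print("constriction effect — while long-range bins stay inside the CI.")
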