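"""Call caste-biased genes per species and test their cross-species sharing.

One pooled sample per caste leaves no replication, so the exact test fixes the
NB dispersion at 0.1.  Cross-species sharing of the called genes is compared
against a permutation null that redraws equally sized random gene sets.
"""

import castekit as ck

cfg = ck.SimulationConfig(n_species=5, n_orthogroups=1500, toolkit_size=100,
                          effect_log2fc=1.5, lib_size=2_000_000, seed=17)
counts, ogmap, truth = ck.generate_dataset(cfg)
hm = ck.harmonize(counts, ogmap, mode="isoforms3_na2")

table = ck.de_table(hm, dispersion=0.1)
degs = ck.call_degs(table, rule="raw_p_0.05")
for sp, calls in degs.items():
    n_queen = int((calls == "queen").sum())
    print(f"{sp}: {len(calls):4d} caste-biased genes at raw p<0.05 "
          f"({n_queen} queen-biased, {len(calls) - n_queen} worker-biased)")

deg_sets = {sp: s.to_dict() for sp, s in degs.items()}
summary = ck.overlap_summary(deg_sets, hm.counts.index, n_perm=1000, seed=17,
                             same_direction=True)
print("\nk  observed  expected(mean+-sd)   Fisher p")
for k, row in summary.iterrows():
    print(f"{k}  {int(row['observed']):8d}  {row['expected_mean']:7.1f}+-{row['expected_sd']:<6.1f}"
          f"  {row['fisher_p']:.2e}")
print("\nGenes biased in the same direction in 4-5 species vastly exceed the")
print("permutation expectation: the planted shared toolkit is visible as")
print("non-random overlap, exactly the signature sought in real data.")

res = ck.hypergeom_overlap_counts(5536, 1420, 353, 35)
print(f"\nWorked example, two analysis routes compared on one dataset:")
print(f"  1,420 SVM predictors vs 353 caste-biased genes in a 5,536-gene universe")
print(f"  share only 35 genes: {res.fold:.2f}-fold under-enriched, "
      f"hypergeometric p = {res.hypergeom_p:.2e}")
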