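"""Generate a synthetic multi-species two-caste brain transcriptome dataset.

Nine wasp-like species, one pooled queen and one pooled worker RNA-seq sample
each, with a planted 150-gene caste toolkit shared by all species, species-
private caste genes, strong per-species expression offsets and NB count noise
at dispersion 0.1.  Everything downstream of this generator is testable
against the returned ground truth.
"""

from pathlib import Path

import castekit as ck

cfg = ck.SimulationConfig(seed=1)
counts, ogmap, truth = ck.generate_dataset(cfg)

out = Path("scratch/example_dataset")
ck.write_dataset(counts, ogmap, truth, out)

print(f"species:            {', '.join(counts.species)}")
print(f"orthogroups:        {len(ogmap)}")
print(f"planted toolkit:    {len(truth.toolkit_genes)} genes "
      f"(consistent queen/worker direction in every species)")
private = truth.table[(truth.table['direction'] != 'none') & ~truth.table['toolkit_member']]
print(f"private caste genes: {len(private)} (biased in exactly one species)")
libs = counts.library_sizes()
print(f"library sizes:      {libs.min()}..{libs.max()} reads "
      f"(target {cfg.lib_size:,}; NB noise at dispersion {cfg.dispersion})")
print(f"files written under {out}/ (per-species count TSVs, Orthogroups.tsv, truth.json)")
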