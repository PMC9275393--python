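# clsig

Detection and characterization of **CLL-like stereotyped immunoglobulin
rearrangements (CLS-IG)** in phenotypically sorted B-cell repertoires.

About 40% of chronic lymphocytic leukemia (CLL) clones carry quasi-identical
("stereotyped") B-cell receptors, grouped into subsets by shared VH CDR3
features. The same rearrangements occur at very low frequency in healthy
repertoires as part of the public repertoire. `clsig` provides the full
computational path for finding and characterizing them in UMI-tagged IGH
amplicon data from B cells sorted by donor × CD5 × light chain (IGκ/IGλ) ×
B-cell subset (TR, N, MZ, MO, SM, DN):

1. **preprocess** — group reads by UMI within each sorted fraction and build
   plurality consensus sequences; only consensuses from ≥2 reads without N
   pass the quality filter.
2. **annotate** — call V/J germline genes by overlap alignment, quantify
   V-region somatic mutation (M ≥ 2% > U over FR1–FR3 through the 2nd-CYS),
   extract the codon-104→118 junction, and decide productivity. I/O uses AIRR
   Rearrangement TSV, which is also an alternative pipeline entry point.
3. **clonotype** — collapse to clonotypes (identical amino-acid CDR3, same
   IGHV and IGHJ gene, per donor) and pick one representative each.
4. **stereotypy** — assign clonotypes to stereotyped subsets: core-feature
   prefilter (clan, mutational status, CDR3 length), then ≥50% CDR3 identity,
   ≥70% physicochemical similarity and an anchored motif against reference
   CDR3s, graded on a borderline < average < good < excellent confidence
   scale (CLS-IG = assigned at "average" or higher). Includes
   reverse-mutational-status chimera analysis (rCLS-IG) and typical /
   non-typical IGHV classification.
5. **cohort** — per-donor stratified frequencies (a frequency needs ≥2 CLS-IG
   to be informative), exact paired Wilcoxon tests (≥3 complete donor pairs),
   exact binomial tests against reference proportions, Bonferroni families.
6. **simulate** — a seeded synthetic cohort generator (germline-derived
   V(D)J molecules, per-stratum mutation composition, stereotype spike-ins at
   known frequencies, UMI-tagged reads with sequencing error) with full truth
   tables, so every stage is testable without any download.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a nine-donor sorted cohort (24 fractions per donor, realistic
compartment sizes) with stereotype spike-ins at equal rates *within* each
mutational status — 0.15% of unmutated and 0.02% of mutated molecules — and a
CD5+ compartment skewed toward unmutated rearrangements, then run the
pipeline:

```python
import numpy as np
from clsig.reference import AnalysisParameters, default_clan_table
from clsig.simulate import (SimulationConfig, SpikePlan, DEFAULT_B_SUBSET_WEIGHTS,
                            simulate_cohort_frame)
from clsig.clonotype import cluster_frame
from clsig.stereotypy import (ResidueClassTable, assign_frame,
                              load_subset_definitions, synthetic_subsets_path)
from clsig.cohort import paired_wilcoxon, stratify

clans = default_clan_table()
defs = load_subset_definitions(synthetic_subsets_path(), clans)
params = AnalysisParameters()

cfg = SimulationConfig(
    seed=42, n_donors=9, molecules_per_fraction=2000,
    b_subset_weights=DEFAULT_B_SUBSET_WEIGHTS,
    spikes=(SpikePlan("T01", 0.0015, "status"),   # U-core subset
            SpikePlan("T02", 0.0002, "status")),  # M-core subset
)
rearr = simulate_cohort_frame(cfg, defs)
clono = cluster_frame(rearr)
clono["mut_status"] = np.where(clono["v_mutation_pct"] >= 2.0, "M", "U")
assigned = assign_frame(clono, defs, clans, ResidueClassTable(), params)

bulk = stratify(assigned, ["cd5"], params)
pos = bulk[bulk.cd5 == "POS"].set_index("donor_id")["freq_pct"]
neg = bulk[bulk.cd5 == "NEG"].set_index("donor_id")["freq_pct"]
test = paired_wilcoxon(pos, neg, params)
```

Output:

```
clonotypes: 431,994   CLS-IG: 449 (0.104%)
bulk CD5+ median 0.129% vs CD5- 0.083%  (paired Wilcoxon p = 0.0078 **)
within U: CD5+ 0.156% vs CD5- 0.160%  (p = 1.000 ns)
within M: CD5+ 0.048% vs CD5- 0.030%  (NOT_COMPUTED)
```

Reading it: in bulk, CD5+ B cells look significantly enriched in CLS-IG —
yet within each mutational status the frequencies are statistically
indistinguishable (the sparse mutated CD5+ strata fail the ≥2-CLS-IG /
≥3-donor gates and are reported as NOT_COMPUTED rather than imputed). The
bulk enrichment is an emergent consequence of CD5+ cells carrying more
unmutated rearrangements, which is exactly how the cohort was simulated.

The same stages are available as a CLI (`clsig simulate | preprocess |
annotate | clonotype | assign | rcls-scan | analyze | run`), driven by a YAML
config with a run manifest recording versions, seeds, digests and per-stage
counts.

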