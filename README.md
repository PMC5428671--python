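# nicheoverlap

Spatial niche-overlap and co-occurrence analysis for species × site
community matrices: the Pianka overlap index with RA1–RA4 Monte-Carlo
null-model tests, the Stone–Roberts C-score as a descriptive segregation
statistic, and mixed-design repeated-measures comparisons of overlap
values across sampling years — plus a synthetic community generator so
the entire pipeline runs and is testable without any external data.

The package targets community ecologists asking whether co-occurring
species use space (or any discrete resource axis) more or less similarly
than chance expects, and how that structure shifts between surveys —
for example groundwater-fed spring invertebrate communities sampled
before and after a major hydrological disturbance, where obligate
groundwater specialists (stygobites) and surface-water species
(non-stygobites) may be forced into closer spatial overlap.

## The statistics

**Pianka overlap.** For species *j*, *k* with utilization proportions
*p·j*, *p·k* over *n* resource states (each species' abundance row
normalized to sum 1),

    O_jk = Σᵢ p_ij p_ik / √(Σᵢ p_ij² · Σᵢ p_ik²)

symmetric and bounded in [0, 1]: 0 for disjoint resource use, 1 for
proportional profiles. Per-species means *O_sp* average a species' O
values over all partners; the assemblage mean averages all C(S, 2)
pairs.

**Null models.** Observed mean overlap is compared with the means of
simulated null assemblages built by randomizing each species' utilization
row: RA1 (replace all entries with uniform draws), RA2 (replace only
nonzero entries, retaining the zero structure), RA3 (permute the row
across all states, retaining niche breadth), RA4 (permute nonzero
entries among nonzero positions). The reported tail probability is
P(observed ≥ expected), the fraction of null assemblages whose mean
overlap reaches the observed one.

**C-score.** On presence/absence data, C_jk = (R_j − SS)(R_k − SS),
with R the row totals and SS the number of shared samples; the
matrix-wide mean is used descriptively (higher = more segregated).

**Between-year comparison.** Pairwise O values (subjects = species
pairs, classified ss / sn / nn by whether each member is a stygobite)
and per-species O_sp values (subjects = species) are compared across
years with mixed-design repeated-measures ANOVAs using Type III sums of
squares, Bonferroni post-hoc comparisons, and paired t-tests, keeping
only subjects present in every year.

## Worked example

```python
import numpy as np
from nicheoverlap import CommunityMatrix, overlap_result, null_test, community_c_score

m = CommunityMatrix(
    label="1997",
    species_ids=("N_pescei", "D_paolae", "A_crassa"),
    resource_ids=("site1", "site2", "site3", "site4"),
    abundance=np.array([[12, 30, 0, 0],
                        [ 4, 18, 2, 0],
                        [ 0,  0, 9, 7]]),
)
res = overlap_result(m)
print(np.round(res.O, 3))        # pairwise overlap matrix
print(round(res.mean_overall, 3))
nt = null_test(m, "RA3", iterations=1000, seed=42)
print(round(nt.expected_mean, 3), round(nt.p_ge, 3))
print(round(community_c_score(m).mean_c, 3))
```

prints

```
[[1.    0.981 0.   ]
 [0.981 1.    0.085]
 [0.    0.085 1.   ]]
0.355
0.443 0.705
2.0
```

The two spring-dwelling species (rows 1–2) use sites almost identically
(O = 0.981) while the third occupies the remaining sites (O ≈ 0);
the assemblage mean 0.355 is *below* the RA3 null expectation 0.443 and
p = 0.705 says the community is, if anything, more segregated than
chance — consistent with the mean C-score of 2.0 checkerboard units per
pair.

The same analyses are available from the shell:

```bash
nicheoverlap simulate --config sim.yaml --out data/
nicheoverlap overlap --matrix data/y1.csv --out overlap.json
nicheoverlap nullmodel --matrix data/y1.csv --algorithm RA3 --iterations 1000 --seed 42
nicheoverlap cscore --matrix data/y1.csv
nicheoverlap compare --matrices y1=data/y1.csv --matrices y2=data/y2.csv \
    --meta data/metadata.csv --config run.yaml --out report/
```

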