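# bearlink

Link GPS-telemetry movement paths to scat contents for free-ranging black
bears (*Ursus americanus*): where an animal foraged in the hours before it
excreted a scat, and how its diet relates to its sex, reproductive status and
the habitat it moved through.

Scat analysis alone tells you *what* was eaten but not *by whom* or *where*.
With collared animals the two can be joined: collect feces at recently
visited GPS locations, reconstruct the space used during the
gastrointestinal transit interval before excretion with Brownian bridges
between consecutive fixes, and relate the habitat composition of that space
to the corrected diet composition of the scat.

## The method

**Movement.** Between two consecutive fixes **a** (time 0) and **b** (time
*T*) the space-use density is a two-fix Brownian bridge: the time average
over *t* ∈ (0, *T*) of a circular bivariate normal with mean
**a** + (*t*/*T*)(**b** − **a**) and variance

σ²(t) = T·α(1−α)·σ₁² + ((1−α)² + α²)·σ₂², α = t/T,

where σ₁ (m·h^−1/2) captures speed and path tortuosity — estimated per
animal by maximum likelihood on alternate fixes — and σ₂ (m) is the GPS
location-error SD (default 5 m, fixes filtered at PDOP < 10). The 75%
cumulative-mass isopleth of each bridge is the "ellipse" used downstream.

**Diet.** Scat residues washed through 1-mm and 0.5-mm sieves give per-sieve
item percent volumes v_{s,j} and sieve mass fractions w_s; the raw
composition is rawⱼ = Σ_s w_s·v_{s,j}, renormalized over identified items,
then converted to percent dry-matter biomass ingested with per-item
digestibility correction factors: corrⱼ = 100·rawⱼcfⱼ / Σ_k raw_k cf_k.
Scats are averaged per collection site; items seen in fewer than three feces
are dropped.

**Inference.** Constrained correspondence analysis (CCA) ordinates the
site-by-item diet matrix in chi-square geometry under a constraint matrix of
either individual traits or habitat composition (proportions of the seven
habitat classes plus road/river densities inside the dissolved backward
ellipses, pruned at pairwise |r| > 0.6 and VIF ≥ 10). Axis tests and
environmental-vector fits (envfit, n = 999) use restricted permutations with
the individual as stratum, so repeated sites on one bear never inflate
significance. The transit window itself is chosen by scanning candidate
lag windows and keeping the one whose habitat matrix explains the most diet
variance in the first two CCA axes.

Because the original field data are an external deposit, the package ships a
full synthetic-study generator (`bearlink.synthetic`) with known ground
truth — landscape, group-structured movement preferences, habitat-dependent
diet kernels, a configurable ingestion-to-excretion lag — against which every
stage is validated.

## Worked example

The numbered scripts under `analysis/` run a complete campaign:

```bash
python analysis/01_simulate_study.py   # 20 bears, 40 days, truth lag 10-16 h
python analysis/02_movement_models.py
python analysis/03_diet_profiles.py
python analysis/04_window_scan.py
python analysis/05_group_cca.py
```

Output of the scan and group stage on the shipped seed:

```
 h_from  h_to  prop_explained_first2  n_sites
    8.0  14.0               0.552861       53
   10.0  16.0               0.587028       53
   12.0  18.0               0.457483       52
selected transit window: 10-16 h before excretion (generator truth: 10-16 h)

trait CCA: first two axes explain 23.2% of diet inertia
significant trait vectors (p < 0.05): ['sex=M',
  'reproductive_status=with_cubs', 'reproductive_status=with_yearlings',
  'weight']
diet groups: ['females_cubs', 'females_yearlings', 'lone_bears']
females_cubs: 16 sites, first two axes explain 73.8%; significant habitat
  vectors: ['Swamp', 'Conifer']
```

Reading this: the scan recovers the generator's true 10–16 h transit window
(the proportion column is the diet variance explained by the first two
constrained axes per candidate window); the trait ordination finds sex and
reproductive status — not age or body condition — structuring diet, giving
the three classic groups; and each group's diet is then explained by the
habitat visited in its foraging window.

The same pipeline runs from a shell on any study directory:

```bash
bearlink simulate --seed 2 --out mystudy
bearlink run --study mystudy --out pipeline_out --seed 2
```

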