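# scentforage

Agent-based simulation of insect pollinators foraging on flowers that carry
**repellent scent marks** — the short-lived chemical cues a visitor leaves on a
corolla, which later foragers can read as a sign of recent nectar depletion.
The package is for behavioural and community ecologists who want to ask how
this inadvertent social information changes (a) individual foraging
efficiency under exploitation competition and (b) community-level outcomes:
the spatial heterogeneity of standing nectar, flower visitation rates, and a
pollen-dispersal proxy.

## The model

A population of *P* identical pollinators forages for *n_steps* discrete
steps on *F* flowers scattered uniformly over a continuous square torus of
side *size_map* (defaults: 50 × 50, *F* = round(0.1 · 50²) = 250,
*P* = round(ratio · F), 1,000 steps).

Each flower holds nectar *N* ∈ [0, 1] (fraction of a unit capacity) and a
scent-mark concentration *S* ∈ [0, 1], both driven by one linear clock, the
time τ since the last harvest:

    N(τ) = min(1, c·τ)        S(τ) = max(0, 1 − c·τ)

with refill coefficient *c* per step (experiment values 0.001, 0.0025,
0.005 ≙ 1, 2.5, 5 full refills per 1,000-step run). A harvest empties the
flower (*N* ← 0, *S* ← 1, τ ← 0). The clock pauses while a pollinator sits on
the flower. Flowers start full and unmarked.

Each step, every pollinator performs one action (activation order is a fresh
random permutation):

* **searching** — if an unoccupied, novel flower lies within the detection
  radius (1 length unit), move onto one chosen uniformly at random and claim
  it; otherwise take a correlated-random-walk step: heading perturbed by a
  Normal(0, σ²) turning angle with σ = 2π · *inertia*, one unit of travel.
  "Novel" excludes the last few flowers recently left or rejected
  (`novelty_memory`, default 4).
* **assessing** — standing on a just-claimed flower, decide: a scent-mark
  user accepts with probability 1 − *S* (a Bernoulli trial; fresh marks
  repel), a non-user always accepts. Accepting harvests all standing nectar;
  rejecting releases the flower.
* **handling** — sit inside an accepted flower for `cost` steps (default 5).

A run reports, over pollinators and flowers, the mean and coefficient of
variation of: nectar collected, nectar remaining at the end, accepted visits
per flower, and pollen carryover (for a focal flower, the number of distinct
flowers its visitors go on to visit — a proxy for pollen dissemination), plus
the mean nectar gained per accepted visit.

## Worked example

Two single runs under the default configuration (250 flowers, 75
pollinators, refill 0.0025), differing only in scent-mark use:

```bash
scentforage run --seed 1 --out demo_scent --use-scent
scentforage run --seed 1 --out demo_noscent --no-use-scent
```

prints (scent users first):

```
"mean_nectar_collected": 10.13   vs   9.88
"mean_nectar_per_visit": 0.395   vs   0.124
"mean_nectar_remaining": 0.199   vs   0.090
"cv_nectar_remaining":   0.781   vs   1.255
"mean_visits_per_flower": 7.70   vs   23.88
"mean_pollen_transfer":  12.29   vs   35.59
```

Read: at 0.3 pollinators per flower, scent users collect about the same
total nectar, but each accepted visit yields ~3× more nectar (they skip
depleted flowers), the standing-nectar landscape is markedly more
homogeneous (lower CV), and flowers receive ~3× fewer visits and spread
their pollen to ~3× fewer downstream flowers. At higher competition the
individual advantage of scent use grows; at very low competition it
reverses.

The experiment harness replicates whole designs:

```bash
scentforage sweep --design design.yaml --seed 0 --out sweep.csv --plot sweep.png
scentforage sense --seed 0 --n-samples 300 --out sense_out/
```

`sense` draws parameter vectors uniformly from each parameter's variation
interval, simulates each, and ranks parameter importance for mean nectar
collected with a 2,000-tree random-forest regression (out-of-bag R²
reported as variance explained).

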