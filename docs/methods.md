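# Methods

This note documents the models and conventions the package implements, the
choices made where the literature leaves room, and what the synthetic-data
generator does and does not emulate.

## Distances

Pairwise divergence uses the Kimura 2-parameter (K80) model. For a pair of
aligned sequences, P and Q are the proportions of compared sites showing a
transition (A↔G, C↔T) or transversion, over sites where both sequences carry
an unambiguous base; the distance is

    d = -1/2 · ln((1 − 2P − Q) · sqrt(1 − 2Q))   [substitutions/site].

*Deletion modes.* `complete` removes every column containing any gap,
ambiguity code or `N` in any sequence before all pairwise computations
(the desktop-package convention used for tree building and reported
summaries); `pairwise` masks sites per pair. Complete deletion is the
default everywhere.

*Undefined pairs.* When a log argument is non-positive (saturation) or no
sites are comparable, the pair is flagged undefined — never NaN and never an
exception in batch mode. Undefined pairs are excluded from all means and
counted in the QC diagnostics; tree building refuses them, and the pipeline
pre-filters saturated sequences (greedily removing the worst offender)
before ABGD with the removals reported.

*Divergence summaries.* Within-group, between-group and overall means are
averages over defined pairs only; a single-member group has a missing (not
zero) within mean. The standard error of the overall mean is a site
bootstrap: alignment columns are resampled with replacement and the whole
matrix recomputed (1000 replicates by default, seeded). Reporting a
bootstrap SE is a convention of this package; the field's "±" values rarely
name their method. Distances are stored as proportions and rendered as
percentages in reports.

## Trees

Neighbor joining follows the Saitou–Nei Q-criterion with the standard
branch-length formulas; it is exactly consistent on additive matrices (a
property the test suite verifies on random trees). UPGMA is unweighted
average linkage; node heights equal half the merge distance, so its output
is ultrametric by construction.

*Tie-breaks.* Both methods resolve exact ties toward the lowest (i, j) index
pair in the current node ordering (merged nodes append at the end). Because
this makes the topology depend on input order under exact ties (duplicate
haplotypes), `bootstrap_supports` first sorts sequences by id, which makes
the point tree and all supports independent of input order.

*Negative branch lengths.* NJ's estimates can go negative; they are clamped
to zero and the summed deficit recorded in the tree's annotations.

*Bootstrap.* Replicate r resamples alignment columns with replacement using
seed `seed + r`; support for an internal split is the percentage of
replicate trees containing it (unrooted comparison). 1000 replicates is the
default; desk-scale runs in the acceptance script use 100–200, a problem
size chosen to keep full-pipeline demonstrations in the minutes range while
leaving supports stable to a few percent. An alignment with no variation
yields a tree without supports.

*Rooting.* The tree is rooted on the edge separating the outgroup from the
ingroup; a non-monophyletic outgroup is an error unless midpoint fallback is
requested. When outgroup *specimens* (tips not declared as outgroup) nest
inside the outgroup clade, the exact split does not exist; the pipeline then
roots on the longest edge having all declared outgroup tips on one side —
the outgroup stem, by far the longest such edge whenever the outgroup is
distinct.

## ABGD dialect

The published barcode-gap algorithm's slope-based gap significance is not
fully specified by its common descriptions, so this package implements a
deterministic dialect and labels it as such:

* distances are sorted ascending; the gap between D[i] and D[i+1] is
  *significant* iff its width exceeds X times the mean consecutive-gap width
  among all distances up to D[i] (global left window);
* a gap is *admissible* iff its right endpoint exceeds the prior P — the
  barcode gap must end beyond the prior intraspecific divergence;
* a leading-gap clause: if even the smallest distance exceeds P and
  (D_min − P) is more than X times the mean gap width, the threshold is
  (P + D_min)/2 (all sequences more divergent than the prior are split);
* the threshold is the midpoint of the first admissible significant gap;
  the initial partition (IP) is the single-linkage components with edges
  d < threshold; the recursive partition (RP) re-applies detection inside
  each group with the same P and X to a fixed point (max depth 10).

These rules reproduce the expected limiting behaviour — one group when P
reaches the largest distance, all singletons when every distance dwarfs P,
group counts non-increasing in P — and ≥95% true-group recovery on
clean-gap simulations, but exact parity with the original web service is not
promised. The sweep default is 20 log-spaced priors in [0.001, 0.1] with
X ∈ {1.0, 1.5, 2.0}; the selected prior minimises |n(IP) − n(RP)|, ties
broken toward the larger prior (then larger X). On perfectly clean data
every prior gives IP = RP, so the tie rule returns the coarsest partition —
a faithful, if conservative, consequence of the stated rule.

## GMYC (single threshold)

Sequences are first collapsed to unique haplotypes by exact string equality
(ambiguity characters included — deterministic, at the cost of treating an
`N` as a difference). The ultrametric input is either an external chronogram
(accepted if tip heights agree within 1e-6 of the root height) or a UPGMA
tree on K2P distances — the documented desk-scale stand-in for a relaxed/
strict-clock Bayesian chronogram. The pipeline excludes outgroup tips from
chronograms, as is standard when a single clock is assumed.

For a threshold time T, events older than T belong to a diversification
process and younger events to independent within-species coalescents.
During an inter-event interval the total branching rate is

    b = lambda1 · n_d^p1 + lambda2 · Σ_k n_k^p2,

where n_k counts the lineages inside cluster k and n_d counts species
lineages. Two conventions matter and are deliberate:

* **each entity is a species lineage from the present** — stems run through
  the tuft zone, so n_d equals the number of entities below T and decreases
  only at diversification events; this makes the diversification component
  the standard pure-birth likelihood of the species tree;
* **the event term is the total rate**: logL = Σ_events log b_i − Σ b_i·x_i,
  the classic mixed Yule–coalescent waiting-time likelihood. (A per-class
  "component" event term was evaluated and rejected: it handicaps every
  clustered configuration by ~log(number of clusters) per within-cluster
  event, so the all-singleton configuration always wins and the model never
  detects structure.)

The fit scans candidate thresholds at midpoints between consecutive distinct
node heights, plus one below the youngest node. At that extra candidate
every tip is its own entity and the model family coincides with the
single-process null `b = lambda·n^p`, so the null is nested by construction
and `logL_gmyc ≥ logL_null` holds exactly. Rate scales are profiled
analytically where possible; exponents are maximised by L-BFGS-B with 5
seeded restarts within lambda ∈ [1e-8, 1e6], p ∈ [−2, 10]. The LR test uses
chi-square with 3 df (threshold + two extra rate parameters), with an equal
chi-square(1)/chi-square(3) mixture available as a boundary-corrected
option. The confidence set is all thresholds within ΔlogL ≤ 1.92 of the
maximum; the entity-count CI is the range of entity counts across it.
Singletons count as entities but not clusters.

Calibration measured by the acceptance script: type-I error ≈ 2–5% at
nominal α = 0.05 over 100 independent null coalescent trees (generated with
msprime, not this package's own simulator), and ≥ 90% exact entity recovery
on trees with stem/tuft depth ratio 10.

## Assignment rules

* *Curation*: candidates for a species are kept only if conspecifics form a
  monophyletic clade with bootstrap support ≥ 70 (a clade without a recorded
  support passes on topology; "strong monophyly" has no canonical number,
  70 is this package's default and configurable). A candidate whose removal
  restores monophyly and whose nearest K2P neighbour is heterospecific is
  discarded as misplaced. Up to two representatives are kept — the two most
  mutually divergent conspecifics.
* *Per tree*: the smallest clade containing the specimen and ≥ 1 reference;
  several reference species in that clade are resolved by lowest mean K2P to
  the specimen; if the first such clade is the root, the specimen is
  unassigned.
* *Per gene*: strict majority (> half of all tree calls, unassigned calls
  counted in the denominator).
* *Across genes*: equality after synonym mapping → that species; both
  assigned and different → discordant (both names recorded); exactly one
  assigned → that species with a single-gene flag (this covers specimens
  sequenced at only one locus — the rule uses the confident gene regardless
  of its support, which users should keep in mind); neither → unidentified.
  Outgroup references are a pseudo-species, so specimen-vs-outgroup
  conflicts fall under the same discordance rule.
* *Synonyms*: reference species whose between-species mean K2P falls below
  0.002 are merged transitively; the canonical name is alphabetically first
  unless an alias table overrides. The 0.002 default separates "0.0–0.1%"
  synonym pairs from distinct-but-close species complexes around 0.7%.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* a Yule species tree rescaled so the mean between-species divergence equals
  `delta_inter` (default 0.06, the middle of the 1–11% interspecific range
  such surveys report), with shallow nodes raised so the closest species
  pair is at least `min_inter_fraction` (default 0.5) of that target —
  without the floor, Yule realizations occasionally place a pair inside the
  within-species range, which is not the clean-signal design the generator
  advertises. Near-zero species pairs are modelled explicitly instead, as
  synonym reference pairs with identical sequences;
* independent Kingman coalescents within species rescaled so the mean
  within-species divergence equals `delta_intra` (default 0.004, inside the
  reported 0.03–0.9% range);
* K80(kappa = 2) sequence evolution via exact per-branch transition
  probabilities (no Gillespie simulation), per-locus rate multipliers
  (1.0, 1.3) and lengths (813, 732) matching a plastid + ITS design;
* gene-discordant specimens injected at the membership level — the specimen
  draws its sequence from a different species at one locus — which directly
  produces the discordance phenotype without simulating introgression;
* an outgroup clade at twice the interspecific depth, with optional outgroup
  specimens;
* defaults mirror a 215-specimen, 9-species island survey (193 regular
  specimens at realistic per-species abundances, 14 outgroup specimens,
  8 discordants, 23 collection sites).

Because every tree is rescaled to its target, `expected_divergence` is an
exact closed form, and the simulator's empirical means match it within
Monte-Carlo error. Identical config + seed gives bit-identical output.

*What it does not emulate*: indels and alignment error (gap handling is
tested with hand-built fixtures), rate heterogeneity across sites (no
gamma), population structure within species, and real GenBank reference
noise. Passing the end-to-end tests therefore shows the decision logic is
correct under the model's assumptions, not that any particular real dataset
will be this clean — real reference libraries contain mislabels, which is
exactly why the curation stage exists.

## Problem sizes

Defaults are full scale (1000 bootstrap replicates, 20-prior sweep). The
acceptance script runs 200 NJ-consistency matrices, 100 ABGD recovery
simulations, 100 GMYC null trees and 50 recovery trees, the three frozen
fixtures at 100 bootstrap replicates, and one survey-scale pipeline run at
200 replicates — sizes chosen so the whole recomputation stays within a few
minutes on a single core while keeping all Monte-Carlo rates stable to a few
percent.

## Known limitations

* The ABGD dialect is validated by limiting behaviour and synthetic
  recovery, not by parity with the reference web service.
* UPGMA chronograms compress rate variation; on real data GMYC counts from
  them should be treated as indicative, with externally built chronograms
  preferred.
* The selection rule "minimise |IP − RP|, ties to larger P" degenerates to
  the coarsest partition on noiseless data (see above).
* Majority voting needs three inferences per gene to be meaningful; native
  runs provide NJ only, so single-tree majorities pass through unchanged
  unless external ML/BI trees are supplied.
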