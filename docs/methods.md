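# Methods

## Life-event model

Each simulated individual carries a state (current age t′, disease status
δ ∈ {0,1}, rare-variant status x ∈ {0,1}) and experiences three competing
event processes.  Disease onset is a non-homogeneous Poisson process with
intensity λ_onset(t|x): the baseline hazard λ_o(t) for non-carriers and
κ·λ_o(t) for carriers.  Because users observe *population* incidence, the
package takes the population hazard λ_onset(t) as input and recovers the
baseline by the mixture identity

    λ_onset(t) = (1 − p_c) λ_o(t) + κ p_c λ_o(t)
    ⇒ λ_o(t) = λ_onset(t) / (1 + p_c (κ − 1)),

with κ ≥ 1 and p_c ∈ [0, 1].  A consequence worth knowing: at fixed p_c,
non-carriers simulated under a small κ have a *higher* baseline hazard than
non-carriers under a large κ, so sporadic cases are not directly comparable
across κ groups.  Disease strikes at most once (no remission); after onset
the death intensity switches from the unaffected curve λ_u(t) to the
affected curve λ_a(t), and the reproduction rate is rescaled by f ∈ [0, 1]
(default 1).

All hazards are piecewise-constant over a user-supplied age partition
starting at 0 (yearly bins in the bundled curves); integration of the
cumulative hazard is exact, and waiting times are drawn by inverting the
cumulative hazard against an Exp(1) target rather than by thinning.  This
makes every sampler deterministic given the generator state and lets tests
check closed forms exactly.  The final partition boundary (default age 100)
is the maximum modelled age: an individual whose Exp(1) death target exceeds
the remaining hazard mass dies at that boundary, so nobody is immortal.

Reproduction uses a Poisson–Gamma mixture: at birth each individual draws a
lifetime rate γ ~ Gamma(shape 2, scale 4/3), a span start a₁ ~ U(16, 27)
years and span length a₂ − a₁ ~ U(10, 18) years.  Within [a₁, a₂) births
occur at rate γ f^δ/(a₂ − a₁); an unconditional wait w ~ Exp of that rate is
conditioned on the current age (shifted to a₁ if drawn before the span;
taken as the residual wait inside the span; infinite if it would land past
a₂).  The residual-wait convention in the middle branch is the only reading
consistent with the first branch returning a waiting time, and is what
memorylessness of the exponential requires.  For an unaffected individual
surviving the whole span this yields Poisson(γ) offspring, hence a
negative-binomial count with size 2 and success probability
1/(1 + 4/3) = 3/7 after mixing over γ.  (A commonly quoted human offspring
model is NB with success probability ≈ 4/7; that value is inconsistent with
the Gamma(2, 4/3) mixing distribution used here, and the mixture implied by
the explicit γ draw is what the package tests against.)

At each step the three waits are drawn (onset only while δ = 0) and the
minimum wins; ties — a probability-zero event — break death > onset >
reproduction for determinism.  Event calendar years are recorded as
floor(birth_year + age).  Any event that would land after the study stop
year is discarded and the individual is censored at the stop year.

## Pedigree growth and variant introduction

A pedigree grows recursively from one starting founder whose birth year is
uniform (integer years) over a configured range (default 1900–1980).  The
variant is introduced either by that founder with certainty
(`eldest_founder`, appropriate when every genetic family segregates a
variant rare enough to enter through one ancestor) or with probability p_c
(`bernoulli`, allowing fully sporadic families), and is transmitted to each
offspring with probability 1/2 from a carrier parent.  Each lineage member
takes a single mate — a married-in co-parent created at first reproduction,
non-carrier, whose own life history is not simulated (no event years,
missing disease status).  Offspring sex is a fair coin.  The recursion
processes the founder and then every offspring until all descendants are
simulated or censored.

## Ascertainment

A family is ascertained through a proband: an affected member whose onset
year lies in the ascertainment span and who is at least the
`num_affected`-th member of the family to develop disease, ordered by onset
year (ties broken by onset age, then id).  One eligible member is chosen
uniformly.  An affected whose onset is in span is eligible even if they die
before the study's end: contact is presumed at onset.  Relatives are then
trimmed: every blood relative except the proband is kept independently with
its recall probability — by default min(1, 4φ) with φ the kinship
coefficient to the proband, reproducing the 1 / 0.5 / 0.25 ladder for
first/second/third-degree relatives; a user-supplied vector (p₁, …, p_q) is
instead applied by relationship degree d = round(−log₂ 2φ), with degree ≥ q
receiving p_q.  Dropped individuals on a lineage path between kept members
are re-added as unavailable connectors with disease status, relative risk
and all event years (including birth year) missing; a married-in co-parent
is kept iff it co-parents a kept child whose lineage parent is also kept.
If the trimmed family has fewer than `num_affected` members with known
affected status, the entire pedigree is discarded and a new one simulated,
up to a loud ceiling of 10,000 attempts per family.

Study samples draw per-family generators from
`SeedSequence(master_seed, spawn_key=(family_index,))`, so family *i* is
reproducible regardless of how many families are run or in what order.

## Statistics

Kinship is computed by the recursive tabular method on a
parents-before-children ordering (founders non-inbred and mutually
unrelated; φ(x,x) = ½(1 + φ(father, mother))).  A_IBD is the mean over
affected pairs of 2φ, the expected genome fraction shared IBD for non-inbred
pairs, matching the reference values 0.5 (first-degree pairs) and 0.25
(avuncular, grandparent–grandchild).  Generation numbers for anticipation
displays place the affecteds' most recent common ancestor — possibly an
affected member itself — at generation 1, and number every affected
1 + (parent-link depth below it); among tied common ancestors the one
minimising the maximum depth (then total depth, then id) is used, so an
ancestral couple counts as one generation.  The negative-control table
collects death ages of relatives of *known* unaffected status, numbered by
depth below the same ancestor; unaffecteds that do not descend from that
ancestor (married-ins, collateral branches) have no generation under this
convention and are excluded.  Per-family summaries report family size,
affected count, mean onset age over affecteds with known years, A_IBD
(NaN below two affecteds), the ascertainment year (proband onset) and a
segregation flag (any member carries).  The proportion-segregating
estimator restricts to families with at least n_A known affecteds and
reports NaN, not zero, on an empty subset.

## Synthetic hazards

`make_synthetic_hazards` builds yearly-bin curves with the qualitative
shape of an adult-onset disease: onset hazard rising logistically from
1e-4/yr to 4e-3/yr around age 50 (width 8 yr), Gompertz death hazard
1e-4·exp(0.085·t)/yr for unaffecteds, and affected mortality at a constant
excess multiplier 2 at all ages.  The onset level corresponds to a lifetime
risk of roughly 5% — several-fold higher than a rare cancer — chosen so
that multiplex families arise at rates convenient for interactive use while
staying in the rare-disease regime where, at κ = 1, ascertained families
concentrate at the minimum affected count.  The generator emulates curve
*shapes* only: it is not calibrated to any registry, carries no
calendar-period or cohort effects, no infant-mortality hump, and no
sex-specific rates.  Consequently, passing tests demonstrate the simulator's
internal logic and the direction of ascertainment effects, not quantitative
rates for any real disease; studies of a specific disease should supply
registry-derived hazard CSVs.

## Problem sizes and numerical choices

The test suite runs desk-scale versions of the reference study design
(ascertainment span 2000–2015, follow-up to 2017, founders born 1900–1980,
p_c = 0.002, recall (1, 1, 1, 0.5, 0.125)): 200 families per relative-risk
group for the ascertainment-contract, clustering and anticipation checks,
and 10⁴–10⁵ draws for distributional checks at 3-standard-error tolerances.
Cumulative-hazard inversion round-trips to 1e-9; the mixture identity holds
to 1e-12.  Kinship agrees with a gene-dropping Monte Carlo oracle at 10⁵
drops within 3 binomial standard errors.

## Limitations

One mate per individual (no half-sibships), no inbreeding loops, no de novo
variants or homozygous carriers, no X-linkage, no disease remission or
severity, and no modelling of married-in co-parents' life histories.
Anticipation output is descriptive (tables for box plots); no formal test
is provided.  Recall trimming treats recall as independent across relatives
given degree, which ignores correlated recall within households.
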