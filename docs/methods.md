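# Methods

This note documents the models, estimators and design choices behind
`bosgame`, in the order the analysis pipeline applies them.

## Game mechanics

The Bach-or-Stravinsky payoff is parametrized by `PayoffMatrix`
(base own 2, base other 1, coordination bonus 2).  Coordination is a
property of the *physical* targets: both agents touching the same
target means exactly one of them took its preferred color, so the
choice labels differ on coordinated trials and reward sums identify the
outcome class uniquely (7 coordinated, 4 own-own, 2 other-other).  All
sides are stored in the objective frame (agent A's frame); nothing in
the package ever records subjective sides.  Reward units are integers;
any monetary or liquid conversion is metadata and never enters a
computation.

The layout randomizer balances the six possible positions of A's
preferred color in blocks of 18 trials (each position three times).
Sessions whose length is not a multiple of 18 end with a truncated,
freshly shuffled balanced block — the balance error is at most the
truncated remainder, and empirical Q_left equals 0.5 exactly on every
complete-block span.

## Choice metrics

FCO and FCL running series use a **trailing** window (value at trial t
averages trials t−w+1…t, undefined for the first w−1 trials).  A
trailing window is causal and introduces no edge padding; the window
length w = 8 makes windowed values live on the grid 0, 1/8, …, 1.
Steady-state metrics are computed on the last 200 trials; shorter
sessions are used whole and flagged rather than rejected, since real
(especially animal) sessions and barrier segments can be short.
Coordination-rate changes between session halves use Fisher's exact
test; the odds ratio is reported as odds(coordinated | late) /
odds(coordinated | early) so values above 1 mean improvement, and the
Bonferroni factor is supplied by the caller because only the caller
knows the family size.

## Mutual information and Whittle surrogates

MI between binary choice sequences is estimated naively (relative
frequencies in place of probabilities, base-2 logs, 0·log 0 = 0).  The
estimator is symmetric, alphabet-invariant and bounded by the marginal
entropies; its well-known positive bias on independent series,
≈ 1/(2N ln 2) bits, is verified by simulation in the test suite and is
far below the significance thresholds at session lengths (N = 200:
0.0036 bits).

Significance uses surrogates that preserve each series' first-order
Markov structure.  For a binary sequence, fixing the initial symbol and
the 2×2 transition counts fixes the number of runs of each symbol, and
the admissible set is exactly {(composition of the zeros into their
runs) × (composition of the ones into theirs)}; sampling two uniform
compositions therefore draws surrogates exactly uniformly without
rejection.  x- and y-surrogates are drawn independently, which is the
null "each agent's own choice dynamics, no cross-agent dependence".
The threshold is the k-th largest of the surrogate MI values with
k = floor(α (n+1)) (α = 0.01, n = 1000 by default); the observed MI
must strictly exceed it, with a 1e-9 relative tolerance so exact
count ties computed in a different summation order do not flip the
verdict.  Two consequences worth knowing:

- a constant series can never be significant (its surrogate set is a
  singleton and MI is 0);
- a *perfectly periodic* series is also its own only surrogate, so a
  noise-free alternating pair is — correctly — not distinguishable
  from a coincidence of two deterministic clocks.  Real pairs (and the
  simulator with any nonzero lapse rate) are never perfectly periodic.

## Random-play reward and DCR

RPR is the expected joint reward if each agent kept its observed
selection probabilities per layout side but chose independently of the
partner and of history.  It is evaluated in closed form from the eight
probabilities P(agent, preferred/non-preferred, objective side); with
the layout frequencies Q fixed at their design value 0.5, those eight
probabilities are determined by the four marginals FCO_A, FCL_A,
FCO_B, FCL_B via P_{i,2,L} = (FCO_i + FCL_i − 0.5)/2.  "Permuting
choices over trials" must be read per layout side: an unstratified
permutation would break the layout-conditional structure and, e.g.,
assign RPR 2.5 instead of 3.5 to a both-always-left pair.

DCR = R_actual − RPR.  The confidence interval takes the min/max of
DCR over the 16 corners of the box formed by normal-approximation
binomial intervals on the four marginals (RPR is multilinear in each
agent's parameters, so its extrema over the box are at corners;
corner probabilities are clipped to [0, 1]).  Because the corner box
only propagates marginal uncertainty, the interval is additionally
widened by z standard errors of the mean joint reward — without this
the interval ignores the sampling noise of R_actual itself and
under-covers (~91% instead of ≥95% under a permutation null at
n = 300).  The confidence level (z = 1.96) is a parameter; the
permutation-null coverage property in the test suite, not the nominal
level, is what validates significance behavior.

Strategy classification reads the MI plane: *dynamic turn-taking*
requires significant DCR > 0.2 (strict) with both MI side and MI color
significant; *static color* pairs sit near the MI-side axis (MI color
indistinguishable from zero, one physical color dominating ≥ 90% of
coordinated trials); *static side* is the mirror case; a session whose
coordination fraction does not exceed its own random-play expectation
is *uncoordinated*; anything else is unclassified.  The dominance test
is only defined when at least 10% of trials are coordinated, so a
near-zero-coordination session cannot be labeled "static" on the
strength of a handful of lapse coincidences.

## Action times and visibility

t_movement = t_acquisition − t_release and t_action is the reach
midpoint — a proxy for when the movement becomes readable.  The three
Welch (Satterthwaite) comparisons are: both agents' action times over
all trials; the per-trial difference AT_A − AT_B between coordination
on A's color vs. B's color; and |AT_A − AT_B| between coordinated and
uncoordinated trials.  Trials missing either agent's timestamps are
dropped pairwise and counted.

psee(Δt) = 1/(1 + e^(−k(Δt−ΔT0))) with k = 0.04/ms, ΔT0 = 50 ms
(psee(50) = 0.5, psee(150) ≈ 0.98).  For agent i the argument is
Δt = AT_i − AT_partner: positive when i is slower and could therefore
see the partner move first.  The visibility correlation is Pearson's r
between the per-trial psee series and the agent's choosing-other's
indicator (1 − own), reported raw and after the same trailing 8-trial
smoothing as FCO (smoothing inflates autocorrelation, so a shuffle
null for the raw series is available alongside the t-transform
p-value).  The robustness sweep evaluates the stated grids
ΔT0 ∈ {12.5, 25, 50, 75, 100, 200} ms at k = 0.04 and
k ∈ {0.01, 0.02, 0.04, 0.08, 0.16} at ΔT0 = 50 — 11 settings.

## Transitions

Sessions partition into maximal runs of one trial mode (coordination on
A's color / on B's color / own-own / other-other).  A seamless switch
is two adjacent coordinated trials with different coordination colors
(strict adjacency; per boundary, not per trial pair).  The faster agent
on the *switch trial* (smaller t_action there — that is the trial on
which the classified choice is made) is credited with a selfish (own)
or benevolent (other) choice; ties and missing timestamps leave the
switch unattributed.  Balance verdicts use exact binomial
(Clopper–Pearson) 95% intervals on the benevolent proportion against
0.5, for switches and for the own-own/other-other split alike.  The
transition AT profile averages each agent's action time at offsets
−3…+3 around segment boundaries, split by transition type.

## The simulator

Strategies are stationary policies (no cross-session learning): fixed
color, fixed side, block/trial turn-taking (the pair's beneficiary
alternates on a block schedule; equal block length and phase give
perfect coordination), scripted confederate block alternation
(~20-trial blocks, optional jitter), visibility-gated Leader–Follower,
and Bernoulli random.  Every strategy has a lapse probability `noise`
(default 0): with that probability the trial's target is replaced by a
fair coin flip over sides, emulating the exploratory deviations real
pairs show — and guaranteeing the non-degenerate sequence structure
the surrogate test assumes.

Action times are truncated normals (floor 50 ms; the action time is
additionally kept above half the movement so the release stays
positive).  Leader–Follower resolution per trial: both agents draw
provisional targets and times; the slower agent (ties broken by coin
flip), if it follows and the trial is visible, copies the faster
agent's physical target with probability psee(Δt) × follow_fidelity
and its realized action time becomes max(own draw, leader + 150 ms
lag) — the lag reproduces the bimodal AT-difference histograms of
following behavior.  One RNG stream per session, consumed in a fixed
documented order, makes sessions reproducible from a single seed.

Default study conditions used in tests and analysis scripts: sessions
of 300–450 trials; movement times 314 ± 104 ms (human-like) and
171–180 ± 64–77 ms (macaque-like); leader/follower action-time means
450/550 ms with SD 80 ms so the AT difference spans the psee dynamic
range; confederate blocks of 20 trials; opaque segments covering the
middle third of a session.

### What the simulator does and does not emulate

It reproduces the *strategic* structure of dyadic sessions: marginal
choice probabilities, cross-agent dependence (following, turn-taking),
layout-coupled side statistics, action-time asymmetries and
visibility gating.  It does not model learning within or across
sessions, kinematics, gaze or other social signaling, or
reward-history effects; passing tests therefore demonstrate that the
estimators recover the generating structure under realistic sizes and
noise, not that real pairs behave like any particular strategy.

## Problem sizes and numerical choices

Tests and the acceptance script run on constructed 200-trial sessions
(exact counterbalancing makes the reference values exact), simulated
sessions of 300–450 trials, 300–1000 surrogates per MI test, 500
replicates for the false-positive calibration, 200 replicates for the
permutation-null coverage, and 10^5 draws for Monte-Carlo
cross-checks.  Floats in serialized reports are formatted to six
significant digits with fixed key order so identical inputs give
byte-identical output; NaN/infinite diagnostics serialize as null with
their context carried by explicit flags.

## Known limitations

- The naive MI estimator is biased upward on short series; thresholds
  from surrogates share the bias, which is why calibration holds, but
  reported MI values at N ≪ 100 should not be compared across very
  different lengths.
- The DCR CI treats the four marginals as independent binomials; they
  are weakly dependent through the layout, making the corner box
  conservative.
- Seamless-switch attribution uses the switch trial's action times
  only; scripted sessions without timestamps yield unattributed
  switches rather than guesses.
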