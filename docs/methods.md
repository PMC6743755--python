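# Methods

## The model

The BER net is a classical place/transition Petri net: a weighted directed
bipartite graph whose places hold tokens (molecules, complexes, DNA
states) and whose transitions move them (reactions).  It is *qualitative*
— no rate constants — so every conclusion rests either on the structure of
the incidence matrix or on the uniform stochastic firing rule described
below.

Construction (`bernet.ber.build_ber_net`) proceeds in four blocks:

1. **Damage introduction.**  A source transition (`t_170`) replenishes the
   undamaged-DNA pool; a damage-formation event (`t_40`) produces a
   lesion-carrying DNA token that is sorted into one of 26 damage groups.
   Each group is defined by the subset of the 11 human DNA glycosylases
   able to recognise it (UNG2, SMUG, MBD4, MPG, MYH, TDG are
   monofunctional; OGG1, NTH1, NEIL3 are bifunctional β-eliminating
   lyases; NEIL1, NEIL2 are β,δ-eliminating).  Successful repair funnels
   through `t_169` (*DNA back to pool*), the success marker, and out of
   the system (`t_171`); these four transitions appear in every repair
   process and form one MCT set.
2. **AP-site formation.**  Each of the 57 admissible (glycosylase, group)
   pairs contributes a recognition+binding transition and a cleavage
   transition; cleavage leaves the enzyme on an abasic (AP) site and
   releases the excised base into a by-product pool (pooled by chemical
   class — uracil-type, adenine-type purines, oxidised pyrimidines,
   FapyG-type, thymine-glycol-type, …) with a disposal transition each.
3. **AP-site processing.**  β-eliminating lyases incise the AP site to a
   3′dRP end, which APE takes over and cleans; NEIL1/NEIL2 produce a 3′P
   end handed to PNKP.  OGG1's weak lyase product can also be taken over
   by NEIL1 (β,δ-elimination, modelled as one concerted step with the
   PNKP hand-off), and OGG1, NTH1 and NEIL3 can be substituted by APE at
   the AP site before their lyase acts.  Monofunctional enzymes are always
   displaced by APE, whose incision leaves a 5′dRP end.
4. **Repair synthesis and ligation.**  Six sub-paths complete the repair:
   SP(1) Polβ + LIG3-XRCC1 after PNKP end-cleaning; SP(2) Polβ +
   LIG3-XRCC1 after APE 3′dRP removal; SP(3) Polβ removes the 5′dRP and
   ligation proceeds as in SP(2); LP(1) strand-displacement synthesis by
   Polβ with FEN1 flap excision and LIG1; SP(4) FEN1 cleaves the 5′dRP
   and Polβ fills the gap; LP(2)/LP(3) synthesis by Polδ (PCNA-high) or
   Polε (PCNA-low).  dNTP supply is a source/sink pair; each incorporation
   consumes one dNTP token.

**Enzyme handling.**  Every enzyme is *catalytic*: consumed on binding,
returned on displacement or complex dissociation, with no read arcs (the
net is pure).  Glycosylases, APE, the polymerases, FEN1, LIG1 and
LIG3-XRCC1 additionally have source/sink turnover pairs; those pairs are
exactly the 18 protein "fluctuation" invariants, and together with the
PCNA high/low interconversion cycle and the dNTP turnover pair they
account for the 20 trivial one-invariant clusters.

**Conserved pools and the initial marking.**  PNKP and PCNA have no
turnover; they are finite conserved pools seeded by the initial marking
(1 token each by default), as are three accessory factors: HMGB1 (bound at
the APE-incised intermediate until a polymerase or PCNA commits), RFC
(loads PCNA at the long-patch entry points) and RPA (coats the displaced
strand during strand-displacement synthesis).  Because each cofactor is
consumed and returned within every process that touches it, these pools
change neither the invariant set nor the MCT partition; dynamically they
act as concurrency caps, which is what gives the PNKP path and the
PCNA-dependent paths their characteristic low throughput.  All other
places start empty — the sources feed the net.

## Minimal t-invariants

`minimal_t_invariants` runs the classical Fourier–Motzkin/Farkas scheme on
the tableau `[Aᵀ | I]`: place columns are eliminated one at a time
(choosing the column minimising the number of positive×negative row
combinations), each combination is reduced by its gcd, and rows whose
support strictly contains another row's support are discarded as they
arise and again after each elimination round.  Everything is arbitrary-
precision integer arithmetic; the output is the unique set of
support-minimal, gcd-canonical semi-positive solutions of `A·x = 0`,
ordered lexicographically by support.  A configurable row cap
(`max_rows`, default 2·10⁶) turns pathological blow-up into a clear
error.  An independent bounded exhaustive enumerator
(`bernet.exhaustive`) provides ground truth on small nets (all vectors
with entries ≤ 4) and verifies planted synthetic nets at generation time.

On the BER net the enumeration yields 245 invariants (the net is covered):
225 repair processes — 24 through the PNKP path, 16 through the
lyase/APE path, and 37 through each of the five routes that pass the APE
incision (SP(3), SP(4), LP(1), LP(2), LP(3); 21 monofunctional pairs +
OGG1 4 + NTH1 7 + NEIL3 5) — plus the 20 turnover invariants.

## MCT sets

Transitions sharing exactly the same set of invariant supports form one
MCT set (membership is judged on supports, not multiplicities; ids are
assigned by descending size, then lexicographically smallest member, with
an alias table attaching the published `m_k` names to the fixture's sets).
The BER net decomposes into 94 non-trivial sets (size ≥ 2) and 35
singletons.  One reconstruction residual is known: the MPG
detection-plus-disposal set has five members, slightly larger than the
2–4 range the published table sketches for the unnamed sets.

## Invariant clustering

t-invariants are clustered on their binary support indicators by default
(multiplicity vectors are one flag away; on this ordinary net entries
exceed 1 only for dNTP supply).  Eight distances (binary, Canberra,
Euclidean, Manhattan, maximum, Minkowski p = 3, uncentred and centred
Pearson, the latter as `1 − r`) and seven linkages (single, complete,
UPGMA, McQuitty, centroid, median, Ward) are implemented via the
Lance–Williams recurrence with a deterministic tie-break (the pair of
clusters containing the smallest original indices merges first).
Centroid/median/Ward operate on squared distances per their classical
definitions, and centroid/median only compete for "best" under the
Euclidean measure.  Degenerate vectors under the correlation distances
(zero variance / zero norm) are at distance 0 from identical vectors and
1 from everything else.

Two selection protocols are provided:

* `model_selection` — exhaustive (distance, linkage, k) grid scored by the
  Caliński–Harabasz index (B/(k−1))/(W/(N−k)) in the Euclidean geometry of
  the feature vectors and by the Mean Split Silhouette (each cluster of
  size ≥ 3 is re-clustered into two with the same linkage and contributes
  the mean silhouette width of that forced split; clusters too small to
  split contribute the neutral value 1; lower is better).  Best = maximal
  CH, ties broken by minimal MSS, then smaller k.
* `cluster_with_local_ch` — one configuration, with k taken at the
  dominant *interior local maximum* of the CH-versus-k curve.  On invariant
  sets like this one, CH decays from k = 2 because the dominant structure
  is one coarse split (turnover vs. repair invariants, with the 20
  mutually near-orthogonal turnover invariants adding clusters without
  adding between-variance), so the informative cluster number appears as
  an interior optimum rather than the global one.  For centred Pearson
  with UPGMA (or centroid) on the BER invariants that optimum is uniquely
  k = 27: 20 singleton turnover clusters plus seven repair-path clusters.
  The centroid cut sizes are {16, 24, 33, 37, 37, 37, 41}; UPGMA places
  five of the SP(4) invariants with the LP(1) cluster instead
  ({16, 24, 28, 37, 37, 37, 46}) — the two routes share their PCNA entry
  and ligation tail, so their invariants differ in only a few positions
  and the split between them is sensitive to linkage.

## Stochastic simulation

One step of the token game: (1) the enabled set is computed (disabled =
knocked-out transitions excluded); (2) each enabled transition joins the
firing list independently with probability 0.5; (3) the list is visited in
a fresh uniform random order; (4) each listed transition fires only if
still enabled at its turn — competitors can consume each other's tokens
within a step.  A transition therefore fires at most once per step and its
frequency (firings/steps) is in [0, 1].  Per step one uniform pair is
drawn for every transition in index order — membership decision and
visiting-order key — from numpy's PCG64; replicate r of a run seeded s
uses PCG64(s + r), making results bit-for-bit reproducible and the hot
loop (numba-compiled, with an identical pure-Python fallback) independent
of chunking.  Defaults follow the study design: 20 000 steps × 20
replicates, firing probability 0.5, no warm-up discard.

Knockouts rerun the same seeds with transitions silenced and report
per-marker frequency deltas plus a two-sided Welch test across replicates
(reported, not enforced).  The battery covers the critical transition of
each synthesis sub-path (`t_90`, `t_62`, `t_62+t_96`, `t_102`, `t_103`,
`t_100`, `t_60`, `t_61`, `t_60+t_61`); the path report tracks the six
markers `t_95, t_46, t_107, t_106, t_47, t_48` and the success marker
`t_169`.  (One published table prints Path 6's marker as `t_46` where the
definition table says `t_48`; the implementation follows the definition.)

## Synthetic test articles

`generate_planted_net` builds unions of elementary circuits whose minimal
t-invariants are the circuits themselves; overlap plans share a path
prefix between circuits, with fork/join places keeping every circuit
individually balanced, and the construction is verified against the
exhaustive enumerator at generation time.  `generate_random_net` samples
bipartite nets for property-based testing (no ground truth claimed), and
`generate_invariant_vectors` produces labelled integer vectors around
disjoint support templates for the clustering stage.  These articles
exercise the analysis code paths, not BER biology: passing them shows the
algorithms are correct, not that the fixture matches any particular
biological dataset.

## Numerical conventions and limitations

* Incidence sign convention: `a_ij = post − pre`; t-invariants are
  sign-convention invariant.
* All invariant arithmetic is exact; no floats touch `A` or `x`.
* Linkage ties are broken deterministically (document above); merge
  heights of centroid/median linkage may invert (classical behaviour).
* The simulation's "frequency" counts at most one firing per step; it is
  a throughput per step, not a reaction propensity.
* The conserved-pool sizes (PNKP, PCNA, HMGB1, RFC, RPA — one token each)
  are model parameters, not measurements; they set the concurrency of the
  end-cleaning and long-patch machinery, and the reported path throughputs
  scale with them.
* The net is unbounded (not conservative): damage influx exceeds repair
  throughput under the 50 % rule, so intermediate complexes accumulate
  over a run; frequencies reported over 20 000 steps are stable to ~0.003
  (1 sd across replicates) but are not stationary-distribution quantities.
* Qualitative semantics only: no rates, no timed/coloured/continuous
  extensions, no reachability analysis.
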