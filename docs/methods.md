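# Methods

## Problem and model

Overflow metabolism — acetate excretion by aerobically growing *E. coli*
— is studied here through constraint-based modelling.  The cell is a
steady-state flux network: `S v = 0` with per-reaction bounds, biomass
maximized.  Two knobs are varied:

1. **The P/O ratio** (ATP per NADH-equivalent electron pair, i.e. per
   ½ O₂ reduced).  It is imposed on the network by rewriting the proton
   stoichiometry of the respiratory dehydrogenases and terminal oxidases
   (table in the README).  The rewrite is *absolute*: each role reaction's
   stoichiometry is replaced wholesale by the pattern evaluated at P, so
   re-parameterization can never compound, and every grid point rebuilds
   from the untouched template.  ATP synthase (4 h⁺ per ATP) is never
   rewritten.  With those patterns the NADH → NADH-dehydrogenase-I →
   cytochrome *bo* → ATP-synthase chain yields exactly
   (2P + 2P)/4 = P ATP per NADH, which is the definition of the knob; the
   tests assert this closed form by LP on the isolated subnetwork.
2. **Oxygen uptake capacity.**  Scenarios fix maximum uptake bounds
   (negative exchange lower bounds; the optimizer may use less):
   glucose −11 mmol gDW⁻¹ h⁻¹ throughout; oxygen −8 ("low") or −15
   ("max"); VHb expression is modelled *solely* as a 1.25× multiplier on
   the oxygen bound (effective −10 and −18.75).  The documented
   limitation: VHb's other reported effects (cytochrome up-regulation,
   Na⁺ pumping, oxygen buffering) are not modelled.

The theoretical P/O range 0.67–2.67 spans the least efficient chain
(non-translocating NADH dehydrogenase II plus *bd* oxidase) to the most
efficient (NADH dehydrogenase I plus *bo*); scans use an inclusive grid
over [0.67, 2.67], default step 0.05 (41 points).  The step is a
resolution choice: fine enough to place a feature "at 1" versus "near 1"
while keeping a genome-scale scan in tens of seconds.

### Which reactions are rewritten

NADH dehydrogenase II (NADH10) is biochemically non-translocating, so by
default it keeps its native stoichiometry (zero periplasmic-proton
coefficient).  Because one could also read the parameterization as
covering it, `apply_po_ratio(..., nadh2_translocating=True)` applies the
NDH-1 pattern to it instead; both readings are first-class.  The
menaquinol-specific paralogs (NADH17pp/NADH18pp, CYTBD2pp) take their
quinone species from the template model rather than hard-coding
ubiquinone, so the rewrite is correct for any quinone pool.

### Degeneracy handling

Genome-scale FBA optima are massively degenerate, so raw flux values are
solver-dependent.  All reported flux distributions are parsimonious-FBA
solutions (minimize Σ|v| at the fixed optimum, split-variable
reformulation), and the cytochrome *bo*/*bd* fluxes additionally carry
FVA ranges at fraction 1.0 of the optimum.  A switch diagnosis is
annotated as degenerate whenever FVA shows the unused oxidase could have
carried flux at the optimum.

## Solver and numerics

All LPs go through HiGHS (scipy.optimize.linprog) with primal/dual
feasibility tolerances of 1e-10, sorted row/column ordering, and no
randomized components — repeated runs are bit-identical.  Every optimal
solution is re-certified independently of the solver
(‖S·v‖∞ ≤ 1e-8, bounds within 1e-9; violations raise rather than pass
silently).  Fluxes below 1e-6 are treated as zero in diagnostics;
reported table values below 1e-9 are clamped to exact zero.  Infeasible
grid points are recorded as rows with status `infeasible`, never
dropped; switch/turning detection skips them with a warning.

Turning-point detection returns the grid point of an interior peak —
the smallest grid P/O that is reached non-decreasingly and after which
the series strictly decreases (tolerance 1e-6) — and `None` for a
monotone series.  Switch detection returns the first grid point at which
the *bd*-role flux exceeds the *bo*-role flux after a point where the
ordering was reversed.

## The bundled core network

`build_core_fixture()` produces a 17-internal-reaction,
10-exchange lumped network (glucose PTS, redox-neutral glycolysis lump,
pyruvate dehydrogenase, pyruvate-formate lyase, TCA lump,
phosphotransacetylase/acetate-kinase, succinate-dehydrogenase lump, the
four P/O-parameterized ETC reactions, ATP synthase, maintenance,
transports, biomass).  It emulates exactly the trade-off that produces
overflow:

* **Respiration** is carbon-efficient but oxygen-expensive: burning
  acetyl-CoA in the TCA lump yields 3 NADH + FADH₂ whose reoxidation
  costs 2 O per acetyl-CoA.
* **The overflow branch** is oxygen-free but carbon-wasteful: glucose →
  pyruvate → (formate lyase) → acetyl-CoA → acetate yields 3 ATP per
  glucose with zero oxygen, spilling two C as acetate and two as formate.

Design choices worth knowing:

* **Redox assignment.**  NADH appears only on the respiratory side (PDH
  and TCA); the glycolysis lump is redox-neutral.  In real glycolysis
  GAPDH makes NADH, but in genome-scale *E. coli* models the overflow
  carbon leaves through pyruvate-formate lyase with no net NADH burden
  (formate carries the redox out), and the lumped network reproduces that
  balance directly.  This is what makes acetate secretion monotonically
  non-increasing in both the P/O ratio and the oxygen capacity — the
  behaviour the genome-scale model exhibits — rather than coupling
  overflow to oxygen through glycolytic NADH.
* **Biomass** drains 2 g6p + 3 pyr + 12 acetyl-CoA (45 glucose carbons)
  plus 65 ATP per unit.  The ATP coefficient is the sizing constant (and
  a `build_core_fixture` argument): large enough that the oxygen
  constraint binds at low P/O under every scenario (so acetate > 0 and
  growth rises with P/O), small enough that at high P/O the −18.75
  oxygen bound goes slack and acetate vanishes.  The resulting growth
  rates (0.46–1.04 h⁻¹ across the scans) are in the physiological range.
* **Maintenance** is 3.15 mmol ATP gDW⁻¹ h⁻¹, the published iJO1366
  default, so core and genome-scale runs share the convention.
* **Closure exchanges.**  Phosphate, cytosolic protons and water are
  freely exchangeable (medium components/byproducts; without a phosphate
  supply the lumped PTS/glycolysis pair would leak one phosphate per
  glucose and block all flux).  The *periplasmic* proton exchange is
  secretion-only: a free periplasmic proton source plus reversible ATP
  synthase would be an unbounded ATP generator.  CO₂ leaves via a
  diffusion step plus exchange.
* **Out of scope** for the lump: NADPH/pentose-phosphate metabolism,
  elemental/thermodynamic full balancing of the lumped reactions, and
  any quantitative agreement with genome-scale fluxes.  The fixture's
  carbon bookkeeping is exactly closed
  (6·|q_glc| = 2·q_ac + q_CO2 + q_for + 45·μ) and the tests assert it.

## What the scans show, and a known discrepancy

On both the core network and iJO1366, across all four scenarios: growth
is non-decreasing and acetate non-increasing in the P/O ratio; at every
grid point the VHb variant grows at least as fast and secretes at most
as much acetate as its wild-type counterpart; and under VHb at maximum
oxygen (−18.75) acetate reaches exactly zero at high P/O (above ≈ 1.9 on
iJO1366, ≈ 1.4 on the core network), where the oxygen bound goes slack
and carbon, not oxygen, limits growth.  On iJO1366 the CO₂ evolution
rate under VHb-max rises with P/O up to a peak near 1.8–2 and falls
beyond it: once oxygen stops binding, higher P/O lets the optimum meet
its ATP demand with less respiration, so less carbon is fully oxidized.

One reported qualitative feature is **not** reproduced by this
formulation: a replacement of the *bo*-type by the *bd*-type oxidase for
P/O > 1.  Under the parameterization table the two oxidases differ only
in pumping (2P versus P protons per ½ O₂), so *bo* strictly dominates
whenever ATP has positive marginal value; FVA confirms the optimum is
unique in this respect at every grid point of every scenario (the *bd*
flux range is [0, 0]), and the result is unchanged if the uptake bounds
are imposed as equalities instead of capacities.  A bo→bd switch can
only emerge from a different proton-chemistry treatment of the oxidase
rewrite — for instance, keeping each oxidase's native chemistry protons
and setting only the pumped protons to P/2P makes the two oxidases
exactly ATP-equivalent, turning the choice into a solver-arbitrary
degeneracy.  The verbatim patterns are retained here; the switch
detector and its FVA degeneracy annotations are the instrument for
examining the question on any model.

## Scale of the shipped analyses

The default test suite and the acceptance script run two genome-scale
scans (41 grid points × FBA + pFBA, plus oxidase FVA in the tests) and
four core-network scans; on one CPU this is roughly two minutes
end-to-end, dominated by the ~2600-column genome-scale LPs.
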