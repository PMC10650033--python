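# Methods

## Model and assumptions

`intrares` simulates a tumor as a discrete-time multi-type branching
process: cells act independently (no cell–cell interaction, no spatial
structure, no microenvironment), all cells are synchronized to a one-day
update clock, and there is no quiescent compartment — each day a cell
either divides or dies.  These assumptions buy exact per-subclone
multinomial updating, which is what makes 10¹¹-cell tumors simulable; they
also mean the model says nothing about spatial heterogeneity or
niche-driven growth-rate changes.

A cell's type is `(sensitizing gene, resistance counts)`:

* **Sensitization.** At most one of nine driver genes may be mutated (XOR
  gate).  A cell with no driver can gain any one of the nine with
  per-division probability `mu_gene`; afterwards the other eight are
  permanently blocked in that lineage.
* **Resistance.** Per drug class (nine inhibitor classes + platinum), an
  unbounded mechanism count.  A cell gains at most one mechanism per
  division.  Resistance to a targeted inhibitor is only available to cells
  already sensitized to the matching gene — sensitivity precedes
  resistance; platinum resistance is available to every cell (the founder
  cell is platinum-*sensitive* and carries nothing).  The text sources for
  this model are ambiguous about whether an unsensitized cell may gain
  resistance to an inhibitor that cannot target it; we block it, following
  the stated ordering (cells "first gain sensitivity, then resistance"),
  and note that for counting *any*-resistance cells the choice is nearly
  immaterial since the platinum route is open to all.
* **Division semantics.** An asynchronous division keeps one parental
  daughter and creates one mutant daughter.  The expected one-step
  multiplication is therefore `2b = 1 + s` independent of the mutation
  load `u`; the alternative convention (both daughters mutate, or parent
  replaced) would couple growth rate to `u` and is rejected.

One flagged inconsistency: with `b = ½(1+s)`, a 5% selection advantage
makes the division probability exceed the death probability by
`b − d = s = 5%` while exceeding the critical value ½ by `s/2 = 2.5`
percentage points.  Prose descriptions of this model sometimes state the
latter as "b bigger than d by 2.5%"; we implement the formula literally
and report the excess over ½ where a 2.5-point figure is expected.

## Simulation engine

Each day, for each occupied subclone with `n` cells and total transition
rate `u`, the split (deaths, synchronous, asynchronous) is
`Multinomial(n, (d, b(1−u), bu))`, sampled as `n_death ~ Binomial(n, d)`
then `n_async ~ Binomial(n − n_death, u)` — an exact decomposition valid
for arbitrary 64-bit counts.  Mutant daughters are allocated over the
subclone's transitions by a multinomial with probabilities `mu_j/u`.  All
subclones update simultaneously from the pre-step state; zero-count
subclones are dropped, so the sparse state stays at a few dozen entries
even in 10¹¹-cell tumors.

Runs start from a single founder cell.  A founder lineage dies out with
probability `d/b` (≈ 0.90 at s = 5%, ≈ 0.99 at s = 0.5%); by default the
simulator restarts extinct attempts with the day reset to zero and reports
the restart count, i.e. all results condition on tumor survival.  This
conditioning is standard and does not bias crossing-time gaps between
large burdens (growth is effectively deterministic above ~10⁶ cells).
Crossing times use the convention "first day with total ≥ threshold,
evaluated after the daily update"; the initial state counts as day 0.

A closed form anchors the timing results: a large population grows
deterministically by `1+s` per day, so the days from `n0` to `n1` are
`ln(n1/n0)/ln(1+s)` — 94.4 days from 10⁹ to 10¹¹ cells at s = 0.05,
923 days at s = 0.005.  Simulated medians match within a day or two.

## Virtual patients

T stage is multinomial over the default counts T1:272, T2:524, T3:109,
T4:43 (a 950-patient NSCLC cohort; 2 Tx patients with unknown stage are
excluded and the probabilities renormalized, since no diameter range
exists for Tx).  Diameter is uniform on the stage's range — T1 (0.5, 3),
T2 (3, 5), T3 (5, 7), T4 (7, 10) cm — volume is spherical, and burden is
volume × 10⁹ cells/cm³ rounded to an integer.  The analytic mean tumor
volume of this generator is
`Σ w_T (π/6)(hi⁴ − lo⁴)/(4(hi − lo)) ≈ 49.3 cm³`, i.e. a mean diagnosis
burden of ≈ 4.93 × 10¹⁰ cells.  (Published parameter tables for this model
quote a mean of 4.26 × 10¹⁰ cells; that value is not derivable from the
stated generator and is documented here rather than targeted by tests.)

## Parameters

| parameter | default | meaning |
|---|---|---|
| `s` | 0.05 | selection advantage; daily growth factor `1+s` (0.05 = aggressive tumor) |
| `mu_sens` (9) | 0.9–3.15 × 10⁻⁵ | per-division sensitizing-mutation probability per gene |
| `mu_res` (10) | 10⁻⁸ | per-division probability of one more resistance mechanism (point-mutation scale) |
| `signature_threshold` | 0.05 | min. sensitized-cell fraction for a gene to count as mutated in a patient |
| `cells_per_cm3` | 10⁹ | volume→cells conversion |
| `days_per_month` | 30.44 | calendar conversion for reported times |

## Cohort signatures and calibration

Per patient, the sensitized fraction per gene is taken over live cells on
the stopping day; bit g is 1 iff fraction ≥ threshold (boundary
inclusive).  Cohort outputs are per-gene percentages of mutated patients
and the per-patient mutated-gene count distribution; model-vs-data
comparison is a two-sided two-proportion z-test per gene (p = 1 for
degenerate both-zero/both-one cases).

The frequency observable responds steeply to `mu_gene`: the mean
sensitized fraction at diagnosis is roughly `b·mu·T` (T ≈ 500 days of
growth), so for `mu` below ~10⁻⁴ the 5% threshold is only reached via
early "jackpot" clones and per-gene patient frequencies stay in the
0–2% range; between ~1 × 10⁻⁴ and ~3 × 10⁻⁴ the mean fraction itself
crosses 5% and frequencies climb from a few percent to a majority of
patients.  A practical consequence, measured with this package: the
published default `mu_sens` values produce per-gene frequencies of ~0.3–2%,
not the tens-of-percent mutation frequencies of real NSCLC cohorts; users
who want realistic cohort signatures should calibrate, which lands
`mu_sens` in the 10⁻⁴ range.

No fitting algorithm is prescribed by the sources, so calibration is an
artifact design: damped multiplicative updates
`mu ← mu·(target/max(obs, ε))^0.5`, clipped to [10⁻⁹, 10⁻³], with
ε = half a patient's frequency; the genes are fitted jointly because the
XOR gate couples them (raising one gene's rate weakly lowers the others'
frequencies).  Convergence is declared when every gene is within the
absolute tolerance (default 1.5 percentage points) of its target *or* no
gene shows a significant two-proportion difference; non-convergence is
reported, not raised.  Defaults: cohort of 500 per iteration, 15
iterations maximum.  The fixture generator draws synthetic targets
uniformly in [1%, 12%] per gene (sum capped at 60%): inside the regime the
model can reach without pinning rates at the upper clip, which keeps
fixture-driven calibration runs well-posed.

## Experiments

* **Resistance scan.** The scalar `u_resistance` of the resistant-burden
  scan is the *total* per-division probability of gaining one resistance
  mechanism, implemented as a single generic class routed through the
  platinum slot (the one class reachable from every cell type); the
  per-drug 10-way split is a configuration alternative with the same
  totals.  Simulations start from one cell (matching the timing protocol)
  and stop at `M × 10⁹` cells; the heatmap value is `log10(count + 1)` of
  the median resistant count.  An analytic accumulation law,
  median fraction ≈ `b·u·ln(N)/ln(1+s)`, holds within a factor of two for
  `u ≤ 10⁻⁵`; at u = 10⁻⁵, s = 0.05, N = 10¹¹ it gives ≈ 0.27% (0.27 cm³
  of a 100 cm³ tumor) — simulated medians come out slightly lower
  (~0.16 cm³) because the jackpot-skewed distribution has median < mean.
* **Stage timing.** Median (and quartiles) of the day gap between the 10⁹
  and 10¹¹ crossings per selection advantage, reported in days and months.

## Problem sizes and numerical choices

Desk-scale defaults are 20 replicates for the scan and 100 for the
timing experiment, cohorts of 150–500 patients for calibration and tests
(flags expose the full 10,000-patient scale).  These sizes put the
stochastic medians well within the tolerances checked: the timing medians
have interquartile ranges of ~1 day, and doubling the scan replicates
moves its medians by far less than the factor-two analytic band.  RNG
streams are `numpy` PCG64 generators seeded per scenario and replicate
from `(seed, scenario, replicate)`; ties and degenerate inputs are
resolved explicitly (zero-probability transitions omitted; empty cohorts,
non-positive burdens and out-of-range rates raise).

## Limitations

Beyond the model assumptions above: the simulator covers growth to
diagnosis only (no treatment phase, no pharmacodynamics — drugs never act
in-simulation); no N/M staging or metastasis (only T determines burden);
synthetic calibration targets emulate per-gene cohort frequencies but not
the covariance structure of real sequencing cohorts, so passing
calibration tests demonstrates parameter recoverability under the model's
own data-generating process, not fidelity to any real cohort.
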