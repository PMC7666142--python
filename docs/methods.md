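# Methods

## The rate budget and its inversion

All rates are per-capita and per day. The model treats each treatment's net
growth rate as the gross growth rate µ minus a linear combination of three
loss terms: grazing mortality m_g, a resource-limitation constraint r_c and
viral mortality m_v. Dilution by a factor D (fraction of whole seawater
retained, default 0.25 for a 1:4 dilution) scales the encounter-dependent
pressures: grazing and resource competition in the diluted (DI) treatment,
and all three in the virus-reduced (VR) treatment, whose 30-kDa filtrate also
removes free viruses. The 0.2-µm filtrate used for DI passes viruses, so the
viral term is undiluted there. The assumptions are the usual ones for such
budgets: losses are additive and density-independent over the incubation,
rates are constant within the fitted exponential window, and the dilution
scales pressures linearly.

The four equations are linear in (µ, m_g, r_c, m_v) and, for D ≠ 1,
invertible in closed form (at D = 1 the DI and VR rows collapse into CT/PR
combinations and the system is singular; such inputs are rejected). The
solver is exact algebra, so `solve_partition(predict_net_rates(p)) == p` to
floating-point precision; the test suite verifies this on random parameter
sets and against a generic dense 4×4 linear solve.

Two consequences of the algebra worth knowing:

* m_g = k_PR − k_CT identically — grazing mortality is a first difference of
  measured rates, with no dependence on D.
* µ = (k_VR − D·k_CT)/(1 − D) after substitution, so gross growth is mostly
  informed by the virus-reduced treatment.

Negative solved components are physically questionable but arise routinely
from replicate noise (a VR/DI ratio below 1 forces m_v < 0). They are
reported as computed and flagged in `negative_components`; an opt-in
`truncate_negative` clamps them at zero after solving. Partitions are
computed on replicate-mean rates by default; `bootstrap_partition` resamples
replicate bottles (999 draws, seeded) to propagate bottle-to-bottle scatter
into component standard deviations and percentile intervals.

Mortality partitioning uses only the four light-incubated treatments
(CT_L, PR_L, DI_L, VR_L); dark bottles exist only for CT and PR and never
enter the partition.

## Rate estimation

Net growth rates are the slope of ordinary least squares of ln(cells mL⁻¹)
on time in hours, × 24. No weighting is applied (no variance model is
assumed for microscopy counts), and rates are fitted per replicate bottle,
then aggregated to the replicate mean and sample standard deviation.
Two-point series (the AAP protocol) use the exact two-point log difference
and report no r². Zero or negative abundances make the logarithm undefined;
such series are rejected with the offending index, and at table level the
rejection is recorded as an issue rather than aborting the run.

The default fits the full series. An opt-in `best_window` mode scans every
contiguous sub-series of at least `min_points` (default 3) observations and
keeps the window maximizing r², breaking ties toward the longer window and
then the earlier start; with noiseless data a constant segment also has
r² = 1 by convention (zero slope, zero residual), and the length tie-break
then correctly prefers the longer exponential segment. This mode exists for
series with a lag phase or late saturation where only part of the time
course is exponential; both the mode and the window used are recorded in the
output.

Response ratios divide replicate-mean rates between treatment pairs. A
denominator at or below epsilon (default 1e-6 day⁻¹) makes the ratio
undefined — near-zero control rates would otherwise produce arbitrarily
large ratios — so the value is reported missing with the reason, and the
rate difference (numerator − denominator) is always reported as a fallback
effect size.

## The synthetic campaign

The generator emulates a four-season campaign: six treatments (CT_L, CT_D,
PR_L, PR_D, DI_L, VR_L), triplicate bottles, four sampling points evenly
spaced over 36 h (winter, summer) or 48 h (spring, fall). Initial total
density and the per-group fractions of total DAPI counts come from the
packaged in-situ tables (`table1`, `table2`). Each group × treatment
trajectory is exponential at the net rate implied by the group's generating
partition, the treatment's pressure factors and — under light — a
multiplicative light modifier on µ; DI and VR start at 0.25 × the ambient
density because dilution removes starting cells too. AAP, counted by a
different microscopy protocol, is sampled at only the first and last time
point and only in CT/PR; consequently no partition is attempted for it and
the pipeline records that gap as a warning rather than an error.

Default rate parameters are fixed package constants chosen once to sit
within the growth-rate ranges published for the same coastal observatory:
slow, abundant oligotrophs (SAR11: µ ≈ 0.55 day⁻¹) through fast opportunists
(Alteromonadaceae: µ ≈ 3 day⁻¹ ambient, up to ~4 under the seasonal
multipliers). Seasonal multipliers on the loss terms encode the qualitative
seasonal pattern the campaign design anticipates — grazing heaviest in
winter, resource limitation heaviest in summer, viral pressure elevated in
fall and spring — and light modifiers exceed 1 only for groups with known
photoheterotrophic members (SAR11 1.10, Bacteroidetes 1.05,
Rhodobacteraceae 1.05, NOR5 1.05, AAP 1.15). Because the partition is
identified from light-incubated treatments, the retained ground truth stores
µ × light_modifier per group; that is the quantity the solver can recover.

Noise is multiplicative mean-1 lognormal on the expected density with CV
10 % by default, a generic stand-in for microscopy counting scatter; a
Poisson mode (counts at a cells-per-count scale, default 1000 cells mL⁻¹
per counted cell) is available, as is a lag/plateau trajectory mode used to
exercise window detection. Seeds are mandatory in the design object and all
draws flow from one `numpy` Generator, so identical seeds give byte-identical
tables.

What the generator does **not** emulate: mechanistic predator–prey–virus
dynamics (pressures are constant rates, not interacting populations),
nutrient drawdown, bottle effects, grazer regrowth within incubations, the
~20 h between sampling and incubation start, or probe coverage/specificity
biases. Passing recovery tests therefore demonstrate the correctness of the
estimation and partitioning arithmetic under the model's own assumptions,
not robustness to these real-data complications.

### Nesting of probe-defined groups

Taxonomically, ALT and NOR5 nest within GAMMA, and the proteobacterial
groups plus Bacteroidetes nest within EUB. The published in-situ fractions
violate strict child-sum ≤ parent nesting in three of four seasons (probe
coverage is imperfect), so the nesting check is advisory by default: it
returns messages, and `strict=True` raises. Since every group grows
independently exponentially, nesting can only be conserved over time when it
holds at t = 0 and the nested family shares growth parameters; the property
test uses such a compliant family. AAP is a functional category overlapping
several phylogenetic groups and is excluded from the budget check.

## Summary statistics

* **Range summaries** take per-group (min, max) rate pairs across
  experiments, compute overall min-of-mins / max-of-maxes and the exact
  spread, and additionally report the spread rounded half-up to one decimal
  — conventional table rounding, where banker's rounding would differ (0.25
  → 0.3, not 0.2). The packaged multi-study range table carries its printed
  Range row, which is treated as authoritative for spread checks even where
  it disagrees with individual per-experiment cells.
* **ANOVA + Tukey HSD** use scipy's one-way F test and statsmodels'
  `pairwise_tukeyhsd` at α = 0.05. Zero within-group variance with unequal
  means (e.g. constant triplicates) is handled explicitly as F = ∞, p = 0.
  The post hoc table can be skipped (`include_tukey=False`) in simulation
  loops where only the omnibus p matters.
* **Ward clustering** uses scipy's linkage, either classical (euclidean, on
  raw features) or with the minimum-variance update applied to Bray–Curtis
  dissimilarities — the default distance for relative-abundance community
  profiles. The dendrogram exports as Newick-style nested text. Tests check
  the merge heights against an independent O(n³) agglomeration that
  recomputes Ward costs from cluster centroids.
* **PERMANOVA** is implemented in-package as the one-way pseudo-F on squared
  distances with free permutation of raw labels and
  p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1). It is seeded and
  bit-reproducible; groups with a single member are rejected. A test
  cross-checks the pseudo-F against scikit-bio's implementation. The default
  pipeline applies it to Bray–Curtis distances between final-time community
  profiles, grouped by treatment.

## Pipeline and formats

The tidy abundance CSV has columns `season, treatment, replicate, group,
time_h, cells_per_ml` (comma-separated, UTF-8, dot decimals, header
mandatory). The reader validates dtypes, non-negativity and key uniqueness
with file line numbers, and rejects decimal-comma / semicolon dialects with
an explicit hint instead of misparsing them. Every output CSV re-validates
through its own reader. A run writes all intermediates, one machine-readable
warnings table (negative components, skipped ratios, coverage gaps,
unfittable series), and `run_log.json` with the seed, a hash of the run
semantics (excluding the output location) and package versions; identical
configuration and seed reproduce the report byte for byte.

## Problem sizes

The verification scripts use 1,000 random parameter sets for the inversion
round trip, the full four-season noiseless campaign (~2,400 records, 208
fitted rates, 32 partitions), 200 noisy single-season simulations at CV
10 %, 2,000 ANOVA and 500 PERMANOVA null draws (199 permutations each) for
calibration, and 50 lag-series for window detection — sizes at which every
check runs in seconds while keeping Monte-Carlo standard errors well inside
the asserted bands.

## Known limitations

Grazing reduction by 1-µm filtration is treated as complete removal
(grazer_factor 0 for PR), dilution as exactly linear in pressure, and the
budget as identifiable only from the four light treatments. Rates below the
ratio epsilon produce missing ratios rather than signed infinities, which
slightly censors strongly negative control rates. The bootstrap resamples
bottles within treatments and thus ignores any correlation between
treatments induced by shared source water.
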