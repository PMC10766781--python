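# Methods

## The combinatorial TAG-oxidation model

Bulk NMR quantifies oxidation *groups*, not intact species: aldehyde and
epoxide groups add one oxygen to a fatty-acid (FA) chain, a hydroperoxide
adds two. The model makes two assumptions. First, a chain carries at most
one oxidized group — multiple oxidation of the same chain is rare in
predominantly mono-unsaturated oils such as rapeseed, where oleate dominates.
Second, all TAGs share a mean molar mass (default 885 g/mol, triolein), so
1 kg of oil is 1000/885 ≈ 1.13 mol TAG and 3 × that ≈ 3.39 mol FA chains.
Dividing the group concentrations by the chain pool gives per-chain
fractions p₁ (one added oxygen), p₂ (two), p₀ = 1 − p₁ − p₂. The three
glycerol positions are treated as independent draws from (p₀, p₁, p₂); the
TAG-level oxidation-degree distribution P(k), k = 0..6, is the trinomial
expansion over the 27 ordered chain-state triples. P(k) supplies the
composition fractions that normalize the selectivity factor.

Two precision modes exist. Full precision (default) carries the raw
concentrations through unrounded. `round_decimals=3` first rounds p₁ and p₂
to three decimals, reproducing calculation chains that start from fractions
quoted at reporting precision (0.056 / 0.070 / 0.874 for the oxidized oil);
the two modes differ by ≲ 0.15 percentage points in P(0). The acceptance
script uses the reporting-precision mode because the reference percentages
it reproduces were derived from the rounded fractions. Degrees with
P(k) below a configurable threshold (default 0.5 %) are flagged negligible;
for the default oil inputs that is k = 5, 6 (≈ 0.12 % combined).

Chains truncated by aldehyde scission ("2.5 glycerides") are counted as
intact 1-oxygen chains; their true masses fall partly in the non-oxidized
m/z region, which the leakage term of the generator emulates but the
composition model ignores.

## Species, adducts, masses

OOO (triolein, C₅₇H₁₀₄O₆) and OOL (dioleoyl-linoleoyl-glycerol, C₅₇H₁₀₂O₆)
are the built-in species; formulas are parsed and summed with pyteomics.
Oxidation adds n × 15.9949 Da (monoisotopic; 16 in nominal mode). Adducts
[M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ add the cation mass minus the electron. Observed
quadrupole tables are matched at ±0.7 Da only: theoretical masses are
reproducible, instrument calibration offsets are not. Integration windows
are half-open [lo, hi) so a stick is counted in exactly one window of a
partition; boundary handling is a convention, not a measurement claim.

## Spectra and integration

FIA scans are summed, not averaged, into one composite centroided spectrum:
the selectivity factor is scale-invariant, so the choice cannot bias it.
Stage-1 areas sum sticks inside a window; stage-2 extracted-ion areas sum
sticks within ±0.35 Da of the target (unit-resolution default, configurable).
Replicate spread is the sample SD (n − 1); a single replicate reports SD 0
with a flag. mzML support is a compact reader/writer for centroided spectra
(base64 32/64-bit little-endian arrays, optional zlib) plus two-column CSV.

## The selectivity factor

S = (A_ox / f_ox) / (A_nonox / f_nonox). S is computed per replicate and then
averaged — preserving mean ± SD semantics — rather than averaging areas
first; on the generator's multiplicative noise the difference is
second-order. A_nonox = 0 yields an infinity sentinel (possible only if the
non-oxidized species gives no signal at all and nothing fragments into its
mass); sentinels are excluded from ANOVA with a logged count, since an
infinite response cannot enter a linear model. f = 0 (e.g. fresh oil with no
measurable oxidation) raises a normalization-undefined error instead.

## The 3⁵⁻¹ design

Five factors at three levels: additive type (NH₄Fo / NaOAc / NaI —
categorical, no level ordering), additive concentration 0.05 / 0.1 / 0.2 mM,
sheath-gas temperature 150 / 250 / 350 °C, capillary voltage 2000 / 3500 /
5000 V, nozzle voltage 500 / 1000 / 1500 V. The regular one-third fraction
takes the full 3⁴ factorial on A–D in lexicographic order and sets
E = A+B+C+D (mod 3). Any all-nonzero GF(3) generator keeps main effects
unaliased with each other and two-way interactions aliased only with
three-way-or-higher terms; the coefficient vector is configurable. The
lexicographic run numbering is an internal label, though with the default
generator it lines up with the condition-set numbering used in practice
(additive blocks 1–27 / 28–54 / 55–81). Validation checks run count (81),
uniqueness, one-factor balance (27) and two-factor balance (9), and reports
the confounding implied by the generator.

## ANOVA, Tukey, recommendation

Per response (species × oxidation degree; responses are never pooled), the
replicate-level selectivity is decomposed by OLS (statsmodels) into five
main effects (2 df) and ten two-way interactions (4 df) with sequential sums
of squares; on the balanced orthogonal fraction types I/II/III coincide, so
sequential is used with the balance stated as a precondition. A saturated
model (no residual df) is an error directing the user to replicates or a
main-effects-only model. A `log` response transform is exposed: under
multiplicative log-normal noise the log-selectivity errors are exactly
Gaussian, so F tests are exactly calibrated there; raw selectivity is the
default.

Tukey comparisons use the residual mean square of the *factorial* model with
studentized-range critical values (scipy). The usual one-way Tukey helper
would refit a one-way model and use the wrong error term, so the comparison
is implemented directly (Tukey–Kramer form, exact here since levels are
equally replicated).

Condition ranking z-standardizes selectivity within each response, averages
across responses, and breaks ties by lower replicate SD; a response with no
between-condition variance is flagged "no discrimination". Per-factor advice
lists the Tukey-winning levels (not significantly below the best) by
majority across responses. α = 0.05 throughout; no correction is applied
across responses — a documented limitation, as up to eight responses are
tested in a typical campaign.

## The synthetic-data generator

Per ion (species × oxidation degree × adduct), intensity =
scale × species abundance × P(k) × efficiency × adduct weight × noise.
Efficiency is a product of a base term, per-factor level curves (separate
curves for oxidized and non-oxidized species), and optional two-way
multipliers; the stage-2 selectivity of a noise-free spectrum therefore
equals the planted efficiency ratio exactly, which is the package's central
oracle. Adduct weights are keyed to the additive: ammonium formate yields
ammoniated ions with minor protonated/sodiated signal, sodium salts yield
sodiated ions. Leakage moves a fraction f of each oxidized stick to the
species' non-oxidized m/z, conserving total intensity and biasing
window-based selectivity downward, as in-source fragmentation does. Noise is
multiplicative log-normal with unit mean (default CV 10 %, a realistic ESI
repeatability figure); campaigns default to duplicate measurements. Seeding
uses a spawned seed sequence per (run, replicate), so campaigns are
bit-reproducible and replicates independent.

The default planted scenario mirrors the qualitative behavior the method is
meant to detect — sodiated ionization of oxidized TAGs strongly favored over
ammoniated, roughly two-fold gain at the high capillary-voltage level — with
its optimum at (NaOAc, 0.1 mM, 250 °C, 5000 V, 1500 V). It is a test
scenario with arbitrary but plausible magnitudes, not a claim of reproducing
measured selectivities.

What the generator does **not** emulate: isotope envelopes, profile peak
shapes, matrix ion-suppression between co-infused species, mass-calibration
drift, and species-specific oxidation rates (OOL oxidizes faster than OOO in
reality; the generator applies one composition to all species). Passing
tests therefore demonstrate the correctness of the analysis chain on
idealized spectra, not instrument-level fidelity.

## Numerical conventions and test scales

- Distribution probabilities are renormalized after the 27-term summation to
  absorb float drift; invariant checks use 1e-9.
- Selectivity is non-negative by construction; equality-to-oracle tests use
  relative 1e-9; reference values are compared at their reported precision.
- The ANOVA null-calibration test runs 500 seeded single-species campaigns
  at reduced spectrum size (one species, ≤ 3 oxidation degrees) and checks
  the pooled rejection rate of the 15 terms against 0.05 ± 2 binomial SE;
  pooling is used because 15 per-term checks at ±2 SE would fail by
  multiplicity about half the time even under perfect calibration.
- Optimum-recovery uses 20 seeded campaigns at CV 10 % and requires ≥ 18
  successes. Problem sizes throughout the suite (162-spectrum campaigns,
  ≤ 500 repetitions) were chosen so the full distribution of each statistic
  is exercised at desk scale.

## Known limitations

- Only single-generator regular 3⁵⁻¹ fractions are supported; no general
  design-search algebra.
- No peak picking: inputs must be centroided. Profile data and
  chromatographic (time-domain) integration are out of scope.
- Standards' composition distributions must be supplied from their own NMR
  measurements; none are built in.
- Infinite-selectivity records are informative (perfect suppression of the
  non-oxidized signal) but are necessarily excluded from the linear-model
  statistics; heavy censoring of a response will reduce ANOVA power and is
  surfaced via logged exclusion counts.
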