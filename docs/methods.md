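# Methods

This note documents the models implemented in `fabrefine`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that make every run reproducible.

## 1. Mutation-energy scanner

### Model

A candidate point mutation is scored as a folding-free-energy difference,

    ΔΔG = [E_folded(mut) − E_unfolded(mut)] − [E_folded(wt) − E_unfolded(wt)],

with positive values destabilizing. The unfolded-state reference is an
isolated extended tripeptide (φ = ψ = 180°) spanning the mutated site ±1
residue, built with the same side-chain builder and scored with the same
energy terms — a standard minimal reference that keeps ΔΔG finite, fast,
and exactly zero for identity substitutions. Multi-site ΔΔG uses one
tripeptide per site and assumes the sites are non-adjacent in sequence.

`E` is a five-term heavy-atom (united-atom) function; the reported value is
the weight-vector dot product of the terms (`TermWeights`, default
1,1,1,1,1 — the weighting scheme is exposed rather than asserted, since no
canonical weights exist for a function this coarse):

| term | form | key defaults |
|---|---|---|
| van der Waals | Lennard-Jones 6-12, pair ε = √(εᵢεⱼ), rmin = rᵢ+rⱼ | element-based table; 8 Å cutoff, switching from 6.5 Å; +10 kcal/mol per-pair repulsion cap |
| electrostatics | Coulomb, distance-dependent dielectric ε(r) = 4r | per-(residue, atom) charge table, hydrogens folded into heavy atoms |
| polar solvation | pairwise Generalized Born, Still-style | effective radii from a coarse pairwise descreening sum (ρⱼ³/3r⁴ volume term), offset 0.09 Å, solvent ε = 80 |
| non-polar solvation | γ·SASA | γ = 0.0054 kcal/mol/Å², Shrake–Rupley probe 1.4 Å |
| side-chain entropy | RT·ln(n_rot)·burial | RT = 0.596 kcal/mol, n_rot = rotamer-library size, burial = 1 − SASA/maxSASA clipped to [0,1] |

Parameter tables (LJ, charges, GB/SASA radii, rotamer counts and reference
maximal SASA) ship as versioned CSV resources under `fabrefine/data/`.

Numerical conventions: bonds are detected by distance (< 1.95 Å heavy-atom,
< 2.3 Å involving sulfur) restricted to the same or sequence-adjacent
residue; non-bonded exclusions are all pairs within three bonds (1-2, 1-3,
1-4). The repulsion cap exists because mutant side chains are placed with
idealized geometry and never minimized: residual overlaps are inevitable,
and an uncapped r⁻¹² wall would let a single bad contact dominate every
ΔΔG. The cap leaves the attractive well untouched. SASA uses a fixed
960-point golden-spiral sphere so results are bitwise reproducible. The
entropy term is scaled by burial so that it cancels for solvent-exposed
sites and approaches the full RT·ln(n_rot) penalty for buried ones; in the
extended tripeptide reference it is close to zero by construction.

### Mutant construction

Backbone atoms are never moved. The mutant side chain is rebuilt from
internal coordinates (CB from the backbone frame — also used to reconstruct
CB on glycine targets — then side-chain atoms by NeRF placement), with χ
angles drawn from a coarse rotamer library: staggered {−60°, 180°, +60°}
for sp³ torsions, {±90°} for aromatic ring flips, later torsions of long
side chains pinned at 180° to cap combinatorics (library sizes 1–27). The
rotamer with the fewest heavy-atom clashes against all other residues wins
(clash: d < 0.8·(rᵢ+rⱼ); ties → lowest rotamer index). Identity mutations
return the input structure unchanged.

### What the scanner is not

It is a transparent stand-in for the commercial force-field scans used in
practice. Its absolute energies are not comparable to production
molecular-mechanics force fields and are asserted nowhere; the package's tests pin its *properties* (exact
zero for identity, additivity of distant sites, linearity in the weights,
approximate forward/backward cancellation) rather than its numbers. The
construct-design layer therefore consumes externally supplied energy tables
at face value.

## 2. Design rules

The selection logic over a candidate table (each row a mutation with ΔΔG in
the parental/murine structure and in the humanized homology model) is a
small reconstructed rule system, with thresholds exposed in `DesignRules`:

* back mutation → revert if ΔΔG_parental < 0, or ΔΔG_model < −0.5 kcal/mol
  ("strongly model-stabilizing"), or the substitution involves Gly or Pro;
* humanizing mutation → accept if each context is stabilizing (≤ 0) or
  negligible (< 0.5 kcal/mol);
* epitope-ablating mutations are included unconditionally.

Two reconstruction caveats are worth stating plainly. First, the
model-context clause exists to admit back mutations that are mildly
destabilizing in the parental context but strongly stabilizing in the
model; whether such rows were originally selected on that energetic ground
or for other reasons is not documented, so every `Decision` records which
rule fired, making alternative reconstructions easy to compare. Second,
the humanizing rule is deliberately per-context ("stabilizing or
negligible" in *each* structure) — a conjunction over contexts of a
disjunction over reasons — because that is the only simple predicate
consistent with every row of the bundled tables, including a row that is
clearly stabilizing in one context while negligible in the other.

Net energies are exact `math.fsum` sums over selected rows, reported to two
decimals with half-away-from-zero rounding (the convention of printed
tables); ΔTm and potency ratios round the same way at one decimal.

## 3. Humanness scoring

T20-style humanness is the mean percent identity of the query's top 20
matches in a human V-sequence database. Alignment is global (Biopython
`PairwiseAligner`): match +1, mismatch 0, gap open −10 (first gap position)
and −1 per extension; identity = 100·matches/alignment_length, counting gap
columns in the denominator so indels are penalized. The gap parameters are
declared defaults, not values recovered from any reference tool. At
package scale the original tool's similarity-search retrieval step is
replaced by an exhaustive scan — identical top-k result, slower, irrelevant
at a few hundred database entries.

Framework-only scoring masks CDR positions from the *query* (the database
side is aligned full-length). Consequence worth knowing: against a
full-length database, framework-only scores are depressed by the gap
columns where the database entries' CDRs go unmatched, so full-length and
framework-only scores are on different scales — compare constructs within
one scoring mode, never across modes or databases. Absolute scores are
database-dependent by construction; the package ships a synthetic database
generator, not a reference database.

## 4. Epitope scanning

MHC class II presentation is dominated by a 9-mer core inside a ~15-mer
peptide. The scanner scores every 15-residue window by the maximum over
its seven 9-mer core offsets under a 9×20 position-specific scoring matrix
(sequences of length 9–14 are one window); ties go to the leftmost core.
Windows at or above the "moderate" threshold are hits; "high" is a second
threshold. Core coordinates are 1-based with an inclusive start and
exclusive end, and a mutation ablates a hit if its position lies inside the
core. A trained neural predictor is out of scope by design: the downstream
decision consumes a binary "moderate-affinity epitope present" flag, and
any real matrix can be supplied as CSV. The bundled defaults and the toy
matrices in tests/examples carry no immunological calibration.

## 5. SPR kinetics

The bivalent-analyte scheme (both phases, concentration C during
association, 0 after):

    d[AB]/dt  = 2·k_on·C·L − k_off·[AB] − k_on2·[AB]·L + 2·k_off2·[AB2]
    d[AB2]/dt = k_on2·[AB]·L − 2·k_off2·[AB2],   L = R_max − [AB] − [AB2]

response = [AB] + [AB2], zero initial state. The statistical factors
(2·k_on for first attachment of a two-armed analyte, 2·k_off2 for release
of either arm) follow the conventional instrument-software formulation;
K_D = k_off/k_on uses the apparent first-step constants and is reported in
nM to three significant figures. With k_on2 = 0 the scheme reduces to 1:1
Langmuir with apparent association constant 2·k_on, which gives the
closed-form oracle used in tests.

Integration is LSODA with rtol 1e-8/atol 1e-10, association and
dissociation integrated separately onto a fixed output grid; all
concentrations of a series are stacked into one ODE system. The global fit
is least squares in log-parameter space (positivity built in, sane
conditioning across five orders of magnitude), initialized at k_on = 1e5
M⁻¹s⁻¹, k_off = 1e-3 s⁻¹, k_on2 = 1e-4 RU⁻¹s⁻¹, k_off2 = 1e-3 s⁻¹, R_max =
1.1 × max observed response — magnitudes typical of nM-affinity IgG
kinetics. Standard errors come from the Jacobian at the optimum.
Degenerate inputs (flat/zero series) raise a `FitError` carrying the last
iterate rather than returning nonsense. Mass-transport limitation and
surface heterogeneity are not modeled.

## 6. Thermal-shift analysis

Melt curves are analyzed by the derivative method: centered moving-average
smoothing (default window 5 points — the vendor smoothing behind published
Tm values is unpublished, so the window is a documented default),
central-difference dF/dT, local maxima above a prominence floor (default 5%
of the tallest peak), and a parabolic refinement of the peak vertex. Flat
curves return an empty peak list, not an error. Antibody samples show Fab
and Fc transitions; rather than guessing which peak is which, every peak is
returned with its rank and `pick_fab_peak` selects inside an expected Fab
window (default 60–85 °C, the approach of calibrating peak assignment with
Fab/F(ab')₂ reference preparations).

ΔTm is the difference of replicate means (1 decimal, half away from zero);
significance is a two-tailed pooled-variance Student's t — pooled, not
Welch, matching the plain "Student's t" convention of thermal-shift
reporting — available from raw replicates or from (n, mean, SD) summaries.
Published ± values on triplicate Tm are treated as SD, the reading
consistent with the p-values those summaries reproduce.

## 7. ADCC dose-response

Specific lysis = 100·(sample − spontaneous)/(maximal − spontaneous).
Curves are fitted to the variable-slope 4PL in log₁₀ concentration,
initialized from the data (min/max for the asymptotes, the concentration
nearest half-maximum for EC50, hill 1). Falling fits are re-expressed in
the rising parameterization; fits whose EC50 leaves the tested range by
more than 1000× are flagged as unbounded. EC50 comparison refits both
curves with a single shared log₁₀EC50 while top/bottom/hill stay per-curve
— the narrowest null hypothesis matching "best-fit EC50s were compared" —
and applies the extra-sum-of-squares F-test, F = [(RSS_shared −
RSS_sep)/1]/[RSS_sep/(N − 8)]; a shared fit that beats the separate fits
clips F at 0 with p = 1. Sharing all parameters instead is a one-line
config change in the comparison routine. Relative potency is
EC50_ref/EC50_test at one decimal; effector:target ratio is carried as
metadata, not modeled.

## 8. Synthetic data: what it does and does not show

All generators are pure functions of (parameters, seed).

* **Toy structure** — a designed two-chain four-helix bundle (~52
  residues/chain, heptad a/d hydrophobic core, helix roll chosen to point
  core side chains at the bundle axis, one surface glycine per chain as a
  CB-reconstruction test site), packed with the scanner's own deterministic
  builder. It provides genuinely buried and exposed sites and exercises
  every scanner code path, but it is *not* an immunoglobulin fold: nothing
  tested on it speaks to β-sandwich packing, CDR loop strain, or
  VH–VL-interface effects in real Fabs.
* **V-sequence database** — entries derived from two bundled germline-like
  heavy/light templates by seeded uniform point substitution (default rate
  0.05, roughly the identity spread of somatic variants around germline).
  Real repertoires have position-dependent mutation hotspots, indels, and
  family structure; none of that is emulated, which is why absolute T20
  values from this database are meaningless outside it.
* **Assay bundle** — the study conditions, fixed as defaults: a 50–1600 nM
  twofold SPR dilution series (six concentrations, 2-min association,
  300-s dissociation, 1-s grid) around k_on = 1.09×10⁵ M⁻¹s⁻¹, k_off =
  1.25×10⁻³ s⁻¹, R_max = 100 RU; melt curves on a 25–99 °C ramp (~0.74 °C
  step) with Fab (73.6 °C) and Fc (81.6 °C) transitions in triplicate; and
  triplicate 8-point lysis curves (10⁻⁵–10⁻¹ μg/mL) around EC50 =
  2.61×10⁻³ μg/mL, hill 1.2, top 60% lysis. Noise is i.i.d. Gaussian
  (defaults: 2% of R_max on SPR response, SD 0.5 a.u. on fluorescence, 3
  lysis percentage points), which is sufficient for parameter-recovery and
  calibration tests but omits drift, bulk-shift artifacts, heteroscedastic
  counting error, and plate effects — so passing recovery tests bounds
  solver correctness, not robustness to real instrument pathology.

## 9. Scope boundaries and known limitations

* Mutation positions index the mature V-region sequence directly (the
  `HC:G54I` convention); no Kabat/IMGT renumbering is implemented, and
  region labels are supplied annotations, never computed.
* PDB input honors ATOM records only; altlocs resolve to highest occupancy
  (ties → first encountered), hydrogens are dropped, residues with
  incomplete backbones are excluded with a collected warning. Chain → HC/LC
  mapping is always an explicit configuration, never guessed.
* The scanner models no protonation, no minimization, no explicit water,
  and proline's ring is built approximately (no ring-closure constraint).
* Candidate lists are inputs: deciding *which* positions are humanizing or
  back-mutation candidates (germline-template comparison) is upstream of
  this package.
* Wet-lab stages (expression, purification, radiolabeling) and clinical
  interpretation are out of scope.
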