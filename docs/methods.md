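# Methods

This note documents the models and procedures implemented in `cbsvar`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Variant panel and fixtures

The unit of analysis is a single amino-acid substitution in human CBS
(protein reference NP_000062, mRNA NM_000071), carried on a yeast expression
plasmid and assayed by complementation of a *cys4*Δ strain. Two bundled TSV
fixtures transcribe the published panel: the 58-variant pyridoxine-titration
table (four doses: 400, 4, 2, 1 ng/mL) and the 9-variant *hem1*Δ
dual-cofactor table (400/2 ng/mL pyridoxine × 50/5 µg/mL δ-ALA). Rates are
dimensionless ratios to the major-allele strain in the same medium.

Representation decisions:

* "n/d" (not determined) and the printed 0 of a no-growth nonfunctional
  variant are both stored as an absent rate; the category field carries the
  distinction. The scatter output re-materializes the printed 0 for
  nonfunctional records.
* Significance marks are an enum (`p01` for *P* < 0.01, `p001` for
  *P* < 0.001) mirroring the single/double asterisks of the source table.
* Construction method (directed vs random mutagenesis) is `unknown` for all
  bundled records — the table does not print it — so the six-group
  (phenotype × construction) permutation design runs only on synthetic
  panels; the three-group phenotype design runs on the bundled panel.
* Validation treats violations as data (a list of messages), so a panel's
  problems are reported all at once. Checked invariants include unique
  plasmid ids and substitutions, absence of rates on nonfunctional records,
  and consistency of the printed nucleotide position with the codon implied
  by the residue number (±2 nt).

## Growth-rate estimation

For each well: OD₅₉₅ values are rescaled so the final kinetic read equals
the resuspended endpoint read (the endpoint is treated as a calibrated
density, so per-well gain and settling artifacts divide out), log₁₀
transformed, and the rate estimated as the ordinary-least-squares slope
over all reads whose OD lies in a fixed window — 0.05–0.1 for *HEM1*
strains and 0.1–0.2 for *hem1*Δ strains, membership inclusive on both
bounds. A two-point variant (first/last in-window read) is available for
sensitivity analysis. Non-positive readings are dropped before the log
transform with a logged warning. If fewer than two reads fall in the
window, the estimate is reported as "window not attained" rather than as an
error — that state is what identifies no-growth wells.

Plate normalization multiplies every rate on a plate by
(grand mean of reference rates across plates)/(mean reference rate on the
plate), which equalizes per-plate reference means and preserves
within-plate variant/reference ratios; the reference strain is the
major-allele transformant. The formula is anchored this way so that the
major allele's relative rate is exactly 1 by construction.

Numerical properties (all tested): on noise-free exponential curves the
estimator recovers the generating rate to 1e-9 for any window; estimates
are invariant under any uniform multiplicative OD gain; with exactly two
in-window points OLS reduces to the two-point slope.

### Precision under the default noise model

On noisy logistic curves the estimator shows a systematic attenuation:
window membership is decided on the noisy reads themselves, and selecting
on the dependent variable clips high readings at the lower bound and low
readings at the upper bound, flattening the fitted slope by roughly 10–15%
at the default noise level (additive σ = 0.005 OD against a window at
0.05–0.1 OD), on top of the ~7% logistic saturation attenuation at the
window midpoint. Because the attenuation is close to proportional across
strains it cancels almost entirely in the variant/major ratio: recovered
mean ratios are unbiased to within ~0.005. Precision, however, is limited:
a single curve's slope carries a standard error of ~7–10%, so a ratio
estimated from three replicate wells per strain has an SD of ~7%, and the
median absolute relative error of such ratios sits at about 5–6%. This is
an inherent property of the windowed-slope estimator at these noise
settings, not of the implementation; the replicate count (3) matches the
assay's "at least three independent transformants" design.

## Phenotype calls

* **Nonfunctional**: no determinable rate at the 400 ng/mL pyridoxine dose.
* **Sensitive**: at least one dose flagged significant. For the bundled
  fixtures the printed flags are authoritative (no raw replicates exist to
  recompute them); recomputation mode applies a Welch two-sample *t*-test
  to replicate ratios. Welch rather than pooled-variance because replicate
  counts are small and the printed SDs are visibly unequal between strains.
  Identical zero-variance samples give *p* = 1 by convention.
* **Benign**: everything else.
* **Faster than wild type**: a sensitive variant all of whose flagged doses
  point in the faster direction (rate ratio > 1). Mixed-direction variants
  would remain sensitive but not "faster".
* **Dual sensitivity** (*hem1*Δ panel): evaluated at high B6 (400 ng/mL)
  and low δ-ALA (5 µg/mL); a variant is dually cofactor-sensitive if its
  rate there is undeterminable or below a floor, default 0.1. The floor
  operationalizes "extreme" sensitivity: the bundled panel's values at that
  condition are 0.07 and below (the two dual alleles) vs 0.58 and above
  (all others), so any floor in (0.07, 0.58] yields the same set.
* **Heme saturation**: the 430 nm (heme Soret) to 280 nm (aromatic)
  absorbance ratio, clipped to [0, 1], with 1.0 = full incorporation per
  the one-to-one calibration of the fully loaded enzyme.

## Structural features

Structures are read from PDB files (gemmi); hydrogens are ignored, altlocs
resolved to the highest occupancy, insertion codes rejected. File numbering
maps to NP_000062 numbering through an explicit integer offset (or
per-residue map) — deterministic and auditable, no alignment. When a
position occurs in several chains, distances take the minimum over copies,
SASA and B-factor the mean, secondary structure "any".

* **Distances**: minimum Euclidean distance over all heavy-atom pairs
  between the residue and the cofactor group (heme = HEM; PLP = PLP/LLP,
  configurable). Default scope searches all chains, since CBS is oligomeric
  and a neighboring subunit's cofactor may be nearest; a same-chain scope
  supports monomer-level analysis.
* **Solvent accessibility**: Shrake–Rupley rolling-probe area with probe
  1.4 Å and 960 sphere points per atom, element-based van der Waals radii,
  all protein and ligand heavy atoms as occluders. The sample lattice is a
  deterministic Fibonacci spiral oriented per atom in a local frame built
  from its two nearest non-collinear neighbours, which makes the
  discretized area exactly invariant under rigid-body motion for generic
  geometries (a lab-fixed lattice is only approximately invariant). An
  isolated atom's area matches the closed-form sphere 4π(r+1.4)² to the
  sampling resolution (< 1%); absolute residue areas agree with an
  independent implementation (biotite) within ~1%. Relative accessibility
  divides by theoretical tripeptide maxima (Tien et al. scale); since
  downstream use is threshold- and rank-based, any consistent reference
  would do. The buried criterion is RSA ≤ 0.05.
* **Secondary structure**: HELIX/SHEET records are authoritative when the
  file has them; otherwise a backbone-dihedral fallback assigns helix for
  φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] and strand for φ ∈ [−180°, −80°],
  ψ ∈ [80°, 180°] ∪ [−180°, −170°], requiring runs of ≥ 3 consecutive
  residues. This is a coarse stand-in for hydrogen-bond-based assignment
  (DSSP), adequate for the binary regular/irregular feature.
* **B-factor**: unweighted mean over the residue's atoms.

The feature table reports one row per distinct mutated residue; positions
outside the model get all-absent features, and the bookkeeping (44 mapped
residues, 7 unmapped substitutions for the bundled panel against any model
covering the predicted span) is part of the output.

## Permutation analysis

Groups partition the alleles (phenotype, optionally × construction). For
each group × feature, the observed mean is compared with the distribution
of means under random reassignment of alleles to groups with sizes
preserved; feature rows travel whole, preserving the covariance between the
five features. Two one-sided empirical p-values use the add-one correction
p = (1 + #{null ≥ observed})/(n_perm + 1), so the smallest attainable value
is 1/(n_perm + 1); ties count toward both tails (within 1e-12). The default
is 10,000 shuffles from a seeded NumPy PCG64 generator recorded in the
result; `exhaustive_test` enumerates all multiset permutations exactly
(bounded at 10⁶ assignments) and serves as the oracle for the Monte-Carlo
version. No multiplicity correction is applied by default; a Bonferroni
factor over the group × feature grid can be applied by the caller.

Calibration (tested): null p-values are uniform (KS < 0.1 over 500
repetitions), and a 1.5-SD shift planted in a group of 10 among 50 alleles
is detected at *p* < 0.01 in ≥ 80% (measured ~99%) of repetitions.

## ΔΔG threshold analysis

Alleles are scored as growing (category ≠ nonfunctional) or not; for a
cutoff *t*, percent correct counts growing alleles with ΔΔG < *t* plus
non-growing alleles with ΔΔG ≥ *t*, over alleles with predictions. "Below"
is strict and "above" inclusive; the convention rarely binds because the
0.5 kcal/mol grid is offset from the one-decimal ΔΔG values. Accuracy is
piecewise-constant with breakpoints only at observed ΔΔG values, so the
coarse grid finds the global maximum; argmax ties resolve to the smallest
threshold (the most inclusive impaired class). On the bundled panel the 51
scored alleles give a maximum of 82.4% at 3.5 kcal/mol, and 80.4% at
4.0 kcal/mol. The figure legend of the source counts 52 scored alleles
where the fixture's "n/a" accounting yields 51; the pipeline reports the
fixture-derived count rather than asserting either number.

## Synthetic data

* **Curves**: lagged logistic trajectories, OD(t) = K/(1 + ((K−N₀)/N₀)
  e^(−ρ(t−lag))) with ρ the exponential-phase log₁₀ slope × ln 10, sampled
  every 0.5 h for 84 h from N₀ = 0.01, K = 1.0, lag 4 h, additive Gaussian
  reader noise σ = 0.005 OD floored at 0, and an optional per-plate OD
  gain. The endpoint read is the noise-free final density without gain
  (resuspension recalibrates the well). The model choice matters only in
  that the trajectory traverses both density windows; no curve fitting
  happens downstream.
* **Panels**: alleles drawn with the real panel's category proportions
  (19:14:25), three replicate wells per allele and dose, reference wells on
  every plate. Sensitive alleles' true ratios decline monotonically with
  dose (defaults 0.8/0.7/0.45/0.35 across 400/4/2/1 ng/mL — the discrete
  design of the assay, not a parametric dose–response); benign ratios are 1
  at all doses; nonfunctional alleles emit flat curves. A truth ledger
  (categories, per-dose ratios, features, plate assignments) accompanies
  every panel so downstream estimates can be scored without hidden state.
  Per-plate rate multipliers can be planted to exercise plate
  normalization. Synthetic structural features are i.i.d. standard normal
  (binary for secondary structure) with an optional planted shift on the
  sensitive group.
* **Structures**: an ideal α-helix (1.5 Å rise, 100°/residue) with N, CA, C
  and a radially displaced dummy side-chain atom per residue, single-atom
  HEM/PLP HETATM groups at caller-specified coordinates (rejected within
  1 Å of the backbone), a HELIX record, and B-factors from a constant,
  sequence or callable profile. Coordinates are pre-rounded to PDB
  precision (1e-3 Å) so the written file re-reads losslessly. A separate
  generator builds poly-alanine backbones from fixed (φ, ψ) via NeRF
  internal-coordinate construction, written without HELIX records to
  exercise the dihedral fallback.

What the generators do **not** emulate: settling and evaporation kinetics,
edge-well effects, correlated (drift-like) reader noise, lag-time
heterogeneity between replicates, real protein geometry (side-chain
packing, β-sheets in context, oligomeric interfaces), and any relationship
between an allele's structural features and its growth behaviour beyond an
explicitly planted shift. Passing recovery tests therefore demonstrate the
pipeline's correctness under the stated noise model, not robustness to
every artifact of real plate data.

## Known limitations

* The bundled tables carry summary statistics, not replicate-level rates,
  so significance recomputation can only be validated on synthetic data.
* The dihedral secondary-structure fallback is coarser than hydrogen-bond
  based assignment near helix termini and in irregular strands.
* SASA rigid-body invariance is exact only for generic geometries; an atom
  whose neighbours are perfectly collinear falls back to an arbitrary
  lattice orientation.
* Windowed-slope precision at the default noise level limits single-ratio
  accuracy to ~5–6% median error with three replicates (see above);
  studies needing tighter ratios should raise the replicate count or lower
  the read noise.
* No EC50/dose–response modelling, no evaporation or edge-well correction,
  no homology modelling of residues outside the supplied structure, and no
  recomputation of the Rosetta ΔΔG predictions (they are inputs).
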