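# Methods

## Scope and model

The package covers the statistics around structure-based virtual
screening, not the docking itself. A docking run is represented only by
its output: a score per (template, compound) pair, lower = better
(docking-energy convention; a `--higher-is-better` flag negates scores
at ingest for rank-based engines). Benchmarking treats the compound set
as fixed and labeled — actives are known binders, decoys presumed
non-binders matched on physicochemical properties — and asks how early
each template's score ranking recovers the actives.

## Enrichment metrics

Ranking is ascending by score with ties broken by ligand id. A
deterministic lexicographic tie-break was chosen over midpoint-rank
averaging so that repeated runs and the ROC construction are exactly
reproducible; the Mann–Whitney equivalence of the trapezooidal AUC is
asserted on tie-free data, where the two conventions coincide.

The ROC curve is the staircase of cumulative active fraction (y) vs
cumulative decoy fraction (x), one vertex per compound plus the origin.

- **AUC** is the trapezoidal area, reported ×100. On a staircase this
  equals the pair-counting (Mann–Whitney) probability exactly.
- **LogAUC** integrates the true-positive fraction over
  u = log10(fpr) on [log10 λ, 0] with λ = 0.001. Vertices with fpr < λ
  are clipped up to λ: the first vertices of any curve sit at fpr = 0,
  which has no log image, and clipping turns them into a zero-width
  vertical segment at the left edge, so the trapezoid on the clipped
  vertices equals the exact staircase integral (verified against a
  ≥10^6-cell midpoint-rule oracle with breakpoint-aligned cells, which
  is exact for piecewise-constant integrands). The area is divided by
  −log10 λ = 3. The *adjusted* form subtracts the chance baseline
  0.145 — the published constant for λ = 0.001; the exact integral of
  the chance diagonal is (1 − λ)/(3 ln 10) ≈ 0.1446, and the package
  uses the analytic value whenever a non-standard λ is requested.
  Percent scaling happens only at the reporting boundary: the constant
  is subtracted on the fraction scale and the result multiplied by 100,
  giving the documented range [−14.5, 85.5] percent.
- **EF(χ)** counts actives in the top ⌈χ·N⌉ compounds; ceiling
  guarantees a non-empty slice for small N. EF(1) ≡ 1.

Percent-scale metrics everywhere follow the convention of the
enrichment literature (AUC 50% = chance, adjusted LogAUC 0% = chance).

## Template benchmarking

`evaluate_templates` computes the three metrics per template, their
mean ± SD across templates (sample SD, ddof = 1), and the Pearson
correlation between the per-template AUC and LogAUC vectors (reported as
null when either vector has zero variance). Selection maximizes LogAUC;
ties break by EF at the smallest evaluated χ, then AUC, then template
id. Two policies handle compounds a template failed to score: the
default ranks them behind every scored compound (never recovered — the
conservative choice, since a failed docking recovers nothing in
practice), the alternative drops them from that template's evaluation.
Per-template missing counts are always reported.

Hit triage applies the rule-of-five filter (MW ≤ 500, clogP ≤ 5,
HBD ≤ 5, HBA ≤ 10; donor/acceptor counts are the N+O-based rule-of-five
conventions), ranks survivors by score and truncates. Human inspection
notes are a flags file merged into the output: a flagged compound is
annotated, never deleted, because geometric plausibility judgments are
human decisions that the scoring function cannot capture — the package
records them rather than inventing a geometric score.

## Curation

Activity handling: a measured Ki is used as-is; a record with only an
IC50 gets Ki = IC50/2 (the standard Cheng–Prusoff-style convention for
competitive inhibition at S ≈ Km). Actives extraction keeps non-peptide
records with MW < 500 and effective Ki < 10 μM (strict inequalities).
The peptide flag is an input annotation only — peptide removal is a
curator's judgment, and automating it would be invented chemistry.

Ligand efficiency is −1.37·log10(Ki [M]) / HA. The Ki must be on the
molar scale for the −1.37 = RT·ln 10 (298 K) constant to give kcal/mol
per atom. HA is the heavy (non-hydrogen) atom count, the standard LE
convention; a `hetero_only` flag divides by the heteroatom count
instead for comparison with sources that use that reading.

Representative selection is a greedy pass over actives sorted by LE
descending (id tie-break): keep a compound iff its Tanimoto similarity
to every kept compound is ≤ 0.6 (exactly 0.6 keeps; strictly above
excludes). The kept set is asserted pairwise-diverse on every run.

Decoy matching re-implements the property-matched decoy idea in
simplified form: descriptor windows around each active
(±25 Da MW, ±1 clogP, ±1 HBA, ±1 HBD, ±2 rotatable bonds, exact formal
charge) plus a Tanimoto cap of 0.35, 50 decoys per active, most
dissimilar first. The windows are in the spirit of the DUD-E protocol;
50 per active approximates the ~56:1 decoy:active ratio typical of such
benchmarks. All knobs live in `DecoySpec` and are recorded in outputs.
This is not a reproduction of the DUD-E server algorithm.

Fingerprints are Morgan (circular), radius 2, 2048 bits — the community
defaults; the underlying publications for specific Tanimoto values
rarely state these parameters, so both are recorded in every report and
configurable. Tanimoto is |A∩B|/|A∪B| on the bit sets, with the
degenerate empty∩empty case defined as 0 (no-overlap semantics). All
structures are canonicalized (RDKit) at ingest so similarity never
depends on SMILES writing order.

## Synthetic data

`gen_score_matrix` emulates a template × compound score table: decoys ~
Normal(μ_d, σ), actives ~ Normal(μ_d − δ_t σ, σ) with a per-template
effect size δ_t. Defaults (96 actives, 5398 decoys, μ_d = −20, σ = 5)
mirror the proportions of a realistic thrombin benchmark grid. The
Gaussian choice gives the closed form AUC = Φ(δ/√2), which the suite
checks at δ = 0.74 (AUC ≈ 70%, a typical per-template value) over 100
seeds; a Student-t option provides heavier tails for robustness checks.
Ground truth (seed, separations, planted ordering) is emitted as a
sidecar JSON so pipeline code cannot accidentally read it.

`gen_ligand_library` draws unique structures from a two-slot scaffold
grammar (benzene, pyridine, thiophene, cyclohexane, piperidine and
naphthalene cores × 19 substituents; ~1800 unique canonical SMILES).
Regular records are rule-of-five compliant by construction; a requested
fraction of records instead carries a long alkyl chain that guarantees
rule-of-five failure, and another fraction is peptide-flagged, so
filter tests see exact counts rather than binomial ones. Activities are
log-uniform Ki on [10⁻³, 10] μM (the potency span of a typical curated
actives set), with a fraction annotated as IC50 = 2·Ki to exercise the
conversion path. What the generator does **not** emulate: realistic
docking-energy distributions (real score tails are heavier and
correlated across templates), real medicinal-chemistry scaffold
diversity, assay noise, or activity cliffs — so green tests demonstrate
the correctness of the statistics and protocol logic, not performance
on any real screening deck.

## Validation design

Every metric has an independent oracle: exhaustive pair counting for
AUC, breakpoint-aligned midpoint integration for LogAUC, top-slice
recount for EF, and brute-force re-simulation (on RDKit bit vectors,
separate from the package's set-based Tanimoto) for representative
selection and decoy matching. Planted-structure recovery uses the full
benchmark proportions: one template at δ = 1.5σ against 19 null
templates is recovered by LogAUC selection in ≥95 of 100 seeds, with
recovery non-decreasing in δ. The rank-correlation check of 20
linearly-spaced separations uses 1000 actives / 4000 decoys: the larger
compound set keeps per-template LogAUC noise (SD ≈ 2–3 points at 96
actives) below the ~8-point spacing of adjacent templates, giving the
monotone-recovery property adequate power.

## Limitations

- Enrichment metrics quantify ranking power against *presumed*
  non-binders; latent actives among decoys bias all three metrics
  downward.
- The missing-score policy matters when docking failure rates differ
  across templates; both policies are exposed because the right choice
  depends on why dockings fail.
- Tanimoto values depend on fingerprint parameters; comparisons across
  reports are only valid at matching (radius, nbits).
- The LogAUC chance constant 0.145 is the published rounding of 0.1446;
  at the default λ the adjusted metric is therefore offset by ~0.04
  points from the exact-integral convention.
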