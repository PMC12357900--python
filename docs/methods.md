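# Methods

## The signalling model

The network is a deliberately reduced two-pathway NF-κB model with 16
species (time in minutes, concentrations in arbitrary units):

* **Dimers.** RelA:p50 (`A`) and cRel:p50 (`C`) shuttle between cytoplasm
  and nucleus when free (`k_in = 0.01`, `k_out = 0.05` per dimer) and are
  synthesised at constant rates; every dimer-containing species degrades at
  the dimer's turnover rate, so each total pool relaxes to
  k_syn/k_deg (= 100 a.u. for A and C).  RelB is synthesised directly into a
  p100-sequestered pool (`RelB_p100`); NIK-dependent processing converts it
  to active nuclear RelB:p52 (`B_nuc`, half-life ≈ 2.3 h).  p50/p52 monomers
  are treated as non-limiting and IκBβ is omitted — neither has a mechanistic
  role in the crosstalk being modelled.
* **Inhibitors.** IκBα, IκBε and p100 (whose multimeric IκBδ activity is
  represented by the p100 pool directly) bind free cytoplasmic dimers by
  mass action.  Affinity orderings are structural constraints:
  IκBδ binds cRel:p50 more tightly than RelA:p50, IκBα binds RelA:p50 more
  tightly than cRel:p50, and (a calibration choice) IκBε is the dominant
  constitutive cRel inhibitor.  All three are induced by nuclear RelA via a
  shared Hill term (h = 4, K = 6 a.u.) on top of constitutive synthesis.
* **Canonical input.** IKK activity equals the basal activation fraction
  b ∈ [0, 0.005] (the 0–0.5 % sweep; 0.05 % = "low"/RIVA-like, 0.5 % =
  "high"/SUDHL8-like) plus an optional BCR pulse, scaled by a BTK-inhibitor
  occupancy factor.  IKK degrades free and bound IκBα/IκBε, releasing the
  bound dimer.
* **Non-canonical input.** NIK turns over quickly (t½ ≈ 69 min); CD40
  ligation multiplies its degradation rate by 1/(1 + t/600), t in minutes
  since onset — by 24 h NIK has accumulated ≈ 3-fold.  NIK processes free
  p100 (removing IκBδ activity), IκBδ-bound dimers (releasing them) and
  RelB:p100 (activating RelB:p52), all at `k_proc·NIK`, scaled by a
  NIK-inhibitor occupancy factor.

The crosstalk emerges, rather than being wired in: at low b, cRel is held
by IκBα/IκBε and p100 is scarce, so CD40 releases almost nothing; at high b,
IKK strips IκBα/IκBε while RelA-driven p100 synthesis builds a large IκBδ
pool that captures cRel, and CD40-stabilised NIK then releases it.

### Time units

The NIK-stabilisation law 1/(1 + (t/600)) is interpreted with t in minutes:
600 min ≈ 10 h puts the half-effect inside the 24-h co-culture window,
which is the only reading under which a 24-h simulation shows meaningful
RelB induction.

### Parameter calibration

No rate measurements exist for this reduced network, so the canonical
parameter set (shipped as `data/canonical_params.yaml`, identical to the
dataclass defaults) was calibrated by manual search against six
machine-checkable constraints, evaluated by `validate_calibration`:

* C1 — nuclear RelA higher at b = 0.005 than at b = 0.0005;
* C2 — 24-h CD40 raises nuclear RelB:p52 > 2-fold at both basal levels;
* C3 — nuclear RelA changes ≤ ±20 % under CD40;
* C4 — nuclear cRel rises ≥ 1.5-fold under CD40 at high basal only
  (< 1.1-fold at low basal);
* C5 — IκBα+IκBε hold ≤ 14 % of the inhibitor-bound cRel pool at the
  high-basal steady state;
* C6 — the binding-affinity orderings above.

The qualitative claims are the constraint surface; individual rate values
have no measurement-level meaning.  The search proceeded by (i) setting pool
sizes and turnover times to biologically sensible scales (dimer totals
100 a.u., protein half-lives hours, NIK ~1 h), (ii) making inhibitor supply
comfortably exceed dimer demand at low basal (so NF-κB is mostly
sequestered at rest), and (iii) adjusting the p100 induction gain, the
IκBδ turnover and the Hill steepness until C4's two-sided requirement held
with margin.  Two further qualitative behaviours were imposed during
calibration: the IκBε knock-out must free cRel more than RelA (which forces
IκBε to carry most of the resting cRel inhibition), and BTK inhibition
during CD40 co-culture must blunt MCL1 induction (see below).

### Genotypes

`IkBe_KO` zeroes both IκBε synthesis terms.  `IkBa_kBkB` models a κB-site
promoter mutant: it scales only the RelA-inducible IκBα synthesis term
(default ×0.5), leaving constitutive synthesis intact — that is what a
κB-enhancer mutation does, and scaling the constitutive term as well would
produce a strong RelA-selective phenotype that contradicts the intended
"non-selective" control behaviour.  Genotype ensembles reuse the same
jittered virtual population under each genotype so fold changes isolate the
genotype effect from sampling noise; the fold-change denominator is the
wild-type ensemble mean (the populations are conceptually unpaired).

### Virtual-cell ensembles

Cell-to-cell variability is multiplicative log-normal jitter (median 1,
log-sd = cv, default 0.15) on all synthesis and degradation rates — the
expression-level parameters — never on binding affinities or transport,
which are treated as shared biophysics.  Default ensemble size is 25.
Everything is reproducible bitwise from a seed.

## BCL2-family induction and the viability surrogate

Each protein follows dX/dt = basal + Σ_d w·Hill(dimer_nuc) − X·ln2/t½
integrated along the trajectory with an exact exponential step per grid
interval.  Weights encode the TSS-binding logic: RelB:p52 dominates BCLXL
(with small promiscuous RelA/cRel weights), cRel:p50 dominates MCL1 with a
smaller RelA weight (RelA also binds the MCL1 TSS; this term is what makes
BTK inhibition blunt MCL1 induction, since canonical shutdown collapses
nuclear RelA within the 24-h window while the released-cRel transient is
still decaying), and BCL2 is constitutive.

Viability is a minimal sequestration-capacity surrogate, not an apoptosis
model: effective capacity E(d) = Σ_X dep_X·abundance_X/(1 + d_X/Ki_X), and
viability = Φ((ln E − ln T_med)/σ) for a log-normal cell-threshold
distribution (T_med = 1, σ = 0.35).  It guarantees monotone dose response,
compensation by non-targeted proteins, and sensible combination behaviour —
nothing more.  Only LC50 *orderings* between conditions are meaningful.
Cell-line basal profiles place the dependence where the lines' known
sensitivities are (RIVA/U2932 BCL2-dependent, SUDHL8 BCLXL-dependent).

LC50 is the inflection dose of a 4PL fitted by least squares on log-dose
with multi-start initialisation and box bounds; a response range < 1e-3 is
flagged degenerate (no LC50), and an LC50 outside the fitted dose span is
flagged extrapolated.

## Quantification procedures

* **MFI.** Median of stained over median of matched unstained control;
  fold changes are ratios of identically normalised medians.
* **Fingerprints.** Per-cell z-scores of log10 intensities against a pooled
  reference (flow intensities are log-distributed; the z-scale makes
  fingerprints invariant to common gain changes), Gaussian KDE (Scott's
  rule) on a 200×200 grid over z ∈ [−4, 4], renormalised to unit mass on
  the grid; contour levels are density quantiles; per-sample median dots
  overlaid.
* **TSS windows.** 0-based half-open peak intervals; "within 1 kb" means
  overlap with [position − 1000, position + 1000] (closed, i.e. half-open
  against position + 1001), strand-ignored.
* **ROUT.** Constant-model robust fit (IRLS with bisquare weights seeded at
  the median), scale = RSDR (68.27th percentile of absolute residuals with
  an n/(n−K) correction), two-tailed t-tail p-values, removal from the most
  extreme point inward by a Benjamini–Hochberg-style threshold at rate q
  (default 1 %), capped at 30 % of the data.  The originators' exact
  numerics are proprietary, so correctness is established by property —
  ≥ 6-SD planted contaminants are removed with probability ≥ 0.99, and the
  mean removed fraction on clean Gaussian data stays below 2q — not by
  bit-match.

## Synthetic data

Generators emulate: stained/unstained flow pairs (log-normal mixtures over
an autofluorescence floor, supporting biclonal CD20-high/low populations),
4PL viability assays (default reference curve: top 1.0, bottom 0.05,
hill 2 — BH3-mimetic kill curves are steep — LC50 0.5 on a 9-dose
1e-4–100 grid with 3 replicates and N(0, 0.05) noise clipped to [0, 1.05]),
per-cell N:C ratio tables with planted co-culture shifts, and ChIP peak
sets with exact in/out-of-window counts and optional planted score
outliers.  Every generator returns a machine-readable ground-truth sidecar;
estimator tests read truth only from sidecars.  What the generators do
*not* emulate: spillover/compensation, instrument saturation, doublets,
batch effects, peak-calling artefacts — a green estimator test certifies the
estimator on the stated distributions, not robustness to those.

## Numerics

Integration uses LSODA at rtol = atol = 1e-8 with ≥ 97 evenly spaced output
points; the first output state is the exact initial state.  Steady states
are found by 20 000-min integration plus a Newton polish, accepted only if
max|dy/dt| < 1e-10·max(y), and verified stable (< 1e-6 relative drift over
a further unstimulated 24 h).  A fixed-step RK4 oracle (dt = 0.01 min)
cross-checks the adaptive solution to < 1e-5 relative; the oracle window in
the test suite is 120 min under CD40 (all stiff terms active) to keep the
pure-Python oracle inside the time budget.  In closed test mode (all
synthesis and degradation zeroed) each Rel-monomer total is conserved to
machine precision.  Species are clamped at zero on output only.  Degenerate
inputs: an empty inhibitor-bound pool reports flagged zero fractions rather
than NaNs; a flat dose response reports a degenerate fit rather than an
arbitrary LC50.

## Known limitations

* Rate constants are calibration artifacts; only the constraint surface
  C1–C6 and the tested orderings are claims.
* The viability surrogate has no mitochondrial dynamics, no BH3-only
  profiling, no Bax/Bak; absolute LC50 values are not in assay units.
* The IKK cascade is collapsed into the basal fraction b; receptor-level
  CD40 dynamics, PK/PD and drug transport are out of scope.
* Ensembles model extrinsic (expression) heterogeneity only — no intrinsic
  stochasticity, no spatial effects.
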