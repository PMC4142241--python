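# Methods

## Scope and model

`hdxpred` predicts backbone-amide hydrogen–deuterium exchange of protein
fragments from atomic coordinates. The central approximation is that an
amide's protection factor is a function of its instantaneous local
environment,

    ln P_i(X) = β_c N_i^c(X) + β_h N_i^h(X),

evaluated per conformation and averaged over an ensemble, combined with
EX2 kinetics D_i(t) = 1 − exp(−(k_int,i/P_i) t) and an unweighted mean
over a fragment's amides. This presumes (i) exchange in the EX2 limit
(closing much faster than intrinsic chemistry — the regime test in
`exchange_kinetics.classify_regime` makes the assumption explicit),
(ii) that burial (heavy-atom contacts) and hydrogen bonding capture the
free-energy cost of opening, and (iii) that the supplied ensemble samples
the native-state fluctuations relevant on the experimental timescale.
Slow conformational changes absent from the ensemble (e.g. loop
remodelling, ring opening of an oligomer) appear as systematic
prediction/experiment discrepancies — which is informative rather than a
failure mode, and is what the closed/open ensemble machinery in
`fixtures` emulates.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| β_c | 0.35 | – | published best-prediction weight for heavy-atom contacts |
| β_h | 2.0 | – | published best-prediction weight for amide H-bonds |
| contact cutoff | 6.5 | Å | heavy atoms around the amide N; strict `<` |
| H-bond cutoff | 2.4 | Å | acceptor O around the amide H; strict `<` |
| contact exclusion | i−1, i, i+1 | – | removes a constant offset from covalently bonded atoms; configurable (incl. "i only") |
| acceptor policy | protein O only | – | water acceptors would spuriously protect exposed amides; `all_oxygen` available |
| pH | 7.9 | – | electrode reading used verbatim; `pD_correction` adds +0.4 if desired |
| temperature | 298 | K | Arrhenius scaling per catalysis channel from the 293 K reference |
| reassignment tolerance | 50 | ppm | typical peptide-mass accuracy for the instrument class |
| SASA probe / points | 1.4 Å / 960 | – | water probe; quadrature error ≪ 1% (see below) |

Intrinsic rates use the vendored poly-DL-alanine calibration
(`src/hdxpred/data/bai1993_rates.json`): decadic neighbour factors for
acid/base/water catalysis ("own" λ and "predecessor" ρ per side chain,
water sharing the base factors), reference rates log10 kA = 1.62,
log10 kB = 10.05, log10 kW = −1.5 (per minute, 293 K), pK of D2O 15.05,
activation energies 14/17/19 kcal mol⁻¹. Asp/Glu/His factors are blended
between protonated and deprotonated forms with Henderson–Hasselbalch
populations at the working pD (side-chain pK 4.48/4.93/7.42); the
protonated N-terminal amine contributes ρ factors to residue 2 and the
deprotonated C-terminal carboxylate λ factors to the last amide (the
acidic COOH form is not modelled, a negligible approximation above
pH ≈ 5). The water-ion product is held at its reference value rather
than temperature-corrected; near-ambient temperatures make this a
second-order effect relative to the channel activation energies. Rates
are per minute internally, converted to s⁻¹ at the uptake layer.

## Numerical and design choices

* **Amide-hydrogen construction.** Crystal structures lack hydrogens;
  H is placed 1.01 Å from N along the external bisector of the
  C(i−1)–N–CA angle — in the peptide plane and trans to the preceding
  carbonyl — the standard sp2 rule. Existing hydrogens are never moved,
  so MD frames with explicit hydrogens pass through unchanged. Residues
  missing backbone context (chain start, after a numbering gap) carry no
  amide H and drop out of exchange sums, mirroring how unmodelled loop
  neighbours behave in real structures.
* **Counting.** KD-trees give the neighbour lists; both cutoffs are
  strict inequalities. Minimum-image distances are used when an
  orthorhombic box is present. Exactness against O(N²) double loops is
  enforced by test (100 random instances).
* **Ensemble averaging.** `mean_lnP` averages lnP (equivalently the
  β-weighted counts, by linearity) over frames and chains with the
  ensemble weights; `mean_D` averages per-(frame, chain) uptake curves.
  Both are first-class because they answer different questions: the
  former is the single-profile summary, the latter is sensitive to
  heterogeneity (Jensen's inequality makes `mean_D` ≥ D(mean lnP) while
  fractions remain below 1 − 1/e, the convex region of D in lnP).
* **Apparent rates.** Summarised by a single-exponential fit
  D(t) = A(1 − e^(−k_app t)), A ∈ (0,1], initialised deterministically
  from the half-rise time. This is the simplest reading of "apparent
  rate"; strongly biphasic kinetics is deliberately *not* modelled and
  is flagged via the residual norm instead.
* **Assignment.** Neutral monoisotopic peptide masses (residue masses
  from the standard proteomics tables plus water); exhaustive
  contiguous-subsequence scan via prefix sums, ranked by |ppm| error
  with ties broken by length then start. Windows with identical
  composition (anagrams, I/L swaps) are physically indistinguishable by
  mass and rank as ties.
* **SASA.** Shrake–Rupley with a deterministic golden-spiral point set
  (rotation of the molecule therefore changes results only within
  quadrature noise); Bondi van der Waals radii, heavy atoms only by
  default. Isolated-sphere and two-sphere cap closed forms agree within
  0.01% at 960 points.
* **RMSF.** Kabsch superposition of every frame onto the ensemble mean,
  with one mean-refinement pass; backbone heavy atoms by default
  (CA-only and all-heavy selections available); which atom set an
  experimentalist's B-factor comparison wants is context-dependent, so
  it is an argument, not a constant.
* **Altlocs** keep the highest-occupancy conformer (ties → first);
  non-standard (HETATM) amino acids are excluded with a warning;
  mmCIF, structure repair and protonation-state prediction are out of
  scope.

## The synthetic test systems

The `fixtures` module generates the study systems used by the tests and
the acceptance script: ideal α-helices (canonical dihedrals, giving
exactly one i→i−4 H-bond per interior amide under the 2.4 Å criterion),
fully extended chains (zero H-bonds), C6 ring oligomers of helices with
a controlled interface (ring radius 8 Å, chain separation equal to the
radius), Gaussian-jitter pseudo-trajectories (σ = 0.3 Å per coordinate,
20–25 frames — enough to randomise marginal contacts without unfolding
the backbone), a closed/open two-state mixture (open ring radius +6 to
+8 Å, exposing the interfaces), and planted-parameter uptake tables
(lnP uniform in [0.5, 7], k_int log-uniform in [10⁻³·⁵, 10⁻¹·⁵] s⁻¹,
the 10-point 30 s–4 h grid, Gaussian noise sd 0.02 truncated to [0,1]).
All generators are bit-reproducible from their seed.

These fixtures exercise the pipeline's mathematics — counting rules,
averaging conventions, kinetics, recovery of planted parameters — not
force-field realism: they contain no side chains (beyond optional CB
dummies), no solvent, no correlated dynamics. Passing tests therefore
demonstrates that the implementation computes the model correctly and
that the model behaves as designed on controlled inputs; they say
nothing about how well the phenomenological β-weights transfer to any
particular real protein, which is exactly what comparison against real
HDX-MS tables (module `compare`) is for. Problem sizes (≤ 500-atom
random frames, 12-residue hexamer rings, ≤ 25-frame ensembles, 100-fold
replicate loops) were chosen so the whole suite runs in seconds while
keeping every statistical check well-powered.

## Known limitations

* EX2 only: bimodal (EX1) isotopic envelopes and mixed-regime kinetics
  are out of scope; the two-state module classifies regimes but uptake
  always uses k_int/P.
* No back-exchange correction: predictions are for fully forward
  exchange; experimental tables are assumed already corrected.
* Hard distance cutoffs, no angular H-bond criterion, no smoothing.
* The optional crystal-structure validation against the P4 helicase
  hexamer requires the user to download the 4BLR PDB file; it is not
  bundled.
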