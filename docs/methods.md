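# Methods

## Interaction model

A fingerprint is computed per (receptor residue, ligand pose) pair as nine
boolean bits; ensemble averaging turns booleans into per-residue
frequencies in [0, 1]. The geometric criteria and their defaults:

| quantity | default | meaning |
|---|---|---|
| `contact_cutoff` | 4.5 Å | heavy-atom pair distance defining *any* contact and the hydrophobic C/S–C/S contact |
| `polar_max` | 3.8 Å | N/O–N/O pair distance for the polar bit |
| `hbond_da_max` | 3.5 Å | donor–acceptor distance for both H-bond bits |
| `hbond_angle_min` | 120° | minimum donor–H–acceptor angle, applied only when the donor's hydrogen is present |
| `aromatic_centroid_max` | 5.0 Å | ring-centroid distance for the aromatic (π) bit |
| `charged_max` | 4.0 Å | cation–anion distance for the charged bit |

These sit in the conventional ranges used for crystallographic contact
analysis. They are deliberate design choices, exposed in
`InteractionParams`, not fitted quantities: typical docking workflows
specify only "a cutoff range", and any specific ensemble statistic will
shift with them. All distances are between heavy atoms; hydrogens and
waters are carried through parsing but excluded from contact detection.

Conventions worth making explicit:

* **Direction of the H-bond bits.** `hbond_acceptor` means *the receptor
  atom accepts* from a ligand donor; `hbond_donor` means the receptor
  donates. Published fingerprint tables are not consistent about this
  orientation, so it is fixed here and documented.
* **Hydrogen-free structures.** Deposited receptor structures usually lack
  hydrogens, so for receptor donors the criterion is distance-only. Ligand
  files from docking typically keep polar hydrogens; when present, the
  angle test is applied on the ligand side.
* **Charged bit = salt bridge.** It requires opposite formal charges
  (cation against anion) within `charged_max`, not mere proximity of two
  charged residues. This keeps the bit rare and specific, matching how
  averaged fingerprint tables mark charged contacts only against
  oppositely charged sidechains.
* **Aromatic bit is distance-only.** No interplanar-angle filter: both
  stacked and T-shaped geometries count. An angle criterion is specified
  for hydrogen bonds only.
* **Bit hierarchy.** `any` is true whenever any other bit is true, and in
  every average frequency(any) ≥ frequency(b). The container classes
  enforce this as an invariant; a rounded published table can appear to
  violate it, an exactly computed one cannot.
* **Sparsity.** Residues with all-zero rows are omitted from fingerprints
  and averages; absence means "no interaction".

Receptor atom typing is table-driven (backbone N donor / backbone O
acceptor for every residue; canonical sidechain donors, acceptors, charge
centres; Phe/Tyr/His rings and both Trp rings with centroid and
best-fit-plane normal). Ligand typing is necessarily heuristic, from a
covalent-radius bond graph: O is an acceptor (donor when protonated,
anionic in a carboxylate), N donates when protonated and accepts when
bare with ≤2 heavy neighbours, rings of size 5–6 that are all C/N/O/S and
planar within 0.15 Å count as aromatic. A pose carrying no hydrogens at
all falls back to treating every N/O as donor+acceptor.

## Pose clustering and comparison

In-place heavy-atom RMSD (no superposition — docked poses share the
receptor frame) feeds greedy leader clustering: scan poses in file order,
join the first cluster whose representative is within the cutoff (default
1.0 Å), else found a new one. The algorithm is order-dependent by design;
it reproduces the convention of docking packages and is deterministic for
a fixed pose order. Fingerprints are compared with Tanimoto similarity
over set (residue, bit) pairs, defined as 1.0 for two empty fingerprints.

## Kinetics

The Hill model v = Vmax·S^h/(Km^h + S^h) is fitted by unweighted nonlinear
least squares in (log Vmax, log Km, log h), which enforces positivity
without constrained optimization. Initialisation: Vmax₀ = max observed
velocity, Km₀ = the concentration whose velocity is nearest Vmax₀/2,
h₀ = 1; Levenberg–Marquardt with tight (1e-12) tolerances, capped at 500
iterations per parameter. Standard errors come from the Jacobian at the
optimum — cov = (JᵀJ)⁻¹·RSS/(n−p) on the log scale, mapped to the natural
scale by the delta method (SE(x) = x·SE(log x)); the SE of kcat/Km uses
the full covariance of log Vmax and log Km. Replicates are fitted pooled,
not averaged, so replicate scatter propagates into the standard errors.

Degenerate data (velocity range indistinguishable from zero) short-circuit
to `converged=False` with no standard errors rather than returning a
silently meaningless optimum. `fix_h=1` reduces the model to
Michaelis–Menten exactly.

kcat = Vmax/[E]₀ requires the enzyme concentration as an explicit user
input — assay tables do not carry it, and no default could be right.
Synthetic tests set [E]₀ = 1 µM so Vmax equals kcat numerically.

The Hill coefficient is reported but, for the protease data this package
models, the interesting constants are kcat and Km; h hovers at 1 for
non-cooperative substrates.

### Accounting tables

Relative activity divides each condition by a designated reference
(defined as 100%); "ND" entries (enzyme precipitated, not measurable)
propagate as missing rather than zero. Purification tables derive
specific activity = total activity / total protein per step, yield %
against a designated reference step, and fold purification against a
baseline specific activity. The fold baseline may be given as an explicit
number rather than a step label: the true starting material (a crude
extract) often cannot be assayed directly, and published fold columns are
computed against a rounded printed baseline — an explicit numeric baseline
lets the table reproduce such accounting exactly.

## Sequence identity

Global alignment uses Biopython's `PairwiseAligner` with BLOSUM62, gap
open 10, gap extension 0.5 — standard protein-alignment defaults, chosen
because homolog-comparison figures rarely state their tool or parameters.
Identity is 100 × matches / aligned columns by default; a
shorter-sequence denominator is available since terminal gaps otherwise
dilute identity between sequences of unequal length. Ties among
co-optimal alignments resolve to the aligner's first enumerated alignment,
which is deterministic. Identity between closely related proteases
(~90%) is robust to these choices to within a percentage point or two;
that tolerance is kept in mind wherever identity is asserted.

## Synthetic data: what it does and does not emulate

`make_complex` places one pseudo-residue per planted interaction on a
sparse grid (spacing ≥ 15 Å, default 20 Å) so that nothing but the planted
geometry can register — each bit is isolated for unit testing. Residue
templates carry the minimal atoms their roles require (Tyr = backbone +
ring + OH; Lys = backbone + CB + NZ; …), not rotamer libraries. The
interacting ligand fragment (single C, hydroxyl, carbonyl, carboxylate,
ammonium, or benzene ring) is placed so the stated interaction distance is
realized *exactly*, pointing away from the rest of the residue to avoid
incidental contacts. Violating geometries default to just beyond the
relevant cutoff (e.g. an H-bond planted at 3.9 Å against the 3.5 Å
criterion).

`sample_ensemble` switches each planted fragment between its exact
geometry and a 40 Å-displaced position, per pose: independently with
probability f (Bernoulli mode), or in exactly round(f·n) poses chosen by
a seeded shuffle (`exact=True`) when an integer count is the point of the
fixture. All randomness flows through one `numpy` generator seeded from
the spec; identical seeds give identical ensembles.

`simulate_kinetics` draws v = v(S)·(1+ε), ε ~ N(0, CV²) truncated at
−0.99, over a default grid of 10 log-spaced concentrations spanning
0.5–400 µM with 3 replicates and CV = 3% — the operating conditions of a
fluorogenic protease saturation assay.

What passing tests on these fixtures demonstrate: the geometric criteria
fire exactly when their conditions hold, frequencies average correctly,
files round-trip through the real PDB/PDBQT readers, and the fitter
recovers generating parameters under realistic noise. What they do not
demonstrate: realism of docking ensembles (no pose-energy weighting, no
correlated pose geometry, no solvent), correctness of ligand typing on
arbitrary drug-like chemistry, or behaviour on disordered/altloc-laden
crystal structures.

## Problem sizes used in the test suite

Planted-frequency recovery runs at n = 1000 poses per frequency point
with a 99% binomial acceptance interval; the frequency fixture mirroring a
29-pose ensemble with 12 hydrogen-bonding poses uses exact counts; Km
recovery statistics aggregate 200 independent simulated datasets (30
points each). These sizes give stable statistics while keeping the whole
suite in the seconds range.

## Known limitations

* No structure repair, protonation, or symmetry expansion: oligomeric
  binding sites spanning protomer interfaces must be provided as
  pre-expanded multi-chain files, and residues are keyed by chain +
  author number only (composite renumbering schemes across protomers are
  the user's mapping to make).
* No water-mediated, halogen-bond, or cation–π bits.
* Ligand role perception is a bond-graph heuristic, not a full
  perception stack; exotic functional groups may type incorrectly.
* The RMSD is in-place by convention; it is not meaningful for poses in
  different receptor frames.
* PDB only (no mmCIF); PDBQT reading covers the AutoDock4 multi-MODEL
  dialect.
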